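# popphylo

Population phylogenies from genome-wide SNPs, straight from a multi-sample
VCF file.

Whole-genome resequencing projects routinely deliver genotype calls for a
cohort of individuals as a single multi-sample VCF. Turning that file into a
picture of how the individuals (or the populations they represent) relate to
one another usually means converting to alignments or allele-frequency
tables for a conventional phylogenetics package. `popphylo` skips the
conversion: it streams the VCF directly — plain text or gzipped, millions of
records, constant memory — computes pairwise distances between the diploid
genomes, and builds UPGMA or neighbour-joining trees, with exports in
Newick, MEGA and PHYLIP formats. It is aimed at population geneticists who
want a distance tree of *individuals within and between populations*, not a
species phylogeny.

## The distances

At each biallelic SNP, with genotypes written as reference/alternate allele
pairs (`0/0`, `0/1`, `1/1`), two per-site measures between genomes *X* and
*Y* are defined:

* **Genetic distance** — all four cross-genome allele comparisons are made
  and their mismatch indicators averaged:
  d_site = (𝟙[x₁≠y₁] + 𝟙[x₁≠y₂] + 𝟙[x₂≠y₁] + 𝟙[x₂≠y₂]) / 4.
  Two heterozygotes (`0/1` vs `0/1`) are at distance 2/4 = **0.5**.
* **Drift distance** — only the dissimilarity of alternate-allele
  frequencies counts: d_site = |f_X − f_Y| with f = dosage/2.
  Two heterozygotes are at distance **0** — the allele frequencies agree, so
  the measure reflects frequency change (drift) rather than heterozygosity.

Per-site values are summed over all usable SNPs into a pairwise matrix of
raw differences (exact, since every value is a multiple of ¼). Sites that
are indels, multi-allelic, below the QUAL threshold, or missing (`./.`,
including calls demoted by the per-sample DP threshold) are excluded and
counted. Missing data is handled either with complete sites only (SNPs
called in every genome) or pair-by-pair.

Given a total genome length *L*, raw sums convert to **p-distances**
p = diffs / L_eff, where the effective length L_eff subtracts the excluded
missing, filtered and multi-allelic sites from *L*, and optionally to
**Jukes–Cantor distances** d = −(3/4)·ln(1 − (4/3)p), which correct for
multiple substitutions at a site.

Trees come from the distance matrix via **UPGMA** (size-weighted average
linkage; rooted, ultrametric, assumes a molecular clock) or classical
**neighbour joining** (Saitou–Nei; unrooted, written with a trifurcating
root; recovers additive matrices exactly). Tree building requires at least
four genomes.

## Worked example

```sh
$ python examples/build_tree_from_vcf.py
samples: S1, S6, S3, S7, S4, S8, S2, S5
usable biallelic SNPs: 178 of 200 records (12 indels, 10 multi-allelic skipped)
raw differences between first two samples (S1, S6): 28.5
((((S1:10.875000,(S3:8.750000,S7:8.750000):2.125000):2.125000,S6:13.000000):2.062500,S4:15.062500):5.187500,(S8:19.875000,(S2:18.000000,S5:18.000000):1.875000):0.375000);
```

The synthetic cohort has 8 diploid genomes at 200 variant records; 22
records are rejected by the biallelic-SNP filter. The 28.5 is the summed
per-site genetic distance between S1 and S6 over the usable sites, and the
Newick tree is the UPGMA clustering of the full pairwise matrix — branch
lengths are on the same summed-differences scale, so leaves joining at low
heights are close relatives. The other scripts in `examples/` show the
p/Jukes–Cantor scales, exact tree recovery from additive matrices, and
MEGA/PHYLIP export.

The same run from the shell:

```sh
popphylo --vcf cohort.vcf --metric genetic --algorithm upgma --newick tree.nwk
popphylo --vcf cohort.vcf.gz --min-qual 30 --min-depth 10 \
         --scale jc --genome-length 3000000 --mega out.meg --phylip out.dist
```

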