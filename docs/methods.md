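# Methods

## Model and procedure

`popphylo` treats each sample in a multi-sample VCF as a diploid genome and
summarises divergence between genomes by summing per-site distances over
biallelic SNPs. All computation is a single streaming pass: records are
parsed line by line, classified, and folded into a pairwise accumulator, so
memory use depends on the number of samples but not the number of records.
Every derived product (distance scales, trees, exports) is computed from the
in-memory accumulator without re-reading the file.

### Site filters

A record is usable when REF and the single ALT are one base each. Indels
(any allele longer than one base), multi-allelic records (more than one
ALT), and symbolic or missing ALT alleles (`*`, `<DEL>`, `.`) are skipped.
Two user thresholds apply, both inclusive lower bounds:

* `min_qual` (Phred, default 0) is compared to the site QUAL column and
  drops the whole record — QUAL is a site-level statement about the variant
  call. An absent QUAL (`.`) passes: absence of evidence is not treated as
  failure, matching the default behaviour of considering all SNPs when no
  threshold is entered.
* `min_depth` (reads, default 0) is compared to each sample's FORMAT/DP and
  demotes only that sample's call to missing — DP is per-sample evidence.
  Absent DP likewise passes.

Half-missing genotypes (`./1`) are treated as wholly missing, since the
four-comparison distance needs two full diploid calls; haploid or polyploid
GT fields are format errors rather than silently coerced. The FILTER column
is ignored.

### Per-site distances

For non-missing diploid calls (x₁,x₂) and (y₁,y₂):

* genetic: (𝟙[x₁≠y₁] + 𝟙[x₁≠y₂] + 𝟙[x₂≠y₁] + 𝟙[x₂≠y₂]) / 4
* drift: |f_X − f_Y|, f = (alternate-allele dosage)/2

The drift definition is the minimal function consistent with "dissimilarity
of allele frequencies" and the anchor value 0 for a heterozygote pair. With
binary alleles both measures take values in {0, ½, 1} and drift ≤ genetic
site by site (a frequency difference requires at least that many mismatched
comparisons).

### Accumulation and missing-data policies

Under the **complete-sites** policy a usable SNP contributes to every pair
only if all genomes are called; under the **pairwise** policy it
contributes to pair (i,j) whenever both i and j are called, and each pair
skipped at a site increments that pair's exclusion counter. The paper-style
alternative reading of pairwise use — keeping a site when only *one* of the
two genomes is called — is not implementable: the four-comparison formula
needs two called genotypes, so both-called is required.

Exclusion bookkeeping per usable-but-affected site: a site with at least
one depth-demoted call counts once as *filtered*; otherwise a site with at
least one `./.` counts once as *missing*; skipped low-QUAL records also
count as filtered and multi-allelic records as multi-allelic. Indel records
are not subtracted from the genome length (they are not SNP sites lost to
filtering but a different variant class); this is a deliberate choice where
the accounting could be argued either way. One known overlap: under the
pairwise policy, a site with a demotion in one genome is globally counted
as filtered *and* pair-skipped for pairs involving that genome, so the
effective length can subtract it twice for those pairs. The effect is a
conservative (slightly short) denominator in rare configurations; the raw
sums are unaffected.

Every per-site value is a multiple of ¼, so the accumulator sums int64
quarter-counts (internally via blocked integer matrix products over chunks
of 4096 sites). Raw matrices are therefore exact and bit-identical under
any record ordering; no floating-point summation order enters until the
p/JC division.

### Distance scales

* raw: summed differences.
* p: raw / L_eff, with L_eff = genome_length − missing − filtered −
  multi-allelic exclusions (global under complete-sites, per-pair under
  pairwise). L_eff ≤ 0 is a configuration error.
* Jukes–Cantor: −(3/4)·ln(1 − (4/3)p), defined for 0 ≤ p < 3/4; p at or
  beyond saturation raises a domain error rather than clamping.

### Trees

UPGMA joins the closest pair at height d/2 with size-weighted average
linkage (true group-average UPGMA, not the simple midpoint of the two old
distances); branch length = parent height − child height; the output is
ultrametric to floating-point precision. Neighbour joining is the classical
Saitou–Nei iteration on Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ with the standard
branch-length formulas, terminating in a trifurcating root; negative branch
lengths are emitted as computed, because clamping belongs to later
variants. Tie-breaking in both algorithms is deterministic: the candidate
pair with the smallest first index, then smallest second index, in the
current cluster ordering wins, and the merged cluster takes the first
index's position. Both algorithms require ≥ 4 genomes; distance matrices
for 2–3 genomes remain computable and exportable.

Newick output lists children in construction order, branch lengths in
fixed-point with a configurable number of decimals (default 6), and quotes
labels containing reserved characters.

## Synthetic data generator

`simdata` plants a random binary tree and evolves two binary haplotypes per
genome down it, flipping each site on each branch with probability equal to
the branch length (a two-state symmetric model matching the VCF 0/1 allele
coding — expected distances stay exactly computable, which is the point).
Contaminant records (indels as `AT→A`, multi-allelic as `A→T,G`), missing
calls, uniform QUAL and uniform integer DP values are injected from
separate PCG64 streams spawned from one SeedSequence, so changing a
contaminant rate never changes the genotype draws and a fixed seed
reproduces the file byte for byte (gzip output zeroes the header timestamp
and filename).

Defaults — the generator's study conditions — are a small resequencing
cohort: 8 genomes, 200 sites, branch lengths U(0.02, 0.2)
substitutions/site, 5% missing calls, 5% indel and 5% multi-allelic
records, QUAL U(10, 60), DP uniform on 5–40. The sidecar of expected
answers (per-pair difference sums, used-site counts, every exclusion
tally, for both metrics × both policies) is computed directly from the
simulation arrays under the thresholds stored in the spec.

What the generator does **not** emulate: linkage and recombination,
realistic site-frequency spectra (no coalescent), sequencing-error
structure in QUAL/DP (they are independent uniforms), more than one
alternate nucleotide identity, or population structure beyond the planted
tree. Passing tests therefore certify the *bookkeeping and algorithms* —
that the pipeline computes exactly the defined quantities and recovers
planted trees from exact matrices — not that the distances are well-suited
estimators for any particular demographic history.

## Numerical choices and limitations

* Distance sums: exact integer quarter-counts; p/JC values are double
  precision thereafter.
* Matrix validation: symmetry and zero diagonal to 1e-9 relative / 1e-12
  absolute; negative input entries are rejected for tree building.
* Ultrametricity and additive-recovery test tolerances: 1e-9 relative.
* Problem sizes used in the test suite: oracle-equivalence fixtures up to
  10 genomes × 200 sites across 20 seeds; tree-recovery sweeps over 100
  additive matrices (4–12 taxa); a streaming check at 1 million SNPs × 10
  genomes, chosen as a size that exercises constant-memory streaming while
  keeping the suite quick to run.
* The tool builds trees of individual genomes within populations; it is not
  intended for species-level phylogenetics, where alignment-based
  substitution models are more appropriate.
* BCF, tabix-indexed access, phasing, FST-style statistics and bootstrap
  support are out of scope.
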