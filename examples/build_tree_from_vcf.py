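"""Build a population tree from a multi-sample VCF, end to end.

Generates a small synthetic cohort (8 diploid genomes, 200 SNP records with
some indel/multi-allelic/missing contamination), streams it through the
reader and pairwise accumulator, and prints the UPGMA tree in Newick form.
"""
import tempfile
from pathlib import Path

from popphylo import (
    MetricKind,
    MissingPolicy,
    VcfReader,
    accumulate,
    raw_matrix,
    to_newick,
    upgma,
)
from popphylo.simdata import SimSpec, generate_vcf

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "cohort.vcf"
    generate_vcf(SimSpec(seed=7), path=vcf, with_expected=False)

    reader = VcfReader(vcf)
    acc = accumulate(reader, reader.samples, MetricKind.GENETIC,
                     MissingPolicy.COMPLETE_SITES)

print(f"samples: {', '.join(acc.samples)}")
print(f"usable biallelic SNPs: {acc.n_usable} of {acc.n_records} records "
      f"({acc.n_indel} indels, {acc.n_multiallelic} multi-allelic skipped)")
matrix = raw_matrix(acc)
print("raw differences between first two samples "
      f"({matrix.samples[0]}, {matrix.samples[1]}): {matrix.values[0, 1]}")
print(to_newick(upgma(matrix)))
print("The Newick branch lengths are summed per-site differences; "
      "closely related genomes join at low heights.")
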