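"""Pairwise genetic and drift distances between diploid genomes.

Two per-site measures are defined between two diploid genotype calls at a
biallelic SNP:

* **genetic distance** — all four cross-genome allele comparisons are made
  and their mismatch indicators averaged, so two heterozygotes (0/1 vs 0/1)
  are at distance 2/4 = 0.5;
* **drift distance** — only the dissimilarity of alternate-allele
  frequencies |f1 - f2| is scored (f = dosage/2), so two heterozygotes are
  at distance 0.

Per-site values are summed over all usable sites into a pairwise matrix of
raw differences.  Given a total genome length the raw sums convert to
proportions (p-distance) over an *effective* length — the genome length
minus the sites excluded as missing, filtered or multi-allelic — and
optionally to Jukes–Cantor corrected distances d = -(3/4)·ln(1 - (4/3)p).

Every per-site value is a multiple of 1/4, so the accumulator sums integer
quarter-counts: raw matrices are exact and independent of record order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, DomainError, ValidationError
from .vcf_io import GenotypeCall, RecordCategory, VcfRecord

__all__ = [
    "MetricKind",
    "MissingPolicy",
    "DistanceScale",
    "DistanceMatrix",
    "PairwiseAccumulator",
    "site_genetic_distance",
    "site_drift_distance",
    "accumulate",
    "raw_matrix",
    "effective_length",
    "p_matrix",
    "jc_correct",
    "jc_matrix",
]


class MetricKind(Enum):
    GENETIC = "genetic"
    DRIFT = "drift"


class MissingPolicy(Enum):
    """How sites with missing genotypes enter the pairwise sums.

    COMPLETE_SITES uses only SNPs called in *all* genomes; PAIRWISE_SITES
    uses, for each pair, every SNP where both members of the pair are
    called.
    """

    COMPLETE_SITES = "complete"
    PAIRWISE_SITES = "pairwise"


class DistanceScale(Enum):
    RAW_DIFFERENCES = "raw"
    P_DISTANCE = "p"
    JC_DISTANCE = "jc"


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    samples: list[str]
    values: np.ndarray
    scale: DistanceScale = DistanceScale.RAW_DIFFERENCES
    metric: Optional[MetricKind] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} sample labels"
            )

    @property
    def n(self) -> int:
        return len(self.samples)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.samples.index(pair[0])
        j = self.samples.index(pair[1])
        return float(self.values[i, j])

    def subset(self, names: Sequence[str]) -> "DistanceMatrix":
        """Sub-matrix restricted to ``names``, in the given order."""
        if len(set(names)) != len(names):
            raise ValidationError("sample names for subsetting must be distinct")
        unknown = [s for s in names if s not in self.samples]
        if unknown:
            raise ValidationError(
                "unknown sample name(s): " + ", ".join(unknown)
            )
        idx = np.array([self.samples.index(s) for s in names])
        return DistanceMatrix(list(names), self.values[np.ix_(idx, idx)],
                              self.scale, self.metric)


def _genetic_quarters(d1: int, d2: int) -> int:
    # mismatching ordered allele comparisons among the four cross pairs,
    # expressed through alt-allele dosages (alleles are binary 0/1)
    return d1 * (2 - d2) + d2 * (2 - d1)


def site_genetic_distance(g1: GenotypeCall, g2: GenotypeCall) -> float:
    """Average of the four cross-genome allele mismatch indicators.

    Both calls must be non-missing; for binary alleles the value is one of
    {0, 0.5, 1}.
    """
    if g1.is_missing or g2.is_missing:
        raise ValueError("site distance requires two non-missing calls")
    return _genetic_quarters(g1.dosage, g2.dosage) / 4.0


def site_drift_distance(g1: GenotypeCall, g2: GenotypeCall) -> float:
    """|f1 - f2| where f is each genome's alternate-allele frequency (dosage/2)."""
    if g1.is_missing or g2.is_missing:
        raise ValueError("site distance requires two non-missing calls")
    return abs(g1.dosage - g2.dosage) / 2.0


class PairwiseAccumulator:
    """Running per-pair difference sums and exclusion counts.

    Feed ``(record, category)`` pairs from :class:`~popphylo.vcf_io.VcfReader`
    via :meth:`add`; read the results from the properties (which finalise the
    internal buffer automatically).  Sums are held as integer quarter-counts
    so ``diff_sum`` is exact regardless of record order.
    """

    _BLOCK = 4096

    def __init__(self, samples: Sequence[str], metric: MetricKind,
                 policy: MissingPolicy) -> None:
        n = len(samples)
        if n < 2:
            raise ConfigurationError("at least two samples are required")
        self.samples = list(samples)
        self.metric = metric
        self.policy = policy
        self._quarters = np.zeros((n, n), dtype=np.int64)
        self._used = np.zeros((n, n), dtype=np.int64)
        self._missing_pair = np.zeros((n, n), dtype=np.int64)
        self.excluded_missing = 0
        self.excluded_filtered = 0
        self.excluded_multiallelic = 0
        # per-category record tallies, for logging and the partition invariant
        self.n_usable = 0
        self.n_indel = 0
        self.n_multiallelic = 0
        self.n_low_qual = 0
        self.n_other = 0
        self.n_records = 0
        self._buf_dos: list[np.ndarray] = []
        self._buf_valid: list[np.ndarray] = []

    # -- streaming -----------------------------------------------------

    def add(self, record: VcfRecord, category: RecordCategory) -> None:
        self.n_records += 1
        if category is RecordCategory.SKIP_INDEL:
            self.n_indel += 1
            return
        if category is RecordCategory.SKIP_MULTIALLELIC:
            self.n_multiallelic += 1
            self.excluded_multiallelic += 1
            return
        if category is RecordCategory.SKIP_LOW_QUAL:
            self.n_low_qual += 1
            self.excluded_filtered += 1
            return
        if category is RecordCategory.SKIP_NON_SNP_OTHER:
            self.n_other += 1
            return

        self.n_usable += 1
        calls = record.calls
        dos = np.array(
            [-1 if c.allele_a is None else c.allele_a + c.allele_b for c in calls],
            dtype=np.int8,
        )
        valid = dos >= 0
        demoted_any = record.any_demoted
        if demoted_any:
            # depth-demoted sites are "filtered", counted once per site
            self.excluded_filtered += 1
        elif not valid.all():
            self.excluded_missing += 1

        if self.policy is MissingPolicy.COMPLETE_SITES:
            if valid.all():
                self._buf_dos.append(dos)
                if len(self._buf_dos) >= self._BLOCK:
                    self._flush()
        else:
            self._buf_dos.append(dos)
            self._buf_valid.append(valid)
            if len(self._buf_dos) >= self._BLOCK:
                self._flush()

    def add_all(self, stream: Iterable[tuple[VcfRecord, RecordCategory]]) -> None:
        for record, category in stream:
            self.add(record, category)

    def _flush(self) -> None:
        if not self._buf_dos:
            return
        D = np.array(self._buf_dos, dtype=np.int64)
        s = D.shape[0]
        self._buf_dos.clear()
        if self.policy is MissingPolicy.COMPLETE_SITES:
            V = None
            Dz = D
            self._used += s
        else:
            V = np.array(self._buf_valid, dtype=np.int64)
            self._buf_valid.clear()
            Dz = np.where(V == 1, D, 0)
            both = V.T @ V
            self._used += both
            self._missing_pair += s - both
        if self.metric is MetricKind.GENETIC:
            comp = (2 - Dz) if V is None else (2 - Dz) * V
            A = Dz.T @ comp
            self._quarters += A + A.T
        else:
            if V is None:
                I0 = (Dz == 0).astype(np.int64)
                I1 = (Dz == 1).astype(np.int64)
                I2 = (Dz == 2).astype(np.int64)
            else:
                I0 = ((Dz == 0) & (V == 1)).astype(np.int64)
                I1 = ((Dz == 1) & (V == 1)).astype(np.int64)
                I2 = ((Dz == 2) & (V == 1)).astype(np.int64)
            X = I0.T @ I1 + I1.T @ I2
            C = I0.T @ I2
            self._quarters += 2 * (X + X.T) + 4 * (C + C.T)

    def _finalized(self) -> None:
        self._flush()
        np.fill_diagonal(self._quarters, 0)
        np.fill_diagonal(self._used, 0)
        np.fill_diagonal(self._missing_pair, 0)

    # -- results -------------------------------------------------------

    @property
    def diff_sum(self) -> np.ndarray:
        """Summed per-site distances per pair (exact multiples of 0.25)."""
        self._finalized()
        return self._quarters / 4.0

    @property
    def used_sites(self) -> np.ndarray:
        self._finalized()
        return self._used.copy()

    @property
    def excluded_missing_pair(self) -> np.ndarray:
        """Per-pair count of usable sites skipped for that pair (pairwise policy)."""
        self._finalized()
        return self._missing_pair.copy()


def accumulate(
    records: Iterable[tuple[VcfRecord, RecordCategory]],
    samples: Sequence[str],
    metric: MetricKind = MetricKind.GENETIC,
    policy: MissingPolicy = MissingPolicy.COMPLETE_SITES,
) -> PairwiseAccumulator:
    """Stream classified records into a :class:`PairwiseAccumulator`."""
    acc = PairwiseAccumulator(samples, metric, policy)
    acc.add_all(records)
    return acc


def raw_matrix(acc: PairwiseAccumulator) -> DistanceMatrix:
    """Matrix of raw summed differences (the number-of-differences scale)."""
    return DistanceMatrix(acc.samples, acc.diff_sum,
                          DistanceScale.RAW_DIFFERENCES, acc.metric)


def _effective_length_matrix(acc: PairwiseAccumulator,
                             genome_length: int) -> np.ndarray:
    if genome_length <= 0:
        raise ConfigurationError("genome length must be positive")
    common = acc.excluded_filtered + acc.excluded_multiallelic
    n = len(acc.samples)
    if acc.policy is MissingPolicy.COMPLETE_SITES:
        L = np.full((n, n), genome_length - acc.excluded_missing - common,
                    dtype=float)
    else:
        L = genome_length - acc.excluded_missing_pair.astype(float) - common
    off = ~np.eye(n, dtype=bool)
    if n > 1 and (L[off] <= 0).any():
        raise ConfigurationError("genome length smaller than excluded sites")
    return L


def effective_length(
    acc: PairwiseAccumulator,
    genome_length: int,
    pair: Optional[tuple[Union[int, str], Union[int, str]]] = None,
) -> float:
    """Genome length minus the missing/filtered/multi-allelic exclusions.

    Under COMPLETE_SITES the value is the same for every pair; under
    PAIRWISE_SITES it is pair-specific (``pair`` may give indices or names).
    """
    L = _effective_length_matrix(acc, genome_length)
    if pair is None:
        if acc.policy is MissingPolicy.PAIRWISE_SITES:
            raise ValidationError(
                "a pair is required for the pairwise-sites policy")
        i, j = 0, min(1, len(acc.samples) - 1)
    else:
        i, j = (acc.samples.index(p) if isinstance(p, str) else p for p in pair)
    return float(L[i, j])


def p_matrix(acc: PairwiseAccumulator, genome_length: int) -> DistanceMatrix:
    """Proportions of differences: diff_sum over the effective length."""
    L = _effective_length_matrix(acc, genome_length)
    values = acc.diff_sum / L
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(acc.samples, values, DistanceScale.P_DISTANCE,
                          acc.metric)


def jc_correct(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4)·ln(1 - (4/3)·p), for 0 <= p < 3/4."""
    if p < 0:
        raise DomainError(f"p-distance must be non-negative, got {p}")
    if p >= 0.75:
        raise DomainError(
            f"p-distance {p} is at or beyond the Jukes-Cantor saturation "
            "point 0.75"
        )
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc_matrix(acc: PairwiseAccumulator, genome_length: int) -> DistanceMatrix:
    """Jukes–Cantor corrected distance matrix from p-distances."""
    pm = p_matrix(acc, genome_length)
    p = pm.values
    if (p >= 0.75).any():
        raise DomainError(
            "a pairwise p-distance is at or beyond the Jukes-Cantor "
            "saturation point 0.75"
        )
    values = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(acc.samples, values, DistanceScale.JC_DISTANCE,
                          acc.metric)
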