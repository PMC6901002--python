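"""Streaming reader for multi-sample VCF files.

Reads plain or gzip-compressed VCF 4.x text line by line, parses diploid GT
(and optional per-sample DP) fields, and classifies each record against the
SNP filters used for distance computation: only biallelic single-nucleotide
sites are usable; indels, multi-allelic sites and low-quality sites are
skipped but counted so they can later be subtracted from the genome length.

The reader never materialises the file: memory use is independent of the
number of records for a fixed sample count.

Only the CHROM, POS, REF, ALT, QUAL, FORMAT and sample columns are
consulted; ID, FILTER and INFO are ignored.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from enum import Enum
from os import PathLike
from typing import Iterator, Optional, Sequence, Union

from .errors import VcfFormatError

__all__ = [
    "GenotypeCall",
    "VcfRecord",
    "FilterConfig",
    "RecordCategory",
    "open_vcf_stream",
    "parse_sample_names",
    "parse_record",
    "classify_record",
    "VcfReader",
]

_GZIP_MAGIC = b"\x1f\x8b"

#: Number of fixed VCF columns before the per-sample genotype columns.
_N_FIXED_COLS = 9


class RecordCategory(Enum):
    """Classification of one VCF data line against the SNP filters."""

    USABLE_BIALLELIC_SNP = "usable_biallelic_snp"
    SKIP_INDEL = "skip_indel"
    SKIP_MULTIALLELIC = "skip_multiallelic"
    SKIP_LOW_QUAL = "skip_low_qual"
    SKIP_NON_SNP_OTHER = "skip_non_snp_other"


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One diploid genotype for one sample at one site.

    A call is wholly present (both alleles 0/1 integers) or wholly missing
    (both alleles ``None``).  ``demoted`` marks a call that *was* present in
    the file but fell below the depth-of-coverage threshold and is therefore
    treated as missing; such sites count as "filtered" rather than "missing"
    in the genome-length bookkeeping.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    depth: Optional[int] = None
    demoted: bool = False

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError("a genotype call is wholly present or wholly missing")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def dosage(self) -> int:
        """Count of alternate (non-reference) alleles, 0..2. Call must be present."""
        if self.allele_a is None or self.allele_b is None:
            raise ValueError("dosage of a missing call is undefined")
        return self.allele_a + self.allele_b


MISSING_CALL = GenotypeCall(None, None)


@dataclass(frozen=True, slots=True)
class VcfRecord:
    """One parsed variant line."""

    chrom: str
    pos: int  # 1-based, per the VCF standard
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float]
    calls: tuple[GenotypeCall, ...]

    @property
    def any_demoted(self) -> bool:
        return any(c.demoted for c in self.calls)

    @property
    def any_missing(self) -> bool:
        return any(c.is_missing for c in self.calls)


@dataclass(frozen=True)
class FilterConfig:
    """Site-quality and depth thresholds; both are inclusive lower bounds.

    ``min_qual`` applies to the site-level QUAL column (Phred scale) and
    drops the whole record; ``min_depth`` applies to each sample's FORMAT/DP
    value and demotes only that sample's call to missing.  Absent QUAL (".")
    and absent DP pass their filter.
    """

    min_qual: float = 0.0
    min_depth: int = 0

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")


def open_vcf_stream(path: Union[str, PathLike]) -> Iterator[str]:
    """Yield decoded text lines from a plain or gzipped VCF file.

    gzip is detected from the two magic bytes, not the file extension.  The
    first non-empty line must start with ``##`` or ``#CHROM``; anything else
    raises :class:`VcfFormatError`.  Lines are yielded one at a time with the
    trailing newline stripped; the whole file is never held in memory.
    """
    raw = open(path, "rb")
    try:
        magic = raw.read(2)
        raw.seek(0)
    except OSError:
        raw.close()
        raise
    if magic == _GZIP_MAGIC:
        handle: io.TextIOBase = io.TextIOWrapper(
            gzip.GzipFile(fileobj=raw), encoding="utf-8"
        )
    else:
        handle = io.TextIOWrapper(raw, encoding="utf-8")

    def _lines() -> Iterator[str]:
        validated = False
        try:
            with handle:
                for line in handle:
                    line = line.rstrip("\r\n")
                    if not validated and line.strip():
                        if not (line.startswith("##") or line.startswith("#CHROM")):
                            raise VcfFormatError(
                                "not a VCF file: first non-empty line does not "
                                "start with '##' or '#CHROM'"
                            )
                        validated = True
                    yield line
        except (UnicodeDecodeError, gzip.BadGzipFile, EOFError) as exc:
            raise VcfFormatError(f"not a readable VCF text file: {exc}") from exc

    return _lines()


def parse_sample_names(header_line: str) -> list[str]:
    """Extract sample names, in file order, from the ``#CHROM`` header line."""
    if not header_line.startswith("#CHROM"):
        raise VcfFormatError("header line must start with '#CHROM'")
    cols = header_line.split("\t")
    if len(cols) < _N_FIXED_COLS + 1:
        raise VcfFormatError(
            "sites-only VCF: #CHROM line has no FORMAT/sample columns "
            f"({len(cols)} fields, need >= {_N_FIXED_COLS + 1})"
        )
    return cols[_N_FIXED_COLS:]


def _parse_call(
    sample_field: str,
    gt_index: int,
    dp_index: Optional[int],
    n_alts: int,
    depth_threshold: int,
    where: str,
) -> GenotypeCall:
    parts = sample_field.split(":")
    try:
        gt = parts[gt_index]
    except IndexError:
        raise VcfFormatError(f"{where}: sample field '{sample_field}' lacks GT")

    depth: Optional[int] = None
    if dp_index is not None and dp_index < len(parts):
        dp_str = parts[dp_index]
        if dp_str not in (".", ""):
            try:
                depth = int(dp_str)
            except ValueError:
                raise VcfFormatError(f"{where}: bad DP value '{dp_str}'")

    alleles = gt.replace("|", "/").split("/")
    if len(alleles) == 1:
        if alleles[0] == ".":
            return GenotypeCall(None, None, depth)
        raise VcfFormatError(
            f"{where}: haploid genotype '{gt}' — diploid calls are required"
        )
    if len(alleles) != 2:
        raise VcfFormatError(
            f"{where}: genotype '{gt}' has {len(alleles)} alleles — "
            "diploid calls are required"
        )
    if "." in alleles:
        # "./." and half-missing calls alike are wholly missing.
        return GenotypeCall(None, None, depth)
    try:
        a, b = int(alleles[0]), int(alleles[1])
    except ValueError:
        raise VcfFormatError(f"{where}: unparseable genotype '{gt}'")
    if a > n_alts or b > n_alts or a < 0 or b < 0:
        raise VcfFormatError(
            f"{where}: genotype '{gt}' indexes allele beyond the ALT list"
        )
    if depth is not None and depth < depth_threshold:
        return GenotypeCall(None, None, depth, demoted=True)
    return GenotypeCall(a, b, depth)


def parse_record(
    line: str,
    n_samples: int,
    depth_threshold: int = 0,
    line_number: Optional[int] = None,
) -> VcfRecord:
    """Parse one tab-separated VCF data line into a :class:`VcfRecord`.

    GT accepts "/" and "|" separators; "./.", ".|." and bare "." are missing
    calls.  If FORMAT declares DP and a sample's DP is below
    ``depth_threshold``, that sample's call is demoted to missing.  A QUAL of
    "." is parsed as absent.
    """
    where = f"line {line_number}" if line_number is not None else "data line"
    cols = line.split("\t")
    if len(cols) != _N_FIXED_COLS + n_samples:
        raise VcfFormatError(
            f"{where}: expected {_N_FIXED_COLS + n_samples} columns for "
            f"{n_samples} samples, found {len(cols)}"
        )
    try:
        pos = int(cols[1])
    except ValueError:
        raise VcfFormatError(f"{where}: bad POS '{cols[1]}'")
    if pos < 1:
        raise VcfFormatError(f"{where}: POS must be >= 1, got {pos}")

    alt_field = cols[4]
    alts: tuple[str, ...] = () if alt_field in (".", "") else tuple(alt_field.split(","))

    qual_str = cols[5]
    if qual_str in (".", ""):
        qual: Optional[float] = None
    else:
        try:
            qual = float(qual_str)
        except ValueError:
            raise VcfFormatError(f"{where}: bad QUAL '{qual_str}'")

    fmt = cols[8].split(":")
    try:
        gt_index = fmt.index("GT")
    except ValueError:
        raise VcfFormatError(f"{where}: FORMAT has no GT field")
    dp_index = fmt.index("DP") if "DP" in fmt else None

    calls = tuple(
        _parse_call(cols[_N_FIXED_COLS + i], gt_index, dp_index, len(alts),
                    depth_threshold, where)
        for i in range(n_samples)
    )
    return VcfRecord(cols[0], pos, cols[3], alts, qual, calls)


def _is_symbolic(alt: str) -> bool:
    return alt == "*" or (alt.startswith("<") and alt.endswith(">"))


def classify_record(record: VcfRecord, config: FilterConfig) -> RecordCategory:
    """Classify a parsed record; classification is total (never raises).

    Order of precedence: non-SNP/symbolic alleles, indels, multi-allelic
    sites, then the QUAL threshold.  An absent QUAL passes the filter.
    """
    alts = record.alts
    if not alts:
        return RecordCategory.SKIP_NON_SNP_OTHER
    symbolic = any(_is_symbolic(a) for a in alts)
    if not symbolic and (len(record.ref) != 1 or any(len(a) != 1 for a in alts)):
        return RecordCategory.SKIP_INDEL
    if len(alts) > 1:
        return RecordCategory.SKIP_MULTIALLELIC
    if symbolic:
        return RecordCategory.SKIP_NON_SNP_OTHER
    if record.qual is not None and record.qual < config.min_qual:
        return RecordCategory.SKIP_LOW_QUAL
    return RecordCategory.USABLE_BIALLELIC_SNP


class VcfReader:
    """Iterate ``(VcfRecord, RecordCategory)`` pairs from a VCF file.

    The header is consumed eagerly on construction so ``samples`` is
    available before iteration; data lines are then parsed lazily in a
    single streaming pass.  The underlying file is opened exactly once.
    """

    def __init__(self, path: Union[str, PathLike],
                 filter_config: Optional[FilterConfig] = None) -> None:
        self.path = path
        self.config = filter_config or FilterConfig()
        self._lines = open_vcf_stream(path)
        self._lineno = 0
        self.samples: list[str] = []
        for line in self._lines:
            self._lineno += 1
            if not line.strip() or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                self.samples = parse_sample_names(line)
                break
            raise VcfFormatError(
                f"line {self._lineno}: data before the #CHROM header line"
            )
        if not self.samples:
            raise VcfFormatError("no #CHROM header line found")
        self._consumed = False

    def __iter__(self) -> Iterator[tuple[VcfRecord, RecordCategory]]:
        if self._consumed:
            raise RuntimeError("VcfReader is single-pass; create a new reader")
        self._consumed = True
        n = len(self.samples)
        min_depth = self.config.min_depth
        for line in self._lines:
            self._lineno += 1
            if not line.strip():
                continue
            record = parse_record(line, n, min_depth, self._lineno)
            yield record, classify_record(record, self.config)
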