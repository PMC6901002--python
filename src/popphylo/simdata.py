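"""Synthetic multi-sample VCF fixtures with exactly known expected answers.

The generator plants a binary tree, evolves binary (0/1) haplotypes down it
— each branch flips each site independently with probability equal to the
branch length — and writes a standard VCF v4.2 text (optionally gzipped)
with per-site QUAL and per-call DP values.  Contaminant records (indels,
multi-allelic sites) and missing calls ("./.") are injected at configurable
rates at known positions.  Alongside the file the generator computes an
expected-answer sidecar — per-pair difference sums, used-site counts and
all exclusion tallies, for both metrics and both missing-data policies —
directly from the simulated arrays, so the streaming pipeline can be
checked against exact values.

Randomness comes from numpy's PCG64 seeded through a SeedSequence, with one
spawned stream per purpose (tree shape, genotypes, site classes, QUAL, DP,
missingness): changing a contaminant rate never perturbs the genotype
draws, and a fixed seed reproduces the file byte for byte.
"""
from __future__ import annotations

import gzip as _gzip
import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .errors import ValidationError
from .tree import TreeNode, leaf_distance_matrix
from .distance import DistanceMatrix

__all__ = [
    "SimSpec",
    "VcfFixture",
    "generate_vcf",
    "generate_additive_matrix",
    "generate_ultrametric_matrix",
    "random_binary_tree",
    "random_ultrametric_tree",
]

_CHUNK = 20_000  # records per write when streaming to disk


@dataclass
class SimSpec:
    """Conditions for one synthetic VCF.

    Defaults describe a small resequencing cohort: 8 diploid genomes at 200
    variable sites on a random planted tree with branch lengths (expected
    substitutions per site) drawn uniformly from 0.02–0.2, 5% of calls
    missing, 5% indel and 5% multi-allelic contaminant records, site QUAL
    uniform on 10–60 Phred and per-call depth uniform on 5–40 reads.
    ``min_qual``/``min_depth`` are the filter thresholds the expected-answer
    sidecar is computed under (0 = no filtering).
    """

    seed: int
    n_samples: int = 8
    n_sites: int = 200
    planted_tree: Optional[TreeNode] = None
    missing_rate: float = 0.05
    indel_rate: float = 0.05
    multiallelic_rate: float = 0.05
    qual_range: tuple[float, float] = (10.0, 60.0)
    dp_range: tuple[int, int] = (5, 40)
    branch_length_range: tuple[float, float] = (0.02, 0.2)
    min_qual: float = 0.0
    min_depth: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        if self.n_sites < 1:
            raise ValidationError("need at least 1 site")
        for rate in (self.missing_rate, self.indel_rate, self.multiallelic_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rate {rate} outside [0, 1]")
        if self.indel_rate + self.multiallelic_rate > 1.0:
            raise ValidationError("contaminant class rates must sum to <= 1")
        if self.qual_range[0] > self.qual_range[1] or self.qual_range[0] < 0:
            raise ValidationError("invalid qual_range")
        if self.dp_range[0] > self.dp_range[1] or self.dp_range[0] < 0:
            raise ValidationError("invalid dp_range")


@dataclass
class VcfFixture:
    """A generated VCF plus its provenance and expected answers."""

    samples: list[str]
    tree: TreeNode
    text: Optional[str]
    path: Optional[Path]
    expected: Optional[dict]

    def write_sidecar(self, path: Union[str, PathLike]) -> None:
        if self.expected is None:
            raise ValidationError("fixture was generated without expected answers")
        Path(path).write_text(json.dumps(self.expected, indent=1) + "\n")


# -- random trees ------------------------------------------------------


def random_binary_tree(
    n: int,
    rng: np.random.Generator,
    branch_length_range: tuple[float, float],
    labels: Optional[list[str]] = None,
) -> TreeNode:
    """Random rooted binary tree over ``n`` leaves, i.i.d. uniform branch lengths."""
    labels = labels or [f"T{i + 1}" for i in range(n)]
    lo, hi = branch_length_range
    nodes = [TreeNode(label=s) for s in labels[:n]]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        j = int(rng.integers(len(nodes) - 1))
        if j >= i:
            j += 1
        a, b = nodes[min(i, j)], nodes[max(i, j)]
        parent = TreeNode(children=[(a, float(rng.uniform(lo, hi))),
                                    (b, float(rng.uniform(lo, hi)))])
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    return nodes[0]


def random_ultrametric_tree(
    n: int,
    rng: np.random.Generator,
    step_range: tuple[float, float] = (0.2, 1.0),
    labels: Optional[list[str]] = None,
) -> TreeNode:
    """Random clock-like tree: joins occur at strictly increasing heights."""
    labels = labels or [f"T{i + 1}" for i in range(n)]
    nodes = [TreeNode(label=s, height=0.0) for s in labels[:n]]
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.uniform(*step_range))
        i = int(rng.integers(len(nodes)))
        j = int(rng.integers(len(nodes) - 1))
        if j >= i:
            j += 1
        a, b = nodes[min(i, j)], nodes[max(i, j)]
        parent = TreeNode(children=[(a, h - a.height), (b, h - b.height)],
                          height=h)
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    return nodes[0]


def generate_additive_matrix(n: int, seed: int) -> tuple[TreeNode, DistanceMatrix]:
    """Random binary tree (branch lengths U(0.5, 2)) and its exact path-sum matrix.

    The matrix satisfies the four-point condition by construction, so
    neighbour joining must recover the generating topology exactly.
    """
    if not 4 <= n <= 20:
        raise ValidationError("n must be between 4 and 20")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tree = random_binary_tree(n, rng, (0.5, 2.0))
    return tree, leaf_distance_matrix(tree)


def generate_ultrametric_matrix(n: int, seed: int) -> tuple[TreeNode, DistanceMatrix]:
    """Random clock-like tree and its (ultrametric) path-sum matrix."""
    if not 4 <= n <= 20:
        raise ValidationError("n must be between 4 and 20")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tree = random_ultrametric_tree(n, rng)
    return tree, leaf_distance_matrix(tree)


# -- genotype simulation ----------------------------------------------


def _simulate_haplotypes(
    tree: TreeNode, n_sites: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve two haplotypes per sample down the tree; returns label -> (2, S)."""
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, state: np.ndarray) -> None:
        if node.is_leaf:
            out[node.label] = state
            return
        for child, bl in node.children:
            p = min(max(bl, 0.0), 0.5)
            flips = rng.random((2, n_sites)) < p
            descend(child, state ^ flips)

    descend(tree, np.zeros((2, n_sites), dtype=bool))
    return out


# site classes
_SNP, _INDEL, _MULTI = 0, 1, 2


def _expected_counts(
    spec: SimSpec,
    site_class: np.ndarray,
    dosage: np.ndarray,
    present: np.ndarray,
    dp: np.ndarray,
    qual: np.ndarray,
    samples: list[str],
) -> dict:
    """Exact expected accumulator state, computed from the simulation arrays."""
    n = len(samples)
    snp = site_class == _SNP
    low_qual = snp & (qual < spec.min_qual)
    usable = snp & ~low_qual
    demote = present & (dp < spec.min_depth)
    valid = present & ~demote

    u_dos = dosage[usable]
    u_valid = valid[usable]
    demoted_any = demote[usable].any(axis=1)
    missing_any = (~present[usable]).any(axis=1)

    n_usable = int(usable.sum())
    excluded_multiallelic = int((site_class == _MULTI).sum())
    excluded_filtered = int(low_qual.sum()) + int(demoted_any.sum())
    excluded_missing = int((~demoted_any & missing_any).sum())

    def pair_sums(policy: str) -> dict:
        diff_g = np.zeros((n, n))
        diff_d = np.zeros((n, n))
        used = np.zeros((n, n), dtype=int)
        miss_pair = np.zeros((n, n), dtype=int)
        if policy == "complete":
            rows = u_valid.all(axis=1)
        for i in range(n):
            for j in range(i + 1, n):
                if policy == "complete":
                    sel = rows
                else:
                    sel = u_valid[:, i] & u_valid[:, j]
                    miss_pair[i, j] = miss_pair[j, i] = n_usable - int(sel.sum())
                di = u_dos[sel, i].astype(np.int64)
                dj = u_dos[sel, j].astype(np.int64)
                used[i, j] = used[j, i] = int(sel.sum())
                g = (di * (2 - dj) + dj * (2 - di)).sum() / 4.0
                dr = np.abs(di - dj).sum() / 2.0
                diff_g[i, j] = diff_g[j, i] = g
                diff_d[i, j] = diff_d[j, i] = dr
        out = {
            "used_sites": used.tolist(),
            "diff_sum_genetic": diff_g.tolist(),
            "diff_sum_drift": diff_d.tolist(),
        }
        if policy == "pairwise":
            out["excluded_missing_pair"] = miss_pair.tolist()
        return out

    return {
        "samples": samples,
        "n_sites": spec.n_sites,
        "counts": {
            "usable": n_usable,
            "indel": int((site_class == _INDEL).sum()),
            "multiallelic": excluded_multiallelic,
            "low_qual": int(low_qual.sum()),
        },
        "excluded_missing": excluded_missing,
        "excluded_filtered": excluded_filtered,
        "excluded_multiallelic": excluded_multiallelic,
        "complete": pair_sums("complete"),
        "pairwise": pair_sums("pairwise"),
    }


def _record_lines(
    spec: SimSpec,
    site_class: np.ndarray,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    present: np.ndarray,
    dp: np.ndarray,
    qual: np.ndarray,
) -> Iterator[str]:
    n = hap_a.shape[1]
    ref_alt = {_SNP: ("A", "T"), _INDEL: ("AT", "A"), _MULTI: ("A", "T,G")}
    gt_lookup = ("0/0", "0/1", "1/0", "1/1")
    for s in range(spec.n_sites):
        ref, alt = ref_alt[int(site_class[s])]
        fields = ["1", str(s + 1), ".", ref, alt, f"{qual[s]:.1f}", ".", ".",
                  "GT:DP"]
        for k in range(n):
            if present[s, k]:
                gt = gt_lookup[2 * int(hap_a[s, k]) + int(hap_b[s, k])]
            else:
                gt = "./."
            fields.append(f"{gt}:{dp[s, k]}")
        yield "\t".join(fields)


def generate_vcf(
    spec: SimSpec,
    path: Optional[Union[str, PathLike]] = None,
    compress: bool = False,
    with_expected: bool = True,
) -> VcfFixture:
    """Generate a synthetic VCF and (optionally) its expected-answer sidecar.

    If ``path`` is given the text is streamed to disk in chunks (gzipped
    with a zeroed timestamp when ``compress`` is set, so output is
    deterministic) and ``text`` is ``None``; otherwise the full text is
    returned in memory.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_tree, rng_geno, rng_class, rng_qual, rng_dp, rng_miss = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    tree = spec.planted_tree
    if tree is None:
        labels = [f"S{i + 1}" for i in range(spec.n_samples)]
        tree = random_binary_tree(spec.n_samples, rng_tree,
                                  spec.branch_length_range, labels)
    samples = tree.leaf_labels()
    if len(samples) != spec.n_samples:
        raise ValidationError(
            "planted tree leaf count does not match n_samples")
    n, S = len(samples), spec.n_sites

    haps = _simulate_haplotypes(tree, S, rng_geno)
    hap_a = np.stack([haps[s][0] for s in samples], axis=1)  # (S, n)
    hap_b = np.stack([haps[s][1] for s in samples], axis=1)

    u = rng_class.random(S)
    site_class = np.full(S, _SNP, dtype=np.int8)
    site_class[u < spec.indel_rate] = _INDEL
    site_class[(u >= spec.indel_rate)
               & (u < spec.indel_rate + spec.multiallelic_rate)] = _MULTI

    qual = np.round(rng_qual.uniform(*spec.qual_range, size=S), 1)
    dp = rng_dp.integers(spec.dp_range[0], spec.dp_range[1] + 1,
                         size=(S, n)).astype(np.int32)
    present = rng_miss.random((S, n)) >= spec.missing_rate

    header = (
        "##fileformat=VCFv4.2\n"
        "##source=popphylo-simdata\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )

    expected = None
    if with_expected:
        dosage = (hap_a.astype(np.int8) + hap_b.astype(np.int8))
        expected = _expected_counts(spec, site_class, dosage, present, dp,
                                    qual, samples)

    lines = _record_lines(spec, site_class, hap_a, hap_b, present, dp, qual)

    if path is None:
        text = header + "".join(line + "\n" for line in lines)
        if compress:
            raise ValidationError("in-memory output cannot be compressed; "
                                  "pass a path")
        return VcfFixture(samples, tree, text, None, expected)

    path = Path(path)
    raw = open(path, "wb")
    # empty filename + zero mtime keep the gzip header deterministic
    handle = (_gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
              if compress else raw)
    try:
        handle.write(header.encode())
        chunk: list[str] = []
        for line in lines:
            chunk.append(line)
            if len(chunk) >= _CHUNK:
                handle.write(("\n".join(chunk) + "\n").encode())
                chunk.clear()
        if chunk:
            handle.write(("\n".join(chunk) + "\n").encode())
    finally:
        handle.close()
        if handle is not raw:
            raw.close()
    return VcfFixture(samples, tree, None, path, expected)
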