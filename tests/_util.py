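"""Shared test helpers: independent oracles and re-parsers.

The oracles deliberately avoid the library's accumulation code paths:
per-site distances are computed by explicit enumeration of the four allele
comparisons (not dosage algebra) and accumulation is a plain double loop
over pairs and sites (not blocked matrix products).
"""
from __future__ import annotations

import numpy as np

from popphylo.vcf_io import GenotypeCall, RecordCategory, VcfRecord


def oracle_site_genetic(c1: GenotypeCall, c2: GenotypeCall) -> float:
    total = 0
    for a in (c1.allele_a, c1.allele_b):
        for b in (c2.allele_a, c2.allele_b):
            total += int(a != b)
    return total / 4.0


def oracle_site_drift(c1: GenotypeCall, c2: GenotypeCall) -> float:
    f1 = (c1.allele_a + c1.allele_b) / 2.0
    f2 = (c2.allele_a + c2.allele_b) / 2.0
    return abs(f1 - f2)


def oracle_counts(classified, n: int, metric: str, policy: str) -> dict:
    """Brute-force re-accumulation over (pairs x sites).

    ``classified`` is a sequence of (VcfRecord, RecordCategory); ``metric``
    is "genetic"/"drift" and ``policy`` "complete"/"pairwise".
    """
    site = oracle_site_genetic if metric == "genetic" else oracle_site_drift
    diff = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    miss_pair = np.zeros((n, n), dtype=int)
    excl_missing = excl_filtered = excl_multi = 0
    for record, category in classified:
        if category is RecordCategory.SKIP_MULTIALLELIC:
            excl_multi += 1
            continue
        if category is RecordCategory.SKIP_LOW_QUAL:
            excl_filtered += 1
            continue
        if category is not RecordCategory.USABLE_BIALLELIC_SNP:
            continue
        calls = record.calls
        if any(c.demoted for c in calls):
            excl_filtered += 1
        elif any(c.is_missing for c in calls):
            excl_missing += 1
        complete = all(not c.is_missing for c in calls)
        for i in range(n):
            for j in range(i + 1, n):
                if policy == "complete":
                    if not complete:
                        continue
                elif calls[i].is_missing or calls[j].is_missing:
                    miss_pair[i, j] += 1
                    miss_pair[j, i] += 1
                    continue
                d = site(calls[i], calls[j])
                diff[i, j] += d
                diff[j, i] += d
                used[i, j] += 1
                used[j, i] += 1
    return {
        "diff_sum": diff,
        "used_sites": used,
        "excluded_missing_pair": miss_pair,
        "excluded_missing": excl_missing,
        "excluded_filtered": excl_filtered,
        "excluded_multiallelic": excl_multi,
    }


# -- re-parsers for format round-trips --------------------------------


def parse_mega(body: str) -> tuple[list[str], np.ndarray]:
    lines = [ln for ln in body.splitlines() if ln.strip()]
    assert lines[0] == "#mega"
    names = [ln[1:] for ln in lines[3:] if ln.startswith("#")]
    n = len(names)
    rows = [ln for ln in lines[3:] if not ln.startswith("#")]
    d = np.zeros((n, n))
    for i, row in enumerate(rows, start=1):
        vals = [float(v) for v in row.split()]
        assert len(vals) == i
        for j, v in enumerate(vals):
            d[i, j] = d[j, i] = v
    return names, d


def parse_phylip(body: str) -> tuple[list[str], np.ndarray]:
    lines = body.splitlines()
    n = int(lines[0])
    names, rows = [], []
    for line in lines[1:n + 1]:
        names.append(line[:10].rstrip())
        rows.append([float(v) for v in line[10:].split()])
    return names, np.asarray(rows)


# -- tree helpers ------------------------------------------------------


def root_leaf_depths(root) -> dict[str, float]:
    depths: dict[str, float] = {}

    def walk(node, acc: float) -> None:
        if node.is_leaf:
            depths[node.label] = acc
        for child, bl in node.children:
            walk(child, acc + bl)

    walk(root, 0.0)
    return depths


def rooted_clusters(root) -> set[frozenset]:
    """Leaf set of every internal node — compares rooted topologies."""
    clusters: set[frozenset] = set()

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        s = frozenset().union(*(walk(c) for c, _ in node.children))
        clusters.add(s)
        return s

    walk(root)
    return clusters


def cluster_heights(root) -> dict[frozenset, float]:
    heights: dict[frozenset, float] = {}

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        s = frozenset().union(*(walk(c) for c, _ in node.children))
        heights[s] = node.height
        return s

    walk(root)
    return heights
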