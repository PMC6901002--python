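"""Per-site distances, streaming accumulation, and distance scales."""
import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from popphylo import (
    ConfigurationError,
    DistanceScale,
    DomainError,
    FilterConfig,
    GenotypeCall,
    MetricKind,
    MissingPolicy,
    PairwiseAccumulator,
    VcfReader,
    accumulate,
    effective_length,
    jc_correct,
    jc_matrix,
    p_matrix,
    parse_record,
    raw_matrix,
    site_drift_distance,
    site_genetic_distance,
)
from popphylo.simdata import SimSpec, generate_vcf
from popphylo.vcf_io import RecordCategory

from _util import oracle_counts, oracle_site_drift, oracle_site_genetic

CALL = {0: GenotypeCall(0, 0), 1: GenotypeCall(0, 1), 2: GenotypeCall(1, 1)}


class TestSiteDistances:
    @pytest.mark.parametrize(
        "d1,d2,genetic,drift",
        [
            (1, 1, 0.5, 0.0),  # two heterozygotes: 2 of 4 comparisons differ
            (0, 0, 0.0, 0.0),
            (2, 2, 0.0, 0.0),
            (0, 2, 1.0, 1.0),
            (0, 1, 0.5, 0.5),
            (1, 2, 0.5, 0.5),
        ],
    )
    def test_dosage_table(self, d1, d2, genetic, drift):
        g1, g2 = CALL[d1], CALL[d2]
        assert site_genetic_distance(g1, g2) == genetic
        assert site_drift_distance(g1, g2) == drift
        # and both agree with explicit four-comparison / frequency oracles
        assert site_genetic_distance(g1, g2) == oracle_site_genetic(g1, g2)
        assert site_drift_distance(g1, g2) == oracle_site_drift(g1, g2)

    def test_missing_call_rejected(self):
        with pytest.raises(ValueError):
            site_genetic_distance(GenotypeCall(None, None), CALL[1])
        with pytest.raises(ValueError):
            site_drift_distance(CALL[1], GenotypeCall(None, None))

    @given(st.tuples(*[st.integers(0, 1)] * 4))
    def test_drift_never_exceeds_genetic(self, alleles):
        a1, a2, b1, b2 = alleles
        g1, g2 = GenotypeCall(a1, a2), GenotypeCall(b1, b2)
        g = site_genetic_distance(g1, g2)
        d = site_drift_distance(g1, g2)
        assert d <= g
        assert g == site_genetic_distance(g2, g1)  # symmetry
        assert g in (0.0, 0.5, 1.0) and d in (0.0, 0.5, 1.0)
        assert g == oracle_site_genetic(g1, g2)


def _records(samples, gt_rows, **kw):
    """Parse genotype rows like ['0/1', '0/0', ...] into classified records."""
    out = []
    for row in gt_rows:
        line = "\t".join(["1", "1", ".", "A", "T", "50", ".", ".", "GT"] + row)
        rec = parse_record(line, len(samples), kw.get("depth_threshold", 0))
        out.append((rec, RecordCategory.USABLE_BIALLELIC_SNP))
    return out


class TestAccumulate:
    def test_three_heterozygous_samples(self):
        samples = ["A", "B", "C"]
        acc = accumulate(_records(samples, [["0/1", "0/1", "0/1"]]), samples,
                         MetricKind.GENETIC, MissingPolicy.COMPLETE_SITES)
        off = ~np.eye(3, dtype=bool)
        assert (acc.diff_sum[off] == 0.5).all()
        assert (acc.used_sites[off] == 1).all()

    def test_complete_sites_excludes_site_with_any_missing(self):
        samples = ["A", "B", "C"]
        acc = accumulate(_records(samples, [["0/1", "0/1", "./."]]), samples,
                         MetricKind.GENETIC, MissingPolicy.COMPLETE_SITES)
        assert (acc.used_sites == 0).all()
        assert acc.excluded_missing == 1

    def test_pairwise_sites_keeps_called_pair(self):
        samples = ["A", "B", "C"]
        acc = accumulate(_records(samples, [["0/1", "0/1", "./."]]), samples,
                         MetricKind.GENETIC, MissingPolicy.PAIRWISE_SITES)
        assert acc.used_sites[0, 1] == 1 and acc.diff_sum[0, 1] == 0.5
        assert acc.used_sites[0, 2] == 0 and acc.used_sites[1, 2] == 0
        assert acc.excluded_missing_pair[0, 2] == 1
        assert acc.excluded_missing_pair[0, 1] == 0

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            PairwiseAccumulator(["A"], MetricKind.GENETIC,
                                MissingPolicy.COMPLETE_SITES)

    def test_order_independent_exact(self):
        """Raw sums are integer quarter-counts: any record order, same bits."""
        samples = ["A", "B", "C", "D"]
        rows = [["0/1", "1/1", "0/0", "0/1"] for _ in range(50)]
        rows += [["1/1", "0/0", "0/1", "1/1"] for _ in range(50)]
        recs = _records(samples, rows)
        fwd = accumulate(recs, samples).diff_sum
        rng = random.Random(0)
        shuffled = recs[:]
        rng.shuffle(shuffled)
        rev = accumulate(shuffled, samples).diff_sum
        assert (fwd == rev).all()


@pytest.mark.parametrize("metric", ["genetic", "drift"])
@pytest.mark.parametrize("policy", ["complete", "pairwise"])
class TestOracleEquivalence:
    """Streamed accumulator vs brute-force double loop, exact equality."""

    def test_matches_bruteforce_and_sidecar(self, tmp_path, metric, policy):
        spec = SimSpec(seed=42, n_samples=7, n_sites=150, missing_rate=0.15,
                       indel_rate=0.1, multiallelic_rate=0.1, min_qual=25.0,
                       min_depth=12)
        path = tmp_path / "sim.vcf"
        fx = generate_vcf(spec, path=path)
        cfg = FilterConfig(min_qual=spec.min_qual, min_depth=spec.min_depth)
        classified = list(VcfReader(path, cfg))
        acc = accumulate(classified, fx.samples, MetricKind(metric),
                         MissingPolicy(policy))
        oracle = oracle_counts(classified, len(fx.samples), metric, policy)
        assert (acc.diff_sum == oracle["diff_sum"]).all()
        assert (acc.used_sites == oracle["used_sites"]).all()
        assert acc.excluded_missing == oracle["excluded_missing"]
        assert acc.excluded_filtered == oracle["excluded_filtered"]
        assert acc.excluded_multiallelic == oracle["excluded_multiallelic"]
        if policy == "pairwise":
            assert (acc.excluded_missing_pair
                    == oracle["excluded_missing_pair"]).all()
        # generator sidecar agrees too (third, construction-time route)
        exp = fx.expected[policy]
        assert (acc.diff_sum
                == np.asarray(exp[f"diff_sum_{metric}"])).all()
        assert (acc.used_sites == np.asarray(exp["used_sites"])).all()


class TestPoliciesAndMetrics:
    def test_policies_agree_without_missing_data(self, tmp_path):
        spec = SimSpec(seed=5, n_samples=6, n_sites=120, missing_rate=0.0,
                       indel_rate=0.0, multiallelic_rate=0.0)
        path = tmp_path / "clean.vcf"
        fx = generate_vcf(spec, path=path, with_expected=False)
        mats = {}
        for policy in MissingPolicy:
            acc = accumulate(VcfReader(path), fx.samples,
                             MetricKind.GENETIC, policy)
            mats[policy] = acc.diff_sum
        assert (mats[MissingPolicy.COMPLETE_SITES]
                == mats[MissingPolicy.PAIRWISE_SITES]).all()

    def test_drift_sum_bounded_by_genetic_sum(self, tmp_path):
        path = tmp_path / "sim.vcf"
        fx = generate_vcf(SimSpec(seed=9, n_samples=6, n_sites=150,
                                  missing_rate=0.1), path=path,
                          with_expected=False)
        sums = {}
        for metric in MetricKind:
            sums[metric] = accumulate(VcfReader(path), fx.samples, metric,
                                      MissingPolicy.COMPLETE_SITES).diff_sum
        assert (sums[MetricKind.DRIFT] <= sums[MetricKind.GENETIC]).all()


def _acc_with_exclusions(missing=0, filtered=0, multi=0):
    samples = ["A", "B", "C"]
    acc = PairwiseAccumulator(samples, MetricKind.GENETIC,
                              MissingPolicy.COMPLETE_SITES)
    acc.excluded_missing = missing
    acc.excluded_filtered = filtered
    acc.excluded_multiallelic = multi
    return acc


class TestScales:
    def test_effective_length_subtracts_exclusions(self):
        acc = _acc_with_exclusions(missing=10, filtered=5, multi=2)
        assert effective_length(acc, 1000) == 983

    def test_effective_length_identity_without_exclusions(self):
        assert effective_length(_acc_with_exclusions(), 1000) == 1000

    def test_effective_length_exhausted_genome(self):
        acc = _acc_with_exclusions(missing=12)
        with pytest.raises(ConfigurationError):
            effective_length(acc, 10)

    def test_effective_length_per_pair_under_pairwise_policy(self):
        samples = ["A", "B", "C"]
        recs = _records(samples, [["0/1", "0/1", "./."], ["0/0", "1/1", "0/1"]])
        acc = accumulate(recs, samples, MetricKind.GENETIC,
                         MissingPolicy.PAIRWISE_SITES)
        assert effective_length(acc, 100, ("A", "B")) == 100
        assert effective_length(acc, 100, ("A", "C")) == 99

    def test_p_matrix_divides_by_effective_length(self):
        samples = ["A", "B", "C"]
        acc = accumulate(_records(samples, [["0/1", "0/1", "0/1"]]), samples,
                         MetricKind.GENETIC, MissingPolicy.COMPLETE_SITES)
        pm = p_matrix(acc, 1000)
        assert pm.scale is DistanceScale.P_DISTANCE
        assert pm.values[0, 1] == 0.5 / 1000
        assert (np.diag(pm.values) == 0).all()

    def test_p_matrix_entries_within_unit_interval(self, tmp_path):
        path = tmp_path / "sim.vcf"
        fx = generate_vcf(SimSpec(seed=2, n_samples=5, n_sites=100),
                          path=path, with_expected=False)
        acc = accumulate(VcfReader(path), fx.samples, MetricKind.GENETIC,
                         MissingPolicy.COMPLETE_SITES)
        pv = p_matrix(acc, 10_000).values
        assert (pv >= 0).all() and (pv <= 1).all()

    def test_jc_of_zero_is_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_jc_known_value(self):
        # -(3/4) ln(1 - 0.4/3) evaluated independently
        assert jc_correct(0.1) == pytest.approx(0.107326, abs=5e-7)
        assert jc_correct(0.1) == pytest.approx(
            -0.75 * math.log(1 - 4 * 0.1 / 3), rel=1e-12)

    def test_jc_small_p_limit(self):
        p = 1e-6
        assert jc_correct(p) / p == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("p", [0.75, 0.9, -0.01])
    def test_jc_domain_errors(self, p):
        with pytest.raises(DomainError):
            jc_correct(p)

    def test_jc_matrix_matches_scalar_correction(self, tmp_path):
        path = tmp_path / "sim.vcf"
        fx = generate_vcf(SimSpec(seed=8, n_samples=5, n_sites=100),
                          path=path, with_expected=False)
        acc = accumulate(VcfReader(path), fx.samples, MetricKind.GENETIC,
                         MissingPolicy.COMPLETE_SITES)
        pm = p_matrix(acc, 5000)
        jm = jc_matrix(acc, 5000)
        i, j = 0, 1
        assert jm.values[i, j] == pytest.approx(jc_correct(pm.values[i, j]),
                                                rel=1e-12)
        assert raw_matrix(acc).scale is DistanceScale.RAW_DIFFERENCES
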