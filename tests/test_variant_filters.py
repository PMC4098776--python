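from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exoqc import (
    FilterThresholds,
    apply_genotype_filters,
    apply_variant_filters,
    apply_vqsr,
    average_gq,
    call_rate,
    hwe_exact_pvalue,
    hwe_filter,
)
from exoqc.errors import UndefinedMetricError
from exoqc.model import CohortDataset
from exoqc.variant_filters import average_gq_array, call_rate_array


# --- independent exact-arithmetic oracle for the HWE conditional test ----
@lru_cache(maxsize=None)
def _oracle_distribution(n_minor: int, n: int) -> tuple[tuple[int, Fraction], ...]:
    dist = []
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        dist.append((h, Fraction(comb(n, h) * comb(n - h, hom_minor) * 2 ** h,
                                 comb(2 * n, n_minor))))
    assert sum(p for _, p in dist) == 1
    return tuple(dist)


def hwe_oracle(a: int, b: int, c: int) -> float:
    n = a + b + c
    dist = _oracle_distribution(min(2 * a + b, 2 * c + b), n)
    p_obs = dict(dist)[b]
    return float(sum(p for _, p in dist if p <= p_obs))


class TestHweExactPvalue:
    def test_monomorphic_site_is_certain(self):
        assert hwe_exact_pvalue((100, 0, 0)) == 1.0
        assert hwe_exact_pvalue((0, 0, 7)) == 1.0

    def test_no_heterozygotes_among_ten_diploids(self):
        # 10 minor alleles in 10 diploids: achievable het counts {0,2,...,10}
        assert hwe_exact_pvalue((5, 0, 5)) == pytest.approx(hwe_oracle(5, 0, 5), abs=1e-14)

    def test_large_counts_match_oracle_tightly(self):
        p = hwe_exact_pvalue((57, 14, 50))
        assert p == pytest.approx(hwe_oracle(57, 14, 50), abs=1e-12, rel=1e-9)

    def test_exhaustive_small_configurations(self):
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    c = n - a - b
                    assert hwe_exact_pvalue((a, b, c)) == pytest.approx(
                        hwe_oracle(a, b, c), abs=1e-12), (a, b, c)

    @given(a=st.integers(0, 40), b=st.integers(0, 40), c=st.integers(0, 40))
    def test_allele_relabelling_invariance(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_pvalue((a, b, c)) == pytest.approx(
            hwe_exact_pvalue((c, b, a)), rel=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue((0, 0, 0))


def _dataset_with_counts(counts_per_variant):
    """One variant per (a, b, c) triple, all over the same sample roster."""
    n = max(sum(t) for t in counts_per_variant)
    samples = [f"S{i}" for i in range(n)]
    records = []
    for i, (a, b, c) in enumerate(counts_per_variant):
        gt = [0] * a + [1] * b + [2] * c + [-1] * (n - a - b - c)
        records.append({"chrom": "1", "pos": 10 * (i + 1), "ref": "A", "alt": "G",
                        "gt": gt, "dp": [30] * n, "gq": [60] * n})
    return CohortDataset.from_variant_records(samples, records)


class TestHweFilter:
    def test_removes_only_extreme_deviation(self):
        conformant = [(25, 50, 25)] * 99
        dataset = _dataset_with_counts(conformant + [(50, 0, 50)])
        survivors, removed = hwe_filter(dataset, alpha=0.05)
        assert len(removed) == 1 and removed[0].pos == 1000
        assert survivors.n_variants == 99

    def test_tiny_alpha_removes_nothing(self):
        dataset = _dataset_with_counts([(50, 0, 50), (25, 50, 25)])
        survivors, removed = hwe_filter(dataset, alpha=1e-300)
        assert removed == [] and survivors.n_variants == 2

    def test_enriched_for_violating_sites(self, sim_small):
        dataset, truth = sim_small
        masked, _ = apply_genotype_filters(dataset)
        _, removed = hwe_filter(masked, alpha=0.05)
        removed_keys = {v.key for v in removed}
        violating = truth.labels["hwe_violating"].to_numpy()
        keys = dataset.keys()
        hit_viol = sum(1 for i, k in enumerate(keys) if violating[i] and k in removed_keys)
        hit_conf = len(removed_keys) - hit_viol
        n_viol = int(violating.sum())
        assert hit_viol / n_viol > 10 * max(hit_conf, 1) / (len(keys) - n_viol)


class TestSiteMetrics:
    def test_average_gq_ignores_missing(self):
        ds = CohortDataset.from_variant_records(
            ["A", "B", "C", "D"],
            [{"chrom": "1", "pos": 1, "ref": "A", "alt": "G",
              "gt": [0, 1, 2, -1], "gq": [20, 30, 40, -1], "dp": [9, 9, 9, -1]}])
        assert average_gq(ds.variant(0)) == 30.0

    def test_single_genotype_identity(self):
        ds = CohortDataset.from_variant_records(
            ["A"], [{"chrom": "1", "pos": 1, "ref": "A", "alt": "G",
                     "gt": [2], "gq": [99], "dp": [9]}])
        assert average_gq(ds.variant(0)) == 99.0

    def test_all_missing_is_undefined(self, tiny_dataset):
        with pytest.raises(UndefinedMetricError):
            average_gq(tiny_dataset.variant(2))

    @pytest.mark.parametrize("gts,expected", [
        ([0, 1, 2, -1], 0.75), ([-1, -1, -1, -1], 0.0), ([0, 0, 1, 2], 1.0),
    ])
    def test_call_rate(self, gts, expected):
        ds = CohortDataset.from_variant_records(
            ["A", "B", "C", "D"],
            [{"chrom": "1", "pos": 1, "ref": "A", "alt": "G", "gt": gts}])
        assert call_rate(ds.variant(0)) == expected

    def test_vectorised_metrics_match_scalar(self, sim_small):
        dataset, _ = sim_small
        sub = dataset.subset_variants(np.arange(200))
        avg = average_gq_array(sub)
        cr = call_rate_array(sub)
        for i in range(sub.n_variants):
            v = sub.variant(i)
            assert cr[i] == call_rate(v)
            if v.n_called:
                assert avg[i] == pytest.approx(average_gq(v))
            else:
                assert np.isnan(avg[i])


class TestApplyVqsr:
    def test_retains_passing_variants(self, tiny_dataset):
        survivors, removed = apply_vqsr(tiny_dataset)
        assert survivors.n_variants == 2
        assert [v.pos for v in removed] == [200]

    def test_none_pass_gives_valid_empty_dataset(self, tiny_dataset):
        ds = tiny_dataset.copy()
        ds.vqsr_pass[:] = False
        survivors, removed = apply_vqsr(ds)
        assert survivors.n_variants == 0 and len(removed) == 3


PERMISSIVE = dict(hwe_alpha=1e-300, min_avg_gq=0.0, min_call_rate=0.0, vqsr_position="off")


class TestApplyVariantFilters:
    def test_permissive_thresholds_are_identity(self, tiny_dataset):
        out, report = apply_variant_filters(tiny_dataset, FilterThresholds(**PERMISSIVE))
        assert out.equal_genotypes(tiny_dataset)
        assert all(n == 0 for _, n in report.stages)

    def test_call_rate_strictness(self):
        # 87/100 called with min_call_rate=0.88 -> removed at the call-rate stage
        gt = [0] * 87 + [-1] * 13
        ds = CohortDataset.from_variant_records(
            [f"S{i}" for i in range(100)],
            [{"chrom": "1", "pos": 1, "ref": "A", "alt": "G", "gt": gt,
              "dp": [30] * 100, "gq": [60] * 100}])
        _, report = apply_variant_filters(ds, FilterThresholds(min_call_rate=0.88,
                                                               vqsr_position="off"))
        assert dict(report.stages)["call_rate"] == 1

    def test_report_counts_are_consistent(self, sim_small):
        dataset, _ = sim_small
        masked, _ = apply_genotype_filters(dataset)
        out, report = apply_variant_filters(masked, FilterThresholds())
        assert report.n_input == masked.n_variants
        assert report.n_surviving == out.n_variants
        assert sum(n for _, n in report.stages) + out.n_variants == masked.n_variants

    @pytest.mark.parametrize("order", ["after_manual", "before_manual"])
    def test_matches_set_algebra_oracle(self, sim_small, order):
        """Each order's survivor set equals the directly computed composition
        of per-variant keep-masks with the stage-appropriate HWE denominator."""
        dataset, _ = sim_small
        masked, _ = apply_genotype_filters(dataset)
        thr = FilterThresholds(vqsr_position=order)
        out, _ = apply_variant_filters(masked, thr)

        from exoqc.variant_filters import hwe_pvalues
        pool = masked if order == "after_manual" else masked.subset_variants(masked.vqsr_pass)
        pvals = hwe_pvalues(pool)
        n_tested = int(np.count_nonzero(~np.isnan(pvals)))
        keep = ~(~np.isnan(pvals) & (pvals <= thr.hwe_alpha / n_tested))
        hwe_pass = pool.subset_variants(keep)
        avg = average_gq_array(hwe_pass)
        cr = call_rate_array(hwe_pass)
        with np.errstate(invalid="ignore"):
            manual = (avg >= thr.min_avg_gq) & (cr >= thr.min_call_rate)
        expected = {k for k, m, vq in zip(hwe_pass.keys(), manual, hwe_pass.vqsr_pass)
                    if m and vq}
        assert set(out.keys()) == expected
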