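"""Variant-level filters: Hardy-Weinberg exact test (Bonferroni-corrected),
average genotype quality, call rate, and the upstream VQSR verdict.

The HWE test is the exact conditional test: with the minor-allele count and
diploid sample size fixed, every achievable heterozygote count is weighted
by its exact probability under random mating, and the p-value is the sum of
probabilities of all configurations no more probable than the observed one.
A chi-square approximation is deliberately avoided — it is anti-conservative
exactly where exome data live, at rare minor-allele frequencies.

The full cascade applies, in order: HWE, average GQ, call rate, then the
VQSR verdict (``after_manual``, the default) — or VQSR first
(``before_manual``). All thresholds are "keep if metric ≥ threshold";
HWE removes on ``p ≤ alpha / N`` where N counts the variants tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import UndefinedMetricError
from .model import CohortDataset, HET, HOM_ALT, HOM_REF, VariantSite


class GenotypeCounts(tuple):
    """(n_hom_ref, n_het, n_hom_alt) genotype counts at one site."""

    def __new__(cls, n_hom_ref: int, n_het: int, n_hom_alt: int):
        if min(n_hom_ref, n_het, n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")
        return super().__new__(cls, (int(n_hom_ref), int(n_het), int(n_hom_alt)))

    n_hom_ref = property(lambda self: self[0])
    n_het = property(lambda self: self[1])
    n_hom_alt = property(lambda self: self[2])


# Comparisons of "no more probable than observed" use a relative epsilon so
# exact ties (symmetric configurations) are kept despite float rounding.
_TIE_EPS = 1e-9


@lru_cache(maxsize=100_000)
def _het_probabilities(n_minor: int, n_diploid: int) -> dict[int, float]:
    """Exact P(het count = h | minor-allele count, sample size) for every
    achievable h, via the stable two-sided recurrence from the mode."""
    if n_minor == 0:
        return {0: 1.0}
    # start near the expected heterozygote count, matching parity
    mid = n_minor * (2 * n_diploid - n_minor) // (2 * n_diploid)
    if (mid % 2) != (n_minor % 2):
        mid += 1
    probs = {mid: 1.0}
    h, p = mid, 1.0
    while h >= 2:
        hom_minor = (n_minor - h) // 2
        hom_major = n_diploid - h - hom_minor
        p = p * h * (h - 1) / (4.0 * (hom_minor + 1) * (hom_major + 1))
        h -= 2
        probs[h] = p
    h, p = mid, 1.0
    while h + 2 <= n_minor:
        hom_minor = (n_minor - h) // 2
        hom_major = n_diploid - h - hom_minor
        if hom_minor == 0 or hom_major == 0:
            break
        p = p * 4.0 * hom_minor * hom_major / ((h + 2) * (h + 1))
        h += 2
        probs[h] = p
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def hwe_exact_pvalue(counts: GenotypeCounts | tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg test p-value for one site's genotype counts.

    Invariant under allele relabelling; equals 1 for monomorphic sites.
    """
    a, b, c = counts
    counts = GenotypeCounts(a, b, c)
    n = a + b + c
    if n == 0:
        raise ValueError("no genotypes: all counts are zero")
    n_minor = min(2 * a + b, 2 * c + b)
    probs = _het_probabilities(n_minor, n)
    p_obs = probs[b]
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + _TIE_EPS))
    return min(1.0, p)


def genotype_count_matrix(dataset: CohortDataset) -> np.ndarray:
    """(n_variants, 3) matrix of HOM_REF/HET/HOM_ALT counts."""
    out = np.empty((dataset.n_variants, 3), dtype=np.int64)
    for code, col in ((HOM_REF, 0), (HET, 1), (HOM_ALT, 2)):
        out[:, col] = np.count_nonzero(dataset.gt == code, axis=1)
    return out


def hwe_pvalues(dataset: CohortDataset) -> np.ndarray:
    """Per-variant exact HWE p-values (NaN where no genotype is called)."""
    counts = genotype_count_matrix(dataset)
    out = np.full(dataset.n_variants, np.nan)
    for i, (a, b, c) in enumerate(counts):
        if a + b + c > 0:
            out[i] = hwe_exact_pvalue((int(a), int(b), int(c)))
    return out


def hwe_filter(
    dataset: CohortDataset, alpha: float = 0.05
) -> tuple[CohortDataset, list[VariantSite]]:
    """Remove variants whose exact HWE p ≤ alpha / N (Bonferroni), where N
    is the number of variants with at least one called genotype."""
    pvals = hwe_pvalues(dataset)
    n_tested = int(np.count_nonzero(~np.isnan(pvals)))
    if n_tested == 0:
        return dataset.copy(), []
    threshold = alpha / n_tested
    remove = ~np.isnan(pvals) & (pvals <= threshold)
    removed = [dataset.variant(i) for i in np.flatnonzero(remove)]
    return dataset.subset_variants(~remove), removed


def average_gq(variant: VariantSite) -> float:
    """Mean GQ over called genotypes at one site."""
    called = variant.gt >= 0
    if not called.any():
        raise UndefinedMetricError(f"{variant.key}: no called genotypes")
    return float(variant.gq[called].mean())


def call_rate(variant: VariantSite) -> float:
    """Fraction of cohort samples with a called genotype."""
    if len(variant.samples) == 0:
        raise UndefinedMetricError("cohort has no samples")
    return variant.n_called / len(variant.samples)


def average_gq_array(dataset: CohortDataset) -> np.ndarray:
    """Per-variant mean GQ over called genotypes (NaN when none called)."""
    called = dataset.called_mask()
    n_called = called.sum(axis=1)
    total = np.where(called, dataset.gq, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, total / n_called, np.nan)


def call_rate_array(dataset: CohortDataset) -> np.ndarray:
    return dataset.called_mask().sum(axis=1) / dataset.n_samples


VQSR_POSITIONS = ("after_manual", "before_manual", "off")


@dataclass(frozen=True)
class FilterThresholds:
    """All cascade thresholds with the study defaults."""

    min_dp: int = 8
    min_gq: int = 20
    hwe_alpha: float = 0.05
    min_avg_gq: float = 35.0
    min_call_rate: float = 0.88
    vqsr_position: str = "after_manual"

    def __post_init__(self) -> None:
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must lie in [0, 1]")
        if not 0 < self.hwe_alpha <= 1:
            raise ValueError("hwe_alpha must lie in (0, 1]")
        if self.vqsr_position not in VQSR_POSITIONS:
            raise ValueError(f"vqsr_position must be one of {VQSR_POSITIONS}")
        if self.min_dp < 0 or self.min_gq < 0 or self.min_avg_gq < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class VariantFilterReport:
    """Per-stage removal counts, in application order."""

    n_input: int
    stages: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return self.n_input - sum(n for _, n in self.stages)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stages": [{"filter": name, "n_removed": n} for name, n in self.stages],
            "n_surviving": self.n_surviving,
        }


def apply_vqsr(dataset: CohortDataset) -> tuple[CohortDataset, list[VariantSite]]:
    """Keep variants carrying a passing upstream VQSR verdict."""
    remove = ~dataset.vqsr_pass
    removed = [dataset.variant(i) for i in np.flatnonzero(remove)]
    return dataset.subset_variants(~remove), removed


def _metric_filter(dataset: CohortDataset, metric: np.ndarray, threshold: float) -> np.ndarray:
    """Keep-mask for "metric ≥ threshold"; NaN (no called genotypes) fails
    any positive threshold."""
    with np.errstate(invalid="ignore"):
        keep = metric >= threshold
    if threshold <= 0:
        keep |= np.isnan(metric)
    return keep


def apply_variant_filters(
    dataset: CohortDataset, thresholds: FilterThresholds | None = None
) -> tuple[CohortDataset, VariantFilterReport]:
    """Run the site-level cascade in the configured order.

    Genotype-level filtering is assumed to have been applied already:
    every metric here is computed over post-masking genotypes.
    """
    thr = thresholds or FilterThresholds()
    report = VariantFilterReport(n_input=dataset.n_variants)
    current = dataset

    def _vqsr_stage(ds: CohortDataset) -> CohortDataset:
        ds, removed = apply_vqsr(ds)
        report.stages.append(("vqsr", len(removed)))
        return ds

    if thr.vqsr_position == "before_manual":
        current = _vqsr_stage(current)

    current, removed = hwe_filter(current, alpha=thr.hwe_alpha)
    report.stages.append(("hwe", len(removed)))

    keep = _metric_filter(current, average_gq_array(current), thr.min_avg_gq)
    report.stages.append(("avg_gq", int(np.count_nonzero(~keep))))
    current = current.subset_variants(keep)

    keep = _metric_filter(current, call_rate_array(current), thr.min_call_rate)
    report.stages.append(("call_rate", int(np.count_nonzero(~keep))))
    current = current.subset_variants(keep)

    if thr.vqsr_position == "after_manual":
        current = _vqsr_stage(current)

    return current, report
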