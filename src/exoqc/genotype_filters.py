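"""Genotype-level DP/GQ filtering and the probabilistic rationale behind
the default thresholds.

A called genotype is masked (set to MISSING) when its read depth or
Phred-scaled quality falls below threshold. Masking rather than deletion
means downstream call-rate computations see filtered genotypes as missing,
which is what the variant-level cascade relies on.

Default thresholds correspond to ~99% genotype confidence:

* ``min_dp = 8`` — a true heterozygote covered by 8 reads has probability
  2·(1/2)^8 ≈ 0.8% of showing only one allele (two-tailed binomial with
  each allele equally likely per read);
* ``min_gq = 20`` — Phred 20 means a 1% chance the call is wrong.

A called genotype lacking the DP (resp. GQ) field fails that filter
whenever the filter is active; pass ``None`` to disable a filter entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CohortDataset, HOM_REF, MISSING


def het_mono_probability(dp: int) -> float:
    """Two-tailed binomial probability that all ``dp`` reads of a true
    heterozygote carry the same allele, i.e. min(1, 2·(1/2)^dp)."""
    if dp < 1:
        raise ValueError(f"dp must be >= 1, got {dp}")
    return min(1.0, 2.0 * 0.5 ** dp)


def min_dp_for_confidence(max_mono_probability: float) -> int:
    """Smallest integer depth at which :func:`het_mono_probability` drops
    below ``max_mono_probability`` (e.g. 0.01 → 8 reads, 0.001 → 11)."""
    if not 0 < max_mono_probability <= 1:
        raise ValueError("max_mono_probability must lie in (0, 1]")
    dp = 1
    while het_mono_probability(dp) >= max_mono_probability:
        dp += 1
    return dp


def phred_accuracy(gq: float) -> float:
    """Genotype accuracy implied by a Phred-scaled quality: 1 − 10^(−gq/10)."""
    if gq < 0:
        raise ValueError(f"gq must be >= 0, got {gq}")
    return 1.0 - 10.0 ** (-gq / 10.0)


@dataclass(frozen=True)
class ClassMaskCounts:
    """Masking counts within one genotype class (reference or non-reference)."""

    n_before: int
    n_masked_dp: int
    n_masked_gq: int
    n_masked_total: int  # union of the two conditions, not their sum


@dataclass(frozen=True)
class GenotypeFilterReport:
    """Bookkeeping for one DP/GQ masking pass, split by genotype class."""

    ref: ClassMaskCounts
    nonref: ClassMaskCounts

    @property
    def n_genotypes_before(self) -> int:
        return self.ref.n_before + self.nonref.n_before

    @property
    def n_masked_dp(self) -> int:
        return self.ref.n_masked_dp + self.nonref.n_masked_dp

    @property
    def n_masked_gq(self) -> int:
        return self.ref.n_masked_gq + self.nonref.n_masked_gq

    @property
    def n_masked_total(self) -> int:
        return self.ref.n_masked_total + self.nonref.n_masked_total

    def to_dict(self) -> dict:
        return {
            "n_genotypes_before": self.n_genotypes_before,
            "n_masked_dp": self.n_masked_dp,
            "n_masked_gq": self.n_masked_gq,
            "n_masked_total": self.n_masked_total,
            "ref": vars(self.ref).copy(),
            "nonref": vars(self.nonref).copy(),
        }


def apply_genotype_filters(
    dataset: CohortDataset,
    min_dp: int | None = 8,
    min_gq: int | None = 20,
) -> tuple[CohortDataset, GenotypeFilterReport]:
    """Mask called genotypes with ``dp < min_dp`` or ``gq < min_gq``.

    ``None`` disables a filter. An active filter also masks called
    genotypes whose field is absent (conservative). The variant set is
    unchanged; only genotypes are set to MISSING.
    """
    if (min_dp is not None and min_dp < 0) or (min_gq is not None and min_gq < 0):
        raise ValueError("thresholds must be >= 0")
    called = dataset.called_mask()
    fail_dp = np.zeros_like(called)
    fail_gq = np.zeros_like(called)
    if min_dp is not None:
        fail_dp = called & ((dataset.dp < 0) | (dataset.dp < min_dp))
    if min_gq is not None:
        fail_gq = called & ((dataset.gq < 0) | (dataset.gq < min_gq))
    fail = fail_dp | fail_gq

    is_ref = dataset.gt == HOM_REF
    is_nonref = called & ~is_ref

    def _counts(cls_mask: np.ndarray) -> ClassMaskCounts:
        return ClassMaskCounts(
            n_before=int(np.count_nonzero(cls_mask)),
            n_masked_dp=int(np.count_nonzero(fail_dp & cls_mask)),
            n_masked_gq=int(np.count_nonzero(fail_gq & cls_mask)),
            n_masked_total=int(np.count_nonzero(fail & cls_mask)),
        )

    report = GenotypeFilterReport(ref=_counts(is_ref & called), nonref=_counts(is_nonref))

    out = dataset.copy()
    out.gt[fail] = MISSING
    out.dp[fail] = -1
    out.gq[fail] = -1
    return out, report
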