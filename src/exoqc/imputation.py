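"""Filtering of imputed genotype panels.

Imputed genotypes carry a per-genotype GQ (from the imputation engine's
genotype probabilities) and a per-variant allelic R². The filtering stage
masks genotypes below a GQ threshold (default 20, ~99% confidence), then
prunes variants the masking has made uninformative:

* ``no_genotype`` — every genotype at the site was masked;
* ``monoallelic`` — all surviving genotypes are homozygous for one and the
  same allele (all HOM_REF or all HOM_ALT);
* ``polymorphic`` — everything else.

The widely used alternative of keeping variants with R² > 0.3 is provided
for comparison; it acts on whole variants and leaves low-confidence
genotypes at well-imputed sites untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HET, HOM_ALT, HOM_REF, ImputedPanel, MISSING, VariantSite

POLYMORPHIC, MONOALLELIC, NO_GENOTYPE = "polymorphic", "monoallelic", "no_genotype"
CLASSES = (POLYMORPHIC, MONOALLELIC, NO_GENOTYPE)


@dataclass(frozen=True)
class ImputedGenotypeFilterReport:
    n_called_before: int
    n_masked_ref: int
    n_masked_nonref: int

    @property
    def n_masked_total(self) -> int:
        return self.n_masked_ref + self.n_masked_nonref

    def to_dict(self) -> dict:
        return {
            "n_called_before": self.n_called_before,
            "n_masked_ref": self.n_masked_ref,
            "n_masked_nonref": self.n_masked_nonref,
            "n_masked_total": self.n_masked_total,
        }


def filter_imputed_genotypes(
    panel: ImputedPanel, min_gq: int = 20
) -> tuple[ImputedPanel, ImputedGenotypeFilterReport]:
    """Mask imputed genotypes with GQ below threshold; variants untouched."""
    if min_gq < 0:
        raise ValueError("min_gq must be >= 0")
    called = panel.called_mask()
    fail = called & ((panel.gq < 0) | (panel.gq < min_gq)) if min_gq > 0 else np.zeros_like(called)
    report = ImputedGenotypeFilterReport(
        n_called_before=int(np.count_nonzero(called)),
        n_masked_ref=int(np.count_nonzero(fail & (panel.gt == HOM_REF))),
        n_masked_nonref=int(np.count_nonzero(fail & (panel.gt > HOM_REF))),
    )
    out = panel.subset_variants(np.arange(panel.n_variants))
    out.gt[fail] = MISSING
    out.gq[fail] = -1
    out.dp[fail] = -1
    return out, report


def _classify_row(gt_row: np.ndarray) -> str:
    called = gt_row[gt_row >= 0]
    if called.size == 0:
        return NO_GENOTYPE
    if np.all(called == HOM_REF) or np.all(called == HOM_ALT):
        return MONOALLELIC
    return POLYMORPHIC


def classify_imputed_variant(variant: VariantSite) -> str:
    """Class of one variant after GQ masking (see module docstring)."""
    return _classify_row(np.asarray(variant.gt))


def classify_all(panel: ImputedPanel) -> np.ndarray:
    """Per-variant class labels as an object array."""
    return np.array([_classify_row(panel.gt[i]) for i in range(panel.n_variants)], dtype=object)


@dataclass(frozen=True)
class ImputedVariantClassReport:
    n_polymorphic: int
    n_monoallelic: int
    n_no_genotype: int
    mean_r2: dict[str, float]  # NaN where the class is empty

    def to_dict(self) -> dict:
        return {
            "n_polymorphic": self.n_polymorphic,
            "n_monoallelic": self.n_monoallelic,
            "n_no_genotype": self.n_no_genotype,
            "mean_r2": dict(self.mean_r2),
        }


def _class_report(panel: ImputedPanel, labels: np.ndarray) -> ImputedVariantClassReport:
    mean_r2 = {}
    counts = {}
    for cls in CLASSES:
        mask = labels == cls
        counts[cls] = int(np.count_nonzero(mask))
        mean_r2[cls] = float(panel.r2[mask].mean()) if counts[cls] else float("nan")
    return ImputedVariantClassReport(
        n_polymorphic=counts[POLYMORPHIC],
        n_monoallelic=counts[MONOALLELIC],
        n_no_genotype=counts[NO_GENOTYPE],
        mean_r2=mean_r2,
    )


def prune_uninformative(panel: ImputedPanel) -> tuple[ImputedPanel, ImputedVariantClassReport]:
    """Drop monoallelic and no-genotype variants; report class counts and
    the mean R² per class."""
    labels = classify_all(panel)
    report = _class_report(panel, labels)
    return panel.subset_variants(labels == POLYMORPHIC), report


@dataclass(frozen=True)
class R2FilterReport:
    n_removed: int
    n_retained: int
    mean_r2_removed: float
    mean_r2_retained: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_removed", "n_retained", "mean_r2_removed", "mean_r2_retained")}


def r2_threshold_filter(
    panel: ImputedPanel, min_r2: float = 0.3
) -> tuple[ImputedPanel, R2FilterReport]:
    """Keep variants with R² strictly greater than ``min_r2``; genotypes
    are untouched."""
    if not 0 <= min_r2 <= 1:
        raise ValueError("min_r2 must lie in [0, 1]")
    keep = panel.r2 > min_r2
    report = R2FilterReport(
        n_removed=int(np.count_nonzero(~keep)),
        n_retained=int(np.count_nonzero(keep)),
        mean_r2_removed=float(panel.r2[~keep].mean()) if (~keep).any() else float("nan"),
        mean_r2_retained=float(panel.r2[keep].mean()) if keep.any() else float("nan"),
    )
    return panel.subset_variants(keep), report
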