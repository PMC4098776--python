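"""Threshold-selection sweeps.

Genotype sweeps re-run a single DP or GQ filter over a threshold grid and
track, relative to the unfiltered comparison, the percent of non-reference
discordant genotypes removed and non-reference concordant genotypes
retained (plus sensitivity/specificity of the filtered comparison).
Variant sweeps track Ti/Tv per stratum and truth-set retention as the
average-GQ or call-rate threshold rises. A threshold is then selected as
the largest grid value whose retention metric still meets a target —
the formalisation of "capture most of the quality gain while sacrificing
a minimal fraction of true variants".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concordance import concordance_report, metrics_from_counts, removal_fractions
from .errors import SelectionError, UndefinedMetricError
from .genotype_filters import apply_genotype_filters
from .model import ArrayGenotypes, CohortDataset, SiteSet
from .titv import titv_summary, truth_retention
from .variant_filters import average_gq_array, call_rate_array, _metric_filter

DEFAULT_GRIDS = {
    "dp": list(range(0, 31)),
    "gq": list(range(0, 61)),
    "avg_gq": list(range(0, 91)),
    "call_rate": [round(x, 2) for x in np.arange(0, 1.0001, 0.02)],
}


@dataclass(frozen=True)
class SweepCurve:
    """Named metric values along a strictly increasing threshold grid."""

    metric_name: str
    points: tuple[tuple[float, dict[str, float]], ...]

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("sweep thresholds must be strictly increasing")

    @property
    def thresholds(self) -> list[float]:
        return [t for t, _ in self.points]

    def series(self, name: str) -> list[float]:
        return [values[name] for _, values in self.points]

    def to_rows(self) -> list[dict]:
        return [{"threshold": t, **values} for t, values in self.points]


def _safe(callable_, default=float("nan")):
    try:
        return callable_()
    except UndefinedMetricError:
        return default


def sweep_genotype_thresholds(
    dataset: CohortDataset,
    array: ArrayGenotypes,
    which: str,
    grid: list[float] | None = None,
) -> SweepCurve:
    """Concordance-vs-loss curve for a single genotype filter (dp or gq)."""
    if which not in ("dp", "gq"):
        raise ValueError("which must be 'dp' or 'gq'")
    grid = DEFAULT_GRIDS[which] if grid is None else list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    baseline = concordance_report(dataset, array)
    points = []
    for t in grid:
        kwargs = {"min_dp": int(t), "min_gq": None} if which == "dp" else \
                 {"min_dp": None, "min_gq": int(t)}
        filtered, _ = apply_genotype_filters(dataset, **kwargs)
        table = concordance_report(filtered, array)
        frac = removal_fractions(baseline, table)
        metrics = metrics_from_counts(table)
        points.append((float(t), {
            "pct_nonref_discordant_removed": _safe(lambda: frac.nonref_discordant_removed),
            "pct_nonref_concordant_retained": _safe(lambda: 1.0 - frac.nonref_concordant_removed),
            "sensitivity": _safe(lambda: metrics.sensitivity),
            "specificity": _safe(lambda: metrics.specificity),
        }))
    return SweepCurve(metric_name=which, points=tuple(points))


def sweep_variant_metric(
    dataset: CohortDataset,
    which: str,
    grid: list[float] | None = None,
    known: SiteSet | None = None,
    truth: SiteSet | None = None,
) -> SweepCurve:
    """Ti/Tv and truth-retention curve for an average-GQ or call-rate filter."""
    if which not in ("avg_gq", "call_rate"):
        raise ValueError("which must be 'avg_gq' or 'call_rate'")
    grid = DEFAULT_GRIDS[which] if grid is None else list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    known = known if known is not None else SiteSet(frozenset())
    truth = truth if truth is not None else SiteSet(frozenset())
    metric = average_gq_array(dataset) if which == "avg_gq" else call_rate_array(dataset)
    points = []
    for t in grid:
        survivors = dataset.subset_variants(_metric_filter(dataset, metric, float(t)))
        summary = titv_summary(survivors, known, truth)
        points.append((float(t), {
            "n_variants": float(survivors.n_variants),
            "titv_all": summary.ratio("all"),
            "titv_known": summary.ratio("known"),
            "titv_novel": summary.ratio("novel"),
            "titv_truth": summary.ratio("truth"),
            "truth_retention": truth_retention(dataset, survivors, truth),
        }))
    return SweepCurve(metric_name=which, points=tuple(points))


def select_threshold(curve: SweepCurve, retention_metric: str, min_retention: float) -> float:
    """Largest grid threshold whose retention metric is still ≥ the target."""
    qualifying = [
        t for t, values in curve.points
        if retention_metric in values and values[retention_metric] >= min_retention
    ]
    if any(retention_metric not in values for _, values in curve.points):
        raise KeyError(f"curve lacks metric {retention_metric!r} at some point")
    if not qualifying:
        raise SelectionError(
            f"no threshold keeps {retention_metric} >= {min_retention}"
        )
    return max(qualifying)
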