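"""End-to-end orchestration: batch splitting, the full filter cascade, and
batched-vs-unbatched / filter-order comparisons.

Large exome studies accumulate samples under different capture designs and
chemistry versions; pooling them makes per-variant call rates heterogeneous
and lets a pooled call-rate filter discard variants that are perfectly well
covered within the batch whose design targets them. The batched pipeline
therefore splits the cohort, filters each batch independently (genotype
masking first, then the site-level cascade), and merges survivors: a
variant passing in at least one batch is kept, with genotypes taken from
the batches where it passed and set MISSING for samples of batches where
it failed or was absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .concordance import ConcordanceTable, concordance_report
from .errors import ValidationError
from .genotype_filters import GenotypeFilterReport, apply_genotype_filters
from .io import assign_batches
from .model import MISSING, ArrayGenotypes, CohortDataset, SiteSet, VariantKey
from .titv import TiTvSummary, titv_summary, tv_enrichment_pvalue
from .variant_filters import FilterThresholds, VariantFilterReport, apply_variant_filters


@dataclass
class PipelineConfig:
    """Everything one filtering run needs."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    batch_of: Mapping[str, str] | None = None  # sample -> batch label
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        thr = FilterThresholds(**data.get("thresholds", {}))
        return cls(thresholds=thr, batch_of=data.get("batch_of"), seed=data.get("seed", 0))


@dataclass
class PipelineResult:
    dataset: CohortDataset
    genotype_reports: dict[str, GenotypeFilterReport]
    variant_reports: dict[str, VariantFilterReport]

    def to_dict(self) -> dict:
        return {
            "genotype_reports": {b: r.to_dict() for b, r in self.genotype_reports.items()},
            "variant_reports": {b: r.to_dict() for b, r in self.variant_reports.items()},
            "n_variants_out": self.dataset.n_variants,
        }


def _run_cascade(
    dataset: CohortDataset, thresholds: FilterThresholds
) -> tuple[CohortDataset, GenotypeFilterReport, VariantFilterReport]:
    masked, greport = apply_genotype_filters(
        dataset, min_dp=thresholds.min_dp, min_gq=thresholds.min_gq
    )
    filtered, vreport = apply_variant_filters(masked, thresholds)
    return filtered, greport, vreport


def run_unbatched_pipeline(dataset: CohortDataset, config: PipelineConfig) -> PipelineResult:
    """Genotype masking followed by the site-level cascade on the pooled cohort."""
    filtered, greport, vreport = _run_cascade(dataset, config.thresholds)
    return PipelineResult(filtered, {"all": greport}, {"all": vreport})


def run_batched_pipeline(dataset: CohortDataset, config: PipelineConfig) -> PipelineResult:
    """Filter each batch independently and merge surviving variants.

    The merged output is the union, in input order, of variant keys passing
    in at least one batch; for each merged variant the genotypes come from
    the batches where it passed (post-masking) and are MISSING elsewhere.
    """
    batch_of = config.batch_of or dataset.batch_of
    if not batch_of:
        raise ValidationError("batched pipeline needs a sample->batch assignment")
    batches = assign_batches(dataset, batch_of)
    if any(b.n_samples == 0 for b in batches):
        raise ValidationError("a batch has zero samples")

    genotype_reports: dict[str, GenotypeFilterReport] = {}
    variant_reports: dict[str, VariantFilterReport] = {}
    filtered_batches: list[CohortDataset] = []
    for batch in batches:
        label = next(iter(batch.batch_of.values()))
        filtered, greport, vreport = _run_cascade(batch, config.thresholds)
        genotype_reports[label] = greport
        variant_reports[label] = vreport
        filtered_batches.append(filtered)

    surviving: set[VariantKey] = set()
    for fb in filtered_batches:
        surviving.update(fb.keys())
    keep_rows = [i for i, k in enumerate(dataset.keys()) if k in surviving]
    merged = dataset.subset_variants(np.array(keep_rows, dtype=int))
    merged.batch_of = dict(batch_of)
    # start fully missing; fill from batches where the variant passed
    merged.gt[:] = MISSING
    merged.dp[:] = -1
    merged.gq[:] = -1
    merged_row = {k: i for i, k in enumerate(merged.keys())}
    col = {s: j for j, s in enumerate(merged.samples)}
    for fb in filtered_batches:
        cols = np.array([col[s] for s in fb.samples], dtype=int)
        for i, key in enumerate(fb.keys()):
            row = merged_row[key]
            merged.gt[row, cols] = fb.gt[i]
            merged.dp[row, cols] = fb.dp[i]
            merged.gq[row, cols] = fb.gq[i]
    return PipelineResult(merged, genotype_reports, variant_reports)


@dataclass
class UniqueSetSummary:
    keys: list[VariantKey]
    titv: TiTvSummary
    concordance: ConcordanceTable | None

    @property
    def count(self) -> int:
        return len(self.keys)


@dataclass
class BatchComparisonReport:
    """Variants unique to the batched vs the unbatched run, with quality
    summaries for each unique set."""

    unique_to_batched: UniqueSetSummary
    unique_to_unbatched: UniqueSetSummary

    def to_dict(self) -> dict:
        def _side(s: UniqueSetSummary) -> dict:
            return {
                "count": s.count,
                "titv": s.titv.to_rows(),
                "concordance": s.concordance.to_dict() if s.concordance else None,
            }
        return {
            "unique_to_batched": _side(self.unique_to_batched),
            "unique_to_unbatched": _side(self.unique_to_unbatched),
        }


def compare_batched_unbatched(
    batched: CohortDataset,
    unbatched: CohortDataset,
    known: SiteSet,
    array: ArrayGenotypes | None = None,
    truth: SiteSet | None = None,
) -> BatchComparisonReport:
    """Symmetric-difference summary of two filtered datasets from the same cohort."""
    truth = truth if truth is not None else SiteSet(frozenset())
    keys_b, keys_u = set(batched.keys()), set(unbatched.keys())

    def _summary(source: CohortDataset, unique: set[VariantKey]) -> UniqueSetSummary:
        rows = [i for i, k in enumerate(source.keys()) if k in unique]
        subset = source.subset_variants(np.array(rows, dtype=int))
        table = concordance_report(subset, array) if array is not None else None
        return UniqueSetSummary(
            keys=[source.keys()[i] for i in rows],
            titv=titv_summary(subset, known, truth),
            concordance=table,
        )

    return BatchComparisonReport(
        unique_to_batched=_summary(batched, keys_b - keys_u),
        unique_to_unbatched=_summary(unbatched, keys_u - keys_b),
    )


@dataclass
class OrderComparisonReport:
    """Effect of applying the VQSR verdict before vs after the manual filters."""

    n_survivors: dict[str, int]
    titv: dict[str, TiTvSummary]
    extra_removed: dict[str, list[VariantKey]]  # removed by this order only
    tv_enrichment_p: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_survivors": self.n_survivors,
            "titv": {k: v.to_rows() for k, v in self.titv.items()},
            "n_extra_removed": {k: len(v) for k, v in self.extra_removed.items()},
            "tv_enrichment_p": self.tv_enrichment_p,
        }


def compare_filter_orders(
    dataset: CohortDataset,
    config: PipelineConfig,
    known: SiteSet,
    truth: SiteSet,
) -> OrderComparisonReport:
    """Run the variant cascade under both VQSR orderings on the same
    genotype-masked input and test the extra removals of each order for
    transversion enrichment against the shared pre-filter pool."""
    masked, _ = apply_genotype_filters(
        dataset, min_dp=config.thresholds.min_dp, min_gq=config.thresholds.min_gq
    )
    pool = titv_summary(masked, known, truth)
    survivors: dict[str, CohortDataset] = {}
    for order in ("after_manual", "before_manual"):
        thr = FilterThresholds(
            min_dp=config.thresholds.min_dp, min_gq=config.thresholds.min_gq,
            hwe_alpha=config.thresholds.hwe_alpha,
            min_avg_gq=config.thresholds.min_avg_gq,
            min_call_rate=config.thresholds.min_call_rate,
            vqsr_position=order,
        )
        survivors[order], _ = apply_variant_filters(masked, thr)

    keys = {order: set(ds.keys()) for order, ds in survivors.items()}
    all_keys = set(masked.keys())
    removed = {order: all_keys - k for order, k in keys.items()}
    extra = {
        "after_manual": sorted(removed["after_manual"] - removed["before_manual"]),
        "before_manual": sorted(removed["before_manual"] - removed["after_manual"]),
    }
    key_ti = dict(zip(masked.keys(), (str(r) + str(a) for r, a in zip(masked.ref, masked.alt))))
    from .titv import is_transition  # local import avoids a cycle at module load

    enrichment = {}
    for order, keys_extra in extra.items():
        n_tv_removed = sum(1 for k in keys_extra if not is_transition(key_ti[k][0], key_ti[k][1]))
        enrichment[order] = tv_enrichment_pvalue(
            n_ti_before=pool.n_ti["all"],
            n_tv_before=pool.n_tv["all"],
            n_removed=len(keys_extra),
            n_tv_removed=n_tv_removed,
        )
    return OrderComparisonReport(
        n_survivors={order: ds.n_variants for order, ds in survivors.items()},
        titv={order: titv_summary(ds, known, truth) for order, ds in survivors.items()},
        extra_removed=extra,
        tv_enrichment_p=enrichment,
    )
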