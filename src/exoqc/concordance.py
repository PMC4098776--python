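"""Sequencing-vs-array genotype concordance with gold-standard semantics.

Each comparable (sample, site) pair — same sample, identical
(chrom, pos, ref, alt) key in both sources — is classified by
alternate-allele counting against the array call:

* identical homozygous-reference pair → TN
* identical heterozygous or homozygous-alternate pair → TP
* sequencing call has fewer alternate alleles than the array → FN
* sequencing call has more alternate alleles than the array → FP
* missing sequencing genotype → excluded from the comparison

Concordance is reported separately for array homozygous-reference
comparisons and array non-reference (het + hom-alt) comparisons, so that
the overwhelming mass of reference matches cannot inflate the headline
number. Excluding missing sequencing genotypes is what lets a genotype
filter "remove" discordant genotypes from the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .model import ArrayGenotypes, CohortDataset, HOM_REF, MISSING

logger = logging.getLogger(__name__)

TP, TN, FP, FN, EXCLUDED = "TP", "TN", "FP", "FN", "EXCLUDED"


def classify_genotype_pair(wes: int, array: int) -> str:
    """Classify one sequencing/array genotype pair (shared integer encoding;
    the code of a called genotype equals its alternate-allele count)."""
    if array not in (0, 1, 2):
        raise ValueError(f"array genotype cannot be missing/invalid: {array}")
    if wes == MISSING:
        return EXCLUDED
    if wes not in (0, 1, 2):
        raise ValueError(f"invalid sequencing genotype code: {wes}")
    if wes == array:
        return TN if array == HOM_REF else TP
    return FN if wes < array else FP


@dataclass(frozen=True)
class ConcordanceTable:
    """Pair-classification counts from one sequencing-vs-array comparison."""

    tp: int
    tn: int
    fp: int
    fn: int
    nonref_concordant: int
    nonref_discordant: int
    ref_concordant: int
    ref_discordant: int
    n_compared: int
    n_excluded: int = 0
    n_allele_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.tp + self.tn + self.fp + self.fn != self.n_compared:
            raise ValidationError("TP+TN+FP+FN must equal n_compared")
        if self.nonref_concordant != self.tp or self.ref_concordant != self.tn:
            raise ValidationError("concordant counts must mirror TP/TN")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tp", "tn", "fp", "fn", "nonref_concordant", "nonref_discordant",
            "ref_concordant", "ref_discordant", "n_compared", "n_excluded",
            "n_allele_mismatch",
        )}

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int,
                    nonref_discordant: int | None = None,
                    ref_discordant: int | None = None,
                    **kwargs) -> "ConcordanceTable":
        """Build a table from printed TP/TN/FP/FN counts. When the
        discordant split is not given, FN (resp. FP) is used — mismatches
        then land entirely in the array class their definition implies."""
        return cls(
            tp=tp, tn=tn, fp=fp, fn=fn,
            nonref_concordant=tp,
            nonref_discordant=fn if nonref_discordant is None else nonref_discordant,
            ref_concordant=tn,
            ref_discordant=fp if ref_discordant is None else ref_discordant,
            n_compared=tp + tn + fp + fn,
            **kwargs,
        )


def concordance_report(dataset: CohortDataset, array: ArrayGenotypes) -> ConcordanceTable:
    """Classify every (sample, site) pair present in both sources.

    Sites sharing (chrom, pos) but disagreeing on ref/alt are logged and
    excluded; sites absent from the sequencing dataset are not compared.
    """
    recs = array.records
    key_df = pd.DataFrame({
        "chrom": [k[0] for k in dataset.keys()],
        "pos": [k[1] for k in dataset.keys()],
        "ref": [k[2] for k in dataset.keys()],
        "alt": [k[3] for k in dataset.keys()],
        "_row": np.arange(dataset.n_variants),
    })
    merged = recs.merge(key_df, on=["chrom", "pos", "ref", "alt"], how="left")
    matched = merged["_row"].notna()
    # allele-mismatch accounting: same position present, different alleles
    pos_keys = set(zip(key_df["chrom"], key_df["pos"]))
    unmatched = merged[~matched]
    n_mismatch = int(sum(
        (c, p) in pos_keys for c, p in zip(unmatched["chrom"], unmatched["pos"])
    ))
    if n_mismatch:
        logger.warning("%d array records share a position but disagree on alleles; excluded",
                       n_mismatch)
    merged = merged[matched]
    col = {s: j for j, s in enumerate(dataset.samples)}
    in_cohort = merged["sample"].isin(col)
    merged = merged[in_cohort]
    rows = merged["_row"].to_numpy(dtype=int)
    cols = merged["sample"].map(col).to_numpy(dtype=int)
    wes = dataset.gt[rows, cols].astype(int)
    arr = merged["gt"].to_numpy(dtype=int)

    compared = wes != MISSING
    n_excluded = int(np.count_nonzero(~compared))
    wes, arr = wes[compared], arr[compared]
    eq = wes == arr
    arr_nonref = arr != HOM_REF
    tp = int(np.count_nonzero(eq & arr_nonref))
    tn = int(np.count_nonzero(eq & ~arr_nonref))
    fn = int(np.count_nonzero(~eq & (wes < arr)))
    fp = int(np.count_nonzero(~eq & (wes > arr)))
    return ConcordanceTable(
        tp=tp, tn=tn, fp=fp, fn=fn,
        nonref_concordant=tp,
        nonref_discordant=int(np.count_nonzero(~eq & arr_nonref)),
        ref_concordant=tn,
        ref_discordant=int(np.count_nonzero(~eq & ~arr_nonref)),
        n_compared=int(eq.size),
        n_excluded=n_excluded,
        n_allele_mismatch=n_mismatch,
    )


class ConcordanceMetrics:
    """Derived fractions; each raises :class:`UndefinedMetricError` when its
    denominator is zero (only that metric becomes unavailable)."""

    def __init__(self, table: ConcordanceTable):
        self._t = table

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            raise UndefinedMetricError(f"{name} undefined: zero denominator")
        return num / den

    @property
    def sensitivity(self) -> float:
        return self._ratio(self._t.tp, self._t.tp + self._t.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return self._ratio(self._t.tn, self._t.tn + self._t.fp, "specificity")

    # Under alt-allele-count classification the array non-reference
    # concordance coincides with sensitivity (and reference with specificity).
    nonref_concordance = sensitivity
    ref_concordance = specificity

    def to_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity"):
            try:
                out[name] = getattr(self, name)
            except UndefinedMetricError:
                out[name] = None
        out["nonref_concordance"] = out["sensitivity"]
        out["ref_concordance"] = out["specificity"]
        return out


def metrics_from_counts(table: ConcordanceTable) -> ConcordanceMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and the matching
    concordance fractions, from an already-aggregated table."""
    return ConcordanceMetrics(table)


class RemovalFractions:
    """Fractions of concordant/discordant comparisons removed between two
    tables (e.g. before and after a filter)."""

    def __init__(self, before: ConcordanceTable, after: ConcordanceTable):
        for fieldname in ("nonref_concordant", "nonref_discordant",
                          "ref_concordant", "ref_discordant"):
            if getattr(after, fieldname) > getattr(before, fieldname):
                raise ValidationError(f"{fieldname} grew between tables")
        self._b, self._a = before, after

    def _frac(self, fieldname: str) -> float:
        b = getattr(self._b, fieldname)
        if b == 0:
            raise UndefinedMetricError(f"no {fieldname} comparisons before filtering")
        return (b - getattr(self._a, fieldname)) / b

    @property
    def nonref_concordant_removed(self) -> float:
        return self._frac("nonref_concordant")

    @property
    def nonref_discordant_removed(self) -> float:
        return self._frac("nonref_discordant")

    @property
    def ref_concordant_removed(self) -> float:
        return self._frac("ref_concordant")

    @property
    def ref_discordant_removed(self) -> float:
        return self._frac("ref_discordant")

    def to_dict(self) -> dict:
        out = {}
        for name in ("nonref_concordant_removed", "nonref_discordant_removed",
                     "ref_concordant_removed", "ref_discordant_removed"):
            try:
                out[name] = getattr(self, name)
            except UndefinedMetricError:
                out[name] = None
        return out


def removal_fractions(before: ConcordanceTable, after: ConcordanceTable) -> RemovalFractions:
    """Percent of concordant / discordant genotype comparisons a filter
    removed, per array genotype class."""
    return RemovalFractions(before, after)
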