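"""Transition/transversion accounting and the transversion-enrichment test.

Ti/Tv is a coarse but useful purity signal for exome variant sets: random
substitutions give a ratio of 0.5 (4 of the 12 ordered substitutions are
transitions) while high-quality exome SNV sets sit around 2.8–3.0, so a
filter that raises Ti/Tv is preferentially discarding artifacts.  Whether a
filter removes significantly more transversions than chance is assessed
with a one-tailed hypergeometric test on the pre-filter pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
from scipy.stats import hypergeom

from .errors import ValidationError
from .model import NUCLEOTIDES, CohortDataset, SiteSet, VariantKey, VariantSite

_TRANSITIONS = (frozenset("AG"), frozenset("CT"))

Variants = Union[CohortDataset, Iterable[VariantSite]]


def is_transition(ref: str, alt: str) -> bool:
    """True iff ref→alt is a purine↔purine or pyrimidine↔pyrimidine change."""
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"not nucleotides: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r})")
    return frozenset((ref, alt)) in _TRANSITIONS


def _keys_and_ti(variants: Variants) -> tuple[list[VariantKey], np.ndarray]:
    if isinstance(variants, CohortDataset):
        keys = variants.keys()
        ti = np.fromiter(
            (is_transition(str(r), str(a)) for r, a in zip(variants.ref, variants.alt)),
            dtype=bool, count=variants.n_variants,
        )
    else:
        sites = list(variants)
        keys = [v.key for v in sites]
        ti = np.fromiter((is_transition(v.ref, v.alt) for v in sites), dtype=bool, count=len(sites))
    return keys, ti


STRATA = ("all", "known", "novel", "truth")


@dataclass(frozen=True)
class TiTvSummary:
    """Transition/transversion counts per stratum (all/known/novel/truth)."""

    n_ti: dict[str, int]
    n_tv: dict[str, int]

    def ratio(self, stratum: str = "all") -> float:
        """Ti/Tv ratio; NaN when the stratum has no transversions."""
        tv = self.n_tv[stratum]
        return self.n_ti[stratum] / tv if tv else float("nan")

    def to_rows(self) -> list[dict]:
        return [
            {"stratum": s, "n_ti": self.n_ti[s], "n_tv": self.n_tv[s], "ratio": self.ratio(s)}
            for s in STRATA
        ]


def titv_summary(variants: Variants, known: SiteSet, truth: SiteSet) -> TiTvSummary:
    """Count transitions/transversions overall and within the known, novel
    (= not known) and truth strata. Each variant counts once."""
    keys, ti = _keys_and_ti(variants)
    in_known = known.member_mask(keys) if keys else np.zeros(0, dtype=bool)
    in_truth = truth.member_mask(keys) if keys else np.zeros(0, dtype=bool)
    masks = {"all": np.ones(len(keys), dtype=bool), "known": in_known,
             "novel": ~in_known, "truth": in_truth}
    n_ti = {s: int(np.count_nonzero(ti & m)) for s, m in masks.items()}
    n_tv = {s: int(np.count_nonzero(~ti & m)) for s, m in masks.items()}
    return TiTvSummary(n_ti=n_ti, n_tv=n_tv)


def tv_enrichment_pvalue(
    n_ti_before: int, n_tv_before: int, n_removed: int, n_tv_removed: int
) -> float:
    """One-tailed hypergeometric P(X ≥ n_tv_removed) for the number of
    transversions in a uniform draw of ``n_removed`` variants from a pool
    of ``n_ti_before`` transitions and ``n_tv_before`` transversions."""
    pool = n_ti_before + n_tv_before
    if min(n_ti_before, n_tv_before, n_removed, n_tv_removed) < 0:
        raise ValueError("counts must be non-negative")
    if n_removed > pool:
        raise ValueError("more variants removed than in the pool")
    if n_tv_removed > min(n_removed, n_tv_before):
        raise ValueError("n_tv_removed exceeds what the pool allows")
    if n_removed - n_tv_removed > n_ti_before:
        raise ValueError("implied transition removals exceed the pool")
    if n_tv_removed == 0:
        return 1.0  # the upper tail from zero is certain
    # sf(k-1) = P(X >= k) for the upper tail
    return float(hypergeom.sf(n_tv_removed - 1, pool, n_tv_before, n_removed))


def truth_retention(variants_before: Variants, variants_after: Variants, truth: SiteSet) -> float:
    """Fraction of truth-set variants surviving a filtering step.

    Returns 1.0 (by convention) when the input contains no truth variants.
    """
    keys_before, _ = _keys_and_ti(variants_before)
    keys_after, _ = _keys_and_ti(variants_after)
    after_set = set(keys_after)
    if not after_set <= set(keys_before):
        raise ValidationError("variants_after is not a subset of variants_before")
    n_before = sum(1 for k in keys_before if k in truth)
    if n_before == 0:
        return 1.0
    n_after = sum(1 for k in after_set if k in truth)
    return n_after / n_before
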