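"""Core data model for exome QC.

Genotypes are unphased, unordered diploid calls at biallelic SNVs, encoded
as small integers for vectorised work:

* ``HOM_REF = 0`` — two reference alleles
* ``HET = 1`` — one reference, one alternate allele
* ``HOM_ALT = 2`` — two alternate alleles
* ``MISSING = -1`` — no call (a genotype is missing as a unit; half calls
  are coerced to MISSING at parse time)

The encoding doubles as the alternate-allele count for called genotypes,
which the concordance classifier exploits.  Per-genotype read depth (DP)
and Phred-scaled genotype quality (GQ) use ``-1`` for "absent".

A :class:`CohortDataset` stores the cohort as dense ``(n_variants,
n_samples)`` matrices; :class:`VariantSite` and :class:`GenotypeCall` are
lightweight per-site / per-call views over those matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

# Genotype codes.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_CODES = (HOM_REF, HET, HOM_ALT, MISSING)
GENOTYPE_NAMES = {HOM_REF: "HOM_REF", HET: "HET", HOM_ALT: "HOM_ALT", MISSING: "MISSING"}
GENOTYPE_BY_NAME = {name: code for code, name in GENOTYPE_NAMES.items()}

NUCLEOTIDES = frozenset("ACGT")

#: Variant identity: (chrom, pos, ref, alt) with 1-based VCF positions.
VariantKey = tuple[str, int, str, str]


def _as_genotype_code(value: int) -> int:
    code = int(value)
    if code not in GENOTYPE_CODES:
        raise ValidationError(f"invalid genotype code {value!r}")
    return code


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's called genotype at one site, with optional DP and GQ."""

    sample_id: str
    code: int
    dp: int | None = None
    gq: int | None = None

    def __post_init__(self) -> None:
        _as_genotype_code(self.code)
        if self.dp is not None and self.dp < 0:
            raise ValidationError(f"negative DP {self.dp}")
        if self.gq is not None and self.gq < 0:
            raise ValidationError(f"negative GQ {self.gq}")

    @property
    def alleles(self) -> tuple[str, str]:
        """Unordered allele pair as symbolic labels (REF/ALT/MISSING)."""
        return {
            HOM_REF: ("REF", "REF"),
            HET: ("REF", "ALT"),
            HOM_ALT: ("ALT", "ALT"),
            MISSING: ("MISSING", "MISSING"),
        }[self.code]

    @property
    def is_missing(self) -> bool:
        return self.code == MISSING

    @property
    def alt_allele_count(self) -> int | None:
        return None if self.code == MISSING else self.code


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV with its per-sample genotype, DP and GQ vectors.

    This is a read-only view onto one row of a :class:`CohortDataset`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vqsr_pass: bool
    samples: tuple[str, ...]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def genotypes(self) -> list[GenotypeCall]:
        calls = []
        for j, sample in enumerate(self.samples):
            dp = None if self.dp[j] < 0 else int(self.dp[j])
            gq = None if self.gq[j] < 0 else int(self.gq[j])
            if self.gt[j] == MISSING:
                dp = gq = None
            calls.append(GenotypeCall(sample, int(self.gt[j]), dp=dp, gq=gq))
        return calls

    @property
    def n_called(self) -> int:
        return int(np.count_nonzero(self.gt >= 0))


def _validate_snv(ref: str, alt: str) -> None:
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValidationError(f"not a single-nucleotide allele pair: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref!r})")


@dataclass(eq=False)
class CohortDataset:
    """Sample roster plus an ordered collection of biallelic SNVs.

    ``gt``, ``dp`` and ``gq`` are ``(n_variants, n_samples)`` integer
    matrices; ``-1`` marks a missing genotype / absent field.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    vqsr_pass: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    batch_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.vqsr_pass = np.asarray(self.vqsr_pass, dtype=bool)
        n_var = len(self.chrom)
        for name in ("pos", "ref", "alt", "vqsr_pass"):
            if len(getattr(self, name)) != n_var:
                raise ValidationError(f"{name} length mismatch")
        shape = (n_var, len(self.samples))
        for name in ("gt", "dp", "gq"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValidationError(f"{name} shape {arr.shape} != {shape}")
            setattr(self, name, arr)
        self.gt = self.gt.astype(np.int8, copy=False)
        self.dp = self.dp.astype(np.int32, copy=False)
        self.gq = self.gq.astype(np.int32, copy=False)
        for r, a in zip(self.ref, self.alt):
            _validate_snv(str(r), str(a))
        if np.any(self.pos < 1):
            raise ValidationError("positions must be 1-based (>= 1)")
        keys = self.keys()
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate variant keys")
        if self.batch_of is not None:
            unknown = set(self.batch_of) - set(self.samples)
            if unknown:
                raise ValidationError(f"batch table lists unknown samples: {sorted(unknown)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.chrom)

    def keys(self) -> list[VariantKey]:
        return [
            (str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(self.chrom, self.pos, self.ref, self.alt)
        ]

    @cached_property
    def key_index(self) -> dict[VariantKey, int]:
        return {key: i for i, key in enumerate(self.keys())}

    # -- views ----------------------------------------------------------
    def variant(self, i: int) -> VariantSite:
        return VariantSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alt=str(self.alt[i]),
            vqsr_pass=bool(self.vqsr_pass[i]),
            samples=tuple(self.samples),
            gt=self.gt[i],
            dp=self.dp[i],
            gq=self.gq[i],
        )

    def variants(self) -> Iterator[VariantSite]:
        for i in range(self.n_variants):
            yield self.variant(i)

    def called_mask(self) -> np.ndarray:
        return self.gt >= 0

    # -- subsetting -----------------------------------------------------
    def subset_variants(self, index: np.ndarray) -> "CohortDataset":
        """New dataset restricted to the given variant rows (mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortDataset(
            samples=list(self.samples),
            chrom=self.chrom[index].copy(),
            pos=self.pos[index].copy(),
            ref=self.ref[index].copy(),
            alt=self.alt[index].copy(),
            vqsr_pass=self.vqsr_pass[index].copy(),
            gt=self.gt[index].copy(),
            dp=self.dp[index].copy(),
            gq=self.gq[index].copy(),
            batch_of=dict(self.batch_of) if self.batch_of else None,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CohortDataset":
        """New dataset restricted to the given sample columns (order preserved)."""
        wanted = list(sample_ids)
        col = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in wanted if s not in col]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        idx = np.array([col[s] for s in wanted], dtype=int)
        batch_of = {s: self.batch_of[s] for s in wanted if s in self.batch_of} if self.batch_of else None
        return CohortDataset(
            samples=wanted,
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            vqsr_pass=self.vqsr_pass.copy(),
            gt=self.gt[:, idx].copy(),
            dp=self.dp[:, idx].copy(),
            gq=self.gq[:, idx].copy(),
            batch_of=batch_of,
        )

    def copy(self) -> "CohortDataset":
        return self.subset_variants(np.arange(self.n_variants))

    def equal_genotypes(self, other: "CohortDataset") -> bool:
        """Field-for-field equality of samples, keys, GT, DP, GQ and VQSR verdicts."""
        return (
            self.samples == other.samples
            and self.keys() == other.keys()
            and np.array_equal(self.vqsr_pass, other.vqsr_pass)
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.gq, other.gq)
        )

    @classmethod
    def from_variant_records(
        cls,
        samples: list[str],
        records: list[dict],
        batch_of: dict[str, str] | None = None,
    ) -> "CohortDataset":
        """Build a dataset from per-variant dicts (keys: chrom, pos, ref, alt,
        vqsr_pass, gt, dp, gq). Convenience constructor for tests and fixtures."""
        n = len(records)
        s = len(samples)
        chrom = np.array([r["chrom"] for r in records], dtype=object)
        pos = np.array([r["pos"] for r in records], dtype=np.int64)
        ref = np.array([r["ref"] for r in records], dtype=object)
        alt = np.array([r["alt"] for r in records], dtype=object)
        vqsr = np.array([r.get("vqsr_pass", True) for r in records], dtype=bool)
        gt = np.full((n, s), MISSING, dtype=np.int8)
        dp = np.full((n, s), -1, dtype=np.int32)
        gq = np.full((n, s), -1, dtype=np.int32)
        for i, r in enumerate(records):
            gt[i] = r["gt"]
            if "dp" in r:
                dp[i] = r["dp"]
            if "gq" in r:
                gq[i] = r["gq"]
        return cls(samples, chrom, pos, ref, alt, vqsr, gt, dp, gq, batch_of=batch_of)


class ImputedPanel(CohortDataset):
    """A cohort of imputed genotypes with a per-variant allelic R² annotation."""

    def __init__(self, *args, r2: np.ndarray, **kwargs):
        super().__init__(*args, **kwargs)
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (self.n_variants,):
            raise ValidationError("r2 length mismatch")
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValidationError("r2 must lie in [0, 1]")
        self.r2 = r2

    def subset_variants(self, index: np.ndarray) -> "ImputedPanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        base = CohortDataset.subset_variants(self, index)
        return ImputedPanel(
            base.samples, base.chrom, base.pos, base.ref, base.alt,
            base.vqsr_pass, base.gt, base.dp, base.gq,
            batch_of=base.batch_of, r2=self.r2[index].copy(),
        )


@dataclass(frozen=True)
class SiteSet:
    """A set of variant keys, used for dbSNP-style "known" and HapMap-style
    "truth" membership."""

    keys: frozenset[VariantKey]

    @classmethod
    def from_keys(cls, keys: Iterable[VariantKey]) -> "SiteSet":
        return cls(frozenset((str(c), int(p), str(r), str(a)) for c, p, r, a in keys))

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    def member_mask(self, keys: Iterable[VariantKey]) -> np.ndarray:
        return np.fromiter((k in self.keys for k in keys), dtype=bool)


EMPTY_SITE_SET = SiteSet(frozenset())


@dataclass
class ArrayGenotypes:
    """Gold-standard array genotypes with GenCall confidence scores.

    Backed by a DataFrame with columns ``sample, chrom, pos, ref, alt,
    gt, gencall_score`` where ``gt`` uses the shared genotype encoding
    (array genotypes are never missing).
    """

    records: pd.DataFrame
    min_gencall: float = 0.0

    REQUIRED = ("sample", "chrom", "pos", "ref", "alt", "gt", "gencall_score")

    def __post_init__(self) -> None:
        df = self.records
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"array genotypes missing column {col!r}")
        if not df["gt"].isin([HOM_REF, HET, HOM_ALT]).all():
            raise ValidationError("array genotypes must be HOM_REF/HET/HOM_ALT")
        if ((df["gencall_score"] < 0) | (df["gencall_score"] > 1)).any():
            raise ValidationError("gencall_score must lie in [0, 1]")
        if (df["gencall_score"] < self.min_gencall).any():
            raise ValidationError("record below the configured GenCall minimum")
        dup = df.duplicated(subset=["sample", "chrom", "pos", "ref", "alt"])
        if dup.any():
            raise ValidationError("duplicate (sample, site) array records")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def filter_gencall(self, min_gencall: float) -> "ArrayGenotypes":
        kept = self.records[self.records["gencall_score"] >= min_gencall]
        return ArrayGenotypes(kept.copy(), min_gencall=min_gencall)
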