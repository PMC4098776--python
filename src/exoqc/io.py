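"""Readers and writers for the file formats the toolkit touches.

* multi-sample VCF 4.x with GT/DP/GQ FORMAT fields (read via cyvcf2, which
  also handles gzip/bgzip input); the FILTER column carries the upstream
  VQSR verdict — ``PASS`` or ``.`` map to ``vqsr_pass=True``, anything
  else to ``False``
* array gold-standard genotypes, site sets and sample→batch assignments
  as headered TSV (optionally gzipped)

Coordinates are 1-based VCF positions throughout. Only biallelic SNVs are
modelled: indels and symbolic alleles are skipped with a logged count and
multiallelic records are either split into one site per ALT (other ALT
alleles recoded as REF, as ``bcftools norm -m-`` does) or skipped,
depending on ``split_multiallelic``.
"""

from __future__ import annotations

import gzip
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import TableParseError, ValidationError, VcfParseError
from .model import (
    MISSING,
    NUCLEOTIDES,
    ArrayGenotypes,
    CohortDataset,
    GENOTYPE_BY_NAME,
    GENOTYPE_NAMES,
    ImputedPanel,
    SiteSet,
)

logger = logging.getLogger(__name__)

GENCALL_DEFAULT_MIN = 0.30


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in NUCLEOTIDES and alt in NUCLEOTIDES


def _row_from_record(genotypes: list, alt_index: int, chrom: str, pos: int) -> tuple[np.ndarray, int]:
    """Diploid genotype codes for one ALT of one record.

    Returns (codes, n_half_missing). Alleles other than ``alt_index`` count
    as REF for the split site; a half-missing pair is coerced to MISSING.
    """
    codes = np.empty(len(genotypes), dtype=np.int8)
    half_missing = 0
    for j, g in enumerate(genotypes):
        if len(g) != 3:  # cyvcf2: [allele, allele, phased] for diploid calls
            raise VcfParseError(f"{chrom}:{pos} sample #{j + 1}: GT ploidy != 2")
        a, b = g[0], g[1]
        if a < 0 and b < 0:
            codes[j] = MISSING
        elif a < 0 or b < 0:
            codes[j] = MISSING
            half_missing += 1
        else:
            codes[j] = (a == alt_index) + (b == alt_index)
    return codes, half_missing


def _format_ints(variant, field: str, n: int) -> np.ndarray:
    """Per-sample integer FORMAT values with -1 for absent/missing."""
    raw = variant.format(field)
    if raw is None:
        return np.full(n, -1, dtype=np.int32)
    vals = np.asarray(raw).reshape(n, -1)[:, 0].astype(np.int64)
    vals[vals < 0] = -1  # htslib missing sentinel is a large negative int
    return vals.astype(np.int32)


def read_vcf(path: str, split_multiallelic: bool = True) -> CohortDataset:
    """Read a VCF 4.x into a :class:`CohortDataset` of biallelic SNVs."""
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib reports header problems on open
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    vqsr: list[bool] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    n_skipped_nonsnv = 0
    n_skipped_multi = 0
    n_half_missing = 0
    record_no = 0
    try:
        for variant in vcf:
            record_no += 1
            alt_alleles = variant.ALT
            if len(alt_alleles) > 1 and not split_multiallelic:
                n_skipped_multi += 1
                continue
            is_pass = variant.FILTER is None  # cyvcf2: None for PASS and '.'
            dp = _format_ints(variant, "DP", n)
            gq = _format_ints(variant, "GQ", n)
            genotypes = variant.genotypes
            for k, alt in enumerate(alt_alleles):
                if not _is_snv(variant.REF, alt):
                    n_skipped_nonsnv += 1
                    continue
                codes, hm = _row_from_record(genotypes, k + 1, variant.CHROM, variant.POS)
                n_half_missing += hm
                chroms.append(variant.CHROM)
                poss.append(variant.POS)
                refs.append(variant.REF)
                alts.append(alt)
                vqsr.append(is_pass)
                gts.append(codes)
                dps.append(dp)
                gqs.append(gq)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed record #{record_no + 1}: {exc}") from exc
    if n_skipped_nonsnv:
        logger.info("%s: skipped %d non-SNV ALT alleles", path, n_skipped_nonsnv)
    if n_skipped_multi:
        logger.info("%s: skipped %d multiallelic records", path, n_skipped_multi)
    if n_half_missing:
        logger.info("%s: coerced %d half-missing genotypes to MISSING", path, n_half_missing)
    n_var = len(chroms)
    shape = (n_var, n)
    dataset = CohortDataset(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        vqsr_pass=np.array(vqsr, dtype=bool),
        gt=np.vstack(gts).astype(np.int8) if n_var else np.empty(shape, dtype=np.int8),
        dp=np.vstack(dps).astype(np.int32) if n_var else np.empty(shape, dtype=np.int32),
        gq=np.vstack(gqs).astype(np.int32) if n_var else np.empty(shape, dtype=np.int32),
    )
    # Masked genotypes carry no DP/GQ.
    dataset.dp[dataset.gt == MISSING] = -1
    dataset.gq[dataset.gt == MISSING] = -1
    return dataset


VQSR_FAIL_LABEL = "VQSR_FAIL"
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(dataset: CohortDataset, path: str, extra_info: Mapping[int, str] | None = None) -> None:
    """Write a dataset as VCF 4.2 so that ``read_vcf`` round-trips GT, DP,
    GQ and the VQSR verdict exactly.

    ``extra_info`` optionally maps variant row index → INFO string.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=%s,Description="Failed upstream VQSR">\n' % VQSR_FAIL_LABEL)
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation allelic R-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        seen: list[str] = []
        for c in dataset.chrom:
            if c not in seen:
                seen.append(str(c))
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.samples) + "\n")
        for i in range(dataset.n_variants):
            filt = "PASS" if dataset.vqsr_pass[i] else VQSR_FAIL_LABEL
            info = extra_info.get(i, ".") if extra_info else "."
            fields = [
                str(dataset.chrom[i]), str(dataset.pos[i]), ".",
                str(dataset.ref[i]), str(dataset.alt[i]), ".", filt, info, "GT:DP:GQ",
            ]
            for j in range(dataset.n_samples):
                dp = dataset.dp[i, j]
                gq = dataset.gq[i, j]
                fields.append(
                    f"{_GT_STRINGS[int(dataset.gt[i, j])]}:"
                    f"{'.' if dp < 0 else int(dp)}:{'.' if gq < 0 else int(gq)}"
                )
            fh.write("\t".join(fields) + "\n")


def write_imputed_vcf(panel: ImputedPanel, path: str) -> None:
    """Write an imputed panel with per-variant R2 INFO annotations."""
    info = {i: f"R2={panel.r2[i]:.6g}" for i in range(panel.n_variants)}
    write_vcf(panel, path, extra_info=info)


def read_imputed_vcf(path: str) -> ImputedPanel:
    """Read a VCF carrying per-variant R2 INFO annotations."""
    dataset = read_vcf(path, split_multiallelic=True)
    r2 = np.empty(dataset.n_variants, dtype=float)
    vcf = VCF(str(path))
    i = 0
    for variant in vcf:
        for alt in variant.ALT:
            if not _is_snv(variant.REF, alt):
                continue
            val = variant.INFO.get("R2")
            if val is None:
                raise VcfParseError(f"{path}: {variant.CHROM}:{variant.POS} lacks R2 INFO")
            r2[i] = float(val)
            i += 1
    return ImputedPanel(
        dataset.samples, dataset.chrom, dataset.pos, dataset.ref, dataset.alt,
        dataset.vqsr_pass, dataset.gt, dataset.dp, dataset.gq, r2=r2,
    )


def _read_tsv(path: str, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    except Exception as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    return df


def read_array_genotypes(path: str, min_gencall: float = GENCALL_DEFAULT_MIN) -> ArrayGenotypes:
    """Read array gold-standard genotypes, dropping records below the
    GenCall score threshold (default 0.30)."""
    df = _read_tsv(path, ("sample", "chrom", "pos", "ref", "alt", "genotype", "gencall_score"))
    unknown = set(df["genotype"].unique()) - set(GENOTYPE_BY_NAME) - {"MISSING"}
    if unknown:
        raise TableParseError(f"{path}: unknown genotype tokens {sorted(unknown)}")
    if (df["genotype"] == "MISSING").any():
        raise TableParseError(f"{path}: array genotypes may not be MISSING")
    dup = df.duplicated(subset=["sample", "chrom", "pos", "ref", "alt"])
    if dup.any():
        raise TableParseError(f"{path}: duplicate (sample, site) records")
    n_before = len(df)
    kept = df[df["gencall_score"] >= min_gencall].copy()
    logger.info("%s: %d of %d array records retained at GenCall >= %g",
                path, len(kept), n_before, min_gencall)
    kept["gt"] = kept["genotype"].map(GENOTYPE_BY_NAME).astype(np.int8)
    kept["pos"] = kept["pos"].astype(np.int64)
    return ArrayGenotypes(
        kept[["sample", "chrom", "pos", "ref", "alt", "gt", "gencall_score"]],
        min_gencall=min_gencall,
    )


def write_array_genotypes(array: ArrayGenotypes, path: str) -> None:
    df = array.records.copy()
    df["genotype"] = df["gt"].map(GENOTYPE_NAMES)
    df[["sample", "chrom", "pos", "ref", "alt", "genotype", "gencall_score"]].to_csv(
        path, sep="\t", index=False
    )


def read_site_set(path: str) -> SiteSet:
    """Read a TSV of (chrom, pos, ref, alt) keys into a :class:`SiteSet`."""
    df = _read_tsv(path, ("chrom", "pos", "ref", "alt"))
    if len(df) and (df["pos"] < 1).any():
        raise TableParseError(f"{path}: positions must be 1-based (>= 1)")
    return SiteSet.from_keys(
        zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"])
    )


def write_site_set(sites: SiteSet, path: str) -> None:
    df = pd.DataFrame(sorted(sites.keys), columns=["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)


def read_batch_table(path: str) -> dict[str, str]:
    """Read a sample→batch TSV (columns ``sample`` and ``batch``)."""
    df = _read_tsv(path, ("sample", "batch"))
    if df["sample"].duplicated().any():
        raise TableParseError(f"{path}: sample assigned to more than one batch")
    return dict(zip(df["sample"].astype(str), df["batch"].astype(str)))


def assign_batches(dataset: CohortDataset, table: str | Mapping[str, str]) -> list[CohortDataset]:
    """Split a cohort into per-batch datasets whose sample sets partition it.

    Every sample must be assigned exactly once; unknown or missing samples
    are errors.  Each batch keeps every variant, restricted to the batch's
    genotype columns. Batches are returned in sorted label order.
    """
    mapping = read_batch_table(table) if isinstance(table, str) else dict(table)
    unknown = set(mapping) - set(dataset.samples)
    if unknown:
        raise ValidationError(f"batch table lists unknown samples: {sorted(unknown)}")
    unassigned = set(dataset.samples) - set(mapping)
    if unassigned:
        raise ValidationError(f"samples missing from batch table: {sorted(unassigned)}")
    batches: dict[str, list[str]] = {}
    for sample in dataset.samples:  # preserve cohort sample order within batches
        batches.setdefault(mapping[sample], []).append(sample)
    out = []
    for label in sorted(batches):
        sub = dataset.subset_samples(batches[label])
        sub.batch_of = {s: label for s in batches[label]}
        out.append(sub)
    return out
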