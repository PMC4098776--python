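"""Synthetic cohorts with known truth for exercising every filter.

The generator emulates the statistical structure the filters assume:

* a rare-skewed minor-allele-frequency spectrum with genotypes drawn under
  Hardy-Weinberg equilibrium, except a designated fraction of sites drawn
  with a heterozygote excess (negative inbreeding-like coefficient);
* a partition of sites into *true* variants (Ti/Tv ≈ 2.8, the expectation
  for clean exome SNV sets) and *false* artifact sites (Ti/Tv = 0.5, the
  random expectation, truly homozygous reference in every sample) whose
  coverage is low — so quality filters carry Ti/Tv signal;
* per-genotype read depth from a batch-specific gamma-Poisson model, with
  near-zero depth off the batch's capture target — so pooled call rates
  are heterogeneous across batches;
* per-genotype GQ increasing in depth, and genotype errors injected at
  exactly the Phred-implied rate 10^(−GQ/10), biased toward the adjacent
  genotype class (hom↔het more likely than hom-ref↔hom-alt);
* a VQSR-style verdict that fails artifact sites far more often than true
  sites;
* an array gold standard on a sample subset, with GenCall scores, and an
  imputed panel whose genotype quality falls with the variant's allelic R².

All randomness flows through one integer-seeded ``numpy`` generator, so a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    ArrayGenotypes,
    CohortDataset,
    HET,
    HOM_ALT,
    HOM_REF,
    ImputedPanel,
    MISSING,
    SiteSet,
)

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass(frozen=True)
class BatchSpec:
    """One processing batch: its share of samples and of batch-private
    target regions."""

    label: str
    sample_fraction: float
    private_target_fraction: float


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; the defaults are the conditions the filters
    were designed for (see docs/methods.md for the rationale)."""

    n_samples: int = 200
    n_variants: int = 20_000
    seed: int = 2026

    # site classes
    false_site_fraction: float = 0.15
    hwe_violating_fraction: float = 0.05
    hwe_inbreeding_f: float = -0.4          # heterozygote excess at violating sites
    hwe_violating_maf_range: tuple[float, float] = (0.3, 0.5)

    # minor-allele-frequency spectrum (true sites): 0.5 * Beta(a, b)
    maf_beta: tuple[float, float] = (0.3, 2.5)

    # batches and capture targets
    batches: tuple[BatchSpec, ...] = (
        BatchSpec("kit50mb", 0.75, 0.10),
        BatchSpec("kitV4", 0.25, 0.10),
    )

    # depth model (gamma-Poisson): mean/shape on-target, artifact sites, off-target
    depth_mean_on: float = 30.0
    depth_shape_on: float = 4.0
    depth_mean_false: float = 6.0
    depth_shape_false: float = 2.0
    depth_mean_off: float = 0.4

    # GQ model: gq = clip(round(gq_per_read * dp * lognormal(sigma)), 0, 99)
    gq_per_read: float = 3.0
    gq_sigma: float = 0.35

    # VQSR verdict
    vqsr_fail_true: float = 0.05
    vqsr_fail_false: float = 0.70

    # membership and substitution spectra
    known_fraction_true: float = 0.64
    known_fraction_false: float = 0.20
    truth_fraction: float = 0.50            # of known true sites
    titv_true: float = 2.8
    titv_false: float = 0.5

    # array gold standard
    array_n_samples: int = 10
    array_site_fraction: float = 0.4        # of known sites
    array_error_rate: float = 0.001
    gencall_low_fraction: float = 0.012

    # imputed panel
    imputed_n_variants: int = 4_000
    imputed_poor_fraction: float = 0.45
    imputed_good_r2_beta: tuple[float, float] = (8.0, 1.6)
    imputed_poor_r2_beta: tuple[float, float] = (1.0, 16.0)
    imputed_gq_scale: float = 50.0
    imputed_gq_sigma: float = 0.30
    imputed_maf_beta: tuple[float, float] = (0.25, 4.0)

    def __post_init__(self) -> None:
        for name in ("false_site_fraction", "hwe_violating_fraction", "vqsr_fail_true",
                     "vqsr_fail_false", "known_fraction_true", "known_fraction_false",
                     "truth_fraction", "array_site_fraction", "array_error_rate",
                     "gencall_low_fraction", "imputed_poor_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValidationError("n_samples and n_variants must be positive")
        if abs(sum(b.sample_fraction for b in self.batches) - 1.0) > 1e-9:
            raise ValidationError("batch sample fractions must sum to 1")
        if self.array_n_samples > self.n_samples:
            raise ValidationError("array subset larger than the cohort")
        if sum(b.private_target_fraction for b in self.batches) > 1.0 + 1e-9:
            raise ValidationError("private target fractions exceed 1")


@dataclass
class TruthBundle:
    """Ground truth accompanying a simulated dataset."""

    samples: list[str]
    keys: list[tuple[str, int, str, str]]
    true_gt: np.ndarray          # (n_variants, n_samples), MISSING never occurs
    error_mask: np.ndarray       # called genotype differs from truth
    labels: pd.DataFrame         # per-variant: site_class, hwe_violating, known, truth, maf
    on_target: dict[str, np.ndarray] = field(default_factory=dict)  # batch label -> bool
    array_sites: np.ndarray | None = None

    def known_sites(self) -> SiteSet:
        return SiteSet.from_keys(k for k, m in zip(self.keys, self.labels["known_member"]) if m)

    def truth_sites(self) -> SiteSet:
        return SiteSet.from_keys(k for k, m in zip(self.keys, self.labels["truth_member"]) if m)

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.copy()
        df.insert(0, "chrom", [k[0] for k in self.keys])
        df.insert(1, "pos", [k[1] for k in self.keys])
        df.insert(2, "ref", [k[2] for k in self.keys])
        df.insert(3, "alt", [k[3] for k in self.keys])
        for label, mask in self.on_target.items():
            df[f"on_target_{label}"] = mask
        return df


def _draw_ref_alt(rng: np.random.Generator, n: int, titv: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw ref/alt pairs with the requested transition/transversion ratio."""
    refs = np.array(list("ACGT"), dtype=object)[rng.integers(0, 4, size=n)]
    is_ti = rng.random(n) < titv / (1.0 + titv)
    alts = np.empty(n, dtype=object)
    pick = rng.integers(0, 2, size=n)
    for i in range(n):
        r = refs[i]
        alts[i] = _TRANSITION_PARTNER[r] if is_ti[i] else _TRANSVERSION_PARTNERS[r][pick[i]]
    return refs, alts


def _draw_genotypes(rng: np.random.Generator, maf: np.ndarray, f: np.ndarray,
                    n_samples: int) -> np.ndarray:
    """HWE genotypes with an optional inbreeding-like distortion F per site:
    P(het) = 2pq(1−F), homozygotes absorb the difference symmetrically."""
    q = maf
    p = 1.0 - q
    p_het = np.clip(2 * p * q * (1 - f), 0, 1)
    p_hom_alt = np.clip(q * q + p * q * f, 0, 1)
    u = rng.random((len(maf), n_samples))
    gt = np.zeros((len(maf), n_samples), dtype=np.int8)
    gt[u < (p_het + p_hom_alt)[:, None]] = HET
    gt[u < p_hom_alt[:, None]] = HOM_ALT
    return gt


def _corrupt(rng: np.random.Generator, gt: np.ndarray, err_mask: np.ndarray) -> np.ndarray:
    """Flip erroneous genotypes toward the adjacent class (hom↔het favoured
    9:1 over hom-ref↔hom-alt; het errors split evenly between homozygotes)."""
    out = gt.copy()
    u = rng.random(gt.shape)
    hr = err_mask & (gt == HOM_REF)
    out[hr] = np.where(u[hr] < 0.9, HET, HOM_ALT)
    het = err_mask & (gt == HET)
    out[het] = np.where(u[het] < 0.5, HOM_REF, HOM_ALT)
    ha = err_mask & (gt == HOM_ALT)
    out[ha] = np.where(u[ha] < 0.9, HET, HOM_REF)
    return out


def _largest_remainder_counts(fractions: list[float], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(total - sum(counts)):
        counts[remainders[i % len(raw)]] += 1
    return counts


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[CohortDataset, TruthBundle]:
    """Generate a sequenced cohort plus its ground truth."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    v, s = cfg.n_variants, cfg.n_samples

    samples = [f"S{j:05d}" for j in range(s)]
    batch_counts = _largest_remainder_counts([b.sample_fraction for b in cfg.batches], s)
    sample_batch = np.repeat(np.arange(len(cfg.batches)), batch_counts)
    batch_of = {samples[j]: cfg.batches[sample_batch[j]].label for j in range(s)}

    # site classes
    is_false = rng.random(v) < cfg.false_site_fraction
    is_violating = ~is_false & (rng.random(v) < cfg.hwe_violating_fraction / (1 - cfg.false_site_fraction))

    # substitution spectrum per class
    ref = np.empty(v, dtype=object)
    alt = np.empty(v, dtype=object)
    idx_true, idx_false = np.flatnonzero(~is_false), np.flatnonzero(is_false)
    ref[idx_true], alt[idx_true] = _draw_ref_alt(rng, len(idx_true), cfg.titv_true)
    ref[idx_false], alt[idx_false] = _draw_ref_alt(rng, len(idx_false), cfg.titv_false)

    # allele frequencies and true genotypes
    a, b = cfg.maf_beta
    maf = 0.5 * rng.beta(a, b, size=v)
    maf = np.clip(maf, 1.0 / (2 * s), 0.5)
    lo, hi = cfg.hwe_violating_maf_range
    maf[is_violating] = rng.uniform(lo, hi, size=int(is_violating.sum()))
    maf[is_false] = 0.0
    f = np.where(is_violating, cfg.hwe_inbreeding_f, 0.0)
    true_gt = _draw_genotypes(rng, maf, f, s)
    true_gt[is_false] = HOM_REF  # artifact sites carry no real variation

    # capture targets: shared / private-per-batch categories
    private = [bspec.private_target_fraction for bspec in cfg.batches]
    probs = [1.0 - sum(private)] + private
    category = rng.choice(len(probs), size=v, p=probs)  # 0 = shared
    on_target = {
        bspec.label: (category == 0) | (category == bi + 1)
        for bi, bspec in enumerate(cfg.batches)
    }
    on_target_vs = np.stack(
        [on_target[cfg.batches[bi].label] for bi in range(len(cfg.batches))], axis=1
    )[:, sample_batch]  # (v, s)

    # depth: gamma-Poisson with per-cell mean and shape
    mean = np.where(is_false[:, None], cfg.depth_mean_false, cfg.depth_mean_on)
    shape = np.where(is_false[:, None], cfg.depth_shape_false, cfg.depth_shape_on)
    mean = np.where(on_target_vs, mean, cfg.depth_mean_off)
    shape = np.where(on_target_vs, shape, 10.0)  # off-target ~ Poisson
    lam = rng.gamma(np.broadcast_to(shape, (v, s)), mean / shape)
    dp = rng.poisson(lam).astype(np.int32)
    called = dp >= 1

    # GQ increasing in depth, with multiplicative noise
    noise = rng.lognormal(mean=-cfg.gq_sigma ** 2 / 2, sigma=cfg.gq_sigma, size=(v, s))
    gq = np.clip(np.rint(cfg.gq_per_read * dp * noise), 0, 99).astype(np.int32)

    # genotype errors at the Phred-implied rate
    err_prob = np.where(called, 10.0 ** (-gq / 10.0), 0.0)
    err_mask = rng.random((v, s)) < err_prob
    obs_gt = _corrupt(rng, true_gt, err_mask)
    obs_gt[~called] = MISSING
    dp_out = np.where(called, dp, -1).astype(np.int32)
    gq_out = np.where(called, gq, -1).astype(np.int32)

    vqsr_fail_p = np.where(is_false, cfg.vqsr_fail_false, cfg.vqsr_fail_true)
    vqsr_pass = rng.random(v) >= vqsr_fail_p

    known = np.where(is_false, rng.random(v) < cfg.known_fraction_false,
                     rng.random(v) < cfg.known_fraction_true)
    truth_member = known & ~is_false & (rng.random(v) < cfg.truth_fraction)
    array_sites = known & (rng.random(v) < cfg.array_site_fraction)

    chrom = np.full(v, "1", dtype=object)
    pos = np.arange(1, v + 1, dtype=np.int64) * 10
    dataset = CohortDataset(
        samples=samples, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vqsr_pass=vqsr_pass, gt=obs_gt, dp=dp_out, gq=gq_out, batch_of=batch_of,
    )
    labels = pd.DataFrame({
        "site_class": np.where(is_false, "false", "true"),
        "hwe_violating": is_violating,
        "known_member": known,
        "truth_member": truth_member,
        "maf": maf,
    })
    truth = TruthBundle(
        samples=samples,
        keys=dataset.keys(),
        true_gt=true_gt,
        error_mask=err_mask & called,
        labels=labels,
        on_target=on_target,
        array_sites=array_sites,
    )
    return dataset, truth


def simulate_array(
    truth: TruthBundle,
    sample_subset: list[str],
    array_error_rate: float = 0.001,
    seed: int = 0,
    gencall_low_fraction: float = 0.012,
) -> ArrayGenotypes:
    """Array gold-standard genotypes for a sample subset at the truth
    bundle's array sites: the true genotypes, corrupted at
    ``array_error_rate``, each with a GenCall confidence score (a
    configurable fraction falls below the usual 0.30 cutoff)."""
    unknown = set(sample_subset) - set(truth.samples)
    if unknown:
        raise ValidationError(f"unknown samples: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    col = {smp: j for j, smp in enumerate(truth.samples)}
    site_rows = np.flatnonzero(truth.array_sites) if truth.array_sites is not None \
        else np.arange(len(truth.keys))
    records = []
    for smp in sample_subset:
        j = col[smp]
        gts = truth.true_gt[site_rows, j].astype(int)
        errs = rng.random(len(site_rows)) < array_error_rate
        shift = rng.integers(1, 3, size=len(site_rows))
        gts = np.where(errs, (gts + shift) % 3, gts)
        low = rng.random(len(site_rows)) < gencall_low_fraction
        score = np.where(low, rng.uniform(0.0, 0.3, len(site_rows)),
                         rng.uniform(0.3, 1.0, len(site_rows)))
        for r, gt, sc in zip(site_rows, gts, score):
            c, p, ref, alt = truth.keys[r]
            records.append((smp, c, p, ref, alt, int(gt), float(sc)))
    df = pd.DataFrame(records, columns=["sample", "chrom", "pos", "ref", "alt",
                                        "gt", "gencall_score"])
    return ArrayGenotypes(df)


def simulate_imputed(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ImputedPanel, TruthBundle]:
    """Generate an imputed panel: every genotype is called pre-filter, GQ
    scales with the variant's allelic R², errors follow 10^(−GQ/10)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    v, s = cfg.imputed_n_variants, cfg.n_samples
    samples = [f"S{j:05d}" for j in range(s)]

    poor = rng.random(v) < cfg.imputed_poor_fraction
    ga, gb = cfg.imputed_good_r2_beta
    pa, pb = cfg.imputed_poor_r2_beta
    r2 = np.where(poor, rng.beta(pa, pb, size=v), rng.beta(ga, gb, size=v))

    a, b = cfg.imputed_maf_beta
    maf = np.clip(0.5 * rng.beta(a, b, size=v), 0.0, 0.5)
    true_gt = _draw_genotypes(rng, maf, np.zeros(v), s)

    noise = rng.lognormal(mean=-cfg.imputed_gq_sigma ** 2 / 2,
                          sigma=cfg.imputed_gq_sigma, size=(v, s))
    gq = np.clip(np.rint(cfg.imputed_gq_scale * r2[:, None] * noise), 0, 99).astype(np.int32)
    err_mask = rng.random((v, s)) < 10.0 ** (-gq / 10.0)
    obs_gt = _corrupt(rng, true_gt, err_mask)

    ref, alt = _draw_ref_alt(rng, v, cfg.titv_true)
    chrom = np.full(v, "2", dtype=object)
    pos = np.arange(1, v + 1, dtype=np.int64) * 10
    panel = ImputedPanel(
        samples, chrom, pos, ref, alt,
        np.ones(v, dtype=bool),
        obs_gt,
        np.full((v, s), -1, dtype=np.int32),
        gq,
        r2=r2,
    )
    labels = pd.DataFrame({
        "site_class": np.where(poor, "poorly_imputed", "well_imputed"),
        "hwe_violating": np.zeros(v, dtype=bool),
        "known_member": np.ones(v, dtype=bool),
        "truth_member": np.zeros(v, dtype=bool),
        "maf": maf,
    })
    truth = TruthBundle(
        samples=samples, keys=panel.keys(), true_gt=true_gt,
        error_mask=err_mask, labels=labels,
        array_sites=np.ones(v, dtype=bool),
    )
    return panel, truth
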