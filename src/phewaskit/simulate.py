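"""Synthetic two-site genotype + ICD-9 billing data with planted effects.

The generator emulates the statistical structure the analysis assumes:

* two sites of ~3,000 subjects sharing one SNP panel (MAF >= 1%, blockwise
  LD, per-SNP imputation info scores), with genotypes drawn independently
  per site;
* hundreds of ICD-9 codes per site whose vocabularies overlap in a
  controlled number of exact codes plus codes that match only at the
  3-digit category level;
* per-code latent disease liability ``logit p = alpha_code + beta*dosage +
  gamma_age*age + gamma_sex*sex`` with planted SNP -> diagnosis log-odds
  effects;
* billing counts: affected persons bill ``4 + Poisson(lambda_case)``
  instances (so the "more than three instances" case rule always captures
  them), unaffected persons bill a zero-inflated Poisson(lambda_background)
  count, creating the control stratum holding 1-3 stray instances.

Genotypes use blockwise Gaussian-copula haplotypes: within each LD block the
latent Gaussians follow an AR(1) with correlation ``ld_rho`` and are
thresholded at the allele frequency, so each SNP is exactly Hardy-Weinberg
while adjacent SNPs are correlated (realized allele correlation is somewhat
below the latent ``ld_rho``).  Population structure, when requested, draws
subpopulation allele frequencies from the Balding-Nichols construction at
the given FST.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from .errors import AlignmentError, ConfigError, UnknownReferenceError
from .genoqc import GenotypeMatrix

AGE_COEF = 0.01   # log-odds per year of age (centered at 55)
SEX_COEF = 0.25   # log-odds for sex = 1 (centered at 0.5)
AGE_MEAN, AGE_SD = 55.0, 12.0
AGE_RANGE = (18.0, 95.0)
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters for the two-site generator.

    Defaults reflect the study this generator emulates: ~3,000 subjects per
    site, hundreds of billing codes with 50 exact / 186 category-level
    shared codes, MAF >= 1%, case counts spanning roughly a dozen to well
    over a thousand.  The SNP panel size defaults to 1,000 (a scaled-down
    stand-in for a genome-wide post-imputation panel).
    """

    n_samples_per_site: int = 3000
    n_snps: int = 1000
    maf_range: tuple = (0.01, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.7
    n_subpops: int = 1
    fst: float = 0.0
    n_codes_per_site: int = 300
    n_exact_shared_codes: int = 50
    n_category_shared_codes: int = 186
    baseline_prevalence_range: tuple = (0.005, 0.6)
    lambda_case: float = 3.0
    lambda_background: float = 0.5
    background_zero_prob: float = 0.7
    info_score_params: tuple = (8.0, 1.0)
    site_b_prevalence_shift: float = 0.0  # optional logit shift at site B, off by default
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("n_samples_per_site", "n_snps", "ld_block_size", "n_subpops",
                     "n_codes_per_site"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0, 1)")
        if not (0 <= self.fst < 0.5):
            raise ConfigError("fst must be in [0, 0.5)")
        if self.n_subpops > 1 and self.fst == 0:
            raise ConfigError("fst must be positive when n_subpops > 1")
        if self.n_exact_shared_codes < 0 or self.n_category_shared_codes < 0:
            raise ConfigError("shared-code counts must be non-negative")
        if self.n_exact_shared_codes + self.n_category_shared_codes > self.n_codes_per_site:
            raise ConfigError(
                "n_exact_shared_codes + n_category_shared_codes exceeds n_codes_per_site"
            )
        plo, phi = self.baseline_prevalence_range
        if not (0 < plo <= phi < 1):
            raise ConfigError("baseline_prevalence_range must lie within (0, 1)")
        if self.lambda_case < 0 or self.lambda_background < 0:
            raise ConfigError("billing-count rates must be non-negative")
        if not (0 <= self.background_zero_prob <= 1):
            raise ConfigError("background_zero_prob must be in [0, 1]")
        a, b = self.info_score_params
        if a <= 0 or b <= 0:
            raise ConfigError("info_score_params must be positive Beta shapes")


@dataclass
class EffectSpec:
    """Planted truth: log-odds ratio ``beta`` per coded-allele dosage for one
    SNP -> ICD-9 code pair."""

    snp_id: str
    icd9_code: str
    beta: float

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ConfigError("effect beta must be finite")


def _tag(text: str) -> int:
    """Stable 31-bit stream tag for seeding independent RNG streams."""
    return zlib.crc32(str(text).encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# SNP panel (shared across sites)
# ---------------------------------------------------------------------------

def make_panel(cfg: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Shared SNP metadata and per-subpopulation allele frequencies.

    Returns (snps frame, freqs of shape (n_subpops, n_snps)).  Deterministic
    in ``cfg.seed`` alone, so both sites see identical metadata.
    """
    rng = np.random.default_rng([cfg.seed, _tag("panel")])
    m = cfg.n_snps
    anc = rng.uniform(*cfg.maf_range, size=m)
    if cfg.n_subpops > 1:
        f = cfg.fst
        a = anc * (1 - f) / f
        b = (1 - anc) * (1 - f) / f
        freqs = rng.beta(a, b, size=(cfg.n_subpops, m))
        freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
    else:
        freqs = anc[None, :]
    alleles = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(m)],
            "chrom": "1",
            "pos": 5000 * (np.arange(m) + 1),
            "allele_coded": _BASES[alleles[:, 0]],
            "allele_other": _BASES[alleles[:, 1]],
            "info_score": rng.beta(*cfg.info_score_params, size=m),
        }
    )
    return snps, freqs


def simulate_genotypes(cfg: SimConfig, site: str = "site_a") -> GenotypeMatrix:
    """Draw one site's dosage matrix from the shared panel.

    Dosages are hard {0, 1, 2} sums of two copula haplotypes, so every SNP
    is Hardy-Weinberg at its (subpopulation) frequency.  Samples are split
    evenly across subpopulations in id order.
    """
    snps, freqs = make_panel(cfg)
    rng = np.random.default_rng([cfg.seed, _tag(site), _tag("genotypes")])
    n, m = cfg.n_samples_per_site, cfg.n_snps

    z = rng.standard_normal((2 * n, m))
    rho = cfg.ld_rho
    if rho > 0:
        scale = np.sqrt(1 - rho**2)
        for j in range(1, m):
            if j % cfg.ld_block_size != 0:  # block boundary resets the chain
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]

    subpop = np.arange(n) % cfg.n_subpops
    thresholds = ndtri(freqs)  # allele present iff latent z below the quantile
    hap_thresh = thresholds[np.repeat(subpop, 2)]
    hap = (z < hap_thresh).astype(float)
    dosages = hap[0::2] + hap[1::2]

    samples = np.array([f"{site}-{i:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages=dosages, samples=samples, snps=snps)


def simulate_covariates(cfg: SimConfig, site: str = "site_a") -> pd.DataFrame:
    """Age (Normal(55, 12) clipped to [18, 95]) and sex (Bernoulli 1/2)."""
    rng = np.random.default_rng([cfg.seed, _tag(site), _tag("covariates")])
    n = cfg.n_samples_per_site
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n), *AGE_RANGE)
    sex = rng.integers(0, 2, size=n)
    return pd.DataFrame(
        {
            "person_id": [f"{site}-{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
        }
    )


# ---------------------------------------------------------------------------
# ICD-9 vocabularies
# ---------------------------------------------------------------------------

def _category_pool() -> list:
    return [f"{i:03d}" for i in range(1, 1000)] + [f"V{i:02d}" for i in range(1, 92)]


def default_vocabulary(cfg: SimConfig) -> list:
    """Single-site vocabulary (used when events are simulated standalone)."""
    rng = np.random.default_rng([cfg.seed, _tag("vocabulary")])
    cats = rng.choice(_category_pool(), size=cfg.n_codes_per_site, replace=False)
    return sorted(f"{c}.{rng.integers(0, 10)}" for c in cats)


def make_two_site_vocabularies(cfg: SimConfig) -> tuple[list, list]:
    """Two code vocabularies with controlled exact/category-level overlap.

    Exactly ``n_exact_shared_codes`` codes are identical across sites and
    ``n_category_shared_codes`` further codes share only their 3-digit
    category (different sub-codes); all remaining codes live in categories
    private to one site, so the requested overlap is exact by construction.
    """
    rng = np.random.default_rng([cfg.seed, _tag("vocabulary")])
    n_exact, n_cat = cfg.n_exact_shared_codes, cfg.n_category_shared_codes
    n_private = cfg.n_codes_per_site - n_exact - n_cat
    need = n_exact + n_cat + 2 * n_private
    pool = _category_pool()
    if need > len(pool):
        raise ConfigError(f"needs {need} distinct ICD-9 categories, pool has {len(pool)}")
    cats = list(rng.choice(pool, size=need, replace=False))

    exact_cats = cats[:n_exact]
    cat_cats = cats[n_exact:n_exact + n_cat]
    priv_a = cats[n_exact + n_cat:n_exact + n_cat + n_private]
    priv_b = cats[n_exact + n_cat + n_private:]

    vocab_a, vocab_b = [], []
    for c in exact_cats:
        code = f"{c}.{rng.integers(0, 10)}"
        vocab_a.append(code)
        vocab_b.append(code)
    for c in cat_cats:
        d1, d2 = rng.choice(10, size=2, replace=False)
        vocab_a.append(f"{c}.{d1}")
        vocab_b.append(f"{c}.{d2}")
    for c in priv_a:
        vocab_a.append(f"{c}.{rng.integers(0, 10)}")
    for c in priv_b:
        vocab_b.append(f"{c}.{rng.integers(0, 10)}")
    return sorted(vocab_a), sorted(vocab_b)


def vocabulary_overlap(codes_a, codes_b) -> tuple[int, int]:
    """(exact matches, category-only matches) between two vocabularies.

    A category-only match is a 3-digit category present in both vocabularies
    that is not already covered by an exact code match.
    """
    from .phenotypes import truncate_to_category

    a, b = set(codes_a), set(codes_b)
    exact = a & b
    cats_exact = {truncate_to_category(c) for c in exact}
    cat_only = (
        {truncate_to_category(c) for c in a} & {truncate_to_category(c) for c in b}
    ) - cats_exact
    return len(exact), len(cat_only)


# ---------------------------------------------------------------------------
# Billing events
# ---------------------------------------------------------------------------

def simulate_icd_events(
    geno: GenotypeMatrix,
    covars: pd.DataFrame,
    effects,
    cfg: SimConfig,
    codes=None,
    logit_shift: float = 0.0,
) -> pd.DataFrame:
    """Billing events from latent per-code disease liabilities.

    For each (person, code): draw affected status from the logistic
    liability, then a billing count (affected: ``4 + Poisson(lambda_case)``;
    unaffected: zero-inflated Poisson(lambda_background)), and emit that
    many ``person_id, icd9_code, event_date`` rows.  ``logit_shift`` moves
    every code's baseline log-odds (the optional site-prevalence-skew knob).
    Deterministic given the config seed and the genotype sample ids.
    """
    if list(covars["person_id"]) != list(geno.samples):
        raise AlignmentError("covariate person_ids must match genotype samples in order")
    codes = list(codes) if codes is not None else default_vocabulary(cfg)

    snp_index = {s: i for i, s in enumerate(geno.snps["snp_id"])}
    code_set = set(codes)
    effect_map: dict[str, list] = {}
    for e in effects:
        if e.snp_id not in snp_index:
            raise UnknownReferenceError(f"effect references unknown SNP {e.snp_id!r}")
        if e.icd9_code not in code_set:
            raise UnknownReferenceError(f"effect references unknown code {e.icd9_code!r}")
        effect_map.setdefault(e.icd9_code, []).append((snp_index[e.snp_id], e.beta))

    rng = np.random.default_rng(
        [cfg.seed, _tag("|".join(map(str, geno.samples[:10])) + str(len(geno.samples))),
         _tag("events")]
    )
    n = geno.n_samples
    age = covars["age"].to_numpy(dtype=float) - AGE_MEAN
    sex = covars["sex"].to_numpy(dtype=float) - 0.5
    cov_eta = AGE_COEF * age + SEX_COEF * sex

    plo, phi = cfg.baseline_prevalence_range
    prevalence = np.exp(rng.uniform(np.log(plo), np.log(phi), size=len(codes)))

    person_idx_parts, code_parts, date_parts = [], [], []
    base_date = np.datetime64("2000-01-01")
    for c, code in enumerate(codes):
        eta = logit(prevalence[c]) + logit_shift + cov_eta
        for j, beta in effect_map.get(code, ()):
            eta = eta + beta * geno.dosages[:, j]
        affected = rng.random(n) < expit(eta)

        counts = np.zeros(n, dtype=int)
        n_aff = int(affected.sum())
        counts[affected] = 4 + rng.poisson(cfg.lambda_case, size=n_aff)
        n_un = n - n_aff
        bg = rng.poisson(cfg.lambda_background, size=n_un)
        bg[rng.random(n_un) < cfg.background_zero_prob] = 0
        counts[~affected] = bg

        total = int(counts.sum())
        if total == 0:
            continue
        person_idx_parts.append(np.repeat(np.arange(n), counts))
        code_parts.append(np.full(total, code, dtype=object))
        date_parts.append(base_date + rng.integers(0, 5478, size=total))

    if not person_idx_parts:
        return pd.DataFrame(columns=["person_id", "icd9_code", "event_date"])
    person_idx = np.concatenate(person_idx_parts)
    events = pd.DataFrame(
        {
            "person_id": geno.samples[person_idx],
            "icd9_code": np.concatenate(code_parts),
            "event_date": np.concatenate(date_parts).astype("datetime64[D]").astype(str),
        }
    )
    return events


# ---------------------------------------------------------------------------
# Two-site bundles
# ---------------------------------------------------------------------------

@dataclass
class SiteData:
    """One site's simulated inputs."""

    site: str
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    events: pd.DataFrame
    codes: list


@dataclass
class TwoSiteStudy:
    """Paired site bundles plus the planted-effect truth table."""

    site_a: SiteData
    site_b: SiteData
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sites(self):
        return [self.site_a, self.site_b]


def simulate_two_sites(cfg: SimConfig, effects=()) -> TwoSiteStudy:
    """Generate both sites: shared SNP panel, controlled code overlap,
    independent genotype/covariate/event draws, planted effects applied at
    every site whose vocabulary contains the effect's code."""
    vocab_a, vocab_b = make_two_site_vocabularies(cfg)
    snps, _ = make_panel(cfg)
    snp_ids = set(snps["snp_id"])
    for e in effects:
        if e.snp_id not in snp_ids:
            raise UnknownReferenceError(f"effect references unknown SNP {e.snp_id!r}")
        if e.icd9_code not in vocab_a and e.icd9_code not in vocab_b:
            raise UnknownReferenceError(
                f"effect code {e.icd9_code!r} absent from both site vocabularies"
            )

    bundles = []
    for site, vocab, shift in (
        ("site_a", vocab_a, 0.0),
        ("site_b", vocab_b, cfg.site_b_prevalence_shift),
    ):
        geno = simulate_genotypes(cfg, site)
        covars = simulate_covariates(cfg, site)
        site_effects = [e for e in effects if e.icd9_code in set(vocab)]
        events = simulate_icd_events(geno, covars, site_effects, cfg, codes=vocab,
                                     logit_shift=shift)
        bundles.append(SiteData(site=site, genotypes=geno, covariates=covars,
                                events=events, codes=vocab))

    truth = pd.DataFrame(
        [(e.snp_id, e.icd9_code, e.beta) for e in effects],
        columns=["snp_id", "icd9_code", "beta"],
    )
    return TwoSiteStudy(site_a=bundles[0], site_b=bundles[1], truth=truth)
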