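"""Generative contracts of the synthetic two-site EHR simulator."""

import numpy as np
import pandas as pd
import pytest
from helpers import weir_cockerham_fst
from scipy import stats

from phewaskit import (EffectSpec, SimConfig, derive_status_table, fit_logistic,
                       simulate_covariates, simulate_genotypes,
                       simulate_icd_events, simulate_two_sites,
                       vocabulary_overlap)
from phewaskit.errors import ConfigError, UnknownReferenceError
from phewaskit.simulate import default_vocabulary, make_panel


def small_cfg(**kw):
    base = dict(n_samples_per_site=400, n_snps=50, n_codes_per_site=12,
                n_exact_shared_codes=3, n_category_shared_codes=3, seed=123,
                baseline_prevalence_range=(0.1, 0.3))
    base.update(kw)
    return SimConfig(**base)


# -- config validation -------------------------------------------------------

@pytest.mark.parametrize(
    "kw",
    [
        dict(maf_range=(0.0, 0.5)),
        dict(maf_range=(0.1, 0.6)),
        dict(n_snps=0),
        dict(ld_rho=1.0),
        dict(fst=0.5, n_subpops=2),
        dict(n_subpops=2),  # fst left at 0
        dict(n_exact_shared_codes=10, n_category_shared_codes=3),
        dict(baseline_prevalence_range=(0.0, 0.2)),
        dict(info_score_params=(0, 1)),
    ],
)
def test_invalid_config_rejected(kw):
    with pytest.raises(ConfigError):
        small_cfg(**kw)


def test_effect_reference_errors():
    cfg = small_cfg()
    geno = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    codes = default_vocabulary(cfg)
    with pytest.raises(UnknownReferenceError):
        simulate_icd_events(geno, cov, [EffectSpec("rs999999", codes[0], 0.5)], cfg, codes)
    with pytest.raises(UnknownReferenceError):
        simulate_icd_events(geno, cov, [EffectSpec("rs000001", "999.9", 0.5)], cfg, codes)
    with pytest.raises(ConfigError):
        EffectSpec("rs000001", codes[0], np.inf)


# -- determinism -------------------------------------------------------------

def test_seed_determinism_everywhere():
    cfg = small_cfg()
    s1 = simulate_two_sites(cfg, [])
    s2 = simulate_two_sites(cfg, [])
    np.testing.assert_array_equal(s1.site_a.genotypes.dosages, s2.site_a.genotypes.dosages)
    pd.testing.assert_frame_equal(s1.site_b.events, s2.site_b.events)
    pd.testing.assert_frame_equal(s1.site_a.covariates, s2.site_a.covariates)
    # different seed changes the draw
    s3 = simulate_two_sites(small_cfg(seed=124), [])
    assert not np.array_equal(s1.site_a.genotypes.dosages, s3.site_a.genotypes.dosages)


# -- genotype model ----------------------------------------------------------

def test_hardy_weinberg_single_population():
    cfg = SimConfig(n_samples_per_site=1500, n_snps=300, n_subpops=1, fst=0.0,
                    seed=42, maf_range=(0.05, 0.5))
    geno = simulate_genotypes(cfg)
    _, freqs = make_panel(cfg)
    p = freqs[0]
    rejected = 0
    for j in range(cfg.n_snps):
        counts = np.bincount(geno.dosages[:, j].astype(int), minlength=3)
        exp = cfg.n_samples_per_site * np.array(
            [(1 - p[j]) ** 2, 2 * p[j] * (1 - p[j]), p[j] ** 2]
        )
        chi2 = ((counts - exp) ** 2 / exp).sum()
        if stats.chi2.sf(chi2, df=2) < 0.001:
            rejected += 1
    assert rejected <= 0.01 * cfg.n_snps
    assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}


def test_ld_rho_zero_gives_independence():
    cfg = SimConfig(n_samples_per_site=500, n_snps=60, ld_rho=0.0, seed=43,
                    maf_range=(0.2, 0.5))
    geno = simulate_genotypes(cfg)
    r = np.corrcoef(geno.dosages.T)
    iu = np.triu_indices(cfg.n_snps, k=1)
    mean_r2 = (r[iu] ** 2).mean()
    # for independent SNPs E[r^2] ~ 1/n
    assert mean_r2 == pytest.approx(1 / cfg.n_samples_per_site, rel=0.5)


def test_ld_blocks_are_correlated():
    cfg = SimConfig(n_samples_per_site=800, n_snps=40, ld_block_size=8, ld_rho=0.9,
                    seed=44, maf_range=(0.2, 0.5))
    geno = simulate_genotypes(cfg)
    d = geno.dosages
    within = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
              for j in range(39) if (j + 1) % 8 != 0]
    across = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
              for j in range(39) if (j + 1) % 8 == 0]
    assert np.mean(within) > 0.3
    assert np.mean(across) < 0.05


def test_balding_nichols_fst_recovered():
    cfg = SimConfig(n_samples_per_site=1000, n_snps=2000, n_subpops=2, fst=0.05,
                    ld_rho=0.0, seed=45)
    geno = simulate_genotypes(cfg)
    labels = np.arange(geno.n_samples) % 2
    fst = weir_cockerham_fst(geno.dosages, labels)
    assert abs(fst - 0.05) < 0.01


def test_info_scores_straddle_qc_threshold():
    snps, _ = make_panel(small_cfg(n_snps=400))
    info = snps["info_score"]
    assert ((info > 0.9).mean() > 0.1) and ((info <= 0.9).mean() > 0.1)


# -- event model -------------------------------------------------------------

def test_null_prevalence_matches_target():
    cfg = SimConfig(n_samples_per_site=3000, n_snps=5, n_codes_per_site=5,
                    n_exact_shared_codes=0, n_category_shared_codes=0,
                    baseline_prevalence_range=(0.10, 0.10), seed=46)
    geno = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    events = simulate_icd_events(geno, cov, [], cfg)
    statuses = derive_status_table(events, list(cov["person_id"]))
    frac = statuses.mean(axis=0)
    # per the >3-instance rule, case fraction ~ 0.10 up to Monte-Carlo error
    assert np.allclose(frac, 0.10, atol=0.02)


def test_degenerate_background_no_control_events():
    cfg = SimConfig(n_samples_per_site=800, n_snps=5, n_codes_per_site=3,
                    n_exact_shared_codes=0, n_category_shared_codes=0,
                    lambda_background=0.0, background_zero_prob=1.0,
                    baseline_prevalence_range=(0.2, 0.2), seed=47)
    geno = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    events = simulate_icd_events(geno, cov, [], cfg)
    counts = events.groupby(["person_id", "icd9_code"]).size()
    assert (counts >= 4).all()  # every person with any events is affected


def test_controls_hold_stray_instances():
    cfg = small_cfg(n_samples_per_site=2000, lambda_background=0.8,
                    background_zero_prob=0.5)
    geno = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    events = simulate_icd_events(geno, cov, [], cfg)
    counts = events.groupby(["person_id", "icd9_code"]).size()
    assert ((counts >= 1) & (counts <= 3)).any()


def test_planted_effect_recovered_in_refit():
    """Logistic refit of derived status on dosage covers the planted beta."""
    covered = 0
    for seed in range(20):
        cfg = SimConfig(n_samples_per_site=1500, n_snps=10, n_codes_per_site=3,
                        n_exact_shared_codes=0, n_category_shared_codes=0,
                        maf_range=(0.3, 0.3), ld_rho=0.0,
                        baseline_prevalence_range=(0.2, 0.2), seed=100 + seed)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        codes = default_vocabulary(cfg)
        events = simulate_icd_events(geno, cov, [EffectSpec("rs000003", codes[0], 0.7)],
                                     cfg, codes)
        y = derive_status_table(events, list(cov["person_id"]))[codes[0]].to_numpy()
        f = fit_logistic(y, geno.dosages[:, 2], cov[["age", "sex"]])
        if f.beta - 1.96 * f.se <= 0.7 <= f.beta + 1.96 * f.se:
            covered += 1
    assert covered >= 16  # nominal 95% coverage, generous Monte-Carlo slack


# -- two-site structure ------------------------------------------------------

def test_two_site_overlap_counts():
    cfg = small_cfg(n_codes_per_site=30, n_exact_shared_codes=7,
                    n_category_shared_codes=9)
    study = simulate_two_sites(cfg, [])
    assert vocabulary_overlap(study.site_a.codes, study.site_b.codes) == (7, 9)
    assert len(study.site_a.codes) == len(study.site_b.codes) == 30
    # study-scale vocabularies: 50 exact and 186 category-level shared codes
    from phewaskit.simulate import make_two_site_vocabularies

    va, vb = make_two_site_vocabularies(SimConfig())
    assert vocabulary_overlap(va, vb) == (50, 186)


def test_two_site_identical_vocabularies():
    cfg = small_cfg(n_codes_per_site=12, n_exact_shared_codes=12,
                    n_category_shared_codes=0)
    study = simulate_two_sites(cfg, [])
    assert study.site_a.codes == study.site_b.codes


def test_two_site_shared_panel_independent_draws():
    study = simulate_two_sites(small_cfg(), [])
    ga, gb = study.site_a.genotypes, study.site_b.genotypes
    pd.testing.assert_frame_equal(ga.snps, gb.snps)  # identical metadata
    assert not np.array_equal(ga.dosages, gb.dosages)


def test_two_site_plants_effects_on_shared_codes():
    cfg = small_cfg()
    study0 = simulate_two_sites(cfg, [])
    shared = sorted(set(study0.site_a.codes) & set(study0.site_b.codes))[0]
    study = simulate_two_sites(cfg, [EffectSpec("rs000001", shared, 0.9)])
    assert list(study.truth.itertuples(index=False)) == [("rs000001", shared, 0.9)]
    with pytest.raises(UnknownReferenceError):
        simulate_two_sites(cfg, [EffectSpec("rs000001", "123.4", 0.9)])
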