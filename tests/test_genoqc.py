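"""Genotype QC chain, relatedness, LD pruning, PCs, region selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from helpers import make_geno, rank_auc

from phewaskit import (SimConfig, apply_qc_filters, compute_pcs,
                       estimate_relatedness, ld_prune, remove_related,
                       select_snps_by_regions, simulate_genotypes)
from phewaskit.errors import QcError
from phewaskit.genoqc import read_bed


def brute_force_qc(dosages, info, min_info=0.9, snp_call=0.99, sample_call=0.99, min_maf=0.01):
    """Rule-by-rule oracle for the four-step filter chain."""
    d = np.asarray(dosages, dtype=float)
    snp_keep = np.asarray(info) > min_info
    d = d[:, snp_keep]
    cr = 1 - np.isnan(d).mean(axis=0)
    snp_keep2 = cr >= snp_call
    d = d[:, snp_keep2]
    scr = 1 - np.isnan(d).mean(axis=1)
    sample_keep = scr >= sample_call
    d = d[sample_keep]
    p = np.nanmean(d, axis=0) / 2
    maf_keep = np.minimum(p, 1 - p) >= min_maf
    return snp_keep, snp_keep2, sample_keep, maf_keep


def test_qc_toy_matrix_matches_oracle():
    rng = np.random.default_rng(11)
    n, m = 200, 10
    dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    dosages[:, 3] = 0.0                  # monomorphic -> MAF filter
    dosages[:6, 5] = np.nan              # SNP call rate 0.97 -> call filter
    dosages[0, [0, 2, 4, 6]] = np.nan    # sample 0 call rate 0.6 -> removed
    info = np.array([0.95, 0.85, 0.99, 0.98, 0.97, 0.96, 1.0, 0.91, 0.5, 0.92])

    geno = make_geno(dosages, info=info)
    out, report = apply_qc_filters(geno)

    k1, k2, ks, k4 = brute_force_qc(dosages, info)
    surviving = geno.snps.loc[k1, "snp_id"].to_numpy()[k2][k4]
    assert list(out.snps["snp_id"]) == list(surviving)
    assert list(out.samples) == list(geno.samples[ks])
    assert report.removed_info == int((~k1).sum())
    assert report.removed_maf == int((~k4).sum())


def test_qc_identity_and_idempotence():
    rng = np.random.default_rng(1)
    geno = make_geno(rng.binomial(2, 0.4, size=(50, 6)).astype(float))
    out, report = apply_qc_filters(geno)
    assert out.n_snps == 6 and out.n_samples == 50
    np.testing.assert_array_equal(out.dosages, geno.dosages)
    # idempotence
    out2, report2 = apply_qc_filters(out)
    np.testing.assert_array_equal(out2.dosages, out.dosages)
    assert report2.removed_info == report2.removed_maf == 0


def test_qc_paper_thresholds():
    """info 0.85 fails the >0.9 rule; MAF 0.005 fails the 1% rule."""
    n = 2000
    rng = np.random.default_rng(2)
    d = np.column_stack([
        rng.binomial(2, 0.3, n),   # healthy SNP
        rng.binomial(2, 0.3, n),   # info 0.85 -> step 1
        rng.binomial(2, 0.005, n), # MAF ~0.005 -> step 4
    ]).astype(float)
    geno = make_geno(d, info=[0.95, 0.85, 0.99])
    out, report = apply_qc_filters(geno)
    assert list(out.snps["snp_id"]) == ["snp000"]
    assert report.removed_info == 1 and report.removed_maf == 1


def test_qc_everything_removed_is_hard_error():
    geno = make_geno(np.zeros((10, 2)), info=[0.1, 0.2])
    with pytest.raises(QcError) as exc:
        apply_qc_filters(geno)
    assert exc.value.report is not None


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def _sim_unrelated(n, m, seed=0, maf=None):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m) if maf is None else np.full(m, maf)
    return rng.binomial(2, p, size=(n, m)).astype(float), p


def test_pi_hat_duplicate_and_unrelated():
    d, _ = _sim_unrelated(20, 2500, seed=5)
    d[1] = d[0]  # duplicated sample
    geno = make_geno(d)
    pairs = estimate_relatedness(geno)
    pairs = pairs.set_index(["sample_a", "sample_b"])["pi_hat"]
    assert pairs.loc[("s000", "s001")] > 0.95
    others = pairs.drop(index=("s000", "s001"))
    assert (others < 0.05).mean() > 0.95


def test_pi_hat_parent_offspring():
    """Child inherits one gamete from the parent: pi-hat = 0.5 +/- 0.05."""
    rng = np.random.default_rng(9)
    m = 4000
    p = rng.uniform(0.2, 0.5, m)
    hap = lambda: (rng.random(m) < p).astype(float)
    parent_h1, parent_h2 = hap(), hap()
    transmitted = np.where(rng.random(m) < 0.5, parent_h1, parent_h2)
    child = transmitted + hap()
    parent = parent_h1 + parent_h2
    others = np.array([hap() + hap() for _ in range(8)])
    d = np.vstack([parent, child, others])
    pairs = estimate_relatedness(make_geno(d))
    po = pairs.set_index(["sample_a", "sample_b"])["pi_hat"].loc[("s000", "s001")]
    assert abs(po - 0.5) < 0.05


def test_remove_related_rules():
    d, _ = _sim_unrelated(6, 500, seed=3)
    geno = make_geno(d)
    # one pair above threshold -> exactly one member dropped
    pairs = pd.DataFrame({"sample_a": ["s000"], "sample_b": ["s001"], "pi_hat": [0.5]})
    keep = remove_related(pairs, geno)
    assert len(keep) == 5 and ("s000" in keep) != ("s001" in keep)
    # no pair above threshold -> identity
    pairs2 = pd.DataFrame({"sample_a": ["s000"], "sample_b": ["s001"], "pi_hat": [0.1]})
    assert remove_related(pairs2, geno) == sorted(geno.samples)


def test_remove_related_triangle_matches_exhaustive_search():
    d, _ = _sim_unrelated(5, 500, seed=4)
    geno = make_geno(d)
    trio = ["s000", "s001", "s002"]
    pairs = pd.DataFrame(
        [(a, b, 0.5) for a, b in itertools.combinations(trio, 2)],
        columns=["sample_a", "sample_b", "pi_hat"],
    )
    keep = remove_related(pairs, geno, threshold=0.1875)
    # exhaustive search: maximal subset of the clique with no related pair
    related = {frozenset(p) for p in itertools.combinations(trio, 2)}
    best = 0
    for r in range(len(trio), 0, -1):
        for subset in itertools.combinations(trio, r):
            if not any(frozenset(p) in related for p in itertools.combinations(subset, 2)):
                best = max(best, r)
        if best:
            break
    assert len([s for s in keep if s in trio]) == best == 1
    # invariant: no retained pair above threshold
    kept = set(keep)
    assert not any(
        a in kept and b in kept
        for a, b, ph in pairs.itertuples(index=False)
        if ph > 0.1875
    )


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_independent_all_kept():
    d, _ = _sim_unrelated(800, 30, seed=6)
    geno = make_geno(d)
    assert ld_prune(geno) == list(geno.snps["snp_id"])


def test_ld_prune_duplicate_column():
    d, _ = _sim_unrelated(300, 5, seed=7)
    d[:, 2] = d[:, 1]
    kept = ld_prune(make_geno(d))
    assert ("snp001" in kept) != ("snp002" in kept)
    assert len(kept) == 4


def test_ld_prune_blocks_brute_force_r2():
    cfg = SimConfig(n_samples_per_site=500, n_snps=100, ld_block_size=10,
                    ld_rho=0.95, seed=8, maf_range=(0.2, 0.5))
    geno = simulate_genotypes(cfg)
    kept = ld_prune(geno, r2_max=0.3, window=50, step=5)
    assert 0 < len(kept) < 100
    idx = geno.snps["snp_id"].isin(set(kept)).to_numpy().nonzero()[0]
    d = geno.dosages
    # brute-force pairwise check of every retained pair within the window span
    for a_i, a in enumerate(idx):
        for b in idx[a_i + 1:]:
            if b - a < 50:
                r = np.corrcoef(d[:, a], d[:, b])[0, 1]
                assert r**2 <= 0.3 + 1e-12, (a, b, r**2)


def test_ld_prune_requires_sorted_positions():
    d, _ = _sim_unrelated(50, 4, seed=1)
    geno = make_geno(d, pos=[400, 300, 200, 100])
    with pytest.raises(ValueError, match="sort"):
        ld_prune(geno)


def test_ld_prune_sample_order_invariance():
    cfg = SimConfig(n_samples_per_site=300, n_snps=60, ld_block_size=6,
                    ld_rho=0.9, seed=12, maf_range=(0.1, 0.5))
    geno = simulate_genotypes(cfg)
    kept = ld_prune(geno)
    perm = np.random.default_rng(0).permutation(geno.n_samples)
    shuffled = geno.subset(sample_mask=perm)
    assert ld_prune(shuffled) == kept


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def test_pcs_orthogonal_and_rank_guard():
    d, _ = _sim_unrelated(100, 40, seed=2)
    pcs = compute_pcs(make_geno(d), k=5)
    gram = pcs.scores.T @ pcs.scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
    with pytest.raises(ValueError, match="rank"):
        compute_pcs(make_geno(d[:, :3]), k=5)


def test_pc1_separates_subpopulations():
    cfg = SimConfig(n_samples_per_site=1000, n_snps=2000, n_subpops=2, fst=0.05,
                    ld_rho=0.0, seed=13)
    geno = simulate_genotypes(cfg)
    labels = np.arange(geno.n_samples) % 2
    pcs = compute_pcs(geno, k=5)
    auc = rank_auc(pcs.scores[:, 0], labels)
    assert max(auc, 1 - auc) > 0.9


def test_pc_variance_share_homogeneous_null():
    """In a structure-free population the top share stays near the bulk."""
    d, _ = _sim_unrelated(300, 600, seed=14)
    pcs = compute_pcs(make_geno(d), k=5)
    # Marchenko-Pastur style reference: shares of the same matrix with
    # permuted columns (destroys any sample-level structure)
    rng = np.random.default_rng(0)
    d_null = np.column_stack([rng.permutation(d[:, j]) for j in range(d.shape[1])])
    null_share = compute_pcs(make_geno(d_null), k=1).variance_share[0]
    assert pcs.variance_share[0] < 2 * null_share


# ---------------------------------------------------------------------------
# Region selection
# ---------------------------------------------------------------------------

def test_region_boundary_semantics(tmp_path):
    """BED 0-based half-open region 99-100 covers 1-based position 100."""
    d = np.zeros((4, 3)) + 1.0
    geno = make_geno(d, pos=[99, 100, 101])
    bed = tmp_path / "r.bed"
    bed.write_text("1\t99\t100\tg1\n")
    out = select_snps_by_regions(geno, regions=read_bed(bed))
    assert list(out.snps["pos"]) == [100]


def test_region_selection_brute_force_and_union(tmp_path):
    rng = np.random.default_rng(5)
    pos = np.sort(rng.choice(np.arange(1, 2000), size=20, replace=False))
    geno = make_geno(np.ones((3, 20)), pos=pos)
    bed = tmp_path / "r.bed"
    bed.write_text("1\t100\t400\ta\n1\t900\t950\tb\n2\t0\t5000\tc\n")
    regions = read_bed(bed)
    out = select_snps_by_regions(geno, regions=regions, snp_list=["snp019"])
    expected = {
        geno.snps["snp_id"][j]
        for j, p in enumerate(pos)
        if (100 < p <= 400) or (900 < p <= 950)
    } | {"snp019"}
    assert set(out.snps["snp_id"]) == expected


def test_region_selection_empty_warns():
    geno = make_geno(np.ones((2, 3)))
    with pytest.warns(UserWarning):
        out = select_snps_by_regions(geno, regions=None, snp_list=[])
    assert out.n_snps == 0
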