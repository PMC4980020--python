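"""Post-imputation genotype QC, relatedness, principal components, LD pruning.

The container here is :class:`GenotypeMatrix`: a dense samples x SNPs dosage
array (expected coded-allele count in [0, 2], NaN for missing) plus a per-SNP
metadata frame.  All QC operations are pure: they return a new, filtered
matrix and leave their input untouched.

The QC filter chain is applied in a fixed, audited order:

1. drop SNPs with imputation info score <= ``min_info`` (default 0.9);
2. drop SNPs with genotype call rate < ``snp_call`` (default 0.99);
3. drop samples with call rate < ``sample_call`` (default 0.99);
4. drop SNPs whose minor allele frequency, recomputed after sample removal,
   is below ``min_maf`` (default 0.01).

Relatedness uses the method-of-moments IBS-based estimator of the IBD
proportion pi-hat (PLINK-style P(IBD=0,1,2) from allele frequencies), and
``ld_prune`` is a deterministic sliding-window greedy prune at an r^2
ceiling, whose surviving count feeds the Bonferroni denominator downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, QcError

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "allele_coded", "allele_other", "info_score"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage store with per-SNP metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_snps)
        Expected coded-allele counts in [0, 2]; NaN marks a missing call.
    samples : ndarray of str
        Sample identifiers, one per row.
    snps : DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, allele_coded,
        allele_other, info_score``.  Positions are 1-based.
    """

    dosages: np.ndarray
    samples: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = np.asarray(self.samples, dtype=object)
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snp metadata missing columns: {missing}")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")
        with np.errstate(invalid="ignore"):
            bad = np.logical_or(self.dosages < 0, self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def coded_freq(self) -> np.ndarray:
        """Coded-allele frequency per SNP (missing-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.coded_freq()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to the nearest integer genotype (NaN preserved)."""
        return np.round(self.dosages)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        d, s, m = self.dosages, self.samples, self.snps
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            d, s = d[sample_mask], s[sample_mask]
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            d, m = d[:, snp_mask], m.iloc[snp_mask]
        return GenotypeMatrix(d.copy(), s.copy(), m.reset_index(drop=True))

    def align_samples(self, ids) -> "GenotypeMatrix":
        """Reorder/subset rows to the given sample ids (must all be present)."""
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = np.array([index[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(self.dosages[rows], np.asarray(list(ids), dtype=object), self.snps)


@dataclass
class QcReport:
    """Stepwise audit of the QC filter chain."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    removed_info: int = 0
    removed_snp_call: int = 0
    removed_sample_call: int = 0
    removed_maf: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_snps_in),
            ("input_samples", self.n_samples_in),
            ("removed_low_info", self.removed_info),
            ("removed_snp_call_rate", self.removed_snp_call),
            ("removed_sample_call_rate", self.removed_sample_call),
            ("removed_low_maf", self.removed_maf),
            ("output_snps", self.n_snps_out),
            ("output_samples", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def apply_qc_filters(
    geno: GenotypeMatrix,
    min_info: float = 0.9,
    snp_call: float = 0.99,
    sample_call: float = 0.99,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the four-step post-imputation filter chain.

    Steps run in the fixed order info -> SNP call rate -> sample call rate ->
    MAF, with MAF recomputed after sample removal.  Raises :class:`QcError`
    (report attached) if nothing survives.
    """
    if geno.n_snps == 0 or geno.n_samples == 0:
        raise QcError("empty genotype matrix")
    report = QcReport(
        n_snps_in=geno.n_snps,
        n_samples_in=geno.n_samples,
        thresholds=dict(min_info=min_info, snp_call=snp_call, sample_call=sample_call, min_maf=min_maf),
    )

    keep = geno.snps["info_score"].to_numpy() > min_info
    report.removed_info = int((~keep).sum())
    g = geno.subset(snp_mask=keep)

    keep = g.snp_call_rate() >= snp_call
    report.removed_snp_call = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    if g.n_snps == 0:
        report.n_snps_out = 0
        report.n_samples_out = g.n_samples
        raise QcError("all SNPs removed by QC", report=report)

    keep = g.sample_call_rate() >= sample_call
    report.removed_sample_call = int((~keep).sum())
    g = g.subset(sample_mask=keep)
    if g.n_samples == 0:
        report.n_samples_out = 0
        raise QcError("all samples removed by QC", report=report)

    keep = g.maf() >= min_maf
    report.removed_maf = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    report.n_snps_out = g.n_snps
    report.n_samples_out = g.n_samples
    if g.n_snps == 0:
        raise QcError("all SNPs removed by QC", report=report)
    return g, report


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def estimate_relatedness(geno: GenotypeMatrix, min_pi_hat: float = 0.0) -> pd.DataFrame:
    """Method-of-moments IBD estimation for every sample pair.

    Genotypes are rounded to hard calls; SNPs with missing calls or
    monomorphic frequency are dropped for the estimate.  Per pair, observed
    identity-by-state (IBS) counts are matched to their expectations under
    IBD state Z in {0, 1, 2} given coded-allele frequencies, yielding
    P(Z=0..2) and ``pi_hat = P(Z=1)/2 + P(Z=2)`` clipped to [0, 1].

    Returns a frame of pairs with columns ``sample_a, sample_b, pi_hat``
    restricted to ``pi_hat >= min_pi_hat``.
    """
    calls = geno.hard_calls()
    ok = ~np.isnan(calls).any(axis=0)
    p = geno.coded_freq()
    ok &= (p > 0) & (p < 1)
    calls = calls[:, ok]
    n, L = calls.shape
    if L < 50:
        warnings.warn(f"only {L} usable SNPs; pi-hat estimates will be unstable")

    # Per-SNP IBS probabilities conditional on the IBD state, using unbiased
    # factorial moments of the allele counts (k of 2n chromosomes) in place
    # of plug-in powers of p-hat — the finite-sample correction that keeps
    # unrelated pairs centred at pi-hat = 0.
    k = calls.sum(axis=0)
    x = np.full(L, 2.0 * n)
    kq = x - k

    def ff(a, r):
        out = np.ones_like(a)
        for i in range(r):
            out = out * (a - i)
        return out

    denom4 = ff(x, 4)
    denom3 = ff(x, 3)
    p2q2 = ff(k, 2) * ff(kq, 2) / denom4
    p3q = ff(k, 3) * kq / denom4
    pq3 = k * ff(kq, 3) / denom4
    p2q = ff(k, 2) * kq / denom3
    pq2 = k * ff(kq, 2) / denom3
    p3 = ff(k, 3) / denom3
    q3 = ff(kq, 3) / denom3

    e0_z0 = 2 * p2q2
    e1_z0 = 4 * p3q + 4 * pq3
    e2_z0 = 1.0 - e0_z0 - e1_z0
    e1_z1 = 2 * p2q + 2 * pq2
    e2_z1 = p3 + q3 + p2q + pq2
    S = dict(
        s0_z0=e0_z0.sum(), s1_z0=e1_z0.sum(), s2_z0=e2_z0.sum(),
        s1_z1=e1_z1.sum(), s2_z1=e2_z1.sum(),
    )

    # Pairwise IBS counts via genotype-class indicator products.
    ind = [(calls == g_).astype(float) for g_ in (0.0, 1.0, 2.0)]
    n00 = ind[0] @ ind[2].T + ind[2] @ ind[0].T           # IBS 0
    n22 = ind[0] @ ind[0].T + ind[1] @ ind[1].T + ind[2] @ ind[2].T  # IBS 2
    n11 = L - n00 - n22

    iu = np.triu_indices(n, k=1)
    ibs0, ibs1, ibs2 = n00[iu], n11[iu], n22[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0 / S["s0_z0"]
        p1 = (ibs1 - p0 * S["s1_z0"]) / S["s1_z1"]
        p2 = (ibs2 - p0 * S["s2_z0"] - p1 * S["s2_z1"]) / L
    # the three state estimates are left unclipped so their multinomial
    # sampling noise cancels in the combination; only pi-hat is bounded
    pi_hat = np.clip(0.5 * p1 + p2, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "sample_a": geno.samples[iu[0]],
            "sample_b": geno.samples[iu[1]],
            "pi_hat": pi_hat,
        }
    )
    return out[out["pi_hat"] >= min_pi_hat].reset_index(drop=True)


def remove_related(pairs: pd.DataFrame, geno: GenotypeMatrix, threshold: float = 0.1875) -> list:
    """Greedy keep-list construction from pairwise pi-hat estimates.

    While any retained pair exceeds ``threshold``, drop the member with the
    lower sample call rate; ties drop the lexicographically larger id.
    Deterministic, and the retained set never contains a pair above the
    threshold.
    """
    call_rate = dict(zip(geno.samples, geno.sample_call_rate()))
    kept = set(geno.samples)
    active = pairs[pairs["pi_hat"] > threshold].copy()
    active = active.sort_values(["pi_hat", "sample_a", "sample_b"], ascending=[False, True, True])
    # iterate until no active pair has both members retained
    changed = True
    while changed:
        changed = False
        for a, b in zip(active["sample_a"], active["sample_b"]):
            if a in kept and b in kept:
                ca, cb = call_rate.get(a, 1.0), call_rate.get(b, 1.0)
                if ca < cb:
                    kept.discard(a)
                elif cb < ca:
                    kept.discard(b)
                else:
                    kept.discard(max(a, b))
                changed = True
    return sorted(kept)


# ---------------------------------------------------------------------------
# LD pruning and principal components
# ---------------------------------------------------------------------------

def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between hard-call dosage columns."""
    x = block - block.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / len(x)
    r = c / np.outer(sd, sd)
    return np.nan_to_num(r**2, nan=1.0)  # constant columns treated as redundant


def ld_prune(
    geno: GenotypeMatrix, r2_max: float = 0.3, window: int = 50, step: int = 5
) -> list:
    """Sliding-window greedy LD prune; returns the kept snp_id list.

    Within each window of ``window`` SNPs (advanced by ``step``), pairs of
    retained SNPs with hard-call r^2 above ``r2_max`` are resolved by
    dropping the later SNP in position order.  Requires position-sorted
    input so the scan is deterministic.
    """
    pos = geno.snps["pos"].to_numpy()
    chrom = geno.snps["chrom"].to_numpy()
    order_key = pd.DataFrame({"chrom": chrom, "pos": pos})
    if not order_key.sort_values(["chrom", "pos"]).index.equals(order_key.index):
        raise ValueError("SNPs must be sorted by (chrom, pos) before LD pruning; sort first")

    calls = geno.hard_calls()
    # mean-impute missing for correlation purposes
    if np.isnan(calls).any():
        col_mean = np.nanmean(calls, axis=0)
        nan_r, nan_c = np.where(np.isnan(calls))
        calls = calls.copy()
        calls[nan_r, nan_c] = col_mean[nan_c]

    m = geno.n_snps
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        end = min(start + window, m)
        idx = np.arange(start, end)
        same_chrom = chrom[idx] == chrom[idx[0]]
        idx = idx[same_chrom]
        live = idx[keep[idx]]
        if len(live) > 1:
            r2 = _pairwise_r2(calls[:, live])
            for i in range(len(live)):
                if not keep[live[i]]:
                    continue
                for j in range(i + 1, len(live)):
                    if keep[live[j]] and r2[i, j] > r2_max:
                        keep[live[j]] = False
        if end == m:
            break
        start += step
    return list(geno.snps.loc[keep, "snp_id"])


@dataclass
class PcMatrix:
    """Top-k principal component scores of the standardized dosage matrix."""

    scores: np.ndarray          # samples x k
    variance_share: np.ndarray  # length k
    samples: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pc{i+1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"person_id": self.samples, **cols})


def compute_pcs(geno: GenotypeMatrix, k: int = 5) -> PcMatrix:
    """PCA of the column-standardized (mean-imputed) dosage matrix.

    Sign convention: within each component the largest-magnitude SNP loading
    is made positive, so scores are reproducible across runs.
    """
    x = geno.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"requested k={k} components but matrix rank is {rank}")
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    var = s**2
    return PcMatrix(scores=scores, variance_share=var[:k] / var.sum(), samples=geno.samples.copy())


# ---------------------------------------------------------------------------
# Region-based SNP selection
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED interval file (0-based half-open) into a frame."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: BED line needs >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer BED coordinates") from None
            if start < 0 or end < start:
                raise ParseError(f"{path}:{ln}: invalid BED interval {start}-{end}")
            name = parts[3] if len(parts) > 3 else f"region{ln}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def select_snps_by_regions(
    geno: GenotypeMatrix, regions: pd.DataFrame | None = None, snp_list=None
) -> GenotypeMatrix:
    """Keep SNPs inside any BED region or named in ``snp_list`` (union).

    BED intervals are 0-based half-open; internal positions 1-based, so a
    SNP at 1-based position p is inside [start, end) iff start < p <= end.
    """
    keep = np.zeros(geno.n_snps, dtype=bool)
    if regions is not None and len(regions):
        pos = geno.snps["pos"].to_numpy()
        chrom = geno.snps["chrom"].astype(str).to_numpy()
        for _, r in regions.iterrows():
            keep |= (chrom == str(r["chrom"])) & (pos > r["start"]) & (pos <= r["end"])
    if snp_list:
        wanted = set(snp_list)
        keep |= geno.snps["snp_id"].isin(wanted).to_numpy()
    if not keep.any():
        warnings.warn("region/SNP-list selection kept no SNPs")
    return geno.subset(snp_mask=keep)
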