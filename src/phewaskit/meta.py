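"""Sample-size-weighted signed-Z pooled analysis of replicated pairs.

Each site's two-sided p-value and effect direction are converted to a signed
normal deviate Z = sign * Phi^-1(1 - p/2); site Zs are combined with weights
w_i = sqrt(n_i) (n_i = cases + controls) as

    Z_meta = sum(w_i Z_i) / sqrt(sum(w_i^2))

and the pooled two-sided p is 2 * Phi(-|Z_meta|).  This is the standard
sample-size scheme for p-value + direction meta-analysis (the METAL
default); tail quantities are computed in log space, so p-values are exact
down to ~1e-300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri_exp
from scipy.stats import norm

LOG2 = np.log(2.0)


def signed_z_from_p(p, direction) -> float | np.ndarray:
    """Direction-signed normal deviate of a two-sided p-value.

    ``direction`` is +/-1 (the sign of the effect).  Computed as
    ``-ndtri_exp(log(p) - log 2)``, a log-space inverse of the upper tail
    that stays accurate for p down to 1e-300.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = -ndtri_exp(np.log(p) - LOG2)
    z = np.where(z == 0, 0.0, z)  # avoid signed zero at p == 1
    out = np.sign(direction) * z
    return float(out) if out.ndim == 0 else out


@dataclass
class MetaResult:
    """One pooled SNP-phenotype record."""

    snp_id: str
    code: str
    match_level: str
    z_meta: float
    p_meta: float
    entries: list  # per-site (p, direction, n_effective)


def combine_sample_weighted(entries) -> MetaResult:
    """Pool per-site (p, direction, n) triples into a signed meta Z and p.

    Weights are sqrt(n); scaling every n by a constant leaves the result
    unchanged.  A single entry round-trips: p_meta == p.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("need at least one entry to combine")
    p = np.array([e[0] for e in entries], dtype=float)
    d = np.array([e[1] for e in entries], dtype=float)
    n = np.array([e[2] for e in entries], dtype=float)
    if np.any(n <= 0):
        raise ValueError("effective sample sizes must be positive")
    z = signed_z_from_p(p, d)
    w = np.sqrt(n)
    z_meta = float((w * z).sum() / np.sqrt((w**2).sum()))
    p_meta = float(min(2.0 * norm.sf(abs(z_meta)), 1.0))
    p_meta = max(p_meta, 5e-324)
    return MetaResult(
        snp_id="", code="", match_level="", z_meta=z_meta, p_meta=p_meta, entries=entries
    )


def meta_analyze(pairs: pd.DataFrame, representatives_only: bool = True) -> pd.DataFrame:
    """Pool a replication table (one row per cross-site pair) site by site.

    Expects the columns produced by :mod:`phewaskit.replicate`:
    ``snp_id, match_level, code_a, code_b, category, beta_a, p_a, n_case_a,
    n_control_a, beta_b, p_b, n_case_b, n_control_b`` (and
    ``is_representative`` for category-level tables).  For category-level
    pairs only the minimum-p representative per (snp, category) is pooled
    unless ``representatives_only=False``.
    """
    if pairs.empty:
        return pd.DataFrame(
            columns=["snp_id", "code", "category", "match_level",
                     "z_meta", "p_meta", "p_a", "p_b", "n_a", "n_b"]
        )
    df = pairs
    if representatives_only and "is_representative" in df.columns:
        df = df[(df["match_level"] == "exact") | df["is_representative"]]
    rows = []
    for _, r in df.iterrows():
        n_a = r["n_case_a"] + r["n_control_a"]
        n_b = r["n_case_b"] + r["n_control_b"]
        res = combine_sample_weighted(
            [(r["p_a"], np.sign(r["beta_a"]), n_a), (r["p_b"], np.sign(r["beta_b"]), n_b)]
        )
        code = r["code_a"] if r["match_level"] == "exact" else r["category"]
        rows.append(
            (r["snp_id"], code, r["category"], r["match_level"],
             res.z_meta, res.p_meta, r["p_a"], r["p_b"], n_a, n_b)
        )
    out = pd.DataFrame(
        rows,
        columns=["snp_id", "code", "category", "match_level",
                 "z_meta", "p_meta", "p_a", "p_b", "n_a", "n_b"],
    )
    return out.sort_values("p_meta").reset_index(drop=True)
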