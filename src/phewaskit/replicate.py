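"""Cross-site replication of association results.

A SNP-phenotype association *replicates* when the same SNP is associated in
both cohorts at p below the replication threshold (default 0.01) with the
same direction of effect after allele harmonization, either for the exact
ICD-9 code (``match_exact``) or for the 3-digit code category
(``match_category``).

Allele harmonization: if the coded/other alleles are swapped between sites,
the second site's beta sign is flipped and labels swapped; if they differ by
strand, alleles are complemented first.  Strand-ambiguous SNPs (A/T or C/G)
cannot be resolved and are excluded (and counted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlleleMismatchError, AmbiguousAllelesError
from .phenotypes import truncate_to_category

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "snp_id", "match_level", "code_a", "code_b", "category",
    "beta_a", "se_a", "p_a", "n_case_a", "n_control_a",
    "beta_b", "se_b", "p_b", "n_case_b", "n_control_b",
    "direction_consistent", "is_representative",
]


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return None


def is_strand_ambiguous(allele_coded: str, allele_other: str) -> bool:
    """A/T and C/G SNPs look identical after strand flip."""
    return _complement(allele_coded) == allele_other.upper()


def harmonize_alleles(res_a, res_b):
    """Align site B's result to site A's coded allele.

    ``res_a``/``res_b`` are mappings with keys ``allele_coded, allele_other,
    beta`` (pandas Series or dicts).  Returns ``(res_a, res_b')`` where
    ``res_b'`` has beta sign and allele labels adjusted if the sites coded
    opposite alleles, possibly after strand complementation.  Raises
    :class:`AmbiguousAllelesError` for A/T and C/G SNPs and
    :class:`AlleleMismatchError` when the allele sets are incompatible.
    """
    ca, oa = str(res_a["allele_coded"]).upper(), str(res_a["allele_other"]).upper()
    cb, ob = str(res_b["allele_coded"]).upper(), str(res_b["allele_other"]).upper()
    if is_strand_ambiguous(ca, oa):
        raise AmbiguousAllelesError(f"strand-ambiguous alleles {ca}/{oa}")

    def adjusted(flip: bool):
        out = dict(res_b) if not isinstance(res_b, pd.Series) else res_b.copy()
        if flip:
            out["beta"] = -res_b["beta"]
            out["allele_coded"], out["allele_other"] = ca, oa
        else:
            out["allele_coded"], out["allele_other"] = ca, oa
        return res_a, out

    if (cb, ob) == (ca, oa):
        return adjusted(flip=False)
    if (cb, ob) == (oa, ca):
        return adjusted(flip=True)
    ccb, cob = _complement(cb), _complement(ob)
    if ccb is not None and (ccb, cob) == (ca, oa):
        return adjusted(flip=False)
    if ccb is not None and (ccb, cob) == (oa, ca):
        return adjusted(flip=True)
    # an ambiguous B with an unambiguous A is necessarily incompatible, so
    # falling through to a mismatch here is always correct
    raise AlleleMismatchError(f"incompatible alleles {ca}/{oa} vs {cb}/{ob}")


def _harmonized_sign_b(merged: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized harmonization over a merged result frame.

    Returns (sign_flip for beta_b, keep mask); rows that are ambiguous or
    incompatible are dropped via the mask.
    """
    ca = merged["allele_coded_a"].str.upper()
    oa = merged["allele_other_a"].str.upper()
    cb = merged["allele_coded_b"].str.upper()
    ob = merged["allele_other_b"].str.upper()

    comp = lambda s: s.map(lambda x: _complement(x) or "?")
    ambiguous = (comp(ca) == oa) | (comp(cb) == ob)
    same = (cb == ca) & (ob == oa)
    swapped = (cb == oa) & (ob == ca)
    strand_same = (comp(cb) == ca) & (comp(ob) == oa)
    strand_swapped = (comp(cb) == oa) & (comp(ob) == ca)

    flip = (swapped | strand_swapped).to_numpy()
    keep = ((same | swapped | strand_same | strand_swapped) & ~ambiguous).to_numpy()
    return flip, keep


def _build_pairs(merged: pd.DataFrame, match_level: str, p_threshold: float) -> pd.DataFrame:
    if merged.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    flip, keep = _harmonized_sign_b(merged)
    merged = merged.loc[keep].copy()
    beta_b = merged["beta_b"].to_numpy() * np.where(flip[keep], -1.0, 1.0)
    merged["beta_b"] = beta_b

    same_dir = np.sign(merged["beta_a"].to_numpy()) == np.sign(beta_b)
    sig = (merged["p_a"].to_numpy() < p_threshold) & (merged["p_b"].to_numpy() < p_threshold)
    conv = np.ones(len(merged), dtype=bool)
    if "converged_a" in merged.columns:
        conv = merged["converged_a"].to_numpy() & merged["converged_b"].to_numpy()
    merged = merged.loc[same_dir & sig & conv].copy()
    if merged.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    out = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "match_level": match_level,
            "code_a": merged["icd9_code_a"],
            "code_b": merged["icd9_code_b"],
            "category": merged["category"],
            "beta_a": merged["beta_a"], "se_a": merged["se_a"], "p_a": merged["p_a"],
            "n_case_a": merged["n_case_a"], "n_control_a": merged["n_control_a"],
            "beta_b": merged["beta_b"], "se_b": merged["se_b"], "p_b": merged["p_b"],
            "n_case_b": merged["n_case_b"], "n_control_b": merged["n_control_b"],
            "direction_consistent": True,
        }
    )
    if match_level == "exact":
        out["is_representative"] = True
    else:
        # minimum-p representative per (snp, category) and site, for meta input
        rep = np.zeros(len(out), dtype=bool)
        for _, idx in out.groupby(["snp_id", "category"]).groups.items():
            sub = out.loc[idx]
            best_a = sub["p_a"].idxmin()
            best_b = sub["p_b"].idxmin()
            best = sub[
                (sub["code_a"] == sub.loc[best_a, "code_a"])
                & (sub["code_b"] == sub.loc[best_b, "code_b"])
            ]
            rep[out.index.get_indexer([best.index[0] if len(best) else best_a])] = True
        out["is_representative"] = rep
    return out.reset_index(drop=True)


def _prep(results: pd.DataFrame, suffix: str) -> pd.DataFrame:
    df = results.copy()
    if "category" not in df.columns:
        df["category"] = df["icd9_code"].map(truncate_to_category)
    return df


def match_exact(results_a: pd.DataFrame, results_b: pd.DataFrame, p_threshold: float = 0.01) -> pd.DataFrame:
    """Replicated pairs for the same SNP and exact ICD-9 code.

    Both sites must show p below ``p_threshold`` and the same effect
    direction after allele harmonization.
    """
    a, b = _prep(results_a, "a"), _prep(results_b, "b")
    merged = a.merge(
        b, on=["snp_id", "icd9_code"], suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    merged["icd9_code_a"] = merged["icd9_code"]
    merged["icd9_code_b"] = merged["icd9_code"]
    merged["category"] = merged["category_a"]
    return _build_pairs(merged, "exact", p_threshold)


def match_category(results_a: pd.DataFrame, results_b: pd.DataFrame, p_threshold: float = 0.01) -> pd.DataFrame:
    """Replicated pairs for the same SNP and 3-digit ICD-9 category.

    Codes are truncated to their category before matching, so distinct
    sub-codes of one category can pair up across sites; every cross pair is
    emitted, with the minimum-p representative per (snp, category) flagged
    for meta-analysis.
    """
    a, b = _prep(results_a, "a"), _prep(results_b, "b")
    merged = a.merge(b, on=["snp_id", "category"], suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return _build_pairs(merged, "category", p_threshold)
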