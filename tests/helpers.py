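"""Shared test utilities: toy matrix builders and independent oracles."""

import numpy as np
import pandas as pd

from phewaskit.genoqc import GenotypeMatrix


def make_geno(dosages, info=None, pos=None, samples=None, alleles=None, chrom="1"):
    """Build a GenotypeMatrix from a plain (samples x snps) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if samples is None:
        samples = [f"s{i:03d}" for i in range(n)]
    if info is None:
        info = np.ones(m)
    if pos is None:
        pos = 1000 * (np.arange(m) + 1)
    if alleles is None:
        alleles = [("G", "A")] * m
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:03d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele_coded": [a for a, _ in alleles],
            "allele_other": [b for _, b in alleles],
            "info_score": info,
        }
    )
    return GenotypeMatrix(dosages=dosages, samples=np.array(samples, dtype=object), snps=snps)


def weir_cockerham_fst(dosages, labels):
    """Weir & Cockerham (1984) multi-SNP FST from genotype dosages.

    Independent oracle: per-SNP variance components a (among populations),
    b (among individuals within populations) and c (within individuals),
    combined as sum(a) / sum(a + b + c) over polymorphic SNPs.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    r = len(pops)
    a_sum = abc_sum = 0.0
    for j in range(dosages.shape[1]):
        g = dosages[:, j]
        n_i = np.array([np.sum(labels == k) for k in pops], dtype=float)
        p_i = np.array([g[labels == k].mean() / 2 for k in pops])
        h_i = np.array([np.mean(g[labels == k] == 1) for k in pops])
        n_bar = n_i.mean()
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        if p_bar <= 0 or p_bar >= 1:
            continue
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum / abc_sum


def rank_auc(scores, labels):
    """AUC of scores for binary labels via the rank-sum statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    ranks = pd.Series(scores).rank().to_numpy()
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n0)
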