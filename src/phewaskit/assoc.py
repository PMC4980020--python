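"""Covariate-adjusted logistic scan of every phenotype on every SNP.

The model for one (SNP, diagnosis) pair is an additive-coding logistic
regression

    logit P(case_i) = b0 + b_g * g_i + gamma' x_i

with g the coded-allele dosage in [0, 2] and x the covariates (age, sex and
the first principal components).  Fitting is maximum likelihood by
iteratively reweighted least squares; the reported test is the two-sided
Wald test on b_g.  Non-convergence or quasi-separation (|b_g| > 15) marks
the fit unconverged, and such rows are excluded downstream.

The scan surface is statsmodels-shaped: build a :class:`PhewasScan` from a
status matrix, a genotype matrix and a covariate table, call ``fit()``, and
get a :class:`PhewasResults` carrying the per-pair association table plus
``summary()`` and QQ-plot diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import norm

from .errors import AlignmentError, RankDeficiencyError, SingleClassError
from .genoqc import GenotypeMatrix
from .phenotypes import StatusMatrix, truncate_to_category

MAX_ITER = 50
REL_TOL = 1e-8
SEPARATION_BETA = 15.0

RESULT_COLUMNS = [
    "snp_id", "icd9_code", "category", "site", "beta", "se", "p",
    "n_case", "n_control", "allele_coded", "allele_other", "converged",
]


@dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    converged: bool
    n_case: int
    n_control: int


def _check_rank(X: np.ndarray, names: list) -> None:
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        raise RankDeficiencyError([names[i] for i in piv[rank:]])


def fit_logistic(y, g, covars=None, check_rank: bool = True) -> LogisticFit:
    """ML logistic fit of binary ``y`` on dosage ``g`` plus covariates.

    Rows with missing dosage are dropped pairwise for this fit.  Raises
    :class:`SingleClassError` if (after deletion) only one outcome class
    remains, and :class:`RankDeficiencyError` naming offending columns when
    the design is collinear.  Separation or non-convergence is reported via
    ``converged=False`` rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if covars is None:
        C = np.empty((len(y), 0))
        cov_names = []
    elif isinstance(covars, pd.DataFrame):
        cov_names = list(covars.columns)
        C = covars.to_numpy(dtype=float)
    else:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_names = [f"x{i}" for i in range(C.shape[1])]
    if not (len(y) == len(g) == len(C)):
        raise ValueError("y, g and covariates must have equal length")

    ok = ~np.isnan(g)
    y, g, C = y[ok], g[ok], C[ok]
    if len(np.unique(y)) < 2:
        raise SingleClassError("outcome has a single class after pairwise deletion")

    X = np.column_stack([np.ones(len(y)), g, C])
    names = ["intercept", "dosage"] + cov_names
    if check_rank:
        _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    ybar = y.mean()
    beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        xtw = X.T * w
        try:
            delta = np.linalg.solve(xtw @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.abs(beta[1]) > SEPARATION_BETA:
            break
        if np.max(np.abs(delta) / (np.abs(beta) + 1.0)) < REL_TOL:
            converged = True
            break

    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if converged and np.abs(beta[1]) > SEPARATION_BETA:
        converged = False
    if converged and se > 0:
        z = beta[1] / se
        p = float(2.0 * norm.sf(abs(z)))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    else:
        p = np.nan
    return LogisticFit(
        beta=float(beta[1]), se=se, p=p, converged=bool(converged),
        n_case=int(y.sum()), n_control=int(len(y) - y.sum()),
    )


def bonferroni_threshold(n_independent_snps: int, n_phenotypes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (independent SNPs x phenotypes)."""
    if n_independent_snps <= 0 or n_phenotypes <= 0:
        raise ValueError("counts must be positive")
    return alpha / (n_independent_snps * n_phenotypes)


class PhewasScan:
    """Phenome-wide logistic scan model: every retained code against every SNP.

    Parameters
    ----------
    statuses : StatusMatrix or DataFrame
        Persons x codes case/control assignments (already inclusion-filtered).
    geno : GenotypeMatrix
        QC'd dosages; aligned to the status persons by sample id.
    covars : DataFrame
        Columns ``person_id, age, sex`` plus any ``pc*`` columns; all persons
        in the status matrix must be present.
    site : str
        Label recorded on every result row.
    """

    def __init__(self, statuses, geno: GenotypeMatrix, covars: pd.DataFrame, site: str = "site"):
        status_df = statuses.statuses if isinstance(statuses, StatusMatrix) else statuses
        persons = list(status_df.index)
        geno_ids = set(geno.samples)
        cov_ids = set(covars["person_id"])
        missing = [p for p in persons if p not in geno_ids or p not in cov_ids][:5]
        if missing:
            raise AlignmentError(
                f"persons missing from genotypes or covariates, e.g. {missing}"
            )
        self.site = site
        self.statuses = status_df
        self.geno = geno.align_samples(persons)
        cov = covars.set_index("person_id").loc[persons]
        cov_cols = ["age", "sex"] + sorted(
            [c for c in cov.columns if c.startswith("pc")],
            key=lambda c: int(c[2:]) if c[2:].isdigit() else 0,
        )
        self.covars = cov[cov_cols]
        if self.covars.isna().any().any():
            raise AlignmentError("missing covariate values among fitted persons")
        # collinearity among covariates is checked once; per-SNP singularities
        # (e.g. a monomorphic dosage) surface as non-converged fits instead
        _check_rank(
            np.column_stack([np.ones(len(persons)), self.covars.to_numpy(float)]),
            ["intercept"] + cov_cols,
        )

    def fit(self, p_ceiling: float | None = None, progress_every: int = 0) -> "PhewasResults":
        """Run all (SNP, code) logistic fits.

        ``p_ceiling`` keeps only rows with p below it in the output table
        (counts of fits/skips are kept regardless).  ``progress_every`` > 0
        prints a progress line every that many fits.
        """
        geno, cov = self.geno, self.covars
        C = cov.to_numpy(dtype=float)
        dosages = geno.dosages
        meta = geno.snps
        rows = []
        n_fits = n_skipped = n_nonconv = 0
        for code in self.statuses.columns:
            y = self.statuses[code].to_numpy(dtype=float)
            category = truncate_to_category(code)
            for j in range(geno.n_snps):
                n_fits += 1
                if progress_every and n_fits % progress_every == 0:
                    print(f"[{self.site}] {n_fits} fits done")
                try:
                    f = fit_logistic(y, dosages[:, j], C, check_rank=False)
                except SingleClassError:
                    n_skipped += 1
                    continue
                if not f.converged:
                    n_nonconv += 1
                    continue
                if p_ceiling is not None and f.p >= p_ceiling:
                    continue
                rows.append(
                    (
                        meta["snp_id"].iat[j], code, category, self.site,
                        f.beta, f.se, f.p, f.n_case, f.n_control,
                        meta["allele_coded"].iat[j], meta["allele_other"].iat[j], True,
                    )
                )
        table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return PhewasResults(
            table=table, site=self.site, n_fits=n_fits,
            n_skipped=n_skipped, n_nonconverged=n_nonconv,
            n_snps=geno.n_snps, n_phenotypes=self.statuses.shape[1],
        )


@dataclass
class PhewasResults:
    """Association table plus scan-level diagnostics."""

    table: pd.DataFrame
    site: str
    n_fits: int
    n_skipped: int
    n_nonconverged: int
    n_snps: int
    n_phenotypes: int

    def bonferroni(self, n_independent_snps: int | None = None, alpha: float = 0.05) -> float:
        """Scan-wide threshold; pass the LD-pruned SNP count when available."""
        n = n_independent_snps if n_independent_snps is not None else self.n_snps
        return bonferroni_threshold(n, self.n_phenotypes, alpha)

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["p"] < threshold].sort_values("p")

    def summary(self) -> str:
        top = self.table.nsmallest(1, "p") if len(self.table) else None
        lines = [
            f"PheWAS scan summary [{self.site}]",
            f"  SNPs x phenotypes : {self.n_snps} x {self.n_phenotypes}",
            f"  fits attempted    : {self.n_fits}",
            f"  skipped (1-class) : {self.n_skipped}",
            f"  non-converged     : {self.n_nonconverged}",
            f"  rows in table     : {len(self.table)}",
        ]
        if top is not None and len(top):
            t = top.iloc[0]
            lines.append(
                f"  top association   : {t.snp_id} x {t.icd9_code} "
                f"(beta={t.beta:.3f}, p={t.p:.3g}, cases={t.n_case})"
            )
        return "\n".join(lines)

    def plot_qq(self, ax=None):
        """QQ plot of -log10 p against the uniform expectation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.sort(self.table["p"].to_numpy())
        n = len(p)
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        ax.scatter(exp, -np.log10(p), s=6)
        lim = max(exp.max(), -np.log10(p.min())) if n else 1.0
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"{self.site}: QQ of scan p-values")
        return ax


def run_phewas(
    geno: GenotypeMatrix,
    statuses,
    covars: pd.DataFrame,
    site: str = "site",
    p_ceiling: float | None = 0.01,
) -> PhewasResults:
    """Convenience wrapper: build the scan model and fit it.

    The default output ceiling p < 0.01 matches the working-set convention
    for downstream replication; pass ``p_ceiling=None`` to keep every row.
    """
    return PhewasScan(statuses, geno, covars, site=site).fit(p_ceiling=p_ceiling)
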