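"""Per-SNP additive regression of the CS score.

Each SNP is tested with ordinary least squares, entering the genotype as a
0/1/2 minor-allele count so a single coefficient (CS units per minor
allele) summarises the additive effect.  Two models are fitted per SNP:

* Model 1 — CS ~ genotype (unadjusted),
* Model 2 — CS ~ genotype + age + sex.

Individuals with a missing genotype or covariate are dropped listwise for
that SNP.  p-values are two-sided from the t distribution with residual
degrees of freedom; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class RegressionResult:
    snp_id: str
    model: int  # 1 = unadjusted, 2 = age+sex adjusted
    coefficient: float
    se: float
    t: float
    p: float
    n_used: int
    note: str = "ok"  # "ok" | "rank_deficient" | "constant_phenotype"

    @property
    def ok(self) -> bool:
        return self.note == "ok"


def fit_additive(
    pheno: np.ndarray,
    genotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "",
) -> RegressionResult:
    """OLS of phenotype on minor-allele count, optionally adjusted.

    ``covariates``, when given, must contain ``age`` (years) and ``sex``
    (0 = male, 1 = female); their presence switches the result to Model 2.
    Rank-deficient designs (e.g. a monomorphic SNP) yield a flagged result
    with NaN estimates instead of raising.
    """
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(genotype, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    model = 1 if covariates is None else 2

    cols = [g]
    if covariates is not None:
        cols.append(np.asarray(covariates["age"], dtype=float))
        cols.append(np.asarray(covariates["sex"], dtype=float))
    X = np.column_stack([np.ones_like(y)] + cols)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    n_used = int(ok.sum())

    def _flagged(note: str) -> RegressionResult:
        nan = float("nan")
        return RegressionResult(snp_id, model, nan, nan, nan, nan, n_used, note)

    if n_used <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
        return _flagged("rank_deficient")

    fit = sm.OLS(y, X).fit()
    coef, se = float(fit.params[1]), float(fit.bse[1])
    if np.ptp(y) == 0.0:
        # constant phenotype: slope is exactly 0 with no sampling noise
        return RegressionResult(snp_id, model, 0.0, 0.0, 0.0, 1.0, n_used, "constant_phenotype")
    if se == 0.0:
        # exact fit with no residual: report an infinite t by convention
        t = float(np.inf) if coef > 0 else float(-np.inf) if coef < 0 else 0.0
        return RegressionResult(snp_id, model, coef, 0.0, t, 0.0 if coef else 1.0, n_used)
    return RegressionResult(
        snp_id, model, coef, se, float(fit.tvalues[1]), float(fit.pvalues[1]), n_used
    )


def association_table(
    matrix: GenotypeMatrix,
    pheno: np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Both models for every SNP, one row per SNP.

    Columns mirror the conventional report: gene, snp_id, then
    coefficient/SE/t/p for the unadjusted and the age+sex-adjusted model.
    """
    rows = []
    for j, rec in enumerate(matrix.snps):
        g = matrix.values[:, j]
        m1 = fit_additive(pheno, g, None, rec.id)
        m2 = fit_additive(pheno, g, covariates, rec.id)
        rows.append(
            {
                "gene": rec.gene,
                "snp_id": rec.id,
                "coef_m1": m1.coefficient,
                "se_m1": m1.se,
                "t_m1": m1.t,
                "p_m1": m1.p,
                "coef_m2": m2.coefficient,
                "se_m2": m2.se,
                "t_m2": m2.t,
                "p_m2": m2.p,
                "n_m1": m1.n_used,
                "n_m2": m2.n_used,
                "note": m1.note if m1.note != "ok" else m2.note,
            }
        )
    return pd.DataFrame(rows)
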