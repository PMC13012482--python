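"""Exploratory statistics: pairwise Pearson correlations and multiple
linear regression of pool composition on donor covariates.

This mirrors the milk bank's exploratory stage: which donor characteristics
(lactation stage, BMI, age, diet, preterm delivery, expressed volume) move
crude protein and energy, before any predictive modelling.  Binary covariates
are treated as 0/1 numerics, so their "Pearson" correlation is the
point-biserial coefficient.  No multiple-testing correction is applied: the
analysis is exploratory, and the conventional 0.05 threshold is reported but
not acted on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CollinearityError, UndefinedCorrelationError, ValidationError

__all__ = [
    "pearson",
    "correlation_table",
    "multiple_linear_regression",
    "RegressionResult",
    "format_p",
    "NUTRIENTS",
    "COVARIATES",
]

NUTRIENTS = ["crude_protein", "energy"]
COVARIATES = ["days_postpartum", "avg_volume", "bmi", "preterm", "age", "vegetarian"]


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value.

    The p-value comes from ``t = r * sqrt((n-2) / (1-r^2))`` against a t
    distribution with ``n-2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"pearson needs two equal-length vectors, got {x.shape} / {y.shape}")
    if len(x) < 3:
        raise ValidationError(f"pearson needs n >= 3, got n = {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation is undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def format_p(p: float, floor: float = 0.001) -> str:
    """Report tiny p-values as ``<0.001`` the way correlation tables print them."""
    return f"<{floor:g}" if p < floor else f"{p:.3f}"


def correlation_table(pool_table: pd.DataFrame) -> pd.DataFrame:
    """Correlations of every covariate with each nutrient, plus the
    protein-energy cross-correlation.

    Returns a tidy frame: variable, nutrient, r, p, p_formatted.  Errors from
    degenerate columns are re-raised naming the offending pair.
    """
    missing = [c for c in NUTRIENTS + COVARIATES if c not in pool_table.columns]
    if missing:
        raise ValidationError(f"pool table missing column(s): {', '.join(missing)}")
    rows = []
    pairs = [(cov, nut) for nut in NUTRIENTS for cov in COVARIATES]
    pairs.append(("crude_protein", "energy"))
    for var, nut in pairs:
        try:
            r, p = pearson(pool_table[var], pool_table[nut])
        except (UndefinedCorrelationError, ValidationError) as exc:
            raise type(exc)(f"correlation ({var}, {nut}): {exc}") from exc
        rows.append(
            {"variable": var, "nutrient": nut, "r": r, "p": p, "p_formatted": format_p(p)}
        )
    return pd.DataFrame(rows)


class RegressionResult:
    """OLS fit summary: per-coefficient estimates, SEs, t-test p-values, R^2."""

    def __init__(self, params: pd.Series, bse: pd.Series, pvalues: pd.Series,
                 r_squared: float, nobs: int):
        self.params = params
        self.bse = bse
        self.pvalues = pvalues
        self.r_squared = r_squared
        self.nobs = nobs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )

    def __repr__(self):  # pragma: no cover
        return f"RegressionResult(nobs={self.nobs}, r_squared={self.r_squared:.4f})"


def multiple_linear_regression(X: pd.DataFrame, y) -> RegressionResult:
    """Ordinary least squares of a nutrient on the covariates, with intercept.

    Raises :class:`CollinearityError` naming the dependent column(s) when the
    design (with intercept) is rank deficient.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValidationError(f"X has {len(X)} rows but y has {len(y)}")
    if len(X) <= X.shape[1] + 1:
        raise ValidationError(
            f"need n > p + 1 observations, got n = {len(X)}, p = {X.shape[1]}"
        )
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns linearly dependent on the ones before them
        dependent = []
        cols = design.to_numpy()
        for j in range(1, cols.shape[1]):
            if np.linalg.matrix_rank(cols[:, : j + 1]) == np.linalg.matrix_rank(cols[:, :j]):
                dependent.append(design.columns[j])
        raise CollinearityError(
            f"design matrix is rank deficient; dependent column(s): "
            f"{', '.join(map(str, dependent))}",
            columns=dependent,
        )
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        nobs=int(fit.nobs),
    )
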