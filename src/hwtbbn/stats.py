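"""Supporting classical analyses: forced-entry OLS and chi-square tests.

The regression mirrors the survey-analysis convention: the continuous HWT
behaviour score regressed on all sixteen RANAS sub-factor items entered
simultaneously, with listwise deletion of incomplete households,
unstandardized (B) and standardized (β) coefficients, and significance
stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class RegressionResult:
    coefficients: pd.DataFrame   # predictor, B, SE_B, beta, t, p, stars
    adj_r_squared: float
    r_squared: float
    n_used: int
    n_dropped: int

    def text_table(self) -> str:
        lines = [f"{'Variable':<28}{'B':>9}{'SE B':>9}{'beta':>9}"]
        for _, row in self.coefficients.iterrows():
            lines.append(f"{row['predictor']:<28}{row['B']:>9.3f}"
                         f"{row['SE_B']:>9.3f}{row['beta']:>9.3f}{row['stars']}")
        lines.append(f"Adjusted R^2 = {self.adj_r_squared:.3f}, N = {self.n_used}")
        return "\n".join(lines)


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def ols_forced_entry(y: np.ndarray | pd.Series,
                     X: pd.DataFrame) -> RegressionResult:
    """OLS of y on all columns of X entered together (plus an intercept).

    Rows with any missing predictor or outcome are listwise deleted.
    Standardized coefficients use sample SDs on the analysed rows:
    beta_j = B_j * sd(x_j) / sd(y).
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    X = X.astype(float)
    complete = y.notna() & X.notna().all(axis=1)
    n_total = len(y)
    yv = y[complete].to_numpy()
    Xv = X[complete]
    n, p = Xv.shape
    if n <= p + 1:
        raise StatsError(f"need more than {p + 1} complete rows, have {n}")

    design = sm.add_constant(Xv.to_numpy())
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns via near-zero singular directions
        _, s, vt = np.linalg.svd(design)
        bad = np.abs(vt[rank:]).sum(axis=0) > 1e-8
        names = [c for c, b in zip(["const"] + list(Xv.columns), bad) if b]
        raise StatsError(f"rank-deficient design; collinear columns: {names}")

    fit = sm.OLS(yv, design).fit()
    sd_y = yv.std(ddof=1)
    rows = []
    for j, name in enumerate(Xv.columns):
        b = float(fit.params[j + 1])
        beta = b * Xv[name].std(ddof=1) / sd_y if sd_y > 0 else np.nan
        pval = float(fit.pvalues[j + 1])
        rows.append({"predictor": name, "B": b, "SE_B": float(fit.bse[j + 1]),
                     "beta": float(beta), "t": float(fit.tvalues[j + 1]),
                     "p": pval, "stars": _stars(pval)})
    return RegressionResult(
        coefficients=pd.DataFrame(rows),
        adj_r_squared=float(fit.rsquared_adj),
        r_squared=float(fit.rsquared),
        n_used=int(n), n_dropped=int(n_total - n))


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame


def chi_square(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction).

    Pairs with a missing value on either side are dropped.
    """
    a = pd.Series(a).reset_index(drop=True)
    b = pd.Series(b).reset_index(drop=True)
    if len(a) != len(b):
        raise StatsError("vectors must have the same length")
    keep = a.notna() & b.notna()
    table = pd.crosstab(a[keep], b[keep])
    if table.size == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        raise StatsError("need at least a 2x2 table of observed states")
    observed = table.to_numpy(dtype=float)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
    if (expected == 0).any():
        raise StatsError("structural zero: an expected cell count is 0")
    stat, p, df, exp = sps.chi2_contingency(observed, correction=False)
    return ChiSquareResult(
        statistic=float(stat), df=int(df), p_value=float(p),
        observed=table,
        expected=pd.DataFrame(exp, index=table.index, columns=table.columns))
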