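"""Statistical battery over the accounting outputs.

Three families of tests cover inference on the accounting outputs: paired Wilcoxon
signed-rank tests between event-rate series, generalized least squares with
AR1 errors and a timebin-by-epoch interaction (epoch split at the Miocene
boundary, 23.03 Ma), and linear mixed models with random intercepts for
standardized realm-level predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

__all__ = [
    "MIOCENE_BOUNDARY_MA",
    "TestResult",
    "GLSResult",
    "paired_wilcoxon",
    "gls_ar1",
    "lmm_random_intercepts",
]

MIOCENE_BOUNDARY_MA = 23.03


@dataclass
class TestResult:
    """One statistic with its p-value and method details."""

    statistic_name: str
    value: float
    pvalue: float
    n: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def paired_wilcoxon(x, y, alternative: str = "two-sided") -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped (reducing n); V is the sum of the ranks of
    the positive differences.  The p-value is exact (sign-pattern
    enumeration) for n <= 25, otherwise a normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    method = "exact" if n <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        d, alternative=alternative, correction=True, method=method
    )
    return TestResult(
        statistic_name="V",
        value=V,
        pvalue=float(res.pvalue),
        n=int(n),
        details={"alternative": alternative, "method": method},
    )


@dataclass
class GLSResult:
    """AR1 generalized least squares fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rho: float
    n: int
    loglik: float
    fallback_independent: bool = False

    def test(self, term: str) -> TestResult:
        return TestResult(
            statistic_name="t",
            value=float(self.tvalues[term]),
            pvalue=float(self.pvalues[term]),
            n=self.n,
            details={"rho": self.rho, "term": term},
        )


def _ar1_whiten(y: np.ndarray, X: np.ndarray, rho: float):
    n = y.size
    yw = np.empty_like(y)
    Xw = np.empty_like(X)
    c = np.sqrt(1.0 - rho * rho)
    yw[0] = c * y[0]
    Xw[0] = c * X[0]
    yw[1:] = y[1:] - rho * y[:-1]
    Xw[1:] = X[1:] - rho * X[:-1]
    return yw, Xw


def _ar1_profile_loglik(rho: float, y: np.ndarray, X: np.ndarray) -> float:
    yw, Xw = _ar1_whiten(y, X, rho)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = y.size
    ssr = float(resid @ resid)
    if ssr <= 0:
        ssr = 1e-300
    return (
        -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(ssr / n))
        + 0.5 * np.log(1.0 - rho * rho)
    )


def gls_ar1(
    data: pd.DataFrame,
    response: str,
    time_col: str = "timebin",
    epoch_boundary: float = MIOCENE_BOUNDARY_MA,
    by: str | None = None,
    log_response: bool = False,
    rho: float | None = None,
) -> GLSResult:
    """GLS regression of a time series on ``timebin * epoch`` with AR1 errors.

    ``epoch`` is a binary factor for timebins older than ``epoch_boundary``
    (the Miocene onset by default).  With ``by`` set (e.g. a realm column)
    the design becomes the triple interaction ``timebin * epoch * by``.
    rho is estimated by maximum likelihood jointly with the coefficients
    (profile likelihood over the exact AR1 whitening) unless given; if the
    optimization fails the model falls back to independent errors, flagged.
    """
    df = data.sort_values(time_col, ascending=False).reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    if log_response:
        if (y <= 0).any():
            raise ValueError("log_response requires strictly positive values")
        y = np.log(y)
    t = df[time_col].to_numpy(dtype=float)
    epoch = (t >= epoch_boundary).astype(float)  # 1 = pre-Miocene

    cols = {"const": np.ones_like(t), time_col: t, "epoch": epoch,
            f"{time_col}:epoch": t * epoch}
    if by is not None:
        levels = sorted(df[by].unique())
        for lev in levels[1:]:
            ind = (df[by] == lev).to_numpy(dtype=float)
            cols[f"{by}[{lev}]"] = ind
            cols[f"{time_col}:{by}[{lev}]"] = t * ind
            cols[f"epoch:{by}[{lev}]"] = epoch * ind
            cols[f"{time_col}:epoch:{by}[{lev}]"] = t * epoch * ind
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    fallback = False
    if rho is None:
        try:
            opt = minimize_scalar(
                lambda r: -_ar1_profile_loglik(r, y, X),
                bounds=(-0.99, 0.99),
                method="bounded",
            )
            if not opt.success:
                raise RuntimeError("rho optimization failed")
            rho = float(opt.x)
        except Exception:
            warnings.warn("AR1 estimation failed; falling back to independent errors")
            rho, fallback = 0.0, True

    yw, Xw = _ar1_whiten(y, X, rho)
    ols = sm.OLS(yw, Xw).fit()
    return GLSResult(
        params=pd.Series(ols.params, index=names),
        bse=pd.Series(ols.bse, index=names),
        tvalues=pd.Series(ols.tvalues, index=names),
        pvalues=pd.Series(ols.pvalues, index=names),
        rho=float(rho),
        n=int(y.size),
        loglik=_ar1_profile_loglik(rho, y, X) if abs(rho) < 1 else float(ols.llf),
        fallback_independent=fallback,
    )


def lmm_random_intercepts(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    group: str,
    extra_group: str | None = None,
    standardize: bool = True,
) -> tuple[list[TestResult], dict]:
    """Linear mixed model with random intercepts (REML, Wald intervals).

    Predictors are z-scored before fitting.  ``group`` supplies the primary
    random intercept; an ``extra_group`` (e.g. realm crossed with taxonomic
    group) enters as an additional variance component.  Returns one
    TestResult per retained predictor (effect size beta, Wald 95% CI and
    p-value in details) plus the random-intercept variance estimates.
    """
    df = data.copy()
    kept = []
    for p in predictors:
        v = df[p].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"predictor {p!r} is constant or empty: dropped")
            continue
        if standardize:
            df[p] = (v - np.nanmean(v)) / sd
        kept.append(p)
    if not kept:
        raise ValueError("no usable predictors")
    df = df.dropna(subset=[response, *kept, group])
    if df[group].nunique() < 2:
        raise ValueError("grouping factor needs at least 2 levels")

    formula = f"{response} ~ " + " + ".join(kept)
    vc = None
    if extra_group is not None:
        vc = {extra_group: f"0 + C({extra_group})"}
    model = sm.MixedLM.from_formula(
        formula, data=df, groups=df[group], re_formula="1", vc_formula=vc
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    results = []
    for p in kept:
        est = float(fit.params[p])
        se = float(fit.bse[p])
        results.append(
            TestResult(
                statistic_name="beta",
                value=est,
                pvalue=float(fit.pvalues[p]),
                n=int(df.shape[0]),
                details={
                    "lower": est - 1.96 * se,
                    "upper": est + 1.96 * se,
                    "se": se,
                    "predictor": p,
                },
            )
        )
    variances = {"group_intercept_var": float(fit.cov_re.iloc[0, 0])}
    if extra_group is not None and getattr(fit, "vcomp", None) is not None and len(fit.vcomp):
        variances["extra_group_var"] = float(fit.vcomp[0])
    return results, variances
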