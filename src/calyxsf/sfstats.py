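"""Statistical layer: the structure-function power law and its companions.

The central fit is ``EPSP rate of rise = beta * area**alpha``, estimated by
ordinary least squares of log RoR on log contact area; ``alpha`` is the
log-log slope and ``beta`` the exponentiated intercept (SE by the delta
method). Companions: Pearson/Spearman correlations, simple and age-corrected
(rank) regressions with F statistics, Bonferroni correction, the logistic
developmental switch of prespike presence, Welch's t test, and the crude
conduction-speed estimate from evoked latencies.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .datatypes import LogisticFit, PowerLawFit, RegressionResult
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "powerlaw_fit",
    "pearson_r",
    "spearman_rho",
    "regression_f",
    "bonferroni",
    "logistic_fit",
    "conduction_speed",
    "welch_t_test",
]

_BIG_F = 1e12  # overflow-safe stand-in for an exact fit


def powerlaw_fit(areas, rors, method: str = "ols") -> PowerLawFit:
    """Fit ``ror = beta * area**alpha``.

    ``method="ols"`` (default) fits by ordinary least squares on the
    log-log scale; ``method="nls"`` refines by nonlinear least squares on
    the raw scale, initialized at the OLS solution."""
    areas = np.asarray(areas, float)
    rors = np.asarray(rors, float)
    if areas.size != rors.size or areas.size < 3:
        raise InsufficientDataError("power-law fit needs >= 3 paired values")
    if np.any(areas <= 0) or np.any(rors <= 0):
        raise ParameterError("areas and rates of rise must be positive")
    x, y = np.log(areas), np.log(rors)
    res = regression_f(x, y)
    alpha = float(res.params[1])
    beta = float(math.exp(res.params[0]))
    r_log = float(np.corrcoef(x, y)[0, 1])
    if method == "nls":
        from scipy.optimize import curve_fit

        popt, pcov = curve_fit(
            lambda a, b, al: b * a**al, areas, rors, p0=(beta, alpha), maxfev=10000
        )
        beta, alpha = float(popt[0]), float(popt[1])
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        return PowerLawFit(
            beta=beta, alpha=alpha, se_beta=float(se[0]), se_alpha=float(se[1]),
            r_log=r_log, F=res.F, p=res.p, n=int(areas.size),
        )
    elif method != "ols":
        raise ParameterError("method must be 'ols' or 'nls'")
    return PowerLawFit(
        beta=beta,
        alpha=alpha,
        se_beta=beta * float(res.bse[0]),  # delta method
        se_alpha=float(res.bse[1]),
        r_log=r_log,
        F=res.F,
        p=res.p,
        n=int(areas.size),
    )


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise InsufficientDataError("correlation undefined for zero variance")
    return float(sps.pearsonr(x, y).statistic)


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson r of the midranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    return pearson_r(sps.rankdata(x), sps.rankdata(y))


def _ols(X: np.ndarray, y: np.ndarray) -> RegressionResult:
    n, k = X.shape  # k includes the intercept column
    if np.linalg.matrix_rank(X) < k:
        raise ParameterError("collinear design matrix (rank deficient)")
    if n < k + 1:
        raise InsufficientDataError("too few observations for the design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = k - 1, n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    if rss <= 1e-12 * max(tss, 1.0):
        F = _BIG_F
        sigma2 = 0.0
    else:
        sigma2 = rss / df2
        F = ((tss - rss) / df1) / sigma2 if df1 else np.nan
    bse = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, np.sign(beta) * np.inf)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    if F >= _BIG_F:
        p = 0.0
    p_coef = 2.0 * sps.t.sf(np.abs(tvals), df2)
    return RegressionResult(
        params=beta, bse=bse, tvalues=tvals, F=float(F), df=(df1, df2), p=p, p_coef=p_coef
    )


def regression_f(x, y, covariate=None, rank_transform: bool = False) -> RegressionResult:
    """Simple linear regression of ``y`` on ``x`` with optional rank
    transform (midranks on both sides, plus the covariate) and an optional
    covariate column -- the age-correction pattern: significance of ``x``
    is then read from its coefficient's t within the two-predictor model."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cols = [x] if covariate is None else [x, np.asarray(covariate, float)]
    if rank_transform:
        cols = [sps.rankdata(c) for c in cols]
        y = sps.rankdata(y)
    X = np.column_stack([np.ones_like(y)] + cols)
    return _ols(X, y)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni correction: ``min(1, m * p)``; ``m`` defaults to the
    number of p values."""
    p = np.atleast_1d(np.asarray(p_values, float))
    m_eff = m if m is not None else p.size
    if m_eff < p.size:
        raise ParameterError("m must be at least the number of tests")
    out = np.minimum(1.0, m_eff * p)
    return float(out[0]) if np.isscalar(p_values) or np.asarray(p_values).ndim == 0 else out


def logistic_fit(ages, present, min_steepness: float = 0.1, max_iter: int = 200) -> LogisticFit:
    """Maximum-likelihood logistic fit of presence against age.

    Model: ``P = 1 / (1 + exp(-(age - m)/s))`` with midpoint ``m`` (days)
    and steepness ``s`` (days). Newton-Raphson on the canonical
    parametrization; quasi-separated data are flagged non-converged with
    ``s`` floored at ``min_steepness``.
    """
    ages = np.asarray(ages, float)
    y = np.asarray(present, float)
    if ages.size != y.size or ages.size < 3:
        raise InsufficientDataError("logistic fit needs >= 3 observations")
    if y.min() == y.max():
        raise InsufficientDataError("logistic fit needs both outcome classes")
    X = np.column_stack([np.ones_like(ages), ages])
    b = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ b
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            break
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    slope = b[1]
    separated = (not converged) or slope <= 0 or (1.0 / max(slope, 1e-12)) < min_steepness
    if slope <= 0:
        # degenerate direction; report midpoint at the class boundary
        s = min_steepness
        m = float(np.mean(ages))
        return LogisticFit(m, s, np.nan, np.nan, converged=False)
    s = 1.0 / slope
    m = -b[0] / slope
    if s < min_steepness:
        s = min_steepness
        separated = True
    # delta-method SEs from the inverse Fisher information
    eta = X @ b
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = p * (1 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        g_m = np.array([-1.0 / slope, b[0] / slope**2])
        g_s = np.array([0.0, -1.0 / slope**2])
        se_m = float(np.sqrt(g_m @ cov @ g_m))
        se_s = float(np.sqrt(g_s @ cov @ g_s))
    except np.linalg.LinAlgError:
        se_m = se_s = np.nan
    return LogisticFit(float(m), float(s), se_m, se_s, converged=not separated)


def conduction_speed(latency_ms: float, axon_length_mm: float = 1.0, synaptic_delay_ms: float = 0.5) -> float:
    """Crude axonal conduction speed (m/s): axon length over the latency
    after subtracting the synaptic delay (AP initiation time neglected)."""
    if latency_ms <= synaptic_delay_ms:
        raise ParameterError("latency must exceed the synaptic delay")
    return axon_length_mm / (latency_ms - synaptic_delay_ms)


def welch_t_test(x, y) -> RegressionResult:
    """Welch's unequal-variance t test with Satterthwaite df, two-sided p.
    Packed as a RegressionResult: params = group means, t of the difference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("Welch test needs >= 2 values per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    t = float(res.statistic)
    df = float(res.df)
    p = float(res.pvalue)
    return RegressionResult(
        params=np.array([x.mean(), y.mean()]),
        bse=np.array([x.std(ddof=1) / math.sqrt(x.size), y.std(ddof=1) / math.sqrt(y.size)]),
        tvalues=np.array([t]),
        F=t**2,
        df=(1, int(round(df))),
        p=p,
    )
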