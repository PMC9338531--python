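"""Statistical primitives shared by every analysis stage.

Correlations, rank tests, multiple-testing adjustment, survival statistics,
logistic/penalized-logistic regression, k-means and ROC/AUC, all returning a
uniform :class:`TestResult` (or small typed containers) so downstream modules
never depend on a particular library's result object.

Conventions
-----------
* All hypothesis tests are two-sided.
* Small-sample rules are explicit and deterministic: Spearman p is an exact
  permutation p for n <= 9; the Mann-Whitney p is exact for min(n) <= 8
  without ties, otherwise a tie-corrected normal approximation.
* Every stochastic routine takes an explicit seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans as _SkKMeans
from sklearn.metrics import roc_auc_score as _sk_auc
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "LogisticFit",
    "spearman_rho",
    "pearson_r",
    "mann_whitney_u",
    "welch_t",
    "bh_adjust",
    "km_curve",
    "logrank",
    "cox_fit",
    "logistic_fit",
    "lasso_lambda_max",
    "lasso_logistic_path",
    "cv_lambda",
    "kmeans",
    "roc_auc",
]


@dataclass(frozen=True)
class TestResult:
    """Uniform result of a two-sided test or a single-parameter fit.

    ``estimate`` is the quantity of scientific interest (rho, r, a mean
    difference, a log-hazard beta, ...); ``statistic`` is the raw test
    statistic (t, U, chi-square, z). Confidence bounds are NaN when the
    method defines none.
    """

    statistic: float
    p_value: float
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_used: int = 0
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _pearson_of(x, y) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        return math.nan
    return float(np.clip((x @ y) / denom, -1.0, 1.0))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (n <= 9, ties ok)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((ryc * ryc).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rho_null = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rho_null) >= abs(rho_obs) - 1e-12))


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    Pairwise-complete; requires >= 3 complete pairs. p is an exact
    permutation p for n <= 9, otherwise the t approximation with n-2 df.
    Constant inputs yield an undefined rho flagged ``"constant"``.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"spearman_rho needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, math.nan, math.nan, n_used=n,
                          method="spearman", flags=("constant",))
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _pearson_of(rx, ry)
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
        method = "spearman-exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
        method = "spearman-t"
    if n > 3 and abs(rho) < 1.0:
        z = math.atanh(rho)
        se = 1.0 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - 1.959963984540054 * se), math.tanh(z + 1.959963984540054 * se)
    else:
        lo = hi = math.nan
    return TestResult(rho, float(min(p, 1.0)), rho, lo, hi, n, method)


def pearson_r(x, y) -> TestResult:
    """Pearson correlation on pairwise-complete values (n >= 3)."""
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"pearson_r needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, math.nan, math.nan, n_used=n,
                          method="pearson", flags=("constant",))
    res = sps.pearsonr(x, y)
    try:
        ci = res.confidence_interval()
        lo, hi = float(ci.low), float(ci.high)
    except ValueError:
        lo = hi = math.nan
    return TestResult(float(res.statistic), float(res.pvalue), float(res.statistic),
                      lo, hi, n, "pearson")


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when min(n) <= 8 and no ties are present;
    tie-corrected normal approximation otherwise. The estimate is the
    common-language effect size U1/(n1*n2) (the probability a random value
    of ``a`` exceeds one of ``b``, ties halved).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("mann_whitney_u requires two nonempty samples")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # every value tied across both groups
        return TestResult(n1 * n2 / 2.0, 1.0, 0.5, n_used=n1 + n2,
                          method="mann-whitney-degenerate", flags=("all-tied",))
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(n1, n2) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    return TestResult(u1, float(res.pvalue), u1 / (n1 * n2), n_used=n1 + n2,
                      method=f"mann-whitney-{method}")


def welch_t(a, b) -> TestResult:
    """Welch two-sample t test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: no within-group variance at all
        if diff == 0.0:
            return TestResult(0.0, 1.0, 0.0, n_used=len(a) + len(b),
                              method="welch-degenerate", flags=("zero-variance",))
        stat = math.copysign(math.inf, diff)
        return TestResult(stat, 0.0, diff, n_used=len(a) + len(b),
                          method="welch-degenerate", flags=("zero-variance",))
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval()
    return TestResult(float(res.statistic), float(res.pvalue), diff,
                      float(ci.low), float(ci.high), len(a) + len(b), "welch")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival) step table."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("km_curve requires at least one subject")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(times, events, groups) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df, two-sided)."""
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"logrank requires exactly two groups, got {list(labels)}")
    m0 = groups == labels[0]
    if m0.sum() == 0 or (~m0).sum() == 0:
        raise ValueError("logrank requires both groups nonempty")
    res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
    return TestResult(float(res.test_statistic), float(res.p_value), math.nan,
                      n_used=len(times), method="logrank")


def cox_fit(covariates: pd.DataFrame, times, events) -> dict[str, TestResult]:
    """Univariate Cox proportional-hazards fit per covariate (Efron ties).

    Returns one TestResult per column: estimate = log-hazard beta, CI is the
    95% Wald interval on beta (exponentiate for the HR). A constant covariate
    or a monotone-likelihood (separation-like) fit is returned flagged with
    NaN estimates rather than a spurious number.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    covariates = pd.DataFrame(covariates)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("cox_fit requires at least one observed event")
    out: dict[str, TestResult] = {}
    for col in covariates.columns:
        x = covariates[col].to_numpy(dtype=float)
        n = len(x)
        if np.nanstd(x) == 0.0:
            out[col] = TestResult(math.nan, math.nan, math.nan, n_used=n,
                                  method="cox-efron", flags=("constant-covariate",))
            continue
        df = pd.DataFrame({"x": x, "T": times, "E": events})
        cph = CoxPHFitter()
        flags: tuple[str, ...] = ()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cph.fit(df, duration_col="T", event_col="E")
            for w in caught:
                if issubclass(w.category, ConvergenceWarning):
                    flags = flags + ("convergence-warning",)
        except ConvergenceError:
            out[col] = TestResult(math.nan, math.nan, math.nan, n_used=n,
                                  method="cox-efron", flags=("monotone-likelihood",))
            continue
        s = cph.summary.loc["x"]
        out[col] = TestResult(float(s["z"]), float(s["p"]), float(s["coef"]),
                              float(s["coef lower 95%"]), float(s["coef upper 95%"]),
                              n, "cox-efron", flags)
    return out


# ---------------------------------------------------------------------------
# logistic regression (Newton/IRLS) and the penalized path
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood (optionally ridge-stabilized) logistic fit."""

    coef: pd.Series            # includes "(Intercept)"
    se: pd.Series
    p_values: pd.Series        # Wald, two-sided
    deviance: float
    converged: bool
    n_iter: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def logistic_fit(X, y, ridge: float = 0.0, firth: bool = False,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Binary logistic regression by Newton iteration with step halving.

    ``ridge`` adds an L2 penalty (not applied to the intercept); ``firth``
    switches to Firth's bias-reduced score (Jeffreys-prior penalty), the
    documented fallback when complete or quasi-complete separation makes
    the MLE diverge. Plain-ML deviance decreases monotonically (steps are
    halved until it does).
    """
    if firth:
        return _firth_fit(X, y, tol=tol, max_iter=max_iter)
    Xraw, names = _as_design(X)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) != 2:
        raise ValueError("y must be binary with both classes present")
    n, p = Xraw.shape
    D = np.column_stack([np.ones(n), Xraw])
    pen = np.zeros(p + 1)
    pen[1:] = ridge
    beta = np.zeros(p + 1)

    def deviance(b):
        eta = np.clip(D @ b, -500, 500)
        return float(2.0 * np.sum(np.log1p(np.exp(eta)) - y * eta)) + float(pen @ (b * b))

    dev = deviance(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(D @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = D.T @ (y - mu) - 2.0 * pen * beta
        H = (D.T * w) @ D + 2.0 * np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the deviance monotone
        scale = 1.0
        new_dev = deviance(beta + step)
        while new_dev > dev + 1e-12 and scale > 1e-8:
            scale *= 0.5
            new_dev = deviance(beta + scale * step)
        beta = beta + scale * step
        if abs(dev - new_dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev

    flags: tuple[str, ...] = ()
    eta = np.clip(D @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if ridge == 0.0:
        # (quasi-)separation: diverging MLE, detected scale-invariantly as an
        # absurd per-SD log-odds effect (Wald p is then Hauck-Donner-broken)
        scale_x = np.concatenate([[1.0], Xraw.std(axis=0)])
        if np.max(np.abs(beta[1:]) * scale_x[1:], initial=0.0) > 5.0:
            flags = ("separation",)
        elif not converged:
            flags = ("not-converged",)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (D.T * w) @ D + 2.0 * np.diag(pen)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    idx = ["(Intercept)"] + names
    return LogisticFit(pd.Series(beta, index=idx), pd.Series(se, index=idx),
                       pd.Series(pvals, index=idx), dev, converged, it, flags)


def _firth_fit(X, y, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Firth bias-reduced logistic regression (finite under separation)."""
    Xraw, names = _as_design(X)
    y = np.asarray(y, dtype=float)
    n, p = Xraw.shape
    D = np.column_stack([np.ones(n), Xraw])
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(D @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = (D.T * w) @ D
        Hinv = np.linalg.pinv(H)
        # hat-matrix leverages of W^(1/2) D
        h = np.einsum("ij,jk,ik->i", D, Hinv, D) * w
        score = D.T @ (y - mu + h * (0.5 - mu))
        step = Hinv @ score
        # damp oversized steps instead of halving on a penalized objective
        m = np.max(np.abs(step))
        if m > 5.0:
            step *= 5.0 / m
        beta = beta + step
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    eta = np.clip(D @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = float(2.0 * np.sum(np.log1p(np.exp(eta)) - y * eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (D.T * w) @ D
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    idx = ["(Intercept)"] + names
    return LogisticFit(pd.Series(beta, index=idx), pd.Series(se, index=idx),
                       pd.Series(pvals, index=idx), dev, converged, it,
                       ("firth",))


def lasso_lambda_max(X, y) -> float:
    """Smallest penalty at which the L1-logistic solution is all-zero."""
    X, _ = _as_design(X)
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def _l1_logistic_fista(Xa: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                       L: float, tol: float = 1e-7,
                       max_iter: int = 20_000) -> np.ndarray:
    """Accelerated proximal-gradient (FISTA) path for L1 logistic regression.

    ``Xa`` includes the leading intercept column (unpenalized). The
    objective is mean log-loss + lambda * ||w||_1; soft-thresholding yields
    exact zeros. Warm starts down the (decreasing) lambda grid; gradient
    restarts keep the acceleration stable. Convergence is checked on the
    KKT residual.
    """
    n, p1 = Xa.shape
    out = np.empty((len(lambdas), p1))
    w = np.zeros(p1)
    for row, lam in enumerate(lambdas):
        v = w.copy()
        t = 1.0
        w_prev = w.copy()
        thr = lam / L
        for it in range(max_iter):
            mu = 1.0 / (1.0 + np.exp(-np.clip(Xa @ v, -500, 500)))
            grad = Xa.T @ (mu - y) / n
            raw = v - grad / L
            w_new = np.sign(raw) * np.maximum(np.abs(raw) - thr, 0.0)
            w_new[0] = raw[0]  # intercept unpenalized
            if (w_prev - w_new) @ (w_new - w) > 0.0:  # gradient restart
                t = 1.0
            t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
            v = w_new + ((t - 1.0) / t_new) * (w_new - w)
            w_prev, w, t = w, w_new, t_new
            if it % 10 == 9 or it == max_iter - 1:
                mu = 1.0 / (1.0 + np.exp(-np.clip(Xa @ w, -500, 500)))
                g = Xa.T @ (mu - y) / n
                active = w != 0.0
                active[0] = False
                kkt = abs(g[0])
                if active.any():
                    kkt = max(kkt, np.max(np.abs(g[active] + lam * np.sign(w[active]))))
                inactive = ~active
                inactive[0] = False
                if inactive.any():
                    kkt = max(kkt, np.max(np.abs(g[inactive])) - lam)
                if kkt < tol:
                    break
        out[row] = w
    return out


def lasso_logistic_path(X, y, lambdas, tol: float = 1e-7) -> pd.DataFrame:
    """L1-penalized logistic coefficients along a decreasing lambda grid.

    Penalty parameterization matches glmnet: the objective is mean log-loss
    plus lambda * ||beta||_1 (intercept unpenalized). Rows are lambdas,
    columns covariates plus an ``(Intercept)`` column; exact zeros mark
    excluded covariates. At lambda >= lasso_lambda_max the solution is
    all-zero; as lambda -> 0 it approaches the unpenalized fit.
    """
    Xm, names = _as_design(X)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("y must be binary with both classes present")
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be decreasing")
    Xa = np.column_stack([np.ones(len(y)), Xm])
    L = np.linalg.norm(Xa, 2) ** 2 / (4.0 * len(y))
    coefs = _l1_logistic_fista(Xa, y, lambdas, L, tol=tol)
    return pd.DataFrame(coefs, index=lambdas, columns=["(Intercept)"] + names)


def default_lambda_grid(X, y, n_lambda: int = 20, ratio: float = 0.05) -> np.ndarray:
    lmax = lasso_lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def cv_lambda(X, y, n_folds: int = 10, seed: int = 0, lambdas=None,
              rule: str = "1se") -> tuple[float, pd.DataFrame]:
    """Cross-validated penalty choice for the L1 logistic model.

    Stratified ``n_folds``-fold CV of validation log-loss over the lambda
    grid; ``rule='1se'`` (default, glmnet convention) returns the largest
    lambda whose mean loss is within one standard error of the minimum,
    ``rule='min'`` the minimizer itself.
    """
    Xm, _ = _as_design(X)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = default_lambda_grid(Xm, y)
    lambdas = np.asarray(lambdas, dtype=float)
    n = len(y)
    n_folds = min(n_folds, int(np.bincount(y.astype(int)).min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = np.empty((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(Xm, y)):
        Xa_tr = np.column_stack([np.ones(len(tr)), Xm[tr]])
        L = np.linalg.norm(Xa_tr, 2) ** 2 / (4.0 * len(tr))
        W = _l1_logistic_fista(Xa_tr, y[tr], lambdas, L, tol=1e-4,
                               max_iter=2000)
        Xa_va = np.column_stack([np.ones(len(va)), Xm[va]])
        prob = 1.0 / (1.0 + np.exp(-np.clip(Xa_va @ W.T, -500, 500)))
        prob = np.clip(prob, 1e-12, 1 - 1e-12)
        yv = y[va][:, None]
        losses[f] = -np.mean(yv * np.log(prob) + (1 - yv) * np.log(1 - prob), axis=0)
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / math.sqrt(n_folds)
    j_min = int(np.argmin(mean))
    if rule == "min":
        j = j_min
    elif rule == "1se":
        ok = np.where(mean <= mean[j_min] + se[j_min])[0]
        j = int(ok[0])  # grid is decreasing: first index = largest lambda
    else:
        raise ValueError(f"unknown rule {rule!r}")
    table = pd.DataFrame({"lambda": lambdas, "mean_loss": mean, "se_loss": se})
    return float(lambdas[j]), table


def kmeans(X, k: int, seed: int = 0, n_init: int = 10):
    """Lloyd k-means, best of ``n_init`` seeded restarts by inertia."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    km = _SkKMeans(n_clusters=k, n_init=n_init, random_state=seed,
                   algorithm="lloyd").fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc requires both classes present")
    return float(_sk_auc(labels, scores))
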