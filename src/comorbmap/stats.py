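"""Statistical layer: contingency odds ratios, ordinal ORs, group tests,
bootstrap machinery (BCa, bootstrapped t-test, wild-bootstrap regression)
and Benjamini–Hochberg q-values.

Conventions
-----------
* All p-values are two-sided.
* The 2x2 odds ratio is the cross-product ratio ``ad/bc`` (identical to
  the binomial-logistic MLE for a binary exposure), with a Woolf
  log-scale 95% interval.  Any zero cell makes the OR undefined (reported
  as NaN) unless the Haldane–Anscombe +0.5 correction is explicitly
  requested.
* Bootstrap intervals are bias-corrected and accelerated (BCa): the bias
  correction ``z0`` comes from the fraction of resample statistics below
  the point estimate, the acceleration ``a`` from the jackknife skewness.
* The wild bootstrap resamples regression responses as
  ``y* = yhat + w * e`` with i.i.d. random signs ``w`` (Rademacher by
  default, Mammen's two-point law optionally), preserving the per-
  observation error scale and hence heteroscedasticity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit, ndtr, ndtri

__all__ = [
    "OddsRatioResult", "TestResult", "BootstrapResult", "RegressionResult",
    "odds_ratio_2x2", "cumulative_logit_or", "chi_square", "fisher_exact",
    "likelihood_ratio_test", "mann_whitney", "welch_t", "cohen_d",
    "bootstrap_t", "wild_bootstrap_regression", "bca_interval", "bh_fdr",
]


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float

    @property
    def defined(self) -> bool:
        return self.odds_ratio == self.odds_ratio  # not NaN


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    effect_size: float | None = None
    q_value: float | None = None
    note: str | None = None


@dataclass
class BootstrapResult:
    estimate: float
    n_resamples: int
    resample_stats: np.ndarray
    ci_low: float
    ci_high: float
    seed: int | None
    p_value: float | None = None
    note: str | None = None


@dataclass
class RegressionResult:
    names: list[str]
    coefficients: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    adj_r_squared: float
    r_squared: float
    n_resamples: int
    resample_coefficients: np.ndarray  # B x p
    residuals: np.ndarray
    fitted: np.ndarray
    seed: int | None

    def coefficient(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.coefficients[i]), float(self.ci_low[i]), float(self.ci_high[i])


# ---------------------------------------------------------------------------
# contingency tables

def odds_ratio_2x2(a: int, b: int, c: int, d: int, *,
                   haldane: bool = False, level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf (log-OR Wald) interval.

    Cells: ``a`` exposed-impaired, ``b`` exposed-unimpaired, ``c``
    unexposed-impaired, ``d`` unexposed-unimpaired.  For a 2x2 table the
    logistic-regression MLE of the exposure OR equals ``ad/bc`` exactly.
    """
    cells = [a, b, c, d]
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cells must be non-negative integers")
    if any(x == 0 for x in cells):
        if not haldane:
            return OddsRatioResult(float("nan"), float("nan"), float("nan"),
                                   float("nan"))
        a, b, c, d = (x + 0.5 for x in cells)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = ndtri(0.5 + level / 2)
    return OddsRatioResult(math.exp(log_or), math.exp(log_or - z * se),
                           math.exp(log_or + z * se), se)


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c count table (no Yates correction).

    All-zero rows/columns are dropped with a warning; the degrees of
    freedom follow the reduced table.
    """
    table, note = _drop_zero_margins(np.asarray(table, dtype=float))
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), df=float(df), note=note)


def likelihood_ratio_test(table) -> TestResult:
    """Likelihood-ratio G-test: G = 2 * sum O * ln(O/E), df = (r-1)(c-1).

    Zero observed cells contribute nothing to G.
    """
    table, note = _drop_zero_margins(np.asarray(table, dtype=float))
    stat, p, df, _ = sps.chi2_contingency(table, correction=False,
                                          lambda_="log-likelihood")
    return TestResult(float(stat), float(p), df=float(df), note=note)


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table (hypergeometric p)."""
    stat, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(stat), float(p))


def _drop_zero_margins(table: np.ndarray) -> tuple[np.ndarray, str | None]:
    note = None
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        note = "all-zero rows/columns dropped; df adjusted"
        warnings.warn(note, stacklevel=3)
        table = table[rows][:, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table degenerate after dropping zero margins")
    return table, note


# ---------------------------------------------------------------------------
# cumulative-logit (proportional odds) OR

def cumulative_logit_or(outcome, group, *, level: float = 0.95,
                        max_iter: int = 100, tol: float = 1e-10) -> TestResult:
    """Common odds ratio of a binary group on an ordinal outcome.

    Fits the proportional-odds model ``P(Y <= j | x) = expit(theta_j -
    beta * x)`` by damped Newton iteration on the multinomial likelihood
    and returns ``exp(beta)`` with a Wald interval; with a two-level
    outcome this reduces exactly to binary logistic regression (the
    cross-product OR).  Complete separation is reported as non-convergent.
    """
    y = np.asarray(outcome)
    x = np.asarray(group, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and group must have equal length")
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 observed levels")
    if len(np.unique(x)) < 2:
        raise ValueError("need observations in both groups")
    y_idx = np.searchsorted(levels, y)
    K = len(levels)

    # counts n[g, j] for g in {0, 1}
    counts = np.zeros((2, K))
    for g in (0, 1):
        for j in range(K):
            counts[g, j] = np.sum((x == sorted(set(x))[g]) & (y_idx == j))

    def nll(params):
        theta, beta = params[:-1], params[-1]
        total = 0.0
        for g, xv in enumerate((0.0, 1.0)):
            gam = np.concatenate(([0.0], expit(theta - beta * xv), [1.0]))
            pi = np.clip(np.diff(gam), 1e-300, None)
            total -= float(np.sum(counts[g] * np.log(pi)))
        return total

    def grad(params):
        theta, beta = params[:-1], params[-1]
        g_theta = np.zeros(K - 1)
        g_beta = 0.0
        for g, xv in enumerate((0.0, 1.0)):
            gamma = expit(theta - beta * xv)
            gfull = np.concatenate(([0.0], gamma, [1.0]))
            pi = np.clip(np.diff(gfull), 1e-300, None)
            w = counts[g] / pi
            dgam = gamma * (1 - gamma)
            # d pi_j / d theta_j = dgam_j ; d pi_{j+1} / d theta_j = -dgam_j
            g_theta += -(w[:-1] - w[1:]) * dgam
            g_beta += xv * float(np.sum((w[:-1] - w[1:]) * dgam))
        return np.concatenate([g_theta, [g_beta]])

    # start at pooled cumulative logits, beta = 0
    pooled = counts.sum(axis=0)
    cum = np.clip(np.cumsum(pooled)[:-1] / pooled.sum(), 1e-6, 1 - 1e-6)
    params = np.concatenate([np.log(cum / (1 - cum)), [0.0]])

    converged = False
    for _ in range(max_iter):
        g = grad(params)
        if not np.all(np.isfinite(g)):
            break
        # numeric Hessian of the analytic gradient
        h = 1e-6 * np.maximum(1.0, np.abs(params))
        H = np.empty((K, K))
        for i in range(K):
            step = np.zeros(K)
            step[i] = h[i]
            H[:, i] = (grad(params + step) - grad(params - step)) / (2 * h[i])
        H = (H + H.T) / 2
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # damped step keeping cutpoints ordered and NLL decreasing
        step_size, f0 = 1.0, nll(params)
        for _ in range(40):
            cand = params - step_size * delta
            if np.all(np.diff(cand[:-1]) > 0) or K == 2:
                if nll(cand) <= f0 + 1e-12:
                    break
            step_size /= 2
        params = params - step_size * delta
        if np.max(np.abs(g)) < tol or np.max(np.abs(step_size * delta)) < 1e-12:
            converged = True
            break

    beta = float(params[-1])
    if not converged or abs(beta) > 30 or not np.isfinite(beta):
        return TestResult(float("nan"), float("nan"),
                          note="non-convergent (possible separation)")
    # Wald SE from the numeric Hessian at the optimum
    h = 1e-6 * np.maximum(1.0, np.abs(params))
    H = np.empty((K, K))
    for i in range(K):
        step = np.zeros(K)
        step[i] = h[i]
        H[:, i] = (grad(params + step) - grad(params - step)) / (2 * h[i])
    H = (H + H.T) / 2
    try:
        se = math.sqrt(np.linalg.inv(H)[-1, -1])
    except (np.linalg.LinAlgError, ValueError):
        se = float("nan")
    z = abs(beta) / se if se and se > 0 else float("inf")
    p = 2 * (1 - ndtr(z))
    res = TestResult(math.exp(beta), float(p))
    zc = ndtri(0.5 + level / 2)
    res.note = (f"95% CI ({math.exp(beta - zc * se):.4g}, "
                f"{math.exp(beta + zc * se):.4g})")
    res.ci = (math.exp(beta - zc * se), math.exp(beta + zc * se))
    return res


# ---------------------------------------------------------------------------
# two-sample tests

def mann_whitney(x, y) -> TestResult:
    """Mann–Whitney U with midranks, tie correction and continuity correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; U test degenerate", stacklevel=2)
        return TestResult(float(len(x) * len(y) / 2), 1.0, note="all tied")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue))


def welch_t(x, y) -> TestResult:
    """Welch's t-test with Satterthwaite degrees of freedom."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue),
                      df=float(res.df), effect_size=cohen_d(x, y))


def cohen_d(x, y) -> float:
    """Standardised mean difference with the pooled (n-1 weighted) SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / math.sqrt(sp2))


# ---------------------------------------------------------------------------
# BCa and bootstraps

def bca_interval(estimate: float, resample_stats, jackknife_stats,
                 level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    ``z0`` is the normal quantile of the fraction of resample statistics
    strictly below the estimate; the acceleration ``a`` is the jackknife
    skewness ``sum((mean - theta_i)^3) / (6 * sum((mean - theta_i)^2)^1.5)``.
    The endpoints are empirical quantiles of the resample distribution at
    ``Phi(z0 + (z0 +/- z_alpha) / (1 - a (z0 +/- z_alpha)))``.
    """
    theta = np.asarray(resample_stats, dtype=float)
    if len(theta) < 100:
        raise ValueError("need at least 100 resample statistics for BCa")
    if np.all(theta == theta[0]):
        warnings.warn("all resample statistics identical; degenerate interval",
                      stacklevel=2)
        return (float(estimate), float(estimate))
    frac = np.mean(theta < estimate)
    B = len(theta)
    if frac == 0.0 or frac == 1.0:
        warnings.warn("all resamples on one side of the estimate; "
                      "bias correction clamped", stacklevel=2)
        frac = min(max(frac, 1 / (B + 1)), B / (B + 1))
    z0 = ndtri(frac)
    jack = np.asarray(jackknife_stats, dtype=float)
    dev = jack.mean() - jack
    denom = np.sum(dev ** 2) ** 1.5
    a = float(np.sum(dev ** 3) / (6 * denom)) if denom > 0 else 0.0
    z_alpha = ndtri(0.5 + level / 2)
    lo_z, hi_z = z0 - z_alpha, z0 + z_alpha
    alphas = [ndtr(z0 + zz / (1 - a * zz)) for zz in (lo_z, hi_z)]
    lo, hi = np.quantile(theta, np.clip(alphas, 0.0, 1.0))
    return float(lo), float(hi)


def _jackknife_mean_diff(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out mean differences over the combined observations."""
    nx, ny = len(x), len(y)
    sx, sy = x.sum(), y.sum()
    mean_y, mean_x = sy / ny, sx / nx
    jx = (sx - x) / (nx - 1) - mean_y
    jy = mean_x - (sy - y) / (ny - 1)
    return np.concatenate([jx, jy])


def bootstrap_t(x, y, n_resamples: int = 1000, seed: int | None = None,
                level: float = 0.95) -> BootstrapResult:
    """Bootstrapped two-sample t-test on the mean difference.

    Each group is resampled with replacement; the BCa interval covers the
    mean difference.  The two-sided p-value studentises each resample
    under the null (both groups recentred on the grand mean) and compares
    Welch t statistics.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    rng = np.random.default_rng(seed)
    estimate = float(x.mean() - y.mean())
    if np.var(x) == 0 and np.var(y) == 0:
        warnings.warn("zero variance in both groups; degenerate bootstrap",
                      stacklevel=2)
        return BootstrapResult(estimate, n_resamples,
                               np.full(n_resamples, estimate), estimate,
                               estimate, seed, p_value=1.0, note="degenerate")
    bx = rng.integers(0, len(x), size=(n_resamples, len(x)))
    by = rng.integers(0, len(y), size=(n_resamples, len(y)))
    diffs = x[bx].mean(axis=1) - y[by].mean(axis=1)
    ci_lo, ci_hi = bca_interval(estimate, diffs, _jackknife_mean_diff(x, y),
                                level)

    def welch_stat(xs, ys):
        vx = xs.var(axis=1, ddof=1) / xs.shape[1]
        vy = ys.var(axis=1, ddof=1) / ys.shape[1]
        denom = np.sqrt(vx + vy)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (xs.mean(axis=1) - ys.mean(axis=1)) / denom

    grand = np.concatenate([x, y]).mean()
    x0, y0 = x - x.mean() + grand, y - y.mean() + grand
    t_null = welch_stat(x0[rng.integers(0, len(x), size=(n_resamples, len(x)))],
                        y0[rng.integers(0, len(y), size=(n_resamples, len(y)))])
    t_obs = welch_stat(x[None, :], y[None, :])[0]
    t_null = t_null[np.isfinite(t_null)]
    p = float((1 + np.sum(np.abs(t_null) >= abs(t_obs))) / (len(t_null) + 1))
    return BootstrapResult(estimate, n_resamples, diffs, ci_lo, ci_hi, seed,
                           p_value=p)


def _mammen_weights(rng, shape):
    # Mammen's two-point law: matches second and third error moments
    golden = (1 + math.sqrt(5)) / 2
    p = (golden) / math.sqrt(5)  # P(w = (1 - sqrt(5))/2)
    lo, hi = (1 - math.sqrt(5)) / 2, (1 + math.sqrt(5)) / 2
    return np.where(rng.random(shape) < p, lo, hi)


def wild_bootstrap_regression(X, y, names=None, n_resamples: int = 2000,
                              seed: int | None = None, level: float = 0.95,
                              weights: str = "rademacher") -> RegressionResult:
    """OLS with wild-bootstrap BCa intervals per coefficient.

    Resampled responses are ``y* = yhat + w * e`` with i.i.d. signs ``w``
    (Rademacher, or Mammen's two-point law), so skewed and heteroscedastic
    errors keep their per-observation scale.  Jackknife coefficients for
    the acceleration come from the leave-one-out OLS update.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length must match number of columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in range(p)
               if diag[j] < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(f"design matrix is rank deficient; "
                         f"collinear columns: {bad or 'undetermined'}")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - p) if n > p else float("nan")

    rng = np.random.default_rng(seed)
    if weights == "rademacher":
        w = rng.integers(0, 2, size=(n_resamples, n)) * 2.0 - 1.0
    elif weights == "mammen":
        w = _mammen_weights(rng, (n_resamples, n))
    else:
        raise ValueError("weights must be 'rademacher' or 'mammen'")
    boot = beta[None, :] + (w * resid[None, :]) @ pinv.T  # B x p

    # leave-one-out coefficients via the hat-matrix update
    h = np.einsum("ij,ji->i", X, pinv)
    denom = np.clip(1.0 - h, 1e-12, None)
    jack = beta[None, :] - (pinv.T * (resid / denom)[:, None])  # n x p

    lo = np.empty(p)
    hi = np.empty(p)
    for j in range(p):
        lo[j], hi[j] = bca_interval(float(beta[j]), boot[:, j], jack[:, j],
                                    level)
    return RegressionResult(names, beta, lo, hi, float(adj_r2), float(r2),
                            n_resamples, boot, resid, fitted, seed)


# ---------------------------------------------------------------------------
# multiple testing

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order of input preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
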