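"""Reusable statistical primitives.

The centrepiece is a linear-model fit with empirical-Bayes variance
moderation: per-feature residual variances s_g^2 (df d) are assumed to
follow a scaled-F prior with hyperparameters (d0, s0^2) estimated by
moment-matching the distribution of log s_g^2, and each feature's
variance is shrunk to the posterior

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

giving a moderated t-statistic with d0 + d degrees of freedom.  This is
the standard microarray linear-model machinery (the limma model); it is
implemented here directly from the closed forms.

The remaining primitives — Bartlett's variance-homogeneity test, Welch
and Student two-sample t-tests, Benjamini–Hochberg FDR, Fisher's exact
test for 2x2 enrichment and covariate-association checks — are thin,
vectorised wrappers with the guard behaviour the pipeline relies on
(NaN-aware FDR, zero-variance logging, Haldane–Anscombe odds ratios).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    q_value: float | None = None
    direction: int = 0  # sign of the effect, 0 when undefined
    significant: bool | None = None


@dataclass
class ModeratedFit:
    """Result of a moderated linear-model fit for one contrast.

    Arrays are aligned with ``feature_ids``.  ``df_prior`` may be
    ``inf`` when log-variances are near-constant across features (full
    shrinkage to the common prior variance).
    """

    feature_ids: pd.Index
    coefficients: np.ndarray       # effect estimates on the model scale
    sigma2: np.ndarray             # per-feature residual variance s^2
    df_residual: float             # residual df d
    df_prior: float                # d0
    s2_prior: float                # s0^2
    s2_post: np.ndarray            # posterior (shrunk) variance
    t: np.ndarray                  # moderated t
    p: np.ndarray                  # two-sided p on t(d0 + d)
    stdev_unscaled: float          # sqrt(v), v = unscaled coef variance

    @property
    def df_total(self) -> float:
        return self.df_prior + self.df_residual

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coefficients, "t": self.t, "p": self.p,
             "s2": self.sigma2, "s2_post": self.s2_post},
            index=self.feature_ids,
        )


# ---------------------------------------------------------------------------
# Empirical-Bayes hyperparameter estimation


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing and convex in 1/x, so the Newton
    step on that scale converges monotonically from x0 = 0.5 + 1/y.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-F prior for variances ``s2``.

    Matches the first two moments of log(s2): for s2 ~ s0^2 * F(d, d0),
    E[log s2] and Var[log s2] have closed forms in digamma/trigamma, so
    d0 solves trigamma(d0/2) = var(e) - trigamma(d/2) with
    e = log(s2) - digamma(d/2) + log(d/2).  A non-positive right-hand
    side (log-variances no more dispersed than chi-square sampling
    noise) yields d0 = inf and s0^2 = exp(mean(e)).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive finite variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if not np.isfinite(d0):
            logger.warning("trigamma inversion failed to bracket; using d0 = inf")
            return math.inf, float(np.mean(s2[ok]))
        s02 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # log-variances no more dispersed than chi-square sampling noise:
        # infinite prior df, prior variance = plain mean of the variances
        d0 = math.inf
        s02 = float(np.mean(s2[ok]))
    return d0, s02


def squeeze_var(s2: np.ndarray, df: float,
                d0: float | None = None, s02: float | None = None
                ) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward the fitted prior.

    Returns (posterior variances, d0, s0^2); hyperparameters may be
    supplied to bypass estimation (d0 = 0 disables shrinkage).
    """
    if d0 is None or s02 is None:
        d0, s02 = fit_f_dist(s2, df)
    if math.isinf(d0):
        post = np.full_like(np.asarray(s2, dtype=float), s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


def moderated_t_fit(M, design: pd.DataFrame, contrast: str,
                    d0_override: float | None = None,
                    s02_override: float | None = None) -> ModeratedFit:
    """Feature-wise OLS fit with empirical-Bayes moderated t for one
    design column.

    Parameters
    ----------
    M : MValueMatrix, ExpressionMatrix or DataFrame
        Feature x sample matrix; samples must match ``design`` rows.
    design : DataFrame
        Sample x covariate design matrix (full column rank required);
        for a paired analysis the pair-indicator columns are simply part
        of the design (fixed-effect blocking).
    contrast : str
        Name of the design column whose coefficient is tested.
    d0_override, s02_override :
        Fix the prior hyperparameters instead of estimating them
        (``d0_override=0`` reproduces the classical per-feature t).
    """
    data = M.data if hasattr(M, "data") else M
    Y = data.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    if list(design.index) != list(data.columns):
        data = data.loc[:, design.index]
        Y = data.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    d = n - p
    if d < 1:
        raise ValueError(
            "no residual degrees of freedom; drop covariates or add samples"
        )
    if contrast not in design.columns:
        raise ValueError(f"contrast {contrast!r} not a design column")
    j = design.columns.get_loc(contrast)

    xtx_inv = np.linalg.inv(X.T @ X)
    coef_all = Y @ (xtx_inv @ X.T).T          # features x p
    resid = Y - coef_all @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / d
    v = xtx_inv[j, j]
    coef = coef_all[:, j]

    if (d0_override is not None and d0_override == 0) or len(s2) < 2:
        if len(s2) < 2 and d0_override != 0:
            logger.info("fewer than 2 features: no variance shrinkage applied")
        s2_post, d0, s02 = s2.copy(), 0.0, float("nan")
    else:
        s2_post, d0, s02 = squeeze_var(s2, d, d0_override, s02_override)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / np.sqrt(s2_post * v)
    df_total = d0 + d
    if math.isinf(df_total):
        p_val = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_val = 2.0 * stats.t.sf(np.abs(t), df_total)

    return ModeratedFit(
        feature_ids=data.index, coefficients=coef, sigma2=s2,
        df_residual=float(d), df_prior=float(d0), s2_prior=float(s02),
        s2_post=s2_post, t=t, p=p_val, stdev_unscaled=float(math.sqrt(v)),
    )


# ---------------------------------------------------------------------------
# Variance-homogeneity and mean tests


def bartlett_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group Bartlett test.

    T = [(N - k) ln s_p^2 - sum_i (n_i - 1) ln s_i^2] / C with k = 2 and
    the Bartlett small-sample correction C; p from chi-square(1).  Rows
    with zero variance in either group get NaN p (logged by callers).
    """
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    v1 = np.var(X, axis=1, ddof=1)
    v2 = np.var(Y, axis=1, ddof=1)
    N, k = n1 + n2, 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (N - k)
    C = 1.0 + (1.0 / (3.0 * (k - 1))) * (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (N - k))
    with np.errstate(divide="ignore", invalid="ignore"):
        T = ((N - k) * np.log(sp2)
             - (n1 - 1) * np.log(v1) - (n2 - 1) * np.log(v2)) / C
    bad = (v1 <= 0) | (v2 <= 0)
    T = np.where(bad, np.nan, T)
    p = stats.chi2.sf(T, k - 1)
    p = np.where(bad, np.nan, p)
    return T, p


def bartlett_test(x, y) -> TestResult:
    """Two-group Bartlett variance-homogeneity test on 1-D samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
        logger.info("bartlett_test: zero variance in a group, p undefined")
        return TestResult(statistic=float("nan"), p_value=float("nan"))
    T, p = bartlett_rows(x[None, :], y[None, :])
    return TestResult(statistic=float(T[0]), p_value=float(p[0]),
                      direction=int(np.sign(np.var(x, ddof=1) - np.var(y, ddof=1))))


def welch_t_rows(X: np.ndarray, Y: np.ndarray,
                 equal_var: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t (Welch by default) via scipy."""
    res = stats.ttest_ind(X, Y, axis=1, equal_var=equal_var)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def two_sample_t(x, y, variant: str = "welch") -> TestResult:
    """Two-sample t-test; ``variant`` is 'student' (pooled) or 'welch'."""
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        logger.info("two_sample_t: degenerate group sizes, p undefined")
        return TestResult(statistic=float("nan"), p_value=float("nan"))
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      direction=int(np.sign(np.mean(x) - np.mean(y))))


# ---------------------------------------------------------------------------
# Multiple testing


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, NaN-aware.

    Missing p-values are excluded from the number of tests m and stay
    NaN in the output; the input order is restored.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# 2x2 enrichment


@dataclass
class EnrichmentResult:
    odds_ratio: float
    log_odds_ratio: float
    p_value: float


def enrichment_2x2(in_set_in_cat: int, in_set_out_cat: int,
                   bg_in_cat: int, bg_out_cat: int) -> EnrichmentResult:
    """Fisher's exact test on a disjoint 2x2 query/background table.

    The background counts must exclude the query set.  The odds ratio
    uses the Haldane–Anscombe +0.5 correction when any cell is zero, so
    log OR is always finite.
    """
    a, b, c, d = in_set_in_cat, in_set_out_cat, bg_in_cat, bg_out_cat
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(odds_ratio=float(orr),
                            log_odds_ratio=float(np.log(orr)),
                            p_value=float(p))


# ---------------------------------------------------------------------------
# Covariate association


def covariate_association(sample_summaries, covariate, kind: str,
                          alpha: float = 0.05) -> TestResult:
    """Associate a per-sample summary with a covariate.

    Continuous covariates use Pearson correlation (t-approximation p);
    categorical covariates (exactly two levels) use the two-sample
    rank-sum comparison.  ``significant`` flags p < alpha.
    """
    s = np.asarray(sample_summaries, dtype=float)
    if len(s) < 3:
        raise ValueError("need >= 3 samples")
    if kind == "continuous":
        c = np.asarray(covariate, dtype=float)
        ok = ~(np.isnan(s) | np.isnan(c))
        s, c = s[ok], c[ok]
        if np.std(c) == 0 or np.std(s) == 0:
            logger.info("covariate_association: constant input, p undefined")
            return TestResult(statistic=float("nan"), p_value=float("nan"))
        r, p = stats.pearsonr(c, s)
        return TestResult(statistic=float(r), p_value=float(p),
                          direction=int(np.sign(r)), significant=bool(p < alpha))
    if kind == "categorical":
        cov = pd.Series(covariate)
        ok = ~(pd.isna(cov).to_numpy() | np.isnan(s))
        cov, sv = cov[ok], s[ok]
        levels = sorted(cov.unique())
        if len(levels) != 2:
            raise ValueError(f"categorical covariate must have 2 levels, got {levels}")
        g0 = sv[(cov == levels[0]).to_numpy()]
        g1 = sv[(cov == levels[1]).to_numpy()]
        if np.all(g0[:, None] == g1[None, :]) and g0.size == g1.size:
            # identical distributions with zero spread: rank test is degenerate
            return TestResult(statistic=float("nan"), p_value=1.0,
                              significant=False)
        stat, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        return TestResult(statistic=float(stat), p_value=float(p),
                          direction=int(np.sign(np.mean(g0) - np.mean(g1))),
                          significant=bool(p < alpha))
    raise ValueError(f"kind must be 'continuous' or 'categorical', got {kind!r}")
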