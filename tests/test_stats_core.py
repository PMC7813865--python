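import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylstage.io_formats import MValueMatrix
from methylstage.stats_core import (
    bartlett_rows,
    bartlett_test,
    bh_fdr,
    covariate_association,
    enrichment_2x2,
    fit_f_dist,
    moderated_t_fit,
    two_sample_t,
)


def _random_m(n_features, n_samples, seed, scale_spread=True):
    rng = np.random.default_rng(seed)
    Y = rng.normal(0, 1, (n_features, n_samples))
    if scale_spread:
        Y *= rng.uniform(0.5, 2.0, (n_features, 1))
    return MValueMatrix(pd.DataFrame(
        Y, index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)]))


def _two_group_design(n1, n2):
    samples = [f"s{j}" for j in range(n1 + n2)]
    return pd.DataFrame({"intercept": 1.0,
                         "group": [0.0] * n1 + [1.0] * n2}, index=samples)


# ---------------------------------------------------------------------------
# moderated t


def test_no_shrinkage_limit_equals_classical_t():
    """With d0 forced to 0 the moderated t is the pooled two-sample t."""
    M = _random_m(30, 10, seed=1)
    design = _two_group_design(5, 5)
    fit = moderated_t_fit(M, design, "group", d0_override=0)
    Y = M.values
    ref = stats.ttest_ind(Y[:, 5:], Y[:, :5], axis=1, equal_var=True)
    np.testing.assert_allclose(fit.t, ref.statistic, atol=1e-10)
    np.testing.assert_allclose(fit.p, ref.pvalue, atol=1e-10)


def test_constant_variance_limit():
    """Identical per-feature variances give s0^2 = that variance, full
    shrinkage (s2_post = s2) and t = ordinary t with inflated df."""
    M = _random_m(40, 8, seed=2)
    design = _two_group_design(4, 4)
    first = moderated_t_fit(M, design, "group", d0_override=0)
    target = 0.7
    scaled = M.data.mul(np.sqrt(target / first.sigma2), axis=0)
    fit = moderated_t_fit(MValueMatrix(scaled), design, "group")
    assert math.isinf(fit.df_prior)
    assert fit.s2_prior == pytest.approx(target, rel=1e-10)
    np.testing.assert_allclose(fit.s2_post, fit.sigma2, rtol=1e-10)
    # t is the classical statistic evaluated at the common variance
    classical = fit.coefficients / np.sqrt(target) / fit.stdev_unscaled
    np.testing.assert_allclose(fit.t, classical, rtol=1e-10)
    # inflated df: p comes from the normal reference
    np.testing.assert_allclose(fit.p, 2 * stats.norm.sf(np.abs(fit.t)), atol=1e-12)


def test_null_p_values_uniform():
    """Simulated global null: moderated p-values are uniform (KS below
    the alpha=0.01 critical value for n=200)."""
    M = _random_m(200, 8, seed=3)
    fit = moderated_t_fit(M, _two_group_design(4, 4), "group")
    ks = stats.kstest(fit.p, "uniform").statistic
    assert ks < 1.628 / math.sqrt(200)


def test_posterior_variance_between_sample_and_prior():
    M = _random_m(150, 6, seed=4)
    fit = moderated_t_fit(M, _two_group_design(3, 3), "group")
    lo = np.minimum(fit.sigma2, fit.s2_prior)
    hi = np.maximum(fit.sigma2, fit.s2_prior)
    assert np.all(fit.s2_post >= lo - 1e-12)
    assert np.all(fit.s2_post <= hi + 1e-12)
    assert np.all((fit.p >= 0) & (fit.p <= 1))
    assert fit.df_prior >= 0


def test_design_validation():
    M = _random_m(10, 6, seed=5)
    design = _two_group_design(3, 3)
    design["dup"] = design["group"]  # rank-deficient
    with pytest.raises(ValueError, match="rank"):
        moderated_t_fit(M, design, "group")
    tiny = _two_group_design(1, 1)
    with pytest.raises(ValueError, match="residual degrees"):
        moderated_t_fit(_random_m(10, 2, seed=6), tiny, "group")


def test_moderated_fit_matches_limma(tmp_path):
    """Cross-check against the Bioconductor reference implementation on a
    seeded matrix with a covariate column."""
    rng = np.random.default_rng(42)
    Y = rng.normal(0, 1, (50, 6)) * rng.uniform(0.5, 2.0, (50, 1))
    Y[:10, 3:] += 1.5
    age = rng.uniform(40, 80, 6)
    M = MValueMatrix(pd.DataFrame(Y, index=[f"f{i}" for i in range(50)],
                                  columns=[f"s{j}" for j in range(6)]))
    design = pd.DataFrame({"intercept": 1.0,
                           "group": [0, 0, 0, 1, 1, 1],
                           "age": age}, index=M.data.columns, dtype=float)
    fit = moderated_t_fit(M, design, "group")

    ypath, dpath, opath = tmp_path / "y.csv", tmp_path / "d.csv", tmp_path / "o.csv"
    pd.DataFrame(Y).to_csv(ypath, index=False, header=False)
    design.to_csv(dpath, index=False)
    rscript = tmp_path / "check.R"
    rscript.write_text(textwrap.dedent(f"""
        suppressMessages(library(limma))
        Y <- as.matrix(read.csv("{ypath}", header=FALSE))
        design <- as.matrix(read.csv("{dpath}"))
        fit <- eBayes(lmFit(Y, design))
        write.csv(data.frame(t=fit$t[,"group"], p=fit$p.value[,"group"],
                             d0=fit$df.prior, s02=fit$s2.prior),
                  "{opath}", row.names=FALSE)
    """))
    subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
    ref = pd.read_csv(opath)
    np.testing.assert_allclose(fit.t, ref["t"], atol=1e-8)
    np.testing.assert_allclose(fit.p, ref["p"], atol=1e-8)
    assert fit.df_prior == pytest.approx(ref["d0"].iloc[0], abs=1e-6)
    assert fit.s2_prior == pytest.approx(ref["s02"].iloc[0], abs=1e-8)


def test_fit_f_dist_recovers_known_prior():
    """Variances sampled from a scaled-F prior give hyperparameter
    estimates near the truth (moment-matching consistency)."""
    rng = np.random.default_rng(9)
    d, d0_true, s02_true = 10, 8.0, 0.5
    s2 = s02_true * stats.f.rvs(d, d0_true, size=20000, random_state=rng)
    d0, s02 = fit_f_dist(s2, d)
    assert d0 == pytest.approx(d0_true, rel=0.15)
    assert s02 == pytest.approx(s02_true, rel=0.05)


# ---------------------------------------------------------------------------
# Bartlett


def test_bartlett_homogeneous_case():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = bartlett_test(x, x + 10)  # same variance, shifted mean
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_bartlett_formula_oracle():
    """n1=n2=10, s1^2=1, s2^2=4: statistic and p by direct evaluation of
    the corrected likelihood-ratio formula."""
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 10)
    y = rng.normal(0, 2, 10)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    sp2 = (9 * v1 + 9 * v2) / 18
    C = 1 + (1 / 3) * (1 / 9 + 1 / 9 - 1 / 18)
    T = (18 * math.log(sp2) - 9 * math.log(v1) - 9 * math.log(v2)) / C
    p = stats.chi2.sf(T, 1)
    res = bartlett_test(x, y)
    assert res.statistic == pytest.approx(T, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)


def test_bartlett_matches_scipy_rowwise():
    rng = np.random.default_rng(12)
    X = rng.normal(0, 1, (50, 8))
    Y = rng.normal(0, rng.uniform(0.5, 3), (50, 10))
    T, p = bartlett_rows(X, Y)
    for i in range(50):
        ref = stats.bartlett(X[i], Y[i])
        assert T[i] == pytest.approx(ref.statistic, rel=1e-10)
        assert p[i] == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-300)


def test_bartlett_symmetry_and_zero_variance():
    rng = np.random.default_rng(13)
    x, y = rng.normal(0, 1, 6), rng.normal(0, 2, 7)
    assert bartlett_test(x, y).statistic == pytest.approx(
        bartlett_test(y, x).statistic)
    res = bartlett_test(np.full(5, 0.3), y)
    assert math.isnan(res.p_value)


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=0.01, max_value=100.0))
def test_bartlett_scale_invariance(scale):
    rng = np.random.default_rng(14)
    x, y = rng.normal(0, 1, 8), rng.normal(0, 1.7, 8)
    base = bartlett_test(x, y)
    scaled = bartlett_test(x * scale, y * scale)
    assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# two-sample t


def test_t_test_hand_oracle():
    # x=(1,2,3), y=(4,5,6): pooled s^2 = 1, t = -3/sqrt(2/3), df = 4
    res = two_sample_t([1, 2, 3], [4, 5, 6], variant="student")
    t_expected = -3.0 / math.sqrt(2.0 / 3.0)
    assert res.statistic == pytest.approx(t_expected, rel=1e-12)
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_expected), 4), rel=1e-12)
    assert res.direction == -1


def test_t_test_antisymmetry_and_identical():
    rng = np.random.default_rng(15)
    x, y = rng.normal(0, 1, 6), rng.normal(1, 2, 8)
    for variant in ("student", "welch"):
        a = two_sample_t(x, y, variant)
        b = two_sample_t(y, x, variant)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)
    same = two_sample_t(x, x)
    assert same.statistic == pytest.approx(0.0, abs=1e-12)
    assert same.p_value == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# BH FDR


def test_bh_hand_step_up():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_degenerate_cases():
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_fdr([0.37]), [0.37])


def test_bh_matches_statsmodels_and_properties():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(16)
    p = rng.uniform(0, 1, 500)
    q = bh_fdr(p)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, ref, atol=1e-12)
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_nan_aware():
    q = bh_fdr([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))


# ---------------------------------------------------------------------------
# Fisher exact enrichment


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric point masses at
    tables as or more extreme, over all tables with the fixed margins."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    rv = stats.hypergeom(N, c1, r1)
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(x) for x in range(lo, hi + 1)
               if rv.pmf(x) <= p_obs * (1 + 1e-10))


def test_enrichment_no_association():
    res = enrichment_2x2(5, 5, 5, 5)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.log_odds_ratio == pytest.approx(0.0, abs=1e-12)


def test_enrichment_enumeration_oracle():
    res = enrichment_2x2(3, 1, 1, 3)
    assert res.odds_ratio == pytest.approx(9.0)
    assert res.p_value == pytest.approx(_fisher_enumeration(3, 1, 1, 3), rel=1e-10)


def test_enrichment_random_tables_match_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(40):
        a, b, c, d = rng.integers(0, 15, 4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        res = enrichment_2x2(int(a), int(b), int(c), int(d))
        assert res.p_value == pytest.approx(
            _fisher_enumeration(a, b, c, d), rel=1e-9), (a, b, c, d)


def test_enrichment_zero_cell_and_negative():
    res = enrichment_2x2(0, 10, 5, 5)
    assert math.isfinite(res.log_odds_ratio)
    with pytest.raises(ValueError):
        enrichment_2x2(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# covariate association


def test_covariate_linear_in_age():
    age = np.arange(40, 60, 2.0)
    res = covariate_association(0.1 + 0.002 * age, age, kind="continuous")
    assert abs(res.statistic) == pytest.approx(1.0)
    assert res.p_value < 1e-10
    assert res.significant


def test_covariate_identical_two_level():
    vals = np.array([0.5] * 6)
    res = covariate_association(vals, ["F", "M"] * 3, kind="categorical")
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_covariate_constant_guard_and_uniform_null():
    res = covariate_association([1.0, 2.0, 3.0], [5.0, 5.0, 5.0],
                                kind="continuous")
    assert math.isnan(res.p_value)
    rng = np.random.default_rng(18)
    ps = [covariate_association(rng.normal(size=20), rng.normal(size=20),
                                kind="continuous").p_value for _ in range(200)]
    assert stats.kstest(ps, "uniform").statistic < 1.628 / math.sqrt(200)
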