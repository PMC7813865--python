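"""Differential methylation (DMP) and differential variability (DVP)
calling.

DMPs: a probe is called when the disease-vs-control mean beta shift
passes the effect-size threshold (|delta beta| >= 0.1 by default) AND
the moderated-t p-value on the M scale (with additive age/sex
adjustment) is below 0.01.  The p-value is raw, not FDR-adjusted — the
joint effect-size + significance filter is already strongly
conservative.

DVPs: the iEVORA scheme.  Bartlett's test on beta values flags variance
heterogeneity; Benjamini–Hochberg FDR is applied across probes
(q < 0.05), and the surviving probes must also pass an ordinary
two-sample t-test (p < 0.05).  The t-filter regularizes the variance
test, which is overly sensitive to single outliers; called probes are
ranked by the t p-value.

Both callers run on disease group vs control; a paired variant handles
the mono/co-culture design with fixed-effect pair blocking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, DesignError, MValueMatrix, SampleSheet
from .stats_core import bartlett_rows, bh_fdr, moderated_t_fit, welch_t_rows

logger = logging.getLogger(__name__)

DMP_COLUMNS = ["probe_id", "delta_beta", "t", "p", "q", "direction", "called"]
DVP_COLUMNS = ["probe_id", "bartlett_stat", "bartlett_p", "bartlett_q",
               "t_p", "direction", "called", "rank"]


def build_design(sheet: SampleSheet, disease_group: str, control_group: str,
                 covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Design matrix: intercept + disease indicator + additive covariates.

    Samples with missing covariate values are excluded (with a logged
    count) rather than silently imputing or dropping the covariate.
    """
    df = sheet.data
    sel = df[df["group"].isin([disease_group, control_group])].copy()
    for g in (disease_group, control_group):
        if (sel["group"] == g).sum() < 2:
            raise DesignError(f"group {g!r} has fewer than 2 samples")
    cols = {"intercept": np.ones(len(sel)),
            "group": (sel["group"] == disease_group).astype(float).to_numpy()}
    keep = pd.Series(True, index=sel.index)
    for cov in covariates:
        if cov == "sex":
            vals = sel["sex"].map({"F": 0.0, "M": 1.0})
        else:
            vals = pd.to_numeric(sel[cov], errors="coerce")
        keep &= vals.notna()
        cols[cov] = vals.to_numpy(dtype=float)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d sample(s) with missing covariates: %s",
                    n_dropped, list(sel.index[~keep][:5]))
    design = pd.DataFrame(cols, index=sel.index)[["intercept", "group", *covariates]]
    design = design.loc[keep]
    # a covariate constant across retained samples would be collinear with
    # the intercept; drop it rather than fail the rank check
    for cov in covariates:
        if design[cov].nunique() <= 1:
            logger.info("dropping constant covariate %r", cov)
            design = design.drop(columns=cov)
    return design


def call_dmps(beta: BetaMatrix, M: MValueMatrix, sheet: SampleSheet,
              disease_group: str, control_group: str,
              delta_threshold: float = 0.1, p_threshold: float = 0.01,
              covariates: tuple[str, ...] = ("age", "sex"),
              apply_fdr: bool = False) -> pd.DataFrame:
    """Call differentially methylated positions for one stage.

    Tests run on M values (moderated t, additive covariates); the
    reported effect size delta_beta = mean beta(disease) - mean
    beta(control) is computed on the beta scale over the samples that
    enter the design.  ``called`` requires |delta_beta| >=
    delta_threshold AND p < p_threshold (q < p_threshold when
    ``apply_fdr``).
    """
    if list(beta.probe_ids) != list(M.probe_ids):
        raise ValueError("beta and M matrices must share probe axes")
    design = build_design(sheet, disease_group, control_group, covariates)
    samples = design.index
    fit = moderated_t_fit(MValueMatrix(M.data[list(samples)]), design, "group")

    grp = sheet.data.loc[samples, "group"]
    dis_cols = list(samples[grp == disease_group])
    ctl_cols = list(samples[grp == control_group])
    delta = (beta.data[dis_cols].mean(axis=1)
             - beta.data[ctl_cols].mean(axis=1)).to_numpy()

    p = fit.p
    q = bh_fdr(p)
    crit_p = q < p_threshold if apply_fdr else p < p_threshold
    called = (np.abs(delta) >= delta_threshold) & crit_p
    direction = np.where(delta > 0, "hyper", "hypo")
    out = pd.DataFrame({
        "probe_id": beta.probe_ids,
        "delta_beta": delta,
        "t": fit.t,
        "p": p,
        "q": q,
        "direction": direction,
        "called": called,
    })
    return out[["probe_id", "delta_beta", "t", "p", "q", "direction", "called"]]


def call_dvps(beta: BetaMatrix, sheet: SampleSheet,
              disease_group: str, control_group: str,
              fdr_threshold: float = 0.05, t_p_threshold: float = 0.05,
              t_variant: str = "welch") -> pd.DataFrame:
    """Call differentially variable positions (iEVORA) for one stage.

    Bartlett's test runs on beta values probe-wise; BH FDR across
    probes; probes with q < fdr_threshold must additionally pass a
    two-sample t-test at t_p_threshold (Welch by default, since variance
    heterogeneity is the tested hypothesis).  The called set is ranked
    by t p-value ascending (ties: bartlett q, then probe_id).  Direction
    is the sign of the group mean beta difference.
    """
    df = sheet.data
    dis = [s for s in df.index[df["group"] == disease_group] if s in beta.data.columns]
    ctl = [s for s in df.index[df["group"] == control_group] if s in beta.data.columns]
    if len(dis) < 3 or len(ctl) < 3:
        raise DesignError("variance tests need >= 3 samples per group")
    X = beta.data[dis].to_numpy()
    Y = beta.data[ctl].to_numpy()

    T, bart_p = bartlett_rows(X, Y)
    n_degenerate = int(np.isnan(bart_p).sum())
    if n_degenerate:
        logger.info("call_dvps: %d zero-variance probe(s) excluded from FDR",
                    n_degenerate)
    q = bh_fdr(bart_p)
    t_stat, t_p = welch_t_rows(X, Y, equal_var=(t_variant == "student"))

    delta = X.mean(axis=1) - Y.mean(axis=1)
    direction = np.where(delta > 0, "hyper", "hypo")
    called = (q < fdr_threshold) & (t_p < t_p_threshold)
    called = np.where(np.isnan(q) | np.isnan(t_p), False, called)

    out = pd.DataFrame({
        "probe_id": beta.probe_ids,
        "bartlett_stat": T,
        "bartlett_p": bart_p,
        "bartlett_q": q,
        "t_p": t_p,
        "direction": direction,
        "called": called.astype(bool),
    })
    rank = pd.Series(np.nan, index=out.index)
    called_idx = out.index[out["called"]]
    if len(called_idx):
        order = out.loc[called_idx].sort_values(
            ["t_p", "bartlett_q", "probe_id"]).index
        rank.loc[order] = np.arange(1, len(order) + 1)
    out["rank"] = rank
    return out[DVP_COLUMNS]


def call_dmps_paired(beta: BetaMatrix, M: MValueMatrix, sheet: SampleSheet,
                     condition: str = "cocult", baseline: str = "mono",
                     delta_threshold: float = 0.1,
                     p_threshold: float = 0.01) -> pd.DataFrame:
    """Paired DMP calling for the mono/co-culture design.

    Pair indicators enter the design as fixed effects; the tested
    coefficient is the within-pair condition contrast.  delta_beta is
    the mean of within-pair beta differences (condition - baseline).
    """
    sheet.validate_paired()
    df = sheet.data
    samples = [s for s in df.index if s in M.data.columns]
    sub = df.loc[samples]
    incomplete = [pid for pid, g in sub.groupby("pair_id") if len(g) != 2]
    if incomplete:
        raise DesignError(f"incomplete pairs in matrix: {sorted(incomplete)}")

    pair_dummies = pd.get_dummies(sub["pair_id"], prefix="pair").astype(float)
    design = pair_dummies.copy()
    design["condition"] = (sub["group"] == condition).astype(float)
    fit = moderated_t_fit(MValueMatrix(M.data[samples]), design, "condition")

    # within-pair differences, averaged over pairs
    diffs = []
    for pid, g in sub.groupby("pair_id"):
        c = g.index[g["group"] == condition][0]
        b = g.index[g["group"] == baseline][0]
        diffs.append(beta.data[c] - beta.data[b])
    delta = pd.concat(diffs, axis=1).mean(axis=1).to_numpy()

    called = (np.abs(delta) >= delta_threshold) & (fit.p < p_threshold)
    direction = np.where(delta > 0, "hyper", "hypo")
    return pd.DataFrame({
        "probe_id": beta.probe_ids,
        "delta_beta": delta,
        "t": fit.t,
        "p": fit.p,
        "direction": direction,
        "called": called,
    })


def called_sets(result: pd.DataFrame) -> dict[str, set[str]]:
    """Split a caller result into hyper/hypo called probe-id sets."""
    called = result[result["called"]]
    return {
        "hyper": set(called.loc[called["direction"] == "hyper", "probe_id"]),
        "hypo": set(called.loc[called["direction"] == "hypo", "probe_id"]),
    }
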