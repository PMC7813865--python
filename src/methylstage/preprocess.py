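"""Normalization, value transforms and probe/site filtering.

Effect sizes (delta-beta) are reported on the beta scale after quantile
normalization; hypothesis tests run on the M scale, where the additive
Gaussian error model is a far better approximation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import (
    BetaMatrix,
    MValueMatrix,
    ProbeAnnotation,
    RRBSTable,
    SampleSheet,
    SEX_CHROMS,
)

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1e-6


def beta_to_m(beta: BetaMatrix, eps: float = DEFAULT_EPS) -> MValueMatrix:
    """M = log2(b' / (1 - b')) with b' = clip(beta, eps, 1 - eps).

    Clipping bounds |M| at about 19.93 for eps = 1e-6, so the transform
    is finite for boundary beta while preserving ordering.  Missing
    values propagate as NaN.
    """
    if not (0 < eps < 0.5):
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    b = np.clip(beta.data.to_numpy(), eps, 1 - eps)
    b = np.where(np.isnan(beta.data.to_numpy()), np.nan, b)
    m = np.log2(b / (1 - b))
    return MValueMatrix(pd.DataFrame(m, index=beta.probe_ids, columns=beta.sample_ids))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse transform: beta = 2^M / (1 + 2^M)."""
    vals = m.data.to_numpy()
    # expit formulation avoids overflow for large |M|
    b = 1.0 / (1.0 + np.exp2(-vals))
    return BetaMatrix(pd.DataFrame(b, index=m.probe_ids, columns=m.sample_ids))


def _qn_values(vals: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``vals`` in place-free fashion.

    Each column is mapped onto the across-sample mean quantile curve.
    Ties receive the mean of the target quantiles over their rank span.
    Columns with missing values are mapped through interpolated
    fractional ranks against the same reference curve.
    """
    n, k = vals.shape
    sorted_cols = []
    counts = []
    for j in range(k):
        col = vals[:, j]
        obs = np.sort(col[~np.isnan(col)])
        sorted_cols.append(obs)
        counts.append(obs.size)
    # common reference grid of length n (interpolate shorter columns)
    grid = np.linspace(0, 1, n)
    ref = np.zeros(n)
    for obs in sorted_cols:
        if obs.size == n:
            ref += obs
        else:
            q = np.linspace(0, 1, obs.size)
            ref += np.interp(grid, q, obs)
    ref /= k

    out = np.full_like(vals, np.nan)
    for j in range(k):
        col = vals[:, j]
        mask = ~np.isnan(col)
        nj = int(mask.sum())
        # average rank handles ties -> mean of target quantiles on the span
        ranks = rankdata(col[mask], method="average")
        if nj == n:
            positions = ranks - 1.0
        else:
            positions = (ranks - 1.0) * (n - 1) / (nj - 1) if nj > 1 else np.zeros(nj)
        out[mask, j] = np.interp(positions, np.arange(n), ref)
    return out


def quantile_normalize(matrix: BetaMatrix | MValueMatrix):
    """Force every sample onto the mean empirical distribution.

    After normalization each sample's sorted values equal the
    across-sample mean quantile vector; within-sample ranks are
    preserved.  A single-sample matrix is returned unchanged with a
    warning.  The operation is idempotent.
    """
    if matrix.data.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix
    if matrix.data.isna().all(axis=0).any():
        raise ValueError("quantile_normalize: matrix contains an all-missing sample")
    vals = _qn_values(matrix.data.to_numpy(dtype=float))
    out = pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns)
    return type(matrix)(out)


def drop_high_missing_probes(beta: BetaMatrix, sheet: SampleSheet,
                             max_missing_frac: float = 0.2) -> BetaMatrix:
    """Drop probes missing in more than ``max_missing_frac`` of the
    samples of any group, with a logged count."""
    keep = pd.Series(True, index=beta.probe_ids)
    for group, sub in sheet.data.groupby("group"):
        cols = [s for s in sub.index if s in beta.data.columns]
        if not cols:
            continue
        frac = beta.data[cols].isna().mean(axis=1)
        keep &= frac <= max_missing_frac
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d probe(s) with >%d%% missing in a group",
                    dropped, int(max_missing_frac * 100))
    return BetaMatrix(beta.data.loc[keep])


def filter_probes(matrix: BetaMatrix | MValueMatrix, annotation: ProbeAnnotation,
                  drop_sex_chroms: bool = True, drop_blacklist: bool = True):
    """Remove chrX/chrY probes and culture-change blacklisted probes.

    Probes absent from the annotation are dropped and logged (skipped
    records).  Retained probes keep their original order.
    """
    ann = annotation.data
    in_ann = matrix.data.index.isin(ann.index)
    n_missing = int((~in_ann).sum())
    if n_missing:
        logger.warning("filter_probes: %d probe(s) absent from annotation, skipped: %s",
                       n_missing, list(matrix.data.index[~in_ann][:5]))
    keep = matrix.data.index[in_ann]
    sub = ann.loc[keep]
    mask = pd.Series(True, index=keep)
    if drop_sex_chroms:
        mask &= ~sub["chrom"].isin(SEX_CHROMS)
    if drop_blacklist:
        mask &= ~sub["blacklisted"]
    return type(matrix)(matrix.data.loc[keep[mask]])


def rrbs_site_filter(table: RRBSTable, min_reads: int = 5) -> RRBSTable:
    """Coverage-filter RRBS sites and compute per-site methylation.

    A site (chrom, pos) is retained only if its total read count is at
    least ``min_reads`` in *every* group present in the table, so that
    group comparisons use a common well-covered site set.  Retained rows
    gain ``fraction`` = meth_reads / total_reads.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    df = table.data.copy()
    ok = df["total_reads"] >= min_reads
    passing = df[ok].groupby(["chrom", "pos"])["group"].nunique()
    n_groups = df["group"].nunique()
    good_sites = set(passing[passing == n_groups].index)
    present = df.groupby(["chrom", "pos"])["group"].nunique()
    complete = set(present[present == n_groups].index)
    good_sites &= complete
    keep = df.apply(lambda r: (r["chrom"], r["pos"]) in good_sites, axis=1)
    out = df[keep].copy()
    out["fraction"] = out["meth_reads"] / out["total_reads"]
    logger.info("rrbs_site_filter: %d of %d sites pass >=%d reads in all groups",
                len(good_sites), df.groupby(["chrom", "pos"]).ngroups, min_reads)
    return RRBSTable(out)
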