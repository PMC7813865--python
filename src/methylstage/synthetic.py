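"""Synthetic EPIC-like fixture generator with planted, truth-tabled
effects.

The generator emulates the statistical structure of a stage-wise
methylome study on mesenchymal stromal cells: four sample groups
(healthy donors plus three disease stages), a bimodal beta background
(low-methylation mode near 0.1, high near 0.85), additive age/sex
covariate effects, planted mean-shift DMPs and planted outlier-driven
variance DVPs, and gene expression negatively coupled to promoter
methylation.

Noise is Gaussian on the M scale (log2 logit), i.e. beta values are
logit-normal.  That choice makes the M-value linear model exactly
Gaussian, so the moderated-t machinery can be checked against its own
distributional assumptions; it does not emulate probe-chemistry
artefacts of real arrays.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    CGI_RELATIONS,
    CHROMHMM_STATES,
    ExpressionMatrix,
    ProbeAnnotation,
    RRBSTable,
    SampleSheet,
)

logger = logging.getLogger(__name__)

# Study-scale defaults: healthy donors n=8, MGUS n=10, SMM n=8, MM n=9.
DEFAULT_SAMPLES_PER_GROUP = {"HD": 8, "MGUS": 10, "SMM": 8, "MM": 9}
STAGES = ("MGUS", "SMM", "MM")
STAGE_PATTERNS = (("MM",), ("SMM", "MM"), ("MGUS", "SMM", "MM"))

DEFAULT_CGI_FRACTIONS = {
    "Island": 0.20, "N_Shore": 0.10, "S_Shore": 0.10,
    "N_Shelf": 0.05, "S_Shelf": 0.05, "OpenSea": 0.50,
}


def _logit2(b):
    return np.log2(b / (1.0 - b))


def _sigmoid2(m):
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


@dataclass
class SimTruth:
    """Planted-effect ledger: one row per planted probe.

    Columns: probe_id, kind (DMP/DVP), stages (comma-joined subset of
    MGUS,SMM,MM), direction (hyper/hypo), delta_beta (DMP target),
    outlier_frac / outlier_shift (DVP parameters), gene (filled after
    annotation), expr_sign (filled by simulate_expression).
    """

    data: pd.DataFrame

    def probes(self, kind: str | None = None) -> set[str]:
        df = self.data
        if kind is not None:
            df = df[df["kind"] == kind]
        return set(df["probe_id"])

    def stage_sets(self, kind: str) -> dict[str, dict[str, set[str]]]:
        """Expected called sets per stage and direction for one kind."""
        out = {s: {"hyper": set(), "hypo": set()} for s in STAGES}
        for _, row in self.data[self.data["kind"] == kind].iterrows():
            for stage in row["stages"].split(","):
                out[stage][row["direction"]].add(row["probe_id"])
        return out


def simulate_methylome(n_probes: int = 10000,
                       samples_per_group: dict[str, int] | None = None,
                       n_dmp: int = 200, n_dvp: int = 200,
                       dmp_delta: float = 0.25,
                       dvp_outlier_frac: float = 0.3,
                       dvp_outlier_shift: float = 0.4,
                       noise_sd: float = 0.05,
                       age_range: tuple[int, int] = (40, 80),
                       age_slope: float = 0.01,
                       sex_effect: float = 0.5,
                       covariate_probe_frac: float = 0.05,
                       seed: int | None = None,
                       ) -> tuple[BetaMatrix, SampleSheet, SimTruth]:
    """Simulate a stage-structured beta matrix with planted effects.

    Background probes draw a baseline from a bimodal logit-normal
    mixture; per-sample noise is N(0, noise_sd) on the M scale.  Planted
    DMPs shift the affected disease groups' mean to achieve the target
    ``dmp_delta`` on the beta scale; planted DVPs convert a fraction of
    affected-group samples into outliers shifted by
    ``dvp_outlier_shift`` beta units.  Each planted probe is assigned a
    stage pattern uniformly among {MM only, SMM+MM, all three}, so the
    truth table supports progression-set recovery tests.

    Age adds ``age_slope`` M-units per year (centred) and male sex adds
    ``sex_effect`` M-units on a random ``covariate_probe_frac`` of
    probes.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_dmp + n_dvp > n_probes:
        raise ValueError("more planted probes than probes")
    rng = np.random.default_rng(seed)
    spg = dict(samples_per_group or DEFAULT_SAMPLES_PER_GROUP)

    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    sample_ids, groups = [], []
    for g in ("HD", "MGUS", "SMM", "MM"):
        for i in range(spg.get(g, 0)):
            sample_ids.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    n_samples = len(sample_ids)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_samples).astype(float)
    sexes = rng.choice(["F", "M"], size=n_samples)
    sheet = SampleSheet(pd.DataFrame(
        {"group": groups, "age": ages, "sex": sexes, "pair_id": pd.NA},
        index=pd.Index(sample_ids, name="sample_id")))

    # baseline: bimodal mixture on the M scale
    low = rng.random(n_probes) < 0.55
    base_m = np.where(low,
                      rng.normal(_logit2(0.10), 0.8, n_probes),
                      rng.normal(_logit2(0.85), 0.8, n_probes))

    # planted probes get mid-range baselines with headroom for the shifts
    planted_idx = rng.choice(n_probes, size=n_dmp + n_dvp, replace=False)
    dmp_idx = planted_idx[:n_dmp]
    dvp_idx = planted_idx[n_dmp:]
    for idx, shift in ((dmp_idx, dmp_delta), (dvp_idx, dvp_outlier_shift)):
        if shift >= 0.9:
            raise ValueError(f"infeasible planted shift {shift}: no [0,1] headroom")
        lo, hi = 0.05, 0.95 - shift
        base_m[idx] = _logit2(rng.uniform(lo + 0.05, hi - 0.02, size=len(idx)))

    group_arr = np.asarray(groups)
    M = np.tile(base_m[:, None], (1, n_samples))

    # additive covariate effects on a random subset of probes
    n_cov = int(covariate_probe_frac * n_probes)
    age_probes = rng.choice(n_probes, size=n_cov, replace=False)
    sex_probes = rng.choice(n_probes, size=n_cov, replace=False)
    age_c = ages - ages.mean()
    M[age_probes] += age_slope * age_c[None, :]
    M[sex_probes] += sex_effect * (sexes == "M")[None, :].astype(float)

    truth_rows = []
    base_b = _sigmoid2(base_m)

    # DMPs: shift affected stage means to baseline +/- delta on beta scale
    for idx in dmp_idx:
        b0 = base_b[idx]
        direction = rng.choice(["hyper", "hypo"])
        if direction == "hyper" and b0 + dmp_delta > 0.97:
            direction = "hypo"
        if direction == "hypo" and b0 - dmp_delta < 0.03:
            direction = "hyper"
        sign = 1.0 if direction == "hyper" else -1.0
        target = b0 + sign * dmp_delta
        if not (0.0 < target < 1.0):
            raise ValueError(f"infeasible delta {dmp_delta} at baseline {b0:.3f}")
        pattern = STAGE_PATTERNS[rng.integers(len(STAGE_PATTERNS))]
        mask = np.isin(group_arr, pattern)
        M[idx, mask] = _logit2(target)
        truth_rows.append({"probe_id": probe_ids[idx], "kind": "DMP",
                           "stages": ",".join(pattern), "direction": direction,
                           "delta_beta": sign * dmp_delta,
                           "outlier_frac": np.nan, "outlier_shift": np.nan})

    # DVPs: a fraction of affected-group samples become outliers
    for idx in dvp_idx:
        b0 = base_b[idx]
        direction = rng.choice(["hyper", "hypo"])
        if direction == "hyper" and b0 + dvp_outlier_shift > 0.97:
            direction = "hypo"
        if direction == "hypo" and b0 - dvp_outlier_shift < 0.03:
            direction = "hyper"
        sign = 1.0 if direction == "hyper" else -1.0
        target = b0 + sign * dvp_outlier_shift
        if not (0.0 < target < 1.0):
            raise ValueError(
                f"infeasible outlier shift {dvp_outlier_shift} at baseline {b0:.3f}")
        pattern = STAGE_PATTERNS[rng.integers(len(STAGE_PATTERNS))]
        for stage in pattern:
            cols = np.flatnonzero(group_arr == stage)
            n_out = max(1, int(round(dvp_outlier_frac * cols.size)))
            chosen = rng.choice(cols, size=n_out, replace=False)
            M[idx, chosen] = _logit2(target)
        truth_rows.append({"probe_id": probe_ids[idx], "kind": "DVP",
                           "stages": ",".join(pattern), "direction": direction,
                           "delta_beta": np.nan,
                           "outlier_frac": dvp_outlier_frac,
                           "outlier_shift": sign * dvp_outlier_shift})

    M += rng.normal(0.0, noise_sd, size=M.shape)
    beta = _sigmoid2(M)
    beta = np.clip(beta, 1e-12, 1 - 1e-12)  # strictly inside (0,1)

    beta_mat = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=sample_ids))
    truth = SimTruth(pd.DataFrame(
        truth_rows, columns=["probe_id", "kind", "stages", "direction",
                             "delta_beta", "outlier_frac", "outlier_shift"]))
    return beta_mat, sheet, truth


def simulate_annotation(probe_ids, cgi_fractions: dict[str, float] | None = None,
                        n_genes: int = 400, n_chroms: int = 5,
                        planted_probes=None, island_boost: float = 1.0,
                        blacklist_frac: float = 0.01,
                        seed: int | None = None,
                        ) -> tuple[ProbeAnnotation, pd.DataFrame]:
    """Place probes and gene TSSs on synthetic chromosomes.

    CGI-relation labels are drawn per ``cgi_fractions``; for probes in
    ``planted_probes`` the Island probability is multiplied by
    ``island_boost`` (renormalized), creating recoverable enrichment
    signal.  chromHMM states are drawn from a fixed non-uniform
    distribution over the 15 Roadmap labels.  Positions are strictly
    increasing within each chromosome.  Returns the annotation (with
    nearest_gene / tss_distance filled by brute-force nearest-TSS
    search) and the TSS table.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    fr = dict(cgi_fractions or DEFAULT_CGI_FRACTIONS)
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("cgi_fractions must sum to 1")
    levels = list(fr.keys())
    base_p = np.array([fr[l] for l in levels])

    planted = set(planted_probes or [])
    chroms = np.array([f"chr{i + 1}" for i in rng.integers(0, n_chroms, size=n)])
    pos = np.zeros(n, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        gaps = rng.integers(100, 5000, size=idx.size)
        pos[idx] = 1 + np.cumsum(gaps)

    cgi = np.empty(n, dtype=object)
    boost_p = base_p.copy()
    if island_boost != 1.0:
        boost_p[levels.index("Island")] *= island_boost
        boost_p = boost_p / boost_p.sum()
    for i, pid in enumerate(probe_ids):
        p = boost_p if pid in planted else base_p
        cgi[i] = levels[rng.choice(len(levels), p=p)]

    # mildly non-uniform state frequencies (quiescent-heavy, like real maps)
    state_w = np.array([3, 2, 1, 4, 6, 1, 3, 1, 2, 1, 1, 1, 2, 3, 12], dtype=float)
    state_p = state_w / state_w.sum()
    states = np.array(CHROMHMM_STATES)[rng.choice(15, size=n, p=state_p)]

    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    g_chrom = np.array([f"chr{i + 1}" for i in rng.integers(0, n_chroms, size=n_genes)])
    g_pos = np.zeros(n_genes, dtype=int)
    for c in np.unique(g_chrom):
        idx = np.flatnonzero(g_chrom == c)
        span = max(pos[chroms == c].max() if (chroms == c).any() else 10000, 10000)
        g_pos[idx] = np.sort(rng.choice(np.arange(1, span + 1), size=idx.size,
                                        replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    tss = pd.DataFrame({"gene": genes, "chrom": g_chrom,
                        "tss_pos": g_pos, "strand": strands})

    nearest = np.empty(n, dtype=object)
    tss_dist = np.zeros(n, dtype=int)
    for c, sub in tss.groupby("chrom"):
        idx = np.flatnonzero(chroms == c)
        if idx.size == 0:
            continue
        sub = sub.sort_values(["tss_pos", "gene"])
        dists = np.abs(pos[idx][:, None] - sub["tss_pos"].to_numpy()[None, :])
        best = np.argmin(dists, axis=1)
        for k, i in enumerate(idx):
            row = sub.iloc[best[k]]
            nearest[i] = row["gene"]
            signed = pos[i] - int(row["tss_pos"])
            tss_dist[i] = -signed if row["strand"] == "-" else signed

    blacklisted = rng.random(n) < blacklist_frac
    ann = ProbeAnnotation(pd.DataFrame(
        {"chrom": chroms, "pos": pos, "cgi_relation": cgi,
         "chromhmm_state": states, "nearest_gene": nearest,
         "tss_distance": tss_dist, "blacklisted": blacklisted},
        index=pd.Index(probe_ids, name="probe_id")))
    return ann, tss


def attach_genes(truth: SimTruth, annotation: ProbeAnnotation) -> SimTruth:
    """Fill the truth table's gene column from the annotation's
    nearest-gene assignment."""
    df = truth.data.copy()
    df["gene"] = [annotation.data.at[p, "nearest_gene"]
                  if p in annotation.data.index else pd.NA
                  for p in df["probe_id"]]
    return SimTruth(df)


def simulate_expression(truth: SimTruth, sheet: SampleSheet,
                        effect_size: float = 1.5, noise_sd: float = 0.5,
                        coupling_prob: float = 0.9,
                        n_background_genes: int = 300,
                        baseline_mean: float = 7.0, baseline_sd: float = 1.0,
                        seed: int | None = None,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate log-scale expression coupled to planted methylation.

    Each gene linked to a planted DMP receives, in the samples of the
    affected stages, a shift of ``effect_size`` log2 units whose sign
    opposes the methylation direction with probability
    ``coupling_prob`` (hypermethylated promoter -> downregulated gene)
    and matches it otherwise.  Unlinked background genes are pure noise.

    Returns the expression matrix and a gene-level truth table
    (gene, meth_direction, expr_sign, coupled, stages).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if not 0.0 <= coupling_prob <= 1.0:
        raise ValueError("coupling_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if "gene" not in truth.data.columns:
        raise ValueError("truth table lacks gene links; run attach_genes first")

    dmp = truth.data[(truth.data["kind"] == "DMP") & truth.data["gene"].notna()]
    # one expression effect per gene; genes claimed by planted probes with
    # conflicting directions carry no defined coupling and are left unlinked
    consistent = dmp.groupby("gene")["direction"].transform("nunique") == 1
    n_conflicted = int((~consistent).sum())
    if n_conflicted:
        logger.info("simulate_expression: %d probe link(s) dropped "
                    "(conflicting directions at a shared gene)", n_conflicted)
    gene_rows = dmp[consistent].drop_duplicates(subset="gene")
    samples = list(sheet.sample_ids)
    group_arr = sheet.data["group"].to_numpy()

    genes = list(gene_rows["gene"]) + [f"BG{i + 1:04d}"
                                       for i in range(n_background_genes)]
    expr = rng.normal(baseline_mean, baseline_sd, size=(len(genes), 1)) \
        + rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))

    truth_rows = []
    for row_i, (_, row) in enumerate(gene_rows.iterrows()):
        meth_sign = 1.0 if row["direction"] == "hyper" else -1.0
        coupled = rng.random() < coupling_prob
        expr_sign = -meth_sign if coupled else meth_sign
        mask = np.isin(group_arr, row["stages"].split(","))
        expr[row_i, mask] += expr_sign * effect_size
        truth_rows.append({"gene": row["gene"],
                           "meth_direction": row["direction"],
                           "expr_sign": int(expr_sign),
                           "coupled": coupled,
                           "stages": row["stages"]})

    mat = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    return mat, pd.DataFrame(truth_rows, columns=["gene", "meth_direction",
                                                  "expr_sign", "coupled", "stages"])


def simulate_rrbs(n_sites: int = 500, mean_depth: float = 30.0,
                  group_effects: dict[str, float] | None = None,
                  seed: int | None = None) -> RRBSTable:
    """Simulate per-CpG RRBS counts for two or more groups.

    Per site a base methylation fraction is drawn uniformly in
    (0.05, 0.95); each group's fraction adds its entry from
    ``group_effects`` (clipped to (0.01, 0.99)).  Depth is Poisson with
    mean ``mean_depth`` per site and group; methylated reads are
    binomial.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if mean_depth < 0:
        raise ValueError("mean depth must be nonnegative")
    rng = np.random.default_rng(seed)
    effects = dict(group_effects or {"HD": 0.0, "MM": 0.2})
    base = rng.uniform(0.05, 0.95, size=n_sites)
    pos = 1 + np.cumsum(rng.integers(50, 500, size=n_sites))
    rows = []
    for group, eff in effects.items():
        frac = np.clip(base + eff, 0.01, 0.99)
        depth = rng.poisson(mean_depth, size=n_sites)
        meth = rng.binomial(depth, frac)
        for i in range(n_sites):
            rows.append({"chrom": "chr1", "pos": int(pos[i]),
                         "meth_reads": int(meth[i]),
                         "total_reads": int(depth[i]), "group": group})
    return RRBSTable(pd.DataFrame(rows))
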