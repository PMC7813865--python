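"""Stage set algebra, progression-associated CpG selection, nearest-gene
mapping, differential expression and methylation–expression integration,
and categorical genomic-context enrichment.

The progression model treats myeloma as a multi-stage disease
(MGUS -> SMM -> MM vs healthy donors): accumulative methylation changes
are those called only in MM, shared by SMM and MM but not MGUS, or
present in all three stages.  All set operations run within a direction
(hyper / hypo); probes with conflicting directions across stages are
excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ProbeAnnotation, SampleSheet
from .stats_core import EnrichmentResult, enrichment_2x2, moderated_t_fit

logger = logging.getLogger(__name__)

DIRECTIONS = ("hyper", "hypo")
STAGES = ("MGUS", "SMM", "MM")

StageCalls = dict  # stage -> {"hyper": set, "hypo": set}


@dataclass
class ProgressionSets:
    """Progression-associated probe sets, split by direction.

    ``mm_only``, ``smm_and_mm`` and ``all_three`` are pairwise disjoint
    within each direction; ``union`` is their union (always a subset of
    the MM called set).
    """

    mm_only: dict[str, set[str]]
    smm_and_mm: dict[str, set[str]]
    all_three: dict[str, set[str]]
    union: dict[str, set[str]]
    conflicting: set[str] = field(default_factory=set)

    def counts(self) -> pd.DataFrame:
        rows = []
        for comp in ("mm_only", "smm_and_mm", "all_three", "union"):
            d = getattr(self, comp)
            rows.append({"component": comp,
                         "hyper": len(d["hyper"]), "hypo": len(d["hypo"])})
        return pd.DataFrame(rows)


def progression_sets(calls: StageCalls) -> ProgressionSets:
    """Select progression-associated probes from per-stage called sets.

    Within each direction: mm_only = MM minus (MGUS or SMM);
    smm_and_mm = (SMM and MM) minus MGUS; all_three = MGUS and SMM and
    MM.  A probe called hyper in one stage and hypo in another is
    dropped from every component and logged (accumulative changes are
    direction-consistent by definition).
    """
    for stage in STAGES:
        if stage not in calls:
            raise ValueError(f"missing stage {stage!r} in calls")

    hyper_any = set().union(*(calls[s]["hyper"] for s in STAGES))
    hypo_any = set().union(*(calls[s]["hypo"] for s in STAGES))
    conflicting = hyper_any & hypo_any
    if conflicting:
        logger.info("progression_sets: %d probe(s) with conflicting directions "
                    "across stages excluded", len(conflicting))

    out = {comp: {d: set() for d in DIRECTIONS}
           for comp in ("mm_only", "smm_and_mm", "all_three", "union")}
    for d in DIRECTIONS:
        mgus = calls["MGUS"][d] - conflicting
        smm = calls["SMM"][d] - conflicting
        mm = calls["MM"][d] - conflicting
        out["mm_only"][d] = mm - (mgus | smm)
        out["smm_and_mm"][d] = (smm & mm) - mgus
        out["all_three"][d] = mgus & smm & mm
        out["union"][d] = out["mm_only"][d] | out["smm_and_mm"][d] | out["all_three"][d]
        # partition sanity: components disjoint, union inside the MM calls
        assert not (out["mm_only"][d] & out["smm_and_mm"][d])
        assert not (out["mm_only"][d] & out["all_three"][d])
        assert not (out["smm_and_mm"][d] & out["all_three"][d])
        assert out["union"][d] <= mm
    return ProgressionSets(conflicting=conflicting, **out)


@dataclass
class OverlapResult:
    intersection: set[str]
    concordant: set[str]
    discordant: set[str]


def overlap_sets(set_a: dict[str, set[str]], set_b: dict[str, set[str]]
                 ) -> OverlapResult:
    """Intersect two direction-split probe sets.

    Returns the overall intersection plus the direction-concordant and
    discordant subsets (e.g. co-culture DMPs shared with patient DMPs).
    """
    all_a = set_a["hyper"] | set_a["hypo"]
    all_b = set_b["hyper"] | set_b["hypo"]
    inter = all_a & all_b
    concordant = (set_a["hyper"] & set_b["hyper"]) | (set_a["hypo"] & set_b["hypo"])
    return OverlapResult(intersection=inter,
                         concordant=concordant & inter,
                         discordant=inter - concordant)


def nearest_gene_map(probes, annotation: ProbeAnnotation,
                     tss_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each probe the gene with the nearest TSS on its chromosome.

    Distance is signed relative to transcription: negative upstream of
    the TSS.  Equidistant TSSs resolve to the lexicographically first
    gene symbol.  Probes on chromosomes without any TSS are left out of
    the result and logged.
    """
    ann = annotation.data
    rows = []
    unassigned = []
    tss_by_chrom = {c: g.sort_values(["tss_pos", "gene"])
                    for c, g in tss_table.groupby("chrom")}
    for probe in probes:
        if probe not in ann.index:
            unassigned.append(probe)
            continue
        chrom = ann.at[probe, "chrom"]
        pos = int(ann.at[probe, "pos"])
        g = tss_by_chrom.get(chrom)
        if g is None or g.empty:
            unassigned.append(probe)
            continue
        dist = (g["tss_pos"] - pos).abs().to_numpy()
        best = dist.min()
        cand = g[dist == best].sort_values("gene").iloc[0]
        signed = pos - int(cand["tss_pos"])
        if cand["strand"] == "-":
            signed = -signed
        rows.append({"probe_id": probe, "gene": cand["gene"],
                     "tss_distance": signed})
    if unassigned:
        logger.info("nearest_gene_map: %d probe(s) unassigned (no TSS on "
                    "chromosome or missing annotation): %s",
                    len(unassigned), unassigned[:5])
    return pd.DataFrame(rows, columns=["probe_id", "gene", "tss_distance"])


def differential_expression(expr: ExpressionMatrix, sheet: SampleSheet,
                            disease_group: str, control_group: str,
                            p_threshold: float = 0.05) -> pd.DataFrame:
    """Gene-wise moderated-t differential expression between two groups.

    Expression is assumed log-scale and probe-collapsed (duplicate gene
    rows were averaged on load).  Constant genes are excluded with a
    logged count.  ``called`` is p < p_threshold; direction follows the
    coefficient sign (up = higher in disease).
    """
    df = sheet.data
    dis = [s for s in df.index[df["group"] == disease_group]
           if s in expr.data.columns]
    ctl = [s for s in df.index[df["group"] == control_group]
           if s in expr.data.columns]
    if len(dis) < 2 or len(ctl) < 2:
        raise ValueError("need >= 2 samples per group for expression testing")
    samples = dis + ctl
    sub = expr.data[samples]
    variances = sub.var(axis=1, ddof=1)
    constant = variances == 0
    if constant.any():
        logger.info("differential_expression: %d constant gene(s) excluded",
                    int(constant.sum()))
    sub = sub.loc[~constant]
    design = pd.DataFrame(
        {"intercept": 1.0,
         "group": [1.0 if s in set(dis) else 0.0 for s in samples]},
        index=samples,
    )
    fit = moderated_t_fit(sub, design, "group")
    direction = np.where(fit.coefficients > 0, "up", "down")
    return pd.DataFrame({
        "gene": sub.index,
        "log_fc": fit.coefficients,
        "t": fit.t,
        "p": fit.p,
        "direction": direction,
        "called": fit.p < p_threshold,
    }).reset_index(drop=True)


def integrate_meth_expr(gene_meth: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    """Cross methylation direction with expression direction per gene.

    ``gene_meth`` maps called DMPs to genes (columns: probe_id, gene,
    direction); ``de`` is the differential-expression table.  Genes
    without a DE call are absent from the result.  A gene whose DMPs go
    in both directions appears once per direction, flagged ambiguous.
    Categories: hyper-down, hyper-up, hypo-down, hypo-up.
    """
    de_called = de[de["called"]].set_index("gene")
    meth_dirs = (gene_meth.groupby("gene")["direction"]
                 .agg(lambda s: sorted(set(s))))
    rows = []
    for gene, dirs in meth_dirs.items():
        if gene not in de_called.index:
            continue
        expr_dir = de_called.at[gene, "direction"]
        ambiguous = len(dirs) > 1
        for d in dirs:
            rows.append({"gene": gene, "meth_direction": d,
                         "expr_direction": expr_dir,
                         "category": f"{d}-{expr_dir}",
                         "ambiguous": ambiguous})
    return pd.DataFrame(
        rows, columns=["gene", "meth_direction", "expr_direction",
                       "category", "ambiguous"])


def integration_counts(result: pd.DataFrame) -> pd.Series:
    cats = ["hyper-down", "hyper-up", "hypo-down", "hypo-up"]
    if result.empty:
        return pd.Series(0, index=cats)
    return result["category"].value_counts().reindex(cats, fill_value=0)


def category_enrichment(query_probes, annotation: ProbeAnnotation,
                        category_field: str,
                        background_probes=None) -> pd.DataFrame:
    """Per-level 2x2 enrichment of a probe set within a genomic-context
    category (cgi_relation or chromHMM state) against a background.

    The background defaults to every annotated probe and must be a
    proper superset of the query (the 2x2 uses background minus query,
    so query == background is rejected).  The result carries the raw
    level fractions for query and background alongside OR / log OR /
    Fisher p per level.
    """
    if category_field not in ("cgi_relation", "chromhmm_state"):
        raise ValueError(f"unknown category field {category_field!r}")
    ann = annotation.data
    query = set(query_probes)
    bg = set(background_probes) if background_probes is not None else set(ann.index)
    if not query:
        logger.warning("category_enrichment: empty query set")
        return pd.DataFrame(columns=["level", "a", "b", "c", "d",
                                     "query_frac", "bg_frac",
                                     "odds_ratio", "log_odds_ratio", "p"])
    if not query <= bg:
        raise ValueError("query probes must be a subset of the background")
    if query == bg:
        raise ValueError("query must be a proper subset of the background")
    rest = bg - query
    q_cats = ann.loc[sorted(query), category_field]
    r_cats = ann.loc[sorted(rest), category_field]
    levels = sorted(set(ann.loc[sorted(bg), category_field].dropna()))
    rows = []
    for level in levels:
        a = int((q_cats == level).sum())
        b = len(query) - a
        c = int((r_cats == level).sum())
        d = len(rest) - c
        res: EnrichmentResult = enrichment_2x2(a, b, c, d)
        rows.append({"level": level, "a": a, "b": b, "c": c, "d": d,
                     "query_frac": a / len(query),
                     "bg_frac": (a + c) / len(bg),
                     "odds_ratio": res.odds_ratio,
                     "log_odds_ratio": res.log_odds_ratio,
                     "p": res.p_value})
    return pd.DataFrame(rows)
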