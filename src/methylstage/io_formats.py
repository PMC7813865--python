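"""Tabular readers/writers and the shared domain containers.

All pipeline inputs are delimited text: probe x sample methylation
matrices, sample sheets, probe annotation, expression matrices and RRBS
count tables.  Containers are thin validated wrappers around pandas
DataFrames; validation happens at construction so downstream code can
assume the invariants (values in range, unique ids, known vocabularies).

Coordinates are 1-based in every annotation table (Illumina manifest
convention); only BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Disease-stage and co-culture design vocabularies.
STAGE_GROUPS = ("HD", "MGUS", "SMM", "MM")
PAIRED_GROUPS = ("mono", "cocult")
VALID_GROUPS = frozenset(STAGE_GROUPS) | frozenset(PAIRED_GROUPS)

CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

# Roadmap 15-state chromHMM model labels.
CHROMHMM_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk",
    "EnhG", "Enh", "ZNF_Rpts", "Het", "TssBiv",
    "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

NA_VALUES = ("NA", "NaN", "")


class FormatError(ValueError):
    """Malformed file or out-of-range value; the message names the cell."""


class VocabularyError(ValueError):
    """A categorical field holds a label outside its fixed vocabulary."""


class DesignError(ValueError):
    """The sample layout cannot support the requested comparison."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probe x sample matrix of methylation fractions beta in [0, 1].

    ``data`` is indexed by probe_id with sample ids as columns; missing
    entries are NaN.  Construction validates the range and id uniqueness.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value {vals[i, j]!r} outside [0,1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class MValueMatrix:
    """Probe x sample matrix of M-values, M = log2(beta / (1 - beta))."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("M-value matrix contains infinities")
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class SampleSheet:
    """Per-sample metadata: group, optional age/sex/pair_id.

    ``data`` has one row per sample_id (the index) with columns
    ``group`` (HD/MGUS/SMM/MM or mono/cocult), ``age`` (years, float,
    NaN allowed), ``sex`` ('F'/'M', NaN allowed) and ``pair_id``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample ids")
        if "group" not in df.columns:
            raise FormatError("sample sheet lacks a 'group' column")
        bad = set(df["group"].dropna()) - VALID_GROUPS
        if bad:
            raise VocabularyError(
                f"unknown group label(s) {sorted(bad)}; "
                f"expected one of {sorted(VALID_GROUPS)}"
            )
        for col, default in (("age", np.nan), ("sex", pd.NA), ("pair_id", pd.NA)):
            if col not in df.columns:
                df[col] = default
        sexes = set(df["sex"].dropna()) - {"F", "M"}
        if sexes:
            raise VocabularyError(f"unknown sex label(s) {sorted(sexes)}")
        df["age"] = pd.to_numeric(df["age"], errors="raise")
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])

    def validate_paired(self) -> None:
        """In a paired design every pair_id occurs exactly twice, once per condition."""
        df = self.data
        if df["pair_id"].isna().any():
            missing = list(df.index[df["pair_id"].isna()])
            raise DesignError(f"samples without pair_id in paired design: {missing}")
        bad_pairs = []
        for pid, sub in df.groupby("pair_id"):
            if len(sub) != 2 or sub["group"].nunique() != 2:
                bad_pairs.append(pid)
        if bad_pairs:
            raise DesignError(f"incomplete or malformed pairs: {sorted(bad_pairs)}")


@dataclass
class ProbeAnnotation:
    """Per-probe genomic context driving enrichment and gene mapping.

    Columns: chrom, pos (1-based), cgi_relation, chromhmm_state,
    nearest_gene, tss_distance (signed bp), blacklisted (bool flag for
    long-term-culture-associated probes).  Indexed by probe_id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "probe ids")
        for col in ("chrom", "pos", "cgi_relation", "chromhmm_state"):
            if col not in df.columns:
                raise FormatError(f"probe annotation lacks column {col!r}")
        bad = set(df["cgi_relation"].dropna()) - set(CGI_RELATIONS)
        if bad:
            raise VocabularyError(
                f"unknown cgi_relation label(s) {sorted(bad)}; "
                f"expected {CGI_RELATIONS}"
            )
        bad = set(df["chromhmm_state"].dropna()) - set(CHROMHMM_STATES)
        if bad:
            raise VocabularyError(f"unknown chromHMM state label(s) {sorted(bad)}")
        if "blacklisted" not in df.columns:
            df["blacklisted"] = False
        df["blacklisted"] = df["blacklisted"].astype(bool)
        df["pos"] = df["pos"].astype(int)
        self.data = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of normalized log-scale expression.

    Duplicate gene rows (several array probes mapping to one gene) are
    averaged at construction, mirroring standard probe-to-gene collapse.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        if df.index.duplicated().any():
            n = int(df.index.duplicated().sum())
            logger.info("averaging %d duplicate gene rows", n)
            df = df.groupby(level=0, sort=False).mean()
        _check_unique(df.columns, "sample ids")
        self.data = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class RRBSTable:
    """Long-format RRBS counts: one row per (site, group).

    Columns: chrom, pos (1-based), meth_reads, total_reads, group; a
    ``fraction`` column appears after coverage filtering.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("chrom", "pos", "meth_reads", "total_reads", "group"):
            if col not in df.columns:
                raise FormatError(f"RRBS table lacks column {col!r}")
        df["pos"] = df["pos"].astype(int)
        df["meth_reads"] = df["meth_reads"].astype(int)
        df["total_reads"] = df["total_reads"].astype(int)
        if (df["total_reads"] < 0).any() or (df["meth_reads"] < 0).any():
            raise FormatError("negative read counts in RRBS table")
        bad = df["meth_reads"] > df["total_reads"]
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"meth_reads > total_reads at {row['chrom']}:{row['pos']}"
            )
        self.data = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Delimiter handling


def sniff_delimiter(path: str | Path, override: str | None = None) -> str:
    """Choose tab vs comma from the header line unless overridden."""
    if override is not None:
        return override
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# Readers


def read_beta_matrix(path: str | Path, sep: str | None = None) -> BetaMatrix:
    """Read a probe x sample beta matrix from delimited text.

    The header row carries sample ids; the first column carries probe
    ids.  ``NA`` encodes missing.  Out-of-range values raise
    :class:`FormatError` naming the offending probe and sample.
    """
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(NA_VALUES),
                     keep_default_na=False)
    if df.columns.size == 0:
        raise FormatError(f"{path}: no sample columns in header")
    return BetaMatrix(df)


def read_m_matrix(path: str | Path, sep: str | None = None) -> MValueMatrix:
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(NA_VALUES),
                     keep_default_na=False)
    return MValueMatrix(df)


def read_sample_sheet(path: str | Path, sep: str | None = None) -> SampleSheet:
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=list(NA_VALUES),
                     keep_default_na=False, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: sample sheet lacks a 'sample_id' column")
    return SampleSheet(df.set_index("sample_id"))


def read_probe_annotation(path: str | Path, sep: str | None = None) -> ProbeAnnotation:
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=list(NA_VALUES),
                     keep_default_na=False, dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: annotation lacks a 'probe_id' column")
    return ProbeAnnotation(df.set_index("probe_id"))


def read_expression_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(NA_VALUES),
                     keep_default_na=False)
    return ExpressionMatrix(df)


def read_rrbs_table(path: str | Path, sep: str | None = None) -> RRBSTable:
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep, na_values=list(NA_VALUES),
                     keep_default_na=False)
    return RRBSTable(df)


def read_tss_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """TSS table: gene, chrom, tss_pos (1-based), strand (+/-)."""
    sep = sniff_delimiter(path, sep)
    df = pd.read_csv(path, sep=sep)
    for col in ("gene", "chrom", "tss_pos", "strand"):
        if col not in df.columns:
            raise FormatError(f"{path}: TSS table lacks column {col!r}")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise VocabularyError(f"unknown strand label(s) {sorted(bad)}")
    df["tss_pos"] = df["tss_pos"].astype(int)
    return df


def read_blacklist(path: str | Path) -> set[str]:
    """One probe_id per line; '#' starts a comment."""
    probes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                probes.add(line)
    return probes


# ---------------------------------------------------------------------------
# Writers


def write_matrix(matrix: BetaMatrix | MValueMatrix | ExpressionMatrix,
                 path: str | Path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep, na_rep="NA")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  sep: str = "\t") -> dict[str, Path]:
    """Write each result table to ``<out_dir>/<name>.tsv``; column order
    is the table's own (callers build tables with the contract order)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep=sep, na_rep="NA",
                     index=not isinstance(table.index, pd.RangeIndex))
        written[name] = path
    return written


def export_bed(probe_set: Iterable[str], annotation: ProbeAnnotation,
               path: str | Path, name: str = "probes") -> list[str]:
    """Write a probe set as BED (0-based half-open: pos-1, pos).

    Probes absent from the annotation are skipped and returned (and
    logged), never silently dropped.
    """
    ann = annotation.data
    skipped: list[str] = []
    lines: list[str] = []
    for probe in probe_set:
        if probe not in ann.index:
            skipped.append(probe)
            continue
        row = ann.loc[probe]
        lines.append(f"{row['chrom']}\t{int(row['pos']) - 1}\t{int(row['pos'])}\t{probe}")
    with open(path, "w") as fh:
        fh.write(f"# {name}: BED export, 0-based half-open\n")
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
    if skipped:
        logger.warning("BED export skipped %d probe(s) absent from annotation: %s",
                       len(skipped), skipped[:5])
    return skipped
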