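"""Readers and writers for expression, centroid, clinical, and result tables.

All tables are plain UTF-8 text, tab-separated by default (comma accepted).
Floats are serialized with 17 significant digits so that read(write(x)) == x
at full double precision. Sample order is never changed by a reader: the
column order of the expression file is the single source of truth downstream.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical intrinsic subtype order used everywhere (also the tie-break order)
SUBTYPE_ORDER = ("Basal", "Her2", "LumA", "LumB", "Normal")

#: case-insensitive aliases accepted in centroid table headers
_SUBTYPE_ALIASES = {
    "basal": "Basal",
    "basal-like": "Basal",
    "her2": "Her2",
    "her2-enriched": "Her2",
    "her2e": "Her2",
    "luma": "LumA",
    "la": "LumA",
    "luminala": "LumA",
    "luminal a": "LumA",
    "lumb": "LumB",
    "lb": "LumB",
    "luminalb": "LumB",
    "luminal b": "LumB",
    "normal": "Normal",
    "normal-like": "Normal",
}

#: minimum number of panel genes required for classification to proceed
MIN_PANEL_GENES = 40

#: a sample missing more than this fraction of panel genes is rejected
MAX_MISSING_FRACTION = 0.20

FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """Raised for malformed or out-of-contract input tables."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with identifier bookkeeping.

    Values are nonnegative on input (normalized counts or intensities) and
    may become negative after gene centering. Missing values are NaN and are
    excluded pairwise from quantiles, medians, and correlations.
    """

    data: pd.DataFrame  # index = gene_ids, columns = sample_ids

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy())


@dataclass
class CentroidSet:
    """Gene panel with one reference profile per intrinsic subtype."""

    profiles: pd.DataFrame  # index = gene_ids, columns = SUBTYPE_ORDER

    def __post_init__(self) -> None:
        cols = list(self.profiles.columns)
        if sorted(cols) != sorted(SUBTYPE_ORDER):
            raise FormatError(
                f"centroid columns must be exactly {SUBTYPE_ORDER}, got {cols}"
            )
        # fix a canonical column order so downstream argmax tie-breaking is stable
        self.profiles = self.profiles[list(SUBTYPE_ORDER)]
        if self.profiles.index.duplicated().any():
            raise FormatError("duplicate gene identifiers in centroid table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class ClinicalRecord:
    """Per-sample IHC biomarker fields; missing fields stay None, never imputed.

    er_ihc / pr_ihc are either the strings "positive"/"negative" or a percent
    nuclear staining (float). her2_ihc is one of "0", "1+", "2+", "3+".
    """

    sample_id: str
    er_ihc: str | float | None = None
    pr_ihc: str | float | None = None
    her2_ihc: str | None = None
    her2_fish: str | None = None  # "amplified" / "not_amplified"
    ki67_pct: float | None = None


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    # delimiter sniffing is limited to tab and comma by design
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples (or samples x genes) expression table.

    Duplicate gene rows are collapsed by keeping the highest-variance row.
    Non-numeric data cells become NaN; a sample missing more than 20% of its
    values is rejected.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    delim = _sniff_sep(path, sep)
    raw = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")

    # strtod-exact parsing (pandas' fast float parser is not round-trip safe)
    def _cell(x):
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return np.nan
        try:
            return float(x)
        except ValueError:
            return np.nan

    df = raw.map(_cell)
    # report where parsing silently failed (NA tokens are legitimate missing)
    bad = df.isna() & raw.notna() & ~raw.isin(["NA", "NaN", "nan", ""])
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        logger.warning(
            "non-numeric cell at row %r column %r treated as missing",
            df.index[r],
            df.columns[c],
        )
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if df.index.duplicated().any():
        n_before = len(df)
        variances = df.var(axis=1, skipna=True).to_numpy()
        best: dict[str, tuple[int, float]] = {}
        for pos, (gene, var) in enumerate(zip(df.index, variances)):
            if gene not in best or var > best[gene][1]:
                best[gene] = (pos, var)
        keep = sorted(pos for pos, _ in best.values())
        df = df.iloc[keep]
        logger.info("collapsed %d duplicate gene rows by max variance", n_before - len(df))
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values on input")

    missing_frac = df.isna().mean(axis=0)
    too_missing = missing_frac[missing_frac > MAX_MISSING_FRACTION]
    if len(too_missing):
        raise FormatError(
            "samples missing >20% of genes: " + ", ".join(too_missing.index[:5])
        )
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


# ---------------------------------------------------------------------------
# centroids
# ---------------------------------------------------------------------------


def read_centroids(path: str | Path, sep: str | None = None) -> CentroidSet:
    """Read a centroid table: gene column followed by the five subtype columns.

    Column names are canonicalized through case-insensitive aliases
    (LumA/LA, LumB/LB, Her2/HER2-enriched, Basal, Normal). Fewer than 40
    genes is an error; fewer than 50 logs a warning.
    """
    path = Path(path)
    delim = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)

    rename: dict[str, str] = {}
    seen: dict[str, str] = {}
    for col in df.columns:
        canon = _SUBTYPE_ALIASES.get(str(col).strip().lower())
        if canon is None:
            logger.warning("ignoring unrecognized centroid column %r", col)
            continue
        if canon in seen:
            raise FormatError(
                f"ambiguous centroid columns {seen[canon]!r} and {col!r} both map to {canon}"
            )
        seen[canon] = str(col)
        rename[col] = canon
    missing = [s for s in SUBTYPE_ORDER if s not in seen]
    if missing:
        raise FormatError(f"centroid table missing subtype columns: {missing}")
    df = df[list(rename)].rename(columns=rename)
    df = df.apply(pd.to_numeric, errors="raise")

    if len(df) < MIN_PANEL_GENES:
        raise FormatError(
            f"centroid table has {len(df)} genes; at least {MIN_PANEL_GENES} required"
        )
    if len(df) < 50:
        logger.warning("centroid table has %d genes (expected 50)", len(df))
    return CentroidSet(df)


def write_centroids(c: CentroidSet, path: str | Path) -> None:
    c.profiles.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "sample_id": {"sample_id", "sample", "id", "case_id", "patient_id"},
    "er": {"er", "er_ihc", "er_status", "er_pct"},
    "pr": {"pr", "pr_ihc", "pr_status", "pr_pct"},
    "her2": {"her2", "her2_ihc", "her2_score"},
    "fish": {"her2_fish", "fish", "her2_fish_status"},
    "ki67": {"ki67", "ki67_pct", "ki67_percent", "mib1"},
}

_MISSING_TOKENS = {"", "na", "nan", "none", "missing", "unknown", "null", "."}


def _parse_er_pr(token: str | None, sample: str, field_name: str) -> str | float | None:
    if token is None:
        return None
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return None
    if t in {"pos", "positive", "+"}:
        return "positive"
    if t in {"neg", "negative", "-"}:
        return "negative"
    try:
        return float(t.rstrip("%"))
    except ValueError:
        raise FormatError(f"sample {sample}: cannot parse {field_name} value {token!r}")


def _parse_her2(token: str | None, sample: str) -> str | None:
    if token is None:
        return None
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return None
    t = t.rstrip("+")
    if t in {"0", "1", "2", "3"}:
        return "0" if t == "0" else f"{t}+"
    raise FormatError(f"sample {sample}: invalid HER2 IHC score {token!r} (expected 0/1+/2+/3+)")


def _parse_fish(token: str | None, sample: str) -> str | None:
    if token is None:
        return None
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return None
    if t in {"amplified", "amp", "positive", "pos"}:
        return "amplified"
    if t in {"not_amplified", "notamplified", "not-amplified", "negative", "neg", "normal"}:
        return "not_amplified"
    raise FormatError(f"sample {sample}: cannot parse HER2 FISH value {token!r}")


def _parse_ki67(token: str | None, sample: str) -> float | None:
    if token is None:
        return None
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return None
    try:
        return float(t.rstrip("%"))
    except ValueError:
        raise FormatError(f"sample {sample}: cannot parse Ki67 value {token!r}")


def read_clinical(path: str | Path, sep: str | None = None) -> list[ClinicalRecord]:
    """Read a clinical table with a sample_id column and any subset of IHC fields."""
    path = Path(path)
    delim = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=delim, dtype=str)
    colmap: dict[str, str] = {}
    for col in df.columns:
        low = str(col).strip().lower()
        for canon, aliases in _COLUMN_ALIASES.items():
            if low in aliases:
                colmap[canon] = col
                break
    if "sample_id" not in colmap:
        raise FormatError(f"{path}: no sample_id column found (columns: {list(df.columns)})")

    def cell(row: pd.Series, canon: str) -> str | None:
        if canon not in colmap:
            return None
        v = row[colmap[canon]]
        return None if pd.isna(v) else str(v)

    records: list[ClinicalRecord] = []
    for _, row in df.iterrows():
        sid = str(row[colmap["sample_id"]])
        records.append(
            ClinicalRecord(
                sample_id=sid,
                er_ihc=_parse_er_pr(cell(row, "er"), sid, "ER"),
                pr_ihc=_parse_er_pr(cell(row, "pr"), sid, "PR"),
                her2_ihc=_parse_her2(cell(row, "her2"), sid),
                her2_fish=_parse_fish(cell(row, "fish"), sid),
                ki67_pct=_parse_ki67(cell(row, "ki67"), sid),
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "er": "" if r.er_ihc is None else r.er_ihc,
                "pr": "" if r.pr_ihc is None else r.pr_ihc,
                "her2": "" if r.her2_ihc is None else r.her2_ihc,
                "her2_fish": "" if r.her2_fish is None else r.her2_fish,
                "ki67": "" if r.ki67_pct is None else r.ki67_pct,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# call tables
# ---------------------------------------------------------------------------

STAGES = ("conventional", "intermediate", "refined")


def calls_table(callset) -> pd.DataFrame:
    """Flatten a SubtypeCallSet into the stable output schema.

    One row per sample: sample_id, IHC subtype, the three stage labels, five
    per-centroid correlations per stage, and the PC1 coordinate. Columns for
    stages that were not run are emitted empty, never omitted.
    """
    columns = ["sample_id", "ihc_subtype"]
    columns += [f"{stage}_label" for stage in STAGES]
    for stage in STAGES:
        columns += [f"{stage}_r_{s}" for s in SUBTYPE_ORDER]
    columns.append("pc1")

    rows = []
    for sid in callset.sample_ids:
        row: dict[str, object] = {c: "" for c in columns}
        row["sample_id"] = sid
        ihc = callset.ihc_labels.get(sid)
        row["ihc_subtype"] = "" if ihc is None else ihc
        for stage in STAGES:
            calls = getattr(callset, stage)
            if not calls or sid not in calls:
                continue
            call = calls[sid]
            row[f"{stage}_label"] = call.label
            for s in SUBTYPE_ORDER:
                r = call.correlations.get(s)
                row[f"{stage}_r_{s}"] = "" if r is None or math.isnan(r) else FLOAT_FORMAT % r
        if callset.pc1_coords and sid in callset.pc1_coords:
            row["pc1"] = FLOAT_FORMAT % callset.pc1_coords[sid]
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def write_calls(callset, path: str | Path) -> None:
    table = calls_table(callset)
    if all(not getattr(callset, stage) for stage in STAGES):
        raise ValueError("no stage calls populated; nothing to write")
    table.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the calls table (labels come back verbatim)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
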