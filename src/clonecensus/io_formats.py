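"""Readers and writers for the package's tabular interchange formats.

All formats are UTF-8 TSV with a header row and "." for missing values.
Readers validate every row against the type invariants and never drop rows
silently: by default a malformed row raises, and with ``errors="collect"``
readers return the accepted frame together with a rejection report (line
number and reason per rejected row), so rows in = accepted + rejected.
Vendor exports with different column names can be mapped via ``column_map``
({our_name: vendor_name}).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .repertoire import classify_productivity, translate_cdr3
from .types import (
    DNA_ALPHABET,
    STRANDS,
    FeatureTable,
    MarkerHitTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING = "."

INTSITE_COLUMNS = [
    "subject_id", "timepoint_months", "chromosome", "position",
    "strand", "replicate_id", "fragment_length",
]
CLONOTYPE_COLUMNS = [
    "cdr3_nt", "cdr3_aa", "v_gene", "j_gene",
    "frame_status", "template_count", "replicate_id",
]
# optional passthrough columns used for grouping in pipelines
CLONOTYPE_OPTIONAL = ["subject_id", "timepoint_months", "cell_fraction"]


class TableFormatError(ValueError):
    """The file as a whole violates the format (missing columns, etc.)."""


class RowError(ValueError):
    """A single data row violates an invariant; carries a 1-based line number."""

    def __init__(self, line: int, reason: str):
        self.line = line
        self.reason = reason
        super().__init__(f"line {line}: {reason}")


def _read_tsv(path, required: list[str], column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _collect(rows, errors, n_header_lines=1):
    """Split (line, parsed-or-RowError) pairs into a frame and a report."""
    good, bad = [], []
    for line, item in rows:
        if isinstance(item, RowError):
            bad.append({"line": item.line, "reason": item.reason})
        else:
            good.append(item)
    if bad and errors == "raise":
        first = bad[0]
        raise RowError(first["line"], first["reason"])
    report = pd.DataFrame(bad, columns=["line", "reason"])
    return good, report


def read_intsite_table(
    path,
    column_map: dict[str, str] | None = None,
    merge_window: int = 0,
    errors: str = "raise",
):
    """Read an integration-site observation table.

    Returns a validated DataFrame with INTSITE_COLUMNS; duplicate rows are
    legitimate re-detections of the same fragment and are kept.  With
    ``merge_window`` > 0 (max 5 bp), sites on the same chromosome and
    strand within that many bp are merged to the minimum position, to
    absorb off-by-a-few shearing artifacts.  With ``errors="collect"``
    returns ``(frame, rejection_report)``.
    """
    raw = _read_tsv(path, INTSITE_COLUMNS, column_map)
    rows = []
    for i, rec in enumerate(raw[INTSITE_COLUMNS].itertuples(index=False), start=2):
        rows.append((i, _parse_intsite_row(rec, i)))
    good, report = _collect(rows, errors)
    df = pd.DataFrame(good, columns=INTSITE_COLUMNS)
    if len(df):
        df = df.astype({
            "timepoint_months": float, "position": np.int64, "fragment_length": np.int64,
        })
    if merge_window:
        df = merge_nearby_sites(df, merge_window)
    return (df, report) if errors == "collect" else df


def _parse_intsite_row(rec, line: int):
    try:
        subject, tp, chrom, pos, strand, rep, frag = rec
        if strand not in STRANDS:
            return RowError(line, f"invalid strand {strand!r}")
        pos_i = int(pos)
        if pos_i < 1:
            return RowError(line, f"position must be >= 1, got {pos_i}")
        frag_i = int(frag)
        if frag_i < 1:
            return RowError(line, f"fragment_length must be >= 1, got {frag_i}")
        tp_f = float(tp)
        if tp_f < 0:
            return RowError(line, f"timepoint_months must be >= 0, got {tp_f}")
        if not subject or pd.isna(subject):
            return RowError(line, "missing subject_id")
        return (subject, tp_f, chrom, pos_i, strand, rep, frag_i)
    except (TypeError, ValueError) as exc:
        return RowError(line, str(exc))


def merge_nearby_sites(df: pd.DataFrame, window: int) -> pd.DataFrame:
    """Merge integration positions within ``window`` bp (same chromosome and
    strand) to the minimum position of each run.  Window is capped at 5 bp."""
    if not 0 <= window <= 5:
        raise ValidationError("merge window must be in [0, 5] bp")
    if window == 0 or df.empty:
        return df
    df = df.sort_values(["chromosome", "strand", "position"], kind="stable").reset_index(drop=True)
    out = df.copy()
    for (_, _), idx in df.groupby(["chromosome", "strand"]).groups.items():
        pos = df.loc[idx, "position"].to_numpy()
        merged = pos.copy()
        anchor = pos[0]
        for j in range(1, len(pos)):
            if pos[j] - anchor <= window:
                merged[j] = anchor
            else:
                anchor = pos[j]
                merged[j] = anchor
        out.loc[idx, "position"] = merged
    return out


def write_intsite_table(df: pd.DataFrame, path) -> None:
    df[INTSITE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_clonotype_table(
    path,
    column_map: dict[str, str] | None = None,
    errors: str = "raise",
):
    """Read an immunoSeq-style TCR-beta clonotype table.

    Frame status is always recomputed from ``cdr3_nt``; the file's value is
    advisory and mismatches are logged (and counted in
    ``frame.attrs["frame_mismatches"]``), with the recomputed value
    winning.  Optional subject/timepoint/cell-fraction columns are passed
    through when present.
    """
    raw = _read_tsv(path, CLONOTYPE_COLUMNS, column_map)
    optional = [c for c in CLONOTYPE_OPTIONAL if c in raw.columns]
    cols = CLONOTYPE_COLUMNS + optional
    rows, mismatches = [], 0
    for i, rec in enumerate(raw[cols].itertuples(index=False), start=2):
        parsed = _parse_clonotype_row(rec, i, optional)
        if not isinstance(parsed, RowError) and parsed[-1]:
            mismatches += 1
        rows.append((i, parsed if isinstance(parsed, RowError) else parsed[0]))
    good, report = _collect(rows, errors)
    df = pd.DataFrame(good, columns=cols)
    if len(df):
        df = df.astype({"template_count": np.int64})
        if "timepoint_months" in df.columns:
            df = df.astype({"timepoint_months": float})
    if mismatches:
        logger.warning("%s: %d frame_status label(s) disagreed with the sequence; recomputed values used", path, mismatches)
    df.attrs["frame_mismatches"] = mismatches
    return (df, report) if errors == "collect" else df


_FRAME_ALIASES = {
    "in": "in_frame", "in_frame": "in_frame", "in-frame": "in_frame",
    "out": "frameshift", "frameshift": "frameshift",
    "stop": "stop", "has_stop": "stop",
}


def _parse_clonotype_row(rec, line: int, optional: list[str]):
    vals = list(rec)
    nt, aa, v, j, frame_label, templates, rep = vals[:7]
    extra = vals[7:]
    if not isinstance(nt, str) or not nt or not set(nt) <= DNA_ALPHABET:
        return RowError(line, f"cdr3_nt must be nonempty over ACGT, got {nt!r}")
    try:
        t = int(templates)
    except (TypeError, ValueError):
        return RowError(line, f"bad template_count {templates!r}")
    if t < 1:
        return RowError(line, f"template_count must be >= 1, got {t}")
    computed = classify_productivity(nt)
    labeled = _FRAME_ALIASES.get(str(frame_label).strip().lower())
    mismatch = labeled is not None and labeled != computed
    if pd.isna(aa) or aa is np.nan:
        aa = ""
    if computed == "in_frame" and not aa:
        aa = translate_cdr3(nt)
    elif computed != "in_frame":
        aa = ""
    return ((nt, aa, v, j, computed, t, rep, *extra), mismatch)


def write_clonotype_table(df: pd.DataFrame, path) -> None:
    cols = CLONOTYPE_COLUMNS + [c for c in CLONOTYPE_OPTIONAL if c in df.columns]
    out = df[cols].copy()
    out["cdr3_aa"] = out["cdr3_aa"].replace("", MISSING)
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_feature_table(counts_path, meta_path) -> FeatureTable:
    """Read a feature x sample count matrix plus its sample metadata.

    The matrix TSV has feature ids in the first column and one column per
    sample; the metadata TSV is keyed by ``sample_id``.  Samples without
    metadata are rejected with an error listing the orphans; negative
    counts are a format error.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, na_values=[MISSING])
    if counts.isna().any().any():
        raise TableFormatError(f"{counts_path}: missing values in count matrix")
    if (counts.to_numpy() < 0).any():
        bad = counts.lt(0).any()
        raise TableFormatError(
            f"{counts_path}: negative counts in sample(s) {list(bad[bad].index)}"
        )
    meta = pd.read_csv(meta_path, sep="\t", na_values=[MISSING])
    if "sample_id" not in meta.columns:
        raise TableFormatError(f"{meta_path}: missing required column(s): sample_id")
    meta = meta.set_index("sample_id")
    return FeatureTable(counts, meta)


def write_feature_table(table: FeatureTable, counts_path, meta_path) -> None:
    counts = table.counts.copy()
    counts.index.name = counts.index.name or "feature_id"
    counts.to_csv(counts_path, sep="\t", na_rep=MISSING)
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t", na_rep=MISSING)


def read_marker_hit_table(hits_path, samples_path) -> MarkerHitTable:
    """Read marker-gene hit counts for RPKM.

    The hits TSV has columns ``marker_id``, ``target_length_bp``, an
    optional ``marker_class``, then one column per sample; the samples TSV
    has ``sample_id`` and ``total_reads``.
    """
    raw = pd.read_csv(hits_path, sep="\t", na_values=[MISSING])
    for col in ("marker_id", "target_length_bp"):
        if col not in raw.columns:
            raise TableFormatError(f"{hits_path}: missing required column(s): {col}")
    raw = raw.set_index("marker_id")
    marker_class = raw.pop("marker_class") if "marker_class" in raw.columns else None
    lengths = raw.pop("target_length_bp")
    samples = pd.read_csv(samples_path, sep="\t", na_values=[MISSING])
    for col in ("sample_id", "total_reads"):
        if col not in samples.columns:
            raise TableFormatError(f"{samples_path}: missing required column(s): {col}")
    totals = samples.set_index("sample_id")["total_reads"]
    orphans = [s for s in raw.columns if s not in totals.index]
    if orphans:
        raise TableFormatError(f"{hits_path}: samples without total_reads: {orphans}")
    return MarkerHitTable(raw, lengths, totals, marker_class)
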