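"""Readers and writers for the tab-separated table dialects.

Three input dialects are supported:

* **segment tables** — the output shape of coverage segmentation (e.g.
  Circular Binary Segmentation): one genomic interval per row with the
  log2 tumor/normal coverage ratio;
* **pileup tables** — per-SNP allelic fraction and read depth for the
  tumor and the matched normal sample;
* **SNV read-count tables** — somatic variants with reference- and
  alternative-supporting read counts.

All genomic coordinates are 1-based and inclusive internally; the BED
convention (0-based start, half-open end) is applied only on export.
Column-name matching is case-insensitive through a synonym map, because
segment tables come from many upstream producers (CBS, CNVkit,
EXCAVATOR2, FACETS, ...). Missing values are encoded as ``-``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import TableFormatError, TableValidationError

NA_VALUES = ["-", "NA", "nan", ""]
NA_REP = "-"

#: Case-insensitive synonyms accepted for each canonical column name.
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "sample": ("sample", "id", "sample_id", "sample.id"),
    "chrom": ("chrom", "chr", "chromosome", "seqnames"),
    "start": ("start", "start.pos", "loc.start", "pos.start"),
    "end": ("end", "end.pos", "loc.end", "pos.end"),
    "logR": ("logr", "log2", "log2.ratio", "log2ratio", "seg.mean", "mean"),
    "pos": ("pos", "position"),
    "af": ("af", "allelic.fraction", "allele.fraction", "baf"),
    "cov": ("cov", "coverage", "depth", "dp"),
    "ref": ("ref", "ref_base", "reference"),
    "alt": ("alt", "alt_base", "alternative"),
    "rc_ref_tumor": ("rc_ref_tumor", "ref.count", "rc_ref"),
    "rc_alt_tumor": ("rc_alt_tumor", "alt.count", "rc_alt"),
}

#: Python-identifier column names mapped to their dotted on-disk form.
WRITE_RENAMES = {
    "beta_min": "beta.min",
    "beta_max": "beta.max",
    "log2_corr": "log2.corr",
    "cnA_int": "cnA.int",
    "cnB_int": "cnB.int",
    "clonality_min": "clonality.min",
    "clonality_max": "clonality.max",
    "clonality_status": "clonality.status",
    "SNV_clonality": "SNV.clonality",
    "SNV_clonality_min": "SNV.clonality.min",
    "SNV_clonality_max": "SNV.clonality.max",
    "SNV_clonality_status": "SNV.clonality.status",
}
READ_RENAMES = {v: k for k, v in WRITE_RENAMES.items()}


def _canonicalize_columns(df: pd.DataFrame, required: list[str],
                          optional: list[str] = ()) -> pd.DataFrame:
    """Rename recognized columns to canonical names; check required ones."""
    lower_map = {}
    for canonical, synonyms in COLUMN_SYNONYMS.items():
        for s in synonyms:
            lower_map[s] = canonical
    renames = {}
    seen = set()
    for col in df.columns:
        canonical = lower_map.get(str(col).lower())
        if canonical and canonical not in seen and canonical in (*required, *optional):
            renames[col] = canonical
            seen.add(canonical)
    df = df.rename(columns=renames)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"missing required column(s): {', '.join(missing)}", missing=missing
        )
    return df


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=True,
                     comment="#", dtype={"chrom": str})
    return df.rename(columns=READ_RENAMES)


def _check_numeric(df: pd.DataFrame, cols: list[str], table: str,
                   allow_na: tuple[str, ...] = ()) -> None:
    for col in cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if col not in allow_na:
            bad |= df[col].isna()
        if bad.any():
            rows = list(np.flatnonzero(bad.to_numpy()))
            raise TableValidationError(
                f"{table}: non-numeric or missing '{col}' in row(s) {rows}",
                rows=rows,
            )
        df[col] = values


def read_segment_table(path: str | os.PathLike,
                       sample: str | None = None) -> pd.DataFrame:
    """Read a segmented copy-number table.

    Parameters
    ----------
    path
        Tab-separated file with header naming at least chromosome,
        start, end and logR columns (synonyms accepted).
    sample
        Sample identifier used when the table carries no sample column.

    Returns
    -------
    DataFrame with columns ``sample, chrom, start, end, logR`` in the
    input row order. Coordinates are 1-based inclusive; ``logR`` may be
    missing (NaN) on individual rows.
    """
    df = _canonicalize_columns(_read_tsv(path), ["chrom", "start", "end", "logR"],
                               optional=["sample"])
    if "sample" not in df.columns:
        df["sample"] = sample or "sample1"
    _check_numeric(df, ["start", "end"], "segment table")
    _check_numeric(df, ["logR"], "segment table", allow_na=("logR",))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["end"] < df["start"]
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        raise TableValidationError(
            f"segment table: end < start in row(s) {rows}", rows=rows)
    dup = df.duplicated(subset=["sample", "chrom", "start", "end"], keep=False)
    if dup.any():
        rows = list(np.flatnonzero(dup.to_numpy()))
        raise TableValidationError(
            f"segment table: duplicate (chrom, start, end) in row(s) {rows}",
            rows=rows)
    return df[["sample", "chrom", "start", "end", "logR"]].reset_index(drop=True)


def read_pileup_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-SNP pileup table (``chrom, pos, af, cov``).

    Allelic fractions outside [0, 1] and duplicated (chrom, pos) rows
    are rejected with the offending row indices. ``cov = 0`` rows are
    accepted: coverage filtering is an estimation concern, not an I/O
    one.
    """
    df = _canonicalize_columns(_read_tsv(path), ["chrom", "pos", "af", "cov"])
    _check_numeric(df, ["pos", "af", "cov"], "pileup table")
    bad = (df["af"] < 0) | (df["af"] > 1)
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        raise TableValidationError(
            f"pileup table: allelic fraction outside [0, 1] in row(s) {rows}",
            rows=rows)
    bad = df["cov"] < 0
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        raise TableValidationError(
            f"pileup table: negative coverage in row(s) {rows}", rows=rows)
    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        rows = list(np.flatnonzero(dup.to_numpy()))
        dups = df.loc[dup, ["chrom", "pos"]].drop_duplicates()
        pairs = ", ".join(f"{c}:{int(p)}" for c, p in dups.itertuples(index=False))
        raise TableValidationError(
            f"pileup table: duplicate positions ({pairs}) in row(s) {rows}",
            rows=rows)
    df["pos"] = df["pos"].astype(np.int64)
    df["cov"] = df["cov"].astype(np.int64)
    return df[["chrom", "pos", "af", "cov"]].reset_index(drop=True)


def read_snv_table(path: str | os.PathLike,
                   sample: str | None = None) -> pd.DataFrame:
    """Read an SNV read-count table.

    Requires ``chrom, pos, rc_ref_tumor, rc_alt_tumor``; single-base
    ``ref``/``alt`` columns and a ``sample`` column are optional.
    """
    df = _canonicalize_columns(
        _read_tsv(path), ["chrom", "pos", "rc_ref_tumor", "rc_alt_tumor"],
        optional=["sample", "ref", "alt"])
    if "sample" not in df.columns:
        df["sample"] = sample or "sample1"
    for col in ("ref", "alt"):
        if col not in df.columns:
            df[col] = "N"
    _check_numeric(df, ["pos", "rc_ref_tumor", "rc_alt_tumor"], "SNV table")
    bad = (df["rc_ref_tumor"] < 0) | (df["rc_alt_tumor"] < 0)
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy()))
        raise TableValidationError(
            f"SNV table: negative read count in row(s) {rows}", rows=rows)
    df["pos"] = df["pos"].astype(np.int64)
    df["rc_ref_tumor"] = df["rc_ref_tumor"].astype(np.int64)
    df["rc_alt_tumor"] = df["rc_alt_tumor"].astype(np.int64)
    cols = ["sample", "chrom", "pos", "ref", "alt", "rc_ref_tumor", "rc_alt_tumor"]
    return df[cols].reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any result table as TSV with dotted column names and ``-`` NA."""
    df.rename(columns=WRITE_RENAMES).to_csv(
        path, sep="\t", index=False, na_rep=NA_REP)


def write_bed_compatible(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Export a per-segment table in BED-compatible form.

    The first three columns follow the BED convention (0-based start,
    half-open end: ``start_bed = start - 1``, ``end_bed = end``); every
    other column is appended after them, so the file can be annotated
    against any gene model with standard interval tools.
    """
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise TableFormatError(f"BED export requires column '{col}'",
                                   missing=[col])
    out = df.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    rest = [c for c in out.columns if c not in ("chrom", "start", "end")]
    out = out[["chrom", "start", "end", *rest]]
    out = out.rename(columns=WRITE_RENAMES)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        if len(out):
            out.to_csv(fh, sep="\t", index=False, header=False, na_rep=NA_REP)
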