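"""Readers and writers for count tables, call tables and genome tracks.

Two input dialects are supported:

* generic 6-column TSV: ``chrom  pos  strand  context  n_meth  n_total``
* Bismark-style cytosine report:
  ``chrom  pos  strand  count_methylated  count_unmethylated  context  tricontext``
  (``n_total`` is the sum of the two counts).

Input coordinates are 1-based; BED output is 0-based half-open.  Context
labels are normalized so that ``CG``/``CpG`` compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CALL_NO_DATA, COUNT_COLUMNS, CALL_METHYLATED

__all__ = [
    "CountTable",
    "read_counts",
    "write_counts",
    "write_calls",
    "write_bed",
    "write_bedgraph",
    "read_bed",
]

_CONTEXT_ALIASES = {"CG": "CpG", "CPG": "CpG", "CHG": "CHG", "CHH": "CHH"}


def _normalize_context(values: pd.Series) -> pd.Series:
    upper = values.astype(str).str.upper()
    return upper.map(_CONTEXT_ALIASES).fillna(values.astype(str))


@dataclass
class CountTable:
    """Ordered per-cytosine counts plus provenance metadata."""

    df: pd.DataFrame
    source: str = ""
    dialect: str = "generic"
    context_filter: str | None = None

    def __len__(self) -> int:
        return len(self.df)


def _validate_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in ("n_meth", "n_total", "pos"):
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise ValueError(f"{source}: malformed numeric field in column {col!r} at line {line}")
    df = df.astype({"pos": np.int64, "n_meth": np.int64, "n_total": np.int64})
    bad = (df["n_meth"] < 0) | (df["n_total"] < 0) | (df["n_meth"] > df["n_total"])
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise ValueError(f"{source}: n_meth > n_total (or negative counts) at line {line}")
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise ValueError(f"{source}: positions must be >= 1 (line {line})")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"{source}: duplicate site {row['chrom']}:{row['pos']}({row['strand']})"
        )
    return df[COUNT_COLUMNS]


def read_counts(
    path,
    format: str = "auto",
    context: str | None = "CpG",
    merge_strands: bool = False,
) -> CountTable:
    """Read a per-cytosine count table.

    Parameters
    ----------
    path
        TSV file in either supported dialect.
    format
        ``"generic"``, ``"bismark"`` or ``"auto"`` (detect by column count).
    context
        Keep only this sequence context (default CpG); ``None`` keeps all.
    merge_strands
        Sum the counts of +/- strand pairs at adjacent positions into one
        record on the + strand (symmetric CpG merging).  Off by default.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if format == "auto":
        format = "bismark" if raw.shape[1] >= 7 else "generic"
    if format == "generic":
        if raw.shape[1] < 6:
            raise ValueError(f"{path}: expected 6 columns, found {raw.shape[1]}")
        df = raw.iloc[:, :6].copy()
        df.columns = COUNT_COLUMNS
    elif format == "bismark":
        if raw.shape[1] < 6:
            raise ValueError(f"{path}: expected >= 6 columns for a cytosine report")
        df = pd.DataFrame(
            {
                "chrom": raw.iloc[:, 0],
                "pos": raw.iloc[:, 1],
                "strand": raw.iloc[:, 2],
                "context": raw.iloc[:, 5],
                "n_meth": pd.to_numeric(raw.iloc[:, 3], errors="coerce"),
                "n_total": pd.to_numeric(raw.iloc[:, 3], errors="coerce")
                + pd.to_numeric(raw.iloc[:, 4], errors="coerce"),
            }
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    df["context"] = _normalize_context(df["context"])
    df = _validate_counts(df, str(path))
    if context is not None:
        want = _normalize_context(pd.Series([context]))[0]
        df = df[df["context"] == want].reset_index(drop=True)
    if merge_strands:
        df = merge_symmetric_strands(df)
    return CountTable(df=df, source=str(path), dialect=format, context_filter=context)


def merge_symmetric_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Sum counts of symmetric CpG strand pairs onto the + strand position.

    A - strand cytosine at position p+1 is merged into the + strand
    cytosine at position p; unpaired records pass through unchanged.
    """
    plus = df[df["strand"] == "+"].copy()
    minus = df[df["strand"] == "-"].copy()
    other = df[~df["strand"].isin(["+", "-"])]
    minus = minus.assign(pos=minus["pos"] - 1)
    merged = plus.merge(
        minus[["chrom", "pos", "n_meth", "n_total"]],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("", "_m"),
    )
    for col in ("n_meth", "n_total"):
        merged[col] = merged[col].fillna(0) + merged[col + "_m"].fillna(0)
    merged["strand"] = "+"
    merged["context"] = merged["context"].fillna("CpG")
    merged = merged[COUNT_COLUMNS]
    out = pd.concat([merged, other], ignore_index=True)
    out = out.astype({"pos": np.int64, "n_meth": np.int64, "n_total": np.int64})
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def write_counts(df: pd.DataFrame, path) -> None:
    """Write a count table in the generic 6-column TSV dialect."""
    df[COUNT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _fmt_float(x) -> str:
    if pd.isna(x):
        return ""
    return f"{x:.6g}"


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a call table as TSV with a header row.

    Statistic columns absent from the input (e.g. ``p_value`` for the
    posterior-odds caller) and statistics of uncovered sites serialize as
    empty fields, never as 0 or 1.
    """
    cols = ["chrom", "pos", "strand", "n_meth", "n_total", "p_value", "q_value", "prior", "odds", "call"]
    out = calls.copy()
    for col in cols:
        if col not in out.columns:
            out[col] = np.nan
    out = out[cols]
    for col in ("p_value", "q_value", "prior", "odds"):
        out[col] = out[col].map(_fmt_float)
    out.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    """Read back a call table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t")
    df["call"] = df["call"].fillna(CALL_NO_DATA)
    return df


def write_bed(calls: pd.DataFrame, path, width: int = 1) -> None:
    """Write methylated sites as BED intervals (0-based half-open)."""
    meth = calls[calls["call"] == CALL_METHYLATED]
    bed = pd.DataFrame(
        {
            "chrom": meth["chrom"],
            "start": meth["pos"] - 1,
            "end": meth["pos"] - 1 + width,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: pd.DataFrame, path, span: int = 1) -> None:
    """Write a smoothed methylation track as bedGraph."""
    bg = pd.DataFrame(
        {
            "chrom": track["chrom"],
            "start": track["pos"] - 1,
            "end": track["pos"] - 1 + span,
            "value": track["level"].map(lambda x: f"{x:.6g}"),
        }
    )
    bg.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file of features (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3].copy()
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": np.int64, "end": np.int64})
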