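"""Readers and writers for the standard formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open. Conversion from
the 1-based input dialects (Bismark coverage files, Bismark cytosine reports)
happens here and only here, guarded by an explicit ``dialect`` argument, so
downstream code never has to reason about off-by-one shifts.

Per-CpG data are held as pandas DataFrames with columns
``chrom, pos, strand, n_meth, n_unmeth`` (``pos`` 0-based). Interval data use
``chrom, start, end`` (+ optional ``name``, ``score``), 0-based half-open.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

CPG_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
DMT_COLUMNS = ["chrom", "start", "end", "meth_diff", "p", "q", "direction"]

COVERAGE_DIALECTS = ("bismark-coverage", "cytosine-report")


class CpGSite(NamedTuple):
    """One cytosine's methylated/unmethylated read counts in one sample."""

    chrom: str
    pos: int  # 0-based
    strand: str  # '+', '-', or '.' when unknown
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


class GenomicInterval(NamedTuple):
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str = ""
    score: float = 0.0


class FormatError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def _fail(path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


def read_coverage_file(path, dialect: str) -> pd.DataFrame:
    """Read a per-CpG count table into the internal 0-based frame.

    Parameters
    ----------
    path
        Tab-separated input file.
    dialect
        ``"bismark-coverage"``: ``chrom  start  end  %meth  n_meth  n_unmeth``
        with 1-based inclusive ``start == end`` per CpG, strand unknown.
        ``"cytosine-report"``: ``chrom  pos  strand  n_meth  n_unmeth  context
        [tri]`` with 1-based ``pos``; zero-coverage rows are retained and
        flagged by the ``covered`` column.

    The %methylation column of the coverage dialect is never trusted: values
    inconsistent with the counts beyond rounding raise a warning and the
    counts win. Methylation percentages downstream are always recomputed as
    ``100 * n_meth / (n_meth + n_unmeth)``.
    """
    if dialect not in COVERAGE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {COVERAGE_DIALECTS}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bismark-coverage":
                if len(fields) < 6:
                    _fail(path, lineno, f"expected 6 tab-separated fields, got {len(fields)}")
                chrom, start_s, end_s, pct_s, m_s, u_s = fields[:6]
                try:
                    start, end = int(start_s), int(end_s)
                    pct, n_meth, n_unmeth = float(pct_s), int(m_s), int(u_s)
                except ValueError as exc:
                    _fail(path, lineno, f"unparseable field ({exc})")
                if n_meth < 0 or n_unmeth < 0:
                    _fail(path, lineno, "negative count")
                if start != end:
                    _fail(path, lineno, f"coverage rows are single CpGs, got start={start} end={end}")
                cov = n_meth + n_unmeth
                if cov > 0 and abs(pct - 100.0 * n_meth / cov) > 0.5:
                    warnings.warn(
                        f"{path}:{lineno}: %methylation {pct} inconsistent with counts "
                        f"{n_meth}/{cov}; counts win",
                        stacklevel=2,
                    )
                rows.append((chrom, start - 1, ".", n_meth, n_unmeth))
            else:  # cytosine-report
                if len(fields) < 5:
                    _fail(path, lineno, f"expected >=5 tab-separated fields, got {len(fields)}")
                chrom, pos_s, strand, m_s, u_s = fields[:5]
                try:
                    pos, n_meth, n_unmeth = int(pos_s), int(m_s), int(u_s)
                except ValueError as exc:
                    _fail(path, lineno, f"unparseable field ({exc})")
                if strand not in ("+", "-"):
                    _fail(path, lineno, f"bad strand {strand!r}")
                if n_meth < 0 or n_unmeth < 0:
                    _fail(path, lineno, "negative count")
                rows.append((chrom, pos - 1, strand, n_meth, n_unmeth))
    df = pd.DataFrame(rows, columns=CPG_COLUMNS)
    df["covered"] = (df["n_meth"] + df["n_unmeth"]) > 0
    return df


def write_coverage_file(sites: pd.DataFrame, path) -> None:
    """Write the internal CpG frame in Bismark coverage format (1-based)."""
    cov = sites["n_meth"] + sites["n_unmeth"]
    keep = cov > 0  # Bismark coverage files only list covered cytosines
    out = sites.loc[keep]
    covk = cov[keep].to_numpy()
    pct = 100.0 * out["n_meth"].to_numpy() / covk
    with open(path, "w") as fh:
        for chrom, pos, m, u, p in zip(
            out["chrom"], out["pos"], out["n_meth"], out["n_unmeth"], pct
        ):
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{p:.10g}\t{m}\t{u}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ intervals, 0-based half-open, sorted by (chrom, start).

    Overlapping intervals are preserved, never merged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"expected >=3 BED fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                _fail(path, lineno, f"unparseable coordinate ({exc})")
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError:
                score = 0.0
            rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path, columns: int = 6) -> None:
    """Write intervals as BED (0-based half-open), BED3 or BED6."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            if columns <= 3:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                name = getattr(row, "name", "") or "."
                score = getattr(row, "score", 0.0)
                strand = getattr(row, "strand", ".") or "."
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score:g}\t{strand}\n")


def write_dmt_table(calls: pd.DataFrame, path) -> None:
    """Write DMT calls as a BED-sortable tab-separated table with header.

    Columns: chrom, start, end, meth_diff, p, q, direction. Floats are
    written with 17 significant digits so a re-read reproduces them exactly.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(DMT_COLUMNS) + "\n")
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{row.meth_diff:.17g}\t{row.p:.17g}\t{row.q:.17g}\t{row.direction}\n"
            )


def read_dmt_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "start": np.int64,
            "end": np.int64,
            "meth_diff": float,
            "p": float,
            "q": float,
            "direction": str,
        },
    )
    missing = set(DMT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing DMT columns {sorted(missing)}")
    return df[DMT_COLUMNS]
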