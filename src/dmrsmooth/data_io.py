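"""Reading, validating and writing methylation count tables and region calls.

Input counts are per-CpG-site, per-replicate (methylated, total) pairs from
whole-genome bisulfite sequencing, either in the 6-column Bismark coverage
dialect or a generic 4-column TSV. Internally coordinates are 1-based site
positions; BED output converts to 0-based half-open. Strand is ignored: CpG
sites are treated as strand-collapsed single coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteTable",
    "read_counts",
    "merge_replicates",
    "filter_zero_total",
    "write_bed",
    "read_bed",
    "write_regions_tsv",
]

#: columns of a single-replicate count table
COUNT_COLUMNS = ("chrom", "pos", "meth", "total")


class CountTableError(ValueError):
    """Raised for malformed or invariant-violating count input."""


@dataclass
class SiteTable:
    """Aligned per-site counts for two groups of replicates on one chromosome.

    Count arrays have shape ``(n_sites, n_replicates)``; replicate columns are
    aligned by position across replicates (missing cells are explicit zero
    fills recorded by :func:`merge_replicates`, never silent).
    """

    chrom: str
    pos: np.ndarray  # 1-based bp, strictly increasing
    a_meth: np.ndarray
    a_total: np.ndarray
    b_meth: np.ndarray
    b_total: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for name in ("a_meth", "a_total", "b_meth", "b_total"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=np.int64))
            setattr(self, name, arr)
        n = self.pos.shape[0]
        for name in ("a_meth", "a_total", "b_meth", "b_total"):
            if getattr(self, name).shape[0] != n:
                raise CountTableError(f"{name} has wrong number of sites")
        if n > 1 and not np.all(np.diff(self.pos) > 0):
            raise CountTableError(
                f"positions must be strictly increasing within {self.chrom!r} "
                "(duplicates rejected)"
            )
        for meth, total in ((self.a_meth, self.a_total), (self.b_meth, self.b_total)):
            if np.any(meth < 0) or np.any(total < 0):
                raise CountTableError("negative counts")
            if np.any(meth > total):
                raise CountTableError("methylated count exceeds total count")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_reps(self) -> tuple[int, int]:
        return self.a_meth.shape[1], self.b_meth.shape[1]

    def take(self, idx: np.ndarray) -> "SiteTable":
        return SiteTable(
            self.chrom,
            self.pos[idx],
            self.a_meth[idx],
            self.a_total[idx],
            self.b_meth[idx],
            self.b_total[idx],
        )


def read_counts(path: str | Path, format: str = "bismark_cov") -> pd.DataFrame:
    """Read a single-replicate count table.

    ``bismark_cov``: 6 columns (chrom, start, end, meth%, count_meth,
    count_unmeth), 1-based; converted to pos=start, meth=count_meth,
    total=count_meth+count_unmeth. ``tsv``: 4 columns (chrom, pos, meth,
    total). gzip is handled transparently. Lines starting with ``#`` are
    ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("bismark_cov", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", compression="infer", dtype=str
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty count file: %s", path)
        return pd.DataFrame(columns=COUNT_COLUMNS).astype(
            {"pos": np.int64, "meth": np.int64, "total": np.int64}, errors="ignore"
        )

    ncol = 6 if format == "bismark_cov" else 4
    if raw.shape[1] < ncol:
        raise CountTableError(
            f"{path}: expected {ncol} tab-separated columns for {format}, "
            f"got {raw.shape[1]}"
        )

    def _int_col(col: pd.Series, name: str) -> np.ndarray:
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CountTableError(f"{path}: malformed {name} field at data line {line}")
        return vals.to_numpy(dtype=np.int64)

    chrom = raw[0].astype(str)
    if format == "bismark_cov":
        pos = _int_col(raw[1], "start")
        meth = _int_col(raw[4], "count_meth")
        unmeth = _int_col(raw[5], "count_unmeth")
        total = meth + unmeth
    else:
        pos = _int_col(raw[1], "pos")
        meth = _int_col(raw[2], "meth")
        total = _int_col(raw[3], "total")

    df = pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "total": total})
    for cond, msg in (
        (df["meth"] < 0, "negative methylated count"),
        (df["total"] < 0, "negative total count"),
        (df["meth"] > df["total"], "methylated count exceeds total"),
    ):
        if cond.any():
            line = int(np.flatnonzero(cond.to_numpy())[0]) + 1
            raise CountTableError(f"{path}: {msg} at data line {line}")
    return df


def merge_replicates(
    tables: Sequence[pd.DataFrame],
    group_a_ids: Sequence[int],
    group_b_ids: Sequence[int],
) -> tuple[SiteTable, int]:
    """Outer-join replicate tables on position into an aligned SiteTable.

    ``group_a_ids``/``group_b_ids`` index into ``tables``. Positions are
    unioned across replicates; absent (position, replicate) cells are filled
    with (0, 0) counts — the fill count is returned and logged, never silent.
    All tables must carry a single, identical chromosome label.
    """
    if len(group_a_ids) == 0 or len(group_b_ids) == 0:
        raise CountTableError("each group needs at least one replicate")
    used = list(group_a_ids) + list(group_b_ids)
    chroms = set()
    for i in used:
        t = tables[i]
        chroms.update(t["chrom"].unique().tolist())
    if len(chroms) > 1:
        raise CountTableError(
            f"inconsistent chromosome labels across replicates: {sorted(chroms)}; "
            "split input by chromosome first"
        )
    chrom = chroms.pop() if chroms else "chrUnknown"

    pos_union = np.unique(np.concatenate([tables[i]["pos"].to_numpy() for i in used]))
    n = pos_union.shape[0]
    n_filled = 0

    def _stack(ids: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        nonlocal n_filled
        meth = np.zeros((n, len(ids)), dtype=np.int64)
        total = np.zeros((n, len(ids)), dtype=np.int64)
        for r, i in enumerate(ids):
            t = tables[i]
            p = t["pos"].to_numpy()
            if np.unique(p).shape[0] != p.shape[0]:
                raise CountTableError(f"replicate {i}: duplicate positions")
            loc = np.searchsorted(pos_union, p)
            meth[loc, r] = t["meth"].to_numpy()
            total[loc, r] = t["total"].to_numpy()
            n_filled += n - p.shape[0]
        return meth, total

    a_meth, a_total = _stack(group_a_ids)
    b_meth, b_total = _stack(group_b_ids)
    if n_filled:
        logger.info("merge_replicates: zero-filled %d absent (position, replicate) cells", n_filled)
    st = SiteTable(chrom, pos_union, a_meth, a_total, b_meth, b_total)
    return st, n_filled


def filter_zero_total(
    sites: SiteTable, mode: str = "per_group"
) -> tuple[SiteTable, int]:
    """Drop sites whose methylation level is undefined (0/0 pooled total).

    ``per_group`` (default): a site is removed when EITHER group's summed
    total count is zero — the weakest condition guaranteeing both group
    levels are defined. ``pooled``: removed only when the total over all
    replicates of both groups is zero.
    """
    ta = sites.a_total.sum(axis=1)
    tb = sites.b_total.sum(axis=1)
    if mode == "per_group":
        keep = (ta > 0) & (tb > 0)
    elif mode == "pooled":
        keep = (ta + tb) > 0
    else:
        raise ValueError(f"unknown zero-total mode {mode!r}")
    n_removed = int((~keep).sum())
    return sites.take(np.flatnonzero(keep)), n_removed


# ---------------------------------------------------------------------------
# region output

_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand"


def _bed_score(p_value: float) -> int:
    """Phred-like BED score min(1000, round(-10 log10 p)); untested -> 0."""
    if p_value is None or (isinstance(p_value, float) and math.isnan(p_value)):
        return 0
    if p_value <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(p_value))))


def write_bed(regions: Sequence, path: str | Path) -> None:
    """Write region records as BED6 (0-based half-open), named DMR_<k>.

    Input must already be sorted by (chrom, start); unsorted input is an
    error rather than being silently re-sorted.
    """
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by (chrom, start) before write_bed")
    lines = [_BED_HEADER]
    for k, r in enumerate(regions, start=1):
        lines.append(
            f"{r.chrom}\t{r.start - 1}\t{r.end}\tDMR_{k}\t{_bed_score(r.p_value)}\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file back to 1-based (chrom, start, end) plus name/score."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score"])
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df["start"] = df["start"].astype(np.int64) + 1  # back to 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    return df


def write_regions_tsv(regions: Sequence, path: str | Path) -> None:
    """Full per-region TSV with every call field (significant and not)."""
    cols = [
        "chrom", "start", "end", "n_sites", "mean_diff", "t_stat", "p_value",
        "alpha_used", "n_tested", "significant", "window_method", "tested",
    ]
    rows = []
    for r in regions:
        rows.append({c: getattr(r, c, None) for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
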