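"""Genome tiling, BED handling and CGI-context annotation.

The pipeline's atomic unit is a fixed-width, non-overlapping genomic window
(300 bp by default). Windows overlapping an exclusion list are flagged and
never receive fragment counts downstream.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .containers import WINDOW_COLUMNS

CONTEXT_LABELS = ("CGI", "shore", "shelf", "open_sea")


class BedParseError(ValueError):
    """Malformed BED input; message carries the 1-based line number."""


def read_bed(path) -> pd.DataFrame:
    """Read a BED3(+) file into a (contig, start, end, ...) frame.

    Raises :class:`BedParseError` naming the offending line for malformed
    records (too few columns, non-integer or inverted coordinates).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from err
            if start < 0 or end < start:
                raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
            rows.append((parts[0], start, end) + tuple(parts[3:4]))
    cols = ["contig", "start", "end"]
    if rows and len(rows[0]) == 4:
        cols.append("name")
        rows = [r if len(r) == 4 else r + ("",) for r in rows]
    return pd.DataFrame(rows, columns=cols)


def write_bed(windows: pd.DataFrame, path, score_col: str = "cpg_count") -> None:
    """Write windows as BED4 with the CpG count in the fourth column."""
    out = windows[["contig", "start", "end", score_col]]
    out.to_csv(path, sep="\t", header=False, index=False)


def tile_genome(
    contig_lengths: Mapping[str, int],
    exclusion: pd.DataFrame | str | None = None,
    window_size: int = 300,
    cpg_counts: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Tile contigs into fixed-width half-open windows.

    Trailing partial windows are dropped so the width invariant holds
    exactly. Any window overlapping an exclusion interval is flagged
    ``excluded``. ``cpg_counts`` optionally supplies per-window CpG counts
    per contig (otherwise zero).
    """
    if isinstance(exclusion, str):
        exclusion = read_bed(exclusion)
    frames = []
    for contig, length in contig_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length")
        n = length // window_size
        starts = np.arange(n, dtype=np.int64) * window_size
        d = np.zeros(n, dtype=np.int64)
        if cpg_counts is not None and contig in cpg_counts:
            given = np.asarray(cpg_counts[contig], dtype=np.int64)
            if len(given) != n:
                raise ValueError(
                    f"cpg_counts for contig {contig!r}: expected {n} windows, got {len(given)}")
            d = given
        frames.append(pd.DataFrame({
            "contig": contig,
            "start": starts,
            "end": starts + window_size,
            "cpg_count": d,
            "excluded": False,
            "qc_always_methylated": False,
            "cgi": False,
        }))
    windows = pd.concat(frames, ignore_index=True)
    if exclusion is not None and len(exclusion):
        excl = np.zeros(len(windows), dtype=bool)
        offsets = {}
        pos = 0
        for contig, length in contig_lengths.items():
            offsets[contig] = pos
            pos += int(length) // window_size
        for _, row in exclusion.iterrows():
            contig = row["contig"]
            if contig not in offsets:
                continue
            n_contig = int(contig_lengths[contig]) // window_size
            first = max(0, int(row["start"]) // window_size)
            # half-open exclusion interval: last overlapped window
            last = min(n_contig - 1, (int(row["end"]) - 1) // window_size)
            if int(row["end"]) > int(row["start"]) and first <= last:
                excl[offsets[contig] + first: offsets[contig] + last + 1] = True
        windows["excluded"] = excl
    return windows[WINDOW_COLUMNS]


def cgi_intervals(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of CGI-flagged windows into half-open intervals."""
    rows = []
    for contig, grp in windows.groupby("contig", sort=False):
        flags = grp["cgi"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not flags.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[0, flags.astype(int), 0]))
        for a, b in zip(edges[::2], edges[1::2]):
            rows.append((contig, int(starts[a]), int(ends[b - 1])))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def window_context(
    windows: pd.DataFrame,
    cgi: pd.DataFrame,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> np.ndarray:
    """Label each window CGI / shore / shelf / open_sea.

    Precedence CGI > shore > shelf: a window overlapping a CGI is a CGI
    window; otherwise the gap to the nearest CGI decides (< ``shore_bp``
    shore, < ``shore_bp + shelf_bp`` shelf, else open sea).
    """
    labels = np.full(len(windows), "open_sea", dtype=object)
    for contig, grp in windows.groupby("contig", sort=False):
        c = cgi[cgi["contig"] == contig]
        if c.empty:
            continue
        cs = np.sort(c["start"].to_numpy())
        ce = np.sort(c["end"].to_numpy())
        ws = grp["start"].to_numpy()
        we = grp["end"].to_numpy()
        # nearest interval on each side of the window
        right_idx = np.searchsorted(cs, we, side="left")
        left_idx = np.searchsorted(ce, ws, side="right") - 1
        gap_right = np.where(right_idx < len(cs), cs[np.clip(right_idx, 0, len(cs) - 1)] - we,
                             np.inf)
        gap_left = np.where(left_idx >= 0, ws - ce[np.clip(left_idx, 0, len(ce) - 1)],
                            np.inf)
        gap = np.minimum(np.maximum(gap_right, 0), np.maximum(gap_left, 0))
        # overlap iff some interval has start < we and end > ws
        overlap = np.searchsorted(cs, we, side="left") - 1 >= np.searchsorted(ce, ws, side="right")
        lab = np.where(overlap, "CGI",
                       np.where(gap < shore_bp, "shore",
                                np.where(gap < shore_bp + shelf_bp, "shelf",
                                         "open_sea")))
        labels[grp.index.to_numpy()] = lab
    return labels
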