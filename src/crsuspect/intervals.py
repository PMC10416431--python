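"""Interval arithmetic kernels: merging, overlap queries, intersections.

All functions operate on canonical interval DataFrames (``chrom``,
``start``, ``end``; 0-based half-open) and are deliberately simple
numpy-sweep implementations so that each one can be checked against a
per-basepair brute-force oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeLayout, intervals_frame, sort_intervals

__all__ = ["merge_frame", "overlaps_any", "intersection_bp", "total_bp"]


def merge_frame(
    df: pd.DataFrame,
    layout: GenomeLayout,
    gap: int = 0,
    value_col: str | None = None,
) -> pd.DataFrame:
    """Union overlapping or touching intervals (within ``gap`` bp).

    Touching intervals (``end == start``) merge at ``gap=0``.  When
    ``value_col`` is given the merged interval carries the maximum of that
    column over its constituents (used for consensus support).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if len(df) == 0:
        out = intervals_frame()
        if value_col:
            out[value_col] = pd.Series(dtype=df[value_col].dtype if value_col in df else float)
        return out
    df = sort_intervals(df, layout)
    out_rows: list[tuple] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub[value_col].to_numpy() if value_col else None
        # running maximum of end handles contained intervals
        run_end = np.maximum.accumulate(ends)
        new_group = np.concatenate([[True], starts[1:] > run_end[:-1] + gap])
        group_ids = np.cumsum(new_group) - 1
        for g in range(group_ids[-1] + 1):
            mask = group_ids == g
            row = [chrom, int(starts[mask][0]), int(run_end[mask][-1])]
            if vals is not None:
                row.append(vals[mask].max())
            out_rows.append(tuple(row))
    cols = ["chrom", "start", "end"] + ([value_col] if value_col else [])
    out = pd.DataFrame(out_rows, columns=cols)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return sort_intervals(out, layout)


def _merged_arrays(
    regions: pd.DataFrame, layout: GenomeLayout
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_frame(regions, layout)
    return {
        str(chrom): (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in merged.groupby("chrom", sort=False)
    }


def overlaps_any(
    query: pd.DataFrame, regions: pd.DataFrame, layout: GenomeLayout
) -> np.ndarray:
    """Boolean per query row: does it overlap any region by >= 1 bp?"""
    hits = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(regions) == 0:
        return hits
    by_chrom = _merged_arrays(regions, layout)
    query = query.reset_index(drop=True)
    for chrom, sub in query.groupby("chrom", sort=False):
        arrays = by_chrom.get(str(chrom))
        if arrays is None:
            continue
        rstarts, rends = arrays
        qstart = sub["start"].to_numpy()
        qend = sub["end"].to_numpy()
        # first region ending strictly after the query start
        idx = np.searchsorted(rends, qstart, side="right")
        ok = idx < len(rstarts)
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = rstarts[idx[ok]] < qend[ok]
        hits[sub.index.to_numpy()] = hit
    return hits


def intersection_bp(a: pd.DataFrame, b: pd.DataFrame, layout: GenomeLayout) -> int:
    """Total basepairs in the intersection of two interval sets."""
    if len(a) == 0 or len(b) == 0:
        return 0
    a_arr = _merged_arrays(a, layout)
    b_arr = _merged_arrays(b, layout)
    total = 0
    for chrom in set(a_arr) & set(b_arr):
        astart, aend = a_arr[chrom]
        bstart, bend = b_arr[chrom]
        i = j = 0
        while i < len(astart) and j < len(bstart):
            lo = max(astart[i], bstart[j])
            hi = min(aend[i], bend[j])
            if hi > lo:
                total += int(hi - lo)
            if aend[i] <= bend[j]:
                i += 1
            else:
                j += 1
    return total


def total_bp(df: pd.DataFrame, layout: GenomeLayout) -> int:
    """Basepairs covered by the union of the intervals."""
    merged = merge_frame(df, layout)
    return int((merged["end"] - merged["start"]).sum())
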