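"""Shared fixtures and per-basepair brute-force oracles.

The oracles deliberately materialise chromosomes as dense numpy arrays
and answer interval questions basepair by basepair; they are slow but
obviously correct, and every vectorised interval kernel in the package is
tested against them on small random instances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crsuspect import GenomeLayout, intervals_frame


@pytest.fixture
def layout_small() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2", "chrM"), (10_000, 8_000, 2_000))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_intervals(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    max_len: int = 500,
    chroms: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """n random intervals over the layout (unsorted, may overlap)."""
    chroms = chroms or layout.names
    rows = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = layout.length_of(chrom)
        length = int(rng.integers(1, min(max_len, clen)))
        start = int(rng.integers(0, clen - length + 1))
        rows.append((chrom, start, start + length))
    return intervals_frame(rows)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_coverage(df: pd.DataFrame, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-basepair pileup as dense arrays."""
    cov = {c: np.zeros(layout.length_of(c), dtype=np.int64) for c in layout.names}
    for rec in df.itertuples(index=False):
        cov[rec.chrom][rec.start : rec.end] += 1
    return cov


def brute_blocks(cov: dict[str, np.ndarray], layout: GenomeLayout) -> pd.DataFrame:
    """Maximal positive runs with AUC and max, scanned basepair by basepair."""
    rows = []
    for chrom in layout.names:
        arr = cov[chrom]
        in_block = False
        start = 0
        for p in range(len(arr) + 1):
            val = arr[p] if p < len(arr) else 0
            if val > 0 and not in_block:
                in_block, start = True, p
            elif val <= 0 and in_block:
                seg = arr[start:p]
                rows.append((chrom, start, p, float(seg.sum()), float(seg.max())))
                in_block = False
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "auc", "max_height"])


def brute_union(df: pd.DataFrame, layout: GenomeLayout, gap: int = 0) -> pd.DataFrame:
    """Interval union via a per-basepair mask (gap bridges short holes)."""
    rows = []
    for chrom in layout.names:
        mask = np.zeros(layout.length_of(chrom), dtype=bool)
        sub = df[df["chrom"] == chrom]
        for rec in sub.itertuples(index=False):
            mask[rec.start : rec.end] = True
        if gap > 0:
            # bridge gaps of <= gap bp between covered stretches
            covered = np.flatnonzero(mask)
            for a, b in zip(covered[:-1], covered[1:]):
                if 0 < b - a - 1 <= gap:
                    mask[a : b + 1] = True
        p = 0
        while p < len(mask):
            if mask[p]:
                q = p
                while q < len(mask) and mask[q]:
                    q += 1
                rows.append((chrom, p, q))
                p = q
            else:
                p += 1
    return intervals_frame(rows)


def brute_support(peak_frames: list[pd.DataFrame], layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-basepair count of distinct samples covering each position."""
    support = {c: np.zeros(layout.length_of(c), dtype=np.int64) for c in layout.names}
    for df in peak_frames:
        seen = {c: np.zeros(layout.length_of(c), dtype=bool) for c in layout.names}
        for rec in df.itertuples(index=False):
            seen[rec.chrom][rec.start : rec.end] = True
        for c in layout.names:
            support[c] += seen[c]
    return support


def brute_overlaps(query: pd.DataFrame, regions: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    """Per query row: >= 1 bp overlap with any region, by dense masks."""
    mask = {c: np.zeros(layout.length_of(c), dtype=bool) for c in layout.names}
    for rec in regions.itertuples(index=False):
        mask[rec.chrom][rec.start : rec.end] = True
    return np.array(
        [bool(mask[rec.chrom][rec.start : rec.end].any())
         for rec in query.itertuples(index=False)]
    )
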