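"""Consensus suspect-list construction from per-sample peak sets.

The procedure mirrors standard blacklist construction from panels of
negative controls: each sample's peaks are extended by a fixed margin (to
absorb small positional shifts between datasets), the genome is segmented
at every extended-peak boundary, each segment is annotated with its
cross-sample support (the number of distinct samples covering it), and
segments whose support strictly exceeds a reproducibility fraction of the
panel are merged into the final list.  With the canonical panel of N=20
controls and a 30% fraction the support threshold is 7 (6/20 = 30% is not
strictly greater than 30%).

Support counting is segment-based (per-basepair) rather than whole-peak
based: it is independent of sample processing order and can be verified
against a per-basepair brute-force oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import PeakSet
from .genome import (
    GenomeLayout,
    intervals_frame,
    read_bed,
    sort_intervals,
    write_bed,
)
from .intervals import merge_frame

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusParams",
    "SuspectList",
    "ReproducibilityCurve",
    "AnnotationTables",
    "min_support",
    "extend_peaks",
    "count_support",
    "merge_intervals",
    "build_suspect_list",
    "reproducibility_curve",
    "annotate_regions",
]


@dataclass
class ConsensusParams:
    """Consensus parameters.

    extension
        Basepairs added on both sides of every peak before overlapping
        (default 1000, absorbing slightly shifted peaks between datasets).
    reproducibility_fraction
        Fraction ``r`` of the panel a segment must strictly exceed to be
        kept (default 0.30; with N=20 this keeps support >= 7).
    include_mitochondrial
        Append the whole mitochondrial chromosome as a policy region
        (negative-control panels are invariably contaminated by chrM).
    """

    extension: int = 1000
    reproducibility_fraction: float = 0.30
    include_mitochondrial: bool = True

    def __post_init__(self) -> None:
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if not (0.0 < self.reproducibility_fraction < 1.0):
            raise ValueError("reproducibility_fraction must lie in (0, 1)")


@dataclass
class SuspectList:
    """Merged, sorted artifact-prone regions with per-region support.

    ``regions`` columns: chrom, start, end, support, plus optional
    annotation columns (note, category, closest_gene, tss_distance,
    low_mappability, ...). Regions are non-overlapping and sorted in
    layout order.
    """

    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.regions = self.regions.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_bp(self) -> int:
        return int((self.regions["end"] - self.regions["start"]).sum())

    def to_bed(self, path: str | Path, layout: GenomeLayout) -> None:
        extra = [c for c in self.regions.columns if c not in ("chrom", "start", "end")]
        write_bed(self.regions, path, layout, extra_columns=extra)

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout) -> "SuspectList":
        df = read_bed(path, layout)
        if "name" in df.columns:
            support = pd.to_numeric(df["name"], errors="coerce")
            df = df[["chrom", "start", "end"]].copy()
            df["support"] = support.fillna(0).astype(int)
        else:
            df = df[["chrom", "start", "end"]].copy()
            df["support"] = 0
        return cls(sort_intervals(df, layout))


def min_support(n_samples: int, fraction: float) -> int:
    """Smallest integer k with ``k / n_samples`` strictly greater than the fraction.

    With a 20-sample panel and fraction 0.30 this is 7.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    k = math.floor(n_samples * fraction) + 1
    # guard float fuzz at exact multiples, e.g. 20 * 0.30
    if (k - 1) / n_samples > fraction:
        k -= 1
    return k


def extend_peaks(peaks: PeakSet, extension: int, layout: GenomeLayout) -> PeakSet:
    """Grow every peak by ``extension`` bp on both sides, clamped to the
    chromosome; the result may overlap and is deliberately not merged."""
    df = peaks.data.copy()
    if len(df):
        lengths = df["chrom"].map(layout.length_of)
        df["start"] = np.maximum(df["start"] - extension, 0)
        df["end"] = np.minimum(df["end"] + extension, lengths).astype(np.int64)
    return PeakSet(peaks.sample_id, df)


def merge_intervals(df: pd.DataFrame, layout: GenomeLayout, gap: int = 0) -> pd.DataFrame:
    """Union overlapping or touching intervals (within ``gap`` bp); sorted."""
    return merge_frame(df, layout, gap=gap)


def count_support(peak_sets: list[PeakSet], layout: GenomeLayout) -> pd.DataFrame:
    """Segment the genome at peak boundaries and count covering samples.

    Each sample's peaks are merged internally first, so within-sample
    overlap counts once.  Returns a frame chrom/start/end/support covering
    exactly the peak-covered basepairs (support >= 1), with adjacent
    equal-support segments coalesced.
    """
    events: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for ps in peak_sets:
        merged = merge_frame(ps.data[["chrom", "start", "end"]], layout)
        for chrom, sub in merged.groupby("chrom", sort=False):
            events.setdefault(str(chrom), []).append(
                (sub["start"].to_numpy(), sub["end"].to_numpy())
            )
    rows: list[tuple[str, int, int, int]] = []
    for chrom in layout.names:
        if chrom not in events:
            continue
        starts = np.concatenate([s for s, _ in events[chrom]])
        ends = np.concatenate([e for _, e in events[chrom]])
        bounds = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(len(bounds), dtype=np.int64)
        np.add.at(delta, np.searchsorted(bounds, starts), 1)
        np.add.at(delta, np.searchsorted(bounds, ends), -1)
        support = np.cumsum(delta)[:-1]
        seg_start, seg_end = bounds[:-1], bounds[1:]
        # coalesce touching equal-support segments, drop uncovered gaps
        keep = support > 0
        i = 0
        idx = np.flatnonzero(keep)
        while i < len(idx):
            j = i
            while (
                j + 1 < len(idx)
                and idx[j + 1] == idx[j] + 1
                and support[idx[j + 1]] == support[idx[i]]
                and seg_start[idx[j + 1]] == seg_end[idx[j]]
            ):
                j += 1
            rows.append(
                (chrom, int(seg_start[idx[i]]), int(seg_end[idx[j]]), int(support[idx[i]]))
            )
            i = j + 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "support"])
    if len(out):
        out["start"] = out["start"].astype(np.int64)
        out["end"] = out["end"].astype(np.int64)
    return out


def build_suspect_list(
    peak_sets: list[PeakSet],
    params: ConsensusParams,
    layout: GenomeLayout,
) -> SuspectList:
    """Extend, overlap, threshold and merge a panel of peak sets.

    Keeps genome segments covered by extended peaks from at least
    ``min_support(N, r)`` distinct samples, merges touching survivors, and
    (by default) appends the full mitochondrial chromosome as a flagged
    policy region.
    """
    n = len(peak_sets)
    if n < 2:
        raise ValueError("consensus requires multiple samples (got %d)" % n)
    k = min_support(n, params.reproducibility_fraction)
    extended = [extend_peaks(ps, params.extension, layout) for ps in peak_sets]
    segments = count_support(extended, layout)
    kept = segments[segments["support"] >= k]
    merged = merge_frame(kept, layout, value_col="support")
    if len(merged):
        merged["support"] = merged["support"].astype(int)
    else:
        merged["support"] = pd.Series(dtype=int)
    merged["note"] = ""
    mito = layout.mito_name
    if params.include_mitochondrial and mito is not None:
        on_m = merged["chrom"] == mito
        prior_support = int(merged.loc[on_m, "support"].max()) if on_m.any() else 0
        merged = merged[~on_m]
        chrm_row = pd.DataFrame(
            {
                "chrom": [mito],
                "start": [0],
                "end": [layout.length_of(mito)],
                "support": [prior_support],
                "note": ["chrM-policy"],
            }
        )
        merged = pd.concat([merged, chrm_row], ignore_index=True)
    merged["start"] = merged["start"].astype(np.int64)
    merged["end"] = merged["end"].astype(np.int64)
    out = sort_intervals(merged, layout)
    logger.info(
        "suspect list: N=%d, k=%d, %d segments kept, %d regions", n, k, len(kept), len(out)
    )
    return SuspectList(out)


@dataclass
class ReproducibilityCurve:
    """Region count as a function of the minimum support m = 1..N."""

    m: np.ndarray
    counts: np.ndarray
    knee: int
    knee_defined: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"min_support": self.m, "region_count": self.counts})


def reproducibility_curve(
    extended_peak_sets: list[PeakSet], layout: GenomeLayout
) -> ReproducibilityCurve:
    """Count candidate regions supported by at least m samples, m = 1..N.

    Candidate regions are the merged union of all peak-covered segments;
    a candidate counts towards level m when its maximum segment support
    reaches m.  Defined this way the curve is non-increasing in m by
    construction (thresholding segments first and re-merging per level is
    not: merging at low levels fuses candidates and can make the count
    rise before it falls).

    The knee is the threshold maximising the perpendicular distance of
    the (m, count) polyline from the chord joining its endpoints; a
    constant curve has no knee and is reported as 1 with
    ``knee_defined=False``.
    """
    n = len(extended_peak_sets)
    segments = count_support(extended_peak_sets, layout)
    candidates = merge_frame(segments, layout, value_col="support")
    max_support = candidates["support"].to_numpy() if len(candidates) else np.empty(0)
    counts = np.array([(max_support >= m).sum() for m in range(1, n + 1)], dtype=np.int64)
    ms = np.arange(1, n + 1)
    if n < 3 or counts[0] == counts[-1]:
        return ReproducibilityCurve(ms, counts, 1, False)
    # perpendicular distance from the chord (1, c1) -- (N, cN)
    x1, y1, x2, y2 = 1.0, float(counts[0]), float(n), float(counts[-1])
    norm = math.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * ms - (x2 - x1) * counts + x2 * y1 - y2 * x1) / norm
    knee = int(ms[int(np.argmax(dist))])
    return ReproducibilityCurve(ms, counts, knee, True)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class AnnotationTables:
    """Annotation inputs: TSS table plus exon and intron intervals.

    ``tss`` columns: chrom, pos (0-based TSS coordinate), strand ('+'/'-'),
    gene.  The promoter window is -1000/+100 bp around the TSS in the
    gene's orientation.
    """

    tss: pd.DataFrame
    exons: pd.DataFrame | None = None
    introns: pd.DataFrame | None = None
    promoter_upstream: int = 1000
    promoter_downstream: int = 100

    def promoter_windows(self, layout: GenomeLayout) -> pd.DataFrame:
        rows = []
        for rec in self.tss.itertuples(index=False):
            if rec.strand == "-":
                start = rec.pos - self.promoter_downstream
                end = rec.pos + self.promoter_upstream
            else:
                start = rec.pos - self.promoter_upstream
                end = rec.pos + self.promoter_downstream
            clen = layout.length_of(rec.chrom)
            rows.append((rec.chrom, max(0, int(start)), min(clen, int(end))))
        return intervals_frame(rows)


def annotate_regions(
    slist: SuspectList,
    annotation: AnnotationTables | None,
    layout: GenomeLayout,
) -> SuspectList:
    """Label regions by genomic category and closest TSS.

    Category precedence: promoter > exon > intron > intergenic (a region
    overlapping a promoter window anywhere is a promoter region).  The
    closest TSS is chosen by minimal distance from the region midpoint;
    the signed distance is negative when the midpoint lies upstream of the
    TSS in the gene's orientation.
    """
    from .intervals import overlaps_any

    regions = slist.regions.copy()
    if annotation is None or len(annotation.tss) == 0:
        regions["category"] = "unannotated"
        regions["closest_gene"] = ""
        regions["tss_distance"] = np.nan
        return SuspectList(regions)

    promoters = annotation.promoter_windows(layout)
    is_prom = overlaps_any(regions, promoters, layout)
    is_exon = (
        overlaps_any(regions, annotation.exons, layout)
        if annotation.exons is not None and len(annotation.exons)
        else np.zeros(len(regions), dtype=bool)
    )
    is_intron = (
        overlaps_any(regions, annotation.introns, layout)
        if annotation.introns is not None and len(annotation.introns)
        else np.zeros(len(regions), dtype=bool)
    )
    category = np.where(
        is_prom, "promoter", np.where(is_exon, "exon", np.where(is_intron, "intron", "intergenic"))
    )
    regions["category"] = category

    genes: list[str] = []
    distances: list[float] = []
    tss = annotation.tss
    for rec in regions.itertuples(index=False):
        mid = (rec.start + rec.end) // 2
        sub = tss[tss["chrom"] == rec.chrom]
        pool = sub if len(sub) else tss
        d = np.abs(pool["pos"].to_numpy() - mid) if len(sub) else None
        if d is None:
            genes.append("")
            distances.append(np.nan)
            continue
        j = int(np.argmin(d))
        row = pool.iloc[j]
        signed = int(mid - row["pos"]) if row["strand"] != "-" else int(row["pos"] - mid)
        genes.append(str(row["gene"]))
        distances.append(float(signed))
    regions["closest_gene"] = genes
    regions["tss_distance"] = distances
    return SuspectList(regions)
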