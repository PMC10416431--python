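"""Suspect-list filtering and quality-control statistics.

Implements the evaluation toolkit around a suspect list: duplicate
removal, fragment/peak filtering (the >= 1 bp overlap rule throughout),
FRIP (fraction of fragments in regions), binned Spearman correlation
matrices, genome-wide PCA with scree fractions, the inter-/intra-target
distance ratio, genome-coverage and list-vs-list comparisons, average
signal profiles over regions, and low-mappability flagging.

The guiding observation is that artifact regions shared across unrelated
experiments inflate apparent sample similarity: correlation restricted to
suspect regions is far higher than genome-wide correlation, and a large
share of PC1 variance collapses once the regions (or the fragments in
them) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

from .coverage import BinnedMatrix, PeakSet
from .genome import CoverageTrack, FragmentSet, GenomeLayout
from .consensus import SuspectList
from .intervals import intersection_bp, overlaps_any, total_bp

logger = logging.getLogger(__name__)

__all__ = [
    "QCSummary",
    "PCAResult",
    "DistanceReport",
    "ListComparison",
    "ProfileResult",
    "dedup_fragments",
    "filter_fragments",
    "subtract_peaks",
    "frip",
    "spearman_matrix",
    "mean_offdiagonal",
    "exclude_bins",
    "pca_scree",
    "distance_ratio",
    "genome_fraction",
    "compare_lists",
    "average_profile",
    "flag_low_mappability",
]


@dataclass
class QCSummary:
    """FRIP summary: fragments overlapping a region set by >= 1 bp."""

    frip: float
    total_fragments: int
    fragments_in_regions: int


def dedup_fragments(frags: FragmentSet) -> tuple[FragmentSet, int]:
    """Collapse exact-coordinate duplicate fragments to one copy.

    Returns the deduplicated set and the number of fragments removed.
    """
    deduped = frags.data.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    removed = len(frags.data) - len(deduped)
    if removed:
        logger.info("%s: removed %d duplicate fragments", frags.sample_id, removed)
    return FragmentSet(frags.sample_id, deduped.reset_index(drop=True)), removed


def _region_frame(regions: SuspectList | pd.DataFrame) -> pd.DataFrame:
    if isinstance(regions, SuspectList):
        return regions.regions
    return regions


def filter_fragments(
    frags: FragmentSet, slist: SuspectList | pd.DataFrame, layout: GenomeLayout
) -> FragmentSet:
    """Remove fragments overlapping any list region by >= 1 bp.

    A fragment ending exactly where a region starts does not overlap
    (half-open convention) and is kept.  Together with its complement this
    partitions the input: no fragment is lost or duplicated.
    """
    hits = overlaps_any(frags.data, _region_frame(slist), layout)
    kept = frags.data[~hits].reset_index(drop=True)
    logger.info("%s: filtered %d/%d fragments", frags.sample_id, int(hits.sum()), len(frags))
    return FragmentSet(frags.sample_id, kept)


def subtract_peaks(
    peaks: PeakSet, slist: SuspectList | pd.DataFrame, layout: GenomeLayout
) -> PeakSet:
    """Remove whole peaks overlapping any list region by >= 1 bp (no trimming)."""
    hits = overlaps_any(peaks.data, _region_frame(slist), layout)
    return PeakSet(peaks.sample_id, peaks.data[~hits].reset_index(drop=True))


def frip(
    frags: FragmentSet, regions: SuspectList | pd.DataFrame, layout: GenomeLayout
) -> QCSummary:
    """Fraction of fragments overlapping the regions by >= 1 bp.

    The total number of fragments mapping to the regions divided by the
    total number of mapped fragments.
    """
    if len(frags) == 0:
        raise ValueError("no mapped fragments")
    hits = overlaps_any(frags.data, _region_frame(regions), layout)
    n_in = int(hits.sum())
    return QCSummary(frip=n_in / len(frags), total_fragments=len(frags), fragments_in_regions=n_in)


# ---------------------------------------------------------------------------
# correlation / PCA / distances


def spearman_matrix(matrix: BinnedMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation between samples over bins.

    Ties receive average ranks.  A sample with zero variance across bins
    has undefined correlations, reported as NaN (not 0); the diagonal is
    1 by convention.
    """
    counts = matrix.counts.astype(float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    ranks = np.vstack([rankdata(row, method="average") for row in counts])
    sd = ranks.std(axis=1)
    corr = np.full((n, n), np.nan)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(ranks[ok])
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.sample_ids, columns=matrix.sample_ids)


def mean_offdiagonal(corr: pd.DataFrame) -> float:
    """Mean of the off-diagonal correlations, ignoring undefined entries."""
    values = corr.to_numpy().copy()
    np.fill_diagonal(values, np.nan)
    return float(np.nanmean(values))


def exclude_bins(
    matrix: BinnedMatrix, regions: SuspectList | pd.DataFrame, layout: GenomeLayout
) -> BinnedMatrix:
    """Drop bins overlapping the regions by >= 1 bp (blacklist-style).

    This is how post-filtering correlation/PCA matrices are built: bins
    touching a suspect region are removed from the analysis rather than
    left in with partially depleted counts (which would otherwise imprint
    a shared depletion signature on every sample).
    """
    drop = overlaps_any(matrix.bins, _region_frame(regions), layout)
    return BinnedMatrix(
        matrix.bins[~drop].reset_index(drop=True),
        matrix.counts[:, ~drop],
        matrix.sample_ids,
    )


@dataclass
class PCAResult:
    """PCA of samples over bins, with scree fractions.

    ``percent_variance`` sums to 100 over all computed components.
    """

    coordinates: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    n_bins_used: int


def pca_scree(matrix: BinnedMatrix, exclude: SuspectList | pd.DataFrame | None = None,
              layout: GenomeLayout | None = None) -> PCAResult:
    """PCA of the per-bin mean-centred count matrix (samples are observations).

    With ``exclude`` given, bins overlapping the list are dropped before
    the analysis (blacklist-style exclusion); ``layout`` is then required.
    """
    counts = matrix.counts.astype(float)
    bins = matrix.bins
    if exclude is not None:
        if layout is None:
            raise ValueError("layout required when excluding regions")
        drop = overlaps_any(bins, _region_frame(exclude), layout)
        counts = counts[:, ~drop]
    n, b = counts.shape
    if b < 2:
        raise ValueError("need >= 2 bins for PCA")
    if n < 2:
        raise ValueError("need >= 2 samples for PCA")
    centered = counts - counts.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total <= 0:
        raise ValueError("no variance across samples")
    pct = 100.0 * eig / total
    coords = pd.DataFrame(
        u * s,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PCAResult(coords, eig, pct, n_bins_used=b)


@dataclass
class DistanceReport:
    """Mean Euclidean distances within and between target groups."""

    intra: float
    inter: float
    ratio: float  # inter : intra


def distance_ratio(matrix: BinnedMatrix, labels: list[str]) -> DistanceReport:
    """Inter- vs intra-target mean Euclidean distance over the bin counts.

    Larger ratios indicate samples cluster by target rather than by the
    shared artifact signal; suspect-list filtering should increase it.
    """
    if len(labels) != len(matrix.sample_ids):
        raise ValueError("one label per sample required")
    labels_arr = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("need >= 2 distinct labels")
    dists = squareform(pdist(matrix.counts.astype(float)))
    n = len(labels_arr)
    iu = np.triu_indices(n, k=1)
    same = labels_arr[iu[0]] == labels_arr[iu[1]]
    if not same.any():
        raise ValueError("no intra-target pairs")
    intra = float(dists[iu][same].mean())
    inter = float(dists[iu][~same].mean()) if (~same).any() else float("nan")
    if intra == 0:
        raise ValueError("intra-target distance is zero; ratio undefined")
    return DistanceReport(intra=intra, inter=inter, ratio=inter / intra)


# ---------------------------------------------------------------------------
# list-level statistics


def genome_fraction(slist: SuspectList | pd.DataFrame, layout: GenomeLayout) -> float:
    """Fraction of the genome covered by the list regions."""
    return total_bp(_region_frame(slist), layout) / layout.total_length


@dataclass
class ListComparison:
    """Region- and basepair-level agreement between two region lists."""

    unique_a: int
    unique_b: int
    shared_a: int  # regions of A overlapping B by >= 1 bp
    shared_b: int
    bp_a: int
    bp_b: int
    bp_shared: int
    fraction_a: float
    fraction_b: float


def compare_lists(
    a: SuspectList | pd.DataFrame, b: SuspectList | pd.DataFrame, layout: GenomeLayout
) -> ListComparison:
    """Overlap and genome-coverage comparison of two region lists."""
    fa, fb = _region_frame(a), _region_frame(b)
    a_hits = overlaps_any(fa, fb, layout)
    b_hits = overlaps_any(fb, fa, layout)
    return ListComparison(
        unique_a=int((~a_hits).sum()),
        unique_b=int((~b_hits).sum()),
        shared_a=int(a_hits.sum()),
        shared_b=int(b_hits.sum()),
        bp_a=total_bp(fa, layout),
        bp_b=total_bp(fb, layout),
        bp_shared=intersection_bp(fa, fb, layout),
        fraction_a=genome_fraction(fa, layout),
        fraction_b=genome_fraction(fb, layout),
    )


# ---------------------------------------------------------------------------
# profiles and mappability


@dataclass
class ProfileResult:
    """Mean signal per rescaled position across regions."""

    profile: np.ndarray
    n_regions: int
    n_truncated: int


def average_profile(
    track: CoverageTrack,
    regions: SuspectList | pd.DataFrame,
    flank: int = 0,
    nbins: int = 100,
) -> ProfileResult:
    """Mean coverage over regions rescaled to a fixed number of positions.

    Each region plus its flanks is divided into ``nbins`` equal parts; the
    profile is the across-region mean of the mean coverage per part.
    Spans reaching past a chromosome end are truncated (and counted).
    """
    frame = _region_frame(regions)
    if len(frame) == 0:
        raise ValueError("no regions for profile")
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    profiles = np.zeros((len(frame), nbins))
    truncated = 0
    for i, rec in enumerate(frame.itertuples(index=False)):
        clen = track.layout.length_of(rec.chrom)
        lo = rec.start - flank
        hi = rec.end + flank
        if lo < 0 or hi > clen:
            truncated += 1
            lo, hi = max(0, lo), min(clen, hi)
        edges = np.linspace(lo, hi, nbins + 1)
        aucs = np.array([track.auc(rec.chrom, edges[j], edges[j + 1]) for j in range(nbins)])
        widths = np.diff(edges)
        profiles[i] = aucs / widths
    return ProfileResult(profiles.mean(axis=0), n_regions=len(frame), n_truncated=truncated)


def flag_low_mappability(
    slist: SuspectList, mappability: CoverageTrack, cutoff: float = 0.5
) -> SuspectList:
    """Flag regions whose mean mappability falls below the cutoff.

    The mappability track must hold values in [0, 1] (e.g. a multi-read
    mappability bedgraph).
    """
    for _, (_, _, values) in mappability.runs.items():
        if len(values) and (values.min() < 0 or values.max() > 1):
            raise ValueError("mappability values must lie in [0, 1]")
    regions = slist.regions.copy()
    means = [
        mappability.mean_in(rec.chrom, rec.start, rec.end)
        for rec in regions.itertuples(index=False)
    ]
    regions["mean_mappability"] = means
    regions["low_mappability"] = np.asarray(means) < cutoff
    return SuspectList(regions)
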