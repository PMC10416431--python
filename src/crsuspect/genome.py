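"""Genome coordinate types and text-format I/O.

Coordinates are 0-based and half-open (``[start, end)``) everywhere, the
BED/bedgraph convention; any 1-based source must be converted at the
boundary.  All interval outputs are sorted by the chromosome order of the
active :class:`GenomeLayout` (file order of the chrom.sizes input), then by
start -- deterministic without imposing lexicographic chromosome order.

Interval collections are plain :class:`pandas.DataFrame` objects with
``chrom``, ``start`` and ``end`` columns; the dataclasses in this module
wrap them with the sample / signal semantics the pipeline needs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "FormatError",
    "GenomeLayout",
    "GenomicInterval",
    "FragmentSet",
    "CoverageTrack",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fragments",
    "sort_intervals",
    "is_sorted",
    "validate_intervals",
    "intervals_frame",
]

#: chromosome names recognised as the mitochondrial genome
MITO_NAMES = ("chrM", "MT", "chrMT", "M")

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class FormatError(ValueError):
    """A text input violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate universe.

    The order of ``names`` is stable and defines the sort order of every
    interval output produced by the package.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _order: dict[str, int] = field(init=False, repr=False, compare=False)
    _sizes: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.lengths = tuple(int(x) for x in self.lengths)
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if not self.names:
            raise ValueError("no chromosomes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        self._order = {name: i for i, name in enumerate(self.names)}
        self._sizes = dict(zip(self.names, self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __len__(self) -> int:
        return len(self.names)

    def length_of(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None

    def order_of(self, chrom: str) -> int:
        try:
            return self._order[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def mito_name(self) -> str | None:
        """Name of the mitochondrial chromosome, if the layout has one."""
        for name in self.names:
            if name in MITO_NAMES:
                return name
        return None


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a UCSC-style two-column chrom.sizes file, in file order."""
    names: list[str] = []
    lengths: list[int] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            names.append(name)
            lengths.append(length)
    if not names:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(names), tuple(lengths))


# ---------------------------------------------------------------------------
# interval frames


def intervals_frame(records: Iterable[tuple[str, int, int]] | None = None) -> pd.DataFrame:
    """Build a canonical interval DataFrame from (chrom, start, end) tuples."""
    recs = list(records or [])
    if not recs:
        return pd.DataFrame({"chrom": pd.Series(dtype=object),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    df = pd.DataFrame(recs, columns=INTERVAL_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout, what: str = "interval") -> None:
    """Check every row satisfies 0 <= start < end <= chromosome length.

    Raises :class:`FormatError` listing (up to five) offending records.
    """
    if len(df) == 0:
        return
    bad: list[str] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout:
            bad.extend(f"{chrom}:{s}-{e} (unknown chromosome)"
                       for s, e in zip(sub["start"], sub["end"]))
            continue
        clen = layout.length_of(str(chrom))
        mask = (sub["start"] < 0) | (sub["start"] >= sub["end"]) | (sub["end"] > clen)
        for s, e in zip(sub.loc[mask, "start"], sub.loc[mask, "end"]):
            bad.append(f"{chrom}:{s}-{e}")
    if bad:
        shown = ", ".join(bad[:5])
        more = f" (+{len(bad) - 5} more)" if len(bad) > 5 else ""
        raise FormatError(f"{len(bad)} invalid {what} record(s): {shown}{more}")


def sort_intervals(df: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Sort by layout chromosome order, then start, then end."""
    if len(df) == 0:
        return df.reset_index(drop=True)
    key = df["chrom"].map(layout.order_of)
    order = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def is_sorted(df: pd.DataFrame, layout: GenomeLayout) -> bool:
    if len(df) <= 1:
        return True
    key = df["chrom"].map(layout.order_of).to_numpy()
    start = df["start"].to_numpy()
    prev = np.diff(key)
    same = prev == 0
    return bool(np.all(prev >= 0) and np.all(np.diff(start)[same] >= 0))


# ---------------------------------------------------------------------------
# fragments


@dataclass
class FragmentSet:
    """One sample's paired-end fragments as half-open intervals.

    Duplicates are permitted (the pre-deduplication state); see
    :func:`crsuspect.qc.dedup_fragments`.
    """

    sample_id: str
    data: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def sorted(self, layout: GenomeLayout) -> "FragmentSet":
        return FragmentSet(self.sample_id, sort_intervals(self.data, layout))


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read BED3+ into an interval frame; extra columns keep BED names.

    Columns beyond chrom/start/end are named ``name``, ``score``, ``strand``
    then ``extra4``...; ``score`` is parsed numerically when possible.
    """
    extra_names = ["name", "score", "strand"]
    rows: list[list] = []
    ncols = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            rows.append([fields[0], start, end, *fields[3:]])
            ncols = max(ncols, len(fields))
    columns = INTERVAL_COLUMNS + [
        extra_names[i] if i < len(extra_names) else f"extra{i + 1}"
        for i in range(ncols - 3)
    ]
    df = pd.DataFrame(rows, columns=columns[: max(ncols, 3)]) if rows else intervals_frame()
    if rows:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if "score" in df.columns:
            score = pd.to_numeric(df["score"], errors="coerce")
            if not score.isna().any():
                df["score"] = score
    if layout is not None:
        validate_intervals(df, layout, what="BED")
    return df


def write_bed(
    df: pd.DataFrame,
    path: str | Path,
    layout: GenomeLayout,
    extra_columns: Sequence[str] = (),
) -> None:
    """Write sorted intervals as tab-delimited BED; byte-deterministic.

    ``extra_columns`` names DataFrame columns appended after chrom/start/end.
    Input must already be sorted in layout order (erroring beats silently
    re-sorting a caller's carefully ordered list).
    """
    if not is_sorted(df, layout):
        raise ValueError("intervals must be sorted in genome-layout order before writing")
    validate_intervals(df, layout, what="BED")
    cols = list(INTERVAL_COLUMNS) + [c for c in extra_columns if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        f = float(value)
        return str(int(f)) if f.is_integer() else repr(f)
    return str(value)


# ---------------------------------------------------------------------------
# coverage tracks (bedgraph semantics)


def _coalesce_runs(bounds: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse adjacent equal-valued runs; returns (starts, ends, values)."""
    if len(values) == 0:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    keep = np.concatenate([[True], values[1:] != values[:-1]])
    starts = bounds[:-1][keep]
    ends = np.concatenate([starts[1:], bounds[-1:]])
    return starts.astype(np.int64), ends.astype(np.int64), values[keep].astype(float)


@dataclass
class CoverageTrack:
    """Stepwise per-basepair signal over a genome (bedgraph semantics).

    Runs are stored as a full tiling of each chromosome, zero runs
    included, with adjacent runs holding distinct values (maximal runs).
    """

    layout: GenomeLayout
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "CoverageTrack":
        runs = {
            name: (np.array([0], dtype=np.int64),
                   np.array([layout.length_of(name)], dtype=np.int64),
                   np.array([0.0]))
            for name in layout.names
        }
        return cls(layout, runs)

    @classmethod
    def from_steps(
        cls, layout: GenomeLayout, steps: dict[str, tuple[np.ndarray, np.ndarray]]
    ) -> "CoverageTrack":
        """Build from per-chromosome (boundaries, values) step arrays.

        ``boundaries`` has one more element than ``values`` and must start
        at 0 and end at the chromosome length.
        """
        runs = {}
        for name in layout.names:
            if name in steps:
                bounds, values = steps[name]
                runs[name] = _coalesce_runs(np.asarray(bounds), np.asarray(values, dtype=float))
            else:
                runs[name] = (
                    np.array([0], dtype=np.int64),
                    np.array([layout.length_of(name)], dtype=np.int64),
                    np.array([0.0]),
                )
        return cls(layout, runs)

    def chrom_runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.runs[chrom]

    def nonzero_runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        starts, ends, values = self.runs[chrom]
        mask = values != 0
        return starts[mask], ends[mask], values[mask]

    def value_at(self, chrom: str, pos: int) -> float:
        starts, ends, values = self.runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return 0.0
        return float(values[i])

    def auc(self, chrom: str, start: float, end: float) -> float:
        """Total signal over [start, end): sum over basepairs of the value."""
        starts, ends, values = self.runs[chrom]
        if end <= start:
            return 0.0
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        for i in range(i0, i1):
            lo = max(float(starts[i]), start)
            hi = min(float(ends[i]), end)
            if hi > lo:
                total += values[i] * (hi - lo)
        return total

    def max_in(self, chrom: str, start: int, end: int) -> float:
        starts, ends, values = self.runs[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return 0.0
        return float(values[i0:i1].max())

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return self.auc(chrom, start, end) / (end - start)

    @property
    def total_auc(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.runs.values())
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        runs = {
            name: (s.copy(), e.copy(), v * factor) for name, (s, e, v) in self.runs.items()
        }
        return CoverageTrack(self.layout, runs)

    def equals(self, other: "CoverageTrack") -> bool:
        if self.layout.names != other.layout.names:
            return False
        for name in self.layout.names:
            for a, b in zip(self.runs[name], other.runs[name]):
                if not np.array_equal(a, b):
                    return False
        return True


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> CoverageTrack:
    """Read a 4-column bedgraph; absent basepairs are zero.

    Records within a chromosome may appear in any order but must not
    overlap.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedgraph needs 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed record") from None
            if chrom not in layout:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= layout.length_of(chrom)):
                raise FormatError(f"{path}:{lineno}: interval outside chromosome")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    steps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, recs in per_chrom.items():
        recs.sort()
        clen = layout.length_of(chrom)
        bounds = [0]
        values = []
        for start, end, value in recs:
            if start < bounds[-1]:
                raise FormatError(f"{path}: overlapping records on {chrom} at {start}")
            if start > bounds[-1]:
                values.append(0.0)
                bounds.append(start)
            values.append(value)
            bounds.append(end)
        if bounds[-1] < clen:
            values.append(0.0)
            bounds.append(clen)
        steps[chrom] = (np.array(bounds, dtype=np.int64), np.array(values))
    return CoverageTrack.from_steps(layout, steps)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write only the non-zero runs (genomecov ``-bg`` dialect)."""
    with open(path, "w") as fh:
        for chrom in track.layout.names:
            starts, ends, values = track.nonzero_runs(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# fragment input


def read_fragments(
    path: str | Path,
    layout: GenomeLayout,
    format: str | None = None,
    sample_id: str | None = None,
) -> FragmentSet:
    """Read one sample's fragments from a fragment BED or a paired-end BAM.

    For BAM/SAM input each properly paired pair yields one fragment
    ``[leftmost mate start, rightmost mate end)``; unpaired, discordant,
    secondary and supplementary alignments are skipped (the skip count is
    recorded on the returned set as ``n_skipped``).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bam" if suffix in (".bam", ".sam") else "fragment-bed"
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    if format == "fragment-bed":
        df = read_bed(path, layout)[INTERVAL_COLUMNS]
        frags = FragmentSet(sample_id, df)
        frags.n_skipped = 0  # type: ignore[attr-defined]
        return frags
    if format != "bam":
        raise ValueError(f"unknown fragment format {format!r}")

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    records: list[tuple[str, int, int]] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), mode) as bam:
        header_sort = (bam.header.to_dict().get("HD") or {}).get("SO")
        if header_sort not in (None, "coordinate"):
            raise FormatError(f"{path}: BAM must be coordinate-sorted (SO={header_sort})")
        last: tuple[int, int] | None = None
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                skipped += 1
                continue
            tid, pos = read.reference_id, read.reference_start
            if last is not None and (tid, pos) < last:
                raise FormatError(f"{path}: BAM is not coordinate-sorted")
            last = (tid, pos)
            if not read.is_proper_pair or read.mate_is_unmapped:
                skipped += 1
                continue
            # count each pair once, at its leftmost mate (TLEN > 0)
            if read.template_length <= 0:
                continue
            records.append(
                (read.reference_name, read.reference_start,
                 read.reference_start + read.template_length)
            )
    df = intervals_frame(records)
    validate_intervals(df, layout, what="fragment")
    frags = FragmentSet(sample_id, sort_intervals(df, layout))
    frags.n_skipped = skipped  # type: ignore[attr-defined]
    return frags
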