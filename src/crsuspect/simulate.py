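"""Seeded simulator of negative-control panels with planted artifacts.

Negative-control CUT&RUN data are modelled as a uniform background of
MNase-digestion fragments plus a small set of high-signal artifact
regions that recur across unrelated samples.  Each planted region has a
prevalence: the probability that any given sample is enriched there.
Enriched regions receive ``fold`` times the background fragment density.
A few sample-specific regions model cell-type private artifacts, and
exact duplicates are added at a configurable rate to exercise
deduplication.  Every draw flows from one seed through a documented
sub-seeding rule (stream ``[seed, 0]`` places regions, ``[seed, 1, i]``
drives sample ``i``, ``[seed, 2]`` places binding sites, ``[seed, 3, j]``
drives target-mode samples), so panels are byte-reproducible and stable
under changes of ``n_samples``.

No sequence model is attempted: the pipeline never inspects sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import FragmentSet, GenomeLayout, intervals_frame, sort_intervals

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_layout",
    "simulate_negative_panel",
    "simulate_target_experiment",
    "simulate_two_target_panel",
]


def default_layout() -> GenomeLayout:
    """Two 10 Mb autosomes plus a 16 kb mitochondrial chromosome."""
    return GenomeLayout(("chr1", "chr2", "chrM"), (10_000_000, 10_000_000, 16_000))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panels.

    Defaults emulate a 20-sample negative-control panel: background 1.0
    fragment/kb (a deduplicated IgG-scale library on this genome), 20
    shared ~3 kb artifact regions at 50x fold enrichment cycling through
    prevalences {1.0, 0.6, 0.4, 0.2, 0.05}, 5 sample-specific regions,
    fragment length 150 +/- 30 bp, and a 10% duplicate rate.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    n_samples: int = 20
    background_rate: float = 1.0  # expected fragments per kb
    n_artifact_regions: int = 20
    artifact_size_mean: float = 3000.0
    artifact_fold: float = 50.0
    artifact_prevalences: tuple[float, ...] = (1.0, 0.6, 0.4, 0.2, 0.05)
    n_sample_specific: int = 5
    sample_specific_fold: float = 50.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 30.0
    duplicate_rate: float = 0.10
    seed: int = 0

    #: minimum separation between planted regions (so 1000 bp peak
    #: extensions can never bridge two distinct regions)
    min_region_gap: int = 20_000
    min_edge_distance: int = 5_000

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("background_rate", "artifact_fold", "duplicate_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(not (0.0 < p <= 1.0) for p in self.artifact_prevalences):
            raise ValueError("prevalences must lie in (0, 1]")
        if max(self.layout.lengths) < 4 * self.min_region_gap:
            raise ValueError("layout too small for the requested artifact spacing")

    def to_dict(self) -> dict:
        return {
            "chromosomes": {n: l for n, l in zip(self.layout.names, self.layout.lengths)},
            "n_samples": self.n_samples,
            "background_rate": self.background_rate,
            "n_artifact_regions": self.n_artifact_regions,
            "artifact_size_mean": self.artifact_size_mean,
            "artifact_fold": self.artifact_fold,
            "artifact_prevalences": list(self.artifact_prevalences),
            "n_sample_specific": self.n_sample_specific,
            "sample_specific_fold": self.sample_specific_fold,
            "fragment_length_mean": self.fragment_length_mean,
            "fragment_length_sd": self.fragment_length_sd,
            "duplicate_rate": self.duplicate_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        chroms = kwargs.pop("chromosomes", None)
        if chroms:
            kwargs["layout"] = GenomeLayout(tuple(chroms), tuple(chroms.values()))
        if "artifact_prevalences" in kwargs:
            kwargs["artifact_prevalences"] = tuple(kwargs["artifact_prevalences"])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator knows about what it planted.

    ``artifact_regions``: chrom/start/end/prevalence/kind/region_id (kind
    is ``shared`` or ``sample_specific``).  ``membership``: boolean frame,
    regions x samples, recording which samples were enriched where.
    ``duplicate_counts``: configured duplicates added per sample.
    ``sites``: true binding sites in target mode.
    """

    artifact_regions: pd.DataFrame
    membership: pd.DataFrame
    duplicate_counts: dict[str, int]
    sites: pd.DataFrame | None = None

    def realized_support(self) -> pd.Series:
        """Number of samples enriched per region (realized, not expected)."""
        return self.membership.sum(axis=1)

    def shared_regions(self) -> pd.DataFrame:
        return self.artifact_regions[self.artifact_regions["kind"] == "shared"]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _place_regions(
    config: SimulationConfig, rng: np.random.Generator, n: int, size_mean: float,
    occupied: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Place n non-mitochondrial regions with a minimum mutual gap."""
    chroms = [c for c in config.layout.names if c != config.layout.mito_name]
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 10_000 * max(n, 1):
            raise RuntimeError("could not place artifact regions; layout too crowded")
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = config.layout.length_of(chrom)
        size = int(max(500, rng.gamma(9.0, size_mean / 9.0)))
        lo = config.min_edge_distance
        hi = clen - config.min_edge_distance - size
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        end = start + size
        gap = config.min_region_gap
        clash = any(
            c == chrom and start - gap < e and s < end + gap
            for c, s, e in occupied + placed
        )
        if not clash:
            placed.append((chrom, start, end))
    return placed


def _fragment_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    lens = rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    return np.maximum(lens, 30).astype(np.int64)


def _background_fragments(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[str, int, int]]:
    rows: list[tuple[str, int, int]] = []
    for chrom in config.layout.names:
        clen = config.layout.length_of(chrom)
        n = int(rng.poisson(config.background_rate * clen / 1000.0))
        lens = _fragment_lengths(rng, n, config)
        lens = np.minimum(lens, clen)
        starts = (rng.random(n) * (clen - lens)).astype(np.int64)
        rows.extend(zip([chrom] * n, starts.tolist(), (starts + lens).tolist()))
    return rows


def _enriched_fragments(
    rng: np.random.Generator,
    config: SimulationConfig,
    region: tuple[str, int, int],
    fold: float,
) -> list[tuple[str, int, int]]:
    chrom, start, end = region
    clen = config.layout.length_of(chrom)
    # enrichment scales the background density; with zero background the
    # fold applies to a reference density of 1 fragment/kb so planted
    # regions still carry signal
    base = config.background_rate if config.background_rate > 0 else 1.0
    extra_rate = base * (end - start) / 1000.0 * max(fold - 1.0, 0.0)
    n = int(rng.poisson(extra_rate))
    lens = _fragment_lengths(rng, n, config)
    mids = start + (rng.random(n) * (end - start)).astype(np.int64)
    starts = np.clip(mids - lens // 2, 0, None)
    ends = np.minimum(starts + lens, clen)
    starts = np.maximum(ends - lens, 0)
    return list(zip([chrom] * n, starts.tolist(), ends.tolist()))


def _add_duplicates(
    rng: np.random.Generator, rows: list[tuple[str, int, int]], rate: float
) -> tuple[list[tuple[str, int, int]], int]:
    if rate <= 0 or not rows:
        return rows, 0
    mask = rng.random(len(rows)) < rate
    dups = [rows[i] for i in np.flatnonzero(mask)]
    return rows + dups, len(dups)


def _sample_fragments(
    config: SimulationConfig,
    sample_index: int,
    stream: int,
    shared: pd.DataFrame,
    owned: pd.DataFrame,
    extra_regions: pd.DataFrame | None = None,
    extra_fold: float = 1.0,
) -> tuple[FragmentSet, np.ndarray, int]:
    """One sample: membership draws, background, enrichment, duplicates."""
    rng = _rng(config.seed, stream, sample_index)
    member = rng.random(len(shared)) < shared["prevalence"].to_numpy()
    rows = _background_fragments(rng, config)
    for is_member, rec in zip(member, shared.itertuples(index=False)):
        if is_member:
            rows += _enriched_fragments(
                rng, config, (rec.chrom, rec.start, rec.end), config.artifact_fold
            )
    for rec in owned.itertuples(index=False):
        rows += _enriched_fragments(
            rng, config, (rec.chrom, rec.start, rec.end), config.sample_specific_fold
        )
    if extra_regions is not None:
        for rec in extra_regions.itertuples(index=False):
            rows += _enriched_fragments(
                rng, config, (rec.chrom, rec.start, rec.end), extra_fold
            )
    rows, n_dup = _add_duplicates(rng, rows, config.duplicate_rate)
    df = sort_intervals(intervals_frame(rows), config.layout)
    sample_id = f"sample_{sample_index:02d}"
    return FragmentSet(sample_id, df), member, n_dup


def _artifact_tables(config: SimulationConfig) -> pd.DataFrame:
    """Region placement and prevalence assignment (stream [seed, 0])."""
    rng = _rng(config.seed, 0)
    shared = _place_regions(config, rng, config.n_artifact_regions,
                            config.artifact_size_mean, occupied=[])
    prevalences = [
        config.artifact_prevalences[i % len(config.artifact_prevalences)]
        for i in range(len(shared))
    ]
    # deterministic owner assignment keeps panels stable under n_samples
    owners = np.arange(config.n_sample_specific) % config.n_samples
    specific = _place_regions(config, rng, config.n_sample_specific,
                              config.artifact_size_mean, occupied=shared)
    rows = []
    for i, ((chrom, s, e), p) in enumerate(zip(shared, prevalences)):
        rows.append((f"artifact_{i:03d}", chrom, s, e, p, "shared", -1))
    for j, ((chrom, s, e), owner) in enumerate(zip(specific, owners)):
        rows.append((f"private_{j:03d}", chrom, s, e, 0.0, "sample_specific", int(owner)))
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                     "prevalence", "kind", "owner"])
    return sort_intervals(df, config.layout)[
        ["region_id", "chrom", "start", "end", "prevalence", "kind", "owner"]
    ]


def simulate_negative_panel(
    config: SimulationConfig,
) -> tuple[list[FragmentSet], GroundTruth]:
    """Generate a panel of negative-control samples with shared artifacts.

    Returns the per-sample fragment sets (coordinate-sorted) and the
    ground truth (regions, realized membership, duplicate counts).
    """
    regions = _artifact_tables(config)
    shared = regions[regions["kind"] == "shared"].reset_index(drop=True)
    frag_sets: list[FragmentSet] = []
    membership = np.zeros((len(regions), config.n_samples), dtype=bool)
    shared_idx = regions.index[regions["kind"] == "shared"].to_numpy()
    dup_counts: dict[str, int] = {}
    for i in range(config.n_samples):
        owned = regions[(regions["kind"] == "sample_specific") & (regions["owner"] == i)]
        frags, member, n_dup = _sample_fragments(config, i, 1, shared, owned)
        frag_sets.append(frags)
        membership[shared_idx, i] = member
        membership[regions.index[(regions["kind"] == "sample_specific")
                                 & (regions["owner"] == i)], i] = True
        dup_counts[frags.sample_id] = n_dup
    member_df = pd.DataFrame(
        membership,
        index=regions["region_id"],
        columns=[f.sample_id for f in frag_sets],
    )
    truth = GroundTruth(
        artifact_regions=regions.reset_index(drop=True),
        membership=member_df,
        duplicate_counts=dup_counts,
    )
    return frag_sets, truth


def simulate_target_experiment(
    config: SimulationConfig,
    n_sites: int = 40,
    site_fold: float = 100.0,
    site_size_mean: float = 600.0,
) -> tuple[FragmentSet, FragmentSet, GroundTruth]:
    """A target sample with true binding sites plus a matched control.

    Both share the seed-derived artifact placement, enriched in every
    shared artifact region; only the target carries the binding sites.
    """
    regions = _artifact_tables(config)
    shared = regions[regions["kind"] == "shared"].reset_index(drop=True)
    # target mode: artifacts present in both datasets regardless of prevalence
    shared_all = shared.copy()
    shared_all["prevalence"] = 1.0

    site_rng = _rng(config.seed, 2)
    occupied = [(r.chrom, r.start, r.end) for r in regions.itertuples(index=False)]
    sites = _place_regions(config, site_rng, n_sites, site_size_mean, occupied=occupied)
    sites_df = sort_intervals(intervals_frame(sites), config.layout)

    empty = regions.iloc[0:0]
    target, _, n_dup_t = _sample_fragments(
        config, 0, 3, shared_all, empty, extra_regions=sites_df, extra_fold=site_fold
    )
    control, _, n_dup_c = _sample_fragments(config, 1, 3, shared_all, empty)
    target = FragmentSet("target", target.data)
    control = FragmentSet("control", control.data)

    membership = pd.DataFrame(
        np.ones((len(shared_all), 2), dtype=bool),
        index=shared_all["region_id"],
        columns=["target", "control"],
    )
    truth = GroundTruth(
        artifact_regions=regions.reset_index(drop=True),
        membership=membership,
        duplicate_counts={"target": n_dup_t, "control": n_dup_c},
        sites=sites_df,
    )
    return target, control, truth


def simulate_two_target_panel(
    config: SimulationConfig,
    n_sites: int = 40,
    site_fold: float = 100.0,
    n_replicates: int = 2,
    site_size_mean: float = 600.0,
) -> tuple[list[FragmentSet], list[str], GroundTruth]:
    """Replicated samples of two different targets over shared artifacts.

    Models the inter-/intra-target distance evaluation: targets A and B
    each get their own binding-site set (streams ``[seed, 2, 0]`` and
    ``[seed, 2, 1]``), every sample carries every shared artifact region,
    and replicate ``r`` of target ``t`` draws its fragments from stream
    ``[seed, 3, 2 t + r]``.  Returns the fragment sets, one target label
    per sample, and the ground truth (``sites`` carries a ``target``
    column).
    """
    regions = _artifact_tables(config)
    shared_all = regions[regions["kind"] == "shared"].reset_index(drop=True)
    shared_all["prevalence"] = 1.0
    occupied = [(r.chrom, r.start, r.end) for r in regions.itertuples(index=False)]
    site_frames = []
    for t, name in enumerate("AB"):
        rng = _rng(config.seed, 2, t)
        placed = _place_regions(config, rng, n_sites, site_size_mean, occupied=occupied)
        occupied += placed
        df = sort_intervals(intervals_frame(placed), config.layout)
        df["target"] = name
        site_frames.append(df)
    empty = regions.iloc[0:0]
    frag_sets: list[FragmentSet] = []
    labels: list[str] = []
    dup_counts: dict[str, int] = {}
    for t, name in enumerate("AB"):
        for r in range(n_replicates):
            fs, _, n_dup = _sample_fragments(
                config, n_replicates * t + r, 3, shared_all, empty,
                extra_regions=site_frames[t], extra_fold=site_fold,
            )
            fs = FragmentSet(f"target{name}_rep{r}", fs.data)
            frag_sets.append(fs)
            labels.append(name)
            dup_counts[fs.sample_id] = n_dup
    membership = pd.DataFrame(
        np.ones((len(shared_all), len(frag_sets)), dtype=bool),
        index=shared_all["region_id"],
        columns=[f.sample_id for f in frag_sets],
    )
    truth = GroundTruth(
        artifact_regions=regions.reset_index(drop=True),
        membership=membership,
        duplicate_counts=dup_counts,
        sites=pd.concat(site_frames, ignore_index=True),
    )
    return frag_sets, labels, truth
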