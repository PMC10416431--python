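# Methods

## Coordinate model

All coordinates are 0-based, half-open (`[start, end)`), the BED and
bedgraph convention. A `GenomeLayout` (chromosome names and lengths, in
chrom.sizes file order) defines the coordinate universe; the file order,
not lexicographic order, defines the sort order of every interval output,
so results are deterministic without renaming chromosomes. Overlap means
at least one shared basepair everywhere in the package — fragment
filtering, peak subtraction, FRIP, list comparison and bin exclusion all
use the same rule, and an interval ending exactly where another starts
does not overlap it.

Coverage tracks store a full tiling of each chromosome as maximal
constant-value runs (zero runs included internally; the bedgraph writer
emits only non-zero runs, the `genomecov -bg` dialect, and the reader
treats absent basepairs as zero).

Paired-end input is reduced to fragments at the boundary: one interval
per properly paired read pair, spanning leftmost mate start to rightmost
mate end, counted once at the mate with positive template length.
Secondary, supplementary, unpaired and discordant alignments are skipped
and counted. Duplicate removal is exact-coordinate collapse of fragment
intervals.

## Peak calling

The caller follows the signal-block model used for CUT&RUN: blocks are
maximal runs of strictly positive coverage, scored by AUC (sum of the
coverage value over the block's basepairs) and maximum height.

*Numeric threshold* (the suspect-list mode): with threshold `t` and `B`
blocks, the top `ceil(t*B)` blocks ranked by AUC are retained, keeping
every block tied with the cutoff value (reproducible on small `B`, and
the natural reading of "the highest 0.1 % of signals" at `t = 0.001`).
Stringent mode additionally requires the block's max height to reach the
same-rank cutoff of the height distribution; relaxed mode is the AUC rule
alone. The retained fraction therefore lies in `[t, t + ties/B]` and is
monotone in `t`.

*Control-calibrated*: target blocks are kept when their AUC strictly
exceeds the empirical `1 - t` quantile of the control's block AUCs, after
scaling the control by total-signal ratio when normalisation is on;
stringent mode applies the analogous height cutoff. This captures the
stringent/relaxed contrast of control-calibrated CUT&RUN callers without
claiming bit-for-bit agreement with any particular implementation, whose
total-signal-curve internals are not reproduced here.

## Consensus construction

Per-sample peaks are extended by `e` (default 1000 bp, clamped to the
chromosome) and merged within each sample, so within-sample overlap
counts once. Support counting is segment-based: the genome is segmented
at every extended-peak boundary and each segment carries the number of
distinct samples covering it. Segment counting is order-independent and
testable against a per-basepair oracle, which is why it was chosen over
whole-peak matching (whose semantics differ between overlap tools).

The retention rule is strict: keep segments with `support / N >` the
reproducibility fraction `r` (default 0.30). `min_support(N, r)` is the
smallest such integer; for `N = 20`, `k = 7` (6/20 = 30 % is excluded).
Kept segments are merged (touching intervals merge at gap 0, the default
of standard merge tools) and each merged region reports its maximum
segment support.

The mitochondrial chromosome is appended whole as a region flagged
`chrM-policy` (toggleable) rather than being required to pass thresholds:
negative-control panels are systematically contaminated by mitochondrial
DNA, and its inclusion is a deliberate policy, not a statistical
inference. Unplaced/random scaffolds receive no such treatment and must
pass thresholds.

The reproducibility curve reports, for each `m = 1..N`, the number of
candidate regions (merged union of all covered segments) whose maximum
support reaches `m`. Counting candidates at each level — rather than
re-merging the level-`m` segments — makes the curve non-increasing by
construction; re-merging per level is not monotone, because merging at
low levels fuses candidates and the count can rise before it falls. The
knee is the `m` maximising perpendicular distance from the chord joining
the curve's endpoints; a constant curve has no knee and is flagged.

## Annotation

Category precedence is promoter > exon > intron > intergenic, with the
promoter window spanning 1000 bp upstream to 100 bp downstream of each
TSS in the gene's orientation (the convention of the common annotation
tools). The closest TSS is chosen by minimal distance from the region
midpoint; the signed distance is negative when the midpoint lies upstream
of the TSS on its strand. Regions are "unannotated" when no tables are
supplied. Low-mappability flagging compares a region's mean mappability
(from a `[0, 1]`-valued track) against a cutoff, default 0.5; published
mappability criteria vary, so the cutoff is exposed.

## Evaluation statistics

Binned matrices count fragments by midpoint (`(start + end) // 2`,
boundary midpoints go right), which conserves counts exactly — row sums
equal per-sample totals in bins mode. Default bin width is 10 kb, the
default of the common summary tool. Counts enter correlation and PCA
raw (no normalisation), matching default tooling behaviour; an analysis
needing depth correction can normalise the matrix before the calls.

Spearman matrices use average ranks; a zero-variance sample's
correlations are reported as NaN, not zero. PCA centres each bin across
samples (samples are observations) and reports eigenvalues and percent
variance via SVD; percent variance sums to 100 over computed components.
The distance report takes mean Euclidean distances between binned count
rows within and between target groups; Euclidean distance on the raw
binned matrix is one defensible choice among several (distances could
equally be taken in PCA space) and is stated prominently so users can
compare alternatives.

**After-filtering matrices exclude list bins.** Removing fragments alone
leaves every bin that partially overlaps a suspect region with a
depletion shared by all samples, which rank correlation reads as
*positive* correlation. Post-filter Spearman/PCA/distance statistics are
therefore computed on the filtered fragments *with bins overlapping the
list dropped* (blacklist-style exclusion, `qc.exclude_bins`), which is
also how the corresponding upstream tooling is normally run.

## Synthetic data

The generator emulates the statistical structure of negative-control
panels: uniform background fragments (Poisson count at
`background_rate` per kb, fragment lengths normal 150 ± 30 bp, minimum
30), shared artifact regions receiving `fold` times the background
density in the samples where they are "on", sample-specific private
artifacts, and exact duplicates at a configurable rate. Default study
conditions: two 10 Mb autosomes plus a 16 kb chrM; 20 samples;
background 1.0 fragment/kb (a deduplicated IgG-scale library at this
genome size); 20 shared ~3 kb regions (gamma-distributed sizes, mean
3000 bp) at 50× fold, cycling prevalences {1.0, 0.6, 0.4, 0.2, 0.05};
5 private regions; duplicate rate 0.10. Planted regions are placed at
least 20 kb apart so 1 kb extensions can never bridge two distinct
regions, and at least 5 kb from chromosome ends.

Randomness flows from a single seed through a documented sub-seeding
rule (`SeedSequence([seed, stream, index])`): stream 0 places regions,
stream 1 drives panel sample `i`, stream 2 places binding sites, stream
3 drives target-mode samples. Each sample draws its Bernoulli(prevalence)
region memberships inside its own stream before its fragments, so
panels are byte-reproducible and stable when `n_samples` grows; realized
membership is recorded in the ground truth and tests use realized, not
expected, support. Private-region owners are assigned deterministically
(`region j` to sample `j mod n_samples`) for the same stability reason.
With zero background the enrichment fold applies to a reference density
of 1 fragment/kb, so planted regions still carry signal.

Target mode plants `n_sites` binding sites (default 40, ~600 bp, 100×
fold) away from every artifact region; the matched control shares the
artifact placement exactly and lacks the sites. The two-target panel
gives targets A and B disjoint site sets with replicate samples, for the
inter:intra distance evaluation.

What the simulator does **not** model: sequence (the pipeline never
inspects it), GC or fragmentation bias, chromatin-state-correlated
background, read-level errors, or inter-sample depth variation beyond
Poisson fluctuation. Passing tests therefore demonstrate the pipeline's
correctness and the qualitative artifact signatures (inflated
correlation/PC1, artifact peak calls, their removal by filtering) — not
that any particular genome's published list is reproduced. Panel-scale
numbers from real data (region counts in the thousands, FRIP extremes,
specific distance ratios) require the original public datasets and are
out of desk scale by design.

## Numerical and degenerate-input choices

- `min_support` guards float fuzz at exact multiples (e.g. `20 * 0.30`)
  so strictness is decided mathematically, not by rounding direction.
- Empty block lists yield an empty peak set with a logged warning; an
  empty or zero-signal control is an error ("control has no signal").
- FRIP of an empty fragment set is an error, not 0/0.
- Average profiles rescale each region (plus flanks) to `nbins` equal
  parts by exact prefix-sum integration of the step function; spans
  reaching past a chromosome end are truncated and counted.
- The consensus of fewer than two samples is an error; a panel with no
  peaks anywhere yields only the chrM policy region (or an empty list
  with the policy off).

## Problem sizes

Default test and acceptance runs use the 2 × 10 Mb + chrM genome with
20-sample panels (~24 k fragments per sample) and 10-seed recovery
sweeps; kernel-vs-oracle batteries run on ≤ 10 kb chromosomes where
per-basepair brute force is exact and cheap. These sizes exercise every
code path at full panel dimensionality while keeping a complete run in
the order of seconds.
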