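# Methods

This note documents the models, rules and numerical choices behind
`promoterz`: what each pipeline stage computes, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Coordinate and window conventions

All coordinates are 0-based half-open, the native convention of BED,
BEDPE and bedGraph. A TSS read from BED6 is the feature's 5′ end in gene
orientation: `start` on the plus strand, `end − 1` on the minus strand.

Flank windows come in two presets:

| mode      | −1 window (gene orientation) | +1 window      | used for                      |
|-----------|------------------------------|----------------|-------------------------------|
| hierarchy | −600 .. −100 bp              | +100 .. +600 bp| positional classification     |
| change    | −500 .. 0 bp                 | 0 .. +500 bp   | change partitioning           |

On the minus strand the windows are mirrored about the TSS boundary so
the −1 window is always transcription-upstream. Under this convention,
reflecting every coordinate through its chromosome (`t → L − t` for TSS
boundaries, `[s,e) → [L−e, L−s)` for intervals) and flipping strands maps
the windows exactly onto each other; window means use exact
(order-invariant) summation so the mirrored signal is bit-identical, a
property the test suite checks.

Promoters whose windows cross a chromosome edge are excluded from
downstream statistics and counted (`df.attrs["n_dropped"]`), never
silently truncated.

## Signal and normalisation

Coverage is the per-base count of overlapping fragments. The offered
depth normalisation is CPM (per-base count × 1e6 / number of fragments);
RPKM is computed per region only. The classification is quantile-based
and therefore invariant to any per-condition rescaling; normalisation
matters only where two conditions share one threshold. Log fold changes
use a pseudocount (default 0.01, sized for CPM-scale promoter signals of
order 1–100; configurable).

## Positional classification

Per promoter and side, the signal is the arithmetic mean over the flank
window. The threshold is a nearest-rank top quantile: the k-th largest
value with `k = ceil(q·n)` (default q = 0.25), membership `value ≥
threshold`, ties included. Nearest-rank was chosen over interpolated
quantiles because it is reproducible without interpolation policy and
well defined on discrete data.

By default one threshold is computed on the two sides' scores **pooled**
("top 25 % of all flank scores on both sides"). Because −1-side scores
run systematically lower than +1-side scores, more than a quarter of
promoters exceed the pooled threshold on the +1 side and fewer on the −1
side; the −1-only class is then rare, as the installation hierarchy
predicts. Per-side thresholds (exactly `ceil(q·n)` promoters per side)
are available via `pooled=False` or per-side quantiles. The pooled
default is deliberate: with per-side thresholds at a common q both top
sets have exactly the same size, which forces the One and MinusOnly
classes to be equally large (both `q·n − |Two|`) — incompatible with a
hierarchy in which the −1-only state is rare.

Cross-condition comparisons always reuse the reference condition's
thresholds; the reference is an explicit argument, never inferred.
Transitions are tabulated per promoter as a 4×4 table with the One→Two
("gain at −1") and One→Zero ("loss at +1") margins exposed as promoter
lists.

Change partitioning applies the same top-quantile rule to per-side log
fold changes: a promoter in the top q on the −1 side but not the +1 side
is `IncreasedMinus1`, and symmetrically; top on both is `Both`.

## Fragment-size stratification

Non-nucleosomal fragments (NNFs) are paired-end fragments strictly
shorter than 150 bp; fragments of exactly 150 bp are assigned to the
nucleosomal class so the NNF set matches the strict "< 150 bp"
definition. The per-promoter NNF signal is the CPM-normalised NNF
coverage averaged over TSS ± 250 bp (the NDR locale; half-width
configurable).

## Association statistics

* Quartiles: stable ascending sort cut into four contiguous rank blocks;
  when n is not divisible by 4, earlier quartiles receive the extra items
  (largest-remainder rule — deterministic and order-stable).
* Rank-sum tests: two-sided Wilcoxon/Mann-Whitney per unordered pair of
  groups. When both groups have ≤ 8 observations the p value is an exact
  permutation enumeration over all reassignments of the pooled observed
  values (handles ties exactly); otherwise the tie-corrected normal
  approximation (scipy) is used. The switch at 8 keeps exactness where
  enumeration is cheap. P values are adjusted across pairs with the
  Hochberg step-up procedure (statsmodels `simes-hochberg`).
* Peak overlap: any shared base makes two half-open intervals
  intersect (abutment does not). Enrichment is the hypergeometric upper
  tail P(X ≥ x) for x of K "marked" items in a draw of n from a universe
  of N. The universe is a required argument: it is a modelling choice
  (e.g. number of promoters considered) that should never be guessed by
  the tool.

## Synthetic generator

The generator encodes hierarchical installation as a saturating
targeting model. Per promoter: with probability `p_untargeted` no
variant at all; otherwise targeting `T` from a lognormal (or gamma) law.
Occupancies follow

    occ₊₁ = T/(T+S)            occ₋₁ = max(0, T−c_i)/(max(0, T−c_i)+S)

with saturation `S` and per-promoter spillover capacity
`c_i = c · LogNormal(0, spillover_spread)`. The per-promoter capacity
jitter makes the +1→−1 ordering strict within a promoter but
heterogeneous across promoters, as a single global capacity would make
the −1 ranking a deterministic function of the +1 ranking. Chaperone
loss multiplies `T` by `loss_factor` at a `regulated_fraction` of
promoters — a redistribution, not a uniform global gain, which is what
survives per-library depth normalisation as a net upward shift.

True classes use a fixed occupancy cutoff of 0.5 per side, recorded in
the truth table together with all latent state.

Rendering: ChIP-like fragments (147 bp footprint) are Poisson with mean
`chip_depth · occ` at each dyad (±350 bp from the TSS in gene
orientation), midpoints jittered Normal with sd interpolated from
`positioning_sd_low` (fuzzy, low occupancy) to `positioning_sd_high`
(well positioned), plus a uniform Poisson background sized as
`background_frac` of the fully-occupied signal. ATAC-like data is a
two-component length mixture: NNFs around the TSS (rate
`b0 + b1·occ₊₁ + b2·occ₊₁·occ₋₁`, lengths truncated-normal 30–149 bp)
and nucleosome-sized fragments at the dyads (lengths 160–400 bp), so the
length histogram has the NDR/mononucleosome gap characteristic of real
accessibility libraries.

All randomness flows from a single seed through named substreams
(`SeedSequence.spawn`), so fixtures and every downstream output are
byte-identical across reruns.

Default parameters and rationale:

| parameter           | default | meaning                                            |
|---------------------|---------|----------------------------------------------------|
| `p_untargeted`      | 0.4     | promoters with no variant                          |
| targeting law       | LogNormal(0, 1.6) | heavy-tailed targeting intensity         |
| `saturation` S      | 1.0     | intensity at half-maximal +1 occupancy             |
| `spillover_capacity` c | 4.0  | median +1 capacity before −1 deposition begins     |
| `spillover_spread`  | 0.75    | per-promoter capacity heterogeneity (log-sd)       |
| `loss_factor` α     | 3.0     | targeting multiplier under chaperone loss          |
| `regulated_fraction`| 0.4     | promoters responsive to the chaperone              |
| `chip_depth`        | 100     | expected fragments per fully occupied nucleosome   |
| `background_frac`   | 0.01    | background relative to full-occupancy signal       |
| `dyad_offset`       | 350 bp  | TSS-to-dyad distance (centres of the flank windows)|

The latent-state defaults were chosen so the reference condition's
pooled top-25 % classification lands near the class proportions reported
for wild-type fibroblast promoters (roughly 10–15 % Two, 20–30 % One,
~60 % Zero, −1-only rare).

What the generator does **not** emulate: alignment artifacts and
duplicates, GC and transposase sequence bias, blacklist or mitochondrial
contamination, multiple chromosomes, irregular gene spacing, enhancers
and non-promoter H2A.Z sites, or transcription-coupled turnover. Tests
that pass on synthetic data therefore validate the analysis logic and
its statistical behaviour, not robustness to those real-data artifacts,
which should be handled upstream with standard tools.

## Ground-truth recovery

Measured-class vs true-class agreement anchors the per-side quantiles to
the true per-side exceedance fractions recorded in the truth table
(e.g. if 9 % of promoters truly carry −1 occupancy ≥ 0.5, the −1
threshold is the top-9 % rank of measured −1 signals). Because the
measured signal is a strictly increasing function of occupancy plus
noise, agreement approaches 100 % as depth grows; at `chip_depth` 50
with 1 % background and n = 5,000 the pipeline recovers ≈ 95 % of true
classes. A single common q on both sides cannot converge to the truth,
since the true −1 exceedance fraction is necessarily smaller than the +1
fraction under the hierarchy.

## Problem sizes

The standard analysis sizes used throughout the tests and the
reproduction script are 20,000 promoters for the analytic
independent-sides check, 5,000 for ground-truth recovery and 2,000 for
the chaperone-loss comparison — sizes at which every run completes in
seconds on one CPU while Monte-Carlo error stays well inside the stated
tolerances.

## Known limitations

* The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and is therefore
  capped at groups of 8; above that the tie-corrected normal
  approximation is used (with continuity correction), which is standard
  but approximate for small-ish groups with heavy ties.
* Coverage tracks are dense per-chromosome float arrays: simple and
  fast for the simulated single-chromosome layouts, but memory-hungry
  for full mammalian genomes (~8 bytes/bp); a run-length or binned
  backend would be the natural extension.
* bedGraph values round-trip exactly via shortest-repr floats; bigWig
  binary I/O is intentionally out of scope.
* The hypergeometric peak-overlap test treats peaks as exchangeable
  items; it ignores peak length and genomic clustering, as the plain
  test does.
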