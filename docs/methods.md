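# Methods

This note documents the modelling and numerical conventions behind
`tomometrics`: what each quantity means, the choices made where the
definitions in the field leave room, and what the synthetic-data tests do
and do not demonstrate.

## Plan model

A helical tomotherapy delivery is represented by the fractional
leaf-open-time (FLOT) sinogram `S ∈ [0,1]^{N×L}` plus the projection time
PT (ms). One canonical representation feeds everything: absolute open times
are always `S_ij × PT`, and the binary mask is `O_ij = [S_ij > ε]` with
`ε = 0` by default (a leaf is open iff its open time is nonzero;
configurable for noise-floor studies). Values exceeding 1 by ≤ 1e−9 are
clipped (floating-point dust in TPS exports); larger violations abort with
the offending cell named, because a silently rescaled sinogram would bias
every metric downstream.

The leaf-position array used by the centroid and MSA is
`P = (−L/2, …, −1, +1, …, +L/2)` for even `L` (the MLC center falls between
the two central leaves, so there is no zero entry); both metrics are
reported in these dimensionless number-of-leaves units.

Delivery metadata (field width, gantry period, couch translation, target
length, fraction dose) is carried alongside the sinogram and never guessed:
a metric whose inputs are absent is reported as NaN. Target length is a
metadata pass-through — no convention relating it to couch travel is
imposed. When a stored gantry period contradicts
`PT × projections_per_rotation` by more than 0.1% the sinogram-derived
value wins, with a logged warning, because the sinogram is the delivery
ground truth. `TT = N × PT` excludes ramp-up/dead time; centers comparing
against console-reported beam-on times should add their own offset.

## Statistic conventions

All LOT/FLOT distribution statistics are computed over the **nonzero**
cells. Including structurally closed leaves would let field size swamp
every distributional quantity (the modulation factor, for one, would grow
without bound), and closed-leaf structure is already measured by the
geometry metrics.

* Cumulative scores use strict inequalities: `CLNS_n = P(LOT < n ms)`,
  `CLNS_pt,n = P(LOT > PT − n ms)`, `CFNS_n×100 = P(FLOT < n)`.
* Standard deviations are sample (ddof = 1) estimates; skewness is the
  biased population estimator and kurtosis the biased non-excess estimator
  (normal → 3), matching the defaults of the numerical environment most
  metric libraries in this field were first written in. A single-value
  distribution has sd 0 and NaN skewness/kurtosis.
* The mode of a continuous distribution is estimated as the midpoint of the
  fullest bin of a 100-bin histogram spanning [min, max], ties resolved to
  the lowest bin — deterministic and scale-equivariant, so
  `moFLOT = moLOT / PT` like every other location statistic.

## Geometry conventions

Per projection, the treatment area is the span between the outermost open
leaves, `TA_i = R_i − L_i + 1`; connected components are maximal runs of
consecutive open leaves. Projections with no open leaf have no span, so
they are excluded from the TA/centroid/nCC/lengthCC averages (which run
over the `N_active` projections with at least one open leaf) but they stay
in the denominators of fDISC, CLS and CLS_in, where an empty projection
legitimately contributes "no discontinuity, everything closed, nothing
in-field". `lengthCC` is the grand total component length over the grand
total component count (not a per-projection average of averages). The
`CLS_in,disc` variants restrict both numerator and denominator to the
discontinuous (`nCC_i > 1`) projections and are reported as 0, with a flag
on the result object, when the plan has none. The L0NS/L1NS/L2NS
open-neighbour scores pool open cells over the whole plan before
normalizing — stable for plans with nearly-empty projections — and count
out-of-range neighbours as closed, so they always sum to 1.

## Modulation conventions

The per-leaf normalizer in ELOTV is the leaf's **maximum** opening
`max_i S_ij`. This is the only reading under which the metric is bounded by
1 (each |difference| is at most the leaf maximum) and reduces to the
classical LOTV through `LOTV = 1 − ELOTV_1`; never-open leaves contribute 0
(zero variability). EPSTV sums both directional difference terms over the
common index window `i ≤ N−Δp, j ≤ L−Δl` and normalizes by `N−Δp` (by `N`
when `Δp = 0`); the (0,0) pair is rejected as degenerate. All cells
participate — empty projections are not skipped.

**nOC.** Openings are physically centered within their projection
interval, so a leaf can only remain open across a projection boundary along
fully open cells. The counting model: a maximal run of `S = 1` cells,
together with at most one partial (0 < S < 1) cell at each end — the
ramp-in/ramp-out of one continuous opening — counts as ONE open–close pair
(2 events); every other partial cell closes within its own projection and
is its own pair. A partial cell wedged between two full runs is attached to
the earlier run (greedy-left; the choice only matters in this measure-zero
configuration and is fixed for determinism). Consequences: total events
≤ 2 × (open-cell count) with equality iff no cell is fully open, giving
the exact regime `CLS = 1 − 0.5·nOC` for plans without fully-open cells and
`CLS ≤ 1 − 0.5·nOC` otherwise — the inequality direction follows from
merging only ever *reducing* the event count.

**MI.** No single modulation-index definition is standard for tomotherapy,
so the default is a spectral index defined directly on the sinogram:
`MI = ∫₀² z(f) df`, where `z(f)` is the fraction of adjacent-cell FLOT
changes — along both the projection and the leaf axis — exceeding `f·σ`,
with `σ` the sd of the nonzero FLOTs (Webb-style aperture-modulation
spectrum, extended to both sinogram axes). A constant sinogram scores the
minimum, 0. The definition sits behind a plug-in point
(`RegistryConfig.mi_function`) so a center can substitute its house
definition without touching the registry.

## DICOM dialects

Vendor RT-Plan layouts for the HT sinogram are not publicly documented. The
adapters read one projection per control point from the MLCX
`LeafJawPositions` element — fractional values in plan order for the
Precision dialect, absolute milliseconds in reversed leaf order for the
RayStation dialect — and delivery metadata from a named private block; the
layouts were fixed against generated sample files and are verified by
round-trip and shape checks only. The native JSON exchange format (full
`repr` float precision, deterministic serialization) is the archival and
test substrate, so the math core never depends on clinical DICOM.

## Synthetic plans

The generator emulates the two delivery regimes observed in clinical
cohorts: an *inefficient* regime whose FLOT histogram is bimodal (dominant
peak near 0.5, secondary peak near the maximum opening — modulation
achieved by shortening open times, high modulation factor, high CFNS_75)
and an *efficient* regime with a flat histogram plus a marked last-bin peak
(modulation achieved by splitting the field geometrically, low CFNS_75).
No quantitative histogram parameters are published for these regimes; the
mixture weights (0.70/0.30 around 0.5/0.92 for bimodal; 0.55 flat body +
0.45 end-peak for efficient) were chosen once as qualitative emulations
that reproduce the regime ordering of CFNS_75, and are not tuning knobs.

Each projection carries an open span of `round(open_fraction × L)` leaves
centered at `L/2 + asymmetry_shift` with a Poisson(`discontinuity`) number
of single-leaf gaps placed strictly inside the span (so the span bounds
stay open by construction). Delivery metadata defaults are typical Radixact
values: PT 250 ms (GP 12.75 s at 51 projections/rotation), FW 2.5 cm,
pitch 0.287, 2 Gy/fraction; default desk-scale plans use 400 projections
(clinical plans run into the thousands — the metrics are all intensive,
per-projection or per-cell averages, so size only affects estimator
noise). With `allow_full_open=False` all nonzero FLOTs stay ≤ 0.999,
keeping cohorts in the exact `CLS = 1 − 0.5·nOC` regime. Cohorts derive
per-plan seeds as `master_seed + 1 + index`, so they are reproducible
element-wise and extensible without reshuffling.

What the generator does **not** emulate: optimizer-induced correlation
between adjacent projections, leaf-latency physics, dose realism, or the
site-specific structure of clinical cohorts. Tests passing on synthetic
cohorts therefore validate the *definitions and identities* of the metrics
and the statistical machinery, not any clinical claim about PSQA
predictability.

## Cohort statistics

Spearman correlations use average ranks for ties and the large-sample
two-sided t approximation for p-values (the standard choice down to the
~10-plan cohorts used in testing; exact permutation would change nothing
qualitative at the sizes involved). Correlation magnitudes are graded into
the conventional five classes (very weak < 0.2 ≤ weak < 0.4 ≤ moderate
< 0.6 ≤ strong < 0.8 ≤ very strong); significance defaults to α = 0.05
with no multiplicity correction across the 65-metric family (the screen is
exploratory by design).

The PSQA screen keeps endpoint-significant metrics, then walks them in
descending |ρ| (ties broken by name for determinism) dropping any metric
whose |ρ| with an already-kept metric reaches the redundancy threshold —
default 0.6, i.e. "(very) strongly correlated", switchable to 0.8 via the
`redundancy_threshold` argument. Both the pre- and post-pruning lists are
returned. An empty selection is a valid outcome, not an error.

The efficiency split takes CFNS_75 quartiles with linear-interpolation
percentiles and strict inequalities (plans exactly at a percentile belong
to neither group); group comparisons use the Student equal-variance t-test
by default with Welch as an option, flagged at 0.05/0.01. Per-plan FLOT
histograms (20 bins over (0,1], counts normalized to unit sum) are pooled
per group as mean ± 1.96·sd/√n.

## Problem sizes and limitations

The test suite and the acceptance script run on deliberately small
problems — plans of ~5–100 projections and 4–64 leaves, cohorts of 24–50
plans, 1000-replicate null screens — chosen so the whole suite completes in
well under a minute while still exercising every identity at machine
precision and every stochastic property with comfortable margins.

Known limitations: the DICOM adapters are validated only against generated
sample files, not vendor exports; TL has no computed fallback; MI is a
house definition pending a community standard; the nOC greedy-left
attachment is a convention; and clinical correlation magnitudes between
metrics and γ passing rates cannot be reproduced from synthetic data and
are out of scope.
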