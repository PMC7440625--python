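# Methods

## The measurement problem

Nuclear transgenes in *Chlamydomonas reinhardtii* integrate at essentially
random genomic positions, so independent transformants of the same
construct express it at wildly different levels, and a sizeable fraction
is silenced outright. Any per-strain fluorescence comparison is therefore
confounded by the insertion site. The quantity of interest here — the
read-through rate of a leaky stop codon placed between a gene and a
downstream fluorescent reporter — is instead estimated at the *population*
level: if the distribution of mRNA expression across transformants depends
only on the genomic locus and not on the construct variant, then
population-average reporter fluorescence differs between construct
variants only through the fraction of translation events that produce the
reporter-tagged protein.

## Pipeline

Given a plate-reader table (absorbance at 750 nm, Venus-channel
fluorescence, chlorophyll-channel fluorescence per well) and a layout
assigning wells to blanks or to (construct, strain, replicate):

1. **Zeroing.** Per plate and per channel, the arithmetic mean of the
   blank wells is subtracted from every sample well. Blanks are consumed.
   The mean over available blanks is used because only "subtraction of
   wells not containing algae" is defined by the protocol; the mean is
   well-defined for any number of blanks ≥ 1. Per-plate correction is the
   default; pooling blanks across plates is available behind a flag.
2. **Per-cell normalization.** Zeroed Venus fluorescence is divided by
   zeroed absorbance (default) or zeroed chlorophyll fluorescence, giving
   fluorescence per unit of cell material, `nu`. Wells whose zeroed
   denominator is at or below a positivity floor (default 0, i.e. strictly
   positive required) are flagged invalid, carried through every table for
   auditability, and excluded from all population statistics; near-empty
   wells otherwise produce arbitrarily unstable ratios.
3. **Control scaling.** Within each replicate, `nu` is divided by the mean
   over the no-reporter control population screened alongside the samples,
   so 1 means "typical autofluorescence". The control-population mean is
   exactly 1 by construction.
4. **Detection calling.** A transformant "expresses detectable reporter"
   when its control-scaled value falls strictly outside
   `mean ± 1.959964 · sd` of the control population — a population
   (tolerance) interval on individual wells, not a confidence interval of
   the mean, because single outlying transformants are what the screen
   flags. Boundary values count as not expressing. Both tails flag, since
   the band is symmetric; a one-sided mode (z = 1.6449) and an empirical
   2.5/97.5-percentile mode exist for robustness checks. No
   multiple-testing correction is applied: the call is a screen read-out,
   not a hypothesis test. The normal z rather than a small-sample t is
   used; at the 24–96 controls typical of these screens the difference is
   immaterial.
5. **Anchor rescaling.** Within each replicate, normalized values are
   mapped through `100 · (x − stop_mean) / (fusion_mean − stop_mean)`,
   where the anchors are the means of the valid stop-construct (no
   read-through product) and translational-fusion (tagged protein from
   every translation event) populations of that same replicate. Anchors
   are never pooled across replicates. The stop population mean maps to
   exactly 0 and the fusion mean to exactly 100; the map is invariant
   under any positive affine transform of its inputs, so gain and offset
   choices of the instrument cancel.
6. **Read-through estimate.** The per-replicate leakiness is the mean
   rescaled value over *all* valid leaky-construct transformants,
   expressing and non-expressing alike — conditioning on detection would
   truncate the lower tail and bias the estimate upward. Replicates are
   aggregated as arithmetic mean ± standard error (sample sd over
   √n_replicates); with per-replicate values 1.2, 2.7 and 3.6 this
   aggregation gives 2.5 ± 0.7.

Two side channels share the infrastructure:

* **Transformation efficiency** = colonies / cells plated, normalized
  within each transformation experiment to a positive-control construct
  (by default the one selected for photoautotrophy), whose row maps to
  exactly 100%. Display conventions (e.g. dividing one strain's values by
  10 to fit a plot axis) are never applied to computed values.
* **Immunoblot-based estimates.** Band densitometry values enter only as
  numbers. The coarse band-ratio read-through estimate is
  `100 · mean(leaky bands) / mean(fusion bands)`. The
  fluorescence–protein calibration regresses control-scaled fluorescence
  (response) on relative band intensity (OLS with intercept) over points
  with detectable fluorescence and positive band intensity; inverting the
  line expresses a fluorescence value — the autofluorescence unit, or the
  detection-interval upper bound — as a relative protein level. Fitting
  with an intercept is a deliberate choice: nothing mandates a
  through-origin line, and the distinction between the protein level at
  fluorescence 1 and at the detection threshold is only meaningful with a
  free intercept. Both conventions can be compared since slope and
  intercept are reported.

## Synthetic screen model

The generator emulates the statistical structure the analysis assumes,
with per-well signals (defaults in parentheses):

* density `A ~ lognormal(0, 0.25)` in OD750 units — well-to-well culture
  variation;
* expression `E = 0` with probability `s` (0.1, all-or-nothing silencing;
  silencing is widespread in this organism but no rate is established),
  else `E ~ lognormal(0, 1)` — position-effect variation spanning roughly
  two orders of magnitude;
* construct translation fraction `rho`: fusion 1, leaky 0.025 (the
  module's default encodes a ~2.5% read-through rate), stop and
  no-reporter 0;
* raw venus = 100 + `A · (50 + 2000 · rho · E)` + N(0, 20) — all cells
  autofluoresce (50 fluorescence units per OD unit); the Venus gain of
  2000 makes a typical fusion transformant ~40× autofluorescence while a
  typical leaky one sits around 2× — near the detection band, so an
  appreciable share of leaky wells is *not* individually detectable, as in
  real screens where substantial protein is needed for a detectable
  signal;
* raw od750 = 0.04 + `A` + N(0, 0.005); raw chl = 30 + `1500 · A` +
  N(0, 5);
* blanks (4 per plate; positions and counts are free, the schema accepts
  any number ≥ 1) read baseline + noise; noise is additive Gaussian per
  channel and negative raw readings are allowed, as instruments report
  them.

Each replicate is an independent plate with its own blanks, control,
anchor and leaky populations of 96 wells per construct (3 replicates by
default). All randomness flows from one `numpy` Generator seeded from the
config, so identical configs reproduce datasets bit-exactly.

What the generator does **not** emulate: plate-position (edge/evaporation)
effects, construct-specific mRNA stability or silencing rates, detector
saturation, or correlated channel noise. Passing recovery tests therefore
shows the estimator is correct *under the stated generative assumptions* —
in particular the assumption that expression distributions are shared
across constructs — not that real screens satisfy those assumptions.

## Numerical and design notes

* The read-through estimator is a ratio of sample means; at finite
  population sizes it carries a small Jensen-type bias of relative order
  `CV²(fusion mean)` (~2% relative at 96 wells, i.e. ~0.05 points at a
  2.5% true rate), vanishing as well counts grow. Recovery tests
  therefore compare against tolerances derived from the empirical spread
  of repeat simulations rather than asserting exact unbiasedness.
* Population sd uses the n−1 denominator everywhere; the sd of a single
  observation and statistics of empty groups are emitted as NaN markers
  rather than dropped rows.
* Degenerate anchor scales (fusion mean ≤ stop mean), missing control or
  anchor populations, and sub-minimum population sizes raise analysis
  errors naming the replicate; they are never silently skipped.
* Chlorophyll concentration from a crude extract is
  `0.11 · (OD680 − OD770)` µg/µl; a negative value (OD770 > OD680) is
  returned with an attached warning rather than clamped.
* Problem sizes in the test-suite Monte-Carlo checks: 2000 simulated
  plates of 96 wells for the nominal detection level (±1.5 percentage
  points), 200 repeat screens per condition for parameter recovery
  (tolerance 3 empirical SDs), 1000 draws for Poisson colony-count
  checks. These sizes put Monte-Carlo error well below the tolerances
  they gate.

## Known limitations

* The fluorescence estimator assumes reporter fluorescence is
  proportional to the amount of read-through product; differential
  stability of tagged vs untagged protein or mRNA-level effects are not
  modelled, so fluorescence-based and immunoblot-based estimates need not
  coincide and are both reported without reconciliation.
* With a single replicate the cross-replicate SE is undefined (reported
  as NaN), not approximated from within-replicate spread.
* The calibration regression treats band intensities as supplied
  (relative to their population average) and does not model measurement
  error in the predictor.
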