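# Methods

`cytoferm` packages the data-analysis side of a yeast whole-cell
biocatalysis study: automated flow-cytometry subpopulation gating,
weak-acid partitioning of intracellular pyruvate, bioconversion yield
and mass-balance accounting, and a small statistical comparison
protocol, all exercisable end to end on synthetic data with known
ground truth.

## Subpopulation gating

Four boolean filters are composed on per-event tables with channels
FSC-H (forward-scatter height), pulse width, FL1-H (GFP) and FL3-H
(propidium iodide, PI):

1. **Static filter** — keep events with strictly positive FL1-H *and*
   FL3-H. Zero-channel events are not cells; this filter also
   guarantees all FL3-H values entering the live-gate fit are positive,
   so the log10 transform needs no pseudo-count.
2. **Singlet filter** — pulse width ≤ a user cut-off. Doublets produce
   roughly twice the pulse width of singlets. The cut-off is strain-
   and instrument-specific, so it is a required parameter, never a
   hard-coded default.
3. **GFP gate** — FL1-H ≥ a user cut-off, likewise required.
4. **Live gate** — fitted automatically per sample. PI only enters
   membrane-compromised cells, so dead cells form a high-FL3-H mode.
   Because the dead mode drifts with PI incubation time, this is the
   one gate re-fitted for every sample of a time series.

### The KDE live gate

FL3-H of static-filtered events is log10-transformed (fluorescence
heights are approximately log-normal and span decades) and
density-estimated with a Gaussian kernel under Silverman's
rule-of-thumb bandwidth, evaluated on a 512-point grid covering the
data range ± 3 bandwidths. Strict local maxima of the gridded density
are candidate modes; maxima below 1% of the global peak density are
discarded as finite-sample noise (a real dead subpopulation at 5%
weight peaks near 4% of the live peak, while spurious tail bumps on
unimodal data sit near 0.2%, so the floor separates the two by an
order of magnitude on either side). The threshold is the grid point of
minimum density strictly between the two retained modes of greatest
density, ties broken toward the lower FL3-H value — a conservative
live call. Events strictly below the threshold (linear scale) are live.

Degenerate cases: fewer than 50 static-filtered events refuse to fit;
a constant channel or a single surviving mode sets the
`unimodal_fallback` flag and classifies every event as live.
Unstained or early samples are predominantly live, and a flagged
pass-through is preferable to silent misclassification. Fallback
samples in a time series are reported with the flag, never dropped.

Subpopulation fractions (Live, Live∩Single, Live∩Single∩GFP±, and each
subset's complement) use the static-filtered event count as the common
denominator. The acquisition rules — events triggered above an FSC-H
threshold of 80 000 and a cap of 10 000 registered events per sample —
are emulated on the generator side, since a real instrument applies
them before any analysis sees the data.

What the recovery tests show: on log-normal mixtures whose live and
dead FL3-H modes are separated by ≥ 4 pooled standard deviations, the
automated gate recovers the ground-truth live fraction within ±0.02 at
n = 10 000. Real samples with smeared or overlapping PI distributions
are harder; the test result bounds performance only under clear
separation.

## Weak-acid partitioning

Assuming the neutral acid species equilibrates across the plasma
membrane and the anion does not cross at all, the anion ratio is

    A_in/A_out = (1 + 10^(pH_in − pKa)) / (1 + 10^(pH_out − pKa)),

inverted as `pH_in = pKa + log10(A_in/A_out · (1 + 10^(pH_out−pKa)) − 1)`.
The inversion round-trips with the forward form to 10⁻⁹ pH units over
pKa ∈ {2.5, 4.8}, pH_out ∈ [3, 7], pH_in ∈ [pH_out, 8]. For pyruvate
(pKa 2.5, MW 88.06 g/mol fixed as a named constant, free-acid scale)
with extracellular pH controlled at 5, the factor is ≈10 at
intracellular pH 6 and ≈100 at pH 7. Ratios are reported unrounded; a
one-significant-figure helper reproduces the conventional "10–100"
presentation. The impermeant-anion assumption is documented, not
verified — no transporter kinetics or proton-motive-force corrections
are modelled.

## Yields, mass balance, statistics

Molar yield is mol product per mol benzylacetone (BA) *supplied*
(5 mM unless configured otherwise); a consumed-BA basis is available
but off by default, since supplementation, not consumption, is the
controlled quantity. Fold changes are reported unrounded and at the
one-decimal print precision. The BA mole balance splits the fractional
loss from solution into conversion to MPPA, reduction to the alcohol
side product, adsorption to biomass (supplied as a fraction of the
loss, up to ~10% at high cell density) and an unexplained remainder,
floored at zero with a warning when the stated sinks overshoot.
Components conserve the loss to 10⁻⁹ whenever no flooring occurs.

The comparison protocol:

* **Mann–Whitney U** (primary, two-sided). For pooled n ≤ 12 without
  ties the permutation distribution of U is fully enumerated and the
  p-value is P(|U − n_x·n_y/2| ≥ observed). Larger or tied samples use
  the tie-corrected normal approximation with continuity correction;
  zero rank variance (all values tied) returns p = 1. The exact path is
  validated against an independent exact implementation over every rank
  partition at group sizes ≤ 4+4, and its type-I error at nominal
  α = 0.05 is conservative (≈0.029 at n = 4+4) by discreteness.
* **Welch's t** (robustness check, two-sided).
* **Gated one-sided t-test**: Shapiro–Wilk per group replaces a visual
  QQ normality check as the machine-decidable criterion (QQ coordinates
  are still exported for plotting), and a two-sided F-test checks
  variance equality; only when all pass at α = 0.05 is the pooled
  one-sided t computed. The hypothesised-greater group is named by the
  caller in advance, never inferred from the data. Raw p-values are
  reported; a Benjamini–Hochberg helper exists but is off by default.

## Synthetic data

**Events** are drawn from log-normal mixtures. Defaults: singlet FSC-H
log10 N(5.3, 0.10) (well above the 80 000 trigger), width
log10 N(1.7, 0.05) with doublets at exactly twice the singlet width,
live FL3-H log10 N(2.0, 0.15) vs dead N(4.2, 0.20) (clearly separated,
as for healthy PI staining), GFP-positive FL1-H log10 N(3.5, 0.20) vs
negative N(1.5, 0.20), and low-FSC debris that mostly falls below the
trigger. All moments are configurable; recovery experiments always
compare against the generator's labels, never re-derived ones.

**Fermentations** are phenomenological: logistic biomass growth on
glucose (20 g/L) whose depletion defines the diauxic-shift time, a
second logistic phase on the accumulated ethanol (absent in group II),
pyruvate overflow proportional to glucose consumed with first-order
post-shift clearance (none in group II, whose plateau default of
0.165 g/L sits mid-way in the observed 0.13–0.20 g/L persistence
band), glycerol proportional to glucose consumed with a 2.5× yield
multiplier for the redox-stressed group II, a basal first-order BA
consumption common to all groups, MPPA formation only in group III and
only after the shift (defaults 2.9/2.0/1.1 mM final on 5 mM BA for the
producer variants, i.e. 0.58/0.40/0.22 mol/mol), and alcohol
side-product formation only in strains with the native alanine
transaminase intact (group I). Multiplicative 2% measurement noise is
applied per channel, then physically monotone channels (glucose ↓,
biomass ↑, BA ↓, post-shift MPPA ↑) are re-monotonised so invariants
survive the noise. This generator reproduces the *structure* of
diauxic cultivations, not their kinetics: no Monod terms, no oxygen
limitation, no maintenance energy. Passing tests demonstrate that the
pipeline recovers what the generator encodes, not that the generator
matches any particular culture.

A single seed drives every stochastic component; per-stage streams are
spawned from it with `numpy.random.SeedSequence`, so pipeline reruns
with one configuration are byte-identical.

## Problem sizes and numerical choices

Gating-recovery experiments run at 10 000 acquired events per sample;
the demo pipeline uses 3 000 events × 5 timepoints, 4 replicate
cultivations per group, and 161-point time courses (80 h at 0.5 h) —
sizes at which the full suite completes in seconds while keeping
binomial sampling error well inside the ±0.02 recovery tolerance.
Exact Mann–Whitney enumeration is capped at pooled n = 12
(C(12,6) = 924 arrangements); beyond that the normal approximation is
standard and accurate. CSV outputs are rounded to 6 decimals for
byte-stable reruns; every output table carries the configuration hash
as a leading comment line.

## Known limitations

* The original acquisition software's density routine is not specified
  beyond "kernel density"; bandwidth and grid here are stated defaults,
  so only distributional recovery on synthetic data — not numerical
  equivalence with the original gating output — can be claimed.
* The FCS reader covers list-mode float32/uint32 files with the four
  channels of interest; it is an interchange convenience, not a general
  FCS implementation (no compensation, no analysis segments).
* The partitioning model is an equilibrium bound, not a measurement:
  reported intracellular concentrations inherit both the impermeant-
  anion assumption and the assumed intracellular pH.
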