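# Methods

## Kinetic model

Molecules are simulated as a continuous-time Markov chain over five
conformational states: duplex DNA (`DSDNA`), the R-loop intermediate
(`ISTATE`), G-quadruplex in single-stranded DNA (`GQ_SS`), G-quadruplex
with re-formed duplex around it (`GQ_DS`), and a spare duplex-embedded
label (`DSDNA_GQ_EMBEDDED`) for schemes that distinguish it.  Rates are
condition-dependent; three conditions are built in:

| condition | active channels | rates (s⁻¹) |
|---|---|---|
| `BASELINE` | I → duplex (k₁), I → GQ (k₂); transcription rounds | k₁ = 3.4×10⁻⁴, k₂ = 6.6×10⁻³ |
| `RNASEH` | I → duplex; sensitive GQ → duplex; resistant GQ → GQ_DS (instant) | 1/30.1, 1/87.1 |
| `WASHOUT` | I-state exits as baseline; no rounds, no GQ exits | k₁, k₂ |

Three processes are structural rather than plain transitions:

* **Transcription rounds.**  While duplex under `BASELINE`, initiation
  events arrive as a Poisson process at `round_rate_per_h` (default
  100 h⁻¹, the rounds-per-hour estimate derived from the yield ratio);
  each round independently yields an R-loop with probability `p_rloop`
  (default 0.0026, matching the single-round yield of 0.26%).  Memoryless
  arrivals are the minimal assumption — nothing in the data constrains
  inter-round statistics.  Note the two defaults jointly imply an
  accumulation constant of ≈ 230 min, slower than the directly measured
  45.3 min population constant; the measured curve also saturates well
  below 1, so its effective entry rate cannot be identified from the
  printed numbers alone.  The accumulation *recovery* experiment
  therefore simulates entries directly at 1/45.3 min⁻¹.
* **Quenched RNase-H resistance.**  At each entry into `GQ_SS` the
  molecule is permanently marked resistant with probability
  `gq_resistant_fraction` (default 0.433).  Under `RNASEH`, resistant
  molecules re-form duplex around the quadruplex immediately (relabelled
  `GQ_DS`, FRET 0.75) while sensitive molecules decay to duplex at
  1/87.1 s⁻¹.  Per-molecule (quenched) assignment, rather than a
  per-attempt coin flip, is what produces a persistent plateau.
* **Antibody association.**  When enabled, each I-state entry schedules
  an on-event after an exponential delay (default mean 24.8 s); the event
  is cancelled if the R-loop resolves to duplex first, persists through
  GQ formation, and no dissociation is modelled (only association was
  measured).

Reproducibility: molecule *i* of a run with seed *s* uses the NumPy
substream `default_rng([s, 0, i])` (rendering uses `[s, 1, i]`), so
ensembles are bit-identical regardless of iteration order.

The `occupancy` function is an independent analytic oracle: the matrix
exponential of the condition's generator, with the round process folded
in as an effective duplex→I rate (a thinned Poisson process is again
Poisson) and the quenched resistant fraction handled exactly by moving
that share of initial GQ mass to `GQ_DS` at t = 0⁺.  Simulator tests
compare ensemble frequencies against it within three binomial standard
errors.

## Synthetic traces

Rendering integrates the piecewise-constant emission over each camera
bin (time-weighted averaging, matching camera integration; default bins
0.2 s or 1 s).  Per state the mean apparent FRET is 0.13 / 0.37 / 0.82 /
0.75 for duplex / I-state / GQ_SS / GQ_DS.  Intensities are arbitrary
units (total 1000 by default); Gaussian noise (default SD 50) is added
per channel and negatives are kept — clipping would bias the proximity
ratio.  Acceptor blinks (Poisson arrivals, exponential durations) and
independent donor/acceptor photobleaching drop the channels to
background: blinks and donor bleach zero both channels, acceptor bleach
collapses to donor-only emission.  The antibody channel is a noisy step
function of the binding events.

Real data differ in ways the generator does not emulate: photon shot
noise and EMCCD gain statistics, spectral crosstalk, background drift,
stage drift, and donor blinking.  Passing the recovery tests therefore
shows the analysis chain is unbiased under Gaussian noise with faithful
state dynamics — not that it is robust to every instrumental artefact.

## Measurement layer

* **FRET** is the uncorrected proximity ratio E = I_A/(I_D + I_A); no
  gamma/leakage/direct-excitation correction is applied (a correction
  hook exists, defaulting to identity).  E outside [0, 1] is clamped so
  bins stay countable.
* **Validity.**  Bins below `total_threshold` (default 0.5) times a
  running median of total intensity are dark; the reference is floored
  at half the peak running median so post-bleach noise cannot become the
  local reference.  The terminal dark run is a photobleach; interior
  runs ≤ `max_blink_s` (default 5 s) are blinks; longer interior runs
  censor the dwells around them.  Acceptor bleach leaves the total high
  but E ≈ 0 — below even the duplex level — so a terminal stretch whose
  suffix-mean E (over bright bins) stays under 0.065 for ≥ 5 s is also
  treated as bleached.
* **Idealization** is nearest-class thresholding with fixed boundaries
  0.25 and 0.55 (midpoints between the three population peaks); an
  optional `auto` mode derives boundaries from a three-component
  Gaussian mixture at equal posterior, falling back to the fixed
  defaults with a warning when the mixture degenerates.  Runs shorter
  than `min_dwell_bins` (default 2) merge into their longer neighbour to
  suppress shot-noise flickers.  Threshold idealization was chosen over
  an HMM because three well-separated states at these noise levels do
  not need transition-rate priors.
* **Dwells** are maximal same-label runs with boundaries on bin edges;
  blink gaps flanked by the same label are bridged (the dwell continues
  through the blink), and trace end, bleach, long dark runs, label
  changes hidden in dark gaps, and intervention boundaries all
  right-censor.
* **Post-synchronization** aligns traces at their first LOW→MID
  transition and divides each aligned-time column of the 2-D FRET
  histogram by the number of traces still contributing a valid bin
  there, so every live column sums to one — the photobleach correction.
* **Binding detection** thresholds the Alexa488 channel midway between
  the extrema of a 3-bin median-smoothed series, gated at six noise SDs
  (noise from bin-to-bin differences).  A channel already on at the
  first bin shows no step and is reported as no event — a known
  limitation.  t₁ = (first HIGH entry) − (first on-time); positive means
  binding preceded GQ formation; GQ molecules without binding are listed
  separately.

## Fitting

* **Dwell fits** default to the censoring-aware exponential MLE
  τ̂ = (Σ all durations, censored included)/(number complete), which on
  complete data is the sample mean; a histogram + least-squares mode
  (Freedman–Diaconis bins, 10 s floor) is provided for parity with the
  usual single-molecule presentation.  Standard errors are a seeded
  bootstrap over dwells (1000 resamples by default).
* **Fractions** use Wilson intervals over complete dwells only.
* **Branched rates**: k = 1/τ, k₂ = pk, k₁ = (1 − p)k with first-order
  (delta-method) error propagation.  The uncertainties printed in the
  original measurements have an unstated origin; this package
  standardizes on bootstrap + Wilson and claims to reproduce point
  estimates only.
* **Population curves** are fractions of a fixed denominator (molecules
  scored at t = 0); fits are weighted least squares with per-point
  binomial weights.  The saturating-exponential accumulation model can
  pin its amplitude (used when the asymptote is known, e.g. cumulative
  first-entry fractions, where the amplitude–τ correlation otherwise
  inflates the variance of τ̂ several-fold).  The exponential-plus-plateau
  model reports the persistent (RNase-H-resistant) fraction explicitly.
  Because survival points are serially correlated, the fit's nominal
  stderr understates; recovery tests bootstrap over molecules instead.
* **Rounds estimate**: both the yield-ratio estimator eff_m/eff_s and
  the independent-trials estimator ln(1 − eff_m)/ln(1 − eff_s) are
  returned; with the measured yields they give ≈ 101 and ≈ 118, and
  which one produced the published "roughly 100" is not stated, so
  neither is privileged.

## Problem sizes and numerical choices

Recovery experiments use 5000 molecules for the I-state dwell constant,
1000 for the accumulation course (sampled every 5 min over 90 min), 2000
for the RNase-H I-state lifetime, 1000 for the GQ decay course, and 500
binding events for the association time; full-chain (render + idealize)
recoveries pool ten 100-molecule seeds at 1 s binning.  These sizes put
three standard errors at a few percent of each quantity while keeping
any single experiment in the seconds-to-minutes range.  The
obligatory-intermediate property (every duplex→GQ passage traverses the
I-state) is asserted structurally on simulated paths and, on idealized
traces, for every passage whose true I-state dwell is resolvable at the
binning — an exponential 144 s dwell is shorter than two 0.2 s bins with
probability ~0.3%, and no idealization can see below the bin width.

## Known limitations

* GQ-enhanced R-loop formation (the feedback by which a pre-formed GQ on
  the non-template strand promotes subsequent R-loops) is exposed only
  as a free configuration parameter; no quantitative enhancement factor
  was published, so the default scheme omits the feedback.
* Elongation blockage by R-loops and sequence-level GQ folding are out
  of scope; the I-state's structural identity is unresolved and the
  model treats it as a single kinetic species.
* Under `RNASEH` the I-state exits only to duplex (the minor branch to
  GQ after hybrid degradation has no published rate).
* The camera model is Gaussian; see the synthetic-trace section for the
  instrumental effects deliberately not emulated.
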