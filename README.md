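# gqrloop

Single-molecule kinetics of cotranscriptional G-quadruplex (GQ) and R-loop
formation: a stochastic simulator of the multi-state kinetic scheme, a
synthetic smFRET trace generator, trace idealization and dwell-time
extraction, and the censored-exponential + branched-rate analysis that
turns dwell statistics into microscopic rate constants.

## The science

During transcription, the nascent RNA can re-hybridize with the template
DNA strand to form an **R-loop**, exposing the non-template strand.  If
that strand is G-rich it can fold into a **G-quadruplex**.  In smFRET
traces this appears as three states: duplex DNA (E ≈ 0.13), an R-loop
intermediate called the **I-state** (E ≈ 0.37), and the GQ (E ≈ 0.82; or
E ≈ 0.75 once duplex re-forms around it).

The I-state decays through two competing channels — back to duplex (k₁)
or forward to the GQ (k₂).  Its dwell time is exponential with apparent
rate

    k = k₁ + k₂ = 1/τ,

and the GQ branch fraction is p = k₂/(k₁ + k₂), so measuring τ and p
determines both microscopic rates:

    k₂ = p/τ,    k₁ = (1 − p)/τ.

With τ = 144.1 s and p = 0.95 this gives k = 6.9×10⁻³ s⁻¹,
k₁ ≈ 3.5×10⁻⁴ s⁻¹ and k₂ = 6.6×10⁻³ s⁻¹.  The package implements this
scheme as a continuous-time Markov chain with three experimental
conditions (baseline transcription, RNase H addition, polymerase/rNTP
washout), renders simulated molecules into realistic donor/acceptor/
Alexa488 traces (noise, blinking, photobleaching, antibody-binding
steps), and re-measures every rate with censoring-aware estimators.

## Worked example

```python
from gqrloop import (HIGH, MID, branch_fraction, decompose_branched_rates,
                     fit_exponential_dwells)
from gqrloop.recovery import end_to_end_baseline

# simulate -> render -> idealize -> extract dwells, all under the
# measured rates (fixed seed)
paths, ideals, dwells = end_to_end_baseline(seed=5, n_molecules=200)

fit = fit_exponential_dwells(dwells, MID, seed=5)   # censoring-aware MLE
bf = branch_fraction(dwells, MID, HIGH)             # Wilson interval
dec = decompose_branched_rates(fit.tau_s, bf.fraction, se_tau=fit.se_tau)
```

Running this chain (`python examples/03_dwell_analysis.py`) prints:

```
I-state dwell constant: 147.0 +- 11.0 s (generating value 144.1 s)
GQ branch fraction:     0.966 [0.929, 0.985]  (generating value 0.951)
k1 = 2.28e-04 s^-1 (generating 3.4e-04)
k2 = 6.58e-03 s^-1 (generating 6.6e-03)
```

The dwell constant and k₂ come back within error at 200 molecules; k₁
is noisier because it multiplies the small fraction (1 − p) — the Wilson
interval shows the honest uncertainty.  The `examples/` directory has one
short script per capability (branched-rate algebra, simulation +
rendering, dwell analysis, RNase-H decay, antibody binding); each prints
the numbers it computes and what they mean.

A thin CLI mirrors the library: `gqrloop simulate | render | analyze |
fit | run | fixtures` (see `gqrloop --help`).

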