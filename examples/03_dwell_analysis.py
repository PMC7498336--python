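"""Full measurement chain: traces -> idealization -> dwells -> rates.

Simulates an ensemble under the measured baseline rates, renders noisy
traces, idealizes them into LOW/MID/HIGH (duplex/I-state/GQ), extracts
dwell times with censoring flags, and re-fits the generating constants —
a parameter-recovery check of the whole analysis chain.
"""

from gqrloop import (HIGH, MID, branch_fraction, decompose_branched_rates,
                     fit_exponential_dwells)
from gqrloop.recovery import end_to_end_baseline

paths, ideals, dwells = end_to_end_baseline(seed=5, n_molecules=200)
n_mid = sum(d.state == MID for d in dwells)
n_cens = sum(d.censored for d in dwells if d.state == MID)
print(f"{len(ideals)} traces scored, {n_mid} I-state dwells "
      f"({n_cens} right-censored by bleach or trace end)")

fit = fit_exponential_dwells(dwells, MID, seed=5)
bf = branch_fraction(dwells, MID, HIGH)
dec = decompose_branched_rates(fit.tau_s, bf.fraction, se_tau=fit.se_tau)

print(f"\nI-state dwell constant: {fit.tau_s:.1f} +- {fit.se_tau:.1f} s "
      "(generating value 144.1 s)")
print(f"GQ branch fraction:     {bf.fraction:.3f} "
      f"[{bf.ci_low:.3f}, {bf.ci_high:.3f}]  (generating value 0.951)")
print(f"k1 = {dec.k1:.2e} s^-1 (generating 3.4e-04)")
print(f"k2 = {dec.k2:.2e} s^-1 (generating 6.6e-03)")
print("\nThe censoring-aware MLE uses censored dwell time in the "
      "numerator only, so photobleaching does not bias tau low.")
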