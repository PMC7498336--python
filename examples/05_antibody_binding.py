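"""Timing R-loop formation with a labelled anti-hybrid antibody.

A fluorescent S9.6 antibody binds the DNA:RNA hybrid, putting a step in
the third (Alexa488) channel.  The statistic t1 = (first GQ entry) -
(first binding) is positive when the R-loop was detected before the GQ
formed — evidence that the R-loop comes first.
"""

import numpy as np

from gqrloop import (EmissionModel, ISTATE, KineticScheme,
                     PhotophysicsModel, SimulationConfig,
                     detect_binding_events, render_traces,
                     simulate_ensemble, t1_statistics)
from gqrloop.recovery import analyze_traces, recover_association_time

at = recover_association_time(n_molecules=500, seed=8)
print(f"antibody association time: {at.mean_s:.1f} +- {at.se_s:.2f} s "
      f"over {at.n} events (generating value 24.8 s)")

scheme = KineticScheme.default()
cfg = SimulationConfig(n_molecules=100, duration_s=1500.0, seed=9,
                       initial_state=ISTATE, antibody_mean_assoc_s=24.8)
paths = simulate_ensemble(scheme, cfg)
traces = render_traces(paths, EmissionModel(channel_noise_sd=50.0),
                       PhotophysicsModel.ideal(), 0.2, seed=10)
_, ideals, _ = analyze_traces(traces)
events = {tr.molecule_id: detect_binding_events(tr) for tr in traces}
events = {m: e for m, e in events.items() if e}
stats = t1_statistics(events, ideals)
print(f"\n{stats.t1_s.size} molecules with both binding and GQ formation")
print(f"median t1 = {np.median(stats.t1_s):.0f} s; "
      f"binding precedes GQ in {100 * np.mean(stats.t1_s > 0):.0f}% "
      "of molecules")
print(f"{len(stats.gq_without_binding)} GQ-forming molecules never "
      "bound antibody (reported separately, not folded into t1)")
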