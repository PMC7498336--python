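import numpy as np
import pytest

import gqrloop as g


@pytest.fixture(scope="session")
def default_scheme():
    return g.KineticScheme.default()


@pytest.fixture(scope="session")
def istate_paths(default_scheme):
    """2000 molecules started in the I-state under baseline conditions."""
    cfg = g.SimulationConfig(n_molecules=2000, duration_s=2500.0, seed=101,
                             initial_state=g.ISTATE)
    return g.simulate_ensemble(default_scheme, cfg), cfg


@pytest.fixture(scope="session")
def gq_forming_traces(default_scheme):
    """A small rendered baseline ensemble (noise, no bleach) with its
    ground-truth paths; every molecule starts in the I-state."""
    cfg = g.SimulationConfig(n_molecules=60, duration_s=1000.0, seed=77,
                             initial_state=g.ISTATE)
    paths = g.simulate_ensemble(default_scheme, cfg)
    traces = g.render_traces(paths, g.EmissionModel(channel_noise_sd=50.0),
                             g.PhotophysicsModel.ideal(), 0.2, seed=78)
    return paths, traces


def analyze_traces(traces, **idealize_kwargs):
    """Shared helper: traces -> (fret, idealizations, dwells)."""
    frets, ideals, dwells = [], [], []
    for tr in traces:
        validity = g.detect_dark_and_bleach(tr)
        ft = g.compute_fret(tr, validity)
        if not ft.valid_mask.any():
            continue
        idl = g.idealize(ft, **idealize_kwargs)
        frets.append(ft)
        ideals.append(idl)
        dwells.extend(g.extract_dwells(idl))
    return frets, ideals, dwells
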