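"""Parameter-recovery experiments: simulate under known rates, re-measure.

Each function generates synthetic data with the measured scheme (or the
stated sub-process), runs the package's own measurement/fitting path, and
returns the recovered quantity with its uncertainty.  These are the
experiments that validate the analysis chain end to end; they are also the
recipes behind the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .kinetics import (EXP_PLUS_PLATEAU, SINGLE_EXP, AssociationTime,
                       BranchFraction, ExpFit, PlateauExpFit,
                       association_time, branch_fraction,
                       fit_exponential_dwells, fit_population)
from .photophysics import EmissionModel, PhotophysicsModel, render_traces
from .scheme import (BASELINE, DSDNA, GQ_DS, GQ_SS, ISTATE, RNASEH,
                     KineticScheme, SimulationConfig, simulate_ensemble)
from .traceproc import (DARK, HIGH, MID, compute_fret, detect_dark_and_bleach,
                        dwells_from_path, extract_dwells, idealize)

__all__ = [
    "recover_istate_kinetics", "recover_accumulation_tau",
    "recover_rnaseh_istate_tau", "recover_gq_decay",
    "recover_association_time", "end_to_end_baseline", "end_to_end_rnaseh",
    "survival_curve", "analyze_traces",
]

ACCUMULATION_TAU_S = 45.3 * 60.0  # measured GQ+I accumulation constant


def recover_istate_kinetics(n_molecules: int = 5000,
                            duration_s: float = 2500.0, seed: int = 0,
                            scheme: KineticScheme | None = None
                            ) -> tuple[ExpFit, BranchFraction]:
    """Simulate I-state dwells under the baseline exit rates and re-fit.

    Returns the censoring-aware exponential fit of the I-state dwell time
    and the branch fraction of exits that form a GQ.
    """
    scheme = scheme or KineticScheme.default()
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed, initial_state=ISTATE)
    paths = simulate_ensemble(scheme, cfg)
    dwells = [d for p in paths for d in dwells_from_path(p)]
    fit = fit_exponential_dwells(dwells, ISTATE, seed=seed)
    bf = branch_fraction(dwells, ISTATE, GQ_SS)
    return fit, bf


def recover_accumulation_tau(n_molecules: int = 1000, seed: int = 0,
                             sample_every_s: float = 300.0,
                             duration_s: float = 90.0 * 60.0) -> ExpFit:
    """Recover the population accumulation constant from first entries.

    Each molecule's first entry into the I/GQ ensemble is exponential at
    the measured accumulation rate (modelled as duplex molecules whose
    effective entry rate equals 1/τ_accum); the cumulative entered
    fraction, sampled on a regular grid, is fitted with a saturating
    exponential whose asymptote is pinned at 1 (every molecule eventually
    enters in this generative model).
    """
    scheme = KineticScheme.default(
        round_rate_per_h=3600.0 / ACCUMULATION_TAU_S, p_rloop=1.0)
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed, initial_state=DSDNA)
    paths = simulate_ensemble(scheme, cfg)
    entries = np.array([next((t for t, s in p.entries if s == ISTATE),
                             np.inf) for p in paths])
    grid = np.arange(0.0, duration_s + 1.0, sample_every_s)
    frac = np.array([(entries <= t).mean() for t in grid])
    return fit_population(grid, frac, model=SINGLE_EXP,
                          direction="accumulation", n_total=n_molecules,
                          fix_amplitude=1.0)


def recover_rnaseh_istate_tau(n_molecules: int = 2000,
                              duration_s: float = 400.0,
                              seed: int = 0) -> ExpFit:
    """Recover the I-state lifetime under RNase H from simulated decays."""
    scheme = KineticScheme.default()
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed, initial_state=ISTATE,
                           initial_condition=RNASEH)
    paths = simulate_ensemble(scheme, cfg)
    dwells = [d for p in paths for d in dwells_from_path(p)]
    return fit_exponential_dwells(dwells, ISTATE, seed=seed)


def recover_gq_decay(n_molecules: int = 1000, duration_s: float = 600.0,
                     seed: int = 0, sample_every_s: float = 15.0
                     ) -> PlateauExpFit:
    """Recover the resistant plateau and sensitive decay constant of the
    GQ population after RNase H addition.

    Molecules start in the GQ state; the resistant subpopulation (drawn at
    the measured fraction) survives as duplex-embedded GQ while the rest
    decays exponentially.  The surviving-GQ fraction (either GQ form) is
    fitted with an exponential-plus-plateau model.
    """
    scheme = KineticScheme.default()
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed, initial_state=GQ_SS,
                           initial_condition=RNASEH)
    paths = simulate_ensemble(scheme, cfg)
    grid = np.arange(0.0, duration_s + 1.0, sample_every_s)
    frac = np.array([np.mean([p.state_at(t) in (GQ_SS, GQ_DS)
                              for p in paths]) for t in grid])
    return fit_population(grid, frac, model=EXP_PLUS_PLATEAU,
                          n_total=n_molecules)


def recover_association_time(n_molecules: int = 500, seed: int = 0,
                             duration_s: float = 600.0) -> AssociationTime:
    """Recover the mean antibody association delay after I-state entry."""
    scheme = KineticScheme.default(
        transitions=[], round_rate_per_h=0.0)  # hold molecules in I-state
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed, initial_state=ISTATE,
                           antibody_mean_assoc_s=24.8)
    paths = simulate_ensemble(scheme, cfg)
    on = {p.molecule_id: p.antibody_events[0][0] for p in paths
          if p.antibody_events}
    entry = {p.molecule_id: 0.0 for p in paths}
    return association_time(on, entry)


# ---------------------------------------------------------------------------
# full-chain experiments (simulate -> render -> analyze)

def analyze_traces(traces, thresholds=(0.25, 0.55), min_dwell_bins=2):
    """Traces -> (FRET series, idealizations, dwells), skipping traces
    with no valid bins."""
    frets, ideals, dwells = [], [], []
    for tr in traces:
        ft = compute_fret(tr, detect_dark_and_bleach(tr))
        if not ft.valid_mask.any():
            continue
        idl = idealize(ft, thresholds=thresholds,
                       min_dwell_bins=min_dwell_bins)
        frets.append(ft)
        ideals.append(idl)
        dwells.extend(extract_dwells(idl))
    return frets, ideals, dwells


def end_to_end_baseline(seed: int, n_molecules: int = 100,
                        duration_s: float = 2500.0,
                        bin_width_s: float = 1.0,
                        photophysics: PhotophysicsModel | None = None):
    """Simulate + render + analyze one baseline ensemble started in the
    I-state; returns (paths, idealizations, dwells)."""
    scheme = KineticScheme.default()
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed, initial_state=ISTATE)
    paths = simulate_ensemble(scheme, cfg)
    traces = render_traces(paths, EmissionModel(channel_noise_sd=50.0),
                           photophysics or PhotophysicsModel.typical(),
                           bin_width_s, seed=seed)
    _, ideals, dwells = analyze_traces(traces)
    return paths, ideals, dwells


def end_to_end_rnaseh(seed: int, n_molecules: int = 100,
                      duration_s: float = 600.0, bin_width_s: float = 1.0,
                      photophysics: PhotophysicsModel | None = None):
    """Same chain under RNase H, starting half in the I-state and half in
    the GQ state; returns (paths, idealizations, dwells)."""
    scheme = KineticScheme.default()
    cfg = SimulationConfig(n_molecules=n_molecules, duration_s=duration_s,
                           seed=seed,
                           initial_state={ISTATE: 0.5, GQ_SS: 0.5},
                           initial_condition=RNASEH)
    paths = simulate_ensemble(scheme, cfg)
    traces = render_traces(paths, EmissionModel(channel_noise_sd=50.0),
                           photophysics or PhotophysicsModel.typical(),
                           bin_width_s, seed=seed)
    _, ideals, dwells = analyze_traces(traces)
    return paths, ideals, dwells


def survival_curve(idealizations, grid_s, label=HIGH, t0: float = 0.0):
    """Photobleach-corrected survival of a class: among traces in
    ``label`` at reference time ``t0`` (first valid bin at or after it),
    the fraction still in it at each grid time, over traces still
    scorable (not dark) there."""
    starters = []
    for idl in idealizations:
        valid = np.flatnonzero(idl.labels != DARK)
        b0 = int(t0 / idl.bin_width_s)
        valid = valid[valid >= b0]
        if valid.size and idl.labels[valid[0]] == label:
            starters.append(idl)
    frac = np.full(len(grid_s), np.nan)
    for j, t in enumerate(grid_s):
        num = den = 0
        for idl in starters:
            b = int(t / idl.bin_width_s)
            if b >= len(idl.labels) or idl.labels[b] == DARK:
                continue
            den += 1
            num += idl.labels[b] == label
        if den:
            frac[j] = num / den
    return frac, len(starters)
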