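"""Kinetic scheme for cotranscriptional G-quadruplex / R-loop formation.

The model is a continuous-time Markov chain over molecular conformations of a
transcribed DNA with a GQ-forming non-template strand:

* ``DSDNA`` — relaxed duplex DNA (low FRET).
* ``ISTATE`` — intermediate state coincident with an R-loop; the displaced
  non-template strand brings the dyes to mid FRET.
* ``GQ_SS`` — G-quadruplex embedded in single-stranded DNA (high FRET),
  formed from the I-state.
* ``GQ_DS`` — G-quadruplex embedded in re-formed duplex DNA, the outcome for
  RNase-H-resistant molecules after R-loop degradation.
* ``DSDNA_GQ_EMBEDDED`` — alias-level terminal label for duplex with an
  embedded GQ (kept distinct for schemes that want to separate it from
  ``GQ_DS``; the default scheme does not use it).

Dynamics that go beyond plain per-state exponential exits:

* Transcription rounds arrive as a Poisson process at ``round_rate_per_h``
  while the molecule is duplex under the ``BASELINE`` condition; each round
  independently produces an R-loop (enters ``ISTATE``) with probability
  ``p_rloop``.
* At every entry into ``GQ_SS`` the molecule is marked RNase-H *resistant*
  with probability ``gq_resistant_fraction`` (quenched disorder, fixed for
  the molecule's lifetime).  Under the ``RNASEH`` condition a resistant GQ
  immediately re-forms duplex around the quadruplex (relabelled ``GQ_DS``)
  while a sensitive GQ decays to ``DSDNA`` at the scheme's GQ decay rate.
* Antibody (S9.6, anti DNA:RNA hybrid) association is an exponential delay
  after each I-state entry; the binding is cancelled if the R-loop resolves
  back to duplex before the antibody arrives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.linalg import expm

__all__ = [
    "DSDNA", "ISTATE", "GQ_SS", "GQ_DS", "DSDNA_GQ_EMBEDDED", "STATES",
    "BASELINE", "RNASEH", "WASHOUT", "CONDITIONS",
    "Transition", "KineticScheme", "SimulationConfig", "StatePath",
    "SchemeValidationError",
    "simulate_state_path", "simulate_ensemble",
    "occupancy", "branching_probability",
    "write_state_paths", "read_state_paths",
    "load_scheme", "save_scheme", "load_config", "save_config",
]

# ---------------------------------------------------------------------------
# labels

DSDNA = "DSDNA"
ISTATE = "ISTATE"
GQ_SS = "GQ_SS"
GQ_DS = "GQ_DS"
DSDNA_GQ_EMBEDDED = "DSDNA_GQ_EMBEDDED"
STATES = (DSDNA, ISTATE, GQ_SS, GQ_DS, DSDNA_GQ_EMBEDDED)

BASELINE = "BASELINE"
RNASEH = "RNASEH"
WASHOUT = "WASHOUT"
CONDITIONS = (BASELINE, RNASEH, WASHOUT)

# Measured rate constants (s^-1 unless noted).
K1_I_TO_DSDNA = 3.4e-4        # I-state -> duplex, baseline
K2_I_TO_GQ = 6.6e-3           # I-state -> GQ, baseline
TAU_I_RNASEH_S = 30.1         # I-state lifetime under RNase H
TAU_GQ_SENSITIVE_S = 87.1     # sensitive GQ decay under RNase H
GQ_RESISTANT_FRACTION = 0.433
ROUND_RATE_PER_H = 100.0      # transcription initiations per hour
P_RLOOP_PER_ROUND = 0.0026    # single-round R-loop (I-state) yield
ANTIBODY_MEAN_ASSOC_S = 24.8


class SchemeValidationError(ValueError):
    """Raised when a scheme, config or path violates its invariants."""


@dataclass(frozen=True)
class Transition:
    """One reaction channel: ``from_state -> to_state`` at ``rate_per_s``
    while ``condition`` is active."""

    from_state: str
    to_state: str
    rate_per_s: float
    condition: str


@dataclass
class KineticScheme:
    """Named states plus condition-dependent transition rates.

    ``transitions`` holds the plain exponential channels.  The transcription
    round process, the quenched GQ resistance and the antibody channel are
    structural features controlled by the scalar fields (see module
    docstring); they are not representable as single Markov transitions.
    """

    transitions: list[Transition] = field(default_factory=list)
    states: tuple[str, ...] = STATES
    conditions: tuple[str, ...] = CONDITIONS
    round_rate_per_h: float = ROUND_RATE_PER_H
    p_rloop: float = P_RLOOP_PER_ROUND
    gq_resistant_fraction: float = GQ_RESISTANT_FRACTION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for tr in self.transitions:
            if not (math.isfinite(tr.rate_per_s) and tr.rate_per_s >= 0):
                raise SchemeValidationError(
                    f"rate must be finite and >= 0, got {tr.rate_per_s!r} "
                    f"for {tr.from_state}->{tr.to_state}")
            if tr.from_state == tr.to_state:
                raise SchemeValidationError(
                    f"self-transition on {tr.from_state!r}")
            if tr.from_state not in self.states or tr.to_state not in self.states:
                raise SchemeValidationError(
                    f"unknown state in {tr.from_state}->{tr.to_state}")
            if tr.condition not in self.conditions:
                raise SchemeValidationError(
                    f"unknown condition {tr.condition!r}")
        if not 0.0 <= self.p_rloop <= 1.0:
            raise SchemeValidationError("p_rloop must lie in [0, 1]")
        if not 0.0 <= self.gq_resistant_fraction <= 1.0:
            raise SchemeValidationError(
                "gq_resistant_fraction must lie in [0, 1]")
        if not (math.isfinite(self.round_rate_per_h)
                and self.round_rate_per_h >= 0):
            raise SchemeValidationError("round_rate_per_h must be >= 0")

    # -- queries ----------------------------------------------------------

    def exits(self, state: str, condition: str) -> list[tuple[str, float]]:
        """Plain exponential exit channels of ``state`` under ``condition``."""
        return [(t.to_state, t.rate_per_s) for t in self.transitions
                if t.from_state == state and t.condition == condition
                and t.rate_per_s > 0]

    @property
    def round_rate_per_s(self) -> float:
        return self.round_rate_per_h / 3600.0

    # -- construction -----------------------------------------------------

    @classmethod
    def default(cls, **overrides) -> "KineticScheme":
        """The measured scheme: baseline I-state branching k1/k2, RNase-H
        resolution of the I-state and of sensitive GQs, and washout with
        baseline I-state exits but no further transcription."""
        transitions = [
            Transition(ISTATE, DSDNA, K1_I_TO_DSDNA, BASELINE),
            Transition(ISTATE, GQ_SS, K2_I_TO_GQ, BASELINE),
            Transition(ISTATE, DSDNA, 1.0 / TAU_I_RNASEH_S, RNASEH),
            Transition(GQ_SS, DSDNA, 1.0 / TAU_GQ_SENSITIVE_S, RNASEH),
            Transition(ISTATE, DSDNA, K1_I_TO_DSDNA, WASHOUT),
            Transition(ISTATE, GQ_SS, K2_I_TO_GQ, WASHOUT),
        ]
        kwargs = dict(transitions=transitions)
        kwargs.update(overrides)
        return cls(**kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "conditions": list(self.conditions),
            "round_rate_per_h": self.round_rate_per_h,
            "p_rloop": self.p_rloop,
            "gq_resistant_fraction": self.gq_resistant_fraction,
            "transitions": [
                {"from": t.from_state, "to": t.to_state,
                 "rate_per_s": t.rate_per_s, "condition": t.condition}
                for t in self.transitions],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticScheme":
        return cls(
            transitions=[Transition(t["from"], t["to"],
                                    float(t["rate_per_s"]), t["condition"])
                         for t in d.get("transitions", [])],
            states=tuple(d.get("states", STATES)),
            conditions=tuple(d.get("conditions", CONDITIONS)),
            round_rate_per_h=float(d.get("round_rate_per_h", ROUND_RATE_PER_H)),
            p_rloop=float(d.get("p_rloop", P_RLOOP_PER_ROUND)),
            gq_resistant_fraction=float(
                d.get("gq_resistant_fraction", GQ_RESISTANT_FRACTION)),
        )


@dataclass
class SimulationConfig:
    """Run-level parameters for an ensemble simulation.

    ``interventions`` is an ordered list of ``(time_s, condition)`` pairs;
    the condition active before the first intervention is
    ``initial_condition`` (``BASELINE`` by default).  ``seed`` fully
    determines the ensemble: molecule ``i`` uses the independent substream
    ``default_rng([seed, i])`` so results do not depend on iteration order.
    """

    n_molecules: int = 100
    duration_s: float = 3600.0
    seed: int = 0
    interventions: list[tuple[float, str]] = field(default_factory=list)
    initial_state: str | dict[str, float] = DSDNA
    initial_condition: str = BASELINE
    antibody_mean_assoc_s: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise SchemeValidationError("n_molecules must be >= 1")
        if self.duration_s <= 0:
            raise SchemeValidationError("duration_s must be > 0")
        times = [t for t, _ in self.interventions]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise SchemeValidationError(
                "intervention times must be strictly increasing")
        if any(not 0.0 <= t <= self.duration_s for t in times):
            raise SchemeValidationError(
                "intervention times must lie within [0, duration_s]")
        if isinstance(self.initial_state, dict):
            total = sum(self.initial_state.values())
            if abs(total - 1.0) > 1e-9:
                raise SchemeValidationError(
                    "initial_state distribution must sum to 1")
        if (self.antibody_mean_assoc_s is not None
                and self.antibody_mean_assoc_s <= 0):
            raise SchemeValidationError("antibody_mean_assoc_s must be > 0")

    def condition_segments(self) -> list[tuple[float, float, str]]:
        """Time segments ``(t0, t1, condition)`` covering [0, duration]."""
        points = [(0.0, self.initial_condition)]
        for t, cond in self.interventions:
            if t == 0.0:
                points = [(0.0, cond)]
            else:
                points.append((t, cond))
        segs = []
        for i, (t0, cond) in enumerate(points):
            t1 = points[i + 1][0] if i + 1 < len(points) else self.duration_s
            if t1 > t0:
                segs.append((t0, t1, cond))
        return segs

    def to_dict(self) -> dict:
        d = {
            "n_molecules": self.n_molecules,
            "duration_s": self.duration_s,
            "seed": self.seed,
            "interventions": [[t, c] for t, c in self.interventions],
            "initial_state": self.initial_state,
            "initial_condition": self.initial_condition,
        }
        if self.antibody_mean_assoc_s is not None:
            d["antibody_mean_assoc_s"] = self.antibody_mean_assoc_s
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(
            n_molecules=int(d.get("n_molecules", 100)),
            duration_s=float(d.get("duration_s", 3600.0)),
            seed=int(d.get("seed", 0)),
            interventions=[(float(t), str(c))
                           for t, c in d.get("interventions", [])],
            initial_state=d.get("initial_state", DSDNA),
            initial_condition=d.get("initial_condition", BASELINE),
            antibody_mean_assoc_s=d.get("antibody_mean_assoc_s"),
        )


@dataclass
class StatePath:
    """One molecule's piecewise-constant trajectory.

    ``entries`` are ``(time_s, state)`` pairs; each state persists until the
    next entry or ``duration_s``.  ``antibody_events`` are ``(on_time_s,
    off_time_s)`` pairs with ``off_time_s = None`` for events that persist to
    the end of the observation (dissociation is not modelled).
    """

    molecule_id: int
    duration_s: float
    entries: list[tuple[float, str]]
    antibody_events: list[tuple[float, float | None]] = field(
        default_factory=list)
    resistant: bool | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.entries or self.entries[0][0] != 0.0:
            raise SchemeValidationError("first entry must be at time 0")
        times = [t for t, _ in self.entries]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise SchemeValidationError("entry times must strictly increase")
        states = [s for _, s in self.entries]
        if any(s1 == s2 for s1, s2 in zip(states, states[1:])):
            raise SchemeValidationError("consecutive states must differ")
        for on, off in self.antibody_events:
            if off is not None and off <= on:
                raise SchemeValidationError("antibody off time must be > on")

    def state_at(self, t: float) -> str:
        """State occupied at time ``t`` (right-continuous)."""
        state = self.entries[0][1]
        for et, es in self.entries:
            if et <= t:
                state = es
            else:
                break
        return state

    def dwell_segments(self) -> list[tuple[float, float, str]]:
        """``(t_start, t_end, state)`` segments covering [0, duration]."""
        segs = []
        for i, (t, s) in enumerate(self.entries):
            t_end = (self.entries[i + 1][0] if i + 1 < len(self.entries)
                     else self.duration_s)
            segs.append((t, t_end, s))
        return segs


# ---------------------------------------------------------------------------
# stochastic simulation

def _molecule_rng(seed: int, molecule_index: int) -> np.random.Generator:
    # Fixed-offset substream: independent of iteration order; the leading
    # 0 keeps simulation streams disjoint from rendering streams.
    return np.random.default_rng([seed, 0, molecule_index])


def _draw_initial_state(initial, rng: np.random.Generator) -> str:
    if isinstance(initial, str):
        return initial
    labels = sorted(initial)
    probs = np.array([initial[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def simulate_state_path(scheme: KineticScheme, config: SimulationConfig,
                        molecule_index: int) -> StatePath:
    """Exact-jump (Gillespie) simulation of one molecule.

    Exponential waiting times and categorical exit choices under the
    condition active at each instant; condition changes are handled by
    re-drawing the (memoryless) waiting time at each segment boundary.
    """
    if not 0 <= molecule_index < config.n_molecules:
        raise SchemeValidationError(
            f"molecule_index {molecule_index} outside [0, n_molecules)")
    scheme.validate()
    rng = _molecule_rng(config.seed, molecule_index)

    state = _draw_initial_state(config.initial_state, rng)
    entries: list[tuple[float, str]] = [(0.0, state)]
    ab_events: list[tuple[float, float | None]] = []
    pending_ab: float | None = None
    resistant: bool | None = None
    ab_mean = config.antibody_mean_assoc_s

    def enter(t: float, new_state: str) -> str:
        nonlocal resistant, pending_ab
        entries.append((t, new_state))
        if new_state == GQ_SS and resistant is None:
            resistant = bool(rng.random() < scheme.gq_resistant_fraction)
        if new_state == ISTATE and ab_mean is not None:
            pending_ab = t + rng.exponential(ab_mean)
        return new_state

    def commit_antibody(now: float) -> None:
        nonlocal pending_ab
        if pending_ab is not None and pending_ab <= now:
            if pending_ab < config.duration_s:
                ab_events.append((pending_ab, None))
            pending_ab = None

    if state == GQ_SS:
        resistant = bool(rng.random() < scheme.gq_resistant_fraction)
    if state == ISTATE and ab_mean is not None:
        pending_ab = rng.exponential(ab_mean)

    for t0, t1, cond in config.condition_segments():
        t = t0
        # RNase H instantly re-forms duplex around a resistant GQ.
        if cond == RNASEH and state == GQ_SS and resistant:
            commit_antibody(t)
            relabel_t = t if t > entries[-1][0] else t + 1e-9
            state = enter(relabel_t, GQ_DS)
        while t < t1:
            channels = list(scheme.exits(state, cond))
            if state == GQ_SS and resistant:
                channels = []  # resistant GQ does not decay
            rates = np.array([r for _, r in channels], dtype=float)

            if state == DSDNA and cond == BASELINE and \
                    scheme.round_rate_per_s > 0:
                # Transcription rounds: Poisson arrivals, thinned by p_rloop.
                dt = rng.exponential(1.0 / scheme.round_rate_per_s)
                if t + dt >= t1:
                    break
                t += dt
                commit_antibody(t)
                if rng.random() < scheme.p_rloop:
                    state = enter(t, ISTATE)
                continue

            total = rates.sum()
            if total <= 0:
                break  # absorbing under this condition
            dt = rng.exponential(1.0 / total)
            if t + dt >= t1:
                break
            t += dt
            commit_antibody(t)
            nxt = channels[int(rng.choice(len(channels), p=rates / total))][0]
            if state == ISTATE and nxt == DSDNA:
                pending_ab = None  # R-loop resolved before antibody arrived
            if nxt == GQ_SS and cond == RNASEH:
                if resistant is None:
                    resistant = bool(
                        rng.random() < scheme.gq_resistant_fraction)
                if resistant:
                    nxt = GQ_DS  # duplex re-forms around the GQ at once
            state = enter(t, nxt)
        commit_antibody(t1)
    commit_antibody(config.duration_s)

    return StatePath(molecule_id=molecule_index,
                     duration_s=config.duration_s,
                     entries=entries, antibody_events=ab_events,
                     resistant=resistant)


def simulate_ensemble(scheme: KineticScheme,
                      config: SimulationConfig) -> list[StatePath]:
    """Simulate all ``config.n_molecules`` molecules (seed-reproducible)."""
    return [simulate_state_path(scheme, config, i)
            for i in range(config.n_molecules)]


# ---------------------------------------------------------------------------
# analytic occupancy oracle

def occupancy(scheme: KineticScheme, condition: str, t: float,
              initial: Mapping[str, float]) -> dict[str, float]:
    """State-occupancy probabilities at time ``t`` via the matrix exponential
    of the condition's generator.

    The transcription round process contributes an effective
    ``DSDNA -> ISTATE`` rate of ``round_rate * p_rloop`` under ``BASELINE``
    (thinning a Poisson process is again Poisson).  Under ``RNASEH`` the
    quenched resistant subpopulation is handled exactly by moving the
    resistant share of initial ``GQ_SS`` mass to ``GQ_DS`` at t=0+, since
    resistant relabelling is instantaneous and no new ``GQ_SS`` is produced
    under that condition in the default scheme.
    """
    if t < 0:
        raise SchemeValidationError("t must be >= 0")
    if condition not in scheme.conditions:
        raise SchemeValidationError(f"unknown condition {condition!r}")
    states = list(scheme.states)
    p0 = np.array([float(initial.get(s, 0.0)) for s in states])
    if abs(p0.sum() - 1.0) > 1e-9 or (p0 < 0).any():
        raise SchemeValidationError("initial must be a probability vector")
    if t == 0:
        return dict(zip(states, p0))

    idx = {s: i for i, s in enumerate(states)}
    f = scheme.gq_resistant_fraction
    if condition == RNASEH and f > 0 and p0[idx[GQ_SS]] > 0:
        moved = f * p0[idx[GQ_SS]]
        p0 = p0.copy()
        p0[idx[GQ_SS]] -= moved
        p0[idx[GQ_DS]] += moved

    n = len(states)
    Q = np.zeros((n, n))
    for tr in scheme.transitions:
        if tr.condition == condition:
            Q[idx[tr.from_state], idx[tr.to_state]] += tr.rate_per_s
    if condition == BASELINE:
        Q[idx[DSDNA], idx[ISTATE]] += scheme.round_rate_per_s * scheme.p_rloop
    if condition == RNASEH and f > 0:
        # Sensitive GQs only (resistant mass already moved): the stored
        # GQ_SS rate is the per-sensitive-molecule decay rate, unchanged.
        pass
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    p = p0 @ expm(Q * t)
    return dict(zip(states, p))


def branching_probability(scheme: KineticScheme, condition: str,
                          state: str) -> dict[str, float] | None:
    """Exit-branching probabilities ``rate / sum(rates)`` of ``state``.

    Returns ``None`` when the state has no outgoing transition under the
    condition (absorbing) — callers must handle that signal.
    """
    channels = scheme.exits(state, condition)
    if state == DSDNA and condition == BASELINE and scheme.round_rate_per_s:
        eff = scheme.round_rate_per_s * scheme.p_rloop
        if eff > 0:
            channels = channels + [(ISTATE, eff)]
    if not channels:
        return None
    total = sum(r for _, r in channels)
    out: dict[str, float] = {}
    for to, r in channels:
        out[to] = out.get(to, 0.0) + r / total
    return out


# ---------------------------------------------------------------------------
# IO

def write_state_paths(paths: Sequence[StatePath], filename) -> None:
    """TSV with columns molecule_id, time_s, state; one row per entry.

    Antibody events, when present, go to a sibling file with suffix
    ``.antibody.tsv`` (columns molecule_id, on_time_s, off_time_s).
    """
    import pandas as pd
    rows = [(p.molecule_id, t, s) for p in paths for t, s in p.entries]
    df = pd.DataFrame(rows, columns=["molecule_id", "time_s", "state"])
    df.to_csv(filename, sep="\t", index=False)
    ab_rows = [(p.molecule_id, on, "" if off is None else off)
               for p in paths for on, off in p.antibody_events]
    if ab_rows:
        ab = pd.DataFrame(ab_rows,
                          columns=["molecule_id", "on_time_s", "off_time_s"])
        ab.to_csv(str(filename) + ".antibody.tsv", sep="\t", index=False)


def read_state_paths(filename, duration_s: float) -> list[StatePath]:
    import pandas as pd
    df = pd.read_csv(filename, sep="\t")
    paths = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        entries = list(zip(grp["time_s"].astype(float),
                           grp["state"].astype(str)))
        paths.append(StatePath(molecule_id=int(mol), duration_s=duration_s,
                               entries=entries))
    return paths


def save_scheme(scheme: KineticScheme, filename) -> None:
    with open(filename, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)


def load_scheme(filename) -> KineticScheme:
    with open(filename) as fh:
        return KineticScheme.from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, filename) -> None:
    with open(filename, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(filename) -> SimulationConfig:
    with open(filename) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
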