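"""Kinetic fits: dwell-time constants, branched rates, populations, rounds.

The central algebra: the I-state decays through two competing channels
(back to duplex at k1, forward to G-quadruplex at k2).  Its dwell time is
then exponential with apparent rate k = k1 + k2 = 1/τ, and the GQ branch
fraction is p = k2 / (k1 + k2); measuring τ and p therefore determines the
microscopic rates

    k2 = p / τ,        k1 = (1 − p) / τ.

Dwell fitting is censoring-aware by default: with right-censored
observations the exponential MLE is (sum of all durations, censored
included) / (number of complete dwells).  A histogram + least-squares mode
is provided for parity with the usual single-molecule presentation.
Uncertainties come from seeded bootstrap resampling (fits) and Wilson
intervals (fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from lmfit import Model
from statsmodels.stats.proportion import proportion_confint

from .traceproc import Dwell

__all__ = [
    "MLE_CENSORED", "HIST_LSQ", "SINGLE_EXP", "EXP_PLUS_PLATEAU",
    "UnfittableError", "ExpFit", "PlateauExpFit", "RateDecomposition",
    "BranchFraction", "PopulationCurve", "RoundsEstimate", "AssociationTime",
    "fit_exponential_dwells", "branch_fraction", "decompose_branched_rates",
    "population_curve", "fit_population", "estimate_rounds",
    "association_time",
]

MLE_CENSORED = "MLE_CENSORED"
HIST_LSQ = "HIST_LSQ"
SINGLE_EXP = "SINGLE_EXP"
EXP_PLUS_PLATEAU = "EXP_PLUS_PLATEAU"


class UnfittableError(ValueError):
    """Raised when the data cannot support the requested fit."""


@dataclass
class ExpFit:
    """Single-exponential time constant with bootstrap uncertainty."""

    tau_s: float
    se_tau: float
    n_complete: int
    n_censored: int
    method: str
    amplitude: float | None = None  # HIST_LSQ / population fits only
    offset: float | None = None


@dataclass
class PlateauExpFit:
    """Exponential decay onto a plateau: y = plateau + amplitude·exp(−t/τ).

    The plateau is the persistent (RNase-H-resistant) fraction.
    """

    plateau_fraction: float
    amplitude: float
    tau_s: float
    se_plateau: float
    se_amplitude: float
    se_tau: float


@dataclass
class RateDecomposition:
    """Branched-rate result: τ, apparent k, branch fraction p, and the
    microscopic rates k1 (to duplex) and k2 (to GQ), with propagated SEs."""

    tau_s: float
    k: float
    p: float
    k1: float
    k2: float
    se_tau: float = 0.0
    se_k: float = 0.0
    se_p: float = 0.0
    se_k1: float = 0.0
    se_k2: float = 0.0


@dataclass
class BranchFraction:
    """Exit fraction over complete dwells with a Wilson interval."""

    fraction: float
    ci_low: float
    ci_high: float
    n_to: int
    n_exits: int


@dataclass
class PopulationCurve:
    """Per-state population fractions over time.

    Fractions are relative to the fixed denominator ``n_total`` (all scored
    molecules at t = 0), so photobleached molecules leaving the ensemble
    show up as population loss rather than renormalization.
    """

    time_s: np.ndarray
    fractions: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    n_total: int


@dataclass
class RoundsEstimate:
    """Transcription rounds per observation from multi- vs single-round
    GQ yields: the ratio estimator eff_multi/eff_single and the
    independent-trials estimator ln(1−eff_multi)/ln(1−eff_single)."""

    n_ratio: float
    n_independent_trials: float
    eff_multi: float
    eff_single: float


@dataclass
class AssociationTime:
    """Mean antibody association delay after I-state entry."""

    mean_s: float
    se_s: float
    n: int
    delays_s: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# dwell fitting

def _dwell_arrays(dwells: Sequence[Dwell], state: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    sel = [d for d in dwells if d.state == state]
    dur = np.array([d.duration_s for d in sel], float)
    cens = np.array([d.censored for d in sel], bool)
    return dur, cens


def _exp_mle(dur: np.ndarray, cens: np.ndarray) -> float:
    n_complete = int((~cens).sum())
    if n_complete == 0:
        raise UnfittableError("no complete dwells")
    return float(dur.sum() / n_complete)


def _hist_lsq_tau(complete: np.ndarray, min_bin_s: float) -> float:
    # Freedman–Diaconis width with a floor, exponential-decay LSQ.
    n = len(complete)
    iqr = np.subtract(*np.percentile(complete, [75, 25]))
    width = max(2.0 * iqr / max(n, 1) ** (1 / 3), min_bin_s)
    edges = np.arange(0.0, complete.max() + width, width)
    if len(edges) < 4:
        edges = np.linspace(0.0, complete.max() + width, 4)
    counts, edges = np.histogram(complete, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def decay(t, a, tau):
        return a * np.exp(-t / tau)

    model = Model(decay)
    params = model.make_params(a=max(counts.max(), 1.0),
                               tau=max(complete.mean(), 1e-9))
    params["tau"].set(min=1e-12)
    res = model.fit(counts, params, t=centers)
    return float(res.params["tau"].value)


def fit_exponential_dwells(dwells: Sequence[Dwell], state: str,
                           method: str = MLE_CENSORED,
                           n_boot: int = 1000, seed: int = 0,
                           hist_min_bin_s: float = 10.0,
                           min_complete: int = 5) -> ExpFit:
    """Fit a single-exponential time constant to the dwells of ``state``.

    ``MLE_CENSORED``: τ̂ = Σ(all durations, censored included) / n_complete —
    the censoring-aware exponential MLE; on fully complete data this is the
    sample mean.  ``HIST_LSQ``: unweighted least squares of A·exp(−t/τ) to
    the binned histogram of complete dwells only.  The standard error is a
    seeded bootstrap over dwells (``n_boot`` resamples).
    """
    dur, cens = _dwell_arrays(dwells, state)
    n_complete = int((~cens).sum())
    if n_complete == 0:
        raise UnfittableError(f"no complete {state} dwells")
    if n_complete < min_complete:
        raise UnfittableError(
            f"need >= {min_complete} complete {state} dwells, "
            f"got {n_complete}")

    if method == MLE_CENSORED:
        def estimator(d, c):
            return _exp_mle(d, c)
    elif method == HIST_LSQ:
        def estimator(d, c):
            return _hist_lsq_tau(d[~c], hist_min_bin_s)
    else:
        raise ValueError(f"unknown method {method!r}")

    tau = estimator(dur, cens)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(dur), len(dur))
        d, c = dur[idx], cens[idx]
        if (~c).sum() == 0:
            continue
        try:
            boots.append(estimator(d, c))
        except Exception:
            continue
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return ExpFit(tau_s=float(tau), se_tau=se, n_complete=n_complete,
                  n_censored=int(cens.sum()), method=method)


def branch_fraction(dwells: Sequence[Dwell], from_state: str,
                    to_state: str) -> BranchFraction:
    """Fraction of complete ``from_state`` dwells exiting to ``to_state``,
    with a Wilson 95% interval. Censored dwells carry no exit information
    and are excluded."""
    complete = [d for d in dwells
                if d.state == from_state and not d.censored
                and d.exit_state is not None]
    if not complete:
        raise UnfittableError(f"no complete {from_state} dwells with exits")
    n = len(complete)
    k = sum(1 for d in complete if d.exit_state == to_state)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return BranchFraction(fraction=k / n, ci_low=float(lo), ci_high=float(hi),
                          n_to=k, n_exits=n)


def decompose_branched_rates(tau_s: float, p: float, se_tau: float = 0.0,
                             se_p: float = 0.0) -> RateDecomposition:
    """Branched-reaction algebra: k = 1/τ, k2 = p·k, k1 = (1−p)·k.

    First-order (delta-method) error propagation from independent
    uncertainties on τ and p.
    """
    if not tau_s > 0:
        raise ValueError("tau_s must be > 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    k = 1.0 / tau_s
    k1 = (1.0 - p) * k
    k2 = p * k
    se_k = se_tau / tau_s ** 2
    se_k1 = math.hypot((1.0 - p) * se_k, k * se_p)
    se_k2 = math.hypot(p * se_k, k * se_p)
    return RateDecomposition(tau_s=tau_s, k=k, p=p, k1=k1, k2=k2,
                             se_tau=se_tau, se_k=se_k, se_p=se_p,
                             se_k1=se_k1, se_k2=se_k2)


# ---------------------------------------------------------------------------
# population curves

def population_curve(idealizations, time_grid_s: np.ndarray,
                     labels: Sequence[str] = ("MID", "HIGH"),
                     ) -> PopulationCurve:
    """Fraction of molecules in each idealized class at each grid time.

    The denominator is the number of scored molecules (fixed at t = 0);
    molecules dark (bleached) at a grid time count toward no class.
    """
    time_grid_s = np.asarray(time_grid_s, float)
    n_total = len(idealizations)
    counts = {lab: np.zeros(len(time_grid_s), int) for lab in labels}
    for idl in idealizations:
        w = idl.bin_width_s
        bins = np.minimum((time_grid_s / w).astype(int),
                          len(idl.labels) - 1)
        for j, b in enumerate(bins):
            lab = idl.labels[b]
            if lab in counts:
                counts[lab][j] += 1
    fractions = {lab: c / max(n_total, 1) for lab, c in counts.items()}
    return PopulationCurve(time_s=time_grid_s, fractions=fractions,
                           counts=counts, n_total=n_total)


def _binomial_weights(y: np.ndarray, n: int | None) -> np.ndarray:
    if n is None:
        return np.ones_like(y)
    var = np.clip(y * (1.0 - y), 1e-4, None) / n
    return 1.0 / np.sqrt(var)


def fit_population(time: np.ndarray, fraction: np.ndarray,
                   model: str = SINGLE_EXP, direction: str = "accumulation",
                   n_total: int | None = None,
                   fix_amplitude: float | None = None
                   ) -> ExpFit | PlateauExpFit:
    """Weighted least-squares fit of a population time course.

    ``SINGLE_EXP`` fits A·(1 − exp(−t/τ)) for ``direction="accumulation"``
    or A·exp(−t/τ) + c for ``direction="decay"``.  ``EXP_PLUS_PLATEAU``
    fits plateau + amplitude·exp(−t/τ) and reports the plateau (the
    persistent fraction) explicitly.  Points are weighted by inverse
    binomial standard deviations when ``n_total`` is given.

    ``fix_amplitude`` pins A in the accumulation model; use it when the
    asymptote is known (e.g. a cumulative first-entry fraction, which must
    saturate at 1) — the amplitude–τ correlation of the free fit then no
    longer inflates the variance of τ̂.
    """
    t = np.asarray(time, float)
    y = np.asarray(fraction, float)
    if len(t) < 4:
        raise UnfittableError("need >= 4 time points")
    weights = _binomial_weights(y, n_total)
    tau0 = max((t.max() - t.min()) / 3.0, np.finfo(float).tiny)

    if model == SINGLE_EXP and direction == "accumulation":
        def f(t, a, tau):
            return a * (1.0 - np.exp(-t / tau))
        m = Model(f)
        params = m.make_params(a=max(y.max(), 1e-6), tau=tau0)
        params["tau"].set(min=1e-9)
        params["a"].set(min=0.0)
        if fix_amplitude is not None:
            params["a"].set(value=fix_amplitude, vary=False)
        res = m.fit(y, params, t=t, weights=weights)
        return ExpFit(tau_s=float(res.params["tau"].value),
                      se_tau=float(res.params["tau"].stderr or np.nan),
                      n_complete=len(t), n_censored=0, method=SINGLE_EXP,
                      amplitude=float(res.params["a"].value))
    if model == SINGLE_EXP and direction == "decay":
        def f(t, a, tau, c):
            return a * np.exp(-t / tau) + c
        m = Model(f)
        params = m.make_params(a=max(y.max() - y.min(), 1e-6), tau=tau0,
                               c=max(y.min(), 0.0))
        params["tau"].set(min=1e-9)
        res = m.fit(y, params, t=t, weights=weights)
        return ExpFit(tau_s=float(res.params["tau"].value),
                      se_tau=float(res.params["tau"].stderr or np.nan),
                      n_complete=len(t), n_censored=0, method=SINGLE_EXP,
                      amplitude=float(res.params["a"].value),
                      offset=float(res.params["c"].value))
    if model == EXP_PLUS_PLATEAU:
        def f(t, plateau, amplitude, tau):
            return plateau + amplitude * np.exp(-t / tau)
        m = Model(f)
        params = m.make_params(plateau=max(y.min(), 0.0),
                               amplitude=max(y.max() - y.min(), 1e-6),
                               tau=tau0)
        params["plateau"].set(min=0.0, max=1.0)
        params["amplitude"].set(min=0.0)
        params["tau"].set(min=1e-9)
        res = m.fit(y, params, t=t, weights=weights)
        def err(name):
            return float(res.params[name].stderr or np.nan)
        return PlateauExpFit(
            plateau_fraction=float(res.params["plateau"].value),
            amplitude=float(res.params["amplitude"].value),
            tau_s=float(res.params["tau"].value),
            se_plateau=err("plateau"), se_amplitude=err("amplitude"),
            se_tau=err("tau"))
    raise ValueError(f"unknown model/direction {model!r}/{direction!r}")


# ---------------------------------------------------------------------------
# derived quantities

def estimate_rounds(eff_multi: float, eff_single: float) -> RoundsEstimate:
    """Transcription rounds per observation window from GQ yields.

    The ratio estimator treats per-round yields as additive; the
    independent-trials estimator solves 1−eff_multi = (1−eff_single)^n.
    Both are reported; neither is privileged.
    """
    if not 0.0 < eff_single < 1.0:
        raise ValueError("eff_single must lie in (0, 1)")
    if not eff_single <= eff_multi < 1.0:
        raise ValueError("need eff_single <= eff_multi < 1")
    n_ratio = eff_multi / eff_single
    n_trials = math.log1p(-eff_multi) / math.log1p(-eff_single)
    return RoundsEstimate(n_ratio=n_ratio, n_independent_trials=n_trials,
                          eff_multi=eff_multi, eff_single=eff_single)


def association_time(on_times_by_molecule: Mapping[int, float],
                     entry_times_by_molecule: Mapping[int, float],
                     min_pairs: int = 5) -> AssociationTime:
    """Mean antibody association delay (first on-time − I-state entry)
    over molecules with both events; SE = SD/√n.

    For exponentially distributed delays the sample mean is also the MLE of
    the association time constant.
    """
    delays = []
    for mol, on in on_times_by_molecule.items():
        entry = entry_times_by_molecule.get(mol)
        if entry is not None and on >= entry:
            delays.append(on - entry)
    if len(delays) < min_pairs:
        raise UnfittableError(
            f"need >= {min_pairs} paired events, got {len(delays)}")
    d = np.asarray(delays, float)
    return AssociationTime(mean_s=float(d.mean()),
                           se_s=float(d.std(ddof=1) / np.sqrt(len(d))),
                           n=len(d), delays_s=d)
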