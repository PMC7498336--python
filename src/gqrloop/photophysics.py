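"""Forward model: state trajectories -> multi-channel fluorescence traces.

Renders a :class:`~gqrloop.scheme.StatePath` into binned donor (Cy3),
acceptor (Cy5) and antibody (Alexa488) intensity series the way a TIRF
camera would record them: per-bin time-weighted averaging of the underlying
piecewise-constant emission, acceptor blinking, independent donor/acceptor
photobleaching, and additive Gaussian channel noise.

Intensities are in arbitrary units; only the acceptor fraction (apparent
FRET efficiency) matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scheme import (DSDNA, DSDNA_GQ_EMBEDDED, GQ_DS, GQ_SS, ISTATE,
                     SchemeValidationError, StatePath)

__all__ = [
    "EmissionModel", "PhotophysicsModel", "Trace", "TraceParseError",
    "render_trace", "render_traces", "write_traces", "read_traces",
]

DEFAULT_STATE_FRET = {
    DSDNA: 0.13,
    ISTATE: 0.37,
    GQ_SS: 0.82,
    GQ_DS: 0.75,
    DSDNA_GQ_EMBEDDED: 0.75,
}


class TraceParseError(ValueError):
    """Raised for malformed or inconsistent trace files."""


@dataclass
class EmissionModel:
    """Mean apparent FRET per state plus intensity/noise scales."""

    state_fret: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_FRET))
    total_intensity: float = 1000.0
    channel_noise_sd: float = 50.0
    antibody_intensity: float = 400.0

    def __post_init__(self) -> None:
        for s, e in self.state_fret.items():
            if not 0.0 <= e <= 1.0:
                raise SchemeValidationError(
                    f"state FRET for {s!r} must be in [0, 1], got {e}")
        if self.total_intensity <= 0:
            raise SchemeValidationError("total_intensity must be > 0")
        if self.channel_noise_sd < 0:
            raise SchemeValidationError("channel_noise_sd must be >= 0")

    @classmethod
    def noiseless(cls, **overrides) -> "EmissionModel":
        kwargs = dict(channel_noise_sd=0.0)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PhotophysicsModel:
    """Dye photophysics: bleach rates (s^-1) and acceptor blinking.

    Blinks arrive as a Poisson process on the acceptor and last an
    exponential time; both channels drop to background for their duration
    (the total-intensity drop is what dark-state detection keys on).
    Defaults give traces resembling a several-hundred-second observation
    window with occasional short blinks.
    """

    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    blink_rate: float = 0.0
    blink_mean_duration_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("donor_bleach_rate", "acceptor_bleach_rate",
                     "blink_rate", "blink_mean_duration_s"):
            if getattr(self, name) < 0:
                raise SchemeValidationError(f"{name} must be >= 0")

    @classmethod
    def ideal(cls) -> "PhotophysicsModel":
        """No bleaching, no blinking."""
        return cls()

    @classmethod
    def typical(cls) -> "PhotophysicsModel":
        """Visually realistic dye behaviour for synthetic movies."""
        return cls(donor_bleach_rate=2e-4, acceptor_bleach_rate=2e-4,
                   blink_rate=1e-3, blink_mean_duration_s=2.0)


@dataclass
class Trace:
    """Binned multi-channel intensities for one molecule.

    ``time_s`` holds bin centers; all series have equal length.
    """

    molecule_id: int
    bin_width_s: float
    time_s: np.ndarray
    i_donor: np.ndarray
    i_acceptor: np.ndarray
    i_488: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0:
            raise SchemeValidationError("bin_width_s must be > 0")
        n = len(self.time_s)
        if not (len(self.i_donor) == len(self.i_acceptor)
                == len(self.i_488) == n):
            raise SchemeValidationError("channel series lengths must match")

    @property
    def n_bins(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# rendering

def _merge_intervals(intervals: list[tuple[float, float]]
                     ) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return merged


def _bin_overlap(edges: np.ndarray, a: float, b: float) -> np.ndarray:
    """Per-bin overlap length with interval [a, b)."""
    lo = np.clip(a, edges[:-1], edges[1:])
    hi = np.clip(b, edges[:-1], edges[1:])
    return np.maximum(hi - lo, 0.0)


def render_trace(path: StatePath, emission: EmissionModel,
                 photo: PhotophysicsModel, bin_width_s: float,
                 seed: int | Sequence[int]) -> Trace:
    """Render one state path into a noisy three-channel trace.

    Per bin the expected acceptor fraction is the time-weighted mean of the
    state FRET over the bin (camera integration); blink intervals drop both
    channels to background, acceptor bleach collapses the signal to
    donor-only, donor bleach drops both channels.  Gaussian noise of
    ``emission.channel_noise_sd`` is then added per channel (negatives are
    kept — symmetric noise gives unbiased downstream FRET).
    """
    if bin_width_s <= 0:
        raise SchemeValidationError("bin_width_s must be > 0")
    duration = path.duration_s
    n_bins = int(np.floor(duration / bin_width_s + 1e-9))
    if n_bins < 1:
        raise SchemeValidationError("path shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_width_s
    rng = np.random.default_rng(seed)

    t_donor = (rng.exponential(1.0 / photo.donor_bleach_rate)
               if photo.donor_bleach_rate > 0 else np.inf)
    t_acceptor = (rng.exponential(1.0 / photo.acceptor_bleach_rate)
                  if photo.acceptor_bleach_rate > 0 else np.inf)

    blinks: list[tuple[float, float]] = []
    if photo.blink_rate > 0:
        t = rng.exponential(1.0 / photo.blink_rate)
        while t < duration:
            d = rng.exponential(photo.blink_mean_duration_s)
            blinks.append((t, min(t + d, duration)))
            t = t + d + rng.exponential(1.0 / photo.blink_rate)
        blinks = _merge_intervals(blinks)

    T = emission.total_intensity
    donor = np.zeros(n_bins)
    acceptor = np.zeros(n_bins)

    # FRET emission while both dyes are alive and not blinking.
    t_live = min(t_donor, t_acceptor, duration)
    for seg_a, seg_b, state in path.dwell_segments():
        a, b = seg_a, min(seg_b, t_live)
        if b <= a:
            continue
        e = emission.state_fret[state]
        w = _bin_overlap(edges, a, b)
        acceptor += w * (T * e)
        donor += w * (T * (1.0 - e))
    # Donor-only emission after acceptor bleach (donor still alive).
    if t_acceptor < min(t_donor, duration):
        w = _bin_overlap(edges, t_acceptor, min(t_donor, duration))
        donor += w * T
    # Blink intervals: both channels to background — subtract whatever
    # emission was accumulated there, interval by interval (exact).
    for a, b in blinks:
        b = min(b, t_donor, duration)  # bleach overrides
        if b <= a or a >= t_donor:
            continue
        for seg_a, seg_b, state in path.dwell_segments():
            lo, hi = max(seg_a, a), min(seg_b, b, t_live)
            if hi > lo:
                e = emission.state_fret[state]
                w = _bin_overlap(edges, lo, hi)
                acceptor -= w * (T * e)
                donor -= w * (T * (1.0 - e))
        if t_acceptor < t_donor:
            lo, hi = max(t_acceptor, a), min(min(t_donor, duration), b)
            if hi > lo:
                donor -= _bin_overlap(edges, lo, hi) * T

    donor /= bin_width_s
    acceptor /= bin_width_s

    i488 = np.zeros(n_bins)
    for on, off in path.antibody_events:
        off = duration if off is None else min(off, duration)
        if off > on:
            i488 += _bin_overlap(edges, on, off) * emission.antibody_intensity
    i488 /= bin_width_s

    if emission.channel_noise_sd > 0:
        sd = emission.channel_noise_sd
        donor = donor + rng.normal(0.0, sd, n_bins)
        acceptor = acceptor + rng.normal(0.0, sd, n_bins)
        i488 = i488 + rng.normal(0.0, sd, n_bins)

    centers = (edges[:-1] + edges[1:]) / 2.0
    return Trace(molecule_id=path.molecule_id, bin_width_s=bin_width_s,
                 time_s=centers, i_donor=donor, i_acceptor=acceptor,
                 i_488=i488)


def render_traces(paths: Sequence[StatePath], emission: EmissionModel,
                  photo: PhotophysicsModel, bin_width_s: float,
                  seed: int) -> list[Trace]:
    """Render an ensemble; molecule ``i`` uses substream ``[seed, 1, i]``
    (disjoint from the simulator's ``[seed, 0, i]`` streams)."""
    return [render_trace(p, emission, photo, bin_width_s,
                         seed=[seed, 1, p.molecule_id]) for p in paths]


# ---------------------------------------------------------------------------
# IO (TSV schema: molecule_id, time_s, i_donor, i_acceptor, i_488)

_COLUMNS = ["molecule_id", "time_s", "i_donor", "i_acceptor", "i_488"]


def write_traces(traces: Sequence[Trace], filename) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "molecule_id": tr.molecule_id,
            "time_s": tr.time_s,
            "i_donor": tr.i_donor,
            "i_acceptor": tr.i_acceptor,
            "i_488": tr.i_488,
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_COLUMNS)
    df.to_csv(filename, sep="\t", index=False)  # full precision: lossless


def read_traces(filename) -> list[Trace]:
    """Read the TSV trace schema back into :class:`Trace` objects.

    Malformed rows are reported with their 1-based file line number; the
    time grid of every molecule must be uniform and non-negative.
    """
    df = pd.read_csv(filename, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"missing columns: {missing}")
    if df.empty:
        return []
    for col in _COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-base
            raise TraceParseError(
                f"malformed value in column {col!r} at line {line}")
        df[col] = vals
    neg = df["time_s"] < 0
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 2
        raise TraceParseError(f"negative time_s at line {line}")

    traces = []
    bin_widths = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        t = grp["time_s"].to_numpy(float)
        if len(t) < 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise TraceParseError(
                f"times for molecule {mol} must strictly increase")
        if len(t) > 1:
            steps = np.diff(t)
            w = steps[0]
            if not np.allclose(steps, w, rtol=1e-6, atol=1e-9):
                raise TraceParseError(
                    f"non-uniform time grid for molecule {mol}")
        else:
            w = 2 * t[0] if t[0] > 0 else 1.0
        bin_widths.append(w)
        traces.append(Trace(
            molecule_id=int(mol), bin_width_s=float(w), time_s=t,
            i_donor=grp["i_donor"].to_numpy(float),
            i_acceptor=grp["i_acceptor"].to_numpy(float),
            i_488=grp["i_488"].to_numpy(float)))
    if len(set(np.round(bin_widths, 9))) > 1:
        raise TraceParseError("ragged molecule blocks: bin widths differ")
    return traces
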