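"""Trace processing: FRET series, idealization, dwells, contours, binding.

This is the measurement layer.  It converts rendered (or recorded)
intensity traces into apparent FRET efficiency series, masks dark bins
(blinks) and photobleached tails, idealizes each trace into the three
FRET classes LOW / MID / HIGH (duplex / I-state / G-quadruplex), extracts
dwell times with right-censoring flags, builds post-synchronized FRET
contours, and detects antibody-binding steps on the Alexa488 channel.

Conventions: bin timestamps are bin centers, dwell boundaries lie on bin
edges, all times are seconds.  FRET is the uncorrected proximity ratio
``I_A / (I_D + I_A)`` — no gamma, leakage or direct-excitation correction
is applied (hooks exist but default to identity); values pushed outside
[0, 1] by noise are clamped to the boundary so bins stay countable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .photophysics import Trace
from .scheme import SchemeValidationError

__all__ = [
    "LOW", "MID", "HIGH", "DARK", "DEFAULT_THRESHOLDS",
    "FretTrace", "TraceValidity", "Idealization", "Dwell", "BindingEvent",
    "SyncContour", "T1Stats",
    "compute_fret", "detect_dark_and_bleach", "idealize", "auto_thresholds",
    "extract_dwells", "dwells_from_path", "postsynchronize",
    "detect_binding_events",
    "t1_statistics", "write_dwells", "read_dwells", "write_contour",
]

LOW = "LOW"    # duplex DNA,  E ~ 0.13
MID = "MID"    # I-state,     E ~ 0.37
HIGH = "HIGH"  # G-quadruplex, E ~ 0.82 (ssDNA) / 0.75 (duplex-embedded)
DARK = "DARK"  # invalid: blink, bleach, long dark run

# Midpoints between the three population peaks (0.13 / 0.37 / 0.82).
DEFAULT_THRESHOLDS = (0.25, 0.55)


@dataclass
class FretTrace:
    """Apparent FRET efficiency per bin, with validity mask."""

    molecule_id: int
    bin_width_s: float
    time_s: np.ndarray
    efficiency: np.ndarray        # NaN where invalid
    valid_mask: np.ndarray        # bool per bin

    @property
    def n_bins(self) -> int:
        return len(self.time_s)


@dataclass
class TraceValidity:
    """Classification of dark bins in a trace."""

    valid_mask: np.ndarray
    bleach_bin: int | None                 # first bin of terminal dark run
    blink_runs: list[tuple[int, int]]      # [start, end) bin ranges
    long_dark_runs: list[tuple[int, int]]  # interior dark > max_blink


@dataclass
class Idealization:
    """Per-bin state labels for one trace.

    ``labels`` contains LOW/MID/HIGH exactly on valid bins and DARK exactly
    on invalid ones.  ``thresholds`` are the two FRET boundaries used.
    """

    molecule_id: int
    bin_width_s: float
    time_s: np.ndarray
    labels: np.ndarray
    thresholds: tuple[float, float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class Dwell:
    """A maximal same-state run: right-censored iff truncated by trace end,
    bleach, a long dark run, or an intervention boundary."""

    molecule_id: int
    state: str
    start_s: float
    duration_s: float
    exit_state: str | None
    censored: bool


@dataclass
class BindingEvent:
    """An antibody on-event on the Alexa488 channel."""

    molecule_id: int
    on_time_s: float
    off_time_s: float | None  # None: persists to trace end


@dataclass
class SyncContour:
    """Post-synchronized FRET density: (fret bins x aligned-time bins)."""

    density: np.ndarray
    fret_edges: np.ndarray
    time_s: np.ndarray            # aligned-time bin centers
    survivors: np.ndarray         # contributing traces per time column
    n_traces: int

    @property
    def empty(self) -> bool:
        return self.density.shape[1] == 0


@dataclass
class T1Stats:
    """Per-molecule t1 = (first HIGH entry) − (first antibody on-time).

    Positive values mean antibody binding preceded GQ formation.
    Molecules that formed a GQ without any binding event are listed in
    ``gq_without_binding``.
    """

    t1_s: np.ndarray
    molecule_ids: np.ndarray
    gq_without_binding: list[int]


# ---------------------------------------------------------------------------
# FRET + validity

def detect_dark_and_bleach(trace: Trace, total_threshold: float = 0.5,
                           max_blink_s: float = 5.0,
                           window_bins: int = 51,
                           detect_acceptor_dark: bool = True,
                           acceptor_dark_e: float = 0.065,
                           acceptor_dark_min_s: float = 5.0
                           ) -> TraceValidity:
    """Mask dark bins and classify them as blink, bleach or long dark.

    A bin is dark when its total intensity falls below ``total_threshold``
    times a running median of the total (floored at half the bright level
    so that long dark tails cannot drag the reference down).  The terminal
    dark run is a photobleach; interior runs no longer than ``max_blink_s``
    are blinks; longer interior runs censor the dwells around them.

    Acceptor photobleach leaves the total intensity high but collapses the
    proximity ratio to ~0, below even the duplex level; when
    ``detect_acceptor_dark`` is set, a terminal stretch whose suffix-mean
    E stays below ``acceptor_dark_e`` (for at least ``acceptor_dark_min_s``)
    is treated as bleached as well.
    """
    if not 0.0 < total_threshold < 1.0:
        raise SchemeValidationError("total_threshold must be in (0, 1)")
    total = np.asarray(trace.i_donor, float) + np.asarray(trace.i_acceptor,
                                                          float)
    n = len(total)
    w = trace.bin_width_s
    runmed = median_filter(total, size=min(window_bins, max(n, 1)),
                           mode="nearest")
    # Floor the reference at half the peak running median so a long dark
    # tail (post-bleach noise) cannot drag the local reference down to the
    # noise level and let noise bins pass as valid.
    bright = runmed.max() if n else 0.0
    if bright <= 0:
        return TraceValidity(valid_mask=np.zeros(n, bool),
                             bleach_bin=0 if n else None,
                             blink_runs=[], long_dark_runs=[])
    ref = np.maximum(runmed, 0.5 * bright)
    invalid = total < total_threshold * ref

    if detect_acceptor_dark and n and not invalid.all():
        # Suffix means over *bright* bins only, so a dark (total-intensity)
        # tail cannot drag the mean below threshold by itself.
        bright_idx = np.flatnonzero(~invalid)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(total > 0, trace.i_acceptor / total, 0.0)
        eb = e[bright_idx]
        min_bins = max(1, int(round(acceptor_dark_min_s / w)))
        m = len(eb)
        csum = np.cumsum(eb[::-1])[::-1]
        lens = m - np.arange(m)
        suffix_mean = csum / lens
        cand = np.flatnonzero((suffix_mean < acceptor_dark_e)
                              & (lens >= min_bins))
        if cand.size:
            invalid = invalid.copy()
            invalid[bright_idx[cand[0]]:] = True

    max_blink_bins = max(1, int(round(max_blink_s / w)))
    bleach_bin = None
    blink_runs: list[tuple[int, int]] = []
    long_runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not invalid[i]:
            i += 1
            continue
        j = i
        while j < n and invalid[j]:
            j += 1
        if j == n:
            bleach_bin = i
        elif j - i <= max_blink_bins:
            blink_runs.append((i, j))
        else:
            long_runs.append((i, j))
        i = j
    return TraceValidity(valid_mask=~invalid, bleach_bin=bleach_bin,
                         blink_runs=blink_runs, long_dark_runs=long_runs)


def compute_fret(trace: Trace, validity: TraceValidity | None = None,
                 correction: Callable[[np.ndarray], np.ndarray] | None = None
                 ) -> FretTrace:
    """Apparent FRET ``E = I_A / (I_D + I_A)`` per bin.

    Bins flagged invalid by ``validity`` (computed with defaults when not
    given) and bins with non-positive total are masked; valid E is clamped
    to [0, 1].  ``correction`` is an optional hook applied to the raw ratio
    (identity by default — the proximity ratio is reported uncorrected).
    """
    if validity is None:
        validity = detect_dark_and_bleach(trace)
    total = np.asarray(trace.i_donor, float) + np.asarray(trace.i_acceptor,
                                                          float)
    mask = validity.valid_mask & (total > 0)
    e = np.full(len(total), np.nan)
    e[mask] = np.asarray(trace.i_acceptor, float)[mask] / total[mask]
    if correction is not None:
        e[mask] = correction(e[mask])
    e[mask] = np.clip(e[mask], 0.0, 1.0)
    return FretTrace(molecule_id=trace.molecule_id,
                     bin_width_s=trace.bin_width_s, time_s=trace.time_s,
                     efficiency=e, valid_mask=mask)


# ---------------------------------------------------------------------------
# idealization

def auto_thresholds(fret_traces: Sequence[FretTrace],
                    random_state: int = 0
                    ) -> tuple[tuple[float, float], list[str]]:
    """Derive the two class boundaries from a 3-component Gaussian mixture
    over pooled valid E values (boundaries at equal posterior).

    Falls back to :data:`DEFAULT_THRESHOLDS` with a warning record when the
    mixture is degenerate (an empty class or unseparated means).
    """
    from sklearn.mixture import GaussianMixture

    pooled = np.concatenate([ft.efficiency[ft.valid_mask]
                             for ft in fret_traces]) if fret_traces else \
        np.empty(0)
    warnings: list[str] = []
    if pooled.size < 30:
        warnings.append("too few valid bins for mixture; using defaults")
        return DEFAULT_THRESHOLDS, warnings
    gm = GaussianMixture(n_components=3, random_state=random_state,
                         n_init=3).fit(pooled.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    weights = gm.weights_.ravel()[order]
    if weights.min() < 0.02 or np.diff(means).min() < 0.05:
        warnings.append(
            f"degenerate mixture (means={means.round(3)}, "
            f"weights={weights.round(3)}); using defaults")
        return DEFAULT_THRESHOLDS, warnings
    grid = np.linspace(0.0, 1.0, 2001).reshape(-1, 1)
    resp = gm.predict_proba(grid)[:, order]
    cls = np.argmax(resp, axis=1)
    bounds = []
    for k in (0, 1):
        above = np.flatnonzero(cls > k)
        if above.size == 0 or above[0] == 0:
            warnings.append("no posterior crossing; using defaults")
            return DEFAULT_THRESHOLDS, warnings
        bounds.append(float(grid[above[0], 0]))
    if not bounds[0] < bounds[1]:
        warnings.append("crossings out of order; using defaults")
        return DEFAULT_THRESHOLDS, warnings
    return (bounds[0], bounds[1]), warnings


def _suppress_flickers(labels: np.ndarray, valid_idx: np.ndarray,
                       min_dwell_bins: int) -> np.ndarray:
    """Merge same-class runs shorter than ``min_dwell_bins`` (counted over
    valid bins, dark gaps transparent) into their longer neighbour."""
    if min_dwell_bins <= 1 or valid_idx.size == 0:
        return labels
    seq = labels[valid_idx]
    for _ in range(len(seq)):  # bounded; converges much sooner
        runs = []  # (start, end) over seq
        s = 0
        for i in range(1, len(seq) + 1):
            if i == len(seq) or seq[i] != seq[s]:
                runs.append((s, i))
                s = i
        if len(runs) <= 1:
            break
        changed = False
        for ri, (a, b) in enumerate(runs):
            if b - a < min_dwell_bins:
                if ri == 0:
                    seq[a:b] = seq[runs[1][0]]
                else:
                    prev_len = runs[ri - 1][1] - runs[ri - 1][0]
                    next_len = (runs[ri + 1][1] - runs[ri + 1][0]
                                if ri + 1 < len(runs) else -1)
                    donor = (runs[ri + 1][0] if next_len > prev_len
                             else runs[ri - 1][0])
                    seq[a:b] = seq[donor]
                changed = True
                break
        if not changed:
            break
    out = labels.copy()
    out[valid_idx] = seq
    return out


def idealize(fret: FretTrace,
             thresholds: tuple[float, float] | str = DEFAULT_THRESHOLDS,
             min_dwell_bins: int = 2) -> Idealization:
    """Threshold idealization into LOW / MID / HIGH (DARK where invalid).

    ``thresholds`` is a (low/mid, mid/high) boundary pair or ``"auto"`` to
    derive boundaries from this trace's own pooled E values via the
    Gaussian-mixture rule.  Runs shorter than ``min_dwell_bins`` (counting
    valid bins only) are merged into a neighbouring run to suppress
    shot-noise flickers.
    """
    if not fret.valid_mask.any():
        raise SchemeValidationError("trace has no valid bins")
    warnings: list[str] = []
    if isinstance(thresholds, str):
        if thresholds.lower() != "auto":
            raise SchemeValidationError(f"unknown thresholds {thresholds!r}")
        thresholds, warnings = auto_thresholds([fret])
    lo, hi = thresholds
    if not 0.0 < lo < hi < 1.0:
        raise SchemeValidationError("thresholds must satisfy 0 < lo < hi < 1")

    labels = np.full(fret.n_bins, DARK, dtype=object)
    e = fret.efficiency
    m = fret.valid_mask
    labels[m & (e < lo)] = LOW
    labels[m & (e >= lo) & (e <= hi)] = MID
    labels[m & (e > hi)] = HIGH
    labels = _suppress_flickers(labels, np.flatnonzero(m), min_dwell_bins)
    return Idealization(molecule_id=fret.molecule_id,
                        bin_width_s=fret.bin_width_s, time_s=fret.time_s,
                        labels=labels, thresholds=(float(lo), float(hi)),
                        warnings=warnings)


# ---------------------------------------------------------------------------
# dwell extraction

def extract_dwells(ideal: Idealization,
                   interventions: Sequence[float] = (),
                   max_blink_s: float = 5.0) -> list[Dwell]:
    """Maximal same-label runs as dwells, with censoring bookkeeping.

    Dark runs no longer than ``max_blink_s`` flanked by the same label are
    bridged (the dwell continues through the blink); a label change hidden
    inside a dark run, a long dark run, a bleach, the trace end, or an
    intervention boundary all right-censor the enclosing dwell.  Dwell
    boundaries lie on bin edges.
    """
    labels = ideal.labels
    n = len(labels)
    w = ideal.bin_width_s
    max_blink_bins = max(1, int(round(max_blink_s / w)))
    dwells: list[Dwell] = []

    cur: str | None = None
    cur_start = 0.0

    def close(end_s: float, exit_state: str | None, censored: bool) -> None:
        nonlocal cur
        if cur is not None and end_s > cur_start:
            dwells.append(Dwell(molecule_id=ideal.molecule_id, state=cur,
                                start_s=cur_start,
                                duration_s=end_s - cur_start,
                                exit_state=exit_state, censored=censored))
        cur = None

    i = 0
    while i < n:
        lab = labels[i]
        if lab == DARK:
            j = i
            while j < n and labels[j] == DARK:
                j += 1
            bridgeable = (j < n and j - i <= max_blink_bins
                          and labels[j] == cur)
            if cur is not None and not bridgeable:
                close(i * w, None, True)
            i = j
            continue
        if cur is None:
            cur, cur_start = lab, i * w
        elif lab != cur:
            close(i * w, lab, False)
            cur, cur_start = lab, i * w
        i += 1
    close(n * w, None, True)

    # Split dwells at intervention boundaries; both halves censored there.
    for tb in sorted(interventions):
        out: list[Dwell] = []
        for d in dwells:
            end = d.start_s + d.duration_s
            if d.start_s < tb < end:
                out.append(Dwell(d.molecule_id, d.state, d.start_s,
                                 tb - d.start_s, None, True))
                out.append(Dwell(d.molecule_id, d.state, tb, end - tb,
                                 d.exit_state, d.censored))
            else:
                out.append(d)
        dwells = out
    return dwells


def dwells_from_path(path, interventions: Sequence[float] = ()
                     ) -> list[Dwell]:
    """Ground-truth dwells straight from a simulated state path.

    The terminal segment is right-censored by the observation end; segments
    spanning an intervention time are split and censored at the boundary,
    mirroring :func:`extract_dwells` on idealized traces.
    """
    segs = path.dwell_segments()
    dwells = []
    for i, (a, b, state) in enumerate(segs):
        exit_state = segs[i + 1][2] if i + 1 < len(segs) else None
        censored = exit_state is None
        dwells.append(Dwell(molecule_id=path.molecule_id, state=state,
                            start_s=a, duration_s=b - a,
                            exit_state=exit_state, censored=censored))
    for tb in sorted(interventions):
        out = []
        for d in dwells:
            end = d.start_s + d.duration_s
            if d.start_s < tb < end:
                out.append(Dwell(d.molecule_id, d.state, d.start_s,
                                 tb - d.start_s, None, True))
                out.append(Dwell(d.molecule_id, d.state, tb, end - tb,
                                 d.exit_state, d.censored))
            else:
                out.append(d)
        dwells = out
    return dwells


# ---------------------------------------------------------------------------
# post-synchronization

def _first_transition_bin(ideal: Idealization, from_label: str,
                          to_label: str) -> int | None:
    """Bin index of the first ``from_label -> to_label`` transition
    (index of the first ``to_label`` bin), dark gaps transparent."""
    m = ideal.labels != DARK
    idx = np.flatnonzero(m)
    seq = ideal.labels[idx]
    for k in range(1, len(seq)):
        if seq[k - 1] == from_label and seq[k] == to_label:
            return int(idx[k])
    return None


def postsynchronize(fret_traces: Sequence[FretTrace],
                    idealizations: Sequence[Idealization],
                    n_fret_bins: int = 30,
                    max_time_s: float | None = None,
                    sync_from: str = LOW, sync_to: str = MID) -> SyncContour:
    """Align traces at their first LOW→MID transition and build the
    photobleach-corrected FRET density contour.

    Each aligned-time column is divided by the number of traces still
    contributing a valid bin there, so every column with at least one
    survivor sums to one — this is the normalization that corrects for the
    molecule number decreasing through photobleaching.
    """
    if len(fret_traces) != len(idealizations):
        raise SchemeValidationError("fret/idealization lists must pair up")
    fret_edges = np.linspace(0.0, 1.0, n_fret_bins + 1)
    aligned: list[tuple[FretTrace, int]] = []
    for ft, idl in zip(fret_traces, idealizations):
        sb = _first_transition_bin(idl, sync_from, sync_to)
        if sb is not None:
            aligned.append((ft, sb))
    if not aligned:
        w = fret_traces[0].bin_width_s if fret_traces else 1.0
        return SyncContour(density=np.zeros((n_fret_bins, 0)),
                           fret_edges=fret_edges,
                           time_s=np.empty(0), survivors=np.empty(0, int),
                           n_traces=0)
    w = aligned[0][0].bin_width_s
    n_cols = max(ft.n_bins - sb for ft, sb in aligned)
    if max_time_s is not None:
        n_cols = min(n_cols, int(np.ceil(max_time_s / w)))
    counts = np.zeros((len(fret_edges) - 1, n_cols))
    survivors = np.zeros(n_cols, dtype=int)
    for ft, sb in aligned:
        cols = np.arange(sb, min(ft.n_bins, sb + n_cols)) - sb
        valid = ft.valid_mask[sb:sb + len(cols)]
        e = np.clip(ft.efficiency[sb:sb + len(cols)], 0.0,
                    np.nextafter(1.0, 0.0))
        fbin = np.minimum((e * (len(fret_edges) - 1)).astype(int),
                          len(fret_edges) - 2)
        for c, v, fb in zip(cols, valid, fbin):
            if v:
                counts[fb, c] += 1.0
                survivors[c] += 1
    density = np.divide(counts, survivors, where=survivors > 0,
                        out=np.zeros_like(counts))
    centers = (np.arange(n_cols) + 0.5) * w
    return SyncContour(density=density, fret_edges=fret_edges,
                       time_s=centers, survivors=survivors,
                       n_traces=len(aligned))


# ---------------------------------------------------------------------------
# antibody binding

def detect_binding_events(trace: Trace, threshold: float | None = None,
                          min_bins: int = 2) -> list[BindingEvent]:
    """Step detection on the Alexa488 channel.

    With ``threshold=None`` the off/on levels are the extrema of a
    median-smoothed channel, so even a few-bin off (or on) period anchors
    its level; the channel counts as stepped only when the level gap
    clears six noise SDs (noise from bin-to-bin differences), which
    rejects flat channels — including one that is already on at the first
    bin, where no step is observable.  Runs of at least ``min_bins``
    above-threshold bins become events; an event running to the trace end
    has ``off_time_s=None``.
    """
    x = np.asarray(trace.i_488, float)
    n = len(x)
    w = trace.bin_width_s
    if n == 0:
        return []
    if threshold is None:
        xs = median_filter(x, size=min(3, n), mode="nearest")
        lo, hi = xs.min(), xs.max()
        noise = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2.0) \
            if n > 1 else 0.0
        if hi - lo <= max(6.0 * noise, 1e-12):
            return []
        threshold = 0.5 * (lo + hi)
    above = x > threshold
    events: list[BindingEvent] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_bins:
            on = trace.time_s[i] - w / 2.0
            off = None if j == n else trace.time_s[j - 1] + w / 2.0
            events.append(BindingEvent(trace.molecule_id, float(on),
                                       None if off is None else float(off)))
        i = j
    return events


def t1_statistics(events_by_molecule: Mapping[int, Sequence[BindingEvent]],
                  idealizations: Sequence[Idealization]) -> T1Stats:
    """t1 = (first HIGH entry time) − (first antibody on-time), per molecule.

    Positive t1 means the antibody bound (the R-loop was detectable) before
    the GQ formed.  Molecules with a HIGH entry but no binding event are
    reported separately, not folded into the statistic.
    """
    t1s, ids, unbound = [], [], []
    for idl in idealizations:
        hb = None
        m = idl.labels != DARK
        idx = np.flatnonzero(m & (idl.labels == HIGH))
        if idx.size:
            hb = idx[0] * idl.bin_width_s  # entry edge of first HIGH bin
        if hb is None:
            continue
        evs = events_by_molecule.get(idl.molecule_id, ())
        if not evs:
            unbound.append(idl.molecule_id)
            continue
        on = min(ev.on_time_s for ev in evs)
        t1s.append(hb - on)
        ids.append(idl.molecule_id)
    return T1Stats(t1_s=np.asarray(t1s, float),
                   molecule_ids=np.asarray(ids, int),
                   gq_without_binding=unbound)


# ---------------------------------------------------------------------------
# IO

def write_dwells(dwells: Sequence[Dwell], filename) -> None:
    import pandas as pd
    df = pd.DataFrame(
        [(d.molecule_id, d.state, d.start_s, d.duration_s,
          "" if d.exit_state is None else d.exit_state, int(d.censored))
         for d in dwells],
        columns=["molecule_id", "state", "start_s", "duration_s",
                 "exit_state", "censored"])
    df.to_csv(filename, sep="\t", index=False)


def read_dwells(filename) -> list[Dwell]:
    import pandas as pd
    df = pd.read_csv(filename, sep="\t",
                     dtype={"exit_state": "string"})
    out = []
    for row in df.itertuples(index=False):
        exit_state = (None if row.exit_state is None or pd.isna(row.exit_state)
                      or row.exit_state == "" else str(row.exit_state))
        out.append(Dwell(molecule_id=int(row.molecule_id),
                         state=str(row.state), start_s=float(row.start_s),
                         duration_s=float(row.duration_s),
                         exit_state=exit_state,
                         censored=bool(row.censored)))
    return out


def write_contour(contour: SyncContour, filename) -> None:
    """TSV grid: first column FRET bin centers, remaining columns the
    aligned-time columns (header carries the time centers)."""
    import pandas as pd
    fcenters = (contour.fret_edges[:-1] + contour.fret_edges[1:]) / 2.0
    df = pd.DataFrame(contour.density,
                      columns=[f"t={t:.3f}" for t in contour.time_s])
    df.insert(0, "fret", fcenters)
    df.to_csv(filename, sep="\t", index=False, float_format="%.6g")
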