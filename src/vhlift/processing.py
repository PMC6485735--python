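"""Force-trace processing: filtering, event detection, scalar parameters,
binned force profiles, reach kinematics, trial screening, and condition
averaging.

Conventions
-----------
- Load force (LF) = thumb_vertical + index_vertical (N).
- Grip force (GF) = (thumb_normal + index_normal) / 2 (N).
- Force rates by central differences on the filtered signals (one-sided at
  the endpoints).
- Event times are resolved to the first sample at-or-above threshold; no
  sub-sample interpolation.  Comparisons use a 1e-9 N numerical tolerance
  so that a noiseless curve touching its plateau exactly is detected on
  the correct sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ForceTrace",
    "GripLoadSeries",
    "LiftEvents",
    "ForceParameters",
    "BinnedProfile",
    "KinematicParameters",
    "AveragedCurve",
    "ScreenInput",
    "TrialError",
    "TechnicalError",
    "NoLiftError",
    "NoLiftoffError",
    "NoMovementError",
    "preprocess",
    "grip_load",
    "detect_events",
    "force_parameters",
    "binned_areas",
    "kinematics",
    "screen_trials",
    "average_curves",
]

#: numerical slack for threshold crossings (N)
_EPS = 1e-9


class TrialError(Exception):
    """A trial could not be analysed; ``reason`` matches screening categories."""

    reason = "technical"


class TechnicalError(TrialError):
    reason = "technical"


class NoLiftError(TrialError):
    """Load force never reached the onset threshold."""

    reason = "no_lift"


class NoLiftoffError(TrialError):
    """Load force never reached the cube weight."""

    reason = "drop"


class NoMovementError(TrialError):
    """Reach velocity never reached the movement-start threshold."""

    reason = "no_movement"


@dataclass
class ForceTrace:
    """One trial's uniformly sampled per-finger force (and position) series.

    Forces in newtons, positions (optional, shape ``(n, 3)``) in mm, time in
    seconds at a fixed sampling rate.
    """

    time: np.ndarray
    thumb_normal: np.ndarray
    index_normal: np.ndarray
    thumb_vertical: np.ndarray
    index_vertical: np.ndarray
    thumb_pos: np.ndarray | None = None
    index_pos: np.ndarray | None = None
    mass_g: float | None = None
    delay_ms: float | None = None
    participant_id: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("thumb_normal", "index_normal", "thumb_vertical", "index_vertical"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} length {arr.size} != time length {self.time.size}")
            setattr(self, name, arr)
        for name in ("thumb_pos", "index_pos"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.time.size, 3):
                    raise ValueError(f"{name} must have shape (n, 3)")
                setattr(self, name, arr)
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.time)
        if dt.min() <= 0 or np.max(np.abs(dt - dt[0])) > 1e-6:
            raise ValueError("time base must be uniform and strictly increasing")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def force_channels(self) -> dict[str, np.ndarray]:
        return {
            "thumb_normal": self.thumb_normal,
            "index_normal": self.index_normal,
            "thumb_vertical": self.thumb_vertical,
            "index_vertical": self.index_vertical,
        }


@dataclass
class GripLoadSeries:
    """Filtered grip/load forces and their rates on a common time base."""

    time: np.ndarray
    gf: np.ndarray
    lf: np.ndarray
    gfr: np.ndarray
    lfr: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class LiftEvents:
    lf_onset: float
    gf_onset: float
    liftoff: float


@dataclass(frozen=True)
class ForceParameters:
    lfr_max: float
    gfr_max: float
    lpd: float
    gf_at_lo: float
    truncated_window: bool = False


@dataclass(frozen=True)
class BinnedProfile:
    """Signed trapezoidal areas per 100-ms bin from GF onset (10 bins, 1 s)."""

    lf: np.ndarray
    gf: np.ndarray
    lfr: np.ndarray
    gfr: np.ndarray
    bin_width: float = 0.1


@dataclass(frozen=True)
class KinematicParameters:
    peak_velocity: float  # mm/s, averaged over fingers
    path_length: float  # mm, averaged over fingers
    curvature: float  # mm, max deviation from straight line, averaged
    contact_position_thumb: float  # mm along the reach axis
    contact_position_index: float
    movement_start: float  # s


def zero_phase_lowpass(
    x: np.ndarray, fs: float, cutoff: float = 15.0, order: int = 2
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag)."""
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _interpolate_missing(x: np.ndarray, max_missing_frac: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    frac = bad.mean()
    if frac > max_missing_frac:
        raise TechnicalError(
            f"{frac:.1%} samples missing exceeds limit {max_missing_frac:.0%}"
        )
    if bad.all():
        raise TechnicalError("all samples missing")
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def preprocess(
    trace: ForceTrace,
    cutoff: float = 15.0,
    order: int = 2,
    max_missing_frac: float = 0.1,
) -> ForceTrace:
    """Interpolate missing samples and low-pass filter all force channels.

    Raises :class:`TechnicalError` when more than ``max_missing_frac`` of any
    channel is missing.
    """
    if trace.time[-1] - trace.time[0] < 1.0:
        raise TechnicalError("trace shorter than 1 s")
    fs = trace.sampling_rate
    filtered = {}
    for name, x in trace.force_channels().items():
        x = _interpolate_missing(x, max_missing_frac)
        filtered[name] = zero_phase_lowpass(x, fs, cutoff=cutoff, order=order)
    return replace(trace, **filtered)


def grip_load(trace: ForceTrace) -> GripLoadSeries:
    """Combine finger channels into grip/load forces and differentiate."""
    lf = trace.thumb_vertical + trace.index_vertical
    gf = 0.5 * (trace.thumb_normal + trace.index_normal)
    dt = trace.dt
    return GripLoadSeries(
        time=trace.time.copy(),
        gf=gf,
        lf=lf,
        gfr=np.gradient(gf, dt),
        lfr=np.gradient(lf, dt),
    )


def _first_crossing(time: np.ndarray, x: np.ndarray, threshold: float,
                    start_index: int = 0) -> int | None:
    hits = np.nonzero(x[start_index:] >= threshold - _EPS)[0]
    if hits.size == 0:
        return None
    return start_index + int(hits[0])


def detect_events(
    gls: GripLoadSeries, cube_weight: float, threshold: float = 0.1
) -> LiftEvents:
    """Detect LF onset, GF onset (first 0.1 N crossings) and lift-off
    (first time LF reaches the cube weight at or after LF onset)."""
    i_lf = _first_crossing(gls.time, gls.lf, threshold)
    if i_lf is None:
        raise NoLiftError("load force never reached onset threshold")
    i_gf = _first_crossing(gls.time, gls.gf, threshold)
    if i_gf is None:
        raise NoLiftError("grip force never reached onset threshold")
    i_lo = _first_crossing(gls.time, gls.lf, cube_weight, start_index=i_lf)
    if i_lo is None:
        raise NoLiftoffError("load force never reached cube weight")
    return LiftEvents(
        lf_onset=float(gls.time[i_lf]),
        gf_onset=float(gls.time[i_gf]),
        liftoff=float(gls.time[i_lo]),
    )


def force_parameters(
    gls: GripLoadSeries, ev: LiftEvents, margin: float = 0.05
) -> ForceParameters:
    """Scalar force-scaling outcomes.

    Maxima of the force rates are taken between ``margin`` (50 ms) before
    onset and ``margin`` after lift-off; windows that fall off the trace are
    truncated and flagged.
    """
    t = gls.time
    truncated = False

    def window_max(x: np.ndarray, start: float, stop: float) -> float:
        nonlocal truncated
        if start < t[0] or stop > t[-1]:
            truncated = True
        mask = (t >= start - _EPS) & (t <= stop + _EPS)
        return float(np.max(x[mask]))

    lfr_max = window_max(gls.lfr, ev.lf_onset - margin, ev.liftoff + margin)
    gfr_max = window_max(gls.gfr, ev.gf_onset - margin, ev.liftoff + margin)
    i_lo = int(round((ev.liftoff - t[0]) / gls.dt))
    return ForceParameters(
        lfr_max=lfr_max,
        gfr_max=gfr_max,
        lpd=ev.liftoff - ev.lf_onset,
        gf_at_lo=float(gls.gf[i_lo]),
        truncated_window=truncated,
    )


def binned_areas(
    gls: GripLoadSeries,
    ev: LiftEvents,
    n_bins: int = 10,
    bin_width: float = 0.1,
) -> BinnedProfile:
    """Signed trapezoidal area of lf/gf/lfr/gfr in consecutive 100-ms bins
    starting at GF onset (10 bins covering 1 s)."""
    dt = gls.dt
    i0 = int(round((ev.gf_onset - gls.time[0]) / dt))
    per_bin = int(round(bin_width / dt))
    needed = i0 + n_bins * per_bin + 1
    if needed > gls.time.size:
        raise ValueError(
            f"need {n_bins * bin_width:.1f} s of data after GF onset; trace too short"
        )

    def areas(x: np.ndarray) -> np.ndarray:
        out = np.empty(n_bins)
        for k in range(n_bins):
            a = i0 + k * per_bin
            out[k] = np.trapezoid(x[a : a + per_bin + 1], dx=dt)
        return out

    return BinnedProfile(
        lf=areas(gls.lf),
        gf=areas(gls.gf),
        lfr=areas(gls.lfr),
        gfr=areas(gls.gfr),
        bin_width=bin_width,
    )


def kinematics(
    trace: ForceTrace,
    ev: LiftEvents,
    velocity_threshold: float = 10.0,
) -> KinematicParameters:
    """Reach-phase kinematics from movement start to object contact.

    Movement start is the first sample where either finger's velocity
    component toward the cube (along the straight start-to-contact axis)
    reaches ``velocity_threshold`` mm/s; contact is GF onset.  Peak speed,
    path length and curvature (max perpendicular deviation from the
    straight start-contact segment) are averaged across fingers.
    """
    if trace.thumb_pos is None or trace.index_pos is None:
        raise ValueError("kinematics requires per-finger positions")
    dt = trace.dt
    i_contact = int(round((ev.gf_onset - trace.time[0]) / dt))
    if i_contact < 2:
        raise NoMovementError("no reach samples before contact")

    fingers = {"thumb": trace.thumb_pos, "index": trace.index_pos}
    velocities = {k: np.gradient(p, dt, axis=0) for k, p in fingers.items()}

    # reach axis per finger: from initial position to contact position
    axes = {}
    for k, p in fingers.items():
        vec = p[i_contact] - p[0]
        norm = np.linalg.norm(vec)
        axes[k] = vec / norm if norm > 0 else np.array([0.0, 1.0, 0.0])

    toward = {k: velocities[k] @ axes[k] for k in fingers}
    started = np.zeros(trace.time.size, dtype=bool)
    for k in fingers:
        started |= toward[k] >= velocity_threshold
    hits = np.nonzero(started[: i_contact + 1])[0]
    if hits.size == 0:
        raise NoMovementError("movement-start velocity threshold never reached")
    i_start = int(hits[0])

    peak_v, path_len, curv, contact_pos = [], [], [], {}
    for k, p in fingers.items():
        seg = p[i_start : i_contact + 1]
        v = velocities[k][i_start : i_contact + 1]
        peak_v.append(float(np.max(np.linalg.norm(v, axis=1))))
        path_len.append(float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1))))
        start, end = seg[0], seg[-1]
        chord = end - start
        cn = np.linalg.norm(chord)
        if cn == 0:
            curv.append(0.0)
        else:
            rel = seg - start
            along = np.outer(rel @ chord / cn**2, chord)
            curv.append(float(np.max(np.linalg.norm(rel - along, axis=1))))
        contact_pos[k] = float((p[i_contact] - p[0]) @ axes[k])

    return KinematicParameters(
        peak_velocity=float(np.mean(peak_v)),
        path_length=float(np.mean(path_len)),
        curvature=float(np.mean(curv)),
        contact_position_thumb=contact_pos["thumb"],
        contact_position_index=contact_pos["index"],
        movement_start=float(trace.time[i_start]),
    )


@dataclass
class ScreenInput:
    """Per-trial bundle for screening decisions."""

    trial_id: str
    gls: GripLoadSeries | None
    events: LiftEvents | None
    cube_weight: float
    hold_start: float | None = None  # defaults to liftoff
    hold_end: float | None = None  # defaults to end of trace
    start_offset_mm: float | None = None
    failure: str | None = None  # pre-existing failure reason (e.g. technical)


def screen_trials(
    items: Sequence[ScreenInput],
    drop_fraction: float = 0.5,
    recross_tol: float = 0.1,
    start_tolerance_mm: float = 10.0,
) -> pd.DataFrame:
    """Classify every trial as kept or excluded.

    Exclusion reasons: ``technical`` (processing failure), ``no_lift``,
    ``multiple_lift`` (LF dips below ``weight - recross_tol`` after lift-off
    and then recovers above it), ``drop`` (LF falls below
    ``drop_fraction * weight`` during the hold window without re-lifting).
    Trials whose start-position offset exceeds ``start_tolerance_mm`` stay
    in the force analysis but are flagged out of the kinematic analysis.
    """
    rows = []
    for item in items:
        keep, reason = True, "none"
        kinematics_ok = True
        if item.failure is not None:
            keep, reason = False, item.failure
        elif item.events is None or item.gls is None:
            keep, reason = False, "technical"
        else:
            t = item.gls.time
            lf = item.gls.lf
            h0 = item.events.liftoff if item.hold_start is None else item.hold_start
            h1 = float(t[-1]) if item.hold_end is None else item.hold_end
            mask = (t >= h0 - _EPS) & (t <= h1 + _EPS)
            seg = lf[mask]
            if seg.size:
                low = seg < item.cube_weight - recross_tol
                if low.any():
                    first_low = int(np.argmax(low))
                    recovered = np.any(
                        seg[first_low:] >= item.cube_weight - recross_tol + _EPS
                    ) and not low[-1]
                    if recovered:
                        keep, reason = False, "multiple_lift"
                    elif np.min(seg) < drop_fraction * item.cube_weight:
                        keep, reason = False, "drop"
        if (
            item.start_offset_mm is not None
            and item.start_offset_mm > start_tolerance_mm
        ):
            kinematics_ok = False
            if reason == "none":
                reason = "not_at_start"
        rows.append(
            {
                "trial_id": item.trial_id,
                "keep": keep,
                "reason": reason,
                "kinematics_ok": kinematics_ok and keep,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AveragedCurve:
    """Per-condition mean lf/gf curves aligned at GF onset (time zero)."""

    time: np.ndarray
    lf: np.ndarray
    gf: np.ndarray
    n_trials: int


def average_curves(
    trials: Sequence[GripLoadSeries], events: Sequence[LiftEvents]
) -> AveragedCurve:
    """Sample-wise mean after aligning each trial at its GF onset.

    The averaging window is ``[0, shortest post-onset duration]``; lift-off
    should be re-detected on the averaged curve with :func:`detect_events`.
    """
    if len(trials) == 0:
        raise ValueError("no trials to average")
    if len(trials) != len(events):
        raise ValueError("trials and events must have equal length")
    aligned_lf, aligned_gf = [], []
    n = None
    for gls, ev in zip(trials, events):
        i0 = int(round((ev.gf_onset - gls.time[0]) / gls.dt))
        lf = gls.lf[i0:]
        gf = gls.gf[i0:]
        n = lf.size if n is None else min(n, lf.size)
        aligned_lf.append(lf)
        aligned_gf.append(gf)
    dt = trials[0].dt
    lf_mean = np.mean([x[:n] for x in aligned_lf], axis=0)
    gf_mean = np.mean([x[:n] for x in aligned_gf], axis=0)
    return AveragedCurve(
        time=np.arange(n) * dt, lf=lf_mean, gf=gf_mean, n_trials=len(trials)
    )
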