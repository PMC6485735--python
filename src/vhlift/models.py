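"""Sigmoid load-force curves and delay models.

The load-force profile of a well-scaled lift is modelled as the double
integral of a single-period sine: the force *acceleration* is
``G * sin(f * t)`` with frequency ``f = 2*pi/d`` and amplitude
``G = 2*pi*m/d**2``, where ``m`` is the object's weight (N) and ``d`` the
loading-phase duration (s).  Integrating twice from rest gives the closed
form used throughout::

    LF(t) = (m/d) * (t - sin(f*t)/f)      for 0 <= t <= d

which starts at 0, saturates at ``m`` exactly at ``t = d``, and has a
bell-shaped rate peaking at ``2*m/d``.

A visual delay can transform the base curve in three ways, controlled by the
relative visual weight ``w_v`` (haptic weight ``w_h = 1 - w_v``):

- ``shift``   — the onset moves by ``w_v * delay``;
- ``stretch`` — the duration grows to ``d + w_v * delay`` (amplitude
  recomputed so the plateau stays at ``m``);
- ``sum``     — a ``w_h``-weighted copy at the original onset plus a
  ``w_v``-weighted copy delayed by the full delay.

Fitting recovers ``d`` from no-delay average curves and ``w_v`` from delay
curves by minimising the RMSE between model and data on the window from
grip-force onset to lift-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SineLiftParams",
    "DelaySpec",
    "FitResult",
    "MODEL_KINDS",
    "lf_curve",
    "lf_rate",
    "model_curve",
    "model_liftoff_time",
    "rmse",
    "fit_duration",
    "fit_weight",
    "compare_models",
]

ModelKind = Literal["shift", "stretch", "sum"]
MODEL_KINDS: tuple[str, ...] = ("shift", "stretch", "sum")


@dataclass(frozen=True)
class SineLiftParams:
    """Parameters of the base sigmoid curve.

    Attributes
    ----------
    m : float
        Cube weight as a force in newtons (mass_kg * 9.81); the curve
        saturates at this value.
    d : float
        Loading-phase duration in seconds.
    onset : float
        Time at which the curve starts to rise (grip-force onset), seconds.
    """

    m: float
    d: float
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"weight m must be positive, got {self.m}")
        if self.d <= 0:
            raise ValueError(f"duration d must be positive, got {self.d}")

    @property
    def f(self) -> float:
        """Angular frequency of the underlying sine, rad/s."""
        return 2.0 * np.pi / self.d

    @property
    def G(self) -> float:
        """Amplitude of the underlying sine (peak force acceleration), N/s^2."""
        return 2.0 * np.pi * self.m / self.d**2


@dataclass(frozen=True)
class DelaySpec:
    """Visual delay (s) and the relative weight of vision, ``w_v``."""

    delay: float
    w_v: float

    @property
    def w_h(self) -> float:
        return 1.0 - self.w_v


def lf_curve(p: SineLiftParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the base sigmoid load-force curve at ``times`` (s).

    Closed form: 0 before onset, ``(m/d)*(tau - sin(f*tau)/f)`` during the
    loading phase (``tau`` = time since onset), and ``m`` afterwards.
    Continuous and non-decreasing.
    """
    t = np.asarray(times, dtype=float)
    tau = t - p.onset
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau <= p.d)
    tr = tau[rising]
    out[rising] = (p.m / p.d) * (tr - np.sin(p.f * tr) / p.f)
    out[tau > p.d] = p.m
    return out


def lf_rate(p: SineLiftParams, times: np.ndarray) -> np.ndarray:
    """Analytic derivative of :func:`lf_curve`: ``(m/d)*(1 - cos(f*tau))``."""
    t = np.asarray(times, dtype=float)
    tau = t - p.onset
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau <= p.d)
    out[rising] = (p.m / p.d) * (1.0 - np.cos(p.f * tau[rising]))
    return out


def model_curve(
    kind: str, p: SineLiftParams, ds: DelaySpec, times: np.ndarray
) -> np.ndarray:
    """Evaluate one of the delay models at ``times``.

    shift   : base curve with onset moved by ``w_v * delay``.
    stretch : base curve with duration ``d + w_v * delay``.
    sum     : ``w_h * base(onset) + w_v * base(onset + delay)``.
    """
    if kind == "shift":
        return lf_curve(replace(p, onset=p.onset + ds.w_v * ds.delay), times)
    if kind == "stretch":
        return lf_curve(replace(p, d=p.d + ds.w_v * ds.delay), times)
    if kind == "sum":
        haptic = lf_curve(p, times)
        visual = lf_curve(replace(p, onset=p.onset + ds.delay), times)
        return ds.w_h * haptic + ds.w_v * visual
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def model_liftoff_time(kind: str, p: SineLiftParams, ds: DelaySpec) -> float:
    """Time at which the model curve first reaches the plateau weight ``m``."""
    if kind == "shift":
        return p.onset + ds.w_v * ds.delay + p.d
    if kind == "stretch":
        return p.onset + p.d + ds.w_v * ds.delay
    if kind == "sum":
        # w_v > 0: the visually delayed component is the last to saturate.
        if ds.w_v > 0:
            return p.onset + p.d + ds.delay
        return p.onset + p.d
    raise ValueError(f"unknown model kind {kind!r}")


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a duration or weight fit."""

    kind: str
    rmse: float
    n: int
    converged: bool
    d: float | None = None
    w_v: float | None = None


def _fit_window(
    times: np.ndarray, lf: np.ndarray, start: float, stop: float
) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    lf = np.asarray(lf, dtype=float)
    mask = (times >= start - 1e-12) & (times <= stop + 1e-12)
    t, y = times[mask], lf[mask]
    if t.size < 2:
        raise ValueError(
            f"fit window [{start}, {stop}] contains {t.size} samples; need >= 2"
        )
    return t, y


def fit_duration(
    times: np.ndarray,
    mean_lf: np.ndarray,
    m: float,
    gf_onset: float,
    liftoff: float,
    bounds: tuple[float, float] = (0.05, 3.0),
) -> FitResult:
    """Fit the loading duration ``d`` to an averaged no-delay curve.

    Minimises the RMSE between :func:`lf_curve` (onset fixed at
    ``gf_onset``, plateau fixed at ``m``) and the measured curve over the
    samples between grip-force onset and the lift-off detected on the
    averaged curve.  With zero delay all three model kinds coincide, so a
    single fit serves every model.
    """
    if liftoff <= gf_onset:
        raise ValueError("liftoff must come after gf_onset")
    t, y = _fit_window(times, mean_lf, gf_onset, liftoff)

    def objective(d: float) -> float:
        return rmse(y, lf_curve(SineLiftParams(m=m, d=d, onset=gf_onset), t))

    res = optimize.minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": 1e-8}
    )
    return FitResult(
        kind="base",
        d=float(res.x),
        rmse=float(res.fun),
        n=t.size,
        converged=bool(res.success),
    )


def fit_weight(
    times: np.ndarray,
    mean_lf_delay: np.ndarray,
    kind: str,
    p: SineLiftParams,
    delay: float,
    gf_onset: float | None = None,
    liftoff: float | None = None,
    bounds: tuple[float, float] | None = None,
) -> FitResult:
    """Fit the visual weight ``w_v`` of one delay model to a delay curve.

    ``p`` carries the duration ``d`` fitted on the matching no-delay curve
    and the onset of the delay curve.  The fit window runs from
    ``gf_onset`` (default ``p.onset``) to ``liftoff`` detected on the
    measured delay curve (default: last sample).  ``w_v`` is unconstrained
    by default (searched on a wide interval); pass ``bounds=(0, 1)`` to
    restrict it.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    start = p.onset if gf_onset is None else gf_onset
    stop = float(np.asarray(times)[-1]) if liftoff is None else liftoff
    t, y = _fit_window(times, mean_lf_delay, start, stop)
    search = (-2.0, 3.0) if bounds is None else bounds

    def objective(w_v: float) -> float:
        return rmse(y, model_curve(kind, p, DelaySpec(delay=delay, w_v=w_v), t))

    res = optimize.minimize_scalar(
        objective, bounds=search, method="bounded", options={"xatol": 1e-8}
    )
    return FitResult(
        kind=kind,
        w_v=float(res.x),
        d=p.d,
        rmse=float(res.fun),
        n=t.size,
        converged=bool(res.success),
    )


def compare_models(fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank the three model kinds per participant and condition by RMSE.

    Parameters
    ----------
    fits : DataFrame
        Tidy table with columns ``participant``, ``mass_g``, ``delay_ms``,
        ``kind``, ``w_v``, ``rmse`` (and optionally more), one row per fit.
        All three kinds must be present for each participant x condition.

    Returns
    -------
    per_condition, aggregate : DataFrame
        ``per_condition`` has one row per participant x condition with the
        RMSE of each kind, the best (lowest-RMSE) kind, and a ``tie`` flag.
        ``aggregate`` has one row per kind with mean RMSE, win counts, and
        mean fitted ``w_v``.
    """
    required = {"participant", "mass_g", "delay_ms", "kind", "rmse"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")

    rows = []
    keys = ["participant", "mass_g", "delay_ms"]
    for key, grp in fits.groupby(keys, sort=True):
        kinds = set(grp["kind"])
        if kinds != set(MODEL_KINDS):
            raise ValueError(
                f"condition {key} has kinds {sorted(kinds)}; need all of {MODEL_KINDS}"
            )
        by_kind = grp.set_index("kind")["rmse"]
        best_val = by_kind.min()
        winners = by_kind.index[np.isclose(by_kind.values, best_val, rtol=0, atol=1e-15)]
        rows.append(
            dict(
                zip(keys, key),
                rmse_shift=by_kind["shift"],
                rmse_stretch=by_kind["stretch"],
                rmse_sum=by_kind["sum"],
                best_kind=by_kind.idxmin(),
                tie=len(winners) > 1,
            )
        )
    per_condition = pd.DataFrame(rows)

    agg_rows = []
    for kind in MODEL_KINDS:
        sub = fits[fits["kind"] == kind]
        agg_rows.append(
            {
                "kind": kind,
                "mean_rmse": sub["rmse"].mean(),
                "wins": int((per_condition["best_kind"] == kind).sum()),
                "mean_w_v": sub["w_v"].mean() if "w_v" in sub.columns else np.nan,
            }
        )
    aggregate = pd.DataFrame(agg_rows)
    return per_condition, aggregate
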