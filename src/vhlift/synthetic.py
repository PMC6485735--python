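"""Synthetic lift trials, reach trajectories, and simulated observers.

Every downstream stage of the pipeline is testable against data generated
here: grip/load force traces built from the closed-form sigmoid curves in
:mod:`vhlift.models`, minimum-jerk reaches with delay-dependent curvature
and overshoot, and simulated observers for magnitude estimation and
two-interval heaviness comparison.

Generative conventions
----------------------
- Cube weight (N) = mass_g / 1000 * 9.81.
- The load-force curve follows the configured generative model (default
  ``sum``) with true duration ``d`` and visual weight ``w_v``; a brief
  negative pre-load dip is added just after contact.
- Grip force is an affine function of load force plus a fast baseline ramp
  at contact (so GF onset marks contact to within one sample) and a smooth
  delay-proportional increment after lift-off.
- All delay-dependent effects (force and kinematic) are gated by the
  visual weight: with ``true_w_v = 0`` vision is ignored and delayed trials
  are sample-identical to no-delay trials.
- Measurement noise is white Gaussian force noise shaped by the same 15-Hz
  zero-phase low-pass used in preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .models import DelaySpec, SineLiftParams, model_curve, model_liftoff_time
from .processing import ForceTrace, zero_phase_lowpass

__all__ = [
    "GRAVITY",
    "LiftSimConfig",
    "ObserverConfig",
    "TrialRecord",
    "ExperimentDesign",
    "make_design_exp1",
    "synth_lift_trial",
    "synth_reach",
    "simulate_rating",
    "simulate_choice",
    "simulate_experiment1",
]

GRAVITY = 9.81  # m/s^2

#: device constants retained as documentation for an optional physics mode
#: (forces are generated from the closed-form curves, not by integrating
#: the spring/damper dynamics)
DEVICE_STIFFNESS_N_PER_MM = 0.4
DEVICE_DAMPING_KG_PER_S = 2.0


@dataclass
class LiftSimConfig:
    """Configuration of one synthetic lift trial."""

    sampling_rate: float = 500.0  # Hz
    cube_mass: float = 200.0  # g
    visual_delay: float = 0.0  # ms
    true_duration_d: float = 0.4  # s
    true_w_v: float = 0.36
    generative_model: str = "sum"
    grip_gain: float = 1.5  # N grip per N load
    grip_baseline: float = 0.5  # N
    grip_ramp: float = 0.05  # s, duration of the baseline grip engagement
    post_liftoff_grip_increment_per_delay: float = 0.003  # N per ms of delay
    preload_dip: float = 0.2  # N, magnitude of the post-contact negative dip
    preload_dip_duration: float = 0.1  # s
    noise_sd: float = 0.0  # N
    hold_duration: float = 1.2  # s
    reach_amplitude: float = 200.0  # mm
    reach_duration: float = 0.8  # s
    delay_curvature_gain: float = 0.15  # mm per ms of delay
    delay_overshoot_gain: float = 0.05  # mm per ms of delay
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.cube_mass <= 0:
            raise ValueError("cube_mass must be positive")
        if self.true_duration_d <= 0:
            raise ValueError("true_duration_d must be positive")
        if not 0.0 <= self.true_w_v <= 1.0:
            raise ValueError("true_w_v must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.visual_delay < 0:
            raise ValueError("visual_delay must be non-negative")

    @property
    def cube_weight(self) -> float:
        """Cube weight as a force in newtons."""
        return self.cube_mass / 1000.0 * GRAVITY


@dataclass
class ObserverConfig:
    """A simulated observer for heaviness judgments.

    ``delay_heaviness_gain`` maps delay (ms) to the fractional increase in
    felt heaviness; ``judgment_sd`` is internal comparison noise in grams.
    The rating scale is participant-specific and removed by z-scoring.
    """

    delay_heaviness_gain: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 100.0: 0.04, 200.0: 0.18}
    )
    judgment_sd: float = 10.0  # g
    stevens_exponent: float = 1.45
    rating_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.judgment_sd < 0:
            raise ValueError("judgment_sd must be non-negative")
        if self.rating_scale <= 0:
            raise ValueError("rating_scale must be positive")
        if self.stevens_exponent <= 0:
            raise ValueError("stevens_exponent must be positive")

    def gain(self, delay_ms: float) -> float:
        return float(self.delay_heaviness_gain.get(float(delay_ms), 0.0))

    def felt_mass(self, mass_g: float, delay_ms: float) -> float:
        return mass_g * (1.0 + self.gain(delay_ms))


@dataclass
class TrialRecord:
    """A synthetic trial: trace plus ground-truth events and parameters."""

    trial_id: str
    participant_id: str
    mass_g: float
    delay_ms: float
    trace: ForceTrace
    truth_contact: float  # s; also the 0.1-N grip-onset crossing by design
    truth_liftoff: float  # s
    truth_lf_onset: float  # s; 0.1-N crossing of the clean load force
    truth_d: float
    truth_w_v: float
    truth_model: str
    valid: bool = True
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.truth_contact < self.truth_liftoff:
            raise ValueError("contact must precede lift-off")


@dataclass
class ExperimentDesign:
    """An ordered list of (participant, mass_g, delay_ms, repetition)."""

    trials: list[tuple[str, float, float, int]]
    seed: int
    label: str

    def __len__(self) -> int:
        return len(self.trials)

    def counts(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.trials, columns=["participant", "mass_g", "delay_ms", "repetition"]
        )
        return df.groupby(["mass_g", "delay_ms"]).size().rename("n").reset_index()


def make_design_exp1(
    seed: int,
    participant: str = "p01",
    masses: Sequence[float] = (100.0, 200.0, 300.0, 400.0),
    delays: Sequence[float] = (100.0, 200.0),
    n_no_delay: int = 40,
    n_delay: int = 10,
) -> ExperimentDesign:
    """Randomized single-participant design: per mass, ``n_no_delay`` trials
    at zero delay plus ``n_delay`` at each nonzero delay (defaults: 40 + 10
    + 10 per mass over four masses, 240 trials total)."""
    trials: list[tuple[str, float, float, int]] = []
    for mass in masses:
        rep = 0
        for _ in range(n_no_delay):
            trials.append((participant, float(mass), 0.0, rep))
            rep += 1
        for delay in delays:
            for _ in range(n_delay):
                trials.append((participant, float(mass), float(delay), rep))
                rep += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    return ExperimentDesign(trials=trials, seed=seed, label="exp1")


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def synth_reach(
    cfg: LiftSimConfig,
    times: np.ndarray | None = None,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-finger 3-D reach positions (mm) over ``times`` (s).

    The reach axis is y; fingers keep a fixed aperture along x; curvature
    appears as a perpendicular (z) deviation.  With zero delay gains the
    path is a straight minimum-jerk segment of length ``reach_amplitude``
    ending at the object contact position.  A visual delay (gated by the
    visual weight) bends the path and pushes the contact position farther
    along the reach axis (overshoot).

    Returns ``(thumb_pos, index_pos)`` of shape ``(n, 3)``.
    """
    if cfg.reach_amplitude <= 0 or cfg.reach_duration <= 0:
        raise ValueError("reach_amplitude and reach_duration must be positive")
    if times is None:
        times = np.arange(0.0, cfg.reach_duration + 0.5 / cfg.sampling_rate,
                          1.0 / cfg.sampling_rate)
    t = np.asarray(times, dtype=float)
    s = np.clip(t / cfg.reach_duration, 0.0, 1.0)
    effective_delay = cfg.visual_delay * cfg.true_w_v  # ms; vision-gated
    overshoot = cfg.delay_overshoot_gain * effective_delay
    y = (cfg.reach_amplitude + overshoot) * _minimum_jerk(s)
    z = cfg.delay_curvature_gain * effective_delay * np.sin(np.pi * s)
    base = start if start is not None else np.zeros(3)
    aperture = 50.0  # mm between fingertips across the grip axis
    thumb = np.column_stack([np.full_like(y, -aperture / 2), y, z]) + base
    index = np.column_stack([np.full_like(y, +aperture / 2), y, z]) + base
    return thumb, index


def synth_lift_trial(
    cfg: LiftSimConfig,
    rng: np.random.Generator | None = None,
    participant_id: str = "p01",
    trial_id: str = "t000",
    start_offset_mm: float = 0.0,
) -> TrialRecord:
    """Generate one lift trial from the closed-form generative model.

    Timeline: a short stationary baseline, the reach, contact at ``t0``,
    the loading phase (model curve plus pre-load dip), and a hold at the
    plateau weight until the end of the trace.

    The baseline grip engages with a minimum-jerk ramp timed so that the
    grip force crosses the 0.1-N onset threshold exactly at ``t0``, the
    onset of the load-force curve: GF onset is the contact marker the
    analysis aligns on, so the generative contact and the detectable
    contact coincide by construction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sampling_rate
    delay_s = cfg.visual_delay / 1000.0
    m = cfg.cube_weight

    params = SineLiftParams(m=m, d=cfg.true_duration_d)
    ds = DelaySpec(delay=delay_s, w_v=cfg.true_w_v)
    loading_span = model_liftoff_time(cfg.generative_model, params, ds) - params.onset
    if cfg.hold_duration < loading_span:
        raise ValueError(
            f"hold_duration {cfg.hold_duration} s is shorter than the generated "
            f"loading phase {loading_span:.3f} s"
        )

    pre = 0.1  # s stationary before the reach
    t0 = round((pre + cfg.reach_duration) / dt) * dt  # contact, on-grid
    total = t0 + loading_span + cfg.hold_duration
    n = int(round(total / dt)) + 1
    time = np.arange(n) * dt
    tau = time - t0

    lift_params = SineLiftParams(m=m, d=cfg.true_duration_d, onset=t0)

    def clean_lf(t: np.ndarray) -> np.ndarray:
        out = model_curve(cfg.generative_model, lift_params, ds, t)
        if cfg.preload_dip > 0:
            rel = np.asarray(t, dtype=float) - t0
            in_dip = (rel >= 0) & (rel <= cfg.preload_dip_duration)
            out = out - np.where(
                in_dip,
                cfg.preload_dip
                * np.sin(np.pi * rel / cfg.preload_dip_duration) ** 2,
                0.0,
            )
        return out

    lf = clean_lf(time)

    # grip: baseline min-jerk engagement crossing 0.1 N at t0 + load coupling
    onset_frac = min(0.1 / cfg.grip_baseline, 1.0)
    s_cross = float(
        optimize.brentq(lambda s: _minimum_jerk(np.array([s]))[0] - onset_frac, 0, 1)
    )
    ramp_start = t0 - s_cross * cfg.grip_ramp
    ramp = _minimum_jerk(np.clip((time - ramp_start) / cfg.grip_ramp, 0.0, 1.0))
    gf = cfg.grip_baseline * ramp + cfg.grip_gain * np.maximum(lf, 0.0)

    # delay-proportional grip increment after lift-off, gated by w_v
    truth_liftoff = t0 + loading_span
    increment = (
        cfg.post_liftoff_grip_increment_per_delay * cfg.visual_delay * cfg.true_w_v
    )
    if increment > 0:
        rise = np.clip((time - truth_liftoff) / 0.2, 0.0, 1.0)
        gf = gf + increment * _minimum_jerk(rise)

    thumb_vertical = 0.5 * lf
    index_vertical = 0.5 * lf
    thumb_normal = gf.copy()
    index_normal = gf.copy()

    if cfg.noise_sd > 0:
        channels = [thumb_vertical, index_vertical, thumb_normal, index_normal]
        for i, ch in enumerate(channels):
            noise = zero_phase_lowpass(
                rng.normal(0.0, cfg.noise_sd, size=n), cfg.sampling_rate
            )
            channels[i] = ch + noise
        thumb_vertical, index_vertical, thumb_normal, index_normal = channels

    # ground-truth LF onset: 0.1-N crossing of the clean curve on a fine grid
    fine = np.arange(t0, t0 + loading_span, dt / 20.0)
    fine_lf = clean_lf(fine)
    hits = np.nonzero(fine_lf >= 0.1 - 1e-12)[0]
    truth_lf_onset = float(fine[hits[0]]) if hits.size else float("nan")

    # positions: stationary, reach, then parked at the contact position
    start = np.array([start_offset_mm, 0.0, 0.0])
    reach_times = np.clip(time - pre, 0.0, cfg.reach_duration)
    thumb_pos, index_pos = synth_reach(cfg, times=reach_times, start=start)

    trace = ForceTrace(
        time=time,
        thumb_normal=thumb_normal,
        index_normal=index_normal,
        thumb_vertical=thumb_vertical,
        index_vertical=index_vertical,
        thumb_pos=thumb_pos,
        index_pos=index_pos,
        mass_g=cfg.cube_mass,
        delay_ms=cfg.visual_delay,
        participant_id=participant_id,
        trial_id=trial_id,
    )
    return TrialRecord(
        trial_id=trial_id,
        participant_id=participant_id,
        mass_g=cfg.cube_mass,
        delay_ms=cfg.visual_delay,
        trace=trace,
        truth_contact=t0,
        truth_liftoff=truth_liftoff,
        truth_lf_onset=truth_lf_onset,
        truth_d=cfg.true_duration_d,
        truth_w_v=cfg.true_w_v,
        truth_model=cfg.generative_model,
    )


def simulate_rating(
    obs: ObserverConfig, mass_g: float, delay_ms: float, rng: np.random.Generator
) -> float:
    """Magnitude-estimation rating: a power law of the felt mass on the
    observer's private scale.  Strictly positive."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    felt = obs.felt_mass(mass_g, delay_ms)
    if obs.judgment_sd > 0:
        felt = felt + rng.normal(0.0, obs.judgment_sd)
    felt = max(felt, 1e-6)
    return obs.rating_scale * felt**obs.stevens_exponent


def simulate_choice(
    obs: ObserverConfig,
    first: tuple[float, float],
    second: tuple[float, float],
    rng: np.random.Generator,
) -> str:
    """Two-interval heaviness comparison; returns ``"first"`` or ``"second"``.

    Each interval's felt weight is mass * (1 + gain(delay)) plus Gaussian
    noise; exact ties are broken by a coin flip.
    """
    felts = []
    for mass_g, delay_ms in (first, second):
        if mass_g <= 0:
            raise ValueError("mass must be positive")
        felt = obs.felt_mass(mass_g, delay_ms)
        if obs.judgment_sd > 0:
            felt = felt + rng.normal(0.0, obs.judgment_sd)
        felts.append(felt)
    if felts[0] > felts[1]:
        return "first"
    if felts[1] > felts[0]:
        return "second"
    return "first" if rng.random() < 0.5 else "second"


def simulate_experiment1(
    design: ExperimentDesign,
    cfg: LiftSimConfig,
    obs: ObserverConfig,
    seed: int | None = None,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Run every trial of a design: traces plus a magnitude-estimation table.

    Returns the trial records and a tidy ratings DataFrame with columns
    ``participant``, ``trial_id``, ``mass_g``, ``delay_ms``, ``rating``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[TrialRecord] = []
    rating_rows = []
    for i, (participant, mass, delay, _rep) in enumerate(design.trials):
        trial_cfg = _replace(cfg, cube_mass=mass, visual_delay=delay)
        trial_id = f"{participant}-{design.label}-{i:04d}"
        rec = synth_lift_trial(
            trial_cfg, rng=rng, participant_id=participant, trial_id=trial_id
        )
        records.append(rec)
        rating_rows.append(
            {
                "participant": participant,
                "trial_id": trial_id,
                "mass_g": mass,
                "delay_ms": delay,
                "rating": simulate_rating(obs, mass, delay, rng),
            }
        )
    return records, pd.DataFrame(rating_rows)
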