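"""Magnitude-estimation z-scoring, the interleaved one-up/one-down
staircase, the weighted cumulative-Gaussian psychometric fit, and the
total-bias computation.

The psychometric curve is fitted on the percentage scale::

    P(x) = 50 + 50 * erf((x - mu) / (sigma * sqrt(2)))

with each test-mass level weighted by its presentation count.  The total
perceptual bias of a delay level combines the two session PSEs
(standard-delayed and test-delayed) as half their difference, expressed as
a percentage of the 200-g standard; session biases beyond the largest
representable value (45% of the standard for the 110-290-g test range) are
clamped to that maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .synthetic import ObserverConfig, simulate_choice

__all__ = [
    "ZScoreSummary",
    "StaircaseSession",
    "PsychometricData",
    "PsychometricFit",
    "BiasResult",
    "PsychometricFitError",
    "zscore_ratings",
    "staircase_next",
    "run_session",
    "psychometric_pct",
    "fit_psychometric",
    "total_bias",
]

STANDARD_MASS = 200.0  # g
TEST_MASS_MIN = 110.0  # g
TEST_MASS_MAX = 290.0  # g
STEP = 15.0  # g
COMPARISON_BUDGET = 15
#: largest session bias expressible as % of the standard mass
MAX_BIAS_PCT = (TEST_MASS_MAX - STANDARD_MASS) / STANDARD_MASS * 100.0  # 45%


class PsychometricFitError(RuntimeError):
    """Raised when psychometric data cannot support a fit."""


@dataclass
class ZScoreSummary:
    """Per participant x mass x delay mean z-scored rating."""

    table: pd.DataFrame  # columns participant, mass_g, delay_ms, mean_z


def zscore_ratings(ratings: pd.DataFrame) -> ZScoreSummary:
    """z-score each participant's ratings over all their trials, then
    average within participant x mass x delay cells.

    ``ratings`` needs columns ``participant``, ``mass_g``, ``delay_ms``,
    ``rating``.  Raises ``ValueError`` for a participant with zero rating
    variance (z-scores undefined).
    """
    required = {"participant", "mass_g", "delay_ms", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    df = ratings.copy()
    out = []
    for participant, grp in df.groupby("participant"):
        if grp["rating"].nunique() < 2:
            raise ValueError(
                f"participant {participant!r} has zero rating variance; "
                "z-scores are undefined"
            )
        z = stats.zscore(grp["rating"].to_numpy(), ddof=0)
        sub = grp.assign(z=z)
        cell = (
            sub.groupby(["mass_g", "delay_ms"])["z"]
            .mean()
            .rename("mean_z")
            .reset_index()
        )
        cell.insert(0, "participant", participant)
        out.append(cell)
    return ZScoreSummary(table=pd.concat(out, ignore_index=True))


@dataclass
class StaircaseSession:
    """State of one two-chain interleaved staircase session.

    ``delay_placement`` says which interval carries the visual delay:
    ``"standard"`` (the 200-g standard is delayed) or ``"test"``.
    """

    delay_placement: str
    delay_level: float  # ms
    standard_mass: float = STANDARD_MASS
    step: float = STEP
    bounds: tuple[float, float] = (TEST_MASS_MIN, TEST_MASS_MAX)
    comparisons_budget: int = COMPARISON_BUDGET
    chain_masses: list[float] = field(
        default_factory=lambda: [TEST_MASS_MIN, TEST_MASS_MAX]
    )
    active_chain: int = 0
    history: list[tuple[int, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.delay_placement not in ("standard", "test"):
            raise ValueError("delay_placement must be 'standard' or 'test'")

    @property
    def exhausted(self) -> bool:
        return len(self.history) >= self.comparisons_budget

    @property
    def current_test_mass(self) -> float:
        return self.chain_masses[self.active_chain]

    def pse_estimate(self) -> float:
        """Mean of the two chains' converged (next-to-present) masses."""
        return float(np.mean(self.chain_masses))


def staircase_next(session: StaircaseSession, response: str) -> float:
    """Record a response for the active chain and return the next test mass.

    ``response`` is ``"test_heavier"`` (step the chain down) or
    ``"test_lighter"`` (step up).  Steps saturate at the 110/290-g bounds;
    chains alternate strictly.
    """
    if session.exhausted:
        raise RuntimeError("staircase budget exhausted")
    if response not in ("test_heavier", "test_lighter"):
        raise ValueError(f"bad response {response!r}")
    chain = session.active_chain
    mass = session.chain_masses[chain]
    session.history.append((chain, mass, response))
    delta = -session.step if response == "test_heavier" else session.step
    lo, hi = session.bounds
    session.chain_masses[chain] = float(np.clip(mass + delta, lo, hi))
    session.active_chain = 1 - chain
    return session.current_test_mass


@dataclass
class PsychometricData:
    """Per-test-mass response counts from one session."""

    masses: np.ndarray  # g, ascending
    n_presented: np.ndarray
    n_test_heavier: np.ndarray
    n_lifts: int = 0

    @property
    def pct_test_heavier(self) -> np.ndarray:
        return 100.0 * self.n_test_heavier / self.n_presented


def run_session(
    obs: ObserverConfig,
    session: StaircaseSession,
    rng: np.random.Generator,
) -> PsychometricData:
    """Run a full staircase session against a simulated observer.

    Each comparison presents the standard and the test cube in random
    order (two lifts), with the visual delay on the interval named by
    ``session.delay_placement``; the observer's choice drives the
    staircase.  Terminates after the comparison budget (15 comparisons,
    30 lifts).
    """
    session.active_chain = int(rng.integers(2))
    n_lifts = 0
    while not session.exhausted:
        test_mass = session.current_test_mass
        standard = (
            session.standard_mass,
            session.delay_level if session.delay_placement == "standard" else 0.0,
        )
        test = (
            test_mass,
            session.delay_level if session.delay_placement == "test" else 0.0,
        )
        test_first = bool(rng.integers(2))
        first, second = (test, standard) if test_first else (standard, test)
        choice = simulate_choice(obs, first, second, rng)
        n_lifts += 2
        test_chosen = (choice == "first") == test_first
        staircase_next(
            session, "test_heavier" if test_chosen else "test_lighter"
        )

    hist = pd.DataFrame(session.history, columns=["chain", "mass_g", "response"])
    counts = hist.groupby("mass_g").agg(
        n_presented=("response", "size"),
        n_test_heavier=("response", lambda r: int((r == "test_heavier").sum())),
    )
    counts = counts.sort_index()
    return PsychometricData(
        masses=counts.index.to_numpy(dtype=float),
        n_presented=counts["n_presented"].to_numpy(),
        n_test_heavier=counts["n_test_heavier"].to_numpy(),
        n_lifts=n_lifts,
    )


@dataclass(frozen=True)
class PsychometricFit:
    mu: float  # g
    sigma: float  # g
    weights: np.ndarray
    residual: float  # weighted RMS residual, percentage points

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def psychometric_pct(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Cumulative-Gaussian percentage curve, 0-100 scale."""
    x = np.asarray(x, dtype=float)
    return 50.0 + 50.0 * special.erf((x - mu) / (sigma * np.sqrt(2.0)))


def fit_psychometric(data: PsychometricData) -> PsychometricFit:
    """Weighted least-squares fit of the percentage curve.

    Points are weighted by presentation count (levels never presented are
    simply absent).  Degenerate data — fewer than two levels, or every
    response identical — raise :class:`PsychometricFitError`.
    """
    mask = data.n_presented > 0
    x = np.asarray(data.masses, dtype=float)[mask]
    n = np.asarray(data.n_presented, dtype=float)[mask]
    pct = 100.0 * np.asarray(data.n_test_heavier, dtype=float)[mask] / n
    if x.size < 2:
        raise PsychometricFitError("need at least two test-mass levels with data")
    if np.all(pct == pct[0]):
        raise PsychometricFitError(
            f"all responses identical ({pct[0]:.0f}%); PSE is not identified"
        )

    # initial mu: interpolated 50% crossing; sigma: quarter of the span
    order = np.argsort(x)
    xs, ps = x[order], pct[order]
    if np.any(ps <= 50.0) and np.any(ps >= 50.0):
        mu0 = float(np.interp(50.0, ps, xs)) if np.all(np.diff(ps) >= 0) else float(
            np.average(xs, weights=n[order])
        )
    else:
        mu0 = float(np.average(xs, weights=n[order]))
    sigma0 = max((xs[-1] - xs[0]) / 4.0, 5.0)

    popt, _ = optimize.curve_fit(
        psychometric_pct,
        x,
        pct,
        p0=[mu0, sigma0],
        sigma=1.0 / np.sqrt(n),
        absolute_sigma=False,
        bounds=([0.0, 0.5], [400.0, 500.0]),
        maxfev=10000,
    )
    mu, sigma = float(popt[0]), float(popt[1])
    resid = psychometric_pct(x, mu, sigma) - pct
    wrms = float(np.sqrt(np.average(resid**2, weights=n)))
    return PsychometricFit(mu=mu, sigma=sigma, weights=n, residual=wrms)


@dataclass(frozen=True)
class BiasResult:
    mu_standard_delay: float  # g
    mu_test_delay: float  # g
    total_bias: float  # % of the standard mass; positive = delayed heavier
    clamped: bool


def total_bias(
    fit_standard_delay: PsychometricFit,
    fit_test_delay: PsychometricFit,
    standard_mass: float = STANDARD_MASS,
    max_bias_pct: float = MAX_BIAS_PCT,
) -> BiasResult:
    """Combine the two session PSEs into the total perceptual bias.

    Session biases are ``(mu - standard)`` as a percentage of the standard;
    a session bias whose magnitude exceeds ``max_bias_pct`` (the largest
    value the test-mass range can express) is clamped to ``+-max_bias_pct``
    first.  The total bias is half the difference between the
    standard-delay and test-delay session biases.
    """
    clamped = False

    def session_bias(mu: float) -> float:
        nonlocal clamped
        bias = (mu - standard_mass) / standard_mass * 100.0
        if abs(bias) > max_bias_pct:
            clamped = True
            bias = float(np.sign(bias)) * max_bias_pct
        return bias

    b_sd = session_bias(fit_standard_delay.mu)
    b_td = session_bias(fit_test_delay.mu)
    return BiasResult(
        mu_standard_delay=fit_standard_delay.mu,
        mu_test_delay=fit_test_delay.mu,
        total_bias=(b_sd - b_td) / 2.0,
        clamped=clamped,
    )
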