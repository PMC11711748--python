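"""Virtual observers: the synthetic stand-in for human participants.

A :class:`VirtualObserver` is a generative model of one walker on the
split-belt treadmill: a true detection threshold per perturbation direction,
a Weibull response model with lapses, a per-trial non-response probability,
and a steps-to-response latency distribution.  :func:`sample_population` draws
a cohort whose thresholds have the statistical structure the downstream
analysis assumes — lognormal between-participant spread (5th–95th percentile
ratio around 7), a high latent correlation between increase and decrease
thresholds, and a mild negative coupling between threshold and response
latency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .exceptions import ParameterError, ParseError
from .quest import psychometric

__all__ = [
    "VirtualObserver",
    "PopulationSpec",
    "TrialRecord",
    "sample_population",
    "p_correct",
    "simulate_trial",
    "write_population",
    "read_population",
]

DIRECTIONS = ("increase", "decrease")
SIDES = ("left", "right")

#: response window: number of steps after perturbation onset within which a
#: button press counts; reaching it without a press is a non-response.
RESPONSE_WINDOW_STEPS = 10
#: the on-screen left-or-right question appears three steps after onset, so
#: no response can be earlier than step 3.
LATENCY_FLOOR_STEPS = 3


@dataclass(frozen=True)
class VirtualObserver:
    """Generative parameters of one simulated participant."""

    threshold_inc: float
    threshold_dec: float
    slope: float = 3.5
    lapse: float = 0.02
    guess: float = 0.5
    p_nonresponse: float = 0.026
    latency_mean: float = 5.11
    latency_sd: float = 1.8

    def __post_init__(self) -> None:
        for name in ("threshold_inc", "threshold_dec"):
            v = getattr(self, name)
            if not (0.0 < v < 0.9):
                raise ParameterError(f"{name} must be in (0, 0.9), got {v}")
        if not (0.0 <= self.lapse <= 0.1):
            raise ParameterError(f"lapse must be in [0, 0.1], got {self.lapse}")
        if not (0.0 < self.guess < 1.0):
            raise ParameterError(f"guess must be in (0, 1), got {self.guess}")
        if not (0.0 <= self.p_nonresponse <= 0.2):
            raise ParameterError(f"p_nonresponse must be in [0, 0.2], got {self.p_nonresponse}")
        if not (3.0 <= self.latency_mean <= 10.0):
            raise ParameterError(f"latency_mean must be in [3, 10], got {self.latency_mean}")
        if not self.latency_sd >= 0:
            raise ParameterError(f"latency_sd must be >= 0, got {self.latency_sd}")
        if not self.slope > 0:
            raise ParameterError(f"slope must be > 0, got {self.slope}")

    def threshold(self, direction: str) -> float:
        _check_direction(direction)
        return self.threshold_inc if direction == "increase" else self.threshold_dec


@dataclass(frozen=True)
class PopulationSpec:
    """Between-participant distribution of observer parameters.

    ``sigma_log`` controls the lognormal spread of thresholds; the default
    0.59 gives a 95th/5th percentile ratio of ``exp(2 * 1.645 * 0.59) ~ 7``.
    ``rho_types`` is the latent (log-scale) correlation between an
    individual's increase and decrease thresholds; ``rho_latency`` the latent
    correlation between log-threshold and mean response latency (negative:
    slower responders tend to have lower thresholds).
    """

    n: int = 48
    median_threshold: float = 0.06
    sigma_log: float = 0.59
    rho_types: float = 0.8
    rho_latency: float = -0.3
    latency_between_sd: float = 1.0
    lapse: float = 0.02
    p_nonresponse: float = 0.026
    latency_mean: float = 5.11
    latency_sd: float = 1.8
    slope: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if self.sigma_log < 0:
            raise ParameterError(f"sigma_log must be >= 0, got {self.sigma_log}")
        for name in ("rho_types", "rho_latency"):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [-1, 1], got {v}")
        if not (0.0 < self.median_threshold < 0.9):
            raise ParameterError(f"median_threshold must be in (0, 0.9), got {self.median_threshold}")
        if self.latency_between_sd < 0:
            raise ParameterError(f"latency_between_sd must be >= 0, got {self.latency_between_sd}")


@dataclass(frozen=True)
class TrialRecord:
    """One perturbation trial as logged by the session layer."""

    direction: str        # "increase" | "decrease"
    side: str             # perturbed belt: "left" | "right"
    intensity_mps: float  # magnitude of the speed difference, m/s
    response: str         # reported faster side, or "none" for a non-response
    correct: bool
    steps_to_response: int

    @property
    def responded(self) -> bool:
        return self.response != "none"

    def faster_side(self) -> str:
        """Which belt actually ran faster on this trial.

        An *increase* perturbation speeds up the perturbed belt, so the
        perturbed side is the faster one; a *decrease* slows it down, so the
        faster belt is the opposite, unperturbed side.
        """
        return faster_side(self.direction, self.side)


def faster_side(direction: str, perturbed_side: str) -> str:
    _check_direction(direction)
    if perturbed_side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}, got {perturbed_side!r}")
    if direction == "increase":
        return perturbed_side
    return "left" if perturbed_side == "right" else "right"


def sample_population(spec: PopulationSpec, rng: np.random.Generator | None = None) -> list[VirtualObserver]:
    """Draw ``spec.n`` observers; fully reproducible given ``spec.seed``.

    Thresholds: bivariate lognormal with common median, shape ``sigma_log``
    and log-scale correlation ``rho_types``.  Latency means: normal around
    ``spec.latency_mean`` with SD ``latency_between_sd``, correlated with the
    (common) log-threshold factor at ``rho_latency`` and truncated to the
    [3, 10]-step response window.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rt, rl = spec.rho_types, spec.rho_latency
    corr = np.array([[1.0, rt, rl], [rt, 1.0, rl], [rl, rl, 1.0]])
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < -1e-10:
        raise ParameterError(
            f"rho_types={rt}, rho_latency={rl} give a non-positive-semidefinite latent covariance"
        )
    chol_cov = corr + np.eye(3) * max(0.0, -evals.min() + 1e-12)
    z = rng.multivariate_normal(np.zeros(3), chol_cov, size=spec.n, method="cholesky")
    thr_inc = np.clip(spec.median_threshold * np.exp(spec.sigma_log * z[:, 0]), 0.005, 0.895)
    thr_dec = np.clip(spec.median_threshold * np.exp(spec.sigma_log * z[:, 1]), 0.005, 0.895)
    latency = np.clip(spec.latency_mean + spec.latency_between_sd * z[:, 2], 3.0, 10.0)
    return [
        VirtualObserver(
            threshold_inc=float(thr_inc[i]),
            threshold_dec=float(thr_dec[i]),
            slope=spec.slope,
            lapse=spec.lapse,
            p_nonresponse=spec.p_nonresponse,
            latency_mean=float(latency[i]),
            latency_sd=spec.latency_sd,
        )
        for i in range(spec.n)
    ]


def p_correct(observer: VirtualObserver, delta_v: float, direction: str) -> float:
    """Probability the observer reports the faster belt correctly.

    Same Weibull family as the staircase's psychometric function, evaluated at
    the observer's own threshold for the given direction (the observer's lapse
    and slope stand in for the staircase's delta and beta).
    """
    if delta_v < 0:
        raise ParameterError(f"delta_v must be >= 0, got {delta_v}")
    model = SimpleNamespace(beta=observer.slope, delta=observer.lapse, gamma=observer.guess,
                            scale="log")
    return float(psychometric(delta_v, observer.threshold(direction), model))


def simulate_trial(
    observer: VirtualObserver,
    delta_v: float,
    direction: str,
    side: str,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate one 2AFC perturbation trial.

    With probability ``p_nonresponse`` the observer never presses a button:
    the trial is logged with response ``"none"``, counted incorrect, and
    assigned the full 10-step window as its step count (excluded from latency
    averages downstream).  Otherwise correctness is Bernoulli in
    :func:`p_correct`, the reported side follows from correctness and the true
    faster belt, and the latency is a rounded truncated normal on the integer
    steps [3, 10].
    """
    _check_direction(direction)
    fast = faster_side(direction, side)
    if rng.random() < observer.p_nonresponse:
        return TrialRecord(direction, side, float(delta_v), "none", False, RESPONSE_WINDOW_STEPS)
    correct = bool(rng.random() < p_correct(observer, delta_v, direction))
    response = fast if correct else ("left" if fast == "right" else "right")
    steps = _draw_latency(observer.latency_mean, observer.latency_sd, rng)
    return TrialRecord(direction, side, float(delta_v), response, correct, steps)


def _draw_latency(mean: float, sd: float, rng: np.random.Generator) -> int:
    """Integer steps-to-response: truncated normal on [2.5, 10.5), rounded."""
    if sd == 0:
        x = mean
    else:
        a = ndtr((2.5 - mean) / sd)
        b = ndtr((10.49 - mean) / sd)
        u = rng.uniform(a, b)
        x = mean + sd * float(ndtri(u))
    return int(min(max(round(x), LATENCY_FLOOR_STEPS), RESPONSE_WINDOW_STEPS))


def write_population(observers: list[VirtualObserver], path) -> None:
    """One row per observer, all generative parameters, full precision."""
    df = pd.DataFrame([asdict(o) for o in observers])
    df.insert(0, "observer", np.arange(len(observers)))
    df.to_csv(path, index=False)


def read_population(path) -> list[VirtualObserver]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {f.name for f in fields(VirtualObserver)}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"population file missing columns: {sorted(missing)}")
    return [
        VirtualObserver(**{name: row[name] for name in required})
        for _, row in df.iterrows()
    ]


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ParameterError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
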