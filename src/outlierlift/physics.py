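"""Clamped-spring release dynamics and per-trial feedback.

On each trial the participant stretches a spring attached to the top of a
clamped object; on release the object hangs from the spring and its motion
follows a mass-spring-damper.  The spring length that exactly counteracts a
weight is m*g/k.  Feedback is computed from the signed spring-length error
e = set length - equilibrium length (cm): a points score from an inverted
truncated quadratic, y = 100*(1 - min(|e/2.5|^2, 1)) rounded to the nearest
integer, and a release-phase duration t = 1 + 5*min(|e/6|^2, 1) seconds.

Units: k is interpreted as 100 N/m, c as 3 N*s/m, masses in grams at the
interface (kg internally); lengths are reported in cm, which puts the
equilibrium lengths of the 300-800 g objects at 2.9-7.8 cm, commensurate
with the 2.5 cm and 6 cm error scales of the feedback functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PhysicsParams:
    """Spring-mass-damper constants (SI convention)."""

    k: float = 100.0  # N/m
    c: float = 3.0  # N*s/m
    g: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("spring stiffness k must be positive")
        if self.c < 0:
            raise ValueError("damping coefficient c must be non-negative")
        if self.g <= 0:
            raise ValueError("gravitational acceleration g must be positive")


DEFAULT_PARAMS = PhysicsParams()


def equilibrium_length(mass_g: float, params: PhysicsParams = DEFAULT_PARAMS) -> float:
    """Spring length (cm) that exactly counteracts ``mass_g`` grams: m*g/k."""
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    return (mass_g / 1000.0) * params.g / params.k * 100.0


def score_points(e_cm: float) -> int:
    """Points for spring-length error ``e_cm``: 100*(1 - min(|e/2.5|^2, 1)).

    Rounded half-away-from-zero to the nearest integer; even in e; 0 beyond
    |e| = 2.5 cm.
    """
    if not math.isfinite(e_cm):
        raise ValueError("error must be finite")
    y = 100.0 * (1.0 - min(abs(e_cm / 2.5) ** 2, 1.0))
    return int(math.floor(y + 0.5))


def time_penalty(e_cm: float) -> float:
    """Release-phase duration (s): 1 + 5*min(|e/6|^2, 1), in [1, 6]."""
    if not math.isfinite(e_cm):
        raise ValueError("error must be finite")
    return 1.0 + 5.0 * min(abs(e_cm / 6.0) ** 2, 1.0)


def _free_decay(x0_m: float, t: np.ndarray, mass_kg: float, params: PhysicsParams) -> np.ndarray:
    """Closed-form damped-oscillator solution x(t), x(0)=x0, x'(0)=0.

    Handles the underdamped, critically damped, and overdamped branches
    (the task's 300-800 g objects are all underdamped at k=100, c=3).
    """
    w0 = math.sqrt(params.k / mass_kg)
    zeta = params.c / (2.0 * math.sqrt(params.k * mass_kg))
    if zeta < 1.0:
        wd = w0 * math.sqrt(1.0 - zeta * zeta)
        env = np.exp(-zeta * w0 * t)
        return env * (x0_m * np.cos(wd * t) + (zeta * w0 * x0_m / wd) * np.sin(wd * t))
    if zeta == 1.0:
        return (x0_m + w0 * x0_m * t) * np.exp(-w0 * t)
    disc = math.sqrt(zeta * zeta - 1.0)
    r1 = -w0 * (zeta - disc)
    r2 = -w0 * (zeta + disc)
    a = x0_m * r2 / (r2 - r1)
    b = -x0_m * r1 / (r2 - r1)
    return a * np.exp(r1 * t) + b * np.exp(r2 * t)


@dataclass(frozen=True)
class ReleaseOutcome:
    """Feedback quantities for one release."""

    error_cm: float
    times_s: np.ndarray
    positions_cm: np.ndarray  # object vertical offset from its clamped position
    points: int
    penalty_s: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times_s, "position_cm": self.positions_cm})


def simulate_release(
    mass_g: float,
    set_length_cm: float,
    params: PhysicsParams = DEFAULT_PARAMS,
    duration_s: float = 3.0,
    step_s: float = 0.01,
) -> ReleaseOutcome:
    """Analytic release trajectory plus score and time penalty.

    The object starts at rest at its clamped position with the spring
    stretched to ``set_length_cm``; the new equilibrium sits ``e`` above it,
    where e = set length - m*g/k.  The vertical offset u(t) therefore starts
    at 0 and relaxes to e through the damped-oscillator solution.
    """
    if set_length_cm < 0:
        raise ValueError("set_length must be non-negative")
    if step_s <= 0:
        raise ValueError("step must be positive")
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    eq_cm = equilibrium_length(mass_g, params)
    e_cm = set_length_cm - eq_cm
    t = np.arange(0.0, duration_s + 0.5 * step_s, step_s)
    # displacement from final equilibrium; initial displacement is -e
    x = _free_decay(-e_cm / 100.0, t, mass_g / 1000.0, params)
    positions_cm = (e_cm / 100.0 + x) * 100.0
    return ReleaseOutcome(
        error_cm=e_cm,
        times_s=t,
        positions_cm=positions_cm,
        points=score_points(e_cm),
        penalty_s=time_penalty(e_cm),
    )


def perturb_mass(mass_g: float, halfwidth_g: float, rng: np.random.Generator) -> float:
    """Uniform weight perturbation on [mass - halfwidth, mass + halfwidth]."""
    if halfwidth_g < 0:
        raise ValueError("halfwidth must be non-negative")
    if halfwidth_g == 0:
        return mass_g
    m = rng.uniform(mass_g - halfwidth_g, mass_g + halfwidth_g)
    if m <= 0:
        raise ValueError("perturbed mass must remain positive")
    return m


#: Speeded-response time limit (s); applies after the first 12 trials.
SPEEDED_LIMIT_S = 2.25
SPEEDED_FREE_TRIALS = 12


@dataclass(frozen=True)
class SpeededOutcome:
    timed_out: bool
    points_delta: int
    timeout_duration_s: float


def speeded_outcome(response_time_s: float, prior_timeouts: int = 0) -> SpeededOutcome:
    """Timeout rule for the speeded condition.

    Exceeding the 2.25 s limit costs 100 points and a timeout that starts at
    6 s and grows by 2 s with each subsequent violation.
    """
    if response_time_s < 0:
        raise ValueError("response time must be non-negative")
    if response_time_s > SPEEDED_LIMIT_S:
        return SpeededOutcome(True, -100, 6.0 + 2.0 * prior_timeouts)
    return SpeededOutcome(False, 0, 0.0)
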