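"""Synthetic behavioral cohorts with a latent categorical-encoding strength.

The generative model is deliberately minimal plumbing, not a fitted model of
real participants: it exists so that the exclusion rules, the encoding
metric, and the Bayesian comparisons can be exercised and validated by
parameter recovery.  Each synthetic participant carries a latent
categorical-encoding strength (``latent_ce``, percent).  Family responses
converge exponentially from the family-mean spring length to the
participant's internal linear size->length category line; outlier responses
mix the category-line prediction (weight ``latent_ce``/100) with the true
equilibrium length.  Unexplained error experienced on outlier trials pulls
the category line multiplicatively toward the outlier (gain
``category_update_gain``), mimicking the observed upward drift of the family
regression.  Gaussian motor noise is added to every spring-length response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .conditions import ConditionSpec, TrialSchedule, generate_schedule
from .physics import (
    DEFAULT_PARAMS,
    PhysicsParams,
    SPEEDED_FREE_TRIALS,
    equilibrium_length,
    perturb_mass,
    score_points,
    speeded_outcome,
)

#: Column schema shared by all trial tables in this package.
TRIAL_COLUMNS = (
    "participant",
    "condition",
    "trial",
    "block",
    "object_height_cm",
    "object_mass_g",
    "spring_length_cm",
    "response_time_s",
    "points",
    "is_outlier",
)


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of one synthetic participant.

    latent_ce: categorical-encoding strength in percent [0, 100].
    motor_noise_sd: Gaussian response noise, cm.
    learning_rate: per-trial exponential rate of early family acquisition.
    category_update_gain: fractional pull of unexplained outlier error on the
        category line (0 freezes the line).
    rt_log_mean, rt_log_sd: log-normal response-time parameters (log-seconds).
    """

    latent_ce: float = 80.0
    motor_noise_sd: float = 0.5
    learning_rate: float = 0.15
    category_update_gain: float = 0.01
    rt_log_mean: float = float(np.log(2.33))
    rt_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.latent_ce <= 100.0:
            raise ValueError("latent_ce must lie in [0, 100]")
        for name in ("motor_noise_sd", "learning_rate", "category_update_gain", "rt_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def default_params(spec: ConditionSpec, **overrides) -> BehaviorParams:
    """Condition-aware defaults (speeded cohorts respond faster)."""
    p = BehaviorParams()
    if spec.speeded:
        p = replace(p, rt_log_mean=float(np.log(1.42)))
    return replace(p, **overrides) if overrides else p


def _true_family_line(spec: ConditionSpec, physics: PhysicsParams) -> tuple[float, float]:
    """OLS fit of true equilibrium length on height over the family objects."""
    h = np.array([o.height_cm for o in spec.family])
    y = np.array([equilibrium_length(o.mass_g, physics) for o in spec.family])
    slope, intercept = np.polyfit(h, y, 1)
    return float(slope), float(intercept)


def simulate_participant(
    spec: ConditionSpec,
    params: BehaviorParams,
    seed: int,
    participant_id: str = "S000",
    physics: PhysicsParams = DEFAULT_PARAMS,
    schedule: TrialSchedule | None = None,
) -> pd.DataFrame:
    """Simulate one participant's trial table.

    The trial schedule is generated from ``seed`` (or supplied); response
    noise, weight perturbations and response times come from an independent
    stream spawned from the same seed, so identical seeds give byte-identical
    tables.
    """
    ss = np.random.SeedSequence(seed)
    sched_ss, noise_ss = ss.spawn(2)
    if schedule is None:
        schedule = generate_schedule(spec, int(sched_ss.generate_state(1)[0] % (2**31)))
    rng = np.random.default_rng(noise_ss)

    slope_t, icept_t = _true_family_line(spec, physics)
    h_out = spec.outlier.height_cm
    e_out_true = equilibrium_length(spec.outlier.mass_g, physics)
    fam_mean_len = float(
        np.mean([equilibrium_length(o.mass_g, physics) for o in spec.family])
    )
    ce = params.latent_ce / 100.0
    line_scale = 1.0  # multiplicative drift of the category line

    # family learning is complete once the outlier phase (or, in Concurrent,
    # the analysis half of the session) begins
    learn_until = spec.outlier_intro_trial if spec.outlier_intro_trial > 0 else spec.n_trials // 2

    rows = []
    n_timeouts = 0
    for entry in schedule.entries:
        obj = entry.obj
        t0 = entry.trial - 1  # trials completed before this one
        conv = 1.0 if t0 >= learn_until else 1.0 - np.exp(-params.learning_rate * t0)

        def line(h: float) -> float:
            return line_scale * (slope_t * h + icept_t)

        presented_mass = perturb_mass(obj.mass_g, spec.mass_noise_halfwidth, rng)
        if obj.is_outlier:
            target = ce * line(h_out) + (1.0 - ce) * e_out_true
        else:
            target = line(obj.height_cm)
        planned = (1.0 - conv) * fam_mean_len + conv * target
        response = max(planned + rng.normal(0.0, params.motor_noise_sd), 0.0)

        rt = float(rng.lognormal(params.rt_log_mean, params.rt_log_sd))
        eq_presented = equilibrium_length(presented_mass, physics)
        points = score_points(response - eq_presented)
        if spec.speeded and entry.trial > SPEEDED_FREE_TRIALS:
            out = speeded_outcome(rt, n_timeouts)
            if out.timed_out:
                n_timeouts += 1
                points = -100

        if obj.is_outlier and params.category_update_gain > 0:
            # credit assignment: only error unexplained by the plan updates
            # the category line (scales slope and intercept together)
            err = eq_presented - response
            line_scale += params.category_update_gain * err / (slope_t * h_out + icept_t)

        rows.append(
            (
                participant_id,
                spec.name,
                entry.trial,
                entry.block,
                obj.height_cm,
                presented_mass,
                response,
                rt,
                points,
                obj.is_outlier,
            )
        )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


ParamsSampler = Callable[[np.random.Generator], BehaviorParams]


def simulate_cohort(
    spec: ConditionSpec,
    params: BehaviorParams | ParamsSampler,
    n: int = 20,
    seed: int = 0,
    physics: PhysicsParams = DEFAULT_PARAMS,
) -> list[pd.DataFrame]:
    """Simulate ``n`` independent participants.

    ``params`` may be a fixed ``BehaviorParams`` (degenerate sampler) or a
    callable drawing one ``BehaviorParams`` per participant from a
    participant-level distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    tables = []
    for i, child in enumerate(children):
        p_rng = np.random.default_rng(child)
        p = params(p_rng) if callable(params) else params
        part_seed = int(child.generate_state(1)[0] % (2**31))
        tables.append(
            simulate_participant(
                spec, p, part_seed, participant_id=f"S{i:03d}", physics=physics
            )
        )
    return tables


def normal_ce_sampler(
    mean: float, sd: float, base: BehaviorParams | None = None
) -> ParamsSampler:
    """Participant-level sampler: latent_ce ~ Normal(mean, sd) clipped to [0, 100]."""
    base = base or BehaviorParams()

    def sample(rng: np.random.Generator) -> BehaviorParams:
        ce = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        return replace(base, latent_ce=ce)

    return sample


def simulate_low_effort_participant(
    spec: ConditionSpec,
    seed: int,
    mode: str = "max",
    participant_id: str = "BAD",
    physics: PhysicsParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """A non-compliant responder: constant maximal (or minimal) spring stretch.

    Emulates the low-effort strategies that participant-level screening must
    flag (one participant stretching the spring to its maximum on every
    trial, another barely stretching it).
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    schedule = generate_schedule(spec, seed)
    level = 12.0 if mode == "max" else 0.05
    rng = np.random.default_rng(seed)
    rows = []
    for entry in schedule.entries:
        response = level + rng.normal(0.0, 0.01)
        eq = equilibrium_length(entry.obj.mass_g, physics)
        rows.append(
            (
                participant_id,
                spec.name,
                entry.trial,
                entry.block,
                entry.obj.height_cm,
                entry.obj.mass_g,
                max(response, 0.0),
                float(rng.lognormal(np.log(1.0), 0.2)),
                score_points(response - eq),
                entry.obj.is_outlier,
            )
        )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def fixture_table(seed: int = 7, n: int = 4, condition: str = "same_color") -> list[pd.DataFrame]:
    """Small deterministic cohort for unit tests (noise-free apart from motor noise)."""
    from .conditions import make_condition

    spec = make_condition(condition)
    params = BehaviorParams(latent_ce=75.0, motor_noise_sd=0.3)
    return simulate_cohort(spec, params, n=n, seed=seed)
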