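"""Condition specifications and randomized trial schedules for the outlier paradigm.

The task presents a "family" of constant-density cylinders (size linearly
related to weight) plus a single denser "outlier" of intermediate size.
Twelve conditions manipulate color similarity, family cardinality, outlier
frequency, family structure (linear vs. sigmoidal), introduction history,
weight noise, display persistence, and time pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: Cylinder radius shared by all objects (cm).
OBJECT_RADIUS_CM = 3.5

#: Standard object set: heights 5-9 cm; family weighs 300/400/600/700 g,
#: the middle (7 cm) object is the 800 g outlier.
STANDARD_HEIGHTS = (5.0, 6.0, 7.0, 8.0, 9.0)
STANDARD_MASSES = (300.0, 400.0, 800.0, 600.0, 700.0)
SIGMOIDAL_MASSES = (300.0, 320.0, 800.0, 680.0, 700.0)
SMALL_FAMILY_HEIGHTS = (6.0, 7.0, 8.0)
SMALL_FAMILY_MASSES = (400.0, 800.0, 600.0)

CONDITION_NAMES = (
    "same_color",
    "similar_colors",
    "distinct_colors",
    "small_family",
    "frequent_outlier",
    "nonlinear",
    "concurrent",
    "added_noise",
    "one_by_one",
    "speeded_response",
    "nonlinear_plus",
    "concurrent_plus",
)


@dataclass(frozen=True)
class ObjectSpec:
    """One cylinder: geometry, nominal mass, and outlier status."""

    height_cm: float
    mass_g: float
    is_outlier: bool = False
    radius_cm: float = OBJECT_RADIUS_CM

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError(f"height must be positive, got {self.height_cm}")
        if self.mass_g <= 0:
            raise ValueError(f"mass must be positive, got {self.mass_g}")


@dataclass(frozen=True)
class ConditionSpec:
    """Full specification of one experimental condition.

    ``outlier_intro_trial`` is the 0-based trial index at which the outlier
    may first appear (40 for sequential conditions, 0 for Concurrent).
    ``color_scheme`` is metadata only; colors never enter the physics.
    """

    name: str
    objects: tuple[ObjectSpec, ...]
    n_trials: int = 100
    outlier_intro_trial: int = 40
    outlier_per_block: int = 1
    mass_noise_halfwidth: float = 0.0
    speeded: bool = False
    persistent_display: bool = True
    color_scheme: str = "same"

    def __post_init__(self) -> None:
        n_out = sum(o.is_outlier for o in self.objects)
        if n_out != 1:
            raise ValueError(f"exactly one outlier required, got {n_out}")
        if self.mass_noise_halfwidth < 0:
            raise ValueError("mass_noise_halfwidth must be >= 0")
        if self.outlier_per_block not in (1, 3):
            raise ValueError("outlier_per_block must be 1 or 3")
        # Pre-phase must be whole family blocks; post-phase whole mixed blocks.
        if self.outlier_intro_trial % self.n_family:
            raise ValueError("pre-phase is not a whole number of family blocks")
        if (self.n_trials - self.outlier_intro_trial) % self.post_block_size:
            raise ValueError("post-phase is not a whole number of blocks")

    @property
    def family(self) -> tuple[ObjectSpec, ...]:
        return tuple(o for o in self.objects if not o.is_outlier)

    @property
    def outlier(self) -> ObjectSpec:
        return next(o for o in self.objects if o.is_outlier)

    @property
    def n_family(self) -> int:
        return len(self.family)

    @property
    def post_block_size(self) -> int:
        return self.n_family + self.outlier_per_block

    @property
    def n_pre_blocks(self) -> int:
        return self.outlier_intro_trial // self.n_family

    @property
    def n_post_blocks(self) -> int:
        return (self.n_trials - self.outlier_intro_trial) // self.post_block_size

    @property
    def n_blocks(self) -> int:
        return self.n_pre_blocks + self.n_post_blocks

    @property
    def first_outlier_block(self) -> int:
        """1-based index of the first block that can contain the outlier."""
        return self.n_pre_blocks + 1

    def block_composition(self, block: int) -> dict[ObjectSpec, int]:
        """Scheduled presentation count per object in 1-based ``block``."""
        if not 1 <= block <= self.n_blocks:
            raise ValueError(f"block {block} out of range 1..{self.n_blocks}")
        counts = {o: 1 for o in self.family}
        if block >= self.first_outlier_block:
            counts[self.outlier] = self.outlier_per_block
        return counts

    def to_config(self) -> dict:
        """Structured, serializable form (plain scalars and lists)."""
        return {
            "name": self.name,
            "objects": [
                {
                    "height_cm": o.height_cm,
                    "mass_g": o.mass_g,
                    "is_outlier": o.is_outlier,
                    "radius_cm": o.radius_cm,
                }
                for o in self.objects
            ],
            "n_trials": self.n_trials,
            "outlier_intro_trial": self.outlier_intro_trial,
            "outlier_per_block": self.outlier_per_block,
            "mass_noise_halfwidth": self.mass_noise_halfwidth,
            "speeded": self.speeded,
            "persistent_display": self.persistent_display,
            "color_scheme": self.color_scheme,
        }


def _objects(heights, masses, outlier_mass: float = 800.0) -> tuple[ObjectSpec, ...]:
    return tuple(
        ObjectSpec(height_cm=h, mass_g=m, is_outlier=(m == outlier_mass))
        for h, m in zip(heights, masses, strict=True)
    )


def make_condition(name: str) -> ConditionSpec:
    """Build the specification for one of the 12 named conditions.

    Raises ``ValueError`` listing the valid identifiers for an unknown name.
    """
    if name not in CONDITION_NAMES:
        raise ValueError(
            f"unknown condition {name!r}; valid names: {', '.join(CONDITION_NAMES)}"
        )
    std = _objects(STANDARD_HEIGHTS, STANDARD_MASSES)
    if name == "same_color":
        return ConditionSpec(name=name, objects=std, color_scheme="same")
    if name == "similar_colors":
        return ConditionSpec(name=name, objects=std, color_scheme="similar")
    if name == "distinct_colors":
        return ConditionSpec(name=name, objects=std, color_scheme="distinct")
    if name == "small_family":
        # Pre-phase stays 40 family-only trials (20 blocks of 2), then 20
        # blocks of 3 including the outlier: 100 trials total.
        return ConditionSpec(
            name=name,
            objects=_objects(SMALL_FAMILY_HEIGHTS, SMALL_FAMILY_MASSES),
            color_scheme="same",
        )
    if name == "frequent_outlier":
        # 10 family blocks of 4, then 9 blocks of 7 (4 family + 3 outlier)
        # giving the 3:4 outlier:family ratio and 103 trials.
        return ConditionSpec(
            name=name, objects=std, n_trials=103, outlier_per_block=3,
            color_scheme="same",
        )
    if name == "nonlinear":
        return ConditionSpec(
            name=name,
            objects=_objects(STANDARD_HEIGHTS, SIGMOIDAL_MASSES),
            color_scheme="same",
        )
    if name == "nonlinear_plus":
        return ConditionSpec(
            name=name,
            objects=_objects(STANDARD_HEIGHTS, SIGMOIDAL_MASSES),
            color_scheme="distinct",
        )
    if name == "concurrent":
        return ConditionSpec(
            name=name, objects=std, outlier_intro_trial=0, color_scheme="same"
        )
    if name == "concurrent_plus":
        return ConditionSpec(
            name=name, objects=std, outlier_intro_trial=0, color_scheme="distinct"
        )
    if name == "added_noise":
        return ConditionSpec(
            name=name, objects=std, mass_noise_halfwidth=150.0,
            color_scheme="distinct",
        )
    if name == "one_by_one":
        return ConditionSpec(
            name=name, objects=std, persistent_display=False,
            color_scheme="distinct",
        )
    if name == "speeded_response":
        return ConditionSpec(
            name=name, objects=std, speeded=True, color_scheme="distinct"
        )
    raise AssertionError("unreachable")


def all_conditions() -> Iterator[ConditionSpec]:
    for name in CONDITION_NAMES:
        yield make_condition(name)


@dataclass(frozen=True)
class ScheduleEntry:
    trial: int  # 1-based
    block: int  # 1-based
    obj: ObjectSpec


@dataclass(frozen=True)
class TrialSchedule:
    """Randomized presentation order for one participant."""

    entries: tuple[ScheduleEntry, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [e.trial for e in self.entries],
                "block": [e.block for e in self.entries],
                "object_height_cm": [e.obj.height_cm for e in self.entries],
                "object_mass_g": [e.obj.mass_g for e in self.entries],
                "is_outlier": [e.obj.is_outlier for e in self.entries],
            }
        )


_MAX_BLOCK_ATTEMPTS = 10_000


def generate_schedule(spec: ConditionSpec, seed: int) -> TrialSchedule:
    """Randomize the within-block object order under the repeat constraints.

    Every block presents each family object once (plus ``outlier_per_block``
    outlier presentations from the outlier's introduction onward).  The last
    object of block *t* never opens block *t*+1.  Consecutive outlier
    presentations within a block are possible only when the block contains
    several (Frequent Outlier).  Uses rejection sampling of within-block
    permutations; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    entries: list[ScheduleEntry] = []
    prev_last: ObjectSpec | None = None
    trial = 1
    for block in range(1, spec.n_blocks + 1):
        pool: list[ObjectSpec] = []
        for obj, count in spec.block_composition(block).items():
            pool.extend([obj] * count)
        if len(set(pool)) == 1 and spec.n_blocks > 1:
            raise ValueError(
                "boundary constraint unsatisfiable: single distinct object per block"
            )
        for _ in range(_MAX_BLOCK_ATTEMPTS):
            order = [pool[i] for i in rng.permutation(len(pool))]
            if prev_last is not None and order[0] is prev_last:
                continue
            break
        else:
            raise RuntimeError("could not satisfy block-boundary constraint")
        for obj in order:
            entries.append(ScheduleEntry(trial=trial, block=block, obj=obj))
            trial += 1
        prev_last = order[-1]
    assert len(entries) == spec.n_trials
    return TrialSchedule(entries=tuple(entries), seed=seed)


@dataclass(frozen=True)
class AnalysisWindows:
    """Block windows used by the categorical-encoding analysis.

    ``post_blocks``: family-regression window (all blocks after the first
    outlier-containing block; blocks 12-22 in the standard design).
    ``pre_blocks``: pre-outlier window for the slope-shift analysis (second
    half of the pre-phase; blocks 6-10 in the standard design).
    ``screen_blocks``: window over which mean family responses feed
    participant-level exclusion (first outlier block onward).
    ``outlier_after_trial``: outlier responses enter the metric only from
    trials strictly after this 1-based trial index (the very first outlier
    presentation, or the end of block 10 in the Concurrent conditions).
    """

    pre_blocks: range
    post_blocks: range
    screen_blocks: range
    outlier_after_trial: int | None
    outlier_blocks: range


def analysis_windows(spec: ConditionSpec) -> AnalysisWindows:
    last = spec.n_blocks
    if spec.outlier_intro_trial == 0:
        # Concurrent: outlier present throughout; analysis uses the second
        # half of the experiment (after block 10).
        half = spec.n_blocks // 2
        return AnalysisWindows(
            pre_blocks=range(half // 2 + 1, half + 1),
            post_blocks=range(half + 1, last + 1),
            screen_blocks=range(half + 1, last + 1),
            outlier_after_trial=None,
            outlier_blocks=range(half + 1, last + 1),
        )
    npre = spec.n_pre_blocks
    first_out = spec.first_outlier_block
    return AnalysisWindows(
        pre_blocks=range(npre // 2 + 1, npre + 1),
        post_blocks=range(first_out + 1, last + 1),
        screen_blocks=range(first_out, last + 1),
        outlier_after_trial=None,  # resolved per schedule: first outlier trial
        outlier_blocks=range(first_out + 1, last + 1),
    )


def outlier_window_mask(table: pd.DataFrame, spec: ConditionSpec) -> pd.Series:
    """Boolean mask of the outlier trials entering the encoding metric.

    Sequential conditions: all outlier trials strictly after the very first
    outlier presentation.  Concurrent conditions: outlier trials after the
    tenth block.
    """
    is_out = table["is_outlier"].astype(bool)
    if spec.outlier_intro_trial == 0:
        win = analysis_windows(spec)
        return is_out & table["block"].isin(win.outlier_blocks)
    if not is_out.any():
        return is_out
    first_trial = table.loc[is_out, "trial"].min()
    return is_out & (table["trial"] > first_trial)
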