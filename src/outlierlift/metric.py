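"""Exclusion rules and the strength-of-categorical-encoding metric.

The per-participant metric compares the mean anticipatory spring length for
the outlier object against the value predicted for the outlier's height by
a linear regression fit to the family-object responses (the
"family-predicted" length), normalized by the true separation between the
outlier's equilibrium length and the length it would have as a true family
member:

    ce% = 100 * (1 - (outlier_mean - family_predicted)
                     / (true_outlier - true_family_predicted))

100% means the outlier response sits on the family regression line (pure
categorical encoding, no learning of the outlier); 0% means both the family
and the outlier were learned perfectly.

Robust exclusion uses the scaled median absolute deviation (MAD x 1.4826,
the normal-consistency convention): single-pass trial exclusion at 4 scaled
MADs per participant x family object (never applied to outlier trials), and
participant exclusion at 5 scaled MADs of the cohort's mean family response
over the post-introduction window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import ConditionSpec, analysis_windows, outlier_window_mask
from .physics import DEFAULT_PARAMS, PhysicsParams, equilibrium_length

logger = logging.getLogger(__name__)

#: Normal-consistency constant for the scaled MAD.
MAD_SCALE = 1.4826
TRIAL_MAD_THRESHOLD = 4.0
PARTICIPANT_MAD_THRESHOLD = 5.0
_MIN_CELL_TRIALS = 3


def scaled_mad(values) -> float:
    """1.4826 * median(|x - median(x)|) over finite values."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("scaled_mad requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("scaled_mad requires finite values")
    med = np.median(x)
    return float(MAD_SCALE * np.median(np.abs(x - med)))


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of an exclusion pass."""

    flags: pd.Series  # boolean, aligned to the input index
    reasons: dict
    n_flagged: int
    fraction: float


def exclude_trials(table: pd.DataFrame) -> ExclusionReport:
    """Flag family-object responses beyond 4 scaled MADs of their cell median.

    Cells are (participant implicit: one table) x family object.  Outlier
    trials are never flagged, since learning can change outlier responses
    abruptly.  Single pass: medians/MADs are not recomputed after flagging.
    Cells with fewer than 3 trials are exempt (the MAD is degenerate) and
    logged.
    """
    flags = pd.Series(False, index=table.index)
    reasons: dict = {}
    fam = table.loc[~table["is_outlier"].astype(bool)]
    for height, cell in fam.groupby("object_height_cm"):
        if len(cell) < _MIN_CELL_TRIALS:
            logger.warning(
                "cell with %d trial(s) at height %.1f cm exempt from exclusion",
                len(cell), height,
            )
            continue
        vals = cell["spring_length_cm"].to_numpy()
        med = np.median(vals)
        smad = scaled_mad(vals)
        bad = np.abs(vals - med) > TRIAL_MAD_THRESHOLD * smad
        flags.loc[cell.index[bad]] = True
        for idx in cell.index[bad]:
            reasons[idx] = f"height {height:.1f} cm: > {TRIAL_MAD_THRESHOLD:g} scaled MADs"
    n = int(flags.sum())
    return ExclusionReport(flags=flags, reasons=reasons, n_flagged=n,
                           fraction=n / max(len(table), 1))


def exclude_participants(
    tables: list[pd.DataFrame], spec: ConditionSpec
) -> ExclusionReport:
    """Flag participants whose mean family response over the screening window
    lies beyond 5 scaled MADs of the cohort median."""
    if len(tables) < 3:
        raise ValueError("participant exclusion requires at least 3 participants")
    win = analysis_windows(spec)
    ids, means = [], []
    for t in tables:
        fam = t[(~t["is_outlier"].astype(bool)) & t["block"].isin(win.screen_blocks)]
        ids.append(t["participant"].iloc[0])
        means.append(float(fam["spring_length_cm"].mean()))
    means_arr = np.asarray(means)
    med = np.median(means_arr)
    smad = scaled_mad(means_arr)
    bad = np.abs(means_arr - med) > PARTICIPANT_MAD_THRESHOLD * smad
    flags = pd.Series(bad, index=pd.Index(ids, name="participant"))
    reasons = {
        pid: f"mean family response {m:.2f} cm > {PARTICIPANT_MAD_THRESHOLD:g} scaled MADs from median {med:.2f}"
        for pid, m, b in zip(ids, means, bad) if b
    }
    n = int(bad.sum())
    return ExclusionReport(flags=flags, reasons=reasons, n_flagged=n,
                           fraction=n / len(tables))


def family_regression(
    table: pd.DataFrame, window: range
) -> tuple[float, float, float]:
    """OLS of family spring length (cm) on object height (cm) over ``window``.

    Returns (slope, intercept, R^2).  The caller applies trial exclusion
    first; rows passed in are taken as-is.
    """
    fam = table[(~table["is_outlier"].astype(bool)) & table["block"].isin(window)]
    if fam.empty:
        raise ValueError("family regression window contains no family trials")
    heights = fam["object_height_cm"].to_numpy(dtype=float)
    if np.unique(heights).size < 2:
        raise ValueError("family regression needs at least two distinct heights")
    res = stats.linregress(heights, fam["spring_length_cm"].to_numpy(dtype=float))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass(frozen=True)
class EncodingResult:
    """Per-participant categorical-encoding summary."""

    participant: str
    slope: float
    intercept: float
    r_squared: float
    outlier_mean_response: float
    family_predicted: float
    true_outlier_length: float
    true_family_predicted: float
    ce_percent: float
    n_trials_excluded: int


def true_family_prediction(
    spec: ConditionSpec, physics: PhysicsParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """(true outlier equilibrium length, family-line prediction at the
    outlier's height), both cm, from the nominal masses."""
    h = np.array([o.height_cm for o in spec.family])
    y = np.array([equilibrium_length(o.mass_g, physics) for o in spec.family])
    slope, intercept = np.polyfit(h, y, 1)
    return (
        equilibrium_length(spec.outlier.mass_g, physics),
        float(slope * spec.outlier.height_cm + intercept),
    )


def encoding_strength(
    table: pd.DataFrame,
    spec: ConditionSpec,
    physics: PhysicsParams = DEFAULT_PARAMS,
    apply_trial_exclusion: bool = True,
) -> EncodingResult:
    """Strength of categorical encoding for one participant's table."""
    report = exclude_trials(table) if apply_trial_exclusion else None
    clean = table.loc[~report.flags] if report is not None else table

    win = analysis_windows(spec)
    out_mask = outlier_window_mask(clean, spec)
    out_responses = clean.loc[out_mask, "spring_length_cm"]
    if len(out_responses) < 1:
        raise ValueError("outlier analysis window is empty (outlier presented < 2 times?)")
    slope, intercept, r2 = family_regression(clean, win.post_blocks)
    family_predicted = slope * spec.outlier.height_cm + intercept
    true_out, true_fam = true_family_prediction(spec, physics)
    denom = true_out - true_fam
    if abs(denom) < 1e-12:
        raise ValueError("degenerate design: outlier equals its family prediction")
    outlier_mean = float(out_responses.mean())
    ce = 100.0 * (1.0 - (outlier_mean - family_predicted) / denom)
    return EncodingResult(
        participant=str(table["participant"].iloc[0]),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        outlier_mean_response=outlier_mean,
        family_predicted=float(family_predicted),
        true_outlier_length=true_out,
        true_family_predicted=true_fam,
        ce_percent=float(ce),
        n_trials_excluded=report.n_flagged if report is not None else 0,
    )


def family_predicted_equals_family_mean_check(
    table: pd.DataFrame, spec: ConditionSpec, tol: float = 1e-9
) -> bool | None:
    """For the symmetric standard design, the regression prediction at the
    outlier's height equals the mean family response.

    Requires family heights symmetric about the outlier height and equal
    per-object trial counts in the regression window; otherwise the check is
    skipped (returns ``None``).  Returns ``True``/``False`` for the identity
    at tolerance ``tol`` cm.
    """
    win = analysis_windows(spec)
    fam = table[(~table["is_outlier"].astype(bool)) & table["block"].isin(win.post_blocks)]
    heights = np.array([o.height_cm for o in spec.family])
    if abs(float(np.mean(heights)) - spec.outlier.height_cm) > 1e-12:
        return None
    counts = fam.groupby("object_height_cm").size()
    if counts.nunique() != 1:
        return None
    slope, intercept, _ = family_regression(table, win.post_blocks)
    pred = slope * spec.outlier.height_cm + intercept
    return bool(abs(pred - fam["spring_length_cm"].mean()) < tol)


def slope_shift(
    table: pd.DataFrame, spec: ConditionSpec, apply_trial_exclusion: bool = True
) -> tuple[float, float, float]:
    """Family-regression slopes before and after the outlier's introduction.

    Returns (pre_slope, post_slope, post - pre) over the pre-outlier window
    (blocks 6-10 in the standard design) and the post-introduction window
    (blocks 12-22).  A positive shift indicates the outlier pulled the
    category line upward.
    """
    if apply_trial_exclusion:
        table = table.loc[~exclude_trials(table).flags]
    win = analysis_windows(spec)
    pre, _, _ = family_regression(table, win.pre_blocks)
    post, _, _ = family_regression(table, win.post_blocks)
    return pre, post, post - pre


def bootstrap_sem(values, reps: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of the mean: SD of resampled means."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap_sem requires at least 2 values")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    return float(np.std(x[idx].mean(axis=1), ddof=1))


def cohort_encoding(
    tables: list[pd.DataFrame],
    spec: ConditionSpec,
    physics: PhysicsParams = DEFAULT_PARAMS,
    apply_participant_exclusion: bool = True,
) -> pd.DataFrame:
    """Per-participant encoding results for a cohort, after both exclusion
    stages (trials first, then participants)."""
    if apply_participant_exclusion and len(tables) >= 3:
        prt = exclude_participants(tables, spec)
        kept = [t for t in tables if not prt.flags.loc[t["participant"].iloc[0]]]
    else:
        kept = tables
    rows = [encoding_strength(t, spec, physics) for t in kept]
    return pd.DataFrame(
        {
            "participant": [r.participant for r in rows],
            "ce_percent": [r.ce_percent for r in rows],
            "slope": [r.slope for r in rows],
            "intercept": [r.intercept for r in rows],
            "r_squared": [r.r_squared for r in rows],
            "outlier_mean_response": [r.outlier_mean_response for r in rows],
            "family_predicted": [r.family_predicted for r in rows],
            "n_trials_excluded": [r.n_trials_excluded for r in rows],
        }
    )
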