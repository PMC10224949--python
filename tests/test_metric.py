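"""Exclusion rules and the categorical-encoding metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from outlierlift import (
    BehaviorParams,
    ConditionSpec,
    ObjectSpec,
    bootstrap_sem,
    encoding_strength,
    exclude_participants,
    exclude_trials,
    family_regression,
    make_condition,
    scaled_mad,
    simulate_cohort,
    simulate_participant,
    slope_shift,
)
from outlierlift.conditions import analysis_windows
from outlierlift.metric import (
    family_predicted_equals_family_mean_check,
    true_family_prediction,
)


class TestScaledMad:
    def test_constant_input_is_zero(self):
        assert scaled_mad([5, 5, 5, 5]) == 0.0

    def test_hand_computed_example(self):
        # median 3, |dev| = [2,1,0,1,97], median dev 1
        assert scaled_mad([1, 2, 3, 4, 100]) == pytest.approx(1.4826)

    def test_consistent_for_standard_normal(self, rng):
        x = rng.standard_normal(100_000)
        assert scaled_mad(x) == pytest.approx(1.0, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scaled_mad([])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=20),
        st.floats(-50, 50),
        st.floats(0.1, 10),
    )
    def test_affine_equivariance(self, xs, shift, scale):
        base = scaled_mad(xs)
        assert scaled_mad([x + shift for x in xs]) == pytest.approx(base, abs=1e-8)
        assert scaled_mad([x * scale for x in xs]) == pytest.approx(scale * base, rel=1e-9, abs=1e-8)


def _flat_table(std_spec, seed=11, noise=0.1):
    """Stationary clean table: responses on the family line plus small noise,
    with no learning transient (the transient is itself a legitimate target
    of the MAD rule, so these tests build it out)."""
    from outlierlift import generate_schedule

    from outlierlift import equilibrium_length

    df = generate_schedule(std_spec, seed).to_frame()
    rng = np.random.default_rng(seed)
    h = np.array([o.height_cm for o in std_spec.family])
    y = np.array([equilibrium_length(o.mass_g) for o in std_spec.family])
    b, a = np.polyfit(h, y, 1)
    resp = b * df["object_height_cm"] + a + rng.normal(0, noise, len(df))
    resp[df["is_outlier"]] = b * std_spec.outlier.height_cm + a
    return pd.DataFrame(
        {
            "participant": "S000",
            "condition": std_spec.name,
            "trial": df["trial"],
            "block": df["block"],
            "object_height_cm": df["object_height_cm"],
            "object_mass_g": df["object_mass_g"],
            "spring_length_cm": resp,
            "response_time_s": 2.0,
            "points": 50,
            "is_outlier": df["is_outlier"],
        }
    )


class TestTrialExclusion:
    def test_clean_table_has_no_flags(self, std_spec):
        t = _flat_table(std_spec)
        assert exclude_trials(t).n_flagged == 0

    def test_injected_spike_is_flagged_exactly(self, std_spec):
        t = _flat_table(std_spec)
        idx = t.index[(~t["is_outlier"]) & (t["block"] > 12)][0]
        t.loc[idx, "spring_length_cm"] += 30.0
        report = exclude_trials(t)
        assert report.n_flagged == 1
        assert report.flags.loc[idx]

    def test_outlier_object_trials_never_flagged(self, std_spec):
        t = _flat_table(std_spec)
        out_idx = t.index[t["is_outlier"]]
        t.loc[out_idx, "spring_length_cm"] += 50.0  # huge spike on every outlier trial
        assert exclude_trials(t).n_flagged == 0

    def test_small_cells_exempt(self, std_spec, caplog):
        t = _flat_table(std_spec).head(8)  # two blocks: 2 trials per object
        with caplog.at_level("WARNING"):
            report = exclude_trials(t)
        assert report.n_flagged == 0
        assert "exempt" in caplog.text

    def test_exclusion_fraction_small_on_clean_cohorts(self, std_spec):
        tables = simulate_cohort(std_spec, BehaviorParams(latent_ce=80.0), n=10, seed=21)
        total = sum(len(t) for t in tables)
        flagged = sum(exclude_trials(t).n_flagged for t in tables)
        assert flagged / total < 0.08


class TestParticipantExclusion:
    def test_homogeneous_cohort_unflagged(self, std_spec):
        tables = simulate_cohort(std_spec, BehaviorParams(latent_ce=80.0), n=8, seed=2)
        assert exclude_participants(tables, std_spec).n_flagged == 0

    def test_fewer_than_three_rejected(self, std_spec):
        tables = simulate_cohort(std_spec, BehaviorParams(), n=2, seed=2)
        with pytest.raises(ValueError):
            exclude_participants(tables, std_spec)


class TestFamilyRegression:
    def test_exact_line_recovered(self, std_spec):
        t = simulate_participant(
            std_spec, BehaviorParams(latent_ce=50.0, motor_noise_sd=0.0, category_update_gain=0.0), seed=1
        )
        win = analysis_windows(std_spec)
        slope, intercept, r2 = family_regression(t, win.post_blocks)
        # true family line: equilibrium length 0.981*h/... fitted on 300..700 g
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope * 7 + intercept == pytest.approx(true_family_prediction(std_spec)[1], abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        spec = make_condition("same_color")
        win = analysis_windows(spec)
        for _ in range(20):
            t = simulate_participant(
                spec, BehaviorParams(latent_ce=60.0, motor_noise_sd=0.6), seed=int(rng.integers(1 << 30))
            )
            slope, intercept, r2 = family_regression(t, win.post_blocks)
            fam = t[(~t["is_outlier"]) & t["block"].isin(win.post_blocks)]
            x = fam["object_height_cm"].to_numpy()
            y = fam["spring_length_cm"].to_numpy()
            X = np.column_stack([x, np.ones_like(x)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            ss_res = np.sum((y - X @ beta) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            assert slope == pytest.approx(beta[0], abs=1e-10)
            assert intercept == pytest.approx(beta[1], abs=1e-10)
            assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_sigmoidal_targets_fit_imperfectly(self):
        spec = make_condition("nonlinear")
        # noiseless responder at the true equilibrium lengths of the
        # sigmoidal family: a line cannot fit them exactly
        t = simulate_participant(
            spec, BehaviorParams(latent_ce=0.0, motor_noise_sd=0.0, category_update_gain=0.0), seed=1
        )
        win = analysis_windows(spec)
        fam = t[(~t["is_outlier"]) & t["block"].isin(win.post_blocks)].copy()
        heights = {o.height_cm: o.mass_g for o in spec.family}
        from outlierlift import equilibrium_length

        fam["spring_length_cm"] = fam["object_height_cm"].map(
            lambda h: equilibrium_length(heights[h])
        )
        t.loc[fam.index, "spring_length_cm"] = fam["spring_length_cm"]
        _, _, r2 = family_regression(t, win.post_blocks)
        assert r2 < 1.0 - 1e-6

    def test_empty_window_rejected(self, std_spec):
        t = _flat_table(std_spec)
        with pytest.raises(ValueError):
            family_regression(t, range(50, 60))


class TestEncodingStrength:
    def test_midpoint_response_gives_50_percent(self, std_spec):
        """Outlier response halfway between family prediction and truth -> 50%."""
        t = simulate_participant(
            std_spec, BehaviorParams(latent_ce=50.0, motor_noise_sd=0.0, category_update_gain=0.0), seed=2
        )
        res = encoding_strength(t, std_spec)
        midpoint = 0.5 * (res.family_predicted + res.true_outlier_length)
        assert res.outlier_mean_response == pytest.approx(midpoint, abs=1e-9)
        assert res.ce_percent == pytest.approx(50.0, abs=1e-9)

    def test_normalization_arithmetic(self, std_spec):
        """ce% = 100*(1 - 1.5/3.0) = 50 for a 1.5 cm residual over a 3.0 cm gap."""
        t = simulate_participant(
            std_spec, BehaviorParams(latent_ce=0.0, motor_noise_sd=0.0, category_update_gain=0.0), seed=2
        )
        res = encoding_strength(t, std_spec)
        gap = res.true_outlier_length - res.true_family_predicted
        t.loc[t["is_outlier"], "spring_length_cm"] = res.true_family_predicted + gap / 2
        res2 = encoding_strength(t, std_spec)
        assert res2.ce_percent == pytest.approx(50.0, abs=1e-9)

    def test_invariant_to_height_translation(self):
        base = make_condition("same_color")
        shifted = ConditionSpec(
            name="shifted",
            objects=tuple(
                ObjectSpec(o.height_cm + 10.0, o.mass_g, o.is_outlier) for o in base.objects
            ),
        )
        p = BehaviorParams(latent_ce=64.0, motor_noise_sd=0.0, category_update_gain=0.0)
        a = encoding_strength(simulate_participant(base, p, seed=6), base)
        b = encoding_strength(simulate_participant(shifted, p, seed=6), shifted)
        assert a.ce_percent == pytest.approx(b.ce_percent, abs=1e-9)


class TestSymmetricEquality:
    @pytest.mark.parametrize("condition", ["same_color", "small_family"])
    def test_prediction_equals_family_mean_for_symmetric_design(self, condition):
        spec = make_condition(condition)
        t = simulate_participant(spec, BehaviorParams(latent_ce=70.0, motor_noise_sd=0.4), seed=8)
        assert family_predicted_equals_family_mean_check(t, spec) is True

    def test_unbalanced_counts_skip_check(self, std_spec):
        t = simulate_participant(std_spec, BehaviorParams(motor_noise_sd=0.4), seed=8)
        win = analysis_windows(std_spec)
        fam = t[(~t["is_outlier"]) & t["block"].isin(win.post_blocks)]
        drop = fam[fam["object_height_cm"] == 5.0].index[:3]
        assert family_predicted_equals_family_mean_check(t.drop(drop), std_spec) is None
        # and the identity genuinely fails once counts are unbalanced
        slope, intercept, _ = family_regression(t.drop(drop), win.post_blocks)
        fam2 = fam.drop(drop)
        assert abs(slope * 7 + intercept - fam2["spring_length_cm"].mean()) > 1e-6


class TestSlopeShift:
    def test_frozen_line_gives_zero_shift(self, std_spec):
        # fully converged responder (no learning transient), frozen line
        p = BehaviorParams(
            latent_ce=80.0, motor_noise_sd=0.0, category_update_gain=0.0,
            learning_rate=50.0,
        )
        t = simulate_participant(std_spec, p, seed=3)
        pre, post, delta = slope_shift(t, std_spec, apply_trial_exclusion=False)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_category_update_pulls_slope_up(self, std_spec):
        p = BehaviorParams(latent_ce=90.0, motor_noise_sd=0.3, category_update_gain=0.05)
        deltas = [
            slope_shift(simulate_participant(std_spec, p, seed=100 + i), std_spec)[2]
            for i in range(12)
        ]
        assert np.mean(deltas) > 0


class TestBootstrapSem:
    def test_constant_values_give_zero(self):
        assert bootstrap_sem([3.0] * 10, seed=0) == 0.0

    def test_close_to_analytic_sem(self, rng):
        x = rng.normal(50, 12, size=400)
        sem = bootstrap_sem(x, reps=2000, seed=1)
        assert sem == pytest.approx(x.std(ddof=1) / np.sqrt(len(x)), rel=0.10)

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=30)
        assert bootstrap_sem(x, seed=7) == bootstrap_sem(x, seed=7)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sem([1.0], seed=0)
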