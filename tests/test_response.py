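"""Decay-model evaluation, fitting and threshold extraction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import leafheat as lh
from leafheat.response import ResponseCurve, eq1, eq1_slope


def make_curve(a=0.8, b=25.0, c=-0.5, t_low=20.0, t_high=50.0):
    return ResponseCurve(a, b, c, t_low, t_high, 0.0, 42, True)


admissible = st.tuples(
    st.floats(0.3, 1.0),            # theta_a
    st.floats(0.05, 2.0),           # |theta_c|
    st.floats(30.0, 49.0),          # T50 target used to back out theta_b
)


def params_from(a, abs_c, t50):
    """theta_b chosen so the curve crosses a/2 at t50; keeps params admissible."""
    b = np.log(2.0) + abs_c * t50
    return a, b, -abs_c


class TestEq1:
    def test_known_point_is_zero_where_exponent_vanishes(self):
        # at T = -theta_b/theta_c the exponent is zero and y = 0
        assert eq1(50.0, 0.8, 25.0, -0.5) == pytest.approx(0.0, abs=1e-12)

    def test_asymptote_at_low_temperature(self):
        assert eq1(-200.0, 0.8, 25.0, -0.5) == pytest.approx(0.8, abs=1e-12)

    def test_value_matches_independent_evaluation(self):
        # frozen from a 30-digit mpmath evaluation of 0.8*(1 - exp(-(25 - 0.5*45)))
        assert eq1(45.0, 0.8, 25.0, -0.5) == pytest.approx(0.734332001100880963864, abs=1e-15)

    def test_predict_wrapper_uses_curve_parameters(self):
        curve = make_curve()
        t = np.array([30.0, 45.0, 50.0])
        np.testing.assert_allclose(lh.eq1_predict(curve, t), eq1(t, 0.8, 25.0, -0.5))

    def test_curve_is_monotonically_decreasing_over_domain(self):
        t = np.linspace(20, 50, 200)
        y = eq1(t, 0.8, 25.0, -0.5)
        assert np.all(np.diff(y) < 0)


class TestClosedFormThresholds:
    def test_t50_closed_form_example(self):
        curve = make_curve()
        t50 = lh.compute_reduction_threshold(curve, 0.5, 0.8)
        assert t50 == pytest.approx(2.0 * (25.0 - np.log(2.0)), abs=1e-12)

    def test_zero_fraction_with_reference_at_asymptote_hits_curve_zero(self):
        # y = theta_a requires the exponential term to vanish only at
        # T -> -inf; fraction 1 (full reduction) instead lands on y = 0
        curve = make_curve()
        t = lh.compute_reduction_threshold(curve, 1.0 - 1e-12, 0.8)
        assert t == pytest.approx(-curve.theta_b / curve.theta_c, abs=1e-6)

    def test_t50_below_t95_always(self):
        curve = make_curve()
        t50 = lh.compute_reduction_threshold(curve, 0.5, 0.8)
        t95 = lh.compute_reduction_threshold(curve, 0.95, 0.8)
        assert t50 < t95

    def test_unreachable_target_is_nan(self):
        curve = make_curve(a=0.3)
        assert np.isnan(lh.compute_reduction_threshold(curve, 0.5, 0.9))

    def test_tcrit_closed_form_example(self):
        curve = make_curve()
        assert lh.compute_tcrit(curve) == pytest.approx(50.0 + np.log(0.15) / 0.5, abs=1e-12)

    def test_tcrit_approaches_domain_edge_for_instant_collapse(self):
        curve = make_curve(c=-500.0)
        assert lh.compute_tcrit(curve) == pytest.approx(50.0, abs=0.01)

    def test_shallow_curve_warns_when_tcrit_leaves_domain(self):
        curve = make_curve(c=-0.05, t_low=40.0)
        with pytest.warns(UserWarning, match="below the fitted domain"):
            lh.compute_tcrit(curve)

    @settings(max_examples=60, deadline=None)
    @given(admissible)
    def test_closed_forms_agree_with_numeric_root_finding(self, draw):
        a, b, c = params_from(*draw)
        curve = ResponseCurve(a, b, c, 20.0, 50.0, 0.0, 42, True)
        ref = 0.9 * a
        # reduction thresholds: root of eq1 - target
        for frac in (0.5, 0.95):
            target = (1.0 - frac) * ref
            closed = lh.compute_reduction_threshold(curve, frac, ref)
            numeric = brentq(lambda t: eq1(t, a, b, c) - target, -200.0, 400.0, xtol=1e-10)
            assert closed == pytest.approx(numeric, abs=1e-6)
        # Tcrit: root of |slope| - 0.15 * steepest over the domain
        # (shallow draws legitimately warn that Tcrit leaves the domain)
        import warnings

        steepest = abs(eq1_slope(50.0, a, b, c))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            closed = lh.compute_tcrit(curve)
        numeric = brentq(
            lambda t: abs(eq1_slope(t, a, b, c)) - 0.15 * steepest, -400.0, 50.0, xtol=1e-10
        )
        assert closed == pytest.approx(numeric, abs=1e-6)


class TestFitResponseCurve:
    def test_noise_free_parameters_recovered_exactly(self, noiseless_config):
        obs = lh.simulate_fluorescence_dataset(noiseless_config)
        for key in [("Cme", "LE"), ("Pfu", "HE")]:
            group = obs[(obs.species == key[0]) & (obs.site == key[1])]
            curve = lh.fit_response_curve(group)
            truth = noiseless_config.true_thetas[key]
            assert curve.converged
            np.testing.assert_allclose(curve.thetas, truth, rtol=1e-6)

    def test_fit_beats_or_ties_grid_search_oracle(self, small_config):
        obs = lh.simulate_fluorescence_dataset(small_config)
        curve = lh.fit_response_curve(obs)
        from leafheat.response import _fitting_arrays

        t, y = _fitting_arrays(obs)

        def sse(a, b, c):
            return float(np.sum((np.maximum(eq1(t, a, b, c), 0.0) - y) ** 2))

        best_grid = min(
            sse(a, np.log(2.0) + k * t50, -k)
            for a in np.linspace(0.7, 0.95, 11)
            for k in np.linspace(0.05, 2.0, 40)
            for t50 in np.linspace(38.0, 48.0, 41)
        )
        assert sse(*curve.thetas) <= best_grid * (1.0 + 1e-9)

    def test_constant_fvfm_group_is_flagged_unfittable(self):
        group = pd.DataFrame(
            {
                "species": "X", "site": "S",
                "leaf_id": [f"L{i}" for i in range(12)],
                "temperature": np.repeat([34.0, 42.0, 50.0], 4),
                "fvfm": 0.8,
                "control_fvfm": 0.8,
            }
        )
        curve = lh.fit_response_curve(group)
        assert not curve.converged
        assert "decline" in curve.message

    def test_too_few_observations_flagged(self):
        group = pd.DataFrame(
            {"species": "X", "site": "S", "leaf_id": ["a", "b"],
             "temperature": [34.0, 50.0], "fvfm": [0.8, 0.0]}
        )
        assert not lh.fit_response_curve(group).converged

    def test_temperature_shift_equivariance(self, noiseless_config):
        """Shifting all temperatures by +delta shifts all thresholds by +delta."""
        delta = 4.0
        obs = lh.simulate_fluorescence_dataset(noiseless_config)
        group = obs[(obs.species == "Afa") & (obs.site == "ME")].copy()
        ref = lh.group_reference_fvfm(group)
        base = lh.thresholds_from_curve(lh.fit_response_curve(group), ref)
        shifted = group.assign(temperature=group.temperature + delta)
        moved = lh.thresholds_from_curve(
            lh.fit_response_curve(shifted, control_temperature=22.5 + delta), ref
        )
        for kind in ("Tcrit", "T50", "T95"):
            assert moved[kind] - base[kind] == pytest.approx(delta, abs=1e-4)


class TestBootstrap:
    def test_zero_noise_bootstrap_collapses_to_point_estimate(self, noiseless_config):
        obs = lh.simulate_fluorescence_dataset(noiseless_config)
        group = obs[(obs.species == "Mla") & (obs.site == "LE")]
        _, ests = lh.bootstrap_thresholds(group, n_boot=50, seed=5)
        for est in ests.values():
            assert est.boot_mean == pytest.approx(est.point, abs=1e-4)
            assert est.boot_se == pytest.approx(0.0, abs=1e-4)
            assert est.n_boot_success == 50

    def test_same_seed_reproduces_bootstrap_exactly(self, small_config):
        obs = lh.simulate_fluorescence_dataset(small_config)
        _, a = lh.bootstrap_thresholds(obs, n_boot=40, seed=9)
        _, b = lh.bootstrap_thresholds(obs, n_boot=40, seed=9)
        for kind in a:
            assert a[kind].boot_mean == b[kind].boot_mean
            assert a[kind].boot_se == b[kind].boot_se

    def test_different_seeds_differ(self, small_config):
        obs = lh.simulate_fluorescence_dataset(small_config)
        _, a = lh.bootstrap_thresholds(obs, n_boot=40, seed=9)
        _, b = lh.bootstrap_thresholds(obs, n_boot=40, seed=10)
        assert a["T50"].boot_mean != b["T50"].boot_mean


class TestFitAllGroups:
    def test_one_row_per_group_and_determinism(self, fluorescence):
        res1 = lh.fit_all_groups(fluorescence, n_boot=20, seed=3)
        assert len(res1) == 36
        assert res1["converged"].all()
        res2 = lh.fit_all_groups(
            fluorescence.sample(frac=1, random_state=0), n_boot=20, seed=3
        )
        pd.testing.assert_frame_equal(res1, res2)

    def test_unfittable_group_yields_flagged_row_not_abort(self, small_config):
        obs = lh.simulate_fluorescence_dataset(small_config)
        flat = obs.head(12).copy()
        flat[["species", "fvfm", "control_fvfm"]] = ["Flat", 0.8, 0.8]
        res = lh.fit_all_groups(pd.concat([obs, flat]), n_boot=10, seed=1)
        assert len(res) == 2
        bad = res[res.species == "Flat"].iloc[0]
        assert not bad["converged"]
        assert res[res.species != "Flat"]["converged"].all()

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            lh.fit_all_groups(pd.DataFrame(columns=["species", "site", "temperature", "fvfm"]))

    def test_fixed_reference_policy_changes_reference(self, small_config):
        obs = lh.simulate_fluorescence_dataset(small_config)
        grp = lh.fit_all_groups(obs, n_boot=0, seed=0, reference_policy="group_control")
        fix = lh.fit_all_groups(obs, n_boot=0, seed=0, reference_policy="fixed")
        assert fix["reference_fvfm"].iloc[0] == pytest.approx(0.803)
        assert grp["reference_fvfm"].iloc[0] != fix["reference_fvfm"].iloc[0]
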