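import math

import numpy as np
import pytest

from zebratk import (
    BodyComposition,
    ExposureScenario,
    FitError,
    MultiCompartmentParams,
    NoiseModel,
    OneCompartmentParams,
    combine_whole_body,
    compartment_half_lives,
    fit_multi_compartment,
    gen_timecourse,
    simulate_multi_compartment,
    simulate_one_compartment,
)

TIMES = np.array([0.25, 1.0, 3.0, 6.0, 8.0, 9.0, 11.0, 14.0, 26.0, 32.0, 35.0, 56.0])


class TestBodyComposition:
    def test_fraction_round_trip(self):
        body = BodyComposition.from_fraction(3.6e-7, 0.10)
        assert body.eye_mass_fraction == pytest.approx(0.10)
        assert body.total_weight == pytest.approx(3.6e-7)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            BodyComposition(w_eyes=0.0, w_rest=1e-7)
        with pytest.raises(ValueError):
            BodyComposition.from_fraction(3.6e-7, 1.0)


class TestSimulate:
    def test_end_of_uptake_levels(self, multicomp_params):
        # frozen from independent ODE integration of each compartment
        sc = ExposureScenario(c_w=0.98, t_uptake=8.0, t_depuration=48.0)
        c_eyes, c_rest = simulate_multi_compartment(multicomp_params, sc, [8.0])
        assert c_eyes[0] == pytest.approx(2100.06, rel=1e-4)
        assert c_rest[0] == pytest.approx(175.13, rel=1e-4)

    def test_zero_water_concentration_gives_zero(self, multicomp_params):
        sc = ExposureScenario(c_w=0.0, t_uptake=8.0, t_depuration=48.0)
        c_eyes, c_rest = simulate_multi_compartment(multicomp_params, sc, TIMES)
        assert np.all(c_eyes == 0) and np.all(c_rest == 0)

    def test_closed_form_matches_ode(self, multicomp_params, scenario):
        a_eyes, a_rest = simulate_multi_compartment(multicomp_params, scenario, TIMES)
        n_eyes, n_rest = simulate_multi_compartment(
            multicomp_params, scenario, TIMES, method="ode"
        )
        np.testing.assert_allclose(n_eyes, a_eyes, rtol=1e-6, atol=a_eyes.max() * 1e-12)
        np.testing.assert_allclose(n_rest, a_rest, rtol=1e-6, atol=a_rest.max() * 1e-12)

    def test_identical_rates_collapse_to_one_compartment(self, scenario):
        p = MultiCompartmentParams(112.9, 0.25, 112.9, 0.25)
        body = BodyComposition.from_fraction(3.6e-7, 0.3)
        c_eyes, c_rest = simulate_multi_compartment(p, scenario, TIMES)
        whole = combine_whole_body(c_eyes, c_rest, body)
        one = simulate_one_compartment(
            OneCompartmentParams(112.9, 0.25), scenario, TIMES
        )
        np.testing.assert_allclose(whole, one, rtol=1e-12)


class TestCombine:
    def test_degenerate_mixture(self, body):
        assert combine_whole_body(5.0, 5.0, body) == pytest.approx(5.0)
        assert combine_whole_body(0.0, 0.0, body) == 0.0

    def test_hand_weighted_mean(self, body):
        got = combine_whole_body(2100.06, 175.13, body)
        assert got == pytest.approx(0.10 * 2100.06 + 0.90 * 175.13, rel=1e-12)

    def test_mass_conservation(self, multicomp_params, scenario, body):
        """Whole-body amount equals the sum of compartment amounts at every
        time point (the weighted mean conserves chemical mass)."""
        c_eyes, c_rest = simulate_multi_compartment(multicomp_params, scenario, TIMES)
        whole = combine_whole_body(c_eyes, c_rest, body)
        amount_whole = whole * body.total_weight
        amount_parts = c_eyes * body.w_eyes + c_rest * body.w_rest
        rel = np.abs(amount_whole - amount_parts) / np.abs(amount_parts)
        assert rel.max() <= 1e-9


class TestDepurationShape:
    def test_eye_fraction_of_burden_grows_during_depuration(
        self, multicomp_params, scenario, body
    ):
        t = np.linspace(scenario.t_uptake, scenario.t_end, 40)
        c_eyes, c_rest = simulate_multi_compartment(multicomp_params, scenario, t)
        burden_eyes = c_eyes * body.w_eyes
        total = burden_eyes + c_rest * body.w_rest
        frac = burden_eyes / total
        assert np.all(np.diff(frac) >= 0)

    def test_whole_body_decay_is_biphasic(self, multicomp_params, scenario, body):
        """Early log-concentration decay is steeper than late decay when the
        eye compartment empties much more slowly than the rest."""

        def log_slope(t0, t1):
            t = np.array([t0, t1]) + scenario.t_uptake
            c_eyes, c_rest = simulate_multi_compartment(multicomp_params, scenario, t)
            w = combine_whole_body(c_eyes, c_rest, body)
            return (math.log(w[1]) - math.log(w[0])) / (t1 - t0)

        assert abs(log_slope(0.0, 6.0)) > abs(log_slope(24.0, 48.0))


class TestFit:
    def test_noise_free_round_trip(self, multicomp_params, scenario, body):
        data = gen_timecourse(
            multicomp_params,
            scenario,
            n_replicates=4,
            noise=NoiseModel(cv=0.0, seed=0),
            body=body,
        )
        fit = fit_multi_compartment(data, data, body, scenario)
        for name in ("k_in_eyes", "k_out_eyes", "k_in_rest", "k_out_rest"):
            assert getattr(fit, name) == pytest.approx(
                getattr(multicomp_params, name), rel=1e-6
            )

    def test_noisy_recovery_within_20_percent(self, multicomp_params, scenario, body):
        data = gen_timecourse(
            multicomp_params,
            scenario,
            n_replicates=16,
            noise=NoiseModel(cv=0.06, seed=11),
            body=body,
        )
        fit = fit_multi_compartment(data, data, body, scenario)
        for name in ("k_in_eyes", "k_out_eyes", "k_in_rest", "k_out_rest"):
            assert getattr(fit, name) == pytest.approx(
                getattr(multicomp_params, name), rel=0.20
            )

    def test_missing_eye_data_directs_to_one_compartment(
        self, onecomp_params, scenario, body
    ):
        whole_only = gen_timecourse(
            onecomp_params, scenario, n_replicates=4, noise=NoiseModel(cv=0.0, seed=0)
        )
        with pytest.raises(FitError, match="one-compartment"):
            fit_multi_compartment(whole_only, whole_only, body, scenario)

    def test_incompatible_scenario_rejected(self, multicomp_params, scenario, body):
        data = gen_timecourse(
            multicomp_params,
            scenario,
            n_replicates=2,
            noise=NoiseModel(cv=0.0, seed=0),
            body=body,
        )
        shorter = ExposureScenario(c_w=scenario.c_w, t_uptake=4.0, t_depuration=48.0)
        with pytest.raises(ValueError):
            fit_multi_compartment(data, data, body, shorter)


class TestHalfLives:
    def test_half_lives_from_printed_rates(self, multicomp_params):
        hl = compartment_half_lives(multicomp_params)
        assert hl["eyes"] == pytest.approx(13.86, abs=0.01)
        assert hl["rest"] * 60 == pytest.approx(52.0, abs=0.5)

    def test_ln2_rate_gives_unit_half_life(self):
        p = MultiCompartmentParams(1.0, math.log(2.0), 1.0, math.log(2.0))
        hl = compartment_half_lives(p)
        assert hl["eyes"] == pytest.approx(1.0)
        assert hl["rest"] == pytest.approx(1.0)
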