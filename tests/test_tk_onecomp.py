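import numpy as np
import pytest

from zebratk import (
    ExposureScenario,
    FitError,
    NoiseModel,
    OneCompartmentParams,
    fit_one_compartment,
    gen_timecourse,
    simulate_one_compartment,
)

TIMES = np.array([0.0, 0.25, 1.0, 3.0, 6.0, 8.0, 9.0, 11.0, 14.0, 26.0, 32.0, 35.0, 56.0])


class TestScenario:
    def test_forcing_function(self, scenario):
        assert scenario.water_conc(0.5) == scenario.c_w
        assert scenario.water_conc(8.0) == scenario.c_w
        assert scenario.water_conc(8.01) == 0.0

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            ExposureScenario(c_w=-0.1, t_uptake=8.0)
        with pytest.raises(ValueError):
            ExposureScenario(c_w=1.0, t_uptake=0.0)
        with pytest.raises(ValueError):
            ExposureScenario(c_w=1.0, t_uptake=8.0, t_depuration=-1.0)


class TestSimulate:
    def test_starts_at_zero(self, onecomp_params, scenario):
        assert simulate_one_compartment(onecomp_params, scenario, [0.0])[0] == 0.0

    def test_end_of_uptake_level(self, onecomp_params):
        # closed form at the study conditions, frozen from an independent
        # ODE integration: 382.67 mg/kg after 8 h at 0.98 mg/L
        sc = ExposureScenario(c_w=0.98, t_uptake=8.0, t_depuration=48.0)
        c = simulate_one_compartment(onecomp_params, sc, [8.0])[0]
        assert c == pytest.approx(382.673, rel=1e-4)

    def test_single_compartment_retains_nothing_after_48h(self, onecomp_params):
        # pure first-order loss at k_out=0.25/h leaves ~e^-12 of the peak:
        # a one-compartment model cannot produce double-digit retention
        sc = ExposureScenario(c_w=0.98, t_uptake=8.0, t_depuration=48.0)
        c8, c56 = simulate_one_compartment(onecomp_params, sc, [8.0, 56.0])
        assert c56 == pytest.approx(c8 * np.exp(-12.0), rel=1e-9)
        assert 100.0 * c56 / c8 < 0.01  # far below the measured 13%

    def test_uptake_monotone_and_bounded_by_steady_state(self, onecomp_params, scenario):
        t = np.linspace(0.0, scenario.t_uptake, 50)
        c = simulate_one_compartment(onecomp_params, scenario, t)
        ss = onecomp_params.k_in / onecomp_params.k_out * scenario.c_w
        assert np.all(np.diff(c) > 0)
        assert np.all(c <= ss)

    def test_depuration_monotone_decreasing(self, onecomp_params, scenario):
        t = np.linspace(scenario.t_uptake + 0.01, scenario.t_end, 50)
        c = simulate_one_compartment(onecomp_params, scenario, t)
        assert np.all(np.diff(c) < 0)
        assert c[-1] > 0

    @pytest.mark.parametrize(
        "k_in, k_out",
        [(112.9, 0.25), (325.0, 0.05), (143.2, 0.8), (10.0, 2.0)],
    )
    def test_closed_form_matches_ode_integration(self, scenario, k_in, k_out):
        p = OneCompartmentParams(k_in, k_out)
        analytic = simulate_one_compartment(p, scenario, TIMES)
        numeric = simulate_one_compartment(p, scenario, TIMES, method="ode")
        # absolute floor covers terminal values decayed below machine
        # resolution relative to the curve maximum
        np.testing.assert_allclose(
            numeric, analytic, rtol=1e-6, atol=analytic.max() * 1e-12
        )

    def test_invalid_times_rejected(self, onecomp_params, scenario):
        with pytest.raises(ValueError):
            simulate_one_compartment(onecomp_params, scenario, [3.0, 1.0])
        with pytest.raises(ValueError):
            simulate_one_compartment(onecomp_params, scenario, [-1.0, 1.0])


class TestFit:
    def test_noise_free_round_trip(self, onecomp_params, scenario):
        data = gen_timecourse(
            onecomp_params, scenario, n_replicates=4, noise=NoiseModel(cv=0.0, seed=0)
        )
        fit = fit_one_compartment(data, scenario)
        assert fit.k_in == pytest.approx(onecomp_params.k_in, rel=1e-6)
        assert fit.k_out == pytest.approx(onecomp_params.k_out, rel=1e-6)
        assert fit.fit.success

    def test_noisy_recovery_within_15_percent(self, onecomp_params, scenario):
        data = gen_timecourse(
            onecomp_params, scenario, n_replicates=16, noise=NoiseModel(cv=0.06, seed=42)
        )
        fit = fit_one_compartment(data, scenario)
        assert fit.k_in == pytest.approx(onecomp_params.k_in, rel=0.15)
        assert fit.k_out == pytest.approx(onecomp_params.k_out, rel=0.15)
        assert fit.k_in_se > 0 and fit.k_out_se > 0

    def test_log_scale_option(self, onecomp_params, scenario):
        data = gen_timecourse(
            onecomp_params, scenario, n_replicates=8, noise=NoiseModel(cv=0.06, seed=3)
        )
        fit = fit_one_compartment(data, scenario, log_scale=True)
        assert fit.k_in == pytest.approx(onecomp_params.k_in, rel=0.15)

    def test_single_time_point_is_underdetermined(self, onecomp_params, scenario):
        data = gen_timecourse(
            onecomp_params,
            scenario,
            times=[8.0],
            n_replicates=4,
            noise=NoiseModel(cv=0.0, seed=0),
        )
        with pytest.raises(FitError):
            fit_one_compartment(data, scenario)

    def test_all_zero_data_raises(self, scenario):
        data = gen_timecourse(
            OneCompartmentParams(1.0, 1.0),
            ExposureScenario(c_w=0.0, t_uptake=8.0, t_depuration=48.0),
            n_replicates=2,
            noise=NoiseModel(cv=0.0, seed=0),
        )
        with pytest.raises(FitError):
            fit_one_compartment(data, scenario)

    def test_parameter_recovery_median_bias_under_5_percent(
        self, onecomp_params, scenario
    ):
        """Over 100 stochastic datasets at 6% CV the median relative bias of
        both rate constants stays within 5%."""
        bias_in, bias_out = [], []
        for seed in range(100):
            data = gen_timecourse(
                onecomp_params,
                scenario,
                n_replicates=16,
                noise=NoiseModel(cv=0.06, seed=seed),
            )
            fit = fit_one_compartment(data, scenario)
            bias_in.append((fit.k_in - onecomp_params.k_in) / onecomp_params.k_in)
            bias_out.append((fit.k_out - onecomp_params.k_out) / onecomp_params.k_out)
        assert abs(np.median(bias_in)) <= 0.05
        assert abs(np.median(bias_out)) <= 0.05
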