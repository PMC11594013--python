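import numpy as np
import pytest

from convdry import (
    FitOptions,
    compute_moisture_ratio,
    evaluate_model,
    fit_arrhenius,
    fit_model,
)
from convdry.errors import ConfigError, InvalidInputError
from convdry.simulate import (
    DEFAULT_DILUTION_GRID,
    SimulationConfig,
    default_equilibrium_mr,
    simulate_arrhenius_set,
    simulate_dose_response,
    simulate_drying_experiment,
    simulate_property_table,
)


class TestDryingSimulator:
    def test_noiseless_closed_loop(self):
        cfg = SimulationConfig(noise_sd_mr=0.0, seed=1)
        series, truth = simulate_drying_experiment(cfg)
        mr = compute_moisture_ratio(series, truth.m_e)
        expected = np.maximum(
            evaluate_model(truth.model, truth.params, series.times / 60.0),
            truth.equilibrium_mr,
        )
        np.testing.assert_allclose(mr.mr, expected, rtol=1e-12)

    def test_same_seed_same_series(self):
        cfg = SimulationConfig(seed=42)
        a, _ = simulate_drying_experiment(cfg)
        b, _ = simulate_drying_experiment(cfg)
        np.testing.assert_array_equal(a.moisture, b.moisture)

    def test_different_seed_differs(self):
        a, _ = simulate_drying_experiment(SimulationConfig(seed=1))
        b, _ = simulate_drying_experiment(SimulationConfig(seed=2))
        assert not np.array_equal(a.moisture, b.moisture)

    def test_equilibrium_floor_rises_with_temperature(self):
        assert default_equilibrium_mr(50.0) == pytest.approx(3.5e-3)
        assert default_equilibrium_mr(90.0) == pytest.approx(1.54e-2)
        assert default_equilibrium_mr(70.0) == pytest.approx((3.5e-3 + 1.54e-2) / 2)

    def test_excessive_noise_rejected(self):
        cfg = SimulationConfig(noise_sd_mr=0.2, seed=0)
        with pytest.raises(ConfigError):
            simulate_drying_experiment(cfg)

    def test_truth_sidecar_supports_recovery_without_reentry(self):
        cfg = SimulationConfig(
            params={"k": 0.6635, "n": 1.0826}, temperature_C=70.0,
            noise_sd_mr=0.0, seed=0, time_end_min=600.0,
        )
        series, truth = simulate_drying_experiment(cfg)
        mr = compute_moisture_ratio(series, truth.m_e)
        fit = fit_model(mr, truth.model, FitOptions(seed=0))
        # the equilibrium-plateau clip perturbs the tail slightly, so the
        # refit is close to, not identical with, the generating constant
        assert fit.params["k"] == pytest.approx(truth.params["k"], rel=5e-3)

    def test_fit_bias_small_over_replicates(self):
        # noisy generator at the 70 °C truth; mean bias on k below 1%
        truth_k = 0.6635
        ks = []
        for rep in range(100):
            cfg = SimulationConfig(
                params={"k": truth_k, "n": 1.0826}, noise_sd_mr=0.005,
                seed=5000 + rep, time_end_min=600.0,
            )
            series, truth = simulate_drying_experiment(cfg)
            mr = compute_moisture_ratio(series, truth.m_e)
            ks.append(fit_model(mr, "page", FitOptions(seed=0)).params["k"])
        assert abs(np.mean(ks) - truth_k) / truth_k < 0.01

    def test_balance_quantization_limits_resolution(self):
        cfg = SimulationConfig(noise_sd_mr=0.0, quantize_balance=True, seed=0)
        series, _ = simulate_drying_experiment(cfg)
        mass = 50.0 * (1.0 + series.moisture)
        np.testing.assert_allclose(mass, np.round(mass, 3), atol=1e-9)


class TestArrheniusSimulator:
    def test_noiseless_exact_recovery(self):
        pts = simulate_arrhenius_set(1e-5, 34.90)
        res = fit_arrhenius(pts)
        assert res.e_a_kj_mol == pytest.approx(34.90, abs=1e-9)

    def test_zero_activation_energy_is_flat(self):
        pts = simulate_arrhenius_set(2e-10, 0.0)
        assert all(d == pytest.approx(2e-10) for _, d in pts)

    def test_noisy_recovery_rmse_stable(self):
        errs = []
        for rep in range(200):
            pts = simulate_arrhenius_set(1e-5, 34.90, noise_sd_log_d=0.05,
                                         seed=rep)
            errs.append(fit_arrhenius(pts).e_a_kj_mol - 34.90)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        # rerun with same seeds is identical
        errs2 = [
            fit_arrhenius(
                simulate_arrhenius_set(1e-5, 34.90, noise_sd_log_d=0.05, seed=rep)
            ).e_a_kj_mol
            - 34.90
            for rep in range(200)
        ]
        assert rmse == pytest.approx(float(np.sqrt(np.mean(np.square(errs2)))))
        assert rmse < 5.0  # kJ/mol, sanity bound for 5-point fits at 5% log-noise

    def test_rejects_bad_d0(self):
        with pytest.raises(InvalidInputError):
            simulate_arrhenius_set(0.0, 30.0)


class TestDoseResponseSimulator:
    def test_noiseless_is_exactly_logistic(self):
        s = simulate_dose_response(0.016, hill=1.0)
        expected = 100.0 / (1.0 + 0.016 / s.concentrations)
        np.testing.assert_allclose(s.inhibition_pct, expected, atol=1e-12)

    def test_default_grid_is_eight_twofold_dilutions(self):
        grid = DEFAULT_DILUTION_GRID
        assert len(grid) == 8
        assert grid[-1] == pytest.approx(0.13)
        np.testing.assert_allclose(grid[1:] / grid[:-1], 2.0, rtol=1e-12)

    def test_noise_clipped_to_measurement_window(self):
        s = simulate_dose_response(0.016, noise_sd_pct=5.0, seed=9)
        assert s.inhibition_pct.min() >= -5.0
        assert s.inhibition_pct.max() <= 105.0


class TestPropertyTableSimulator:
    def test_zero_sd_reproduces_means(self):
        table = simulate_property_table({"a": 5.0, "b": 7.0}, {"a": 0.0, "b": 0.0})
        np.testing.assert_allclose(table.groups["a"], 5.0)
        np.testing.assert_allclose(table.groups["b"], 7.0)

    def test_seeded_determinism(self):
        kw = dict(means={"a": 5.0, "b": 7.0}, sds={"a": 1.0, "b": 1.0}, seed=4)
        t1 = simulate_property_table(**kw)
        t2 = simulate_property_table(**kw)
        np.testing.assert_array_equal(t1.groups["a"], t2.groups["a"])

    def test_sample_means_within_three_se(self):
        # soluble-fiber row: means/SDs per treatment, n=3 replicates
        means = {"fd": 2.35, "50C": 2.77, "60C": 3.08, "70C": 3.37,
                 "80C": 3.87, "90C": 3.40}
        sds = {"fd": 0.15, "50C": 0.36, "60C": 0.47, "70C": 0.19,
               "80C": 0.43, "90C": 0.16}
        n = 3
        ok = 0
        trials = 0
        for rep in range(100):
            table = simulate_property_table(means, sds, n_replicates=n, seed=rep)
            for label, vals in table.groups.items():
                trials += 1
                se = sds[label] / np.sqrt(n)
                ok += abs(vals.mean() - means[label]) <= 3 * se
        assert ok / trials >= 0.99

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            simulate_property_table({"a": 1.0}, {"b": 1.0})
        with pytest.raises(ConfigError):
            simulate_property_table({"a": 1.0}, {"a": -0.1})
        with pytest.raises(ConfigError):
            simulate_property_table({"a": 1.0}, {"a": 0.1}, n_replicates=1)
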