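"""Chi-square objective, bounded fitting and the perturbation uncertainty procedure."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from vesiclesaxs.curves import ScatteringCurve
from vesiclesaxs.fitting import (
    FitConfig,
    chi2,
    dict_to_model,
    fit,
    fit_report,
    model_to_dict,
    perturbation_uncertainty,
)
from vesiclesaxs.model import QGrid, model_intensity
from vesiclesaxs.synthetic import NoiseModel, generate_curve


@pytest.fixture()
def truth(etho_ei):
    return etho_ei


@pytest.fixture()
def displaced_start(truth):
    d = model_to_dict(truth)
    d.update(R1=0.55, R2=1.2, R3=0.2, c=30.0, g_c=0.4, scale=2e-8, background=0.03)
    return dict_to_model(d)


class TestChi2:
    def test_exact_model_gives_zero(self, truth):
        grid = QGrid.default(n=50)
        ideal = model_intensity(grid, truth)
        curve = ScatteringCurve(grid, ideal, np.full(50, 0.1))
        assert chi2(curve, truth) == 0.0

    def test_three_point_hand_computed(self, truth):
        grid = QGrid(np.array([0.5, 1.0, 2.0]))
        ideal = model_intensity(grid, truth)
        obs = ideal + np.array([0.1, -0.2, 0.05])
        sigma = np.array([0.1, 0.1, 0.05])
        curve = ScatteringCurve(grid, obs, sigma)
        expected = (0.1 / 0.1) ** 2 + (0.2 / 0.1) ** 2 + (0.05 / 0.05) ** 2
        assert chi2(curve, truth) == pytest.approx(expected, rel=1e-10)

    def test_doubling_sigma_quarters_chi2(self, truth):
        grid = QGrid.default(n=30)
        ideal = model_intensity(grid, truth)
        obs = ideal * 1.02
        a = ScatteringCurve(grid, obs, 0.01 * ideal)
        b = ScatteringCurve(grid, obs, 0.02 * ideal)
        assert chi2(b, truth) == pytest.approx(chi2(a, truth) / 4, rel=1e-10)

    def test_nonpositive_sigma_rejected(self, truth):
        grid = QGrid.default(n=10)
        ideal = model_intensity(grid, truth)
        curve = ScatteringCurve(grid, ideal, np.full(10, 1.0))
        object.__setattr__(curve, "sigma", np.zeros(10))
        with pytest.raises(ValueError):
            chi2(curve, truth)


class TestFit:
    def test_truth_is_stationary_on_noiseless_data(self, truth, noiseless):
        curve = generate_curve(truth, noise=noiseless, seed=0)
        res = fit(curve, truth, FitConfig(seed=0))
        d0, d1 = model_to_dict(truth), model_to_dict(res.model)
        for name in ("R1", "R2", "R3", "c", "g_c", "scale"):
            assert d1[name] == pytest.approx(d0[name], rel=1e-6)

    def test_chi2_never_worse_than_initial(self, truth, displaced_start):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=4)
        res = fit(curve, displaced_start, FitConfig(seed=0))
        assert res.chi2 <= chi2(curve, displaced_start) + 1e-9

    def test_recovers_spacing_within_ten_percent(self, truth, displaced_start):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=5)
        res = fit(curve, displaced_start, FitConfig(seed=0))
        assert res.model.stack.c == pytest.approx(truth.stack.c, rel=0.10)

    def test_integer_grid_selects_generating_lamellarity(self, etho_wi):
        curve = generate_curve(etho_wi, noise=NoiseModel(0.01), seed=42)
        start = dict_to_model({**model_to_dict(etho_wi), "c": 12.0, "g_c": 0.2})
        cfg = FitConfig(
            free=frozenset({"scale", "background", "R1", "R2", "R3", "c", "g_c", "N"}),
            bounds={"N": (1, 8)},
            seed=0,
        )
        res = fit(curve, start, cfg)
        assert res.model.stack.N == 5

    def test_out_of_bounds_initial_rejected(self, truth):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=1)
        bad = dict_to_model({**model_to_dict(truth), "c": 3.9})
        with pytest.raises(ValueError, match="bounds"):
            fit(curve, bad, FitConfig(seed=0))

    def test_deterministic_given_seed(self, truth, displaced_start):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=9)
        a = fit(curve, displaced_start, FitConfig(seed=3, n_starts=3))
        b = fit(curve, displaced_start, FitConfig(seed=3, n_starts=3))
        assert model_to_dict(a.model) == model_to_dict(b.model)

    def test_free_and_fixed_must_be_disjoint(self):
        with pytest.raises(ValueError):
            FitConfig(free=frozenset({"c"}), fixed_values={"c": 14.0})


class TestPerturbationUncertainty:
    def test_vanishing_sigma_gives_zero_spread(self, truth):
        grid = QGrid.default(n=80)
        ideal = model_intensity(grid, truth)
        # sigma far below double precision of the intensity: every replicate
        # sees identical data, so the replicate spread collapses to zero
        curve = ScatteringCurve(grid, ideal, np.full(80, 1e-300))
        res = perturbation_uncertainty(curve, truth, FitConfig(seed=0), n_replicates=3)
        assert res.parameter_stats
        assert res.n_failed_replicates == 0
        for mean, sd in res.parameter_stats.values():
            # identical replicates; spread is zero up to the rounding of the mean
            assert sd <= 1e-12 * (1.0 + abs(mean))

    def test_same_seed_identical_statistics(self, truth, displaced_start):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=12)
        cfg = FitConfig(seed=21)
        a = perturbation_uncertainty(curve, displaced_start, cfg, n_replicates=5)
        b = perturbation_uncertainty(curve, displaced_start, cfg, n_replicates=5)
        assert a.parameter_stats == b.parameter_stats

    def test_spread_grows_with_noise(self, truth, displaced_start):
        sds = {}
        for rel in (0.01, 0.04):
            spread = []
            for seed in range(3):
                curve = generate_curve(truth, noise=NoiseModel(rel), seed=30 + seed)
                res = perturbation_uncertainty(
                    curve, displaced_start, FitConfig(seed=seed), n_replicates=8
                )
                spread.append(res.parameter_stats["c"][1])
            sds[rel] = np.mean(spread)
        assert sds[0.04] > sds[0.01]

    def test_replicate_count_floor(self, truth):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=2)
        with pytest.raises(ValueError):
            perturbation_uncertainty(curve, truth, FitConfig(seed=0), n_replicates=1)

    def test_report_contains_replicate_statistics(self, truth, displaced_start):
        curve = generate_curve(truth, noise=NoiseModel(0.01), seed=13)
        res = perturbation_uncertainty(curve, displaced_start, FitConfig(seed=1), n_replicates=4)
        text = fit_report(res)
        assert "parameter" in text and "s.d." in text
        assert "c\t" in text
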