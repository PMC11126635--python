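"""Prediction products: ensembling, summaries, phenology, dominance,
bias correction, scenario projection, transect smoothing."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import multisdm as m
from multisdm.inference import (
    PredictionCube,
    ScenarioSpec,
    find_modes,
    gradient_profile,
)


def small_cube(probs, days=None):
    t, d, p = probs.shape
    return PredictionCube(
        probs=probs,
        taxa=[f"t{i}" for i in range(t)],
        days=np.arange(1, d + 1, dtype=float) if days is None else days,
        pixel_index=np.arange(p),
        grid_shape=(1, p),
    )


class TestEnsemble:
    def test_two_member_hand_value(self):
        p1 = small_cube(np.array([0.8, 0.2]).reshape(2, 1, 1))
        p2 = small_cube(np.array([0.5, 0.5]).reshape(2, 1, 1))
        out = m.ensemble_predictions([p1, p2], renormalize=False)
        assert out.probs[0, 0, 0] == pytest.approx(0.4**0.25, abs=1e-12)
        assert out.probs[1, 0, 0] == pytest.approx(0.1**0.25, abs=1e-12)
        norm = m.ensemble_predictions([p1, p2])
        total = 0.4**0.25 + 0.1**0.25
        assert norm.probs[0, 0, 0] == pytest.approx(0.4**0.25 / total, abs=1e-9)
        assert norm.probs[1, 0, 0] == pytest.approx(0.1**0.25 / total, abs=1e-9)

    def test_identical_members_square_root_and_rank_preserving(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(6), size=(4, 5)).transpose(2, 0, 1)
        cube = small_cube(raw)
        out = m.ensemble_predictions([cube, cube], renormalize=False)
        assert np.allclose(out.probs, np.sqrt(raw), atol=1e-12)
        norm = m.ensemble_predictions([cube, cube])
        assert np.array_equal(
            np.argsort(norm.probs, axis=0), np.argsort(raw, axis=0)
        )

    def test_zero_probability_annihilates(self):
        p1 = small_cube(np.array([0.0, 1.0]).reshape(2, 1, 1))
        p2 = small_cube(np.array([0.5, 0.5]).reshape(2, 1, 1))
        out = m.ensemble_predictions([p1, p2], renormalize=False)
        assert out.probs[0, 0, 0] == 0.0

    def test_misaligned_members_rejected(self):
        p1 = small_cube(np.full((2, 1, 1), 0.5))
        p2 = small_cube(np.full((2, 2, 1), 0.5))
        with pytest.raises(ValueError):
            m.ensemble_predictions([p1, p2])


class TestAnnualSummary:
    def test_constant_series_unchanged(self):
        cube = small_cube(np.full((2, 10, 3), 0.25))
        assert np.allclose(m.annual_summary(cube), 0.25)

    def test_linear_interpolated_percentile(self):
        series = np.arange(1.0, 11.0).reshape(1, 10, 1)
        cube = small_cube(series)
        assert m.annual_summary(cube)[0, 0] == pytest.approx(9.1)

    def test_monotone_under_pointwise_increase(self):
        rng = np.random.default_rng(1)
        a = rng.random((3, 20, 4))
        cube_a = small_cube(a)
        cube_b = small_cube(a + 0.1)
        assert np.all(m.annual_summary(cube_b) >= m.annual_summary(cube_a))


class TestSmoothing:
    def test_constant_and_interior_ramp_unchanged(self):
        assert np.allclose(m.smooth_seasonal(np.full(50, 3.0), 22), 3.0)
        ramp = np.arange(100.0)
        # odd kernel: exact on the interior of a linear ramp
        sm = m.smooth_seasonal(ramp, 21)
        assert np.allclose(sm[21:-21], ramp[21:-21], atol=1e-9)
        # even kernel: linear ramp shifted by exactly half a sample
        sm22 = m.smooth_seasonal(ramp, 22)
        assert np.allclose(sm22[22:-22], ramp[22:-22] - 0.5, atol=1e-9)

    def test_even_kernel_extra_tap_earlier(self):
        x = np.zeros(50)
        x[30] = 1.0
        sm = m.smooth_seasonal(x, 4)  # window [t-2, t+1]
        assert sm[29] == pytest.approx(0.25)  # t=29 window {27..30} includes spike
        assert sm[32] == pytest.approx(0.25)  # t=32 window {30..33}
        assert sm[33] == pytest.approx(0.0)  # t=33 window {31..34} excludes

    def test_symmetric_peak_argmax_preserved(self):
        days = np.arange(1, 301)
        curve = np.exp(-0.5 * ((days - 150) / 20.0) ** 2)
        sm = m.smooth_seasonal(curve, 22)
        assert abs(days[np.argmax(sm)] - 150) <= 1


class TestPhenologyPeaks:
    def test_unimodal_curve_recovers_peak(self):
        days = np.arange(60, 274)
        curve = 0.05 * np.exp(-0.5 * ((days - 150) / 15.0) ** 2)
        day, smax = m.tpmax(curve, days)
        assert abs(day - 150) <= 1
        assert smax > 0.01

    def test_below_threshold_masked(self):
        days = np.arange(60, 274)
        curve = 0.005 * np.exp(-0.5 * ((days - 150) / 15.0) ** 2)
        day, smax = m.tpmax(curve, days)
        assert np.isnan(day) and smax < 0.01

    def test_highest_of_two_modes_wins(self):
        days = np.arange(60, 274)
        curve = 0.03 * np.exp(-0.5 * ((days - 100) / 10.0) ** 2)
        curve += 0.05 * np.exp(-0.5 * ((days - 230) / 10.0) ** 2)
        day, _ = m.tpmax(curve, days)
        assert abs(day - 230) <= 2

    def test_monotone_series_has_no_interior_mode(self):
        days = np.arange(60, 274)
        day, _ = m.tpmax(np.linspace(0, 0.2, len(days)), days)
        assert np.isnan(day)

    def test_scale_invariance_above_threshold(self):
        days = np.arange(60, 274)
        curve = 0.05 * np.exp(-0.5 * ((days - 180) / 12.0) ** 2)
        d1, _ = m.tpmax(curve, days)
        d2, _ = m.tpmax(curve * 7.3, days)
        assert d1 == d2

    def test_plateau_takes_centre_and_ties_earliest(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0, 2.0, 0.0])
        assert find_modes(x) == [3, 7]
        days = np.arange(len(x), dtype=float)
        day, _ = m.tpmax(x, days, kernel=1, threshold=0.0)
        assert day == 3.0  # equal heights -> earliest mode


class TestAggregation:
    def test_block_of_equal_values(self):
        a = np.full((4, 4), 5.0)
        assert np.allclose(m.aggregate_map(a, 2, "median"), 5.0)

    def test_median_ignores_masked(self):
        a = np.array([[10.0, 20.0], [30.0, np.nan]])
        assert m.aggregate_map(a, 2, "median")[0, 0] == 20.0

    def test_mode_plurality_and_tie_break(self):
        a = np.array([[1, 1], [2, -1]])
        assert m.aggregate_map(a, 2, "mode")[0, 0] == 1
        b = np.array([[2, 2], [1, 1]])
        assert m.aggregate_map(b, 2, "mode")[0, 0] == 1  # tie -> lowest index

    def test_fully_masked_block_stays_masked(self):
        a = np.full((2, 2), np.nan)
        assert np.isnan(m.aggregate_map(a, 2, "median")[0, 0])
        b = np.full((2, 2), -1)
        assert m.aggregate_map(b, 2, "mode")[0, 0] == -1


def survey_on_pixels(cover_rows, taxa):
    n = len(cover_rows)
    sites = pd.DataFrame(
        {
            "site": [f"s{i}" for i in range(n)],
            "x": np.arange(n) + 0.5,
            "y": np.full(n, 0.5),
        }
    )
    cover = pd.DataFrame(
        np.asarray(cover_rows, dtype=float),
        index=pd.Index(sites["site"]),
        columns=taxa,
    )
    return m.SurveyTable(sites=sites, cover=cover)


class TestBiasCorrection:
    def test_matching_sums_give_unit_weights(self):
        probs = np.tile(np.array([0.6, 0.4])[:, None, None], (1, 3, 2))
        cube = small_cube(probs)
        survey = survey_on_pixels([[60.0, 40.0], [60.0, 40.0]], cube.taxa)
        w = m.bias_correction_weights(survey, cube)
        assert np.allclose(w.w, [100.0, 100.0])  # cover % vs probability scale

    def test_ratio_weights_hand_value(self):
        probs = np.tile(np.array([0.5, 0.5])[:, None, None], (1, 2, 2))
        cube = small_cube(probs)
        survey = survey_on_pixels([[100.0, 50.0], [100.0, 50.0]], cube.taxa)
        w = m.bias_correction_weights(survey, cube)
        assert w.w[0] / w.w[1] == pytest.approx(2.0, abs=1e-12)

    def test_weighted_sums_restore_cover_exactly(self, tiny_bundle):
        from multisdm.synth import conditional_probability_cube

        b = tiny_bundle
        cube = conditional_probability_cube(
            b.landscape, b.species, np.arange(32, 335, 7)
        )
        w = m.bias_correction_weights(b.surveys, cube)
        pos = np.searchsorted(
            cube.pixel_index,
            (b.surveys.sites["y"].astype(int) * b.landscape.shape[1]
             + b.surveys.sites["x"].astype(int)).to_numpy(),
        )
        mean_p = cube.mean_over_days()[:, pos]
        for i, taxon in enumerate(cube.taxa):
            lhs = (w.w[i] * mean_p[i]).sum()
            rhs = b.surveys.cover[taxon].sum()
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_zero_probability_with_cover_is_an_error(self):
        probs = np.tile(np.array([1.0, 0.0])[:, None, None], (1, 2, 2))
        cube = small_cube(probs)
        survey = survey_on_pixels([[50.0, 50.0], [50.0, 50.0]], cube.taxa)
        with pytest.raises(ZeroDivisionError, match="t1"):
            m.bias_correction_weights(survey, cube)


class TestDominance:
    def test_unit_weights_equal_raw_argmax(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=(2, 6)).transpose(2, 0, 1)
        cube = small_cube(probs)
        wooded = np.ones((1, 6), dtype=bool)
        raw = m.dominance_map(cube, None, wooded)
        unit = m.dominance_map(
            cube, m.BiasWeights(taxa=cube.taxa, w=np.ones(4)), wooded
        )
        assert np.array_equal(raw.winner, unit.winner)

    def test_doubling_weight_only_promotes(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(3), size=(2, 8)).transpose(2, 0, 1)
        cube = small_cube(probs)
        wooded = np.ones((1, 8), dtype=bool)
        w = np.ones(3)
        before = m.dominance_map(cube, m.BiasWeights(cube.taxa, w.copy()), wooded)
        w[1] *= 2
        after = m.dominance_map(cube, m.BiasWeights(cube.taxa, w), wooded)
        was_winner = before.winner == 1
        assert np.all(after.winner[was_winner] == 1)

    def test_non_wooded_pixels_masked(self):
        probs = np.full((2, 1, 4), 0.5)
        cube = small_cube(probs)
        wooded = np.array([[True, False, True, False]])
        dom = m.dominance_map(cube, None, wooded)
        assert dom.winner[0, 1] == -1 and dom.winner[0, 3] == -1

    def test_nan_weight_excludes_taxon(self):
        probs = np.tile(np.array([0.9, 0.1])[:, None, None], (1, 1, 3))
        cube = small_cube(probs)
        wooded = np.ones((1, 3), dtype=bool)
        w = m.BiasWeights(cube.taxa, np.array([np.nan, 1.0]))
        dom = m.dominance_map(cube, w, wooded)
        assert np.all(dom.winner == 1)


class TestScenario:
    def _grid_and_model(self):
        bundle = m.make_demo_bundle(
            seed=11, n_species=5, size=12, n_obs=4000, n_sites=30
        )
        tc = m.TrainingConfig(loss="cel", phase1_epochs=1, phase2_max_epochs=2, seed=1)
        model, _ = m.fit_model(
            bundle.observations.copy(),
            bundle.landscape.grid,
            training=tc,
            width=16,
            n_blocks=1,
            min_train=10,
            seed=1,
        )
        return bundle.landscape.grid, model

    def test_zero_delta_bitwise_identity(self):
        grid, model = self._grid_and_model()
        days = [100.0, 150.0]
        current = m.predict_cube(model, grid, days)
        cube, flags = m.apply_scenario(grid, ScenarioSpec(), model, days)
        assert np.array_equal(cube.probs, current.probs)
        assert not flags.any()

    def test_warming_beyond_training_range_flagged(self):
        grid, model = self._grid_and_model()
        shift = ScenarioSpec(add={"elevation": 100.0})
        cube, flags = m.apply_scenario(grid, shift, model, [100.0])
        raw_max = grid.layer("elevation").max()
        idx = model.scaling.names.index("elevation")
        assert flags.any()
        exceed = (grid.layer("elevation").reshape(-1) + 100.0) > model.scaling.maxs[idx]
        assert np.array_equal(flags, exceed)

    def test_multiplicative_delta_applied_before_rescaling(self):
        grid, model = self._grid_and_model()
        spec = ScenarioSpec(mul={"env1": 0.825})
        cube, _ = m.apply_scenario(grid, spec, model, [100.0])
        shifted = replace(
            grid,
            values=np.stack(
                [
                    grid.layer("elevation"),
                    grid.layer("env1") * 0.825,
                    grid.layer("env2"),
                ]
            ),
            scaling=None,
        )
        direct = m.predict_cube(model, shifted, [100.0])
        assert np.array_equal(cube.probs, direct.probs)

    def test_unknown_layer_rejected(self):
        grid, model = self._grid_and_model()
        with pytest.raises(ValueError):
            m.apply_scenario(grid, ScenarioSpec(add={"nope": 1.0}), model, [100.0])


class TestGradientProfile:
    def test_constant_curve_fits_constant(self):
        x = np.linspace(0, 1, 60)
        fit = gradient_profile(x, np.full((2, 60), 0.3))
        assert np.allclose(fit, 0.3, atol=1e-9)

    def test_local_quadratic_exactness(self):
        x = np.linspace(0, 10, 80)
        y = 2.0 + 0.5 * x - 0.25 * x**2
        fit = gradient_profile(x, y[None, :], span=0.2, degree=2)
        assert np.allclose(fit[0], y, atol=1e-8)

    def test_noisy_transect_tracks_block_means(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 200)
        truth = np.sin(2 * np.pi * x) * 0.2 + 0.5
        noisy = truth + rng.normal(0, 0.02, size=200)
        fit = gradient_profile(x, noisy[None, :], span=0.15)[0]
        assert np.sqrt(np.mean((fit - truth) ** 2)) < 0.02
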