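"""Seasonal encoding, predictor rescaling, filtering, pooling, partition."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import multisdm as m
from multisdm.grids import PredictorGrid
from multisdm.observations import ObservationTable


def obs_table(rows):
    df = pd.DataFrame(
        rows, columns=["taxon", "x", "y", "doy", "year", "coord_uncertainty"]
    )
    return ObservationTable(df)


class TestSeasonalEncoding:
    @pytest.mark.parametrize(
        "doy,expected",
        [
            (0.0, (0.0, 1.0)),
            (182.625, (0.0, -1.0)),
            (
                100.0,
                (
                    math.sin(2 * math.pi * 100 / 365.25),
                    math.cos(2 * math.pi * 100 / 365.25),
                ),
            ),
        ],
    )
    def test_known_angles(self, doy, expected):
        s1, s2 = m.encode_season(doy, 365.25)
        assert s1 == pytest.approx(expected[0], abs=1e-5)
        assert s2 == pytest.approx(expected[1], abs=1e-5)

    def test_out_of_range_rejected_unless_wrapped(self):
        with pytest.raises(ValueError):
            m.encode_season(400.0, 365.25)
        s = m.encode_season(400.0, 365.25, wrap=True)
        assert s == pytest.approx(m.encode_season(400.0 - 365.25, 365.25))

    @given(st.floats(0.0, 365.25))
    def test_on_unit_circle_and_periodic(self, doy):
        s1, s2 = m.encode_season(doy)
        assert s1**2 + s2**2 == pytest.approx(1.0, abs=1e-12)
        t1, t2 = m.encode_season(doy + 365.25, wrap=True)
        assert (t1, t2) == (pytest.approx(s1, abs=1e-9), pytest.approx(s2, abs=1e-9))


class TestRescaling:
    def test_affine_map_examples(self):
        grid = PredictorGrid(
            names=["a", "b"],
            values=np.array(
                [[[0.0, 5.0, 10.0]], [[2.0, 3.0, 6.0]]]
            ),
        )
        scaled = m.rescale_predictors(grid)
        assert scaled.values[0, 0].tolist() == [-1.0, 0.0, 1.0]
        assert scaled.values[1, 0].tolist() == [-1.0, -0.5, 1.0]

    def test_constant_layer_maps_to_zero_with_warning(self):
        grid = PredictorGrid(names=["flat"], values=np.full((1, 2, 2), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            scaled = m.rescale_predictors(grid)
        assert np.all(scaled.values == 0.0)

    def test_roundtrip_reproduces_raw_values(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-50, 300, size=(3, 6, 5))
        grid = PredictorGrid(names=["a", "b", "c"], values=vals)
        scaled = m.rescale_predictors(grid)
        assert np.all(scaled.values >= -1.0) and np.all(scaled.values <= 1.0)
        back = scaled.scaling.unscale(scaled.values, axis=0)
        assert np.allclose(back, vals, rtol=1e-12, atol=1e-9)

    def test_corner_point_assigned_up_right(self):
        grid = PredictorGrid(
            names=["a"], values=np.zeros((1, 4, 4)), cell_size=10.0
        )
        row, col = grid.pixel_of(10.0, 20.0)  # exactly on a shared corner
        assert (row, col) == (2, 1)

    def test_grid_io_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        grid = PredictorGrid(
            names=["a", "b"],
            values=rng.standard_normal((2, 4, 4)),
            cell_size=25.0,
            origin=(100.0, -50.0),
            landcover=rng.integers(0, 3, size=(4, 4)),
        )
        grid = m.rescale_predictors(grid)
        m.save_grid(tmp_path / "g.npz", grid)
        loaded = m.load_grid(tmp_path / "g.npz")
        assert loaded.names == grid.names
        assert np.array_equal(loaded.values, grid.values)
        assert np.array_equal(loaded.landcover, grid.landcover)
        assert np.array_equal(loaded.scaling.mins, grid.scaling.mins)


class TestFiltering:
    def test_uncertainty_threshold(self):
        t = obs_table(
            [
                ("a", 0.5, 0.5, 100, 2000, 10.0),
                ("a", 1.5, 0.5, 100, 2000, 30.0),
                ("a", 2.5, 0.5, 100, 2000, 120.0),
            ]
        )
        out = m.filter_observations(t, max_uncertainty=25.0, min_year=1971)
        assert len(out) == 1

    def test_min_year_and_year_sentinel_days(self):
        t = obs_table(
            [
                ("a", 0.5, 0.5, 100.0, 1960, 0.0),  # too old
                ("a", 1.5, 0.5, 1.0, 2000, 0.0),  # first-second sentinel
                ("a", 2.5, 0.5, 365.0, 2000, 0.0),  # last-second sentinel
                ("a", 3.5, 0.5, 100.0, 2000, 0.0),
            ]
        )
        out = m.filter_observations(t, max_uncertainty=100, min_year=1971)
        assert len(out) == 1 and out.df.iloc[0]["x"] == 3.5

    def test_duplicates_collapse_and_idempotence(self):
        t = obs_table(
            [
                ("a", 0.5, 0.5, 100.0, 2000, 5.0),
                ("a", 0.5, 0.5, 100.0, 2000, 5.0),
                ("b", 0.5, 0.5, 100.0, 2000, 5.0),
            ]
        )
        once = m.filter_observations(t)
        twice = m.filter_observations(once)
        assert len(once) == 2
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestPooling:
    def test_relabel_unmapped_identity_and_collapse(self):
        t = obs_table(
            [
                ("Aster subsp. x", 0.5, 0.5, 100.0, 2000, 0.0),
                ("Aster", 0.5, 0.5, 100.0, 2000, 0.0),
                ("Bellis", 1.5, 0.5, 120.0, 2000, 0.0),
            ]
        )
        out = m.pool_taxa(t, {"Aster subsp. x": "Aster"})
        assert sorted(out.df["taxon"]) == ["Aster", "Bellis"]  # collapsed
        assert "Bellis" in out.df["taxon"].values  # unmapped unchanged


class TestPartition:
    def _table(self, counts):
        rows = []
        i = 0
        for taxon, n in counts.items():
            for _ in range(n):
                rows.append((taxon, i + 0.5, 0.5, 100.0, 2000, 0.0))
                i += 1
        return obs_table(rows)

    def test_boundary_counts(self):
        t = self._table({"keep": 25, "drop": 24})
        p = m.partition_train_test(t, n_test=5, min_train=20, seed=0)
        assert p.taxa == ["keep"]
        assert len(p.test_idx["keep"]) == 5
        assert len(p.train_idx["keep"]) == 20
        assert p.n_train["keep"] == 20

    def test_same_seed_identical_different_seed_not(self):
        t = self._table({"a": 40, "b": 60})
        p1 = m.partition_train_test(t, seed=3)
        p2 = m.partition_train_test(t, seed=3)
        p3 = m.partition_train_test(t, seed=4)
        for taxon in p1.taxa:
            assert np.array_equal(p1.test_idx[taxon], p2.test_idx[taxon])
        assert any(
            not np.array_equal(p1.test_idx[t_], p3.test_idx[t_]) for t_ in p1.taxa
        )

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefg", min_size=1, max_size=2),
            st.integers(0, 60),
            min_size=1,
            max_size=6,
        )
    )
    def test_partition_contract_exhaustive(self, counts):
        t = self._table({k: v for k, v in counts.items() if v > 0})
        if len(t) == 0:
            return
        p = m.partition_train_test(t, n_test=5, min_train=20, seed=1)
        for taxon, n in counts.items():
            if n >= 25:
                assert taxon in p.taxa
                train, test = p.train_idx[taxon], p.test_idx[taxon]
                assert len(test) == 5 and len(train) == n - 5
                assert not set(train) & set(test)
                all_rows = set(
                    t.df.index[t.df["taxon"] == taxon].tolist()
                )
                assert set(train) | set(test) == all_rows
            else:
                assert taxon not in p.taxa

    def test_partition_json_roundtrip(self, tmp_path):
        from multisdm.io import load_partition, save_partition

        t = self._table({"a": 30, "b": 50})
        p = m.partition_train_test(t, seed=0)
        save_partition(tmp_path / "p.json", p)
        q = load_partition(tmp_path / "p.json")
        assert q.taxa == p.taxa
        for taxon in p.taxa:
            assert np.array_equal(q.train_idx[taxon], p.train_idx[taxon])
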