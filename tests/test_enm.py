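"""ASCII-grid I/O, occurrence preprocessing and the maximum-entropy model."""

import numpy as np
import pytest

from phyloniche import ValidationError
from phyloniche.enm import (
    EnvStack,
    MaxentModel,
    OccurrenceSet,
    auc_from_scores,
    evaluate_auc,
    jackknife_importance,
    lpt_threshold,
    prune_correlated_layers,
    read_ascii_grid,
    read_occurrences,
    thin_occurrences,
    train_test_split,
    write_ascii_grid,
    write_occurrences,
)
from phyloniche.simulate import NicheTruth, simulate_env, simulate_occurrences


class TestAsciiGrid:
    def test_round_trip_with_nodata(self, tmp_path):
        vals = np.array([[1.5, np.nan], [3.25, -2.0]])
        p = tmp_path / "g.asc"
        write_ascii_grid(p, vals, xllcorner=10.0, yllcorner=20.0, cellsize=0.5)
        back, hdr = read_ascii_grid(p)
        np.testing.assert_array_equal(np.isnan(back), np.isnan(vals))
        np.testing.assert_allclose(back[~np.isnan(back)], vals[~np.isnan(vals)])
        assert hdr["xllcorner"] == 10.0 and hdr["cellsize"] == 0.5

    def test_header_only_file_rejected(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n")
        with pytest.raises(ValidationError):
            read_ascii_grid(p)

    def test_missing_header_key_rejected(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols 1\nnrows 1\n0.0\n")
        with pytest.raises(ValidationError, match="xllcorner"):
            read_ascii_grid(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
                     "1 2\n3\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_ascii_grid(p)

    def test_arcminute_cellsize_preserved(self, tmp_path):
        p = tmp_path / "g.asc"
        write_ascii_grid(p, np.ones((1, 1)), 0.0, 0.0, 0.041666)
        _, hdr = read_ascii_grid(p)
        assert hdr["cellsize"] == 0.041666

    def test_occurrence_csv_round_trip(self, tmp_path):
        occ = OccurrenceSet(np.array([[100.25, 25.5], [101.0, 26.0]]))
        p = tmp_path / "occ.csv"
        write_occurrences(occ, p)
        back = read_occurrences(p)
        np.testing.assert_allclose(back.points, occ.points)


class TestCellAssignment:
    def test_floor_rule_and_boundary(self):
        env = EnvStack.from_layers({"a": np.zeros((4, 4))}, xllcorner=0.0,
                                   yllcorner=0.0, cellsize=1.0)
        assert env.cell_of(0.5, 0.5) == (3, 0)      # bottom-left cell
        assert env.cell_of(3.5, 3.5) == (0, 3)      # top-right cell
        # boundary point goes to the higher-index cell
        assert env.cell_of(1.0, 0.5) == (3, 1)
        assert env.cell_of(4.5, 0.5) is None         # off-grid

    def test_cell_center_inverts_cell_of(self):
        env = EnvStack.from_layers({"a": np.zeros((5, 7))}, xllcorner=-3.0,
                                   yllcorner=10.0, cellsize=0.25)
        for rc in [(0, 0), (4, 6), (2, 3)]:
            lon, lat = env.cell_center(*rc)
            assert env.cell_of(lon, lat) == rc


class TestThinning:
    def test_empty_set(self):
        assert len(thin_occurrences(OccurrenceSet(np.empty((0, 2))))) == 0

    def test_close_pair_collapsed(self):
        occ = OccurrenceSet(np.array([[0.0, 0.0], [0.03, 0.04]]))  # 0.05 deg apart
        assert len(thin_occurrences(occ, 0.1)) == 1

    def test_exact_spacing_kept(self):
        # points at exactly 0.1 degrees: strictly-less-than rule keeps all
        pts = np.array([[0.1 * i, 0.0] for i in range(5)])
        assert len(thin_occurrences(OccurrenceSet(pts), 0.1)) == 5

    def test_order_dependence_is_input_order(self):
        pts = np.array([[0.0, 0.0], [0.05, 0.0], [0.12, 0.0]])
        kept = thin_occurrences(OccurrenceSet(pts), 0.1).points
        np.testing.assert_allclose(kept, [[0.0, 0.0], [0.12, 0.0]])


class TestPruning:
    def test_duplicate_layer_dropped(self, rng):
        a = rng.normal(size=(20, 20))
        env = EnvStack.from_layers({"a": a, "b": a.copy(), "c": rng.normal(size=(20, 20))})
        pruned, dropped = prune_correlated_layers(env)
        assert pruned.names == ["a", "c"]
        assert dropped[0][:2] == ("a", "b") and dropped[0][2] == pytest.approx(1.0)

    def test_negated_layer_dropped(self, rng):
        a = rng.normal(size=(15, 15))
        env = EnvStack.from_layers({"a": a, "neg": -a})
        pruned, dropped = prune_correlated_layers(env)
        assert pruned.names == ["a"]
        assert dropped[0][2] == pytest.approx(-1.0)

    def test_independent_layers_survive(self, rng):
        env = EnvStack.from_layers(
            {f"l{i}": rng.normal(size=(30, 30)) for i in range(4)}
        )
        pruned, dropped = prune_correlated_layers(env)
        assert pruned.names == env.names and not dropped

    def test_priority_decides_loser(self, rng):
        a = rng.normal(size=(10, 10))
        env = EnvStack.from_layers({"mean_temp": a, "seasonality": a.copy()})
        pruned, _ = prune_correlated_layers(env, priority=["seasonality", "mean_temp"])
        assert pruned.names == ["seasonality"]

    def test_constant_layer_warns_but_kept(self, rng):
        env = EnvStack.from_layers({"flat": np.ones((5, 5)),
                                    "x": rng.normal(size=(5, 5))})
        with pytest.warns(UserWarning, match="constant"):
            pruned, _ = prune_correlated_layers(env)
        assert "flat" in pruned.names


def _uniform_occ(env, n, rng):
    cells = np.argwhere(env.mask)
    chosen = cells[rng.choice(len(cells), n)]
    jit = rng.uniform(0, 1, size=(n, 2))
    lon = env.xllcorner + (chosen[:, 1] + jit[:, 0]) * env.cellsize
    lat = env.yllcorner + (env.nrows - chosen[:, 0] - jit[:, 1]) * env.cellsize
    return OccurrenceSet(np.column_stack([lon, lat]))


class TestMaxentModel:
    @pytest.fixture(scope="class")
    def env(self):
        truth = NicheTruth(nrows=40, ncols=40, n_layers=2, seed=11)
        return simulate_env(truth)

    def test_uniform_presences_give_near_zero_coefficients(self, env, rng):
        occ = _uniform_occ(env, 400, rng)
        m = MaxentModel(n_background=800, reg=0.05, seed=1).fit(occ, env)
        assert np.max(np.abs(m.coef_)) < 0.25
        raw = m.predict(env, form="raw").masked_values()
        assert raw.max() / raw.min() < 3.0  # near-uniform surface

    def test_informative_layer_gets_positive_linear_weight(self, rng):
        truth = NicheTruth(nrows=40, ncols=40, n_layers=2,
                           lineage_coefs={"A": (-2.0, {"env1": 3.0})}, seed=3)
        env = simulate_env(truth)
        occ = simulate_occurrences(truth, env, "A", 150, seed=4)
        m = MaxentModel(n_background=800, reg=0.05, seed=5).fit(occ, env)
        i_env1 = m.layer_names_.index("env1")
        assert m.coef_[i_env1] > 0.5

    def test_huge_regularization_zeroes_coefficients(self, env, rng):
        truth = NicheTruth(nrows=40, ncols=40, n_layers=2, seed=11)
        occ = simulate_occurrences(truth, env, "A", 60, seed=6)
        m = MaxentModel(n_background=500, reg=100.0, seed=7).fit(occ, env)
        np.testing.assert_allclose(m.coef_, 0.0, atol=1e-8)

    def test_raw_prediction_sums_to_one(self, env, rng):
        occ = _uniform_occ(env, 50, rng)
        m = MaxentModel(n_background=500, reg=0.1, seed=8).fit(occ, env)
        assert m.predict(env, form="raw").masked_values().sum() == pytest.approx(1.0)

    def test_logistic_in_unit_interval_and_rank_preserving(self, env, rng):
        occ = _uniform_occ(env, 50, rng)
        m = MaxentModel(n_background=500, reg=0.1, seed=9).fit(occ, env)
        raw = m.predict(env, form="raw").masked_values()
        logi = m.predict(env, form="logistic").masked_values()
        assert np.all(logi > 0) and np.all(logi < 1)
        assert np.array_equal(np.argsort(raw), np.argsort(logi))

    def test_missing_layer_named_in_error(self, env, rng):
        occ = _uniform_occ(env, 50, rng)
        m = MaxentModel(n_background=300, seed=10).fit(occ, env)
        other = EnvStack.from_layers({"env1": np.zeros((40, 40))},
                                     cellsize=env.cellsize)
        with pytest.raises(ValidationError, match="env2"):
            m.predict(other)

    def test_too_few_presences_rejected(self, env):
        occ = OccurrenceSet(np.array([[1.0, 1.0]]))
        from phyloniche import DegenerateInputError

        with pytest.raises(DegenerateInputError):
            MaxentModel(min_presences=5, n_background=300).fit(occ, env)

    def test_json_round_trip_reproduces_prediction(self, env, rng):
        occ = _uniform_occ(env, 50, rng)
        m = MaxentModel(n_background=400, reg=0.1, seed=12).fit(occ, env)
        m2 = MaxentModel.from_json(m.to_json())
        np.testing.assert_allclose(
            m.predict(env, "logistic").values, m2.predict(env, "logistic").values
        )

    def test_sklearn_param_protocol(self):
        m = MaxentModel(reg=0.3)
        assert m.get_params()["reg"] == 0.3
        m.set_params(reg=0.7, n_background=123)
        assert m.reg == 0.7 and m.n_background == 123
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


class TestEvaluation:
    def test_all_ties_auc_half(self):
        with pytest.warns(UserWarning, match="constant"):
            assert auc_from_scores([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_perfect_separation(self):
        assert auc_from_scores([3.0, 4.0], [1.0, 2.0]) == 1.0

    def test_one_inversion_of_four_pairs(self):
        # presences {3, 1.5}, background {1, 2}: 3 of 4 pairs correct
        assert auc_from_scores([3.0, 1.5], [1.0, 2.0]) == 0.75

    def test_split_sizes_and_determinism(self):
        occ = OccurrenceSet(np.column_stack([np.linspace(0, 10, 220),
                                             np.linspace(0, 5, 220)]))
        train, test = train_test_split(occ, 0.25, seed=1)
        assert len(train) == 55 and len(test) == 165
        train2, _ = train_test_split(occ, 0.25, seed=1)
        np.testing.assert_array_equal(train.points, train2.points)

    def test_degenerate_fraction_rejected(self):
        occ = OccurrenceSet(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValidationError):
            train_test_split(occ, 0.01, seed=0)
        with pytest.raises(ValidationError):
            train_test_split(occ, 1.5, seed=0)


class TestLptThreshold:
    def test_all_training_presences_suitable(self, rng):
        truth = NicheTruth(nrows=30, ncols=30, n_layers=2, seed=21)
        env = simulate_env(truth)
        occ = simulate_occurrences(truth, env, "A", 30, seed=22)
        m = MaxentModel(n_background=400, reg=0.1, seed=23).fit(occ, env)
        surface = m.predict(env, "logistic")
        thr, suitable = lpt_threshold(surface, env, occ)
        from phyloniche.enm import rasterize_presences

        rows, cols, _ = rasterize_presences(occ, env)
        assert np.all(suitable[rows, cols])
        assert thr == pytest.approx(surface.values[rows, cols].min())

    def test_uniform_surface_everything_suitable(self):
        env = EnvStack.from_layers({"a": np.zeros((10, 10))}, cellsize=1.0)
        from phyloniche.enm import SuitabilitySurface

        surface = SuitabilitySurface(np.full((10, 10), 0.5), env.mask, "logistic")
        occ = OccurrenceSet(np.array([[2.5, 2.5]]))
        _, suitable = lpt_threshold(surface, env, occ)
        assert suitable.sum() == 100


class TestJackknife:
    def test_informative_layer_dominates(self):
        truth = NicheTruth(nrows=50, ncols=50, n_layers=2, n_noise_layers=1,
                           lineage_coefs={"A": (-8.0, {"env1": 8.0})}, seed=31)
        env = simulate_env(truth)
        occ = simulate_occurrences(truth, env, "A", 120, seed=32)
        out = jackknife_importance(occ, env, train_fraction=0.5, seed=33,
                                   n_background=800, reg=0.05)
        only = {k: v["only"] for k, v in out.items()}
        assert max(only, key=only.get) == "env1"
        # a pure-noise layer alone carries ~no signal
        assert abs(only["noise1"] - 0.5) < 0.12


class TestReplicateAuc:
    def test_averages_k_split_replicates(self):
        from phyloniche.enm import replicate_auc

        truth = NicheTruth(nrows=40, ncols=40, n_layers=2, seed=41)
        env = simulate_env(truth)
        occ = simulate_occurrences(truth, env, "A", 80, seed=42)
        mean_auc, aucs = replicate_auc(occ, env, k=4, train_fraction=0.5,
                                       seed=43, n_background=500, reg=0.1)
        assert len(aucs) == 4
        assert mean_auc == pytest.approx(np.mean(aucs))
        assert mean_auc > 0.8  # strong single-driver truth
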