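import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seatsom.som import (HexGrid, SomModel, SomPostureClassifier, TrainConfig,
                         assign_labels, eta_at, find_bmu, neighborhood,
                         normalize, predict_features, sigma_at, train,
                         update_weights)


class TestHexGrid:
    def test_default_is_six_nodes(self):
        grid = HexGrid()
        assert grid.n_nodes == 6
        assert grid.positions.shape == (6, 2)

    def test_lattice_neighbours_at_unit_distance(self):
        grid = HexGrid()
        d = grid.distances()
        adj = grid.adjacency()
        # every adjacent pair sits exactly 1 apart; each node has 2-4 neighbours
        assert np.allclose(d[adj], 1.0)
        degree = adj.sum(axis=1)
        assert degree.min() >= 2 and degree.max() <= 4

    def test_second_row_is_offset(self):
        grid = HexGrid()
        assert grid.positions[3, 0] == pytest.approx(0.5)
        assert grid.positions[3, 1] == pytest.approx(np.sqrt(3) / 2)

    def test_neighbors_listing(self):
        grid = HexGrid()
        assert set(grid.neighbors(0)) == {1, 3}
        assert set(grid.neighbors(4)) == {1, 2, 3, 5}


class TestNormalize:
    def test_three_four_five(self):
        v = np.zeros(256)
        v[0], v[1] = 3.0, 4.0
        out = normalize(v)
        assert out[0] == pytest.approx(0.6)
        assert out[1] == pytest.approx(0.8)

    def test_unit_vector_unchanged(self):
        v = np.zeros(16)
        v[3] = 1.0
        np.testing.assert_array_equal(normalize(v), v)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_norm_is_one(self, seed):
        v = np.random.default_rng(seed).normal(size=64)
        assert np.linalg.norm(normalize(v)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(8))


class TestBmu:
    def test_exact_match_wins_with_zero_distance(self):
        w = normalize(np.random.default_rng(0).normal(size=(6, 16)))
        c, d = find_bmu(w[3], w)
        assert c == 3
        assert d == pytest.approx(0.0)

    def test_tie_goes_to_lowest_index(self):
        w = np.tile(np.array([0.0, -1.0, 0.0, 0.0]), (6, 1))
        w[2] = [1.0, 0.0, 0.0, 0.0]
        w[5] = [1.0, 0.0, 0.0, 0.0]   # nodes 2 and 5 equidistant winners
        x = np.array([1.0, 0.0, 0.0, 0.0])
        c, _ = find_bmu(x, w)
        assert c == 2

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        w = normalize(rng.normal(size=(6, 32)))
        for _ in range(50):
            x = normalize(rng.normal(size=32))
            dists = [np.sqrt(((x - wj) ** 2).sum()) for wj in w]
            assert find_bmu(x, w) == (int(np.argmin(dists)), pytest.approx(min(dists)))


class TestSchedules:
    CFG = TrainConfig()

    def test_initial_values_match_configuration(self):
        assert sigma_at(0, self.CFG) == pytest.approx(10.0)
        assert eta_at(0, self.CFG) == pytest.approx(0.6)

    def test_time_constant_points(self):
        assert sigma_at(2.0, self.CFG) == pytest.approx(10.0 / np.e)
        assert eta_at(1000.0, self.CFG) == pytest.approx(0.6 / np.e)

    def test_strictly_decreasing_and_positive(self):
        t = np.arange(0, 50)
        sig = [sigma_at(x, self.CFG) for x in t]
        eta = [eta_at(x, self.CFG) for x in t]
        assert all(a > b > 0 for a, b in zip(sig, sig[1:]))
        assert all(a > b > 0 for a, b in zip(eta, eta[1:]))

    def test_neighborhood_gaussian_values(self):
        grid = HexGrid()
        assert neighborhood(2, 2, 1.7, grid) == pytest.approx(1.0)
        # adjacent nodes are distance 1 apart: sigma=1 gives exp(-1/2)
        assert neighborhood(0, 1, 1.0, grid) == pytest.approx(np.exp(-0.5))

    def test_neighborhood_decreases_with_distance(self):
        grid = HexGrid()
        h01 = neighborhood(0, 1, 1.0, grid)   # distance 1
        h02 = neighborhood(0, 2, 1.0, grid)   # distance 2
        assert h01 > h02


class TestUpdateWeights:
    def _model(self, seed=0, dim=16):
        rng = np.random.default_rng(seed)
        return SomModel(HexGrid(), normalize(rng.normal(size=(6, dim))))

    def test_full_step_moves_winner_onto_sample(self):
        model = self._model()
        x = normalize(np.random.default_rng(1).normal(size=16))
        cfg = TrainConfig(eta0=1.0, sigma0=1e-6, tau_sigma=1e9, nc0=0.5)
        c, _ = find_bmu(x, model.weights)
        update_weights(model, x, c, t=0, cfg=cfg)
        np.testing.assert_allclose(model.weights[c], x, atol=1e-9)

    def test_vanishing_learning_rate_freezes_model(self):
        model = self._model()
        before = model.weights.copy()
        x = normalize(np.random.default_rng(2).normal(size=16))
        cfg = TrainConfig(eta0=1e-9, nc0=3.0)
        update_weights(model, x, 0, t=0, cfg=cfg)
        np.testing.assert_allclose(model.weights, before, atol=1e-8)

    def test_update_contracts_distance_to_sample(self):
        rng = np.random.default_rng(987)
        for trial in range(10):
            model = self._model(seed=trial)
            x = normalize(rng.normal(size=16))
            c, d_before = find_bmu(x, model.weights)
            update_weights(model, x, c, t=1.0, cfg=TrainConfig())
            d_after = np.linalg.norm(x - model.weights[c])
            assert d_after < d_before

    def test_weights_stay_unit_norm(self):
        model = self._model()
        rng = np.random.default_rng(4)
        for t in range(200):
            x = normalize(rng.normal(size=16))
            c, _ = find_bmu(x, model.weights)
            update_weights(model, x, c, t, TrainConfig())
        np.testing.assert_allclose(np.linalg.norm(model.weights, axis=1), 1.0,
                                   atol=1e-9)

    def test_large_t_sigma_underflow_is_safe(self):
        model = self._model()
        x = normalize(np.random.default_rng(5).normal(size=16))
        update_weights(model, x, 0, t=1e6, cfg=TrainConfig())
        assert np.all(np.isfinite(model.weights))


class TestTrain:
    def test_orthogonal_inputs_claim_distinct_nodes(self):
        X = np.eye(6, 64)  # six mutually orthogonal inputs
        model = train(X, TrainConfig(max_iters=3000, seed=0))
        bmus = {find_bmu(x, model.weights)[0] for x in normalize(X)}
        assert len(bmus) == 6

    def test_single_sample_is_fixed_point(self):
        x = normalize(np.random.default_rng(6).normal(size=32))
        model = train(x[None], TrainConfig(max_iters=2000, seed=1))
        _, d = find_bmu(x, model.weights)
        assert d < 1e-3

    def test_same_seed_reproduces_weights(self, small_features, fast_config):
        X, _ = small_features
        a = train(X, fast_config)
        b = train(X, fast_config)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train(np.empty((0, 256)), TrainConfig())

    def test_quantization_error_restart_selection(self, small_features):
        """More restarts can only lower the selected quantization error."""
        X, _ = small_features
        Xn = normalize(X)

        def qe(model):
            return np.min(np.linalg.norm(Xn[:, None] - model.weights[None],
                                         axis=2), axis=1).mean()

        one = train(X, TrainConfig(max_iters=1500, n_restarts=1, seed=5))
        five = train(X, TrainConfig(max_iters=1500, n_restarts=5, seed=5))
        assert qe(five) <= qe(one) + 1e-12


class TestLabelsAndPredict:
    def test_majority_and_tie_rules(self):
        w = np.eye(6, 16)
        model = SomModel(HexGrid(), w)
        # ten LL to node 2, three LC to node 2 -> LL wins; 5-5 tie on node 0
        X = np.vstack([np.tile(w[2], (13, 1)), np.tile(w[0], (10, 1))])
        y = ["LL"] * 10 + ["LC"] * 3 + ["WB"] * 5 + ["SS"] * 5
        assign_labels(model, X, y)
        assert model.node_labels[2] == "LL"
        assert model.node_labels[0] == "WB"  # WB precedes SS in class order

    def test_unhit_node_inherits_nearest_label(self):
        w = np.eye(6, 16)
        model = SomModel(HexGrid(), w)
        X = np.tile(w[0], (4, 1))
        assign_labels(model, X, ["RC"] * 4)
        assert model.node_labels == ["RC"] * 6

    def test_no_labels_rejected(self):
        model = SomModel(HexGrid(), np.eye(6, 16))
        with pytest.raises(ValueError):
            assign_labels(model, np.empty((0, 16)), [])

    def test_predict_returns_bmu_label(self, trained, small_features):
        X, y = small_features
        preds = predict_features(trained, X[:10])
        assert all(p in set(y) for p in preds)
        # a feature equal to a node weight maps to that node's label
        for j in range(6):
            assert predict_features(trained, trained.weights[j])[0] == \
                trained.node_labels[j]

    def test_model_json_round_trip_is_bit_stable(self, trained):
        text = trained.to_json()
        back = SomModel.from_json(text)
        np.testing.assert_array_equal(back.weights, trained.weights)
        assert back.node_labels == trained.node_labels
        assert back.to_json() == text


class TestClassifier:
    def test_fit_predict_recovers_classes(self, small_features):
        X, y = small_features
        clf = SomPostureClassifier(max_iters=2000, n_restarts=3,
                                   random_state=0).fit(X, y)
        acc = (clf.predict(X) == np.asarray(y)).mean()
        assert acc >= 0.9

    def test_sklearn_param_interface(self):
        clf = SomPostureClassifier(eta0=0.5)
        assert clf.get_params()["eta0"] == 0.5
        clf.set_params(max_iters=10)
        assert clf.max_iters == 10

    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            SomPostureClassifier().predict(np.zeros((1, 256)))
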