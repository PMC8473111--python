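import numpy as np
import pytest

from seatsom.filtering import (DifferentiationRecord, IsomPostureClassifier,
                               differentiation, differentiation_records,
                               filter_samples, isom_train, recompute_distances)
from seatsom.som import (HexGrid, SomModel, SomPostureClassifier, TrainConfig,
                         find_bmu, normalize, train)


def toy_model():
    """Six orthogonal unit weights on the hex grid."""
    return SomModel(HexGrid(), np.eye(6, 16))


class TestRecomputeDistances:
    def test_sample_equal_to_weight_has_zero_entry(self):
        model = toy_model()
        d = recompute_distances(model, model.weights[2][None])
        assert d[0, 2] == pytest.approx(0.0)
        assert np.all(d >= 0)

    def test_argmin_matches_bmu_search(self, trained, small_features):
        X, _ = small_features
        d = recompute_distances(trained, X)
        for i, x in enumerate(normalize(X)):
            c, dist = find_bmu(x, trained.weights)
            assert d[i].argmin() == c
            assert d[i, c] == pytest.approx(dist)


class TestDifferentiation:
    def _distances(self, row):
        """Distance table with one sample row."""
        return np.asarray(row, dtype=float)[None]

    def test_equidistant_sample_scores_zero(self):
        model = toy_model()
        # BMU node 0 (d=.2); its hex neighbours are 1 and 3 (closest rival .2)
        d = self._distances([0.2, 0.2, 9, 9, 9, 9])
        rec = differentiation(model, d, 0)
        assert rec.bmu == 0 and rec.rival == 1
        assert rec.r_jk == pytest.approx(0.0)

    def test_direct_evaluation(self):
        model = toy_model()
        d = self._distances([0.2, 0.6, 9, 9, 9, 9])
        rec = differentiation(model, d, 0)
        assert rec.e_jk == pytest.approx(-0.4)
        assert rec.r_jk == pytest.approx(0.5)

    def test_zero_bmu_distance_is_perfect(self):
        model = toy_model()
        d = self._distances([0.0, 0.7, 9, 9, 9, 9])
        assert differentiation(model, d, 0).r_jk == pytest.approx(1.0)

    def test_degenerate_double_zero_is_ambiguous(self):
        model = toy_model()
        d = self._distances([0.0, 0.0, 9, 9, 9, 9])
        assert differentiation(model, d, 0).r_jk == 0.0

    def test_rival_is_hex_adjacent(self, trained, small_features):
        X, _ = small_features
        for rec in differentiation_records(trained, X[:20]):
            assert rec.rival in set(trained.grid.neighbors(rec.bmu))

    def test_worst_case_mode_never_scores_higher(self, trained, small_features):
        X, _ = small_features
        nearest = differentiation_records(trained, X, rival="nearest")
        worst = differentiation_records(trained, X, rival="all")
        for a, b in zip(nearest, worst):
            assert b.r_jk <= a.r_jk + 1e-12

    def test_scores_lie_in_unit_interval(self, trained, small_features):
        X, _ = small_features
        for rec in differentiation_records(trained, X):
            assert 0.0 <= rec.r_jk <= 1.0


class TestFilterSamples:
    def _records(self, scores):
        return [DifferentiationRecord(i, 0, 1, 0.1, 0.2, -0.1, r)
                for i, r in enumerate(scores)]

    def test_threshold_partition(self):
        kept, removed = filter_samples(self._records([0.5, 0.1, 0.15, 0.0]), 0.15)
        assert kept == [0, 2]
        assert removed == [1, 3]

    def test_zero_threshold_removes_nothing(self):
        kept, removed = filter_samples(self._records([0.0, 0.3]), 0.0)
        assert removed == []
        assert kept == [0, 1]

    def test_removed_count_monotone_in_threshold(self, trained, small_features):
        X, _ = small_features
        records = differentiation_records(trained, X)
        sizes = [len(filter_samples(records, r)[1])
                 for r in np.linspace(0, 1, 21)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == len(records) or sizes[-1] >= sizes[0]


class TestIsomTrain:
    def test_filter_noop_equals_plain_fit(self, small_features, fast_config):
        """With r_min=0 nothing is removed, so the improved pipeline reduces
        to a plain second fit on the full data."""
        X, y = small_features
        cfg = TrainConfig(max_iters=1500, n_restarts=2, seed=11, r_min=0.0)
        model, records, kept, removed = isom_train(X, y, cfg)
        assert removed == []
        assert kept == list(range(len(X)))
        plain = train(X, cfg)
        np.testing.assert_array_equal(model.weights, plain.weights)

    def test_midpoint_samples_score_below_threshold(self, trained):
        """Samples halfway between a node and its strongest hex rival score
        r ~ 0 and are filtered at the default threshold, while the node
        prototypes themselves survive."""
        mids, protos = [], []
        for j in range(6):
            k = int(trained.grid.neighbors(j)[0])
            mids.append(normalize(0.5 * (trained.weights[j] + trained.weights[k])))
            protos.append(trained.weights[j])
        X_probe = np.vstack(mids + protos)
        records = differentiation_records(trained, X_probe)
        kept, removed = filter_samples(records, 0.15)
        assert set(removed) >= set(range(6))          # all midpoints dropped
        assert set(kept) >= set(range(6, 12))         # all prototypes kept

    def test_deterministic_given_seed(self, small_features, fast_config):
        X, y = small_features
        a, *_ = isom_train(X, y, fast_config)
        b, *_ = isom_train(X, y, fast_config)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.node_labels == b.node_labels

    def test_class_extinction_guard(self):
        """A class whose every sample is ambiguous keeps its best ones unless
        strict mode is on."""
        rng = np.random.default_rng(0)
        protos = np.eye(6, 32)
        X, y = [], []
        classes = ["LC", "RC", "LL", "LR", "WB"]
        for i, cls in enumerate(classes):
            for _ in range(10):
                X.append(normalize(protos[i] + rng.normal(0, 0.05, 32)))
                y.append(cls)
        # SS sits exactly between LC and RC prototypes -> r ~ 0 everywhere
        for _ in range(10):
            X.append(normalize(0.5 * protos[0] + 0.5 * protos[1]
                               + rng.normal(0, 0.01, 32)))
            y.append("SS")
        X = np.asarray(X)
        cfg = TrainConfig(max_iters=2000, n_restarts=3, seed=2, r_min=0.3)
        _, _, kept, _ = isom_train(X, y, cfg)
        kept_classes = {y[i] for i in kept}
        assert "SS" in kept_classes

    def test_empty_after_filter_rejected(self):
        X = np.tile(normalize(np.ones(16)), (4, 1))
        with pytest.raises(ValueError, match="every sample"):
            # identical samples on one node: r=0 against any rival
            isom_train(X, ["LC", "LC", "RC", "RC"],
                       TrainConfig(max_iters=100, n_restarts=1, r_min=0.9),
                       strict_paper_mode=True)


class TestIsomClassifier:
    def test_fit_exposes_filter_attributes(self, small_features):
        X, y = small_features
        clf = IsomPostureClassifier(max_iters=1500, n_restarts=2,
                                    random_state=3).fit(X, y)
        assert len(clf.filter_records_) == len(X)
        assert set(clf.kept_idx_) | set(clf.removed_idx_) == set(range(len(X)))
        assert not set(clf.kept_idx_) & set(clf.removed_idx_)

    def test_accuracy_not_catastrophically_below_som(self, small_features):
        X, y = small_features
        y = np.asarray(y)
        som = SomPostureClassifier(max_iters=1500, n_restarts=2,
                                   random_state=3).fit(X, y)
        isom = IsomPostureClassifier(max_iters=1500, n_restarts=2,
                                     random_state=3).fit(X, y)
        assert (isom.predict(X) == y).mean() >= (som.predict(X) == y).mean() - 0.15
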