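import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crrnet.dataset import (
    BACKGROUND_RATIO,
    THREE_CLASS_SCHEME,
    TWO_CLASS_SCHEME,
    FeatureMatrix,
    aggregate_ratio,
    apply_minmax,
    featurize,
    fit_minmax,
    make_background_test,
    make_balanced_training,
    map_classes,
    split_train_valid,
)
from crrnet.labeling import LabeledRegion
from crrnet.regions import GenomeTable, GenomicRegion, SignalTrack, bin_mean_signal


def matrix_from_counts(counts: dict[str, int], n_features: int = 3, seed: int = 0):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(n, c, dtype=object) for c, n in counts.items()])
    X = rng.normal(size=(len(labels), n_features))
    ids = [f"r{i}" for i in range(len(labels))]
    return FeatureMatrix(X, [f"f{j}" for j in range(n_features)], labels, ids)


class TestFeaturize:
    def setup_method(self):
        self.genome = GenomeTable({"chr1": 10_000})
        self.corpus = [
            LabeledRegion(GenomicRegion("chr1", 400, 600), "UK"),
            LabeledRegion(GenomicRegion("chr1", 2_000, 2_200), "UK"),
        ]

    def test_constant_tracks_give_constant_grid(self):
        tracks = {
            "a": SignalTrack.from_segments([("chr1", 0, 10_000, 1.0)]),
            "b": SignalTrack.from_segments([("chr1", 0, 10_000, 2.0)]),
        }
        m = featurize(self.corpus, tracks, 200, self.genome)
        assert np.allclose(m.X, [[1.0, 2.0], [1.0, 2.0]])
        assert m.feature_names == ["a", "b"]

    def test_grid_equals_elementwise_bin_mean_calls(self):
        rng = np.random.default_rng(4)
        entries = [("chr1", s, s + 100, float(v))
                   for s, v in zip(range(0, 5000, 250), rng.uniform(0, 5, 20))]
        track = SignalTrack.from_segments(entries)
        m = featurize(self.corpus, {"t": track}, 200, self.genome)
        for i, lr in enumerate(self.corpus):
            assert m.X[i, 0] == bin_mean_signal(track, lr.region, 200, self.genome)

    def test_empty_corpus(self):
        m = featurize([], {"a": SignalTrack.from_segments([])}, 200, self.genome)
        assert m.n_regions == 0 and m.n_features == 1

    def test_duplicate_track_names_rejected(self):
        t = SignalTrack.from_segments([])
        with pytest.raises(ValueError, match="duplicate"):
            featurize(self.corpus, [("a", t), ("a", t)], 200, self.genome)


class TestMinMaxScaling:
    def test_linear_map(self):
        m = FeatureMatrix([[2.0], [4.0], [6.0]], ["f"], ["x", "x", "y"], ["a", "b", "c"])
        scaled = apply_minmax(m, fit_minmax(m))
        assert scaled.X[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_test_values_not_clamped(self):
        train = FeatureMatrix([[2.0], [6.0]], ["f"], ["x", "y"], ["a", "b"])
        test = FeatureMatrix([[8.0]], ["f"], ["x"], ["c"])
        scaled = apply_minmax(test, fit_minmax(train))
        assert scaled.X[0, 0] == pytest.approx(1.5)

    def test_constant_feature_maps_to_zero(self):
        m = FeatureMatrix([[7.0], [7.0]], ["f"], ["x", "y"], ["a", "b"])
        assert apply_minmax(m, fit_minmax(m)).X[:, 0].tolist() == [0.0, 0.0]

    def test_unknown_features_rejected(self):
        train = FeatureMatrix([[1.0], [2.0]], ["f"], ["x", "y"], ["a", "b"])
        other = FeatureMatrix([[1.0], [2.0]], ["g"], ["x", "y"], ["a", "b"])
        with pytest.raises(KeyError):
            apply_minmax(other, fit_minmax(train))

    def test_train_rescales_to_unit_range(self):
        rng = np.random.default_rng(0)
        m = FeatureMatrix(rng.normal(size=(30, 4)), list("abcd"),
                          ["x"] * 30, [f"r{i}" for i in range(30)])
        scaled = apply_minmax(m, fit_minmax(m))
        assert np.allclose(scaled.X.min(axis=0), 0.0)
        assert np.allclose(scaled.X.max(axis=0), 1.0)


class TestMapClasses:
    def test_three_class_scheme(self):
        m = matrix_from_counts({"A-E": 1, "I-P": 1, "UK": 1})
        mapped = map_classes(m, THREE_CLASS_SCHEME)
        assert mapped.labels.tolist() == ["A-E", "BG", "BG"]

    def test_crr_super_class(self):
        m = matrix_from_counts({"A-E": 1, "A-P": 1})
        assert map_classes(m, TWO_CLASS_SCHEME).labels.tolist() == ["CRR", "CRR"]

    def test_identity_scheme(self):
        m = matrix_from_counts({"A-E": 2, "UK": 2})
        assert map_classes(m, {"A-E": "A-E", "UK": "UK"}).labels.tolist() == m.labels.tolist()

    def test_missing_label_rejected(self):
        m = matrix_from_counts({"A-E": 1, "UK": 1})
        with pytest.raises(KeyError):
            map_classes(m, {"A-E": "A-E"})


class TestBalancedTraining:
    def test_per_class_cap_rule(self):
        m = matrix_from_counts({"a": 5000, "b": 4000, "c": 2000}, n_features=2)
        train, rest = make_balanced_training(m, seed=1)
        counts = train.class_counts()
        assert counts == {"a": 3000, "b": 2800, "c": 1400}
        assert rest.class_counts() == {"a": 2000, "b": 1200, "c": 600}

    def test_small_class_takes_seventy_percent(self):
        m = matrix_from_counts({"a": 10, "b": 10})
        train, _ = make_balanced_training(m, seed=0)
        assert train.class_counts() == {"a": 7, "b": 7}

    def test_partition_property(self):
        m = matrix_from_counts({"a": 40, "b": 25})
        train, rest = make_balanced_training(m, seed=2)
        assert set(train.region_ids) | set(rest.region_ids) == set(m.region_ids)
        assert not set(train.region_ids) & set(rest.region_ids)

    def test_class_too_small_for_nonempty_draw_rejected(self):
        tiny = matrix_from_counts({"a": 1, "b": 10})
        with pytest.raises(ValueError, match="too small"):
            make_balanced_training(tiny, seed=0)

    def test_deterministic(self):
        m = matrix_from_counts({"a": 50, "b": 50})
        t1, _ = make_balanced_training(m, seed=9)
        t2, _ = make_balanced_training(m, seed=9)
        assert t1.region_ids == t2.region_ids


class TestBackgroundTest:
    def test_exact_ratio_at_limiting_class(self):
        avail = {"A-E": 100, "A-P": 150, "A-X": 120, "I-E": 300, "I-P": 400,
                 "I-X": 130, "UK": 2000}
        m = matrix_from_counts(avail)
        test = make_background_test(m, seed=0)
        assert test.class_counts() == {
            "A-E": 100, "A-P": 100, "A-X": 100, "I-E": 200, "I-P": 200,
            "I-X": 100, "UK": 1000,
        }

    def test_too_small_for_one_unit(self):
        avail = {"A-E": 1, "A-P": 1, "A-X": 1, "I-E": 2, "I-P": 2, "I-X": 1, "UK": 5}
        with pytest.raises(ValueError, match="UK"):
            make_background_test(matrix_from_counts(avail), seed=0)

    def test_missing_class_listed(self):
        avail = {"A-E": 10, "A-P": 10, "A-X": 10, "I-E": 10, "I-P": 10, "I-X": 10}
        with pytest.raises(ValueError, match="UK"):
            make_background_test(matrix_from_counts(avail), seed=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        avail=st.fixed_dictionaries(
            {c: st.integers(r, 40 * r) for c, r in BACKGROUND_RATIO.items()}
        ),
        seed=st.integers(0, 1000),
    )
    def test_ratio_property_random_availabilities(self, avail, seed):
        """Output counts are exactly unit * ratio with the largest feasible unit."""
        m = matrix_from_counts(avail, n_features=1)
        test = make_background_test(m, seed=seed)
        counts = test.class_counts()
        unit = min(avail[c] // r for c, r in BACKGROUND_RATIO.items())
        assert counts == {c: unit * r for c, r in BACKGROUND_RATIO.items()}


class TestSplitTrainValid:
    def test_stratified_fractions(self):
        m = matrix_from_counts({"a": 100, "b": 100})
        fit, valid = split_train_valid(m, 0.2, seed=0)
        assert fit.class_counts() == {"a": 80, "b": 80}
        assert valid.class_counts() == {"a": 20, "b": 20}

    def test_partition_and_determinism(self):
        m = matrix_from_counts({"a": 30, "b": 20})
        f1, v1 = split_train_valid(m, 0.25, seed=5)
        f2, v2 = split_train_valid(m, 0.25, seed=5)
        assert f1.region_ids == f2.region_ids and v1.region_ids == v2.region_ids
        assert sorted(f1.region_ids + v1.region_ids) == sorted(m.region_ids)

    def test_tiny_class_rejected(self):
        m = matrix_from_counts({"a": 1, "b": 10})
        with pytest.raises(ValueError):
            split_train_valid(m, 0.25, seed=0)

    def test_invalid_fraction_rejected(self):
        m = matrix_from_counts({"a": 10})
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                split_train_valid(m, frac, seed=0)


def test_aggregate_ratio_through_schemes():
    assert aggregate_ratio(THREE_CLASS_SCHEME) == {"A-E": 1, "A-P": 1, "BG": 16}
    assert aggregate_ratio(TWO_CLASS_SCHEME) == {"CRR": 2, "BG": 16}


def test_feature_matrix_tsv_round_trip(tmp_path):
    m = matrix_from_counts({"A-E": 3, "UK": 2}, n_features=4, seed=7)
    p = tmp_path / "m.tsv"
    m.to_tsv(p)
    back = FeatureMatrix.from_tsv(p)
    assert np.allclose(back.X, m.X)
    assert back.labels.tolist() == m.labels.tolist()
    assert back.feature_names == m.feature_names
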