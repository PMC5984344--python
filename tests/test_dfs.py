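import numpy as np
import pytest
from scipy.stats import spearmanr

from crrnet import SimSpec, simulate_feature_data
from crrnet.dataset import FeatureMatrix, apply_minmax, fit_minmax, split_train_valid
from crrnet.dfs import (
    DFSConfig,
    DFSNetwork,
    FeatureImportance,
    feature_weights,
    incremental_feature_eval,
    randomized_dfs,
    top_k_features,
    train_dfs,
)
from crrnet.mlp import NetworkSpec, TrainConfig, train_network


@pytest.fixture(scope="module")
def single_signal_split():
    """Feature 0 separates two classes; features 1..9 are pure noise."""
    matrix, _ = simulate_feature_data(
        SimSpec(
            seed=21,
            class_sizes={"A-E": 300, "BG": 300},
            n_informative=1,
            n_noise=9,
        )
    )
    scaled = apply_minmax(matrix, fit_minmax(matrix))
    return split_train_valid(scaled, seed=2)


class TestTrainDfs:
    def test_frozen_identity_weights_reduce_to_plain_network(self, single_signal_split):
        """lambda=0 with w frozen at ones reproduces the plain net bitwise."""
        fit_s, val_s = single_signal_split
        cfg = TrainConfig(max_iter=40, seed=13)
        plain = train_network(fit_s, val_s, NetworkSpec((8,)), cfg)
        dfs_net = train_dfs(
            fit_s, val_s,
            DFSConfig(lam=0.0, body=NetworkSpec((8,)), train=cfg),
            freeze_w=True,
        )
        assert np.array_equal(
            plain.predict_proba(val_s.X), dfs_net.predict_proba(val_s.X)
        )

    def test_planted_feature_dominates_weights(self, single_signal_split):
        fit_s, val_s = single_signal_split
        net = train_dfs(
            fit_s, val_s,
            DFSConfig(lam=0.05, body=NetworkSpec((8,)),
                      train=TrainConfig(max_iter=80, seed=0)),
        )
        w = np.abs(net.w)
        assert w[0] > w[1:].max()

    def test_huge_penalty_kills_all_weights(self, single_signal_split):
        fit_s, val_s = single_signal_split
        net = train_dfs(
            fit_s, val_s,
            DFSConfig(lam=50.0, body=NetworkSpec((8,)),
                      train=TrainConfig(max_iter=60, seed=0)),
        )
        assert np.all(np.abs(net.w) < 1e-3)
        # with every input silenced the classifier cannot beat chance
        probs = net.predict_proba(val_s.X)
        acc = np.mean(
            np.array(net.classes, dtype=object)[probs.argmax(axis=1)] == val_s.labels
        )
        assert acc <= 0.6

    def test_zero_weight_features_are_inert(self, single_signal_split):
        """Arbitrary perturbation of a w_i = 0 feature changes no score."""
        fit_s, val_s = single_signal_split
        net = train_dfs(
            fit_s, val_s,
            DFSConfig(lam=0.2, body=NetworkSpec((8,)),
                      train=TrainConfig(max_iter=80, seed=1)),
        )
        zero_idx = np.flatnonzero(net.w == 0.0)
        assert len(zero_idx) > 0
        before = net.predict_proba(val_s.X)
        X = val_s.X.copy()
        X[:, zero_idx] += 1e9
        after = net.predict_proba(X)
        assert np.array_equal(before, after)

    def test_sparsity_non_increasing_along_penalty_path(self, single_signal_split):
        fit_s, val_s = single_signal_split
        nonzero = []
        for lam in (0.0, 0.02, 0.2, 2.0):
            net = train_dfs(
                fit_s, val_s,
                DFSConfig(lam=lam, body=NetworkSpec((8,)),
                          train=TrainConfig(max_iter=60, seed=3)),
            )
            nonzero.append(int(np.sum(np.abs(net.w) > 1e-6)))
        violations = sum(b > a for a, b in zip(nonzero, nonzero[1:]))
        assert violations <= 1


class TestFeatureWeights:
    def test_absolute_values_by_name(self):
        body = train_network(
            *_tiny_split(), NetworkSpec(()), TrainConfig(max_iter=5, seed=0)
        )
        net = DFSNetwork(w=np.array([0.5, -0.2, 0.0]), body=body)
        assert feature_weights(net) == {"f0": 0.5, "f1": 0.2, "f2": 0.0}

    def test_top_k_ranking_stable_under_ties(self):
        w = np.array([0.5, 0.9, 0.5, 0.0])
        assert top_k_features(w, 3).tolist() == [1, 0, 2]

    def test_top_k_never_selects_exact_zeros(self):
        w = np.array([0.4, 0.0, 0.0, 0.1])
        assert top_k_features(w, 3).tolist() == [0, 3]


def _tiny_split():
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(20, 3))
    y = np.array(["a", "b"] * 10, dtype=object)
    m = FeatureMatrix(X, ["f0", "f1", "f2"], y, [f"r{i}" for i in range(20)])
    return m, m


class TestRandomizedDfs:
    CFG = DFSConfig(lam=0.02, body=NetworkSpec((8,)), train=TrainConfig(max_iter=40, seed=0))

    def test_single_run_selects_exactly_k(self, single_signal_split):
        fit_s, _ = single_signal_split
        imp = randomized_dfs(fit_s, R=1, K=3, config=self.CFG, seed=9)
        assert np.sum(imp.probabilities == 1.0) == 3
        assert np.sum(imp.probabilities == 0.0) == len(imp.feature_names) - 3

    def test_importances_are_selection_frequencies(self, single_signal_split):
        fit_s, _ = single_signal_split
        imp = randomized_dfs(fit_s, R=4, K=2, config=self.CFG, seed=9)
        assert np.all((imp.probabilities * 4) % 1 == 0)  # multiples of 1/R
        assert imp.probabilities.min() >= 0 and imp.probabilities.max() <= 1

    def test_k_larger_than_feature_count_rejected(self, single_signal_split):
        fit_s, _ = single_signal_split
        with pytest.raises(ValueError):
            randomized_dfs(fit_s, R=1, K=11, config=self.CFG, seed=0)

    def test_deterministic_given_seed(self, single_signal_split):
        fit_s, _ = single_signal_split
        a = randomized_dfs(fit_s, R=3, K=3, config=self.CFG, seed=5)
        b = randomized_dfs(fit_s, R=3, K=3, config=self.CFG, seed=5)
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_importances_stable_across_disjoint_seed_sets(self, planted_scaled):
        """Two independent seed sets rank the planted features identically."""
        scaled, truth = planted_scaled
        cfg = DFSConfig(lam=0.3, body=NetworkSpec((16,)),
                        train=TrainConfig(max_iter=80, seed=0))
        a = randomized_dfs(scaled, R=25, K=10, config=cfg, seed=100)
        b = randomized_dfs(scaled, R=25, K=10, config=cfg, seed=20_000)
        rho = spearmanr(a.probabilities, b.probabilities).statistic
        assert rho >= 0.9
        n_inf = len(truth.informative_features)
        for imp in (a, b):
            top = set(np.argsort(-imp.probabilities, kind="stable")[:n_inf])
            assert top == set(range(n_inf))

    def test_tsv_output(self, tmp_path, single_signal_split):
        fit_s, _ = single_signal_split
        imp = randomized_dfs(fit_s, R=2, K=3, config=self.CFG, seed=1)
        p = tmp_path / "imp.tsv"
        imp.to_tsv(p)
        header = p.read_text().splitlines()[0]
        assert header == "feature\timportance\tmean_abs_w"


class TestIncrementalEval:
    def test_full_prefix_matches_direct_run(self, planted_scaled):
        scaled, truth = planted_scaled
        sub = scaled.select_rows(np.arange(0, scaled.n_regions, 6))
        names = list(sub.feature_names)
        cfg = TrainConfig(max_iter=30, seed=7)
        curve = incremental_feature_eval(
            names[-2:], sub, sub, NetworkSpec(()), cfg, max_m=2
        )
        # direct run on the same 2 features reproduces the m=2 point
        from crrnet.dfs import incremental_feature_eval as ife

        again = ife(names[-2:], sub, sub, NetworkSpec(()), cfg, max_m=2)
        assert curve == again

    def test_uninformative_prefix_near_chance(self, planted_scaled):
        """Noise-only features give auPRC near class prevalence."""
        scaled, truth = planted_scaled
        sub = scaled.select_rows(np.arange(0, scaled.n_regions, 3))
        adversarial = truth.noise_features[:1]
        cfg = TrainConfig(max_iter=30, seed=7)
        curve = incremental_feature_eval(
            adversarial, sub, sub, NetworkSpec(()), cfg
        )
        prevalence = 1 / 3  # balanced three-class corpus
        assert curve[0][1] <= prevalence + 0.15

    def test_informative_prefix_beats_noise_prefix(self, planted_scaled):
        scaled, truth = planted_scaled
        sub = scaled.select_rows(np.arange(0, scaled.n_regions, 3))
        cfg = TrainConfig(max_iter=40, seed=7)
        good = incremental_feature_eval(
            truth.informative_features[:3], sub, sub, NetworkSpec(()), cfg, max_m=3
        )
        bad = incremental_feature_eval(
            truth.noise_features[:3], sub, sub, NetworkSpec(()), cfg, max_m=3
        )
        assert good[-1][1] > bad[-1][1] + 0.2

    def test_empty_ranking_rejected(self, planted_scaled):
        scaled, _ = planted_scaled
        with pytest.raises(ValueError):
            incremental_feature_eval([], scaled, scaled, NetworkSpec(()), TrainConfig())
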