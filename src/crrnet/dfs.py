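"""Deep feature selection (DFS) and its randomized stability extension.

A one-to-one linear layer precedes the feedforward classifier: input feature
x_i enters the network as w_i * x_i, so the selection layer's parameter is a
single vector w.  An l1 penalty lambda * ||w||_1 shrinks elements of w to
exactly zero (proximal soft-threshold updates), and a feature with w_i = 0
has provably no influence on any prediction.  Because the upper layers are
non-linear, a single subset of features can be selected for multi-class
problems.

Randomized DFS repeats training R times on class-stratified half-subsamples
with per-feature penalties perturbed by Uniform[alpha, 1] multipliers (the
randomized-LASSO scheme), records the top-K features by |w| each run, and
reports each feature's empirical selection probability as its importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import FeatureMatrix, apply_minmax, fit_minmax, split_train_valid
from .evaluation import macro_ovr, pr_auc
from .mlp import (
    NetworkSpec,
    TrainConfig,
    TrainedNetwork,
    _encode_labels,
    predict_membership,
    sgd_train,
    train_network,
)

#: Weights at or below this magnitude are treated as exactly zero when
#: ranking; proximal updates produce true zeros, so this only guards
#: against representation noise.
ZERO_TOL = 0.0


@dataclass(frozen=True)
class DFSConfig:
    """Sparsity and training settings for the feature-selection network."""

    lam: float = 0.2  # l1 strength on the selection layer
    alpha: float = 0.5  # lower bound of the per-feature penalty multiplier
    l1_mix: float = 1.0  # 1.0 = pure l1; <1 mixes in an l2 (elastic-net) term
    body: NetworkSpec = field(default_factory=lambda: NetworkSpec((16,)))
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= self.l1_mix <= 1:
            raise ValueError("l1_mix must be in [0, 1]")


@dataclass
class DFSNetwork:
    """Selection weights w plus the trained body network acting on w*x."""

    w: np.ndarray
    body: TrainedNetwork

    @property
    def feature_names(self) -> list[str]:
        return self.body.feature_names

    @property
    def classes(self) -> list[str]:
        return self.body.classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.body.predict_proba(np.asarray(X, dtype=float) * self.w)

    def predict_membership(self, m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        scaled = FeatureMatrix(
            m.X * self.w, list(m.feature_names), m.labels, list(m.region_ids)
        )
        return predict_membership(self.body, scaled)


def train_dfs(
    fit_subset: FeatureMatrix,
    valid_subset: FeatureMatrix,
    config: DFSConfig,
    freeze_w: bool = False,
    lam_per_feature: np.ndarray | None = None,
) -> DFSNetwork:
    """Jointly optimize the selection vector w and the body network.

    w starts at ones; with ``freeze_w`` and lam = 0 the result is identical
    to a plain network of the same body spec and seed (shared SGD loop, no
    extra random draws).  ``lam_per_feature`` overrides the uniform lam, as
    used by the randomized runs.
    """
    if fit_subset.feature_names != valid_subset.feature_names:
        raise ValueError("fit and validation subsets disagree on features")
    classes = sorted({str(l) for l in fit_subset.labels} | {str(l) for l in valid_subset.labels})
    y = _encode_labels(fit_subset.labels, classes)
    yv = _encode_labels(valid_subset.labels, classes)
    p = fit_subset.n_features
    lam = (
        np.full(p, config.lam) if lam_per_feature is None
        else np.asarray(lam_per_feature, dtype=float)
    )
    Ws, bs, w, history = sgd_train(
        fit_subset.X, y, valid_subset.X, yv, len(classes),
        config.body, config.train,
        w=np.ones(p), freeze_w=freeze_w, l1=lam, l1_mix=config.l1_mix,
    )
    body = TrainedNetwork(
        spec=config.body, weights=Ws, biases=bs, classes=classes,
        feature_names=list(fit_subset.feature_names), history=history,
    )
    return DFSNetwork(w=w, body=body)


def feature_weights(net: DFSNetwork) -> dict[str, float]:
    """|w_i| per named feature, in input order."""
    return {name: float(abs(wi)) for name, wi in zip(net.feature_names, net.w)}


def top_k_features(w: np.ndarray, k: int) -> np.ndarray:
    """Indices of the K largest |w|, descending, index tie-break.

    Features with weight exactly zero are never selected (a zero-weight
    feature is inert by construction), so fewer than K indices may return.
    """
    absw = np.abs(np.asarray(w, dtype=float))
    order = np.argsort(-absw, kind="stable")
    order = order[absw[order] > ZERO_TOL]
    return order[:k]


@dataclass
class FeatureImportance:
    """Empirical selection probabilities from randomized DFS."""

    feature_names: list[str]
    probabilities: np.ndarray  # (times in top-K) / R
    mean_abs_w: np.ndarray
    n_runs: int
    k: int

    def ranked(self) -> list[tuple[str, float]]:
        order = np.argsort(-self.probabilities, kind="stable")
        return [(self.feature_names[i], float(self.probabilities[i])) for i in order]

    def to_tsv(self, path) -> None:
        import pandas as pd

        order = np.argsort(-self.probabilities, kind="stable")
        pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in order],
                "importance": self.probabilities[order],
                "mean_abs_w": self.mean_abs_w[order],
            }
        ).to_csv(path, sep="\t", index=False)


def _stratified_subsample(
    labels: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    labels = labels.astype(str)
    picks = []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        k = max(1, int(round(frac * len(idx))))
        picks.append(np.sort(rng.choice(idx, size=k, replace=False)))
    return np.concatenate(picks)


def randomized_dfs(
    train: FeatureMatrix,
    R: int,
    K: int = 10,
    subsample: float = 0.5,
    config: DFSConfig | None = None,
    seed: int = 0,
    valid_frac: float = 0.25,
) -> FeatureImportance:
    """Stability selection: importance = top-K selection frequency over R runs."""
    config = config or DFSConfig()
    if R < 1:
        raise ValueError("R must be >= 1")
    if K > train.n_features:
        raise ValueError(f"K={K} exceeds feature count {train.n_features}")
    p = train.n_features
    counts = np.zeros(p)
    abs_sum = np.zeros(p)
    children = np.random.SeedSequence(seed).spawn(R)
    for child in children:
        s1, s2, s3 = child.generate_state(3) % (2**31)
        rng = np.random.default_rng(int(s1))
        rows = _stratified_subsample(train.labels, subsample, rng)
        sub = train.select_rows(rows)
        multipliers = rng.uniform(config.alpha, 1.0, size=p)
        fit_sub, valid_sub = split_train_valid(sub, valid_frac, seed=int(s2))
        run_cfg = replace(config, train=replace(config.train, seed=int(s3)))
        net = train_dfs(
            fit_sub, valid_sub, run_cfg, lam_per_feature=config.lam * multipliers
        )
        sel = top_k_features(net.w, K)
        counts[sel] += 1
        abs_sum += np.abs(net.w)
    return FeatureImportance(
        feature_names=list(train.feature_names),
        probabilities=counts / R,
        mean_abs_w=abs_sum / R,
        n_runs=R,
        k=K,
    )


def incremental_feature_eval(
    ranked_features: Sequence[str],
    train: FeatureMatrix,
    test: FeatureMatrix,
    body_spec: NetworkSpec,
    config: TrainConfig,
    valid_frac: float = 0.25,
    max_m: int | None = None,
) -> list[tuple[int, float]]:
    """auPRC of networks trained on growing prefixes of a feature ranking.

    For m = 1..M the top-m features are kept, scaling factors are re-fit on
    the training rows, a network is trained with the given config, and the
    macro one-vs-rest auPRC on the test set is recorded.
    """
    if not ranked_features:
        raise ValueError("ranked feature list is empty")
    M = min(max_m or len(ranked_features), len(ranked_features))
    curve: list[tuple[int, float]] = []
    for m in range(1, M + 1):
        names = list(ranked_features[:m])
        try:
            sub_train = train.select_features(names)
            factors = fit_minmax(sub_train)
            fit_sub, valid_sub = split_train_valid(
                apply_minmax(sub_train, factors), valid_frac, seed=config.seed
            )
            net = train_network(fit_sub, valid_sub, body_spec, config, scaling=factors)
            scores, _ = predict_membership(net, test.select_features(names))
            auprc = macro_ovr(pr_auc, scores, test.labels, net.classes)
        except Exception as exc:
            raise RuntimeError(f"incremental evaluation failed at m={m}") from exc
        curve.append((m, float(auprc)))
    return curve
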