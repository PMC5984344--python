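"""Feedforward softmax classifier trained by mini-batch SGD with momentum.

The protocol: rectified-linear hidden layers (at most three, searched up to
256/128/64 units), multinomial output with normalized membership scores,
cross-entropy loss with an l2 penalty, batch size 100, a cap of 1000
iterations (epochs), an optionally decaying learning rate, and early
termination on a validation subset with the best-validation snapshot
returned.  All randomness (weight initialization, batch shuffling) flows
from a single seeded generator so training is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import FeatureMatrix, ScalingFactors

MAX_HIDDEN_LAYERS = 3
#: Unit caps per hidden layer explored during model search.
HIDDEN_UNIT_CAPS = (256, 128, 64)


class TrainingDivergedError(RuntimeError):
    def __init__(self, iteration: int, learning_rate: float):
        super().__init__(
            f"loss became non-finite at iteration {iteration} "
            f"(learning rate {learning_rate:g}); reduce the learning rate"
        )
        self.iteration = iteration
        self.learning_rate = learning_rate


@dataclass(frozen=True)
class NetworkSpec:
    """Hidden layer sizes; empty tuple = softmax regression (no hidden layer)."""

    hidden: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.hidden) > MAX_HIDDEN_LAYERS:
            raise ValueError(f"at most {MAX_HIDDEN_LAYERS} hidden layers")
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    lr_decay: float = 0.0  # rate_i = learning_rate / (1 + lr_decay * i)
    l2: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 100
    max_iter: int = 1000
    patience: int = 10  # validation checks without improvement before stopping
    eval_every: int = 5  # validate every this many iterations (epochs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.l2 < 0 or self.momentum < 0 or self.lr_decay < 0:
            raise ValueError("l2, momentum and lr_decay must be non-negative")


def _init_params(sizes: Sequence[int], rng: np.random.Generator):
    """Symmetric uniform init scaled by fan-in + fan-out."""
    Ws, bs = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        Ws.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        bs.append(np.zeros(n_out))
    return Ws, bs


def _forward(Ws, bs, X):
    acts = [X]
    a = X
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = np.maximum(a @ W + b, 0.0)
        acts.append(a)
    logits = a @ Ws[-1] + bs[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return acts, probs


def _cross_entropy(probs, y_idx):
    eps = 1e-300
    return float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + eps)))


def _backward(Ws, bs, acts, probs, y_idx, l2):
    """Gradients of mean cross-entropy + (l2/2)*sum ||W||^2 w.r.t. weights.

    Returns (dWs, dbs, dX) where dX is the gradient w.r.t. the input batch
    (needed by the one-to-one feature-selection layer).
    """
    B = len(y_idx)
    delta = probs.copy()
    delta[np.arange(B), y_idx] -= 1.0
    delta /= B
    dWs = [None] * len(Ws)
    dbs = [None] * len(bs)
    for li in range(len(Ws) - 1, -1, -1):
        dWs[li] = acts[li].T @ delta + l2 * Ws[li]
        dbs[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ Ws[li].T) * (acts[li] > 0)
        else:
            delta = delta @ Ws[li].T
    return dWs, dbs, delta


def _soft_threshold(x: np.ndarray, t) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def sgd_train(
    X: np.ndarray,
    y_idx: np.ndarray,
    Xv: np.ndarray,
    yv_idx: np.ndarray,
    n_classes: int,
    spec: NetworkSpec,
    config: TrainConfig,
    *,
    w: np.ndarray | None = None,
    freeze_w: bool = True,
    l1: np.ndarray | None = None,
    l1_mix: float = 1.0,
):
    """Shared SGD loop for the plain network and the feature-selection variant.

    When ``w`` is given, the effective input is the elementwise product w*x;
    if not frozen, w receives momentum-SGD updates on the smooth loss followed
    by a proximal soft-threshold step for the per-feature l1 penalty ``l1``
    (mixed with an l2 term when ``l1_mix`` < 1).  With w frozen at ones and
    zero penalty this reduces exactly to the plain network.

    Returns (Ws, bs, w, history) for the best-validation snapshot.
    """
    rng = np.random.default_rng(config.seed)
    sizes = [X.shape[1], *spec.hidden, n_classes]
    Ws, bs = _init_params(sizes, rng)
    vWs = [np.zeros_like(W) for W in Ws]
    vbs = [np.zeros_like(b) for b in bs]
    if w is not None:
        w = np.array(w, dtype=float)
        vw = np.zeros_like(w)
        if l1 is None:
            l1 = np.zeros_like(w)
        else:
            l1 = np.broadcast_to(np.asarray(l1, dtype=float), w.shape).copy()

    def val_loss(cWs, cbs, cw):
        Zv = Xv if cw is None else Xv * cw
        _, pv = _forward(cWs, cbs, Zv)
        return _cross_entropy(pv, yv_idx)

    best = ([W.copy() for W in Ws], [b.copy() for b in bs],
            None if w is None else w.copy())
    best_val = val_loss(*best)
    history = {"train_loss": [], "valid_loss": [(0, best_val)]}
    checks_since_best = 0
    n = X.shape[0]

    for it in range(config.max_iter):
        lr = config.learning_rate / (1.0 + config.lr_decay * it)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            sel = order[lo : lo + config.batch_size]
            Xb = X[sel]
            Zb = Xb if w is None else Xb * w
            acts, probs = _forward(Ws, bs, Zb)
            loss = _cross_entropy(probs, y_idx[sel])
            if not np.isfinite(loss):
                raise TrainingDivergedError(it, lr)
            epoch_loss += loss
            n_batches += 1
            dWs, dbs, dZ = _backward(Ws, bs, acts, probs, y_idx[sel], config.l2)
            for li in range(len(Ws)):
                vWs[li] = config.momentum * vWs[li] - lr * dWs[li]
                vbs[li] = config.momentum * vbs[li] - lr * dbs[li]
                Ws[li] += vWs[li]
                bs[li] += vbs[li]
            if w is not None and not freeze_w:
                dw = (dZ * Xb).sum(axis=0) + (1.0 - l1_mix) * l1 * w
                vw = config.momentum * vw - lr * dw
                w = w + vw
                w = _soft_threshold(w, lr * l1_mix * l1)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))

        if (it + 1) % config.eval_every == 0 or it + 1 == config.max_iter:
            vloss = val_loss(Ws, bs, w)
            history["valid_loss"].append((it + 1, vloss))
            if vloss < best_val:
                best_val = vloss
                best = ([W.copy() for W in Ws], [b.copy() for b in bs],
                        None if w is None else w.copy())
                checks_since_best = 0
            else:
                checks_since_best += 1
                if checks_since_best >= config.patience:
                    break
    history["best_valid_loss"] = best_val
    return best[0], best[1], best[2], history


@dataclass
class TrainedNetwork:
    """A trained classifier with its class order and optional scaling factors."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: list[str]
    feature_names: list[str]
    scaling: ScalingFactors | None = None
    history: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return int(sum(W.size for W in self.weights) + sum(b.size for b in self.biases))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, probs = _forward(self.weights, self.biases, np.asarray(X, dtype=float))
        return probs

    def to_json(self, path) -> None:
        payload = {
            "format": "crrnet-model-v1",
            "hidden": list(self.spec.hidden),
            "classes": self.classes,
            "feature_names": self.feature_names,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaling": None
            if self.scaling is None
            else {
                "feature_names": self.scaling.feature_names,
                "mins": self.scaling.mins.tolist(),
                "maxs": self.scaling.maxs.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "crrnet-model-v1":
            raise ValueError("unrecognized model file format")
        scaling = None
        if payload["scaling"] is not None:
            s = payload["scaling"]
            scaling = ScalingFactors(
                s["feature_names"], np.array(s["mins"]), np.array(s["maxs"])
            )
        return cls(
            spec=NetworkSpec(tuple(payload["hidden"])),
            weights=[np.array(W) for W in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
            classes=list(payload["classes"]),
            feature_names=list(payload["feature_names"]),
            scaling=scaling,
        )


def _encode_labels(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[str(l)] for l in labels], dtype=np.intp)


def train_network(
    fit_subset: FeatureMatrix,
    valid_subset: FeatureMatrix,
    spec: NetworkSpec,
    config: TrainConfig,
    scaling: ScalingFactors | None = None,
) -> TrainedNetwork:
    """Train on the fit subset with early termination on the validation subset.

    Inputs are expected to be scaled already; ``scaling`` is attached to the
    returned network so genome-wide prediction can apply the same factors.
    """
    if fit_subset.feature_names != valid_subset.feature_names:
        raise ValueError("fit and validation subsets disagree on features")
    classes = sorted({str(l) for l in fit_subset.labels} | {str(l) for l in valid_subset.labels})
    y = _encode_labels(fit_subset.labels, classes)
    yv = _encode_labels(valid_subset.labels, classes)
    Ws, bs, _, history = sgd_train(
        fit_subset.X, y, valid_subset.X, yv, len(classes), spec, config
    )
    return TrainedNetwork(
        spec=spec,
        weights=Ws,
        biases=bs,
        classes=classes,
        feature_names=list(fit_subset.feature_names),
        scaling=scaling,
        history=history,
    )


def predict_membership(net: TrainedNetwork, m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-region per-class membership scores and argmax labels.

    Applies the network's stored scaling factors when present.  Scores are in
    [0,1] and each row sums to 1; ties resolve to the lowest class index.
    """
    if m.feature_names != net.feature_names:
        missing = sorted(set(net.feature_names) - set(m.feature_names))
        raise KeyError(f"feature mismatch; missing features: {missing}")
    X = m.X
    if net.scaling is not None:
        X = net.scaling.transform(X, m.feature_names)
    scores = net.predict_proba(X)
    labels = np.array([net.classes[i] for i in scores.argmax(axis=1)], dtype=object)
    return scores, labels


def default_search_grid(config: TrainConfig | None = None):
    """Architecture grid from no hidden layers up to three, within unit caps."""
    config = config or TrainConfig()
    specs = [
        NetworkSpec(()),
        NetworkSpec((64,)),
        NetworkSpec((256,)),
        NetworkSpec((128, 64)),
        NetworkSpec((256, 128)),
        NetworkSpec((256, 128, 64)),
    ]
    return [(s, config) for s in specs]


def model_search(
    fit_subset: FeatureMatrix,
    valid_subset: FeatureMatrix,
    grid: Sequence[tuple[NetworkSpec, TrainConfig]],
    scaling: ScalingFactors | None = None,
) -> tuple[NetworkSpec, TrainConfig, TrainedNetwork]:
    """Train every candidate and keep the best validation class-wise rate.

    Ties break toward the network with fewer parameters.
    """
    from .evaluation import class_wise_rate, confusion_matrix

    if not grid:
        raise ValueError("empty model grid")
    best = None
    errors = []
    for spec, config in grid:
        try:
            net = train_network(fit_subset, valid_subset, spec, config, scaling=scaling)
        except Exception as exc:  # noqa: BLE001 - aggregated below
            errors.append((spec, exc))
            continue
        # the validation subset is already scaled; bypass the attached factors
        probs = net.predict_proba(valid_subset.X)
        pred = np.array([net.classes[i] for i in probs.argmax(axis=1)], dtype=object)
        cm = confusion_matrix(valid_subset.labels, pred, net.classes)
        cwr = class_wise_rate(cm)
        key = (-cwr, net.n_parameters())
        if best is None or key < best[0]:
            best = (key, spec, config, net)
    if best is None:
        raise RuntimeError(f"all {len(errors)} model candidates failed: {errors}")
    return best[1], best[2], best[3]
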