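"""Classification metrics and the resample-retrain evaluation protocol.

Metrics follow the conventions the printed numbers depend on:

* class-wise rate (CWR): the unweighted mean of per-class sensitivities,
  which for two classes equals the mean of sensitivity and specificity;
* auROC: probability that a random positive outscores a random negative,
  with ties counted one half;
* auPRC: step-wise integration of precision over recall, thresholding at
  every item in descending-score order with index tie-break (no
  interpolation) — i.e. average precision.

Multi-class areas are macro-averaged one-vs-rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import (
    BACKGROUND_RATIO,
    FeatureMatrix,
    aggregate_ratio,
    apply_minmax,
    fit_minmax,
    make_background_test,
    make_balanced_training,
    map_classes,
    split_train_valid,
)
from .mlp import NetworkSpec, TrainConfig, model_search, predict_membership


def confusion_matrix(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence[str]
) -> np.ndarray:
    """Square count grid indexed (true class, predicted class)."""
    lut = {str(c): i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        cm[lut[str(t)], lut[str(p)]] += 1
    return cm


def class_wise_rate(cm: np.ndarray) -> float:
    """Unweighted mean of per-class sensitivities (recalls).

    For two classes this equals the averaged sensitivity and specificity.
    """
    cm = np.asarray(cm)
    totals = cm.sum(axis=1)
    if np.any(totals == 0):
        empty = np.flatnonzero(totals == 0).tolist()
        raise ValueError(f"true classes with no examples at indices {empty}")
    return float(np.mean(np.diag(cm) / totals))


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pairwise-concordance auROC; tied scores count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks implement the tie-1/2 convention
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise area under the precision-recall curve.

    Items are ranked by descending score with index tie-break; precision is
    accumulated at each recall step (each positive encountered), without
    interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("at least one positive example required")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    tp = np.cumsum(ranked)
    k = np.arange(1, len(ranked) + 1)
    precision = tp / k
    return float(precision[ranked == 1].sum() / n_pos)


def macro_ovr(
    metric, scores: np.ndarray, labels: Sequence, classes: Sequence[str]
) -> float:
    """Macro one-vs-rest reduction of a binary score metric."""
    labels = np.asarray(labels).astype(str)
    vals = []
    for j, c in enumerate(classes):
        y = (labels == str(c)).astype(int)
        vals.append(metric(scores[:, j], y))
    return float(np.mean(vals))


@dataclass
class EvalSummary:
    """Per-run metrics with means and standard deviations across runs."""

    runs: pd.DataFrame  # columns: run, cwr, auroc, auprc

    @property
    def mean(self) -> dict[str, float]:
        return self.runs[["cwr", "auroc", "auprc"]].mean().to_dict()

    @property
    def std(self) -> dict[str, float]:
        return self.runs[["cwr", "auroc", "auprc"]].std(ddof=1).fillna(0.0).to_dict()

    def to_long(self) -> pd.DataFrame:
        return self.runs.melt(id_vars="run", var_name="metric", value_name="value")


def _default_task_ratio(
    corpus_labels: set[str], scheme: Mapping[str, str]
) -> dict[str, int]:
    """Background ratio keyed by the corpus labels.

    Base-labelled corpora use the canonical seven-class ratio; corpora already
    carrying task classes use the seven-class ratio aggregated through the
    scheme (e.g. A-E:A-P:BG = 1:1:16).
    """
    if corpus_labels <= set(BACKGROUND_RATIO):
        return {c: BACKGROUND_RATIO[c] for c in corpus_labels}
    from .dataset import THREE_CLASS_SCHEME, TWO_CLASS_SCHEME

    agg = aggregate_ratio(scheme)
    canonical = {
        **aggregate_ratio(THREE_CLASS_SCHEME),
        **aggregate_ratio(TWO_CLASS_SCHEME),
    }
    out: dict[str, int] = {}
    for c in corpus_labels:
        value = agg.get(c, canonical.get(c))
        if value is None:
            raise ValueError(
                f"no background ratio derivable for label {c!r}; "
                "pass test_ratio explicitly"
            )
        out[c] = value
    return out


def run_single_protocol(
    corpus: FeatureMatrix,
    scheme: Mapping[str, str],
    seed: int,
    grid: Sequence[tuple[NetworkSpec, TrainConfig]],
    valid_frac: float = 0.25,
    test_ratio: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """One resample-train-test pass; returns cwr/auroc/auprc.

    Balanced training and the background-ratio test draw operate on the
    corpus labels; the scheme is applied before scaling and training.
    """
    labels = {str(l) for l in corpus.labels}
    ratio = dict(test_ratio) if test_ratio is not None else _default_task_ratio(labels, scheme)
    task_scheme = {l: scheme.get(l, l) for l in labels}

    train, remainder = make_balanced_training(
        map_classes(corpus, task_scheme), seed=seed
    )
    # the remainder rows carry the corpus (base) labels for the ratio draw
    row_of = {rid: i for i, rid in enumerate(corpus.region_ids)}
    base_remainder = corpus.select_rows([row_of[rid] for rid in remainder.region_ids])
    test = map_classes(make_background_test(base_remainder, seed=seed, ratio=ratio), task_scheme)

    factors = fit_minmax(train)
    train_scaled = apply_minmax(train, factors)
    fit_subset, valid_subset = split_train_valid(train_scaled, valid_frac, seed=seed)
    seeded_grid = [(s, TrainConfig(**{**c.__dict__, "seed": seed})) for s, c in grid]
    _, _, net = model_search(fit_subset, valid_subset, seeded_grid, scaling=factors)

    scores, pred = predict_membership(net, test)
    cm = confusion_matrix(test.labels, pred, net.classes)
    return {
        "cwr": class_wise_rate(cm),
        "auroc": macro_ovr(roc_auc, scores, test.labels, net.classes),
        "auprc": macro_ovr(pr_auc, scores, test.labels, net.classes),
    }


def repeat_protocol(
    corpus: FeatureMatrix,
    scheme: Mapping[str, str],
    n_runs: int,
    base_seed: int,
    grid: Sequence[tuple[NetworkSpec, TrainConfig]],
    valid_frac: float = 0.25,
    test_ratio: Mapping[str, int] | None = None,
) -> EvalSummary:
    """Repeat the resample-retrain protocol and summarize mean/deviation."""
    rows = []
    failures = []
    for run in range(n_runs):
        try:
            metrics = run_single_protocol(
                corpus, scheme, base_seed + run, grid, valid_frac, test_ratio
            )
        except Exception as exc:  # noqa: BLE001 - recorded, summary needs >=1 success
            failures.append((run, exc))
            continue
        rows.append({"run": run, **metrics})
    if not rows:
        raise RuntimeError(f"all {n_runs} runs failed; first failure: {failures[0][1]!r}")
    return EvalSummary(runs=pd.DataFrame(rows))
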