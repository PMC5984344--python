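"""Feature matrices, [0,1] scaling, class schemes, and train/test construction.

The evaluation protocol trains on a balanced subset (at most 70% of each
class and at most 3000 examples per class) and tests on a remainder sample
whose class composition mimics the genome-wide background,
A-E:A-P:A-X:I-E:I-P:I-X:UK = 1:1:1:2:2:1:10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labeling import BASE_LABELS, LabeledRegion
from .regions import DEFAULT_BIN_WIDTH, GenomeTable, SignalTrack, bin_mean_signal

#: Genome-wide background composition used for test-set construction.
BACKGROUND_RATIO: dict[str, int] = {
    "A-E": 1, "A-P": 1, "A-X": 1, "I-E": 2, "I-P": 2, "I-X": 1, "UK": 10,
}

#: Three-class task: active enhancer vs active promoter vs super background.
THREE_CLASS_SCHEME: dict[str, str] = {
    "A-E": "A-E", "A-P": "A-P",
    "I-E": "BG", "I-P": "BG", "A-X": "BG", "I-X": "BG", "UK": "BG",
}

#: Two-class task: merged cis-regulatory super-class vs super background.
TWO_CLASS_SCHEME: dict[str, str] = {
    "A-E": "CRR", "A-P": "CRR",
    "I-E": "BG", "I-P": "BG", "A-X": "BG", "I-X": "BG", "UK": "BG",
}

IDENTITY_SCHEME: dict[str, str] = {lbl: lbl for lbl in BASE_LABELS}


@dataclass
class FeatureMatrix:
    """Regions x named features with aligned class labels."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature name count does not match columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("label count does not match rows")
        if len(self.region_ids) != self.X.shape[0]:
            raise ValueError("region id count does not match rows")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.X[idx],
            list(self.feature_names),
            self.labels[idx],
            [self.region_ids[i] for i in idx],
        )

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        cols = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.X[:, cols], list(names), self.labels, list(self.region_ids))

    def with_labels(self, labels) -> "FeatureMatrix":
        return FeatureMatrix(self.X, list(self.feature_names), labels, list(self.region_ids))

    def class_counts(self) -> dict[str, int]:
        uniq, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "region_id", self.region_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "region_id" or df.columns[1] != "label":
            raise ValueError("TSV must start with region_id and label columns")
        return cls(
            df.iloc[:, 2:].to_numpy(dtype=float),
            list(df.columns[2:]),
            df["label"].to_numpy(dtype=object),
            df["region_id"].astype(str).tolist(),
        )


@dataclass
class ScalingFactors:
    """Per-feature (min, max) estimated on a training subset."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaling factors")

    def transform(self, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
        if list(feature_names) != list(self.feature_names):
            missing = set(self.feature_names) - set(feature_names)
            raise KeyError(
                f"feature names do not match scaling factors; missing {sorted(missing)}"
            )
        span = self.maxs - self.mins
        out = np.zeros_like(np.asarray(X, dtype=float))
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / span[nz]
        return out


def featurize(
    corpus: Sequence[LabeledRegion],
    tracks: Mapping[str, SignalTrack] | Sequence[tuple[str, SignalTrack]],
    bin_width: int = DEFAULT_BIN_WIDTH,
    genome: GenomeTable | None = None,
) -> FeatureMatrix:
    """Bin-mean feature extraction: grid[i, j] = mean of track j around region i."""
    if isinstance(tracks, Mapping):
        items = list(tracks.items())
    else:
        items = list(tracks)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate track names")
    names = [n for n, _ in items]
    X = np.zeros((len(corpus), len(items)), dtype=float)
    labels = np.array([lr.label for lr in corpus], dtype=object)
    ids = []
    for i, lr in enumerate(corpus):
        r = lr.region
        ids.append(r.name or f"{r.chrom}:{r.start}-{r.end}")
        for j, (_, track) in enumerate(items):
            X[i, j] = bin_mean_signal(track, r, bin_width=bin_width, genome=genome)
    return FeatureMatrix(X, names, labels, ids)


def fit_minmax(train: FeatureMatrix) -> ScalingFactors:
    """Estimate per-feature (min, max) on the training subset."""
    if train.n_regions < 1:
        raise ValueError("cannot fit scaling factors on an empty matrix")
    return ScalingFactors(
        list(train.feature_names), train.X.min(axis=0), train.X.max(axis=0)
    )


def apply_minmax(m: FeatureMatrix, factors: ScalingFactors) -> FeatureMatrix:
    """Scale to [0,1] with training factors; constant features map to 0.

    Values outside the training range are not clamped, so test values may
    fall outside [0,1].
    """
    return FeatureMatrix(
        factors.transform(m.X, m.feature_names),
        list(m.feature_names),
        m.labels,
        list(m.region_ids),
    )


def map_classes(m: FeatureMatrix, scheme: Mapping[str, str]) -> FeatureMatrix:
    """Replace base labels with task classes according to a total scheme."""
    missing = sorted({str(l) for l in m.labels} - set(scheme))
    if missing:
        raise KeyError(f"labels absent from scheme: {missing}")
    return m.with_labels(np.array([scheme[str(l)] for l in m.labels], dtype=object))


def aggregate_ratio(
    scheme: Mapping[str, str], base_ratio: Mapping[str, int] = BACKGROUND_RATIO
) -> dict[str, int]:
    """Sum the base-class background ratio through a class scheme."""
    out: dict[str, int] = {}
    for base, task in scheme.items():
        if base in base_ratio:
            out[task] = out.get(task, 0) + base_ratio[base]
    return out


def _class_indices(labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = labels.astype(str)
    return {c: np.flatnonzero(labels == c) for c in sorted(set(labels.tolist()))}


def make_balanced_training(
    m: FeatureMatrix,
    max_frac: float = 0.7,
    max_per_class: int = 3000,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Balanced training draw: per class min(floor(max_frac*n), max_per_class).

    Returns (train, remainder); together they partition the input rows.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    rest_idx: list[np.ndarray] = []
    for cls, idx in _class_indices(m.labels).items():
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} has no examples")
        k = min(int(np.floor(max_frac * len(idx))), max_per_class)
        if k == 0:
            raise ValueError(f"class {cls!r} too small for a non-empty training draw")
        chosen = rng.choice(idx, size=k, replace=False)
        train_idx.append(np.sort(chosen))
        rest_idx.append(np.setdiff1d(idx, chosen))
    train = m.select_rows(np.concatenate(train_idx))
    rest = m.select_rows(np.concatenate(rest_idx) if rest_idx else np.array([], dtype=int))
    return train, rest


def make_background_test(
    remainder: FeatureMatrix,
    seed: int = 0,
    ratio: Mapping[str, int] = BACKGROUND_RATIO,
) -> FeatureMatrix:
    """Sample a test set matching the background class ratio exactly.

    The ratio is scaled by the largest integer unit u such that
    u * ratio[c] examples are available for every class c; counts are then
    exactly u * ratio[c].
    """
    by_class = _class_indices(remainder.labels)
    missing = [c for c in ratio if c not in by_class or len(by_class[c]) == 0]
    if missing:
        raise ValueError(f"remainder lacks examples for classes: {sorted(missing)}")
    unit = min(len(by_class[c]) // r for c, r in ratio.items())
    if unit == 0:
        short = [c for c, r in ratio.items() if len(by_class[c]) < r]
        raise ValueError(
            f"remainder too small for one background unit; limiting classes: {sorted(short)}"
        )
    rng = np.random.default_rng(seed)
    picks = []
    for c in sorted(ratio):
        k = unit * ratio[c]
        picks.append(np.sort(rng.choice(by_class[c], size=k, replace=False)))
    return remainder.select_rows(np.concatenate(picks))


def split_train_valid(
    train: FeatureMatrix, valid_frac: float = 0.25, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified split of the training set into fit and validation subsets."""
    if not 0 < valid_frac < 1:
        raise ValueError("valid_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    fit_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for cls, idx in _class_indices(train.labels).items():
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 examples")
        k = int(np.floor(valid_frac * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        chosen = rng.choice(idx, size=k, replace=False)
        val_idx.append(np.sort(chosen))
        fit_idx.append(np.setdiff1d(idx, chosen))
    return (
        train.select_rows(np.concatenate(fit_idx)),
        train.select_rows(np.concatenate(val_idx)),
    )
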