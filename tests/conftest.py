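import numpy as np
import pytest

from crrnet import SimSpec, simulate_feature_data
from crrnet.dataset import apply_minmax, fit_minmax
from crrnet.regions import GenomeTable, GenomicRegion, SignalTrack


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeTable({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture()
def constant_track():
    return SignalTrack.from_segments([("chr1", 0, 10_000, 3.0)])


@pytest.fixture(scope="session")
def planted_scaled():
    """Scaled matrix with 5 planted markers among 50 features, 600/class."""
    matrix, truth = simulate_feature_data(
        SimSpec(
            seed=5,
            class_sizes={"A-E": 600, "A-P": 600, "BG": 600},
            n_informative=5,
            n_noise=45,
        )
    )
    scaled = apply_minmax(matrix, fit_minmax(matrix))
    return scaled, truth


@pytest.fixture(scope="session")
def blobs():
    """Linearly separable 2-class, 2-feature Gaussian blobs (6 sigma apart)."""
    rng = np.random.default_rng(17)
    n = 150
    a = rng.normal([0.0, 0.0], 1.0, size=(n, 2))
    b = rng.normal([6.0, 6.0], 1.0, size=(n, 2))
    X = np.vstack([a, b])
    y = np.array(["neg"] * n + ["pos"] * n, dtype=object)
    return X, y


# ---------------------------------------------------------------- oracles


def bruteforce_window_mean(segments, lo, hi):
    """Per-base summation oracle for the bin-mean feature."""
    total = 0.0
    for s, e, v in segments:
        for base in range(max(s, lo), min(e, hi)):
            total += v
    return total / (hi - lo)


def pairwise_roc_oracle(scores, labels):
    """auROC as pairwise concordance over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def threshold_sweep_pr_oracle(scores, labels):
    """auPRC by exhaustive sweep over every item in ranked order."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    n_pos = sum(labels)
    area = 0.0
    tp = 0
    prev_recall = 0.0
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
        recall = tp / n_pos
        precision = tp / rank
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area
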