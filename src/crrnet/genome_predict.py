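"""Genome-wide annotation: tile, featurize, classify, merge, emit BED.

The genome is tiled into fixed-width bins, each bin is featurized from the
signal tracks, classified with a trained network, and maximal runs of
adjacent same-class bins are merged into regions.  Arbitrary candidate loci
(e.g. bidirectionally transcribed sites) can also be re-classified directly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .dataset import featurize
from .labeling import LabeledRegion
from .mlp import TrainedNetwork, predict_membership
from .regions import DEFAULT_BIN_WIDTH, GenomeTable, GenomicRegion, SignalTrack


@dataclass(frozen=True)
class ClassifiedBin:
    region: GenomicRegion
    label: str
    score: float  # membership score of the predicted class
    scores: tuple[float, ...]  # full membership vector


@dataclass(frozen=True)
class MergedRegion:
    region: GenomicRegion
    label: str
    score: float
    n_bins: int


@dataclass
class AnnotationSet:
    """Merged same-class regions plus per-class genome coverage fractions."""

    regions: list[MergedRegion]
    classes: list[str]
    genome: GenomeTable

    def coverage_fractions(self) -> dict[str, float]:
        total = self.genome.total_bases()
        bases: Counter[str] = Counter()
        for mr in self.regions:
            bases[mr.label] += len(mr.region)
        return {c: bases.get(c, 0) / total for c in self.classes}

    def class_counts(self) -> dict[str, int]:
        counts = Counter(mr.label for mr in self.regions)
        return {c: counts.get(c, 0) for c in self.classes}

    def write_bed(self, path, drop_classes: Sequence[str] = ("BG",)) -> None:
        """BED6 with name = class, score = round(1000 * membership)."""
        with open(path, "w") as fh:
            for mr in self.regions:
                if mr.label in drop_classes:
                    continue
                r = mr.region
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{mr.label}\t"
                    f"{round(1000 * mr.score)}\t.\n"
                )

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "class_counts": self.class_counts(),
                    "coverage_fractions": self.coverage_fractions(),
                },
                fh,
                indent=2,
            )


def tile_genome(
    genome: GenomeTable, bin_width: int = DEFAULT_BIN_WIDTH
) -> Iterator[GenomicRegion]:
    """Non-overlapping consecutive bins per chromosome; last partial bin dropped."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    for chrom, length in genome.items():
        for start in range(0, length - bin_width + 1, bin_width):
            yield GenomicRegion(chrom, start, start + bin_width)


def classify_regions(
    net: TrainedNetwork,
    regions: Iterable[GenomicRegion],
    tracks: Mapping[str, SignalTrack],
    genome: GenomeTable,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> Iterator[ClassifiedBin]:
    """Featurize and classify a region stream; one chromosome in memory at a time."""
    missing = [f for f in net.feature_names if f not in tracks]
    if missing:
        raise KeyError(f"missing feature tracks: {missing}")
    ordered = [(name, tracks[name]) for name in net.feature_names]

    def flush(batch: list[GenomicRegion]) -> Iterator[ClassifiedBin]:
        corpus = [LabeledRegion(r, "UK") for r in batch]
        m = featurize(corpus, ordered, bin_width=bin_width, genome=genome)
        scores, labels = predict_membership(net, m)
        for r, lbl, row in zip(batch, labels, scores):
            yield ClassifiedBin(r, str(lbl), float(row.max()), tuple(row.tolist()))

    batch: list[GenomicRegion] = []
    current: str | None = None
    for r in regions:
        if current is not None and r.chrom != current:
            yield from flush(batch)
            batch = []
        current = r.chrom
        batch.append(r)
    if batch:
        yield from flush(batch)


def merge_adjacent(
    bins: Iterable[ClassifiedBin],
    genome: GenomeTable,
    classes: Sequence[str] | None = None,
    score_mode: str = "mean",
) -> AnnotationSet:
    """Merge maximal runs of touching same-class bins into regions.

    Bins must be sorted within each chromosome; the merged score is the mean
    (or max, with ``score_mode='max'``) of the constituent bin scores.
    """
    if score_mode not in ("mean", "max"):
        raise ValueError("score_mode must be 'mean' or 'max'")
    merged: list[MergedRegion] = []
    seen_classes: set[str] = set()
    run: list[ClassifiedBin] = []

    def close_run() -> None:
        if not run:
            return
        first, last = run[0], run[-1]
        scores = [b.score for b in run]
        score = float(np.mean(scores) if score_mode == "mean" else np.max(scores))
        merged.append(
            MergedRegion(
                GenomicRegion(first.region.chrom, first.region.start, last.region.end),
                first.label,
                score,
                len(run),
            )
        )

    prev: ClassifiedBin | None = None
    for b in bins:
        seen_classes.add(b.label)
        if prev is not None and b.region.chrom == prev.region.chrom:
            if b.region.start < prev.region.end:
                raise ValueError(
                    f"bins unsorted or overlapping at {b.region.chrom}:{b.region.start}"
                )
            contiguous = b.region.start == prev.region.end and b.label == prev.label
        else:
            contiguous = False
        if contiguous:
            run.append(b)
        else:
            close_run()
            run = [b]
        prev = b
    close_run()
    cls = list(classes) if classes is not None else sorted(seen_classes)
    return AnnotationSet(regions=merged, classes=cls, genome=genome)


def annotate_genome(
    net: TrainedNetwork,
    tracks: Mapping[str, SignalTrack],
    genome: GenomeTable,
    bin_width: int = DEFAULT_BIN_WIDTH,
    score_mode: str = "mean",
) -> AnnotationSet:
    """Tile -> classify -> merge convenience pipeline."""
    bins = classify_regions(net, tile_genome(genome, bin_width), tracks, genome, bin_width)
    return merge_adjacent(bins, genome, classes=net.classes, score_mode=score_mode)


def reclassify_loci(
    net: TrainedNetwork,
    loci: Sequence[GenomicRegion],
    tracks: Mapping[str, SignalTrack],
    genome: GenomeTable,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> tuple[list[ClassifiedBin], dict[str, int]]:
    """Classify arbitrary candidate loci; returns per-locus calls and class counts."""
    calls = list(classify_regions(net, loci, tracks, genome, bin_width))
    counts = Counter(c.label for c in calls)
    return calls, {c: counts.get(c, 0) for c in net.classes}
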