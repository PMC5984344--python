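"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* ``simulate_feature_data`` draws a labelled feature matrix with planted
  informative features: signals are log-normal (non-negative, right-skewed,
  like coverage data), and each informative feature is a "marker" for one
  class whose latent location is shifted by the effect size (in pooled-SD
  units of the latent scale).  Noise features are identically distributed
  across classes.

* ``simulate_genome_fixture`` builds a toy genome with planted enhancer,
  promoter and exon loci, class-specific signal tracks (enhancer marks high
  at active enhancers, promoter marks at active promoters, transcription at
  active exons), activity metrics (TPM, peak-max) consistent with the
  labeling thresholds, and an exclusion mask — so that
  label -> featurize -> train -> tile -> classify -> merge runs end-to-end
  with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import FeatureMatrix
from .labeling import (
    ExclusionMask,
    LabeledCorpus,
    LabeledRegion,
    assemble_labeled_set,
    sample_unknown,
)
from .regions import GenomeTable, GenomicRegion, SignalTrack


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the feature-matrix simulation."""

    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"A-E": 600, "A-P": 600, "BG": 600}
    )
    n_informative: int = 20
    n_noise: int = 30
    effect_size: float = 2.0  # latent location shift in pooled-SD units
    latent_sd: float = 0.5  # SD of the log-scale latent signal
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be positive")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")


@dataclass
class TruthRecord:
    informative_features: list[str]
    noise_features: list[str]
    marker_class: dict[str, str]  # informative feature -> class it marks


def simulate_feature_data(spec: SimSpec) -> tuple[FeatureMatrix, TruthRecord]:
    """Labelled log-normal feature matrix with planted class markers.

    Informative feature j marks class (j mod n_classes): rows of that class
    have latent mean shifted up by effect_size * latent_sd before
    exponentiation.  Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_sizes)
    n_total = sum(spec.class_sizes.values())
    p = spec.n_informative + spec.n_noise
    inf_names = [f"mark_{j:02d}" for j in range(spec.n_informative)]
    noise_names = [f"noise_{j:02d}" for j in range(spec.n_noise)]
    names = inf_names + noise_names

    labels = np.concatenate(
        [np.full(n, c, dtype=object) for c, n in spec.class_sizes.items()]
    )
    latent = rng.normal(0.0, spec.latent_sd, size=(n_total, p))
    marker_class: dict[str, str] = {}
    shift = spec.effect_size * spec.latent_sd
    for j, name in enumerate(inf_names):
        cls = classes[j % len(classes)]
        marker_class[name] = cls
        latent[labels == cls, j] += shift
    X = np.exp(latent)
    ids = [f"r{i:05d}" for i in range(n_total)]
    matrix = FeatureMatrix(X, names, labels, ids)
    truth = TruthRecord(
        informative_features=inf_names,
        noise_features=noise_names,
        marker_class=marker_class,
    )
    return matrix, truth


#: Track -> classes in which the track is elevated, emulating the
#: class-conditional signal levels of regulatory marks.
TRACK_PROFILES: dict[str, tuple[str, ...]] = {
    "enh_mark": ("A-E",),            # e.g. H3K4me1-like
    "prom_mark": ("A-P",),           # e.g. H3K4me3-like
    "activity_mark": ("A-E", "A-P"),  # e.g. H3K27ac-like
    "open_chromatin": ("A-E", "A-P"),  # DNase-like
    "transcription": ("A-X",),       # RNA-seq-like
}


@dataclass(frozen=True)
class GenomeSimSpec:
    """Study conditions for the toy-genome fixture."""

    n_active_enhancers: int = 40
    n_active_promoters: int = 40
    n_inactive_enhancers: int = 30
    n_inactive_promoters: int = 30
    n_active_exons: int = 20
    n_inactive_exons: int = 20
    n_unknown: int = 100
    region_width: int = 400  # two 200-bp bins per planted locus
    baseline_log_mean: float = 0.0
    elevated_log_mean: float = 2.0
    log_sd: float = 0.25
    seed: int = 0


@dataclass
class GenomeFixture:
    genome: GenomeTable
    tracks: dict[str, SignalTrack]
    corpus: LabeledCorpus
    mask: ExclusionMask
    truth: dict  # planted loci per class


def _default_genome() -> GenomeTable:
    return GenomeTable({"chrS1": 100_000, "chrS2": 100_000})


def simulate_genome_fixture(
    spec: GenomeSimSpec = GenomeSimSpec(),
    genome: GenomeTable | None = None,
    bin_width: int = 200,
) -> GenomeFixture:
    """Plant labelled loci on a toy genome with class-specific signal tracks.

    Planted loci are bin-aligned and separated by at least one empty slot so
    background bins stay clean.  Active loci get elevated log-normal signal
    on their profile tracks over the full locus; everything else carries
    baseline signal.  TPM and peak-max metrics are drawn consistent with the
    labeling thresholds.
    """
    genome = genome or _default_genome()
    rng = np.random.default_rng(spec.seed)
    width = spec.region_width
    if width % bin_width:
        raise ValueError("region_width must be a multiple of bin_width")

    # candidate slots: every other width-sized slot, so planted loci never touch
    slots: list[tuple[str, int]] = []
    for chrom, length in genome.items():
        for start in range(0, length - width + 1, 2 * width):
            slots.append((chrom, start))
    per_class = {
        "A-E": spec.n_active_enhancers,
        "A-P": spec.n_active_promoters,
        "I-E": spec.n_inactive_enhancers,
        "I-P": spec.n_inactive_promoters,
        "A-X": spec.n_active_exons,
        "I-X": spec.n_inactive_exons,
    }
    need = sum(per_class.values())
    if need > len(slots):
        raise ValueError(f"genome too small: need {need} slots, have {len(slots)}")
    order = rng.permutation(len(slots))
    assigned: dict[str, list[GenomicRegion]] = {}
    cursor = 0
    for label, count in per_class.items():
        regs = []
        for _ in range(count):
            chrom, start = slots[order[cursor]]
            cursor += 1
            regs.append(GenomicRegion(chrom, start, start + width, name=label))
        assigned[label] = regs

    sources: dict[str, list[LabeledRegion]] = {}
    sources["A-E"] = [
        LabeledRegion(r, "A-E", tpm=float(rng.uniform(0.5, 20))) for r in assigned["A-E"]
    ]
    sources["I-E"] = [LabeledRegion(r, "I-E", tpm=0.0) for r in assigned["I-E"]]
    sources["A-P"] = [
        LabeledRegion(r, "A-P", tpm=float(rng.uniform(6, 60))) for r in assigned["A-P"]
    ]
    sources["I-P"] = [LabeledRegion(r, "I-P", tpm=0.0) for r in assigned["I-P"]]
    sources["A-X"] = [
        LabeledRegion(r, "A-X", peak_max=float(rng.uniform(450, 2000)))
        for r in assigned["A-X"]
    ]
    sources["I-X"] = [LabeledRegion(r, "I-X", peak_max=0.0) for r in assigned["I-X"]]

    # exclusion mask: every planted locus (transcribed/open/exonic space)
    mask = ExclusionMask.from_regions(
        [r for regs in assigned.values() for r in regs]
    )
    uk_seed = int(rng.integers(2**31))
    sources["UK"] = sample_unknown(genome, mask, spec.n_unknown, bin_width, seed=uk_seed)
    corpus = assemble_labeled_set(sources)

    # tracks: per-bin baseline log-normal segments, elevated over active loci
    tracks: dict[str, SignalTrack] = {}
    for track_name, elevated_in in TRACK_PROFILES.items():
        entries: list[tuple[str, int, int, float]] = []
        for chrom, length in genome.items():
            n_bins = length // bin_width
            values = np.exp(
                rng.normal(spec.baseline_log_mean, spec.log_sd, size=n_bins)
            )
            for label in elevated_in:
                for r in assigned.get(label, []):
                    if r.chrom != chrom:
                        continue
                    b0, b1 = r.start // bin_width, r.end // bin_width
                    values[b0:b1] = np.exp(
                        rng.normal(spec.elevated_log_mean, spec.log_sd, size=b1 - b0)
                    )
            for i, v in enumerate(values):
                entries.append((chrom, i * bin_width, (i + 1) * bin_width, float(v)))
        tracks[track_name] = SignalTrack.from_segments(entries)

    truth = {
        "planted": {
            label: [[r.chrom, r.start, r.end] for r in regs]
            for label, regs in assigned.items()
        },
        "bin_width": bin_width,
        "region_width": width,
    }
    return GenomeFixture(genome=genome, tracks=tracks, corpus=corpus, mask=mask, truth=truth)
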