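"""Seven-class labeling of candidate regulatory regions.

Classes are defined from transcription evidence: enhancers and promoters from
a CAGE-derived atlas carry a tags-per-million (TPM) activity level, exons an
RNA-seq peak-max level, and "unknown" background windows are drawn from the
genome outside any transcribed/open region.

    A-E  active enhancer    TPM > 0
    I-E  inactive enhancer  TPM = 0
    A-P  active promoter    TPM > 5
    I-P  inactive promoter  TPM = 0
    A-X  active exon        peak-max > 400
    I-X  inactive exon      peak-max = 0
    UK   unknown            sampled outside tags/exons/open chromatin

Promoters with 0 < TPM <= 5 and exons with 0 < peak-max <= 400 fall between
the two tails of the definitions and are left unlabelled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regions import GenomeTable, GenomicRegion

ENHANCER_ACTIVE_TPM = 0.0  # strictly greater -> active
PROMOTER_ACTIVE_TPM = 5.0  # strictly greater -> active
EXON_ACTIVE_PEAK_MAX = 400.0  # strictly greater -> active

BASE_LABELS = ("A-E", "A-P", "A-X", "I-E", "I-P", "I-X", "UK")


@dataclass(frozen=True)
class LabeledRegion:
    region: GenomicRegion
    label: str
    tpm: float | None = None
    peak_max: float | None = None

    def __post_init__(self) -> None:
        if self.label not in BASE_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label in ("A-E", "I-E", "A-P", "I-P") and self.tpm is None:
            raise ValueError(f"{self.label} requires a TPM value")
        if self.label in ("A-X", "I-X") and self.peak_max is None:
            raise ValueError(f"{self.label} requires a peak-max value")


class LabelConflictError(ValueError):
    """Same interval assigned two different labels."""


def label_crr(region: GenomicRegion, kind: str, tpm: float) -> LabeledRegion | None:
    """Label an atlas enhancer or promoter from its TPM.

    Enhancers: TPM > 0 -> A-E, TPM = 0 -> I-E.  Promoters: TPM > 5 -> A-P,
    TPM = 0 -> I-P, intermediate TPM -> None (unlabelled).
    """
    if tpm < 0:
        raise ValueError(f"negative TPM {tpm}")
    if kind == "enhancer":
        label = "A-E" if tpm > ENHANCER_ACTIVE_TPM else "I-E"
        return LabeledRegion(region, label, tpm=tpm)
    if kind == "promoter":
        if tpm > PROMOTER_ACTIVE_TPM:
            return LabeledRegion(region, "A-P", tpm=tpm)
        if tpm == 0:
            return LabeledRegion(region, "I-P", tpm=tpm)
        return None
    raise ValueError(f"kind must be 'enhancer' or 'promoter', got {kind!r}")


def label_exon(region: GenomicRegion, peak_max: float) -> LabeledRegion | None:
    """Label an exon: peak-max > 400 -> A-X, = 0 -> I-X, otherwise None."""
    if peak_max < 0:
        raise ValueError(f"negative peak-max {peak_max}")
    if peak_max > EXON_ACTIVE_PEAK_MAX:
        return LabeledRegion(region, "A-X", peak_max=peak_max)
    if peak_max == 0:
        return LabeledRegion(region, "I-X", peak_max=peak_max)
    return None


class ExclusionMask:
    """Per-chromosome sorted union of intervals to exclude from UK sampling."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]]):
        self._iv: dict[str, np.ndarray] = {}
        for chrom, pairs in intervals.items():
            merged = _merge_intervals(pairs)
            self._iv[chrom] = merged

    @classmethod
    def from_regions(cls, regions: Iterable[GenomicRegion]) -> "ExclusionMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        return cls(by_chrom)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._iv.get(chrom, np.empty((0, 2), dtype=np.int64))

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        iv = self.intervals(chrom)
        if not len(iv):
            return 0
        ov = np.minimum(iv[:, 1], end) - np.maximum(iv[:, 0], start)
        return int(np.clip(ov, 0, None).sum())


def _merge_intervals(pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    if not len(pairs):
        return np.empty((0, 2), dtype=np.int64)
    arr = sorted((int(s), int(e)) for s, e in pairs)
    out: list[list[int]] = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _free_gaps(genome: GenomeTable, mask: ExclusionMask) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom, length in genome.items():
        pos = 0
        for s, e in mask.intervals(chrom):
            if s > pos:
                gaps.append((chrom, pos, min(int(s), length)))
            pos = max(pos, int(e))
        if pos < length:
            gaps.append((chrom, pos, length))
    return gaps


def sample_unknown(
    genome: GenomeTable,
    mask: ExclusionMask,
    n: int,
    width: int,
    seed: int,
) -> list[LabeledRegion]:
    """Sample ``n`` disjoint UK windows of ``width`` bases outside the mask.

    Uniform rejection sampling over the genome, deterministic given ``seed``.
    Raises if the unmasked space cannot hold ``n`` disjoint windows, reporting
    the achievable maximum.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    gaps = _free_gaps(genome, mask)
    capacity = sum((e - s) // width for _, s, e in gaps)
    if n > capacity:
        raise ValueError(
            f"cannot place {n} disjoint windows of {width} bp; "
            f"unmasked space admits at most {capacity}"
        )
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[LabeledRegion] = []
    attempts = 0
    max_attempts = 1000 * n + 10_000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection sampling failed to place {n} windows after "
                f"{max_attempts} attempts ({len(out)} placed)"
            )
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        limit = genome[chrom] - width
        if limit < 0:
            continue
        start = int(rng.integers(0, limit + 1))
        end = start + width
        if mask.overlap_bases(chrom, start, end) > 0:
            continue
        if any(s < end and start < e for s, e in taken[chrom]):
            continue
        taken[chrom].append((start, end))
        out.append(LabeledRegion(GenomicRegion(chrom, start, end, name="UK"), "UK"))
    return out


@dataclass
class LabeledCorpus:
    """Concatenated labelled regions with per-class counts."""

    regions: list[LabeledRegion]
    class_counts: dict[str, int]


def assemble_labeled_set(sources: Mapping[str, Sequence[LabeledRegion]]) -> LabeledCorpus:
    """Concatenate homogeneous per-class lists into one corpus.

    Rejects an interval that appears under two different labels.
    """
    seen: dict[tuple[str, int, int], str] = {}
    regions: list[LabeledRegion] = []
    counts: Counter[str] = Counter()
    for label, sub in sources.items():
        for lr in sub:
            if lr.label != label:
                raise ValueError(
                    f"sub-list for {label!r} contains a region labelled {lr.label!r}"
                )
            key = lr.region.key()
            prev = seen.get(key)
            if prev is not None and prev != label:
                raise LabelConflictError(
                    f"interval {key} labelled both {prev!r} and {label!r}"
                )
            seen[key] = label
            regions.append(lr)
            counts[label] += 1
    return LabeledCorpus(regions=regions, class_counts=dict(counts))


def write_labeled_bed(corpus: Iterable[LabeledRegion], path) -> None:
    """Serialize as BED6+2: name = label, columns 7/8 = TPM, peak-max ('.' if absent)."""
    with open(path, "w") as fh:
        for lr in corpus:
            r = lr.region
            tpm = "." if lr.tpm is None else f"{lr.tpm:g}"
            pk = "." if lr.peak_max is None else f"{lr.peak_max:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{lr.label}\t0\t{r.strand}\t{tpm}\t{pk}\n")


def read_labeled_bed(path) -> list[LabeledRegion]:
    out: list[LabeledRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            tpm = None if len(f) < 7 or f[6] == "." else float(f[6])
            pk = None if len(f) < 8 or f[7] == "." else float(f[7])
            out.append(
                LabeledRegion(
                    GenomicRegion(f[0], int(f[1]), int(f[2]), name=f[3], strand=f[5]),
                    f[3],
                    tpm=tpm,
                    peak_max=pk,
                )
            )
    return out
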