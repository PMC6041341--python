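"""Genome survey from a k-mer depth histogram.

A k-mer depth histogram (jellyfish ``histo`` dialect: depth, count per line)
from whole-genome shotgun reads typically shows a spike at depth 1–2 from
sequencing errors, a valley, and a main bump whose mode is the per-base
sequencing depth of single-copy sequence.  With the error spike excluded,

    genome size  =  KmerCount / Depth

where ``KmerCount`` is the total k-mer mass above the error threshold and
``Depth`` the main-peak depth.  Repetitive sequence shows up as k-mer mass at
multiples of the main peak; the mass at depth ≥ ``repeat_multiplier`` × peak,
as a fraction of the total, estimates the repeat content.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "KmerHistogram",
    "SurveyEstimate",
    "load_histogram",
    "find_peak",
    "estimate_genome_size",
    "survey",
]


@dataclass(frozen=True)
class KmerHistogram:
    """Depth → distinct-k-mer-count table, depths unique and ascending."""

    depths: np.ndarray
    counts: np.ndarray
    k: int | None = None

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if depths.ndim != 1 or depths.shape != counts.shape:
            raise ValidationError("depths and counts must be 1-D and equal length")
        if depths.size == 0:
            raise ValidationError("empty histogram")
        if (depths < 1).any():
            raise ValidationError("depths must be ≥ 1")
        if (np.diff(depths) <= 0).any():
            raise ValidationError("depths must be strictly ascending")
        if (counts < 0).any():
            raise ValidationError("counts must be ≥ 0")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return int(self.depths.size)

    @property
    def total_mass(self) -> int:
        """Total k-mer observations, Σ depth × count."""
        return int((self.depths * self.counts).sum())

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for d, c in zip(self.depths, self.counts):
                handle.write(f"{d} {c}\n")


def load_histogram(path: str | os.PathLike, k: int | None = None) -> KmerHistogram:
    """Read a two-column whitespace-separated depth histogram."""
    path = os.fspath(path)
    depths: list[int] = []
    counts: list[int] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                d, c = int(fields[0]), int(fields[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer value") from None
            depths.append(d)
            counts.append(c)
    if not depths:
        raise ParseError(f"{path}: empty histogram")
    try:
        return KmerHistogram(np.array(depths), np.array(counts), k=k)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def find_peak(h: KmerHistogram) -> tuple[int, int]:
    """Locate the error threshold and the main coverage peak.

    The error threshold is the depth of the first local minimum of count
    versus depth (the valley after the error spike); the peak is the depth of
    the maximal count strictly above the threshold, the smaller depth winning
    ties.  A histogram that only decreases (no valley) is rejected with advice
    to set the threshold manually.
    """
    if h.n_bins < 3:
        raise ValidationError("histogram needs at least 3 bins")
    c = h.counts
    valley = None
    for i in range(1, h.n_bins - 1):
        if c[i - 1] >= c[i] and c[i] < c[i + 1]:
            valley = i
            break
    if valley is None:
        raise ValidationError(
            "no valley found in the histogram; supply an error threshold manually"
        )
    error_threshold = int(h.depths[valley])
    above = h.depths > error_threshold
    if not above.any():
        raise ValidationError("no histogram mass above the error threshold")
    idx = np.flatnonzero(above)
    peak = int(h.depths[idx[np.argmax(c[idx])]])  # argmax takes the first = smallest depth
    return error_threshold, peak


@dataclass(frozen=True)
class SurveyEstimate:
    """Genome-survey estimates derived from a k-mer histogram."""

    error_threshold: int
    peak_depth: int
    kmer_count: int  # Σ depth × count above the error threshold
    genome_size: float  # bases
    repeat_fraction: float
    repeat_multiplier: float


def estimate_genome_size(
    h: KmerHistogram,
    error_threshold: int,
    peak_depth: int,
    repeat_multiplier: float = 1.5,
) -> SurveyEstimate:
    """Estimate genome size and repeat content.

    ``K = Σ_{depth > error_threshold} depth × count`` and the genome size is
    ``K / peak_depth``.  The repeat fraction is the share of ``K`` at depth
    ≥ ``repeat_multiplier × peak_depth``; the default multiplier 1.5 places
    the cut midway between the single-copy peak and the first repeat peak, so
    essentially all multi-copy mass and almost no single-copy mass is counted.
    """
    if peak_depth <= error_threshold:
        raise ValidationError("peak_depth must exceed error_threshold")
    if repeat_multiplier <= 1:
        raise ValidationError("repeat_multiplier must be > 1")
    mask = h.depths > error_threshold
    mass = h.depths[mask].astype(np.float64) * h.counts[mask]
    K = float(mass.sum())
    if K == 0:
        raise ValidationError("no k-mer mass above the error threshold")
    repeat_mask = h.depths[mask] >= repeat_multiplier * peak_depth
    repeat_mass = float(mass[repeat_mask].sum())
    return SurveyEstimate(
        error_threshold=int(error_threshold),
        peak_depth=int(peak_depth),
        kmer_count=int(K),
        genome_size=K / peak_depth,
        repeat_fraction=repeat_mass / K,
        repeat_multiplier=float(repeat_multiplier),
    )


def survey(h: KmerHistogram, repeat_multiplier: float = 1.5,
           error_threshold: int | None = None) -> SurveyEstimate:
    """Full survey: peak detection followed by the size/repeat estimates.

    ``error_threshold`` overrides the automatic valley detection; the peak is
    then located above the supplied threshold.
    """
    if error_threshold is None:
        error_threshold, peak = find_peak(h)
    else:
        above = h.depths > error_threshold
        if not above.any():
            raise ValidationError("no histogram mass above the error threshold")
        idx = np.flatnonzero(above)
        peak = int(h.depths[idx[np.argmax(h.counts[idx])]])
    return estimate_genome_size(h, error_threshold, peak, repeat_multiplier)
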