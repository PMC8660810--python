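"""Binned genome coverage tracks, z-score normalization and summit-centered profiles.

Coverage is binned at a fixed width (10 bp by default) per chromosome. A bin's
value is the number of fragments overlapping it by at least one base.
z-score normalization standardizes the pooled genome-wide bin distribution
(all chromosomes, zero bins included) to mean 0 and population SD 1, which is
how the browser tracks and heatmaps are scaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, Peak, ValidationError


@dataclass
class BinnedTrack:
    """Fixed-width per-bin values for each chromosome.

    ``data[chrom]`` has length ``ceil(chrom_sizes[chrom] / bin_width)``.
    """

    bin_width: int
    chrom_sizes: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValidationError("bin_width must be >= 1")
        for chrom, size in self.chrom_sizes.items():
            n = self.n_bins(chrom)
            if chrom not in self.data:
                self.data[chrom] = np.zeros(n, dtype=float)
            elif len(self.data[chrom]) != n:
                raise ValidationError(
                    f"{chrom}: expected {n} bins for length {size}, got {len(self.data[chrom])}"
                )
        for chrom in self.data:
            if chrom not in self.chrom_sizes:
                raise ValidationError(f"track data for unknown chromosome {chrom}")
            if not np.all(np.isfinite(self.data[chrom])):
                raise ValidationError(f"{chrom}: non-finite bin values")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_sizes[chrom] / self.bin_width)

    def pooled(self) -> np.ndarray:
        """All genome bins concatenated in chromosome-name order."""
        return np.concatenate([self.data[c] for c in sorted(self.chrom_sizes)])


def bin_coverage(
    fragments: list[GenomicInterval],
    bin_width: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedTrack:
    """Count, per bin, the fragments overlapping it by >= 1 bp.

    Raises if any fragment lies on an unknown chromosome or outside its bounds;
    the error names the offenders.
    """
    if chrom_sizes is None:
        raise ValidationError("chrom_sizes is required")
    offenders = [
        f"{f.chrom}:{f.start}-{f.end}"
        for f in fragments
        if f.chrom not in chrom_sizes or f.end > chrom_sizes[f.chrom]
    ]
    if offenders:
        raise ValidationError(
            "fragments on unknown chromosomes or out of bounds: " + ", ".join(offenders[:10])
        )
    track = BinnedTrack(bin_width=bin_width, chrom_sizes=dict(chrom_sizes))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, frags in by_chrom.items():
        n = track.n_bins(chrom)
        # difference-array trick: +1 at first overlapped bin, -1 past the last
        starts = np.array([f.start // bin_width for f in frags], dtype=np.int64)
        ends = np.array([(f.end - 1) // bin_width + 1 for f in frags], dtype=np.int64)
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        track.data[chrom] = np.cumsum(diff[:-1]).astype(float)
    return track


def zscore_normalize(track: BinnedTrack) -> BinnedTrack:
    """Standardize the genome-wide bin distribution to mean 0, population SD 1.

    The mean and SD are pooled over all chromosomes, zero bins included, so the
    output is an affine map of the input. A constant track (zero SD) is an error.
    """
    pooled = track.pooled()
    if pooled.size < 2:
        raise ValidationError("track must have >= 2 bins")
    mean = pooled.mean()
    sd = pooled.std()  # population SD
    if sd == 0:
        raise ValidationError("constant track: zero standard deviation")
    return BinnedTrack(
        bin_width=track.bin_width,
        chrom_sizes=dict(track.chrom_sizes),
        data={c: (v - mean) / sd for c, v in track.data.items()},
    )


@dataclass
class ProfileMatrix:
    """Per-peak rows of track values over ``[summit - flank, summit + flank)``.

    ``values`` is peaks x bins; ``oob`` flags bins that fell outside the
    chromosome (those values are 0). Row order follows the declared ranking.
    """

    values: np.ndarray
    peaks: list[Peak]
    flank: int
    bin_width: int
    oob: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _rank_peaks(peaks: list[Peak], ranking) -> list[Peak]:
    if ranking is None or ranking == "none":
        return list(peaks)
    if ranking == "zscore":
        if any(p.zscore is None for p in peaks):
            raise ValidationError("ranking='zscore' requires annotated zscores")
        return sorted(peaks, key=lambda p: (-p.zscore, p.chrom, p.start))
    # explicit permutation of row indices
    idx = list(ranking)
    if sorted(idx) != list(range(len(peaks))):
        raise ValidationError("ranking must be 'zscore', 'none' or a permutation of indices")
    return [peaks[i] for i in idx]


def profile_matrix(
    track: BinnedTrack,
    peaks: list[Peak],
    flank: int = 600,
    ranking="zscore",
) -> ProfileMatrix:
    """Summit-centered matrix of track values with ``2 * flank / bin_width`` columns.

    Column ``k`` reads the track bin containing position
    ``summit - flank + k * bin_width``; positions outside the chromosome give 0
    and are flagged in ``oob``.
    """
    w = track.bin_width
    if flank % w != 0:
        raise ValidationError("flank must be a multiple of bin_width")
    ordered = _rank_peaks(peaks, ranking)
    ncol = 2 * flank // w
    values = np.zeros((len(ordered), ncol), dtype=float)
    oob = np.zeros((len(ordered), ncol), dtype=bool)
    offsets = np.arange(ncol) * w - flank
    for i, p in enumerate(ordered):
        if p.chrom not in track.chrom_sizes:
            raise ValidationError(f"peak on unknown chromosome {p.chrom}")
        pos = p.summit + offsets
        bins = pos // w
        valid = (pos >= 0) & (pos < track.chrom_sizes[p.chrom])
        values[i, valid] = track.data[p.chrom][bins[valid]]
        oob[i] = ~valid
    return ProfileMatrix(values=values, peaks=ordered, flank=flank, bin_width=w, oob=oob)


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column-wise arithmetic mean of the profile matrix (the metaplot line)."""
    if matrix.values.shape[0] == 0:
        raise ValidationError("empty profile matrix")
    return matrix.values.mean(axis=0)


def peak_zscores(track: BinnedTrack, peaks: list[Peak]) -> list[Peak]:
    """Annotate each peak with the mean track value over the bins it overlaps.

    Applied to a z-normalized track this yields the per-peak z score used for
    ranking. Returns the same Peak objects with ``zscore`` set.
    """
    w = track.bin_width
    for p in peaks:
        if p.chrom not in track.chrom_sizes or p.end > track.chrom_sizes[p.chrom]:
            raise ValidationError(f"peak {p.chrom}:{p.start}-{p.end} outside genome")
        b0 = p.start // w
        b1 = (p.end - 1) // w + 1
        p.zscore = float(track.data[p.chrom][b0:b1].mean())
    return peaks
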