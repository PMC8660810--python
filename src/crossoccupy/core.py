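"""Core genomic value types shared across the package.

All internal coordinates are 0-based half-open ``[start, end)``, BED-style.
Formats with other conventions (GTF) are converted at the I/O boundary and
nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass
class GenomicInterval:
    """A chrom/start/end/strand span; the atom of all peak and feature arithmetic.

    Invariants: ``0 <= start < end`` and non-empty ``chrom``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """An interval plus its summit (base of maximal enrichment) and score.

    ``zscore`` is the mean z-score-normalized coverage over the interval; it is
    ``None`` until annotated by :func:`crossoccupy.tracks.peak_zscores` (or set
    directly by the synthetic generator).
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    zscore: float | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) on {self.interval.chrom}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass
class GeneModel:
    """A gene span with TSS, exons and optional annotated UTRs.

    TSS is the leftmost base for ``+`` genes and ``end - 1`` for ``-`` genes.
    Exons must be non-overlapping once sorted.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: require 0 <= start < end")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1
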