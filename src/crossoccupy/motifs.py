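"""IUPAC motif matching over genomic sequence, per-region presence tallies,
and rank-binned motif-fraction tables.

A pattern position matches iff every sequence base is a member of the IUPAC
class of the corresponding pattern base. ``N`` in the *sequence* matches
nothing (assembly gaps must not create motifs). Both-strand scanning is the
default; minus-strand hits are found by scanning the reverse complement of the
pattern on the forward sequence, so all reported start positions are
forward-strand leftmost coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .core import GenomicInterval, Peak, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Motif dictionary used throughout: the canonical pioneer-factor motif
#: (CAGGTAG and its CAGGTA core), its degenerate variant, and the
#: promoter/insulator factor motifs tallied alongside it.
DEFAULT_MOTIFS: dict[str, str] = {
    "zld_canonical": "CAGGTAG",
    "zld_core": "CAGGTA",
    "zld_degenerate": "CAGGTARV",
    "clamp": "ACMGRG",
    "dref_beaf32": "HATCGATA",
    "m1bp": "GGTCACA",
    "erm": "AAAWGVVCMNH",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement; degenerate IUPAC codes map to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC degenerate motif."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValidationError("empty motif pattern")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValidationError(f"invalid IUPAC characters in {self.name!r}: {sorted(bad)}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def _regex(self, pattern: str) -> re.Pattern:
        # overlapping matches via lookahead; classes never include N, so gap
        # bases in the sequence cannot match
        return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in pattern) + ")")

    @property
    def forward_regex(self) -> re.Pattern:
        return self._regex(self.iupac)

    @property
    def reverse_regex(self) -> re.Pattern:
        return self._regex(reverse_complement(self.iupac))


def default_motifs() -> list[MotifPattern]:
    return [MotifPattern(name=n, iupac=p) for n, p in DEFAULT_MOTIFS.items()]


def read_motifs_tsv(path: str) -> list[MotifPattern]:
    """Read a two-column (name, IUPAC) motif dictionary."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, iupac = line.split("\t")[:2]
            motifs.append(MotifPattern(name=name, iupac=iupac))
    return motifs


def find_matches(
    pattern: MotifPattern, sequence: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (start, strand) matches of ``pattern`` in ``sequence``.

    Starts are forward-strand leftmost coordinates on both strands; overlapping
    matches are all reported.
    """
    seq = sequence.upper()
    hits = [(m.start(), "+") for m in pattern.forward_regex.finditer(seq)]
    if both_strands:
        hits += [(m.start(), "-") for m in pattern.reverse_regex.finditer(seq)]
    hits.sort()
    return hits


def count_regions_with_motif(
    pattern: MotifPattern,
    regions: list[GenomicInterval],
    genome: dict[str, str],
    both_strands: bool = True,
) -> tuple[int, list[bool]]:
    """Tally regions containing >= 1 match fully inside the region."""
    flags = []
    for iv in regions:
        if iv.chrom not in genome or iv.end > len(genome[iv.chrom]):
            raise ValidationError(f"region {iv.chrom}:{iv.start}-{iv.end} exceeds genome")
        sub = genome[iv.chrom][iv.start : iv.end]
        flags.append(bool(find_matches(pattern, sub, both_strands=both_strands)))
    return sum(flags), flags


def motif_near_summit(
    pattern: MotifPattern,
    peaks: list[Peak],
    genome: dict[str, str],
    window: int = 200,
    both_strands: bool = True,
) -> list[bool]:
    """Per-peak flag: >= 1 match starting within ``[summit - window, summit + window]``
    (closed window on the match start, clipped at chromosome bounds)."""
    flags = []
    for p in peaks:
        seq = genome[p.chrom]
        lo = max(0, p.summit - window)
        # a match may extend past the window; only its start must fall inside
        hi = min(len(seq), p.summit + window + len(pattern))
        sub = seq[lo:hi]
        ok = any(lo + pos <= p.summit + window for pos, _ in find_matches(pattern, sub, both_strands))
        flags.append(ok)
    return flags


@dataclass
class MotifBinTable:
    """Per-bin motif-presence fractions for z-ranked peaks.

    ``table`` columns: ``bin`` (0 = highest-ranked), ``n_peaks``, then one
    fraction column per motif name.
    """

    table: pd.DataFrame
    bin_size: int

    def fractions(self, motif_name: str) -> pd.Series:
        return self.table[motif_name]


def rank_binned_fraction(
    peaks: list[Peak],
    motifs: list[MotifPattern],
    genome: dict[str, str],
    bin_size: int = 100,
    both_strands: bool = True,
) -> MotifBinTable:
    """Bin peaks (ranked by z score, highest first) into groups of ``bin_size``
    and compute the fraction of each bin containing each motif.

    Ties in z score break by (chrom, start); the final partial bin is kept and
    its fraction uses its own size.
    """
    if any(p.zscore is None for p in peaks):
        raise ValidationError("rank_binned_fraction requires peaks annotated with zscore")
    ranked = sorted(peaks, key=lambda p: (-p.zscore, p.chrom, p.start))
    regions = [p.interval for p in ranked]
    presence = {
        m.name: count_regions_with_motif(m, regions, genome, both_strands)[1] for m in motifs
    }
    rows = []
    for b, lo in enumerate(range(0, len(ranked), bin_size)):
        hi = min(lo + bin_size, len(ranked))
        row = {"bin": b, "n_peaks": hi - lo}
        for m in motifs:
            row[m.name] = sum(presence[m.name][lo:hi]) / (hi - lo)
        rows.append(row)
    return MotifBinTable(table=pd.DataFrame(rows), bin_size=bin_size)
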