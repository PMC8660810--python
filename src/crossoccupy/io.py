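"""Readers and writers for the standard formats the pipeline touches.

BED and narrowPeak are adopted verbatim (they are already 0-based half-open).
GTF is 1-based closed and is converted here, at the boundary. bedGraph is the
canonical serialization of binned tracks; records are maximal runs of
equal-valued adjacent bins so a round trip reproduces bin values exactly.
Chromosome names are matched as exact strings — no "chr" aliasing.
"""

from __future__ import annotations

import os
import re

import numpy as np
from pyfaidx import Fasta

from .core import FormatError, GenomicInterval, GeneModel, Peak, ValidationError
from .tracks import BinnedTrack


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals in file order; strand from column 6 when present."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom=fields[0], start=start, end=end, strand=strand, name=name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def read_narrowpeak(path: str) -> list[Peak]:
    """Read ENCODE 10-column narrowPeak records as Peaks.

    Summit = start + column-10 offset; a ``-1`` offset (peaks called without
    summits) falls back to the interval midpoint (floor). Score is the
    column-7 signalValue.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from exc
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            try:
                iv = GenomicInterval(
                    chrom=fields[0], start=start, end=end,
                    strand=fields[5] if fields[5] in ("+", "-", ".") else ".",
                    name=fields[3],
                )
                peaks.append(Peak(interval=iv, summit=summit, score=signal))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: list[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t0\t{p.interval.strand}"
                f"\t{p.score:g}\t-1\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# GTF

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_genes(path: str) -> list[GeneModel]:
    """Parse gene models from GTF (1-based closed -> internal 0-based half-open).

    ``gene`` features define the span; ``exon``, ``five_prime_utr`` and
    ``three_prime_utr`` features are attached to their gene. A gene span is
    inferred from its exons when no ``gene`` feature is present.
    """
    spans: dict[str, tuple[str, str, int, int]] = {}
    explicit: set[str] = set()
    parts: dict[str, dict[str, list[GenomicInterval]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GTF requires 9 columns")
            chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = fields
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end < start")
            if gene_id not in parts:
                parts[gene_id] = {"exon": [], "five_prime_utr": [], "three_prime_utr": []}
                order.append(gene_id)
            if feature == "gene":
                spans[gene_id] = (chrom, strand, start, end)
                explicit.add(gene_id)
                continue
            if feature in parts[gene_id]:
                parts[gene_id][feature].append(
                    GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)
                )
            # infer the span from features when no explicit gene record exists
            if gene_id not in explicit:
                if gene_id in spans:
                    c, s, lo, hi = spans[gene_id]
                    spans[gene_id] = (c, s, min(lo, start), max(hi, end))
                else:
                    spans[gene_id] = (chrom, strand, start, end)
    genes = []
    for gene_id in order:
        chrom, strand, start, end = spans[gene_id]
        genes.append(
            GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
                exons=parts[gene_id]["exon"],
                utr5=parts[gene_id]["five_prime_utr"],
                utr3=parts[gene_id]["three_prime_utr"],
            )
        )
    return genes


def write_gtf(genes: list[GeneModel], path: str, source: str = "crossoccupy") -> None:
    """Write gene models as GTF (converting back to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for feature, ivs in (
                ("exon", g.exons), ("five_prime_utr", g.utr5), ("three_prime_utr", g.utr3)
            ):
                for iv in ivs:
                    fh.write(
                        f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{g.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA / chrom.sizes


def load_genome(path: str) -> dict[str, str]:
    """Load a FASTA genome as an upper-case chrom -> sequence dict."""
    fa = Fasta(path, rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    # drop a stale pyfaidx index if present so reloads see the new content
    for ext in (".fai",):
        idx = path + ext
        if os.path.exists(idx):
            os.remove(idx)


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: BinnedTrack, path: str) -> None:
    """Serialize a binned track; one record per maximal run of equal bins.

    Record coordinates are half-open multiples of the bin width, clipped at
    the chromosome length.
    """
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            values = track.data[chrom]
            size = track.chrom_sizes[chrom]
            if len(values) == 0:
                continue
            breaks = np.flatnonzero(np.diff(values)) + 1
            run_starts = np.concatenate(([0], breaks))
            run_ends = np.concatenate((breaks, [len(values)]))
            for b0, b1 in zip(run_starts, run_ends):
                fh.write(f"{chrom}\t{b0 * w}\t{min(b1 * w, size)}\t{values[b0]:.17g}\n")


def read_bedgraph(path: str, bin_width: int, chrom_sizes: dict[str, int]) -> BinnedTrack:
    """Read a bedGraph written by :func:`write_bedgraph` back into a track."""
    track = BinnedTrack(bin_width=bin_width, chrom_sizes=dict(chrom_sizes))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph requires 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in chrom_sizes:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start % bin_width != 0:
                raise FormatError(f"{path}:{lineno}: record not aligned to bin width")
            b0 = start // bin_width
            b1 = (end - 1) // bin_width + 1
            track.data[chrom][b0:b1] = value
    return track


# ---------------------------------------------------------------------------
# fragment BED (BED with MAPQ in the score column)


def read_fragments_bed(path: str):
    """Read aligned fragments from BED; column 5 holds the mapping quality."""
    from .dynamics import FragmentRecord

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                iv = GenomicInterval(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    strand=fields[5] if len(fields) > 5 else ".",
                    name=fields[3] if len(fields) > 3 else "",
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            mapq = int(float(fields[4])) if len(fields) > 4 else 0
            records.append(FragmentRecord(interval=iv, mapq=mapq))
    return records


def write_fragments_bed(fragments, path: str) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{f.mapq}\t{iv.strand}\n")
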