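"""Assign peaks to genomic features, nearest genes, and enrichment against a
randomized background.

Classification is by summit position with a fixed priority:
promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic.
The promoter window is strand-aware: the summit must fall in
``[TSS - 500, TSS + 150]`` measured in the gene's orientation (the analysis
redefines TSS regions that way). "Downstream" means within ``downstream_max``
(1 kb by default) past the gene's 3' end. Every peak gets exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, GeneModel, Peak, ValidationError
from .stats import fisher_exact_two_sided, odds_ratio

FEATURE_CLASSES = (
    "promoter", "5'UTR", "3'UTR", "exon", "intron", "downstream", "distal intergenic",
)


@dataclass
class FeatureAssignment:
    """Per-peak feature class, nearest gene and signed TSS distance.

    ``table`` columns: peak, chrom, summit, feature, gene_id, distance.
    Distances are in the gene's orientation (negative = upstream of the TSS).
    """

    table: pd.DataFrame

    def class_counts(self) -> pd.Series:
        return self.table["feature"].value_counts().reindex(FEATURE_CLASSES, fill_value=0)

    def class_fractions(self) -> pd.Series:
        return self.class_counts() / len(self.table)


def _oriented_offset(summit: int, gene: GeneModel) -> int:
    """Summit position relative to the TSS, measured along the gene."""
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def _in_any(summit: int, intervals: list[GenomicInterval]) -> bool:
    return any(iv.start <= summit < iv.end for iv in intervals)


def _classify_summit(
    summit: int,
    genes: list[GeneModel],
    promoter_window: tuple[int, int],
    downstream_max: int,
) -> str:
    lo, hi = promoter_window
    checks = {c: False for c in FEATURE_CLASSES}
    for g in genes:
        off = _oriented_offset(summit, g)
        if lo <= off <= hi:
            checks["promoter"] = True
        if _in_any(summit, g.utr5):
            checks["5'UTR"] = True
        if _in_any(summit, g.utr3):
            checks["3'UTR"] = True
        if _in_any(summit, g.exons):
            checks["exon"] = True
        if g.start <= summit < g.end:
            checks["intron"] = True  # downgraded to intron unless exonic elsewhere
        gene_end_3p = g.end if g.strand == "+" else g.start
        past = summit - gene_end_3p if g.strand == "+" else gene_end_3p - 1 - summit
        if 0 <= past < downstream_max:
            checks["downstream"] = True
    for cls in FEATURE_CLASSES[:-1]:
        if checks[cls]:
            return cls
    return "distal intergenic"


def nearest_gene(peaks: list[Peak], genes: list[GeneModel]) -> pd.DataFrame:
    """Nearest-TSS gene per peak (ties break to the lexicographically smaller
    gene_id); distance is signed in the gene's orientation."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for p in peaks:
        cands = by_chrom.get(p.chrom, [])
        if not cands:
            rows.append({"peak": p.name, "gene_id": "none", "distance": np.nan})
            continue
        best = min(cands, key=lambda g: (abs(p.summit - g.tss), g.gene_id))
        rows.append(
            {"peak": p.name, "gene_id": best.gene_id, "distance": _oriented_offset(p.summit, best)}
        )
    return pd.DataFrame(rows)


def assign_features(
    peaks: list[Peak],
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = (-500, 150),
    downstream_max: int = 1000,
) -> FeatureAssignment:
    """Classify each peak summit into exactly one genomic feature class."""
    if not genes:
        raise ValidationError("gene models must be non-empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    nearest = nearest_gene(peaks, genes)
    rows = []
    for i, p in enumerate(peaks):
        cls = _classify_summit(
            p.summit, by_chrom.get(p.chrom, []), promoter_window, downstream_max
        )
        rows.append(
            {
                "peak": p.name, "chrom": p.chrom, "summit": p.summit, "feature": cls,
                "gene_id": nearest.loc[i, "gene_id"], "distance": nearest.loc[i, "distance"],
            }
        )
    return FeatureAssignment(table=pd.DataFrame(rows))


def randomized_background(
    peaks: list[Peak] | list[GenomicInterval],
    chrom_sizes: dict[str, int],
    seed: int,
) -> list[GenomicInterval]:
    """Length- and chromosome-preserving uniform random re-placement of regions."""
    rng = np.random.default_rng(seed)
    out = []
    for p in peaks:
        iv = p.interval if isinstance(p, Peak) else p
        if iv.chrom not in chrom_sizes:
            raise ValidationError(f"no chromosome size for {iv.chrom}")
        length = len(iv)
        limit = chrom_sizes[iv.chrom] - length
        if limit < 0:
            raise ValidationError(f"region longer than chromosome {iv.chrom}")
        start = int(rng.integers(0, limit + 1))
        out.append(GenomicInterval(chrom=iv.chrom, start=start, end=start + length, name=iv.name))
    return out


def category_enrichment(
    observed_in: int, observed_total: int, background_in: int, background_total: int
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher p for category membership, observed vs
    background. Returns (odds_ratio, p)."""
    if min(observed_in, observed_total, background_in, background_total) < 0:
        raise ValidationError("counts must be non-negative")
    if observed_in > observed_total or background_in > background_total:
        raise ValidationError("category counts exceed totals")
    a, b = observed_in, observed_total - observed_in
    c, d = background_in, background_total - background_in
    return odds_ratio(a, b, c, d), fisher_exact_two_sided(a, b, c, d)
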