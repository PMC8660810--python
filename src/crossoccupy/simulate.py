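"""Ground-truth-labelled synthetic inputs with the statistical structure the
analysis assumes.

The generator builds a small random genome, plants two conditions' peak sets
with an exactly controlled shared fraction (shared pairs overlap by >= 10 bp by
construction, unique peaks by 0 bp), plants or rejection-samples motif
occurrences near peak summits, lays down accessible regions hitting an exact
fraction of one condition's peaks, simulates nucleosome-free/mono-nucleosome
fragment mixtures over those regions, and emits negative-binomial time-course
count matrices whose regions follow six named trajectory archetypes. Every
claim the generator makes (shared status, motif presence, archetype label,
overlap rate) is literally true of the emitted data, so each pipeline stage
can be tested as a closure against this ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .core import GenomicInterval, GeneModel, Peak, ValidationError
from .dynamics import CountMatrix, DEFAULT_TIMEPOINTS, FragmentRecord
from .motifs import IUPAC, MotifPattern, find_matches

#: Relative mean accessibility over the five timepoints for each trajectory
#: archetype. "Loss" shapes start at the undifferentiated baseline and decay;
#: "increase" shapes are their rising counterparts.
ARCHETYPES: dict[str, tuple[float, ...]] = {
    "early_increase": (1.0, 2.5, 3.0, 3.0, 3.0),
    "late_increase": (1.0, 1.0, 1.2, 2.0, 3.0),
    "transient_increase": (1.0, 2.5, 3.0, 1.5, 1.0),
    "early_loss": (1.0, 0.4, 0.3, 0.3, 0.3),
    "late_loss": (1.0, 1.0, 0.8, 0.5, 0.3),
    "transient_loss": (1.0, 0.4, 0.3, 0.7, 1.0),
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class WorldConfig:
    """Generator parameters; the defaults are the study conditions."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 500_000, "chr2R": 500_000}
    )
    gc: float = 0.43
    n_genes: int = 60
    n_peaks: int = 500  # per condition
    shared_fraction: float = 0.4
    peak_width: int = 200
    motif: str = "CAGGTA"
    motif_fraction: float = 0.4
    motif_gradient: tuple[float, float] | None = None  # (p at top z rank, p at bottom)
    accessible_overlap: float = 0.92  # fraction of condition-B peaks overlapped
    n_extra_accessible: int = 100
    accessible_halfwidth: int = 250
    min_spacing: int = 700

    def validate(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValidationError("shared_fraction must be in [0, 1]")
        if not (0.0 <= self.accessible_overlap <= 1.0):
            raise ValidationError("accessible_overlap must be in [0, 1]")
        if self.n_peaks < 1:
            raise ValidationError("need >= 1 peak per condition")


@dataclass
class SyntheticWorld:
    """A generated genome plus every planted truth about it."""

    config: WorldConfig
    seed: int
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    accessible: list[GenomicInterval]
    truth: pd.DataFrame  # one row per peak: set, shared, motif, accessible (B only)

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        cio.write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        cio.write_gtf(self.genes, os.path.join(outdir, "genes.gtf"))
        cio.write_narrowpeak(self.peaks_a, os.path.join(outdir, "condition_a.narrowPeak"))
        cio.write_narrowpeak(self.peaks_b, os.path.join(outdir, "condition_b.narrowPeak"))
        cio.write_bed(self.accessible, os.path.join(outdir, "accessible.bed"))
        cio.write_chrom_sizes(self.chrom_sizes, os.path.join(outdir, "genome.chrom.sizes"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def _random_genome(rng: np.random.Generator, chrom_lengths: dict[str, int], gc: float):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        chrom: rng.choice(_BASES, size=length, p=p).copy()
        for chrom, length in chrom_lengths.items()
    }


def _realize_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


def _place_genes(rng: np.random.Generator, cfg: WorldConfig) -> list[GeneModel]:
    genes = []
    chroms = list(cfg.chrom_lengths)
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    gid = 0
    for chrom in chroms:
        length = cfg.chrom_lengths[chrom]
        step = length // (per_chrom + 1)
        for j in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            span = int(rng.integers(2000, 8001))
            start = (j + 1) * step + int(rng.integers(-step // 4, step // 4 + 1))
            start = max(0, min(start, length - span - 1))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            exon1 = GenomicInterval(chrom=chrom, start=start, end=start + 400, strand=strand)
            exon2 = GenomicInterval(chrom=chrom, start=end - 400, end=end, strand=strand)
            if strand == "+":
                utr5 = [GenomicInterval(chrom=chrom, start=start, end=start + 150, strand=strand)]
                utr3 = [GenomicInterval(chrom=chrom, start=end - 150, end=end, strand=strand)]
            else:
                utr5 = [GenomicInterval(chrom=chrom, start=end - 150, end=end, strand=strand)]
                utr3 = [GenomicInterval(chrom=chrom, start=start, end=start + 150, strand=strand)]
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}", chrom=chrom, strand=strand,
                    start=start, end=end, exons=[exon1, exon2], utr5=utr5, utr3=utr3,
                )
            )
            gid += 1
    return genes


def _slot_positions(rng: np.random.Generator, cfg: WorldConfig, n_slots: int):
    """Evenly spaced, jittered slot anchors; guarantees inter-slot spacing large
    enough that planted windows never interact."""
    total = sum(cfg.chrom_lengths.values())
    slots = []
    margin = 600  # room for the peak + motif window at each edge
    for chrom, length in cfg.chrom_lengths.items():
        n_here = int(round(n_slots * length / total))
        usable = length - 2 * margin
        if n_here == 0:
            continue
        step = usable // n_here
        if step < cfg.min_spacing:
            raise ValidationError(
                f"infeasible config: {n_slots} slots need spacing {cfg.min_spacing}, "
                f"{chrom} offers {step}"
            )
        jitter = (step - cfg.min_spacing) // 2
        for j in range(n_here):
            base = margin + j * step
            off = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
            slots.append((chrom, base + max(0, off)))
    if len(slots) < n_slots:  # rounding shortfall: fail loudly rather than under-plant
        raise ValidationError("infeasible config: slot rounding shortfall; reduce peak count")
    rng.shuffle(slots)
    return slots[:n_slots]


def make_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a synthetic genome with planted peak sets and ground truth.

    Deterministic given the seed. Shared peak pairs are emitted with >= 100 bp
    mutual overlap, unique peaks with zero cross-condition overlap.
    Motif-positive peaks contain a planted occurrence of the configured motif
    within the peak region (hence within 200 bp of the summit); motif-negative
    windows are rejection-sampled to contain no occurrence on either strand.
    """
    cfg = config or WorldConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    genome = _random_genome(rng, cfg.chrom_lengths, cfg.gc)
    genes = _place_genes(rng, cfg)

    w = cfg.peak_width
    half = w // 2
    motif = MotifPattern(name="planted", iupac=cfg.motif)
    L = len(motif)

    n_shared = int(round(cfg.shared_fraction * cfg.n_peaks))
    n_unique = cfg.n_peaks - n_shared
    n_acc_hits = int(round(cfg.accessible_overlap * cfg.n_peaks))
    n_slots = n_shared + 2 * n_unique + cfg.n_extra_accessible
    slots = _slot_positions(rng, cfg, n_slots)

    # peak scaffolding: (chrom, anchor) -> intervals/summits for each condition
    records = []  # rows for truth table
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []

    def add_peak(which: list[Peak], chrom: str, start: int, label: str, shared: bool):
        iv = GenomicInterval(chrom=chrom, start=start, end=start + w, name=label)
        pk = Peak(interval=iv, summit=start + half)
        which.append(pk)
        return pk

    pair_meta = []  # (peaks in pair, chrom, window for motif planting/rejection)
    si = 0
    for i in range(n_shared):
        chrom, pos = slots[si]
        si += 1
        delta = int(rng.integers(10, 101))  # overlap w - delta in [100, 190]
        pa = add_peak(peaks_a, chrom, pos, f"shared{i:05d}_a", True)
        pb = add_peak(peaks_b, chrom, pos + delta, f"shared{i:05d}_b", True)
        window = (chrom, pa.summit - 200, pb.summit + 200 + L)
        plant_lo, plant_hi = pb.start, pa.end - L  # intersection of both intervals
        pair_meta.append(([pa, pb], window, (plant_lo, plant_hi)))
    for i in range(n_unique):
        chrom, pos = slots[si]
        si += 1
        pa = add_peak(peaks_a, chrom, pos, f"uniqueA{i:05d}", False)
        pair_meta.append(([pa], (chrom, pa.summit - 200, pa.summit + 200 + L), (pa.start, pa.end - L)))
    for i in range(n_unique):
        chrom, pos = slots[si]
        si += 1
        pb = add_peak(peaks_b, chrom, pos, f"uniqueB{i:05d}", False)
        pair_meta.append(([pb], (chrom, pb.summit - 200, pb.summit + 200 + L), (pb.start, pb.end - L)))

    # per-peak z scores (synthetic enrichment strength) and motif flags
    all_groups = pair_meta
    zscores = rng.normal(2.0, 1.0, size=len(all_groups))
    if cfg.motif_gradient is not None:
        p_top, p_bot = cfg.motif_gradient
        ranks = (-zscores).argsort().argsort()  # 0 = highest z
        probs = p_top + (p_bot - p_top) * ranks / max(len(all_groups) - 1, 1)
        motif_flags = rng.random(len(all_groups)) < probs
    else:
        # exact-count planting so tallies recover the planted number exactly
        n_pos = int(round(cfg.motif_fraction * len(all_groups)))
        motif_flags = np.zeros(len(all_groups), dtype=bool)
        motif_flags[rng.choice(len(all_groups), size=n_pos, replace=False)] = True

    for gi, (group, (chrom, wlo, whi), (plo, phi)) in enumerate(all_groups):
        seq = genome[chrom]
        wlo, whi = max(0, wlo), min(len(seq), whi)
        if motif_flags[gi]:
            instance = _realize_iupac(rng, cfg.motif)
            pos = int(rng.integers(plo, phi + 1))
            seq[pos : pos + L] = np.frombuffer(instance.encode(), dtype="S1")
        else:
            # rejection-sample the whole window until motif-free on both strands
            p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
            for _ in range(200):
                sub = seq[wlo:whi].tobytes().decode()
                if not find_matches(motif, sub, both_strands=True):
                    break
                seq[wlo:whi] = rng.choice(_BASES, size=whi - wlo, p=p)
            else:
                raise RuntimeError("rejection sampling failed to clear motif window")
        for pk in group:
            pk.zscore = float(zscores[gi])

    # accessible regions: exact-count overlap of condition-B peaks
    hit_idx = rng.choice(cfg.n_peaks, size=n_acc_hits, replace=False)
    accessible: list[GenomicInterval] = []
    hw = cfg.accessible_halfwidth
    b_hit = np.zeros(cfg.n_peaks, dtype=bool)
    for j in sorted(hit_idx):
        pk = peaks_b[j]
        size = cfg.chrom_lengths[pk.chrom]
        accessible.append(
            GenomicInterval(
                chrom=pk.chrom, start=max(0, pk.summit - hw),
                end=min(size, pk.summit + hw), name=f"acc_{pk.name}",
            )
        )
        b_hit[j] = True
    for i in range(cfg.n_extra_accessible):
        chrom, pos = slots[si]
        si += 1
        size = cfg.chrom_lengths[chrom]
        accessible.append(
            GenomicInterval(
                chrom=chrom, start=max(0, pos), end=min(size, pos + 2 * hw),
                name=f"acc_bg{i:04d}",
            )
        )

    b_hit_by_name = {pk.name: bool(b_hit[j]) for j, pk in enumerate(peaks_b)}
    rows = []
    for gi, (group, _, _) in enumerate(all_groups):
        for pk in group:
            cond = "B" if pk.name in b_hit_by_name else "A"
            rows.append(
                {
                    "name": pk.name, "set": cond, "chrom": pk.chrom,
                    "start": pk.start, "end": pk.end, "summit": pk.summit,
                    "shared": pk.name.startswith("shared"), "motif": bool(motif_flags[gi]),
                    "zscore": pk.zscore,
                    "accessible": b_hit_by_name.get(pk.name, False),
                }
            )
    truth = pd.DataFrame(rows)

    genome_str = {c: a.tobytes().decode() for c, a in genome.items()}
    return SyntheticWorld(
        config=cfg, seed=seed, genome=genome_str, chrom_sizes=dict(cfg.chrom_lengths),
        genes=genes, peaks_a=peaks_a, peaks_b=peaks_b, accessible=accessible, truth=truth,
    )


# ---------------------------------------------------------------------------
# fragments


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def make_fragments(
    world: SyntheticWorld,
    depth: int,
    nucleosome_free_fraction: float = 0.85,
    rate_ratio: float = 5.0,
    low_mapq_fraction: float = 0.1,
    seed: int = 0,
    sample_name: str = "sample",
) -> list[FragmentRecord]:
    """Simulate aligned fragments for one sample.

    Lengths come from the mixture f * N(60, 15) + (1 - f) * N(200, 25),
    truncated to [20, 500] (nucleosome-free vs mono-nucleosome modes).
    Fragment midpoints fall uniformly over the genome except inside accessible
    regions, whose placement rate is ``rate_ratio`` times background
    (``rate_ratio=1`` gives a homogeneous Poisson background). A
    ``low_mapq_fraction`` of fragments get MAPQ <= 30, the rest MAPQ > 30.
    """
    if depth == 0:
        return []
    rng = np.random.default_rng(seed)
    f = nucleosome_free_fraction
    is_nf = rng.random(depth) < f
    lengths = np.empty(depth)
    n_nf = int(is_nf.sum())
    lengths[is_nf] = _truncated_normal(rng, 60, 15, 20, 500, n_nf)
    lengths[~is_nf] = _truncated_normal(rng, 200, 25, 20, 500, depth - n_nf)
    lengths = np.round(lengths).astype(int)

    chroms = sorted(world.chrom_sizes)
    sizes = np.array([world.chrom_sizes[c] for c in chroms], dtype=float)
    acc_starts = {c: [] for c in chroms}
    acc_ends = {c: [] for c in chroms}
    for iv in sorted(world.accessible, key=lambda v: (v.chrom, v.start)):
        acc_starts[iv.chrom].append(iv.start)
        acc_ends[iv.chrom].append(iv.end)
    acc_starts = {c: np.array(v, dtype=np.int64) for c, v in acc_starts.items()}
    acc_ends = {c: np.array(v, dtype=np.int64) for c, v in acc_ends.items()}
    acc_len = sum(len(iv) for iv in world.accessible)
    g_total = sizes.sum()
    p_acc = rate_ratio * acc_len / (g_total - acc_len + rate_ratio * acc_len)

    acc_cum = np.cumsum([len(iv) for iv in world.accessible]) if world.accessible else np.array([])
    frags = []
    in_acc = rng.random(depth) < p_acc
    for i in range(depth):
        length = int(lengths[i])
        if in_acc[i] and acc_len > 0:
            u = rng.integers(0, acc_len)
            j = int(np.searchsorted(acc_cum, u, side="right"))
            iv = world.accessible[j]
            mid = iv.start + int(u - (acc_cum[j] - len(iv)))
            chrom = iv.chrom
        else:
            # uniform over the non-accessible genome by rejection
            while True:
                ci = int(rng.choice(len(chroms), p=sizes / g_total))
                chrom = chroms[ci]
                mid = int(rng.integers(0, world.chrom_sizes[chrom]))
                j = int(np.searchsorted(acc_starts[chrom], mid, side="right")) - 1
                if j < 0 or mid >= acc_ends[chrom][j]:
                    break
        size = world.chrom_sizes[chrom]
        start = max(0, min(mid - length // 2, size - length))
        iv_f = GenomicInterval(
            chrom=chrom, start=start, end=start + length, name=f"{sample_name}_{i}"
        )
        mapq = int(rng.integers(0, 31)) if rng.random() < low_mapq_fraction else int(rng.integers(31, 61))
        frags.append(FragmentRecord(interval=iv_f, mapq=mapq))
    return frags


# ---------------------------------------------------------------------------
# time-course counts


def _scale_profile(profile: np.ndarray, effect_size: float | None) -> np.ndarray:
    if effect_size is None:
        return profile
    logp = np.log(profile)
    spread = logp.max() - logp.min()
    if spread == 0:
        return profile
    return np.exp(logp * np.log(effect_size) / spread)


def make_timecourse(
    n_regions: int = 2000,
    changing_fraction: float = 0.3,
    archetype_mix: dict[str, float] | None = None,
    dispersion: float = 0.1,
    base_mean: float = 50.0,
    replicates: int = 2,
    timepoints: tuple = DEFAULT_TIMEPOINTS,
    planted_size_factors: np.ndarray | None = None,
    effect_size: float | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Simulate a five-timepoint NB count matrix with archetype truth labels.

    A ``changing_fraction`` of regions follow trajectory archetypes (equal mix
    by default); the rest are flat. Counts are NB with mean
    ``base_mean * profile(t) * size_factor(sample)`` and the given dispersion.
    ``effect_size`` rescales archetype profiles so their max/min fold change
    equals it. Returns the count matrix and per-region truth labels
    ("null" or the archetype name).
    """
    rng = np.random.default_rng(seed)
    T = len(timepoints)
    samples = []
    for t in timepoints:
        for r in range(replicates):
            samples.append((f"t{t}_r{r + 1}", t, r + 1))
    sample_ids = [s[0] for s in samples]
    sheet = pd.DataFrame(
        {"timepoint": [s[1] for s in samples], "replicate": [s[2] for s in samples]},
        index=sample_ids,
    )
    if planted_size_factors is None:
        sf = np.ones(len(samples))
    else:
        sf = np.asarray(planted_size_factors, dtype=float)
        if len(sf) != len(samples):
            raise ValidationError("planted_size_factors length must match sample count")

    mix = archetype_mix or {a: 1.0 / len(ARCHETYPES) for a in ARCHETYPES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValidationError("archetype_mix must sum to 1")
    n_changing = int(round(changing_fraction * n_regions))
    labels = ["null"] * (n_regions - n_changing)
    names = list(mix)
    counts_per = {a: int(round(mix[a] * n_changing)) for a in names}
    # fix rounding drift on the last archetype
    drift = n_changing - sum(counts_per.values())
    counts_per[names[-1]] += drift
    for a in names:
        labels += [a] * counts_per[a]
    labels = pd.Series(labels, index=[f"region{i:05d}" for i in range(n_regions)], name="archetype")

    profiles = {a: _scale_profile(np.array(ARCHETYPES[a]), effect_size) for a in ARCHETYPES}
    profiles["null"] = np.ones(T)
    mean_matrix = np.empty((n_regions, len(samples)))
    tp_index = np.array([timepoints.index(s[1]) for s in samples])
    for i, lab in enumerate(labels):
        mean_matrix[i] = base_mean * profiles[lab][tp_index] * sf
    if dispersion < 1e-8:
        counts = rng.poisson(mean_matrix)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean_matrix)
        counts = rng.negative_binomial(r, p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=labels.index, columns=sample_ids), samples=sheet
    )
    return cm, labels


def make_trajectories(
    n_per_archetype: int = 100, noise_sd: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Noisy z-scored archetype trajectories for clustering recovery tests."""
    rng = np.random.default_rng(seed)
    rows, labs = [], []
    for a, profile in ARCHETYPES.items():
        base = np.array(profile)
        z = (base - base.mean()) / base.std()
        for _ in range(n_per_archetype):
            rows.append(z + rng.normal(0, noise_sd, size=len(z)))
            labs.append(a)
    idx = [f"traj{i:05d}" for i in range(len(rows))]
    X = pd.DataFrame(rows, index=idx, columns=list(DEFAULT_TIMEPOINTS))
    return X, pd.Series(labs, index=idx, name="archetype")
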