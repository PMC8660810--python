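"""IUPAC motif scanning, region tallies and rank-binned fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossoccupy import (
    GenomicInterval,
    MotifPattern,
    ValidationError,
    count_regions_with_motif,
    default_motifs,
    find_matches,
    motif_near_summit,
    rank_binned_fraction,
    reverse_complement,
)
from crossoccupy.motifs import IUPAC
from conftest import make_peak


def brute_force_matches(pattern, seq, both_strands=True):
    """Independent position-by-position membership scanner."""
    seq = seq.upper()
    hits = []
    for pat, strand in ((pattern.iupac, "+"), (reverse_complement(pattern.iupac), "-")):
        if strand == "-" and not both_strands:
            continue
        L = len(pat)
        for p in range(len(seq) - L + 1):
            if all(seq[p + i] in IUPAC[pat[i]] for i in range(L)):
                hits.append((p, strand))
    return sorted(hits)


class TestPattern:
    def test_invalid_character_rejected(self):
        with pytest.raises(ValidationError):
            MotifPattern(name="bad", iupac="CAGX")
        with pytest.raises(ValidationError):
            MotifPattern(name="empty", iupac="")

    def test_reverse_complement_degenerate(self):
        assert reverse_complement("CAGGTARV") == "BYTACCTG"
        assert reverse_complement(reverse_complement("AAAWGVVCMNH")) == "AAAWGVVCMNH"


class TestFindMatches:
    def test_literal_match(self):
        pat = MotifPattern(name="zld", iupac="CAGGTAG")
        assert find_matches(pat, "ACAGGTAGT") == [(1, "+")]

    def test_reverse_complement_embedded(self):
        # CTACCTG at position 2 is the reverse complement of CAGGTAG
        pat = MotifPattern(name="zld", iupac="CAGGTAG")
        hits = find_matches(pat, "ACTACCTGT")
        assert hits == [(1, "-")]

    def test_iupac_expansion(self):
        pat = MotifPattern(name="zldvar", iupac="CAGGTARV")
        assert (0, "+") in find_matches(pat, "CAGGTAGA")  # R<-G, V<-A

    def test_n_in_sequence_matches_nothing(self):
        pat = MotifPattern(name="anyN", iupac="NNN")
        assert find_matches(pat, "ACNGT") == []
        assert find_matches(pat, "ACGGT") != []

    def test_overlapping_matches_all_reported(self):
        pat = MotifPattern(name="aa", iupac="AA")
        hits = find_matches(pat, "AAAA", both_strands=False)
        assert [h[0] for h in hits] == [0, 1, 2]

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=300))
        for pat in default_motifs():
            assert find_matches(pat, seq) == brute_force_matches(pat, seq)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_reverse_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pat = MotifPattern(name="zldvar", iupac="CAGGTARV")
        rc_pat = MotifPattern(name="rc", iupac=reverse_complement(pat.iupac))
        fwd = find_matches(pat, seq)
        # matching P on S equals matching revcomp(P) on revcomp(S), coordinates flipped
        rev = find_matches(rc_pat, reverse_complement(seq))
        L = len(pat)
        flipped = sorted((len(seq) - p - L, strand) for p, strand in rev)
        assert flipped == fwd


class TestRegionTallies:
    def test_empty_region_list(self):
        pat = MotifPattern(name="m", iupac="CAGGTA")
        count, flags = count_regions_with_motif(pat, [], {"c": "ACGT" * 100})
        assert count == 0 and flags == []

    def test_match_straddling_edge_not_counted(self):
        genome = {"c": "TTTTTTCAGGTAGTTT"}
        pat = MotifPattern(name="zld", iupac="CAGGTAG")
        region_cut = [GenomicInterval(chrom="c", start=0, end=9)]  # motif runs 6..13
        region_full = [GenomicInterval(chrom="c", start=0, end=13)]
        assert count_regions_with_motif(pat, region_cut, genome)[0] == 0
        assert count_regions_with_motif(pat, region_full, genome)[0] == 1

    def test_region_exceeding_chromosome_errors(self):
        pat = MotifPattern(name="m", iupac="CA")
        with pytest.raises(ValidationError):
            count_regions_with_motif(pat, [GenomicInterval(chrom="c", start=0, end=99)], {"c": "ACGT"})

    def test_monotone_under_region_extension(self, world):
        pat = MotifPattern(name="planted", iupac=world.config.motif)
        regions = [p.interval for p in world.peaks_a[:100]]
        wide = [
            GenomicInterval(chrom=r.chrom, start=max(0, r.start - 50), end=r.end + 50)
            for r in regions
        ]
        _, base = count_regions_with_motif(pat, regions, world.genome)
        _, wider = count_regions_with_motif(pat, wide, world.genome)
        assert all(w or not b for b, w in zip(base, wider))

    def test_recovers_planted_count_exactly(self, world):
        pat = MotifPattern(name="planted", iupac=world.config.motif)
        truth_a = world.truth[world.truth.set == "A"].set_index("name")
        regions = [p.interval for p in world.peaks_a]
        count, flags = count_regions_with_motif(pat, regions, world.genome)
        assert count == int(truth_a.motif.sum())
        for p, f in zip(world.peaks_a, flags):
            assert f == bool(truth_a.loc[p.name, "motif"])


class TestNearSummit:
    GENOME = {"c": "T" * 2000}

    def _genome_with(self, pos):
        s = list("T" * 2000)
        s[pos : pos + 6] = "CAGGTA"
        return {"c": "".join(s)}

    def test_boundary_exactly_200_positive(self):
        pk = make_peak("c", 900, 1100, summit=1000)
        pat = MotifPattern(name="m", iupac="CAGGTA")
        assert motif_near_summit(pat, [pk], self._genome_with(1200)) == [True]

    def test_boundary_201_negative(self):
        pk = make_peak("c", 900, 1100, summit=1000)
        pat = MotifPattern(name="m", iupac="CAGGTA")
        assert motif_near_summit(pat, [pk], self._genome_with(1201)) == [False]

    def test_planted_summit_motifs_recovered(self, world):
        pat = MotifPattern(name="planted", iupac=world.config.motif)
        flags = motif_near_summit(pat, world.peaks_b, world.genome, window=200)
        truth_b = world.truth[world.truth.set == "B"].set_index("name")
        for p, f in zip(world.peaks_b, flags):
            assert f == bool(truth_b.loc[p.name, "motif"])


class TestRankBinned:
    def test_partition_arithmetic(self, rng):
        genome = {"c": "".join(rng.choice(list("ACGT"), size=300_000))}
        peaks = [
            make_peak("c", i * 1000, i * 1000 + 200, zscore=float(z))
            for i, z in enumerate(rng.normal(size=250))
        ]
        table = rank_binned_fraction(peaks, [MotifPattern(name="m", iupac="CAGGTA")], genome)
        assert list(table.table["n_peaks"]) == [100, 100, 50]

    def test_all_positive_fractions_one(self):
        genome = {"c": "CAGGTA" * 100_000}
        peaks = [
            make_peak("c", i * 1000, i * 1000 + 200, zscore=float(i)) for i in range(150)
        ]
        table = rank_binned_fraction(peaks, [MotifPattern(name="m", iupac="CAGGTA")], genome)
        assert (table.table["m"] == 1.0).all()

    def test_requires_zscores(self):
        with pytest.raises(ValidationError):
            rank_binned_fraction(
                [make_peak("c", 0, 200)], [MotifPattern(name="m", iupac="CAGGTA")], {"c": "A" * 300}
            )
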