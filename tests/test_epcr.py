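"""Electronic-PCR engine: index construction, hit finding, classification."""

import numpy as np
import pytest

from oracles import find_all, naive_epcr
from pseudomap.epcr import PcrHit, PrimerIndex, build_index, classify_mapping, epcr
from pseudomap.model import GenomicInterval, PrimerPair, revcomp
from pseudomap.synthetic import make_genome


class TestIndex:
    def test_hand_enumerated_word_positions(self):
        idx = build_index({"c": "ACGTACGT"}, word_size=4)
        assert idx.lookup("ACGT") == [("c", 1), ("c", 5)]
        assert idx.lookup("CGTA") == [("c", 2)]
        assert idx.lookup("AAAA") == []

    def test_words_containing_n_are_omitted(self):
        idx = build_index({"c": "ACGTNACGTACG"}, word_size=4)
        assert all("N" not in w for w in idx.word_map)
        # words starting at 2..5 overlap the N at position 5 and are dropped
        assert idx.lookup("ACGT") == [("c", 1), ("c", 6)]
        assert idx.lookup("CGTN") == []
        assert idx.lookup("CGTA") == [("c", 7)]

    def test_short_chromosome_warns_and_contributes_nothing(self):
        with pytest.warns(UserWarning, match="shorter than word_size"):
            idx = build_index({"tiny": "ACGTAC", "ok": "ACGTACGTACGT"}, word_size=8)
        assert all(chrom == "ok" for occ in idx.word_map.values() for chrom, _ in occ)

    def test_word_map_equals_naive_substring_scan(self):
        genome, _ = make_genome(7, n_chrom=1, lengths=[12_000])
        k = 8
        idx = build_index(genome, word_size=k)
        seq = genome["chr1"]
        expected = {}
        for i in range(len(seq) - k + 1):
            expected.setdefault(seq[i : i + k], []).append(("chr1", i + 1))
        assert idx.word_map == expected

    def test_save_and_load_round_trip(self, tmp_path, small_index):
        path = tmp_path / "genome.idx"
        small_index.save(path)
        loaded = PrimerIndex.load(path)
        assert loaded.word_size == small_index.word_size
        assert loaded.word_map == small_index.word_map
        assert loaded.genome == small_index.genome


class TestEpcr:
    def _planted_pair(self, genome):
        t = genome["chr1"]
        fwd = t[10:30]                 # 1-based [11, 30]
        rev = revcomp(t[40:60])        # 1-based [41, 60]
        return PrimerPair("planted", fwd, rev)

    def test_planted_construction_recovered(self, small_genome, small_index):
        genome, _ = small_genome
        pair = self._planted_pair(genome)
        hits = epcr(pair, small_index, max_amplicon=1000)
        assert [h for h in hits if h.interval.start == 11] == [
            PcrHit("planted", GenomicInterval("chr1", 11, 60), 50, "forward")
        ]

    def test_single_substitution_gives_zero_hits(self, small_genome, small_index):
        genome, _ = small_genome
        pair = self._planted_pair(genome)
        mutated = list(pair.forward)
        mutated[10] = {"A": "C"}.get(mutated[10], "A")
        bad = PrimerPair("mut", "".join(mutated), pair.reverse)
        starts = {h.interval.start for h in epcr(bad, small_index, 1000)}
        assert 11 not in starts

    def test_planted_fixture_recall_and_precision(self, planted_epcr):
        genome, log, pairs = planted_epcr
        index = build_index(genome, word_size=12)
        planted = {
            s["marker_id"]: (s["chrom"], s["start"], s["end"], s["plus_strand_primer"])
            for s in log.primer_sites
        }
        for pair in pairs:
            hits = epcr(pair, index, max_amplicon=500)
            assert classify_mapping(hits) == "unique"
            (h,) = hits
            chrom, start, end, plus = planted[pair.marker_id]
            assert (h.interval.chrom, h.interval.start, h.interval.end) == (
                chrom, start, end)
            assert h.plus_strand_primer == plus
            assert h.amplicon_len == end - start + 1

    def test_equals_naive_two_strand_scan(self, planted_epcr):
        genome, _, pairs = planted_epcr
        index = build_index(genome, word_size=12)
        for pair in pairs:
            got = [
                (h.interval.chrom, h.interval.start, h.interval.end)
                for h in epcr(pair, index, max_amplicon=500)
            ]
            assert got == naive_epcr(genome, pair.forward, pair.reverse, 500)

    def test_random_primers_equal_naive_scan(self):
        """Primers sampled from the genome with random lengths, including
        pairs that will hit nothing in valid orientation."""
        genome, _ = make_genome(13, n_chrom=1, lengths=[40_000])
        index = build_index(genome, word_size=12)
        rng = np.random.default_rng(13)
        seq = genome["chr1"]
        for i in range(30):
            lf, lr = rng.integers(15, 26, size=2)
            a = int(rng.integers(0, len(seq) - 400))
            b = a + int(rng.integers(50, 380))
            fwd = seq[a : a + lf]
            rev = revcomp(seq[b : b + lr]) if i % 2 == 0 else seq[b : b + lr]
            pair = PrimerPair(f"r{i}", fwd, rev)
            got = [
                (h.interval.chrom, h.interval.start, h.interval.end)
                for h in epcr(pair, index, max_amplicon=2000)
            ]
            assert got == naive_epcr(genome, fwd, rev, 2000)

    def test_strand_symmetry(self, planted_epcr):
        """e-PCR on the reverse-complemented genome mirrors all coordinates."""
        genome, _, pairs = planted_epcr
        flipped = {c: revcomp(s) for c, s in genome.items()}
        fwd_index = build_index(genome, word_size=12)
        rc_index = build_index(flipped, word_size=12)
        for pair in pairs:
            direct = {
                (h.interval.chrom, h.interval.start, h.interval.end)
                for h in epcr(pair, fwd_index, 500)
            }
            mirrored = set()
            for h in epcr(pair, rc_index, 500):
                L = len(genome[h.interval.chrom])
                mirrored.add(
                    (h.interval.chrom, L - h.interval.end + 1, L - h.interval.start + 1)
                )
            assert direct == mirrored

    def test_overlapping_primer_footprints_rejected(self):
        # forward and reverse annealing sites overlap -> amplicon shorter
        # than the primer-length sum -> invalid
        core = "ATCGGATCCGTTAGCAACGG"
        genome = {"c": "T" * 2000 + core + "A" * 2000}
        index = build_index(genome, word_size=12)
        pair = PrimerPair("ov", core[:15], revcomp(core)[:15])  # 20 bp apart
        assert epcr(pair, index, 1000) == []

    def test_max_amplicon_bound(self, small_genome):
        genome, _ = small_genome
        index = build_index(genome, word_size=12)
        t = genome["chr2"]
        pair = PrimerPair("wide", t[0:20], revcomp(t[5000:5020]))
        assert epcr(pair, index, max_amplicon=1000) == []
        hits = epcr(pair, index, max_amplicon=10_000)
        assert [h.amplicon_len for h in hits] == [5020]

    def test_primer_shorter_than_word_size_rejected(self, small_index):
        pair = PrimerPair("short", "ACGTACGTAC", "ACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="word_size"):
            epcr(pair, small_index, 1000)


@pytest.mark.parametrize(
    "n_hits,expected", [(0, "unmapped"), (1, "unique"), (2, "multi"), (5, "multi")]
)
def test_classify_mapping(n_hits, expected):
    hits = [
        PcrHit("m", GenomicInterval(f"chr{i % 2 + 4}", 10 + 100 * i, 59 + 100 * i),
               50, "forward")
        for i in range(n_hits)
    ]
    assert classify_mapping(hits) == expected
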