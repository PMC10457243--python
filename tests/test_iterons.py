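"""Tandem iteron detection, degenerate consensus notation, upstream windows."""

import numpy as np
import pytest

from oracles import enumerate_tandem_arrays
from plasmidnet import (
    GeneFeature,
    IteronSpec,
    PlasmidRecord,
    RepModuleSpec,
    build_consensus,
    find_iteron_arrays,
    find_iteron_arrays_both_strands,
    generate_plasmid,
    parse_consensus,
    upstream_window,
)
from plasmidnet.iterons import IteronError
from plasmidnet.seqio import reverse_complement

PA3H1_UNIT = "CATAAAGCTACGTTTAGCGACC"  # 22-bp Rep_3-type iteron unit

# the eight published oriV consensus strings of the ANT_H3 set
PUBLISHED_CONSENSI = {
    "CATAAAGCTACGTTTAGCGACC": 22,
    "CATACCCTTACGTTTAGCGACC": 22,
    "CATACCACTACGTCTATCGACC": 22,
    "CATATGACGACAAATTCCTACC": 22,
    "CT(A/T)(T/G)ATGACTACAAATCCTTAC": 22,
    "(G/C)ATA(A/G)(A/G)(C/T)ATACGTTTATACACC": 22,
    "(A/T)(A/T)(A/G)AAGCTAC(A/G)(A/T)(C/T)(A/T)ATCATA(A/G)": 21,
    "AGAAAAAACAGTAAATGAGC": 20,
}


def _random_dna(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), n))


class TestConsensusNotation:
    @pytest.mark.parametrize("text,unit_bp", sorted(PUBLISHED_CONSENSI.items()))
    def test_published_strings_parse_to_stated_unit_lengths(self, text, unit_bp):
        cons = parse_consensus(text)
        assert len(cons) == unit_bp

    @pytest.mark.parametrize("text", sorted(PUBLISHED_CONSENSI))
    def test_parse_render_round_trip_is_identity(self, text):
        assert parse_consensus(text).render() == text

    def test_build_orders_bases_by_count_then_alphabet(self):
        assert build_consensus(["ACG", "ACG", "ACT", "ACT"]).render() == "AC(G/T)"
        assert build_consensus(["ACG", "ACT", "ACT"]).render() == "AC(T/G)"
        assert build_consensus(["AAA", "AAA", "AAA"]).render() == "AAA"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(IteronError):
            build_consensus(["ACGT", "ACG"])

    def test_garbage_rejected(self):
        with pytest.raises(IteronError):
            parse_consensus("AC(G/)")


class TestFindIteronArrays:
    def test_four_exact_copies_of_published_unit(self):
        seq = _random_dna(1, 300) + PA3H1_UNIT * 4 + _random_dna(2, 300)
        (arr,) = find_iteron_arrays(seq)
        assert arr.unit_length == 22
        assert arr.copy_count == 4
        assert arr.start == 301
        assert arr.consensus.render() == PA3H1_UNIT
        assert arr.mean_mismatch_frac == 0.0

    def test_homopolymer_suppressed_as_low_complexity(self):
        assert find_iteron_arrays("A" * 200) == []

    def test_dinucleotide_repeat_suppressed(self):
        assert find_iteron_arrays("AT" * 120) == []

    def test_inverted_unit_range_rejected(self):
        with pytest.raises(IteronError):
            find_iteron_arrays("ACGT" * 50, unit_range=(24, 18))

    def test_planted_noisy_array_matches_exhaustive_enumeration(self):
        # one 21-bp x4 array with 1 substitution per copy inside 1 kb
        rng = np.random.default_rng(99)
        unit = "GATCCATTGACGTAGGCTACA"
        copies = []
        for _ in range(4):
            c = list(unit)
            i = int(rng.integers(len(c)))
            c[i] = rng.choice([b for b in "ACGT" if b != c[i]])
            copies.append("".join(c))
        seq = _random_dna(5, 450) + "".join(copies) + _random_dna(6, 450)
        found = find_iteron_arrays(seq, min_copies=4)
        assert len(found) == 1
        assert (found[0].unit_length, found[0].copy_count) == (21, 4)
        # brute force: no qualifying (start, unit, >=4 copies) outside the plant
        oracle = enumerate_tandem_arrays(seq, (18, 24), 4, 0.15)
        spans = {(s, s + u * c) for s, u, c in oracle}
        assert any(s <= 450 < e for s, e in spans)
        assert all(450 - 24 * 4 <= s and e <= 450 + 21 * 4 + 24 * 4 for s, e in spans)

    def test_zero_mismatch_mode_equals_exact_scan_oracle(self):
        seq = _random_dna(11, 600) + "CATTGACGTAGGCTACAC" * 3 + _random_dna(12, 600)
        found = find_iteron_arrays(seq, max_mismatch_frac=0.0)
        oracle = enumerate_tandem_arrays(seq, (18, 24), 3, 0.0)
        assert len(found) == 1
        starts = {s for s, u, c in oracle}
        assert found[0].start - 1 in starts
        assert (found[0].unit_length, found[0].copy_count) in {
            (u, c) for s, u, c in oracle
        }

    def test_detection_is_rotation_invariant(self, small_plasmid):
        rec, truth = small_plasmid
        planted = truth.planted_iterons[0]
        for k in (0, 1234, 2500):
            rot = rec.rotated(k)
            # search the whole (rotated) plasmid doubled to erase the cut
            found = find_iteron_arrays(rot.sequence + rot.sequence[:200], min_copies=4)
            assert any(
                a.unit_length == planted.unit_length and a.copy_count >= 4 for a in found
            )

    def test_recovery_rate_at_low_noise(self):
        """>=95% of planted 4-copy arrays recovered exactly at <=5% noise."""
        ok = 0
        n = 60
        for seed in range(n):
            rec, truth = generate_plasmid(
                3000,
                0.40,
                rep=RepModuleSpec(
                    iterons=IteronSpec(unit_length=22, copies=4, substitution_prob=0.05)
                ),
                seed=seed,
                plasmid_id=f"p{seed}",
            )
            planted = truth.planted_iterons[0]
            repf = rec.features[0]
            win = upstream_window(rec, repf, 500)
            found = find_iteron_arrays_both_strands(win)
            if any(
                a.unit_length == planted.unit_length and a.copy_count == planted.copy_count
                for a in found
            ):
                ok += 1
        assert ok / n >= 0.95

    def test_both_strands_collapse_duplicate_calls(self):
        seq = _random_dna(21, 200) + PA3H1_UNIT * 4 + _random_dna(22, 200)
        found = find_iteron_arrays_both_strands(seq)
        assert len(found) == 1
        assert found[0].strand == "+"

    def test_reverse_complement_array_detected_once(self):
        # a tandem array is strand-symmetric: its reverse complement is a
        # tandem array of the reverse-complemented unit, caught on plus
        seq = _random_dna(31, 200) + reverse_complement(PA3H1_UNIT * 4) + _random_dna(32, 200)
        found = find_iteron_arrays_both_strands(seq)
        assert len(found) == 1
        assert (found[0].unit_length, found[0].copy_count) == (22, 4)
        assert reverse_complement(found[0].consensus.render()) == PA3H1_UNIT


class TestUpstreamWindow:
    def _record(self, n=2000, start=1000, strand="+"):
        seq = _random_dna(41, n)
        feat = GeneFeature("rep", start, start + 299, strand, "replication protein")
        return PlasmidRecord("p", seq, features=[feat]), feat

    def test_plus_strand_window_coordinates(self):
        rec, feat = self._record()
        win = upstream_window(rec, feat, 500)
        assert win == rec.sequence[499:999]  # positions 500..999

    def test_minus_strand_is_reverse_complement_of_3prime_flank(self):
        rec, feat = self._record(strand="-")
        win = upstream_window(rec, feat, 500)
        assert win == reverse_complement(rec.sequence[feat.end : feat.end + 500])

    def test_wraps_through_origin(self):
        rec, _ = self._record()
        feat = GeneFeature("rep", 100, 399, "+", "rep")
        win = upstream_window(rec, feat, 500)
        assert win == rec.sequence[-401:] + rec.sequence[:99]

    def test_oversized_window_truncates_with_warning(self):
        rec, feat = self._record()
        with pytest.warns(UserWarning):
            win = upstream_window(rec, feat, 5000)
        assert len(win) == rec.length

    def test_planted_array_recovered_through_window(self, small_plasmid):
        rec, truth = small_plasmid
        planted = truth.planted_iterons[0]
        repf = rec.features[0]
        win = upstream_window(rec, repf, 500)
        found = find_iteron_arrays(win, min_copies=4)
        assert [a for a in found if a.unit_length == planted.unit_length]
        (arr,) = [a for a in found if a.unit_length == planted.unit_length]
        assert arr.copies == planted.copies
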