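"""Palindrome construction, classification, scanning and annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palfork.sequences import (
    InvalidAlphabetError,
    PalindromeSite,
    annotate_structure,
    build_palindrome,
    classify_palindrome,
    find_inverted_repeats,
    read_fasta,
    reverse_complement,
    sites_to_bed6,
    write_fasta,
)

from conftest import brute_force_sites, random_arm, random_dna, random_spacer

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(dna)
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


class TestBuildPalindrome:
    @pytest.mark.parametrize(
        ("arm_len", "spacer_len", "total", "kind"),
        [
            (230, 0, 460, "perfect"),  # the perfect construct
            (230, 20, 480, "interrupted"),  # same arms, 20 bp asymmetry
            (111, 24, 246, "interrupted"),  # the shorter historical construct
        ],
    )
    def test_construct_geometry(self, rng, arm_len, spacer_len, total, kind):
        construct = build_palindrome(
            random_arm(rng, arm_len), random_spacer(rng, spacer_len)
        )
        assert construct.total_length == total
        assert construct.arm_length == arm_len
        assert construct.spacer_length == spacer_len
        assert construct.classification == kind
        assert len(construct.sequence) == total

    def test_full_sequence_structure(self):
        construct = build_palindrome("ACG")
        assert construct.sequence == "ACGCGT"
        assert construct.sequence == reverse_complement(construct.sequence)

    def test_perfect_construct_is_self_reverse_complementary(self, rng):
        for n in (5, 17, 60):
            seq = build_palindrome(random_arm(rng, n)).sequence
            assert seq == reverse_complement(seq)

    def test_rejects_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            build_palindrome("ACGN")
        with pytest.raises(InvalidAlphabetError):
            build_palindrome("ACG", "aXg")
        with pytest.raises(ValueError):
            build_palindrome("")


class TestClassifyPalindrome:
    def test_perfect_example(self):
        assert classify_palindrome("ACGCGT", min_arm=2) == ("perfect", 3, 0, 3.0)

    def test_maximal_arm_decomposition(self):
        # "ACGT" + "T" + revcomp("ACGT"): the maximal arm is 4, not the
        # shorter arm-3/spacer-3 reading of the same string
        kind, arm, spacer, center = classify_palindrome("ACGTTACGT", min_arm=2)
        assert (kind, arm, spacer) == ("interrupted", 4, 1)
        assert center == 4.5

    def test_no_palindrome(self):
        assert classify_palindrome("AAAAAA", min_arm=2)[0] == "none"

    def test_short_arm_below_minimum_is_none(self):
        assert classify_palindrome("ACGCGT", min_arm=10)[0] == "none"

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            classify_palindrome("ACGU")

    def test_build_then_classify_is_identity(self, rng):
        for arm_len, spacer_len in [(10, 0), (25, 0), (12, 5), (30, 21), (111, 24)]:
            construct = build_palindrome(
                random_arm(rng, arm_len), random_spacer(rng, spacer_len)
            )
            kind, arm, spacer, _ = classify_palindrome(
                construct.sequence, min_arm=arm_len
            )
            assert (arm, spacer) == (arm_len, spacer_len)
            assert kind == construct.classification


class TestScanner:
    def test_a4t4(self):
        sites = find_inverted_repeats("AAAATTTT", min_arm=4, max_spacer=0)
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end, site.arm_length, site.spacer_length) == (
            0, 8, 4, 0,
        )

    def test_embedded_perfect_palindrome_in_random_background(self, rng):
        background = random_dna(rng, 5000)
        palindrome = build_palindrome(random_arm(rng, 230)).sequence
        seq = background[:1000] + palindrome + background[1000:]
        sites = find_inverted_repeats(seq, min_arm=25, max_spacer=5)
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end) == (1000, 1460)
        assert (site.arm_length, site.spacer_length) == (230, 0)
        assert site.classification == "perfect"

    def test_random_sequence_has_no_long_arms(self, rng):
        seq = random_dna(rng, 1000)
        assert find_inverted_repeats(seq, min_arm=25, max_spacer=0) == []

    def test_embedded_interrupted_site(self, rng):
        arm = random_arm(rng, 30)
        spacer = random_spacer(rng, 10)
        insert = build_palindrome(arm, spacer).sequence
        seq = random_dna(rng, 300) + insert + random_dna(rng, 300)
        sites = find_inverted_repeats(seq, min_arm=20, max_spacer=10)
        assert len(sites) == 1
        assert (sites[0].arm_length, sites[0].spacer_length) == (30, 10)

    def test_agrees_with_brute_force_span_checker(self, rng):
        """Scanner output matches an independent exhaustive span checker
        in both directions, on random and palindrome-seeded sequences."""
        cases = []
        for _ in range(4):
            cases.append(random_dna(rng, 250))
        planted = (
            random_dna(rng, 80)
            + build_palindrome(random_arm(rng, 15)).sequence
            + random_dna(rng, 40)
            + build_palindrome(random_arm(rng, 12), random_spacer(rng, 2)).sequence
            + random_dna(rng, 80)
        )
        cases.append(planted)
        for seq in cases:
            for min_arm, max_spacer in [(4, 0), (4, 2), (5, 3)]:
                got = sorted(
                    (s.start, s.end, s.arm_length, s.spacer_length)
                    for s in find_inverted_repeats(
                        seq, min_arm=min_arm, max_spacer=max_spacer
                    )
                )
                expected = brute_force_sites(seq, min_arm, max_spacer)
                assert got == expected

    def test_sites_sorted_and_valid(self, rng):
        seq = random_dna(rng, 600)
        sites = find_inverted_repeats(seq, min_arm=4, max_spacer=2)
        starts = [s.start for s in sites]
        assert starts == sorted(starts)
        for s in sites:
            assert s.end - s.start == 2 * s.arm_length + s.spacer_length
            left = seq[s.start : s.start + s.arm_length]
            right = seq[s.end - s.arm_length : s.end]
            assert left == reverse_complement(right)

    def test_empty_sequence(self):
        assert find_inverted_repeats("", min_arm=4, max_spacer=0) == []

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT", min_arm=1)
        with pytest.raises(InvalidAlphabetError):
            find_inverted_repeats("ACGTN", min_arm=4)


class TestAnnotateStructure:
    @staticmethod
    def _site(arm: int, spacer: int) -> PalindromeSite:
        return PalindromeSite(
            sequence_id="chr", start=100, end=100 + 2 * arm + spacer,
            arm_length=arm, spacer_length=spacer,
        )

    def test_perfect_460_forms_hairpins_on_both_strands(self):
        site = annotate_structure(self._site(230, 0))
        assert site.sbccd_susceptible is True
        assert site.structure_forming_strands == "both"

    def test_interrupted_480_is_lagging_only(self):
        site = annotate_structure(self._site(230, 20))
        assert site.sbccd_susceptible is True
        assert site.structure_forming_strands == "lagging_only"

    def test_short_perfect_palindrome_not_targeted(self):
        site = annotate_structure(self._site(6, 0))  # 12 bp total
        assert site.sbccd_susceptible is False

    def test_intermediate_spacer_flagged_unknown(self):
        with pytest.warns(UserWarning, match="unknown"):
            site = annotate_structure(self._site(30, 10))
        assert site.structure_forming_strands == "unknown"


class TestIO:
    def test_fasta_round_trip(self, rng, tmp_path):
        records = [("a", random_dna(rng, 150)), ("b", random_dna(rng, 7))]
        path = tmp_path / "seqs.fa"
        write_fasta(records, path)
        assert list(read_fasta(path)) == records

    def test_bed6_output(self):
        site = PalindromeSite("chr1", 10, 18, arm_length=4, spacer_length=0)
        assert sites_to_bed6([site]) == "chr1\t10\t18\tperfect\t4\t.\n"
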