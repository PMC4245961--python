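"""DNA palindrome construction, classification and genome scanning.

A *perfect* palindrome is a sequence equal to its own reverse complement:
two inverted-repeat arms with no central spacer.  An *interrupted*
palindrome carries a non-self-complementary spacer between the arms.  The
distinction matters biologically: a perfect palindrome can fold into a
hairpin on either template strand of a replication fork (or extrude a
cruciform from duplex DNA), whereas a central asymmetry of ~20 bp or more
kinetically restricts structure formation to the transiently
single-stranded lagging-strand template.

Coordinates are 0-based, half-open.  Palindromes are strand-symmetric, so
sites carry no strand field.  Arm matching is exact (the experimental
constructs are exact inverted repeats); degenerate bases and mismatched
quasi-palindromes are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "InvalidAlphabetError",
    "PalindromeConstruct",
    "PalindromeSite",
    "reverse_complement",
    "build_palindrome",
    "classify_palindrome",
    "find_inverted_repeats",
    "annotate_structure",
    "read_fasta",
    "write_fasta",
    "sites_to_bed6",
    "sites_to_table",
]

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default minimum total palindrome length (bp) for SbcCD cleavage of the
#: folded hairpin.  In vitro the enzyme requires structures formed by
#: palindromes of roughly 20-36 bp; the conservative upper bound of that
#: range is used so that short, naturally occurring genomic palindromes
#: are classified as not targeted.
DEFAULT_SUSCEPTIBILITY_THRESHOLD = 36

#: Default minimum spacer length (bp) at which structure formation is
#: confidently restricted to the lagging-strand template.  Spacers of 20
#: and 24 bp are the experimentally characterised interrupted cases;
#: shorter non-zero spacers are flagged ``unknown``.
DEFAULT_INTERRUPTED_THRESHOLD = 20


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T."""


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"{what} contains non-ACGT characters: {sorted(bad)}"
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string (uppercase)."""
    _check_alphabet(seq)
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PalindromeConstruct:
    """An inserted palindrome: two exact inverted arms around a spacer.

    The full sequence is ``arm + spacer + reverse_complement(arm)``; it is
    perfect (self-reverse-complementary) exactly when the spacer is empty.
    """

    arm_sequence: str
    spacer_sequence: str = ""

    def __post_init__(self) -> None:
        if not self.arm_sequence:
            raise ValueError("arm_sequence must be non-empty")
        _check_alphabet(self.arm_sequence, "arm_sequence")
        _check_alphabet(self.spacer_sequence, "spacer_sequence")

    @property
    def arm_length(self) -> int:
        return len(self.arm_sequence)

    @property
    def spacer_length(self) -> int:
        return len(self.spacer_sequence)

    @property
    def total_length(self) -> int:
        return 2 * self.arm_length + self.spacer_length

    @property
    def sequence(self) -> str:
        return (
            self.arm_sequence
            + self.spacer_sequence
            + reverse_complement(self.arm_sequence)
        )

    @property
    def is_perfect(self) -> bool:
        return self.spacer_length == 0

    @property
    def classification(self) -> str:
        return "perfect" if self.is_perfect else "interrupted"


@dataclass(frozen=True)
class PalindromeSite:
    """A palindrome occurrence in a longer sequence.

    ``start``/``end`` are 0-based half-open coordinates of the full
    palindrome span, so ``end - start == 2*arm_length + spacer_length``.
    ``sbccd_susceptible`` and ``structure_forming_strands`` are ``None``
    until filled by :func:`annotate_structure`.
    """

    sequence_id: str
    start: int
    end: int
    arm_length: int
    spacer_length: int
    sbccd_susceptible: bool | None = None
    structure_forming_strands: str | None = None  # both | lagging_only | unknown

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.arm_length + self.spacer_length:
            raise ValueError(
                "span length must equal 2*arm_length + spacer_length"
            )
        if self.arm_length < 1 or self.spacer_length < 0 or self.start < 0:
            raise ValueError("invalid site geometry")

    @property
    def total_length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        """0-based position of the spacer midpoint."""
        return self.start + self.arm_length + self.spacer_length / 2

    @property
    def classification(self) -> str:
        return "perfect" if self.spacer_length == 0 else "interrupted"

    def contains(self, other: "PalindromeSite") -> bool:
        return (
            self.start <= other.start
            and other.end <= self.end
            and (self.start, self.end) != (other.start, other.end)
        )


def build_palindrome(arm: str, spacer: str = "") -> PalindromeConstruct:
    """Assemble a palindrome construct from an arm and an optional spacer.

    Examples
    --------
    A 230 bp arm with no spacer gives a 460 bp perfect palindrome; the
    same arm with a 20 bp spacer gives a 480 bp interrupted palindrome.
    """
    return PalindromeConstruct(arm_sequence=arm, spacer_sequence=spacer)


def classify_palindrome(
    sequence: str, min_arm: int = 10
) -> tuple[str, int, int, float]:
    """Decompose ``sequence`` as ``arm + spacer + revcomp(arm)`` with the
    maximal arm.

    Returns ``(classification, arm_length, spacer_length, center)`` where
    classification is ``perfect``, ``interrupted`` or ``none`` (maximal arm
    below ``min_arm``).  The maximal arm is found by pairing bases inward
    from the two ends; pairing is prefix-monotone, so the expansion stops
    at the unique maximal arm.
    """
    _check_alphabet(sequence)
    n = len(sequence)
    arm = 0
    while arm < n // 2 and sequence[arm] == _COMPLEMENT[sequence[n - 1 - arm]]:
        arm += 1
    spacer = n - 2 * arm
    center = arm + spacer / 2
    if arm < min_arm:
        return ("none", arm, spacer, center)
    kind = "perfect" if spacer == 0 else "interrupted"
    return (kind, arm, spacer, center)


def _suppress_nested(sites: list[PalindromeSite]) -> list[PalindromeSite]:
    """Drop sites whose span is strictly contained in another site's span."""
    kept: list[PalindromeSite] = []
    for site in sorted(
        sites, key=lambda s: (-(s.end - s.start), s.start)
    ):
        if not any(k.contains(site) for k in kept):
            kept.append(site)
    kept.sort(key=lambda s: (s.start, s.end))
    return kept


def find_inverted_repeats(
    sequence: str,
    min_arm: int = 10,
    max_spacer: int = 0,
    sequence_id: str = "seq",
) -> list[PalindromeSite]:
    """Scan a sequence for inverted repeats (palindrome sites).

    For every candidate spacer placement the arms are expanded outward to
    their maximal exactly-complementary extent; sites with arm >=
    ``min_arm`` are kept, and any site strictly nested inside a reported
    site's span is suppressed (sub-arms of a maximal palindrome are not
    re-reported).  Results are sorted by start coordinate.
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    _check_alphabet(sequence)
    n = len(sequence)
    comp = _COMPLEMENT
    raw: list[PalindromeSite] = []
    for spacer in range(max_spacer + 1):
        # spacer occupies sequence[i : i + spacer)
        for i in range(1, n - spacer):
            arm = 0
            left = i - 1
            right = i + spacer
            while left - arm >= 0 and right + arm < n and (
                sequence[left - arm] == comp[sequence[right + arm]]
            ):
                arm += 1
            if arm >= min_arm:
                raw.append(
                    PalindromeSite(
                        sequence_id=sequence_id,
                        start=i - arm,
                        end=i + spacer + arm,
                        arm_length=arm,
                        spacer_length=spacer,
                    )
                )
    # one span can be reached from several spacer placements (e.g. a
    # perfect palindrome also decomposes with a 2 bp self-complementary
    # "spacer"); keep the maximal-arm decomposition per span
    best: dict[tuple[int, int], PalindromeSite] = {}
    for site in raw:
        key = (site.start, site.end)
        if key not in best or site.arm_length > best[key].arm_length:
            best[key] = site
    return _suppress_nested(list(best.values()))


def annotate_structure(
    site: PalindromeSite,
    susceptibility_threshold: int = DEFAULT_SUSCEPTIBILITY_THRESHOLD,
    interrupted_threshold: int = DEFAULT_INTERRUPTED_THRESHOLD,
) -> PalindromeSite:
    """Fill in SbcCD susceptibility and the predicted structure-forming
    strands for a palindrome site.

    A site is SbcCD-susceptible when its total length reaches
    ``susceptibility_threshold`` (default 36 bp).  A perfect palindrome
    (no spacer) can fold a hairpin on either template strand (``both``);
    a spacer of at least ``interrupted_threshold`` bp restricts folding
    to the lagging-strand template (``lagging_only``).  Intermediate
    spacers (1..threshold-1 bp) are experimentally uncharacterised and
    flagged ``unknown`` with a warning; downstream models treat them as
    lagging-only.
    """
    susceptible = site.total_length >= susceptibility_threshold
    if site.spacer_length == 0:
        strands = "both"
    elif site.spacer_length >= interrupted_threshold:
        strands = "lagging_only"
    else:
        strands = "unknown"
        warnings.warn(
            f"site {site.sequence_id}:{site.start}-{site.end} has a "
            f"{site.spacer_length} bp spacer (1-{interrupted_threshold - 1} "
            "bp): structure-forming strands unknown, treated as "
            "lagging-only downstream",
            stacklevel=2,
        )
    return replace(
        site, sbccd_susceptible=susceptible, structure_forming_strands=strands
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from a FASTA file (uppercased)."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def sites_to_bed6(sites: Iterable[PalindromeSite]) -> str:
    """BED6 lines: name=classification, score=arm_length, strand='.'."""
    lines = [
        f"{s.sequence_id}\t{s.start}\t{s.end}\t{s.classification}"
        f"\t{s.arm_length}\t."
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def sites_to_table(sites: Iterable[PalindromeSite]) -> str:
    """Extended TSV with every site field (header included)."""
    header = (
        "sequence_id\tstart\tend\tcenter\tarm_length\tspacer_length"
        "\tclassification\tsbccd_susceptible\tstructure_forming_strands"
    )
    rows = [
        f"{s.sequence_id}\t{s.start}\t{s.end}\t{s.center:g}\t{s.arm_length}"
        f"\t{s.spacer_length}\t{s.classification}"
        f"\t{'' if s.sbccd_susceptible is None else s.sbccd_susceptible}"
        f"\t{'' if s.structure_forming_strands is None else s.structure_forming_strands}"
        for s in sites
    ]
    return "\n".join([header, *rows]) + "\n"
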