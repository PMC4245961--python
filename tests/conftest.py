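"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def random_arm(rng: np.random.Generator, n: int) -> str:
    """Seeded uniform arm; no rejection needed for perfect palindromes."""
    return random_dna(rng, n)


def random_spacer(rng: np.random.Generator, n: int) -> str:
    """Spacer whose ends are not mutually complementary, so the arms of
    ``arm + spacer + revcomp(arm)`` cannot accidentally extend into it."""
    while True:
        s = random_dna(rng, n)
        if n == 0 or n == 1:
            return s
        if s[0] != _COMPLEMENT[s[-1]]:
            return s


def brute_force_remaining(p: float, q: float, repair: str) -> float:
    """Expected remaining fraction per cycle by enumerating the four
    (leading cut?, lagging cut?) sister outcomes."""
    expected_intact = 0.0
    for lead_cut, w_lead in ((True, p), (False, 1 - p)):
        for lag_cut, w_lag in ((True, q), (False, 1 - q)):
            weight = w_lead * w_lag
            if repair == "rec_plus":
                # a cut sister is repaired from its intact sibling; both
                # copies are lost only when both are cut
                intact = 0 if (lead_cut and lag_cut) else 2
            else:
                intact = (0 if lead_cut else 1) + (0 if lag_cut else 1)
            expected_intact += weight * intact
    return expected_intact / 2.0


def brute_force_sites(
    seq: str, min_arm: int, max_spacer: int
) -> list[tuple[int, int, int, int]]:
    """O(n^3)-style span checker: every (start, end, arm, spacer) whose
    maximal-arm decomposition qualifies, with spans nested inside another
    qualifying span suppressed.  Independent of the scanner's
    center-expansion algorithm."""
    n = len(seq)
    qualifying: list[tuple[int, int, int, int]] = []
    for i in range(n):
        for j in range(i + 2 * min_arm, n + 1):
            arm = 0
            while arm < (j - i) // 2 and (
                seq[i + arm] == _COMPLEMENT[seq[j - 1 - arm]]
            ):
                arm += 1
            spacer = (j - i) - 2 * arm
            if arm >= min_arm and spacer <= max_spacer:
                qualifying.append((i, j, arm, spacer))
    kept: list[tuple[int, int, int, int]] = []
    for cand in sorted(qualifying, key=lambda x: (-(x[1] - x[0]), x[0])):
        contained = any(
            k[0] <= cand[0] and cand[1] <= k[1] and (k[0], k[1]) != (cand[0], cand[1])
            for k in kept
        )
        if not contained:
            kept.append(cand)
    return sorted(kept)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
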