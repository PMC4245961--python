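"""Per-replication-cycle survival model for a palindrome-bearing locus
under SbcCD hairpin cleavage.

Model
-----
Each replication cycle a fork passes the palindrome.  A hairpin folded on
the leading-strand template is cleaved with probability ``p``; a hairpin
on the lagging-strand template with probability ``q``.  The two cuts fall
on different sister chromosomes.

* In a recombination-proficient host (``rec_plus``) a broken sister is
  repaired by homologous recombination provided the other sister is
  intact; the locus is lost only when *both* sisters are cut, so the
  fraction of DNA remaining per cycle is ``R+ = 1 - p*q``.
* In a ``recB`` null host no double-strand-break repair occurs, every cut
  chromosome is lost, and the per-cycle *loss* is the mean cut fraction
  ``(p + q) / 2`` over the two sisters — i.e. remaining
  ``R- = 1 - (p + q)/2``.  (Note ``(p+q)/2`` is the per-cycle loss, not
  the remaining fraction: at p = q = 0 nothing is lost.)

Loss compounds over continuous generations: after time ``t`` with
generation time ``tau`` the remaining fraction is ``R**(t/tau)``.  When
replication is inactive (a dnaA-ts host at the restrictive temperature)
no fork passes the palindrome, no hairpin forms, and the remaining
fraction is 1 under this model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REC_PLUS",
    "RECB_NULL",
    "HYPOTHESES",
    "CleavageParams",
    "HostGenotype",
    "SurvivalPrediction",
    "per_cycle_remaining",
    "per_cycle_loss",
    "loss_after_time",
    "prediction_grid",
    "viability_class",
    "hypothesis_table",
    "discriminate",
]

REC_PLUS = "rec_plus"
RECB_NULL = "recB_null"
_REPAIR_STATES = (REC_PLUS, RECB_NULL)

HYPOTHESES = (
    "A_cruciform",
    "Bi_recleavage_cycle",
    "Bii_recleavage_both",
    "C_dual_hairpin",
)


@dataclass(frozen=True)
class CleavageParams:
    """Per-cycle cleavage probabilities.

    ``p``: probability the leading-strand-template hairpin is cleaved.
    ``q``: probability the lagging-strand-template hairpin is cleaved.
    """

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError(
                f"cleavage probabilities must lie in [0,1]; got p={self.p}, "
                f"q={self.q}"
            )

    @classmethod
    def lagging_only(cls, q: float) -> "CleavageParams":
        """Interrupted-palindrome regime: hairpin only on the lagging
        template (p = 0)."""
        return cls(p=0.0, q=q)

    @classmethod
    def equal_both(cls, r: float) -> "CleavageParams":
        """Perfect-palindrome regime with symmetric cleavage (p = q)."""
        return cls(p=r, q=r)


@dataclass(frozen=True)
class HostGenotype:
    """Repair capacity and replication status of the host.

    ``replication_active=False`` models a dnaA-ts mutant held at 42 deg C,
    where no new replication forks are fired.
    """

    repair: str = REC_PLUS
    replication_active: bool = True

    def __post_init__(self) -> None:
        if self.repair not in _REPAIR_STATES:
            raise ValueError(
                f"repair must be one of {_REPAIR_STATES}; got {self.repair!r}"
            )


@dataclass(frozen=True)
class SurvivalPrediction:
    per_cycle_remaining: float
    generations: float
    cumulative_loss_percent: float


def per_cycle_remaining(params: CleavageParams, genotype: HostGenotype) -> float:
    """Fraction of palindrome-bearing fragments remaining after one
    replication cycle."""
    if not genotype.replication_active:
        return 1.0
    if genotype.repair == REC_PLUS:
        return 1.0 - params.p * params.q
    return 1.0 - (params.p + params.q) / 2.0


def per_cycle_loss(params: CleavageParams, genotype: HostGenotype) -> float:
    return 1.0 - per_cycle_remaining(params, genotype)


def loss_after_time(
    params: CleavageParams,
    genotype: HostGenotype,
    minutes: float,
    generation_time: float,
) -> SurvivalPrediction:
    """Cumulative % DNA loss after ``minutes`` of SbcCD induction.

    Generations are continuous (``minutes / generation_time``); remaining
    DNA compounds as ``R**generations``.
    """
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    remaining = per_cycle_remaining(params, genotype)
    generations = minutes / generation_time
    cumulative = 100.0 * (1.0 - remaining**generations)
    return SurvivalPrediction(
        per_cycle_remaining=remaining,
        generations=generations,
        cumulative_loss_percent=cumulative,
    )


def _grid_param_combos(
    levels: Sequence[float], mode: str
) -> list[CleavageParams]:
    if mode == "lagging_only":
        return [CleavageParams.lagging_only(q) for q in levels]
    if mode == "equal_both":
        return [CleavageParams.equal_both(r) for r in levels]
    if mode == "matrix":
        # leading-strand cleavage can equal but not exceed lagging-strand
        # cleavage: all p <= q pairs
        return [
            CleavageParams(p=p, q=q)
            for q in levels
            for p in levels
            if p <= q
        ]
    raise ValueError(f"unknown grid mode {mode!r}")


def prediction_grid(
    probability_levels: Sequence[float],
    mode: str,
    genotype: HostGenotype,
    generations: int = 3,
) -> pd.DataFrame:
    """Table of predicted cumulative % loss per generation.

    Rows are parameter combinations (indexed by ``(p, q)``), columns are
    generations 1..``generations``.  ``mode`` selects the parameter
    family: ``lagging_only`` (q varies, p=0), ``equal_both`` (p=q) or
    ``matrix`` (all p <= q pairs).
    """
    if len(probability_levels) == 0:
        raise ValueError("probability_levels must be non-empty")
    combos = _grid_param_combos(probability_levels, mode)
    gens = np.arange(1, generations + 1)
    rows = []
    for params in combos:
        remaining = per_cycle_remaining(params, genotype)
        rows.append(100.0 * (1.0 - remaining ** gens.astype(float)))
    index = pd.MultiIndex.from_tuples(
        [(c.p, c.q) for c in combos], names=["p", "q"]
    )
    return pd.DataFrame(rows, index=index, columns=[f"gen{g}" for g in gens])


def viability_class(
    params: CleavageParams,
    genotype: HostGenotype,
    construct_class: str,
    kill_threshold: float = 0.05,
) -> str:
    """Qualitative spot-test outcome: ``dead`` or ``viable``.

    The per-generation cell-kill probability is ``p*q`` in a rec+ host
    (death requires both sisters cut, leaving no repair template) and
    ``(p+q)/2`` in a recB host (any unrepaired break kills).  A strain
    without a palindrome has p = q = 0; an interrupted palindrome folds
    only on the lagging template, so p = 0.  A strain is called dead when
    the kill probability exceeds ``kill_threshold`` per generation
    (spot tests resolve roughly 10-fold viability differences; the
    threshold only drives this qualitative call).
    """
    if construct_class == "none":
        params = CleavageParams(0.0, 0.0)
    elif construct_class == "interrupted":
        params = CleavageParams.lagging_only(params.q)
    elif construct_class != "perfect":
        raise ValueError(f"unknown construct_class {construct_class!r}")
    if not genotype.replication_active:
        return "viable"
    kill = (
        params.p * params.q
        if genotype.repair == REC_PLUS
        else (params.p + params.q) / 2.0
    )
    return "dead" if kill > kill_threshold else "viable"


# ---------------------------------------------------------------------------
# Mechanistic hypothesis discrimination

_FEATURES = (
    "rec_plus_fragment_loss",
    "replication_dependent_loss",
    "recB_loss_exceeds_interrupted",
    "ruv_dependent_death",
)

# Predicted feature vector per hypothesis; "any" = the hypothesis does not
# constrain the feature.
#  A   cruciform extrusion from supercoiled duplex: cleavage of both strands
#      without replication (RuvABC involvement possible but not required).
#  Bi  lagging-strand cleavage, repair regenerates the hairpin on one sister
#      and the break/repair cycle repeats; extra loss requires repair, so
#      recB loss cannot exceed the interrupted-palindrome level.
#  Bii as Bi but both repaired sisters are re-cleaved (repair fails).
#  C   hairpins on both leading- and lagging-strand templates are cleaved
#      during replication itself.
_HYPOTHESIS_PREDICTIONS: dict[str, dict[str, str]] = {
    "A_cruciform": {
        "rec_plus_fragment_loss": "yes",
        "replication_dependent_loss": "no",
        "recB_loss_exceeds_interrupted": "any",
        "ruv_dependent_death": "any",
    },
    "Bi_recleavage_cycle": {
        "rec_plus_fragment_loss": "any",
        "replication_dependent_loss": "yes",
        "recB_loss_exceeds_interrupted": "no",
        "ruv_dependent_death": "no",
    },
    "Bii_recleavage_both": {
        "rec_plus_fragment_loss": "yes",
        "replication_dependent_loss": "yes",
        "recB_loss_exceeds_interrupted": "no",
        "ruv_dependent_death": "no",
    },
    "C_dual_hairpin": {
        "rec_plus_fragment_loss": "yes",
        "replication_dependent_loss": "yes",
        "recB_loss_exceeds_interrupted": "yes",
        "ruv_dependent_death": "no",
    },
}


def hypothesis_table() -> pd.DataFrame:
    """Predicted observable features for each mechanistic hypothesis."""
    return pd.DataFrame(_HYPOTHESIS_PREDICTIONS).T[list(_FEATURES)]


def discriminate(observations: Mapping[str, str]) -> set[str]:
    """Hypotheses compatible with a (partial) set of observations.

    ``observations`` maps feature names to ``yes``/``no``/``untested``.  A
    hypothesis is retained when its prediction matches (or does not
    constrain) every non-untested observation.
    """
    for key, value in observations.items():
        if key not in _FEATURES:
            raise KeyError(
                f"unknown feature {key!r}; expected one of {_FEATURES}"
            )
        if value not in ("yes", "no", "untested"):
            raise ValueError(
                f"observation value must be yes/no/untested; got {value!r}"
            )
    compatible = set()
    for hyp, predicted in _HYPOTHESIS_PREDICTIONS.items():
        ok = all(
            predicted[feat] in ("any", obs)
            for feat, obs in observations.items()
            if obs != "untested"
        )
        if ok:
            compatible.add(hyp)
    return compatible
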