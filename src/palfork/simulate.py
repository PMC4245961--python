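"""Seeded stochastic simulation of palindrome cleavage in a replicating
population, under each competing mechanistic hypothesis.

The simulator is the Monte-Carlo counterpart of the closed-form model in
:mod:`palfork.cleavage` and additionally covers the mechanisms the closed
form does not: replication-independent cruciform cleavage (hypothesis A)
and re-cleavage of repair products (hypotheses B(i)/B(ii)).

Hypotheses
----------
``A_cruciform``
    The palindrome extrudes a cruciform from (super)coiled duplex DNA and
    is cleaved with ``cruciform_cleavage_prob`` per unit cycle-time,
    independent of replication.  Both strands are cut, so there is never a
    repair template.
``Bi_recleavage_cycle``
    Replication-coupled cleavage of the lagging-strand-template hairpin
    (probability ``q``).  In a rec+ host repair synthesis regenerates the
    hairpin on the repaired sister and the break/repair cycle repeats
    (capped at ``max_recleavage_rounds`` per replication cycle).
``Bii_recleavage_both``
    As B(i), but repair regenerates hairpins on *both* sisters, both are
    re-cleaved and repair fails outright.
``C_dual_hairpin``
    Hairpins fold on both the leading- and lagging-strand templates
    during replication; the leading-template hairpin is cleaved with
    probability ``p`` on one sister and the lagging-template hairpin with
    probability ``q`` on the other.  rec+ repairs a cut sister iff its
    sibling is intact.

Modes
-----
``paper_simple``
    Every chromosome replicates each cycle regardless of the fate of the
    cell that carries it — the implicit assumption behind compounding a
    per-cycle remaining fraction ``R**g``.  This is the mode the analytic
    model corresponds to.
``population``
    Cells that cannot restore an intact locus stop dividing, but their
    DNA persists in the harvested-culture counts (a Southern blot of a
    whole culture sees dead cells' DNA too).  Exploratory.

Reproducibility: one ``numpy`` generator seeded from ``SimConfig.seed``;
random draws are consumed in a fixed order, so the same seed yields a
bit-identical :class:`SimulationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cleavage import HYPOTHESES, CleavageParams, HostGenotype, REC_PLUS

__all__ = ["SimConfig", "SimulationResult", "simulate"]


@dataclass(frozen=True)
class SimConfig:
    params: CleavageParams
    genotype: HostGenotype = field(default_factory=HostGenotype)
    hypothesis: str = "C_dual_hairpin"
    n_cells: int = 10_000
    generations: int = 3
    mode: str = "paper_simple"
    seed: int = 0
    #: Hypothesis A only: per-cycle-time cruciform cleavage probability.
    #: The mechanism supplies no measured rate; 0.5 gives a clear
    #: qualitative contrast.
    cruciform_cleavage_prob: float = 0.5
    #: B(i) only: cap on break/repair rounds within one replication cycle.
    max_recleavage_rounds: int = 10

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(
                f"hypothesis must be one of {HYPOTHESES}; got "
                f"{self.hypothesis!r}"
            )
        if self.mode not in ("paper_simple", "population"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.cruciform_cleavage_prob <= 1.0:
            raise ValueError("cruciform_cleavage_prob must lie in [0,1]")


@dataclass(frozen=True)
class SimulationResult:
    """Per-generation population state (index 0 is the initial state)."""

    generation: np.ndarray
    intact_fragment_count: np.ndarray
    broken_fragment_count: np.ndarray
    control_locus_count: np.ndarray
    viable_cell_count: np.ndarray

    @property
    def loss_percent(self) -> np.ndarray:
        """% loss of the intact palindrome-bearing band, normalized to the
        loading-control locus."""
        return 100.0 * (
            1.0 - self.intact_fragment_count / self.control_locus_count
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "intact_fragment_count": self.intact_fragment_count,
                "broken_fragment_count": self.broken_fragment_count,
                "control_locus_count": self.control_locus_count,
                "viable_cell_count": self.viable_cell_count,
                "loss_percent": self.loss_percent,
            }
        )


def _cycle_paper_simple(
    cfg: SimConfig, rng: np.random.Generator, intact: int
) -> tuple[int, int, int]:
    """One replication cycle on ``intact`` chromosomes.

    Returns (new_intact, newly_broken, deaths) where deaths counts
    daughter cells receiving an irreparably broken chromosome.
    """
    p, q = cfg.params.p, cfg.params.q
    rec = cfg.genotype.repair == REC_PLUS
    hyp = cfg.hypothesis
    n = intact

    if hyp == "A_cruciform":
        # handled outside the replication step
        raise AssertionError("hypothesis A has no replication-coupled step")

    if n == 0:
        return 0, 0, 0

    if hyp == "C_dual_hairpin":
        lead_cut = rng.random(n) < p
        lag_cut = rng.random(n) < q
        if rec:
            both = lead_cut & lag_cut
            n_both = int(both.sum())
            return 2 * (n - n_both), 2 * n_both, 2 * n_both
        cuts = lead_cut.astype(int) + lag_cut.astype(int)
        n_cut = int(cuts.sum())
        return 2 * n - n_cut, n_cut, n_cut

    if hyp == "Bi_recleavage_cycle":
        if rec:
            # the cut sister is repaired and re-cleaved up to the round
            # cap; it ends the cycle broken only if cut in every round
            p_end_broken = q ** (cfg.max_recleavage_rounds + 1)
            end_broken = rng.random(n) < p_end_broken
            n_b = int(end_broken.sum())
            return 2 * n - n_b, n_b, n_b
        lag_cut = rng.random(n) < q
        n_cut = int(lag_cut.sum())
        return 2 * n - n_cut, n_cut, n_cut

    if hyp == "Bii_recleavage_both":
        if rec:
            # repair regenerates hairpins on both sisters; both re-cleaved,
            # so an initial lagging cut costs both copies
            lag_cut = rng.random(n) < q
            n_cut = int(lag_cut.sum())
            return 2 * (n - n_cut), 2 * n_cut, 2 * n_cut
        lag_cut = rng.random(n) < q
        n_cut = int(lag_cut.sum())
        return 2 * n - n_cut, n_cut, n_cut

    raise AssertionError(f"unhandled hypothesis {hyp}")


def _simulate_paper_simple(cfg: SimConfig, rng: np.random.Generator) -> SimulationResult:
    intact = cfg.n_cells
    broken = 0
    control = cfg.n_cells
    viable = cfg.n_cells
    replicating = cfg.genotype.replication_active

    gens = [0]
    intact_t = [intact]
    broken_t = [broken]
    control_t = [control]
    viable_t = [viable]

    for g in range(1, cfg.generations + 1):
        if cfg.hypothesis == "A_cruciform":
            # cruciform cleavage needs no fork passage
            cut = int((rng.random(intact) < cfg.cruciform_cleavage_prob).sum())
            intact -= cut
            broken += cut
            viable = max(viable - cut, 0)
            if replicating:
                intact *= 2
                broken *= 2  # broken fragments persist; sampled culture doubles
                control *= 2
                viable *= 2
        elif replicating:
            intact, newly_broken, deaths = _cycle_paper_simple(cfg, rng, intact)
            broken = 2 * broken + newly_broken
            control *= 2
            viable = max(2 * viable - deaths, 0)
        # replication off, hypotheses B/C: no fork, no hairpin, no change
        gens.append(g)
        intact_t.append(intact)
        broken_t.append(broken)
        control_t.append(control)
        viable_t.append(viable)

    return SimulationResult(
        generation=np.array(gens),
        intact_fragment_count=np.array(intact_t),
        broken_fragment_count=np.array(broken_t),
        control_locus_count=np.array(control_t),
        viable_cell_count=np.array(viable_t),
    )


def _simulate_population(cfg: SimConfig, rng: np.random.Generator) -> SimulationResult:
    """Cells with an unrepairable break stop dividing; their DNA persists
    in the harvested counts."""
    p, q = cfg.params.p, cfg.params.q
    rec = cfg.genotype.repair == REC_PLUS
    replicating = cfg.genotype.replication_active

    live = cfg.n_cells  # live cells, each: 1 intact fragment + 1 control
    dead_intact = 0  # frozen DNA pools from arrested cells
    dead_broken = 0
    dead_control = 0

    def snapshot(g: int) -> tuple[int, int, int, int, int]:
        return (
            g,
            live + dead_intact,
            dead_broken,
            live + dead_control,
            live,
        )

    rows = [snapshot(0)]
    for g in range(1, cfg.generations + 1):
        if cfg.hypothesis == "A_cruciform":
            cut = int((rng.random(live) < cfg.cruciform_cleavage_prob).sum())
            live -= cut
            dead_broken += cut
            dead_control += cut
            if replicating:
                live *= 2
        elif replicating and live > 0:
            if cfg.hypothesis == "C_dual_hairpin":
                lead_cut = rng.random(live) < p
                lag_cut = rng.random(live) < q
                if rec:
                    both = int((lead_cut & lag_cut).sum())
                    live = 2 * (live - both)
                    dead_broken += 2 * both
                    dead_control += 2 * both
                else:
                    cuts = int(lead_cut.sum()) + int(lag_cut.sum())
                    live = 2 * live - cuts
                    dead_broken += cuts
                    dead_control += cuts
            elif cfg.hypothesis == "Bi_recleavage_cycle":
                if rec:
                    pb = q ** (cfg.max_recleavage_rounds + 1)
                    n_b = int((rng.random(live) < pb).sum())
                    live = 2 * live - n_b
                    dead_broken += n_b
                    dead_control += n_b
                else:
                    n_cut = int((rng.random(live) < q).sum())
                    live = 2 * live - n_cut
                    dead_broken += n_cut
                    dead_control += n_cut
            elif cfg.hypothesis == "Bii_recleavage_both":
                n_cut = int((rng.random(live) < q).sum())
                if rec:
                    live = 2 * (live - n_cut)
                    dead_broken += 2 * n_cut
                    dead_control += 2 * n_cut
                else:
                    live = 2 * live - n_cut
                    dead_broken += n_cut
                    dead_control += n_cut
        rows.append(snapshot(g))

    arr = np.array(rows)
    return SimulationResult(
        generation=arr[:, 0],
        intact_fragment_count=arr[:, 1],
        broken_fragment_count=arr[:, 2],
        control_locus_count=arr[:, 3],
        viable_cell_count=arr[:, 4],
    )


def simulate(config: SimConfig) -> SimulationResult:
    """Run the seeded population simulation described in the module docs."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "paper_simple":
        return _simulate_paper_simple(config, rng)
    return _simulate_population(config, rng)
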