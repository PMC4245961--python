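"""Synthetic Southern-blot lane tables and loss time courses.

No raw densitometry data are deposited with palindrome-cleavage
experiments of this design, so the generator emulates them: for every
strain (construct x genotype), treatment, timepoint and biological
replicate it produces a lane whose band signals follow the per-cycle
cleavage model with multiplicative lognormal noise (densitometry noise
is scale-free, so lognormal rather than additive Gaussian).

Signal model per lane, with per-cycle remaining fraction ``R`` from
:mod:`palfork.cleavage` and generation time ``tau``:

* loading control: ``cysN = scale * 2**(t/tau) * e_1 + bg``
* probed locus:    ``lacZ = scale * 2**(t/tau) * R**(t/tau) * e_2 + bg``

where ``e_i ~ lognormal(0, sigma)`` i.i.d. and ``bg`` is the lane
background (itself lognormally perturbed around ``background_level``).
The recorded ``background`` field equals the true added ``bg``, so at
``sigma = 0`` quantification recovers the model loss exactly.

Glucose treatment represses SbcCD expression, so glucose lanes use
p = q = 0.  A dnaA-ts strain held at the restrictive temperature (42 C)
replicates no DNA: signals stop growing, cleavage stops, and the total
DNA yield is reduced by ``yield_reduction_42C`` (the reduction cancels
in the loading normalization).

Dead cells' DNA persists in the harvested culture (the ``paper_simple``
assumption), so generator and analytic model agree exactly at zero
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cleavage import (
    RECB_NULL,
    REC_PLUS,
    CleavageParams,
    HostGenotype,
    per_cycle_remaining,
)
from .infer import LossTimecourse
from .quantify import CONSTRUCTS, LaneMeasurement

__all__ = ["StrainSpec", "GeneratorConfig", "generate_lanes", "generate_timecourse"]

#: True per-cycle cleavage probabilities per construct class.  The
#: perfect palindrome folds hairpins on both templates (p = q = 0.75, the
#: symmetric level matching the observed rec+ loss); interrupted
#: palindromes fold only on the lagging template (p = 0), with q = 0.7 in
#: the middle-upper part of the 50-75% regime the interrupted time
#: courses support.
DEFAULT_TRUE_PARAMS: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "perfect_460": (0.75, 0.75),
    "interrupted_480": (0.0, 0.70),
    "interrupted_246": (0.0, 0.70),
}

#: Measured generation times (min) under the two growth conditions used:
#: 23 min for the rec+ background, 56 min for the recB background.
DEFAULT_GENERATION_TIMES: dict[str, float] = {REC_PLUS: 23.0, RECB_NULL: 56.0}


@dataclass(frozen=True)
class StrainSpec:
    strain_id: str
    construct: str
    rec_status: str = REC_PLUS
    dnaA_status: str = "wt"  # "wt" or "ts"

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.rec_status not in (REC_PLUS, RECB_NULL):
            raise ValueError(f"unknown rec_status {self.rec_status!r}")
        if self.dnaA_status not in ("wt", "ts"):
            raise ValueError(f"unknown dnaA_status {self.dnaA_status!r}")


def _default_strains() -> tuple[StrainSpec, ...]:
    return tuple(
        StrainSpec(
            strain_id=f"{rec}_{construct}",
            construct=construct,
            rec_status=rec,
        )
        for rec in (REC_PLUS, RECB_NULL)
        for construct in ("none", "perfect_460", "interrupted_480")
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Experimental design and noise model for synthetic lane tables."""

    strains: tuple[StrainSpec, ...] = field(default_factory=_default_strains)
    treatments: tuple[str, ...] = ("arabinose", "glucose")
    timepoints_minutes: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0)
    replicates: int = 3
    true_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PARAMS)
    )
    generation_times: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENERATION_TIMES)
    )
    noise_sigma: float = 0.1
    background_level: float = 10.0
    background_sigma: float = 0.1
    base_signal_scale: float = 1000.0
    #: Hold dnaA-ts strains at 42 C (replication off) for t > 0.
    restrictive_temperature: bool = False
    #: Overall DNA-yield factor at 42 C (cancelled by cysN normalization).
    yield_reduction_42C: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.background_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.base_signal_scale <= 0:
            raise ValueError("base_signal_scale must be > 0")
        for construct in CONSTRUCTS:
            if construct not in self.true_params:
                raise ValueError(f"true_params missing construct {construct!r}")
        for rec in (REC_PLUS, RECB_NULL):
            if self.generation_times.get(rec, 0) <= 0:
                raise ValueError(f"generation_times[{rec!r}] must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        if "strains" in raw:
            raw["strains"] = tuple(StrainSpec(**s) for s in raw["strains"])
        for key in ("treatments", "timepoints_minutes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "true_params" in raw:
            raw["true_params"] = {
                k: tuple(v) for k, v in raw["true_params"].items()
            }
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _effective_state(
    config: GeneratorConfig, strain: StrainSpec, treatment: str
) -> tuple[CleavageParams, HostGenotype, float]:
    """(params, genotype, generation_time) in effect for a lane."""
    p, q = config.true_params[strain.construct]
    if treatment == "glucose":  # SbcCD repressed
        p, q = 0.0, 0.0
    replication_active = not (
        strain.dnaA_status == "ts" and config.restrictive_temperature
    )
    genotype = HostGenotype(
        repair=strain.rec_status, replication_active=replication_active
    )
    tau = float(config.generation_times[strain.rec_status])
    return CleavageParams(p, q), genotype, tau


def generate_lanes(config: GeneratorConfig) -> list[LaneMeasurement]:
    """Generate the full synthetic lane table for the configured design.

    Deterministic for a fixed seed: lanes are emitted, and random draws
    consumed, in strain -> treatment -> timepoint -> replicate order.
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.noise_sigma
    lanes: list[LaneMeasurement] = []
    for strain in config.strains:
        for treatment in config.treatments:
            params, genotype, tau = _effective_state(config, strain, treatment)
            remaining_cycle = per_cycle_remaining(params, genotype)
            for t in config.timepoints_minutes:
                gens = (t / tau) if genotype.replication_active else 0.0
                growth = 2.0**gens
                remaining = remaining_cycle ** (t / tau)
                yield_factor = (
                    config.yield_reduction_42C
                    if (strain.dnaA_status == "ts"
                        and config.restrictive_temperature
                        and t > 0)
                    else 1.0
                )
                cysn_true = config.base_signal_scale * growth * yield_factor
                lacz_true = cysn_true * remaining
                for rep in range(1, config.replicates + 1):
                    e1 = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
                    e2 = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
                    bg = config.background_level * (
                        rng.lognormal(0.0, config.background_sigma)
                        if config.background_sigma > 0
                        and config.background_level > 0
                        else 1.0
                    )
                    lanes.append(
                        LaneMeasurement(
                            strain_id=strain.strain_id,
                            construct=strain.construct,
                            rec_status=strain.rec_status,
                            dnaA_status=strain.dnaA_status,
                            treatment=treatment,
                            timepoint_minutes=float(t),
                            replicate=rep,
                            lacZ_signal=lacz_true * e2 + bg,
                            cysN_signal=cysn_true * e1 + bg,
                            background=bg,
                        )
                    )
    return lanes


def generate_timecourse(
    config: GeneratorConfig, construct: str, genotype: HostGenotype
) -> LossTimecourse:
    """Directly generate a noisy loss time course for one strain.

    The remaining fraction at each timepoint is perturbed by a lognormal
    factor ``e ~ lognormal(0, sigma)`` and the implied loss is clipped to
    [0, 100]%.
    """
    if construct not in CONSTRUCTS:
        raise ValueError(f"unknown construct {construct!r}")
    rng = np.random.default_rng(config.seed)
    p, q = config.true_params[construct]
    params = CleavageParams(p, q)
    tau = float(config.generation_times[genotype.repair])
    remaining_cycle = per_cycle_remaining(params, genotype)
    obs = []
    for t in config.timepoints_minutes:
        remaining = remaining_cycle ** (t / tau)
        if config.noise_sigma > 0:
            remaining *= rng.lognormal(0.0, config.noise_sigma)
        loss = float(np.clip(100.0 * (1.0 - remaining), 0.0, 100.0))
        obs.append((float(t), loss))
    construct_class = (
        "none"
        if construct == "none"
        else ("perfect" if construct == "perfect_460" else "interrupted")
    )
    return LossTimecourse(
        genotype=genotype,
        construct_class=construct_class,
        generation_time=tau,
        observations=tuple(obs),
    )
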