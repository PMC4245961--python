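"""Least-squares estimation of cleavage probabilities from DNA-loss
time courses.

The observable is cumulative % loss of the palindrome-bearing fragment
at a few induction times.  Under the per-cycle model the remaining
fraction after time ``t`` is ``R(p, q)**(t/tau)`` with ``R`` from
:func:`palfork.cleavage.per_cycle_remaining`.  The fit minimises the sum
of squared residuals on the remaining-fraction scale (not log scale:
losses approaching 100% would otherwise dominate), by dense grid search
at resolution 0.001 with bounded local refinement.

Constraint modes
----------------
``lagging_only``
    p = 0, fit q — the identifiable regime for an interrupted palindrome.
``equal_both``
    p = q, fit the common value — the symmetric perfect-palindrome regime.
``free``
    both parameters vary; reported but flagged non-identifiable, since
    recB data constrain only p + q and rec+ data only p*q.

The profile interval per parameter collects values whose RSS stays
within 50% of the minimum (an artefact convention for a quick
identifiability readout, not a calibrated confidence level).  Ties on a
flat RSS region resolve to the smallest parameter value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .cleavage import (
    RECB_NULL,
    REC_PLUS,
    CleavageParams,
    HostGenotype,
    per_cycle_remaining,
)

__all__ = [
    "LossTimecourse",
    "FitResult",
    "fit_cleavage",
    "nearest_grid_level",
]

_MIN_REMAINING = 1e-12  # floor so 100% observed loss stays finite


@dataclass(frozen=True)
class LossTimecourse:
    """Observed (or predicted) % DNA loss at sampled induction times for
    one strain."""

    genotype: HostGenotype
    construct_class: str
    generation_time: float
    observations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        times = [t for t, _ in self.observations]
        if any(t < 0 for t in times):
            raise ValueError("observation times must be >= 0")
        if times != sorted(set(times)):
            raise ValueError("observation times must be strictly increasing")
        if any(not (0 <= loss <= 100) for _, loss in self.observations):
            raise ValueError("loss_percent must lie in [0, 100]")

    @property
    def minutes(self) -> np.ndarray:
        return np.array([t for t, _ in self.observations], dtype=float)

    @property
    def loss_percent(self) -> np.ndarray:
        return np.array([l for _, l in self.observations], dtype=float)


@dataclass(frozen=True)
class FitResult:
    constraint: str
    p_hat: float
    q_hat: float
    rss: float
    p_interval: tuple[float, float]
    q_interval: tuple[float, float]
    identifiable: bool = True


def _remaining_per_cycle(p: np.ndarray, q: np.ndarray, genotype: HostGenotype) -> np.ndarray:
    if genotype.repair == REC_PLUS:
        return 1.0 - p * q
    return 1.0 - (p + q) / 2.0


def _rss_curve(
    p: np.ndarray,
    q: np.ndarray,
    genotype: HostGenotype,
    gens: np.ndarray,
    r_obs: np.ndarray,
) -> np.ndarray:
    """Vectorised RSS over parameter arrays (broadcast against time)."""
    R = np.clip(_remaining_per_cycle(p, q, genotype), _MIN_REMAINING, 1.0)
    pred = R[..., None] ** gens
    return ((pred - r_obs) ** 2).sum(axis=-1)


def fit_cleavage(
    timecourse: LossTimecourse,
    constraint: str = "lagging_only",
    grid_resolution: float = 0.001,
    profile_rss_ratio: float = 1.5,
) -> FitResult:
    """Fit cleavage probabilities to a loss time course by least squares.

    Raises
    ------
    ValueError
        If no observation has ``minutes > 0`` (the per-cycle probability
        is then unidentifiable: any parameter predicts 0 loss at t=0).
    """
    if not timecourse.genotype.replication_active:
        raise ValueError(
            "cleavage probabilities are unidentifiable without replication"
        )
    t = timecourse.minutes
    if not np.any(t > 0):
        raise ValueError(
            "all observations at t=0: cleavage probabilities unidentifiable"
        )
    gens = t / timecourse.generation_time
    r_obs = np.clip(1.0 - timecourse.loss_percent / 100.0, _MIN_REMAINING, 1.0)
    genotype = timecourse.genotype

    grid = np.round(
        np.arange(0.0, 1.0 + grid_resolution / 2, grid_resolution), 9
    )

    if constraint in ("lagging_only", "equal_both"):
        if constraint == "lagging_only":
            p_of = lambda x: np.zeros_like(x)
        else:
            p_of = lambda x: x
        rss = _rss_curve(p_of(grid), grid, genotype, gens, r_obs)
        i = int(np.argmin(rss))  # first minimum = smallest value on ties
        # bounded local refinement around the best grid point
        lo = max(grid[i] - grid_resolution, 0.0)
        hi = min(grid[i] + grid_resolution, 1.0)
        res = minimize_scalar(
            lambda x: float(
                _rss_curve(
                    p_of(np.asarray(x)), np.asarray(x), genotype, gens, r_obs
                )
            ),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        q_hat = float(res.x) if res.fun <= rss[i] else float(grid[i])
        rss_min = float(min(res.fun, rss[i]))
        thresh = rss_min * profile_rss_ratio + 1e-15
        in_prof = grid[rss <= thresh]
        q_int = (float(in_prof.min()), float(in_prof.max()))
        p_hat = 0.0 if constraint == "lagging_only" else q_hat
        p_int = (0.0, 0.0) if constraint == "lagging_only" else q_int
        return FitResult(
            constraint=constraint,
            p_hat=p_hat,
            q_hat=q_hat,
            rss=rss_min,
            p_interval=p_int,
            q_interval=q_int,
        )

    if constraint == "free":
        # coarse 2D grid then bounded refinement; flagged non-identifiable
        # (recB sees only p+q, rec+ only p*q)
        coarse = np.round(np.arange(0.0, 1.0 + 0.0025, 0.005), 9)
        P, Q = np.meshgrid(coarse, coarse, indexing="ij")
        rss2 = _rss_curve(P.ravel(), Q.ravel(), genotype, gens, r_obs)
        j = int(np.argmin(rss2))
        p0, q0 = float(P.ravel()[j]), float(Q.ravel()[j])
        from scipy.optimize import minimize

        res = minimize(
            lambda x: float(
                _rss_curve(
                    np.asarray(x[0]), np.asarray(x[1]), genotype, gens, r_obs
                )
            ),
            x0=[p0, q0],
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            method="L-BFGS-B",
        )
        p_hat, q_hat = (float(res.x[0]), float(res.x[1]))
        rss_min = float(res.fun)
        thresh = rss_min * profile_rss_ratio + 1e-15
        mask = rss2 <= thresh
        p_in, q_in = P.ravel()[mask], Q.ravel()[mask]
        return FitResult(
            constraint="free",
            p_hat=p_hat,
            q_hat=q_hat,
            rss=rss_min,
            p_interval=(float(p_in.min()), float(p_in.max())),
            q_interval=(float(q_in.min()), float(q_in.max())),
            identifiable=False,
        )

    raise ValueError(f"unknown constraint {constraint!r}")


def nearest_grid_level(
    observed_loss_percent: float,
    generations: float,
    genotype: HostGenotype,
    constraint: str = "equal_both",
    levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> float:
    """The candidate cleavage level whose predicted cumulative loss is
    closest to an observed loss.

    Mirrors reading a prediction grid against a measured loss: each level
    L is expanded to parameters under ``constraint`` (``lagging_only``:
    p=0, q=L; ``equal_both``: p=q=L), its loss after ``generations`` is
    computed, and the level minimising the absolute difference is
    returned (ties resolve to the smaller level).
    """
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    best_level, best_diff = None, np.inf
    for level in sorted(levels):
        if constraint == "lagging_only":
            params = CleavageParams.lagging_only(level)
        elif constraint == "equal_both":
            params = CleavageParams.equal_both(level)
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        remaining = per_cycle_remaining(params, genotype)
        pred = 100.0 * (1.0 - remaining**generations)
        diff = abs(pred - observed_loss_percent)
        if diff < best_diff:
            best_level, best_diff = level, diff
    return float(best_level)
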