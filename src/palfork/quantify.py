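"""Southern-blot densitometry normalization.

Each gel lane carries two band signals: the probed palindrome-bearing
restriction fragment (*lacZ* locus) and a loading-control fragment from
the opposite side of the chromosome (*cysN* locus), plus a background
estimate.  Normalization proceeds in three steps:

1. subtract the lane background from both band signals;
2. divide the probed-locus signal by the loading-control signal
   (corrects gel loading and total DNA yield);
3. divide that ratio by a reference lane's ratio — either the same
   strain's T0 lane (before induction) or a palindrome-free control
   strain in the same condition — and report ``loss % = 100*(1 - ratio)``.

Background is modelled per lane; a gel-wide background is the special
case of repeating one value.  Negative loss estimates (measurement
noise) are clipped to 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaneMeasurement",
    "NormalizedLoss",
    "DegenerateLaneError",
    "MissingReferenceError",
    "normalize_lanes",
    "summarize_replicates",
    "lanes_to_frame",
    "frame_to_lanes",
    "read_lanes_tsv",
    "write_lanes_tsv",
    "losses_to_frame",
]

CONSTRUCTS = ("none", "perfect_460", "interrupted_480", "interrupted_246")

LANE_COLUMNS = [
    "strain_id",
    "construct",
    "rec_status",
    "dnaA_status",
    "treatment",
    "timepoint_minutes",
    "replicate",
    "lacZ_signal",
    "cysN_signal",
    "background",
]


class DegenerateLaneError(ValueError):
    """Loading-control signal at or below background: the lane carries no
    usable normalization information."""


class MissingReferenceError(ValueError):
    """No reference lane found for the requested normalization mode."""


@dataclass(frozen=True)
class LaneMeasurement:
    """One gel lane: probed-locus and loading-control band signals
    (arbitrary densitometry units) with sample annotations."""

    strain_id: str
    construct: str
    rec_status: str
    treatment: str
    timepoint_minutes: float
    lacZ_signal: float
    cysN_signal: float
    background: float = 0.0
    dnaA_status: str = "wt"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(
                f"construct must be one of {CONSTRUCTS}; got {self.construct!r}"
            )
        if self.lacZ_signal < 0 or self.cysN_signal < 0 or self.background < 0:
            raise ValueError("signals and background must be >= 0")

    @property
    def key(self) -> str:
        return (
            f"{self.strain_id}/{self.treatment}/t{self.timepoint_minutes:g}"
            f"/rep{self.replicate}"
        )


@dataclass(frozen=True)
class NormalizedLoss:
    lane: LaneMeasurement
    normalized_ratio: float
    loss_percent: float


def _corrected_ratio(lane: LaneMeasurement) -> float:
    denom = lane.cysN_signal - lane.background
    if denom <= 0:
        raise DegenerateLaneError(
            f"lane {lane.key}: cysN signal ({lane.cysN_signal}) at or below "
            f"background ({lane.background})"
        )
    return (lane.lacZ_signal - lane.background) / denom


def _find_reference(
    lane: LaneMeasurement,
    lanes: Sequence[LaneMeasurement],
    reference_mode: str,
) -> LaneMeasurement:
    if reference_mode == "t0":
        matches = [
            c
            for c in lanes
            if c.strain_id == lane.strain_id
            and c.replicate == lane.replicate
            and c.treatment == lane.treatment
            and c.timepoint_minutes == 0
        ]
        what = f"T0 lane for strain {lane.strain_id}"
    elif reference_mode == "no_palindrome":
        matches = [
            c
            for c in lanes
            if c.construct == "none"
            and c.rec_status == lane.rec_status
            and c.dnaA_status == lane.dnaA_status
            and c.treatment == lane.treatment
            and c.timepoint_minutes == lane.timepoint_minutes
            and c.replicate == lane.replicate
        ]
        what = f"no-palindrome control for lane {lane.key}"
    else:
        raise ValueError(
            f"reference_mode must be 't0' or 'no_palindrome'; got "
            f"{reference_mode!r}"
        )
    if not matches:
        raise MissingReferenceError(f"missing {what}")
    return matches[0]


def normalize_lanes(
    lanes: Sequence[LaneMeasurement], reference_mode: str = "t0"
) -> list[NormalizedLoss]:
    """Background-subtract, loading-normalize and reference-normalize each
    lane, returning % DNA loss per lane.

    ``reference_mode='t0'`` divides by the same strain's (same treatment,
    same replicate) ratio at timepoint 0; ``'no_palindrome'`` divides by
    the palindrome-free strain's ratio in the matched condition.
    """
    results: list[NormalizedLoss] = []
    for lane in lanes:
        ref = _find_reference(lane, lanes, reference_mode)
        ratio = _corrected_ratio(lane) / _corrected_ratio(ref)
        loss = 100.0 * (1.0 - ratio)
        if loss < 0:
            warnings.warn(
                f"lane {lane.key}: negative loss estimate "
                f"({loss:.2f}%) clipped to 0",
                stacklevel=2,
            )
            loss = 0.0
        results.append(
            NormalizedLoss(lane=lane, normalized_ratio=ratio, loss_percent=loss)
        )
    return results


def losses_to_frame(losses: Iterable[NormalizedLoss]) -> pd.DataFrame:
    rows = []
    for nl in losses:
        row = {col: getattr(nl.lane, col) for col in LANE_COLUMNS}
        row["normalized_ratio"] = nl.normalized_ratio
        row["loss_percent"] = nl.loss_percent
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(
    losses: Iterable[NormalizedLoss],
    group_by: Sequence[str] = (
        "strain_id",
        "construct",
        "rec_status",
        "dnaA_status",
        "treatment",
        "timepoint_minutes",
    ),
) -> pd.DataFrame:
    """Mean, standard error of the mean (sample SD / sqrt(n)) and n of the
    loss per strain x treatment x timepoint group.

    SEM is NaN for n = 1 (undefined from a single replicate).
    """
    frame = losses_to_frame(losses)
    if frame.empty:
        raise ValueError("no losses to summarize")
    grouped = frame.groupby(list(group_by))["loss_percent"]
    out = grouped.agg(
        mean_loss_percent="mean",
        sem_loss_percent=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
        n="size",
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# TSV I/O (documented header = LANE_COLUMNS)


def lanes_to_frame(lanes: Iterable[LaneMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [{col: getattr(lane, col) for col in LANE_COLUMNS} for lane in lanes]
    )


def frame_to_lanes(frame: pd.DataFrame) -> list[LaneMeasurement]:
    missing = set(LANE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"lane table missing columns: {sorted(missing)}")
    return [
        LaneMeasurement(
            strain_id=str(row.strain_id),
            construct=str(row.construct),
            rec_status=str(row.rec_status),
            dnaA_status=str(row.dnaA_status),
            treatment=str(row.treatment),
            timepoint_minutes=float(row.timepoint_minutes),
            replicate=int(row.replicate),
            lacZ_signal=float(row.lacZ_signal),
            cysN_signal=float(row.cysN_signal),
            background=float(row.background),
        )
        for row in frame.itertuples(index=False)
    ]


def read_lanes_tsv(path: str | Path) -> list[LaneMeasurement]:
    return frame_to_lanes(
        pd.read_csv(path, sep="\t", float_precision="round_trip")
    )


def write_lanes_tsv(lanes: Iterable[LaneMeasurement], path: str | Path) -> None:
    # %.17g keeps full float64 precision so the TSV round-trips exactly
    lanes_to_frame(lanes).to_csv(path, sep="\t", index=False, float_format="%.17g")
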