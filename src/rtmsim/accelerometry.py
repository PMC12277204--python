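"""Sensing and outcome path of the wristwatch: 5 Hz samples → 2-s epochs →
per-axis activity counts → daily and trial-level movement-frequency outcomes.

An *activity count* is the device's unit of movement: the number of
consecutive-sample acceleration changes within an epoch whose absolute value
exceeds a per-axis threshold. The physical threshold of the real counter is
not published; the default of 1 device unit is an explicit, documented
placeholder (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engines import CueEvent

SAMPLE_HZ = 5
EPOCH_S = 2.0
SAMPLES_PER_EPOCH = int(SAMPLE_HZ * EPOCH_S)  # 10
DIFFS_PER_EPOCH = SAMPLES_PER_EPOCH - 1  # 9 within-epoch first differences


class FormatError(ValueError):
    """Raised for malformed sample streams or log files."""


class DesignError(ValueError):
    """Raised when trial-level inputs violate the study design."""


@dataclass(frozen=True)
class MovementThreshold:
    """Per-axis minimum absolute sample-to-sample change that counts as
    movement, in device units."""

    x: float = 1.0
    y: float = 1.0
    z: float = 1.0

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def uniform(cls, value: float) -> "MovementThreshold":
        return cls(value, value, value)

    @property
    def magnitude(self) -> float:
        """Euclidean norm, used by the vector-magnitude counting variant."""
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))


def epochize(
    samples: pd.DataFrame,
    threshold: MovementThreshold = MovementThreshold(),
) -> pd.DataFrame:
    """Aggregate a 5 Hz tri-axial sample stream into 2-s epoch records.

    Parameters
    ----------
    samples
        DataFrame with columns ``t_s, ax, ay, az`` on an exact 0.2-s grid,
        with a whole number of 10-sample epochs.

    Returns
    -------
    DataFrame with one row per epoch: ``epoch_index``, per-axis counts of
    above-threshold absolute first differences (``counts_x/y/z``),
    ``counts_mag`` (the vector-magnitude counting variant), and ``moved``
    (any per-axis count nonzero).
    """
    required = ["t_s", "ax", "ay", "az"]
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise FormatError(f"sample stream missing columns: {missing}")
    n = len(samples)
    if n == 0 or n % SAMPLES_PER_EPOCH != 0:
        raise FormatError(
            f"sample stream length {n} is not a whole number of "
            f"{SAMPLES_PER_EPOCH}-sample epochs"
        )
    t = samples["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, 1.0 / SAMPLE_HZ, atol=1e-6):
        bad = int(np.argmax(~np.isclose(dt, 1.0 / SAMPLE_HZ, atol=1e-6)))
        raise FormatError(
            f"samples are off the {SAMPLE_HZ} Hz grid near row {bad + 1} "
            f"(t={t[bad + 1]:g})"
        )

    xyz = samples[["ax", "ay", "az"]].to_numpy(dtype=float)
    n_epochs = n // SAMPLES_PER_EPOCH
    blocks = xyz.reshape(n_epochs, SAMPLES_PER_EPOCH, 3)
    diffs = np.diff(blocks, axis=1)  # within-epoch first differences only
    thr = np.array([threshold.x, threshold.y, threshold.z])
    counts = (np.abs(diffs) > thr).sum(axis=1)
    mag = np.sqrt((diffs**2).sum(axis=2))
    counts_mag = (mag > threshold.magnitude).sum(axis=1)

    out = pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "counts_x": counts[:, 0],
            "counts_y": counts[:, 1],
            "counts_z": counts[:, 2],
            "counts_mag": counts_mag,
            "moved": counts.sum(axis=1) > 0,
        }
    )
    return out


@dataclass
class DeviceLog:
    """One subject-day of device output: the epoch stream plus cue events.

    The wearing session is ``session_hours`` of consecutive 2-s epochs
    (3 waking hours by default); ``day`` indexes the 14-day intervention.
    """

    subject_id: str
    day: int
    epochs: pd.DataFrame
    cue_events: list[CueEvent] = field(default_factory=list)
    group: str = ""
    fthue_level: int = 0
    threshold: float = 1.0
    session_hours: float = 3.0

    def __post_init__(self) -> None:
        if not 1 <= self.day <= 14:
            raise DesignError(f"day must be in 1..14, got {self.day}")

    @property
    def expected_epochs(self) -> int:
        return int(round(self.session_hours * 3600.0 / EPOCH_S))

    @property
    def complete(self) -> bool:
        """True when at least 90% of the expected epochs are present."""
        return len(self.epochs) >= 0.9 * self.expected_epochs


@dataclass(frozen=True)
class DailyCount:
    """Total activity counts of one wearing day, with a completeness flag."""

    day: int
    count: int
    n_epochs: int
    expected_epochs: int
    complete: bool


def daily_movement_frequency(
    log: DeviceLog, axis_mode: str = "sum"
) -> DailyCount:
    """Total number of movements in the wearing session.

    ``axis_mode="sum"`` (default) totals the per-axis counts across X, Y and
    Z; ``"magnitude"`` uses the vector-magnitude counting variant instead.
    Days with missing epochs are returned as-is with ``complete=False`` —
    never silently rescaled.
    """
    if axis_mode == "sum":
        count = int(
            log.epochs[["counts_x", "counts_y", "counts_z"]].to_numpy().sum()
        )
    elif axis_mode == "magnitude":
        count = int(log.epochs["counts_mag"].to_numpy().sum())
    else:
        raise ValueError("axis_mode must be 'sum' or 'magnitude'")
    return DailyCount(
        day=log.day,
        count=count,
        n_epochs=len(log.epochs),
        expected_epochs=log.expected_epochs,
        complete=log.complete,
    )


@dataclass(frozen=True)
class KinematicOutcomes:
    """Trial-level movement-frequency outcomes of one subject."""

    avg14: float  # mean daily count over the 14 intervention days
    gain_f3l3: float  # mean(days 12-14) - mean(days 1-3)
    daily_counts: tuple[int, ...]
    all_complete: bool


def trial_kinematic_outcomes(
    logs: Sequence[DeviceLog], axis_mode: str = "sum"
) -> KinematicOutcomes:
    """14-day average movement frequency and the first-3/last-3-day gain.

    Requires exactly 14 daily logs ordered day 1..14. The gain score is
    mean(days 12-14) minus mean(days 1-3).
    """
    if len(logs) != 14:
        raise DesignError(f"expected exactly 14 daily logs, got {len(logs)}")
    days = [log.day for log in logs]
    if days != list(range(1, 15)):
        raise DesignError(f"logs must be ordered day 1..14, got days {days}")
    dailies = [daily_movement_frequency(log, axis_mode=axis_mode) for log in logs]
    counts = np.array([d.count for d in dailies], dtype=float)
    return KinematicOutcomes(
        avg14=float(counts.mean()),
        gain_f3l3=float(counts[11:14].mean() - counts[0:3].mean()),
        daily_counts=tuple(int(c) for c in counts),
        all_complete=all(d.complete for d in dailies),
    )
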