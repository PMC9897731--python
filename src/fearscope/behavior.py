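"""Freezing segmentation and epoch bookkeeping from the movement index.

A frame is freezing iff it belongs to a maximal below-threshold run of the
movement index lasting at least the minimum duration (default 0.5 s).  The
default threshold is 40 a.u. without a cable attached and 120 a.u. with one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fearscope.core import InvalidArgumentError
from fearscope.synthetic import ExperimentSchedule

FREEZE_THRESHOLD_NO_CABLE = 40.0
FREEZE_THRESHOLD_CABLE = 120.0
MIN_FREEZE_DURATION = 0.5  # s
PERCENT_FREEZING_BIN = 10.0  # s


def default_threshold(cable_attached: bool) -> float:
    return FREEZE_THRESHOLD_CABLE if cable_attached else FREEZE_THRESHOLD_NO_CABLE


@dataclass
class BehaviorTrace:
    """Movement index at the behavior frame rate plus derived freezing state."""

    movement_index: np.ndarray
    frame_rate: float = 30.0
    freezing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.movement_index = np.asarray(self.movement_index, dtype=float)
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame_rate must be positive")
        if self.freezing is not None:
            self.freezing = np.asarray(self.freezing, dtype=np.int8)
            if self.freezing.shape != self.movement_index.shape:
                raise InvalidArgumentError("freezing and index lengths differ")


def detect_freezing(
    movement_index: np.ndarray,
    frame_rate: float = 30.0,
    threshold: float = FREEZE_THRESHOLD_NO_CABLE,
    min_duration: float = MIN_FREEZE_DURATION,
) -> np.ndarray:
    """Binary freezing trace from the movement index.

    A maximal run of frames strictly below ``threshold`` is freezing iff its
    duration (frames / frame_rate) is at least ``min_duration``.  A run
    truncated by either trace end still counts if long enough.
    """
    movement_index = np.asarray(movement_index, dtype=float)
    if movement_index.size == 0:
        raise InvalidArgumentError("empty movement-index trace")
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    if min_duration < 0:
        raise InvalidArgumentError("min_duration must be >= 0")

    below = movement_index < threshold
    freezing = np.zeros(movement_index.size, dtype=np.int8)
    min_frames = int(np.ceil(min_duration * frame_rate))
    # run-length encode the below-threshold mask
    edges = np.flatnonzero(np.diff(below.astype(np.int8))) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [below.size]])
    for s, e in zip(starts, ends):
        if below[s] and (e - s) >= max(min_frames, 1):
            freezing[s:e] = 1
    return freezing


def percent_freezing(
    freezing: np.ndarray,
    frame_rate: float = 30.0,
    bin_width: float = PERCENT_FREEZING_BIN,
) -> np.ndarray:
    """Per-bin percent of frames spent freezing; trailing partial bin dropped."""
    freezing = np.asarray(freezing)
    frames_per_bin = bin_width * frame_rate
    if frames_per_bin < 1:
        raise InvalidArgumentError("bin shorter than one frame")
    if abs(frames_per_bin - round(frames_per_bin)) > 1e-9:
        raise InvalidArgumentError("bin_width must span a whole number of frames")
    fpb = int(round(frames_per_bin))
    n_bins = freezing.size // fpb
    if n_bins == 0:
        return np.empty(0)
    binned = freezing[: n_bins * fpb].reshape(n_bins, fpb)
    return binned.mean(axis=1) * 100.0


def movement_on_events(freezing: np.ndarray, frame_rate: float = 30.0) -> np.ndarray:
    """Times (s) of freezing -> moving transitions of the binary trace."""
    freezing = np.asarray(freezing)
    idx = np.flatnonzero((freezing[:-1] == 1) & (freezing[1:] == 0)) + 1
    return idx / frame_rate


@dataclass
class EpochSet:
    """Labeled analysis intervals; labels are 'CS' or 'noCS'."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    source_day: str = ""

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, l in self.intervals if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "label"])


def build_epochs(
    schedule: ExperimentSchedule,
    no_cs_duration: float = 30.0,
    us_exclusion: float = 5.0,
) -> EpochSet:
    """CS epochs (the 30 s tone blocks) plus no-CS analysis windows.

    No-CS windows are centred midway between consecutive CS blocks, with one
    more after the last block; windows are shifted forward out of the first
    ``us_exclusion`` seconds after any footshock and clipped to the session.
    Overlap of a no-CS window with a CS block raises.
    """
    intervals: list[tuple[float, float, str]] = [
        (s, e, "CS") for s, e in schedule.block_intervals
    ]
    blocks = schedule.block_intervals
    gap_centres = [
        0.5 * (blocks[i][1] + blocks[i + 1][0]) for i in range(len(blocks) - 1)
    ]
    gap_centres.append(
        min(blocks[-1][1] + 0.5 * (schedule.session_length - blocks[-1][1]),
            schedule.session_length - 0.5 * no_cs_duration)
    )
    for centre in gap_centres:
        start = centre - 0.5 * no_cs_duration
        end = centre + 0.5 * no_cs_duration
        for us in schedule.us_onsets:
            if start < us + schedule.us_duration + us_exclusion and end > us:
                shift = us + schedule.us_duration + us_exclusion - start
                start += shift
                end += shift
        end = min(end, schedule.session_length)
        for bs, be in blocks:
            if start < be and end > bs:
                raise InvalidArgumentError(
                    "no-CS window overlaps a CS block; adjust no_cs_duration"
                )
        intervals.append((start, end, "noCS"))
    return EpochSet(intervals=intervals, source_day=schedule.day_kind)
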