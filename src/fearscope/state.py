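"""State-conditional, amplitude-weighted event frequency.

Each analyzed behavior frame carries exactly one of four labels — freezing
or moving, crossed with CS block or no CS — and the per-neuron metric for a
label is the summed sigma-normalised amplitude of the events falling in its
frames divided by the label's total duration.  Frames are half-open
``[k/rate, (k+1)/rate)`` so boundary events are counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fearscope.core import AlignmentError, EventSeries, InvalidArgumentError
from fearscope.synthetic import ExperimentSchedule

STATES = ("Frz_noCS", "Mov_noCS", "Frz_CS", "Mov_CS")
_STATE_CODE = {name: k for k, name in enumerate(STATES)}
US_PAD = 1.0  # s excluded around each footshock when exclude_us is set


@dataclass
class StateLabels:
    """Per-frame state codes (0..3 per STATES order; -1 = excluded)."""

    codes: np.ndarray
    frame_rate: float

    def durations(self) -> dict[str, float]:
        return {
            name: float(np.sum(self.codes == k)) / self.frame_rate
            for name, k in _STATE_CODE.items()
        }


def label_state_intervals(
    freezing: np.ndarray,
    frame_rate: float,
    schedule: ExperimentSchedule,
    exclude_us: bool = True,
    us_pad: float = US_PAD,
) -> StateLabels:
    """Label every behavior frame with one of the four CS x movement states.

    ``exclude_us`` removes frames within ``us_pad`` seconds of a footshock
    (code -1), so shock artifacts do not contaminate the state metric.
    """
    freezing = np.asarray(freezing)
    n = freezing.size
    expected = int(round(schedule.session_length * frame_rate))
    if abs(n - expected) > frame_rate:  # tolerate < 1 s of trailing mismatch
        raise AlignmentError(
            f"freezing trace has {n} frames; schedule implies {expected}"
        )
    t = np.arange(n) / frame_rate
    in_cs = np.zeros(n, dtype=bool)
    for s, e in schedule.block_intervals:
        in_cs |= (t >= s) & (t < e)
    codes = np.where(
        freezing.astype(bool),
        np.where(in_cs, _STATE_CODE["Frz_CS"], _STATE_CODE["Frz_noCS"]),
        np.where(in_cs, _STATE_CODE["Mov_CS"], _STATE_CODE["Mov_noCS"]),
    ).astype(np.int8)
    if exclude_us and schedule.us_onsets.size:
        for us in schedule.us_onsets:
            codes[(t >= us - us_pad) & (t < us + schedule.us_duration + us_pad)] = -1
    return StateLabels(codes=codes, frame_rate=frame_rate)


def amplitude_weighted_frequency(
    events: EventSeries, labels: StateLabels
) -> pd.DataFrame:
    """Per-neuron amplitude-weighted event frequency in each state.

    Returns a long DataFrame (neuron, state, freq_sigma_per_s, duration_s);
    states with zero duration get NaN frequency.  Events on excluded frames
    are dropped.
    """
    durations = labels.durations()
    n_frames = labels.codes.size
    table = events.table
    frame = np.floor(table["time_s"].to_numpy() * labels.frame_rate).astype(int)
    if len(table) and (frame.min() < 0 or frame.max() >= n_frames):
        raise InvalidArgumentError("event outside the labeled session")
    codes = labels.codes[frame] if len(table) else np.empty(0, dtype=np.int8)

    rows = []
    neurons = sorted(table["neuron"].unique()) if len(table) else []
    amp = table["amplitude_sigma"].to_numpy() if len(table) else np.empty(0)
    neuron_col = table["neuron"].to_numpy() if len(table) else np.empty(0, dtype=int)
    for neuron in neurons:
        sel = neuron_col == neuron
        for name, k in _STATE_CODE.items():
            dur = durations[name]
            total = float(amp[sel & (codes == k)].sum())
            freq = total / dur if dur > 0 else np.nan
            rows.append(
                {
                    "neuron": int(neuron),
                    "state": name,
                    "freq_sigma_per_s": freq,
                    "duration_s": dur,
                }
            )
    return pd.DataFrame(
        rows, columns=["neuron", "state", "freq_sigma_per_s", "duration_s"]
    )
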