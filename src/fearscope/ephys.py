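"""Synaptic metrics from stimulus-aligned current traces.

Implements peak EPSC amplitude, onset delay, input-output curves with a
saturation flag, the paired-pulse ratio with decay-extrapolated subtraction
of the first response, and the AMPA/NMDA ratio measured at a fixed delay on
the +50 mV trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from fearscope.core import DataError, InvalidArgumentError

PEAK_SEARCH_WINDOW = 0.1  # s after stimulus onset
DEFAULT_BASELINE_WINDOW = 0.05  # s before stimulus
NOISE_FACTOR = 3.0  # detection: peak must exceed this multiple of baseline SD
NMDA_MEASUREMENT_TIME = 0.05  # s post-stimulus, the dashed-line analysis time
DELAY_FRACTION = 0.1  # delay = first crossing of this fraction of peak
SATURATION_TOLERANCE = 0.1  # top-two amplitudes within 10% -> saturated


@dataclass
class EphysRecording:
    """One stimulus-aligned voltage-clamp sweep (inward currents negative)."""

    time: np.ndarray
    current: np.ndarray
    holding_mv: float
    light_intensity: float
    stim_onsets: np.ndarray
    cell_id: int = 0
    genotype: str = ""
    companion: Optional["EphysRecording"] = None  # e.g. the +50 mV sweep

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.stim_onsets = np.atleast_1d(np.asarray(self.stim_onsets, dtype=float))
        if self.time.shape != self.current.shape:
            raise DataError("time and current lengths differ")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise DataError("sampling must be uniform")
        if self.stim_onsets.size and (
            self.stim_onsets.min() < self.time[0]
            or self.stim_onsets.max() > self.time[-1]
        ):
            raise DataError("stimulus onset outside the trace")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def index_at(self, t: float) -> int:
        return int(round((t - self.time[0]) / self.dt))


def _inward_sign(holding_mv: float) -> float:
    """-1 when the synaptic current is inward (negative), +1 when outward."""
    return -1.0 if holding_mv < 0 else 1.0


def epsc_peak(
    recording: EphysRecording,
    stimulus_index: int = 0,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    search_window: float = PEAK_SEARCH_WINDOW,
) -> tuple[float, bool]:
    """Baseline-subtracted EPSC peak amplitude after one stimulus.

    Returns ``(amplitude, detected)``; the amplitude is the absolute
    extremum (sign chosen by holding potential) within ``search_window``
    after the stimulus, relative to the pre-stimulus baseline mean.
    ``detected`` is False when the peak stays below ``NOISE_FACTOR`` baseline
    SDs (flat/noise-only trace), in which case the amplitude is still
    reported.
    """
    onset = recording.stim_onsets[stimulus_index]
    i_on = recording.index_at(onset)
    i_base = recording.index_at(max(onset - baseline_window, recording.time[0]))
    if i_base >= i_on:
        raise InvalidArgumentError("baseline window must precede the stimulus")
    baseline = recording.current[i_base:i_on]
    base_mean = float(baseline.mean())
    base_sd = float(baseline.std())
    i_end = min(recording.index_at(onset + search_window), recording.current.size)
    segment = recording.current[i_on:i_end] - base_mean
    sign = _inward_sign(recording.holding_mv)
    amplitude = float(np.max(sign * segment))
    amplitude = max(amplitude, 0.0)
    detected = amplitude > NOISE_FACTOR * base_sd if base_sd > 0 else amplitude > 0
    return amplitude, detected


def input_output_curve(recordings: Sequence[EphysRecording]) -> pd.DataFrame:
    """Per-intensity EPSC amplitudes, sorted, with a saturation flag.

    Duplicate intensities are aggregated by mean.  The result frame carries
    a ``saturated`` attribute: True when the top two amplitudes differ by
    less than 10% of the larger one.
    """
    if len(recordings) < 3:
        raise InvalidArgumentError("need recordings at >= 3 intensities")
    rows = []
    for rec in recordings:
        amp, detected = epsc_peak(rec)
        rows.append(
            {"intensity": rec.light_intensity, "amplitude_nA": amp, "detected": detected}
        )
    frame = (
        pd.DataFrame(rows)
        .groupby("intensity", as_index=False)
        .agg({"amplitude_nA": "mean", "detected": "any"})
        .sort_values("intensity", ignore_index=True)
    )
    top2 = frame["amplitude_nA"].to_numpy()[-2:]
    hi = max(top2)
    saturated = bool(hi > 0 and (hi - min(top2)) < SATURATION_TOLERANCE * hi)
    frame.attrs["saturated"] = saturated
    return frame


def paired_pulse_ratio(
    recording: EphysRecording,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
) -> float:
    """Paired-pulse ratio ``peak2 / peak1``.

    The second peak is measured after subtracting the mono-exponential decay
    of the first EPSC, fitted between the first peak and the second stimulus
    and extrapolated under the second response.
    """
    if recording.stim_onsets.size < 2:
        raise InvalidArgumentError("need two stimuli for a paired-pulse ratio")
    amp1, detected = epsc_peak(recording, 0, baseline_window)
    if not detected or amp1 <= 0:
        raise DataError("first EPSC not detectable; PPR undefined")

    sign = _inward_sign(recording.holding_mv)
    on1, on2 = recording.stim_onsets[:2]
    i_on1, i_on2 = recording.index_at(on1), recording.index_at(on2)
    i_base = recording.index_at(max(on1 - baseline_window, recording.time[0]))
    base_mean = recording.current[i_base:i_on1].mean()
    rectified = sign * (recording.current - base_mean)  # peaks positive

    i_pk1 = i_on1 + int(np.argmax(rectified[i_on1:i_on2]))
    # fit a*exp(-t/tau) to the decaying flank of the first EPSC
    seg = rectified[i_pk1:i_on2]
    t_seg = recording.time[i_pk1:i_on2] - recording.time[i_pk1]
    if seg.size >= 4 and seg[0] > 0:
        try:
            popt, _ = curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau),
                t_seg,
                seg,
                p0=(seg[0], max(t_seg[-1] / 2.0, recording.dt)),
                maxfev=2000,
            )
            a_fit, tau_fit = popt
        except RuntimeError:
            a_fit, tau_fit = seg[0], max(t_seg[-1] / 2.0, recording.dt)
        tail = a_fit * np.exp(
            -(recording.time - recording.time[i_pk1]) / max(tau_fit, 1e-9)
        )
        tail[: i_pk1] = 0.0
    else:
        tail = np.zeros_like(rectified)

    corrected = rectified - tail
    i_end = min(recording.index_at(on2 + PEAK_SEARCH_WINDOW), corrected.size)
    amp2 = float(np.max(corrected[i_on2:i_end]))
    return amp2 / amp1


def ampa_nmda_ratio(
    trace_minus70: EphysRecording,
    trace_plus50: EphysRecording,
    t_nmda: float = NMDA_MEASUREMENT_TIME,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
) -> float:
    """AMPA peak at -70 mV divided by the NMDA current ``t_nmda`` s
    post-stimulus at +50 mV."""
    if abs(trace_minus70.stim_onsets[0] - trace_plus50.stim_onsets[0]) > 1e-9:
        raise InvalidArgumentError("traces must share the stimulus clock")
    ampa, detected = epsc_peak(trace_minus70, 0, baseline_window)
    onset = trace_plus50.stim_onsets[0]
    i_on = trace_plus50.index_at(onset)
    i_base = trace_plus50.index_at(max(onset - baseline_window, trace_plus50.time[0]))
    baseline = trace_plus50.current[i_base:i_on]
    i_nmda = trace_plus50.index_at(onset + t_nmda)
    nmda = float(trace_plus50.current[i_nmda] - baseline.mean())
    base_sd = float(baseline.std())
    if nmda <= max(NOISE_FACTOR * base_sd, 0.0) or nmda <= 0:
        raise DataError("NMDA current below noise; ratio undefined")
    return ampa / nmda


def epsc_delay(
    recording: EphysRecording,
    stimulus_index: int = 0,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    fraction: float = DELAY_FRACTION,
) -> float:
    """Latency (ms) from stimulus onset to the first crossing of
    ``fraction`` of the peak amplitude."""
    amp, detected = epsc_peak(recording, stimulus_index, baseline_window)
    if not detected or amp <= 0:
        raise DataError("no detectable EPSC; delay undefined")
    onset = recording.stim_onsets[stimulus_index]
    i_on = recording.index_at(onset)
    i_base = recording.index_at(max(onset - baseline_window, recording.time[0]))
    base_mean = recording.current[i_base:i_on].mean()
    sign = _inward_sign(recording.holding_mv)
    i_end = min(recording.index_at(onset + PEAK_SEARCH_WINDOW), recording.current.size)
    segment = sign * (recording.current[i_on:i_end] - base_mean)
    crossing = np.flatnonzero(segment >= fraction * amp)
    if crossing.size == 0:
        raise DataError("threshold never crossed; delay undefined")
    return float(crossing[0] * recording.dt * 1e3)


def excitation_inhibition_ratio(
    trace_minus70: EphysRecording, trace_0mv: EphysRecording
) -> float:
    """Direct excitation over feedforward inhibition: peak inward EPSC at
    -70 mV divided by peak outward current at 0 mV."""
    exc, exc_ok = epsc_peak(trace_minus70)
    inh, inh_ok = epsc_peak(trace_0mv)
    if not (exc_ok and inh_ok) or inh <= 0:
        raise DataError("E/I ratio undefined for undetectable components")
    return exc / inh
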