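"""Synthetic session generator with planted ground truth.

Produces the three-day conditioning schedules, a two-state movement/freezing
behavior model emitting a movement-index trace, neuron populations with
planted stimulus-locked responses plus state-dependent background events,
and light-evoked EPSC traces with saturating intensity dependence.

Everything is driven by explicit integer seeds and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from fearscope.core import InvalidArgumentError, TraceSet

DAY_KINDS = ("habituation", "training", "recall")

#: beeps per 30 s block, one per second
BEEPS_PER_BLOCK = 30
BLOCK_DURATION = 30.0
HABITUATION_BLOCKS = 6
TRAINING_BLOCKS = 6
RECALL_BLOCKS = 4
FIXED_BLOCK_GAP = 90.0  # habituation / recall inter-block spacing, s
TRAINING_GAP_RANGE = (60.0, 120.0)  # pseudo-random training spacing, s
US_DURATION = 1.0
SESSION_LEAD_IN = 60.0
SESSION_TAIL = 60.0


@dataclass
class ExperimentSchedule:
    """Timed stimuli for one session.

    ``block_intervals`` are half-open ``(start, end)`` pairs of the 30 s tone
    blocks; ``beep_onsets`` hold every individual beep onset (1 Hz within a
    block); ``us_onsets`` is empty except on the training day, where each
    block end is followed immediately by a 1 s footshock.
    """

    day_kind: str
    beep_onsets: np.ndarray
    block_intervals: list[tuple[float, float]]
    us_onsets: np.ndarray
    us_duration: float
    session_length: float

    def __post_init__(self) -> None:
        self.beep_onsets = np.asarray(self.beep_onsets, dtype=float)
        self.us_onsets = np.asarray(self.us_onsets, dtype=float)
        if self.day_kind not in DAY_KINDS:
            raise InvalidArgumentError(f"unknown day_kind {self.day_kind!r}")
        events = list(self.beep_onsets) + list(self.us_onsets)
        if events and max(events) >= self.session_length:
            raise InvalidArgumentError("event beyond session_length")

    @property
    def n_blocks(self) -> int:
        return len(self.block_intervals)


def build_schedule(day_kind: str, seed: int = 0) -> ExperimentSchedule:
    """Build a session schedule for one day of the 3-day protocol.

    Habituation: 6 tone blocks of 30 beeps (1 Hz), 90 s apart.
    Training: 6 blocks spaced pseudo-randomly 60-120 s apart, each followed
    by a 1 s footshock starting at the block end.
    Recall: 4 blocks, no footshock.
    """
    if day_kind not in DAY_KINDS:
        raise InvalidArgumentError(f"unknown day_kind {day_kind!r}")
    rng = np.random.default_rng(seed)
    if day_kind == "habituation":
        n_blocks, gaps, n_us = HABITUATION_BLOCKS, None, 0
    elif day_kind == "training":
        n_blocks, n_us = TRAINING_BLOCKS, TRAINING_BLOCKS
        gaps = rng.uniform(*TRAINING_GAP_RANGE, size=n_blocks - 1)
    else:
        n_blocks, gaps, n_us = RECALL_BLOCKS, None, 0
    if gaps is None:
        gaps = np.full(n_blocks - 1, FIXED_BLOCK_GAP)

    starts = [SESSION_LEAD_IN]
    for g in gaps:
        starts.append(starts[-1] + BLOCK_DURATION + float(g))
    block_intervals = [(s, s + BLOCK_DURATION) for s in starts]
    beep_onsets = np.concatenate(
        [s + np.arange(BEEPS_PER_BLOCK, dtype=float) for s in starts]
    )
    if n_us:
        us_onsets = np.array([e for _, e in block_intervals])
    else:
        us_onsets = np.empty(0)
    session_length = block_intervals[-1][1] + SESSION_TAIL
    return ExperimentSchedule(
        day_kind=day_kind,
        beep_onsets=beep_onsets,
        block_intervals=block_intervals,
        us_onsets=us_onsets,
        us_duration=US_DURATION,
        session_length=session_length,
    )


@dataclass
class BehaviorSpec:
    """Parameters of the two-state (move/freeze) behavior model."""

    frame_rate: float = 30.0
    mean_move_bout: float = 8.0
    mean_freeze_bout: float = 4.0
    move_level: float = 200.0
    freeze_level: float = 10.0
    index_noise_sd: float = 5.0
    cs_freeze_bias: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame_rate must be positive")
        if self.move_level < 0 or self.freeze_level < 0:
            raise InvalidArgumentError("index levels must be non-negative")
        if self.mean_move_bout <= 0 or self.mean_freeze_bout < 0:
            raise InvalidArgumentError("bout means must be positive")
        if self.index_noise_sd < 0:
            raise InvalidArgumentError("index_noise_sd must be non-negative")


@dataclass
class SimulatedBehavior:
    """Movement-index trace plus the hidden state sequence (ground truth)."""

    movement_index: np.ndarray
    frame_rate: float
    state: np.ndarray  # 1 = freezing, 0 = moving (hidden)

    @property
    def n_frames(self) -> int:
        return self.movement_index.size

    def hidden_movement_on_times(self) -> np.ndarray:
        """Times of hidden freeze->move transitions, in seconds."""
        s = self.state
        idx = np.flatnonzero((s[:-1] == 1) & (s[1:] == 0)) + 1
        return idx / self.frame_rate


def simulate_behavior(
    schedule: ExperimentSchedule, spec: BehaviorSpec
) -> SimulatedBehavior:
    """Simulate a 30 Hz movement-index trace over one session.

    The hidden state is a two-state semi-Markov chain with geometric
    (frame-wise) bout lengths, so bout durations have the requested means.
    During CS blocks the per-frame probability of entering freezing is
    multiplied by ``1 + cs_freeze_bias`` and the probability of leaving it is
    divided by the same factor.  ``mean_freeze_bout == 0`` disables freezing
    entirely.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fr = spec.frame_rate
    n = int(round(schedule.session_length * fr))

    in_cs = np.zeros(n, dtype=bool)
    for s, e in schedule.block_intervals:
        in_cs[int(np.floor(s * fr)) : int(np.ceil(e * fr))] = True

    p_enter = 1.0 / (spec.mean_move_bout * fr)
    freezing_enabled = spec.mean_freeze_bout > 0
    p_exit = 1.0 / (spec.mean_freeze_bout * fr) if freezing_enabled else 1.0
    bias = 1.0 + max(spec.cs_freeze_bias, 0.0)

    state = np.zeros(n, dtype=np.int8)
    u = rng.random(n)
    cur = 0
    for t in range(1, n):
        if cur == 0:
            p = p_enter * (bias if in_cs[t] else 1.0) if freezing_enabled else 0.0
            if u[t] < min(p, 1.0):
                cur = 1
        else:
            p = p_exit / (bias if in_cs[t] else 1.0)
            if u[t] < min(p, 1.0):
                cur = 0
        state[t] = cur

    level = np.where(state == 1, spec.freeze_level, spec.move_level)
    index = level + rng.normal(0.0, spec.index_noise_sd, size=n)
    return SimulatedBehavior(movement_index=index, frame_rate=fr, state=state)


@dataclass
class PopulationSpec:
    """Parameters of the simulated neuron population.

    Responder counts are planted in disjoint subsets; amplitudes are stated
    in multiples of the per-trace noise SD.  Rates are events/s and depend on
    the hidden movement state.
    """

    n_neurons: int = 50
    n_us_responders: int = 0
    n_cs_responders: int = 0
    n_movon_responders: int = 0
    response_amplitude: float = 5.0
    response_latency: float = 0.1
    background_rate_moving: float = 0.02
    background_rate_freezing: float = 0.02
    background_amplitude: float = 2.0  # mean, multiples of noise SD
    kernel_decay: float = 1.0  # s; AR(1) gamma = exp(-dt / kernel_decay)
    noise_sd: float = 1.0
    sampling_rate: float = 10.0
    n_planes: int = 3
    duplicate_fraction: float = 0.0
    duplicate_gain: float = 0.8
    fov_radius_um: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_us_responders,
            self.n_cs_responders,
            self.n_movon_responders,
        )
        if any(c < 0 or c > self.n_neurons for c in counts):
            raise InvalidArgumentError("responder counts must be in [0, n_neurons]")
        if sum(counts) > self.n_neurons:
            raise InvalidArgumentError(
                "responder subsets are disjoint; counts sum beyond n_neurons"
            )
        if self.background_rate_moving < 0 or self.background_rate_freezing < 0:
            raise InvalidArgumentError("background rates must be non-negative")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise InvalidArgumentError("duplicate_fraction must be in [0, 1]")
        if self.kernel_decay <= 0 or self.noise_sd < 0 or self.sampling_rate <= 0:
            raise InvalidArgumentError("kinetic parameters must be positive")

    @property
    def gamma(self) -> float:
        return float(np.exp(-1.0 / (self.sampling_rate * self.kernel_decay)))


@dataclass
class GroundTruth:
    """Planted event trains and labels for one simulated population."""

    event_times: list[np.ndarray]
    event_amplitudes: list[np.ndarray]  # absolute fluorescence units
    us_responder: np.ndarray
    cs_responder: np.ndarray
    movon_responder: np.ndarray
    duplicate_map: dict[int, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "us": int(self.us_responder.sum()),
            "cs": int(self.cs_responder.sum()),
            "movon": int(self.movon_responder.sum()),
        }


def exponential_kernel_trace(
    event_indices: np.ndarray,
    event_amplitudes: np.ndarray,
    n_samples: int,
    gamma: float,
) -> np.ndarray:
    """Noiseless trace: events convolved with the AR(1) exponential kernel."""
    s = np.zeros(n_samples)
    np.add.at(s, event_indices, event_amplitudes)
    return lfilter([1.0], [1.0, -gamma], s)


def simulate_population(
    schedule: ExperimentSchedule,
    behavior: SimulatedBehavior,
    spec: PopulationSpec,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate fluorescence traces with planted responses.

    Each planted responder fires one event per matching trigger (US onset,
    every beep, or every hidden freeze->move transition) at
    ``response_latency`` with amplitude ``response_amplitude * noise_sd``.
    All neurons additionally receive Poisson background events whose rate
    depends on the hidden movement state (nearest behavior frame).  Traces
    are the event trains convolved with a single-exponential kernel plus
    Gaussian noise at 10 Hz per plane.  A ``duplicate_fraction`` of cells is
    copied onto a neighbouring focal plane with identical event trains,
    coordinates jittered by less than 20 um, reduced gain and independent
    noise.
    """
    spec.validate()
    if behavior.n_frames < int(schedule.session_length * behavior.frame_rate):
        raise InvalidArgumentError("behavior trace does not cover the schedule")
    rng = np.random.default_rng(spec.seed)
    rate = spec.sampling_rate
    dt = 1.0 / rate
    n_samples = int(round(schedule.session_length * rate))
    gamma = spec.gamma

    order = rng.permutation(spec.n_neurons)
    us_ids = order[: spec.n_us_responders]
    cs_ids = order[spec.n_us_responders : spec.n_us_responders + spec.n_cs_responders]
    mv_ids = order[
        spec.n_us_responders
        + spec.n_cs_responders : spec.n_us_responders
        + spec.n_cs_responders
        + spec.n_movon_responders
    ]
    us_flag = np.zeros(spec.n_neurons, dtype=bool)
    cs_flag = np.zeros(spec.n_neurons, dtype=bool)
    mv_flag = np.zeros(spec.n_neurons, dtype=bool)
    us_flag[us_ids] = True
    cs_flag[cs_ids] = True
    mv_flag[mv_ids] = True

    movon_times = behavior.hidden_movement_on_times()

    # hidden state at each Ca sample, by nearest behavior frame
    sample_times = np.arange(n_samples) * dt
    frame_idx = np.clip(
        np.rint(sample_times * behavior.frame_rate).astype(int),
        0,
        behavior.n_frames - 1,
    )
    state_at_sample = behavior.state[frame_idx]
    p_event = np.where(
        state_at_sample == 1,
        spec.background_rate_freezing * dt,
        spec.background_rate_moving * dt,
    )

    event_times: list[np.ndarray] = []
    event_amps: list[np.ndarray] = []
    traces = np.empty((spec.n_neurons, n_samples))
    amp = spec.response_amplitude * spec.noise_sd
    for i in range(spec.n_neurons):
        times = []
        if us_flag[i]:
            times.append(schedule.us_onsets + spec.response_latency)
        if cs_flag[i]:
            times.append(schedule.beep_onsets + spec.response_latency)
        if mv_flag[i]:
            times.append(movon_times + spec.response_latency)
        planted = np.concatenate(times) if times else np.empty(0)
        planted_amp = np.full(planted.size, amp)

        bg_mask = rng.random(n_samples) < p_event
        bg_idx = np.flatnonzero(bg_mask)
        bg_amp = rng.exponential(
            spec.background_amplitude * spec.noise_sd, size=bg_idx.size
        )

        t_all = np.concatenate([planted, bg_idx * dt])
        a_all = np.concatenate([planted_amp, bg_amp])
        keep = t_all < schedule.session_length
        t_all, a_all = t_all[keep], a_all[keep]
        order_i = np.argsort(t_all, kind="stable")
        t_all, a_all = t_all[order_i], a_all[order_i]
        event_times.append(t_all)
        event_amps.append(a_all)

        idx = np.clip(np.rint(t_all * rate).astype(int), 0, n_samples - 1)
        clean = exponential_kernel_trace(idx, a_all, n_samples, gamma)
        traces[i] = clean + rng.normal(0.0, spec.noise_sd, size=n_samples)

    r = spec.fov_radius_um * np.sqrt(rng.random(spec.n_neurons))
    theta = rng.uniform(0, 2 * np.pi, size=spec.n_neurons)
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    plane = rng.integers(0, spec.n_planes, size=spec.n_neurons)

    n_dup = int(np.floor(spec.duplicate_fraction * spec.n_neurons))
    duplicate_map: dict[int, int] = {}
    if n_dup:
        dup_src = rng.choice(spec.n_neurons, size=n_dup, replace=False)
        dup_rows = []
        dup_coords = []
        dup_planes = []
        for k, src in enumerate(dup_src):
            idx = np.clip(
                np.rint(event_times[src] * rate).astype(int), 0, n_samples - 1
            )
            clean = exponential_kernel_trace(idx, event_amps[src], n_samples, gamma)
            dup_rows.append(
                spec.duplicate_gain * clean
                + rng.normal(0.0, spec.noise_sd, size=n_samples)
            )
            rr = rng.uniform(0.0, 15.0)  # keeps lateral distance < 20 um
            th = rng.uniform(0, 2 * np.pi)
            dup_coords.append(coords[src] + [rr * np.cos(th), rr * np.sin(th)])
            dup_planes.append((plane[src] + 1) % max(spec.n_planes, 2))
            duplicate_map[int(src)] = spec.n_neurons + k
        traces = np.vstack([traces, np.array(dup_rows)])
        coords = np.vstack([coords, np.array(dup_coords)])
        plane = np.concatenate([plane, np.array(dup_planes)])

    n_total = traces.shape[0]
    trace_set = TraceSet(
        traces=traces,
        coords=coords,
        plane=plane,
        rate=rate,
        neuron_ids=np.arange(n_total),
    )
    truth = GroundTruth(
        event_times=event_times,
        event_amplitudes=event_amps,
        us_responder=us_flag,
        cs_responder=cs_flag,
        movon_responder=mv_flag,
        duplicate_map=duplicate_map,
    )
    return trace_set, truth


# ---------------------------------------------------------------------------
# Ex-vivo EPSC traces


@dataclass
class SynapseParams:
    """Parameters of the light-evoked EPSC generator.

    ``max_amp`` is the saturated EPSC amplitude (nA, reported positive);
    the input-output relation is Hill-type in normalised light intensity.
    When ``ppr`` is set a second pulse follows at ``isi`` with the underlying
    amplitude scaled by the factor.  ``nmda_amp > 0`` adds a +50 mV companion
    recording carrying a slow outward NMDA component.
    """

    max_amp: float = 8.8
    half_saturation: float = 0.2
    hill_coef: float = 1.5
    tau_rise: float = 0.001
    tau_decay: float = 0.008
    delay: float = 0.002  # synaptic + conduction delay, s
    ppr: Optional[float] = None
    isi: float = 0.05
    nmda_amp: float = 0.0
    nmda_tau_rise: float = 0.005
    nmda_tau_decay: float = 0.1
    noise_sd: float = 0.0
    sample_rate: float = 2e4
    stim_onset: float = 0.1
    trace_duration: float = 0.6

    def validate(self) -> None:
        for tau in (self.tau_rise, self.tau_decay, self.nmda_tau_rise, self.nmda_tau_decay):
            if tau <= 0:
                raise InvalidArgumentError("time constants must be positive")
        if self.tau_rise >= self.tau_decay:
            raise InvalidArgumentError("tau_rise must be smaller than tau_decay")
        if self.ppr is not None and self.ppr <= 0:
            raise InvalidArgumentError("ppr must be positive")


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak, zero for t<0."""
    k = np.where(
        t >= 0.0, np.exp(-np.maximum(t, 0.0) / tau_decay) - np.exp(-np.maximum(t, 0.0) / tau_rise), 0.0
    )
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return k / peak


def hill_amplitude(intensity: float, params: SynapseParams) -> float:
    """Saturating EPSC amplitude (nA, positive) at a normalised intensity."""
    if intensity <= 0:
        return 0.0
    x = intensity**params.hill_coef
    return params.max_amp * x / (x + params.half_saturation**params.hill_coef)


def simulate_epsc(
    intensities: Sequence[float],
    params: SynapseParams,
    seed: int = 0,
):
    """Simulate stimulus-aligned EPSC recordings over a range of intensities.

    Returns a list of :class:`fearscope.ephys.EphysRecording` (one per
    intensity; recordings at -70 mV, inward currents negative).  When
    ``params.nmda_amp > 0`` each recording's ``companion`` attribute holds
    the +50 mV trace.
    """
    from fearscope.ephys import EphysRecording  # deferred: avoids cycle

    params.validate()
    intensities = list(intensities)
    if any(b < a for a, b in zip(intensities, intensities[1:])):
        raise InvalidArgumentError("intensities must be sorted ascending")
    rng = np.random.default_rng(seed)
    n = int(round(params.trace_duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    stim_onsets = [params.stim_onset]
    if params.ppr is not None:
        stim_onsets.append(params.stim_onset + params.isi)

    recordings = []
    for j, inten in enumerate(intensities):
        a1 = hill_amplitude(float(inten), params)
        current = np.zeros(n)
        for k, onset in enumerate(stim_onsets):
            scale = a1 * (params.ppr if (k == 1 and params.ppr is not None) else 1.0)
            current -= scale * biexp_kernel(
                t - onset - params.delay, params.tau_rise, params.tau_decay
            )
        if params.noise_sd > 0:
            current = current + rng.normal(0.0, params.noise_sd, size=n)
        companion = None
        if params.nmda_amp > 0:
            comp = params.nmda_amp * (a1 / params.max_amp if params.max_amp else 1.0)
            comp_trace = comp * biexp_kernel(
                t - stim_onsets[0] - params.delay,
                params.nmda_tau_rise,
                params.nmda_tau_decay,
            )
            if params.noise_sd > 0:
                comp_trace = comp_trace + rng.normal(0.0, params.noise_sd, size=n)
            companion = EphysRecording(
                time=t,
                current=comp_trace,
                holding_mv=50.0,
                light_intensity=float(inten),
                stim_onsets=np.array(stim_onsets[:1]),
                cell_id=j,
            )
        recordings.append(
            EphysRecording(
                time=t,
                current=current,
                holding_mv=-70.0,
                light_intensity=float(inten),
                stim_onsets=np.array(stim_onsets),
                cell_id=j,
                companion=companion,
            )
        )
    return recordings
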