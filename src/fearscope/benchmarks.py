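"""Planted-ground-truth recovery experiments and worked summary-statistic
reconstructions, shared by the test suite and the acceptance report script.

Each recovery experiment simulates one session, runs the full analysis
chain (deconvolution, Z-scoring, event alignment, classification) and
reports the number of recovered responders alongside the planted count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fearscope import behavior as beh
from fearscope import classify as cls
from fearscope import synthetic as syn
from fearscope.deconvolution import deconvolve_ar1, zscore_trace


@dataclass
class RecoveryResult:
    n_neurons: int
    n_planted: int
    n_recovered: int
    recovered_ids: set[int]
    planted_ids: set[int]
    n_deconvolved_events: int

    @property
    def exact(self) -> bool:
        return self.recovered_ids == self.planted_ids


def _deconvolve_all(traceset) -> int:
    total = 0
    for trace in traceset.traces:
        total += deconvolve_ar1(trace, rate=traceset.rate).event_times.size
    return total


def planted_us_recovery(
    n_neurons: int,
    n_responders: int,
    seed: int,
    response_amplitude: float = 5.0,
    response_latency: float = 0.1,
    background_rate: float = 0.02,
    background_amplitude: float = 1.0,
    run_deconvolution: bool = True,
) -> RecoveryResult:
    """Training-day footshock-responder recovery on synthetic data.

    Simulates 6 CS blocks each followed by a 1 s footshock, plants US-locked
    events in ``n_responders`` of ``n_neurons`` neurons, runs the pipeline
    and classifies with mean Z > 1 over [0, 1) s.
    """
    schedule = syn.build_schedule("training", seed)
    behavior = syn.simulate_behavior(schedule, syn.BehaviorSpec(seed=seed))
    pspec = syn.PopulationSpec(
        n_neurons=n_neurons,
        n_us_responders=n_responders,
        response_amplitude=response_amplitude,
        response_latency=response_latency,
        background_rate_moving=background_rate,
        background_rate_freezing=background_rate,
        background_amplitude=background_amplitude,
        seed=seed,
    )
    traceset, truth = syn.simulate_population(schedule, behavior, pspec)
    n_events = _deconvolve_all(traceset) if run_deconvolution else 0
    z = np.vstack([zscore_trace(tr) for tr in traceset.traces])
    aligned = cls.align_events(z, traceset.rate, schedule.us_onsets, "US")
    table = cls.classify_responders(aligned, day="training")
    recovered = set(table.loc[table["responder"], "neuron"].tolist())
    planted = set(np.flatnonzero(truth.us_responder).tolist())
    return RecoveryResult(
        n_neurons=n_neurons,
        n_planted=n_responders,
        n_recovered=len(recovered),
        recovered_ids=recovered,
        planted_ids=planted,
        n_deconvolved_events=n_events,
    )


def planted_cs_recovery(
    n_neurons: int,
    n_responders: int,
    seed: int,
    response_amplitude: float = 3.0,
    background_rate: float = 0.02,
    background_amplitude: float = 1.0,
    run_deconvolution: bool = True,
) -> RecoveryResult:
    """Habituation-day tone-responder recovery on synthetic data.

    Simulates 6 blocks of 30 beeps, plants beep-locked events in
    ``n_responders`` neurons, removes beeps confounded by movement
    transitions, and classifies with mean Z > 0.2 over [0, 0.5) s averaged
    across the remaining beeps.
    """
    schedule = syn.build_schedule("habituation", seed)
    behavior = syn.simulate_behavior(schedule, syn.BehaviorSpec(seed=seed))
    pspec = syn.PopulationSpec(
        n_neurons=n_neurons,
        n_cs_responders=n_responders,
        response_amplitude=response_amplitude,
        background_rate_moving=background_rate,
        background_rate_freezing=background_rate,
        background_amplitude=background_amplitude,
        seed=seed,
    )
    traceset, truth = syn.simulate_population(schedule, behavior, pspec)
    n_events = _deconvolve_all(traceset) if run_deconvolution else 0
    freezing = beh.detect_freezing(behavior.movement_index)
    movons = beh.movement_on_events(freezing)
    clean_beeps, _, _ = cls.exclude_confounded(schedule.beep_onsets, movons)
    z = np.vstack([zscore_trace(tr) for tr in traceset.traces])
    aligned = cls.align_events(z, traceset.rate, clean_beeps, "CS_beep")
    table = cls.classify_responders(aligned, day="habituation")
    recovered = set(table.loc[table["responder"], "neuron"].tolist())
    planted = set(np.flatnonzero(truth.cs_responder).tolist())
    return RecoveryResult(
        n_neurons=n_neurons,
        n_planted=n_responders,
        n_recovered=len(recovered),
        recovered_ids=recovered,
        planted_ids=planted,
        n_deconvolved_events=n_events,
    )
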