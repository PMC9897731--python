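import numpy as np
import pytest

from fearscope import synthetic as syn
from fearscope.behavior import detect_freezing
from fearscope.core import InvalidArgumentError


class TestBuildSchedule:
    def test_habituation_counts(self):
        s = syn.build_schedule("habituation", 0)
        assert s.n_blocks == 6
        assert s.beep_onsets.size == 180
        assert s.us_onsets.size == 0

    def test_training_us_at_block_ends(self):
        s = syn.build_schedule("training", 0)
        assert s.us_onsets.size == 6
        assert s.us_duration == 1.0
        np.testing.assert_allclose(s.us_onsets, [e for _, e in s.block_intervals])

    def test_recall_counts(self):
        s = syn.build_schedule("recall", 0)
        assert s.n_blocks == 4
        assert s.us_onsets.size == 0
        assert s.beep_onsets.size == 120

    def test_beeps_one_second_apart_within_blocks(self):
        s = syn.build_schedule("habituation", 3)
        per_block = s.beep_onsets.reshape(6, 30)
        np.testing.assert_allclose(np.diff(per_block, axis=1), 1.0)

    def test_training_gaps_in_range(self):
        s = syn.build_schedule("training", 42)
        starts = np.array([b[0] for b in s.block_intervals])
        ends = np.array([b[1] for b in s.block_intervals])
        gaps = starts[1:] - ends[:-1]
        assert np.all(gaps >= 60.0) and np.all(gaps <= 120.0)
        assert len(np.unique(np.round(gaps, 6))) > 1  # pseudo-random

    def test_events_within_session(self):
        for day in syn.DAY_KINDS:
            s = syn.build_schedule(day, 9)
            assert s.beep_onsets.max() < s.session_length
            if s.us_onsets.size:
                assert s.us_onsets.max() < s.session_length

    def test_unknown_day_kind(self):
        with pytest.raises(InvalidArgumentError):
            syn.build_schedule("extinction", 0)

    def test_deterministic(self):
        a = syn.build_schedule("training", 7)
        b = syn.build_schedule("training", 7)
        np.testing.assert_array_equal(a.beep_onsets, b.beep_onsets)
        assert a.block_intervals == b.block_intervals


class TestSimulateBehavior:
    def test_trace_length_and_determinism(self, habituation_schedule):
        spec = syn.BehaviorSpec(seed=4)
        a = syn.simulate_behavior(habituation_schedule, spec)
        b = syn.simulate_behavior(habituation_schedule, spec)
        assert a.n_frames == int(round(habituation_schedule.session_length * 30))
        np.testing.assert_array_equal(a.movement_index, b.movement_index)
        np.testing.assert_array_equal(a.state, b.state)

    def test_freezing_disabled(self, habituation_schedule):
        spec = syn.BehaviorSpec(mean_freeze_bout=0.0, seed=5)
        sim = syn.simulate_behavior(habituation_schedule, spec)
        assert sim.state.sum() == 0
        freezing = detect_freezing(sim.movement_index)
        assert freezing.sum() == 0  # downstream freezing is 0% of frames

    def test_mean_freeze_bout_duration(self):
        # law-of-large-numbers check on the bout sampler over ~10^4 s
        sched = syn.ExperimentSchedule(
            day_kind="habituation",
            beep_onsets=np.empty(0),
            block_intervals=[],
            us_onsets=np.empty(0),
            us_duration=1.0,
            session_length=10_000.0,
        )
        spec = syn.BehaviorSpec(mean_freeze_bout=3.0, mean_move_bout=5.0, seed=6)
        sim = syn.simulate_behavior(sched, spec)
        s = sim.state
        starts = np.flatnonzero((s[1:] == 1) & (s[:-1] == 0)) + 1
        ends = np.flatnonzero((s[1:] == 0) & (s[:-1] == 1)) + 1
        n = min(starts.size, ends.size)
        durations = (ends[:n] - starts[:n]) / 30.0
        assert abs(durations.mean() - 3.0) / 3.0 < 0.10

    def test_cs_freeze_bias_increases_cs_freezing(self, habituation_schedule):
        spec = syn.BehaviorSpec(cs_freeze_bias=3.0, seed=7)
        sim = syn.simulate_behavior(habituation_schedule, spec)
        t = np.arange(sim.n_frames) / 30.0
        in_cs = np.zeros(sim.n_frames, dtype=bool)
        for s0, e0 in habituation_schedule.block_intervals:
            in_cs |= (t >= s0) & (t < e0)
        assert sim.state[in_cs].mean() > sim.state[~in_cs].mean()


class TestSimulatePopulation:
    def test_pure_noise_population(self, habituation_schedule):
        behavior = syn.simulate_behavior(habituation_schedule, syn.BehaviorSpec(seed=1))
        spec = syn.PopulationSpec(
            n_neurons=10,
            background_rate_moving=0.0,
            background_rate_freezing=0.0,
            seed=1,
        )
        ts, truth = syn.simulate_population(habituation_schedule, behavior, spec)
        assert all(t.size == 0 for t in truth.event_times)
        # traces are pure Gaussian noise
        assert abs(ts.traces.mean()) < 0.05
        assert abs(ts.traces.std() - spec.noise_sd) < 0.05

    def test_planted_counts_conserved(self, small_session):
        _, _, _, truth = small_session
        assert truth.counts() == {"us": 4, "cs": 3, "movon": 3}

    def test_us_responders_have_event_at_every_us(self, small_session):
        schedule, _, _, truth = small_session
        for i in np.flatnonzero(truth.us_responder):
            times = truth.event_times[i]
            for us in schedule.us_onsets:
                assert np.any(np.abs(times - (us + 0.1)) < 1e-9)

    def test_planted_us_alignment_exceeds_threshold(self, small_session):
        # direct computation on generated traces, independent of the classifier
        schedule, _, ts, truth = small_session
        onsets = np.rint(schedule.us_onsets * ts.rate).astype(int)
        for i in np.flatnonzero(truth.us_responder):
            z = (ts.traces[i] - ts.traces[i].mean()) / ts.traces[i].std(ddof=1)
            windows = np.array([z[o : o + 10] for o in onsets])
            assert windows.mean() > 1.0

    def test_trace_equals_kernel_convolution_plus_noise(self, habituation_schedule):
        # event-to-trace consistency: subtracting the kernel convolution of
        # the ground-truth events leaves only the Gaussian noise floor
        behavior = syn.simulate_behavior(habituation_schedule, syn.BehaviorSpec(seed=3))
        spec = syn.PopulationSpec(
            n_neurons=5, n_cs_responders=2, seed=3,
            background_rate_moving=0.1, background_rate_freezing=0.1,
            response_amplitude=5.0, noise_sd=1.0,
        )
        ts, truth = syn.simulate_population(habituation_schedule, behavior, spec)
        for i in range(spec.n_neurons):
            idx = np.clip(
                np.rint(truth.event_times[i] * ts.rate).astype(int),
                0, ts.n_samples - 1,
            )
            expected = syn.exponential_kernel_trace(
                idx, truth.event_amplitudes[i], ts.n_samples, spec.gamma
            )
            residual = ts.traces[i] - expected
            assert abs(residual.std() - spec.noise_sd) < 0.05
            assert np.max(np.abs(residual)) < 6.0 * spec.noise_sd

    def test_duplicates(self, habituation_schedule):
        behavior = syn.simulate_behavior(habituation_schedule, syn.BehaviorSpec(seed=8))
        spec = syn.PopulationSpec(
            n_neurons=10, duplicate_fraction=0.3, seed=8,
            background_rate_moving=0.2, background_rate_freezing=0.2,
            background_amplitude=5.0,
        )
        ts, truth = syn.simulate_population(habituation_schedule, behavior, spec)
        assert ts.n_neurons == 13
        assert len(truth.duplicate_map) == 3
        # injective and cross-plane with jitter < 20 um
        assert len(set(truth.duplicate_map.values())) == 3
        for src, copy in truth.duplicate_map.items():
            assert ts.plane[src] != ts.plane[copy]
            assert np.linalg.norm(ts.coords[src] - ts.coords[copy]) < 20.0

    def test_count_overflow_rejected(self, habituation_schedule):
        behavior = syn.simulate_behavior(habituation_schedule, syn.BehaviorSpec(seed=1))
        spec = syn.PopulationSpec(n_neurons=5, n_us_responders=3, n_cs_responders=3)
        with pytest.raises(InvalidArgumentError):
            syn.simulate_population(habituation_schedule, behavior, spec)

    def test_determinism(self, habituation_schedule):
        behavior = syn.simulate_behavior(habituation_schedule, syn.BehaviorSpec(seed=9))
        spec = syn.PopulationSpec(n_neurons=6, n_us_responders=0, seed=9)
        a, _ = syn.simulate_population(habituation_schedule, behavior, spec)
        b, _ = syn.simulate_population(habituation_schedule, behavior, spec)
        np.testing.assert_array_equal(a.traces, b.traces)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSimulateEpsc:
    def test_zero_intensity_flat(self):
        recs = syn.simulate_epsc([0.0, 0.5, 1.0], syn.SynapseParams(), seed=0)
        assert np.allclose(recs[0].current, 0.0)

    def test_saturation_asymptote(self):
        p = syn.SynapseParams(max_amp=10.0, half_saturation=0.1)
        recs = syn.simulate_epsc([50.0], p, seed=0)
        peak = -recs[0].current.min()
        assert abs(peak - 10.0) / 10.0 < 0.05

    def test_ppr_closed_form(self):
        # decay-corrected second peak = 0.5 x first, by double-exponential
        # superposition arithmetic
        p = syn.SynapseParams(ppr=0.5, isi=0.05)
        rec = syn.simulate_epsc([1.0], p, seed=0)[0]
        t = rec.time
        k1 = syn.biexp_kernel(t - 0.1 - p.delay, p.tau_rise, p.tau_decay)
        k2 = syn.biexp_kernel(t - 0.15 - p.delay, p.tau_rise, p.tau_decay)
        a1 = syn.hill_amplitude(1.0, p)
        np.testing.assert_allclose(rec.current, -(a1 * k1 + 0.5 * a1 * k2), atol=1e-12)

    def test_invalid_time_constant(self):
        with pytest.raises(InvalidArgumentError):
            syn.simulate_epsc([1.0], syn.SynapseParams(tau_decay=-1.0), seed=0)

    def test_unsorted_intensities(self):
        with pytest.raises(InvalidArgumentError):
            syn.simulate_epsc([1.0, 0.5], syn.SynapseParams(), seed=0)

    def test_nmda_companion(self):
        p = syn.SynapseParams(nmda_amp=2.0)
        rec = syn.simulate_epsc([1.0], p, seed=0)[0]
        assert rec.companion is not None
        assert rec.companion.holding_mv == 50.0
        assert rec.companion.current.max() > 0
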