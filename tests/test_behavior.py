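"""Startle-session scheduling and PPI scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_event_counts
from ppiconn.behavior import (
    PPIStats,
    SessionSchedule,
    StartleSession,
    Trial,
    TrialKind,
    build_schedule,
    classify_events,
    integrate_amplitude,
    mean_response_amplitude,
    ppi_effectiveness,
    ppi_percent,
    read_session_tsv,
    score_session,
    write_session_tsv,
)
from ppiconn.errors import UndefinedStatisticError, UnscorableSessionError


def make_session(trials, amplitudes, habituation=()):
    schedule = SessionSchedule(habituation=tuple(habituation), trials=tuple(trials), rng_seed=0)
    return StartleSession(schedule=schedule, amplitudes=np.asarray(amplitudes, float))


def sa(amp):
    return Trial(TrialKind.STARTLE_ALONE, isi_s=5.0), amp


def pps(amp, db=78.0):
    return Trial(TrialKind.PREPULSE_STARTLE, isi_s=5.0, prepulse_db=db), amp


class TestSchedule:
    def test_standard_paradigm_composition(self):
        sched = build_schedule(trials_per_type=30, prepulse_levels=(68, 72, 78, 84),
                               habituation_n=25, rng_seed=7)
        assert sched.n_trials == 300
        assert len(sched.habituation) == 25
        assert all(t.kind == TrialKind.STARTLE_ALONE for t in sched.habituation)
        counts = {}
        for t in sched.trials:
            counts[(t.kind, t.prepulse_db)] = counts.get((t.kind, t.prepulse_db), 0) + 1
        assert len(counts) == 10
        assert set(counts.values()) == {30}

    def test_minimal_schedule(self):
        sched = build_schedule(trials_per_type=1, prepulse_levels=[68], habituation_n=0)
        assert sched.n_trials == 4
        assert len({(t.kind, t.prepulse_db) for t in sched.trials}) == 4

    def test_same_seed_identical_schedules(self):
        a = build_schedule(trials_per_type=5, rng_seed=123)
        b = build_schedule(trials_per_type=5, rng_seed=123)
        assert a == b

    def test_isis_within_range(self):
        sched = build_schedule(trials_per_type=10, isi_range_s=(3.0, 13.0), rng_seed=2)
        for t in sched.all_trials:
            assert 3.0 <= t.isi_s <= 13.0

    @pytest.mark.parametrize(
        "kwargs", [dict(trials_per_type=0), dict(prepulse_levels=[]),
                   dict(isi_range_s=(5.0, 3.0)), dict(habituation_n=-1)]
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            build_schedule(**kwargs)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), trials_per_type=st.integers(1, 10))
    def test_per_type_counts_exhaustive(self, seed, trials_per_type):
        sched = build_schedule(trials_per_type=trials_per_type, rng_seed=seed)
        counts = {}
        for t in sched.trials:
            counts[(t.kind, t.prepulse_db)] = counts.get((t.kind, t.prepulse_db), 0) + 1
        assert set(counts.values()) == {trials_per_type}


class TestIntegrateAmplitude:
    fs = 1000.0

    def test_zero_signal(self):
        w = np.zeros(400)
        assert integrate_amplitude(w, self.fs, stimulus_onset_s=0.2) == 0.0

    def test_constant_baseline_cancels(self):
        w = np.ones(400)
        assert integrate_amplitude(w, self.fs, stimulus_onset_s=0.2) == pytest.approx(0.0)

    def test_half_sine_matches_quadrature(self):
        # 40 ms half-sine of 12 mV peak, inside the 5-105 ms response window
        t = np.arange(400) / self.fs
        w = np.zeros_like(t)
        pulse = (t >= 0.22) & (t < 0.26)
        w[pulse] = 12.0 * np.sin(np.pi * (t[pulse] - 0.22) / 0.04)
        got = integrate_amplitude(w, self.fs, stimulus_onset_s=0.2)
        i0, i1 = 205, 305
        expected = np.trapezoid(w[i0:i1], dx=1.0)  # dt = 1 ms
        # sample-sum vs trapezoid differ only by the half-weighted endpoints
        assert got == pytest.approx(expected, rel=0.01)

    def test_mean_convention_scales_by_window(self):
        w = np.zeros(400)
        w[205:305] = 3.0
        integral = integrate_amplitude(w, self.fs, stimulus_onset_s=0.2)
        assert integral == pytest.approx(300.0)
        assert mean_response_amplitude(w, self.fs, 0.2) == pytest.approx(3.0)

    def test_window_beyond_trace_raises(self):
        with pytest.raises(ValueError):
            integrate_amplitude(np.zeros(100), self.fs, stimulus_onset_s=0.2)


class TestPPIPercent:
    @pytest.mark.parametrize(
        "a_sa,a_pp,expected", [(100.0, 40.0, 60.0), (5.0, 5.0, 0.0), (100.0, 120.0, -20.0)]
    )
    def test_formula(self, a_sa, a_pp, expected):
        assert ppi_percent(a_sa, a_pp) == pytest.approx(expected)

    def test_nonpositive_denominator_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ppi_percent(0.0, 10.0)


class TestClassifyEvents:
    def test_single_startle_above_threshold(self):
        session = make_session(*zip(sa(31.0)))
        assert classify_events(session) == (1, 0)

    def test_exact_threshold_is_no_event(self):
        session = make_session(*zip(sa(30.0)))
        assert classify_events(session) == (0, 0)

    def test_per_trial_ppi_against_session_mean(self):
        # A_sa = 100; prepulse+startle amplitudes 80, 90, 50 -> PPI 20, 10, 50
        trials, amps = zip(pps(80.0), pps(90.0), pps(50.0))
        session = make_session(trials, amps)
        assert classify_events(session, a_startle_alone=100.0) == (1, 2)

    def test_exact_ppi_threshold_is_no_event(self):
        trials, amps = zip(pps(85.0),)
        session = make_session(trials, amps)
        assert classify_events(session, a_startle_alone=100.0) == (0, 0)

    def test_controls_and_prepulse_alone_do_not_count(self):
        trials, amps = zip(
            sa(100.0),
            (Trial(TrialKind.CONTROL, isi_s=4.0), 200.0),
            (Trial(TrialKind.PREPULSE_ALONE, isi_s=4.0, prepulse_db=72.0), 200.0),
        )
        assert classify_events(make_session(trials, amps)) == (1, 0)

    def test_habituation_trials_excluded(self):
        hab = (Trial(TrialKind.STARTLE_ALONE, isi_s=5.0),)
        trials, amps = zip(sa(40.0))
        session = make_session(trials, (99.0,) + tuple(amps), habituation=hab)
        # habituation amplitude 99 would count if included; main 40 -> one event
        assert classify_events(session) == (1, 0)

    def test_no_startle_alone_unscorable(self):
        trials, amps = zip(pps(50.0))
        with pytest.raises(UnscorableSessionError):
            classify_events(make_session(trials, amps))

    def test_scale_invariance_with_scaled_threshold(self):
        rng = np.random.default_rng(0)
        trials, amps = zip(
            *(sa(float(a)) for a in rng.uniform(10, 80, 5)),
            *(pps(float(a)) for a in rng.uniform(10, 80, 8)),
        )
        session = make_session(trials, amps)
        scaled = make_session(trials, np.asarray(amps) * 7.3)
        assert classify_events(session, startle_mv_threshold=30.0) == classify_events(
            scaled, startle_mv_threshold=30.0 * 7.3
        )


class TestEffectiveness:
    def test_reported_mean_event_counts(self):
        assert ppi_effectiveness(95, 87) == pytest.approx(8 * 100 / 182)

    def test_symmetry_and_extremes(self):
        assert ppi_effectiveness(17, 17) == 0.0
        assert ppi_effectiveness(100, 0) == 100.0
        assert ppi_effectiveness(0, 42) == -100.0

    def test_no_events_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ppi_effectiveness(0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.integers(0, 300), b=st.integers(0, 300))
    def test_antisymmetry(self, a, b):
        if a + b == 0:
            return
        assert ppi_effectiveness(a, b) == pytest.approx(-ppi_effectiveness(b, a))
        assert -100.0 <= ppi_effectiveness(a, b) <= 100.0


def random_session(rng: np.random.Generator) -> StartleSession:
    n_sa = int(rng.integers(1, 8))
    n_pp = int(rng.integers(0, 20))
    n_other = int(rng.integers(0, 10))
    trials = [Trial(TrialKind.STARTLE_ALONE, isi_s=5.0)] * n_sa
    trials += [
        Trial(TrialKind.PREPULSE_STARTLE, isi_s=5.0, prepulse_db=float(rng.choice([68, 72, 78, 84])))
        for _ in range(n_pp)
    ]
    trials += [Trial(TrialKind.CONTROL, isi_s=5.0)] * n_other
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    amps = rng.uniform(1.0, 120.0, len(trials))
    return make_session(trials, amps)


def test_classification_matches_brute_force_enumeration():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        session = random_session(rng)
        assert classify_events(session) == brute_force_event_counts(session)


def test_score_session_summary_consistency():
    sched = build_schedule(trials_per_type=10, habituation_n=5, rng_seed=3)
    rng = np.random.default_rng(1)
    session = StartleSession(sched, rng.uniform(5, 90, len(sched.all_trials)), animal_id="r1")
    stats = score_session(session)
    assert isinstance(stats, PPIStats)
    n_startle, n_ppi = classify_events(session)
    assert (stats.n_startle, stats.n_ppi) == (n_startle, n_ppi)
    assert stats.effectiveness == pytest.approx(ppi_effectiveness(n_ppi, n_startle))
    assert set(stats.per_intensity_ppi) == {68.0, 72.0, 78.0, 84.0}


def test_session_tsv_roundtrip(tmp_path):
    sched = build_schedule(trials_per_type=3, habituation_n=2, rng_seed=9)
    rng = np.random.default_rng(4)
    session = StartleSession(sched, rng.uniform(1, 80, len(sched.all_trials)), animal_id="r7")
    path = tmp_path / "r7.tsv"
    write_session_tsv(session, path)
    loaded = read_session_tsv(path, animal_id="r7")
    np.testing.assert_allclose(loaded.amplitudes, session.amplitudes)
    assert [t.kind for t in loaded.schedule.trials] == [t.kind for t in sched.trials]
    assert classify_events(loaded) == classify_events(session)
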