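"""Acoustic startle / prepulse inhibition (PPI) sessions and their scoring.

A PPI session interleaves four acoustic trial types — background-only control,
a 110 dB startle pulse alone, a weak prepulse alone, and prepulse followed by
startle pulse — at several prepulse intensities.  The whole-body startle
response is recorded per trial as a baseline-corrected integrated amplitude.
Scoring reduces a session to per-intensity PPI percentages, per-trial
startle/PPI event counts, and a single PPI-effectiveness summary in
[−100, 100] that the imaging analyses use as the behavioral covariate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, UnscorableSessionError

#: Prepulse intensities used in the standard paradigm (dB SPL).
STANDARD_PREPULSE_LEVELS_DB: tuple[int, ...] = (68, 72, 78, 84)
#: Startle pulse intensity (dB SPL).
STARTLE_LEVEL_DB: float = 110.0
#: Continuous background noise level (dB SPL).
BACKGROUND_LEVEL_DB: float = 65.0


class TrialKind(str, enum.Enum):
    """The four stimulus types of a PPI paradigm."""

    CONTROL = "control"
    STARTLE_ALONE = "startle_alone"
    PREPULSE_ALONE = "prepulse_alone"
    PREPULSE_STARTLE = "prepulse_startle"

    @property
    def has_prepulse(self) -> bool:
        return self in (TrialKind.PREPULSE_ALONE, TrialKind.PREPULSE_STARTLE)


@dataclass(frozen=True)
class Trial:
    """A single stimulus presentation with its following inter-stimulus interval."""

    kind: TrialKind
    isi_s: float
    prepulse_db: float | None = None

    def __post_init__(self) -> None:
        if self.kind.has_prepulse and self.prepulse_db is None:
            raise ValueError(f"{self.kind.value} trial requires a prepulse level")
        if not self.kind.has_prepulse and self.prepulse_db is not None:
            raise ValueError(f"{self.kind.value} trial cannot carry a prepulse level")
        if self.isi_s < 0:
            raise ValueError("inter-stimulus interval must be non-negative")


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered habituation block plus pseudorandomized main paradigm.

    The habituation block consists of startle-alone stimuli only; the main
    block contains ``trials_per_type`` presentations of each stimulus type
    (control, startle-alone, and one prepulse-alone plus one prepulse+startle
    trial type per prepulse intensity) in a seeded pseudorandom order.
    """

    habituation: tuple[Trial, ...]
    trials: tuple[Trial, ...]
    rng_seed: int
    isi_range_s: tuple[float, float] = (3.0, 13.0)

    @property
    def all_trials(self) -> tuple[Trial, ...]:
        return self.habituation + self.trials

    @property
    def n_trials(self) -> int:
        """Number of main-block trials (habituation excluded)."""
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, trial in enumerate(self.all_trials):
            rows.append(
                {
                    "trial_index": i,
                    "block": "habituation" if i < len(self.habituation) else "main",
                    "kind": trial.kind.value,
                    "prepulse_db": trial.prepulse_db,
                    "isi_s": trial.isi_s,
                }
            )
        return pd.DataFrame(rows)


def build_schedule(
    trials_per_type: int = 30,
    prepulse_levels: Sequence[float] = STANDARD_PREPULSE_LEVELS_DB,
    habituation_n: int = 25,
    isi_range_s: tuple[float, float] = (3.0, 13.0),
    rng_seed: int = 0,
    isi_distribution: str = "uniform",
) -> SessionSchedule:
    """Generate a seeded pseudorandomized session schedule.

    The main block holds ``trials_per_type`` copies of each of the
    ``2 + 2 * len(prepulse_levels)`` stimulus types; with the standard four
    prepulse intensities and 30 trials per type this is the 300-trial
    paradigm.  ISIs are drawn i.i.d. from ``isi_distribution`` over
    ``isi_range_s`` (only ``"uniform"`` is implemented; the range is a
    configuration choice).  The same seed reproduces the identical schedule.
    """
    if trials_per_type <= 0:
        raise ValueError("trials_per_type must be positive")
    if len(prepulse_levels) == 0:
        raise ValueError("prepulse_levels must be non-empty")
    if habituation_n < 0:
        raise ValueError("habituation_n must be non-negative")
    lo, hi = isi_range_s
    if lo > hi:
        raise ValueError("isi_range_s must satisfy min <= max")
    if isi_distribution != "uniform":
        raise ValueError(f"unknown ISI distribution: {isi_distribution!r}")

    rng = np.random.default_rng(rng_seed)

    def draw_isi() -> float:
        return float(rng.uniform(lo, hi))

    habituation = tuple(
        Trial(TrialKind.STARTLE_ALONE, isi_s=draw_isi()) for _ in range(habituation_n)
    )

    type_list: list[tuple[TrialKind, float | None]] = [
        (TrialKind.CONTROL, None),
        (TrialKind.STARTLE_ALONE, None),
    ]
    for level in prepulse_levels:
        type_list.append((TrialKind.PREPULSE_ALONE, float(level)))
    for level in prepulse_levels:
        type_list.append((TrialKind.PREPULSE_STARTLE, float(level)))

    pool = type_list * trials_per_type
    order = rng.permutation(len(pool))
    trials = tuple(
        Trial(pool[i][0], isi_s=draw_isi(), prepulse_db=pool[i][1]) for i in order
    )
    return SessionSchedule(
        habituation=habituation,
        trials=trials,
        rng_seed=rng_seed,
        isi_range_s=(float(lo), float(hi)),
    )


@dataclass(frozen=True)
class StartleSession:
    """A schedule plus one baseline-corrected response amplitude per trial.

    ``amplitudes`` is aligned with ``schedule.all_trials`` (habituation block
    first) and uses the mean-amplitude convention in mV: the 100 ms integrated
    response divided by the window length, so it is directly comparable to
    the 30 mV startle-event threshold.
    """

    schedule: SessionSchedule
    amplitudes: np.ndarray
    animal_id: str = ""
    strain: str | None = None

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1 or len(amps) != len(self.schedule.all_trials):
            raise ValueError(
                f"expected {len(self.schedule.all_trials)} amplitudes, "
                f"got shape {amps.shape}"
            )
        if not np.all(np.isfinite(amps)):
            raise ValueError("amplitudes must be finite")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def main_amplitudes(self) -> np.ndarray:
        return self.amplitudes[len(self.schedule.habituation):]

    def main_amplitudes_of(
        self, kind: TrialKind, prepulse_db: float | None = None
    ) -> np.ndarray:
        """Main-block amplitudes for one trial kind (optionally one intensity)."""
        sel = [
            amp
            for trial, amp in zip(self.schedule.trials, self.main_amplitudes)
            if trial.kind == kind
            and (prepulse_db is None or trial.prepulse_db == prepulse_db)
        ]
        return np.asarray(sel, dtype=float)


@dataclass(frozen=True)
class PPIStats:
    """Per-animal session summary.

    ``effectiveness`` is (n_ppi − n_startle)·100/(n_ppi + n_startle): −100
    means every scored event was a startle, +100 means pure PPI.
    """

    a_startle_alone: float
    per_intensity_ppi: Mapping[float, float]
    n_ppi: int
    n_startle: int
    effectiveness: float
    animal_id: str = ""


def integrate_amplitude(
    waveform: np.ndarray,
    sample_rate_hz: float,
    stimulus_onset_s: float,
    response_start_offset_ms: float = 5.0,
    response_length_ms: float = 100.0,
    baseline_window_s: tuple[float, float] | None = None,
) -> float:
    """Baseline-corrected integrated response, in mV·ms.

    The baseline mean (over ``baseline_window_s``, default the whole
    pre-stimulus span) is subtracted from the trace, and the result is
    integrated (sample sum × sample interval) over the response window
    starting ``response_start_offset_ms`` after stimulus onset.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    dt_ms = 1000.0 / sample_rate_hz

    start_s = stimulus_onset_s + response_start_offset_ms / 1000.0
    i0 = int(round(start_s * sample_rate_hz))
    n = int(round(response_length_ms / 1000.0 * sample_rate_hz))
    if i0 < 0 or i0 + n > len(w):
        raise ValueError("response window exceeds waveform extent")

    if baseline_window_s is None:
        b0, b1 = 0, int(round(stimulus_onset_s * sample_rate_hz))
    else:
        b0 = int(round(baseline_window_s[0] * sample_rate_hz))
        b1 = int(round(baseline_window_s[1] * sample_rate_hz))
    if b0 < 0 or b1 > len(w) or b1 <= b0:
        raise ValueError("baseline window exceeds waveform extent or is empty")

    baseline = w[b0:b1].mean()
    return float((w[i0:i0 + n] - baseline).sum() * dt_ms)


def mean_response_amplitude(
    waveform: np.ndarray,
    sample_rate_hz: float,
    stimulus_onset_s: float,
    response_start_offset_ms: float = 5.0,
    response_length_ms: float = 100.0,
    baseline_window_s: tuple[float, float] | None = None,
) -> float:
    """Integrated response divided by window length → mean amplitude in mV.

    This is the convention under which the 30 mV startle-event threshold is
    applied.
    """
    integral = integrate_amplitude(
        waveform,
        sample_rate_hz,
        stimulus_onset_s,
        response_start_offset_ms,
        response_length_ms,
        baseline_window_s,
    )
    return integral / response_length_ms


def ppi_percent(a_startle_alone: float, a_prepulse_startle: float) -> float:
    """PPI [%] = (A_startle_alone − A_prepulse+startle) × 100 / A_startle_alone.

    Negative values indicate facilitation (larger response with prepulse).
    """
    if a_startle_alone <= 0:
        raise UndefinedStatisticError(
            "PPI% undefined: startle-alone amplitude must be positive"
        )
    return (a_startle_alone - a_prepulse_startle) * 100.0 / a_startle_alone


def ppi_effectiveness(n_ppi: int, n_startle: int) -> float:
    """PPI effectiveness [%] = (n_PPI − n_startle) × 100 / (n_PPI + n_startle)."""
    if n_ppi < 0 or n_startle < 0:
        raise ValueError("event counts must be non-negative")
    total = n_ppi + n_startle
    if total == 0:
        raise UndefinedStatisticError("PPI effectiveness undefined: no events")
    return (n_ppi - n_startle) * 100.0 / total


def startle_alone_mean(session: StartleSession) -> float:
    """Session-mean startle-alone amplitude over the main block (A_startle_alone)."""
    amps = session.main_amplitudes_of(TrialKind.STARTLE_ALONE)
    if len(amps) == 0:
        raise UnscorableSessionError(
            f"session {session.animal_id!r} has no startle-alone trials"
        )
    return float(amps.mean())


def classify_events(
    session: StartleSession,
    startle_mv_threshold: float = 30.0,
    ppi_pct_threshold: float = 15.0,
    a_startle_alone: float | None = None,
) -> tuple[int, int]:
    """Count (n_startle, n_ppi) events over the main block.

    A startle-alone trial with amplitude strictly above ``startle_mv_threshold``
    is a startle event.  Each prepulse+startle trial is scored by its
    per-trial PPI% against the session-mean startle-alone amplitude (override
    the denominator via ``a_startle_alone``): PPI strictly below the threshold
    is a startle event, strictly above it a PPI event, exactly at it neither.
    Control and prepulse-alone trials contribute to neither count.
    """
    denom = startle_alone_mean(session) if a_startle_alone is None else a_startle_alone
    if denom <= 0:
        raise UnscorableSessionError(
            f"session {session.animal_id!r}: non-positive mean startle-alone amplitude"
        )
    n_startle = 0
    n_ppi = 0
    for trial, amp in zip(session.schedule.trials, session.main_amplitudes):
        if trial.kind == TrialKind.STARTLE_ALONE:
            if amp > startle_mv_threshold:
                n_startle += 1
        elif trial.kind == TrialKind.PREPULSE_STARTLE:
            ppi = ppi_percent(denom, amp)
            if ppi < ppi_pct_threshold:
                n_startle += 1
            elif ppi > ppi_pct_threshold:
                n_ppi += 1
    return n_startle, n_ppi


def score_session(
    session: StartleSession,
    startle_mv_threshold: float = 30.0,
    ppi_pct_threshold: float = 15.0,
) -> PPIStats:
    """Full per-animal summary: per-intensity PPI%, event counts, effectiveness."""
    a_sa = startle_alone_mean(session)
    if a_sa <= 0:
        raise UnscorableSessionError(
            f"session {session.animal_id!r}: non-positive mean startle-alone amplitude"
        )
    levels = sorted(
        {
            t.prepulse_db
            for t in session.schedule.trials
            if t.kind == TrialKind.PREPULSE_STARTLE
        }
    )
    per_intensity = {}
    for level in levels:
        amps = session.main_amplitudes_of(TrialKind.PREPULSE_STARTLE, level)
        if len(amps):
            per_intensity[float(level)] = ppi_percent(a_sa, float(amps.mean()))
    n_startle, n_ppi = classify_events(
        session, startle_mv_threshold, ppi_pct_threshold, a_startle_alone=a_sa
    )
    return PPIStats(
        a_startle_alone=a_sa,
        per_intensity_ppi=per_intensity,
        n_ppi=n_ppi,
        n_startle=n_startle,
        effectiveness=ppi_effectiveness(n_ppi, n_startle),
        animal_id=session.animal_id,
    )


# ---------------------------------------------------------------------------
# TSV interfaces


def session_to_frame(session: StartleSession) -> pd.DataFrame:
    frame = session.schedule.to_frame()
    frame["amplitude"] = session.amplitudes
    return frame


def write_session_tsv(session: StartleSession, path: str | Path) -> None:
    session_to_frame(session).to_csv(path, sep="\t", index=False)


def read_session_tsv(path: str | Path, animal_id: str = "") -> StartleSession:
    """Rebuild a session from its trial-table TSV.

    The originating RNG seed is not stored in the table; the reloaded
    schedule carries ``rng_seed=-1``.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"block", "kind", "isi_s", "amplitude"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"session table missing columns: {sorted(missing)}")

    def to_trial(row: pd.Series) -> Trial:
        db = row.get("prepulse_db")
        db = None if pd.isna(db) else float(db)
        return Trial(TrialKind(row["kind"]), isi_s=float(row["isi_s"]), prepulse_db=db)

    hab = tuple(to_trial(r) for _, r in frame[frame["block"] == "habituation"].iterrows())
    main = tuple(to_trial(r) for _, r in frame[frame["block"] == "main"].iterrows())
    schedule = SessionSchedule(habituation=hab, trials=main, rng_seed=-1)
    amps = np.concatenate(
        [
            frame.loc[frame["block"] == "habituation", "amplitude"].to_numpy(float),
            frame.loc[frame["block"] == "main", "amplitude"].to_numpy(float),
        ]
    )
    return StartleSession(schedule=schedule, amplitudes=amps, animal_id=animal_id)


def scores_to_frame(stats: Sequence[PPIStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {
            "animal_id": s.animal_id,
            "n_ppi": s.n_ppi,
            "n_startle": s.n_startle,
            "effectiveness": s.effectiveness,
        }
        for level, value in sorted(s.per_intensity_ppi.items()):
            row[f"ppi{int(level)}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_tsv(stats: Sequence[PPIStats], path: str | Path) -> None:
    scores_to_frame(stats).to_csv(path, sep="\t", index=False)
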