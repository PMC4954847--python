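"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from ppiconn.behavior import StartleSession, TrialKind
from ppiconn.imaging import build_subject_record
from ppiconn.synth import PhantomDesign, generate_cohort
from ppiconn.tfce import TFCEParams, connectivity_structure

# ---------------------------------------------------------------------------
# oracles


def naive_tfce(values: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Three-loop TFCE reference: thresholds -> components -> member voxels.

    Deliberately naive and independent of the production implementation's
    vectorized accumulation; both signs handled by negation.
    """
    out = np.zeros_like(values, dtype=float)
    structure = connectivity_structure(params.connectivity)
    for sign in (1.0, -1.0):
        v = sign * values
        n_steps = int(np.floor(v.max() / params.dh + 1e-9))
        for k in range(1, n_steps + 1):
            h = k * params.dh
            supra = v >= h - 1e-12
            labels, n_lab = ndimage.label(supra, structure=structure)
            for lab in range(1, n_lab + 1):
                members = np.argwhere(labels == lab)
                increment = (len(members) ** params.E) * (h**params.H) * params.dh
                for i, j, kk in members:
                    out[i, j, kk] += sign * increment
    return out


def brute_force_event_counts(
    session: StartleSession,
    startle_mv_threshold: float = 30.0,
    ppi_pct_threshold: float = 15.0,
) -> tuple[int, int]:
    """Plain-python enumeration of (n_startle, n_ppi) over the main block."""
    startle_alone = [
        amp
        for trial, amp in zip(session.schedule.trials, session.main_amplitudes)
        if trial.kind == TrialKind.STARTLE_ALONE
    ]
    mean_sa = sum(startle_alone) / len(startle_alone)
    n_startle = 0
    n_ppi = 0
    for trial, amp in zip(session.schedule.trials, session.main_amplitudes):
        if trial.kind == TrialKind.STARTLE_ALONE and amp > startle_mv_threshold:
            n_startle += 1
        if trial.kind == TrialKind.PREPULSE_STARTLE:
            ppi = (mean_sa - amp) * 100.0 / mean_sa
            if ppi > ppi_pct_threshold:
                n_ppi += 1
            elif ppi < ppi_pct_threshold:
                n_startle += 1
    return n_startle, n_ppi


def build_records(pairs, truth, masks, fwhm_mm: float = 1.5, effectiveness=None):
    """Normalize a generated cohort into SubjectRecords."""
    eff = truth.covariate if effectiveness is None else effectiveness
    return [
        build_subject_record(animal_id, ppi, bg, masks, eff[i], fwhm_mm=fwhm_mm)
        for i, (animal_id, ppi, bg) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_design() -> PhantomDesign:
    return PhantomDesign(shape=(20, 20, 12), rng_seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    pairs, truth = generate_cohort(small_design)
    return pairs, truth, small_design.mask_set()


@pytest.fixture(scope="session")
def small_records(small_cohort):
    pairs, truth, masks = small_cohort
    return build_records(pairs, truth, masks), truth, masks
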