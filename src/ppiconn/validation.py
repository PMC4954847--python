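"""Calibration and parameter-recovery experiments on phantom cohorts.

These experiments validate the inference machinery against known ground
truth: family-wise error calibration of the max-TFCE permutation test on
null phantoms, and recovery of the embedded networks (Dice overlap, sign
patterns) on effect phantoms.  The test suite and the reproduction script
both run these experiments.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import behavior
from .groupstats import (
    SeedSpec,
    behavior_correlation_map,
    paired_t_map,
    stack_diff_values,
)
from .imaging import build_subject_record
from .synth import (
    PhantomDesign,
    dice_coefficient,
    generate_cohort,
    generate_sessions,
)
from .tfce import TFCEParams, correlation_tfce_null, permutation_null


def _records(design: PhantomDesign, effectiveness=None):
    pairs, truth = generate_cohort(design)
    masks = design.mask_set()
    eff = truth.covariate if effectiveness is None else effectiveness
    records = [
        build_subject_record(animal_id, ppi, bg, masks, eff[i])
        for i, (animal_id, ppi, bg) in enumerate(pairs)
    ]
    return records, truth, masks


def fwer_calibration(
    n_datasets: int = 200,
    shape: tuple[int, int, int] = (16, 16, 10),
    n_subjects: int = 19,
    n_perm: int = 200,
    alpha: float = 0.01,
    rng_seed: int = 0,
    params: TFCEParams = TFCEParams(),
) -> dict:
    """Observed family-wise error rate of the corrected correlation test.

    Each Monte-Carlo dataset is a null phantom (all network effect
    amplitudes zero) with an independent covariate; a dataset counts as a
    false positive when any voxel survives the max-TFCE threshold.  Under a
    valid test the hit fraction should match ``alpha`` up to the
    order-statistic convention and binomial noise.
    """
    root = np.random.SeedSequence(rng_seed)
    children = root.spawn(n_datasets)
    hits = 0
    for d in range(n_datasets):
        child = np.random.default_rng(children[d])
        design = PhantomDesign(
            shape=shape,
            n_subjects=n_subjects,
            effect_amp={"lateral": 0.0, "medial": 0.0, "dmn": 0.0},
            rng_seed=int(child.integers(2**31)),
        )
        records, truth, masks = _records(design)
        X = stack_diff_values(records, masks.brain)
        result = correlation_tfce_null(
            X,
            masks.brain,
            truth.covariate,
            params=params,
            n_perm=n_perm,
            rng_seed=int(child.integers(2**31)),
            alpha=alpha,
        )
        hits += int(result.sig_mask.any())
    return {
        "n_datasets": n_datasets,
        "hits": hits,
        "fwer": hits / n_datasets,
        "alpha": alpha,
        "n_perm": n_perm,
    }


def recovery_experiment(
    design: PhantomDesign | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    alpha: float = 0.01,
    params: TFCEParams = TFCEParams(),
) -> dict:
    """Ground-truth recovery on the default effect phantom.

    Runs the seed-connectivity analysis from the lateral and medial seeds
    with max-TFCE correction and reports the Dice overlap of the significant
    voxels with the true network masks, the mean behavior-correlation r
    inside the lateral/medial networks (expected positive/negative), and the
    mean paired t inside the deactivated network (expected negative).
    """
    design = PhantomDesign(rng_seed=rng_seed) if design is None else design
    records, truth, masks = _records(design)
    out: dict = {"n_subjects": design.n_subjects}

    for net in ("lateral", "medial"):
        seed = SeedSpec(f"{net}_seed", masks.seeds[f"{net}_seed"])
        result = permutation_null(
            records,
            seed,
            masks.brain,
            params=params,
            n_perm=n_perm,
            rng_seed=rng_seed + 1,
            alpha=alpha,
        )
        out[f"dice_{net}"] = dice_coefficient(
            result.sig_mask, truth.network_masks[net]
        )
        out[f"n_sig_{net}"] = int(result.sig_mask.sum())

    r_stat = behavior_correlation_map(records, masks.brain, truth.covariate)
    out["behavior_r_mean_lateral"] = float(
        r_stat.data[truth.network_masks["lateral"]].mean()
    )
    out["behavior_r_mean_medial"] = float(
        r_stat.data[truth.network_masks["medial"]].mean()
    )
    t_stat = paired_t_map(records, masks.brain)
    out["paired_t_mean_dmn"] = float(t_stat.data[truth.network_masks["dmn"]].mean())
    return out


def behavior_linkage_experiment(
    design: PhantomDesign | None = None, rng_seed: int = 0
) -> dict:
    """Spearman rank correlation between scored effectiveness and true covariate."""
    design = (
        PhantomDesign(shape=(16, 16, 10), rng_seed=rng_seed)
        if design is None
        else design
    )
    _, truth = generate_cohort(design)
    sessions = generate_sessions(truth, rng_seed=rng_seed + 1)
    stats = [behavior.score_session(s) for s in sessions]
    eff = [s.effectiveness for s in stats]
    return {
        "spearman": float(sps.spearmanr(eff, truth.covariate).statistic),
        "mean_n_ppi": float(np.mean([s.n_ppi for s in stats])),
        "mean_n_startle": float(np.mean([s.n_startle for s in stats])),
        "mean_effectiveness": float(np.mean(eff)),
    }
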