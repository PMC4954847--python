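"""End-to-end orchestration: scoring → normalization → maps → TFCE inference.

``run_pipeline`` executes the full analysis from a :class:`~ppiconn.config.RunConfig`
and writes NIfTI maps, TSV tables and a JSON run record into the output
directory.  When a ``truth.json`` (as written by the phantom simulator) sits
next to the manifest, a ground-truth recovery report is produced as well.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior import PPIStats, read_session_tsv, score_session, write_scores_tsv
from .config import RunConfig
from .errors import InsufficientSubjectsError, MissingInputError
from .groupstats import (
    SeedSpec,
    StatMap,
    behavior_correlation_map,
    cluster_table,
    paired_t_map,
    save_statmap,
    seed_correlation_map,
    significance_mask,
    uncorrected_threshold,
)
from .imaging import (
    MaskSet,
    SubjectRecord,
    VolumeImage,
    build_subject_record,
    load_mask,
    load_volume,
    read_manifest,
    save_volume,
)
from .synth import dice_coefficient
from .tfce import TFCEResult, paired_sign_flip_null, permutation_null

log = logging.getLogger("ppiconn")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage stream derived from the single config seed."""
    entropy = [root_seed] + [ord(c) for c in stage]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def load_subjects(config: RunConfig) -> tuple[list[SubjectRecord], MaskSet, list[PPIStats]]:
    """Resolve the manifest into scored, normalized subject records."""
    manifest = read_manifest(config.manifest)
    if len(manifest) < 2:
        raise InsufficientSubjectsError(
            f"insufficient subjects: need at least 2, manifest lists {len(manifest)}"
        )
    base = Path(config.manifest).parent

    brain = load_mask(config.brain_mask)
    reference = load_mask(config.reference_mask)
    seeds = {name: load_mask(path) for name, path in config.seed_masks.items()}
    masks = MaskSet(brain=brain, reference=reference, seeds=seeds)
    log.info(
        "masks: %d brain voxels, %d reference voxels, %d seeds",
        int(brain.sum()), int(reference.sum()), len(seeds),
    )

    subjects: list[SubjectRecord] = []
    stats: list[PPIStats] = []
    for _, row in manifest.iterrows():
        animal_id = str(row["animal_id"])
        if "session_path" in manifest.columns and pd.notna(row.get("session_path")):
            session = read_session_tsv(base / str(row["session_path"]), animal_id)
            st = score_session(
                session, config.startle_mv_threshold, config.ppi_pct_threshold
            )
            effectiveness = st.effectiveness
            stats.append(st)
            log.info(
                "scored %s: n_ppi=%d n_startle=%d effectiveness=%.1f%%",
                animal_id, st.n_ppi, st.n_startle, st.effectiveness,
            )
        elif "effectiveness" in manifest.columns and pd.notna(row.get("effectiveness")):
            effectiveness = float(row["effectiveness"])
        else:
            raise MissingInputError(
                f"subject {animal_id}: neither session_path nor effectiveness given"
            )
        raw_ppi = load_volume(base / str(row["ppi_path"]))
        raw_bg = load_volume(base / str(row["background_path"]))
        subjects.append(
            build_subject_record(
                animal_id,
                raw_ppi,
                raw_bg,
                masks,
                effectiveness,
                fwhm_mm=config.fwhm_mm,
                smooth_diff=True,
                sign_convention=config.sign_convention,
                strain=str(row["strain"]) if "strain" in manifest.columns and pd.notna(row.get("strain")) else None,
            )
        )
    return subjects, masks, stats


def _write_map_outputs(
    out_dir: Path,
    name: str,
    stat: StatMap,
    tfce_result: TFCEResult | None,
    config: RunConfig,
    voxel_size_mm: tuple[float, float, float],
    space_tag: str,
) -> dict:
    """Write a statistic map, its uncorrected mask, cluster table and TFCE outputs."""
    save_statmap(stat, out_dir / f"{name}.nii.gz", voxel_size_mm, space_tag)
    unc_thr = uncorrected_threshold(stat, config.alpha_uncorrected)
    unc_mask = significance_mask(stat, config.alpha_uncorrected)
    save_volume(
        VolumeImage(unc_mask.astype(float), voxel_size_mm, space_tag),
        out_dir / f"{name}_uncorrected_mask.nii.gz",
    )
    cluster_table(stat, unc_thr, voxel_size_mm, config.connectivity).to_csv(
        out_dir / f"{name}_clusters.tsv", sep="\t", index=False
    )
    record: dict = {
        "kind": stat.kind,
        "n": stat.n,
        "df": stat.df,
        "uncorrected_threshold": unc_thr,
        "n_uncorrected_voxels": int(unc_mask.sum()),
        "n_zero_variance": stat.info.get("n_zero_variance", 0),
    }
    if tfce_result is not None:
        save_volume(
            VolumeImage(tfce_result.enhanced, voxel_size_mm, space_tag),
            out_dir / f"{name}_tfce.nii.gz",
        )
        save_volume(
            VolumeImage(tfce_result.sig_mask.astype(float), voxel_size_mm, space_tag),
            out_dir / f"{name}_tfce_sig_mask.nii.gz",
        )
        pd.DataFrame({"max_tfce": tfce_result.null_max}).to_csv(
            out_dir / f"{name}_tfce_null.tsv", sep="\t", index=False
        )
        record.update(
            {
                "tfce_threshold": tfce_result.threshold,
                "tfce_n_perm": tfce_result.n_perm,
                "tfce_alpha": tfce_result.alpha,
                "n_tfce_sig_voxels": int(tfce_result.sig_mask.sum()),
            }
        )
    return record


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the output directory.

    Stages: behavioral scoring → ratio normalization and difference images →
    paired t-map (sign-flip TFCE) → behavior-correlation map (permutation
    TFCE) → one seed-correlation map with permutation TFCE per configured
    seed.  Reruns with the same config and seed are bit-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    subjects, masks, stats = load_subjects(config)
    n = len(subjects)
    ref = subjects[0].diff
    vs, tag = ref.voxel_size_mm, ref.space_tag
    if stats:
        write_scores_tsv(stats, out_dir / "scores.tsv")

    params = config.tfce_params
    maps_record: dict[str, dict] = {}

    log.info("paired t-test over %d subjects", n)
    t_stat = paired_t_map(subjects, masks.brain, use_smoothed_diff=config.ttest_on_smoothed)
    t_tfce = paired_sign_flip_null(
        subjects,
        masks.brain,
        params,
        n_perm=config.n_perm,
        rng_seed=_stage_seed(config.rng_seed, "tfce_paired"),
        alpha=config.alpha_corrected,
        use_smoothed_diff=config.ttest_on_smoothed,
    )
    maps_record["paired_t"] = _write_map_outputs(
        out_dir, "paired_t", t_stat, t_tfce, config, vs, tag
    )

    log.info("behavior correlation map")
    covariate = np.array([rec.effectiveness for rec in subjects])
    b_stat = behavior_correlation_map(subjects, masks.brain, covariate)
    b_tfce = permutation_null(
        subjects,
        covariate,
        masks.brain,
        params,
        n_perm=config.n_perm,
        rng_seed=_stage_seed(config.rng_seed, "tfce_behavior"),
        alpha=config.alpha_corrected,
    )
    maps_record["behavior_r"] = _write_map_outputs(
        out_dir, "behavior_r", b_stat, b_tfce, config, vs, tag
    )

    for name in sorted(masks.seeds):
        log.info("seed correlation map: %s", name)
        seed = SeedSpec(name=name, mask=masks.seeds[name])
        s_stat = seed_correlation_map(
            subjects, masks.brain, seed, smoothed_seed=config.smooth_seed_extract
        )
        s_tfce = permutation_null(
            subjects,
            seed,
            masks.brain,
            params,
            n_perm=config.n_perm,
            rng_seed=_stage_seed(config.rng_seed, f"tfce_seed_{name}"),
            alpha=config.alpha_corrected,
        )
        maps_record[f"seed_{name}_r"] = _write_map_outputs(
            out_dir, f"seed_{name}_r", s_stat, s_tfce, config, vs, tag
        )

    run_record = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "n_subjects": n,
        "n_brain_voxels": int(masks.brain.sum()),
        "maps": maps_record,
    }
    (out_dir / "run_record.json").write_text(json.dumps(run_record, indent=2, sort_keys=True))

    truth_path = Path(config.manifest).parent / "truth.json"
    if truth_path.exists():
        report = recovery_report(out_dir, truth_path)
        (out_dir / "recovery.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        log.info("ground-truth recovery report written")
    return out_dir


def recovery_report(run_dir: str | Path, truth_path: str | Path) -> dict:
    """Compare pipeline significance masks against phantom ground truth.

    Reports, per network with a matching seed map, the Dice overlap of the
    TFCE-significant voxels with the true network mask, plus the sign checks:
    behavior correlation positive in lateral / negative in medial regions and
    paired-t negative in the deactivated network.
    """
    run_dir = Path(run_dir)
    truth_path = Path(truth_path)
    truth = json.loads(truth_path.read_text())
    base = truth_path.parent

    networks = {
        net: load_mask(base / rel) for net, rel in truth["network_masks"].items()
    }
    report: dict = {"dice": {}, "signs": {}}
    for net, mask in networks.items():
        sig_path = run_dir / f"seed_{net}_seed_r_tfce_sig_mask.nii.gz"
        if sig_path.exists():
            sig = load_volume(sig_path).data > 0.5
            report["dice"][net] = dice_coefficient(sig, mask)

    behavior_map = run_dir / "behavior_r.nii.gz"
    paired_map = run_dir / "paired_t.nii.gz"
    if behavior_map.exists():
        r = load_volume(behavior_map).data
        report["signs"]["behavior_r_mean_lateral"] = float(r[networks["lateral"]].mean())
        report["signs"]["behavior_r_mean_medial"] = float(r[networks["medial"]].mean())
    if paired_map.exists():
        t = load_volume(paired_map).data
        report["signs"]["paired_t_mean_dmn"] = float(t[networks["dmn"]].mean())
    return report
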