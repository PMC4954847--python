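"""Phantom cohorts with known ground truth for end-to-end pipeline validation.

The generator emulates the study design the pipeline targets: a cohort
(default 19 subjects) with one task ("ppi") and one control ("background")
uptake volume each on a small common grid, plus matched synthetic startle
sessions.  Three voxel networks are embedded:

* a **lateral** network whose task activation covaries positively with the
  behavioral covariate,
* a **medial** network covarying negatively with it, and
* a **dmn** network deactivated during the task (task − control negative).

Each network's regions share one per-subject latent factor, producing the
inter-subject covariance that seed-based correlation should recover; the
reference region carries no condition effect, so ratio normalization to it is
exact by construction.  Subject-level global intensity scaling emulates dose
and body-weight differences and must cancel under ratio normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior
from .behavior import SessionSchedule, StartleSession, TrialKind, build_schedule
from .imaging import (
    DEFAULT_VOXEL_SIZE_MM,
    MaskSet,
    VolumeImage,
    save_mask,
    save_volume,
    write_manifest,
)

NETWORKS = ("lateral", "medial", "dmn")

#: name -> ((x0,x1),(y0,y1),(z0,z1), network) on the default 40x40x24 grid.
#: Blocks are 9x9x6; the in-plane smoothing halo (~2 voxels at 1.5 mm FWHM /
#: 0.38 mm voxels) is then small relative to each region.
_DEFAULT_REGIONS: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int], str]] = {
    "reference":    ((4, 13),  (4, 13),  (4, 10),  "none"),
    "null_b":       ((15, 24), (4, 13),  (4, 10),  "none"),
    "lateral_seed": ((26, 35), (4, 13),  (4, 10),  "lateral"),
    "medial_seed":  ((4, 13),  (15, 24), (4, 10),  "medial"),
    "dmn_a":        ((15, 24), (15, 24), (4, 10),  "dmn"),
    "lateral_a":    ((26, 35), (15, 24), (4, 10),  "lateral"),
    "null_a":       ((4, 13),  (4, 13),  (12, 18), "none"),
    "dmn_seed":     ((15, 24), (4, 13),  (12, 18), "dmn"),
    "medial_b":     ((4, 13),  (15, 24), (12, 18), "medial"),
    "medial_a":     ((15, 24), (15, 24), (12, 18), "medial"),
    "lateral_b":    ((26, 35), (15, 24), (12, 18), "lateral"),
}


def _scaled_bounds(
    bounds: tuple[int, int], default_extent: int, extent: int
) -> tuple[int, int]:
    lo = int(round(bounds[0] * extent / default_extent))
    hi = int(round(bounds[1] * extent / default_extent))
    return lo, max(hi, lo + 1)


@dataclass(frozen=True)
class PhantomDesign:
    """Geometry, effect sizes and noise levels of a phantom cohort.

    Amplitudes are in raw uptake units against a baseline of ``baseline``;
    ``noise_sd`` is i.i.d. voxel noise, ``baseline_sd`` the s.d. of the
    log global per-subject scale factor.  ``subject_factor_weight`` sets how
    strongly the standard-normal network factors modulate the regional
    effect; ``covariate_noise_sd`` the behavioral covariate's residual noise.
    Region blocks scale with the grid; ``region_shape="ellipsoid"`` inscribes
    ellipsoids into the blocks for smoothness experiments.
    """

    shape: tuple[int, int, int] = (40, 40, 24)
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    n_subjects: int = 19
    baseline: float = 100.0
    noise_sd: float = 2.0
    baseline_sd: float = 0.15
    effect_amp: Mapping[str, float] = field(
        default_factory=lambda: {"lateral": 8.0, "medial": 8.0, "dmn": 8.0}
    )
    subject_factor_weight: float = 0.5
    covariate_noise_sd: float = 0.4
    region_shape: str = "block"
    rng_seed: int = 0
    space_tag: str = "phantom"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if any(s < 10 for s in self.shape):
            raise ValueError("phantom grid must be at least 10 voxels per axis")
        if self.region_shape not in ("block", "ellipsoid"):
            raise ValueError("region_shape must be 'block' or 'ellipsoid'")
        if any(a < 0 for a in self.effect_amp.values()):
            raise ValueError("effect amplitudes must be non-negative")
        regions = self.regions()
        total = np.zeros(self.shape, dtype=int)
        for mask in regions.values():
            total += mask
        if total.max() > 1:
            raise ValueError("phantom regions overlap")

    def brain_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        sl = []
        for ax, default in zip(self.shape, (40, 40, 24)):
            lo, hi = _scaled_bounds((4, 36) if default != 24 else (3, 21), default, ax)
            sl.append(slice(lo, hi))
        mask[tuple(sl)] = True
        return mask

    def regions(self) -> dict[str, np.ndarray]:
        out = {}
        for name, (bx, by, bz, _net) in _DEFAULT_REGIONS.items():
            (x0, x1) = _scaled_bounds(bx, 40, self.shape[0])
            (y0, y1) = _scaled_bounds(by, 40, self.shape[1])
            (z0, z1) = _scaled_bounds(bz, 24, self.shape[2])
            mask = np.zeros(self.shape, dtype=bool)
            if self.region_shape == "block":
                mask[x0:x1, y0:y1, z0:z1] = True
            else:
                cx, cy, cz = (x0 + x1 - 1) / 2, (y0 + y1 - 1) / 2, (z0 + z1 - 1) / 2
                rx, ry, rz = (x1 - x0) / 2, (y1 - y0) / 2, (z1 - z0) / 2
                ix, iy, iz = np.ogrid[: self.shape[0], : self.shape[1], : self.shape[2]]
                mask = (
                    ((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2
                ) <= 1.0
            out[name] = mask
        return out

    @property
    def network_assignments(self) -> dict[str, str]:
        return {name: net for name, (_, _, _, net) in _DEFAULT_REGIONS.items()}

    def network_masks(self) -> dict[str, np.ndarray]:
        regions = self.regions()
        out = {}
        for net in NETWORKS:
            mask = np.zeros(self.shape, dtype=bool)
            for name, assigned in self.network_assignments.items():
                if assigned == net:
                    mask |= regions[name]
            out[net] = mask
        return out

    def mask_set(self) -> MaskSet:
        regions = self.regions()
        return MaskSet(
            brain=self.brain_mask(),
            reference=regions["reference"],
            seeds={
                name: regions[name]
                for name in ("lateral_seed", "medial_seed", "dmn_seed")
            },
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-subject latent factors, the true covariate, and true network masks."""

    lateral_k: np.ndarray
    medial_k: np.ndarray
    dmn_k: np.ndarray
    covariate: np.ndarray
    subject_scales: np.ndarray
    network_masks: Mapping[str, np.ndarray]
    design: PhantomDesign

    @property
    def n_subjects(self) -> int:
        return len(self.covariate)


def generate_cohort(
    design: PhantomDesign,
) -> tuple[list[tuple[str, VolumeImage, VolumeImage]], GroundTruth]:
    """Draw a phantom cohort of raw (task, control) volume pairs.

    The control image is ``scale_s * (baseline + noise)`` inside the brain;
    the task image additionally adds, in each network region,
    ``±effect_amp * (1 + w * k)`` with k the subject's network factor (the
    minus sign applies to the deactivated "dmn" network).  The reference
    region belongs to no network, hence receives no condition effect.  The
    true covariate is ``(lateral_k − medial_k)/√2`` plus noise, so it
    correlates positively with the lateral and negatively with the medial
    factor by construction.  The same seed reproduces the identical cohort.
    """
    rng = np.random.default_rng(design.rng_seed)
    n = design.n_subjects
    factors = {net: rng.standard_normal(n) for net in NETWORKS}
    covariate = (factors["lateral"] - factors["medial"]) / np.sqrt(2.0)
    covariate = covariate + design.covariate_noise_sd * rng.standard_normal(n)
    scales = np.exp(design.baseline_sd * rng.standard_normal(n))

    brain = design.brain_mask()
    regions = design.regions()
    assignments = design.network_assignments
    pattern = np.where(brain, design.baseline, 0.0)

    pairs = []
    for s in range(n):
        effect = np.zeros(design.shape)
        for name, net in assignments.items():
            if net == "none":
                continue
            sign = -1.0 if net == "dmn" else 1.0
            amp = design.effect_amp.get(net, 0.0)
            effect[regions[name]] += sign * amp * (
                1.0 + design.subject_factor_weight * factors[net][s]
            )
        noise_bg = design.noise_sd * rng.standard_normal(design.shape) * brain
        noise_ppi = design.noise_sd * rng.standard_normal(design.shape) * brain
        bg = VolumeImage(
            scales[s] * (pattern + noise_bg), design.voxel_size_mm, design.space_tag
        )
        ppi = VolumeImage(
            scales[s] * (pattern + effect * brain + noise_ppi),
            design.voxel_size_mm,
            design.space_tag,
        )
        pairs.append((f"rat{s + 1:02d}", ppi, bg))

    truth = GroundTruth(
        lateral_k=factors["lateral"],
        medial_k=factors["medial"],
        dmn_k=factors["dmn"],
        covariate=covariate,
        subject_scales=scales,
        network_masks=design.network_masks(),
        design=design,
    )
    return pairs, truth


def generate_sessions(
    truth: GroundTruth,
    trials_per_type: int = 30,
    prepulse_levels: Sequence[float] = behavior.STANDARD_PREPULSE_LEVELS_DB,
    habituation_n: int = 25,
    isi_range_s: tuple[float, float] = (3.0, 13.0),
    rng_seed: int = 0,
    attenuation_prob: float | None = None,
    suppression: float | tuple[float, float] = (0.4, 0.9),
    base_prob: float = 0.1,
    prob_gain: float = 0.8,
    startle_median_mv: float = 60.0,
    startle_sigma: float = 0.3,
    residual_f_sd: float = 0.05,
    motor_noise_mv: float = 2.0,
) -> list[StartleSession]:
    """Draw startle sessions whose scored effectiveness tracks the true covariate.

    Startle-alone amplitudes are lognormal (median ``startle_median_mv``).
    On each prepulse+startle trial the prepulse takes effect with a
    probability increasing in the subject's standardized true covariate
    (``base_prob + prob_gain·Φ(z)`` unless overridden by
    ``attenuation_prob``); effective prepulses suppress the response by a
    fraction drawn from ``suppression`` (a scalar means fixed suppression,
    1.0 full), ineffective ones leave near-zero inhibition.  Scored PPI
    effectiveness is then rank-correlated with the true covariate across the
    cohort.
    """
    n = truth.n_subjects
    cov = np.asarray(truth.covariate, dtype=float)
    sd = cov.std()
    z = (cov - cov.mean()) / sd if sd > 0 else np.zeros(n)

    root = np.random.SeedSequence(rng_seed)
    children = root.spawn(n)
    sessions = []
    for s in range(n):
        rng = np.random.default_rng(children[s])
        p_eff = (
            attenuation_prob
            if attenuation_prob is not None
            else float(np.clip(base_prob + prob_gain * stats.norm.cdf(z[s]), 0.0, 1.0))
        )
        schedule = build_schedule(
            trials_per_type=trials_per_type,
            prepulse_levels=prepulse_levels,
            habituation_n=habituation_n,
            isi_range_s=isi_range_s,
            rng_seed=int(rng.integers(2**31)),
        )

        def startle_amp() -> float:
            return float(
                np.exp(np.log(startle_median_mv) + startle_sigma * rng.standard_normal())
            )

        amps = []
        for trial in schedule.all_trials:
            if trial.kind == TrialKind.STARTLE_ALONE:
                amps.append(startle_amp())
            elif trial.kind == TrialKind.PREPULSE_STARTLE:
                if rng.random() < p_eff:
                    if np.isscalar(suppression):
                        f = float(suppression)
                    else:
                        f = float(rng.uniform(*suppression))
                else:
                    f = float(np.clip(rng.normal(0.0, residual_f_sd), 0.0, 1.0))
                amps.append(startle_amp() * (1.0 - f))
            else:
                amps.append(abs(rng.normal(0.0, motor_noise_mv)))
        sessions.append(
            StartleSession(
                schedule=schedule,
                amplitudes=np.asarray(amps),
                animal_id=f"rat{s + 1:02d}",
            )
        )
    return sessions


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / total


def write_cohort(
    out_dir: str | Path,
    design: PhantomDesign,
    session_seed: int | None = None,
) -> Path:
    """Simulate a cohort and write it as a self-contained run-input directory.

    Layout: ``volumes/`` raw NIfTI pairs, ``masks/`` brain/reference/seed and
    true-network masks, ``sessions/`` per-animal trial TSVs, ``manifest.tsv``
    and ``truth.json`` at the root.
    """
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    (out_dir / "sessions").mkdir(exist_ok=True)

    pairs, truth = generate_cohort(design)
    sessions = generate_sessions(
        truth, rng_seed=design.rng_seed + 1 if session_seed is None else session_seed
    )

    masks = design.mask_set()
    vs = design.voxel_size_mm
    save_mask(masks.brain, vs, out_dir / "masks" / "brain.nii.gz")
    save_mask(masks.reference, vs, out_dir / "masks" / "reference.nii.gz")
    for name, seed in masks.seeds.items():
        save_mask(seed, vs, out_dir / "masks" / f"seed_{name}.nii.gz")
    for net, mask in truth.network_masks.items():
        save_mask(mask, vs, out_dir / "masks" / f"network_{net}.nii.gz")

    rows = []
    for (animal_id, ppi, bg), session in zip(pairs, sessions):
        ppi_path = out_dir / "volumes" / f"{animal_id}_ppi.nii.gz"
        bg_path = out_dir / "volumes" / f"{animal_id}_background.nii.gz"
        session_path = out_dir / "sessions" / f"{animal_id}.tsv"
        save_volume(ppi, ppi_path)
        save_volume(bg, bg_path)
        behavior.write_session_tsv(session, session_path)
        rows.append(
            {
                "animal_id": animal_id,
                "ppi_path": str(ppi_path.relative_to(out_dir)),
                "background_path": str(bg_path.relative_to(out_dir)),
                "session_path": str(session_path.relative_to(out_dir)),
            }
        )
    write_manifest(pd.DataFrame(rows), out_dir / "manifest.tsv")

    truth_record = {
        "lateral_k": truth.lateral_k.tolist(),
        "medial_k": truth.medial_k.tolist(),
        "dmn_k": truth.dmn_k.tolist(),
        "covariate": truth.covariate.tolist(),
        "subject_scales": truth.subject_scales.tolist(),
        "network_masks": {
            net: f"masks/network_{net}.nii.gz" for net in truth.network_masks
        },
        "design": {
            "shape": list(design.shape),
            "voxel_size_mm": list(design.voxel_size_mm),
            "n_subjects": design.n_subjects,
            "baseline": design.baseline,
            "noise_sd": design.noise_sd,
            "baseline_sd": design.baseline_sd,
            "effect_amp": dict(design.effect_amp),
            "subject_factor_weight": design.subject_factor_weight,
            "covariate_noise_sd": design.covariate_noise_sd,
            "region_shape": design.region_shape,
            "rng_seed": design.rng_seed,
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_record, indent=2))
    return out_dir
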