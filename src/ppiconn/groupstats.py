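"""Voxelwise group statistics across subjects: paired t, behavior and seed correlations.

All maps are computed over a brain mask from per-subject condition pairs or
difference images.  Because FDG-PET yields one cumulative uptake value per
voxel per session, "connectivity" here is across-subject covariance: a seed
region's difference value is correlated with every brain voxel over the
cohort (metabolic connectivity), and the behavioral covariate (PPI
effectiveness) is correlated the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InsufficientSubjectsError, UndefinedStatisticError
from .imaging import SubjectRecord, VolumeImage, difference_image, save_volume


@dataclass(frozen=True)
class StatMap:
    """Per-voxel statistic over the brain mask.

    ``kind`` is ``"t"`` (df = n−1 paired, or n−2 for a correlation t) or
    ``"r"`` (Pearson, bounded in [−1, 1]).  ``data`` is a full 3D array with
    zeros outside the mask; ``info`` carries QC counts and provenance.
    """

    kind: str
    data: np.ndarray
    mask: np.ndarray
    n: int
    df: int
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("t", "r"):
            raise ValueError(f"unknown statistic kind: {self.kind!r}")
        if self.kind == "r":
            inside = self.data[self.mask]
            if inside.size and (inside.min() < -1.0 - 1e-12 or inside.max() > 1.0 + 1e-12):
                raise ValueError("r-map values outside [-1, 1]")

    @property
    def values(self) -> np.ndarray:
        """Statistic values restricted to the mask (1D)."""
        return self.data[self.mask]


@dataclass(frozen=True)
class SeedSpec:
    """A named seed mask with an optional expected-role annotation."""

    name: str
    mask: np.ndarray
    expected_role: str = "none"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"seed {self.name!r} is empty")
        object.__setattr__(self, "mask", mask)


def stack_diff_values(
    subjects: Sequence[SubjectRecord], mask: np.ndarray, smoothed: bool = True
) -> np.ndarray:
    """(n_subjects, n_voxels) matrix of difference values inside the mask.

    ``smoothed=True`` reads the stored (smoothed) difference image;
    ``smoothed=False`` recomputes the raw normalized-pair difference, which is
    what the paired t-test uses.
    """
    rows = []
    for rec in subjects:
        if smoothed:
            vol = rec.diff
        else:
            vol = difference_image(rec.ppi_norm, rec.background_norm)
        rows.append(vol.data[mask])
    return np.asarray(rows, dtype=float)


def paired_t_map(
    subjects: Sequence[SubjectRecord],
    mask: np.ndarray,
    use_smoothed_diff: bool = False,
) -> StatMap:
    """Paired t-test per voxel on the task-vs-control pairs.

    t = mean(d) / (sd(d)/√n) with d the per-subject difference; positive t
    means higher normalized uptake during the task condition.  Voxels whose
    difference is identical across subjects get t = 0 and are counted in
    ``info["n_zero_variance"]`` rather than returned as NaN.  By default the
    test runs on the unsmoothed normalized pairs.
    """
    n = len(subjects)
    if n < 2:
        raise InsufficientSubjectsError(f"paired t-test needs n >= 2, got {n}")
    mask = np.asarray(mask, dtype=bool)
    d = stack_diff_values(subjects, mask, smoothed=use_smoothed_diff)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var] = 0.0
    data = np.zeros(mask.shape)
    data[mask] = t
    return StatMap(
        kind="t",
        data=data,
        mask=mask,
        n=n,
        df=n - 1,
        info={"contrast": "paired_t", "n_zero_variance": int(zero_var.sum())},
    )


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Columnwise Pearson r between X (n, V) and y (n,); zero-variance -> r=0."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    x_ss = np.einsum("ij,ij->j", Xc, Xc)
    denom = np.sqrt(y_ss * x_ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ Xc) / denom
    zero = denom == 0
    r[zero] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return r, int((x_ss == 0).sum())


def correlation_map(
    subjects: Sequence[SubjectRecord],
    mask: np.ndarray,
    covariate: np.ndarray,
    label: str = "covariate",
) -> StatMap:
    """Across-subject Pearson r between difference images and a covariate."""
    n = len(subjects)
    if n < 3:
        raise InsufficientSubjectsError(f"correlation map needs n >= 3, got {n}")
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (n,):
        raise ValueError("covariate length must equal the number of subjects")
    if np.ptp(covariate) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant covariate")
    mask = np.asarray(mask, dtype=bool)
    X = stack_diff_values(subjects, mask, smoothed=True)
    r, n_zero = _pearson_rows(X, covariate)
    data = np.zeros(mask.shape)
    data[mask] = r
    return StatMap(
        kind="r",
        data=data,
        mask=mask,
        n=n,
        df=n - 2,
        info={"covariate": label, "n_zero_variance": n_zero},
    )


def behavior_correlation_map(
    subjects: Sequence[SubjectRecord],
    mask: np.ndarray,
    covariate: np.ndarray | None = None,
) -> StatMap:
    """Correlate difference images with PPI effectiveness (or a given covariate)."""
    if covariate is None:
        covariate = np.array([rec.effectiveness for rec in subjects], dtype=float)
    return correlation_map(subjects, mask, covariate, label="ppi_effectiveness")


def seed_extract(
    record: SubjectRecord, seed: SeedSpec | np.ndarray, smoothed: bool = True
) -> float:
    """Mean of the subject's (smoothed) difference image over the seed mask."""
    mask = seed.mask if isinstance(seed, SeedSpec) else np.asarray(seed, dtype=bool)
    if not mask.any():
        raise ValueError("seed mask is empty")
    vol = record.diff if smoothed else difference_image(
        record.ppi_norm, record.background_norm
    )
    return float(vol.data[mask].mean())


def seed_correlation_map(
    subjects: Sequence[SubjectRecord],
    mask: np.ndarray,
    seed: SeedSpec,
    smoothed_seed: bool = True,
) -> StatMap:
    """Metabolic connectivity: correlate each voxel with the seed-mean value.

    Voxels inside the seed itself are retained in the map but flagged through
    ``info["seed_name"]`` / the seed mask, since their correlation is partly
    self-correlation.
    """
    covariate = np.array(
        [seed_extract(rec, seed, smoothed=smoothed_seed) for rec in subjects]
    )
    stat = correlation_map(subjects, mask, covariate, label=f"seed:{seed.name}")
    stat.info["seed_name"] = seed.name
    stat.info["seed_voxels"] = int(seed.mask.sum())
    return stat


def r_to_t(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Companion t statistic for a Pearson r at sample size n (df = n−2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0 + 1e-15, 1.0 - 1e-15)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(t) if t.ndim == 0 else t


def t_map_from_r(stat: StatMap) -> StatMap:
    """Convert an r-map to its companion t-map (used for TFCE enhancement)."""
    if stat.kind != "r":
        raise ValueError("expected an r-map")
    data = np.zeros(stat.mask.shape)
    data[stat.mask] = r_to_t(stat.values, stat.n)
    return StatMap(
        kind="t", data=data, mask=stat.mask, n=stat.n, df=stat.df, info=dict(stat.info)
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| at significance alpha for sample size n.

    From the exact relation t = r√(n−2)/√(1−r²): with t* the two-sided
    t(n−2) critical value, |r|* = t*/√(n−2+t*²).  At n=19, alpha=0.05 this is
    ≈0.4555, i.e. the familiar |r| > 0.45 display threshold.
    """
    if n < 3:
        raise InsufficientSubjectsError("critical r requires n >= 3")
    t_crit = stats.t.isf(alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def uncorrected_threshold(stat: StatMap, alpha: float = 0.05) -> float:
    """Two-sided uncorrected threshold on |statistic| at significance alpha."""
    if stat.kind == "r":
        return critical_r(stat.n, alpha)
    return float(stats.t.isf(alpha / 2.0, stat.df))


def significance_mask(stat: StatMap, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of voxels exceeding the two-sided uncorrected threshold."""
    thr = uncorrected_threshold(stat, alpha)
    return (np.abs(stat.data) > thr) & stat.mask


def cluster_table(
    stat: StatMap,
    threshold: float,
    voxel_size_mm: tuple[float, float, float],
    connectivity: int = 26,
) -> pd.DataFrame:
    """Suprathreshold clusters (both signs) with peak location, value, extent.

    Peak coordinates are voxel indices scaled by voxel size (mm in the
    common space; no atlas labeling is attempted).
    """
    from .tfce import connectivity_structure

    structure = connectivity_structure(connectivity)
    rows = []
    for sign in (1.0, -1.0):
        supra = (sign * stat.data > threshold) & stat.mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            member = labels == lab
            vals = sign * stat.data * member
            peak = np.unravel_index(np.argmax(vals), vals.shape)
            rows.append(
                {
                    "x_mm": peak[0] * voxel_size_mm[0],
                    "y_mm": peak[1] * voxel_size_mm[1],
                    "z_mm": peak[2] * voxel_size_mm[2],
                    "stat": float(sign * vals.max()),
                    "extent_voxels": int(member.sum()),
                }
            )
    frame = pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "stat", "extent_voxels"])
    return frame.sort_values("stat", ascending=False, key=abs).reset_index(drop=True) if len(frame) else frame


def save_statmap(
    stat: StatMap,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float],
    space_tag: str = "common",
) -> None:
    """Write the map as NIfTI plus a JSON sidecar with kind, n, df and QC info."""
    path = Path(path)
    save_volume(VolumeImage(stat.data, voxel_size_mm, space_tag), path)
    sidecar = {"kind": stat.kind, "n": stat.n, "df": stat.df}
    sidecar.update(
        {k: v for k, v in stat.info.items() if isinstance(v, (str, int, float, bool))}
    )
    base = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    sidecar_path = path.with_name(base + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
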