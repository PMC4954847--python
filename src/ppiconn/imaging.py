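"""Volume containers, reference-region ratio normalization, difference images.

Volumes are assumed pre-registered to a common space: the pipeline verifies
shape, voxel size and space tag and refuses mismatches — no registration is
performed here.  Uptake images are intensity-normalized by dividing every
voxel by the mean uptake of a reference region whose activity is expected to
be condition-independent (in the rat paradigm, the olfactory bulb), which
cancels global scaling from injected dose and body weight.  The
intra-individual difference image (task minus control) then removes each
subject's baseline metabolic pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError, MissingInputError, UndefinedStatisticError

#: sigma = FWHM * FWHM_TO_SIGMA for a Gaussian kernel.
FWHM_TO_SIGMA: float = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Default scanner-reconstruction voxel size in mm.
DEFAULT_VOXEL_SIZE_MM: tuple[float, float, float] = (0.38, 0.38, 0.82)


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar grid with voxel spacing (mm) and a registration-space tag."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    space_tag: str = "common"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be three positive numbers")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(data, self.voxel_size_mm, self.space_tag)


def ensure_same_grid(*volumes: VolumeImage) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    ref = volumes[0]
    for vol in volumes[1:]:
        if vol.shape != ref.shape:
            raise GridMismatchError(f"shape mismatch: {vol.shape} vs {ref.shape}")
        if not np.allclose(vol.voxel_size_mm, ref.voxel_size_mm):
            raise GridMismatchError(
                f"voxel size mismatch: {vol.voxel_size_mm} vs {ref.voxel_size_mm}"
            )
        if vol.space_tag != ref.space_tag:
            raise GridMismatchError(
                f"space tag mismatch: {vol.space_tag!r} vs {ref.space_tag!r}"
            )


@dataclass(frozen=True)
class MaskSet:
    """Brain mask, reference-region mask, and named seed masks on one grid."""

    brain: np.ndarray
    reference: np.ndarray
    seeds: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        brain = np.asarray(self.brain, dtype=bool)
        reference = np.asarray(self.reference, dtype=bool)
        if reference.shape != brain.shape:
            raise GridMismatchError("reference mask shape differs from brain mask")
        if not brain.any():
            raise ValueError("brain mask is empty")
        if not reference.any():
            raise ValueError("reference mask is empty")
        if np.any(reference & ~brain):
            raise ValueError("reference mask extends outside the brain mask")
        seeds = {}
        for name, seed in dict(self.seeds).items():
            seed = np.asarray(seed, dtype=bool)
            if seed.shape != brain.shape:
                raise GridMismatchError(f"seed {name!r} shape differs from brain mask")
            if not seed.any():
                raise ValueError(f"seed {name!r} is empty")
            if np.any(seed & ~brain):
                raise ValueError(f"seed {name!r} extends outside the brain mask")
            seeds[name] = seed
        object.__setattr__(self, "brain", brain)
        object.__setattr__(self, "reference", reference)
        object.__setattr__(self, "seeds", seeds)


@dataclass(frozen=True)
class SubjectRecord:
    """One animal's normalized condition pair, difference image and behavior score."""

    animal_id: str
    ppi_norm: VolumeImage
    background_norm: VolumeImage
    diff: VolumeImage
    effectiveness: float
    strain: str | None = None

    def __post_init__(self) -> None:
        ensure_same_grid(self.ppi_norm, self.background_norm, self.diff)


def ratio_normalize(vol: VolumeImage, reference: np.ndarray) -> VolumeImage:
    """Divide every voxel by the mean uptake over the reference region.

    The output's mean over the reference mask is exactly 1, which puts all
    subjects and conditions on a common intensity scale.
    """
    reference = np.asarray(reference, dtype=bool)
    if reference.shape != vol.shape:
        raise GridMismatchError("reference mask shape differs from volume")
    if not reference.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(vol.data[reference].mean())
    if ref_mean <= 0:
        raise UndefinedStatisticError(
            f"cannot normalize: reference-region mean is {ref_mean:g}"
        )
    return vol.with_data(vol.data / ref_mean)


def difference_image(a: VolumeImage, b: VolumeImage) -> VolumeImage:
    """Voxelwise a − b (task minus control for intra-individual differences)."""
    ensure_same_grid(a, b)
    return a.with_data(a.data - b.data)


def gaussian_smooth(
    vol: VolumeImage, fwhm_mm: float, mode: str = "nearest"
) -> VolumeImage:
    """Separable Gaussian smoothing at a full-width-half-maximum given in mm.

    Per-axis sigma in voxels is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``, so
    anisotropic voxels receive anisotropic kernels and the smoothing is
    isotropic in physical space.  ``fwhm_mm == 0`` is the identity.  Edges use
    nearest-neighbour replication by default, avoiding rim artifacts on tight
    brain masks.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / v for v in vol.voxel_size_mm]
    return vol.with_data(ndimage.gaussian_filter(vol.data, sigma=sigmas, mode=mode))


def build_subject_record(
    animal_id: str,
    raw_ppi: VolumeImage,
    raw_background: VolumeImage,
    masks: MaskSet,
    effectiveness: float,
    fwhm_mm: float = 1.5,
    smooth_diff: bool = True,
    sign_convention: str = "ppi_minus_background",
    strain: str | None = None,
) -> SubjectRecord:
    """Normalize a raw condition pair and form its difference image.

    Both volumes are ratio-normalized to the reference region; the difference
    (task − control by default, flip with ``sign_convention``) is Gaussian
    smoothed when ``smooth_diff`` is set — smoothing the difference equals
    differencing the smoothed pair by linearity.  Voxels outside the brain
    mask are zeroed in the difference image and excluded from every
    downstream statistic.
    """
    ensure_same_grid(raw_ppi, raw_background)
    if raw_ppi.shape != masks.brain.shape:
        raise GridMismatchError("mask grid differs from volume grid")
    ppi_norm = ratio_normalize(raw_ppi, masks.reference)
    bg_norm = ratio_normalize(raw_background, masks.reference)
    if sign_convention == "ppi_minus_background":
        diff = difference_image(ppi_norm, bg_norm)
    elif sign_convention == "background_minus_ppi":
        diff = difference_image(bg_norm, ppi_norm)
    else:
        raise ValueError(f"unknown sign convention: {sign_convention!r}")
    if smooth_diff and fwhm_mm > 0:
        diff = gaussian_smooth(diff, fwhm_mm)
    diff = diff.with_data(np.where(masks.brain, diff.data, 0.0))
    return SubjectRecord(
        animal_id=animal_id,
        ppi_norm=ppi_norm,
        background_norm=bg_norm,
        diff=diff,
        effectiveness=float(effectiveness),
        strain=strain,
    )


# ---------------------------------------------------------------------------
# NIfTI and manifest I/O


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    affine = np.diag([*vol.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    img.header["descrip"] = vol.space_tag.encode()[:79]
    nib.save(img, str(path))


def load_volume(path: str | Path, space_tag: str | None = None) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"volume not found: {path}")
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    tag = space_tag
    if tag is None:
        raw = bytes(img.header["descrip"].tobytes()).split(b"\x00", 1)[0]
        tag = raw.decode(errors="replace") or "common"
    return VolumeImage(np.asarray(img.dataobj, dtype=float), zooms, tag)


def save_mask(mask: np.ndarray, voxel_size_mm: tuple[float, float, float], path: str | Path) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"mask not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the subject manifest TSV (animal_id, ppi_path, background_path, ...)."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"manifest not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    required = {"animal_id", "ppi_path", "background_path"}
    missing = required - set(frame.columns)
    if missing:
        raise MissingInputError(f"manifest missing columns: {sorted(missing)}")
    return frame


def write_manifest(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
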