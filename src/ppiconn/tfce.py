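"""Threshold-free cluster enhancement (TFCE) and max-statistic permutation inference.

TFCE integrates cluster support over all heights below each voxel's
statistic,

    TFCE(v) = sum over h in {dh, 2*dh, ..., t(v)} of e(h)^E * h^H * dh,

where e(h) is the extent (voxel count) of the connected component containing
v in the suprathreshold set {t >= h}.  With the standard exponents H = 2 and
E = 0.5 this rewards both tall peaks and spatially extended support without
an arbitrary cluster-forming threshold.  Negative lobes are enhanced on the
negated map and returned with negative sign.

Family-wise error is controlled by the max-statistic method: under each
permutation (covariate shuffle) or sign-flip (paired contrast) the full map
is recomputed, enhanced, and its image-wide maximum recorded; the observed
enhanced map is thresholded at an upper order statistic of these maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InsufficientSubjectsError, UndefinedStatisticError
from .groupstats import (
    SeedSpec,
    StatMap,
    _pearson_rows,
    r_to_t,
    seed_extract,
    stack_diff_values,
)
from .imaging import SubjectRecord

_EPS = 1e-12


@dataclass(frozen=True)
class TFCEParams:
    """Enhancement parameters: height/extent exponents, step size, connectivity."""

    H: float = 2.0
    E: float = 0.5
    dh: float = 0.1
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0:
            raise ValueError("exponents H and E must be non-negative")
        if self.dh <= 0:
            raise ValueError("step dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structuring element for 6-, 18- or 26-neighbour components."""
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, rank[connectivity])


def _tfce_one_sided(values: np.ndarray, params: TFCEParams) -> np.ndarray:
    """Enhance the non-negative part of ``values`` (zeros elsewhere)."""
    out = np.zeros_like(values)
    vmax = float(values.max(initial=0.0))
    n_steps = int(math.floor(vmax / params.dh + 1e-9))
    if n_steps == 0:
        return out

    # Work on the bounding box of the lowest suprathreshold set.
    nz = np.nonzero(values >= params.dh - _EPS)
    if nz[0].size == 0:
        return out
    box = tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in nz)
    v = values[box]
    acc = np.zeros_like(v)
    structure = connectivity_structure(params.connectivity)

    for k in range(1, n_steps + 1):
        h = k * params.dh
        supra = v >= h - _EPS
        if not supra.any():
            break
        labels, n_lab = ndimage.label(supra, structure=structure)
        extents = np.bincount(labels.ravel())[1:].astype(float)
        contrib = (extents**params.E) * (h**params.H) * params.dh
        acc[supra] += contrib[labels[supra] - 1]

    out[box] = acc
    return out


def tfce_transform(
    values: np.ndarray | StatMap,
    mask: np.ndarray | None = None,
    params: TFCEParams = TFCEParams(),
) -> np.ndarray:
    """Signed TFCE map: positive and negative lobes enhanced separately.

    Voxels with |t| < dh receive 0.  The height ladder includes every
    multiple of dh up to and including t(v) when t(v) is an exact multiple
    (h = 0 contributes nothing regardless of exponents).
    """
    if isinstance(values, StatMap):
        mask = values.mask if mask is None else mask
        values = values.data
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("statistic map contains non-finite values")
    if mask is not None:
        values = np.where(np.asarray(mask, dtype=bool), values, 0.0)
    pos = _tfce_one_sided(np.maximum(values, 0.0), params)
    neg = _tfce_one_sided(np.maximum(-values, 0.0), params)
    return pos - neg


def null_threshold(null_max: np.ndarray, alpha: float = 0.01) -> float:
    """Upper order-statistic threshold of the permutation maxima.

    The observed dataset is counted as a member of the permutation family, so
    a voxel whose enhanced value strictly exceeds the j-th largest null
    maximum, j = floor(alpha·(n_perm+1)), has permutation p-value
    (1 + #{null ≥ value})/(n_perm + 1) ≤ alpha — the exact max-statistic
    construction, which keeps the family-wise error at or below alpha.  For
    n_perm = 1000 and alpha = 0.01 this is the 991st smallest maximum.  When
    alpha·(n_perm+1) < 1 the overall maximum is used (no attainable level
    below alpha; the most conservative available interpolation-free cut).
    """
    null_max = np.asarray(null_max, dtype=float)
    n_perm = len(null_max)
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    j = max(1, math.floor(alpha * (n_perm + 1)))
    return float(np.sort(null_max)[n_perm - j])


@dataclass(frozen=True)
class TFCEResult:
    """Observed enhanced map plus its permutation null and significance mask."""

    enhanced: np.ndarray
    null_max: np.ndarray
    threshold: float
    sig_mask: np.ndarray
    params: TFCEParams
    alpha: float
    rng_seed: int | None = None
    info: dict = field(default_factory=dict)

    @property
    def n_perm(self) -> int:
        return len(self.null_max)


def _finalize(
    enhanced: np.ndarray,
    null_max: np.ndarray,
    params: TFCEParams,
    alpha: float,
    rng_seed: int | None,
    info: dict,
) -> TFCEResult:
    threshold = null_threshold(null_max, alpha)
    return TFCEResult(
        enhanced=enhanced,
        null_max=np.asarray(null_max, dtype=float),
        threshold=threshold,
        sig_mask=np.abs(enhanced) > threshold,
        params=params,
        alpha=alpha,
        rng_seed=rng_seed,
        info=info,
    )


def _corr_t_data(X: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Correlation t-map (3D) of X (subjects × mask voxels) against y."""
    r, _ = _pearson_rows(X, y)
    data = np.zeros(mask.shape)
    data[mask] = r_to_t(r, len(y))
    return data


def correlation_tfce_null(
    X: np.ndarray,
    mask: np.ndarray,
    covariate: np.ndarray,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 1000,
    rng_seed: int = 0,
    alpha: float = 0.01,
) -> TFCEResult:
    """Max-TFCE permutation test for a correlation map, on a value matrix.

    ``X`` holds one row per subject of difference values inside ``mask``.
    Each permutation shuffles the covariate across subjects, recomputes the
    correlation t-map, enhances it, and records the image-wide max |TFCE|;
    both observed lobes are tested against this common two-sided null.
    """
    X = np.asarray(X, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = len(covariate)
    if X.shape != (n, int(mask.sum())):
        raise ValueError("X must be (n_subjects, n_mask_voxels)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.ptp(covariate) == 0:
        raise UndefinedStatisticError("constant covariate")
    if len(np.unique(covariate)) < 5:
        raise InsufficientSubjectsError(
            "permutation test needs >= 5 distinct covariate values"
        )

    enhanced = tfce_transform(_corr_t_data(X, covariate, mask), params=params)
    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(covariate)
        null_max[p] = float(
            np.abs(tfce_transform(_corr_t_data(X, perm, mask), params=params)).max()
        )
    return _finalize(
        enhanced, null_max, params, alpha, rng_seed, {"test": "correlation", "n": n}
    )


def permutation_null(
    subjects: Sequence[SubjectRecord],
    covariate_or_seed: np.ndarray | SeedSpec,
    mask: np.ndarray,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 1000,
    rng_seed: int = 0,
    alpha: float = 0.01,
) -> TFCEResult:
    """Max-TFCE permutation test for a behavior- or seed-correlation map.

    ``covariate_or_seed`` is a per-subject covariate vector, or a seed
    (SeedSpec / boolean mask) whose per-subject mean difference value becomes
    the covariate.  Identical ``rng_seed`` reproduces the identical result.
    """
    mask = np.asarray(mask, dtype=bool)
    if isinstance(covariate_or_seed, SeedSpec) or (
        isinstance(covariate_or_seed, np.ndarray)
        and covariate_or_seed.dtype == bool
        and covariate_or_seed.shape == mask.shape
    ):
        covariate = np.array(
            [seed_extract(rec, covariate_or_seed) for rec in subjects]
        )
        label = getattr(covariate_or_seed, "name", "seed")
    else:
        covariate = np.asarray(covariate_or_seed, dtype=float)
        label = "covariate"
    X = stack_diff_values(subjects, mask, smoothed=True)
    result = correlation_tfce_null(
        X, mask, covariate, params, n_perm, rng_seed, alpha
    )
    result.info["covariate"] = label
    return result


def _paired_t_data(D: np.ndarray, signs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    d = D * signs[:, None]
    n = len(signs)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = 0.0
    data = np.zeros(mask.shape)
    data[mask] = t
    return data


def paired_sign_flip_null(
    subjects: Sequence[SubjectRecord],
    mask: np.ndarray,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 1000,
    rng_seed: int = 0,
    alpha: float = 0.01,
    use_smoothed_diff: bool = False,
    exhaustive: bool = False,
) -> TFCEResult:
    """Max-TFCE sign-flip test for the paired task-vs-control contrast.

    Under the null of exchangeable condition labels within subject, each
    subject's difference image may flip sign; the null distribution is the
    max |TFCE| over random (or, with ``exhaustive``, all 2^n) sign patterns.
    """
    n = len(subjects)
    if n < 2:
        raise InsufficientSubjectsError(f"sign-flip test needs n >= 2, got {n}")
    mask = np.asarray(mask, dtype=bool)
    D = stack_diff_values(subjects, mask, smoothed=use_smoothed_diff)

    enhanced = tfce_transform(_paired_t_data(D, np.ones(n), mask), params=params)

    if exhaustive:
        patterns = np.array(
            [[1.0 if (i >> b) & 1 else -1.0 for b in range(n)] for i in range(2**n)]
        )
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(rng_seed)
        patterns = rng.choice([-1.0, 1.0], size=(n_perm, n))

    null_max = np.empty(len(patterns))
    for p, signs in enumerate(patterns):
        null_max[p] = float(
            np.abs(tfce_transform(_paired_t_data(D, signs, mask), params=params)).max()
        )
    return _finalize(
        enhanced,
        null_max,
        params,
        alpha,
        rng_seed,
        {"test": "paired_sign_flip", "n": n, "exhaustive": exhaustive},
    )
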