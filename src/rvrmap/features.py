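"""Feature, kernel and design-matrix construction from grey-matter volumes.

The regression consumes preprocessed (spatially normalised, modulated)
grey-matter density maps. This module turns a stack of such volumes into

* a :class:`FeatureMatrix` — N subjects x D masked voxels,
* a :class:`KernelMatrix`  — pairwise dot products (linear kernel),
* a :class:`DesignMatrix`  — ``Phi = [1, K]``, the kernel columns preceded by
  a column of ones that models the score offset.

Vectorisation order is C order (row-major) over the (x, y, z) grid, i.e. the
order of ``values[mask]`` for a C-contiguous array. The order is stable across
calls and is inverted exactly by :func:`devectorize`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "BrainVolume",
    "FeatureMatrix",
    "KernelMatrix",
    "DesignMatrix",
    "smooth_volume",
    "vectorize",
    "devectorize",
    "linear_kernel",
    "build_design",
    "VoxelwiseResidualizer",
    "residualize_voxelwise",
]

#: Conversion between FWHM and Gaussian sigma: fwhm = sigma * 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BrainVolume:
    """A 3D grey-matter density map with its analysis mask.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values. Unitless GM density, non-negative inside the mask
        unless ``signed=True`` (patterns and weight maps are signed).
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in millimetres.
    mask : ndarray of bool, same shape as ``values``
        Analysis mask; voxels outside it are ignored everywhere downstream.
    signed : bool
        Whether negative values are permitted (weight/pattern images).
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive floats")
        inside = self.values[self.mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError("non-finite values inside mask")
        if not self.signed and inside.size and inside.min() < 0:
            raise ValueError("negative values inside mask of an unsigned volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def affine(self) -> np.ndarray:
        """NIfTI affine placing the volume on a mm grid (diagonal scaling)."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.values.astype(np.float32), self.affine())

    def save(self, path) -> None:
        import nibabel as nib

        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None, signed: bool = False):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.get_fdata(), dtype=float)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        return cls(values=values, voxel_size_mm=vox, mask=mask, signed=signed)


def mask_hash(mask: np.ndarray) -> str:
    """Stable identity of a boolean mask (shape + contents)."""
    m = np.ascontiguousarray(np.asarray(mask, dtype=bool))
    h = hashlib.sha1()
    h.update(str(m.shape).encode())
    h.update(np.packbits(m).tobytes())
    return h.hexdigest()


@dataclass
class FeatureMatrix:
    """N x D matrix of masked voxel values, one row per subject."""

    X: np.ndarray
    subject_ids: list[str]
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if self.X.shape[0] != len(self.subject_ids):
            raise ValueError("row count != number of subject ids")
        if self.X.shape[1] != int(np.count_nonzero(self.mask)):
            raise ValueError("column count != number of mask voxels")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def mask_hash(self) -> str:
        return mask_hash(self.mask)

    def subset(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = list(rows)
        return FeatureMatrix(
            X=self.X[rows],
            subject_ids=[self.subject_ids[i] for i in rows],
            mask=self.mask,
            voxel_size_mm=self.voxel_size_mm,
        )


@dataclass
class KernelMatrix:
    """Dot-product kernel of rows against a fixed training set.

    ``K[i, j] = <x_i, x_train_j> / scale`` where ``scale`` is the conditioning
    divisor (mean training-diagonal by default; 1.0 disables it). The scale is
    carried so weight-map back-projection can undo it.
    """

    K: np.ndarray
    train_subject_ids: list[str]
    row_subject_ids: list[str]
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2:
            raise ValueError("K must be 2D")
        if self.K.shape != (len(self.row_subject_ids), len(self.train_subject_ids)):
            raise ValueError("K shape inconsistent with subject id lists")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_train(self) -> int:
        return len(self.train_subject_ids)

    @property
    def train_hash(self) -> str:
        h = hashlib.sha1()
        h.update("|".join(self.train_subject_ids).encode())
        h.update(np.float64(self.scale).tobytes())
        return h.hexdigest()


@dataclass
class DesignMatrix:
    """Basis matrix ``Phi = [1, K]``: offset column followed by kernel columns."""

    Phi: np.ndarray
    train_subject_ids: list[str]
    row_subject_ids: list[str]
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.ndim != 2:
            raise ValueError("Phi must be 2D")
        if self.Phi.shape[1] != len(self.train_subject_ids) + 1:
            raise ValueError("Phi must have n_train + 1 columns")
        if not np.all(self.Phi[:, 0] == 1.0):
            raise ValueError("first column of Phi must be identically 1")

    @property
    def n_train(self) -> int:
        return len(self.train_subject_ids)

    @property
    def train_hash(self) -> str:
        h = hashlib.sha1()
        h.update("|".join(self.train_subject_ids).encode())
        h.update(np.float64(self.scale).tobytes())
        return h.hexdigest()


def smooth_volume(vol: BrainVolume, fwhm_mm: float) -> BrainVolume:
    """Gaussian-smooth a volume with an isotropic kernel of given FWHM (mm).

    sigma per axis (in voxels) is ``fwhm * FWHM_TO_SIGMA / voxel_size``.
    Boundary handling is zero padding; the mask is unchanged. ``fwhm_mm = 0``
    returns the volume untouched.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol
    sigma_vox = [
        fwhm_mm * FWHM_TO_SIGMA / v for v in vol.voxel_size_mm
    ]
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return BrainVolume(
        values=smoothed,
        voxel_size_mm=vol.voxel_size_mm,
        mask=vol.mask,
        signed=vol.signed,
    )


def vectorize(
    volumes: Sequence[BrainVolume],
    mask: np.ndarray,
    subject_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Stack masked voxels of each volume into an N x D feature matrix.

    Row i holds ``volumes[i].values[mask]`` in C order over (x, y, z).
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(np.count_nonzero(mask))
    if n_vox == 0:
        raise ValueError("empty mask: no voxels selected")
    if len(volumes) == 0:
        raise ValueError("no volumes to vectorize")
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(len(volumes))]
    subject_ids = [str(s) for s in subject_ids]
    if len(subject_ids) != len(volumes):
        raise ValueError("subject_ids length != number of volumes")
    rows = np.empty((len(volumes), n_vox), dtype=float)
    for i, vol in enumerate(volumes):
        if vol.shape != mask.shape:
            raise ValueError(
                f"subject {subject_ids[i]}: volume shape {vol.shape} "
                f"!= mask shape {mask.shape}"
            )
        rows[i] = vol.values[mask]
    return FeatureMatrix(
        X=rows,
        subject_ids=subject_ids,
        mask=mask,
        voxel_size_mm=volumes[0].voxel_size_mm,
    )


def devectorize(
    row: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    signed: bool = True,
) -> BrainVolume:
    """Place a feature row back into the 3D grid (zeros outside the mask)."""
    mask = np.asarray(mask, dtype=bool)
    row = np.asarray(row, dtype=float)
    if row.shape != (int(np.count_nonzero(mask)),):
        raise ValueError("row length != number of mask voxels")
    values = np.zeros(mask.shape, dtype=float)
    values[mask] = row
    return BrainVolume(values=values, voxel_size_mm=voxel_size_mm, mask=mask, signed=signed)


def linear_kernel(
    X_a: FeatureMatrix,
    X_b: FeatureMatrix,
    condition: bool = True,
) -> KernelMatrix:
    """Dot-product kernel of rows of ``X_a`` against training rows ``X_b``.

    ``K[i, j]`` sums the product of corresponding voxel values of image i of
    ``X_a`` and image j of ``X_b``. When ``condition`` is true the kernel is
    divided by the mean of the training diagonal (mean squared row norm of
    ``X_b``) to keep its entries O(1) regardless of voxel count; the divisor
    is recorded on the result and predictions are invariant to it.
    """
    if X_a.n_voxels != X_b.n_voxels:
        raise ValueError("feature dimensionality mismatch between the two matrices")
    if X_a.mask_hash != X_b.mask_hash:
        raise ValueError("mask mismatch: kernels require identical masks")
    scale = 1.0
    if condition:
        scale = float(np.mean(np.sum(X_b.X**2, axis=1)))
        if scale <= 0:
            scale = 1.0
    K = X_a.X @ X_b.X.T / scale
    return KernelMatrix(
        K=K,
        train_subject_ids=list(X_b.subject_ids),
        row_subject_ids=list(X_a.subject_ids),
        scale=scale,
    )


def build_design(K: KernelMatrix) -> DesignMatrix:
    """Prepend the offset column of ones: ``Phi = [1, K]``."""
    if K.n_train == 0:
        raise ValueError("empty training set: kernel has no training columns")
    n_rows = K.K.shape[0]
    Phi = np.column_stack([np.ones(n_rows), K.K])
    return DesignMatrix(
        Phi=Phi,
        train_subject_ids=list(K.train_subject_ids),
        row_subject_ids=list(K.row_subject_ids),
        scale=K.scale,
    )


@dataclass
class VoxelwiseResidualizer:
    """Per-voxel linear confound fit learned on training rows.

    For each voxel d a simple regression ``x_d = a_d + b_d * c`` is fitted on
    the training subjects' covariate values c; applying the residualizer
    subtracts the training-estimated fit, so test subjects are corrected with
    training coefficients only (no leakage).
    """

    intercept: np.ndarray
    slope: np.ndarray
    mask_fingerprint: str = ""

    def apply(self, X: FeatureMatrix, covariate: np.ndarray) -> FeatureMatrix:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape != (X.n_subjects,):
            raise ValueError("covariate length != number of subjects")
        if self.mask_fingerprint and X.mask_hash != self.mask_fingerprint:
            raise ValueError("mask mismatch: residualizer fitted on a different mask")
        fitted = self.intercept[None, :] + covariate[:, None] * self.slope[None, :]
        return FeatureMatrix(
            X=X.X - fitted,
            subject_ids=list(X.subject_ids),
            mask=X.mask,
            voxel_size_mm=X.voxel_size_mm,
        )

    @classmethod
    def fit(cls, X: FeatureMatrix, covariate: np.ndarray) -> "VoxelwiseResidualizer":
        c = np.asarray(covariate, dtype=float)
        if c.shape != (X.n_subjects,):
            raise ValueError("covariate length != number of subjects")
        c_mean = c.mean()
        c_centered = c - c_mean
        ss = float(c_centered @ c_centered)
        if ss == 0.0:
            raise ValueError("zero-variance covariate: cannot residualize")
        slope = (c_centered @ X.X) / ss
        intercept = X.X.mean(axis=0) - slope * c_mean
        return cls(intercept=intercept, slope=slope, mask_fingerprint=X.mask_hash)


def residualize_voxelwise(
    X: FeatureMatrix, covariate: np.ndarray
) -> tuple[FeatureMatrix, VoxelwiseResidualizer]:
    """Fit a voxelwise confound model on ``X`` and return residual features.

    Returns the residualized matrix together with the fitted coefficients so
    the identical correction can be applied to held-out subjects.
    """
    rz = VoxelwiseResidualizer.fit(X, covariate)
    return rz.apply(X, covariate), rz
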