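"""Lightweight 3-D image carriers shared by every pipeline stage.

``VolumeImage`` is the universal scalar-grid container (a thin wrapper around a
numpy array plus voxel geometry, round-tripped through NIfTI-1 via nibabel).
``TissueProbabilityMap`` stacks per-voxel class probabilities for the four
segmentation classes (GM, WM, CSF, background) on the same grid and enforces
the per-voxel normalization that every downstream consumer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Gaussian kernel conversion: sigma = FWHM / (2 * sqrt(2 * ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Fixed class order used everywhere a stacked probability array appears.
CLASS_NAMES = ("gm", "wm", "csf", "background")
TISSUE_CLASSES = ("gm", "wm", "csf")


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size) -> tuple:
    """Per-axis Gaussian sigma (in voxels) for a given FWHM in mm."""
    return tuple(fwhm_mm * FWHM_TO_SIGMA / float(v) for v in voxel_size)


def smooth_fwhm(data: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Gaussian-smooth a 3-D array with an isotropic FWHM given in mm."""
    data = np.asarray(data, dtype=float)
    if fwhm_mm <= 0:
        return data.copy()
    return ndimage.gaussian_filter(data, sigma=fwhm_to_sigma_voxels(fwhm_mm, voxel_size))


def _default_affine(voxel_size) -> np.ndarray:
    aff = np.diag([float(voxel_size[0]), float(voxel_size[1]), float(voxel_size[2]), 1.0])
    return aff


@dataclass
class VolumeImage:
    """A 3-D scalar grid with voxel geometry.

    Parameters
    ----------
    data
        3-D array of finite scalars.
    voxel_size
        Physical voxel edge lengths in mm, one per axis.
    affine
        4x4 voxel-to-world transform; defaults to a diagonal scaling by
        ``voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("VolumeImage requires a non-empty 3-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeImage values must be finite")
        self.voxel_size = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel()) \
            if np.ndim(self.voxel_size) else (float(self.voxel_size),) * 3
        if len(self.voxel_size) == 1:
            self.voxel_size = self.voxel_size * 3
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """A copy of this image carrying new values on the same grid."""
        return VolumeImage(np.asarray(data, dtype=float), self.voxel_size, self.affine.copy())

    def smoothed(self, fwhm_mm: float) -> "VolumeImage":
        return self.with_data(smooth_fwhm(self.data, fwhm_mm, self.voxel_size))

    def to_nifti(self, path) -> None:
        nib.Nifti1Image(self.data.astype(np.float32), self.affine).to_filename(str(path))

    @classmethod
    def from_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = img.header.get_zooms()[:3]
        return cls(data, tuple(float(z) for z in zooms), np.asarray(img.affine, dtype=float))


@dataclass
class TissueProbabilityMap:
    """Per-voxel class probabilities for GM, WM, CSF and background.

    ``probabilities`` is a ``(4, nx, ny, nz)`` stack in :data:`CLASS_NAMES`
    order; every voxel's probabilities must lie in [0, 1] and sum to 1 within
    1e-6 (enforced at construction).
    """

    probabilities: np.ndarray
    voxel_size: tuple
    affine: np.ndarray = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 4 or self.probabilities.shape[0] != len(CLASS_NAMES):
            raise ValueError("probabilities must be a (4, nx, ny, nz) stack")
        if not np.all(np.isfinite(self.probabilities)):
            raise ValueError("probabilities must be finite")
        if self.probabilities.min() < -1e-9 or self.probabilities.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probabilities.sum(axis=0)
        if np.max(np.abs(sums - 1.0)) > 1e-6:
            raise ValueError("per-voxel class probabilities must sum to 1 within 1e-6")
        self.voxel_size = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel()) \
            if np.ndim(self.voxel_size) else (float(self.voxel_size),) * 3
        if len(self.voxel_size) == 1:
            self.voxel_size = self.voxel_size * 3
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    # -- convenience accessors -------------------------------------------------
    def class_map(self, name: str) -> np.ndarray:
        return self.probabilities[CLASS_NAMES.index(name)]

    @property
    def gm(self) -> np.ndarray:
        return self.class_map("gm")

    @property
    def wm(self) -> np.ndarray:
        return self.class_map("wm")

    @property
    def csf(self) -> np.ndarray:
        return self.class_map("csf")

    @property
    def background(self) -> np.ndarray:
        return self.class_map("background")

    @property
    def shape(self):
        return self.probabilities.shape[1:]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def hard_labels(self) -> np.ndarray:
        """Argmax class index per voxel (0=GM, 1=WM, 2=CSF, 3=background)."""
        return np.argmax(self.probabilities, axis=0)

    def brain_mask(self, threshold: float = 0.5) -> np.ndarray:
        """Boolean mask of voxels whose non-background probability exceeds ``threshold``."""
        return (1.0 - self.background) > threshold

    def brain_volume_ml(self) -> float:
        """Non-background probability mass times voxel volume, in ml."""
        return float((1.0 - self.background).sum() * self.voxel_volume_ml)

    def class_volumes_ml(self) -> dict:
        """Probability mass per tissue class (GM/WM/CSF), in ml."""
        return {name: float(self.class_map(name).sum() * self.voxel_volume_ml)
                for name in TISSUE_CLASSES}

    def renormalized(self) -> "TissueProbabilityMap":
        probs = np.clip(self.probabilities, 0.0, None)
        total = probs.sum(axis=0)
        total[total <= 0] = 1.0
        return TissueProbabilityMap(probs / total, self.voxel_size, self.affine.copy())

    def smoothed_renormalized(self, fwhm_mm: float) -> "TissueProbabilityMap":
        """Smooth the tissue classes, rebuild background as the complement.

        Background is recomputed as ``1 - (GM + WM + CSF)`` (clipped at 0)
        after smoothing so the per-voxel normalization is guaranteed rather
        than approximated.
        """
        tissue = np.stack([smooth_fwhm(self.class_map(n), fwhm_mm, self.voxel_size)
                           for n in TISSUE_CLASSES])
        tissue = np.clip(tissue, 0.0, None)
        total = tissue.sum(axis=0)
        over = total > 1.0
        if np.any(over):
            tissue[:, over] /= total[over]
        bg = np.clip(1.0 - tissue.sum(axis=0), 0.0, 1.0)
        probs = np.concatenate([tissue, bg[None]], axis=0)
        return TissueProbabilityMap(probs, self.voxel_size, self.affine.copy())

    @classmethod
    def from_labels(cls, labels: np.ndarray, voxel_size, affine=None) -> "TissueProbabilityMap":
        """One-hot probability map from an integer label grid (class indices)."""
        labels = np.asarray(labels)
        probs = np.stack([(labels == k).astype(float) for k in range(len(CLASS_NAMES))])
        return cls(probs, voxel_size, affine)

    def to_nifti(self, path) -> None:
        """Write as a single 4-D NIfTI (last axis = class in CLASS_NAMES order)."""
        arr = np.moveaxis(self.probabilities, 0, -1).astype(np.float32)
        nib.Nifti1Image(arr, self.affine).to_filename(str(path))

    @classmethod
    def from_nifti(cls, path) -> "TissueProbabilityMap":
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj, dtype=float)
        if arr.ndim != 4 or arr.shape[3] != len(CLASS_NAMES):
            raise ValueError("expected a 4-D NIfTI with one volume per class")
        zooms = img.header.get_zooms()[:3]
        return cls(np.moveaxis(arr, -1, 0), tuple(float(z) for z in zooms),
                   np.asarray(img.affine, dtype=float))


def dice_coefficient(labels_a: np.ndarray, labels_b: np.ndarray, class_index: int) -> float:
    """Dice overlap of one class between two integer label grids."""
    a = labels_a == class_index
    b = labels_b == class_index
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
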