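"""Artifact correction, denoising, affine registration and tissue segmentation.

The stage order is fixed by the framework: slice-gain correction first (the
acquisition writes one multiplicative gain per in-plane slice), then
non-local-means denoising, then affine registration to template space, then
segmentation of the registered image against the species tissue probability
map (TPM) with a per-class Gaussian intensity mixture fitted by
expectation-maximization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.restoration import denoise_nl_means

from .image import (CLASS_NAMES, TISSUE_CLASSES, TissueProbabilityMap,
                    VolumeImage, smooth_fwhm)

__all__ = [
    "correct_slice_inhomogeneity",
    "denoise_nlm",
    "affine_register",
    "RegistrationResult",
    "segment_tpm",
    "SegmentationResult",
    "preprocess_subject",
]


# --------------------------------------------------------------------------
# slice-based inhomogeneity correction
# --------------------------------------------------------------------------

def _foreground_mask(data: np.ndarray) -> np.ndarray:
    hi = np.percentile(data, 99)
    if hi <= 0:
        return np.zeros(data.shape, dtype=bool)
    return data > 0.25 * hi


def correct_slice_inhomogeneity(img: VolumeImage, axis: int = 2,
                                n_passes: int = 3, window: int = 5):
    """Estimate and divide out one multiplicative gain per slice.

    The anatomy-driven intensity profile is estimated voxelwise by a running
    median across ``window`` neighbouring slices (the smoothed across-slice
    profile); each slice's gain is the median, over foreground voxels, of the
    ratio of the slice to that profile - a statistic that is insensitive to
    the tissue composition of the slice.  Because the profile itself mixes
    the gains of neighbouring slices, the estimate is refined by a few
    fixed-point passes on the partially corrected volume (the residual gain
    amplitude contracts by roughly half per pass).

    Slices with no foreground voxels (e.g. all-zero slices) receive gain 1,
    and the corrected volume is rescaled so its mean equals the input mean.

    Returns
    -------
    (VolumeImage, np.ndarray)
        Corrected image and the vector of estimated per-slice gains
        (cumulative over passes).
    """
    data = img.data
    if data.shape[axis] < 3:
        raise ValueError("need at least 3 slices along the correction axis")
    work = np.moveaxis(data, axis, 0).astype(float).copy()
    mask = np.moveaxis(_foreground_mask(data), axis, 0)
    n_slices = work.shape[0]
    total_gain = np.ones(n_slices)

    size = (min(window, n_slices), 1, 1)
    for _ in range(max(1, n_passes)):
        profile = ndimage.median_filter(work, size=size, mode="nearest")
        valid = mask & (profile > 0)
        gains = np.ones(n_slices)
        for k in range(n_slices):
            if valid[k].any():
                gains[k] = np.median(work[k][valid[k]] / profile[k][valid[k]])
                if not np.isfinite(gains[k]) or gains[k] <= 0:
                    gains[k] = 1.0
        work /= gains[:, None, None]
        total_gain *= gains

    corrected = np.moveaxis(work, 0, axis)
    in_mean = data.mean()
    out_mean = corrected.mean()
    if out_mean > 0 and in_mean > 0:
        corrected = corrected * (in_mean / out_mean)
    return img.with_data(corrected), total_gain


# --------------------------------------------------------------------------
# non-local means denoising
# --------------------------------------------------------------------------

def estimate_noise_sd(data: np.ndarray) -> float:
    """Robust noise SD from first-difference pseudo-residuals.

    Differences of neighbouring voxels along the first axis are dominated by
    noise away from tissue boundaries; the median absolute difference scaled
    by 1.4826/sqrt(2) is a robust estimate of the additive noise SD.
    """
    diff = np.diff(np.asarray(data, dtype=float), axis=0)
    mad = np.median(np.abs(diff - np.median(diff)))
    return float(1.4826 * mad / np.sqrt(2.0))


def denoise_nlm(img: VolumeImage, search_radius: int = 3, patch_radius: int = 1,
                h="auto") -> VolumeImage:
    """Non-local-means denoising with data-adaptive smoothing strength.

    ``h="auto"`` estimates the noise SD from high-frequency pseudo-residuals
    (:func:`estimate_noise_sd`) and sets the filtering strength to 0.8 of it,
    the usual operating point for the fast patchwise variant.  Piecewise
    constant regions are averaged over similar patches only, so tissue
    boundaries are preserved.
    """
    if search_radius < 1 or patch_radius < 1:
        raise ValueError("radii must be >= 1")
    sigma = estimate_noise_sd(img.data)
    h_val = 0.8 * sigma if h == "auto" else float(h)
    if h_val <= 0:
        return img.with_data(img.data.copy())
    out = denoise_nl_means(img.data, patch_size=2 * patch_radius + 1,
                           patch_distance=search_radius, h=h_val,
                           sigma=sigma, fast_mode=True)
    return img.with_data(out)


# --------------------------------------------------------------------------
# affine registration
# --------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Outcome of an affine registration: transform, resampled image, diagnostics."""

    transform: np.ndarray        # 4x4, fixed-world -> moving-world (pull-back)
    resampled: VolumeImage       # moving resampled into the fixed grid
    converged: bool
    final_cost: float
    n_evaluations: int
    parameters: np.ndarray
    message: str = ""


_DOF_SIZES = {"scale-only": 1, "rigid": 6, "full-affine": 12}


def _rotation(rx, ry, rz):
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(p: np.ndarray, dof: str) -> np.ndarray:
    """3x3 linear part + translation (mm) from the parameter vector."""
    if dof == "scale-only":
        M = np.eye(3) * np.exp(p[0])
        t = np.zeros(3)
    elif dof == "rigid":
        M = _rotation(*p[3:6])
        t = p[:3]
    else:  # full-affine
        S = np.diag(np.exp(p[6:9]))
        Sh = np.array([[1, p[9], p[10]], [0, 1, p[11]], [0, 0, 1]], dtype=float)
        M = _rotation(*p[3:6]) @ S @ Sh
        t = p[:3]
    return M, t


def _world_centers(img: VolumeImage):
    c_vox = (np.asarray(img.shape, dtype=float) - 1) / 2
    return c_vox * np.asarray(img.voxel_size)


def _voxel_affine(moving: VolumeImage, fixed: VolumeImage, M: np.ndarray,
                  t: np.ndarray):
    """Voxel-space mapping v_m = A v_f + b for x_m = M (x_f - c_f) + c_m + t."""
    vs_f = np.asarray(fixed.voxel_size)
    vs_m = np.asarray(moving.voxel_size)
    c_f = _world_centers(fixed)
    c_m = _world_centers(moving)
    A = (M * vs_f[None, :]) / vs_m[:, None]
    b = (-M @ c_f + c_m + t) / vs_m
    return A, b


def _resample_with(moving: VolumeImage, fixed: VolumeImage, M: np.ndarray,
                   t: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Pull ``moving`` back onto the fixed grid through x_m = M (x_f - c_f) + c_m + t."""
    A, b = _voxel_affine(moving, fixed, M, t)
    return ndimage.affine_transform(moving.data, A, offset=b,
                                    output_shape=fixed.shape, order=order,
                                    mode="constant", cval=cval)


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def affine_register(moving: VolumeImage, fixed: VolumeImage,
                    dof: str = "full-affine", fwhm_mm: float = 2.0,
                    coarse: bool = True,
                    init_params: np.ndarray = None,
                    stability_margin: float = 0.0) -> RegistrationResult:
    """Affine registration by mean-squared-difference minimization.

    Both images are smoothed (default FWHM 2 mm) and intensity-normalized,
    then the squared difference over the fixed grid is minimized over the
    transform parameters - a coarse grid search over translations (and scale,
    where applicable) followed by Powell refinement.  The transform maps
    fixed-image world coordinates to moving-image world coordinates about the
    image centers; the resampled moving image lives on the fixed grid
    (trilinear interpolation).

    Non-convergence is flagged on the result, never silently ignored.
    """
    if dof not in _DOF_SIZES:
        raise ValueError(f"dof must be one of {sorted(_DOF_SIZES)}")
    f_sm = smooth_fwhm(fixed.data, fwhm_mm, fixed.voxel_size)
    m_sm = smooth_fwhm(moving.data, fwhm_mm, moving.voxel_size)

    # optimize on a 2x-decimated grid (parameters are in mm, so they carry
    # over unchanged); final resampling happens at full resolution below
    stride = 2 if min(*fixed.shape, *moving.shape) >= 32 else 1
    f_lo = _znorm(f_sm[::stride, ::stride, ::stride])
    m_lo = VolumeImage(m_sm[::stride, ::stride, ::stride],
                       tuple(v * stride for v in moving.voxel_size))
    f_lo_ref = VolumeImage(f_lo, tuple(v * stride for v in fixed.voxel_size))

    n_eval = [0]

    def cost(p):
        n_eval[0] += 1
        M, t = _params_to_matrix(np.asarray(p, dtype=float), dof)
        r = _znorm(_resample_with(m_lo, f_lo_ref, M, t))
        return float(np.mean((f_lo - r) ** 2))

    p0 = np.zeros(_DOF_SIZES[dof])
    if init_params is not None:
        p0 = np.asarray(init_params, dtype=float).copy()
        if p0.shape != (_DOF_SIZES[dof],):
            raise ValueError("init_params does not match the requested dof")
        coarse = False
    if coarse:
        best = (cost(p0), p0)
        if dof == "scale-only":
            for s in np.log([0.7, 0.8, 0.9, 1.0, 1.1, 1.25, 1.4]):
                p = np.array([s])
                c = cost(p)
                if c < best[0]:
                    best = (c, p)
        else:
            step = 2.0 * float(np.mean(fixed.voxel_size))
            for tx in (-step, 0, step):
                for ty in (-step, 0, step):
                    for tz in (-step, 0, step):
                        p = p0.copy()
                        p[:3] = (tx, ty, tz)
                        c = cost(p)
                        if c < best[0]:
                            best = (c, p)
        p0 = best[1]

    cost0 = cost(p0)
    res = optimize.minimize(cost, p0, method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 10})
    p = np.asarray(res.x, dtype=float).ravel()
    final_cost = float(res.fun)
    # stability deadband: when warm-started, keep the previous optimum unless
    # re-optimization improves the cost beyond the margin (prevents a
    # non-contracting register/average feedback loop in template iteration)
    if init_params is not None and stability_margin > 0 and \
            final_cost > (1.0 - stability_margin) * cost0:
        p = p0
        final_cost = cost0
    M, t = _params_to_matrix(p, dof)

    # 4x4 world transform about centers: x_m = M x_f + (c_m + t - M c_f)
    T = np.eye(4)
    T[:3, :3] = M
    T[:3, 3] = _world_centers(moving) + t - M @ _world_centers(fixed)

    resampled = fixed.with_data(_resample_with(moving, fixed, M, t))
    return RegistrationResult(transform=T, resampled=resampled,
                              converged=bool(res.success), final_cost=final_cost,
                              n_evaluations=n_eval[0], parameters=p,
                              message=str(res.message))


def _recover_center_translation(reg: RegistrationResult, mov: VolumeImage,
                                fixed: VolumeImage) -> np.ndarray:
    M = reg.transform[:3, :3]
    return reg.transform[:3, 3] - _world_centers(mov) + M @ _world_centers(fixed)


def apply_registration(moving_data: np.ndarray, reg: RegistrationResult,
                       moving_voxel_size, fixed: VolumeImage,
                       order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample another moving-space grid (e.g. a posterior map) with a fitted
    transform, producing data on the fixed grid."""
    mov = VolumeImage(moving_data, moving_voxel_size)
    M = reg.transform[:3, :3]
    t = _recover_center_translation(reg, mov, fixed)
    return _resample_with(mov, fixed, M, t, order=order, cval=cval)


def apply_registration_inverse(fixed_space_data: np.ndarray,
                               reg: RegistrationResult, moving: VolumeImage,
                               fixed_voxel_size, order: int = 1,
                               cval: float = 0.0) -> np.ndarray:
    """Resample fixed-space data (e.g. a template TPM class) onto the moving
    grid through the inverse of a fitted transform."""
    fixed_ref = VolumeImage(fixed_space_data, fixed_voxel_size)
    M = reg.transform[:3, :3]
    t = _recover_center_translation(reg, moving, fixed_ref)
    A, b = _voxel_affine(moving, fixed_ref, M, t)
    A_inv = np.linalg.inv(A)
    return ndimage.affine_transform(fixed_ref.data, A_inv, offset=-A_inv @ b,
                                    output_shape=moving.shape, order=order,
                                    mode="constant", cval=cval)


# --------------------------------------------------------------------------
# EM segmentation with spatial priors
# --------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Posterior tissue map plus absolute (ml) and fractional (/TIV) volumes."""

    posterior: TissueProbabilityMap
    volumes_ml: dict          # GM/WM/CSF, ml
    tiv_ml: float             # GM + WM + CSF
    fractions: dict           # per tissue, /TIV (sum to 1)
    converged: bool = True
    n_iterations: int = 0
    log_likelihood: float = np.nan
    class_means: dict = field(default_factory=dict)
    class_sds: dict = field(default_factory=dict)

    def __post_init__(self):
        tissue_sum = sum(self.volumes_ml.values())
        if abs(tissue_sum - self.tiv_ml) > 1e-6:
            raise ValueError("TIV must equal GM + WM + CSF within 1e-6 ml")
        if self.tiv_ml > 0 and abs(sum(self.fractions.values()) - 1.0) > 1e-6:
            raise ValueError("fractional volumes must sum to 1 within 1e-6")
        if any(v < 0 for v in self.volumes_ml.values()):
            raise ValueError("volumes must be non-negative")


def segment_tpm(img: VolumeImage, tpm: TissueProbabilityMap, max_iter: int = 50,
                tol: float = 1e-4) -> SegmentationResult:
    """Segment an image against a TPM with a Gaussian-mixture EM.

    One Gaussian intensity model per class (GM, WM, CSF, background); the TPM
    supplies the per-voxel spatial prior.  The E-step sets the posterior
    proportional to prior x Gaussian likelihood (renormalized per voxel); the
    M-step re-estimates class means and SDs from posterior-weighted
    intensities.  Convergence: relative change of the log-likelihood < ``tol``.

    Classes whose prior mass is (numerically) zero are dropped with a warning.
    Absolute volume per class is the posterior mass times voxel volume in ml;
    TIV = GM + WM + CSF and fractional volumes divide by TIV.
    """
    if img.shape != tpm.shape:
        raise ValueError("TPM must be registered to the image geometry")
    y = img.data.ravel()
    n_classes = len(CLASS_NAMES)
    prior = tpm.probabilities.reshape(n_classes, -1).copy()

    active = prior.sum(axis=1) > 1e-8 * y.size
    for k in np.flatnonzero(~active):
        warnings.warn(f"class {CLASS_NAMES[k]!r} has ~zero prior mass; dropped")
    prior = np.clip(prior, 1e-6, None)
    prior[~active] = 0.0
    prior /= prior.sum(axis=0, keepdims=True)

    # prior-weighted moment initialization
    rng_floor = 1e-3 * (y.max() - y.min() + 1e-12)
    mu = np.zeros(n_classes)
    sd = np.full(n_classes, rng_floor)
    for k in range(n_classes):
        if not active[k]:
            continue
        w = prior[k]
        ws = w.sum()
        mu[k] = (w * y).sum() / ws
        sd[k] = max(np.sqrt((w * (y - mu[k]) ** 2).sum() / ws), rng_floor)

    # flat (spatially uninformative) priors give every class the same moments;
    # break the symmetry by spreading initial means over intensity quantiles in
    # the canonical T1 order (background < CSF < GM < WM)
    act = np.flatnonzero(active)
    if len(act) > 1 and np.ptp(mu[act]) < 1e-6 * (np.ptp(y) + 1e-12):
        t1_order = [CLASS_NAMES.index(n) for n in
                    ("background", "csf", "gm", "wm") if active[CLASS_NAMES.index(n)]]
        qs = np.quantile(y, (np.arange(len(t1_order)) + 0.5) / len(t1_order))
        for k, q in zip(t1_order, qs):
            mu[k] = q

    post = prior.copy()
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_p = np.full((n_classes, y.size), -np.inf)
        for k in range(n_classes):
            if not active[k]:
                continue
            log_p[k] = (np.log(prior[k]) - 0.5 * np.log(2 * np.pi * sd[k] ** 2)
                        - 0.5 * ((y - mu[k]) / sd[k]) ** 2)
        m = log_p.max(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.exp(log_p - m)
        p[~np.isfinite(p)] = 0.0
        norm = p.sum(axis=0)
        if np.any(norm <= 0) or not np.all(np.isfinite(norm)):
            raise FloatingPointError("non-finite likelihood in EM segmentation")
        post = p / norm
        ll = float((m + np.log(norm)).sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood in EM segmentation")
        # M-step
        for k in range(n_classes):
            if not active[k]:
                continue
            w = post[k]
            ws = w.sum()
            if ws <= 0:
                continue
            mu[k] = (w * y).sum() / ws
            sd[k] = max(np.sqrt((w * (y - mu[k]) ** 2).sum() / ws), rng_floor)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll

    posterior = TissueProbabilityMap(post.reshape(tpm.probabilities.shape),
                                     img.voxel_size, img.affine)
    vox_ml = img.voxel_volume_ml
    volumes = {name: float(posterior.class_map(name).sum() * vox_ml)
               for name in TISSUE_CLASSES}
    tiv = sum(volumes.values())
    fractions = {name: (volumes[name] / tiv if tiv > 0 else 0.0)
                 for name in TISSUE_CLASSES}
    if tiv > 0:
        # absorb float round-off so the fractions sum to 1 exactly
        s = sum(fractions.values())
        fractions = {k: v / s for k, v in fractions.items()}
    return SegmentationResult(
        posterior=posterior, volumes_ml=volumes, tiv_ml=tiv, fractions=fractions,
        converged=converged, n_iterations=it, log_likelihood=ll,
        class_means={CLASS_NAMES[k]: float(mu[k]) for k in range(n_classes) if active[k]},
        class_sds={CLASS_NAMES[k]: float(sd[k]) for k in range(n_classes) if active[k]})


# --------------------------------------------------------------------------
# full per-subject chain
# --------------------------------------------------------------------------

def preprocess_subject(img: VolumeImage, tpm: TissueProbabilityMap,
                       t1_template: VolumeImage = None, slice_axis: int = 2,
                       register_dof: str = "full-affine"):
    """Run the fixed per-subject chain: slice correction -> denoise -> register
    -> segment.

    If ``t1_template`` is given, the denoised image is affinely registered to
    it and the template-space TPM is pulled back onto the subject grid through
    the inverse transform, so segmentation - and hence every reported volume -
    happens in native space (brain size must not be normalized away before
    volumetry).  Without a template the TPM is assumed to already live on the
    subject grid.

    Returns
    -------
    (SegmentationResult, dict)
        The segmentation and a dict of intermediate products (including the
        GM posterior resampled into template space when a template is given).
    """
    from .image import CLASS_NAMES  # local import to avoid cycle noise

    corrected, gains = correct_slice_inhomogeneity(img, axis=slice_axis)
    denoised = denoise_nlm(corrected)
    reg = None
    prior = tpm
    if t1_template is not None:
        reg = affine_register(denoised, t1_template, dof=register_dof)
        probs = np.stack([
            apply_registration_inverse(tpm.class_map(n), reg, denoised,
                                       tpm.voxel_size,
                                       cval=1.0 if n == "background" else 0.0)
            for n in CLASS_NAMES])
        probs = np.clip(probs, 0.0, 1.0)
        total = probs.sum(axis=0)
        total[total <= 0] = 1.0
        prior = TissueProbabilityMap(probs / total, denoised.voxel_size,
                                     denoised.affine)
    seg = segment_tpm(denoised, prior)
    out = {"corrected": corrected, "gains": gains, "denoised": denoised,
           "registration": reg}
    if reg is not None and t1_template is not None:
        out["gm_template_space"] = apply_registration(
            seg.posterior.gm, reg, denoised.voxel_size, t1_template)
    return seg, out
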