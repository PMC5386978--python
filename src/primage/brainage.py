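"""Brain age estimation: feature reduction, relevance vector regression, LOOCV.

The aging model maps preprocessed gray-matter probability maps to
chronological age.  The maps are smoothed (FWHM 3 mm), resampled to 3 mm,
masked, centered and reduced by PCA; a linear-kernel relevance vector
regression (RVR) - sparse Bayesian regression with one precision
hyperparameter per kernel basis, fitted by type-II maximum likelihood
fixed-point updates - then learns the multidimensional aging pattern.  No
free parameters need hand tuning: the hyperparameters are re-estimated from
the marginal likelihood during training.

Per-subject output is the estimated brain age BA_i; the brain age gap
(BrainAGE) score is BA_i - CA_i, positive when the brain looks older than
the calendar says.  Cohort accuracy is summarized by the mean absolute error
MAE = (1/n) * sum_i |BA_i - CA_i| and by Pearson's r between BA and CA,
pooled over leave-one-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.decomposition import PCA

from .image import smooth_fwhm

__all__ = [
    "FeatureReduction",
    "reduce_features",
    "transform_features",
    "RVRModel",
    "train_rvr",
    "predict_age",
    "BrainAgeResult",
    "loocv_brainage",
    "apply_trained_model",
    "human_equivalent_age",
    "prepare_map",
    "feature_age_snr",
]

#: Baboon-to-human age conversion factor (4 -> 14 y, 22 -> 77 y, 5 -> 17.5 y).
HUMAN_EQUIVALENT_FACTOR = 3.5


def human_equivalent_age(baboon_age):
    """Human-equivalent age for a baboon chronological age (factor 3.5)."""
    age = np.asarray(baboon_age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = HUMAN_EQUIVALENT_FACTOR * age
    return float(out) if np.isscalar(baboon_age) else out


# --------------------------------------------------------------------------
# feature reduction: smooth -> resample -> mask -> center -> PCA
# --------------------------------------------------------------------------

@dataclass
class FeatureReduction:
    """Fitted reduction: geometry, mask, PCA mean/basis and variances."""

    mask: np.ndarray              # boolean, original grid
    fwhm_mm: float
    resample_mm: float
    voxel_size: tuple             # original voxel size (mm)
    resampled_mask: np.ndarray    # boolean, resampled grid
    pca_mean: np.ndarray
    pca_basis: np.ndarray         # (k, p), rows orthonormal
    explained_variance: np.ndarray
    n_components: int

    def __post_init__(self):
        g = self.pca_basis @ self.pca_basis.T
        if not np.allclose(g, np.eye(len(g)), atol=1e-8):
            raise ValueError("PCA components must be orthonormal within 1e-8")
        ev = np.asarray(self.explained_variance)
        if np.any(np.diff(ev) > 1e-10):
            raise ValueError("explained variance must be non-increasing")


def prepare_map(map3d: np.ndarray, voxel_size, fwhm_mm: float, resample_mm: float,
                resampled_mask: np.ndarray = None):
    """Smooth and resample one map; optionally flatten through the mask.

    This is a purely per-subject operation (no cross-subject statistics), so
    it can be computed once per map even when the PCA is refit per fold.
    """
    sm = smooth_fwhm(np.asarray(map3d, dtype=float), fwhm_mm, voxel_size)
    zoom = [v / resample_mm for v in voxel_size]
    res = ndimage.zoom(sm, zoom, order=1)
    if resampled_mask is None:
        return res
    return res[resampled_mask]


def feature_age_snr(clean_maps, noisy_maps, ages, mask, voxel_size,
                    fwhm_mm: float = 3.0, resample_mm: float = 3.0) -> float:
    """Feature-space age SNR of a cohort of GM maps.

    Both map sets are pushed through the deterministic part of the reduction
    (smooth, resample, mask).  The age-attributable signal is the per-feature
    linear regression of the clean features on age; the SNR is the ratio of
    root-mean-square per-subject feature energies,

        SNR = sqrt( E ||age-signal deviation||^2 / E ||map noise||^2 ),

    i.e. how strongly the age pattern stands out against the voxel-level
    noise a subject's map carries into the regression.
    """
    ages = np.asarray(ages, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    rmask = _resample_mask(mask, voxel_size, resample_mm)
    clean = np.stack([prepare_map(m, voxel_size, fwhm_mm, resample_mm, rmask)
                      for m in clean_maps])
    noisy = np.stack([prepare_map(m, voxel_size, fwhm_mm, resample_mm, rmask)
                      for m in noisy_maps])
    Xc = clean - clean.mean(axis=0)
    a = ages - ages.mean()
    beta = Xc.T @ a / (a @ a)
    signal = np.mean(np.sum(np.outer(a, beta) ** 2, axis=1))
    noise = np.mean(np.sum((noisy - clean) ** 2, axis=1))
    if noise <= 0:
        return np.inf
    return float(np.sqrt(signal / noise))


def _resample_mask(mask: np.ndarray, voxel_size, resample_mm: float) -> np.ndarray:
    zoom = [v / resample_mm for v in voxel_size]
    return ndimage.zoom(mask.astype(float), zoom, order=1) > 0.5


def reduce_features(gm_maps, mask: np.ndarray, voxel_size, fwhm_mm: float = 3.0,
                    resample_mm: float = 3.0, n_components="max"):
    """Fit the reduction on a set of GM maps and return per-subject scores.

    Maps are smoothed (default FWHM 3 mm), resampled to the target resolution
    (default 3 mm, trilinear), flattened over the brain mask, centered and
    decomposed by PCA.  The number of components is capped at n - 1.

    Returns
    -------
    (FeatureReduction, np.ndarray)
        The fitted reduction and the (n, k) component-score matrix.
    """
    gm_maps = list(gm_maps)
    if len(gm_maps) < 2:
        raise ValueError("need at least two subjects to fit a reduction")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rmask = _resample_mask(mask, voxel_size, resample_mm)
    if not rmask.any():
        raise ValueError("mask vanished at the reduced resolution")
    X = np.stack([prepare_map(m, voxel_size, fwhm_mm, resample_mm, rmask)
                  for m in gm_maps])
    return fit_pca_reduction(X, mask, rmask, voxel_size, fwhm_mm, resample_mm,
                             n_components)


def fit_pca_reduction(X: np.ndarray, mask, rmask, voxel_size, fwhm_mm,
                      resample_mm, n_components="max"):
    """PCA on an already prepared (n, p) feature block."""
    n = X.shape[0]
    k_max = min(n - 1, X.shape[1])
    k = k_max if n_components == "max" else min(int(n_components), k_max)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    red = FeatureReduction(
        mask=np.asarray(mask, dtype=bool), fwhm_mm=float(fwhm_mm),
        resample_mm=float(resample_mm), voxel_size=tuple(voxel_size),
        resampled_mask=np.asarray(rmask, dtype=bool),
        pca_mean=pca.mean_.copy(), pca_basis=pca.components_.copy(),
        explained_variance=pca.explained_variance_.copy(), n_components=k)
    return red, scores


def transform_features(red: FeatureReduction, gm_maps) -> np.ndarray:
    """Project new GM maps through a fitted reduction."""
    X = np.stack([prepare_map(m, red.voxel_size, red.fwhm_mm, red.resample_mm,
                              red.resampled_mask) for m in gm_maps])
    return (X - red.pca_mean) @ red.pca_basis.T


# --------------------------------------------------------------------------
# relevance vector regression (linear kernel)
# --------------------------------------------------------------------------

@dataclass
class RVRModel:
    """Trained linear-kernel RVR.

    The design matrix is [1 | K] with K(x_i, x_j) = x_i . x_j over the
    training inputs; ``alpha`` holds the per-basis precisions after the
    type-II maximum-likelihood fixed point, ``retained`` the indices of the
    surviving (relevance) columns (0 = bias), and ``weights`` their posterior
    mean.
    """

    kernel: str
    training_inputs: np.ndarray   # (n, d) reference inputs for kernel evaluation
    weights: np.ndarray           # posterior mean over retained columns
    retained: np.ndarray          # column indices into [bias | training bases]
    alpha: np.ndarray             # precisions of retained columns
    beta: float                   # noise precision
    bias: float                   # weight of the bias column (0 if pruned)
    n_iterations: int = 0
    converged: bool = True
    log_marginal_likelihood: float = np.nan

    def __post_init__(self):
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if np.any(self.alpha <= 0) or self.beta <= 0:
            raise ValueError("precisions must be positive")
        n = self.training_inputs.shape[0]
        if np.any(self.retained < 0) or np.any(self.retained > n):
            raise ValueError("retained indices out of range")

    @property
    def n_relevance_vectors(self) -> int:
        """Number of retained training bases (bias excluded)."""
        return int(np.sum(self.retained > 0))


def _design(X: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X @ basis.T])


def _log_marginal(Phi_a, y, alpha_a, beta):
    n = len(y)
    C = Phi_a @ np.diag(1.0 / alpha_a) @ Phi_a.T + np.eye(n) / beta
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    sol = np.linalg.solve(C, y)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + y @ sol))


def train_rvr(X: np.ndarray, y: np.ndarray, max_iter: int = 500,
              prune_threshold: float = 1e6, tol: float = 1e-4,
              alpha_init: float = None, beta_init: float = None,
              update_hyperparams: bool = True) -> RVRModel:
    """Fit a linear-kernel RVR by iterative alpha/beta re-estimation.

    Implements the standard sparse-Bayesian fixed point: with design
    Phi = [1 | K], posterior covariance S = (beta Phi' Phi + A)^-1 and mean
    m = beta S Phi' y, the updates are gamma_i = 1 - alpha_i S_ii,
    alpha_i <- gamma_i / m_i^2 and
    beta <- (n - sum gamma) / ||y - Phi m||^2.  Columns whose precision
    exceeds ``prune_threshold`` are pruned.  The procedure is deterministic -
    there is no random initialization and no tuning parameter to optimize.

    ``update_hyperparams=False`` freezes alpha and beta at their initial
    values, in which case the posterior mean coincides with a generalized
    (per-basis) kernel ridge regression solution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 training subjects")
    if X.shape[0] != n or not np.all(np.isfinite(X)):
        raise ValueError("features must be finite with one row per subject")

    Phi = _design(X, X)
    n_basis = Phi.shape[1]
    var_y = float(np.var(y))
    alpha = np.full(n_basis, alpha_init if alpha_init is not None else 1.0 / n ** 2)
    beta = float(beta_init) if beta_init is not None else \
        (10.0 / var_y if var_y > 1e-12 else 1e6)

    active = alpha < prune_threshold
    m_full = np.zeros(n_basis)
    ll = np.nan
    it = 0
    converged = not update_hyperparams

    def posterior(active_mask, alpha_vec, beta_val):
        Phi_a = Phi[:, active_mask]
        A = np.diag(alpha_vec[active_mask])
        H = beta_val * (Phi_a.T @ Phi_a) + A
        for jitter in (0.0, 1e-8 * np.trace(H) / len(H)):
            try:
                S = np.linalg.inv(H + jitter * np.eye(len(H)))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise np.linalg.LinAlgError("singular RVR system (after ridge jitter)")
        m = beta_val * (S @ (Phi_a.T @ y))
        return Phi_a, S, m

    Phi_a, S, m = posterior(active, alpha, beta)
    if update_hyperparams:
        ll_old = -np.inf
        for it in range(1, max_iter + 1):
            gamma = 1.0 - alpha[active] * np.diag(S)
            gamma = np.clip(gamma, 1e-12, None)
            m_sq = np.clip(m ** 2, 1e-12, None)
            alpha_new = alpha.copy()
            alpha_new[active] = gamma / m_sq
            resid = y - Phi_a @ m
            denom = max(float(resid @ resid), 1e-12)
            beta_new = max((n - gamma.sum()) / denom, 1e-12)

            alpha, beta = alpha_new, beta_new
            active = alpha < prune_threshold
            if not active.any():
                active[np.argmin(alpha)] = True
            Phi_a, S, m = posterior(active, alpha, beta)
            ll = _log_marginal(Phi_a, y, alpha[active], beta)
            if np.isfinite(ll) and abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
                converged = True
                break
            ll_old = ll
    else:
        ll = _log_marginal(Phi_a, y, alpha[active], beta)

    m_full[:] = 0.0
    m_full[active] = m
    retained = np.flatnonzero(active)
    return RVRModel(
        kernel="linear", training_inputs=X.copy(), weights=m.copy(),
        retained=retained, alpha=alpha[active].copy(), beta=float(beta),
        bias=float(m_full[0]), n_iterations=it, converged=converged,
        log_marginal_likelihood=float(ll))


def predict_age(model: RVRModel, X: np.ndarray) -> np.ndarray:
    """Estimated ages for new feature rows (linear in the features)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.training_inputs.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the training "
            f"reference {model.training_inputs.shape[1]}")
    Phi = _design(X, model.training_inputs)
    pred = Phi[:, model.retained] @ model.weights
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("non-finite prediction")
    return pred


# --------------------------------------------------------------------------
# cohort-level results
# --------------------------------------------------------------------------

@dataclass
class BrainAgeResult:
    """Per-subject estimated ages and scores plus cohort accuracy.

    ``table`` has one row per subject with columns id, sex, group, age (CA),
    brain_age (BA) and score (BA - CA).  The score identity, MAE >= 0 and
    |r| <= 1 are enforced at construction.
    """

    table: pd.DataFrame
    mae: float
    r: float
    n: int

    def __post_init__(self):
        t = self.table
        if not np.allclose(t["score"], t["brain_age"] - t["age"], atol=1e-9):
            raise ValueError("score must equal brain_age - age for every subject")
        if self.mae < 0:
            raise ValueError("MAE must be >= 0")
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n != len(t):
            raise ValueError("n must match the table length")

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _result_from(meta: pd.DataFrame, ba: np.ndarray) -> BrainAgeResult:
    ca = meta["age"].to_numpy(dtype=float)
    ba = np.asarray(ba, dtype=float)
    table = pd.DataFrame({
        "id": meta["id"].to_numpy(),
        "sex": meta.get("sex", pd.Series(["?"] * len(meta))).to_numpy(),
        "group": meta.get("group", pd.Series(["CTR"] * len(meta))).to_numpy(),
        "age": ca,
        "brain_age": ba,
        "score": ba - ca,
    })
    mae = float(np.mean(np.abs(ba - ca)))
    if len(ca) >= 3 and np.std(ca) > 0 and np.std(ba) > 0:
        r = float(stats.pearsonr(ca, ba)[0])
    else:
        r = np.nan
    return BrainAgeResult(table=table, mae=mae, r=r, n=len(ca))


def loocv_brainage(gm_maps, metadata: pd.DataFrame, mask, voxel_size,
                   fwhm_mm: float = 3.0, resample_mm: float = 3.0,
                   n_components="max", refit_reduction_per_fold: bool = True,
                   **rvr_kwargs) -> BrainAgeResult:
    """Leave-one-out brain age estimation over a cohort.

    For every subject the reduction (centering + PCA) and the RVR are fitted
    on the remaining n - 1 subjects only - the held-out map never touches the
    training statistics - and the held-out subject's age is then predicted.
    Scores, MAE and Pearson r are pooled over all folds.

    ``refit_reduction_per_fold=False`` instead fits one global PCA on all n
    subjects (faster, but lets the held-out subject influence the basis).
    """
    gm_maps = list(gm_maps)
    n = len(gm_maps)
    if n < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    if len(metadata) != n:
        raise ValueError("metadata must have one row per map")
    mask = np.asarray(mask, dtype=bool)
    rmask = _resample_mask(mask, voxel_size, resample_mm)
    # smoothing/resampling is per-subject deterministic: safe to precompute
    prepared = np.stack([prepare_map(m, voxel_size, fwhm_mm, resample_mm, rmask)
                         for m in gm_maps])
    ages = metadata["age"].to_numpy(dtype=float)

    ba = np.empty(n)
    if refit_reduction_per_fold:
        for i in range(n):
            train = np.arange(n) != i
            try:
                red, scores = fit_pca_reduction(prepared[train], mask, rmask,
                                                voxel_size, fwhm_mm, resample_mm,
                                                n_components)
                model = train_rvr(scores, ages[train], **rvr_kwargs)
                held = (prepared[i] - red.pca_mean) @ red.pca_basis.T
                ba[i] = predict_age(model, held[None, :])[0]
            except Exception as exc:
                raise RuntimeError(f"LOOCV fold {i} "
                                   f"({metadata['id'].iloc[i]}) failed: {exc}") from exc
    else:
        red, scores = fit_pca_reduction(prepared, mask, rmask, voxel_size,
                                        fwhm_mm, resample_mm, n_components)
        for i in range(n):
            train = np.arange(n) != i
            try:
                model = train_rvr(scores[train], ages[train], **rvr_kwargs)
                ba[i] = predict_age(model, scores[i][None, :])[0]
            except Exception as exc:
                raise RuntimeError(f"LOOCV fold {i} "
                                   f"({metadata['id'].iloc[i]}) failed: {exc}") from exc
    return _result_from(metadata, ba)


def apply_trained_model(train_maps, train_metadata: pd.DataFrame, test_maps,
                        test_metadata: pd.DataFrame, mask, voxel_size,
                        fwhm_mm: float = 3.0, resample_mm: float = 3.0,
                        n_components="max", **rvr_kwargs):
    """Fit reduction + RVR on a training cohort, score a test cohort.

    Used for the experimental contrast: the aging model is trained once on
    the full lifespan cohort and then applied to the young-adult MNR/CTR
    subjects.  Returns the test-cohort :class:`BrainAgeResult` and the
    fitted ``(FeatureReduction, RVRModel)`` pair.
    """
    red, scores = reduce_features(train_maps, mask, voxel_size, fwhm_mm,
                                  resample_mm, n_components)
    model = train_rvr(scores, train_metadata["age"].to_numpy(dtype=float),
                      **rvr_kwargs)
    test_scores = transform_features(red, test_maps)
    ba = predict_age(model, test_scores)
    return _result_from(test_metadata, ba), (red, model)
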