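"""Preprocessing chain: slice gains, denoising, registration, segmentation."""

import numpy as np
import pytest
from scipy import ndimage

import primage as pm
from primage.preprocess import (affine_register, correct_slice_inhomogeneity,
                                denoise_nlm, preprocess_subject, segment_tpm)


class TestSliceCorrection:
    def test_exact_inverse_on_uniform_volume(self):
        """Periodic slice gains on a uniform volume are divided out exactly
        (away from the two outermost slices, where the running-median profile
        has no symmetric support)."""
        n = 48
        gains = np.tile([0.8, 1.0, 1.25], n // 3)
        img = pm.VolumeImage(np.full((n, n, n), 0.7) * gains[None, None, :],
                             (2.0, 2.0, 2.0))
        corr, _ = correct_slice_inhomogeneity(img)
        inner = corr.data[:, :, 2:-2]
        assert inner.std() / inner.mean() < 1e-9

    def test_identity_on_gain_free_volume(self, clean_phantom):
        _, img, _ = clean_phantom
        corr, gains = correct_slice_inhomogeneity(img)
        np.testing.assert_allclose(corr.data, img.data, atol=1e-6)
        np.testing.assert_allclose(gains, 1.0, atol=1e-6)

    def test_mean_intensity_preserved(self, clean_phantom):
        _, img, _ = clean_phantom
        rng = np.random.default_rng(0)
        gains = 1 + rng.normal(0, 0.05, img.shape[2])
        noisy = img.with_data(img.data * gains[None, None, :])
        corr, _ = correct_slice_inhomogeneity(noisy)
        assert corr.data.mean() == pytest.approx(noisy.data.mean(), rel=0.01)

    def test_known_gains_recovered_under_noise(self, clean_phantom):
        """Gains recovered within 2% RMS (up to overall scale) on slices with
        real foreground support, at 2% intensity noise."""
        _, img, _ = clean_phantom
        rng = np.random.default_rng(1)
        true_g = 1 + rng.normal(0, 0.05, img.shape[2])
        noisy = img.with_data(img.data * true_g[None, None, :]
                              + rng.normal(0, 0.018, img.shape))
        _, est = correct_slice_inhomogeneity(noisy)
        support = np.array([(img.data[:, :, k] > 0.1).sum()
                            for k in range(img.shape[2])])
        sl = support > 0.1 * support.max()
        ratio = est[sl] / true_g[sl]
        ratio /= ratio.mean()
        assert np.sqrt(np.mean((ratio - 1) ** 2)) < 0.02

    def test_all_zero_slices_get_unit_gain(self):
        data = np.zeros((10, 10, 10))
        data[:, :, 4:7] = 1.0
        _, gains = correct_slice_inhomogeneity(pm.VolumeImage(data, (2, 2, 2)))
        np.testing.assert_allclose(np.delete(gains, [4, 5, 6]), 1.0)

    def test_too_few_slices_raises(self):
        img = pm.VolumeImage(np.ones((8, 8, 2)), (2, 2, 2))
        with pytest.raises(ValueError, match="3 slices"):
            correct_slice_inhomogeneity(img)


class TestDenoiseNlm:
    def test_noise_free_input_passes_through(self, clean_phantom):
        _, img, _ = clean_phantom
        out = denoise_nlm(img)
        assert np.abs(out.data - img.data).max() <= 0.01 * img.data.max()

    def test_reduces_mse_against_clean_truth(self, clean_phantom):
        _, img, _ = clean_phantom
        rng = np.random.default_rng(2)
        noisy = img.with_data(img.data + rng.normal(0, 0.03, img.shape))
        out = denoise_nlm(noisy)
        mse_in = np.mean((noisy.data - img.data) ** 2)
        mse_out = np.mean((out.data - img.data) ** 2)
        assert mse_out < mse_in

    def test_halves_sd_on_constant_image(self):
        rng = np.random.default_rng(3)
        img = pm.VolumeImage(0.5 + rng.normal(0, 0.05, (32, 32, 32)), (2, 2, 2))
        out = denoise_nlm(img)
        assert out.data.std() < img.data.std() / 2

    def test_preserves_between_class_contrast(self, clean_phantom):
        """Tissue boundaries survive: post-filter GM/CSF contrast >= 90%."""
        _, img, truth = clean_phantom
        rng = np.random.default_rng(4)
        noisy = img.with_data(img.data + rng.normal(0, 0.03, img.shape))
        out = denoise_nlm(noisy)
        labels = truth.hard_labels()

        def contrast(d):
            return abs(d[labels == 0].mean() - d[labels == 2].mean())

        assert contrast(out.data) >= 0.9 * contrast(noisy.data)

    def test_invalid_radii_raise(self, clean_phantom):
        _, img, _ = clean_phantom
        with pytest.raises(ValueError):
            denoise_nlm(img, search_radius=0)


class TestAffineRegister:
    def test_identity_when_moving_equals_fixed(self, clean_phantom):
        _, img, _ = clean_phantom
        reg = affine_register(img, img, dof="rigid")
        assert np.abs(reg.parameters).max() < 1e-3
        np.testing.assert_allclose(reg.transform, np.eye(4), atol=1e-3)

    def test_recovers_two_voxel_translation(self, clean_phantom):
        _, img, _ = clean_phantom
        shifted = img.with_data(ndimage.shift(img.data, (2, 0, 0), order=1))
        reg = affine_register(shifted, img, dof="rigid")
        # pull-back convention: moving coordinates = fixed + 2 voxels
        t_vox = reg.parameters[:3] / np.asarray(img.voxel_size)
        np.testing.assert_allclose(t_vox, [2, 0, 0], atol=0.2)

    def test_recovers_ten_percent_scale(self, clean_phantom):
        _, img, _ = clean_phantom
        c = (np.asarray(img.shape) - 1) / 2
        A = np.eye(3) / 1.1
        scaled = img.with_data(ndimage.affine_transform(
            img.data, A, offset=c - A @ c, order=1))
        reg = affine_register(scaled, img, dof="scale-only")
        assert np.exp(reg.parameters[0]) == pytest.approx(1.1, rel=0.01)

    def test_resampled_lives_on_fixed_grid(self, clean_phantom):
        _, img, _ = clean_phantom
        shifted = img.with_data(ndimage.shift(img.data, (1, -1, 0), order=1))
        reg = affine_register(shifted, img, dof="rigid")
        assert reg.resampled.shape == img.shape
        # realignment restores most of the intensity agreement
        assert np.corrcoef(reg.resampled.data.ravel(),
                           img.data.ravel())[0, 1] > 0.98

    def test_unknown_dof_rejected(self, clean_phantom):
        _, img, _ = clean_phantom
        with pytest.raises(ValueError, match="dof"):
            affine_register(img, img, dof="nonlinear")


class TestSegmentTpm:
    def test_self_consistent_prior_near_perfect(self, clean_phantom):
        """Noise-free phantom with its own (smoothed) truth as prior."""
        spec, img, truth = clean_phantom
        seg = segment_tpm(img, truth.smoothed_renormalized(2.0))
        lt, ls = truth.hard_labels(), seg.posterior.hard_labels()
        for k, name in enumerate(("gm", "wm", "csf")):
            assert pm.dice_coefficient(lt, ls, k) >= 0.99
            true_ml = truth.class_volumes_ml()[name]
            assert seg.volumes_ml[name] == pytest.approx(true_ml, rel=0.01)

    def test_noisy_phantom_with_mis_scaled_prior(self, params):
        """3% noise and a 5% size-mis-scaled prior still give Dice >= 0.95."""
        noisy_params = pm.AgingModelParams(intensity_noise_sd=0.03)
        gm, wm, csf = pm.trajectory_fractions(noisy_params, "female", 9.0)
        spec = pm.PhantomSpec(pm.SubjectRecord("S", "female", 9.0),
                              gm, wm, csf, 190.0, 21)
        img, truth = pm.render_phantom(spec, noisy_params)
        sm = truth.smoothed_renormalized(2.0)
        c = (np.asarray(sm.shape) - 1) / 2
        A = np.eye(3) * 1.05
        probs = np.stack([ndimage.affine_transform(
            sm.class_map(n), A, offset=c - A @ c, order=1,
            cval=1.0 if n == "background" else 0.0) for n in pm.CLASS_NAMES])
        probs = np.clip(probs, 0, 1)
        tot = probs.sum(0)
        tot[tot <= 0] = 1
        prior = pm.TissueProbabilityMap(probs / tot, sm.voxel_size)
        seg = segment_tpm(img, prior)
        lt, ls = truth.hard_labels(), seg.posterior.hard_labels()
        for k in range(3):
            assert pm.dice_coefficient(lt, ls, k) >= 0.95

    def test_matches_flat_prior_em_oracle_on_1d_mixture(self):
        """Two-class 1-D Gaussian mixture, flat prior: class means agree with
        an independent brute-force EM to 1e-6."""
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0.3, 0.05, 400),
                            rng.normal(0.8, 0.05, 600)])
        vol = pm.VolumeImage(y.reshape(-1, 1, 1), (1, 1, 1))
        probs = np.zeros((4, y.size, 1, 1))
        probs[0] = probs[1] = 0.5   # flat two-class prior (GM/WM)
        prior = pm.TissueProbabilityMap(probs, (1, 1, 1))

        # independent oracle: textbook EM with fixed equal priors
        mu = np.array([(0.5 * y).mean() / 0.5] * 2)
        w = np.stack([np.full(y.size, 0.5)] * 2)
        mu = np.array([y[y < np.median(y)].mean(), y[y >= np.median(y)].mean()])
        sd = np.array([y.std(), y.std()])
        for _ in range(400):
            logp = np.stack([
                -0.5 * np.log(2 * np.pi * sd[k] ** 2)
                - 0.5 * ((y - mu[k]) / sd[k]) ** 2 + np.log(0.5)
                for k in range(2)])
            m = logp.max(0)
            p = np.exp(logp - m)
            p /= p.sum(0)
            for k in range(2):
                mu[k] = (p[k] * y).sum() / p[k].sum()
                sd[k] = np.sqrt((p[k] * (y - mu[k]) ** 2).sum() / p[k].sum())

        seg = segment_tpm(vol, prior, max_iter=400, tol=1e-12)
        got = sorted([seg.class_means["gm"], seg.class_means["wm"]])
        assert got == pytest.approx(sorted(mu.tolist()), abs=1e-6)

    def test_posterior_normalization_and_volume_identities(self, params,
                                                           small_cohort):
        img = small_cohort.images[0]
        prior = small_cohort.ground_truth[0].smoothed_renormalized(4.0)
        seg = segment_tpm(img, prior)
        sums = seg.posterior.probabilities.sum(axis=0)
        assert np.abs(sums - 1).max() < 1e-6
        assert sum(seg.fractions.values()) == pytest.approx(1.0, abs=1e-6)
        assert seg.tiv_ml == pytest.approx(sum(seg.volumes_ml.values()), abs=1e-6)

    def test_empty_class_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0.5, 0.05, (6, 6, 6))
        probs = np.zeros((4, 6, 6, 6))
        probs[0] = 1.0   # all prior mass on GM
        prior = pm.TissueProbabilityMap(probs, (1, 1, 1))
        with pytest.warns(UserWarning, match="zero prior mass"):
            seg = segment_tpm(pm.VolumeImage(y, (1, 1, 1)), prior)
        assert seg.volumes_ml["wm"] == 0.0

    def test_geometry_mismatch_raises(self, clean_phantom):
        _, img, truth = clean_phantom
        probs = truth.probabilities[:, ::2, ::2, ::2].copy()
        tot = probs.sum(0)
        tot[tot <= 0] = 1
        small = pm.TissueProbabilityMap(probs / tot, truth.voxel_size)
        with pytest.raises(ValueError, match="registered"):
            segment_tpm(img, small)


class TestFullChain:
    def test_stages_are_idempotent_safe_on_clean_input(self, clean_phantom):
        """Slice correction and denoising change an artifact-free image <= 1%."""
        _, img, _ = clean_phantom
        corr, _ = correct_slice_inhomogeneity(img)
        den = denoise_nlm(corr)
        scale = img.data.max()
        assert np.abs(corr.data - img.data).max() <= 0.01 * scale
        assert np.abs(den.data - img.data).max() <= 0.01 * scale

    def test_preprocess_subject_recovers_volumes(self, params):
        noisy_params = pm.AgingModelParams(intensity_noise_sd=0.02)
        cohort = pm.generate_cohort(noisy_params, n_per_sex=(1, 0), master_seed=6)
        img, truth = cohort.images[0], cohort.ground_truth[0]
        prior = truth.smoothed_renormalized(4.0)
        seg, inter = preprocess_subject(img, prior)
        true_tiv = sum(truth.class_volumes_ml().values())
        assert seg.tiv_ml == pytest.approx(true_tiv, rel=0.05)
        assert set(inter) >= {"corrected", "gains", "denoised"}
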