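"""Fourier-amplitude features and the cross-validated linear SVM."""

import numpy as np
import pytest

from coneobserver import amplitude_features, train_and_evaluate
from coneobserver.inference import TrialSet, stimulus_band_mask
from coneobserver.mosaic import sample_mean_at_shift
from coneobserver.runner import simulate_trialset, trial_mean_maps


def _trialset(features, labels, phases=None, contrast=0.05):
    phases = np.full(len(labels), 90.0) if phases is None else phases
    return TrialSet(
        features=np.asarray(features, dtype=np.float32),
        labels=np.asarray(labels),
        phases=np.asarray(phases),
        contrast=contrast,
    )


class TestAmplitudeFeatures:
    def test_uniform_image_is_pure_dc(self):
        n, c = 16, 3.5
        movie = np.full((n, n, 2), c)
        f = amplitude_features(movie).reshape(2, n, n)
        assert f[0, 0, 0] == pytest.approx(c * n * n, rel=1e-6)
        f[:, 0, 0] = 0
        assert np.allclose(f, 0.0, atol=1e-6)

    def test_matches_full_fft_magnitudes(self):
        rng = np.random.default_rng(0)
        movie = rng.poisson(50.0, size=(21, 21, 4)).astype(float)
        f = amplitude_features(movie).reshape(4, 21, 21)
        ref = np.abs(np.fft.fft2(np.moveaxis(movie, -1, 0), axes=(1, 2)))
        assert np.allclose(f, ref, rtol=1e-5)

    def test_phase_pair_invariance_on_uniform_mosaic(self, maps_default, mosaic_small):
        """On a single-cone-type mosaic the two stimulus phases are
        indistinguishable in the amplitude domain (the Gabor has no DC)."""
        m = mosaic_small
        mono = type(m)(
            grid=np.zeros_like(m.grid), density_deg2=m.density_deg2, fov_deg=m.fov_deg,
            lms_ratio=(1, 0, 0), coverage=m.coverage, seed=m.seed,
        )
        f = {}
        for phase in (90.0, 270.0):
            mm = trial_mean_maps(maps_default, 0.8, 15.0, phase, mono)
            means = sample_mean_at_shift(mm, maps_default.irr_grid, mono)
            f[phase] = amplitude_features(means[:, :, None])
        # non-DC amplitudes are exactly equal; the DC bin differs only by the
        # sub-pixel sampling residual of the zero-mean Gabor deviation
        a = f[90.0].reshape(mono.n, mono.n).copy()
        b = f[270.0].reshape(mono.n, mono.n).copy()
        assert abs(a[0, 0] - b[0, 0]) < 1e-4 * a[0, 0]
        a[0, 0] = b[0, 0] = 0.0
        assert np.allclose(a, b, atol=1e-6 * np.abs(a).max())

    def test_translation_invariance_on_uniform_mosaic(self, maps_default, mosaic_small):
        """Translating the noiseless absorption image leaves amplitudes unchanged."""
        m = mosaic_small
        mono = type(m)(
            grid=np.zeros_like(m.grid), density_deg2=m.density_deg2, fov_deg=m.fov_deg,
            lms_ratio=(1, 0, 0), coverage=m.coverage, seed=m.seed,
        )
        mm = trial_mean_maps(maps_default, 0.8, 15.0, 90.0, mono)
        base = sample_mean_at_shift(mm, maps_default.irr_grid, mono, (0, 0))
        rolled = np.roll(base, (0, 2), axis=(0, 1))
        fa = amplitude_features(base[:, :, None])
        fb = amplitude_features(rolled[:, :, None])
        assert np.allclose(fa, fb, rtol=1e-9)
        # the physically sampled 2-cone shift agrees closely on the bins that
        # carry energy (residual differences come from the sub-pixel
        # interpolation of the incommensurate cone/irradiance grids)
        shifted = sample_mean_at_shift(mm, maps_default.irr_grid, mono, (2, 0))
        fc = amplitude_features(shifted[:, :, None])
        strong = fa > 0.01 * fa.max()
        assert np.all(np.abs(fa[strong] - fc[strong]) / fa[strong] < 0.12)
        a, c = fa.copy(), fc.copy()
        a[0] = c[0] = 0.0
        cosine = np.dot(a, c) / (np.linalg.norm(a) * np.linalg.norm(c))
        assert cosine > 0.999


class TestTrainAndEvaluate:
    def test_perfectly_separated_classes(self):
        rng = np.random.default_rng(1)
        n = 40
        x = rng.normal(0, 1.0, size=(2 * n, 30))
        x[:n, 0] += 10.0
        y = np.r_[np.ones(n), -np.ones(n)]
        res = train_and_evaluate(_trialset(x, y), folds=10, seed=0)
        assert res.accuracy == 1.0

    def test_chance_on_unlabelable_noise(self):
        rng = np.random.default_rng(2)
        accs = []
        for rep in range(10):
            x = rng.normal(size=(60, 40))
            y = np.r_[np.ones(30), -np.ones(30)]
            accs.append(train_and_evaluate(_trialset(x, y), folds=10, seed=rep).accuracy)
        assert 0.42 < np.mean(accs) < 0.58

    def test_permutation_null_is_chance(self):
        """Permuting labels on separable data destroys performance."""
        rng = np.random.default_rng(3)
        n = 30
        x = rng.normal(0, 1.0, size=(2 * n, 25))
        x[:n, 0] += 5.0
        accs = []
        for rep in range(20):
            y = np.r_[np.ones(n), -np.ones(n)]
            rng.shuffle(y)
            accs.append(train_and_evaluate(_trialset(x, y), folds=10, seed=rep).accuracy)
        assert 0.42 < np.mean(accs) < 0.58

    def test_degenerate_features_rejected(self):
        x = np.zeros((40, 10))
        y = np.r_[np.ones(20), -np.ones(20)]
        with pytest.raises(ValueError, match="degenerate"):
            train_and_evaluate(_trialset(x, y), folds=10)

    def test_too_few_trials_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 5))
        y = np.r_[np.ones(5), -np.ones(5)]
        with pytest.raises(ValueError, match="trials per class"):
            train_and_evaluate(_trialset(x, y), folds=10)


@pytest.fixture(scope="module")
def high_contrast_result(small_config, maps_default, mosaic_small):
    seeds = np.arange(1000, 1000 + 60)
    trials = simulate_trialset(small_config, maps_default, mosaic_small, 0.10, seeds)
    return train_and_evaluate(trials, folds=10, seed=0, compute_weight_map=True)


class TestPipelineClassification:
    def test_high_contrast_is_classifiable(self, high_contrast_result):
        assert high_contrast_result.accuracy >= 0.75

    def test_weights_concentrate_at_stimulus_band(self, high_contrast_result, mosaic_small):
        """Fold- and frame-averaged |w| peaks at the 4-cpd, +/-15-deg band."""
        wm = np.abs(high_contrast_result.weight_map.mean(axis=0))
        mask = stimulus_band_mask(mosaic_small.n, mosaic_small.fov_deg)
        ratio = wm[mask].mean() / wm[~mask].mean()
        assert ratio >= 2.0

    def test_zero_contrast_at_chance(self, small_config, maps_default, mosaic_small):
        seeds = np.arange(2000, 2000 + 60)
        trials = simulate_trialset(small_config, maps_default, mosaic_small, 0.0, seeds)
        res = train_and_evaluate(trials, folds=10, seed=1)
        assert 0.35 <= res.accuracy <= 0.65
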