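"""Behavioral inference: Fourier-amplitude features and a linear SVM.

The decision stage mimics an observer who knows that spatial frequency and
orientation — but not phase — are task-relevant: each m x m absorption
image is transformed by the 2-D FFT and only the amplitudes are kept
(phase is discarded), so a pure image translation or a 180-deg stimulus
phase flip leaves the features of a single-cone-type mosaic unchanged. The
28 per-frame amplitude images of a trial are concatenated into one feature
vector of length 28*m^2. A linear support-vector machine with per-feature
standardization is trained and scored with stratified 10-fold
cross-validation, separately at each stimulus contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .mosaic import AbsorptionMovie


def amplitude_features(movie: AbsorptionMovie | np.ndarray) -> np.ndarray:
    """Per-frame 2-D FFT amplitude spectrum, concatenated over frames.

    Input counts are (n, n, n_time); the output vector has length
    n_time * n^2. Amplitudes are kept unshifted (DC in the corner), with
    the full conjugate-symmetric redundancy retained (reconstructed from the
    real-input half-spectrum transform for speed).
    """
    counts = movie.counts if isinstance(movie, AbsorptionMovie) else movie
    # frames-first layout so each frame's amplitudes are contiguous
    frames = np.moveaxis(counts, -1, 0).astype(np.float64)
    n = frames.shape[1]
    half = np.abs(np.fft.rfft2(frames, axes=(1, 2)))  # (T, n, n//2 + 1)
    amps = np.empty(frames.shape, dtype=np.float32)
    k = half.shape[2]
    amps[:, :, :k] = half
    # |F(u, v)| = |F(-u mod n, -v mod n)| fills the redundant columns
    mirror_rows = (-np.arange(n)) % n
    amps[:, :, k:] = half[:, mirror_rows, :][:, :, n - np.arange(k, n)]
    return amps.reshape(len(frames), -1).reshape(-1)


@dataclass
class TrialSet:
    """Feature matrix and labels for one contrast level."""

    features: np.ndarray  # (n_trials, n_time * m^2) float32
    labels: np.ndarray  # (n_trials,) in {+1 clockwise, -1 counter-clockwise}
    phases: np.ndarray  # (n_trials,) stimulus phase (deg), for stratification
    contrast: float
    frame_shape: tuple[int, int, int] = (0, 0, 0)  # (n_time, m, m)

    def __post_init__(self):
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")


@dataclass
class ClassifierResult:
    """Cross-validated accuracy and the learned weight map diagnostic."""

    accuracy: float
    fold_accuracies: np.ndarray
    contrast: float
    weight_map: np.ndarray | None = None  # (n_time, m, m) signed fold-averaged w, fftshifted

    def __repr__(self):  # noqa: D105
        return (
            f"ClassifierResult(contrast={self.contrast:.4g}, "
            f"accuracy={self.accuracy:.3f}, folds={len(self.fold_accuracies)})"
        )


def _standardize(x: np.ndarray, train: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    """Z-score all rows using mean/sd fit on the training rows only.

    ``out`` lets callers reuse one buffer across folds; feature matrices can
    reach hundreds of MB for dense mosaics, and reallocating per fold costs
    more than the arithmetic.
    """
    mu = x[train].mean(axis=0)
    sd = x[train].std(axis=0)
    sd[sd == 0] = 1.0
    z = np.subtract(x, mu, out=out)
    np.divide(z, sd, out=z)
    return z


def _fit_fold(z, y, train, test, C, seed):
    """Linear SVM on a standardized fold via a precomputed gram matrix."""
    k_full = z @ z.T  # one BLAS gram; folds slice it without row copies
    clf = SVC(C=C, kernel="precomputed", random_state=seed)
    clf.fit(k_full[np.ix_(train, train)].astype(np.float64), y[train])
    acc = float(clf.score(k_full[np.ix_(test, train)].astype(np.float64), y[test]))
    return clf, acc


def train_and_evaluate(
    trials: TrialSet,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    compute_weight_map: bool = False,
) -> ClassifierResult:
    """Stratified k-fold cross-validated linear-SVM accuracy.

    Standardization statistics are fit on each training fold only (no
    leakage); folds are stratified jointly by class and stimulus phase so
    every fold sees the same label/phase balance. The linear kernel is
    evaluated as a precomputed gram matrix, which is exact and far faster
    than primal solvers in this wide (features >> trials) regime.
    """
    x, y = trials.features, trials.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} trials per class for {folds}-fold CV")
    if float(np.ptp(x)) == 0.0:
        raise ValueError("degenerate features: zero variance everywhere")

    strata = np.asarray(
        [f"{label}:{phase}" for label, phase in zip(y, trials.phases)]
    )
    want_w = compute_weight_map and trials.frame_shape[1] > 0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    w_sum = None
    buf = np.empty_like(x, dtype=np.float32)
    for train, test in skf.split(x, strata):
        z = _standardize(x, train, out=buf)
        clf, acc = _fit_fold(z, y, train, test, C, seed)
        accs.append(acc)
        if want_w:
            # primal weights from the dual solution: w = sum_i alpha_i y_i z_i
            w = clf.dual_coef_[0] @ z[train][clf.support_]
            w_sum = w if w_sum is None else w_sum + w
    accs = np.asarray(accs)

    weight_map = None
    if want_w:
        # signed fold-averaged weights per frame; averaging signed weights
        # (over folds, and over frames downstream) cancels noise-driven
        # components while task-driven ones persist
        w = w_sum / folds
        n_time, m, _ = trials.frame_shape
        weight_map = np.fft.fftshift(w.reshape(n_time, m, m), axes=(1, 2))
    return ClassifierResult(
        accuracy=float(accs.mean()),
        fold_accuracies=accs,
        contrast=trials.contrast,
        weight_map=weight_map,
    )


def stimulus_band_mask(
    m: int,
    samples_fov_deg: float,
    freq_cpd: float = 4.0,
    orientations_deg: tuple[float, float] = (-15.0, 15.0),
    freq_halfwidth_cpd: float = 1.5,
    angle_halfwidth_deg: float = 25.0,
) -> np.ndarray:
    """Boolean mask (fftshifted m x m) of the stimulus frequency/orientation band.

    Marks amplitude-spectrum locations within ``freq_halfwidth_cpd`` of the
    carrier frequency and within ``angle_halfwidth_deg`` of either stimulus
    orientation (both signs of the spectrum).
    """
    freqs = np.fft.fftshift(np.fft.fftfreq(m, d=samples_fov_deg / m))
    fx, fy = np.meshgrid(freqs, freqs)
    fr = np.hypot(fx, fy)
    # orientation of the modulation axis: stripes tilted t deg cw from
    # vertical modulate along an axis t deg from horizontal
    ang = np.rad2deg(np.arctan2(fy, fx))
    mask = np.zeros((m, m), dtype=bool)
    for orient in orientations_deg:
        for a0 in (orient, orient + 180.0):
            d = np.abs((ang - a0 + 180.0) % 360.0 - 180.0)
            mask |= (np.abs(fr - freq_cpd) <= freq_halfwidth_cpd) & (d <= angle_halfwidth_deg)
    return mask


def results_to_csv(results: list[ClassifierResult], file, n_trials: int, seed: int) -> None:
    """Write per-contrast fold accuracies as CSV."""
    import csv

    writer = csv.writer(file)
    nfold = len(results[0].fold_accuracies) if results else 0
    writer.writerow(
        ["contrast", "mean_accuracy"]
        + [f"fold{i}" for i in range(nfold)]
        + ["n_trials", "seed"]
    )
    for r in results:
        writer.writerow(
            [r.contrast, f"{r.accuracy:.4f}"]
            + [f"{a:.4f}" for a in r.fold_accuracies]
            + [n_trials, seed]
        )
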