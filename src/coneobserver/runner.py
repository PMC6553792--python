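"""Experiment orchestration: full simulated 2-AFC experiments and sweeps.

A simulated experiment presents ``trials_per_contrast`` trials at each
contrast level (half clockwise +15 deg, half counter-clockwise -15 deg;
within each class the spatial phase is 90 or 270 deg, randomized when phase
randomization is on), passes each trial through optics, eye movements and
the cone mosaic, classifies orientation from the Fourier amplitudes of the
absorption movies, and fits a Weibull threshold to the accuracy-vs-contrast
curve. Experiments are repeated ``n_repeats`` times with a freshly
randomized cone-type arrangement; accuracies are averaged across repeats
before the summary threshold fit, and per-repeat thresholds give the
standard error.

Because the scene radiance is affine in contrast, the retinal irradiance of
any stimulus is the background plus contrast times a fixed deviation image;
only the two +/-15 deg unit-contrast deviations (phase 270 being the sign
flip of phase 90) and the background require optics convolutions, and all
contrast levels share them.

Every stochastic draw (mosaic arrangement, eye movements, photon noise,
fold assignment) descends from ``master_seed`` through a fixed
``SeedSequence`` spawning order, so reruns are bit-identical regardless of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import eyemove, psychofit
from .inference import TrialSet, amplitude_features, train_and_evaluate
from .mosaic import ConeMosaic, build_mosaic, sample_mean_at_shift, unit_absorption_maps
from .optics import OpticsModel, apply_optics, defocus_um_to_diopters, psf_stack
from .scene import GaborSpec, SceneParams, make_gabor_scene


def default_contrast_levels(n: int = 15, lo: float = 0.0005, hi: float = 0.10,
                            include_zero: bool = True) -> list[float]:
    """Log-spaced contrast grid in [lo, hi] plus the 0% sanity level."""
    levels = list(np.geomspace(lo, hi, n))
    return ([0.0] + levels) if include_zero else levels


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulated experiment."""

    contrast_levels: list[float] = field(default_factory=default_contrast_levels)
    trials_per_contrast: int = 400
    n_repeats: int = 5
    scene: SceneParams = field(default_factory=SceneParams)
    optics: OpticsModel = field(default_factory=OpticsModel)
    density_deg2: float = 1560.0
    lms_ratio: tuple[float, float, float] = (0.6, 0.3, 0.1)
    coverage: float | str = 0.49
    eye_movements: bool = True
    phase_randomization: bool = True
    drift: eyemove.DriftParams = field(default_factory=eyemove.DriftParams)
    microsaccades: eyemove.MicrosaccadeParams = field(default_factory=eyemove.MicrosaccadeParams)
    folds: int = 10
    svm_c: float = 1.0
    master_seed: int = 1

    def scaled(self, factor: float) -> "ExperimentConfig":
        """Proportionally reduced trials/levels/repeats for desk-scale runs."""
        if not (0 < factor <= 1):
            raise ValueError("scale factor must lie in (0, 1]")
        nz = [c for c in self.contrast_levels if c > 0]
        n_levels = max(4, int(round(len(nz) * factor)))
        lo, hi = min(nz), max(nz)
        levels = [0.0] + list(np.geomspace(lo, hi, n_levels)) if 0.0 in self.contrast_levels else list(
            np.geomspace(lo, hi, n_levels)
        )
        per_cell = max(self.folds // 2, int(round(self.trials_per_contrast * factor / 4)))
        return replace(
            self,
            contrast_levels=levels,
            trials_per_contrast=4 * per_cell,
            n_repeats=max(1, int(round(self.n_repeats * factor))),
        )

    def validate(self) -> None:
        n_classes = 2
        n_phases = 2 if self.phase_randomization else 1
        per_cell = self.trials_per_contrast / (n_classes * n_phases)
        if per_cell != int(per_cell) or per_cell < 1:
            raise ValueError(
                f"trials_per_contrast={self.trials_per_contrast} does not divide evenly "
                f"into {n_classes} classes x {n_phases} phases"
            )
        if self.trials_per_contrast // 2 < self.folds:
            raise ValueError("too few trials per class for the requested folds")
        # eye-movement excursions must stay within the optical padding
        max_cones = int(self.optics.pad_deg / (self.scene.fov_deg / max(1, round(
            self.scene.fov_deg * np.sqrt(self.density_deg2)))))
        if self.eye_movements and max_cones < 2:
            raise ValueError("optical padding too small for eye movements at this density")


@dataclass
class StimulusMaps:
    """Cached per-type mean-absorption components for one scene/optics setup.

    Maps are stored per unit collecting area (1 m^2) and are therefore
    shared across mosaics and densities; a mosaic's aperture area scales
    them to per-cone means.
    """

    background: np.ndarray  # (3, H, W) unit-area expected counts per bin, 0% contrast
    deviation: dict[float, np.ndarray]  # orientation -> (3, H, W), unit contrast, phase 90
    irr_grid: object  # RetinalIrradiance carrying the spatial grid
    dt_ms: float


_MAPS_CACHE: dict[tuple, StimulusMaps] = {}


def _maps_key(scene_params: SceneParams, optics_model: OpticsModel) -> tuple:
    return (
        scene_params.fov_deg, scene_params.samples_per_deg, scene_params.dt_ms,
        scene_params.duration_ms, scene_params.mean_luminance_cd_m2,
        scene_params.spatial_freq_cpd, scene_params.gaussian_sd_deg,
        scene_params.luminosity, tuple(scene_params.wavelengths),
        tuple(optics_model.zernike_coeffs_um), optics_model.pupil_diameter_mm,
        optics_model.measured_pupil_mm, optics_model.in_focus_wavelength_nm,
        optics_model.added_defocus_um, optics_model.pad_deg,
        optics_model.psf_oversample, optics_model.pupil_grid,
    )


def build_stimulus_maps(
    scene_params: SceneParams, optics_model: OpticsModel, mosaic: ConeMosaic | None = None
) -> StimulusMaps:
    """Run the optics once per unique stimulus component and cache cone-mean maps.

    Only the two +/-15 deg unit-contrast deviations need convolution (the
    background is uniform, and phase 270 is the sign flip of phase 90); the
    PSF stack is computed once and shared. Results are memoized per
    scene/optics setting (they are deterministic and mosaic-independent).
    """
    key = _maps_key(scene_params, optics_model)
    if key in _MAPS_CACHE:
        return _MAPS_CACHE[key]
    psfs = psf_stack(optics_model, scene_params.wavelengths, scene_params.samples_per_deg)
    bg_scene = make_gabor_scene(GaborSpec(michelson_contrast=0.0), scene_params)
    irr_bg = apply_optics(bg_scene, optics_model, psfs)
    bg_maps = unit_absorption_maps(irr_bg, scene_params.dt_ms)
    deviation = {}
    for orient in (-15.0, 15.0):
        sc = make_gabor_scene(
            GaborSpec(orientation_deg=orient, phase_deg=90.0, michelson_contrast=1.0),
            scene_params,
        )
        irr = apply_optics(sc, optics_model, psfs)
        deviation[orient] = unit_absorption_maps(irr, scene_params.dt_ms) - bg_maps
    maps = StimulusMaps(
        background=bg_maps, deviation=deviation, irr_grid=irr_bg, dt_ms=scene_params.dt_ms
    )
    if len(_MAPS_CACHE) > 16:  # bound memory across long sweeps
        _MAPS_CACHE.clear()
    _MAPS_CACHE[key] = maps
    return maps


def trial_mean_maps(
    maps: StimulusMaps,
    contrast: float,
    orientation: float,
    phase: float,
    mosaic: ConeMosaic | None = None,
) -> np.ndarray:
    """Noiseless (3, H, W) mean maps for one stimulus condition.

    Scaled to per-cone means when a mosaic is given; otherwise per unit
    collecting area.
    """
    sign = 1.0 if phase == 90.0 else -1.0
    out = np.clip(maps.background + sign * contrast * maps.deviation[orientation], 0.0, None)
    if mosaic is not None:
        out = out * mosaic.aperture_area_m2
    return out


def simulate_trialset(
    config: ExperimentConfig,
    maps: StimulusMaps,
    mosaic: ConeMosaic,
    contrast: float,
    trial_seeds: np.ndarray,
) -> TrialSet:
    """Simulate one contrast level's trials and featurize them."""
    n_time = config.scene.n_time
    n_phases = 2 if config.phase_randomization else 1
    per_cell = config.trials_per_contrast // (2 * n_phases)
    conds = [
        (orient, phase)
        for orient in (15.0, -15.0)
        for phase in ((90.0, 270.0) if config.phase_randomization else (90.0,))
        for _ in range(per_cell)
    ]
    mean_cache: dict[tuple[float, float], np.ndarray] = {}
    feats = np.empty((len(conds), n_time * mosaic.n**2), dtype=np.float32)
    labels = np.empty(len(conds), dtype=int)
    phases = np.empty(len(conds))
    for i, (orient, phase) in enumerate(conds):
        rng = np.random.default_rng(trial_seeds[i])
        if (orient, phase) not in mean_cache:
            mean_cache[(orient, phase)] = trial_mean_maps(maps, contrast, orient, phase, mosaic)
        mm = mean_cache[(orient, phase)]
        path = eyemove.simulate_em_path(
            config.scene.duration_ms,
            mosaic.pitch_arcmin,
            config.scene.dt_ms,
            config.drift,
            config.microsaccades,
            enabled=config.eye_movements,
            seed=rng,
        )
        # rare microsaccade excursions beyond the padded field stop at its
        # edge, where the image is the uniform surround anyway
        max_shift = int(maps.irr_grid.pad_deg / mosaic.pitch_deg)
        shifts = np.clip(path.shifts, -max_shift, max_shift)
        shift_cache: dict[tuple[int, int], np.ndarray] = {}
        means = np.empty((mosaic.n, mosaic.n, n_time))
        for t in range(n_time):
            sh = (int(shifts[t, 0]), int(shifts[t, 1]))
            if sh not in shift_cache:
                shift_cache[sh] = sample_mean_at_shift(mm, maps.irr_grid, mosaic, sh)
            means[:, :, t] = shift_cache[sh]
        counts = rng.poisson(means)
        feats[i] = amplitude_features(counts)
        labels[i] = 1 if orient > 0 else -1
        phases[i] = phase
    return TrialSet(
        features=feats, labels=labels, phases=phases, contrast=contrast,
        frame_shape=(n_time, mosaic.n, mosaic.n),
    )


@dataclass
class ExperimentResult:
    """Results table plus summary psychometric fit for one experiment."""

    table: pd.DataFrame  # rows: repeat, contrast, accuracy
    fit: psychofit.PsychometricFit  # on repeat-averaged accuracies
    per_repeat_thresholds: np.ndarray  # percent contrast, nan when unidentifiable
    config: ExperimentConfig

    @property
    def threshold_percent(self) -> float:
        return self.fit.threshold_percent

    @property
    def threshold_se_percent(self) -> float:
        t = self.per_repeat_thresholds
        t = t[np.isfinite(t)]
        if len(t) < 2:
            return float("nan")
        return float(np.std(t, ddof=1) / np.sqrt(len(t)))


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run one full (or scaled) simulated experiment. See the module docstring."""
    config.validate()
    root = np.random.SeedSequence(config.master_seed)
    repeat_seeds = root.spawn(config.n_repeats)
    maps = build_stimulus_maps(config.scene, config.optics)

    rows = []
    for r, rseq in enumerate(repeat_seeds):
        mosaic_seed, *contrast_seeds = rseq.spawn(1 + len(config.contrast_levels))
        mosaic = build_mosaic(
            config.density_deg2,
            config.scene.fov_deg,
            config.lms_ratio,
            config.coverage,
            seed=mosaic_seed.generate_state(1)[0] % (2**31),
        )
        for ci, contrast in enumerate(config.contrast_levels):
            cseq = contrast_seeds[ci]
            seeds = cseq.generate_state(config.trials_per_contrast + 1)
            trials = simulate_trialset(config, maps, mosaic, contrast, seeds[:-1])
            res = train_and_evaluate(
                trials, folds=config.folds, seed=int(seeds[-1] % (2**31)), C=config.svm_c
            )
            rows.append({"repeat": r, "contrast": contrast, "accuracy": res.accuracy})
            if progress:
                print(f"  repeat {r} contrast {contrast:.4f}: acc {res.accuracy:.3f}", flush=True)

    table = pd.DataFrame(rows)
    mean_acc = table.groupby("contrast")["accuracy"].mean()
    fit = psychofit.fit_threshold(mean_acc.index.values, mean_acc.values)
    per_rep = []
    for r in range(config.n_repeats):
        sub = table[table["repeat"] == r]
        f = psychofit.fit_threshold(sub["contrast"].values, sub["accuracy"].values)
        per_rep.append(f.threshold_percent if f.identifiable else np.nan)
    return ExperimentResult(
        table=table, fit=fit, per_repeat_thresholds=np.asarray(per_rep), config=config
    )


def ideal_observer_curve(
    config: ExperimentConfig,
    contrast_grid,
    maps: StimulusMaps | None = None,
    mosaic: ConeMosaic | None = None,
    n_simulated: int = 0,
    seed: int = 0,
):
    """Closed-form ideal-observer percent correct across a contrast grid.

    Uses the same noiseless cone templates as the SVM pipeline for the
    single-phase (90 deg), no-eye-movement condition. Returns a DataFrame of
    (contrast, dprime, pc_closed_form[, pc_simulated]) plus the Weibull
    threshold fit of the closed-form curve.
    """
    from .ideal import IdealTemplates, dprime_closed_form, ideal_decision_simulated

    if mosaic is None:
        mosaic = build_mosaic(
            config.density_deg2, config.scene.fov_deg, config.lms_ratio,
            config.coverage, seed=config.master_seed,
        )
    if maps is None:
        maps = build_stimulus_maps(config.scene, config.optics, mosaic)
    n_time = config.scene.n_time
    rows = []
    rng = np.random.default_rng(seed)
    for c in np.asarray(list(contrast_grid), dtype=float):
        a = sample_mean_at_shift(trial_mean_maps(maps, c, 15.0, 90.0, mosaic), maps.irr_grid, mosaic)
        b = sample_mean_at_shift(trial_mean_maps(maps, c, -15.0, 90.0, mosaic), maps.irr_grid, mosaic)
        tpl = IdealTemplates(
            alpha=np.repeat(a.ravel(), n_time), beta=np.repeat(b.ravel(), n_time), contrast=c
        )
        res = dprime_closed_form(tpl)
        row = {"contrast": c, "dprime": res.dprime, "pc_closed_form": res.percent_correct}
        if n_simulated:
            row["pc_simulated"] = ideal_decision_simulated(tpl, n_simulated, rng).percent_correct
        rows.append(row)
    df = pd.DataFrame(rows)
    fit = None
    if len(df) >= 4:
        fit = psychofit.fit_threshold(df["contrast"].values, df["pc_closed_form"].values)
    return df, fit


SWEEP_FORMS = {"defocus": "linear", "lmratio": "quadratic", "density": "log-linear"}


@dataclass
class SweepResult:
    """Thresholds across a factor grid plus the factor-curve fit."""

    factor: str
    grid: np.ndarray  # factor values as fitted (diopters, pL, cones/deg^2)
    thresholds_percent: np.ndarray
    factor_fit: psychofit.FactorFit
    experiments: list[ExperimentResult]

    def required_change(self, delta_threshold_pp: float) -> float:
        return psychofit.required_factor_change(self.factor_fit, delta_threshold_pp)


def sweep(
    config: ExperimentConfig, factor: str, grid, progress: bool = False
) -> SweepResult:
    """Run one experiment per grid point of a biological factor.

    ``factor`` is 'defocus' (grid in um of added Zernike defocus; fitted
    against the labelled diopters), 'lmratio' (grid of L-cone probabilities
    in an L/M-only mosaic) or 'density' (grid in cones/deg^2 with coverage
    auto-derived from equivalent eccentricity).
    """
    if factor not in SWEEP_FORMS:
        raise ValueError(f"unknown sweep factor {factor!r}")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")
    results = []
    fitted_x = []
    for g in grid:
        if factor == "defocus":
            cfg = replace(config, optics=replace(config.optics, added_defocus_um=float(g)))
            fitted_x.append(defocus_um_to_diopters(float(g), cfg.optics.pupil_diameter_mm))
        elif factor == "lmratio":
            cfg = replace(config, lms_ratio=(float(g), 1.0 - float(g), 0.0))
            fitted_x.append(float(g))
        else:
            cfg = replace(config, density_deg2=float(g), coverage="auto")
            fitted_x.append(float(g))
        if progress:
            print(f"sweep {factor} = {g}", flush=True)
        results.append(run_experiment(cfg, progress=progress))
    thresholds = np.asarray([r.threshold_percent for r in results])
    fit = psychofit.fit_factor_curve(fitted_x, thresholds, SWEEP_FORMS[factor])
    return SweepResult(
        factor=factor, grid=np.asarray(fitted_x), thresholds_percent=thresholds,
        factor_fit=fit, experiments=results,
    )
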