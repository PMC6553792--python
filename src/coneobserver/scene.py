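"""Hyperspectral scene radiance of the oriented-Gabor stimulus.

The 2-AFC task uses achromatic Gabor patches (4 cycles/deg carrier, 0.5 deg
Gaussian envelope) tilted +/-15 deg from vertical with spatial phase 90 or
270 deg, shown for 54 ms on a 100 cd/m^2 background. The scene is the
spectral photon radiance of the display: a 64 x 64 x 31 x 28 array
(row x col x wavelength x time) in quanta/s/sr/nm/m^2, flat in quantal units
across wavelength, identical at all 28 time points (no temporal envelope).

The background quantal radiance is scaled at construction so the mean
photopic luminance is exactly ``mean_luminance_cd_m2``; with the embedded
CIE 1924 table this lands within a few percent of the nominal
3.8e15 quanta/s/sr/nm/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spectra

ALLOWED_ORIENTATIONS = (-15.0, 15.0)
ALLOWED_PHASES = (90.0, 270.0)

#: nominal flat quantal background radiance [quanta/s/sr/nm/m^2]
NOMINAL_BACKGROUND_RADIANCE = 3.8e15


@dataclass(frozen=True)
class SceneParams:
    """Geometry, sampling and photometry of the stimulus scene."""

    fov_deg: float = 2.0
    samples_per_deg: int = 32
    dt_ms: float = 2.0
    duration_ms: float = 54.0
    mean_luminance_cd_m2: float = 100.0
    spatial_freq_cpd: float = 4.0
    gaussian_sd_deg: float = 0.5
    luminosity: str = "cie1924"
    wavelengths: np.ndarray = field(default_factory=lambda: spectra.WAVELENGTHS.copy())

    @property
    def n_spatial(self) -> int:
        return int(round(self.fov_deg * self.samples_per_deg))

    @property
    def n_time(self) -> int:
        # time points at 0, dt, ..., duration inclusive (54 ms -> 28 frames)
        return int(round(self.duration_ms / self.dt_ms)) + 1

    @property
    def n_wave(self) -> int:
        return len(self.wavelengths)

    def spatial_axis_deg(self) -> np.ndarray:
        """Pixel-center coordinates in degrees, patch centered at 0."""
        n = self.n_spatial
        pitch = self.fov_deg / n
        return (np.arange(n) - (n - 1) / 2.0) * pitch

    def background_radiance(self) -> float:
        """Flat quantal radiance giving the requested mean luminance.

        Solves 683 * sum(V(l) * R * hc/l * dl) = L for R.
        """
        v = spectra.luminosity_function(self.luminosity)
        dl = float(np.mean(np.diff(self.wavelengths)))
        energy = spectra.quanta_to_watts(self.wavelengths)
        per_unit = 683.0 * float(np.sum(v * energy)) * dl
        return self.mean_luminance_cd_m2 / per_unit


@dataclass(frozen=True)
class GaborSpec:
    """One stimulus condition: orientation (deg cw from vertical), phase, contrast."""

    orientation_deg: float = 15.0
    phase_deg: float = 90.0
    michelson_contrast: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.michelson_contrast <= 1.0):
            raise ValueError(
                f"michelson_contrast must lie in [0, 1], got {self.michelson_contrast}"
            )
        if self.orientation_deg not in ALLOWED_ORIENTATIONS:
            raise ValueError(
                f"orientation_deg must be one of {ALLOWED_ORIENTATIONS}, got {self.orientation_deg}"
            )
        if self.phase_deg not in ALLOWED_PHASES:
            raise ValueError(f"phase_deg must be one of {ALLOWED_PHASES}, got {self.phase_deg}")


@dataclass
class Scene:
    """Time-varying spectral radiance movie of one stimulus."""

    radiance: np.ndarray  # (row, col, wavelength, time), quanta/s/sr/nm/m^2
    params: SceneParams
    spec: GaborSpec

    @property
    def background(self) -> float:
        return self.params.background_radiance()


def gabor_pattern(
    spec: GaborSpec, params: SceneParams, x_deg: np.ndarray | None = None
) -> np.ndarray:
    """Unit-amplitude oriented Gabor G(x, y) on the scene's spatial grid.

    Carrier cos(2*pi*f*u + phi) along the axis u perpendicular to the
    stripes, orientation measured clockwise from vertical, phase origin at
    the patch center; windowed by an isotropic Gaussian (sd 0.5 deg).
    """
    x = params.spatial_axis_deg() if x_deg is None else x_deg
    xx, yy = np.meshgrid(x, x, indexing="xy")  # rows are y, columns x
    th = np.deg2rad(spec.orientation_deg)
    # u: distance along the modulation axis for stripes tilted th cw from vertical
    u = xx * np.cos(th) + yy * np.sin(th)
    carrier = np.cos(
        2.0 * np.pi * params.spatial_freq_cpd * u + np.deg2rad(spec.phase_deg)
    )
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * params.gaussian_sd_deg**2))
    g = carrier * envelope
    # unit peak on the realized grid so the frame's Michelson contrast is
    # exactly the requested value (the two allowed phases are symmetric, so
    # the normalization preserves their sign-reversal relation)
    return g / np.max(np.abs(g))


def make_gabor_scene(spec: GaborSpec, params: SceneParams | None = None) -> Scene:
    """Build the hyperspectral radiance movie for one Gabor stimulus.

    radiance(x, y, l, t) = R_bg(l) * (1 + c * G(x, y)); all frames identical.
    """
    params = params or SceneParams()
    bg = params.background_radiance()
    g = gabor_pattern(spec, params)
    frame = bg * (1.0 + spec.michelson_contrast * g)  # (n, n)
    radiance = np.broadcast_to(
        frame[:, :, None, None], (params.n_spatial, params.n_spatial, params.n_wave, params.n_time)
    ).copy()
    return Scene(radiance=radiance, params=params, spec=spec)


def scene_luminance(scene: Scene, frame: int = 0) -> np.ndarray:
    """Photopic luminance map [cd/m^2] of one scene frame.

    Integrates quanta -> watts converted radiance against the chosen
    luminosity table with the standard 683 lm/W scaling.
    """
    params = scene.params
    v = spectra.luminosity_function(params.luminosity)
    dl = float(np.mean(np.diff(params.wavelengths)))
    energy = spectra.quanta_to_watts(params.wavelengths)
    weights = 683.0 * v * energy * dl  # per quantal-radiance unit
    return np.tensordot(scene.radiance[:, :, :, frame], weights, axes=([2], [0]))


def michelson_contrast(image: np.ndarray) -> float:
    """(max - min) / (max + min) of a non-negative pattern."""
    hi, lo = float(np.max(image)), float(np.min(image))
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def save_scene(scene: Scene, path) -> None:
    """Write a scene to an HDF5 container with its parameters as attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("radiance", data=scene.radiance, compression="gzip")
        for key in (
            "fov_deg", "samples_per_deg", "dt_ms", "duration_ms",
            "mean_luminance_cd_m2", "spatial_freq_cpd", "gaussian_sd_deg",
        ):
            d.attrs[key] = getattr(scene.params, key)
        d.attrs["luminosity"] = scene.params.luminosity
        f.create_dataset("wavelengths", data=scene.params.wavelengths)
        g = f.create_group("spec")
        g.attrs["orientation_deg"] = scene.spec.orientation_deg
        g.attrs["phase_deg"] = scene.spec.phase_deg
        g.attrs["michelson_contrast"] = scene.spec.michelson_contrast


def load_scene(path) -> Scene:
    """Read a scene previously written by :func:`save_scene`."""
    import h5py

    with h5py.File(path, "r") as f:
        d = f["radiance"]
        attrs = dict(d.attrs)
        params = SceneParams(
            fov_deg=float(attrs["fov_deg"]),
            samples_per_deg=int(attrs["samples_per_deg"]),
            dt_ms=float(attrs["dt_ms"]),
            duration_ms=float(attrs["duration_ms"]),
            mean_luminance_cd_m2=float(attrs["mean_luminance_cd_m2"]),
            spatial_freq_cpd=float(attrs["spatial_freq_cpd"]),
            gaussian_sd_deg=float(attrs["gaussian_sd_deg"]),
            luminosity=str(attrs["luminosity"]),
            wavelengths=np.asarray(f["wavelengths"]),
        )
        spec = GaborSpec(
            orientation_deg=float(f["spec"].attrs["orientation_deg"]),
            phase_deg=float(f["spec"].attrs["phase_deg"]),
            michelson_contrast=float(f["spec"].attrs["michelson_contrast"]),
        )
        return Scene(radiance=np.asarray(d), params=params, spec=spec)
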