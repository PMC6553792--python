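"""Rectangular L/M/S cone mosaics and Poisson photon absorptions.

A mosaic is an n x n uniformly spaced rectangular grid of typed cones over a
2-deg patch, with n = round(fov * sqrt(density)) (79 cones across for the
1,560 cones/deg^2 density matched to ~4.5 deg eccentricity). Cone types are
assigned independently at random with the requested L:M:S probabilities.
Each cone collects photons over a square aperture of area coverage/density
(photons falling in the gaps between apertures are lost); coverage declines
with equivalent eccentricity from 1 at the fovea to 0.25 at 40 deg.

Per 2-ms sample the noiseless absorption mean of a cone is the spectral
irradiance at its (eye-movement shifted) position, integrated against its
photopigment absorptance and scaled by the peak isomerization efficiency
(66.67%) and the aperture collecting area; counts are independent Poisson
draws around those means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import map_coordinates

from . import spectra
from .optics import RetinalIrradiance

CONE_TYPES = ("L", "M", "S")

# Synthetic nasal-meridian cone density table [cones/deg^2 vs deg eccentricity],
# a monotone curve anchored at the literature values used by the model:
# 22,500 at 0 deg, 1,560 at 4.5 deg, 466 at 40 deg; intermediate points follow
# the classic steep foveal falloff with a shallow far periphery.
_ECC_DEG = np.array([0.0, 1.0, 2.0, 3.0, 4.5, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0])
_DENSITY_DEG2 = np.array(
    [22500.0, 9800.0, 5200.0, 3100.0, 1560.0, 1290.0, 1050.0, 900.0, 740.0, 640.0, 535.0, 466.0]
)

_density_of_ecc = PchipInterpolator(_ECC_DEG, np.log10(_DENSITY_DEG2))

#: coverage decay constant [deg]; solves 0.25 + 0.75 exp(-4.5/tau) = 0.49
_COVERAGE_TAU = 4.5 / np.log(0.75 / 0.24)


def density_to_eccentricity(density_deg2: float) -> float:
    """Equivalent retinal eccentricity [deg] for a cone density [cones/deg^2]."""
    lo, hi = _DENSITY_DEG2[-1], _DENSITY_DEG2[0]
    if not (lo <= density_deg2 <= hi):
        raise ValueError(
            f"density {density_deg2} outside the embedded table range [{lo}, {hi}]"
        )
    if density_deg2 == hi:
        return 0.0
    if density_deg2 == lo:
        return float(_ECC_DEG[-1])
    # exact inverse of the monotone density curve
    from scipy.optimize import brentq

    target = np.log10(density_deg2)
    return float(brentq(lambda e: _density_of_ecc(e) - target, 0.0, _ECC_DEG[-1]))


def eccentricity_to_density(ecc_deg: float) -> float:
    """Cone density [cones/deg^2] at a retinal eccentricity [deg]."""
    if not (0.0 <= ecc_deg <= _ECC_DEG[-1]):
        raise ValueError(f"eccentricity {ecc_deg} outside the table range [0, 40]")
    return float(10.0 ** _density_of_ecc(ecc_deg))


def coverage_at_eccentricity(ecc_deg: float) -> float:
    """Cone coverage fraction kappa(e) = 0.25 + 0.75 exp(-e/tau).

    Offset exponential hitting the three anchors kappa(0)=1,
    kappa(4.5)=0.49, kappa(40)~=0.25.
    """
    if ecc_deg < 0:
        raise ValueError("eccentricity must be non-negative")
    return 0.25 + 0.75 * float(np.exp(-ecc_deg / _COVERAGE_TAU))


def cone_quantal_sensitivity(cone_type: str, wavelength_nm=None, normalize_peak: bool = True):
    """Photopigment quantal sensitivity of one cone type (no pre-retinal filtering).

    Self-screened absorptance (1 - 10**(-OD*A)) with axial optical density
    0.5/0.5/0.4 for L/M/S; normalized to unit peak by default (divide by
    1 - 10**(-OD)); with ``normalize_peak=False`` the raw absorptance is
    returned (peak 0.684/0.684/0.602).
    """
    if cone_type not in CONE_TYPES:
        raise ValueError(f"unknown cone type {cone_type!r}")
    wl = spectra.WAVELENGTHS if wavelength_nm is None else np.asarray(wavelength_nm, dtype=float)
    od = spectra.PIGMENT_OPTICAL_DENSITY[cone_type]
    absorbance = spectra.photopigment_absorbance(cone_type, wl)
    absorptance = 1.0 - 10.0 ** (-od * absorbance)
    if normalize_peak:
        return absorptance / (1.0 - 10.0 ** (-od))
    return absorptance


def peak_absorptance(cone_type: str) -> float:
    """1 - 10**(-OD): the un-normalization factor for the assembled efficiency."""
    od = spectra.PIGMENT_OPTICAL_DENSITY[cone_type]
    return 1.0 - 10.0 ** (-od)


@dataclass
class ConeMosaic:
    """Rectangular grid of typed cones covering a square patch."""

    grid: np.ndarray  # (n, n) array of 0 (L), 1 (M), 2 (S)
    density_deg2: float
    fov_deg: float
    lms_ratio: tuple[float, float, float]
    coverage: float
    seed: int
    equivalent_eccentricity_deg: float = field(default=np.nan)

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def pitch_deg(self) -> float:
        return self.fov_deg / self.n

    @property
    def pitch_arcmin(self) -> float:
        return 60.0 * self.pitch_deg

    @property
    def aperture_area_m2(self) -> float:
        """Collecting area per cone: coverage/density, converted to m^2 of retina."""
        area_deg2 = self.coverage / self.density_deg2
        return area_deg2 * (spectra.MM_PER_DEG * 1e-3) ** 2

    def positions_deg(self) -> np.ndarray:
        """Cone-center coordinates along one axis, patch centered at 0."""
        return (np.arange(self.n) - (self.n - 1) / 2.0) * self.pitch_deg

    def type_counts(self) -> dict[str, int]:
        return {t: int(np.sum(self.grid == i)) for i, t in enumerate(CONE_TYPES)}


def build_mosaic(
    density_deg2: float = 1560.0,
    fov_deg: float = 2.0,
    lms_ratio: tuple[float, float, float] = (0.6, 0.3, 0.1),
    coverage: float | str = 0.49,
    seed: int = 0,
) -> ConeMosaic:
    """Assemble a rectangular mosaic; cone types are i.i.d. draws per position.

    ``coverage='auto'`` derives coverage from the density's equivalent
    eccentricity via :func:`coverage_at_eccentricity`.
    """
    if density_deg2 <= 0:
        raise ValueError("density must be positive")
    ratio = np.asarray(lms_ratio, dtype=float)
    if abs(ratio.sum() - 1.0) > 1e-9:
        raise ValueError(f"lms_ratio must sum to 1, got {ratio.sum()!r}")
    ecc = density_to_eccentricity(density_deg2)
    if coverage == "auto":
        coverage = coverage_at_eccentricity(ecc)
    coverage = float(coverage)
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    n = int(round(fov_deg * np.sqrt(density_deg2)))
    rng = np.random.default_rng(seed)
    grid = rng.choice(3, size=(n, n), p=ratio)
    return ConeMosaic(
        grid=grid,
        density_deg2=float(density_deg2),
        fov_deg=float(fov_deg),
        lms_ratio=tuple(ratio),
        coverage=coverage,
        seed=int(seed),
        equivalent_eccentricity_deg=ecc,
    )


@dataclass
class AbsorptionMovie:
    """Per-cone Poisson photon counts per time bin for one trial."""

    counts: np.ndarray  # (n, n, n_time) integers
    mosaic: ConeMosaic
    dt_ms: float
    meta: dict = field(default_factory=dict)

    def rate_per_ms(self, cone_type: str) -> float:
        """Mean photons/ms over all cones of one type and all time bins."""
        idx = CONE_TYPES.index(cone_type)
        mask = self.mosaic.grid == idx
        if not mask.any():
            return float("nan")
        return float(self.counts[mask].mean() / self.dt_ms)


def unit_absorption_maps(irr: RetinalIrradiance, dt_ms: float) -> np.ndarray:
    """Per-type absorption-mean maps for a unit (1 m^2) collecting area.

    Returns a (3, H, W) array: expected photons per ``dt_ms`` bin per m^2 of
    aperture for a cone of each type centered at each irradiance pixel.
    Mosaic-independent; multiply by a mosaic's aperture area to obtain its
    per-cone means.
    """
    wl = irr.wavelengths
    dl = float(np.mean(np.diff(wl)))
    frame = irr.irradiance[:, :, :, 0]  # identical across time
    maps = np.empty((3,) + frame.shape[:2])
    for i, t in enumerate(CONE_TYPES):
        sens = cone_quantal_sensitivity(t, wl, normalize_peak=False)
        weights = sens * spectra.PEAK_EFFICIENCY * dl * (dt_ms * 1e-3)
        maps[i] = np.tensordot(frame, weights, axes=([2], [0]))
    return maps


def mean_absorption_maps(irr: RetinalIrradiance, mosaic: ConeMosaic, dt_ms: float) -> np.ndarray:
    """Noiseless per-type absorption-mean maps on the irradiance grid.

    Expected photons per ``dt_ms`` bin for a cone of each type centered at
    each irradiance pixel, using the mosaic's aperture collecting area.
    Spatial sampling to cone positions happens later (bilinear, sub-pixel).
    """
    return unit_absorption_maps(irr, dt_ms) * mosaic.aperture_area_m2


def sample_mean_at_shift(
    maps: np.ndarray,
    irr: RetinalIrradiance,
    mosaic: ConeMosaic,
    shift_cones: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Per-cone noiseless means for one integer eye-position shift.

    The retinal image is sampled at each cone center displaced by
    ``shift_cones`` (in cone-pitch units); bilinear interpolation handles the
    incommensurate cone/irradiance grids.
    """
    ax = irr.spatial_axis_deg()
    pitch_px = 1.0 / (ax[1] - ax[0])  # irradiance pixels per degree
    pos = mosaic.positions_deg()
    dx, dy = shift_cones
    max_off = max(abs(dx), abs(dy)) * mosaic.pitch_deg
    if max_off > irr.pad_deg + 1e-9:
        raise ValueError(
            f"eye-movement shift {shift_cones} cones exceeds the {irr.pad_deg} deg padding"
        )
    # map cone coordinates (deg) into fractional pixel indices
    col = (pos + dx * mosaic.pitch_deg - ax[0]) * pitch_px
    row = (pos + dy * mosaic.pitch_deg - ax[0]) * pitch_px
    rr, cc = np.meshgrid(row, col, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    out = np.empty((mosaic.n, mosaic.n))
    for i in range(3):
        vals = map_coordinates(maps[i], coords, order=1, mode="nearest").reshape(
            mosaic.n, mosaic.n
        )
        out[mosaic.grid == i] = vals[mosaic.grid == i]
    return out


def compute_isomerizations(
    irr: RetinalIrradiance,
    mosaic: ConeMosaic,
    em_path=None,
    seed: int | np.random.Generator = 0,
    dt_ms: float = 2.0,
    n_time: int | None = None,
    meta: dict | None = None,
) -> AbsorptionMovie:
    """Poisson absorption counts for one trial under an eye-movement path.

    ``em_path`` is a :class:`~coneobserver.eyemove.ConeShiftPath` (or None for
    a stationary eye); its per-bin integer shifts select where each cone
    samples the padded retinal image.
    """
    if n_time is None:
        n_time = irr.irradiance.shape[3]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maps = mean_absorption_maps(irr, mosaic, dt_ms)

    if em_path is None:
        shifts = [(0, 0)] * n_time
    else:
        shifts = [tuple(s) for s in em_path.shifts[:n_time]]
        if len(shifts) < n_time:
            raise ValueError("eye-movement path shorter than the trial")

    cache: dict[tuple[int, int], np.ndarray] = {}
    means = np.empty((mosaic.n, mosaic.n, n_time))
    for t, sh in enumerate(shifts):
        if sh not in cache:
            cache[sh] = sample_mean_at_shift(maps, irr, mosaic, sh)
        means[:, :, t] = cache[sh]
    counts = rng.poisson(means)
    return AbsorptionMovie(counts=counts, mosaic=mosaic, dt_ms=dt_ms, meta=meta or {})
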