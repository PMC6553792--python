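"""Wavefront optics: scene radiance -> retinal irradiance.

The eye's optics are described by the first 15 OSA-indexed Zernike
coefficients (microns of wavefront error over a 3-mm pupil), in focus at
550 nm. For each wavelength the pupil function is built from the Zernike
phase map plus the longitudinal chromatic aberration expressed as an
equivalent defocus coefficient; the PSF is |FT(pupil)|^2, unit-normalized
and box-integrated down to the scene's angular sampling. Each wavelength
plane of the scene is convolved with its PSF, multiplied by the lens and
macular pigment transmittance, converted from radiance to retinal
irradiance by the pupil/eye geometry factor, and finally padded by 0.25 deg
per side with the mean intensity at that wavelength (so cones near the
patch edge keep a defined input when the eye moves).

Following the convention of population wavefront statistics, the Zernike
coefficients (including any added defocus) describe the wavefront over a
``measured_pupil_mm`` aperture (default 7.5 mm); the PSF is computed over the
smaller simulation pupil by evaluating that wavefront on the central
``pupil_diameter_mm`` disc. Added defocus is nevertheless *labelled* in
diopters via the simulation-pupil conversion (1 um <-> 3.08 D at 3 mm), the
labelling used for the threshold-versus-defocus summaries; the effective
dioptric blur over the 3-mm pupil is (3/7.5)^2 = 0.16 of that label, which
is why moderate labelled defocus reduces contrast at 4 cycles/deg only
modestly.

The default coefficient vector represents a typical healthy eye: zero
defocus at the in-focus wavelength and population-typical amounts of
astigmatism, coma, trefoil and spherical aberration for a 7.5-mm measured
pupil, standing in for a draw from a population wavefront model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy.signal import fftconvolve

from . import spectra
from .scene import Scene

#: representative typical-eye OSA Zernike coefficients c0..c14 [um, 7.5-mm pupil]
DEFAULT_ZERNIKE_UM = np.array([
    0.0, 0.0, 0.0,          # piston, tilt x2 (no image effect / ignored)
    0.15, 0.0, 0.35,        # oblique astig, defocus (best focus at 550), astig
    -0.15, -0.10, 0.22, 0.10,       # trefoil, coma x2, trefoil
    0.05, -0.03, 0.04, 0.02, -0.03,  # quadrafoil..secondary astig..spherical..
])


def defocus_um_to_diopters(c4_um: float, pupil_diameter_mm: float) -> float:
    """OSA defocus coefficient (um) -> equivalent defocus in diopters.

    D = 4*sqrt(3) * c4 / r^2 with r the pupil radius in mm (1 um at a 3-mm
    pupil is 3.08 D).
    """
    if pupil_diameter_mm <= 0:
        raise ValueError("pupil diameter must be positive")
    r = pupil_diameter_mm / 2.0
    return 4.0 * np.sqrt(3.0) * c4_um / r**2


def diopters_to_defocus_um(diopters: float, pupil_diameter_mm: float) -> float:
    """Inverse of :func:`defocus_um_to_diopters`."""
    if pupil_diameter_mm <= 0:
        raise ValueError("pupil diameter must be positive")
    r = pupil_diameter_mm / 2.0
    return diopters * r**2 / (4.0 * np.sqrt(3.0))


def lca_defocus(wavelength_nm: float, in_focus_nm: float = 550.0) -> float:
    """Longitudinal chromatic aberration [diopters] relative to the in-focus wavelength.

    Uses the reduced "chromatic eye" dispersion formula
    D(lambda) = p - q / (lambda_um - c) with p=1.7312, q=0.63346, c=0.21410
    (Thibos et al. 1992), re-referenced so the value at ``in_focus_nm`` is
    zero. Negative (myopic) for wavelengths shorter than the reference.
    """
    p, q, c = 1.7312, 0.63346, 0.21410

    def d(l_nm: float) -> float:
        return p - q / (l_nm * 1e-3 - c)

    return d(float(wavelength_nm)) - d(float(in_focus_nm))


# OSA single-index -> (n, m)
def _osa_nm(j: int) -> tuple[int, int]:
    n = int(np.ceil((-3 + np.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def zernike(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """OSA-normalized Zernike polynomial Z_j on the unit pupil (RMS = 1)."""
    n, m = _osa_nm(j)
    am = abs(m)
    # radial polynomial
    R = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        coef = ((-1) ** k * factorial(n - k)
                / (factorial(k)
                   * factorial((n + am) // 2 - k)
                   * factorial((n - am) // 2 - k)))
        R += coef * rho ** (n - 2 * k)
    norm = np.sqrt(2 * (n + 1)) if m != 0 else np.sqrt(n + 1.0)
    if m > 0:
        return norm * R * np.cos(am * theta)
    if m < 0:
        return norm * R * np.sin(am * theta)
    return norm * R


@dataclass
class OpticsModel:
    """Zernike wavefront optics plus pre-retinal spectral filtering."""

    zernike_coeffs_um: np.ndarray = field(default_factory=lambda: DEFAULT_ZERNIKE_UM.copy())
    pupil_diameter_mm: float = 3.0
    measured_pupil_mm: float = 7.5
    in_focus_wavelength_nm: float = 550.0
    added_defocus_um: float = 0.0
    pad_deg: float = 0.25
    #: PSF oversampling relative to the scene grid (odd not required)
    psf_oversample: int = 5
    #: pupil-plane FFT grid size
    pupil_grid: int = 512

    def __post_init__(self):
        self.zernike_coeffs_um = np.asarray(self.zernike_coeffs_um, dtype=float)
        if self.zernike_coeffs_um.shape != (15,):
            raise ValueError("zernike_coeffs_um must have length 15 (OSA j=0..14)")
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil diameter must be positive")

    @property
    def total_defocus_um(self) -> float:
        return float(self.zernike_coeffs_um[4] + self.added_defocus_um)

    def geometry_factor(self) -> float:
        """Solid angle [sr] converting radiance to retinal irradiance."""
        area_m2 = np.pi * (self.pupil_diameter_mm * 1e-3 / 2.0) ** 2
        return area_m2 / spectra.EYE_FOCAL_LENGTH_M**2


@dataclass
class RetinalIrradiance:
    """Padded spectral irradiance at the retina, quanta/s/nm/m^2."""

    irradiance: np.ndarray  # (row, col, wavelength, time)
    wavelengths: np.ndarray
    samples_per_deg: int
    pad_deg: float
    fov_deg: float  # padded field of view

    @property
    def pad_px(self) -> int:
        return int(round(self.pad_deg * self.samples_per_deg))

    def spatial_axis_deg(self) -> np.ndarray:
        n = self.irradiance.shape[0]
        pitch = 1.0 / self.samples_per_deg
        return (np.arange(n) - (n - 1) / 2.0) * pitch


def wavefront_to_psf(
    model: OpticsModel, wavelength_nm: float, samples_per_deg: int, kernel_deg: float = 2.0
) -> np.ndarray:
    """PSF at one wavelength, sampled on the scene's angular grid.

    The pupil function is evaluated on a ``pupil_grid``^2 complex array whose
    sample spacing is chosen per wavelength so the FFT yields a PSF pixel of
    1 / (samples_per_deg * psf_oversample) degrees; the fine PSF is then
    box-integrated to the scene pitch over a ``kernel_deg`` support and
    normalized to unit sum.
    """
    N = model.pupil_grid
    over = model.psf_oversample
    dtheta_rad = np.deg2rad(1.0 / (samples_per_deg * over))
    lam_m = wavelength_nm * 1e-9
    dp = lam_m / (N * dtheta_rad)  # pupil-plane sample spacing [m]
    d_m = model.pupil_diameter_mm * 1e-3
    n_across = d_m / dp
    if n_across > N:
        raise ValueError(
            "angular sampling too coarse: pupil support exceeds the FFT grid; "
            "increase pupil_grid or reduce psf_oversample"
        )
    if n_across < 16:
        raise ValueError("angular sampling too fine: pupil under-sampled")

    ax = (np.arange(N) - N // 2) * dp
    xx, yy = np.meshgrid(ax, ax)
    r = np.sqrt(xx**2 + yy**2)
    rho_calc = r / (d_m / 2.0)
    rho_meas = r / (model.measured_pupil_mm * 1e-3 / 2.0)
    theta = np.arctan2(yy, xx)
    inside = rho_calc <= 1.0

    # coefficient wavefront lives on the measured-pupil basis
    coeffs = model.zernike_coeffs_um.copy()
    coeffs[4] = model.total_defocus_um
    wavefront_um = np.zeros_like(r)
    for j in range(3, 15):  # piston/tilt do not shape the PSF
        if coeffs[j] != 0.0:
            wavefront_um += coeffs[j] * zernike(j, np.where(inside, rho_meas, 0.0), theta)
    # chromatic defocus is physical dioptric power over the simulation pupil;
    # myopic (negative-diopter) error maps to positive Zernike defocus
    # (spherical equivalent M = -4*sqrt(3)*c4/r^2), so short wavelengths get
    # positive c4 and added positive defocus refocuses toward long wavelengths
    c4_lca = diopters_to_defocus_um(
        -lca_defocus(wavelength_nm, model.in_focus_wavelength_nm), model.pupil_diameter_mm
    )
    if c4_lca != 0.0:
        wavefront_um += c4_lca * zernike(4, np.where(inside, rho_calc, 0.0), theta)

    pupil = np.where(inside, np.exp(1j * 2.0 * np.pi * wavefront_um * 1e-6 / lam_m), 0.0)
    psf_fine = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pupil)))) ** 2

    # box-integrate to the scene grid over the requested support
    k_scene = int(round(kernel_deg * samples_per_deg))
    if k_scene % 2 == 0:
        k_scene += 1  # odd kernel keeps the PSF centered
    half_fine = (k_scene * over) // 2
    c = N // 2
    lo, hi = c - half_fine, c + half_fine + 1
    crop = psf_fine[lo:hi, lo:hi]
    m = (crop.shape[0] // over) * over
    crop = crop[:m, :m]
    psf = crop.reshape(m // over, over, m // over, over).sum(axis=(1, 3))
    s = psf.sum()
    if s <= 0:
        raise ValueError("degenerate PSF")
    return psf / s


def psf_stack(model: OpticsModel, wavelengths_nm: np.ndarray, samples_per_deg: int) -> np.ndarray:
    """Stack of unit-sum PSFs, one per wavelength (wavelength-major)."""
    return np.stack(
        [wavefront_to_psf(model, wl, samples_per_deg) for wl in wavelengths_nm]
    )


def mtf_at_frequency(psf: np.ndarray, freq_cpd: float, samples_per_deg: int) -> float:
    """Radially-averaged modulation transfer of a PSF at one spatial frequency."""
    n = psf.shape[0]
    otf = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf))))
    otf /= otf[n // 2, n // 2]
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / samples_per_deg))
    fx, fy = np.meshgrid(freqs, freqs)
    fr = np.sqrt(fx**2 + fy**2)
    band = np.abs(fr - freq_cpd) <= (freqs[1] - freqs[0])
    return float(otf[band].mean())


def apply_optics(scene: Scene, model: OpticsModel, psfs: np.ndarray | None = None) -> RetinalIrradiance:
    """Scene radiance -> padded retinal spectral irradiance.

    Frames are identical in time, so the per-wavelength convolution is done
    once and broadcast over the 28 samples. Convolution uses symmetric
    (reflected) boundary handling, which is inert here because the Gabor is
    windowed well inside the uniform surround.
    """
    params = scene.params
    wl = params.wavelengths
    if model.pad_deg < 0:
        raise ValueError("padding must be non-negative")
    n = params.n_spatial
    pad = int(round(model.pad_deg * params.samples_per_deg))
    geom = model.geometry_factor()
    trans = spectra.ocular_transmittance(wl)

    out = np.empty((n + 2 * pad, n + 2 * pad, len(wl), params.n_time))
    frame0 = scene.radiance[:, :, :, 0]
    for i, w in enumerate(wl):
        plane_in = frame0[:, :, i]
        if np.ptp(plane_in) == 0.0:
            blurred = plane_in  # unit-sum PSF preserves a uniform field
        else:
            psf = psfs[i] if psfs is not None else wavefront_to_psf(model, w, params.samples_per_deg)
            k = psf.shape[0] // 2
            img = np.pad(plane_in, k, mode="symmetric")
            blurred = fftconvolve(img, psf, mode="same")[k : k + n, k : k + n]
        plane = blurred * trans[i] * geom
        padded = np.pad(plane, pad, mode="constant", constant_values=float(plane.mean()))
        out[:, :, i, :] = padded[:, :, None]
    np.clip(out, 0.0, None, out=out)

    return RetinalIrradiance(
        irradiance=out,
        wavelengths=wl,
        samples_per_deg=params.samples_per_deg,
        pad_deg=model.pad_deg,
        fov_deg=params.fov_deg + 2 * model.pad_deg,
    )


def save_psf_stack(model: OpticsModel, wavelengths_nm: np.ndarray, samples_per_deg: int, path) -> None:
    """Export the per-wavelength PSF stack to an HDF5 container."""
    import h5py

    stack = psf_stack(model, np.asarray(wavelengths_nm, dtype=float), samples_per_deg)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("psf", data=stack, compression="gzip")
        d.attrs["pupil_mm"] = model.pupil_diameter_mm
        d.attrs["in_focus_nm"] = model.in_focus_wavelength_nm
        d.attrs["added_defocus_um"] = model.added_defocus_um
        d.attrs["samples_per_deg"] = samples_per_deg
        f.create_dataset("zernike_um", data=model.zernike_coeffs_um)
        f.create_dataset("wavelengths", data=np.asarray(wavelengths_nm, dtype=float))
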