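"""Continuous-wave diffuse-optics forward model for a two-distance NIRS patch.

The patch illuminates the tissue at four near-infrared wavelengths and
measures the diffusely reflected light at two source-detector separations
(25 mm and 32 mm by default).  In the 650-900 nm window the dominant
absorbers are oxy- and deoxyhemoglobin, whose molar extinction spectra are
well separated, so absorption encodes the hemoglobin state of the tissue:

    mu_a(lambda) = ln(10) * [eps_HbO2(lambda) * C_HbO2 + eps_Hb(lambda) * C_Hb]
                   + mu_a,background(lambda)

with concentrations in mM, extinction coefficients in 1/(mM*mm) (decadic,
hence the explicit ln(10)), and a small water/tissue background term.

Light propagation is modelled with the steady-state diffusion approximation
for a homogeneous semi-infinite medium with an extrapolated boundary.  The
detected reflectance at separation rho is the classic two-source (dipole)
expression

    R(rho) = (1/4pi) * [ z0 * (mu_eff + 1/r1) * exp(-mu_eff*r1) / r1^2
                       + (z0 + 2*zb) * (mu_eff + 1/r2) * exp(-mu_eff*r2) / r2^2 ]

where z0 = 1/(mu_a + mu_s'), D = 1/(3*(mu_a + mu_s')),
mu_eff = sqrt(3*mu_a*(mu_a + mu_s')), zb = 2*A*D, r1 = sqrt(rho^2 + z0^2)
and r2 = sqrt(rho^2 + (z0 + 2*zb)^2).  A is the dimensionless internal
reflection parameter of the boundary (A = 1 for a matched boundary,
~2.95 for a tissue-air interface with n ~ 1.4).  Absolute scale is arbitrary
for the downstream pipeline -- constant detector gains cancel in all
difference-based quantities.

The differential pathlength factor (DPF) links small absorption changes to
log-intensity changes through the modified Beer-Lambert law,
-delta ln R ~= DPF * rho * delta mu_a, and is defined here as

    DPF(rho) = (1/rho) * d(-ln R)/d(mu_a),

evaluated exactly via a complex-step derivative of the closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "LN10",
    "DEFAULT_BOUNDARY_A",
    "DEFAULT_MU_S_PRIME",
    "DEFAULT_BACKGROUND_MU_A",
    "PatchGeometry",
    "OpticalProperties",
    "ChromophoreSpectra",
    "diffuse_reflectance",
    "mua_from_chromophores",
    "differential_pathlength_factor",
]

LN10 = math.log(10.0)

#: Internal-reflection boundary parameter for a tissue-air interface (n~1.4).
DEFAULT_BOUNDARY_A = 2.95

#: Reduced scattering prior per wavelength [1/mm]; a Mie-type power law
#: mu_s'(lambda) = 1.0 * (lambda/800 nm)^-1.2, typical of soft tissue.
DEFAULT_MU_S_PRIME = {670.0: 1.237, 780.0: 1.031, 808.0: 0.988, 850.0: 0.930}

#: Nominal non-hemoglobin (water/lipid) background absorption [1/mm].
DEFAULT_BACKGROUND_MU_A = {670.0: 0.0020, 780.0: 0.0025, 808.0: 0.0030, 850.0: 0.0040}


class ParameterError(ValueError):
    """Invalid physical parameter (non-positive coefficient or distance)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. wavelength missing from spectra)."""


@dataclass(frozen=True)
class PatchGeometry:
    """Source-detector layout and sampling of one sensing patch."""

    source_detector_distances_mm: tuple[float, ...] = (25.0, 32.0)
    wavelengths_nm: tuple[float, ...] = (670.0, 780.0, 808.0, 850.0)
    sampling_rate_hz: float = 2.24

    def __post_init__(self) -> None:
        d = self.source_detector_distances_mm
        if len(d) < 1 or any(x <= 0 for x in d):
            raise ParameterError("source-detector distances must be positive")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ParameterError("source-detector distances must be strictly increasing")
        if len(self.wavelengths_nm) < 1:
            raise ParameterError("at least one wavelength required")
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths_nm) * len(self.source_detector_distances_mm)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the probed tissue at one wavelength.

    mu_a and mu_s_prime are in 1/mm.  The diffusion approximation requires
    scattering-dominated transport; a warning is raised when
    mu_a/mu_s' > 0.1.
    """

    mu_a: float
    mu_s_prime: float
    boundary_A: float = DEFAULT_BOUNDARY_A

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ParameterError("mu_a and mu_s_prime must be positive")
        if self.boundary_A < 1:
            raise ParameterError("boundary parameter A must be >= 1")
        if self.mu_a / self.mu_s_prime > 0.1:
            warnings.warn(
                "mu_a/mu_s' > 0.1: diffusion approximation may be inaccurate",
                stacklevel=2,
            )

    def reflectance(self, rho_mm: float) -> float:
        return float(
            diffuse_reflectance(self.mu_a, self.mu_s_prime, rho_mm, self.boundary_A)
        )


def _load_packaged_extinction() -> dict[str, dict[float, float]]:
    table: dict[str, dict[float, float]] = {"HbO2": {}, "Hb": {}}
    src = resources.files("carotid_nirs").joinpath("data/hemoglobin_extinction.csv")
    lines = src.read_text().strip().splitlines()
    for line in lines[1:]:
        wl, chrom, eps = line.split(",")
        # cm^-1/M (literature convention) -> mm^-1/mM
        table[chrom][float(wl)] = float(eps) * 1e-4
    return table


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Decadic molar extinction spectra of HbO2/Hb plus background absorption.

    ``eps_hbo2`` / ``eps_hb`` map wavelength [nm] -> extinction [1/(mM*mm)]
    in the log10 convention; :func:`mua_from_chromophores` applies the ln(10)
    factor explicitly.  ``background_mu_a`` maps wavelength -> baseline
    absorption [1/mm] of non-hemoglobin tissue constituents.
    """

    eps_hbo2: dict[float, float]
    eps_hb: dict[float, float]
    background_mu_a: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wls = set(self.eps_hbo2)
        if wls != set(self.eps_hb):
            raise ConfigurationError("HbO2 and Hb spectra must cover the same wavelengths")
        if any(v <= 0 for v in self.eps_hbo2.values()) or any(
            v <= 0 for v in self.eps_hb.values()
        ):
            raise ConfigurationError("extinction coefficients must be positive")
        if any(v < 0 for v in self.background_mu_a.values()):
            raise ConfigurationError("background absorption must be non-negative")
        # Isosbestic crossover near 800 nm: Hb dominates in the red,
        # HbO2 dominates beyond ~800 nm.
        for wl in wls:
            if wl <= 700 and self.eps_hb[wl] <= self.eps_hbo2[wl]:
                raise ConfigurationError(f"expected eps_Hb > eps_HbO2 at {wl} nm")
            if wl >= 830 and self.eps_hbo2[wl] <= self.eps_hb[wl]:
                raise ConfigurationError(f"expected eps_HbO2 > eps_Hb at {wl} nm")

    @classmethod
    def default(cls) -> "ChromophoreSpectra":
        """Spectra from the packaged table of compiled literature values."""
        tab = _load_packaged_extinction()
        return cls(
            eps_hbo2=tab["HbO2"],
            eps_hb=tab["Hb"],
            background_mu_a=dict(DEFAULT_BACKGROUND_MU_A),
        )

    @property
    def wavelengths_nm(self) -> tuple[float, ...]:
        return tuple(sorted(self.eps_hbo2))

    def background(self, wavelength_nm: float) -> float:
        return self.background_mu_a.get(float(wavelength_nm), 0.0)

    def extinction_matrix(self, wavelengths_nm) -> np.ndarray:
        """(n_wavelengths, 2) matrix of [eps_HbO2, eps_Hb] rows [1/(mM*mm)]."""
        rows = []
        for wl in wavelengths_nm:
            wl = float(wl)
            if wl not in self.eps_hbo2:
                raise ConfigurationError(f"no extinction data at {wl} nm")
            rows.append((self.eps_hbo2[wl], self.eps_hb[wl]))
        return np.asarray(rows, dtype=float)


def diffuse_reflectance(mu_a, mu_s_prime, rho_mm, boundary_A=DEFAULT_BOUNDARY_A):
    """Semi-infinite extrapolated-boundary CW diffuse reflectance R(rho).

    Parameters may be scalars or broadcastable arrays; ``mu_a`` may be complex
    to support complex-step differentiation.  Units: 1/mm and mm; the returned
    reflectance is a relative intensity (arbitrary absolute scale).
    """
    mu_a = np.asarray(mu_a)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(np.real(mu_a) <= 0):
        raise ParameterError("mu_a must be positive")
    if np.any(mu_s_prime <= 0):
        raise ParameterError("mu_s_prime must be positive")
    rho = float(rho_mm)
    if rho <= 0:
        raise ParameterError("rho must be positive")
    if boundary_A < 1:
        raise ParameterError("boundary parameter A must be >= 1")

    mu_t = mu_a + mu_s_prime
    z0 = 1.0 / mu_t
    D = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(3.0 * mu_a * mu_t)
    zb = 2.0 * boundary_A * D
    r1 = np.sqrt(rho * rho + z0 * z0)
    z2 = z0 + 2.0 * zb
    r2 = np.sqrt(rho * rho + z2 * z2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / (r1 * r1)
    term2 = z2 * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / (r2 * r2)
    return (term1 + term2) / (4.0 * np.pi)


def mua_from_chromophores(c_hbo2_mM, c_hb_mM, wavelength_nm, spectra: ChromophoreSpectra):
    """Absorption coefficient [1/mm] from hemoglobin concentrations [mM].

    mu_a = ln(10) * (eps_HbO2*C_HbO2 + eps_Hb*C_Hb) + background(lambda);
    linear in each concentration, equal to the background at zero
    concentration.
    """
    wl = float(wavelength_nm)
    if wl not in spectra.eps_hbo2:
        raise ConfigurationError(f"no extinction data at {wl} nm")
    c1 = np.asarray(c_hbo2_mM, dtype=float)
    c2 = np.asarray(c_hb_mM, dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ParameterError("concentrations must be non-negative")
    return LN10 * (spectra.eps_hbo2[wl] * c1 + spectra.eps_hb[wl] * c2) + spectra.background(wl)


def differential_pathlength_factor(
    mu_a, mu_s_prime, rho_mm, boundary_A=DEFAULT_BOUNDARY_A
):
    """DPF(rho) = (1/rho) * d(-ln R)/d(mu_a), via complex-step differentiation.

    The complex step (h = 1e-30) evaluates the analytic derivative of the
    closed-form reflectance to machine precision, with no subtractive
    cancellation.  DPF > 1 (the mean photon path exceeds the chord) and
    decreases with increasing absorption.
    """
    h = 1e-30
    mu_c = np.asarray(mu_a, dtype=float) + 1j * h
    R = diffuse_reflectance(mu_c, mu_s_prime, rho_mm, boundary_A)
    # d(ln R)/d(mu_a) = Im(log R)/h for a real-analytic positive R
    return -np.imag(np.log(R)) / (h * float(rho_mm))
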