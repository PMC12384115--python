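"""Inversion of raw patch intensities to hemoglobin time series.

The inverse path mirrors a real-time CW-NIRS reconstruction chain:

1. **Delta optical density.**  Per channel (wavelength x distance),
   ``dOD(t) = ln(I_ref / I(t))`` with ``I_ref`` the mean intensity over a
   reference window (default: the first 20 s, the protocol's baseline).
   Constant channel gains cancel here, which is why every downstream
   difference-based quantity is gain-invariant.

2. **Absolute baseline.**  StO2 is reported in absolute percent while CW
   intensities are relative, so baseline optical properties are estimated
   from the spatial decay of the reference intensities across the two
   detector distances: with a reduced-scattering prior, the measured
   two-distance intensity ratio is inverted against the exact closed-form
   reflectance (Brent root-finding in mu_a, per wavelength), and the absolute
   mu_a spectrum is unmixed into baseline HbO2/Hb.  If the inversion fails
   (degenerate geometry, negative chromophore absorption, unphysical
   saturation) a configured default baseline is used and flagged.

3. **Spectral unmixing of changes.**  The modified Beer-Lambert model
   ``dOD(lambda, rho) ~= DPF(lambda, rho) * rho * d mu_a(lambda)`` is solved
   per time sample by weighted least squares over all 8 channels, with DPF
   evaluated at the baseline optical properties and held fixed for the trial
   (linearized reconstruction, as appropriate for small changes) and channel
   weights inversely proportional to the reference-window dOD variance.

Outputs are changes from the trial-start reference (d_HbO2, d_Hb,
d_HbT = d_HbO2 + d_Hb, in uM) and an absolute StO2 trace
``100*(HbO2_0 + d_HbO2)/(HbT_0 + d_HbT)`` clamped to [0, 100] with the clamp
count kept as a quality signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cohort import TissueOptics, TrialRecording
from .optics import (
    LN10,
    ChromophoreSpectra,
    ConfigurationError,
    ParameterError,
    PatchGeometry,
    differential_pathlength_factor,
    diffuse_reflectance,
    mua_from_chromophores,
)

__all__ = ["ReconstructionConfig", "ReconstructedTrace", "delta_optical_density",
           "unmix_concentrations", "absolute_baseline", "reconstruct_trial"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconstructionConfig:
    reference_window_s: tuple[float, float] = (0.0, 20.0)
    spectra: ChromophoreSpectra = field(default_factory=ChromophoreSpectra.default)
    tissue: TissueOptics = field(default_factory=TissueOptics)
    fallback_baseline: tuple[float, float] = (60.0, 70.0)  # HbT0 [uM], StO2_0 [%]
    detrend: bool = False          # linear detrend fitted on normal1+normal3
    detrend_windows_s: tuple[tuple[float, float], ...] = ((0.0, 30.0), (120.0, 150.0))
    max_flagged_fraction: float = 0.2


@dataclass
class ReconstructedTrace:
    """Reconstructed hemodynamics for one trial (same grid as the recording)."""

    subject_id: str
    location: str
    trial_index: int
    time_s: np.ndarray
    d_hbo2_uM: np.ndarray
    d_hb_uM: np.ndarray
    d_hbt_uM: np.ndarray
    sto2_pct: np.ndarray
    hbt0_uM: float
    sto2_0_pct: float
    baseline_reference: np.ndarray      # mean reference intensity per channel
    flags: np.ndarray                   # per-sample bool, True = unusable
    n_clamped: int = 0
    used_fallback_baseline: bool = False
    low_quality: bool = False

    @property
    def hbt_uM(self) -> np.ndarray:
        """Absolute HbT estimate (baseline offset + change)."""
        return self.hbt0_uM + self.d_hbt_uM


def _reference_slice(time_s: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (time_s >= window[0]) & (time_s < window[1])
    if not mask.any():
        raise ParameterError("reference window contains no samples")
    return mask


def delta_optical_density(
    recording: TrialRecording, reference_window_s: tuple[float, float] = (0.0, 20.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel dOD(t) = ln(I_ref/I(t)), plus a per-sample invalid flag.

    Non-positive intensities are flagged and excluded (NaN) rather than
    propagated.  By construction the mean dOD over the reference window is 0.
    """
    mask = _reference_slice(recording.time_s, reference_window_s)
    I = recording.intensity
    bad = I <= 0
    Iv = np.where(bad, np.nan, I)
    with np.errstate(invalid="ignore"):
        I_ref = np.nanmean(Iv[:, :, mask], axis=2)
    if np.any(~np.isfinite(I_ref)) or np.any(I_ref <= 0):
        raise ParameterError("reference window has no valid intensities in some channel")
    dod = np.log(I_ref[:, :, None] / Iv)
    sample_flags = bad.any(axis=(0, 1))
    return dod, sample_flags


def unmix_concentrations(
    dod: np.ndarray,
    geometry: PatchGeometry,
    spectra: ChromophoreSpectra,
    dpf: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares unmixing of dOD into (dHbO2, dHb) [uM] per sample.

    Both source-detector distances are pooled into one system:
    dOD/(DPF*rho) = ln(10) * [eps_HbO2 * dC_HbO2 + eps_Hb * dC_Hb].
    """
    rhos = np.asarray(geometry.source_detector_distances_mm)
    nw, nr, nt = dod.shape
    E = spectra.extinction_matrix(geometry.wavelengths_nm)  # (nw, 2)
    A = LN10 * np.repeat(E, nr, axis=0)                     # (nw*nr, 2)
    if np.linalg.matrix_rank(A) < 2:
        raise ConfigurationError("extinction matrix is rank deficient")
    y = (dod / (dpf * rhos[None, :])[:, :, None]).reshape(nw * nr, nt)
    w = np.ones(nw * nr) if weights is None else np.asarray(weights, dtype=float).reshape(-1)
    w = w / w.sum()
    Aw = A * w[:, None]
    M = np.linalg.solve(A.T @ Aw, Aw.T)     # (2, nw*nr)
    c_mM = M @ np.nan_to_num(y, nan=0.0)
    # restore NaN at flagged samples
    bad = ~np.isfinite(y).all(axis=0)
    c_mM[:, bad] = np.nan
    return 1000.0 * c_mM[0], 1000.0 * c_mM[1]


def absolute_baseline(
    recording: TrialRecording,
    geometry: PatchGeometry,
    spectra: ChromophoreSpectra,
    tissue: TissueOptics | None = None,
    reference_window_s: tuple[float, float] = (0.0, 20.0),
    fallback: tuple[float, float] = (60.0, 70.0),
) -> tuple[float, float, bool]:
    """Absolute baseline (HbT0 [uM], StO2_0 [%]) from two-distance decay.

    Requires calibrated channel gains (recording.gain); inverts the exact
    reflectance ratio R(rho1)/R(rho2) for mu_a per wavelength given the
    scattering prior, then unmixes the absolute absorption spectrum.  Returns
    ``(hbt0, sto2_0, used_fallback)``.
    """
    tissue = tissue or TissueOptics()
    rhos = geometry.source_detector_distances_mm
    if len(rhos) < 2:
        raise ParameterError("absolute baseline needs >= 2 detector distances")
    mask = _reference_slice(recording.time_s, reference_window_s)
    I = np.where(recording.intensity > 0, recording.intensity, np.nan)
    I_ref = np.nanmean(I[:, :, mask], axis=2) / recording.gain

    mu_a_abs = []
    for i, wl in enumerate(geometry.wavelengths_nm):
        musp = tissue.mu_s_prime[float(wl)]
        q_obs = I_ref[i, 0] / I_ref[i, -1]

        def f(mu):
            return (
                diffuse_reflectance(mu, musp, rhos[0], tissue.boundary_A)
                / diffuse_reflectance(mu, musp, rhos[-1], tissue.boundary_A)
                - q_obs
            )

        lo, hi = 1e-6, 1.0
        try:
            if f(lo) * f(hi) > 0:
                raise ValueError("ratio outside invertible range")
            mu_a_abs.append(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))
        except ValueError:
            log.warning(
                "baseline inversion failed at %s nm; using fallback baseline", wl
            )
            return fallback[0], fallback[1], True

    E = spectra.extinction_matrix(geometry.wavelengths_nm)
    bg = np.array([spectra.background(wl) for wl in geometry.wavelengths_nm])
    chrom = np.asarray(mu_a_abs) - bg
    if np.any(chrom <= 0):
        log.warning("negative chromophore absorption; using fallback baseline")
        return fallback[0], fallback[1], True
    c_mM, *_ = np.linalg.lstsq(LN10 * E, chrom, rcond=None)
    hbo2_0, hb_0 = 1000.0 * c_mM
    hbt0 = hbo2_0 + hb_0
    if hbt0 <= 0 or not (0.0 <= 100.0 * hbo2_0 / hbt0 <= 100.0):
        log.warning("unphysical baseline estimate; using fallback baseline")
        return fallback[0], fallback[1], True
    return float(hbt0), float(100.0 * hbo2_0 / hbt0), False


def reconstruct_trial(
    recording: TrialRecording, config: ReconstructionConfig | None = None
) -> ReconstructedTrace:
    """Full inversion of one trial: dOD -> baseline -> unmixed concentration
    changes -> absolute StO2 trace with quality flags."""
    cfg = config or ReconstructionConfig()
    geometry = recording.geometry
    spectra = cfg.spectra

    dod, flags = delta_optical_density(recording, cfg.reference_window_s)
    hbt0, sto2_0, used_fallback = absolute_baseline(
        recording, geometry, spectra, cfg.tissue, cfg.reference_window_s,
        cfg.fallback_baseline,
    )

    # baseline optical properties -> DPF and channel weights, fixed per trial
    hbo2_0 = hbt0 * sto2_0 / 100.0
    hb_0 = hbt0 - hbo2_0
    rhos = geometry.source_detector_distances_mm
    nw, nr = len(geometry.wavelengths_nm), len(rhos)
    dpf = np.empty((nw, nr))
    for i, wl in enumerate(geometry.wavelengths_nm):
        mu_a0 = mua_from_chromophores(hbo2_0 / 1000.0, hb_0 / 1000.0, wl, spectra)
        for j, rho in enumerate(rhos):
            dpf[i, j] = differential_pathlength_factor(
                mu_a0, cfg.tissue.mu_s_prime[float(wl)], rho, cfg.tissue.boundary_A
            )

    ref_mask = _reference_slice(recording.time_s, cfg.reference_window_s)
    var = np.nanvar(dod[:, :, ref_mask], axis=2)
    w = 1.0 / np.maximum(var, 1e-12)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(w)
    # noiseless reference window -> uniform weights
    if np.allclose(var, 0.0, atol=1e-20):
        w = np.ones_like(w)

    d_hbo2, d_hb = unmix_concentrations(dod, geometry, spectra, dpf, w)

    if cfg.detrend:
        t = recording.time_s
        fit_mask = np.zeros_like(t, dtype=bool)
        for a, b in cfg.detrend_windows_s:
            fit_mask |= (t >= a) & (t < b)
        fit_mask &= np.isfinite(d_hbo2)
        if fit_mask.sum() >= 2:
            for arr in (d_hbo2, d_hb):
                coef = np.polyfit(t[fit_mask], arr[fit_mask], 1)
                arr -= np.polyval(coef, t)

    d_hbt = d_hbo2 + d_hb
    with np.errstate(invalid="ignore"):
        sto2 = 100.0 * (hbo2_0 + d_hbo2) / np.maximum(hbt0 + d_hbt, 1e-9)
    n_clamped = int(np.sum((sto2 < 0) | (sto2 > 100)))
    if n_clamped:
        log.warning("clamped %d StO2 samples to [0, 100]", n_clamped)
    sto2 = np.clip(sto2, 0.0, 100.0)

    flags = flags | ~np.isfinite(d_hbt)
    I_ref = np.nanmean(
        np.where(recording.intensity > 0, recording.intensity, np.nan)[:, :, ref_mask],
        axis=2,
    )
    low_quality = flags.mean() > cfg.max_flagged_fraction
    if low_quality:
        log.warning(
            "trial %s/%s/%d marked low-quality (%.0f%% flagged samples)",
            recording.subject_id, recording.location, recording.trial_index,
            100 * flags.mean(),
        )
    return ReconstructedTrace(
        subject_id=recording.subject_id,
        location=recording.location,
        trial_index=recording.trial_index,
        time_s=recording.time_s,
        d_hbo2_uM=d_hbo2,
        d_hb_uM=d_hb,
        d_hbt_uM=d_hbt,
        sto2_pct=sto2,
        hbt0_uM=hbt0,
        sto2_0_pct=sto2_0,
        baseline_reference=I_ref,
        flags=flags,
        n_clamped=n_clamped,
        used_fallback_baseline=used_fallback,
        low_quality=low_quality,
    )
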