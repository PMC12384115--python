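"""Synthetic cohort generator: breathing-protocol hemodynamics to raw patch counts.

The study protocol is a 150-s trial of five contiguous 30-s segments:
normal breathing, a breath hold (~5 s inhalation + ~25 s hold), normal
breathing, deep breathing, and a final normal-breathing recovery.  The
generator produces, per subject x patch location x trial:

* a latent ground truth (HbT [uM] and StO2 [%] sample-by-sample, from which
  HbO2/Hb follow exactly), shaped by the protocol:

  - breath hold: a smoothstep HbT ramp that peaks at the end of the hold
    (vasodilatory response), with a smaller, same-shaped StO2 excursion;
  - deep breathing: an StO2 sinusoid tracking the inhale/exhale cycle and an
    HbT sinusoid at roughly half the StO2 frequency, lagged by a
    chemoreceptor response delay of ~1-2 s, both with per-cycle amplitude
    jitter;
  - normal segments: low-pass Gaussian physiological fluctuation and
    exponential relaxation back to baseline after each challenge;

* raw detector intensities at 4 wavelengths x 2 distances via the diffusion
  forward model, corrupted by multiplicative photon noise, slow per-channel
  drift, and occasional motion artifacts common to all channels of a patch.

Per-location response amplitudes are drawn per subject from distributions
whose means/SDs are the cohort summary statistics of the study population
(moment-matched lognormals for strictly positive amplitudes and times,
normals for signed breath-hold changes), with a configurable between-location
correlation (default 0.5) reflecting shared systemic physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._constants import FEATURE_COLUMNS, LOCATIONS, OSC_TIME_CONVENTION, SKIN_TONES
from .optics import (
    DEFAULT_BOUNDARY_A,
    DEFAULT_MU_S_PRIME,
    ChromophoreSpectra,
    ParameterError,
    PatchGeometry,
    diffuse_reflectance,
    mua_from_chromophores,
)

__all__ = [
    "BreathingProtocol",
    "HemodynamicTruth",
    "LocationHemodynamics",
    "SubjectProfile",
    "NoiseModel",
    "TissueOptics",
    "TrialRecording",
    "Cohort",
    "DEFAULT_FEATURE_DISTRIBUTIONS",
    "generate_truth",
    "truth_to_recording",
    "generate_profiles",
    "generate_cohort",
]

_SEGMENT_LABELS = ("normal1", "breath_hold", "normal2", "deep_breathing", "normal3")


@dataclass(frozen=True)
class BreathingProtocol:
    """Ordered, contiguous breathing segments on a half-open time axis.

    Default: five 30-s segments, 150 s total; the breath hold consists of a
    ~5 s inhalation lead followed by a ~25 s hold.
    """

    segments: tuple[tuple[str, float], ...] = tuple(
        (label, 30.0) for label in _SEGMENT_LABELS
    )
    inhale_lead_s: float = 5.0
    hold_s: float = 25.0

    def __post_init__(self) -> None:
        if len(self.segments) == 0 or any(d <= 0 for _, d in self.segments):
            raise ParameterError("segment durations must be positive")
        labels = [lab for lab, _ in self.segments]
        if len(set(labels)) != len(labels):
            raise ParameterError("segment labels must be unique")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        """label -> [start, end) in seconds from trial start."""
        out, t = {}, 0.0
        for label, dur in self.segments:
            out[label] = (t, t + dur)
            t += dur
        return out


@dataclass(frozen=True)
class LocationHemodynamics:
    """Per-location generator parameters for one subject (the latent truth)."""

    baseline_hbt_uM: float = 60.0
    baseline_sto2_pct: float = 70.0
    bh_hbt_rise_pct: float = 2.5      # peak HbT change during breath hold, % of baseline
    bh_sto2_change_pct: float = 0.5   # peak StO2 change during breath hold, % of baseline
    db_hbt_pkpk_uM: float = 1.2       # deep-breathing HbT peak-to-peak amplitude
    db_sto2_pkpk_pct: float = 0.35    # deep-breathing StO2 peak-to-peak amplitude [% points]
    db_sto2_osc_time_s: float = 3.5   # adjacent-extremum interval of the StO2 oscillation
    db_hbt_osc_time_s: float = 7.0    # adjacent-extremum interval of the HbT oscillation
    hbt_response_delay_s: float = 1.5
    physio_fluct_hbt_uM: float = 0.15
    physio_fluct_sto2_pct: float = 0.05
    db_amp_jitter_cv: float = 0.10
    recovery_tau_s: float = 8.0

    def __post_init__(self) -> None:
        if self.baseline_hbt_uM <= 0 or not (0 < self.baseline_sto2_pct < 100):
            raise ParameterError("invalid baseline hemodynamics")
        for name in (
            "db_hbt_pkpk_uM",
            "db_sto2_pkpk_pct",
            "db_sto2_osc_time_s",
            "db_hbt_osc_time_s",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics, vitals, carotid anatomy and per-location hemodynamics."""

    subject_id: str
    sex_assigned_at_birth: str
    race_group: str
    skin_tone: str
    systolic_bp_mmHg: float
    diastolic_bp_mmHg: float
    heart_rate_bpm: float
    carotid_anatomy: dict[str, dict[str, float]]  # side -> measurement [mm]
    location_params: dict[str, LocationHemodynamics]

    def __post_init__(self) -> None:
        if self.skin_tone not in SKIN_TONES:
            raise ParameterError(f"skin tone must be one of {SKIN_TONES}")
        if min(self.systolic_bp_mmHg, self.diastolic_bp_mmHg, self.heart_rate_bpm) <= 0:
            raise ParameterError("vitals must be positive")


@dataclass
class HemodynamicTruth:
    """Ground-truth hemodynamic time series with protocol annotations.

    Invariants: hbt = hbo2 + hb exactly; sto2 = 100*hbo2/hbt.
    ``true_features`` holds the generating parameters themselves (the values
    a perfect extractor should recover), keyed like the feature table.
    """

    time_s: np.ndarray
    hbo2_uM: np.ndarray
    hb_uM: np.ndarray
    hbt_uM: np.ndarray
    sto2_pct: np.ndarray
    protocol: BreathingProtocol
    true_features: dict[str, float]
    osc_time_convention: str = OSC_TIME_CONVENTION


@dataclass
class TrialRecording:
    """Raw intensities for one trial at one location.

    ``intensity`` has shape (n_wavelengths, n_distances, n_times); ``gain``
    (n_wavelengths, n_distances) is the calibrated channel gain.
    """

    subject_id: str
    location: str
    trial_index: int
    geometry: PatchGeometry
    time_s: np.ndarray
    intensity: np.ndarray
    gain: np.ndarray

    def __post_init__(self) -> None:
        nw = len(self.geometry.wavelengths_nm)
        nr = len(self.geometry.source_detector_distances_mm)
        if self.intensity.shape != (nw, nr, len(self.time_s)):
            raise ParameterError("intensity grid incomplete")


@dataclass(frozen=True)
class TissueOptics:
    """Scattering prior and boundary condition shared by forward and inverse."""

    mu_s_prime: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MU_S_PRIME)
    )
    boundary_A: float = DEFAULT_BOUNDARY_A


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings applied to the raw intensities.

    All amplitudes are fractions of the clean intensity.  Motion artifacts
    are raised-cosine bumps common to all channels of the patch (with random
    per-channel coupling), emulating momentary changes in probe-skin contact.
    """

    multiplicative_sd: float = 1e-3
    additive_sd: float = 0.0
    drift_fraction: float = 2e-3
    motion_rate_per_trial: float = 0.3
    motion_amplitude: float = 0.02
    motion_duration_s: float = 1.5
    intensity_floor: float = 1e-15

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(
            multiplicative_sd=0.0,
            additive_sd=0.0,
            drift_fraction=0.0,
            motion_rate_per_trial=0.0,
        )


def _window_value(t, t0, t1, inside, after, tau):
    """inside(t) on [t0, t1), exponential decay of the boundary value after t1."""
    out = np.zeros_like(t)
    in_mask = (t >= t0) & (t < t1)
    out[in_mask] = inside(t[in_mask])
    post = t >= t1
    if np.any(post) and np.any(in_mask):
        edge = inside(np.asarray([t1 - 1e-9]))[0] if after is None else after
        out[post] = edge * np.exp(-(t[post] - t1) / tau)
    return out


def _oscillation(t, t0, t1, period_s, amp, jitter_cv, rng, decay_tau=3.0):
    """Sinusoid on [t0, t1) starting at zero phase, per-cycle amplitude jitter,
    exponential ring-down after t1 (the subject stops the exercise)."""
    n_cycles = max(1, int(math.ceil((t1 - t0) / period_s)))
    fac = 1.0 + jitter_cv * rng.standard_normal(n_cycles) if jitter_cv > 0 else np.ones(n_cycles)
    fac = np.clip(fac, 0.1, None)

    def inside(tt):
        phase = 2.0 * np.pi * (tt - t0) / period_s
        cyc = np.minimum(((tt - t0) / period_s).astype(int), n_cycles - 1)
        return amp * fac[cyc] * np.sin(phase)

    return _window_value(t, t0, t1, inside, None, decay_tau)


def _smoothstep_ramp(t, t_start, t_peak, tau_recovery):
    """0 -> 1 smoothstep over [t_start, t_peak), exponential recovery after."""

    def inside(tt):
        u = np.clip((tt - t_start) / (t_peak - t_start), 0.0, 1.0)
        return u * u * (3.0 - 2.0 * u)

    return _window_value(t, t_start, t_peak, inside, None, tau_recovery)


def _lowpass_fluctuation(n, fs, sd, rng, corr_time_s=2.0):
    if sd <= 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), sigma=corr_time_s * fs, mode="reflect")
    s = raw.std()
    return sd * raw / s if s > 0 else np.zeros(n)


def generate_truth(
    profile: SubjectProfile,
    location: str,
    protocol: BreathingProtocol | None = None,
    sampling_rate_hz: float = 2.24,
    rng: np.random.Generator | int | None = None,
) -> HemodynamicTruth:
    """Generate the latent hemodynamic truth for one trial.

    The returned ``true_features`` are copied from the generating parameters,
    not re-measured from the waveform.
    """
    protocol = protocol or BreathingProtocol()
    rng = np.random.default_rng(rng)
    p = profile.location_params[location]
    fs = float(sampling_rate_hz)
    n = int(round(protocol.total_duration_s * fs))
    t = np.arange(n) / fs
    bounds = protocol.bounds

    for osc in (p.db_sto2_osc_time_s, p.db_hbt_osc_time_s):
        if 2.0 * osc < 2.0 / fs:
            raise ParameterError(
                f"oscillation period {2 * osc:.3f} s shorter than 2 samples at {fs} Hz"
            )

    hbt0, sto2_0 = p.baseline_hbt_uM, p.baseline_sto2_pct

    # Breath hold: ramp begins after the inhalation lead, peaks at hold end.
    bh0, bh1 = bounds["breath_hold"]
    ramp_start = min(bh0 + protocol.inhale_lead_s, bh1 - 1.0 / fs)
    bh_shape = _smoothstep_ramp(t, ramp_start, bh1, p.recovery_tau_s)
    d_hbt = hbt0 * (p.bh_hbt_rise_pct / 100.0) * bh_shape
    d_sto2 = sto2_0 * (p.bh_sto2_change_pct / 100.0) * bh_shape

    # Deep breathing: StO2 follows the breathing cycle; HbT responds with a
    # delay and at twice the oscillation time (half the frequency).
    db0, db1 = bounds["deep_breathing"]
    d_sto2 = d_sto2 + _oscillation(
        t, db0, db1, 2.0 * p.db_sto2_osc_time_s, p.db_sto2_pkpk_pct / 2.0,
        p.db_amp_jitter_cv, rng,
    )
    d_hbt = d_hbt + _oscillation(
        t, db0 + p.hbt_response_delay_s, db1, 2.0 * p.db_hbt_osc_time_s,
        p.db_hbt_pkpk_uM / 2.0, p.db_amp_jitter_cv, rng,
    )

    d_hbt = d_hbt + _lowpass_fluctuation(n, fs, p.physio_fluct_hbt_uM, rng)
    d_sto2 = d_sto2 + _lowpass_fluctuation(n, fs, p.physio_fluct_sto2_pct, rng)

    hbt = np.maximum(hbt0 + d_hbt, 1.0)
    sto2 = np.clip(sto2_0 + d_sto2, 1.0, 99.0)
    hbo2 = hbt * sto2 / 100.0
    hb = hbt - hbo2

    true_features = {
        "bh_max_pct_change_hbt_pct": p.bh_hbt_rise_pct,
        "bh_max_pct_change_sto2_pct": p.bh_sto2_change_pct,
        "db_mean_osc_time_hbt_s": p.db_hbt_osc_time_s,
        "db_mean_osc_time_sto2_s": p.db_sto2_osc_time_s,
        "db_mean_pkpk_hbt_uM": p.db_hbt_pkpk_uM,
        "db_mean_pkpk_sto2_pct": p.db_sto2_pkpk_pct,
    }
    return HemodynamicTruth(
        time_s=t, hbo2_uM=hbo2, hb_uM=hb, hbt_uM=hbt, sto2_pct=sto2,
        protocol=protocol, true_features=true_features,
    )


def truth_to_recording(
    truth: HemodynamicTruth,
    geometry: PatchGeometry,
    spectra: ChromophoreSpectra,
    optics: TissueOptics | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "S00",
    location: str = "left_radial",
    trial_index: int = 0,
    gains: np.ndarray | None = None,
) -> TrialRecording:
    """Forward-synthesize raw detector counts from the latent truth."""
    optics = optics or TissueOptics()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(rng)
    t = truth.time_s
    n = len(t)
    wavelengths = geometry.wavelengths_nm
    rhos = geometry.source_detector_distances_mm
    nw, nr = len(wavelengths), len(rhos)

    gain = np.ones((nw, nr)) if gains is None else np.asarray(gains, dtype=float)

    intensity = np.empty((nw, nr, n))
    for i, wl in enumerate(wavelengths):
        mu_a = mua_from_chromophores(
            truth.hbo2_uM / 1000.0, truth.hb_uM / 1000.0, wl, spectra
        )
        musp = optics.mu_s_prime[float(wl)]
        for j, rho in enumerate(rhos):
            intensity[i, j] = gain[i, j] * diffuse_reflectance(
                mu_a, musp, rho, optics.boundary_A
            )

    duration = t[-1] - t[0] if n > 1 else 1.0
    if noise.drift_fraction > 0:
        # slow per-channel gain drift: linear trend + one slow sinusoid
        lin = rng.normal(0.0, noise.drift_fraction, (nw, nr))
        amp = rng.normal(0.0, noise.drift_fraction, (nw, nr))
        phase = rng.uniform(0, 2 * np.pi, (nw, nr))
        cycles = rng.uniform(0.5, 1.5, (nw, nr))
        tt = (t - t[0]) / duration
        intensity *= (
            1.0
            + lin[..., None] * tt
            + amp[..., None] * np.sin(2 * np.pi * cycles[..., None] * tt + phase[..., None])
        )

    if noise.motion_rate_per_trial > 0:
        n_events = rng.poisson(noise.motion_rate_per_trial)
        if n_events:
            m = np.zeros(n)
            fs = geometry.sampling_rate_hz
            half = max(1, int(round(noise.motion_duration_s * fs / 2)))
            for _ in range(n_events):
                c = rng.integers(0, n)
                a = noise.motion_amplitude * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
                idx = np.arange(max(0, c - half), min(n, c + half + 1))
                m[idx] += a * 0.5 * (1 + np.cos(np.pi * (idx - c) / half))
            coupling = rng.uniform(0.5, 1.5, (nw, nr))
            intensity *= 1.0 + coupling[..., None] * m[None, None, :]

    if noise.multiplicative_sd > 0:
        intensity *= 1.0 + rng.normal(0.0, noise.multiplicative_sd, intensity.shape)
    if noise.additive_sd > 0:
        scale = noise.additive_sd * intensity.mean(axis=2, keepdims=True)
        intensity += rng.normal(0.0, 1.0, intensity.shape) * scale

    n_clipped = int(np.sum(intensity <= 0))
    if n_clipped:
        import logging

        logging.getLogger(__name__).warning(
            "clipped %d non-positive intensities to floor", n_clipped
        )
        intensity = np.maximum(intensity, noise.intensity_floor)

    return TrialRecording(
        subject_id=subject_id, location=location, trial_index=trial_index,
        geometry=geometry, time_s=t, intensity=intensity, gain=gain,
    )


# --------------------------------------------------------------------------
# Cohort-level generation
# --------------------------------------------------------------------------

#: Per-location response distributions (mean, SD) of the simulated study
#: population.  Strictly positive quantities use moment-matched lognormals
#: (the sample mean then converges to the stated mean exactly); signed
#: breath-hold changes use normals.  Left/right radial and carotid values for
#: the breath-hold and HbT parameters mirror the corresponding contralateral
#: artery.
DEFAULT_FEATURE_DISTRIBUTIONS: dict[str, dict] = {
    "bh_hbt_rise_pct": {
        "dist": "normal",
        "left_radial": (1.4, 1.1), "left_carotid": (3.5, 3.7),
        "right_radial": (1.4, 1.1), "right_carotid": (3.5, 3.7),
    },
    "bh_sto2_change_pct": {
        "dist": "normal",
        "left_radial": (0.3, 0.6), "left_carotid": (1.2, 3.2),
        "right_radial": (0.3, 0.6), "right_carotid": (1.2, 3.2),
    },
    "db_hbt_pkpk_uM": {
        "dist": "lognormal",
        "left_radial": (0.9, 0.8), "left_carotid": (1.6, 1.1),
        "right_radial": (0.9, 0.8), "right_carotid": (1.6, 1.1),
    },
    "db_sto2_pkpk_pct": {
        "dist": "lognormal",
        "left_radial": (0.3, 0.2), "left_carotid": (0.3, 0.2),
        "right_radial": (0.4, 0.5), "right_carotid": (0.5, 0.4),
    },
    "db_hbt_osc_time_s": {
        "dist": "lognormal",
        "left_radial": (7.0, 1.9), "left_carotid": (6.5, 2.1),
        "right_radial": (7.0, 1.9), "right_carotid": (6.5, 2.1),
    },
    "db_sto2_osc_time_s": {
        "dist": "lognormal",
        "left_radial": (3.7, 1.4), "left_carotid": (3.0, 0.8),
        "right_radial": (3.3, 1.2), "right_carotid": (3.3, 1.3),
    },
}

_PARAM_FIELD = {
    "bh_hbt_rise_pct": "bh_hbt_rise_pct",
    "bh_sto2_change_pct": "bh_sto2_change_pct",
    "db_hbt_pkpk_uM": "db_hbt_pkpk_uM",
    "db_sto2_pkpk_pct": "db_sto2_pkpk_pct",
    "db_hbt_osc_time_s": "db_hbt_osc_time_s",
    "db_sto2_osc_time_s": "db_sto2_osc_time_s",
}

#: generator parameter name -> feature-table column it should reproduce
PARAM_TO_FEATURE = {
    "bh_hbt_rise_pct": "bh_max_pct_change_hbt_pct",
    "bh_sto2_change_pct": "bh_max_pct_change_sto2_pct",
    "db_hbt_pkpk_uM": "db_mean_pkpk_hbt_uM",
    "db_sto2_pkpk_pct": "db_mean_pkpk_sto2_pct",
    "db_hbt_osc_time_s": "db_mean_osc_time_hbt_s",
    "db_sto2_osc_time_s": "db_mean_osc_time_sto2_s",
}


def _correlated_standard_normals(k, corr, rng):
    cov = np.full((k, k), corr)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov) @ rng.standard_normal(k)


def _marginal(z, mean, sd, dist):
    if sd < 0:
        raise ParameterError("SD must be non-negative")
    if dist == "normal":
        return mean + sd * z
    if dist == "lognormal":
        if mean <= 0:
            raise ParameterError("lognormal mean must be positive")
        s2 = math.log1p((sd / mean) ** 2)
        return math.exp(math.log(mean) - s2 / 2.0 + math.sqrt(s2) * z)
    raise ParameterError(f"unknown distribution {dist!r}")


def generate_profiles(
    n_subjects: int,
    distributions: dict | None = None,
    between_location_corr: float = 0.5,
    rng: np.random.Generator | int | None = None,
    base_params: LocationHemodynamics | None = None,
) -> list[SubjectProfile]:
    """Draw subject profiles: demographics, vitals, anatomy and response params.

    Demographics match the study population proportions (65% assigned female
    at birth, 70% nonwhite, 40/40/20 fair/olive/dark skin tones) and have no
    effect on the hemodynamic parameters by default.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    dists = distributions or DEFAULT_FEATURE_DISTRIBUTIONS
    rng = np.random.default_rng(rng)
    base = base_params or LocationHemodynamics()
    profiles = []
    for i in range(n_subjects):
        draws: dict[str, dict[str, float]] = {loc: {} for loc in LOCATIONS}
        for pname, spec in dists.items():
            z = _correlated_standard_normals(len(LOCATIONS), between_location_corr, rng)
            for loc, zi in zip(LOCATIONS, z):
                mean, sd = spec[loc]
                v = _marginal(zi, mean, sd, spec["dist"])
                if pname.endswith("osc_time_s"):
                    v = max(v, 1.0)  # protocol/sampling floor
                elif pname.startswith("db_"):
                    v = max(v, 0.01)
                draws[loc][_PARAM_FIELD[pname]] = v
        delay = _marginal(rng.standard_normal(), 1.5, 0.5, "lognormal")
        loc_params = {}
        for loc in LOCATIONS:
            loc_params[loc] = replace(
                base,
                baseline_hbt_uM=float(np.clip(rng.normal(60.0, 5.0), 40.0, 90.0)),
                baseline_sto2_pct=float(np.clip(rng.normal(70.0, 3.0), 55.0, 85.0)),
                hbt_response_delay_s=min(delay, 5.0),
                **draws[loc],
            )
        anatomy = {
            side: {
                "bulb_depth_mm": float(np.clip(rng.normal(15.0, 3.0), 8.0, 25.0)),
                "bulb_diameter_mm": float(np.clip(rng.normal(7.0, 1.0), 4.0, 11.0)),
                "ica_diameter_mm": float(np.clip(rng.normal(5.0, 0.8), 3.0, 8.0)),
                "eca_diameter_mm": float(np.clip(rng.normal(4.5, 0.7), 2.5, 7.0)),
            }
            for side in ("left", "right")
        }
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                sex_assigned_at_birth="female" if rng.random() < 0.65 else "male",
                race_group="nonwhite" if rng.random() < 0.70 else "white",
                skin_tone=rng.choice(SKIN_TONES, p=[0.4, 0.4, 0.2]),
                systolic_bp_mmHg=float(np.clip(rng.normal(115.0, 11.0), 80.0, 160.0)),
                diastolic_bp_mmHg=float(np.clip(rng.normal(71.0, 7.0), 45.0, 100.0)),
                heart_rate_bpm=float(np.clip(rng.normal(72.0, 11.0), 40.0, 110.0)),
                carotid_anatomy=anatomy,
                location_params=loc_params,
            )
        )
    return profiles


@dataclass
class Cohort:
    """A fully simulated cohort: profiles, latent truths and raw recordings."""

    profiles: list[SubjectProfile]
    protocol: BreathingProtocol
    geometry: PatchGeometry
    spectra: ChromophoreSpectra
    optics: TissueOptics
    noise: NoiseModel
    truths: dict[tuple[str, str, int], HemodynamicTruth]
    recordings: dict[tuple[str, str, int], TrialRecording]

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row = {
                "subject_id": p.subject_id,
                "sex_assigned_at_birth": p.sex_assigned_at_birth,
                "race_group": p.race_group,
                "skin_tone": p.skin_tone,
                "systolic_bp_mmHg": p.systolic_bp_mmHg,
                "diastolic_bp_mmHg": p.diastolic_bp_mmHg,
                "heart_rate_bpm": p.heart_rate_bpm,
            }
            for side, meas in p.carotid_anatomy.items():
                for k, v in meas.items():
                    row[f"{side}_{k}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def true_features_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            for loc in LOCATIONS:
                lp = p.location_params[loc]
                rows.append(
                    {
                        "subject_id": p.subject_id,
                        "location": loc,
                        "bh_max_pct_change_hbt_pct": lp.bh_hbt_rise_pct,
                        "bh_max_pct_change_sto2_pct": lp.bh_sto2_change_pct,
                        "db_mean_osc_time_hbt_s": lp.db_hbt_osc_time_s,
                        "db_mean_osc_time_sto2_s": lp.db_sto2_osc_time_s,
                        "db_mean_pkpk_hbt_uM": lp.db_hbt_pkpk_uM,
                        "db_mean_pkpk_sto2_pct": lp.db_sto2_pkpk_pct,
                    }
                )
        return pd.DataFrame(rows, columns=["subject_id", "location", *FEATURE_COLUMNS])

    def recordings_frame(self) -> pd.DataFrame:
        """Long/tidy raw-intensity table (one row per sample per channel)."""
        frames = []
        for (sid, loc, trial), rec in sorted(self.recordings.items()):
            nw, nr, nt = rec.intensity.shape
            wl = np.repeat(rec.geometry.wavelengths_nm, nr * nt)
            dist = np.tile(np.repeat(rec.geometry.source_detector_distances_mm, nt), nw)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "location": loc,
                        "trial": trial,
                        "wavelength_nm": wl,
                        "distance_mm": dist,
                        "time_s": np.tile(rec.time_s, nw * nr),
                        "intensity": rec.intensity.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def truth_frame(self) -> pd.DataFrame:
        frames = []
        for (sid, loc, trial), tr in sorted(self.truths.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "location": loc,
                        "trial": trial,
                        "time_s": tr.time_s,
                        "hbo2_uM": tr.hbo2_uM,
                        "hb_uM": tr.hb_uM,
                        "hbt_uM": tr.hbt_uM,
                        "sto2_pct": tr.sto2_pct,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def generate_cohort(
    n_subjects: int = 20,
    trials_per_subject: int = 3,
    distributions: dict | None = None,
    seed: np.random.Generator | int | None = 0,
    protocol: BreathingProtocol | None = None,
    geometry: PatchGeometry | None = None,
    spectra: ChromophoreSpectra | None = None,
    optics: TissueOptics | None = None,
    noise: NoiseModel | None = None,
    between_location_corr: float = 0.5,
    base_params: LocationHemodynamics | None = None,
) -> Cohort:
    """Simulate a full cohort: n_subjects x 4 locations x trials recordings.

    All randomness flows from a single seeded generator, so a fixed seed
    reproduces the cohort exactly.
    """
    if trials_per_subject < 1:
        raise ParameterError("trials_per_subject must be >= 1")
    protocol = protocol or BreathingProtocol()
    geometry = geometry or PatchGeometry()
    spectra = spectra or ChromophoreSpectra.default()
    optics = optics or TissueOptics()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    profiles = generate_profiles(
        n_subjects, distributions, between_location_corr, rng, base_params
    )
    truths, recordings = {}, {}
    for p in profiles:
        for loc in LOCATIONS:
            for trial in range(trials_per_subject):
                truth = generate_truth(
                    p, loc, protocol, geometry.sampling_rate_hz, rng
                )
                rec = truth_to_recording(
                    truth, geometry, spectra, optics, noise, rng,
                    subject_id=p.subject_id, location=loc, trial_index=trial,
                )
                truths[(p.subject_id, loc, trial)] = truth
                recordings[(p.subject_id, loc, trial)] = rec
    return Cohort(
        profiles=profiles, protocol=protocol, geometry=geometry, spectra=spectra,
        optics=optics, noise=noise, truths=truths, recordings=recordings,
    )
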