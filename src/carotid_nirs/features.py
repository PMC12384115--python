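"""Extraction of the six parameters of interest from reconstructed traces.

Per subject and patch location the pipeline computes, from the least-noisy
trial:

* maximum % change of HbT and of StO2 during the breath hold, relative to
  the mean baseline over the first 20 s of normal breathing;
* mean oscillation time of HbT and StO2 during deep breathing — the mean
  interval between adjacent alternating extrema (peak to the next trough,
  i.e. a half-period for a sinusoid);
* mean peak-to-peak amplitude of HbT [uM] and StO2 [% points] during deep
  breathing — the mean |peak - adjacent trough| difference.

Trial selection uses the signal-to-noise ratio of the HbT trace during the
deep-breathing segment, computed under a sinusoidal signal assumption: the
largest non-DC periodogram component is the fundamental, its first harmonics
are excluded, and everything else is noise.  If no trial at a location
reaches the SNR threshold (1 dB by default) the location is excluded for
that subject.  A single-pass two-standard-deviation outlier screen is then
applied per parameter and location across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, periodogram

from ._constants import FEATURE_COLUMNS, OSC_TIME_CONVENTION
from .cohort import BreathingProtocol
from .optics import ParameterError
from .recon import ReconstructedTrace

__all__ = [
    "ExtractionConfig",
    "segment_masks",
    "baseline_value",
    "bh_max_percent_change",
    "detect_extrema",
    "mean_oscillation_time",
    "mean_pkpk_amplitude",
    "db_snr",
    "select_trial",
    "remove_outliers",
    "extract_trial_features",
    "extract_cohort_features",
    "screen_outliers",
]

log = logging.getLogger(__name__)

SNR_CAP_DB = 100.0


@dataclass(frozen=True)
class ExtractionConfig:
    baseline_window_s: tuple[float, float] = (0.0, 20.0)
    smooth_window: int = 3                 # moving-average width for extremum search
    prominence_iqr_frac: float = 0.2       # prominence floor as fraction of segment IQR
    snr_threshold_db: float = 1.0
    snr_harmonics: int = 5
    osc_time_convention: str = OSC_TIME_CONVENTION


def segment_masks(time_s: np.ndarray, protocol: BreathingProtocol) -> dict[str, np.ndarray]:
    """Boolean masks per protocol segment; half-open [start, end) intervals.

    The masks tile the protocol span with no gaps or overlaps.  Raises if the
    trace does not cover the full protocol.
    """
    t_end = time_s[-1]
    dt = float(np.median(np.diff(time_s))) if len(time_s) > 1 else 0.0
    if t_end + dt < protocol.total_duration_s - dt:
        raise ParameterError(
            f"trace covers {t_end:.1f}s but protocol requires "
            f"{protocol.total_duration_s:.1f}s"
        )
    masks = {}
    for label, (a, b) in protocol.bounds.items():
        masks[label] = (time_s >= a) & (time_s < b)
    return masks


def baseline_value(values: np.ndarray, time_s: np.ndarray,
                   window_s: tuple[float, float] = (0.0, 20.0)) -> float:
    """Mean of the trace over the baseline window (first 20 s by default)."""
    m = (time_s >= window_s[0]) & (time_s < window_s[1])
    if not m.any():
        raise ParameterError("baseline window contains no samples")
    return float(np.nanmean(values[m]))


def bh_max_percent_change(values: np.ndarray, bh_mask: np.ndarray, baseline: float) -> float:
    """100 * (max during breath hold - baseline) / baseline; NaN if baseline 0."""
    if baseline == 0 or not np.isfinite(baseline):
        return float("nan")
    if not bh_mask.any():
        raise ParameterError("breath-hold mask is empty")
    return float(100.0 * (np.nanmax(values[bh_mask]) - baseline) / baseline)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def detect_extrema(
    values: np.ndarray,
    time_s: np.ndarray,
    smooth_window: int = 3,
    prominence_iqr_frac: float = 0.2,
) -> list[tuple[float, float, str]]:
    """Alternating peaks/troughs of an oscillating segment.

    Extrema are located on a lightly smoothed copy (moving average, default
    3 samples) with a prominence floor proportional to the segment's
    interquartile range; alternation is enforced by keeping the more extreme
    of same-kind neighbors.  The reported extremum *values* are read from the
    raw (unsmoothed) samples, refined within +-1 sample, so smoothing does
    not attenuate peak-to-peak amplitudes.

    Returns a time-ordered list of (time, value, 'peak'|'trough'); an empty
    or single-entry list means the oscillation features are undefined.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ParameterError("segment too short for extremum detection")
    finite = np.isfinite(x)
    if not finite.all():
        x = np.interp(np.arange(len(x)), np.flatnonzero(finite), x[finite]) \
            if finite.any() else x
    sm = _moving_average(x, smooth_window)
    q75, q25 = np.percentile(sm, [75, 25])
    floor = prominence_iqr_frac * (q75 - q25)
    if floor <= 0:
        return []
    peaks, _ = find_peaks(sm, prominence=floor)
    troughs, _ = find_peaks(-sm, prominence=floor)
    events = sorted(
        [(i, "peak") for i in peaks] + [(i, "trough") for i in troughs]
    )
    # enforce strict alternation on the smoothed trace
    kept: list[tuple[int, str]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (sm[i] > sm[prev]) if kind == "peak" else (sm[i] < sm[prev])
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    # find_peaks cannot assign full prominence near the segment edges; recover
    # a leading/trailing extremum when the head/tail contains a genuine
    # turning point (never the boundary sample itself, so a segment cut
    # mid-rise does not fake one).
    if kept:
        def _edge_candidate(lo: int, hi: int, anchor: int, want: str):
            if hi - lo < 3:
                return None
            seg = sm[lo:hi]
            j = lo + int(np.argmax(seg) if want == "peak" else np.argmin(seg))
            if j in (lo, hi - 1) or j == anchor:
                return None
            # full prominence toward the interior anchor; half the floor
            # toward the boundary side, which the window truncates
            outer = sm[lo: j + 1] if anchor > j else sm[j:hi]
            if want == "peak":
                ok = sm[j] - sm[anchor] >= floor and sm[j] - outer.min() >= 0.5 * floor
            else:
                ok = sm[anchor] - sm[j] >= floor and outer.max() - sm[j] >= 0.5 * floor
            return (j, want) if ok else None

        first_i, first_kind = kept[0]
        cand = _edge_candidate(
            0, first_i + 1, first_i, "trough" if first_kind == "peak" else "peak"
        )
        if cand:
            kept.insert(0, cand)
        last_i, last_kind = kept[-1]
        cand = _edge_candidate(
            last_i, len(sm), last_i, "trough" if last_kind == "peak" else "peak"
        )
        if cand:
            kept.append(cand)
    out = []
    for i, kind in kept:
        lo, hi = max(0, i - 1), min(len(x), i + 2)
        j = lo + (np.argmax(x[lo:hi]) if kind == "peak" else np.argmin(x[lo:hi]))
        out.append((float(time_s[j]), float(x[j]), kind))
    return out


def mean_oscillation_time(extrema: list[tuple[float, float, str]]) -> float:
    """Mean time between adjacent alternating extrema (half-period); NaN if <2."""
    if len(extrema) < 2:
        return float("nan")
    times = np.array([e[0] for e in extrema])
    return float(np.mean(np.diff(times)))


def mean_pkpk_amplitude(extrema: list[tuple[float, float, str]]) -> float:
    """Mean |peak - adjacent trough| over consecutive alternating pairs."""
    if len(extrema) < 2:
        return float("nan")
    vals = np.array([e[1] for e in extrema])
    return float(np.mean(np.abs(np.diff(vals))))


def db_snr(
    values: np.ndarray,
    sampling_rate_hz: float,
    n_harmonics: int = 5,
) -> tuple[float, bool]:
    """Sinusoid-assuming SNR [dB] of a segment, and a reliability flag.

    The segment is linearly detrended; in its periodogram the largest non-DC
    bin (with its two neighbors, to absorb spectral leakage) is taken as the
    fundamental, the first ``n_harmonics`` harmonics are excluded, and the
    remaining band power (rescaled for the excluded bins) is noise:
    SNR = 10*log10(P_fundamental / P_noise).  A pure sinusoid is capped at
    +100 dB.  The flag is False when the segment is shorter than two
    fundamental periods (estimate unreliable).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        return float("nan"), False
    x = x - x.mean()
    # Hann window: confines the tone (and any slow residual trend) to a
    # narrow lobe instead of a linear-detrend step, which would leak a
    # finite sinusoid across the whole band.
    f, p = periodogram(x, fs=sampling_rate_hz, window="hann", detrend=False)
    n_bins = len(p)
    dc_band = {0, 1}
    search = [b for b in range(n_bins) if b not in dc_band]
    if len(search) < 4:
        return float("nan"), False
    k0 = search[int(np.argmax(p[search]))]

    def _band(k):
        return [b for b in range(k - 2, k + 3) if 2 <= b < n_bins]

    sig_bins = set(_band(k0))
    excl = set(sig_bins)
    for h in range(2, n_harmonics + 2):
        kh = k0 * h
        if kh - 2 >= n_bins:
            break
        excl.update(_band(kh))
    noise_bins = [b for b in range(2, n_bins) if b not in excl]
    p_sig = p[list(sig_bins)].sum()
    duration = len(x) / sampling_rate_hz
    # unreliable when under two fundamental periods fit in the segment, or
    # when the spectrum is dominated by an unresolvable near-DC component
    reliable = bool(f[k0] * duration >= 2.0 and p[k0] >= p[1])
    if not noise_bins:
        return SNR_CAP_DB, reliable
    p_noise = p[noise_bins].sum() * (n_bins - 2) / len(noise_bins)
    if p_noise <= 0 or (p_sig > 0 and p_sig / p_noise > 10 ** (SNR_CAP_DB / 10)):
        return SNR_CAP_DB, reliable
    if p_sig <= 0:
        return float("nan"), False
    return float(10.0 * np.log10(p_sig / p_noise)), reliable


def select_trial(trial_snrs_db: list[float], threshold_db: float = 1.0) -> int | None:
    """Index of the least-noisy trial (highest SNR); None when every trial is
    below threshold (location excluded).  Ties go to the earliest trial."""
    if len(trial_snrs_db) < 1:
        raise ParameterError("need at least one trial")
    arr = np.asarray(trial_snrs_db, dtype=float)
    arr = np.where(np.isfinite(arr), arr, -np.inf)
    best = int(np.argmax(arr))  # argmax takes the first of equal maxima
    if arr[best] < threshold_db:
        return None
    return best


def remove_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 2-SD screen: keep v with |v - mean| <= 2*sample SD.

    Returns (keep_mask, removed_indices); a no-op (with a warning) for fewer
    than 3 finite values.  NaNs are ignored and always kept as NaN.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        log.warning("outlier screen skipped: fewer than 3 values")
        return np.ones(len(v), dtype=bool), np.array([], dtype=int)
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    keep = ~finite | (np.abs(v - mean) <= 2.0 * sd)
    return keep, np.flatnonzero(~keep)


def extract_trial_features(
    trace: ReconstructedTrace,
    protocol: BreathingProtocol,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """The six parameters of interest plus the DB SNR for one trial."""
    cfg = config or ExtractionConfig()
    masks = segment_masks(trace.time_s, protocol)
    bh, db = masks["breath_hold"], masks["deep_breathing"]
    hbt_abs = trace.hbt_uM
    sto2 = trace.sto2_pct

    hbt_base = baseline_value(hbt_abs, trace.time_s, cfg.baseline_window_s)
    sto2_base = baseline_value(sto2, trace.time_s, cfg.baseline_window_s)

    fs = 1.0 / np.median(np.diff(trace.time_s))
    out: dict[str, float] = {}
    out["bh_max_pct_change_hbt_pct"] = bh_max_percent_change(hbt_abs, bh, hbt_base)
    out["bh_max_pct_change_sto2_pct"] = bh_max_percent_change(sto2, bh, sto2_base)
    for name, series in (("hbt", trace.d_hbt_uM), ("sto2", sto2)):
        ext = detect_extrema(
            series[db], trace.time_s[db], cfg.smooth_window, cfg.prominence_iqr_frac
        )
        out[f"db_mean_osc_time_{name}_s"] = mean_oscillation_time(ext)
        unit = "uM" if name == "hbt" else "pct"
        out[f"db_mean_pkpk_{name}_{unit}"] = mean_pkpk_amplitude(ext)
    snr, reliable = db_snr(trace.d_hbt_uM[db], fs, cfg.snr_harmonics)
    out["db_snr_db"] = snr
    out["db_snr_reliable"] = float(reliable)
    return out


def extract_cohort_features(
    traces: dict[tuple[str, str, int], ReconstructedTrace],
    protocol: BreathingProtocol,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Feature table: one row per subject x location, from the selected trial.

    Locations where every trial falls below the SNR threshold are retained as
    excluded rows (features NaN, reason recorded).
    """
    cfg = config or ExtractionConfig()
    by_subj_loc: dict[tuple[str, str], list[tuple[int, ReconstructedTrace]]] = {}
    for (sid, loc, trial), tr in traces.items():
        by_subj_loc.setdefault((sid, loc), []).append((trial, tr))

    rows = []
    for (sid, loc), items in sorted(by_subj_loc.items()):
        items.sort(key=lambda it: it[0])
        feats = [extract_trial_features(tr, protocol, cfg) for _, tr in items]
        snrs = [f["db_snr_db"] for f in feats]
        sel = select_trial(snrs, cfg.snr_threshold_db)
        row: dict[str, object] = {"subject_id": sid, "location": loc}
        if sel is None:
            row.update({c: np.nan for c in FEATURE_COLUMNS})
            row.update(
                db_snr_db=max(snrs) if snrs else np.nan, selected_trial=-1,
                excluded=True, exclusion_reason="all trial SNRs below threshold",
            )
        else:
            chosen = feats[sel]
            row.update({c: chosen[c] for c in FEATURE_COLUMNS})
            row.update(
                db_snr_db=chosen["db_snr_db"],
                selected_trial=items[sel][0],
                excluded=False, exclusion_reason="",
            )
        rows.append(row)
    cols = ["subject_id", "location", *FEATURE_COLUMNS,
            "db_snr_db", "selected_trial", "excluded", "exclusion_reason"]
    return pd.DataFrame(rows, columns=cols)


def screen_outliers(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the 2-SD outlier screen once, per parameter x location group.

    Removed entries become NaN in the returned copy; the second frame logs
    every removal (subject, location, parameter, value).
    """
    out = features.copy()
    removals = []
    for col in FEATURE_COLUMNS:
        for loc, grp in features.groupby("location"):
            keep, removed_idx = remove_outliers(grp[col].to_numpy())
            for pos in removed_idx:
                idx = grp.index[pos]
                removals.append(
                    {
                        "subject_id": grp.loc[idx, "subject_id"],
                        "location": loc,
                        "parameter": col,
                        "value": grp.loc[idx, col],
                    }
                )
                out.loc[idx, col] = np.nan
    rem = pd.DataFrame(removals, columns=["subject_id", "location", "parameter", "value"])
    return out, rem
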