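"""Pipeline orchestration: configuration, file contracts, and run-all.

Stages (simulate -> reconstruct -> features -> stats) communicate through
long/tidy tables so each one can run in a separate process from files plus
the configuration alone.  Time is in seconds from trial start; segment
intervals are half-open; every column name carries its unit suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from ._constants import FEATURE_COLUMNS, LOCATIONS
from .cohort import (
    BreathingProtocol,
    Cohort,
    NoiseModel,
    TissueOptics,
    TrialRecording,
    DEFAULT_FEATURE_DISTRIBUTIONS,
    generate_cohort,
)
from .features import ExtractionConfig, extract_cohort_features, screen_outliers
from .optics import (
    DEFAULT_BOUNDARY_A,
    DEFAULT_MU_S_PRIME,
    ChromophoreSpectra,
    PatchGeometry,
)
from .recon import ReconstructionConfig, reconstruct_trial
from .stats import DEFAULT_EQUIVALENCE_THRESHOLDS, run_equivalence_battery

__all__ = ["PipelineConfig", "run_all", "validate_tables", "reconstruct_cohort",
           "traces_frame", "recordings_to_cohort_arrays"]

log = logging.getLogger(__name__)


class GeometryConfig(BaseModel):
    source_detector_distances_mm: list[float] = [25.0, 32.0]
    wavelengths_nm: list[float] = [670.0, 780.0, 808.0, 850.0]
    sampling_rate_hz: float = 2.24

    def build(self) -> PatchGeometry:
        return PatchGeometry(
            tuple(self.source_detector_distances_mm),
            tuple(self.wavelengths_nm),
            self.sampling_rate_hz,
        )


class ProtocolConfig(BaseModel):
    segment_durations_s: list[float] = [30.0, 30.0, 30.0, 30.0, 30.0]
    inhale_lead_s: float = 5.0
    hold_s: float = 25.0

    def build(self) -> BreathingProtocol:
        labels = ("normal1", "breath_hold", "normal2", "deep_breathing", "normal3")
        return BreathingProtocol(
            tuple(zip(labels, self.segment_durations_s)),
            self.inhale_lead_s,
            self.hold_s,
        )


class OpticsConfig(BaseModel):
    mu_s_prime_per_mm: dict[float, float] = Field(
        default_factory=lambda: dict(DEFAULT_MU_S_PRIME)
    )
    boundary_A: float = DEFAULT_BOUNDARY_A

    def build(self) -> TissueOptics:
        return TissueOptics(dict(self.mu_s_prime_per_mm), self.boundary_A)


class NoiseConfig(BaseModel):
    multiplicative_sd: float = 1e-3
    additive_sd: float = 0.0
    drift_fraction: float = 2e-3
    motion_rate_per_trial: float = 0.3
    motion_amplitude: float = 0.02
    motion_duration_s: float = 1.5

    def build(self) -> NoiseModel:
        return NoiseModel(
            self.multiplicative_sd, self.additive_sd, self.drift_fraction,
            self.motion_rate_per_trial, self.motion_amplitude, self.motion_duration_s,
        )


class GeneratorConfig(BaseModel):
    feature_distributions: dict[str, dict] = Field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_FEATURE_DISTRIBUTIONS.items()
        }
    )
    between_location_corr: float = 0.5

    @field_validator("feature_distributions")
    @classmethod
    def _normalize_entries(cls, v: dict) -> dict:
        # (mean, sd) pairs may arrive as lists after a YAML/JSON round trip
        return {
            k: {
                kk: (tuple(vv) if isinstance(vv, (list, tuple)) else vv)
                for kk, vv in spec.items()
            }
            for k, spec in v.items()
        }

    def distributions(self) -> dict:
        out = {}
        for k, v in self.feature_distributions.items():
            out[k] = {
                kk: (tuple(vv) if isinstance(vv, (list, tuple)) else vv)
                for kk, vv in v.items()
            }
        return out


class ExtractionSettings(BaseModel):
    baseline_window_s: tuple[float, float] = (0.0, 20.0)
    smooth_window: int = 3
    prominence_iqr_frac: float = 0.2
    snr_threshold_db: float = 1.0
    snr_harmonics: int = 5

    def build(self) -> ExtractionConfig:
        return ExtractionConfig(
            tuple(self.baseline_window_s), self.smooth_window,
            self.prominence_iqr_frac, self.snr_threshold_db, self.snr_harmonics,
        )


class StatsConfig(BaseModel):
    thresholds: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EQUIVALENCE_THRESHOLDS)
    )
    bonferroni_m: int = 4
    alpha: float = 0.05


class PipelineConfig(BaseModel):
    """Fully serializable configuration of the end-to-end pipeline."""

    n_subjects: int = 20
    trials_per_subject: int = 3
    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    extraction: ExtractionSettings = Field(default_factory=ExtractionSettings)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    fallback_baseline: tuple[float, float] = (60.0, 70.0)
    detrend: bool = False
    table_format: str = "csv"  # or "parquet"

    model_config = {"extra": "forbid"}

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json())))

    def recon_config(self) -> ReconstructionConfig:
        return ReconstructionConfig(
            reference_window_s=tuple(self.extraction.baseline_window_s),
            spectra=ChromophoreSpectra.default(),
            tissue=self.optics.build(),
            fallback_baseline=tuple(self.fallback_baseline),
            detrend=self.detrend,
        )


# --------------------------------------------------------------------------
# In-memory stage helpers
# --------------------------------------------------------------------------


def simulate(config: PipelineConfig, seed: int | None = None) -> Cohort:
    return generate_cohort(
        n_subjects=config.n_subjects,
        trials_per_subject=config.trials_per_subject,
        distributions=config.generator.distributions(),
        seed=config.seed if seed is None else seed,
        protocol=config.protocol.build(),
        geometry=config.geometry.build(),
        optics=config.optics.build(),
        noise=config.noise.build(),
        between_location_corr=config.generator.between_location_corr,
    )


def reconstruct_cohort(cohort: Cohort, config: PipelineConfig) -> dict:
    rcfg = config.recon_config()
    return {key: reconstruct_trial(rec, rcfg) for key, rec in sorted(cohort.recordings.items())}


def traces_frame(traces: dict) -> pd.DataFrame:
    frames = []
    for (sid, loc, trial), tr in sorted(traces.items()):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid, "location": loc, "trial": trial,
                    "time_s": tr.time_s,
                    "d_hbo2_uM": tr.d_hbo2_uM, "d_hb_uM": tr.d_hb_uM,
                    "d_hbt_uM": tr.d_hbt_uM, "sto2_pct": tr.sto2_pct,
                    "hbt0_uM": tr.hbt0_uM, "sto2_0_pct": tr.sto2_0_pct,
                    "flagged": tr.flags.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def recordings_to_cohort_arrays(
    recordings: pd.DataFrame, geometry: PatchGeometry
) -> dict[tuple[str, str, int], TrialRecording]:
    """Rebuild in-memory recordings from the long table (file-based stages)."""
    out = {}
    nw = len(geometry.wavelengths_nm)
    nr = len(geometry.source_detector_distances_mm)
    for (sid, loc, trial), grp in recordings.groupby(
        ["subject_id", "location", "trial"], sort=True
    ):
        grp = grp.sort_values(["wavelength_nm", "distance_mm", "time_s"])
        t = np.sort(grp["time_s"].unique())
        intensity = grp["intensity"].to_numpy().reshape(nw, nr, len(t))
        out[(sid, loc, int(trial))] = TrialRecording(
            subject_id=sid, location=loc, trial_index=int(trial),
            geometry=geometry, time_s=t, intensity=intensity,
            gain=np.ones((nw, nr)),
        )
    return out


# --------------------------------------------------------------------------
# run-all
# --------------------------------------------------------------------------


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> Path:
    if fmt == "parquet":
        path = path.with_suffix(".parquet")
        df.to_parquet(path, index=False)
    else:
        path = path.with_suffix(".csv")
        df.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages on one seed and write the report bundle.

    Writes per-stage tables, results JSON, a plain-text summary in the
    'MoD [95% CI]; p' reporting format, and a manifest with stage hashes.
    Deterministic: re-running with the same config produces byte-identical
    tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_files: dict[str, str] = {}
    fmt = config.table_format

    log.info("stage=simulate seed=%d", config.seed)
    cohort = simulate(config)
    profiles = cohort.profiles_frame()
    true_feats = cohort.true_features_frame()
    files = {
        "profiles": _write_table(profiles, out / "profiles", "csv"),
        "true_features": _write_table(true_feats, out / "true_features", "csv"),
        "recordings": _write_table(cohort.recordings_frame(), out / "recordings", fmt),
        "truth": _write_table(cohort.truth_frame(), out / "truth", fmt),
    }

    log.info("stage=reconstruct")
    traces = reconstruct_cohort(cohort, config)
    files["traces"] = _write_table(traces_frame(traces), out / "traces", fmt)

    log.info("stage=features")
    feats = extract_cohort_features(traces, cohort.protocol, config.extraction.build())
    feats_screened, removals = screen_outliers(feats)
    files["features"] = _write_table(feats_screened, out / "features", "csv")
    files["outlier_removals"] = _write_table(removals, out / "outlier_removals", "csv")

    log.info("stage=stats")
    battery = run_equivalence_battery(
        feats_screened[~feats_screened["excluded"]], profiles,
        thresholds=config.stats.thresholds, m=config.stats.bonferroni_m,
        alpha=config.stats.alpha,
    )
    for name, df in battery.items():
        files[name] = _write_table(df, out / name, "csv")

    eq = battery["equivalence"]
    results = {
        "n_subjects": config.n_subjects,
        "n_locations": len(LOCATIONS),
        "n_series_before_qc": config.n_subjects * len(LOCATIONS),
        "n_excluded_locations": int(feats_screened["excluded"].sum()),
        "equivalence": json.loads(eq.to_json(orient="records")),
    }
    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    files["results"] = out / "results.json"

    lines = [
        f"Cohort: {config.n_subjects} subjects x {len(LOCATIONS)} locations "
        f"({config.n_subjects * len(LOCATIONS)} artery-level series before QC), "
        f"{config.trials_per_subject} trials each",
        f"Excluded locations (all-trial SNR < threshold): "
        f"{int(feats_screened['excluded'].sum())}",
        "",
    ]
    for _, r in eq.iterrows():
        if r.get("skipped", False):
            lines.append(
                f"{r['parameter']} {r['location_a']} vs {r['location_b']}: "
                f"skipped ({r['skip_reason']})"
            )
        else:
            verdict = "equivalent" if r["equivalent"] else "not equivalent"
            lines.append(
                f"{r['parameter']} {r['location_a']} vs {r['location_b']}: "
                f"MoD {r['mod']:.3g} [{r['ci_low']:.3g}, {r['ci_high']:.3g}]; "
                f"p = {r['p_adjusted']:.3g} ({verdict}, delta = {r['delta']:g})"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    files["summary"] = out / "summary.txt"

    manifest = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": {k: {"file": str(v.name), "sha256": _sha256(v)} for k, v in files.items()},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run-all finished in %.1fs", time.time() - t0)
    return {"files": {k: str(v) for k, v in files.items()}, "results": results,
            "battery": battery, "features": feats_screened}


# --------------------------------------------------------------------------
# Table validation
# --------------------------------------------------------------------------

_SCHEMAS = {
    "recordings": {
        "columns": ["subject_id", "location", "trial", "wavelength_nm",
                     "distance_mm", "time_s", "intensity"],
        "key": ["subject_id", "location", "trial", "wavelength_nm",
                "distance_mm", "time_s"],
        "positive": ["intensity"],
    },
    "traces": {
        "columns": ["subject_id", "location", "trial", "time_s", "d_hbo2_uM",
                     "d_hb_uM", "d_hbt_uM", "sto2_pct"],
        "key": ["subject_id", "location", "trial", "time_s"],
        "positive": [],
    },
    "features": {
        "columns": ["subject_id", "location", *FEATURE_COLUMNS],
        "key": ["subject_id", "location"],
        "positive": [],
    },
}


def validate_tables(path: str | Path, schema_name: str) -> list[dict]:
    """Validate a stage table against its schema; returns a violation list.

    Checks column presence, numeric dtypes, key uniqueness, domain rules
    (positive intensity, StO2 in [0, 100]) and monotone time within trials.
    An empty list means the table is valid; violations are returned, never
    silently coerced.
    """
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    schema = _SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    violations: list[dict] = []
    missing = [c for c in schema["columns"] if c not in df.columns]
    for c in missing:
        violations.append({"kind": "missing_column", "column": c})
    if missing:
        return violations
    for c in schema["columns"]:
        if c in ("subject_id", "location", "exclusion_reason"):
            continue
        if not pd.api.types.is_numeric_dtype(df[c]):
            violations.append({"kind": "dtype", "column": c})
    key = schema["key"]
    dup = df.duplicated(subset=key)
    if dup.any():
        violations.append(
            {"kind": "duplicate_key", "count": int(dup.sum()),
             "example": df.loc[dup.idxmax(), key].to_dict()}
        )
    for c in schema["positive"]:
        bad = ~(df[c] > 0)
        if bad.any():
            violations.append({"kind": "domain", "column": c, "count": int(bad.sum())})
    if "sto2_pct" in df.columns:
        bad = ~df["sto2_pct"].between(0, 100) & df["sto2_pct"].notna()
        if bad.any():
            violations.append({"kind": "domain", "column": "sto2_pct",
                               "count": int(bad.sum())})
    if "time_s" in df.columns and schema_name in ("recordings", "traces"):
        group_cols = [c for c in key if c != "time_s"]
        for g, grp in df.groupby(group_cols, sort=False):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                violations.append({"kind": "nonmonotone_time", "group": g})
                break
    return violations
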