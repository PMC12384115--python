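import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carotid_nirs import (
    BreathingProtocol,
    ChromophoreSpectra,
    LocationHemodynamics,
    NoiseModel,
    PatchGeometry,
    SubjectProfile,
    TissueOptics,
    generate_truth,
    reconstruct_trial,
    truth_to_recording,
)
from carotid_nirs._constants import LOCATIONS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry() -> PatchGeometry:
    return PatchGeometry()


@pytest.fixture(scope="session")
def spectra() -> ChromophoreSpectra:
    return ChromophoreSpectra.default()


@pytest.fixture(scope="session")
def tissue() -> TissueOptics:
    return TissueOptics()


def make_profile(subject_id: str = "S000", **lp_kwargs) -> SubjectProfile:
    """A subject with identical, fully specified hemodynamics at all locations."""
    lp = LocationHemodynamics(**lp_kwargs)
    return SubjectProfile(
        subject_id=subject_id,
        sex_assigned_at_birth="female",
        race_group="nonwhite",
        skin_tone="olive",
        systolic_bp_mmHg=115.0,
        diastolic_bp_mmHg=71.0,
        heart_rate_bpm=72.0,
        carotid_anatomy={
            side: {
                "bulb_depth_mm": 15.0, "bulb_diameter_mm": 7.0,
                "ica_diameter_mm": 5.0, "eca_diameter_mm": 4.5,
            }
            for side in ("left", "right")
        },
        location_params={loc: lp for loc in LOCATIONS},
    )


def quiet_profile(**overrides) -> SubjectProfile:
    """Deterministic subject: no physiological fluctuation or cycle jitter."""
    kwargs = dict(
        bh_hbt_rise_pct=3.5, bh_sto2_change_pct=1.0,
        db_hbt_pkpk_uM=1.6, db_sto2_pkpk_pct=0.5,
        db_sto2_osc_time_s=3.5, db_hbt_osc_time_s=7.0,
        hbt_response_delay_s=1.5,
        physio_fluct_hbt_uM=0.0, physio_fluct_sto2_pct=0.0,
        db_amp_jitter_cv=0.0,
    )
    kwargs.update(overrides)
    return make_profile(**kwargs)


def noiseless_chain(profile, location="left_carotid", seed=0,
                    geometry=None, spectra=None, tissue=None):
    """simulate -> record (no noise) -> reconstruct, for one trial."""
    geometry = geometry or PatchGeometry()
    spectra = spectra or ChromophoreSpectra.default()
    tissue = tissue or TissueOptics()
    rng = np.random.default_rng(seed)
    truth = generate_truth(profile, location, rng=rng)
    rec = truth_to_recording(
        truth, geometry, spectra, tissue, NoiseModel.none(), rng,
        subject_id=profile.subject_id, location=location,
    )
    return truth, rec, reconstruct_trial(rec)


@pytest.fixture()
def protocol() -> BreathingProtocol:
    return BreathingProtocol()
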