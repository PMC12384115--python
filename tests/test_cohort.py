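"""Synthetic-cohort tests: protocol structure, conservation, determinism,
convergence of the population distributions, and noise phenomenology."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

from carotid_nirs import (
    BreathingProtocol,
    NoiseModel,
    generate_cohort,
    generate_profiles,
    generate_truth,
    truth_to_recording,
)
from carotid_nirs._constants import LOCATIONS, OSC_TIME_CONVENTION
from carotid_nirs.cohort import DEFAULT_FEATURE_DISTRIBUTIONS
from carotid_nirs.features import db_snr, segment_masks
from carotid_nirs.optics import ParameterError

from conftest import make_profile, quiet_profile


class TestProtocol:
    def test_default_is_five_30s_segments(self):
        p = BreathingProtocol()
        assert p.total_duration_s == 150.0
        assert [d for _, d in p.segments] == [30.0] * 5
        b = p.bounds
        assert b["breath_hold"] == (30.0, 60.0)
        assert b["deep_breathing"] == (90.0, 120.0)

    def test_segment_masks_tile_the_trace(self):
        p = BreathingProtocol()
        fs = 2.24
        t = np.arange(int(round(150 * fs))) / fs
        masks = segment_masks(t, p)
        total = np.zeros(len(t), dtype=int)
        for m in masks.values():
            total += m.astype(int)
        assert np.all(total == 1)  # partition: no gaps, no overlaps
        # convention: BH mask starts at the first sample with t >= 30 s
        first_bh = np.flatnonzero(masks["breath_hold"])[0]
        assert t[first_bh] >= 30.0 and t[first_bh - 1] < 30.0
        dur = sum(m.sum() for m in masks.values()) / fs
        assert dur == pytest.approx(150.0, abs=1.0 / fs)


class TestTruthGeneration:
    def test_conservation_and_saturation_identity(self):
        prof = make_profile()
        truth = generate_truth(prof, "left_carotid", rng=0)
        np.testing.assert_allclose(truth.hbt_uM, truth.hbo2_uM + truth.hb_uM, rtol=0, atol=1e-12)
        np.testing.assert_allclose(
            truth.sto2_pct, 100 * truth.hbo2_uM / truth.hbt_uM, rtol=1e-12
        )
        assert np.all((truth.sto2_pct >= 0) & (truth.sto2_pct <= 100))

    def test_null_subject_is_flat(self):
        prof = quiet_profile(
            bh_hbt_rise_pct=0.0, bh_sto2_change_pct=0.0,
            db_hbt_pkpk_uM=0.0, db_sto2_pkpk_pct=0.0,
        )
        truth = generate_truth(prof, "left_radial", rng=0)
        assert np.ptp(truth.hbt_uM) == 0.0
        assert np.ptp(truth.sto2_pct) == 0.0
        assert truth.true_features["bh_max_pct_change_hbt_pct"] == 0.0

    def test_generator_writes_its_own_parameters(self):
        """Specified DB amplitude/half-period appear in the waveform itself."""
        prof = quiet_profile(db_sto2_pkpk_pct=0.3, db_sto2_osc_time_s=3.5)
        truth = generate_truth(prof, "left_radial", rng=0)
        db = (truth.time_s >= 90) & (truth.time_s < 120)
        sto2 = truth.sto2_pct[db]
        assert np.ptp(sto2) == pytest.approx(0.3, rel=0.05)
        # adjacent-extremum spacing: sample-grid argrelextrema on the pure tone
        t = truth.time_s[db]
        ext_t = []
        for i in range(1, len(sto2) - 1):
            if (sto2[i] - sto2[i - 1]) * (sto2[i + 1] - sto2[i]) < 0:
                ext_t.append(t[i])
        gaps = np.diff(ext_t)
        assert np.mean(gaps) == pytest.approx(3.5, rel=0.1)
        assert truth.osc_time_convention == OSC_TIME_CONVENTION

    def test_breath_hold_peaks_near_hold_end(self):
        prof = quiet_profile(bh_hbt_rise_pct=3.0)
        truth = generate_truth(prof, "left_radial", rng=0)
        i_max = int(np.argmax(truth.hbt_uM))
        assert 55.0 <= truth.time_s[i_max] < 60.5
        assert truth.hbt_uM.max() == pytest.approx(60.0 * 1.03, rel=1e-3)

    def test_sto2_oscillates_at_twice_the_hbt_frequency(self):
        """Dominant DB-band periodogram peak of StO2 at ~2x the HbT peak."""
        prof = quiet_profile(db_sto2_osc_time_s=3.5, db_hbt_osc_time_s=7.0,
                             hbt_response_delay_s=0.0)
        truth = generate_truth(prof, "left_carotid", rng=0)
        db = (truth.time_s >= 90) & (truth.time_s < 120)
        fs = 2.24
        f_pk = {}
        for name, x in (("sto2", truth.sto2_pct[db]), ("hbt", truth.hbt_uM[db])):
            f, p = periodogram(x - x.mean(), fs=fs)
            f_pk[name] = f[1:][np.argmax(p[1:])]
        assert f_pk["sto2"] == pytest.approx(2 * f_pk["hbt"], rel=0.25)

    def test_too_fast_oscillation_rejected(self):
        prof = quiet_profile(db_sto2_osc_time_s=0.2)
        with pytest.raises(ParameterError, match="period"):
            generate_truth(prof, "left_radial", rng=0)


class TestRecordingSynthesis:
    def test_complete_positive_grid(self, geometry, spectra, tissue):
        truth = generate_truth(quiet_profile(), "left_radial", rng=0)
        rec = truth_to_recording(truth, geometry, spectra, tissue, NoiseModel(), rng=1)
        assert rec.intensity.shape == (4, 2, len(truth.time_s))
        assert np.all(rec.intensity > 0)

    def test_motion_artifact_lowers_db_snr(self, geometry, spectra, tissue):
        truth = generate_truth(quiet_profile(), "left_radial", rng=0)
        from carotid_nirs.recon import reconstruct_trial

        noisy = NoiseModel(multiplicative_sd=5e-4, drift_fraction=0.0,
                           motion_rate_per_trial=0.0)
        snrs = {}
        for label, nm, seed in (
            ("clean", noisy, 3),
            ("motion", dataclasses.replace(
                noisy, motion_rate_per_trial=6.0, motion_amplitude=0.03), 3),
        ):
            rec = truth_to_recording(truth, geometry, spectra, tissue, nm, rng=seed)
            tr = reconstruct_trial(rec)
            db = (tr.time_s >= 90) & (tr.time_s < 120)
            snrs[label], _ = db_snr(tr.d_hbt_uM[db], 2.24)
        assert snrs["motion"] < snrs["clean"]


class TestCohortAssembly:
    def test_default_design_is_80_artery_series(self):
        cohort = generate_cohort(n_subjects=20, trials_per_subject=1, seed=0,
                                 noise=NoiseModel.none())
        keys = {(s, l) for (s, l, _t) in cohort.recordings}
        assert len(keys) == 20 * len(LOCATIONS) == 80

    def test_same_seed_reproduces_cohort_exactly(self):
        a = generate_cohort(n_subjects=2, trials_per_subject=2, seed=42)
        b = generate_cohort(n_subjects=2, trials_per_subject=2, seed=42)
        for key in a.recordings:
            np.testing.assert_array_equal(
                a.recordings[key].intensity, b.recordings[key].intensity
            )
        assert a.profiles_frame().equals(b.profiles_frame())

    def test_population_means_converge_to_specified_values(self):
        """Sample means of the drawn response parameters converge to the
        configured location means (within 3 SE at n=200)."""
        profiles = generate_profiles(200, rng=123)
        checks = [
            ("db_hbt_pkpk_uM", "left_carotid", 1.6, 1.1),
            ("db_hbt_pkpk_uM", "left_radial", 0.9, 0.8),
            ("db_sto2_pkpk_pct", "right_carotid", 0.5, 0.4),
            ("db_sto2_osc_time_s", "left_radial", 3.7, 1.4),
        ]
        for field, loc, mean, sd in checks:
            vals = np.array([getattr(p.location_params[loc], field) for p in profiles])
            assert abs(vals.mean() - mean) <= 3 * sd / np.sqrt(len(vals)), (field, loc)

    def test_demographic_proportions(self):
        profiles = generate_profiles(400, rng=7)
        female = np.mean([p.sex_assigned_at_birth == "female" for p in profiles])
        nonwhite = np.mean([p.race_group == "nonwhite" for p in profiles])
        assert abs(female - 0.65) < 0.08
        assert abs(nonwhite - 0.70) < 0.08
        assert all(p.skin_tone in ("fair", "olive", "dark") for p in profiles)

    def test_invalid_distribution_rejected(self):
        bad = {k: dict(v) for k, v in DEFAULT_FEATURE_DISTRIBUTIONS.items()}
        bad["db_hbt_pkpk_uM"] = dict(bad["db_hbt_pkpk_uM"])
        bad["db_hbt_pkpk_uM"]["left_radial"] = (0.9, -0.8)
        with pytest.raises(ParameterError):
            generate_profiles(3, distributions=bad, rng=0)
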