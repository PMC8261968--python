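"""Synthetic cohort generator: signal, epoch, spectrum and outcome levels."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from paspectrum.processing import (FilterSpec, filter_and_vm, aggregate_epochs,
                                   zero_night, detect_nonwear, assess_validity)
from paspectrum.spectrum import (compute_cutpoint_summary, compute_spectrum,
                                 standardize_spectrum)
from paspectrum.synthetic import (ActivityProfile, CohortConfig,
                                  generate_raw_signal, generate_epoch_cohort,
                                  generate_spectrum_cohort, generate_outcomes,
                                  noise_sd_for_r2, generate_latent_rank_data)


class TestActivityProfile:
    def test_step_frequency_band_enforced(self):
        with pytest.raises(ValueError):
            ActivityProfile(step_frequency_hz=4.0)
        assert 2.5 <= ActivityProfile().step_frequency_hz <= 3.0

    def test_fraction_constraints(self):
        with pytest.raises(ValueError):
            ActivityProfile(sedentary_fraction=1.2)
        with pytest.raises(ValueError):
            # active fraction 0.5 + sedentary 0.9 > 1
            ActivityProfile(bout_rate_per_hour=18.0, bout_duration_s=100.0,
                            sedentary_fraction=0.9)


class TestGenerateRawSignal:
    def test_pure_rest_classifies_all_sedentary(self):
        profile = ActivityProfile(bout_rate_per_hour=0.0)
        rec = generate_raw_signal(profile, duration_days=1.0, seed=0)
        vm = filter_and_vm(rec)
        series = zero_night(aggregate_epochs(vm, t0=rec.t0))
        detect_nonwear(series, lpa_cut_mg=40.0)
        rep = assess_validity(series, min_valid_days=1)
        c = compute_cutpoint_summary(series, validity=rep)
        wear = rep.day_table["wear_min"].sum()
        assert wear > 0 and c.sed == pytest.approx(wear)
        assert c.mvpa == 0.0

    def test_sinusoid_epochs_match_brute_force_oracle(self):
        """Package chain equals an independently coded filter+VM+mean oracle."""
        fs, f, amp = 30.0, 2.8, 0.5
        n = int(fs * 60)
        t = np.arange(n) / fs
        xyz = np.zeros((n, 3))
        xyz[:, 0] = 1.0 + amp * np.sin(2 * np.pi * f * t)
        from paspectrum.processing import RawRecording
        rec = RawRecording("s", np.datetime64("2013-09-02T00:00:00", "s"), fs, xyz)
        series = aggregate_epochs(filter_and_vm(rec), t0=rec.t0)
        # oracle: transfer-function filtering per axis, rectify, mean per 90
        b, a = sps.butter(4, [0.29, 10.0], btype="bandpass", fs=fs)
        filt = np.column_stack([sps.filtfilt(b, a, xyz[:, k]) for k in range(3)])
        vm_o = np.sqrt((filt**2).sum(axis=1)) * 1000.0
        expect = vm_o[: 20 * 90].reshape(20, 90).mean(axis=1)
        np.testing.assert_allclose(series.vm_mg, expect, atol=1e-6)

    def test_deterministic_and_clipped(self):
        profile = ActivityProfile(bout_intensity_mg=8000.0)
        r1 = generate_raw_signal(profile, duration_days=0.05, seed=7)
        r2 = generate_raw_signal(profile, duration_days=0.05, seed=7)
        np.testing.assert_array_equal(r1.xyz, r2.xyz)
        assert r1.xyz.max() <= 6.0 and r1.xyz.min() >= -6.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_raw_signal(ActivityProfile(), duration_days=0.0, seed=0)


class TestGenerateEpochCohort:
    def test_group_shift_dominates_upper_bins(self):
        cfg = CohortConfig(n_subjects=200, n_days=7, groups=("A", "B"),
                           group_shift_mg={"B": 150.0}, seed=4)
        series, conf = generate_epoch_cohort(cfg)
        spectra = []
        for s in series:
            s = zero_night(s)
            detect_nonwear(s)
            spectra.append(compute_spectrum(s).minutes_per_day)
        spectra = np.asarray(spectra)
        is_b = (conf["country"] == "B").to_numpy()
        upper = spectra[:, 8:].sum(axis=1)
        assert upper[is_b].mean() > upper[~is_b].mean()

    def test_null_shift_profiles_agree(self):
        cfg = CohortConfig(n_subjects=120, n_days=7, groups=("A", "B"), seed=5)
        series, conf = generate_epoch_cohort(cfg)
        spectra = np.asarray([
            compute_spectrum(zero_night(s)).minutes_per_day for s in series])
        is_b = (conf["country"] == "B").to_numpy()
        for b in range(22):
            d = spectra[is_b, b].mean() - spectra[~is_b, b].mean()
            se = np.sqrt(spectra[is_b, b].var(ddof=1) / is_b.sum()
                         + spectra[~is_b, b].var(ddof=1) / (~is_b).sum())
            if se > 0:
                assert abs(d) < 4 * se

    def test_deterministic(self):
        cfg = CohortConfig(n_subjects=5, n_days=2, seed=6)
        s1, c1 = generate_epoch_cohort(cfg)
        s2, c2 = generate_epoch_cohort(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.vm_mg, b.vm_mg)

    def test_time_in_bins_bounded_by_wake_window(self):
        cfg = CohortConfig(n_subjects=6, n_days=3, seed=7)
        series, _ = generate_epoch_cohort(cfg)
        wake_min = 17 * 60.0
        for s in series:
            s = zero_night(s)
            sp = compute_spectrum(s, validity=assess_validity(s, min_valid_days=1))
            assert sp.wear_min_per_day <= wake_min + 1e-9

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)


class TestGenerateSpectrumCohort:
    def test_matches_epoch_level_means(self):
        """Fast per-bin sampler converges to the epoch simulator's profile."""
        cfg = CohortConfig(n_subjects=150, n_days=7, seed=8)
        fast, _ = generate_spectrum_cohort(cfg)
        series, _ = generate_epoch_cohort(CohortConfig(n_subjects=40, n_days=7,
                                                       seed=9))
        slow = np.asarray([
            compute_spectrum(zero_night(s)).minutes_per_day for s in series])
        fm, sm = fast.to_numpy().mean(axis=0), slow.mean(axis=0)
        # agree on where the time mass is: same order of magnitude per bin
        big = sm > 5.0
        np.testing.assert_allclose(fm[big], sm[big], rtol=0.35)

    def test_deterministic_and_scales(self):
        cfg = CohortConfig(n_subjects=50, seed=10)
        a, ca = generate_spectrum_cohort(cfg)
        b, cb = generate_spectrum_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)
        assert a.shape == (50, 22)
        assert (a.sum(axis=1) <= 17 * 60.0 + 1e-9).all()


class TestGenerateOutcomes:
    def test_pure_noise_null(self, rng):
        from paspectrum.pls import cv_r2
        cfg = CohortConfig(n_subjects=1000, beta_spectrum=(0.0,) * 22,
                           noise_sd=1.0, seed=11)
        spec, _ = generate_spectrum_cohort(cfg)
        z = standardize_spectrum(spec)
        y, truth = generate_outcomes(z.to_numpy(), None, cfg)
        assert truth["true_r2"] == 0.0
        q2 = cv_r2(z.to_numpy(), y, 1, n_reps=100, seed=0)
        assert q2 <= 0.02

    def test_noiseless_limit_training_r2_one(self, rng):
        from paspectrum.pls import fit_pls, _z
        beta = np.zeros(22)
        beta[9:14] = 1.0
        cfg = CohortConfig(n_subjects=400, beta_spectrum=tuple(beta),
                           noise_sd=1e-8, seed=12)
        spec, _ = generate_spectrum_cohort(cfg)
        z = standardize_spectrum(spec)
        y, truth = generate_outcomes(z.to_numpy(), None, cfg)
        assert truth["true_r2"] > 1 - 1e-10
        from paspectrum.pls import RankError
        try:  # the residual vanishes, so SIMPLS may stop before full rank
            m = fit_pls(_z(z.to_numpy()), _z(y), z.shape[1])
        except RankError as e:
            m = fit_pls(_z(z.to_numpy()), _z(y), e.achieved)
        assert m.training_r2 > 1 - 1e-6

    def test_dimension_mismatch_rejected(self, rng):
        cfg = CohortConfig(n_subjects=10, noise_sd=1.0)
        with pytest.raises(ValueError):
            generate_outcomes(rng.normal(size=(10, 5)), None, cfg)
        with pytest.raises(ValueError):
            generate_outcomes(rng.normal(size=(10, 22)),
                              rng.normal(size=(9, 2)),
                              CohortConfig(n_subjects=10, noise_sd=1.0,
                                           beta_confounders=(1.0, 1.0)))

    def test_confounder_variance_recorded(self, rng):
        cfg = CohortConfig(n_subjects=500, beta_confounders=(2.0,),
                           noise_sd=1.0, seed=13)
        Z = rng.normal(size=(500, 22))
        D = rng.normal(size=(500, 1))
        y, truth = generate_outcomes(Z, D, cfg)
        assert truth["var_confounders"] == pytest.approx(4.0, rel=0.3)

    def test_noise_sd_for_target_r2(self, rng):
        Z = rng.normal(size=(2000, 22))
        beta = np.zeros(22)
        beta[5] = 1.0
        sd = noise_sd_for_r2(Z, beta, 0.25)
        var_sig = np.var(Z @ beta, ddof=1)
        assert var_sig / (var_sig + sd**2) == pytest.approx(0.25, abs=1e-12)


def test_latent_rank_data_shapes_and_determinism():
    X1, y1 = generate_latent_rank_data(200, seed=3)
    X2, y2 = generate_latent_rank_data(200, seed=3)
    np.testing.assert_array_equal(X1, X2)
    np.testing.assert_array_equal(y1, y2)
    assert X1.shape == (200, 22)
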