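"""Generator correctness: integrate-and-fire beats, phase-locked trains,
HR profiles, ECG synthesis, and cohort assembly."""

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

from fmsync import coupling as cp
from fmsync import preprocess as pp
from fmsync import synthgen as sg


class TestMaternalBeats:
    def test_constant_rate_is_exactly_periodic(self):
        params = sg.MaternalSimParams(
            duration=60, hr_base=60, rsa_amp=0, hrv_noise_sd=0, seed=0
        )
        beats = sg.gen_maternal_beats(params)
        assert len(beats) == 61
        np.testing.assert_allclose(beats.times, np.arange(61.0), atol=1e-9)

    def test_80bpm_spacing(self):
        params = sg.MaternalSimParams(
            duration=180, hr_base=80, rsa_amp=0, hrv_noise_sd=0, seed=0
        )
        beats = sg.gen_maternal_beats(params)
        assert len(beats) == 241
        np.testing.assert_allclose(np.diff(beats.times), 0.75, atol=1e-9)

    def test_rsa_line_in_tachogram_spectrum(self):
        # oracle: FFT of the generated tachogram peaks at the RSA frequency
        params = sg.MaternalSimParams(
            duration=180, hr_base=80, rsa_freq=0.25, rsa_amp=5, hrv_noise_sd=0, seed=1
        )
        beats = sg.gen_maternal_beats(params)
        rr_s = np.diff(beats.times)
        assert abs(np.mean(rr_s) - 0.75) / 0.75 < 0.01
        hr = 60.0 / rr_s
        t = beats.times[:-1]
        grid = np.arange(t[0], t[-1], 0.25)
        x = np.interp(grid, t, hr) - np.mean(np.interp(grid, t, hr))
        mag = np.abs(rfft(x, n=8192))
        freqs = rfftfreq(8192, d=0.25)
        sel = freqs > 0.05
        assert abs(freqs[sel][np.argmax(mag[sel])] - 0.25) < 0.01

    def test_fixed_seed_reproducible(self):
        params = sg.MaternalSimParams(duration=120, hrv_noise_sd=2.0, seed=7)
        a = sg.gen_maternal_beats(params)
        b = sg.gen_maternal_beats(params)
        assert np.array_equal(a.times, b.times)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration": -1.0},
            {"hr_base": 20.0},
            {"hr_base": float("nan")},
            {"rsa_freq": 2.0},
            {"rsa_amp": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sg.MaternalSimParams(**kwargs)


class TestLockedFetalBeats:
    def test_1_2_zero_jitter_placement(self, const_maternal_600s):
        fetal = sg.gen_fetal_beats_locked(const_maternal_600s, cp.CouplingRatio(1, 2))
        expected = np.sort(
            np.concatenate([np.arange(600) + 0.25, np.arange(600) + 0.75])
        )
        np.testing.assert_allclose(fetal.times, expected, atol=1e-12)

    def test_2_3_zero_jitter_placement(self):
        maternal = pp.BeatTimes(np.arange(5.0))
        fetal = sg.gen_fetal_beats_locked(maternal, cp.CouplingRatio(2, 3))
        expected = np.sort(
            np.concatenate([2 * np.array([1, 3, 5]) / 6.0, 2 + 2 * np.array([1, 3, 5]) / 6.0])
        )
        np.testing.assert_allclose(fetal.times, expected, atol=1e-12)

    def test_von_mises_resultant_length(self):
        # oracle: closed-form mean resultant length I1(k)/I0(k)
        kappa = 2.0
        maternal = pp.BeatTimes(np.arange(5001.0))
        fetal = sg.gen_fetal_beats_locked(
            maternal, cp.CouplingRatio(1, 2), kappa=kappa, seed=11
        )
        phases = cp.relative_phase(maternal, fetal, cp.CouplingRatio(1, 2))
        theta = 2 * np.pi * 2 * phases.psi
        z = np.exp(1j * theta)
        # target phases map to angle pi; deviations are von Mises around it
        resultant = np.abs(np.mean(z))
        mean_dev = np.angle(np.mean(z * np.exp(-1j * np.pi)))
        rho = sg.bessel_ratio(kappa)
        n = len(theta)
        se = np.sqrt((1 - rho**2) / (2 * n)) + np.sqrt(1 / n)
        assert abs(mean_dev) < 3 * se
        assert abs(resultant - rho) < 3 * se

    def test_circular_variance_matches_bessel(self):
        maternal = pp.BeatTimes(np.arange(5001.0))
        for kappa in (1.0, 4.0):
            fetal = sg.gen_fetal_beats_locked(
                maternal, cp.CouplingRatio(1, 2), kappa=kappa, seed=3
            )
            phases = cp.relative_phase(maternal, fetal, cp.CouplingRatio(1, 2))
            z = np.exp(2j * np.pi * 2 * phases.psi)
            circ_var = 1 - np.abs(np.mean(z))
            expected = 1 - sg.bessel_ratio(kappa)
            assert abs(circ_var - expected) < 3 * np.sqrt(1 / len(z))

    def test_needs_enough_maternal_beats(self):
        with pytest.raises(ValueError):
            sg.gen_fetal_beats_locked(pp.BeatTimes(np.array([0.0, 1.0, 2.0])), cp.CouplingRatio(3, 5))


class TestFetalHrProfile:
    def test_quiet_bound(self):
        params = sg.FetalSimParams(mode="free", baseline_bpm=140, osc_band_bpm=4, seed=0)
        profile = sg.gen_fetal_hr_profile(params, 180.0)
        assert np.max(np.abs(profile.hr - 140)) <= 4 + 1e-9

    def test_acceleration_reaches_amplitude(self):
        params = sg.FetalSimParams(
            mode="free", baseline_bpm=150, osc_band_bpm=0,
            accel_events=((60.0, 20.0, 20.0),), seed=0,
        )
        profile = sg.gen_fetal_hr_profile(params, 180.0)
        assert np.max(profile.hr) >= 168.0
        assert np.max(profile.hr) <= 170.0 + 1e-9

    def test_active_oscillation_round_trip(self):
        from fmsync import fbs

        params = sg.FetalSimParams(mode="free", baseline_bpm=150, osc_band_bpm=10, seed=2)
        label = fbs.classify_state(sg.gen_fetal_hr_profile(params, 180.0))
        assert label.state == "active"

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            sg.gen_fetal_hr_profile(sg.FetalSimParams(mode="free"), -5.0)


class TestSynthesizeEcg:
    def test_peaks_at_beat_times(self):
        beats = pp.BeatTimes(np.array([0.5, 1.5]))
        rec = sg.synthesize_ecg(beats, fs=1000, duration=2.0)
        assert np.argmax(rec.samples[:1000]) == 500
        assert np.argmax(rec.samples[1000:]) + 1000 == 1500

    def test_wander_removed_by_highpass(self):
        # oracle: the 5 Hz high-pass frequency response kills a 0.2 Hz tone
        beats = pp.BeatTimes(np.arange(0.5, 30.0, 0.75))
        rec = sg.synthesize_ecg(beats, fs=500, baseline_wander_amp=0.3, wander_freq_hz=0.2)
        clean = sg.synthesize_ecg(beats, fs=500)
        wander_before = rec.samples - clean.samples
        filtered = pp.highpass_baseline(rec)
        resid = filtered.samples - pp.highpass_baseline(clean).samples
        assert np.sum(resid**2) < 0.01 * np.sum(wander_before**2)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            sg.synthesize_ecg(pp.BeatTimes(np.array([0.5])), fs=100)

    def test_seeded_noise_reproducible(self):
        beats = pp.BeatTimes(np.arange(0.5, 10.0, 0.75))
        a = sg.synthesize_ecg(beats, noise_sd=0.1, seed=5)
        b = sg.synthesize_ecg(beats, noise_sd=0.1, seed=5)
        assert np.array_equal(a.samples, b.samples)


class TestKappaInversion:
    def test_target_one_gives_zero_jitter(self, const_maternal_600s):
        kappa = sg.kappa_for_lambda(1.0)
        assert np.isinf(kappa)
        fetal = sg.gen_fetal_beats_locked(const_maternal_600s, cp.CouplingRatio(1, 2), kappa=kappa)
        lam = cp.coupling_index(
            cp.relative_phase(const_maternal_600s, fetal, cp.CouplingRatio(1, 2)),
            const_maternal_600s,
        )
        assert np.nanmax(np.abs(lam.lam - 1)) < 1e-9

    def test_inversion_is_bessel_root(self):
        # oracle: numerical inversion of the squared Bessel ratio
        kappa = sg.kappa_for_lambda(0.49)
        assert abs(sg.bessel_ratio(kappa) ** 2 - 0.49) < 1e-8

    def test_realized_mean_lambda_near_target(self):
        target = 0.49
        kappa = sg.kappa_for_lambda(target)
        maternal = sg.gen_maternal_beats(
            sg.MaternalSimParams(duration=180, hr_base=72, rsa_amp=0, hrv_noise_sd=0)
        )
        lams = []
        for seed in range(5):
            fetal = sg.gen_fetal_beats_locked(
                maternal, cp.CouplingRatio(1, 2), kappa=kappa, seed=seed
            )
            lam = cp.coupling_index(
                cp.relative_phase(maternal, fetal, cp.CouplingRatio(1, 2)), maternal
            )
            lams.append(np.nanmean(lam.lam))
        assert abs(np.mean(lams) - target) < 0.05

    @pytest.mark.parametrize("bad", [1.2, 0.005, 1.0 / 70])
    def test_unreachable_targets_rejected(self, bad):
        with pytest.raises(ValueError):
            sg.kappa_for_lambda(bad)


class TestCohort:
    def test_row_counts_and_ga_ranges(self):
        spec = sg.CohortSpec(n_subjects_per_group=10, seed=4)
        segments, meta = sg.gen_cohort(spec)
        assert len(segments) == 30
        assert len(meta) == 30
        for (lo, hi), name in zip(spec.ga_ranges, spec.group_names):
            ga = meta.loc[meta["group"] == name, "ga_weeks"]
            assert len(ga) == 10
            assert ((ga >= lo) & (ga < hi)).all()

    def test_ground_truth_columns_present(self):
        _, meta = sg.gen_cohort(sg.CohortSpec(n_subjects_per_group=3, seed=0))
        for col in ("subject_id", "ga_weeks", "group", "state_true", "ratio",
                    "kappa", "lambda_target", "rsa_freq_hz"):
            assert col in meta.columns

    def test_cohort_reproducible(self):
        spec = sg.CohortSpec(n_subjects_per_group=3, seed=9)
        _, meta_a = sg.gen_cohort(spec)
        _, meta_b = sg.gen_cohort(spec)
        assert meta_a.equals(meta_b)

    def test_disordered_ga_ranges_rejected(self):
        with pytest.raises(ValueError):
            sg.CohortSpec(ga_ranges=((16.0, 25.0), (24.0, 32.0), (32.0, 40.0)))

    def test_writer_emits_csvs(self, tmp_path):
        spec = sg.CohortSpec(n_subjects_per_group=2, seed=1)
        segments, meta = sg.gen_cohort(spec)
        sg.write_cohort_csv(segments, meta, tmp_path)
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / f"{segments[0].subject_id}_maternal.csv").exists()
        back = pp.read_beats_csv(
            tmp_path / f"{segments[0].subject_id}_fetal.csv", role="fetal"
        )
        np.testing.assert_allclose(back.times, segments[0].fetal.times, atol=1e-9)
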