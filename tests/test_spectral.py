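"""Preprocessing, sliding-window spectral estimation and z-baselining."""

import numpy as np
import pandas as pd
import pytest

from pceeg import design, spectral, synth
from conftest import make_epochs


def test_baseline_window_constants():
    assert spectral.cue_locked_baseline() == (-650.0, -150.0)
    assert spectral.stimulus_locked_baseline() == (-2550.0, -2050.0)


class TestDetrend:
    def test_constant_trace_becomes_zero(self):
        e = make_epochs(np.full((1, 1, 100), 3.7))
        out = spectral.epoch_and_detrend(e)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_pure_ramp_becomes_zero(self):
        e = make_epochs(np.arange(4, dtype=float).reshape(1, 1, 4))
        out = spectral.epoch_and_detrend(e)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_residual_orthogonal_to_linear_basis(self, rng):
        e = make_epochs(rng.standard_normal((5, 3, 200)))
        out = spectral.epoch_and_detrend(e)
        t = np.arange(200, dtype=float)
        # least-squares oracle: residual must be orthogonal to (1, t)
        assert np.abs(out.data.sum(axis=-1)).max() < 1e-9
        proj = np.abs((out.data * (t - t.mean())).sum(axis=-1))
        norm = np.linalg.norm(t - t.mean()) * np.linalg.norm(out.data, axis=-1)
        assert (proj / norm).max() < 1e-10


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        srate, dur = 500.0, 4.0
        t = np.arange(int(srate * dur)) / srate
        x = np.sin(2 * np.pi * 50.0 * t)
        e = make_epochs(x[None, None, :], srate=srate)
        out = spectral.bandpass(e, 1.0, 100.0)
        mid = slice(200, -200)
        ratio = out.data[0, 0, mid].std() / x[mid].std()
        assert abs(ratio - 1.0) < 0.01

    def test_slow_drift_attenuated(self):
        srate, dur = 250.0, 20.0
        t = np.arange(int(srate * dur)) / srate
        x = np.sin(2 * np.pi * 0.1 * t)
        e = make_epochs(x[None, None, :], srate=srate)
        out = spectral.bandpass(e, 1.0, 100.0)
        assert out.data.std() < 0.1 * x.std()

    def test_impulse_response_time_symmetric(self):
        # long epoch so the 1 Hz high-pass tail decays before the edges
        x = np.zeros((1, 1, 5001))
        x[0, 0, 2500] = 1.0
        e = make_epochs(x, srate=250.0)
        out = spectral.bandpass(e, 1.0, 100.0)
        y = out.data[0, 0]
        assert np.allclose(y[2500 - 400:2500], y[2501:2501 + 400][::-1], atol=1e-12)

    def test_invalid_band_rejected(self):
        e = make_epochs(np.zeros((1, 1, 100)), srate=250.0)
        for lo, hi in ((0.0, 100.0), (50.0, 10.0), (1.0, 200.0)):
            with pytest.raises(ValueError, match="invalid band"):
                spectral.bandpass(e, lo, hi)


class TestRereference:
    def test_two_channel_difference(self, rng):
        a, b = rng.standard_normal((2, 50))
        e = make_epochs(np.stack([a, b])[None, :, :])
        out = spectral.rereference_common_average(e)
        assert np.allclose(out.data[0, 0], (a - b) / 2)
        assert np.allclose(out.data[0, 1], (b - a) / 2)

    def test_zero_mean_data_unchanged(self, rng):
        x = rng.standard_normal((3, 4, 50))
        x -= x.mean(axis=1, keepdims=True)
        out = spectral.rereference_common_average(make_epochs(x))
        assert np.allclose(out.data, x, atol=1e-12)

    def test_channel_mean_zero_everywhere(self, rng):
        out = spectral.rereference_common_average(
            make_epochs(rng.standard_normal((4, 6, 80)))
        )
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12


class TestTimelock:
    def _epochs_with_schedule(self, soas, srate=250.0):
        schedule = pd.DataFrame(
            {
                "block": 1,
                "trial_index": np.arange(len(soas)) + 1,
                "cue_modality": "picture",
                "cue_intensity": "low",
                "stim_modality": "picture",
                "stim_intensity": "low",
                "is_catch": False,
                "soa_ms": soas,
            }
        )
        n_t = int(srate * 6)
        data = np.arange(len(soas) * n_t, dtype=float).reshape(len(soas), 1, n_t)
        e = make_epochs(data, srate=srate, t0_ms=-3000.0)
        return e, schedule

    def test_shift_by_single_offset(self):
        e, schedule = self._epochs_with_schedule([1500.0])
        out = spectral.timelock(e, "cue", schedule)
        assert out.lock == "cue"
        assert np.allclose(out.times, e.times + 1500.0)
        assert np.array_equal(out.data, e.data)

    def test_identity_when_lock_unchanged(self):
        e, schedule = self._epochs_with_schedule([1600.0])
        out = spectral.timelock(e, "stimulus", schedule)
        assert np.array_equal(out.data, e.data)
        assert np.array_equal(out.times, e.times)

    def test_round_trip_restores_data(self):
        e, schedule = self._epochs_with_schedule([1500.0, 1700.0, 1900.0])
        cue = spectral.timelock(e, "cue", schedule)
        back = spectral.timelock(cue, "stimulus", schedule)
        # common range after two crops: data values preserved where defined
        for i in range(3):
            orig = e.data[i, 0]
            rest = back.data[i, 0]
            sel = np.isin(e.times, back.times)
            assert np.array_equal(orig[sel], rest)

    def test_offsets_outside_design_bounds_rejected(self):
        e, schedule = self._epochs_with_schedule([2100.0])
        with pytest.raises(ValueError, match="offsets outside"):
            spectral.timelock(e, "cue", schedule)
        # explicit opt-out accepts them
        out = spectral.timelock(e, "cue", schedule, soa_bounds_ms=None)
        assert out.lock == "cue"

    def test_missing_offset_rejected(self):
        e, schedule = self._epochs_with_schedule([np.nan])
        with pytest.raises(ValueError, match="missing cue-to-stimulus offset"):
            spectral.timelock(e, "cue", schedule)


class TestHanningTFR:
    def test_pure_sinusoid_constant_power_and_selectivity(self):
        srate = 250.0
        t = np.arange(-125, 376) / srate  # -500..1500 ms
        x = np.sin(2 * np.pi * 10.0 * t)
        e = make_epochs(x[None, None, :], srate=srate, t0_ms=-500.0)
        tfr = spectral.tfr_hanning(e, freqs=np.array([10.0, 25.0]))
        p10 = tfr.power[0, 0, 0, :]
        p25 = tfr.power[0, 0, 1, :]
        assert p10.max() / p10.min() < 1.01   # constant over interior centers
        assert (p10 / p25).min() > 100        # Hann sidelobe suppression

    def test_zero_input_gives_zero_power(self):
        e = make_epochs(np.zeros((2, 2, 500)), t0_ms=-500.0)
        tfr = spectral.tfr_hanning(e, freqs=np.array([5.0, 10.0]))
        assert np.all(tfr.power == 0.0)

    def test_power_scales_quadratically_with_amplitude(self, rng):
        x = rng.standard_normal((1, 1, 500))
        e1 = make_epochs(x, t0_ms=-500.0)
        e2 = make_epochs(2 * x, t0_ms=-500.0)
        p1 = spectral.tfr_hanning(e1, freqs=np.array([8.0, 14.0])).power
        p2 = spectral.tfr_hanning(e2, freqs=np.array([8.0, 14.0])).power
        assert np.allclose(p2, 4 * p1, rtol=1e-5)

    def test_window_longer_than_epoch_rejected(self):
        e = make_epochs(np.zeros((1, 1, 50)))
        with pytest.raises(ValueError, match="window longer"):
            spectral.tfr_hanning(e, freqs=np.array([10.0]), window_ms=300.0)

    def test_incomplete_windows_dropped_no_padding(self):
        e = make_epochs(np.ones((1, 1, 250)), t0_ms=-500.0)  # 1 s epoch
        tfr = spectral.tfr_hanning(e, freqs=np.array([10.0]), window_ms=300.0)
        # centers need 150 ms margin on both sides
        assert tfr.times.min() >= -500.0 + 150.0 - 25.0
        assert tfr.times.max() <= 500.0 - 150.0 + 25.0

    def test_offset_invariance_after_detrend(self, rng):
        x = rng.standard_normal((1, 1, 500))
        e1 = spectral.epoch_and_detrend(make_epochs(x, t0_ms=-500.0))
        e2 = spectral.epoch_and_detrend(make_epochs(x + 40.0, t0_ms=-500.0))
        p1 = spectral.tfr_hanning(e1, freqs=np.array([10.0])).power
        p2 = spectral.tfr_hanning(e2, freqs=np.array([10.0])).power
        assert np.allclose(p1, p2, rtol=1e-6)


class TestMultitaperTFR:
    def test_spectral_smoothing_spreads_over_bandwidth(self):
        srate = 250.0
        t = np.arange(1000) / srate
        x = np.sin(2 * np.pi * 55.0 * t)
        e = make_epochs(x[None, None, :], srate=srate, t0_ms=0.0)
        freqs = np.arange(31.0, 101.0)
        tfr = spectral.tfr_multitaper(e, freqs=freqs)
        spec = tfr.power[0, 0, :, :].mean(axis=1)
        inside = spec[(freqs >= 45) & (freqs <= 65)]
        edge = spec[freqs == 31.0]
        assert inside.min() > 10 * edge.max()

    def test_zero_input_gives_zeros(self):
        e = make_epochs(np.zeros((1, 1, 500)))
        tfr = spectral.tfr_multitaper(e, freqs=np.array([40.0, 60.0]))
        assert np.all(tfr.power == 0.0)

    def test_white_noise_spectrum_flat_within_10_percent(self, rng):
        x = rng.standard_normal((150, 1, 300))
        e = make_epochs(x, t0_ms=0.0)
        freqs = np.arange(31.0, 101.0, 3.0)
        tfr = spectral.tfr_multitaper(e, freqs=freqs)
        mean_per_freq = tfr.power.mean(axis=(0, 1, 3))
        rel = mean_per_freq / mean_per_freq.mean()
        assert np.abs(rel - 1.0).max() < 0.10

    def test_default_taper_count_is_five(self):
        import scipy.signal as sig
        nw = 0.2 * 15.0
        k = int(np.floor(2 * nw)) - 1
        assert k == 5
        tapers = sig.windows.dpss(50, nw, Kmax=k)
        assert tapers.shape == (5, 50)


class TestConditionAverage:
    def _tiny_trial_tfr(self, schedule, power_per_trial):
        ref = np.array([
            i for i in range(len(schedule))
            if not schedule.iloc[i]["is_catch"]
            and schedule.iloc[i]["cue_modality"] == "picture"
            and schedule.iloc[i]["stim_modality"] == "picture"
        ])
        power = np.stack([np.full((2, 3, 4), p) for p in power_per_trial])
        return spectral.TrialTFR(
            power=power, freqs=np.arange(1.0, 4.0), times=np.arange(4) * 50.0,
            lock="stimulus", subject_id="s", schedule_ref=ref,
            channel_names=("a", "b"),
        )

    def test_mean_of_two_trials(self, schedule50):
        rows = synth._picture_trial_rows(schedule50)
        tfr = self._tiny_trial_tfr(schedule50, np.arange(len(rows), dtype=float))
        out = spectral.average_by_condition(tfr, schedule50)
        assert out.power.shape == (1, 9, 2, 3, 4)
        assert out.counts.sum() == len(rows)
        # cell averages equal the mean of that cell's per-trial constants
        cue = schedule50["cue_intensity"].to_numpy()[rows]
        stim = schedule50["stim_intensity"].to_numpy()[rows]
        for i, cell in enumerate(design.build_condition_grid()):
            sel = (cue == cell.cue_intensity) & (stim == cell.stim_intensity)
            assert out.power[0, i, 0, 0, 0] == pytest.approx(
                np.arange(len(rows))[sel].mean()
            )

    def test_trial_order_invariance(self, schedule50):
        rows = synth._picture_trial_rows(schedule50)
        vals = np.arange(len(rows), dtype=float)
        tfr = self._tiny_trial_tfr(schedule50, vals)
        out1 = spectral.average_by_condition(tfr, schedule50)
        perm = np.random.default_rng(0).permutation(len(rows))
        tfr2 = spectral.TrialTFR(
            power=tfr.power[perm], freqs=tfr.freqs, times=tfr.times,
            lock="stimulus", subject_id="s", schedule_ref=tfr.schedule_ref[perm],
            channel_names=tfr.channel_names,
        )
        out2 = spectral.average_by_condition(tfr2, schedule50)
        assert np.allclose(out1.power, out2.power)

    def test_empty_cell_error_names_cell(self, schedule50):
        rows = synth._picture_trial_rows(schedule50)
        cue = schedule50["cue_intensity"].to_numpy()[rows]
        stim = schedule50["stim_intensity"].to_numpy()[rows]
        keep = ~((cue == "low") & (stim == "low"))
        tfr = self._tiny_trial_tfr(schedule50, np.zeros(len(rows)))
        tfr2 = spectral.TrialTFR(
            power=tfr.power[keep], freqs=tfr.freqs, times=tfr.times,
            lock="stimulus", subject_id="s", schedule_ref=tfr.schedule_ref[keep],
            channel_names=tfr.channel_names,
        )
        with pytest.raises(ValueError, match="cue=low, stim=low"):
            spectral.average_by_condition(tfr2, schedule50)


def _tfrset(power, times, counts=None, lock="stimulus"):
    power = np.asarray(power, dtype=float)
    s, c = power.shape[:2]
    if counts is None:
        counts = np.ones((s, c), dtype=int)
    return spectral.TFRSet(
        power=power, freqs=np.arange(power.shape[3], dtype=float) + 1.0,
        times=np.asarray(times, dtype=float), band="low", lock=lock,
        baselined=False, baseline_window=None, counts=np.asarray(counts),
        channel_names=tuple(f"ch{i}" for i in range(power.shape[2])),
        subject_ids=tuple(f"s{i}" for i in range(s)),
    )


class TestZBaseline:
    def test_arithmetic_example(self):
        # baseline samples {1, 3}, test point 4: (4 - 2)/sqrt(2) = 1.41421
        power = np.zeros((1, 9, 1, 1, 3))
        power[0, :, 0, 0, :] = [1.0, 3.0, 4.0]
        tfr = _tfrset(power, times=[-200.0, -150.0, 100.0])
        out = spectral.zbaseline(tfr, (-250.0, -100.0))
        assert out.power[0, 0, 0, 0, 2] == pytest.approx(np.sqrt(2), abs=1e-5)
        assert out.baselined and out.baseline_window == (-250.0, -100.0)

    def test_pooled_average_baseline_is_standardized(self, rng):
        power = rng.random((3, 9, 2, 4, 20)) + 0.5
        counts = rng.integers(5, 20, size=(3, 9))
        times = np.arange(20) * 50.0 - 500.0
        out = spectral.zbaseline(_tfrset(power, times, counts), (-500.0, -200.0))
        keep = (out.times >= -500.0) & (out.times <= -200.0)
        w = counts / counts.sum(axis=1, keepdims=True)
        pooled = np.einsum("sc,scxft->sxft", w, out.power)[..., keep]
        assert np.abs(pooled.mean(axis=-1)).max() < 1e-10
        assert np.abs(pooled.std(axis=-1, ddof=1) - 1.0).max() < 1e-10

    def test_zero_sd_error_identifies_location(self):
        power = np.ones((1, 9, 2, 2, 5))
        tfr = _tfrset(power, times=np.arange(5) * 50.0 - 200.0)
        with pytest.raises(ValueError, match="zero baseline SD.*ch0.*1.0 Hz"):
            spectral.zbaseline(tfr, (-200.0, -100.0))

    def test_double_baselining_rejected(self, rng):
        power = rng.random((1, 9, 1, 1, 10)) + 0.5
        out = spectral.zbaseline(
            _tfrset(power, np.arange(10) * 50.0 - 400.0), (-400.0, -200.0)
        )
        with pytest.raises(ValueError, match="already baselined"):
            spectral.zbaseline(out, (-400.0, -200.0))


def test_tfr_linearity_over_random_phases(rng):
    """Power of a sum of independent random-phase signals averages to the
    sum of the individual powers (cross terms vanish in expectation)."""
    srate = 250.0
    n = 400
    t = np.arange(n) / srate
    p_sum, p_a, p_b = 0.0, 0.0, 0.0
    freqs = np.array([10.0])
    for _ in range(200):
        pa, pb = rng.uniform(0, 2 * np.pi, 2)
        a = np.sin(2 * np.pi * 10.0 * t + pa)
        b = np.sin(2 * np.pi * 13.0 * t + pb)
        p_a += spectral.tfr_hanning(make_epochs(a[None, None, :]), freqs=freqs).power
        p_b += spectral.tfr_hanning(make_epochs(b[None, None, :]), freqs=freqs).power
        p_sum += spectral.tfr_hanning(
            make_epochs((a + b)[None, None, :]), freqs=freqs
        ).power
    # cross terms are phase-coherent across window centers, so compare the
    # grand means at a Monte-Carlo tolerance (~4 sigma of the cross term)
    assert p_sum.mean() / 200 == pytest.approx(
        (p_a + p_b).mean() / 200, abs=0.25
    )
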