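"""Event-locked pipelines: EEG/VEP, EMG, fNIRS."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gaitsync as g
from gaitsync.evoked import bandpass_hemo
from gaitsync.simulate import DEFAULT_MONTAGE, synth_fnirs


def make_stream(samples, fs=500.0, labels=None, modality="eeg", clock="eeg"):
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape[0] == 1:
        samples = samples.T
    labels = labels or [f"ch{i}" for i in range(samples.shape[1])]
    return g.TimestampedStream(
        name="x", modality=modality, channel_labels=labels,
        units=["µV"] * samples.shape[1], nominal_rate=fs, samples=samples,
        timestamps=np.arange(samples.shape[0]) / fs, clock_id=clock,
    )


class TestPreprocessEEG:
    def test_notch_attenuates_50hz_over_20db(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        line = np.sin(2 * np.pi * 50 * t)
        s = make_stream(np.column_stack([line, np.zeros_like(t)]), fs)
        out = g.preprocess_eeg(s)
        mid = slice(5000, -5000)
        # residual 50 Hz content via projection onto the line-noise carrier
        residual = 2 * np.mean(out.samples[mid, 0] * line[mid])
        assert abs(residual) < 0.1  # > 20 dB down from unit amplitude

    def test_common_average_reference_zero_mean_per_sample(self):
        rng = np.random.default_rng(0)
        s = make_stream(rng.normal(size=(30000, 4)))
        out = g.preprocess_eeg(s)
        np.testing.assert_allclose(out.samples.mean(axis=1), 0.0, atol=1e-9)

    def test_dc_offset_removed(self):
        s = make_stream(np.column_stack([np.full(60000, 5.0), np.full(60000, -3.0)]))
        out = g.preprocess_eeg(s)
        assert abs(out.samples[30000, 0]) < 0.05

    def test_single_channel_skips_reref_with_warning(self):
        s = make_stream(np.random.default_rng(0).normal(size=(30000, 1)))
        with pytest.warns(UserWarning, match="re-reference"):
            g.preprocess_eeg(s)

    def test_low_sampling_rate_rejected(self):
        s = make_stream(np.zeros((1000, 2)), fs=60.0)
        with pytest.raises(ValueError, match="sampling rate"):
            g.preprocess_eeg(s)


class TestEpoch:
    def test_checkerboard_session_yields_120_trials(self, checker_bundle, checker_vep):
        _, _, epochs = checker_vep
        assert epochs.n_trials == 120
        assert not epochs.qc_excluded.any()

    def test_epoch_content_equals_slice_oracle(self):
        fs = 100.0
        x = np.arange(1000, dtype=float)
        s = make_stream(x, fs=fs, clock="kin")
        ev = [g.MarkerEvent(1, 5.0, "kin", "command"),
              g.MarkerEvent(2, 7.13, "kin", "command")]
        epochs = g.epoch(s, ev, window=(-0.1, 0.2))
        for k, t_ev in enumerate([5.0, 7.13]):
            i = int(np.argmin(np.abs(s.timestamps - t_ev)))  # brute-force anchor
            expected = x[i - 10 : i + 21]
            np.testing.assert_array_equal(epochs.data[k, :, 0], expected)
        np.testing.assert_allclose(epochs.times, np.arange(-10, 21) / fs)

    def test_event_at_recording_edge_flagged_not_dropped(self):
        s = make_stream(np.ones(100), fs=100.0, clock="kin")
        ev = [g.MarkerEvent(1, 0.02, "kin", "command"),
              g.MarkerEvent(1, 0.5, "kin", "command")]
        epochs = g.epoch(s, ev, window=(-0.1, 0.1))
        assert epochs.n_trials == 2
        assert epochs.qc_excluded.tolist() == [True, False]
        assert np.isnan(epochs.data[0, 0, 0])  # padded, stored

    def test_event_on_wrong_clock_rejected(self):
        s = make_stream(np.ones(100), fs=100.0, clock="kin")
        with pytest.raises(ValueError, match="clock"):
            g.epoch(s, [g.MarkerEvent(1, 0.5, "eeg", "command")], window=(-0.1, 0.1))


class TestAverage:
    def _epochs(self, data, fs=100.0, baseline=(-0.1, -0.02)):
        n_tr, n_t = data.shape
        return g.EpochSet(
            data=data[:, :, None], times=np.arange(n_t) / fs - 0.1,
            channel_labels=["c"], baseline_window=baseline,
            event_codes=np.zeros(n_tr, int), qc_excluded=np.zeros(n_tr, bool),
        )

    def test_identical_trials_zero_ci(self):
        data = np.tile(np.sin(np.arange(50)), (8, 1))
        ev = g.detrend_baseline_average(self._epochs(data))
        np.testing.assert_allclose(ev.ci, 0.0, atol=1e-12)

    def test_baseline_window_mean_is_zero(self, checker_vep):
        evoked, _, _ = checker_vep
        m = (evoked.times >= -0.5) & (evoked.times <= -0.1)
        assert abs(evoked.data[m, 0].mean()) < 1e-10

    def test_excluded_trials_not_averaged(self):
        data = np.vstack([np.ones((4, 50)), np.full((1, 50), 100.0)])
        ep = self._epochs(data)
        ep.qc_excluded[4] = True
        ev = g.detrend_baseline_average(ep, detrend=False)
        assert ev.n_trials == 4
        assert np.abs(ev.data).max() < 1e-9  # constant trials, baseline removed

    def test_ci_coverage_near_95_percent(self):
        """Monte-Carlo: the 1.96*SEM band covers the true mean ~95% of the
        time for Gaussian trials."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 500
        times = np.arange(50) / 10.0 - 2.0
        for _ in range(reps):
            trials = rng.normal(0.0, 1.0, size=(25, 50, 1))
            ep = g.EpochSet(
                data=trials, times=times, channel_labels=["c"],
                baseline_window=(-2.0, -1.0), event_codes=np.zeros(25, int),
                qc_excluded=np.zeros(25, bool),
            )
            ev = g.detrend_baseline_average(ep, detrend=False)
            hits += abs(ev.data[-1, 0]) <= ev.ci[-1, 0]  # true mean is zero
        assert 0.92 <= hits / reps <= 0.98


class TestVepPeaks:
    def test_noise_free_session_recovers_template(self):
        """With zero background noise the pipeline returns the template's
        latencies (to one sample) and amplitudes."""
        b = g.simulate_session("checkerboard", seed=0, eeg_noise_rms=0.0)
        decoded = g.decode_events(g.digitize_schmitt(b.stream("photodiode")))
        lock = g.compensate_display_delay(decoded, b.metadata["acquisition_delay_eeg"])
        lock = [dataclasses.replace(e, clock_id="eeg") for e in lock]
        with np.errstate(all="ignore"), pytest.warns(UserWarning):
            _, peaks, _ = g.vep_pipeline(b, lock)
        assert peaks["N75"].latency == pytest.approx(0.065, abs=0.002)
        assert peaks["P100"].latency == pytest.approx(0.090, abs=0.002)
        # small amplitude loss from the band-pass/notch chain is expected
        assert peaks["P100"].amplitude == pytest.approx(9.15, rel=0.10)
        assert peaks["N75"].amplitude == pytest.approx(-5.39, rel=0.15)

    def test_flat_trace_flagged_degenerate(self):
        ev = g.Evoked(
            times=np.linspace(-0.5, 0.4, 451), data=np.zeros((451, 1)),
            ci=np.zeros((451, 1)), channel_labels=["Oz"], n_trials=10,
        )
        peaks = g.find_vep_peaks(ev)
        for p in peaks.values():
            assert p.amplitude == 0.0 and "degenerate" in p.flags
            assert p.latency == pytest.approx(p.window[0], abs=1e-9)

    def test_two_script_jitter_smears_p100(self, checker_vep):
        """Under the faulty two-script chain the grand-average P100 drops
        by > 20% relative to the single-script session with the identical
        template and noise seed."""
        _, peaks_single, _ = checker_vep
        b = g.simulate_session("checkerboard", seed=42,
                               chain=g.DisplayChainConfig(mode="two_script"))
        decoded = g.decode_events(g.digitize_schmitt(b.stream("photodiode")))
        lock = g.compensate_display_delay(decoded, b.metadata["acquisition_delay_eeg"])
        lock = [dataclasses.replace(e, clock_id="eeg") for e in lock]
        with np.errstate(all="ignore"), pytest.warns(UserWarning):
            _, peaks_two, _ = g.vep_pipeline(b, lock)
        assert peaks_two["P100"].amplitude < 0.8 * peaks_single["P100"].amplitude


class TestEMG:
    def test_constant_input_all_zero(self):
        s = make_stream(np.full(30000, 2.5), fs=1000.0, modality="emg", clock="kin")
        ev = [g.MarkerEvent(0, 15.0, "kin", "derived_onset")]
        _, evoked = g.emg_pipeline(s, ev, g.EmgConfig(epoch_window=(-5, 5)))
        np.testing.assert_allclose(evoked.data, 0.0, atol=1e-12)

    def test_moving_average_kernel_spreads_impulse(self):
        x = np.zeros(30000)
        x[15000] = 100.0
        s = make_stream(x, fs=1000.0, modality="emg", clock="kin")
        ev = [g.MarkerEvent(0, 15.0, "kin", "derived_onset")]
        epochs, _ = g.emg_pipeline(s, ev, g.EmgConfig(epoch_window=(-1, 1)))
        tr = epochs.data[0, :, 0]
        # after DC removal the rectified floor is ~mean(x); the impulse is
        # spread by the kernel over exactly 100 samples at ~1/100 its height
        body = tr > 0.5
        assert body.sum() == 100
        np.testing.assert_allclose(tr[body], (100.0 - x.mean()) / 100, rtol=1e-2)

    def test_burst_rises_before_kinetic_onset(self, stg_bundle, stg_detection):
        events, _, _ = stg_detection
        _, evoked = g.emg_pipeline(stg_bundle.stream("emg"), events)
        t, y = evoked.times, evoked.data[:, 0]
        base_sd = y[(t > -4.5) & (t < -1.0)].std()
        pre = y[(t >= -0.12) & (t <= 0.0)]
        assert pre.mean() > 3 * base_sd


class TestHemo:
    def test_constant_intensities_zero_concentration(self):
        n = 500
        s760 = make_stream(np.full((n, 3), 0.8), fs=10.0,
                           labels=["long_1", "long_2", "short_1"],
                           modality="fnirs_intensity", clock="nirs")
        s850 = make_stream(np.full((n, 3), 1.2), fs=10.0,
                           labels=["long_1", "long_2", "short_1"],
                           modality="fnirs_intensity", clock="nirs")
        hemo = g.intensities_to_hemoglobin(s760, s850, DEFAULT_MONTAGE["distances"])
        np.testing.assert_allclose(hemo.samples, 0.0, atol=1e-12)

    def test_doubling_dpf_halves_concentrations(self):
        s760, s850, _ = synth_fnirs([10.0], duration=40.0, noise_rel=0.0, seed=0)
        c1 = g.intensities_to_hemoglobin(
            s760, s850, DEFAULT_MONTAGE["distances"], g.HemoConfig(dpf=6.0))
        c2 = g.intensities_to_hemoglobin(
            s760, s850, DEFAULT_MONTAGE["distances"], g.HemoConfig(dpf=12.0))
        np.testing.assert_allclose(c2.samples, c1.samples / 2, atol=1e-12)

    def test_nonpositive_intensity_interpolated_with_log(self, caplog):
        s760, s850, _ = synth_fnirs([10.0], duration=40.0, noise_rel=0.0, seed=0)
        s760.samples[100, 0] = -0.5
        with caplog.at_level("WARNING", logger="gaitsync"):
            hemo = g.intensities_to_hemoglobin(s760, s850, DEFAULT_MONTAGE["distances"])
        assert "non-positive" in caplog.text
        assert np.isfinite(hemo.samples).all()

    def test_short_channel_identical_gives_zero_residual(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        hemo = make_stream(
            np.column_stack([x, x, -0.3 * x, -0.3 * x]), fs=10.0,
            labels=["long_1_HbO2", "short_1_HbO2", "long_1_HbR", "short_1_HbR"],
            modality="fnirs_hemo", clock="nirs",
        )
        out = g.short_channel_correct(hemo, {"long_1": "short_1"})
        np.testing.assert_allclose(out.channel("long_1_HbO2"), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.channel("long_1_HbR"), 0.0, atol=1e-9)

    def test_short_channel_independent_long_unchanged(self):
        rng = np.random.default_rng(1)
        long_sig = rng.normal(size=2000)
        short_sig = rng.normal(size=2000)
        hemo = make_stream(
            np.column_stack([long_sig, short_sig, long_sig, short_sig]), fs=10.0,
            labels=["long_1_HbO2", "short_1_HbO2", "long_1_HbR", "short_1_HbR"],
            modality="fnirs_hemo", clock="nirs",
        )
        out = g.short_channel_correct(hemo, {"long_1": "short_1"})
        r = np.corrcoef(out.channel("long_1_HbO2"), long_sig)[0, 1]
        assert r > 0.99  # slope ~ 0: residual ~ original

    def test_systemic_power_reduced_by_short_channel_regression(self):
        """On simulated data with systemic weight 0.7, the 0.1 Hz Mayer-wave
        power in the long channels drops >= 80% after correction."""
        from scipy import signal as sps

        s760, s850, _ = synth_fnirs(
            np.arange(5) * 40.0 + 20.0, duration=240.0, noise_rel=1e-6, seed=0
        )
        hemo = g.intensities_to_hemoglobin(s760, s850, DEFAULT_MONTAGE["distances"])
        hemo = bandpass_hemo(hemo)
        corrected = g.short_channel_correct(hemo, DEFAULT_MONTAGE["nearest_short"])

        def power_01(x):
            f, p = sps.periodogram(x, fs=10.0)
            band = (f > 0.08) & (f < 0.12)
            return p[band].sum()

        before = power_01(hemo.channel("long_1_HbO2"))
        after = power_01(corrected.channel("long_1_HbO2"))
        assert after <= 0.2 * before

    def test_metrics_on_noise_free_canonical_hrf(self):
        hrf = g.HRFParams()
        fs = 10.0
        t = np.arange(-50, 151) / fs
        y = hrf.amplitude * hrf.shape(t)
        ev = g.Evoked(times=t, data=y[:, None], ci=np.zeros((len(t), 1)),
                      channel_labels=["long_HbO2"], n_trials=1)
        m = g.hemo_response_metrics(ev, "long_HbO2")
        assert m["HbO2_peak"].latency == pytest.approx(7.0, abs=0.2)
        assert m["HbO2_dip"].latency < 3.0 and m["HbO2_dip"].amplitude < 0
        assert m["HbO2_return"].latency < 15.0

    def test_metrics_flat_input_degenerate(self):
        ev = g.Evoked(times=np.linspace(-5, 15, 201), data=np.zeros((201, 1)),
                      ci=np.zeros((201, 1)), channel_labels=["long_HbO2"], n_trials=1)
        m = g.hemo_response_metrics(ev, "long_HbO2")
        assert all("degenerate" in p.flags for p in m.values())

    def test_full_session_pipeline(self, stg_bundle, stg_detection):
        events, _, _ = stg_detection
        nev = [dataclasses.replace(e, clock_id="nirs") for e in events]
        region, metrics, _ = g.hemo_pipeline(stg_bundle, nev)
        assert region.n_trials == 50
        assert metrics["HbO2_peak"].latency == pytest.approx(7.0, abs=1.0)
        # baseline window mean of the evoked response is zero
        m = (region.times >= -5.0) & (region.times <= -0.1)
        assert abs(region.data[m, 0].mean()) < 1e-10
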