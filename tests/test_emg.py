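"""Startle EMG branch: derivation, envelope, segmentation, ASR scoring,
trial rejection and responder classification."""

import numpy as np
import pandas as pd
import pytest

from ppigate import (ASRTable, ChannelInfo, EventList, Recording,
                     classify_responder, derive_emg_channel, emg_envelope,
                     reject_trials, score_asr, segment_envelope)
from ppigate.emg import EnvelopeTrialSet

from oracles import rejection_oracle

RATE = 512.0


def emg_recording(emg1, emg2):
    n = len(emg1)
    data = np.vstack([np.zeros(n), emg1, emg2])
    chans = [ChannelInfo("Fz", "scalp"), ChannelInfo("EMG1", "emg"),
             ChannelInfo("EMG2", "emg")]
    return Recording(data, RATE, chans)


def make_trials(trials, baselines, conditions, window=(-300.0, 300.0)):
    return EnvelopeTrialSet(np.asarray(trials, dtype=float),
                            np.asarray(conditions, dtype=object),
                            np.asarray(baselines, dtype=float),
                            np.arange(len(trials)), window, (-50.0, 0.0), RATE)


class TestDeriveEMG:
    def test_identical_pair_cancels(self):
        s = np.random.default_rng(0).normal(size=256)
        assert np.allclose(derive_emg_channel(emg_recording(s, s)), 0.0)

    def test_zero_second_channel_passes_first(self):
        s = np.random.default_rng(1).normal(size=256)
        np.testing.assert_allclose(derive_emg_channel(emg_recording(s, np.zeros(256))), s)

    def test_bipolar_difference_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=256), rng.normal(size=256)
        np.testing.assert_allclose(derive_emg_channel(emg_recording(a, b)), a - b)
        np.testing.assert_allclose(
            derive_emg_channel(emg_recording(a, b), bipolar=False), (a + b) / 2)

    def test_requires_two_emg_channels(self):
        rec = Recording(np.zeros((1, 64)), RATE, [ChannelInfo("Fz", "scalp")])
        with pytest.raises(ValueError, match="EMG"):
            derive_emg_channel(rec)


class TestEnvelope:
    def test_zero_in_zero_out(self):
        assert np.allclose(emg_envelope(np.zeros(4096), RATE), 0.0)

    def test_rectified_sine_mean_two_over_pi(self):
        t = np.arange(8192) / RATE
        env = emg_envelope(np.sin(2 * np.pi * 100.0 * t), RATE)
        mid = env[2000:-2000]
        assert abs(mid.mean() - 2 / np.pi) < 0.1 * (2 / np.pi)
        assert np.ptp(mid) < 0.1 * mid.mean() * 2  # steady-state ripple

    def test_below_band_input_attenuated(self):
        t = np.arange(8192) / RATE
        x = np.sin(2 * np.pi * 5.0 * t)
        env = emg_envelope(x, RATE)
        assert np.sqrt(np.mean(env ** 2)) < 0.05 * np.sqrt(np.mean(x ** 2))

    def test_envelope_nonnegative(self):
        rng = np.random.default_rng(3)
        env = emg_envelope(rng.normal(size=4096), RATE)
        assert env.min() >= 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            emg_envelope(np.zeros(4096), 256.0)


class TestSegmentation:
    def test_segment_length_is_307_samples(self):
        env = np.abs(np.random.default_rng(4).normal(size=4096))
        ev = EventList(np.array([1000, 2500]), np.array(["P", "P60"], dtype=object))
        trials = segment_envelope(env, ev, RATE)
        assert trials.trials.shape == (2, 307)

    def test_event_near_edge_excluded(self):
        env = np.abs(np.random.default_rng(5).normal(size=4096))
        # first event 100 ms from start lacks the -300 ms margin
        ev = EventList(np.array([51, 2500]), np.array(["P", "P60"], dtype=object))
        trials = segment_envelope(env, ev, RATE)
        assert len(trials) == 1
        assert trials.conditions[0] == "P60"
        assert trials.trial_index[0] == 1

    def test_constant_envelope_constant_baseline(self):
        env = np.full(4096, 3.25)
        ev = EventList(np.array([1000, 2000, 3000]),
                       np.array(["P", "P", "P"], dtype=object))
        trials = segment_envelope(env, ev, RATE)
        np.testing.assert_allclose(trials.baseline_mean, 3.25)

    def test_no_usable_trials_is_error(self):
        env = np.ones(100)
        ev = EventList(np.array([50]), np.array(["P"], dtype=object))
        with pytest.raises(ValueError, match="margin"):
            segment_envelope(env, ev, RATE)


class TestScoreASR:
    def _flat_with_peak(self, peak_uv, peak_ms, flat=1.0):
        trial = np.full(307, flat)
        idx = int(np.round(peak_ms * RATE / 1000.0)) + 154
        trial[idx] = peak_uv
        return trial

    def test_peak_minus_baseline(self):
        trials = make_trials([self._flat_with_peak(6.0, 60.0)], [1.0], ["P"])
        table = score_asr(trials)
        assert table.per_trial["asr_uv"].iloc[0] == pytest.approx(5.0)

    def test_peak_outside_window_ignored(self):
        trials = make_trials([self._flat_with_peak(9.0, 150.0)], [1.0], ["P"])
        table = score_asr(trials)
        assert table.per_trial["asr_uv"].iloc[0] == pytest.approx(0.0)

    def test_larger_of_two_peaks_wins(self):
        trial = self._flat_with_peak(4.0, 30.0)
        idx110 = int(np.round(110 * RATE / 1000.0)) + 154
        trial[idx110] = 7.0
        table = score_asr(make_trials([trial], [1.0], ["P"]))
        assert table.per_trial["asr_uv"].iloc[0] == pytest.approx(6.0)

    def test_raw_maximum_mode(self):
        trials = make_trials([self._flat_with_peak(6.0, 60.0)], [1.0], ["P"])
        table = score_asr(trials, baseline_subtract=False)
        assert table.per_trial["asr_uv"].iloc[0] == pytest.approx(6.0)

    def test_window_max_against_brute_force(self):
        # oracle: scan every sample, keep those whose time rounds into
        # the 20-120 ms scoring window (half-sample tolerance)
        rng = np.random.default_rng(6)
        trials_data = np.abs(rng.normal(size=(20, 307)))
        trials = make_trials(trials_data, np.zeros(20), ["P"] * 20)
        table = score_asr(trials, baseline_subtract=False)
        half = 0.5 * 1000.0 / RATE
        for k in range(20):
            sel = [trials_data[k, i] for i in range(307)
                   if 20.0 - half <= (i - 154) * 1000.0 / RATE < 120.0 + half]
            assert table.per_trial["asr_uv"].iloc[k] == pytest.approx(max(sel))


class TestRejection:
    def _table(self, max_uv, baselines, conditions):
        df = pd.DataFrame({
            "trial": np.arange(len(max_uv)), "condition": conditions,
            "baseline_uv": baselines, "max_uv": max_uv,
            "asr_uv": np.asarray(max_uv) - np.asarray(baselines),
            "rejected": False, "reason": "",
        })
        return ASRTable(df)

    def test_identical_trials_never_rejected(self):
        table = reject_trials(self._table([5.0] * 10, [1.0] * 10, ["P"] * 10))
        assert not table.per_trial["rejected"].any()

    def test_single_amplitude_outlier_rejected(self):
        # NB a lone 3-SD outlier is only reachable for n > 9 trials
        # (max |z| is bounded by (n-1)/sqrt(n)); the real design has 40-50
        n = 20
        max_uv = [5.0 + 0.1 * i for i in range(n - 1)] + [60.0]
        table = reject_trials(self._table(max_uv, [1.0] * n, ["P"] * n))
        rejected = table.per_trial[table.per_trial["rejected"]]
        assert list(rejected["trial"]) == [n - 1]
        assert rejected["reason"].iloc[0] == "amplitude_outlier"
        # oracle agreement
        oracle = rejection_oracle(np.array(max_uv), np.ones(n), np.array(["P"] * n))
        np.testing.assert_array_equal(table.per_trial["rejected"], oracle)

    def test_baseline_outlier_rejected_with_reason(self):
        n = 20
        baselines = [1.0 + 0.05 * i for i in range(n - 1)] + [25.0]
        table = reject_trials(self._table([5.0 + 0.1 * i for i in range(n)],
                                          baselines, ["P"] * n))
        rejected = table.per_trial[table.per_trial["rejected"]]
        assert list(rejected["trial"]) == [n - 1]
        assert rejected["reason"].iloc[0] == "baseline_outlier"

    def test_statistics_per_condition_oracle(self):
        rng = np.random.default_rng(7)
        n = 40
        conditions = np.array((["P"] * 10 + ["P30"] * 10 + ["P60"] * 10
                               + ["P120"] * 10), dtype=object)
        max_uv = np.abs(rng.normal(5, 2, n)) + rng.exponential(1, n)
        baselines = np.abs(rng.normal(1, 0.3, n))
        table = reject_trials(self._table(max_uv, baselines, conditions))
        oracle = rejection_oracle(max_uv, baselines, conditions)
        np.testing.assert_array_equal(table.per_trial["rejected"].to_numpy(), oracle)

    def test_conjunctive_mode_needs_both(self):
        n = 20
        max_uv = [5.0 + 0.1 * i for i in range(n - 1)] + [60.0]
        table = reject_trials(self._table(max_uv, [1.0] * n, ["P"] * n),
                              conjunctive=True)
        assert not table.per_trial["rejected"].any()

    def test_scaling_leaves_rejected_set_unchanged(self):
        rng = np.random.default_rng(8)
        max_uv = np.abs(rng.normal(5, 2, 20))
        baselines = np.abs(rng.normal(1, 0.3, 20))
        conds = np.array(["P"] * 10 + ["P60"] * 10, dtype=object)
        a = reject_trials(self._table(max_uv, baselines, conds))
        b = reject_trials(self._table(max_uv * 7.3, baselines * 7.3, conds))
        np.testing.assert_array_equal(a.per_trial["rejected"], b.per_trial["rejected"])


class TestResponder:
    def _table(self, p_asrs):
        df = pd.DataFrame({
            "trial": np.arange(len(p_asrs)), "condition": ["P"] * len(p_asrs),
            "baseline_uv": 0.0, "max_uv": p_asrs, "asr_uv": p_asrs,
            "rejected": False, "reason": "",
        })
        return ASRTable(df)

    @pytest.mark.parametrize("mean_asr, expected", [
        (0.5, False),              # below 20 digital units
        (20 * 0.0488, True),       # boundary inclusive
        (10.0, True),
    ])
    def test_threshold_at_20_digital_units(self, mean_asr, expected):
        status = classify_responder(self._table([mean_asr]), 0.0488)
        assert status.threshold_uv == pytest.approx(0.976)
        assert status.is_responder is expected

    def test_only_kept_pulse_trials_count(self):
        table = self._table([10.0, 0.1])
        table.per_trial.loc[0, "rejected"] = True
        status = classify_responder(table, 0.0488)
        assert status.mean_p_asr_uv == pytest.approx(0.1)
        assert not status.is_responder

    def test_no_kept_pulse_trials_is_error(self):
        table = self._table([10.0])
        table.per_trial.loc[0, "rejected"] = True
        with pytest.raises(ValueError, match="pulse-alone"):
            classify_responder(table, 0.0488)
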