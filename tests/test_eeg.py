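"""EEG preprocessing chain: filters, segmentation, ocular correction,
rejection, inclusion gate, baseline/re-reference, averaging."""

import numpy as np
import pytest
from scipy import signal

from flankerlab import behavior, eeg, synthetic
from flankerlab.eeg import (ALL_CHANNELS, SCALP_CHANNELS, ContinuousEEG,
                            EpochSet, RejectionCriteria, average_erp,
                            baseline_and_rereference, filter_continuous,
                            gate_subject, ocular_correct, reject_artifacts,
                            segment)


def _raw(data, events=()):
    return ContinuousEEG(ALL_CHANNELS, 1000.0, data, list(events))


def _epochs(data, conditions=None, tmin=-0.3):
    n_ep = data.shape[0]
    if conditions is None:
        conditions = ["congruent"] * (n_ep // 2) + ["incongruent"] * (n_ep - n_ep // 2)
    return EpochSet(ALL_CHANNELS, 1000.0, tmin, data,
                    np.array(conditions, dtype=object), np.arange(n_ep))


class TestFilter:
    def test_constant_signal_unchanged(self):
        data = np.full((33, 4000), 7.0)
        out = filter_continuous(_raw(data))
        assert np.allclose(out.data, 7.0, atol=1e-6)

    def test_notch_attenuates_50hz_by_20db(self):
        t = np.arange(10000) / 1000.0
        data = np.tile(np.sin(2 * np.pi * 50 * t), (33, 1))
        out = filter_continuous(_raw(data))
        mid = slice(2000, 8000)
        atten = np.sqrt(np.mean(out.data[0, mid] ** 2)) / np.sqrt(0.5)
        assert 20 * np.log10(atten) < -20

    def test_passband_matches_analytic_magnitude(self):
        """Measured sinusoid attenuation equals |H|^2 of the 2nd-order
        Butterworth (squared once more by the forward-backward pass)."""
        for freq in (5.0, 20.0, 35.0):
            t = np.arange(20000) / 1000.0
            data = np.tile(np.sin(2 * np.pi * freq * t), (33, 1))
            out = filter_continuous(_raw(data), notch_hz=50.0)
            mid = slice(5000, 15000)
            measured = np.sqrt(np.mean(out.data[0, mid] ** 2)) / np.sqrt(0.5)
            # zero-phase: magnitude response applies twice
            expect = 1.0 / (1.0 + (freq / 50.0) ** 4)
            sos_n = signal.butter(2, (48, 52), btype="bandstop", fs=1000, output="sos")
            _, h = signal.sosfreqz(sos_n, worN=[freq], fs=1000)
            expect *= np.abs(h[0]) ** 2
            assert measured == pytest.approx(expect, rel=0.02)

    def test_cutoff_above_nyquist_fails(self):
        with pytest.raises(ValueError):
            filter_continuous(_raw(np.zeros((33, 100))), lowpass_hz=600.0)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(33, 3000))
        out1 = filter_continuous(_raw(data)).data
        out3 = filter_continuous(_raw(3.0 * data)).data
        assert np.allclose(out3, 3.0 * out1, atol=1e-8)


class TestSegment:
    def test_one_epoch_per_correct_trial(self, noiseless_subject):
        ds, _ = noiseless_subject
        scored = behavior.score_log(ds.schedule, ds.responses)
        correct = [s.trial.index for s in scored if s.outcome == "correct"]
        epochs, dropped = segment(ds.eeg, correct)
        assert epochs.n_epochs == len(correct)
        assert dropped == []
        assert epochs.data.shape[2] == 1301

    def test_condition_labels_match_schedule(self, noiseless_subject):
        ds, _ = noiseless_subject
        scored = behavior.score_log(ds.schedule, ds.responses)
        correct = [s.trial.index for s in scored if s.outcome == "correct"]
        epochs, _ = segment(ds.eeg, correct)
        lut = {t.index: t.congruency for t in ds.schedule.trials}
        assert all(lut[i] == c for i, c in zip(epochs.trial_ids, epochs.conditions))

    def test_marker_too_close_to_edge_dropped(self):
        data = np.zeros((33, 2500))
        events = [(100, 11, "x"), (1200, 21, "y")]  # first lacks pre-window
        epochs, dropped = segment(_raw(data, events), [0, 1])
        assert epochs.n_epochs == 1 and dropped == [0]


class TestOcularCorrect:
    def test_zero_eog_leaves_data_unchanged(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(6, 33, 1301))
        for ch in ("FP2", "F10"):
            data[:, ALL_CHANNELS.index(ch), :] = 0.0
        epochs = _epochs(data)
        out, coeffs = ocular_correct(epochs)
        assert np.allclose(out.data, data)
        assert np.allclose(coeffs["FP2"], 0.0)

    def test_known_propagation_recovered_exactly(self):
        """Channel = clean + 0.20 x EOG (noiseless) -> coefficient 0.20
        and the corrected channel equals the clean signal."""
        rng = np.random.default_rng(2)
        n_ep = 40
        t = np.arange(1301)
        clean_wave = 4.0 * np.sin(2 * np.pi * t / 400.0)  # deterministic ERP
        clean = np.tile(clean_wave, (n_ep, 33, 1))
        eog = rng.normal(size=(n_ep, 1301)) * 30
        data = clean.copy()
        fp2 = ALL_CHANNELS.index("FP2")
        data[:, fp2, :] = eog
        f5 = ALL_CHANNELS.index("F5")
        data[:, f5, :] = clean[:, f5, :] + 0.20 * eog
        out, coeffs = ocular_correct(_epochs(data))
        assert coeffs["FP2"][f5] == pytest.approx(0.20, abs=1e-6)
        assert np.allclose(out.data[:, f5, :], clean[:, f5, :], atol=1e-6)

    def test_blink_propagation_monotone_front_to_back(self, noisy_subject):
        ds, truth = noisy_subject
        scored = behavior.score_log(ds.schedule, ds.responses)
        correct = [s.trial.index for s in scored if s.outcome == "correct"]
        epochs, _ = segment(ds.eeg, correct)
        _, coeffs = ocular_correct(epochs)
        est = {ch: coeffs["FP2"][ALL_CHANNELS.index(ch)] for ch in SCALP_CHANNELS}
        front = np.mean([est["F5"], est["F3"], est["F4"], est["F6"], est["Fz"]])
        mid = np.mean([est["C5"], est["C3"], est["C4"], est["C6"], est["Cz"]])
        back = np.mean([est["P7"], est["P5"], est["P4"], est["P8"], est["Pz"]])
        assert front > mid > back > 0

    def test_erp_preserved_in_correction(self):
        """The stimulus-locked ERP must survive even when it is correlated
        with an EOG deflection shape (ERP removed before regression)."""
        rng = np.random.default_rng(3)
        n_ep = 30
        t = np.arange(1301)
        erp_wave = 5.0 * np.exp(-0.5 * ((t - 600) / 50.0) ** 2)
        data = rng.normal(size=(n_ep, 33, 1301)) * 0.1
        data[:, :29, :] += erp_wave
        out, _ = ocular_correct(_epochs(data, ["congruent"] * n_ep))
        avg = out.data[:, 0, :].mean(axis=0)
        assert np.corrcoef(avg, erp_wave)[0, 1] > 0.99


class TestRejection:
    def test_all_zero_epochs_nothing_rejected(self):
        epochs = _epochs(np.zeros((4, 33, 1301)))
        out, report = reject_artifacts(epochs)
        assert report["n_rejected_cells"] == 0

    def test_spike_rejects_only_that_cell(self):
        data = np.zeros((4, 33, 1301))
        f5 = ALL_CHANNELS.index("F5")
        data[1, f5, 600] = 500.0
        out, _ = reject_artifacts(_epochs(data), RejectionCriteria(100, 1e9, 1e9))
        assert out.rejected[1, f5]
        assert out.rejected.sum() == 1

    def test_mask_monotone_never_unrejects(self):
        data = np.zeros((3, 33, 1301))
        epochs = _epochs(data)
        epochs.rejected[0, 5] = True
        out, _ = reject_artifacts(epochs)
        assert out.rejected[0, 5]

    def test_injected_artifacts_detected(self, noisy_subject):
        ds, truth = noisy_subject
        if not truth.artifact_injections:
            pytest.skip("no artifacts realized at this seed")
        scored = behavior.score_log(ds.schedule, ds.responses)
        correct = {s.trial.index for s in scored if s.outcome == "correct"}
        epochs, _ = segment(ds.eeg, list(correct))
        epochs, _ = ocular_correct(epochs)
        out, _ = reject_artifacts(epochs)
        id_to_row = {tid: k for k, tid in enumerate(epochs.trial_ids)}
        hits = total = 0
        for trial_idx, ch in truth.artifact_injections:
            if trial_idx in id_to_row:
                total += 1
                hits += bool(out.rejected[id_to_row[trial_idx],
                                          ALL_CHANNELS.index(ch)])
        if total:
            assert hits == total  # 400 uV spikes are unmissable


class TestGate:
    def test_cutoff_is_ceil_third(self):
        epochs = _epochs(np.zeros((240, 33, 1301)),
                         ["congruent"] * 120 + ["incongruent"] * 120)
        included, info = gate_subject(epochs, total_per_condition=120)
        assert info["cutoff"] == 40 and included
        _, info2 = gate_subject(epochs, total_per_condition=100)
        assert info2["cutoff"] == 34

    def test_fourteen_electrodes_excludes(self):
        epochs = _epochs(np.zeros((120, 33, 1301)),
                         ["congruent"] * 60 + ["incongruent"] * 60)
        # wipe incongruent epochs on all but 14 electrodes
        scalp_idx = [ALL_CHANNELS.index(ch) for ch in SCALP_CHANNELS]
        epochs.rejected[60:, scalp_idx[14:]] = True
        included, info = gate_subject(epochs, total_per_condition=60)
        assert info["conditions"]["incongruent"]["electrodes_above_cutoff"] == 14
        assert not included

    def test_monotone_in_surviving_segments(self):
        epochs = _epochs(np.zeros((120, 33, 1301)),
                         ["congruent"] * 60 + ["incongruent"] * 60)
        scalp_idx = [ALL_CHANNELS.index(ch) for ch in SCALP_CHANNELS]
        epochs.rejected[60:, scalp_idx[14:]] = True
        assert not gate_subject(epochs, 60)[0]
        epochs.rejected[:] = False  # adding back segments can only include
        assert gate_subject(epochs, 60)[0]


class TestBaselineRereference:
    def test_constant_epoch_zeroed(self):
        epochs = _epochs(np.full((2, 33, 1301), 5.0))
        out = baseline_and_rereference(epochs)
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_channel_equal_to_mastoids_cancels(self):
        rng = np.random.default_rng(4)
        data = np.zeros((2, 33, 1301))
        wave = rng.normal(size=(2, 1301))
        for ch in ("F5", "TP9", "TP10"):
            data[:, ALL_CHANNELS.index(ch), :] = wave
        out = baseline_and_rereference(_epochs(data))
        assert np.allclose(out.data[:, ALL_CHANNELS.index("F5"), :], 0.0, atol=1e-9)

    def test_order_of_baseline_and_rereference_commutes(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(3, 33, 1301))
        epochs = _epochs(data)
        full = baseline_and_rereference(epochs).data

        # manual: re-reference first, then baseline
        m_idx = [ALL_CHANNELS.index(ch) for ch in ("TP9", "TP10")]
        reref = data.copy()
        mast = reref[:, m_idx, :].mean(axis=1, keepdims=True)
        non_m = [i for i in range(33) if i not in m_idx]
        reref[:, non_m, :] -= mast
        sl = slice(200, 300)  # [-100, 0) ms with tmin -300
        reref -= reref[:, :, sl].mean(axis=2, keepdims=True)
        assert np.allclose(full, reref, atol=1e-9)


class TestAverage:
    def test_mean_of_two_constant_epochs(self):
        data = np.zeros((2, 33, 1301))
        data[0], data[1] = 1.0, 3.0
        erps = average_erp(_epochs(data, ["congruent", "congruent"]))
        assert np.allclose(erps.data["congruent"], 2.0)
        assert np.all(erps.counts["congruent"] == 2)

    def test_rejected_epoch_excluded_from_mean(self):
        data = np.zeros((3, 33, 1301))
        data[0], data[1], data[2] = 1.0, 3.0, 100.0
        epochs = _epochs(data, ["congruent"] * 3)
        epochs.rejected[2, :] = True
        erps = average_erp(epochs)
        assert np.allclose(erps.data["congruent"], 2.0)
        assert np.all(erps.counts["congruent"] == 2)

    def test_channel_with_no_survivors_flagged_nan(self):
        data = np.zeros((2, 33, 1301))
        epochs = _epochs(data, ["congruent", "congruent"])
        epochs.rejected[:, 0] = True
        erps = average_erp(epochs)
        assert np.isnan(erps.data["congruent"][0]).all()
        assert erps.counts["congruent"][0] == 0

    def test_noiseless_roundtrip_recovers_templates(self, noiseless_subject):
        """Full chain on noiseless data returns the injected waveforms."""
        ds, truth = noiseless_subject
        scored = behavior.score_log(ds.schedule, ds.responses)
        correct = [s.trial.index for s in scored if s.outcome == "correct"]
        epochs, _ = segment(ds.eeg, correct)  # unfiltered: exact identity
        epochs, _ = ocular_correct(epochs)
        epochs = baseline_and_rereference(epochs)
        erps = average_erp(epochs)
        t = erps.times_ms
        pz = erps.channel_index("Pz")
        for cond in ("congruent", "incongruent"):
            expect = (truth.p300_amp[cond]
                      * np.exp(-0.5 * ((t - truth.p300_latency_ms[cond]) / 35.0) ** 2))
            expect += (truth.n2pc_amp[cond]
                       * np.exp(-0.5 * ((t - truth.n2pc_latency_ms[cond]) / 12.0) ** 2))
            expect -= expect[(t >= -100) & (t < 0)].mean()
            assert np.allclose(erps.data[cond][pz], expect, atol=1e-3)
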