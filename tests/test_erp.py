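import numpy as np
import pandas as pd
import pytest

from erpsel.erp import (
    ErpParams,
    ERPWaveform,
    InsufficientTrialsError,
    average_condition,
    bandpass_filter,
    baseline_correct,
    detect_component_peak,
    extract_feature_table,
    grand_average,
    indicator_columns,
    process_recording,
    reject_artifact_epochs,
    segment_epochs,
)
from erpsel.erp import EpochSet, PeakMeasure
from erpsel.synth import (
    ComponentParams,
    GenerativeConfig,
    build_trial_schedule,
    component_kernel,
    synthesize_recording,
)

FS = 250.0
TIMES = (np.arange(-50, 150)) / FS * 1000.0


def make_epochs(data, condition="AW", channel="T5", kept=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if kept is None:
        kept = np.ones(data.shape[0], dtype=bool)
    return EpochSet(
        participant_id="p",
        condition=condition,
        channel=channel,
        data=data,
        times_ms=TIMES[: data.shape[1]] if data.shape[1] <= 200 else TIMES,
        fs=FS,
        kept=kept,
    )


def make_waveform(mean, condition="AW", channel="T5"):
    mean = np.asarray(mean, dtype=float)
    return ERPWaveform(
        condition=condition,
        channel=channel,
        mean=mean,
        se=np.zeros_like(mean),
        n_trials=10,
        times_ms=TIMES,
        fs=FS,
    )


class TestBandpassFilter:
    def test_dc_removed(self):
        x = np.full(5000, 10.0)
        y = bandpass_filter(x, FS, 1.0, 20.0)
        interior = y[1000:-1000]
        assert np.max(np.abs(interior)) < 0.01 * 10.0

    def test_passband_sinusoid_amplitude(self):
        t = np.arange(0, 60.0, 1 / FS)
        y = bandpass_filter(np.sin(2 * np.pi * 10.0 * t), FS, 1.0, 20.0)
        steady = y[len(y) // 4 : -len(y) // 4]
        assert 0.9 <= steady.max() <= 1.0

    def test_zero_phase_preserves_peak_latency(self):
        t = np.arange(0, 20.0, 1 / FS) * 1000.0
        x = component_kernel(10_000.0, 6.0, 30.0, t)
        y = bandpass_filter(x, FS, 1.0, 20.0)
        assert abs(t[np.argmax(y)] - t[np.argmax(x)]) <= 4.0

    def test_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(1234)
        assert bandpass_filter(x, FS, 1.0, 20.0).shape == x.shape

    @pytest.mark.parametrize("band", [(0.0, 20.0), (20.0, 1.0), (1.0, 200.0)])
    def test_invalid_band(self, band):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), FS, *band)


@pytest.fixture(scope="module")
def recording():
    config = GenerativeConfig(noise_sd=2.0, artifact_rate=0.0)
    schedule = build_trial_schedule(config, seed=0)
    return synthesize_recording(28.0, schedule, config, seed=0)


class TestSegmentEpochs:

    def test_epoch_sample_count(self, recording):
        epochs = segment_epochs(recording, (-200.0, 600.0), channels=["T5"])
        for es in epochs.values():
            assert es.data.shape[1] == 200  # 0.8 s at 250 Hz

    def test_condition_counts(self, recording):
        epochs = segment_epochs(recording, channels=["T5"])
        assert epochs[("AW", "T5")].n_trials == 120
        assert epochs[("RW", "T5")].n_trials == 120
        assert epochs[("ST", "T5")].n_trials == 60

    def test_window_underrun_dropped(self, recording, caplog):
        events = recording.events.copy()
        events.loc[events.index[0], "onset_sample"] = 10
        events = events.sort_values("onset_sample")
        hacked = recording.__class__(
            participant_id="p",
            channels=recording.channels,
            data=recording.data,
            fs=recording.fs,
            events=events,
        )
        cond = events.iloc[0]["condition"]
        n_before = int((recording.events["condition"] == cond).sum())
        with caplog.at_level("WARNING"):
            epochs = segment_epochs(hacked, channels=["T5"])
        assert epochs[(cond, "T5")].n_trials == n_before - 1
        assert "overrun" in caplog.text


class TestBaselineCorrect:
    def test_constant_epoch_zeroed(self):
        es = make_epochs(np.full((3, 200), 7.0))
        out = baseline_correct(es)
        assert np.allclose(out.data, 0.0)

    def test_kernel_recovered_with_offset(self):
        kernel = component_kernel(170.0, -5.0, 20.0, TIMES)
        es = make_epochs(kernel[None, :] + 3.25)
        out = baseline_correct(es)
        # kernel is ~0 over the baseline window, so it is recovered exactly
        assert np.allclose(out.data[0], kernel, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        es = make_epochs(rng.standard_normal((4, 200)))
        once = baseline_correct(es)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_baseline_mean_zero_invariant(self):
        rng = np.random.default_rng(4)
        es = make_epochs(rng.standard_normal((10, 200)) * 40 + 13)
        out = baseline_correct(es)
        base = out.data[:, out.times_ms < 0]
        assert np.all(np.abs(base.mean(axis=1)) < 1e-9 * np.abs(es.data).max())

    def test_empty_baseline_window_rejected(self):
        es = make_epochs(np.zeros((2, 200)))
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(es, (-500.0, -400.0))


class TestRejectArtifacts:
    def test_injected_artifacts_flagged_exactly(self):
        config = GenerativeConfig(n_sets=2, noise_sd=5.0, artifact_rate=0.1)
        schedule = build_trial_schedule(config, seed=5)
        rec = synthesize_recording(28.0, schedule, config, seed=5)
        epochs = segment_epochs(rec)
        for cond in ("AW", "RW", "ST"):
            truth = rec.events.loc[
                rec.events["condition"] == cond, "artifact"
            ].to_numpy(bool)
            scalp = baseline_correct(epochs[(cond, "T5")])
            eog = [
                baseline_correct(epochs[(cond, ch)])
                for ch in ("EOG_upper", "EOG_lower")
            ]
            flagged = reject_artifact_epochs(scalp, eog, 100.0)
            assert np.array_equal(~flagged.kept, truth)

    def test_infinite_threshold_keeps_all(self):
        es = make_epochs(np.random.default_rng(0).standard_normal((5, 200)) * 500)
        out = reject_artifact_epochs(es, [], np.inf)
        assert out.kept.all()

    def test_all_artifacts_then_averaging_fails(self):
        es = make_epochs(np.full((5, 200), 0.0))
        es.data[:, 100] = 500.0  # every trial exceeds threshold
        out = reject_artifact_epochs(es, [], 100.0)
        assert not out.kept.any()
        with pytest.raises(InsufficientTrialsError):
            average_condition(out, min_trials=1)

    def test_misaligned_trial_counts_rejected(self):
        scalp = make_epochs(np.zeros((5, 200)))
        eog = make_epochs(np.zeros((4, 200)), channel="EOG_upper")
        with pytest.raises(ValueError, match="misaligned"):
            reject_artifact_epochs(scalp, [eog], 100.0)


class TestAverage:
    def test_single_epoch_identity_with_flagged_se(self):
        kernel = component_kernel(200.0, 6.0, 30.0, TIMES)
        wf = average_condition(make_epochs(kernel), min_trials=1)
        assert np.array_equal(wf.mean, kernel)
        assert np.all(np.isnan(wf.se))

    def test_identical_epochs_zero_se(self):
        kernel = component_kernel(200.0, 6.0, 30.0, TIMES)
        wf = average_condition(make_epochs(np.tile(kernel, (5, 1))), min_trials=1)
        assert np.allclose(wf.mean, kernel)
        assert np.allclose(wf.se, 0.0)

    def test_min_trials_enforced(self):
        with pytest.raises(InsufficientTrialsError, match="need 20"):
            average_condition(make_epochs(np.zeros((5, 200))), min_trials=20)

    def test_mean_within_three_se_of_truth(self):
        rng = np.random.default_rng(6)
        kernel = component_kernel(200.0, 6.0, 30.0, TIMES)
        data = kernel[None, :] + rng.standard_normal((120, 200)) * 5.0
        wf = average_condition(make_epochs(data), min_trials=20)
        covered = np.abs(wf.mean - kernel) <= 3 * wf.se
        assert covered.mean() >= 0.99

    def test_rejected_trials_excluded_from_average(self):
        data = np.zeros((4, 200))
        data[0] += 1000.0
        kept = np.array([False, True, True, True])
        wf = average_condition(make_epochs(data, kept=kept), min_trials=1)
        assert np.allclose(wf.mean, 0.0)
        assert wf.n_trials == 3


class TestGrandAverage:
    def test_single_participant_identity(self):
        wf = make_waveform(component_kernel(200.0, 6.0, 30.0, TIMES))
        ga = grand_average([wf])
        assert np.array_equal(ga.mean, wf.mean)

    def test_opposite_waveforms_cancel(self):
        w = component_kernel(200.0, 6.0, 30.0, TIMES)
        ga = grand_average([make_waveform(w), make_waveform(-w)])
        assert np.allclose(ga.mean, 0.0)

    def test_mismatched_axes_rejected(self):
        a = make_waveform(np.zeros(200))
        b = make_waveform(np.zeros(200), condition="RW")
        with pytest.raises(ValueError, match="differ"):
            grand_average([a, b])

    def test_synthetic_grand_average_shows_both_components(self):
        config = GenerativeConfig(n_sets=2, noise_sd=6.0, artifact_rate=0.02)
        params = ErpParams(min_trials=10)
        waveforms = []
        rng = np.random.default_rng(13)
        for i in range(6):
            trait = float(rng.integers(15, 40))
            schedule = build_trial_schedule(config, rng)
            rec = synthesize_recording(trait, schedule, config, rng,
                                       participant_id=f"sub-{i:02d}")
            waveforms.append(process_recording(rec, params)[("AW", "T6")])
        ga = grand_average(waveforms)
        n170 = detect_component_peak(ga, "N170")
        assert n170.identified
        p200 = detect_component_peak(ga, "P200", not_before_ms=n170.latency_ms)
        assert p200.identified
        assert 140 <= n170.latency_ms < 200
        assert 180 <= p200.latency_ms < 240


class TestDetectPeak:
    def test_noiseless_kernel_pair(self):
        # narrow, well-separated kernels: peaks equal the kernel parameters
        wave = component_kernel(168.0, -5.0, 8.0, TIMES) + component_kernel(
            200.0, 6.0, 8.0, TIMES
        )
        wf = make_waveform(wave)
        n170 = detect_component_peak(wf, "N170")
        assert n170.identified
        assert n170.latency_ms == 168.0
        assert n170.amplitude_uv == pytest.approx(-5.0, rel=1e-4)
        p200 = detect_component_peak(wf, "P200", not_before_ms=n170.latency_ms)
        assert p200.identified
        assert p200.latency_ms == 200.0
        assert p200.amplitude_uv == pytest.approx(6.0, rel=1e-4)

    def test_flat_waveform_unidentified(self):
        wf = make_waveform(np.zeros(200))
        assert not detect_component_peak(wf, "N170").identified
        assert not detect_component_peak(wf, "P200").identified

    def test_drift_outside_windows_ignored(self):
        base = component_kernel(168.0, -5.0, 8.0, TIMES) + component_kernel(
            200.0, 6.0, 8.0, TIMES
        )
        drift = np.where(TIMES < 100, -0.05 * (TIMES - 100), 0.0)
        drift += np.where(TIMES >= 300, 0.05 * (TIMES - 300) - 0, 0.0)
        wf = make_waveform(base + drift)
        n170 = detect_component_peak(wf, "N170")
        p200 = detect_component_peak(wf, "P200", not_before_ms=n170.latency_ms)
        assert n170.latency_ms == 168.0
        assert p200.latency_ms == 200.0

    def test_edge_extremum_not_identified(self):
        # ramp rising through the whole window: maximum sits on window edge
        wf = make_waveform(np.linspace(0, 10, 200))
        assert not detect_component_peak(wf, "P200").identified

    def test_wrong_sign_not_identified(self):
        wf = make_waveform(component_kernel(170.0, 5.0, 8.0, TIMES))
        assert not detect_component_peak(wf, "N170").identified

    def test_below_prominence_not_identified(self):
        wf = make_waveform(component_kernel(170.0, -0.5, 8.0, TIMES))
        assert not detect_component_peak(wf, "N170", prominence_min_uv=1.0).identified

    def test_latency_on_sample_grid(self):
        wf = make_waveform(component_kernel(171.0, -5.0, 8.0, TIMES))
        pm = detect_component_peak(wf, "N170")
        assert pm.latency_ms % 4.0 == 0.0


def _measures(identified=True, skip=()):
    out = {}
    for comp in ("N170", "P200"):
        for cond in ("AW", "RW"):
            for elec in ("T5", "T6"):
                flag = identified and (comp, cond, elec) not in skip
                amp = -3.0 if comp == "N170" else 5.0
                out[(comp, cond, elec)] = PeakMeasure(
                    comp, elec, cond, 170.0, amp, flag
                )
    return out


class TestFeatureTable:
    def participants(self, n):
        return pd.DataFrame(
            {"id": [f"sub-{i:02d}" for i in range(n)], "satq": 25 + np.arange(n) % 10}
        )

    def test_exclusion_count_matches_retained(self):
        measures = {}
        for i in range(30):
            skip = {("P200", "AW", "T6")} if i < 4 else set()
            measures[f"sub-{i:02d}"] = _measures(skip=skip)
        tables, exclusions = extract_feature_table(measures, self.participants(30))
        assert len(tables["T6"]) == 26
        assert len(tables["T5"]) == 30
        assert sum(e["electrode"] == "T6" for e in exclusions) == 4

    def test_all_identified_full_columns(self):
        measures = {f"sub-{i:02d}": _measures() for i in range(5)}
        tables, exclusions = extract_feature_table(measures, self.participants(5))
        assert not exclusions
        for elec in ("T5", "T6"):
            assert list(tables[elec].columns) == ["id", "satq"] + indicator_columns(elec)
            assert not tables[elec].isna().any().any()

    def test_missing_rw_p200_excluded_with_reason(self):
        measures = {"sub-00": _measures(skip={("P200", "RW", "T5")}),
                    "sub-01": _measures()}
        tables, exclusions = extract_feature_table(measures, self.participants(2))
        assert len(tables["T5"]) == 1
        (record,) = [e for e in exclusions if e["electrode"] == "T5"]
        assert record["participant_id"] == "sub-00"
        assert "P200_RW" in record["reason"]

    def test_empty_retained_set_raises(self):
        measures = {"sub-00": _measures(identified=False)}
        with pytest.raises(RuntimeError, match="retained"):
            extract_feature_table(measures, self.participants(1))
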