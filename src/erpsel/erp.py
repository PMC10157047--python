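"""ERP extraction: filtering, epoching, artifact rejection, averaging and peaks.

The pipeline turns a continuous recording into per-participant component
measures (latency/amplitude of the negative ~170 ms and positive ~200 ms
peaks on the temporal channels) and assembles the per-electrode feature
table used by the subset-regression stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .synth import (
    ANALYSIS_ELECTRODES,
    COMPONENTS,
    CONDITIONS,
    EOG_CHANNELS,
    SCALP_CHANNELS,
    RawRecording,
)

logger = logging.getLogger(__name__)


class InsufficientTrialsError(RuntimeError):
    """Raised when too few artifact-free trials remain for an average."""


DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "N170": (120.0, 220.0),
    "P200": (150.0, 300.0),
}


@dataclass
class ErpParams:
    """Extraction parameters; defaults follow the recording protocol."""

    band_hz: tuple[float, float] | None = (1.0, 20.0)
    filter_order: int = 4
    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    reject_threshold_uv: float | None = 100.0
    min_trials: int = 20
    peak_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_WINDOWS)
    )
    prominence_min_uv: float = 1.0
    electrodes: tuple[str, ...] = ANALYSIS_ELECTRODES


@dataclass
class EpochSet:
    """Trials x samples for one condition on one channel."""

    participant_id: str
    condition: str
    channel: str
    data: np.ndarray  # trials x samples, uV
    times_ms: np.ndarray
    fs: float
    kept: np.ndarray  # bool per trial

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]


@dataclass
class ERPWaveform:
    condition: str
    channel: str
    mean: np.ndarray
    se: np.ndarray
    n_trials: int
    times_ms: np.ndarray
    fs: float


@dataclass(frozen=True)
class PeakMeasure:
    component: str
    electrode: str
    condition: str
    latency_ms: float
    amplitude_uv: float
    identified: bool


def bandpass_filter(
    x: np.ndarray, fs: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def filter_recording(recording: RawRecording, params: ErpParams) -> RawRecording:
    """Apply the configured band-pass to every channel (no-op if band is None)."""
    if params.band_hz is None:
        return recording
    low, high = params.band_hz
    data = bandpass_filter(recording.data, recording.fs, low, high, params.filter_order)
    return RawRecording(
        participant_id=recording.participant_id,
        channels=recording.channels,
        data=data,
        fs=recording.fs,
        events=recording.events,
    )


def segment_epochs(
    recording: RawRecording,
    window_ms: tuple[float, float] = (-200.0, 600.0),
    channels: Sequence[str] | None = None,
) -> dict[tuple[str, str], EpochSet]:
    """Cut per-condition epochs for each requested channel.

    The window is half-open: at 250 Hz a [-200, 600) ms window holds exactly
    200 samples, with the onset sample on the post-stimulus side.  Trials
    whose window overruns the record are dropped (logged).
    """
    fs = recording.fs
    n_pre = int(round(-window_ms[0] / 1000.0 * fs))
    n_post = int(round(window_ms[1] / 1000.0 * fs))
    n_samp = n_pre + n_post
    times = (np.arange(n_samp) - n_pre) / fs * 1000.0
    if channels is None:
        channels = recording.channels

    out: dict[tuple[str, str], EpochSet] = {}
    for cond in CONDITIONS:
        onsets = recording.events.loc[
            recording.events["condition"] == cond, "onset_sample"
        ].to_numpy()
        if len(onsets) == 0:
            continue
        valid = (onsets - n_pre >= 0) & (onsets + n_post <= recording.n_samples)
        if not valid.all():
            logger.warning(
                "%s/%s: dropped %d trial(s) with window overrun",
                recording.participant_id,
                cond,
                int((~valid).sum()),
            )
        onsets = onsets[valid]
        idx = onsets[:, None] + np.arange(-n_pre, n_post)[None, :]
        for label in channels:
            ch = recording.channels.index(label)
            out[(cond, label)] = EpochSet(
                participant_id=recording.participant_id,
                condition=cond,
                channel=label,
                data=recording.data[ch][idx],
                times_ms=times,
                fs=fs,
                kept=np.ones(len(onsets), dtype=bool),
            )
    return out


def baseline_correct(
    epochs: EpochSet, baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract each epoch's mean over the (half-open) baseline window."""
    lo, hi = baseline_window_ms
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    corrected = epochs.data - epochs.data[:, mask].mean(axis=1, keepdims=True)
    return replace(epochs, data=corrected)


def _peak_to_peak(data: np.ndarray) -> np.ndarray:
    return data.max(axis=1) - data.min(axis=1)


def reject_artifact_epochs(
    epochs: EpochSet,
    eog: Sequence[EpochSet],
    threshold_uv: float | None = 100.0,
) -> EpochSet:
    """Flag trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is rejected if the scalp channel itself or any EOG channel
    exceeds ``threshold_uv`` peak to peak.  ``None`` disables rejection.
    """
    for e in eog:
        if e.n_trials != epochs.n_trials:
            raise ValueError(
                f"EOG epochs ({e.n_trials} trials) misaligned with scalp "
                f"epochs ({epochs.n_trials} trials)"
            )
    if threshold_uv is None or np.isinf(threshold_uv):
        return replace(epochs, kept=epochs.kept.copy())
    bad = _peak_to_peak(epochs.data) > threshold_uv
    for e in eog:
        bad |= _peak_to_peak(e.data) > threshold_uv
    kept = epochs.kept & ~bad
    logger.info(
        "%s/%s/%s: rejected %d of %d trials",
        epochs.participant_id,
        epochs.condition,
        epochs.channel,
        int(bad.sum()),
        epochs.n_trials,
    )
    return replace(epochs, kept=kept)


def average_condition(epochs: EpochSet, min_trials: int = 20) -> ERPWaveform:
    """Point-wise mean and standard error over kept trials."""
    n = epochs.n_kept
    if n < min_trials:
        raise InsufficientTrialsError(
            f"{epochs.participant_id}/{epochs.condition}/{epochs.channel}: "
            f"only {n} kept trial(s), need {min_trials}"
        )
    data = epochs.kept_data
    mean = data.mean(axis=0)
    if n >= 2:
        se = data.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.full(data.shape[1], np.nan)
    return ERPWaveform(
        condition=epochs.condition,
        channel=epochs.channel,
        mean=mean,
        se=se,
        n_trials=n,
        times_ms=epochs.times_ms,
        fs=epochs.fs,
    )


def grand_average(waveforms: Sequence[ERPWaveform]) -> ERPWaveform:
    """Across-participant mean with across-participant standard error."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    first = waveforms[0]
    for w in waveforms[1:]:
        if (
            w.condition != first.condition
            or w.channel != first.channel
            or not np.array_equal(w.times_ms, first.times_ms)
        ):
            raise ValueError("waveforms differ in condition/channel/time axis")
    stack = np.vstack([w.mean for w in waveforms])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else np.full(stack.shape[1], np.nan)
    return ERPWaveform(
        condition=first.condition,
        channel=first.channel,
        mean=mean,
        se=se,
        n_trials=n,
        times_ms=first.times_ms,
        fs=first.fs,
    )


def detect_component_peak(
    waveform: ERPWaveform,
    component: str,
    window_ms: tuple[float, float] | None = None,
    prominence_min_uv: float = 1.0,
    not_before_ms: float | None = None,
) -> PeakMeasure:
    """Locate one component's extremum inside its search window.

    The negative component is the window minimum, the positive one the window
    maximum; when ``not_before_ms`` is given the search is restricted to later
    samples (used to force the positive peak after the identified negative
    one).  A peak is flagged unidentified when its magnitude falls below
    ``prominence_min_uv``, when it has the wrong sign, or when it sits on a
    window edge.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if window_ms is None:
        window_ms = DEFAULT_PEAK_WINDOWS[component]
    lo, hi = window_ms
    t = waveform.times_ms
    mask = (t >= lo) & (t < hi)
    if not_before_ms is not None:
        mask &= t > not_before_ms
    idx = np.flatnonzero(mask)
    unidentified = PeakMeasure(component, waveform.channel, waveform.condition,
                               np.nan, np.nan, False)
    if idx.size < 3:
        return unidentified
    seg = waveform.mean[idx]
    j = int(np.argmin(seg) if component == "N170" else np.argmax(seg))
    value = float(seg[j])
    on_edge = j in (0, len(idx) - 1)
    sign_ok = value <= -prominence_min_uv if component == "N170" else value >= prominence_min_uv
    identified = bool(sign_ok and not on_edge)
    if not identified:
        return unidentified
    return PeakMeasure(
        component=component,
        electrode=waveform.channel,
        condition=waveform.condition,
        latency_ms=float(t[idx[j]]),
        amplitude_uv=value,
        identified=True,
    )


def measure_waveform(
    waveform: ERPWaveform, params: ErpParams
) -> dict[str, PeakMeasure]:
    """Detect both components on one waveform, positive peak after negative."""
    n170 = detect_component_peak(
        waveform, "N170", params.peak_windows["N170"], params.prominence_min_uv
    )
    p200 = detect_component_peak(
        waveform,
        "P200",
        params.peak_windows["P200"],
        params.prominence_min_uv,
        not_before_ms=n170.latency_ms if n170.identified else None,
    )
    return {"N170": n170, "P200": p200}


def process_recording(
    recording: RawRecording, params: ErpParams
) -> dict[tuple[str, str], ERPWaveform]:
    """Filter, epoch, baseline-correct, reject and average one recording.

    Returns per-(condition, scalp channel) waveforms; EOG channels are used
    only for rejection.
    """
    filtered = filter_recording(recording, params)
    epochs = segment_epochs(filtered, params.epoch_window_ms)
    waveforms: dict[tuple[str, str], ERPWaveform] = {}
    for cond in CONDITIONS:
        if (cond, SCALP_CHANNELS[0]) not in epochs:
            continue
        eog_sets = [
            baseline_correct(epochs[(cond, label)], params.baseline_window_ms)
            for label in EOG_CHANNELS
        ]
        for label in SCALP_CHANNELS:
            es = baseline_correct(epochs[(cond, label)], params.baseline_window_ms)
            es = reject_artifact_epochs(es, eog_sets, params.reject_threshold_uv)
            waveforms[(cond, label)] = average_condition(es, params.min_trials)
    return waveforms


FEATURE_CONDITIONS = ("AW", "RW")


def indicator_columns(electrode: str) -> list[str]:
    """The 8 indicator column names for one electrode, in canonical order."""
    return [
        f"{electrode}_{comp}_{cond}_{kind}"
        for comp in COMPONENTS
        for kind in ("latency", "amplitude")
        for cond in FEATURE_CONDITIONS
    ]


def measure_participant(
    waveforms: Mapping[tuple[str, str], ERPWaveform], params: ErpParams
) -> dict[tuple[str, str, str], PeakMeasure]:
    """Peak measures keyed (component, condition, electrode)."""
    measures: dict[tuple[str, str, str], PeakMeasure] = {}
    for cond in FEATURE_CONDITIONS:
        for elec in params.electrodes:
            wf = waveforms.get((cond, elec))
            if wf is None:
                continue
            for comp, pm in measure_waveform(wf, params).items():
                measures[(comp, cond, elec)] = pm
    return measures


def extract_feature_table(
    measures_by_participant: Mapping[str, Mapping[tuple[str, str, str], PeakMeasure]],
    participants: pd.DataFrame,
    electrodes: Sequence[str] = ANALYSIS_ELECTRODES,
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Per-electrode feature tables plus the exclusion log.

    A participant is retained at an electrode only if all four component
    peaks (both components x both walking conditions) were identified there;
    retention is evaluated independently per electrode.
    """
    traits = dict(zip(participants["id"], participants["satq"]))
    tables: dict[str, pd.DataFrame] = {}
    exclusions: list[dict] = []
    for elec in electrodes:
        rows = []
        for pid, measures in measures_by_participant.items():
            missing = [
                f"{comp}_{cond}"
                for comp in COMPONENTS
                for cond in FEATURE_CONDITIONS
                if not measures.get((comp, cond, elec), _MISSING).identified
            ]
            if missing:
                exclusions.append(
                    {
                        "participant_id": pid,
                        "electrode": elec,
                        "reason": "unidentified peaks: " + ", ".join(missing),
                    }
                )
                continue
            row: dict[str, float | str] = {"id": pid, "satq": traits[pid]}
            for comp in COMPONENTS:
                for cond in FEATURE_CONDITIONS:
                    pm = measures[(comp, cond, elec)]
                    row[f"{elec}_{comp}_{cond}_latency"] = pm.latency_ms
                    row[f"{elec}_{comp}_{cond}_amplitude"] = pm.amplitude_uv
            rows.append(row)
        if not rows:
            raise RuntimeError(f"no participants retained at electrode {elec}")
        tables[elec] = pd.DataFrame(rows)[["id", "satq"] + indicator_columns(elec)]
    return tables, exclusions


_MISSING = PeakMeasure("", "", "", np.nan, np.nan, False)


@dataclass
class FeatureExtraction:
    """End-to-end extraction result for a dataset."""

    feature_tables: dict[str, pd.DataFrame]
    exclusions: list[dict]
    waveforms: dict[str, dict[tuple[str, str], ERPWaveform]]  # per participant
    grand_averages: dict[tuple[str, str], ERPWaveform]  # (condition, electrode)


def extract_features(
    recordings: Sequence[RawRecording],
    participants: pd.DataFrame,
    params: ErpParams | None = None,
) -> FeatureExtraction:
    """Run the full extraction over a dataset of recordings."""
    params = params or ErpParams()
    all_waveforms: dict[str, dict[tuple[str, str], ERPWaveform]] = {}
    measures: dict[str, dict[tuple[str, str, str], PeakMeasure]] = {}
    for rec in recordings:
        wfs = process_recording(rec, params)
        all_waveforms[rec.participant_id] = wfs
        measures[rec.participant_id] = measure_participant(wfs, params)

    grand: dict[tuple[str, str], ERPWaveform] = {}
    for cond in CONDITIONS:
        for elec in params.electrodes:
            per_participant = [
                wfs[(cond, elec)] for wfs in all_waveforms.values() if (cond, elec) in wfs
            ]
            if per_participant:
                grand[(cond, elec)] = grand_average(per_participant)

    tables, exclusions = extract_feature_table(measures, participants, params.electrodes)
    return FeatureExtraction(
        feature_tables=tables,
        exclusions=exclusions,
        waveforms=all_waveforms,
        grand_averages=grand,
    )
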