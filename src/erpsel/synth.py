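"""Synthetic evoked-potential datasets: trait scores, trial schedules and recordings.

Generates continuous multi-channel recordings in which two visual-motion
components (a negative peak near 170 ms and a positive peak near 200 ms) are
embedded on the temporal channels for the two walking conditions, with
configurable trait-dependent modulation of latency and amplitude, 1/f-shaped
background noise and injectable blink-like artifacts on the EOG channels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONDITIONS = ("AW", "RW", "ST")
SCALP_CHANNELS = ("C3", "C4", "T5", "T6", "O1", "O2")
EOG_CHANNELS = ("EOG_upper", "EOG_lower")
CHANNELS = SCALP_CHANNELS + EOG_CHANNELS
COMPONENTS = ("N170", "P200")
ANALYSIS_ELECTRODES = ("T5", "T6")

#: (component, condition, electrode) triples carrying evoked activity.
ComponentKey = tuple[str, str, str]


@dataclass(frozen=True)
class ComponentParams:
    """Baseline parameters of one evoked component on one channel/condition."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"width must be positive, got {self.width_ms}")


def default_component_params() -> dict[ComponentKey, ComponentParams]:
    """Both components on T5/T6 for the two walking conditions, absent for ST."""
    params: dict[ComponentKey, ComponentParams] = {}
    for cond in ("AW", "RW"):
        for elec in ANALYSIS_ELECTRODES:
            params[("N170", cond, elec)] = ComponentParams(170.0, -5.0, 20.0)
            params[("P200", cond, elec)] = ComponentParams(200.0, 6.0, 30.0)
    return params


DEFAULT_LATENCY_SLOPES: dict[ComponentKey, float] = {
    ("P200", "AW", "T6"): 0.5,  # ms per trait unit
}
DEFAULT_AMPLITUDE_SLOPES: dict[ComponentKey, float] = {
    ("P200", "AW", "T5"): -0.1,  # uV per trait unit
    ("P200", "AW", "T6"): -0.1,
}


@dataclass
class GenerativeConfig:
    """All knobs of the synthetic dataset generator.

    Trait scores are drawn from a truncated normal, rounded to integers.
    Trial schedules interleave the three conditions at ``condition_ratio``
    within each set.  Timing of one trial is still image + motion video +
    a uniformly drawn fixation interval; the analysis onset is the start of
    the motion video.
    """

    n_participants: int = 30
    trait_mean: float = 27.77
    trait_sd: float = 8.02
    trait_bounds: tuple[int, int] = (0, 72)
    fs: float = 250.0
    n_sets: int = 5
    set_size: int = 60
    condition_ratio: tuple[int, int, int] = (2, 2, 1)  # AW : RW : ST
    still_ms: float = 1200.0
    motion_ms: float = 1220.0
    fixation_ms: tuple[float, float] = (1800.0, 2200.0)
    component_params: dict[ComponentKey, ComponentParams] = field(
        default_factory=default_component_params
    )
    latency_slopes: dict[ComponentKey, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_SLOPES)
    )
    amplitude_slopes: dict[ComponentKey, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_SLOPES)
    )
    noise_sd: float = 10.0
    latency_jitter_sd: float = 0.0
    artifact_rate: float = 0.02
    artifact_amplitude_uv: float = 150.0
    artifact_leakage: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.trait_bounds
        if not lo < hi:
            raise ValueError(f"trait_bounds must satisfy lo < hi, got {self.trait_bounds}")
        ratio_sum = sum(self.condition_ratio)
        if self.set_size % ratio_sum != 0:
            raise ValueError(
                f"set_size {self.set_size} not divisible by ratio sum {ratio_sum}"
            )
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.fixation_ms[0] > self.fixation_ms[1]:
            raise ValueError("fixation interval bounds out of order")
        for key, cp in self.component_params.items():
            if cp.width_ms <= 0:
                raise ValueError(f"component {key} has non-positive width")

    @property
    def min_trial_ms(self) -> float:
        """Shortest possible trial: still + motion + minimum fixation."""
        return self.still_ms + self.motion_ms + self.fixation_ms[0]

    @property
    def max_trial_ms(self) -> float:
        return self.still_ms + self.motion_ms + self.fixation_ms[1]

    @property
    def n_trials(self) -> int:
        return self.n_sets * self.set_size

    def condition_counts(self) -> dict[str, int]:
        ratio_sum = sum(self.condition_ratio)
        per_unit = self.n_trials // ratio_sum
        return {c: r * per_unit for c, r in zip(CONDITIONS, self.condition_ratio)}


@dataclass
class TrialSchedule:
    """Ordered trial list with motion-onset samples."""

    trials: pd.DataFrame  # columns: trial_index, condition, onset_sample
    fs: float

    def __post_init__(self) -> None:
        onsets = self.trials["onset_sample"].to_numpy()
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("trial onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def counts(self) -> dict[str, int]:
        vc = self.trials["condition"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CONDITIONS}

    def onsets(self, condition: str | None = None) -> np.ndarray:
        df = self.trials
        if condition is not None:
            df = df[df["condition"] == condition]
        return df["onset_sample"].to_numpy()


@dataclass
class RawRecording:
    """Continuous multi-channel recording with its event table."""

    participant_id: str
    channels: tuple[str, ...]
    data: np.ndarray  # channels x samples, uV
    fs: float
    events: pd.DataFrame  # columns: trial_index, condition, onset_sample, artifact

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples")
        tail = int(round(0.6 * self.fs))
        last = int(self.events["onset_sample"].max()) if len(self.events) else 0
        if last + tail > self.data.shape[1]:
            raise ValueError("record too short: an event window overruns the data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_trait_scores(
    n: int,
    mean: float = 27.77,
    sd: float = 8.02,
    lo: int = 0,
    hi: int = 72,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Integer trait scores from a truncated normal, rounded then clipped."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not lo < hi:
        raise ValueError(f"invalid bounds: lo={lo}, hi={hi}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = _as_rng(seed)
    if sd == 0:
        value = int(np.clip(round(mean), lo, hi))
        return np.full(n, value, dtype=int)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws), lo, hi).astype(int)


def build_trial_schedule(
    config: GenerativeConfig, seed: int | np.random.Generator = 0
) -> TrialSchedule:
    """Shuffle conditions within each set and lay trials out in time.

    Onsets mark the start of the motion interval, i.e. ``still_ms`` after the
    trial begins; inter-onset spacing therefore spans
    ``[min_trial_ms, max_trial_ms]``.
    """
    rng = _as_rng(seed)
    ratio_sum = sum(config.condition_ratio)
    per_unit = config.set_size // ratio_sum
    base = np.repeat(np.array(CONDITIONS), np.array(config.condition_ratio) * per_unit)

    rows = []
    t_ms = 0.0
    index = 0
    for _ in range(config.n_sets):
        order = base.copy()
        rng.shuffle(order)
        for cond in order:
            onset_ms = t_ms + config.still_ms
            rows.append(
                (index, cond, int(round(onset_ms / 1000.0 * config.fs)))
            )
            fixation = rng.uniform(*config.fixation_ms)
            t_ms += config.still_ms + config.motion_ms + fixation
            index += 1
    trials = pd.DataFrame(rows, columns=["trial_index", "condition", "onset_sample"])
    return TrialSchedule(trials=trials, fs=config.fs)


def component_kernel(
    latency_ms: float,
    amplitude_uv: float,
    width_ms: float,
    t_ms: np.ndarray,
) -> np.ndarray:
    """Symmetric unimodal pulse: ``A * exp(-((t - latency)/width)^2)``.

    Peak value equals ``amplitude_uv`` at ``t = latency_ms`` and the pulse has
    decayed below 1% of the peak beyond three widths.
    """
    if width_ms <= 0:
        raise ValueError(f"width must be positive, got {width_ms}")
    t = np.asarray(t_ms, dtype=float)
    return amplitude_uv * np.exp(-(((t - latency_ms) / width_ms) ** 2))


def trial_components(
    trait: float, config: GenerativeConfig, condition: str, electrode: str
) -> list[ComponentParams]:
    """Effective component parameters for one trait value on one channel."""
    out = []
    for comp in COMPONENTS:
        key = (comp, condition, electrode)
        base = config.component_params.get(key)
        if base is None:
            continue
        delta = trait - config.trait_mean
        out.append(
            ComponentParams(
                latency_ms=base.latency_ms + config.latency_slopes.get(key, 0.0) * delta,
                amplitude_uv=base.amplitude_uv
                + config.amplitude_slopes.get(key, 0.0) * delta,
                width_ms=base.width_ms,
            )
        )
    return out


def evoked_waveform(
    trait: float,
    config: GenerativeConfig,
    condition: str,
    electrode: str,
    t_ms: np.ndarray,
) -> np.ndarray:
    """Noiseless composite evoked response injected on one channel.

    This is the ground truth that the extraction pipeline should recover; it
    is the sum of all component kernels active for the given condition and
    electrode at the given trait value.
    """
    t = np.asarray(t_ms, dtype=float)
    wave = np.zeros_like(t)
    for cp in trial_components(trait, config, condition, electrode):
        wave += component_kernel(cp.latency_ms, cp.amplitude_uv, cp.width_ms, t)
    return wave


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Spectrally 1/f-shaped Gaussian noise with the requested sample SD."""
    from scipy.fft import irfft, next_fast_len, rfft

    m = next_fast_len(n)  # pad to an FFT-friendly length, then truncate
    white = rng.standard_normal(m)
    spec = rfft(white)
    freqs = np.fft.rfftfreq(m)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    x = irfft(spec, m)[:n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def synthesize_recording(
    trait: float,
    schedule: TrialSchedule,
    config: GenerativeConfig,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sub-01",
) -> RawRecording:
    """Render one participant's continuous recording from a trial schedule.

    AW/RW trials carry the trait-modulated evoked components on T5/T6; ST
    trials carry background noise only.  A Bernoulli(artifact_rate) subset of
    trials additionally carries a blink-like transient: full amplitude with
    opposite polarity on the two EOG channels and ``artifact_leakage``-scaled
    leakage on every scalp channel.  The event table records the ground-truth
    artifact flag per trial.
    """
    rng = _as_rng(seed)
    fs = config.fs
    n_trials = len(schedule)
    last_onset = int(schedule.trials["onset_sample"].max())
    n_samples = last_onset + int(round(1.0 * fs))

    data = np.zeros((len(CHANNELS), n_samples))
    if config.noise_sd > 0:
        for ch in range(len(CHANNELS)):
            data[ch] += _pink_noise(n_samples, config.noise_sd, rng)

    artifact = rng.random(n_trials) < config.artifact_rate

    # evoked components, rendered over 0..600 ms after each onset
    n_post = int(round(0.6 * fs))
    t_rel = np.arange(n_post) / fs * 1000.0
    for row in schedule.trials.itertuples(index=False):
        if row.condition == "ST":
            continue
        for elec in ANALYSIS_ELECTRODES:
            ch = CHANNELS.index(elec)
            sl = slice(row.onset_sample, row.onset_sample + n_post)
            for cp in trial_components(trait, config, row.condition, elec):
                lat = cp.latency_ms
                if config.latency_jitter_sd > 0:
                    lat += rng.normal(0.0, config.latency_jitter_sd)
                data[ch, sl] += component_kernel(lat, cp.amplitude_uv, cp.width_ms, t_rel)

    # blink-like artifacts spanning the analysis epoch
    n_pre = int(round(0.2 * fs))
    t_blink = np.arange(-n_pre, n_post) / fs * 1000.0
    blink = config.artifact_amplitude_uv * np.exp(-(((t_blink - 200.0) / 100.0) ** 2))
    for row, is_art in zip(schedule.trials.itertuples(index=False), artifact):
        if not is_art:
            continue
        sl = slice(row.onset_sample - n_pre, row.onset_sample - n_pre + len(t_blink))
        data[CHANNELS.index("EOG_upper"), sl] += blink
        data[CHANNELS.index("EOG_lower"), sl] -= blink
        for label in SCALP_CHANNELS:
            data[CHANNELS.index(label), sl] += config.artifact_leakage * blink

    events = schedule.trials.copy()
    events["artifact"] = artifact.astype(int)
    return RawRecording(
        participant_id=participant_id,
        channels=CHANNELS,
        data=data,
        fs=fs,
        events=events,
    )


def simulate_dataset(
    config: GenerativeConfig, seed: int | None = None
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Draw trait scores and synthesize one recording per participant."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.trait_bounds
    traits = generate_trait_scores(
        config.n_participants, config.trait_mean, config.trait_sd, lo, hi, rng
    )
    recordings = []
    rows = []
    for i, trait in enumerate(traits):
        pid = f"sub-{i + 1:02d}"
        schedule = build_trial_schedule(config, rng)
        recordings.append(
            synthesize_recording(float(trait), schedule, config, rng, participant_id=pid)
        )
        rows.append((pid, int(trait)))
    participants = pd.DataFrame(rows, columns=["id", "satq"])
    return recordings, participants


# ---------------------------------------------------------------------------
# columnar on-disk format: per participant a signals TSV (optionally gzipped)
# with a JSON sidecar, plus an events TSV; one shared participants TSV


def write_dataset(
    recordings: Sequence[RawRecording],
    participants: pd.DataFrame,
    out_dir: str | Path,
    decimals: int = 4,
    compress: bool = False,
) -> list[Path]:
    """Write a dataset as columnar text files; returns the written paths.

    Signals are quantized to ``decimals`` decimal places (the round-trip error
    bound is half of ``10**-decimals`` uV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ppath = out / "participants.tsv"
    participants.to_csv(ppath, sep="\t", index=False)
    written.append(ppath)

    if not recordings:
        warnings.warn("no recordings supplied; wrote participants table only")
        return written

    suffix = ".tsv.gz" if compress else ".tsv"
    for rec in recordings:
        sig = out / f"{rec.participant_id}_signals{suffix}"
        pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(
            sig, sep="\t", index=False, float_format=f"%.{decimals}f"
        )
        written.append(sig)

        meta = out / f"{rec.participant_id}_signals.json"
        meta.write_text(
            json.dumps(
                {
                    "participant_id": rec.participant_id,
                    "fs": rec.fs,
                    "channels": list(rec.channels),
                    "n_samples": rec.n_samples,
                    "decimals": decimals,
                    "units": "uV",
                }
            )
        )
        written.append(meta)

        ev = out / f"{rec.participant_id}_events.tsv"
        rec.events.to_csv(ev, sep="\t", index=False)
        written.append(ev)
    return written


def read_dataset(data_dir: str | Path) -> tuple[list[RawRecording], pd.DataFrame]:
    """Inverse of :func:`write_dataset`."""
    data_dir = Path(data_dir)
    participants = pd.read_csv(data_dir / "participants.tsv", sep="\t")
    recordings = []
    for pid in participants["id"]:
        meta = json.loads((data_dir / f"{pid}_signals.json").read_text())
        sig = None
        for suffix in (".tsv", ".tsv.gz"):
            cand = data_dir / f"{pid}_signals{suffix}"
            if cand.exists():
                sig = cand
                break
        if sig is None:
            raise FileNotFoundError(f"no signals file for participant {pid}")
        frame = pd.read_csv(sig, sep="\t")
        events = pd.read_csv(data_dir / f"{pid}_events.tsv", sep="\t")
        recordings.append(
            RawRecording(
                participant_id=str(meta["participant_id"]),
                channels=tuple(meta["channels"]),
                data=frame[meta["channels"]].to_numpy().T,
                fs=float(meta["fs"]),
                events=events,
            )
        )
    return recordings, participants
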