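"""Synthetic multi-patient EEG cohorts with seizure annotations.

The generator produces the statistical structure the detection pipeline
relies on, without claiming physiological fidelity:

* background activity = 1/f-shaped ("pink") noise plus an alpha-band
  oscillation, scaled to a typical scalp-EEG amplitude, with intermittent
  high-amplitude non-ictal bursts (background nonstationarity, so that
  total power alone does not separate the classes and classifiers must
  use the spectral signature);
* ictal activity = an added spike-wave train at ``ictal_freq_hz`` (a
  fundamental with 2nd/3rd harmonics and an exponential per-cycle spike
  envelope), scaled relative to the background RMS by ``ictal_amp_gain``;
* inter-patient variability = per-patient jitter of the ictal frequency,
  amplitude gain, alpha frequency and noise scale.

Two export shapes are supported: continuous annotated recordings
(long files with seizure intervals inside them) and pre-segmented
fixed-length labeled clips (healthy vs seizure signals).

Everything is reproducible from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Recording, SeizureInterval, ValidationError

__all__ = [
    "PatientSignature",
    "SyntheticConfig",
    "generate_recording",
    "generate_cohort",
    "draw_signatures",
    "draw_seizure_intervals",
    "presegment_recording",
]

#: baseline scalp-EEG RMS, microvolts, multiplied by PatientSignature.noise_scale
BACKGROUND_RMS_UV = 30.0

#: relative amplitude of the alpha oscillation within the background mix
ALPHA_REL_AMP = 0.7

#: minimum gap between consecutive seizure intervals, seconds
MIN_GAP_S = 1.0


@dataclass(frozen=True)
class PatientSignature:
    """Per-patient spectral signature of background and ictal activity."""

    patient_id: str
    ictal_freq_hz: float = 3.0
    ictal_amp_gain: float = 4.0
    background_alpha_hz: float = 10.0
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.ictal_freq_hz <= 0:
            raise ValidationError("ictal_freq_hz must be positive")
        if self.ictal_amp_gain < 1.0:
            raise ValidationError("ictal_amp_gain must be >= 1 (1 = no added amplitude)")
        if self.noise_scale <= 0:
            raise ValidationError("noise_scale must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation settings."""

    n_patients: int = 4
    n_channels: int = 8
    fs: float = 256.0
    duration_s: float = 600.0
    seizure_fraction: float = 0.25
    seed: int = 0
    freq_jitter_hz: float = 0.3
    min_seizure_s: float = 10.0
    burst_fraction: float = 0.15

    def __post_init__(self):
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.n_channels < 1:
            raise ValidationError("need at least one channel")
        if not 0.0 < self.seizure_fraction < 1.0:
            raise ValidationError("seizure_fraction must be in (0, 1)")
        if self.freq_jitter_hz < 0:
            raise ValidationError("freq_jitter_hz must be >= 0")
        if not 0.0 <= self.burst_fraction < 0.5:
            raise ValidationError("burst_fraction must be in [0, 0.5)")


def draw_seizure_intervals(rng: np.random.Generator, duration_s: float,
                           seizure_fraction: float,
                           min_len_s: float = 10.0) -> list[SeizureInterval]:
    """Place non-overlapping seizure intervals uniformly at random.

    Interval lengths are drawn uniformly in [min_len_s, 4*min_len_s] until
    the summed length reaches ``seizure_fraction * duration_s`` (the last
    draw is trimmed toward the target but never below min_len_s), then the
    intervals are dropped into the recording with at least MIN_GAP_S
    between them and the edges.
    """
    target = seizure_fraction * duration_s
    durations: list[float] = []
    total = 0.0
    while total < target:
        d = float(rng.uniform(min_len_s, 4.0 * min_len_s))
        if total + d > target:
            d = max(min_len_s, target - total)
        durations.append(d)
        total += d
    k = len(durations)
    free = duration_s - total - (k + 1) * MIN_GAP_S
    if free < 0:
        raise ValidationError(
            f"cannot fit {total:.1f}s of seizures (+gaps) into {duration_s:.1f}s"
        )
    gaps = MIN_GAP_S + rng.dirichlet(np.ones(k + 1)) * free
    intervals = []
    t = 0.0
    for d, g in zip(durations, gaps[:-1]):
        t += g
        intervals.append(SeizureInterval(t, t + d))
        t += d
    return intervals


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _spike_wave(t: np.ndarray, freq_hz: float, phase: float, fs: float) -> np.ndarray:
    """Unit-RMS spike-wave train: fundamental + harmonics + sharpened spike."""
    w = np.sin(2 * np.pi * freq_hz * t + phase)
    for h, a in ((2, 0.5), (3, 0.25)):
        if h * freq_hz < fs / 2.0:
            w = w + a * np.sin(2 * np.pi * h * freq_hz * t + h * phase)
    spike = np.exp(2.0 * (np.cos(2 * np.pi * freq_hz * t + phase) - 1.0))
    spike = spike - spike.mean()
    w = w + 1.5 * spike
    return w / w.std()


def generate_recording(signature: PatientSignature, config: SyntheticConfig,
                       seed: int,
                       intervals: list[SeizureInterval] | None = None) -> Recording:
    """Synthesize one annotated recording for one patient.

    If ``intervals`` is None, seizure intervals are drawn from the config's
    seizure_fraction; otherwise the given intervals are injected verbatim
    (they must fit inside the recording).
    """
    if config.fs <= 2.0 * signature.ictal_freq_hz:
        raise ValidationError(
            f"fs={config.fs} must exceed twice the ictal frequency "
            f"{signature.ictal_freq_hz} Hz"
        )
    rng = np.random.default_rng(seed)
    n = int(round(config.duration_s * config.fs))
    fs = config.fs
    if intervals is None:
        intervals = draw_seizure_intervals(
            rng, config.duration_s, config.seizure_fraction, config.min_seizure_s
        )
    else:
        for iv in intervals:
            if iv.duration_s > config.duration_s or iv.end_s > config.duration_s:
                raise ValidationError(f"interval {iv} does not fit in the recording")
        intervals = sorted(intervals, key=lambda iv: iv.start_s)

    t = np.arange(n) / fs
    envelope = _burst_envelope(rng, n, fs, config.duration_s, config.burst_fraction)
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        pink = _pink_noise(rng, n, fs)
        phase = rng.uniform(0, 2 * np.pi)
        alpha = ALPHA_REL_AMP * np.sin(2 * np.pi * signature.background_alpha_hz * t + phase)
        bg = pink + alpha
        ch_env = 1.0 + (envelope - 1.0) * rng.uniform(0.9, 1.1)
        data[c] = BACKGROUND_RMS_UV * signature.noise_scale * ch_env * bg / bg.std()

    amp = (signature.ictal_amp_gain - 1.0)
    if amp > 0:
        for iv in intervals:
            i0 = int(round(iv.start_s * fs))
            i1 = min(int(round(iv.end_s * fs)), n)
            seg_t = t[i0:i1]
            phase0 = rng.uniform(0, 2 * np.pi)
            ramp = _edge_ramp(i1 - i0, fs)
            wave = _spike_wave(seg_t, signature.ictal_freq_hz, phase0, fs)
            for c in range(config.n_channels):
                ch_gain = rng.uniform(0.8, 1.2)
                data[c, i0:i1] += (
                    amp * BACKGROUND_RMS_UV * signature.noise_scale * ch_gain * ramp * wave
                )

    return Recording(
        patient_id=signature.patient_id,
        channel_labels=[f"CH{c + 1:02d}" for c in range(config.n_channels)],
        data=data,
        fs=fs,
        annotations=list(intervals),
        source_path="synthetic",
    )


def _burst_envelope(rng: np.random.Generator, n: int, fs: float,
                    duration_s: float, burst_fraction: float) -> np.ndarray:
    """Multiplicative amplitude envelope with intermittent non-ictal bursts.

    Covers roughly ``burst_fraction`` of the recording with episodes of
    2-4x background amplitude (5-20 s long, cosine-ramped), placed
    independently of the seizure intervals.  Real scalp EEG shows this
    kind of nonstationarity; without it, total window power alone would
    separate ictal from background windows.
    """
    env = np.ones(n)
    if burst_fraction <= 0:
        return env
    bursts = draw_seizure_intervals(rng, duration_s, burst_fraction, min_len_s=5.0)
    for b in bursts:
        i0 = int(round(b.start_s * fs))
        i1 = min(int(round(b.end_s * fs)), n)
        if i1 <= i0:
            continue
        factor = rng.uniform(2.0, 4.0)
        env[i0:i1] = np.maximum(
            env[i0:i1], 1.0 + (factor - 1.0) * _edge_ramp(i1 - i0, fs)
        )
    return env


def _edge_ramp(n: int, fs: float, ramp_s: float = 1.0) -> np.ndarray:
    """Cosine on/off ramp so seizure onsets are not step discontinuities."""
    ramp = np.ones(n)
    m = min(int(round(ramp_s * fs)), n // 2)
    if m > 0:
        edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(m) / m))
        ramp[:m] = edge
        ramp[n - m:] = edge[::-1]
    return ramp


def draw_signatures(config: SyntheticConfig,
                    base_freq_hz: float = 3.0) -> list[PatientSignature]:
    """Draw per-patient signatures reproducibly from the cohort seed."""
    rng = np.random.default_rng(config.seed)
    sigs = []
    for i in range(config.n_patients):
        j = config.freq_jitter_hz
        sigs.append(
            PatientSignature(
                patient_id=f"P{i + 1:02d}",
                ictal_freq_hz=base_freq_hz + (rng.uniform(-j, j) if j > 0 else 0.0),
                ictal_amp_gain=float(np.clip(4.0 + rng.uniform(-0.5, 0.5), 1.5, None)),
                background_alpha_hz=float(rng.uniform(9.0, 11.0)),
                noise_scale=float(rng.uniform(0.8, 1.25)),
            )
        )
    return sigs


def generate_cohort(config: SyntheticConfig,
                    signatures: list[PatientSignature] | None = None,
                    ) -> list[tuple[Recording, PatientSignature]]:
    """One recording per patient; signatures drawn from the cohort seed.

    Passing explicit ``signatures`` (e.g. with the target patient's ictal
    frequency shifted out of distribution) overrides the drawn ones.
    """
    if config.n_patients < 2:
        raise ValidationError("a cohort needs at least 2 patients")
    if signatures is None:
        signatures = draw_signatures(config)
    elif len(signatures) != config.n_patients:
        raise ValidationError("one signature per patient required")
    rng = np.random.default_rng(config.seed)
    seeds = [int(s) for s in rng.integers(0, 2 ** 31, size=config.n_patients)]
    return [
        (generate_recording(sig, config, seeds[i]), sig)
        for i, sig in enumerate(signatures)
    ]


def presegment_recording(recording: Recording, segment_s: float = 8.0
                         ) -> list[tuple[np.ndarray, int]]:
    """Export non-overlapping fixed-length labeled clips.

    Emulates pre-segmented datasets (separate healthy vs seizure signals):
    a clip is labeled 1 if it lies entirely inside a seizure interval, 0 if
    entirely outside; boundary-straddling clips are dropped.
    """
    n_seg = int(round(segment_s * recording.fs))
    clips = []
    n_windows = recording.n_samples // n_seg
    for i in range(n_windows):
        a = i * n_seg / recording.fs
        b = a + segment_s
        inside = any(iv.start_s <= a and b <= iv.end_s for iv in recording.annotations)
        outside = all(b <= iv.start_s or a >= iv.end_s for iv in recording.annotations)
        if inside:
            label = 1
        elif outside:
            label = 0
        else:
            continue
        clips.append((recording.data[:, i * n_seg:(i + 1) * n_seg].copy(), label))
    return clips
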