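"""Signal conditioning: normalization, sliding windows, STFT spectrograms.

The chain mirrors the detection pipeline's front end: each recording is
z-scored per channel, cut into overlapping fixed-length windows (default
8 s with a 4 s step), each window is labeled from its overlap with the
annotated seizure intervals, and each window is turned into a
single-channel time-frequency image.

The short-time Fourier transform follows

    X(t, k) = sum_n x[n] w[n - tR] exp(-2*pi*i*k*n / N)

with the *absolute* sample index n in the complex exponential, so each
frame carries a phase factor exp(-2*pi*i*k*tR/N) relative to a plain
per-frame FFT; magnitudes (and hence spectrograms S = |X|^2) are
unaffected.  The taper is the symmetric Hann window

    w[n] = (1 - cos(2*pi*n / (N-1))) / 2,   0 <= n <= N-1.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    Recording,
    SeizureInterval,
    SpectrogramImage,
    StftParams,
    ValidationError,
    WindowSegment,
)

__all__ = [
    "normalize",
    "segment",
    "hann_window",
    "stft",
    "spectrogram",
    "overlap_seconds",
]


def normalize(recording: Recording) -> Recording:
    """Z-score each channel independently (population standard deviation).

    Zero-variance channels map to all zeros.  Annotations and metadata are
    carried over unchanged.  Idempotent on already-normalized data.
    """
    if not np.all(np.isfinite(recording.data)):
        raise ValidationError(
            f"recording {recording.patient_id!r} contains NaN/Inf samples"
        )
    if recording.n_samples < 2:
        raise ValidationError("need at least 2 samples per channel to normalize")
    mean = recording.data.mean(axis=1, keepdims=True)
    std = recording.data.std(axis=1, keepdims=True)  # population std (ddof=0)
    out = np.where(std > 0, (recording.data - mean) / np.where(std > 0, std, 1.0), 0.0)
    return Recording(
        patient_id=recording.patient_id,
        channel_labels=list(recording.channel_labels),
        data=out,
        fs=recording.fs,
        annotations=list(recording.annotations),
        source_path=recording.source_path,
    )


def overlap_seconds(start_s: float, end_s: float,
                    intervals: list[SeizureInterval]) -> float:
    """Length of [start_s, end_s) covered by the union of the intervals.

    Intervals are treated as half-open and assumed non-overlapping (the
    parsers and the generator guarantee that).
    """
    total = 0.0
    for iv in intervals:
        total += max(0.0, min(end_s, iv.end_s) - max(start_s, iv.start_s))
    return total


def segment(recording: Recording, window_s: float = 8.0, step_s: float = 4.0,
            label_threshold: float = 0.5, on_short: str = "warn"
            ) -> list[WindowSegment]:
    """Cut sliding windows and label them from the seizure annotations.

    Windows start at 0, step_s, 2*step_s, ...; the count obeys
    floor((T - W)/S) + 1 in samples.  A window is labeled 1 iff the
    fraction of it inside the annotated seizure union is at least
    ``label_threshold``.

    ``on_short``: behaviour when the window is longer than the recording —
    "warn" returns an empty list with a warning, "error" raises.
    """
    if step_s <= 0:
        raise ValidationError("step_s must be positive")
    if not 0.0 < label_threshold <= 1.0:
        raise ValidationError("label_threshold must be in (0, 1]")
    n_win = int(round(window_s * recording.fs))
    n_step = int(round(step_s * recording.fs))
    if n_win < 1 or n_step < 1:
        raise ValidationError("window and step must be at least one sample")
    if n_win > recording.n_samples:
        msg = (f"window of {window_s}s exceeds recording duration "
               f"{recording.duration_s:.2f}s")
        if on_short == "error":
            raise ValidationError(msg)
        warnings.warn(msg)
        return []
    n_windows = (recording.n_samples - n_win) // n_step + 1
    out = []
    for i in range(n_windows):
        i0 = i * n_step
        start_s = i0 / recording.fs
        ov = overlap_seconds(start_s, start_s + window_s, recording.annotations)
        frac = ov / window_s
        out.append(
            WindowSegment(
                data=recording.data[:, i0:i0 + n_win],
                label=int(frac >= label_threshold),
                patient_id=recording.patient_id,
                start_s=start_s,
                overlap_fraction=frac,
                fs=recording.fs,
            )
        )
    return out


def hann_window(N: int) -> np.ndarray:
    """Symmetric Hann taper w[n] = (1 - cos(2*pi*n/(N-1)))/2, n = 0..N-1.

    N = 1 returns [0.0] by the formula's cos(0) = 1 limit convention.
    """
    if N <= 0:
        raise ValidationError("window length must be positive")
    if N == 1:
        return np.zeros(1)
    n = np.arange(N)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (N - 1)))


def stft(x: np.ndarray, params: StftParams) -> np.ndarray:
    """Short-time Fourier transform of a 1-D signal.

    Returns the complex matrix [n_frames, N] with
    n_frames = floor((len(x) - N)/R) + 1 and the absolute-index phase
    convention described in the module docstring.  Computed with an FFT
    per frame times the frame phase factor; equals the direct double
    summation to ~1e-12 relative error.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("stft expects a 1-D signal")
    N, R = params.N, params.R
    if x.size < N:
        raise ValidationError(f"signal length {x.size} shorter than segment N={N}")
    w = hann_window(N)
    n_frames = (x.size - N) // R + 1
    s0 = x.strides[0]
    frames = np.lib.stride_tricks.as_strided(x, (n_frames, N), (R * s0, s0))
    X = np.fft.fft(frames * w, axis=1)
    k = np.arange(N)
    starts = np.arange(n_frames) * R
    phase = np.exp(-2j * np.pi * np.outer(starts, k) / N)
    return X * phase


def spectrogram(seg: WindowSegment, params: StftParams,
                collapse: str = "mean", log_scaled: bool = True
                ) -> SpectrogramImage:
    """Squared-magnitude STFT of a window, collapsed to one 2-D image.

    Per channel S(t, k) = |X(t, k)|^2, one-sided bins k = 0..N/2 kept.
    ``collapse`` = "mean" averages per-channel power; "stack" concatenates
    the per-channel images along the frequency axis.  With ``log_scaled``
    values become log(1 + S) (dynamic-range compression for the
    classifiers; leave off for spectral analysis).
    """
    if collapse not in ("mean", "stack"):
        raise ValidationError(f"unknown collapse mode {collapse!r}")
    N, R = params.N, params.R
    n_keep = N // 2 + 1
    powers = []
    for c in range(seg.data.shape[0]):
        X = stft(seg.data[c], params)
        powers.append(np.abs(X[:, :n_keep]) ** 2)
    P = np.stack(powers)  # [C, n_frames, n_keep]
    if collapse == "mean":
        img = P.mean(axis=0).T  # [freq, time]
        freq_axis = np.arange(n_keep) * seg.fs / N
    else:
        img = np.concatenate([p.T for p in P], axis=0)
        freq_axis = np.tile(np.arange(n_keep) * seg.fs / N, seg.data.shape[0])
    if log_scaled:
        img = np.log1p(img)
    n_frames = img.shape[1]
    starts = np.arange(n_frames) * R
    time_axis = seg.start_s + (starts + N / 2.0) / seg.fs
    return SpectrogramImage(
        values=img,
        freq_axis=freq_axis,
        time_axis=time_axis,
        log_scaled=log_scaled,
        channel_collapse=collapse,
    )
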