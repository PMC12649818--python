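"""Shared domain types for the seizure-detection pipeline.

Times are seconds from recording start; annotation intervals are half-open
[start_s, end_s).  Signal data is microvolts in [n_channels, n_samples]
layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its expected format."""


@dataclass(frozen=True)
class SeizureInterval:
    """Half-open annotated seizure interval [start_s, end_s), in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if self.start_s < 0:
            raise ValidationError(f"interval start {self.start_s} < 0")
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"interval end {self.end_s} must exceed start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """Multichannel EEG recording with seizure annotations."""

    patient_id: str
    channel_labels: list[str]
    data: np.ndarray  # [n_channels, n_samples], microvolts
    fs: float
    annotations: list[SeizureInterval] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be [n_channels, n_samples]")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        for iv in self.annotations:
            if iv.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"annotation {iv} extends past recording end {self.duration_s:.3f}s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class WindowSegment:
    """Fixed-duration multichannel slice with a binary seizure label."""

    data: np.ndarray  # [n_channels, n_window_samples]
    label: int
    patient_id: str
    start_s: float
    overlap_fraction: float
    fs: float

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError("label must be 0 or 1")


@dataclass
class SpectrogramImage:
    """Single-channel 2-D time-frequency array fed to the classifiers."""

    values: np.ndarray  # [n_freq_bins, n_frames]
    freq_axis: np.ndarray  # Hz per bin
    time_axis: np.ndarray  # seconds per frame (window centers)
    log_scaled: bool = False
    channel_collapse: str = "mean"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("spectrogram must be 2-D [freq, time]")
        if not self.log_scaled and np.any(self.values < 0):
            raise ValidationError("power spectrogram must be non-negative")


@dataclass(frozen=True)
class StftParams:
    """Short-time Fourier transform parameters, in samples.

    N: analysis segment length; R: hop between consecutive frames.
    The taper is the symmetric Hann window of length N.
    """

    N: int
    R: int

    def __post_init__(self):
        if self.N < 1:
            raise ValidationError("segment length N must be >= 1")
        if not 0 < self.R <= self.N:
            raise ValidationError("hop R must satisfy 0 < R <= N")
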