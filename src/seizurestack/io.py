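"""I/O for the formats the pipeline touches.

* EDF recordings — read through mne; a minimal 16-bit EDF writer is
  provided for exporting synthetic fixtures (integer sampling rates,
  one-second data records).
* Seizure annotations — plain-text TSV, one `file_name<TAB>start_s<TAB>end_s`
  row per interval, `#` comments allowed; and the summary dialect used by
  the CHB-MIT scalp EEG corpus (`File Name:` / `Number of Seizures in
  File:` / `Seizure [i ]Start/End Time:` blocks).
* The on-disk spectrogram dataset — a directory with a JSON manifest, a
  JSON-lines index and one compressed array file per item.

Parsers never silently drop malformed rows; every rejection names its
location.  All annotation times are seconds from recording start,
half-open [start_s, end_s).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import (
    FormatError,
    Recording,
    SeizureInterval,
    SpectrogramImage,
    ValidationError,
)

__all__ = [
    "AnnotationSet",
    "SpectrogramDataset",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "parse_chbmit_summary",
    "save_dataset",
    "load_dataset",
]


@dataclass
class AnnotationSet:
    """Map from recording file name to sorted, non-overlapping intervals."""

    by_file: dict[str, list[SeizureInterval]] = field(default_factory=dict)

    def __post_init__(self):
        for name, ivs in self.by_file.items():
            ivs.sort(key=lambda iv: iv.start_s)
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s:
                    raise ValidationError(
                        f"overlapping intervals for {name}: {a} and {b}"
                    )

    def for_file(self, name: str) -> list[SeizureInterval]:
        return self.by_file.get(name, [])


@dataclass
class SpectrogramDataset:
    """In-memory spectrogram dataset: images + labels + provenance.

    ``manifest`` records the preprocessing configuration (window_s, step_s,
    fs, STFT N/R, transform flags) so that training and evaluation can
    refuse incompatible inputs.
    """

    images: list[SpectrogramImage]
    labels: np.ndarray
    patient_ids: list[str]
    window_starts: np.ndarray
    manifest: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.window_starts = np.asarray(self.window_starts, dtype=np.float64)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary")
        n_bins = {img.values.shape[0] for img in self.images}
        if len(n_bins) > 1:
            raise ValidationError(f"inconsistent frequency-bin counts {n_bins}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "SpectrogramDataset":
        idx = np.asarray(idx)
        return SpectrogramDataset(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            window_starts=self.window_starts[idx],
            manifest=dict(self.manifest),
        )

    def stacked(self) -> np.ndarray:
        """All images as one [n, freq, time] array (shapes must agree)."""
        return np.stack([img.values for img in self.images])


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf_header(path: Path) -> tuple[int, list[float], float]:
    """Parse just enough of an EDF header to get per-signal rates."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_s = float(fixed[244:252].decode("ascii").strip())
            ns = int(fixed[252:256].decode("ascii").strip())
        except ValueError as e:
            raise FormatError(f"{path}: malformed EDF header: {e}") from e
        sig = fh.read(ns * 256)
        if len(sig) < ns * 256:
            raise FormatError(f"{path}: truncated EDF signal headers")
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = []
    for i in range(ns):
        raw = sig[off + i * 8: off + (i + 1) * 8].decode("ascii").strip()
        rates.append(int(raw) / record_s)
    return ns, rates, record_s


def read_edf(path, resample: bool = False) -> Recording:
    """Read all signal channels of an EDF file into a Recording.

    Channels with differing sampling rates are rejected unless
    ``resample`` is set, in which case they are brought to the highest
    rate.  Annotations are left empty; attach them separately from an
    AnnotationSet.  Amplitudes are returned in microvolts.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"EDF file not found: {path}")
    _, rates, _ = _read_edf_header(path)
    data_rates = [r for r in rates if r > 0]
    if len(set(data_rates)) > 1 and not resample:
        raise FormatError(
            f"{path}: mixed sampling rates {sorted(set(data_rates))}; "
            "pass resample=True to unify"
        )
    import mne  # deferred: mne import is slow

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        patient_id=path.stem,
        channel_labels=list(raw.ch_names),
        data=data,
        fs=float(raw.info["sfreq"]),
        annotations=[],
        source_path=str(path),
    )


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as a minimal 16-bit EDF file.

    Supports integer sampling rates and whole-second durations (the
    synthetic generator's output); one-second data records, per-channel
    physical scaling over the data range.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    if recording.n_samples % spr:
        raise ValidationError("EDF writer requires a whole number of seconds")
    n_records = recording.n_samples // spr
    ns = recording.n_channels

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    pmins = recording.data.min(axis=1)
    pmaxs = recording.data.max(axis=1)
    pmaxs = np.where(pmaxs - pmins < 1e-9, pmins + 1.0, pmaxs)
    dmin, dmax = -32768, 32767

    header = b"".join([
        f("0", 8),
        f(recording.patient_id, 80),
        f("seizurestack export", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(256 * (ns + 1)), 8),
        f("", 44),
        f(str(n_records), 8),
        f("1", 8),
        f(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(f(lbl, 16) for lbl in recording.channel_labels),
        b"".join(f("", 80) for _ in range(ns)),
        b"".join(f("uV", 8) for _ in range(ns)),
        b"".join(f(f"{pmins[i]:.8g}"[:8], 8) for i in range(ns)),
        b"".join(f(f"{pmaxs[i]:.8g}"[:8], 8) for i in range(ns)),
        b"".join(f(str(dmin), 8) for _ in range(ns)),
        b"".join(f(str(dmax), 8) for _ in range(ns)),
        b"".join(f("", 80) for _ in range(ns)),
        b"".join(f(str(spr), 8) for _ in range(ns)),
        b"".join(f("", 32) for _ in range(ns)),
    ])
    scale = (dmax - dmin) / (pmaxs - pmins)
    digital = np.round((recording.data - pmins[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            for c in range(ns):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> AnnotationSet:
    """Parse a seizure-annotation TSV: file_name<TAB>start_s<TAB>end_s."""
    path = Path(path)
    by_file: dict[str, list[SeizureInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            name, s_raw, e_raw = parts
            try:
                start, end = float(s_raw), float(e_raw)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-numeric interval: {e}") from e
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} <= start {start}"
                )
            by_file.setdefault(name, []).append(SeizureInterval(start, end))
    return AnnotationSet(by_file)


def write_annotations(annset: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# file_name\tstart_s\tend_s\n")
        for name in sorted(annset.by_file):
            for iv in annset.by_file[name]:
                fh.write(f"{name}\t{iv.start_s:g}\t{iv.end_s:g}\n")


_CHB_FILE = re.compile(r"^File Name:\s*(\S+)")
_CHB_COUNT = re.compile(r"^Number of Seizures in File:\s*(\d+)")
_CHB_START = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec")
_CHB_END = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec")


def parse_chbmit_summary(path) -> AnnotationSet:
    """Parse a CHB-MIT `chbXX-summary.txt` file into an AnnotationSet.

    Every `File Name:` block is covered; files with zero seizures map to
    empty lists.  A declared seizure count that disagrees with the parsed
    start/end pairs raises a validation error naming the block.
    """
    path = Path(path)
    by_file: dict[str, list[SeizureInterval]] = {}
    current: str | None = None
    declared: dict[str, int] = {}
    starts: list[float] = []
    ends: list[float] = []

    def close_block():
        nonlocal starts, ends
        if current is None:
            return
        if len(starts) != len(ends):
            raise ValidationError(
                f"{path}: block {current}: {len(starts)} start times "
                f"but {len(ends)} end times"
            )
        n = declared.get(current)
        if n is not None and n != len(starts):
            raise ValidationError(
                f"{path}: block {current}: declares {n} seizures "
                f"but lists {len(starts)}"
            )
        by_file[current] = [SeizureInterval(s, e) for s, e in zip(starts, ends)]
        starts, ends = [], []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            m = _CHB_FILE.match(line)
            if m:
                close_block()
                current = m.group(1)
                continue
            m = _CHB_COUNT.match(line)
            if m and current is not None:
                declared[current] = int(m.group(1))
                continue
            m = _CHB_START.match(line)
            if m and current is not None:
                starts.append(float(m.group(1)))
                continue
            m = _CHB_END.match(line)
            if m and current is not None:
                ends.append(float(m.group(1)))
    close_block()
    return AnnotationSet(by_file)


# ---------------------------------------------------------------------------
# spectrogram dataset container
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.json"
_INDEX = "index.jsonl"


def save_dataset(ds: SpectrogramDataset, path) -> None:
    """Write a dataset directory: manifest + index + one .npz per item."""
    root = Path(path)
    (root / "items").mkdir(parents=True, exist_ok=True)
    manifest = dict(ds.manifest)
    manifest["n_items"] = len(ds)
    if len(ds):
        manifest["n_freq_bins"] = int(ds.images[0].values.shape[0])
    with open(root / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(root / _INDEX, "w") as fh:
        for i, img in enumerate(ds.images):
            rel = f"items/item_{i:06d}.npz"
            np.savez_compressed(
                root / rel,
                values=img.values,
                freq_axis=img.freq_axis,
                time_axis=img.time_axis,
            )
            fh.write(json.dumps({
                "file": rel,
                "label": int(ds.labels[i]),
                "patient_id": ds.patient_ids[i],
                "window_start_s": float(ds.window_starts[i]),
                "log_scaled": bool(img.log_scaled),
                "channel_collapse": img.channel_collapse,
            }) + "\n")


def load_dataset(path) -> SpectrogramDataset:
    root = Path(path)
    mpath = root / _MANIFEST
    if not mpath.is_file():
        raise FormatError(f"{root}: missing {_MANIFEST}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    images, labels, pids, starts = [], [], [], []
    ipath = root / _INDEX
    if not ipath.is_file():
        raise FormatError(f"{root}: missing {_INDEX}")
    with open(ipath) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            row = json.loads(line)
            with np.load(root / row["file"]) as z:
                img = SpectrogramImage(
                    values=z["values"],
                    freq_axis=z["freq_axis"],
                    time_axis=z["time_axis"],
                    log_scaled=row["log_scaled"],
                    channel_collapse=row["channel_collapse"],
                )
            images.append(img)
            labels.append(row["label"])
            pids.append(row["patient_id"])
            starts.append(row["window_start_s"])
    n_expected = manifest.get("n_items")
    if n_expected is not None and n_expected != len(images):
        raise FormatError(
            f"{root}: manifest declares {n_expected} items, index has {len(images)}"
        )
    if images and "n_freq_bins" in manifest:
        if images[0].values.shape[0] != manifest["n_freq_bins"]:
            raise FormatError(f"{root}: frequency-bin count disagrees with manifest")
    return SpectrogramDataset(
        images=images,
        labels=np.asarray(labels),
        patient_ids=pids,
        window_starts=np.asarray(starts),
        manifest=manifest,
    )
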