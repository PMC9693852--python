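"""EEG preprocessing: EDF input, resampling, zero-phase bandpass, epoching.

The staging pipeline fixes the order resample -> bandpass -> segment: any
input rate is first brought to the common 256 Hz grid, the common-rate data
is bandpassed to the 0.3-35 Hz scoring band with a zero-phase (forward-
backward Butterworth) filter, and the record is then cut into consecutive
non-overlapping 30-s epochs of 7680 samples.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .stages import Stage, N_STAGES, EPOCH_SAMPLES, TARGET_FS

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecord",
    "FilterSpec",
    "SleepEpoch",
    "EpochDataset",
    "read_edf",
    "read_labels_csv",
    "resample_to_256",
    "bandpass_zero_phase",
    "segment_epochs",
    "write_epoch_manifest",
    "preprocess_record",
]


@dataclass(frozen=True)
class EEGRecord:
    """A continuous single-channel EEG signal in microvolts."""

    samples: np.ndarray
    fs: float
    channel: str = "EEG"

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise ValueError("samples must be a 1-D series")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth bandpass specification (0.3-35 Hz default)."""

    low_hz: float = 0.3
    high_hz: float = 35.0
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )

    def gain_at(self, freq_hz: float, fs: float) -> float:
        """Magnitude response of the forward-backward (squared) filter."""
        _, h = sps.sosfreqz(self.sos(fs), worN=[freq_hz], fs=fs)
        return float(np.abs(h[0]) ** 2)


@dataclass(frozen=True)
class SleepEpoch:
    """One 30-s epoch: 7680 samples at 256 Hz, plus label and provenance."""

    samples: np.ndarray
    label: int | None
    source_index: int
    sample_span: tuple[int, int]

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.size != EPOCH_SAMPLES:
            raise ValueError(f"epoch must have exactly {EPOCH_SAMPLES} samples, got {s.size}")
        start, end = self.sample_span
        if end - start != EPOCH_SAMPLES:
            raise ValueError("sample_span width must equal the epoch length")
        object.__setattr__(self, "samples", s)


@dataclass
class EpochDataset:
    """An ordered collection of labeled sleep epochs."""

    epochs: list[SleepEpoch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs if e.label is not None], dtype=np.int64)

    @property
    def class_counts(self) -> np.ndarray:
        counts = np.zeros(N_STAGES, dtype=np.int64)
        for e in self.epochs:
            if e.label is not None:
                counts[e.label] += 1
        return counts

    def waveforms(self) -> np.ndarray:
        return np.stack([e.samples for e in self.epochs])


def read_edf(path: str | os.PathLike, channel: str | None = None) -> EEGRecord:
    """Read a single signal from an EDF file into an :class:`EEGRecord`."""
    from ._edf import read_edf_signal

    samples, fs, label = read_edf_signal(path, channel=channel)
    return EEGRecord(samples=samples, fs=fs, channel=label)


def read_labels_csv(path: str | os.PathLike) -> np.ndarray:
    """Read per-epoch stage labels as (epoch_index, stage) CSV.

    Returns an int array ordered by epoch index.  Rows must cover indices
    0..n-1 exactly once.
    """
    rows: dict[int, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("epoch_index", ""):
                continue
            idx = int(row[0])
            if idx in rows:
                raise ValueError(f"duplicate epoch index {idx} in {path}")
            rows[idx] = int(Stage.from_string(row[1]))
    if not rows:
        return np.empty(0, dtype=np.int64)
    n = max(rows) + 1
    if sorted(rows) != list(range(n)):
        raise ValueError(f"label file {path} has gaps in epoch indices")
    return np.array([rows[i] for i in range(n)], dtype=np.int64)


def resample_to_256(record: EEGRecord) -> EEGRecord:
    """Polyphase-resample a record to the common 256 Hz rate.

    No-op when the record is already at 256 Hz.  Duration is preserved to
    within one sample.
    """
    if record.fs == TARGET_FS:
        return record
    frac = Fraction(TARGET_FS) / Fraction(record.fs).limit_denominator(1_000_000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(record.samples, up, down)
    return EEGRecord(samples=out, fs=float(TARGET_FS), channel=record.channel)


def bandpass_zero_phase(record: EEGRecord, spec: FilterSpec | None = None) -> EEGRecord:
    """Apply the zero-phase scoring-band filter (forward-backward)."""
    spec = spec or FilterSpec()
    sos = spec.sos(record.fs)
    out = sps.sosfiltfilt(sos, record.samples)
    return EEGRecord(samples=out, fs=record.fs, channel=record.channel)


def segment_epochs(
    record: EEGRecord,
    labels: np.ndarray | None = None,
    on_missing_label: str = "drop",
) -> EpochDataset:
    """Cut a 256 Hz record into consecutive non-overlapping 30-s epochs.

    Epoch i spans samples [i*7680, (i+1)*7680); a trailing partial epoch is
    discarded with a warning.  ``labels`` (one stage code per epoch) are
    attached by index.  A label count that does not match the number of full
    epochs is an error, except that labels for the discarded tail epoch are
    tolerated.  ``on_missing_label`` controls epochs whose label is the
    sentinel -1: "drop" (default, with warning) or "error".
    """
    if record.fs != TARGET_FS:
        raise ValueError(f"segment_epochs requires fs={TARGET_FS}, got {record.fs}")
    n_full = record.samples.size // EPOCH_SAMPLES
    remainder = record.samples.size - n_full * EPOCH_SAMPLES
    if remainder:
        logger.warning(
            "discarding trailing partial epoch of %d samples (%.1f s)",
            remainder,
            remainder / record.fs,
        )
    if labels is not None:
        labels = np.asarray(labels, dtype=np.int64)
        if not (n_full <= labels.size <= n_full + (1 if remainder else 0)):
            raise ValueError(
                f"label count {labels.size} does not match {n_full} full epochs"
            )
    epochs: list[SleepEpoch] = []
    for i in range(n_full):
        label: int | None
        if labels is None:
            label = None
        else:
            code = int(labels[i])
            if code < 0:
                if on_missing_label == "error":
                    raise ValueError(f"epoch {i} has no stage label")
                logger.warning("dropping unscored epoch %d", i)
                continue
            label = int(Stage(code))
        span = (i * EPOCH_SAMPLES, (i + 1) * EPOCH_SAMPLES)
        epochs.append(
            SleepEpoch(
                samples=record.samples[span[0] : span[1]],
                label=label,
                source_index=i,
                sample_span=span,
            )
        )
    return EpochDataset(epochs=epochs)


def write_epoch_manifest(path: str | os.PathLike, dataset: EpochDataset) -> None:
    """Write (epoch_index, start_sample, end_sample, stage) for each epoch."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "start_sample", "end_sample", "stage"])
        for e in dataset:
            stage = Stage(e.label).name if e.label is not None else ""
            w.writerow([e.source_index, e.sample_span[0], e.sample_span[1], stage])


def preprocess_record(
    record: EEGRecord,
    labels: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
) -> EpochDataset:
    """resample -> bandpass -> segment, the pipeline's fixed order."""
    rec = resample_to_256(record)
    rec = bandpass_zero_phase(rec, filter_spec)
    return segment_epochs(rec, labels)
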