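"""Minimal European Data Format (EDF) reader/writer.

Supports the plain continuous EDF layout: fixed 256-byte main header,
256 bytes per signal, and int16 little-endian data records.  This covers
what the pipeline needs (single- or multi-signal continuous recordings in
physical units); EDF+ annotations, discontinuous records and sub-second
record durations beyond what fits the header fields are out of scope.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["EDFSignalHeader", "read_edf_signal", "write_edf"]

_HDR = 256


@dataclass
class EDFSignalHeader:
    label: str
    physical_dim: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    n_samples_per_record: int


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def read_edf_signal(path: str | os.PathLike, channel: str | None = None):
    """Read one signal from an EDF file.

    Returns ``(samples, fs, label)`` with samples in physical units.  When
    ``channel`` is None the first signal is used; otherwise the signal whose
    label matches (case-insensitive) is selected.

    Raises ``OSError`` for missing/corrupt/truncated files and ``KeyError``
    for an absent channel.
    """
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise OSError(f"{path}: truncated EDF header")
        try:
            header_bytes = int(_field(head, 184, 8))
            n_records = int(_field(head, 236, 8))
            record_duration = float(_field(head, 244, 8))
            n_signals = int(_field(head, 252, 4))
        except ValueError as e:
            raise OSError(f"{path}: malformed EDF header: {e}") from None
        if n_signals < 1:
            raise OSError(f"{path}: EDF file declares no signals")
        sig_head = fh.read(n_signals * _HDR)
        if len(sig_head) < n_signals * _HDR:
            raise OSError(f"{path}: truncated EDF signal headers")

        # signal-header fields are stored blockwise: all labels, then all
        # transducers, ... ; block start offsets are in bytes per the format
        def sfield(block_start: int, width: int, idx: int) -> str:
            base = block_start * n_signals + idx * width
            return sig_head[base : base + width].decode("ascii", errors="replace").strip()

        try:
            headers = [
                EDFSignalHeader(
                    label=sfield(0, 16, i),
                    physical_dim=sfield(96, 8, i),
                    physical_min=float(sfield(104, 8, i)),
                    physical_max=float(sfield(112, 8, i)),
                    digital_min=int(sfield(120, 8, i)),
                    digital_max=int(sfield(128, 8, i)),
                    n_samples_per_record=int(sfield(216, 8, i)),
                )
                for i in range(n_signals)
            ]
        except ValueError as e:
            raise OSError(f"{path}: malformed EDF signal header: {e}") from None

        if channel is None:
            idx = 0
        else:
            labels = [h.label.upper() for h in headers]
            try:
                idx = labels.index(channel.strip().upper())
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in EDF file (available: {[h.label for h in headers]})"
                ) from None

        samples_per_record = sum(h.n_samples_per_record for h in headers)
        record_bytes = samples_per_record * 2
        expected = header_bytes + n_records * record_bytes
        actual = os.fstat(fh.fileno()).st_size
        if actual < expected:
            raise OSError(
                f"{path}: truncated EDF data ({actual} bytes, header promises {expected})"
            )
        fh.seek(header_bytes)
        raw = np.frombuffer(fh.read(n_records * record_bytes), dtype="<i2")

    raw = raw.reshape(n_records, samples_per_record)
    offsets = np.cumsum([0] + [h.n_samples_per_record for h in headers])
    h = headers[idx]
    dig = raw[:, offsets[idx] : offsets[idx + 1]].reshape(-1).astype(np.float64)
    gain = (h.physical_max - h.physical_min) / (h.digital_max - h.digital_min)
    phys = (dig - h.digital_min) * gain + h.physical_min
    fs = h.n_samples_per_record / record_duration
    return phys, fs, h.label


def write_edf(
    path: str | os.PathLike,
    samples: np.ndarray,
    fs: float,
    channel: str = "C4-M1",
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
    physical_dim: str = "uV",
    record_seconds: float = 1.0,
) -> None:
    """Write a single continuous signal as 16-bit EDF.

    Values outside ``physical_range`` are clipped.  The signal is padded
    with zeros to a whole number of data records (the header's record count
    reflects the padded length, so readers recover length information from
    the label CSV / epoch grid rather than the EDF tail).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("samples must be 1-D")
    spr = int(round(fs * record_seconds))
    if not math.isclose(spr, fs * record_seconds):
        raise ValueError("record_seconds * fs must be an integer sample count")
    n_records = int(math.ceil(samples.size / spr)) if samples.size else 0
    padded = np.zeros(n_records * spr)
    padded[: samples.size] = samples

    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    clipped = np.clip(padded, pmin, pmax)
    dig = np.round((clipped - pmin) / (pmax - pmin) * (dmax - dmin) + dmin).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    head = b"".join(
        [
            pad("0", 8),                      # version
            pad("X X X X", 80),               # patient id (anonymous)
            pad("Startdate X X X X", 80),     # recording id
            pad("01.01.00", 8),               # start date
            pad("00.00.00", 8),               # start time
            pad(str(_HDR * 2), 8),            # header bytes (main + 1 signal)
            pad("", 44),                      # reserved
            pad(str(n_records), 8),
            pad(f"{record_seconds:g}", 8),
            pad("1", 4),                      # number of signals
        ]
    )
    sig = b"".join(
        [
            pad(channel, 16),
            pad("synthetic EEG", 80),
            pad(physical_dim, 8),
            pad(f"{pmin:g}", 8),
            pad(f"{pmax:g}", 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),                      # prefiltering
            pad(str(spr), 8),
            pad("", 32),                      # reserved
        ]
    )
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        fh.write(dig.tobytes())
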