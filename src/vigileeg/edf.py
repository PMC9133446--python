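"""Minimal EDF (European Data Format) writer.

Writes 16-bit EDF with one-second data records and physical units of µV,
which is sufficient for round-tripping the synthetic recordings produced
by this package.  Reading goes through :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    signals: np.ndarray,
    sampling_rate: float,
    channel_labels,
    path,
    physical_range: tuple[float, float] = (-4000.0, 4000.0),
) -> Path:
    """Write a (channels, samples) µV matrix as 16-bit EDF.

    Samples are quantized to the 16-bit digital range over
    ``physical_range`` (µV) and clipped to that range; with the default
    ±4000 µV range one quantization step is ≈0.12 µV.
    """
    signals = np.asarray(signals, dtype=float)
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = signals.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel count mismatch between labels and signals")
    n_records = n_samp // fs
    if n_records * fs != n_samp:
        raise ValueError("signal length must be a whole number of seconds")

    pmin, pmax = physical_range
    scale = (DIG_MAX - DIG_MIN) / (pmax - pmin)
    digital = np.clip(
        np.rint((signals - pmin) * scale + DIG_MIN), DIG_MIN, DIG_MAX
    ).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field(0, 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(256 * (n_ch + 1), 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),
            _field(n_ch, 4),
        ]
    )
    per_channel = b"".join(
        [
            b"".join(_field(lab, 16) for lab in channel_labels),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{pmin:g}", 8) for _ in range(n_ch)),
            b"".join(_field(f"{pmax:g}", 8) for _ in range(n_ch)),
            b"".join(_field(DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_field(DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(fs, 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    path = Path(path)
    # records are channel-blocked: all samples of channel 0 for second r,
    # then channel 1, etc.
    blocks = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_channel)
        fh.write(blocks.tobytes())
    return path


def quantization_step(physical_range: tuple[float, float] = (-4000.0, 4000.0)) -> float:
    pmin, pmax = physical_range
    return (pmax - pmin) / (DIG_MAX - DIG_MIN)
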