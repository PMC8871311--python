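"""Minimal EDF (European Data Format) writer for generated records.

Writes plain EDF: ASCII header, 16-bit little-endian samples in 1-second
data records, physical dimension microvolts.  Only what the synthetic
corpus needs is implemented (identical sampling rate on every channel,
integer-second duration); reading goes through mne.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ConfigError


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ConfigError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(record, path: str | Path) -> None:
    """Write an EEGRecord (microvolt samples) as a plain EDF file."""
    fs = record.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ConfigError(f"EDF writer needs an integer sampling rate, got {fs}")
    n_ch, n_samp = record.samples.shape
    n_records = n_samp // spr
    if n_records * spr != n_samp:
        raise ConfigError(
            f"EDF writer needs an integer number of seconds, got {n_samp} samples at {fs} Hz"
        )
    data = record.samples
    dig_min, dig_max = -32768, 32767
    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    flat = phys_max <= phys_min
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X synthetic", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_signal = [
        b"".join(_field(lbl[:16], 16) for lbl in record.channel_labels),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{v:g}"[:8], 8) for v in phys_min),
        b"".join(_field(f"{v:g}"[:8], 8) for v in phys_max),
        b"".join(_field(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(spr), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ]
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - scale * dig_min
    digital = np.rint((data - offset[:, None]) / scale[:, None]).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            fh.write(digital[:, sl].tobytes())
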