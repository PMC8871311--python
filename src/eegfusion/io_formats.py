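"""Readers, segmenters and feature-matrix persistence for the two EEG dialects.

Two on-disk dialects are supported:

* a single-channel plain-ASCII dialect (one sample per line, canonically
  4096 samples per file at 173.6 Hz), and
* multi-channel EDF records (canonically 256 Hz scalp EEG) with ictal
  on/offset intervals supplied separately as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import BoundsError, ConfigError, FormatError, MissingChannelError, SchemaError

#: Default sampling rates of the two dialects, overridable per call.
BONN_FS = 173.6
CHBMIT_FS = 256.0

ICTAL = "ictal"
NON_ICTAL = "non_ictal"


@dataclass
class EEGRecord:
    """A multi- or single-channel sampled signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Channel-major amplitudes (microvolts by convention).
    fs : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str
        Ordered channel labels, one per row of ``samples``.
    annotations : list of (start_s, end_s, label)
        Optional labelled intervals, each within ``[0, duration_s]``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise SchemaError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        for start_s, end_s, label in self.annotations:
            if not (0 <= start_s < end_s <= self.duration_s):
                raise BoundsError(
                    f"annotation ({start_s}, {end_s}, {label!r}) outside "
                    f"record of {self.duration_s:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """A fixed-window, labelled excerpt of one or more channels."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.label not in (ICTAL, NON_ICTAL):
            raise ConfigError(f"label must be {ICTAL!r} or {NON_ICTAL!r}, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_ascii_single_channel(path: str | Path, fs: float = BONN_FS) -> EEGRecord:
    """Read one single-channel ASCII file (one sample per line).

    Blank lines are ignored; any unparseable line raises :class:`FormatError`
    naming its 1-based line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse {text!r} as a sample"
                ) from None
    if not values:
        raise FormatError(f"{path}: file contains no samples")
    return EEGRecord(np.asarray(values, dtype=float), fs=fs, channel_labels=[path.stem])


def read_edf_multichannel(path: str | Path, channels: Sequence[str]) -> EEGRecord:
    """Read an EDF record restricted to ``channels``, in the requested order.

    The sampling rate is taken from the EDF header.  EEG amplitudes are
    returned in microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    missing = [ch for ch in channels if ch not in available]
    if missing:
        raise MissingChannelError(
            f"{path}: channel(s) {missing} not found; available: {available}"
        )
    data = raw.get_data(picks=list(channels)) * 1e6  # mne returns volts
    return EEGRecord(data, fs=float(raw.info["sfreq"]), channel_labels=list(channels))


def extract_segments_multichannel(
    rec: EEGRecord,
    ictal_intervals: Sequence[tuple[float, float]],
    nonictal_window_s: float = 60.0,
    source_id: str = "",
    nonictal_from_gaps: bool = False,
) -> list[Segment]:
    """Cut a multi-channel record into labelled segments.

    One variable-length ictal segment is produced per interval.  Non-ictal
    segments are fixed windows of ``nonictal_window_s`` seconds taken from
    the start of records with no ictal interval (the default), or — when
    ``nonictal_from_gaps`` is set — from the seizure-free gaps of records
    that do contain seizures.
    """
    segments: list[Segment] = []
    for start_s, end_s in ictal_intervals:
        if not (0 <= start_s < end_s <= rec.duration_s):
            raise BoundsError(
                f"ictal interval ({start_s}, {end_s}) exceeds record of "
                f"{rec.duration_s:.3f} s"
            )
        i0, i1 = round(start_s * rec.fs), round(end_s * rec.fs)
        segments.append(
            Segment(rec.samples[:, i0:i1], rec.fs, ICTAL, source_id=f"{source_id}[{start_s},{end_s}]")
        )
    win = round(nonictal_window_s * rec.fs)
    if not ictal_intervals:
        for k in range(rec.n_samples // win):
            segments.append(
                Segment(
                    rec.samples[:, k * win : (k + 1) * win],
                    rec.fs,
                    NON_ICTAL,
                    source_id=f"{source_id}#w{k}",
                )
            )
    elif nonictal_from_gaps:
        bounds = sorted(ictal_intervals)
        gaps, prev = [], 0.0
        for start_s, end_s in bounds:
            gaps.append((prev, start_s))
            prev = end_s
        gaps.append((prev, rec.duration_s))
        for g0, g1 in gaps:
            i0 = round(g0 * rec.fs)
            n_wins = int((round(g1 * rec.fs) - i0) // win)
            for k in range(n_wins):
                a = i0 + k * win
                segments.append(
                    Segment(rec.samples[:, a : a + win], rec.fs, NON_ICTAL,
                            source_id=f"{source_id}#g{g0}w{k}")
                )
    return segments


def split_single_channel(
    rec: EEGRecord, segment_len: int = 512, label: str = NON_ICTAL
) -> list[Segment]:
    """Split a 1-channel record into consecutive non-overlapping segments.

    A trailing remainder shorter than ``segment_len`` is discarded, so the
    concatenation of the outputs equals the input prefix.  The canonical
    single-channel file of 4096 samples yields 8 segments of 512.
    """
    if segment_len < 32:
        raise ConfigError(
            f"segment_len must be >= 32 (level-5 wavelet decomposition needs 2^5 "
            f"samples), got {segment_len}"
        )
    if rec.n_channels != 1:
        raise SchemaError(f"expected a 1-channel record, got {rec.n_channels} channels")
    x = rec.samples[0]
    n_seg = len(x) // segment_len
    src = rec.channel_labels[0]
    return [
        Segment(x[k * segment_len : (k + 1) * segment_len], rec.fs, label,
                source_id=f"{src}#s{k}")
        for k in range(n_seg)
    ]


def write_feature_matrix(fm, path: str | Path) -> None:
    """Write a feature matrix as CSV (feature columns + final ``label`` column)."""
    from .matrix import FeatureMatrix  # local import avoids a cycle

    assert isinstance(fm, FeatureMatrix)
    fm.to_csv(path)


def read_feature_matrix(path: str | Path):
    """Read back a feature matrix written by :func:`write_feature_matrix`."""
    from .matrix import FeatureMatrix

    return FeatureMatrix.from_csv(path)
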