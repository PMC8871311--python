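"""Per-segment feature extraction and feature-level fusion.

Three cases mirror the evaluation protocol:

* ``dwt``   — level-5 Haar wavelet coefficients, 7 stats per sequence
              (42 columns per channel);
* ``emd``   — first 5 IMFs, 6 stats per IMF (30 columns per channel);
* ``fused`` — the dwt matrix column-concatenated with the emd matrix
              (DWT block first).

Columns are nested channel-major, then source sequence, then stat; channel
suffixes ``_ch<k>`` appear only for multi-channel segments.  Variable-length
ictal segments are handled by the 1/n terms already inside the feature
formulas; no resampling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dwt as _dwt
from . import emd as _emd
from .errors import AlignmentError, ConfigError, SchemaError
from .features import featurize_dwt, featurize_emd
from .io_formats import Segment
from .matrix import FeatureMatrix
from .preprocess import FilterSpec, bandpass_array

CASES = ("dwt", "emd", "fused")


@dataclass
class PipelineConfig:
    """Knobs for the segment -> feature-row pipeline."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    preprocess: bool = True
    wavelet: str = _dwt.DEFAULT_WAVELET
    dwt_level: int = _dwt.DEFAULT_LEVEL
    max_imfs: int = 5
    sift_stop: _emd.SiftStop = field(default_factory=_emd.SiftStop)


def _channel_suffix(n_channels: int, ch: int) -> str:
    return f"_ch{ch + 1}" if n_channels > 1 else ""


def _segment_row(seg: Segment, case: str, cfg: PipelineConfig):
    values: list[np.ndarray] = []
    names: list[str] = []
    data = seg.data
    if cfg.preprocess:
        data = bandpass_array(data, seg.fs, cfg.filter_spec)
    for ch in range(seg.n_channels):
        x = data[ch]
        suffix = _channel_suffix(seg.n_channels, ch)
        if case == "dwt":
            fv = featurize_dwt(_dwt.wavedec(x, cfg.wavelet, cfg.dwt_level))
        elif case == "emd":
            fv = featurize_emd(
                _emd.emd_decompose(x, cfg.max_imfs, cfg.sift_stop), cfg.max_imfs
            )
        else:
            raise ConfigError(f"unknown case {case!r}")
        values.append(fv.values)
        names.extend(n + suffix for n in fv.names)
    return np.concatenate(values), names


def build_case_matrix(
    segments: list[Segment], case: str, config: PipelineConfig | None = None
) -> FeatureMatrix:
    """One feature row per segment, in input order.

    Widths: 4-channel dwt = 168, emd = 120, fused = 288; single-channel
    42 / 30 / 72.
    """
    if case not in CASES:
        raise ConfigError(f"case must be one of {CASES}, got {case!r}")
    if not segments:
        raise ConfigError("no segments supplied")
    cfg = config or PipelineConfig()
    n_ch = segments[0].n_channels
    for i, seg in enumerate(segments):
        if seg.n_channels != n_ch:
            raise SchemaError(
                f"segment {i} has {seg.n_channels} channels, expected {n_ch}"
            )
    if case == "fused":
        a = build_case_matrix(segments, "dwt", cfg)
        b = build_case_matrix(segments, "emd", cfg)
        return concat_features(a, b)
    rows, names = [], None
    for seg in segments:
        vals, row_names = _segment_row(seg, case, cfg)
        if names is None:
            names = row_names
        elif row_names != names:
            raise SchemaError("segments produced inconsistent feature schemas")
        rows.append(vals)
    dialect = "multi_channel" if n_ch > 1 else "single_channel"
    return FeatureMatrix(
        np.vstack(rows), names, [seg.label for seg in segments],
        case_tag=case, dialect=dialect,
    )


def concat_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Column-wise fusion of two row-aligned matrices (a's columns first)."""
    if a.n_rows != b.n_rows:
        raise AlignmentError(f"row counts differ: {a.n_rows} vs {b.n_rows}")
    for i, (la, lb) in enumerate(zip(a.labels, b.labels)):
        if la != lb:
            raise AlignmentError(f"label mismatch at row {i}: {la!r} vs {lb!r}")
    overlap = set(a.names) & set(b.names)
    if overlap:
        raise SchemaError(f"column name collision: {sorted(overlap)}")
    return FeatureMatrix(
        np.hstack([a.values, b.values]),
        list(a.names) + list(b.names),
        list(a.labels),
        case_tag="fused",
        dialect=a.dialect or b.dialect,
    )
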