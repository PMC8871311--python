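"""The eight statistical features computed on coefficient and IMF sequences.

All moments are population (1/n) forms: mean, variance, standard deviation,
RMS, skewness and raw (non-excess) kurtosis — a normal sample has kurtosis
near 3, not 0.  Curve length is the natural log of the total variation
``log(sum |x_i - x_{i-1}|)``.  "Minima" is read as the global minimum sample
value (an alternative reading — the smallest absolute amplitude among strict
local minima — is available via ``interpretation='local_min_abs'``).

Degenerate inputs are mapped to finite values so feature matrices never
contain NaN/inf: a constant sequence has zero total variation, so its curve
length is floored at ``log(machine eps)``; zero standard deviation makes
skewness and kurtosis 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import LengthError

logger = logging.getLogger(__name__)

#: Floor returned by curve length when the total variation is zero.
CURVE_LENGTH_FLOOR = float(np.log(np.finfo(float).eps))

#: Fixed stat order for wavelet-coefficient features (7 per sequence).
DWT_STATS = ("mean", "variance", "std", "curve_length", "skewness", "kurtosis", "minima")
#: Fixed stat order for IMF features (6 per IMF).
EMD_STATS = ("variance", "rms", "std", "curve_length", "skewness", "kurtosis")


@dataclass
class FeatureVector:
    """Ordered feature values with names of the form ``<stat>_<source>``."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        assert len(self.values) == len(self.names)


def _as_array(x, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < min_len:
        raise LengthError(f"need at least {min_len} samples, got {x.size}")
    return x


def stat_mean(x) -> float:
    x = _as_array(x, 1)
    return float(np.sum(x) / x.size)


def stat_variance(x) -> float:
    x = _as_array(x, 1)
    mu = np.sum(x) / x.size
    return float(np.sum((x - mu) ** 2) / x.size)


def stat_std(x) -> float:
    return float(np.sqrt(stat_variance(x)))


def stat_rms(x) -> float:
    x = _as_array(x, 1)
    return float(np.sqrt(np.sum(x**2) / x.size))


def stat_curve_length(x) -> float:
    """log of the summed absolute successive differences (waveform complexity)."""
    x = _as_array(x, 2)
    total_variation = float(np.sum(np.abs(np.diff(x))))
    if total_variation == 0.0:
        logger.debug("curve length of a constant sequence floored at %g", CURVE_LENGTH_FLOOR)
        return CURVE_LENGTH_FLOOR
    return float(np.log(total_variation))


def stat_minima(x, interpretation: str = "global_min") -> float:
    x = _as_array(x, 1)
    if interpretation == "global_min":
        return float(np.min(x))
    if interpretation == "local_min_abs":
        interior = x[1:-1]
        mask = (interior < x[:-2]) & (interior < x[2:])
        if not np.any(mask):
            return float(np.min(x))
        return float(np.min(np.abs(interior[mask])))
    raise ValueError(f"unknown minima interpretation {interpretation!r}")


def _standardized_moment(x, power: int) -> float:
    x = _as_array(x, 2)
    mu = np.sum(x) / x.size
    sigma = np.sqrt(np.sum((x - mu) ** 2) / x.size)
    if sigma == 0.0:
        logger.debug("zero standard deviation; standardized moment set to 0")
        return 0.0
    return float(np.sum(((x - mu) / sigma) ** power) / x.size)


def stat_skewness(x) -> float:
    return _standardized_moment(x, 3)


def stat_kurtosis(x) -> float:
    """Raw population kurtosis (normal ~ 3, not excess)."""
    return _standardized_moment(x, 4)


_STAT_FUNCS = {
    "mean": stat_mean,
    "variance": stat_variance,
    "std": stat_std,
    "rms": stat_rms,
    "curve_length": stat_curve_length,
    "skewness": stat_skewness,
    "kurtosis": stat_kurtosis,
    "minima": stat_minima,
}


def compute_stat(name: str, x) -> float:
    return _STAT_FUNCS[name](x)


def featurize_dwt(dec) -> FeatureVector:
    """7 stats per coefficient sequence, source-major: mean_cA5 ... minima_cD1.

    A level-5 decomposition (6 sequences) yields 42 named values.
    """
    values: list[float] = []
    names: list[str] = []
    for seq, src in zip(dec.sequences, dec.sequence_names):
        for stat in DWT_STATS:
            values.append(compute_stat(stat, seq))
            names.append(f"{stat}_{src}")
    return FeatureVector(np.asarray(values), names)


def featurize_emd(imfs, expected_imfs: int = 5) -> FeatureVector:
    """6 stats per IMF, imf1..imfN, padding short sets with all-zero blocks.

    With 5 expected IMFs this yields 30 named values.  A decomposition that
    terminated early (e.g. a trend-dominated segment) contributes zeros for
    the missing IMFs and is flagged in the log.
    """
    if expected_imfs < 1:
        raise ValueError(f"expected_imfs must be >= 1, got {expected_imfs}")
    if imfs.n_imfs < expected_imfs:
        logger.warning(
            "only %d of %d expected IMFs extracted; padding missing blocks with zeros",
            imfs.n_imfs, expected_imfs,
        )
    values: list[float] = []
    names: list[str] = []
    for k in range(expected_imfs):
        src = f"imf{k + 1}"
        if k < imfs.n_imfs:
            seq = imfs.imfs[k]
            for stat in EMD_STATS:
                values.append(compute_stat(stat, seq))
                names.append(f"{stat}_{src}")
        else:
            for stat in EMD_STATS:
                values.append(0.0)
                names.append(f"{stat}_{src}")
    return FeatureVector(np.asarray(values), names)
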