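"""Empirical mode decomposition by sifting.

EMD splits a signal into intrinsic mode functions (IMFs): oscillatory modes
whose extrema and zero-crossing counts differ by at most one and whose local
envelope mean is near zero.  Each IMF is obtained by *sifting*: repeatedly
subtracting the mean of the cubic-spline envelopes through the local maxima
and minima until a Cauchy-style criterion

    SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold

fires (0.2 by default, the convention of the classical EMD literature), with
a hard cap on iterations.  Envelope splines use mirrored boundary extension:
the two extrema nearest each end are reflected across the endpoints before
fitting, which suppresses end swings.  Decomposition stops when the running
residue is monotone (fewer than two maxima or two minima), so a trend yields
zero IMFs.  Mode-mixing remedies (ensemble/multivariate EMD) are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import LengthError, MonotoneSignalError

MIN_EMD_LENGTH = 16


@dataclass(frozen=True)
class SiftStop:
    """Stop criterion for the inner sifting loop."""

    sd_threshold: float = 0.2
    max_iters: int = 100


@dataclass
class IMFSet:
    """Ordered IMFs plus residue for one channel.

    By construction ``sum(imfs) + residue == input`` to floating-point
    bookkeeping accuracy.  ``sift_counts[i]`` is the number of sifting
    iterations spent on ``imfs[i]``.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out

    def imf_health(self, imf_index: int) -> dict:
        """Post-hoc IMF diagnostics: extrema/zero-crossing gap and mean/RMS ratio."""
        imf = self.imfs[imf_index]
        maxima, minima = find_extrema(imf)
        zc = int(np.sum(np.abs(np.diff(np.sign(imf))) > 1))
        rms = float(np.sqrt(np.mean(imf**2)))
        return {
            "extrema_zero_crossing_gap": abs(len(maxima) + len(minima) - zc),
            "mean_to_rms": abs(float(np.mean(imf))) / rms if rms > 0 else 0.0,
        }


def find_extrema(x) -> tuple[list[int], list[int]]:
    """Strict interior local maxima and minima by three-point comparison.

    A plateau of equal values counts as a single extremum placed at the
    plateau midpoint, rounded down.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise LengthError(f"need at least 3 samples, got {x.size}")
    s = np.sign(np.diff(x))
    idx = np.nonzero(s)[0]
    maxima: list[int] = []
    minima: list[int] = []
    for k in range(len(idx) - 1):
        a, b = idx[k], idx[k + 1]
        if s[a] > 0 and s[b] < 0:
            maxima.append((a + 1 + b) // 2)
        elif s[a] < 0 and s[b] > 0:
            minima.append((a + 1 + b) // 2)
    return maxima, minima


def _extend_mirror(indices: list[int], values: np.ndarray, n: int):
    """Reflect the two extrema nearest each end across the endpoints."""
    ts = list(indices)
    vs = [values[i] for i in indices]
    left_t = [-i for i in indices[:2][::-1] if i > 0]
    left_v = [values[i] for i in indices[:2][::-1] if i > 0]
    right_t = [2 * (n - 1) - i for i in indices[-2:][::-1] if i < n - 1]
    right_v = [values[i] for i in indices[-2:][::-1] if i < n - 1]
    t = np.asarray(left_t + ts + right_t, dtype=float)
    v = np.asarray(left_v + vs + right_v, dtype=float)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    keep = np.concatenate(([True], np.diff(t) > 0))
    return t[keep], v[keep]


def envelope_mean(x, maxima: list[int], minima: list[int]) -> np.ndarray:
    """Mean of the cubic-spline upper and lower envelopes at every sample."""
    x = np.asarray(x, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        raise MonotoneSignalError(
            f"need >= 2 maxima and >= 2 minima to build envelopes, "
            f"got {len(maxima)} maxima / {len(minima)} minima"
        )
    n = x.size
    grid = np.arange(n)
    t_up, v_up = _extend_mirror(maxima, x, n)
    t_lo, v_lo = _extend_mirror(minima, x, n)
    upper = CubicSpline(t_up, v_up)(grid)
    lower = CubicSpline(t_lo, v_lo)(grid)
    return (upper + lower) / 2.0


def sift(x, stop: SiftStop | None = None, return_iterations: bool = False):
    """Extract one IMF candidate: ``h <- h - envelope_mean(h)`` until stop.

    Raises :class:`MonotoneSignalError` if the input (or an intermediate h)
    loses its oscillatory structure before any iteration limit is reached.
    """
    stop = stop or SiftStop()
    h = np.asarray(x, dtype=float).copy()
    iters = 0
    for _ in range(stop.max_iters):
        maxima, minima = find_extrema(h)
        m = envelope_mean(h, maxima, minima)  # raises on monotone/trend
        denom = float(np.sum(h**2))
        h_new = h - m
        sd = float(np.sum(m**2)) / denom if denom > 0 else 0.0
        h = h_new
        iters += 1
        if sd < stop.sd_threshold:
            break
    return (h, iters) if return_iterations else h


def emd_decompose(x, max_imfs: int = 5, stop: SiftStop | None = None) -> IMFSet:
    """Decompose ``x`` into up to ``max_imfs`` IMFs plus a residue.

    The residue after the last extracted IMF may still oscillate if
    ``max_imfs`` truncates the decomposition; a monotone/trend residue
    terminates it early (possibly with zero IMFs).
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_EMD_LENGTH:
        raise LengthError(f"need at least {MIN_EMD_LENGTH} samples, got {x.size}")
    stop = stop or SiftStop()
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    for _ in range(max_imfs):
        try:
            imf, n_it = sift(residue, stop, return_iterations=True)
        except MonotoneSignalError:
            break
        imfs.append(imf)
        counts.append(n_it)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, sift_counts=counts)
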