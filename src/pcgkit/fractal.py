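"""Katz fractal dimension and the sliding-window FD profile.

The Katz fractal dimension of a sampled waveform treats the segment as a
planar curve through the points ``(i, s_i)`` at unit sample spacing and
measures how much the curve wanders relative to its extent:

    FD = log10(n) / (log10(n) + log10(d / L))

where ``L`` is the total curve length (sum of Euclidean distances between
successive points), ``d`` the maximum Euclidean distance from the first
point to any other point, and ``n = N - 1`` the number of steps. A straight
line gives FD = 1 (d == L); oscillatory, noise-like content gives larger
values. Heart-sound transients (S1, S2) raise the local FD above the quiet
systolic/diastolic baseline, which is what the segmentation stage exploits.

Katz FD is convention-sensitive: this module fixes unit abscissa spacing,
so the value is *not* invariant under amplitude scaling. Inputs are
expected to be peak-normalized first (see :mod:`pcgkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import AudioSignal

__all__ = ["FDProfile", "katz_fd", "fd_profile"]

# treat d/L >= 1 - _LINE_RTOL as a straight line: L is a float sum of per-step
# lengths and can differ from d by a few ulp on an exactly linear segment.
_LINE_RTOL = 1e-12


@dataclass
class FDProfile:
    """Per-window Katz FD sequence aligned to a waveform.

    ``values[k]`` is the FD of the window starting at sample
    ``start_indices[k]`` and spanning ``window_len`` samples.
    """

    values: np.ndarray
    window_len: int
    hop: int
    fs: float
    start_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.start_indices = np.asarray(self.start_indices, dtype=np.int64)
        if len(self.values) != len(self.start_indices):
            raise ValueError("values and start_indices must have equal length")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")

    def __len__(self) -> int:
        return len(self.values)


def katz_fd(segment: np.ndarray) -> float:
    """Katz fractal dimension of one waveform segment.

    Parameters
    ----------
    segment : array-like
        At least 3 samples.

    Returns
    -------
    float
        FD >= 1. A constant (flat) segment has no extent (d = 0) and
        returns 1.0 by convention; an exactly straight line returns 1.0
        because d == L.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    if x.size < 3:
        raise ValueError(f"segment too short for Katz FD: {x.size} < 3 samples")
    dy = np.diff(x)
    L = float(np.sum(np.hypot(1.0, dy)))
    k = np.arange(x.size, dtype=np.float64)
    d = float(np.max(np.hypot(k, x - x[0])))
    if d == 0.0:
        return 1.0  # constant segment: degenerate flat curve
    ratio = d / L  # d <= L: the path to any point is at least as long as the chord
    if ratio >= 1.0 - _LINE_RTOL:
        return 1.0
    n = x.size - 1
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(ratio)))


def fd_profile(
    signal: AudioSignal, window_s: float = 0.05, overlap: float = 0.99
) -> FDProfile:
    """Sliding-window Katz FD profile of a recording.

    The window length is ``M = floor(window_s * fs)`` samples (400 at
    8 kHz for the default 50 ms window) and consecutive windows overlap by
    the given fraction, i.e. the hop is ``max(1, M - floor(overlap * M))``
    (4 samples at the default 99%). Windows start at samples 0, hop,
    2*hop, ...; trailing samples that do not fill a complete window are
    discarded so every FD value is a true M-sample statistic.

    Raises
    ------
    ValueError
        If the signal is shorter than one window or overlap is outside
        [0, 1).
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    s = signal.samples
    M = int(window_s * signal.fs)
    if M < 3:
        raise ValueError(f"window of {M} samples is too short for Katz FD")
    if s.size < M:
        raise ValueError(
            f"signal of {s.size} samples is shorter than one {M}-sample window"
        )
    hop = max(1, M - int(overlap * M))
    starts = np.arange(0, s.size - M + 1, hop, dtype=np.int64)

    # vectorized Katz FD over all windows at once
    step = np.hypot(1.0, np.diff(s))
    cum = np.concatenate(([0.0], np.cumsum(step)))
    L = cum[starts + M - 1] - cum[starts]

    # max distance from each window's first point, accumulated over the
    # in-window offset k (much cheaper than materializing the window matrix)
    s0 = s[starts]
    acc = np.zeros(starts.size)
    for k in range(M):
        np.maximum(acc, k * k + (s[starts + k] - s0) ** 2, out=acc)
    d = np.sqrt(acc)

    n = M - 1
    log_n = np.log10(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d / L
        fd = log_n / (log_n + np.log10(ratio))
    flat = (d == 0.0) | (ratio >= 1.0 - _LINE_RTOL)
    fd = np.where(flat, 1.0, fd)
    return FDProfile(
        values=fd, window_len=M, hop=hop, fs=signal.fs, start_indices=starts
    )
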