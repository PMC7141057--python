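"""Lag-grid convolution helpers shared by the estimators.

Everything works in integer sample units on a common grid.  A "mass" is a
dimensionless weight vector (e.g. a normalised timestamp distribution); a
"signal" is samples x channels.  Convolutions are computed at full support
and then cropped, so samples inside the requested output window are exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["convolve_signal", "convolve_masses", "crop_to"]


def convolve_signal(
    mass: np.ndarray,
    mass_start: int,
    signal: np.ndarray,
    signal_start: int,
    out_start: int,
    out_n: int,
) -> np.ndarray:
    """(mass * signal)(t) on [out_start, out_start + out_n) sample indices.

    ``mass_start`` / ``signal_start`` are the sample indices of the first
    element of each input.  Output samples outside the full convolution
    support are zero.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] == 1:
        signal = signal.T
    n_ch = signal.shape[1]
    out = np.zeros((out_n, n_ch))
    if mass.size == 0 or not np.any(mass):
        return out
    full = np.empty((mass.size + signal.shape[0] - 1, n_ch))
    for c in range(n_ch):
        full[:, c] = np.convolve(mass, signal[:, c])
    return crop_to(full, mass_start + signal_start, out_start, out_n)


def convolve_masses(
    m1: np.ndarray, s1: int, m2: np.ndarray, s2: int
) -> tuple[np.ndarray, int]:
    """Full convolution of two mass vectors; returns (mass, start_sample)."""
    return np.convolve(m1, m2), s1 + s2


def crop_to(arr: np.ndarray, arr_start: int, out_start: int, out_n: int) -> np.ndarray:
    """Crop/zero-pad ``arr`` (first axis) to [out_start, out_start+out_n)."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[0] == 1 and out_n != 1:
        arr = arr.T
    out = np.zeros((out_n,) + arr.shape[1:])
    lo = max(out_start, arr_start)
    hi = min(out_start + out_n, arr_start + arr.shape[0])
    if hi > lo:
        out[lo - out_start : hi - out_start] = arr[lo - arr_start : hi - arr_start]
    return out
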