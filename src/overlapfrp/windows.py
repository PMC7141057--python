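"""Time windows on a fixed sample grid.

All windows in this package are closed intervals ``[start_ms, end_ms]`` with
*inclusive* endpoints, so a window spanning ``span = end - start`` milliseconds
at sampling rate ``fs`` contains ``span * fs / 1000 + 1`` samples.  With this
convention a [-250, 600] ms window at 1000 Hz holds 851 samples and a
[-200, 1500] ms window holds 1701.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TimeWindow"]


def _on_grid(value_ms: float, fs: float) -> bool:
    x = value_ms * fs / 1000.0
    return abs(x - round(x)) < 1e-9


@dataclass(frozen=True)
class TimeWindow:
    """Closed time interval aligned to a sample grid.

    Parameters
    ----------
    start_ms, end_ms
        Interval bounds in milliseconds (inclusive); ``start_ms`` may be
        negative for pre-event time.
    sample_rate_hz
        Sampling rate of the grid the window lives on.
    """

    start_ms: float
    end_ms: float
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError(
                f"end_ms ({self.end_ms}) must exceed start_ms ({self.start_ms})"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("start_ms", "end_ms"):
            if not _on_grid(getattr(self, name), self.sample_rate_hz):
                raise ValueError(
                    f"{name}={getattr(self, name)} ms is not on the "
                    f"{self.sample_rate_hz} Hz sample grid "
                    f"(step {self.step_ms} ms)"
                )

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return round((self.end_ms - self.start_ms) * self.sample_rate_hz / 1000.0) + 1

    @property
    def start_sample(self) -> int:
        """Start expressed in samples relative to time zero."""
        return round(self.start_ms * self.sample_rate_hz / 1000.0)

    @property
    def end_sample(self) -> int:
        return round(self.end_ms * self.sample_rate_hz / 1000.0)

    def times_ms(self) -> np.ndarray:
        return self.start_ms + self.step_ms * np.arange(self.n_samples)

    def contains(self, other: "TimeWindow") -> bool:
        return (
            other.sample_rate_hz == self.sample_rate_hz
            and other.start_ms >= self.start_ms
            and other.end_ms <= self.end_ms
        )

    def slice_of(self, inner: "TimeWindow") -> slice:
        """Index slice of ``inner`` within this window's sample axis."""
        if not self.contains(inner):
            raise ValueError(f"window {inner} not contained in {self}")
        i0 = inner.start_sample - self.start_sample
        return slice(i0, i0 + inner.n_samples)

    def mask_ms(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Boolean mask of samples with time in [lo_ms, hi_ms]."""
        t = self.times_ms()
        return (t >= lo_ms - 1e-9) & (t <= hi_ms + 1e-9)

    def expand(self, margin_ms: float) -> "TimeWindow":
        return TimeWindow(
            self.start_ms - margin_ms, self.end_ms + margin_ms, self.sample_rate_hz
        )

    def with_rate(self, fs: float) -> "TimeWindow":
        return TimeWindow(self.start_ms, self.end_ms, fs)

    @staticmethod
    def round_up_to_grid(value_ms: float, step_ms: float) -> float:
        """Smallest multiple of ``step_ms`` that is >= ``value_ms``."""
        return math.ceil(value_ms / step_ms - 1e-9) * step_ms
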