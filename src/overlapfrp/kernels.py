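"""Evoked-response waveforms (kernels) over an estimation window."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import TimeWindow

__all__ = ["Kernel", "KernelSpec"]


@dataclass
class Kernel:
    """One evoked-response waveform, samples x channels, in microvolts."""

    window: TimeWindow
    values: np.ndarray
    label: str = "kernel"
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.window.n_samples != 1:
            self.values = self.values.T
        if self.values.shape[0] != self.window.n_samples:
            raise ValueError(
                f"values have {self.values.shape[0]} samples but window "
                f"{self.window.start_ms}..{self.window.end_ms} ms at "
                f"{self.window.sample_rate_hz} Hz has {self.window.n_samples}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.values.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def crop(self, window: TimeWindow) -> "Kernel":
        sl = self.window.slice_of(window)
        return Kernel(window, self.values[sl].copy(), self.label, self.ch_names)

    def interval_mean(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Per-channel mean amplitude over [lo_ms, hi_ms]."""
        m = self.window.mask_ms(lo_ms, hi_ms)
        if not m.any():
            raise ValueError(f"interval [{lo_ms}, {hi_ms}] ms outside kernel window")
        return self.values[m].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.ch_names)
        df.insert(0, "time_ms", self.window.times_ms())
        return df

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __add__(self, other: "Kernel") -> "Kernel":
        if other.window != self.window:
            raise ValueError("kernel windows differ")
        return Kernel(self.window, self.values + other.values, self.label, self.ch_names)

    def __sub__(self, other: "Kernel") -> "Kernel":
        if other.window != self.window:
            raise ValueError("kernel windows differ")
        return Kernel(self.window, self.values - other.values, self.label, self.ch_names)


@dataclass(frozen=True)
class KernelSpec:
    """Parametric kernel: a sum of Gaussian bumps.

    ``components`` is a list of ``(peak_latency_ms, amplitude_uV, width_ms)``
    where width is the Gaussian standard deviation.  A convenient stand-in
    for fixation-locked potentials dominated by the lambda response
    (occipital positivity peaking near 100 ms after fixation onset).
    """

    components: tuple[tuple[float, float, float], ...]
    window: TimeWindow

    def __post_init__(self) -> None:
        for lat, amp, wid in self.components:
            if wid <= 0:
                raise ValueError(f"component width must be positive, got {wid}")

    def render(
        self,
        window: TimeWindow | None = None,
        n_channels: int = 1,
        channel_gains: np.ndarray | None = None,
        label: str = "kernel",
    ) -> Kernel:
        win = window or self.window
        t = win.times_ms()
        wave = np.zeros_like(t)
        for lat, amp, wid in self.components:
            wave += amp * np.exp(-0.5 * ((t - lat) / wid) ** 2)
        gains = np.ones(n_channels) if channel_gains is None else np.asarray(channel_gains)
        return Kernel(win, wave[:, None] * gains[None, :], label)
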