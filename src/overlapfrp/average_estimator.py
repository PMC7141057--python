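"""Time-locked averaging and its analytic overlap decomposition.

Averaging epochs time-locked to an event estimates the evoked response
only when each epoch holds a single response; with overlapping neighbours
the average equals the true kernel plus a sum of convolution products
between the kernel and the normalised timestamp distributions of the
neighbouring events.  That decomposition is computed here both as a
diagnostic and as an oracle for the correction methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._conv import convolve_signal
from .events_epochs import EpochSet, TimestampDistribution
from .kernels import Kernel
from .windows import TimeWindow

__all__ = ["OverlapComponents", "average_epochs", "overlap_decomposition"]


def average_epochs(epochs: EpochSet) -> Kernel:
    """Pointwise mean over epochs, per channel."""
    if epochs.n_epochs < 1:
        raise ValueError("cannot average an empty epoch set")
    return Kernel(
        epochs.window,
        epochs.data.mean(axis=0),
        f"average[{epochs.lock_class}]",
        epochs.ch_names,
    )


@dataclass
class OverlapComponents:
    """Per-offset overlap waveforms ov_f = Q_f * kernel on a shared window."""

    components: dict[int, Kernel]
    window: TimeWindow

    def sum_over(self, offsets) -> Kernel:
        n_ch = next(iter(self.components.values())).n_channels
        total = np.zeros((self.window.n_samples, n_ch))
        for f in offsets:
            if f in self.components:
                total += self.components[f].values
        return Kernel(self.window, total, "overlap_sum")

    @property
    def previous(self) -> Kernel:
        """Sum of overlaps from earlier events (offsets < 0)."""
        return self.sum_over([f for f in self.components if f < 0])

    @property
    def subsequent(self) -> Kernel:
        return self.sum_over([f for f in self.components if f > 0])

    @property
    def total(self) -> Kernel:
        return self.sum_over(self.components)


def overlap_decomposition(
    distributions: dict[int, TimestampDistribution],
    kernel: Kernel,
    out_window: TimeWindow | None = None,
) -> OverlapComponents:
    """Convolve each timestamp distribution with the kernel and crop.

    Convolutions are computed at full support and then cropped to the
    output window, so border samples are exact.
    """
    win = out_window or kernel.window
    comps = {}
    for f, dist in distributions.items():
        if dist.sample_rate_hz != kernel.window.sample_rate_hz:
            raise ValueError(
                f"distribution at offset {f} is on a {dist.sample_rate_hz} Hz "
                f"grid, kernel on {kernel.window.sample_rate_hz} Hz"
            )
        vals = convolve_signal(
            dist.mass,
            dist.start_sample,
            kernel.values,
            kernel.window.start_sample,
            win.start_sample,
            win.n_samples,
        )
        comps[f] = Kernel(win, vals, f"ov[{f:+d}]", kernel.ch_names)
    return OverlapComponents(comps, win)
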