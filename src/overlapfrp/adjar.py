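"""Iterative adjacent-response (ADJAR) overlap correction.

The method assumes every fixation elicits the same response and that only
the immediately previous and subsequent events overlap the locked one.
Starting from the time-locked average restricted to an estimation window
slightly larger than the window of interest, each iteration convolves the
current estimate with the adjacent-event timestamp distributions to form
previous/subsequent overlap estimates, subtracts them from the average and
re-applies a cosine-ramp (Tukey) taper to contain convolution border
effects.  Iterations stop when the relative power of the change between
consecutive estimates falls below a threshold.

Two mass-one adjacent distributions give the update operator a
zero-frequency gain near 2, so when adjacent lags are short relative to
the estimation window the plain iteration diverges through its DC mode
while all oscillatory modes stay contracting.  A divergence guard restarts
the iteration with per-iteration mean removal in that case (flagged in the
result); the mean level is restored by baseline correction downstream.

At convergence the estimate remains biased by second-order overlaps
(distribution self- and cross-convolutions with the kernel), which are
exposed as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

from ._conv import convolve_masses, convolve_signal
from .average_estimator import average_epochs
from .events_epochs import EpochSet, TimestampDistribution, baseline_correct
from .kernels import Kernel
from .windows import TimeWindow

__all__ = ["AdjarConfig", "AdjarResult", "run_adjar", "second_order_overlaps"]


@dataclass(frozen=True)
class AdjarConfig:
    """Iteration control for the adjacent-response correction.

    ``margin_ms`` extends the window of interest on both sides to form the
    estimation window (default 200 ms: interest [-250, 600] gives
    estimation window [-450, 800]); the taper ramps span ``taper_ramp_ms``
    at each end of the estimation window, so the margin must cover the
    ramp.  ``stop_threshold`` bounds the relative power
    ||a_k - a_{k-1}||^2 / ||a_{k-1}||^2 below which iteration stops.
    """

    interest: TimeWindow
    margin_ms: float = 200.0
    taper_ramp_ms: float = 200.0
    stop_threshold: float = 1e-5
    max_iterations: int = 200
    divergence_guard: bool = True
    baseline: TimeWindow | None = None

    def __post_init__(self) -> None:
        if self.margin_ms < self.taper_ramp_ms:
            raise ValueError("margin_ms must be >= taper_ramp_ms")
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")

    @property
    def estimation_window(self) -> TimeWindow:
        return self.interest.expand(self.margin_ms)


@dataclass
class AdjarResult:
    estimate: Kernel  # cropped to the window of interest
    estimate_full: Kernel  # over the estimation window
    ov_p: Kernel
    ov_s: Kernel
    ov_pp: Kernel
    ov_ss: Kernel
    ov_cross: Kernel
    n_iterations: int
    convergence_trace: np.ndarray
    converged: bool
    stabilized: bool = False
    config: AdjarConfig | None = None


class AdjarDivergenceError(RuntimeError):
    pass


def _iterate(
    av: np.ndarray,
    taper: np.ndarray,
    q_prev: TimestampDistribution,
    q_next: TimestampDistribution,
    est_start: int,
    config: AdjarConfig,
    demean: bool,
):
    """One pass of the fixed-point iteration; returns (estimate, trace, converged)."""

    def project(x: np.ndarray) -> np.ndarray:
        return x - x.mean(axis=0, keepdims=True) if demean else x

    n = av.shape[0]
    prev = project(av * taper[:, None])
    trace = []
    n_growing = 0
    for _ in range(config.max_iterations):
        ov_p = convolve_signal(
            q_prev.mass, q_prev.start_sample, prev, est_start, est_start, n
        )
        ov_s = convolve_signal(
            q_next.mass, q_next.start_sample, prev, est_start, est_start, n
        )
        new = project((av - ov_p - ov_s) * taper[:, None])
        denom = np.sum(prev**2, axis=0)
        num = np.sum((new - prev) ** 2, axis=0)
        crit = float(np.max(num / np.where(denom > 0, denom, 1.0)))
        trace.append(crit)
        if not np.isfinite(crit) or crit > 1e9:
            return prev, np.asarray(trace), False
        # geometric growth of the relative change means the fixed-point
        # iteration is diverging; bail out instead of overflowing
        n_growing = n_growing + 1 if crit > 4.0 else 0
        if n_growing >= 5:
            return prev, np.asarray(trace), False
        if crit < config.stop_threshold:
            # "no longer changes": return the iterate whose update fell
            # below threshold (so an infinite threshold returns the
            # untouched average).
            return prev, np.asarray(trace), True
        prev = new
    return prev, np.asarray(trace), False


def run_adjar(
    epochs: EpochSet,
    q_prev: TimestampDistribution,
    q_next: TimestampDistribution,
    config: AdjarConfig,
) -> AdjarResult:
    """Run the iterative adjacent-response correction on an epoch set.

    The epoch window must contain the estimation window; the timestamp
    distributions must live on the epoch sample grid.
    """
    est_win = config.estimation_window
    if not epochs.window.contains(est_win):
        raise ValueError(
            f"epoch window [{epochs.window.start_ms}, {epochs.window.end_ms}] "
            f"does not contain estimation window "
            f"[{est_win.start_ms}, {est_win.end_ms}]"
        )
    av_kernel = average_epochs(epochs)
    av = av_kernel.values[epochs.window.slice_of(est_win)]
    n = est_win.n_samples
    ramp = round(config.taper_ramp_ms * est_win.sample_rate_hz / 1000.0)
    taper = tukey(n, 2.0 * ramp / (n - 1)) if ramp > 0 else np.ones(n)
    est_start = est_win.start_sample

    estimate, trace, converged = _iterate(
        av, taper, q_prev, q_next, est_start, config, demean=False
    )
    stabilized = False
    n_iterations = len(trace)
    if not converged and config.divergence_guard:
        estimate, trace2, converged = _iterate(
            av, taper, q_prev, q_next, est_start, config, demean=True
        )
        trace = np.concatenate([trace, trace2])
        n_iterations = len(trace2)
        stabilized = True
    if not np.all(np.isfinite(estimate)):
        raise AdjarDivergenceError(
            f"non-finite estimate after {len(trace)} iterations"
        )

    full = Kernel(est_win, estimate, "adjar", epochs.ch_names)
    ov_p = Kernel(
        est_win,
        convolve_signal(q_prev.mass, q_prev.start_sample, estimate, est_start,
                        est_start, n),
        "ov_p",
        epochs.ch_names,
    )
    ov_s = Kernel(
        est_win,
        convolve_signal(q_next.mass, q_next.start_sample, estimate, est_start,
                        est_start, n),
        "ov_s",
        epochs.ch_names,
    )
    ov_pp, ov_ss = second_order_overlaps(full, q_prev, q_next)
    ov_cross = _second_order(full, q_prev, q_next, "ov_cross")

    cropped = full.crop(config.interest)
    if config.baseline is not None:
        cropped = baseline_correct(cropped, config.baseline)
    return AdjarResult(
        estimate=cropped,
        estimate_full=full,
        ov_p=ov_p,
        ov_s=ov_s,
        ov_pp=ov_pp,
        ov_ss=ov_ss,
        ov_cross=ov_cross,
        n_iterations=n_iterations,
        convergence_trace=trace,
        converged=converged,
        stabilized=stabilized,
        config=config,
    )


def _second_order(
    kernel: Kernel,
    q_a: TimestampDistribution,
    q_b: TimestampDistribution,
    label: str,
) -> Kernel:
    mass, start = convolve_masses(
        q_a.mass, q_a.start_sample, q_b.mass, q_b.start_sample
    )
    win = kernel.window
    vals = convolve_signal(
        mass, start, kernel.values, win.start_sample, win.start_sample, win.n_samples
    )
    return Kernel(win, vals, label, kernel.ch_names)


def second_order_overlaps(
    result_or_kernel: AdjarResult | Kernel,
    q_prev: TimestampDistribution,
    q_next: TimestampDistribution,
) -> tuple[Kernel, Kernel]:
    """Second-order overlap diagnostics (Q*Q convolved with the estimate).

    Returns ``(ov_pp, ov_ss)``, the previous and subsequent second-order
    response overlaps over the estimation window.  These are the leading
    distortions the first-order correction cannot remove; the cross term
    (previous*subsequent) is available via ``AdjarResult.ov_cross``.
    """
    kernel = (
        result_or_kernel.estimate_full
        if isinstance(result_or_kernel, AdjarResult)
        else result_or_kernel
    )
    ov_pp = _second_order(kernel, q_prev, q_prev, "ov_pp")
    ov_ss = _second_order(kernel, q_next, q_next, "ov_ss")
    return ov_pp, ov_ss
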