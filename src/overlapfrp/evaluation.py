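"""Estimator comparison metrics and the end-to-end pipeline.

Two qualitative criteria summarise estimate quality without ground truth:
stabilisation during the baseline period (variance over [-200, -100] ms)
and the return to zero of the amplitude at the end of the window (mean
absolute amplitude over a late interval, default [450, 600] ms).  On
synthetic sessions the RMSE against the known kernel is added.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .adjar import AdjarConfig, run_adjar
from .average_estimator import average_epochs
from .events_epochs import (
    EpochSet,
    baseline_correct,
    epoch_window_for_participant,
    extract_epochs,
    lag_distribution,
    select_ranks,
)
from .glm_deconv import ClassConfig, build_design, solve_glm
from .kernels import Kernel
from .synthetic import SyntheticSession
from .windows import TimeWindow

__all__ = [
    "ComparisonReport",
    "baseline_variance",
    "tail_deviation",
    "rmse",
    "compare_methods",
]

logger = logging.getLogger(__name__)

DEFAULT_BASELINE = (-200.0, -100.0)
DEFAULT_TAIL = (450.0, 600.0)


def _check_interval(kernel: Kernel, interval: TimeWindow) -> np.ndarray:
    m = kernel.window.mask_ms(interval.start_ms, interval.end_ms)
    if not m.any():
        raise ValueError(
            f"interval [{interval.start_ms}, {interval.end_ms}] ms outside "
            f"kernel window [{kernel.window.start_ms}, {kernel.window.end_ms}] ms"
        )
    return m


def baseline_variance(kernel: Kernel, interval: TimeWindow) -> float:
    """Per-channel variance of the waveform over the interval, channel-averaged."""
    m = _check_interval(kernel, interval)
    return float(kernel.values[m].var(axis=0, ddof=0).mean())


def tail_deviation(kernel: Kernel, interval: TimeWindow) -> float:
    """Mean absolute amplitude over a late interval (return-to-zero check)."""
    m = _check_interval(kernel, interval)
    return float(np.abs(kernel.values[m]).mean())


def rmse(kernel: Kernel, truth: Kernel) -> float:
    """Root-mean-square error on the overlap of both windows."""
    w = kernel.window
    tw = truth.window
    lo, hi = max(w.start_ms, tw.start_ms), min(w.end_ms, tw.end_ms)
    common = TimeWindow(lo, hi, w.sample_rate_hz)
    a = kernel.values[w.slice_of(common)]
    b = truth.values[tw.slice_of(common)]
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class ComparisonReport:
    metrics: dict[str, dict[str, float]]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None, indent: int = 2, deterministic: bool = True) -> str:
        """Serialise; with ``deterministic`` the wall-clock runtimes are
        dropped so reports from identical seeds are byte-identical."""
        metrics = self.metrics
        if deterministic:
            metrics = {
                m: {k: v for k, v in row.items() if k != "runtime_s"}
                for m, row in metrics.items()
            }
        payload = {"metrics": metrics, "metadata": self.metadata}
        text = json.dumps(payload, indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compare_methods(
    session: SyntheticSession,
    methods: tuple[str, ...] = ("average", "adjar", "glm"),
    seed: int | None = None,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    tail: tuple[float, float] = DEFAULT_TAIL,
) -> tuple[ComparisonReport, dict[str, Kernel]]:
    """Run the requested estimators on identical epochs and score them.

    The session's metadata fixes the lock class, the window of interest
    and (for fixation-locked sessions) the lock-rank draw.  All estimates
    receive the same baseline correction before the metrics; RMSE against
    the known kernel is reported for the lock class.
    """
    meta = session.meta
    fs = session.recording.sfreq
    interest = TimeWindow(*meta["interest"], fs)
    lock_class = meta["lock_class"]
    rng = np.random.default_rng(seed)

    if lock_class == "fixation":
        lo, hi = meta.get("rank_range", (3, 9))
        locks = select_ranks(session.events, lo, hi, meta.get("draws", 3), rng)
        if "epoch_window" in meta:
            epoch_win = TimeWindow(*meta["epoch_window"], fs)
        else:
            epoch_win = epoch_window_for_participant(session.events, interest)
        truth_key = "fixation"
    else:
        locks = None
        epoch_win = TimeWindow(*meta.get("epoch_window", meta["interest"]), fs)
        truth_key = "stimulus"
    epochs = extract_epochs(
        session.recording, session.events, lock_class, epoch_win, locks
    )
    truth = session.kernels.get(truth_key)

    bl = TimeWindow(*baseline, fs)
    tl = TimeWindow(*tail, fs) if tail[1] <= interest.end_ms else None
    estimates: dict[str, Kernel] = {}
    metrics: dict[str, dict[str, float]] = {}
    for method in methods:
        t0 = time.perf_counter()
        try:
            if method == "average":
                est = average_epochs(epochs).crop(interest)
            elif method == "adjar":
                cfg = AdjarConfig(
                    interest, margin_ms=meta.get("adjar_margin_ms", 200)
                )
                q_prev = lag_distribution(epochs, lock_class, -1)
                q_next = lag_distribution(epochs, lock_class, +1)
                est = run_adjar(epochs, q_prev, q_next, cfg).estimate
            elif method == "glm":
                classes = [ClassConfig(lock_class, lock_class, interest)]
                design = build_design(epochs, classes)
                est = solve_glm(design, epochs, compute_condition=False).kernels[
                    lock_class
                ]
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:
            raise RuntimeError(f"method {method!r} failed: {exc}") from exc
        runtime = time.perf_counter() - t0
        est = baseline_correct(est, bl)
        estimates[method] = est
        row = {
            "baseline_variance": baseline_variance(est, bl),
            "runtime_s": runtime,
        }
        if tl is not None:
            row["tail_deviation"] = tail_deviation(est, tl)
        if truth is not None:
            truth_bc = baseline_correct(
                truth.crop(interest) if truth.window.contains(interest) else truth,
                bl,
            )
            row["rmse"] = rmse(est, truth_bc)
        metrics[method] = row
    report = ComparisonReport(
        metrics,
        metadata={
            "seed": seed,
            "lock_class": lock_class,
            "interest": [interest.start_ms, interest.end_ms],
            "epoch_window": [epoch_win.start_ms, epoch_win.end_ms],
            "baseline": list(baseline),
            "n_epochs": epochs.n_epochs,
            "sample_rate_hz": fs,
        },
    )
    return report, estimates
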