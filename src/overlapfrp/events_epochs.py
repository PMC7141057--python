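"""Epoch extraction, baseline correction and timestamp distributions.

Epochs are fixed-length segments cut around a lock event (stimulus onset or
a fixation onset).  Besides the signal, each epoch records the lock-relative
onsets of *all* events of its trial, in exact sample units, so that overlap
distributions and deconvolution designs can be built downstream without
revisiting the continuous recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import singledispatch

import numpy as np
import pandas as pd

from .events import EventStream
from .kernels import Kernel
from .recording import Recording
from .windows import TimeWindow

__all__ = [
    "EpochSet",
    "TimestampDistribution",
    "extract_epochs",
    "baseline_correct",
    "lag_distribution",
    "epoch_window_for_participant",
    "ifi_summary",
    "select_ranks",
]

logger = logging.getLogger(__name__)


@dataclass
class TimestampDistribution:
    """Normalised lag histogram of events relative to the lock.

    ``mass[i]`` is the fraction of epochs whose target event falls at lag
    ``lags_ms[i]``; epochs lacking the target contribute nothing, so the
    total mass is <= 1, with equality iff every epoch contributes exactly
    one event.
    """

    lags_ms: np.ndarray
    mass: np.ndarray
    n_epochs: int
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.lags_ms.shape != self.mass.shape:
            raise ValueError("lags_ms and mass must have the same shape")
        if np.any(self.mass < 0):
            raise ValueError("mass must be nonnegative")
        if self.mass.sum() > 1 + 1e-9:
            raise ValueError(f"total mass {self.mass.sum():.6f} exceeds 1")

    @property
    def start_sample(self) -> int:
        return round(self.lags_ms[0] * self.sample_rate_hz / 1000.0)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def mean_lag_ms(self) -> float:
        m = self.total_mass
        if m == 0:
            return float("nan")
        return float((self.lags_ms * self.mass).sum() / m)


@dataclass
class EpochSet:
    """Epochs x samples x channels array time-locked to a lock class.

    ``events`` lists, per epoch, every event of the lock's trial with its
    lag relative to the lock in milliseconds and in exact grid samples
    (``lag_samples`` is authoritative for all sample-grid arithmetic).
    """

    data: np.ndarray  # (E, N_e, n_channels)
    window: TimeWindow
    lock_class: str
    events: pd.DataFrame  # epoch, class, lag_ms, lag_samples, rank, is_lock
    trial_ids: np.ndarray = field(default_factory=lambda: np.array([], int))
    lock_ranks: np.ndarray = field(default_factory=lambda: np.array([], float))
    ch_names: list[str] = field(default_factory=list)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x samples x channels")
        if self.data.shape[1] != self.window.n_samples:
            raise ValueError(
                f"epoch length {self.data.shape[1]} does not match window "
                f"sample count {self.window.n_samples}"
            )
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[2])]
        locks = self.events[self.events["is_lock"]]
        if len(locks) != self.n_epochs or (locks["lag_samples"] != 0).any():
            raise ValueError("each epoch must have exactly one lock event at lag 0")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def epoch_events(self, i: int) -> pd.DataFrame:
        return self.events[self.events["epoch"] == i]

    def reorder(self, order: np.ndarray) -> "EpochSet":
        """Permute epochs (used by invariance tests and the bootstrap)."""
        order = np.asarray(order)
        remap = {int(old): new for new, old in enumerate(order)}
        ev = self.events[self.events["epoch"].isin(remap)].copy()
        ev["epoch"] = ev["epoch"].map(remap)
        ev = ev.sort_values(["epoch", "lag_samples"], kind="stable").reset_index(drop=True)
        return EpochSet(
            self.data[order],
            self.window,
            self.lock_class,
            ev,
            self.trial_ids[order],
            self.lock_ranks[order],
            self.ch_names,
            self.n_rejected,
        )


def extract_epochs(
    recording: Recording,
    events: EventStream,
    lock_class: str,
    window: TimeWindow,
    lock_events: EventStream | None = None,
) -> EpochSet:
    """Cut one epoch per lock event from a continuous recording.

    Lock events are all events of ``lock_class`` unless an explicit
    ``lock_events`` stream (e.g. the output of :func:`select_ranks`) is
    given.  Epochs whose window falls outside the recording are rejected
    with a logged count.
    """
    if window.sample_rate_hz != recording.sfreq:
        raise ValueError(
            f"window grid ({window.sample_rate_hz} Hz) does not match "
            f"recording rate ({recording.sfreq} Hz)"
        )
    locks = (lock_events or events.for_class(lock_class)).df
    locks = locks[locks["class"] == lock_class]
    if locks.empty:
        raise ValueError(f"no events of lock class {lock_class!r}")

    w0, n_e = window.start_sample, window.n_samples
    segs, rows, trials, ranks = [], [], [], []
    n_rejected = 0
    epoch_idx = 0
    for _, lk in locks.iterrows():
        s_lock = recording.event_sample(int(lk["trial_id"]), lk["onset_ms"])
        lo = s_lock + w0
        if lo < 0 or lo + n_e > recording.n_samples:
            n_rejected += 1
            continue
        segs.append(recording.data[:, lo : lo + n_e].T)
        trial = events.for_trial(int(lk["trial_id"]))
        for _, ev in trial.iterrows():
            s_ev = recording.event_sample(int(ev["trial_id"]), ev["onset_ms"])
            rows.append(
                (
                    epoch_idx,
                    ev["class"],
                    ev["onset_ms"] - lk["onset_ms"],
                    s_ev - s_lock,
                    ev["rank"],
                    bool(
                        ev["class"] == lk["class"]
                        and ev["onset_ms"] == lk["onset_ms"]
                    ),
                )
            )
        trials.append(int(lk["trial_id"]))
        ranks.append(float(lk["rank"]) if pd.notna(lk["rank"]) else np.nan)
        epoch_idx += 1
    if n_rejected:
        logger.info(
            "extract_epochs: rejected %d/%d lock events too close to the "
            "recording edge",
            n_rejected,
            len(locks),
        )
    if not segs:
        raise ValueError("all lock events rejected: window exceeds recording")
    ev_df = pd.DataFrame(
        rows, columns=["epoch", "class", "lag_ms", "lag_samples", "rank", "is_lock"]
    )
    ev_df["lag_samples"] = ev_df["lag_samples"].astype(int)
    return EpochSet(
        np.stack(segs),
        window,
        lock_class,
        ev_df,
        np.asarray(trials),
        np.asarray(ranks),
        list(recording.ch_names),
        n_rejected,
    )


@singledispatch
def baseline_correct(obj, baseline: TimeWindow):
    """Subtract the per-channel mean over ``baseline`` (e.g. [-200, -100] ms)."""
    raise TypeError(f"baseline_correct not implemented for {type(obj).__name__}")


def _check_baseline(window: TimeWindow, baseline: TimeWindow) -> np.ndarray:
    if not window.contains(baseline.with_rate(window.sample_rate_hz)):
        raise ValueError(
            f"baseline [{baseline.start_ms}, {baseline.end_ms}] ms outside "
            f"window [{window.start_ms}, {window.end_ms}] ms"
        )
    return window.mask_ms(baseline.start_ms, baseline.end_ms)


@baseline_correct.register
def _(obj: Kernel, baseline: TimeWindow) -> Kernel:
    m = _check_baseline(obj.window, baseline)
    return Kernel(
        obj.window, obj.values - obj.values[m].mean(axis=0), obj.label, obj.ch_names
    )


@baseline_correct.register
def _(obj: EpochSet, baseline: TimeWindow) -> EpochSet:
    m = _check_baseline(obj.window, baseline)
    data = obj.data - obj.data[:, m, :].mean(axis=1, keepdims=True)
    return EpochSet(
        data,
        obj.window,
        obj.lock_class,
        obj.events,
        obj.trial_ids,
        obj.lock_ranks,
        obj.ch_names,
        obj.n_rejected,
    )


def lag_distribution(
    epochs: EpochSet,
    target_class: str,
    relative_rank: int,
    lag_window: TimeWindow | None = None,
) -> TimestampDistribution:
    """Normalised timestamp distribution of the event at ``relative_rank``.

    ``relative_rank`` counts events of ``target_class`` away from the lock
    in time order: -1 is the immediately previous event, +1 the immediately
    subsequent one, 0 the lock itself (a unit mass at lag zero when the
    target class is the lock class).  Mass is normalised by the number of
    epochs; epochs lacking the requested event contribute nothing.
    """
    win = lag_window or epochs.window
    if win.sample_rate_hz != epochs.window.sample_rate_hz:
        raise ValueError("lag window must share the epoch sample grid")
    s0, n = win.start_sample, win.n_samples
    mass = np.zeros(n)
    e = epochs.n_epochs
    ev = epochs.events
    ev = ev[ev["class"] == target_class]
    for i, grp in ev.groupby("epoch"):
        lags = np.sort(grp["lag_samples"].to_numpy())
        if relative_rank == 0:
            sel = lags[lags == 0]
        elif relative_rank < 0:
            prev = lags[lags < 0][::-1]  # nearest first
            sel = prev[-relative_rank - 1 : -relative_rank]
        else:
            nxt = lags[lags > 0]
            sel = nxt[relative_rank - 1 : relative_rank]
        if sel.size:
            idx = int(sel[0]) - s0
            if 0 <= idx < n:
                mass[idx] += 1.0 / e
    return TimestampDistribution(win.times_ms(), mass, e, win.sample_rate_hz)


def ifi_summary(events: EventStream) -> tuple[float, float, float]:
    """Inter-fixation-interval mean, sd and tau = mean + sd, in ms.

    The IFI is the onset-to-onset difference of consecutive fixations
    (fixation duration plus subsequent saccade duration), pooled over
    trials.
    """
    fix = events.for_class("fixation").df
    ifis = []
    for _, grp in fix.groupby("trial_id"):
        ifis.extend(np.diff(grp["onset_ms"].to_numpy()))
    if not ifis:
        raise ValueError("no inter-fixation intervals computable (need >=2 fixations)")
    ifis = np.asarray(ifis)
    mean = float(ifis.mean())
    sd = float(ifis.std(ddof=1)) if ifis.size > 1 else 0.0
    return mean, sd, mean + sd


def epoch_window_for_participant(
    events: EventStream,
    interest: TimeWindow,
    round_up_to_ms: float = 10.0,
) -> TimeWindow:
    """Per-participant epoch window [start - tau, end + tau].

    tau is the sum of the participant's mean and standard deviation of the
    inter-fixation-interval distribution, rounded up to ``round_up_to_ms``
    (and to the sample grid), so the epoch covers the responses of the
    previous and subsequent fixations in nearly all epochs.
    """
    _, _, tau = ifi_summary(events)
    step = max(round_up_to_ms, interest.step_ms)
    tau_r = TimeWindow.round_up_to_grid(tau, step)
    return interest.expand(tau_r)


def select_ranks(
    events: EventStream,
    low: int = 3,
    high: int = 9,
    draws: int = 3,
    seed: int | np.random.Generator | None = None,
) -> EventStream:
    """Randomly draw fixation ranks per trial (uniform, with replacement).

    Emulates lock-event selection in the middle of visual exploration:
    per trial, ``draws`` ranks are drawn uniformly from [low, high] and the
    corresponding fixation events returned (duplicate draws collapse to
    unique events).  Trials whose maximum rank is below ``low`` are skipped
    with a logged count.
    """
    if low > high:
        raise ValueError("low must not exceed high")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fix = events.df[events.df["class"] == "fixation"]  # keep original indices
    chosen: list[int] = []
    n_skipped = n_dup = 0
    for _, grp in fix.groupby("trial_id"):
        max_rank = int(grp["rank"].max()) if grp["rank"].notna().all() else len(grp)
        if max_rank < low:
            n_skipped += 1
            continue
        hi = min(high, max_rank)
        picks = rng.integers(low, hi + 1, size=draws)
        uniq = np.unique(picks)
        n_dup += draws - uniq.size
        for r in uniq:
            chosen.append(grp.index[grp["rank"] == r][0])
    if n_skipped:
        logger.info("select_ranks: skipped %d trials with max rank < %d", n_skipped, low)
    if n_dup:
        logger.info("select_ranks: collapsed %d duplicate draws", n_dup)
    if not chosen:
        raise ValueError(f"no trials with fixations of rank >= {low}")
    return events.subset(chosen)
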