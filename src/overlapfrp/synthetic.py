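"""Ground-truth session generator for estimator validation.

A synthetic session mimics a free-scene-exploration co-registration
experiment: each 4-s trial starts with a stimulus onset at t=0, the first
fixation lands after the first-saccade latency, and subsequent fixations
follow at inter-fixation intervals (IFIs).  The recording is the strictly
linear superposition of one kernel per event plus optional noise, so every
estimator can be scored by parameter recovery.

Defaults reproduce the oculomotor statistics of the emulated paradigm:
first-fixation latency 307.65 (46.14) ms and IFI mean 288.69 ms.  The IFI
draw sd defaults to the *within-participant* spread (117.68 ms, the value
implied by an epoch-margin tau of 406.37 ms = mean + sd); the
between-participant sd of IFI means (26.97 ms) is exposed separately for
multi-participant simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .events import EventStream
from .kernels import Kernel, KernelSpec
from .recording import Recording
from .windows import TimeWindow

__all__ = [
    "OculomotorModel",
    "NoiseModel",
    "SyntheticSession",
    "sample_fixation_sequence",
    "render_session",
    "make_fixture",
    "PRESETS",
]

# Stand-in evoked responses: sums of Gaussian bumps.  The fixation kernel is
# dominated by the lambda response (positive, ~100 ms), followed by an
# N1-like negativity and a small late positivity.
LAMBDA_COMPONENTS = ((100.0, 8.0, 30.0), (180.0, -3.0, 50.0), (280.0, 1.5, 80.0))
# Stimulus-onset kernel: P1, P2 and a slower late component.
STIMULUS_COMPONENTS = ((90.0, 6.0, 25.0), (200.0, 4.0, 50.0), (350.0, 2.0, 120.0))
# First-fixation lambda is larger than at later fixations.
FIRST_FIX_COMPONENTS = ((100.0, 9.5, 30.0), (180.0, -3.0, 50.0), (280.0, 1.5, 80.0))

PRESETS = (
    "mid_exploration",
    "onset_two_class",
    "onset_three_class",
    "first_order_only",
)


@dataclass(frozen=True)
class OculomotorModel:
    """Generative model of per-trial fixation sequences.

    ``first_latency`` and ``ifi`` are (mean_ms, sd_ms) of the first-saccade
    landing time and of the inter-fixation interval; draws below
    ``min_interval_ms`` are floored there (fixations shorter than 50 ms are
    not retained in the emulated paradigm).  ``ifi_between_sd`` adds a
    participant-level offset to the IFI mean when simulating cohorts.
    """

    first_latency: tuple[float, float] = (307.65, 46.14)
    ifi: tuple[float, float] = (288.69, 117.68)
    ifi_between_sd: float = 26.97
    min_interval_ms: float = 50.0
    trial_duration_ms: float = 4000.0

    def __post_init__(self) -> None:
        if self.first_latency[0] <= 0 or self.ifi[0] <= 0:
            raise ValueError("latency and IFI means must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Ongoing-activity noise added to the rendered recording.

    ``family`` is one of ``none``, ``white``, ``ar1``; ``sd_uv`` is the
    marginal standard deviation in microvolts.  For ``ar1`` the innovation
    variance is scaled so the process sd equals ``sd_uv`` regardless of the
    coefficient.
    """

    family: str = "none"
    sd_uv: float = 0.0
    ar_coefficient: float = 0.95

    def __post_init__(self) -> None:
        if self.family not in ("none", "white", "ar1"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.sd_uv < 0:
            raise ValueError("sd_uv must be nonnegative")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in (-1, 1)")

    def sample(self, n_channels: int, n_samples: int, rng: np.random.Generator):
        if self.family == "none" or self.sd_uv == 0:
            return np.zeros((n_channels, n_samples))
        if self.family == "white":
            return rng.normal(0.0, self.sd_uv, (n_channels, n_samples))
        phi = self.ar_coefficient
        burn = 500
        innov = rng.normal(
            0.0, self.sd_uv * np.sqrt(1 - phi**2), (n_channels, n_samples + burn)
        )
        return lfilter([1.0], [1.0, -phi], innov, axis=1)[:, burn:]


def sample_fixation_sequence(
    model: OculomotorModel,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
) -> EventStream:
    """Draw stimulus + fixation events for ``n_trials`` trials.

    Per trial the stimulus sits at 0 ms; fixation k lands at the first
    latency plus the cumulative sum of k-1 IFI draws, stopping before the
    trial ends.  Onsets are rounded to integer milliseconds.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        rows.append((trial, "stimulus", 0.0, 1))
        t = max(model.min_interval_ms, rng.normal(*model.first_latency))
        rank = 1
        while t < model.trial_duration_ms:
            rows.append((trial, "fixation", float(np.floor(t + 0.5)), rank))
            t += max(model.min_interval_ms, rng.normal(*model.ifi))
            rank += 1
    return EventStream(
        pd.DataFrame(rows, columns=["trial_id", "class", "onset_ms", "rank"])
    )


def render_session(
    events: EventStream,
    kernels: dict[str, Kernel],
    noise: NoiseModel | None = None,
    sample_rate_hz: float = 1000.0,
    trial_duration_ms: float = 4000.0,
    pad_ms: float = 2500.0,
    kernel_for=None,
    seed: int | np.random.Generator | None = None,
) -> Recording:
    """Superpose one kernel per event into a continuous recording.

    Trials are laid out consecutively, each padded by ``pad_ms`` of
    event-free signal on both sides so epochs never cross trial bounds.
    ``kernel_for(class_label, rank) -> key`` may remap events to kernel
    keys (e.g. to give the first fixation its own kernel); by default the
    event's class label is the key.
    """
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = sample_rate_hz
    n_ch = next(iter(kernels.values())).n_channels if kernels else 1
    for k in kernels.values():
        if k.window.sample_rate_hz != fs:
            raise ValueError(
                f"kernel {k.label!r} grid {k.window.sample_rate_hz} Hz does "
                f"not match sample_rate_hz {fs}"
            )
        if k.n_channels != n_ch:
            raise ValueError("kernels must share the channel count")
    slot = trial_duration_ms + 2 * pad_ms
    trial_ids = sorted(events.trial_ids) if len(events) else []
    trial_onsets = {t: pad_ms + i * slot for i, t in enumerate(trial_ids)}
    n_samples = max(1, round(len(trial_ids) * slot * fs / 1000.0))
    data = noise.sample(n_ch, n_samples, rng)
    rec = Recording(data, fs, [f"ch{i}" for i in range(n_ch)], trial_onsets)
    for _, ev in events.df.iterrows():
        key = (
            kernel_for(ev["class"], ev["rank"])
            if kernel_for is not None
            else ev["class"]
        )
        if key not in kernels:
            raise KeyError(f"no kernel for event class {key!r}")
        kern = kernels[key]
        s_ev = rec.event_sample(int(ev["trial_id"]), ev["onset_ms"])
        lo = s_ev + kern.window.start_sample
        a, b = max(lo, 0), min(lo + kern.window.n_samples, n_samples)
        if b > a:
            rec.data[:, a:b] += kern.values[a - lo : b - lo].T
    return rec


@dataclass
class SyntheticSession:
    """A rendered session plus its ground truth."""

    recording: Recording
    events: EventStream
    kernels: dict[str, Kernel]
    meta: dict = field(default_factory=dict)
    oculomotor: OculomotorModel | None = None
    noise: NoiseModel | None = None
    seed: int | None = None


def make_fixture(
    preset: str,
    seed: int | None = None,
    n_trials: int = 50,
    sample_rate_hz: float = 1000.0,
    noise: NoiseModel | None = None,
) -> SyntheticSession:
    """Build a named ground-truth session.

    Presets
    -------
    ``mid_exploration``
        Fixation-locked estimation in the middle of exploration: one shared
        fixation kernel, default oculomotor statistics, lock ranks 3-9
        (three draws per trial).
    ``onset_two_class`` / ``onset_three_class``
        Stimulus-locked sessions for the two- and three-class
        deconvolution models (the three-class variant gives the first
        fixation its own, larger-lambda kernel).
    ``first_order_only``
        Sequences engineered so each epoch holds exactly one previous and
        one subsequent event, with second-order lag supports outside the
        [-450, 800] ms estimation window: the validity regime of iterative
        adjacent-response correction.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    noise = noise or NoiseModel()
    fix_win = TimeWindow(-250, 600, fs)
    onset_fix_win = TimeWindow(-200, 800, fs)
    stim_win = TimeWindow(-200, 1500, fs)

    if preset in ("mid_exploration", "first_order_only"):
        if preset == "mid_exploration":
            oculo = OculomotorModel()
            meta = {
                "lock_class": "fixation",
                "interest": (-250, 600),
                "rank_range": (3, 9),
                "draws": 3,
                "adjar_margin_ms": 200,
            }
        else:
            oculo = OculomotorModel(first_latency=(650.0, 30.0), ifi=(650.0, 30.0))
            meta = {
                "lock_class": "fixation",
                "interest": (-250, 600),
                "rank_range": (2, 4),
                "draws": 1,
                "adjar_margin_ms": 200,
                "epoch_window": (-930, 1100),
            }
        events = sample_fixation_sequence(oculo, n_trials, rng)
        kernels = {
            "fixation": KernelSpec(LAMBDA_COMPONENTS, fix_win).render(
                label="fixation"
            )
        }
        rec = render_session(
            events.for_class("fixation"),
            kernels,
            noise,
            fs,
            oculo.trial_duration_ms,
            seed=rng,
        )
        return SyntheticSession(rec, events, kernels, meta, oculo, noise, seed)

    oculo = OculomotorModel()
    events = sample_fixation_sequence(oculo, n_trials, rng)
    stim = KernelSpec(STIMULUS_COMPONENTS, stim_win).render(label="stimulus")
    if preset == "onset_two_class":
        kernels = {
            "stimulus": stim,
            "fixation": KernelSpec(LAMBDA_COMPONENTS, onset_fix_win).render(
                label="fixation"
            ),
        }
        rec = render_session(
            events, kernels, noise, fs, oculo.trial_duration_ms, seed=rng
        )
        meta = {
            "lock_class": "stimulus",
            "interest": (-200, 1500),
            "epoch_window": (-200, 1500),
            "classes": "two",
        }
        return SyntheticSession(rec, events, kernels, meta, oculo, noise, seed)

    kernels = {
        "stimulus": stim,
        "fixation_first": KernelSpec(FIRST_FIX_COMPONENTS, onset_fix_win).render(
            label="fixation_first"
        ),
        "fixation_rest": KernelSpec(LAMBDA_COMPONENTS, onset_fix_win).render(
            label="fixation_rest"
        ),
    }

    def kernel_for(class_label: str, rank) -> str:
        if class_label == "stimulus":
            return "stimulus"
        return "fixation_first" if rank == 1 else "fixation_rest"

    rec = render_session(
        events,
        kernels,
        noise,
        fs,
        oculo.trial_duration_ms,
        kernel_for=kernel_for,
        seed=rng,
    )
    meta = {
        "lock_class": "stimulus",
        "interest": (-200, 1500),
        "epoch_window": (-200, 1500),
        "classes": "three",
    }
    return SyntheticSession(rec, events, kernels, meta, oculo, noise, seed)
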