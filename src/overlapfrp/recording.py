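"""Continuous multichannel recordings with a trial layout.

The container is deliberately minimal: a channels x samples array in
microvolts, a sampling rate, channel names, and the absolute onset of each
trial inside the continuous signal (so per-trial event onsets can be mapped
to absolute sample indices).  HDF5 layout: dataset ``/data`` with attributes
``sfreq`` and ``ch_names``, plus ``/trial_ids`` and ``/trial_onsets_ms``.
A plain-text TSV writer is provided for small recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples), microvolts
    sfreq: float
    ch_names: list[str] = field(default_factory=list)
    trial_onsets_ms: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_sample(self, t_ms: float) -> int:
        """Absolute ms -> sample index, rounding half up (bit-stable)."""
        return int(np.floor(t_ms * self.sfreq / 1000.0 + 0.5))

    def event_sample(self, trial_id: int, onset_ms: float) -> int:
        try:
            t0 = self.trial_onsets_ms[trial_id]
        except KeyError:
            raise KeyError(f"recording has no trial {trial_id}") from None
        return self.to_sample(t0 + onset_ms)

    # -- io --------------------------------------------------------------

    def save_h5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=self.data)
            d.attrs["sfreq"] = self.sfreq
            d.attrs["ch_names"] = [str(c) for c in self.ch_names]
            ids = sorted(self.trial_onsets_ms)
            f.create_dataset("trial_ids", data=np.asarray(ids, dtype=np.int64))
            f.create_dataset(
                "trial_onsets_ms",
                data=np.asarray([self.trial_onsets_ms[i] for i in ids]),
            )

    @classmethod
    def load_h5(cls, path: str | Path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            d = f["data"]
            data = d[()]
            sfreq = float(d.attrs["sfreq"])
            ch_names = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in d.attrs.get("ch_names", [])
            ]
            onsets = {}
            if "trial_ids" in f:
                onsets = dict(
                    zip(
                        (int(i) for i in f["trial_ids"][()]),
                        (float(t) for t in f["trial_onsets_ms"][()]),
                    )
                )
        return cls(data, sfreq, ch_names, onsets)

    def save_tsv(self, path: str | Path) -> None:
        """Delimited text: one row per sample, one column per channel."""
        header = "\t".join(self.ch_names)
        meta = (
            f"# sfreq={self.sfreq}\n# trials="
            + ",".join(f"{k}:{v}" for k, v in sorted(self.trial_onsets_ms.items()))
            + "\n"
        )
        with open(path, "w") as fh:
            fh.write(meta)
            fh.write(header + "\n")
            np.savetxt(fh, self.data.T, delimiter="\t", fmt="%.10g")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Recording":
        sfreq = None
        onsets: dict[int, float] = {}
        with open(path) as fh:
            line = fh.readline()
            while line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sfreq="):
                    sfreq = float(body.split("=", 1)[1])
                elif body.startswith("trials="):
                    items = body.split("=", 1)[1]
                    if items:
                        for kv in items.split(","):
                            k, v = kv.split(":")
                            onsets[int(k)] = float(v)
                line = fh.readline()
            ch_names = line.strip().split("\t")
            data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
        if sfreq is None:
            raise ValueError(f"{path}: missing '# sfreq=' header line")
        return cls(data, sfreq, ch_names, onsets)

    def to_mne_raw(self):
        """Adapter to an :class:`mne.io.RawArray` (requires mne)."""
        import mne

        info = mne.create_info(self.ch_names, self.sfreq, ch_types="eeg")
        # mne expects volts
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")
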