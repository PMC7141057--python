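"""Event streams: class-labelled, trial-organised event onsets.

An :class:`EventStream` holds one row per event with columns
``trial_id, class, onset_ms, rank``.  Onsets are milliseconds from trial
start; ``rank`` orders events of a class within a trial (fixation rank 1 is
the first fixation after stimulus onset).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["EventStream"]

COLUMNS = ["trial_id", "class", "onset_ms", "rank"]


class EventStream:
    """Timestamped, class-labelled events for a set of trials.

    Wraps a :class:`pandas.DataFrame` with columns ``trial_id`` (int),
    ``class`` (str), ``onset_ms`` (float, ms from trial start) and ``rank``
    (nullable int).  Invariants checked on construction: onsets strictly
    increase within (trial, class); ranks, where present, are consecutive
    from 1 in onset order.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS[:3] if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        df = df.copy()
        if "rank" not in df.columns:
            df["rank"] = pd.NA
        df["trial_id"] = df["trial_id"].astype(int)
        df["class"] = df["class"].astype(str)
        df["onset_ms"] = df["onset_ms"].astype(float)
        df["rank"] = df["rank"].astype("Int64")
        df = df.sort_values(["trial_id", "onset_ms"], kind="stable")
        self.df = df.reset_index(drop=True)[COLUMNS]
        if validate:
            self._validate()

    def _validate(self) -> None:
        for (trial, cls), grp in self.df.groupby(["trial_id", "class"], sort=False):
            onsets = grp["onset_ms"].to_numpy()
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(
                    f"onsets not strictly increasing for trial {trial}, "
                    f"class {cls!r}"
                )
            ranks = grp["rank"]
            if ranks.notna().all() and len(ranks):
                expected = np.arange(1, len(ranks) + 1)
                if not np.array_equal(ranks.to_numpy(int), expected):
                    raise ValueError(
                        f"ranks not consecutive from 1 for trial {trial}, "
                        f"class {cls!r}: {list(ranks)}"
                    )

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def trial_ids(self) -> np.ndarray:
        return np.unique(self.df["trial_id"].to_numpy())

    @property
    def classes(self) -> list[str]:
        return sorted(self.df["class"].unique())

    def for_class(self, class_label: str) -> "EventStream":
        return EventStream(self.df[self.df["class"] == class_label], validate=False)

    def for_trial(self, trial_id: int) -> pd.DataFrame:
        return self.df[self.df["trial_id"] == trial_id]

    def subset(self, index: Iterable[int]) -> "EventStream":
        return EventStream(self.df.loc[list(index)], validate=False)

    # -- io --------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "EventStream":
        """Read an event table (CSV or TSV, UTF-8)."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EventStream({len(self)} events, {len(self.trial_ids)} trials, "
            f"classes={self.classes})"
        )
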