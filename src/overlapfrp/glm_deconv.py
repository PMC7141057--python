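"""Multi-class linear deconvolution of overlapping evoked responses.

Each event class contributes a block of columns to a sparse 0/1 design
matrix: an event at epoch-relative onset tau places a diagonal stripe of
ones so that row (epoch offset + tau + j) meets column (class offset + j)
for every lag j of the class's estimation window, with stripes clipped at
epoch edges.  Stacking all epochs gives x = D a + n, solved per channel by
least squares; the condition number of the Gram matrix D'D diagnoses how
much timestamp jitter separates the classes (the pure averaging design has
condition number exactly 1), and a trial-resampling bootstrap estimates
the variance of each recovered waveform.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import lsqr

from .events_epochs import EpochSet, baseline_correct
from .kernels import Kernel
from .windows import TimeWindow

__all__ = [
    "ClassConfig",
    "DesignMatrix",
    "GlmResult",
    "BootstrapReport",
    "build_design",
    "solve_glm",
    "gram_condition_number",
    "bootstrap_variance",
]

logger = logging.getLogger(__name__)


def _parse_rank_spec(spec) -> Callable[[object], bool]:
    """Rank selector from specs like None, 3, "1", ">=2", "2+", "3-9"."""
    if spec is None:
        return lambda r: True
    if isinstance(spec, (int, np.integer)):
        return lambda r, v=int(spec): not pd.isna(r) and int(r) == v
    s = str(spec).strip()
    if m := re.fullmatch(r"(\d+)", s):
        v = int(m.group(1))
        return lambda r: not pd.isna(r) and int(r) == v
    if m := re.fullmatch(r">=\s*(\d+)", s):
        v = int(m.group(1))
        return lambda r: not pd.isna(r) and int(r) >= v
    if m := re.fullmatch(r"(\d+)\+", s):
        v = int(m.group(1))
        return lambda r: not pd.isna(r) and int(r) >= v
    if m := re.fullmatch(r"(\d+)\s*-\s*(\d+)", s):
        lo, hi = int(m.group(1)), int(m.group(2))
        return lambda r: not pd.isna(r) and lo <= int(r) <= hi
    raise ValueError(f"cannot parse rank spec {spec!r}")


@dataclass(frozen=True)
class ClassConfig:
    """One deconvolution class: which events it gathers, over which window."""

    name: str
    class_label: str
    window: TimeWindow
    ranks: object = None  # None (any), int, "1", ">=2", "2+", "3-9"

    def matches(self, class_label: str, rank) -> bool:
        return class_label == self.class_label and _parse_rank_spec(self.ranks)(rank)

    @classmethod
    def from_dict(cls, d: dict, sample_rate_hz: float = 1000.0) -> "ClassConfig":
        w = d["window"]
        return cls(
            name=d.get("name", d["class"]),
            class_label=d["class"],
            window=TimeWindow(w[0], w[1], d.get("sample_rate_hz", sample_rate_hz)),
            ranks=d.get("rank"),
        )


@dataclass
class DesignMatrix:
    matrix: sp.csr_matrix  # (E * N_e) x sum(N_c), entries in {0, 1}
    classes: list[ClassConfig]
    n_epochs: int
    n_samples_epoch: int
    epoch_window: TimeWindow

    @property
    def col_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for c in self.classes:
            out[c.name] = slice(start, start + c.window.n_samples)
            start += c.window.n_samples
        return out

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def rows_of_epoch(self, i: int) -> slice:
        return slice(i * self.n_samples_epoch, (i + 1) * self.n_samples_epoch)

    def events_per_class(self) -> pd.DataFrame:
        """(epoch x class) table of modelled event counts."""
        return self._event_counts

    _event_counts: pd.DataFrame = field(default=None, repr=False)


def build_design(epochs: EpochSet, classes: list[ClassConfig]) -> DesignMatrix:
    """Assemble the stacked sparse Toeplitz design for an epoch set.

    Every event whose response stripe intersects the epoch rows is
    modelled, including events just outside the epoch window whose kernels
    bleed in; stripes are clipped at epoch edges, so partially observed
    responses contribute partial evidence.  An event matched by two
    classes is a configuration error.
    """
    for c in classes:
        if c.window.sample_rate_hz != epochs.window.sample_rate_hz:
            raise ValueError(f"class {c.name!r} window not on the epoch grid")
    n_e = epochs.window.n_samples
    w0 = epochs.window.start_sample
    col_off, offsets = 0, {}
    for c in classes:
        offsets[c.name] = col_off
        col_off += c.window.n_samples
    n_cols = col_off
    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    counts = np.zeros((epochs.n_epochs, len(classes)), dtype=int)

    for _, ev in epochs.events.iterrows():
        matched = [
            (ci, c) for ci, c in enumerate(classes) if c.matches(ev["class"], ev["rank"])
        ]
        if len(matched) > 1:
            names = [c.name for _, c in matched]
            raise ValueError(
                f"event (class={ev['class']!r}, rank={ev['rank']}) matched by "
                f"multiple classes: {names}"
            )
        if not matched:
            continue
        ci, c = matched[0]
        tau = int(ev["lag_samples"])  # epoch-relative onset in samples
        c0, n_c = c.window.start_sample, c.window.n_samples
        # stripe: row r = tau + c0 + j - w0, col = offset + j
        j_lo = max(0, w0 - tau - c0)
        j_hi = min(n_c, w0 + n_e - tau - c0)
        if j_hi <= j_lo:
            continue
        j = np.arange(j_lo, j_hi)
        e = int(ev["epoch"])
        rows_idx.append(e * n_e + tau + c0 + j - w0)
        cols_idx.append(offsets[c.name] + j)
        counts[e, ci] += 1

    if rows_idx:
        rows = np.concatenate(rows_idx)
        cols = np.concatenate(cols_idx)
        data = np.ones(rows.size)
    else:
        rows = cols = np.array([], dtype=int)
        data = np.array([])
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(epochs.n_epochs * n_e, n_cols)
    ).tocsr()
    dm = DesignMatrix(mat, list(classes), epochs.n_epochs, n_e, epochs.window)
    dm._event_counts = pd.DataFrame(counts, columns=[c.name for c in classes])
    return dm


@dataclass
class GlmResult:
    kernels: dict[str, Kernel]
    residual_norm: float
    gram_condition: float
    rank_deficient: bool
    coefficients: np.ndarray = field(default=None, repr=False)  # (P, n_channels)


def solve_glm(
    design: DesignMatrix,
    epochs: EpochSet,
    baseline: TimeWindow | None = None,
    compute_condition: bool = True,
    atol: float = 1e-12,
) -> GlmResult:
    """Least-squares deconvolution, one shared design for all channels.

    Solved per channel with LSQR (a numerically stable Krylov
    factorization that, starting from zero, yields the minimum-norm
    least-squares solution; equal to (D'D)^-1 D'x whenever D'D is
    invertible).  Optional baseline correction is applied to the estimated
    kernels after solving.
    """
    n_rows = design.shape[0]
    if epochs.n_epochs * epochs.window.n_samples != n_rows:
        raise ValueError(
            f"design has {n_rows} rows but epochs flatten to "
            f"{epochs.n_epochs * epochs.window.n_samples} samples"
        )
    x = epochs.data.reshape(n_rows, epochs.n_channels)
    p = design.shape[1]
    coef = np.empty((p, epochs.n_channels))
    for c in range(epochs.n_channels):
        sol = lsqr(design.matrix, x[:, c], atol=atol, btol=atol, iter_lim=8 * p)
        coef[:, c] = sol[0]
    resid = design.matrix @ coef - x
    cond = gram_condition_number(design) if compute_condition else float("nan")
    rank_deficient = not np.isfinite(cond)
    kernels = {}
    for c, slc in zip(design.classes, design.col_slices.values()):
        k = Kernel(c.window, coef[slc].copy(), c.name, epochs.ch_names)
        if baseline is not None:
            k = baseline_correct(k, baseline)
        kernels[c.name] = k
    return GlmResult(
        kernels=kernels,
        residual_norm=float(np.linalg.norm(resid)),
        gram_condition=cond,
        rank_deficient=rank_deficient,
        coefficients=coef,
    )


def gram_condition_number(design: DesignMatrix | sp.spmatrix) -> float:
    """2-norm condition number of the Gram matrix D'D.

    Ratio of its extreme eigenvalues (the squared extreme singular values
    of D); +inf when singular to machine precision.  The single-class
    design with every event at lag zero and the estimation window equal to
    the epoch window has D'D = E*I and condition number exactly 1.
    """
    mat = design.matrix if isinstance(design, DesignMatrix) else design
    p = mat.shape[1]
    if p == 0:
        raise ValueError("empty design")
    if p > 6000:  # dense Gram would not fit comfortably
        raise ValueError(f"design too large for dense Gram diagnostics (P={p})")
    gram = np.asarray((mat.T @ mat).todense())
    ev = np.linalg.eigvalsh(gram)
    lo, hi = float(ev[0]), float(ev[-1])
    if hi <= 0 or lo <= hi * 1e-12:
        return float("inf")
    return hi / lo


@dataclass
class BootstrapReport:
    """Trial-resampling bootstrap of deconvolution variance.

    ``variance`` maps class name to a (N_c, n_channels) array of
    per-sample variances across replications; ``summary`` averages each
    curve over the window of interest and channels.
    """

    replications: int
    variance: dict[str, np.ndarray]
    summary: dict[str, float]
    seed: int | None
    interest: TimeWindow | None = None
    condition_numbers: np.ndarray | None = None
    n_redrawn: int = 0


def bootstrap_variance(
    epochs: EpochSet,
    classes: list[ClassConfig],
    replications: int = 10_000,
    seed: int | None = None,
    interest: TimeWindow | None = None,
    record_condition: bool = False,
    max_redraws: int = 100,
) -> BootstrapReport:
    """Variance of the deconvolved kernels under epoch resampling.

    Epochs (trials) are resampled with replacement; each replication
    re-solves the least-squares problem.  Because a resampled design is a
    reweighting of per-epoch blocks, the normal equations are assembled
    from cached per-epoch Gram blocks and solved by Cholesky — identical
    to the full least-squares solution whenever the resampled design has
    full column rank (singular resamples fall back to a pseudo-inverse
    solve).  Replications in which a class receives zero events are
    redrawn, up to ``max_redraws`` per replication.
    """
    if replications < 2:
        raise ValueError("replications must be >= 2")
    rng = np.random.default_rng(seed)
    design = build_design(epochs, classes)
    e_n, p = epochs.n_epochs, design.shape[1]
    n_ch = epochs.n_channels
    x = epochs.data.reshape(e_n * epochs.window.n_samples, n_ch)

    # per-epoch sufficient statistics
    grams = np.empty((e_n, p, p))
    rhs = np.empty((e_n, p, n_ch))
    for i in range(e_n):
        di = design.matrix[design.rows_of_epoch(i)]
        grams[i] = np.asarray((di.T @ di).todense())
        rhs[i] = di.T @ x[design.rows_of_epoch(i)]
    class_counts = design.events_per_class().to_numpy()  # (E, n_classes)

    s1 = np.zeros((p, n_ch))
    s2 = np.zeros((p, n_ch))
    conds = np.empty(replications) if record_condition else None
    n_redrawn = 0
    for r in range(replications):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, e_n, e_n)
            mult = np.bincount(idx, minlength=e_n).astype(float)
            if np.all(mult @ class_counts > 0):
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                f"replication {r}: a class received zero events in "
                f"{max_redraws} consecutive redraws"
            )
        gram = np.tensordot(mult, grams, axes=1)
        b = np.tensordot(mult, rhs, axes=1)
        try:
            coef = cho_solve(cho_factor(gram), b)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(gram, b, rcond=None)[0]
        if record_condition:
            ev = np.linalg.eigvalsh(gram)
            conds[r] = ev[-1] / ev[0] if ev[0] > ev[-1] * 1e-12 else np.inf
        s1 += coef
        s2 += coef**2

    mean = s1 / replications
    var = np.maximum(s2 / replications - mean**2, 0.0)
    variance, summary = {}, {}
    for c, slc in zip(design.classes, design.col_slices.values()):
        v = var[slc]
        variance[c.name] = v
        if interest is not None and c.window.contains(
            interest.with_rate(c.window.sample_rate_hz)
        ):
            v = v[c.window.slice_of(interest.with_rate(c.window.sample_rate_hz))]
        summary[c.name] = float(v.mean())
    if n_redrawn:
        logger.info("bootstrap_variance: redrew %d resamples", n_redrawn)
    return BootstrapReport(
        replications=replications,
        variance=variance,
        summary=summary,
        seed=seed,
        interest=interest,
        condition_numbers=conds,
        n_redrawn=n_redrawn,
    )
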