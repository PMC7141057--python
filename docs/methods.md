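# Methods

## Signal model

An epoch time-locked to event `i` is modelled as a strictly linear
superposition

```
x_i(t) = Σ_f a_f(t - τ_i^f) + n_i(t)
```

where `a_f` is the kernel of the event at offset `f` (f = 0 the lock,
f < 0 previous, f > 0 subsequent events), `τ_i^f` its epoch-relative
onset, and `n_i` ongoing activity. Averaging over epochs turns the event
timing into normalised timestamp distributions `Q_f` (one count per
epoch, divided by the number of epochs, so total mass ≤ 1 with equality
iff every epoch contributes):

```
â_Av = a + Σ_{f≠0} Q_f ∗ a + n̄ .
```

All three estimators, and the synthetic generator, share one sample-grid
convention: windows are closed intervals `[start, end]` ms with inclusive
endpoints (`(end-start)·fs/1000 + 1` samples — a [-250, 600] ms window at
1000 Hz has 851 samples), and event onsets are quantised to the grid by
rounding half up, once, so that rendering, epoching and lag histograms
agree bit-exactly. Convolutions are evaluated at full support and then
cropped, so samples inside the requested window are exact.

## Windows

Three nested intervals are distinguished: the *window of interest*
(default [-250, 600] ms around fixation onset), the *estimation window*
(equal to it for averaging and GLM; enlarged by a margin, default 200 ms,
for ADJAR to absorb convolution border effects), and the *epoch window*.
For overlap-aware estimation the epoch window is widened per participant
to `[-250-τ, 600+τ]` with `τ = mean + sd` of that participant's
inter-fixation intervals (IFIs, onset-to-onset), rounded up to 10 ms —
wide enough to contain the previous and subsequent responses in nearly
every epoch.

## Synthetic sessions

The generator emulates a free-scene-exploration co-registration
experiment: 4-s trials, stimulus at t = 0, fixation k landing at the
first-saccade latency plus k−1 IFI draws. Defaults (units ms):

| parameter | default | why |
|---|---|---|
| first-fixation latency | 307.65 (sd 46.14) | observed first-saccade landing statistics |
| IFI mean | 288.69 | observed inter-fixation interval mean |
| IFI draw sd | 117.68 | *within*-participant spread: the epoch-margin statistic τ ≈ 406 = mean + sd implies sd ≈ 118; the between-participant sd of IFI means (26.97) is a separate parameter (`ifi_between_sd`) |
| interval floor | 50 | fixations under 50 ms are not retained in such paradigms |
| trial duration | 4000 | stimulus display time |

Draws below the floor are clipped to it (≈2% of IFI draws), which shifts
the realised IFI mean by under 1 ms. Kernels are sums of Gaussian bumps —
the fixation kernel is a lambda-like positivity (100 ms, 8 µV, sd 30 ms)
with an N1-like negativity and a small late positivity; the stimulus
kernel has P1/P2 and a slow late component; the first-fixation variant
has a larger lambda (9.5 µV). Noise is `none`, white, or AR(1) with
marginal sd in µV (coefficient 0.95 per sample; note this is a per-sample
parameter, so its spectrum depends on the sampling rate). Trials are
padded by 2.5 s of event-free signal on both sides so no response crosses
trial bounds and epochs are never clipped by the recording edge.

What the generator does **not** emulate: scalp topography and volume
conduction (channels are identical copies up to gains), saccadic spike
artifacts, amplitude/latency variability of single-trial responses
(kernels are strictly time-invariant), and gaze position. Passing
recovery tests therefore demonstrates correctness of the estimators under
the linear time-invariant superposition model, not robustness to
violations of it.

Presets: `mid_exploration` (fixation-locked, lock ranks drawn uniformly
from 3–9, three draws per trial, ≈5.8 fixations per epoch window);
`onset_two_class` / `onset_three_class` (stimulus-locked, for the
two/three-class deconvolution models); `first_order_only` (adjacent lags
650 ± 30 ms with epoch window [-930, 1100] ms, so each epoch holds
exactly one previous and one subsequent event and the second-order lag
supports (≈ ±1300 ms) fall outside the [-450, 800] ms estimation window —
the validity regime of the iterative correction; the lag mean must exceed
half the estimation-window length, which also makes the iteration's
update operator a contraction).

## ADJAR implementation choices

- **Taper**: Tukey (cosine-ramp) window over the estimation window with
  200 ms ramps, applied to the estimate at every iteration (including
  initialisation). Samples more than one ramp inside the window are
  untouched; the outer 200 ms are biased by the return to zero and are
  excluded from the window of interest by construction (margin ≥ ramp).
- **Update order**: both overlap terms are recomputed from the same
  previous iterate (Jacobi-style).
- **Stopping**: relative power of the change, per channel, maximum over
  channels; default threshold 1e-5, cap 200 iterations. The returned
  estimate is the iterate whose update fell below threshold, so an
  infinite threshold returns the untouched average.
- **Divergence guard**: with two mass-one adjacent distributions the
  update operator has zero-frequency gain near 2; when adjacent lags are
  short relative to the estimation window its leading (DC-like)
  eigenvalue exceeds 1 and the plain iteration diverges, while every
  oscillatory mode stays contracting (measured spectral radius ≈ 0.7
  after removing the mean). The implementation detects sustained growth
  of the convergence criterion and restarts with per-iteration mean
  removal (`stabilized=True` in the result); the mean level is
  indeterminate in that regime and is restored by baseline correction.
  On mid-exploration fixtures the stabilised iteration converges in
  ~10–20 iterations. In the first-order-only regime the guard never
  engages and recovery is exact to <1% relative RMSE.
- **Second-order diagnostics**: `ov_pp = Q_-1^(∗2) ∗ â`,
  `ov_ss = Q_+1^(∗2) ∗ â` and the cross term `Q_-1 ∗ Q_+1 ∗ â` are
  convolved with the *final estimate* and exposed on the estimation
  window. In densely overlapping regimes the cross term — whose lag
  support is centred near zero — dominates the residual bias; the
  self-terms alone can even anti-correlate with the residual because the
  data's own higher-rank overlaps partially cancel them. The failure
  analysis in the tests therefore correlates the residual with the full
  second-order bias (self + cross terms, computed from the known
  kernel).
- **Baseline**: correction over [-200, -100] ms (the pre-saccadic
  interval free of spike-potential activity) is applied at reporting
  time, not inside the iteration.

## GLM implementation choices

- **Design**: per event of class c at epoch-relative onset τ (samples),
  ones at rows `epoch_offset + τ + c_start + j` and columns
  `class_offset + j`, clipped at epoch edges. Every event whose stripe
  intersects the epoch is modelled — including events just outside the
  epoch window whose responses bleed in — so the noiseless model is exact
  and the estimator unbiased; partially visible responses contribute
  partial evidence. Class selectors are (class label, rank predicate)
  pairs; rank predicates accept forms like `1`, `>=2`, `2+`, `3-9` and
  must be disjoint.
- **Solver**: LSQR per channel (tolerances 1e-12). Starting from zero it
  yields the minimum-norm least-squares solution, equal to
  `(D†D)^-1 D†x` whenever the Gram matrix is invertible; rank deficiency
  is flagged via the condition diagnostic rather than failing.
- **Condition number**: eigenvalue ratio of the dense Gram matrix
  (designs here have at most a few thousand columns). The averaging
  design gives exactly 1; low-jitter event sequences inflate it by
  orders of magnitude.
- **Bootstrap**: trials are resampled with replacement; since a resample
  only reweights per-epoch blocks, the normal equations are assembled
  from cached per-epoch Gram blocks and solved by Cholesky — identical
  to the LSQR solution for full-rank resamples and ~100x faster, which
  is what makes thousands of replications practical. Resamples that
  empty a class are redrawn (capped). Per-replication condition numbers
  are optional (off by default; the eigendecomposition dominates the
  cost).
- The variance ordering across model complexity (three-class ≥ two-class
  ≥ averaging for the stimulus-locked kernel) emerges when ongoing
  activity dominates the per-epoch variability, as in real EEG; the
  ordering fixture uses AR(1) noise of sd 20 µV (typical ongoing-EEG
  scale) against ~8 µV kernels. With implausibly small noise the
  *misspecification* of the one-class model dominates its resampling
  variance instead.

## Numerical and scaling choices

Unit and acceptance tests simulate at 200 Hz (5 ms grid) where the check
is rate-independent, and at 1000 Hz where printed sample counts are the
point; windows in ms are identical at both rates. Problem sizes (tens of
trials, ~100–300 epochs, 100-seed Monte-Carlo loops, 1000 bootstrap
replications) were chosen so the full suite runs in a couple of minutes
while leaving Monte-Carlo margins of several standard errors.

## Known limitations

- The ADJAR variant that models non-adjacent events is out of scope (it
  is a documented negative result: the iteration does not converge).
- No regularised (ridge) deconvolution and no continuous-covariate
  (spline/GAMM) expansion of the design.
- Real-data preprocessing (artifact rejection, ICA, saccade detection,
  re-referencing, filtering) is out of scope; recordings are consumed as
  channels x samples arrays with an event table.
- `recording.to_mne_raw()` provides a bridge to MNE-Python for users who
  want those steps; it requires `mne` to be installed separately.
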