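# overlapfrp

Overlap-aware estimation of evoked potentials from co-registered
continuous neural recordings (EEG) and event streams (stimulus onsets,
fixation onsets from eye tracking).

## The problem

During free visual exploration the eyes fixate roughly every 300 ms, while
the potential evoked by each fixation (the *eye fixation related
potential*, EFRP, dominated by the occipital lambda wave near 100 ms)
unfolds over several hundred milliseconds. Neighbouring responses
therefore superpose, and the classical time-locked average

```
â_Av(t) = (1/E) Σ_i x_i(t)
```

is biased: it equals the true response `a(t)` plus a sum of convolution
products `Σ_f Q_f(t) ∗ a(t)` between the kernel and the normalised
timestamp distributions `Q_f` of the neighbouring events. This bias does
not vanish as the number of epochs grows. The package implements and
contrasts three estimators of `a(t)`:

1. **Averaging** — the biased baseline.
2. **ADJAR** — iterative adjacent-response correction: starting from the
   average, the first-order previous/subsequent overlaps
   `ov_p = Q_-1 ∗ â`, `ov_s = Q_+1 ∗ â` are re-estimated from the current
   iterate and subtracted, with a Tukey taper containing convolution
   border effects, until the relative power of the change falls below a
   threshold. At convergence the estimate remains biased by second-order
   overlaps (`Q_-1^(∗2) ∗ a`, `Q_+1^(∗2) ∗ a` and cross terms), which are
   exposed as diagnostics.
3. **GLM deconvolution** — the linear model `x = D a + n`, where `D`
   stacks sparse 0/1 Toeplitz blocks (one diagonal stripe of ones per
   event, one column block per event class), solved per channel by least
   squares. All events in an epoch are modelled jointly, so the solution
   is unbiased for any overlap pattern that leaves `D` full rank. The
   condition number of `D†D` (exactly 1 for the averaging design)
   diagnoses timestamp-jitter-driven variance amplification, and a
   trial-resampling bootstrap quantifies it.

A synthetic-session generator renders ground-truth recordings by strict
linear superposition of parametric kernels over realistic oculomotor
sequences (first-fixation latency 307.65 ± 46.14 ms, inter-fixation
interval mean 288.69 ms), so every estimator is scored by parameter
recovery.

## Worked example

Simulate 40 trials of free exploration with AR(1) ongoing-activity noise
(sd 5 µV), lock epochs at fixations of rank 3–9, and compare the three
estimators on the [-250, 600] ms window of interest:

```sh
overlapfrp compare --preset mid_exploration --trials 40 --seed 7 \
    --sfreq 200 --noise-sd 5 --out demo/
```

which prints (abridged):

```json
{
  "metadata": {"epoch_window": [-630.0, 980.0], "n_epochs": 103, "seed": 7},
  "metrics": {
    "average": {"baseline_variance": 0.335, "rmse": 1.038, "tail_deviation": 0.782},
    "adjar":   {"baseline_variance": 0.119, "rmse": 1.204, "tail_deviation": 0.260},
    "glm":     {"baseline_variance": 0.015, "rmse": 0.280, "tail_deviation": 0.273}
  }
}
```

Reading the numbers: `rmse` is the error against the known kernel in µV
(GLM recovers it 3–4x better than the other two); `baseline_variance` is
the waveform variance over the [-200, -100] ms pre-saccadic baseline
(should be ~0 for a stable estimate); `tail_deviation` is the mean
absolute amplitude over [450, 600] ms, where the response should have
returned to zero. The average keeps its convolution bias in both
intervals, and ADJAR — whose first-order assumption fails in this densely
overlapping regime — ends up *worse* than the average because uncorrected
second-order overlaps accumulate. On `first_order_only` fixtures
(adjacent lags ≈ 650 ms, second-order supports outside the estimation
window) ADJAR converges and recovers the kernel to well under 1%.

The same pipeline is scriptable from Python:

```python
from overlapfrp import (TimeWindow, make_fixture, select_ranks, extract_epochs,
                        ClassConfig, build_design, solve_glm)

ses = make_fixture("mid_exploration", seed=7, n_trials=40, sample_rate_hz=200.0)
locks = select_ranks(ses.events, 3, 9, 3, seed=7)
epochs = extract_epochs(ses.recording, ses.events, "fixation",
                        TimeWindow(-660, 1010, 200.0), locks)
design = build_design(epochs, [ClassConfig("fixation", "fixation",
                                           TimeWindow(-250, 600, 200.0))])
result = solve_glm(design, epochs)
result.kernels["fixation"].to_frame()  # time_ms + one column per channel
```

Other CLI subcommands: `simulate` (write a ground-truth session to disk),
`epoch` (cut epochs from an event table + recording), `estimate`
(average/adjar/glm on stored data, with YAML class configurations for
multi-class models such as stimulus + first fixation + later fixations).

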