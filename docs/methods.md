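# Methods

## Scope

`enosemix` is an end-to-end study of joint gas recognition and
concentration regression on a simulated electronic-nose campaign: a sensor
simulator, a peak-driven featurization pipeline, a multi-task convolutional
network with channel attention, cross-fusion and an uncertainty-weighted
loss, and a grouped cross-validation harness with ablation variants.  This
note records the model assumptions, the defaults and why they hold, and
what the synthetic results do and do not demonstrate.

## Sensor simulator

Each of the eight array sensors is a phenomenological MOS model on the
response ratio `s = R0/R`:

* **Steady state** `s∞ = 1 + a_e C_e^{b_e} + a_p C_p^{b_p}` — additive
  power-law response per gas.  Exactly 1 in clean air; non-decreasing in
  each concentration.  Units: concentrations in ppm, `s` dimensionless.
* **Dynamics** — each gas contributes its *own* first-order component,
  relaxing toward its steady-state amplitude during exposure and toward
  zero during recovery.  The exposure time constant is
  `τ_on · kin_g / (1 + κ · C/100)`: gas-specific through the kinetic
  multiplier `kin_g` (propanol responds slower, multipliers 1.6–2.6 across
  the bank) and faster at higher concentration (`κ` 0.6–1.2), as surface
  adsorption kinetics behave.  Recovery uses `τ_off · kin_g`.  This matters
  because the downstream pipeline min-max-normalizes every feature window:
  with a single shared time constant the normalized rise would be the same
  curve `1 − e^{−t/τ}` for every gas and concentration and the features
  would carry no signal at all.  With per-gas kinetics the normalized rise
  is a composition-weighted mix of two exponentials whose rates shift with
  concentration — amplitude is discarded, shape is informative.
* **Noise** — multiplicative Gaussian on `s`, default relative sd 0.1 %.
  The default is set by the feature selector's operating condition: the
  maximum-variation-rate statistic compares per-step absolute differences,
  and the expected |step| of multiplicative noise (~1.13·σ·s) is largest on
  the response *plateau*.  Above roughly 0.5 % relative noise at 2 Hz that
  term exceeds the true rise slope, the selected windows drift onto plateau
  noise and jitter by hundreds of samples between repeats, and the
  representation collapses — a property of the statistic, not of any
  model.  At 0.1 % the selector locks to the response phase (observed
  start-position spread ≤ 3 samples across repeats), which matches the
  smooth traces real MOS recordings show at this sampling rate.  The noise
  level is a `CampaignConfig` field for studying degradation deliberately.
* **Drift** — optional slow linear baseline drift (fraction of baseline per
  hour), off by default.
* **Protocol** — 7 schemes: G1 pure ethanol, G2 pure n-propanol stepped
  20→100 ppm by 20 (the 0 ppm level is the initial air baseline, so each
  recording yields exactly five counted responses and the default campaign
  7 schemes × 5 cycles × 5 repeats = 175); G3–G5 fix ethanol at 20/60/100
  ppm while propanol steps; G6–G7 fix propanol at 40/80 ppm while ethanol
  steps.  5 min exposure / 5 min recovery at 2 Hz, plus a 240 s air
  lead-in so the first cycle's 700-sample left offset never underruns the
  recording.  Cycles are labeled by actual composition (single propanol /
  single ethanol / mixture); a `label_by="scheme"` switch labels by scheme
  instead, which matters only for custom schedules containing 0-ppm pairs.

## Featurization

Indices are 0-based, ranges half-open.  Per channel:

1. **Peaks** — strict local maxima (`y[i] > y[i±1]`); plateau tops and
   endpoints never qualify.  The pipeline additionally applies a prominence
   floor (default 5 % of the channel's range, via
   `scipy.signal.peak_prominences`) because under any measurement noise
   every wiggle is a strict local maximum; the bare operation with no
   threshold is available as the function default.
2. **Clustering** — greedy left-to-right grouping: a new group starts when
   the gap to the previous peak is ≥ `d_threshold` (default 600 samples =
   the 5-min recovery phase at 2 Hz).  Each group's argmax (ties → smallest
   index) is the cycle's reference peak.
3. **Segments** — `y[p_max − 700, p_max + 400)`; the left offset covers the
   full response phase with margin, the right offset reaches into early
   recovery where settled levels still separate mixing ratios.  Peaks too
   close to a boundary are skipped and logged, never padded.
4. **Window** — starts scanned every 0.5 s (1 sample at 2 Hz); the rate at
   `t` sums the `w` absolute first differences over `y[t..t+w]` (so a
   segment must have ≥ w+1 points) while the extracted window holds the `w`
   points `y[t_max..t_max+w)`; ties → smallest start.  Any positive `w` is
   accepted here; the perfect-square constraint binds at reshape time.
5. **Normalize & stack** — min-max to [0, 1] per window (a constant window
   raises a degenerate-input error naming sensor and segment); row-major
   reshape to √w × √w; channels stacked in fixed sensor order.

Cycles are paired across sensors by order, and each sample is labeled by
locating the first channel's reference peak in the recording's schedule.

## Network

Input `8 × H × W` (H = W; default 16).  All convolutions are 3×3, stride 1,
padding 2, so each layer grows the spatial side by 2 (16 → 18 → 20); no
pooling, no dropout.  Residual shortcuts are 1×1 convolutions with padding
1, which reproduces the +2 growth where channel counts change; batch norm
is applied before the shortcut addition, ReLU after.  Channel attention
(reduction r = 4, i.e. 16 → 4 → 16) sits after the first convolution;
cross-fusion after the per-task second convolutions; both placements follow
the backbone's layer table.  Heads: flatten (32·20·20 = 12 800 features) →
128 → 64 → {3 softmax | 2 linear}.

Constructor flags `use_attention`, `use_cross_fusion`, `task`
(`both`/`class`/`conc`) and the loss mode span the ablation grid: the
experience-initialized and default-initialized dynamic loss, the direct-sum
loss, attention-less, fusion-less, and the plain baseline, plus the two
single-task networks.

The engine is an in-package reverse-mode autodiff on numpy arrays
(`enosemix.autodiff`); analytic gradients of every building block are
checked against central differences to 1e-4 in the test suite.  Parameters
default to float32 (the two 12 800 × 128 layers dominate memory traffic);
float64 is a config switch and is what the gradient-check tests use.

## Training and evaluation

* Adam (fused in-place update), lr 2e-3, step decay ×0.1 at 70 % of
  training, global gradient-norm clip 5, batch size 5, default 20 epochs.
  The paper-stated value is the batch size; the rest is this package's
  choice: batch-5 SGD on 140 samples is noisy, and without the decay and
  clip late-training loss spikes destabilize held-out metrics.  20 epochs
  is where training loss plateaus on the default campaign; it also keeps a
  fold at ~40 s on one CPU.
* Regression targets are scaled to [0, 1] (ppm/100) inside the loop and
  predictions rescaled to ppm at the interface; `conc_scale=1` recovers
  raw-ppm training if wanted, at the cost of far slower head convergence.
* σ scales are stored as log σ (positivity structural), initialized to 1
  by default; the `mrca_1` variant initializes them from experience
  instead.  Single-task variants use the plain loss of their task.
* Folds group by repeat index: fold f holds out repeat f of every scheme —
  whole acquisition groups only, 4:1 train:test, 35 test responses per
  fold.  A repeat count not divisible by k is an explicit error (the
  message suggests a group-shuffled split).
* Classification metrics from the argmax; precision/recall/F1 macro-
  averaged (classes are imbalanced 25/25/125); per-class AUC one-vs-rest on
  softmax scores, reported as NaN when a class is absent from a test set.
  MAE pools both gas targets; R² = 1 − ΣSS_res/ΣSS_tot across both targets
  (per-gas values reported alongside).  Fold aggregates are mean ± sd/√k.

## What the synthetic results show — and what they do not

On the default campaign the cross-validated network reaches perfect
composition recognition and R² ≈ 0.98, and the full model ties or beats its
fusion-less and sum-loss ablations.  This demonstrates that the pipeline
and network *recover the generating structure under the stated protocol* —
parameter recovery, not field performance.  The simulator draws noise
i.i.d. per sample and repeats differ only by noise realization; real
campaigns add sensor drift, humidity/temperature covariates, inter-device
variation and chemically interacting mixtures, none of which are modeled
(drift is available but off).  Absolute metric values here are therefore
optimistic; the directional ablation comparisons and the window-length
insensitivity are the transferable observations.

## Numerical and degenerate-input choices

* All tie-breaks (equal variation rates, equal group maxima) go to the
  smallest index — determinism over arbitrariness.
* Max-pool gradients split evenly across tied maxima.
* Batch norm: eps 1e-5, running-stat momentum 0.1; eval mode uses running
  averages.
* Softmax/cross-entropy use the max-shift trick; the shift is a constant
  (no gradient through it).
* Checkpoints (npz) round-trip every parameter, batch-norm statistic and σ
  bit-faithfully, with the config and its hash embedded.
* Every CLI run writes its resolved config next to its outputs; recordings
  round-trip through CSV + JSON sidecars, feature datasets through NPZ with
  a JSON label manifest.

## Known limitations

* The simulator's separability is tunable by construction; it cannot
  validate absolute accuracy claims on real hardware.
* Peak clustering assumes one exposure per recovery-length window; faster
  cycling than the threshold assumes would merge cycles.
* The variation-rate selector degrades under heavy per-sample noise (see
  above); pipelines for noisier data would need smoothing or a robust rate
  statistic, which this package deliberately does not apply.
* Batch norm with batch size 5 couples samples within a batch; metrics are
  always computed in eval mode with running statistics.
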