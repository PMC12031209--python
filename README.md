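# enosemix

Binary-mixture VOC identification from metal-oxide gas-sensor arrays:
simultaneous gas recognition and concentration prediction with a multi-task
residual network.

## The problem

Electronic noses pair an array of cross-sensitive MOS sensors with a pattern
recognition model: no single sensor separates ethanol from n-propanol, but
the joint response of eight dissimilar sensors does.  Classical pipelines
answer *which gas* and *how much* with two separate models, wasting shared
structure and data — a real cost when a whole measurement campaign is only
175 recordings.  `enosemix` implements a single multi-task network over
peak-aligned response windows that answers both at once, plus everything
around it: a protocol-faithful simulator, the feature pipeline, grouped
cross-validation, and ablation tooling.

## The method

**Featurization.**  Each recording holds repeated 5-min exposure / 5-min
recovery cycles sampled at 2 Hz on the response ratio `s = R0/R`.  Per
channel: strict local maxima are clustered by an index-gap threshold
(d < 600 samples), each cluster's largest peak anchors a slice
`y[p_max − 700, p_max + 400)`, and within that slice a sliding window of
width `w = n²` keeps the start `t_max` maximizing the variation rate

    R_t = (1/w) Σ_{i=t}^{t+w−1} |y_{i+1} − y_i|.

The selected window is min-max normalized to [0, 1], reshaped row-major to
n×n, and the 8 channels stacked into an `8 × n × n` tensor (default
`16 × 16`, i.e. 256 points — about 35 % of the longest window studied).

**Network (MRCA).**  A shared residual block (3×3 conv 8→16, stride 1,
padding 2, channel attention, batch norm, 1×1 projection shortcut, ReLU)
feeds two task branches (conv 16→32 each).  A learnable 2×2 cross-fusion
matrix α, initialized to the identity, blends the branch feature maps
(soft parameter sharing), then each branch flattens through FC 128 → 64
into a 3-way softmax head (single n-propanol / single ethanol / mixture)
and a 2-output regression head (ppm of each gas).  Channel attention gates
each channel by `S = σ(MLP(avgpool) + MLP(maxpool)) ∈ (0,1)`.

**Dynamic weighted loss.**  The three task losses (MSE per gas, cross-
entropy for recognition) are balanced by learnable scales, trained jointly
with the weights:

    L = Lp/(2σp²) + Le/(2σe²) + Lci/σci² + log10(σp σe σci)

**Evaluation.**  Grouped 5-fold cross-validation: each fold holds out one
full repeat run of every scheme (35 of 175 responses), so no repeat leaks
between train and test.  Metrics: accuracy, macro precision/recall/F1,
per-class one-vs-rest AUC, confusion matrix, MAE (ppm) and pooled R² over
both gases, reported as mean ± standard error across folds.

Because no public dataset accompanies the protocol, the package ships a
simulator whose recordings carry the same statistical and temporal
structure (7 schemes G1–G7, concentrations stepped 20→100 ppm by 20,
≥5 repeats, 175 responses); see `docs/methods.md` for its assumptions.

## Worked example

```python
import enosemix as em
from enosemix.training import TrainConfig, cross_validate

recordings = em.generate_campaign(em.CampaignConfig(), seed=1)   # 35 recordings
dataset = em.preprocess_campaign(recordings)                     # 175 tensors
print(dataset.X.shape)
cv = cross_validate(dataset, config=TrainConfig(), k=5, seed=0)
for name, s in cv.summary.items():
    print(f"{name:10s} {s['mean']:.4f} +- {s['stderr']:.4f}")
```

prints

```
(175, 8, 16, 16)
accuracy   1.0000 +- 0.0000
precision  1.0000 +- 0.0000
recall     1.0000 +- 0.0000
f1         1.0000 +- 0.0000
mae        3.7049 +- 0.3427
r2         0.9762 +- 0.0038
```

i.e. on the default low-noise synthetic campaign the network recovers the
gas composition of every held-out response and predicts both concentrations
to ~3.7 ppm mean absolute error (pooled R² 0.98).  The same study runs from
the shell:

```
enosemix simulate   --out-dir runs/sim --seed 1
enosemix preprocess --in-dir runs/sim --out runs/features.npz
enosemix train      --data runs/features.npz --out-dir runs/cv --cv 5
enosemix ablate     --data runs/features.npz --out runs/ablations.csv
enosemix sweep      --in-dir runs/sim --out runs/sweep.csv
```

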