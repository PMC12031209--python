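"""Training loop, grouped 5-fold cross-validation, sweeps and ablations.

Folds respect acquisition groups: every (scheme, repeat) recording stays
whole, and fold f holds out one repeat of every scheme, so a 5-repeat
campaign gives the 4:1 train:test split with 35 test responses per fold and
no leakage between repeat runs of the same concentration schedule.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricsReport, aggregate_reports, evaluate
from .model import (Adam, DynamicLossState, ModelConfig, MRCANet, Tensor,
                    cross_entropy, dynamic_weighted_loss, mse, sum_loss)
from .preprocess import LabeledDataset, PreprocessParams, preprocess_campaign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_index: np.ndarray          # (N,) fold id per sample

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_index == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_index != fold)[0]


def make_folds(dataset: LabeledDataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Grouped fold assignment keyed on repeat index.

    Each fold's test set is whole repeat-groups only (every scheme's
    recording from the same repeat run).  Requires the number of repeats to
    be divisible by k.
    """
    if k < 2:
        raise ValueError("k must be >= 2: a single fold leaves no held-out data")
    if dataset.repeat_index is None:
        raise ValueError("dataset carries no repeat indices to group on")
    repeats = np.unique(dataset.repeat_index)
    if len(repeats) % k != 0:
        raise ValueError(
            f"{len(repeats)} repeat-groups are not divisible into {k} folds; "
            "use a group-shuffled split instead"
        )
    per_fold = len(repeats) // k
    perm = np.random.default_rng(seed).permutation(repeats)
    fold_of_repeat = {int(rep): i // per_fold for i, rep in enumerate(perm)}
    fold_index = np.array([fold_of_repeat[int(r)] for r in dataset.repeat_index])
    return FoldAssignment(k=k, fold_index=fold_index)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (the backbone batch size of 5 is the default)."""

    lr: float = 2e-3
    epochs: int = 20
    batch_size: int = 5
    loss: str = "dynamic"                 # "dynamic" or "sum"
    sigma_init: tuple[float, float, float] = (1.0, 1.0, 1.0)
    conc_scale: float = 100.0             # regression target scaling (ppm / scale)
    lr_decay: float = 0.1                 # step decay factor applied late in training
    lr_decay_at: float = 0.7              # fraction of epochs after which it applies
    clip_norm: float | None = 5.0         # global gradient-norm clip
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("dynamic", "sum"):
            raise ValueError("loss must be 'dynamic' or 'sum'")


@dataclass
class TrainResult:
    net: MRCANet
    loss_state: DynamicLossState | None
    history: pd.DataFrame


def _clip_grad_norm(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= np.asarray(scale, dtype=p.grad.dtype)


def _column(t: Tensor, j: int, width: int) -> Tensor:
    mask = np.zeros((1, width), dtype=t.data.dtype)
    mask[0, j] = 1.0
    return (t * Tensor(mask)).sum(axis=1)


def train(dataset: LabeledDataset, model_config: ModelConfig = ModelConfig(),
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Fit the network on `dataset`; deterministic given the config seed.

    Returns the trained network plus a per-epoch history of the component
    losses, the total loss and the sigma trajectory.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty training set")
    net = MRCANet(model_config, seed=config.seed)
    multitask = model_config.task == "both"
    use_dynamic = config.loss == "dynamic" and multitask
    loss_state = DynamicLossState(config.sigma_init) if use_dynamic else None

    params = net.parameters()
    if loss_state is not None:
        params = params + loss_state.parameters()
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed)

    scale = float(config.conc_scale)
    y_conc = dataset.y_conc / scale
    X = np.ascontiguousarray(dataset.X, dtype=net.dtype)
    rows = []
    decay_from = int(config.lr_decay_at * config.epochs)
    for epoch in range(config.epochs):
        opt.lr = config.lr * (config.lr_decay if epoch >= decay_from else 1.0)
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = Tensor(X[idx])
            logits, conc = net.forward_raw(x, training=True)
            zero = Tensor(0.0)
            l_ci = cross_entropy(logits, dataset.y_class[idx]) if logits is not None else zero
            if conc is not None:
                l_p = mse(_column(conc, 0, 2), y_conc[idx, 0])
                l_e = mse(_column(conc, 1, 2), y_conc[idx, 1])
            else:
                l_p = l_e = zero
            if use_dynamic:
                total = dynamic_weighted_loss(l_p, l_e, l_ci, loss_state)
            else:
                total = sum_loss(l_p, l_e, l_ci)
            opt.zero_grad()
            total.backward()
            if config.clip_norm is not None:
                _clip_grad_norm(params, config.clip_norm)
            opt.step()
            sums += [l_p.item(), l_e.item(), l_ci.item(), total.item()]
            n_batches += 1
        row = dict(zip(["loss_p", "loss_e", "loss_ci", "total"], sums / n_batches))
        row["epoch"] = epoch
        if loss_state is not None:
            row["sigma_p"], row["sigma_e"], row["sigma_ci"] = loss_state.sigmas
        rows.append(row)
    history = pd.DataFrame(rows)
    if not np.isfinite(history["total"].to_numpy()).all():
        logger.warning("non-finite training loss encountered")
    return TrainResult(net=net, loss_state=loss_state, history=history)


@dataclass
class CVResult:
    reports: list[MetricsReport]
    summary: dict[str, dict[str, float]]
    histories: list[pd.DataFrame] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"folds": [r.to_dict() for r in self.reports], "summary": self.summary}


def cross_validate(dataset: LabeledDataset, model_config: ModelConfig = ModelConfig(),
                   config: TrainConfig = TrainConfig(), k: int = 5,
                   seed: int = 0, keep_histories: bool = False) -> CVResult:
    """Grouped k-fold CV; per-fold metric reports plus mean +/- standard error."""
    folds = make_folds(dataset, k=k, seed=seed)
    reports, histories = [], []
    for f in range(k):
        train_set = dataset.subset(folds.train_indices(f))
        test_set = dataset.subset(folds.test_indices(f))
        fold_cfg = dataclasses.replace(config, seed=config.seed + f)
        result = train(train_set, model_config, fold_cfg)
        report = evaluate(result.net, test_set, conc_scale=config.conc_scale)
        reports.append(report)
        if keep_histories:
            histories.append(result.history)
        logger.info("fold %d: accuracy=%.3f r2=%.3f mae=%.2f",
                    f, report.accuracy, report.r2, report.mae)
    return CVResult(reports=reports, summary=aggregate_reports(reports),
                    histories=histories)


def window_length_sweep(recordings, widths: list[int],
                        base_params: PreprocessParams = PreprocessParams(),
                        model_config: ModelConfig = ModelConfig(),
                        config: TrainConfig = TrainConfig(), k: int = 5,
                        seed: int = 0) -> pd.DataFrame:
    """Re-run preprocessing + CV per window width; one metrics row per width.

    Widths whose w+1 samples exceed the segment length are skipped with a
    warning.  Default width list: n^2 for n in 11..17 and odd n in 19..27.
    """
    seg_len = base_params.loffset + base_params.roffset
    rows = []
    for w in widths:
        n = int(math.isqrt(w))
        if n * n != w:
            raise ValueError(f"width {w} is not a perfect square")
        if w + 1 > seg_len:
            logger.warning("width %d exceeds segment length %d, skipped", w, seg_len)
            continue
        params = dataclasses.replace(base_params, window=w)
        dataset = preprocess_campaign(recordings, params)
        mcfg = dataclasses.replace(model_config, input_hw=n)
        cv = cross_validate(dataset, mcfg, config, k=k, seed=seed)
        row = {"width": w, "side": n}
        for key, stats in cv.summary.items():
            row[key] = stats["mean"]
            row[f"{key}_stderr"] = stats["stderr"]
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_SWEEP_WIDTHS = [n * n for n in (11, 12, 13, 14, 15, 16, 17, 19, 21, 23, 25, 27)]

#: ablation variants: (model flags, training-loss mode, sigma initialization)
ABLATION_VARIANTS = {
    "mrca_1": dict(use_attention=True, use_cross_fusion=True, loss="dynamic",
                   sigma_init=(8.0, 8.0, 1.0)),  # experience-initialized scales
    "mrca_2": dict(use_attention=True, use_cross_fusion=True, loss="dynamic"),
    "mrca_3": dict(use_attention=True, use_cross_fusion=True, loss="sum"),
    "no_attention": dict(use_attention=False, use_cross_fusion=True, loss="dynamic"),
    "no_cross": dict(use_attention=True, use_cross_fusion=False, loss="dynamic"),
    "baseline": dict(use_attention=False, use_cross_fusion=False, loss="dynamic"),
}


def ablation_configs(name: str, model_config: ModelConfig = ModelConfig(),
                     config: TrainConfig = TrainConfig()):
    """ModelConfig / TrainConfig pair for a named ablation variant."""
    if name not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {name!r}; one of {sorted(ABLATION_VARIANTS)}")
    v = ABLATION_VARIANTS[name]
    mcfg = dataclasses.replace(model_config, use_attention=v["use_attention"],
                               use_cross_fusion=v["use_cross_fusion"])
    tcfg = dataclasses.replace(config, loss=v["loss"],
                               sigma_init=v.get("sigma_init", config.sigma_init))
    return mcfg, tcfg


def run_ablations(dataset: LabeledDataset, variants: list[str] | None = None,
                  model_config: ModelConfig = ModelConfig(),
                  config: TrainConfig = TrainConfig(), k: int = 5,
                  seed: int = 0) -> pd.DataFrame:
    """Cross-validate each ablation variant on identical folds and seeds."""
    variants = list(ABLATION_VARIANTS) if variants is None else variants
    rows = []
    for name in variants:
        mcfg, tcfg = ablation_configs(name, model_config, config)
        cv = cross_validate(dataset, mcfg, tcfg, k=k, seed=seed)
        row = {"variant": name}
        for key, stats in cv.summary.items():
            row[key] = stats["mean"]
            row[f"{key}_stderr"] = stats["stderr"]
        rows.append(row)
    return pd.DataFrame(rows)
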