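"""Multi-task residual network with channel attention and cross-fusion (MRCA).

Architecture, for 8 x H x W inputs (H = W):

* shared residual block: 3x3 conv (8 -> 16, stride 1, padding 2), channel
  attention, batch norm, plus a 1x1 projection shortcut from the block
  input, then ReLU.  The padding-2 convolution grows each spatial side by
  2, so the shortcut projection uses padding 1 to match.
* per-task residual block: 3x3 conv (16 -> 32, padding 2) per task; the two
  task feature maps are blended by a learnable 2x2 cross-fusion matrix
  (initialized to the identity, i.e. an exact pass-through); then batch
  norm, projection shortcut, ReLU per task.
* heads: flatten -> 128 -> 64 -> 3 (gas class, softmax) for task A and
  flatten -> 128 -> 64 -> 2 (ppm pair, linear) for task B.

No pooling and no dropout anywhere.  The total training loss either sums
the three task losses directly or balances them with learnable
homoscedastic-uncertainty scales (the dynamic weighted loss):

    total = Lp/(2*sigma_p^2) + Le/(2*sigma_e^2) + Lci/sigma_ci^2
            + log10(sigma_p * sigma_e * sigma_ci)

with sigma stored as log(sigma) so positivity is structural.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, conv2d

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ModelConfig:
    """Constructor flags covering the ablation variants.

    task: "both" (full multi-task), "class" (single-task recognition,
    MRCA-C) or "conc" (single-task regression, MRCA-R).  Turning off
    use_attention and use_cross_fusion together gives the plain-backbone
    baseline.
    """
    input_hw: int = 16
    in_channels: int = 8
    n_classes: int = 3
    n_targets: int = 2
    reduction: int = 4
    use_attention: bool = True
    use_cross_fusion: bool = True
    task: str = "both"
    dtype: str = "float32"          # parameter precision ("float32"/"float64")

    def __post_init__(self):
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if self.task not in ("both", "class", "conc"):
            raise ValueError("task must be 'both', 'class' or 'conc'")
        if self.use_attention and 16 % self.reduction != 0:
            raise ValueError("attention channel count (16) must be divisible by r")


def _he_normal(rng, shape, fan_in: int, dtype=np.float64) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2dLayer:
    def __init__(self, rng, in_ch: int, out_ch: int, k: int, padding: int,
                 dtype=np.float64):
        self.k, self.padding = k, padding
        self.w = Tensor(_he_normal(rng, (out_ch, in_ch, k, k), in_ch * k * k, dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.padding)

    def parameters(self):
        return [self.w, self.b]


class Linear:
    def __init__(self, rng, n_in: int, n_out: int, dtype=np.float64):
        self.w = Tensor(_he_normal(rng, (n_out, n_in), n_in, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w.transpose((1, 0)) + self.b

    def parameters(self):
        return [self.w, self.b]


class BatchNorm2d:
    """Per-channel normalization over (batch, H, W) with learnable scale/shift.

    Training mode uses batch statistics and updates exponential running
    averages; eval mode uses the running averages.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = xc * (var + self.eps) ** (-0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mu) * ((var + self.eps) ** (-0.5))
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b

    def parameters(self):
        return [self.gamma, self.beta]


class ChannelAttention:
    """Squeeze-excitation-style channel gate with average and max branches.

    Both pooled channel descriptors pass through the same two pointwise
    channel-mixing transforms (C -> C/r -> C) with a ReLU in between; the
    branch outputs are summed and squashed by a sigmoid into per-channel
    weights in (0, 1) that multiply the input map.
    """

    def __init__(self, rng, channels: int, reduction: int, dtype=np.float64):
        if channels % reduction != 0:
            raise ValueError(f"channels {channels} not divisible by r={reduction}")
        hidden = channels // reduction
        self.fc1 = Linear(rng, channels, hidden, dtype)
        self.fc2 = Linear(rng, hidden, channels, dtype)

    def weights(self, x: Tensor) -> Tensor:
        ca = x.mean(axis=(2, 3))          # (N, C) global average pool
        cm = x.max(axis=(2, 3))           # (N, C) global max pool
        z = self.fc2(self.fc1(ca).relu())
        v = self.fc2(self.fc1(cm).relu())
        return (z + v).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.weights(x).reshape(n, c, 1, 1)

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


class CrossFusion:
    """Learnable 2x2 soft-parameter-sharing mix of the two task maps.

    [TA'; TB'] = [[a_AA, a_AB], [a_BA, a_BB]] [TA; TB], initialized to the
    identity (exact pass-through); entries are unconstrained during
    training.
    """

    def __init__(self, dtype=np.float64):
        self.alpha = Tensor(np.eye(2, dtype=dtype), requires_grad=True)
        self._masks = [[Tensor(np.outer(np.eye(2)[i], np.eye(2)[j]).astype(dtype))
                        for j in range(2)] for i in range(2)]

    def _entry(self, i: int, j: int) -> Tensor:
        return (self.alpha * self._masks[i][j]).sum()

    def __call__(self, ta: Tensor, tb: Tensor) -> tuple[Tensor, Tensor]:
        if ta.shape != tb.shape:
            raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
        ta2 = ta * self._entry(0, 0) + tb * self._entry(0, 1)
        tb2 = ta * self._entry(1, 0) + tb * self._entry(1, 1)
        return ta2, tb2

    def parameters(self):
        return [self.alpha]


class MRCANet:
    """The multi-task residual network; see module docstring."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.dtype = np.dtype(config.dtype).type
        self.output_conc_scale = 1.0  # ppm scaling restored by load_checkpoint
        rng = np.random.default_rng(seed)
        c, dt = config, self.dtype
        self.conv1 = Conv2dLayer(rng, c.in_channels, 16, k=3, padding=2, dtype=dt)
        self.proj1 = Conv2dLayer(rng, c.in_channels, 16, k=1, padding=1, dtype=dt)
        self.bn1 = BatchNorm2d(16, dtype=dt)
        self.attention = ChannelAttention(rng, 16, c.reduction, dtype=dt) \
            if c.use_attention else None

        h2 = c.input_hw + 4  # two padding-2 3x3 convolutions: +2 each
        self.flat_features = 32 * h2 * h2
        self.branches: dict[str, dict] = {}
        heads = []
        if c.task in ("both", "class"):
            heads.append(("class", c.n_classes))
        if c.task in ("both", "conc"):
            heads.append(("conc", c.n_targets))
        for name, n_out in heads:
            self.branches[name] = {
                "conv": Conv2dLayer(rng, 16, 32, k=3, padding=2, dtype=dt),
                "proj": Conv2dLayer(rng, 16, 32, k=1, padding=1, dtype=dt),
                "bn": BatchNorm2d(32, dtype=dt),
                "fc1": Linear(rng, self.flat_features, 128, dtype=dt),
                "fc2": Linear(rng, 128, 64, dtype=dt),
                "fc3": Linear(rng, 64, n_out, dtype=dt),
            }
        self.fusion = CrossFusion(dtype=dt) \
            if (c.use_cross_fusion and c.task == "both") else None

    # -- forward ----------------------------------------------------------

    def _shared(self, x: Tensor, training: bool) -> Tensor:
        h = self.conv1(x)
        if self.attention is not None:
            h = self.attention(h)
        h = self.bn1(h, training)
        h = h + self.proj1(x)
        return h.relu()

    def _branch_tail(self, name: str, t: Tensor, skip: Tensor, training: bool) -> Tensor:
        br = self.branches[name]
        t = br["bn"](t, training) + br["proj"](skip)
        t = t.relu()
        t = t.reshape(t.shape[0], self.flat_features)
        t = br["fc1"](t).relu()
        t = br["fc2"](t).relu()
        return br["fc3"](t)

    def forward_raw(self, x: Tensor, training: bool = False):
        """(class logits | None, concentration predictions | None)."""
        if x.ndim != 4 or x.shape[2] != x.shape[3]:
            raise ValueError(f"expected square NCHW input, got {x.shape}")
        if x.shape[2] != self.config.input_hw:
            raise ValueError(
                f"input is {x.shape[2]}x{x.shape[3]} but the network was built "
                f"for {self.config.input_hw}x{self.config.input_hw}"
            )
        h = self._shared(x, training)
        logits = conc = None
        if self.config.task == "both":
            ta = self.branches["class"]["conv"](h)
            tb = self.branches["conc"]["conv"](h)
            if self.fusion is not None:
                ta, tb = self.fusion(ta, tb)
            logits = self._branch_tail("class", ta, h, training)
            conc = self._branch_tail("conc", tb, h, training)
        elif self.config.task == "class":
            ta = self.branches["class"]["conv"](h)
            logits = self._branch_tail("class", ta, h, training)
        else:
            tb = self.branches["conc"]["conv"](h)
            conc = self._branch_tail("conc", tb, h, training)
        return logits, conc

    def forward(self, x, training: bool = False):
        """Class probabilities (softmax rows) and ppm predictions."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        logits, conc = self.forward_raw(x, training)
        probs = softmax(logits) if logits is not None else None
        return probs, conc

    def predict(self, X: np.ndarray, batch_size: int = 32):
        """Eval-mode numpy predictions: (class_probs, conc) arrays."""
        probs_out, conc_out = [], []
        for i in range(0, len(X), batch_size):
            probs, conc = self.forward(Tensor(X[i:i + batch_size]), training=False)
            probs_out.append(None if probs is None else probs.data)
            conc_out.append(None if conc is None else conc.data)
        probs = None if probs_out[0] is None else np.concatenate(probs_out)
        conc = None if conc_out[0] is None else np.concatenate(conc_out)
        return probs, conc

    # -- parameters & persistence ----------------------------------------

    def _modules(self) -> dict[str, object]:
        mods: dict[str, object] = {"conv1": self.conv1, "proj1": self.proj1,
                                   "bn1": self.bn1}
        if self.attention is not None:
            mods["attention"] = self.attention
        for name, br in self.branches.items():
            for key, layer in br.items():
                mods[f"{name}.{key}"] = layer
        if self.fusion is not None:
            mods["fusion"] = self.fusion
        return mods

    def parameters(self) -> list[Tensor]:
        out = []
        for mod in self._modules().values():
            out.extend(mod.parameters())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, mod in self._modules().items():
            for i, p in enumerate(mod.parameters()):
                state[f"{name}.p{i}"] = p.data
            if isinstance(mod, BatchNorm2d):
                state[f"{name}.running_mean"] = mod.running_mean
                state[f"{name}.running_var"] = mod.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, mod in self._modules().items():
            for i, p in enumerate(mod.parameters()):
                p.data = np.array(state[f"{name}.p{i}"])
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.asarray(state[f"{name}.running_mean"]).copy()
                mod.running_var = np.asarray(state[f"{name}.running_var"]).copy()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self.config), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant shift
    z = (logits - shift).exp()
    return z * z.sum(axis=-1, keepdims=True) ** (-1.0)


def log_softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under the softmax."""
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(log_softmax(logits) * Tensor(onehot)).sum() * (1.0 / n)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    d = pred - Tensor(np.asarray(target, dtype=pred.data.dtype))
    return (d * d).mean()


class DynamicLossState:
    """Learnable task scales sigma_p, sigma_e, sigma_ci (stored as log sigma)."""

    def __init__(self, sigma_init: tuple[float, float, float] = (1.0, 1.0, 1.0)):
        if any(s <= 0 for s in sigma_init):
            raise ValueError("sigma initialization must be positive")
        self.log_sigma = Tensor(np.log(np.asarray(sigma_init, dtype=float)),
                                requires_grad=True)
        self._masks = [Tensor(np.eye(3)[i]) for i in range(3)]

    @property
    def sigmas(self) -> np.ndarray:
        """Current (sigma_p, sigma_e, sigma_ci)."""
        return np.exp(self.log_sigma.data)

    def _s(self, i: int) -> Tensor:
        return (self.log_sigma * self._masks[i]).sum()

    def total(self, loss_p: Tensor, loss_e: Tensor, loss_ci: Tensor) -> Tensor:
        return dynamic_weighted_loss(loss_p, loss_e, loss_ci, self)

    def parameters(self) -> list[Tensor]:
        return [self.log_sigma]


def _as_loss(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(float(x))
    if np.any(t.data < 0):
        raise ValueError("component losses must be non-negative")
    return t


def dynamic_weighted_loss(loss_p, loss_e, loss_ci, state: DynamicLossState) -> Tensor:
    """Uncertainty-weighted total loss.

    total = Lp / (2 sigma_p^2) + Le / (2 sigma_e^2) + Lci / sigma_ci^2
            + log10(sigma_p sigma_e sigma_ci)

    The half factors sit on the two regression losses only, and the base-10
    log regularizer keeps every sigma from growing without bound.
    """
    lp, le, lci = _as_loss(loss_p), _as_loss(loss_e), _as_loss(loss_ci)
    sp, se, sci = state._s(0), state._s(1), state._s(2)
    total = (lp * (sp * (-2.0)).exp() * 0.5
             + le * (se * (-2.0)).exp() * 0.5
             + lci * (sci * (-2.0)).exp()
             + (sp + se + sci) * (1.0 / LN10))
    return total


def sum_loss(loss_p, loss_e, loss_ci) -> Tensor:
    """Plain direct sum of the three task losses (the non-dynamic ablation)."""
    return _as_loss(loss_p) + _as_loss(loss_e) + _as_loss(loss_ci)


try:  # fused in-place update; the big FC layers make Adam memory-bound
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_kernel(p, g, m, v, b1, b2, step_size, eps_t):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= step_size * m[i] / (np.sqrt(v[i]) + eps_t)
except ImportError:  # pragma: no cover
    _adam_kernel = None


class Adam:
    """Standard Adam with bias correction; deterministic given call order."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        # bias correction folded into the step size; updates are in place
        step_size = self.lr * math.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        eps_t = self.eps * math.sqrt(1 - b2 ** self.t)
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            m, v = self.m[i], self.v[i]
            if _adam_kernel is not None and p.data.flags.c_contiguous \
                    and g.dtype == p.data.dtype:
                _adam_kernel(p.data.ravel(), np.ascontiguousarray(g).ravel(),
                             m.ravel(), v.ravel(), b1, b2, step_size, eps_t)
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            g = g * g
            g *= (1 - b2)
            v += g
            denom = np.sqrt(v)
            denom += eps_t
            update = m / denom
            update *= step_size
            p.data -= update


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, net: MRCANet, loss_state: DynamicLossState | None = None,
                    conc_scale: float = 1.0) -> None:
    """Single-file archive of all parameters, config and sigma values.

    `conc_scale` records the regression-target scaling the network was
    trained with, so a reloaded model's ppm predictions can be restored.
    """
    payload = {f"param/{k}": v for k, v in net.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(asdict(net.config), sort_keys=True))
    payload["config_hash"] = np.array(net.config_hash())
    payload["conc_scale"] = np.float64(conc_scale)
    if loss_state is not None:
        payload["log_sigma"] = loss_state.log_sigma.data
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[MRCANet, DynamicLossState | None]:
    z = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(z["config_json"])))
    net = MRCANet(config, seed=0)
    net.load_state_dict({k[len("param/"):]: z[k] for k in z.files
                         if k.startswith("param/")})
    net.output_conc_scale = float(z["conc_scale"]) if "conc_scale" in z.files else 1.0
    loss_state = None
    if "log_sigma" in z.files:
        loss_state = DynamicLossState()
        loss_state.log_sigma.data = np.asarray(z["log_sigma"], dtype=np.float64).copy()
    return net, loss_state
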