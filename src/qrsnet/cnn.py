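"""Two-level 1-D convolutional network with an MLP head, trained by
hand-derived back-propagation.

Architecture (fixed by :class:`NetworkSpec` defaults):

* **object branch** (averaged-difference window, length 56):
  conv(k=5, 5 maps) → ReLU → mean-pool(2) → conv(k=5, 5 maps) → ReLU →
  mean-pool(2); feature lengths 56 → 52 → 26 → 22 → 11, i.e. 55 features.
* **part branch** (difference window, length 56):
  conv(k=5, 5 maps) → ReLU → mean-pool(2); 56 → 52 → 26, i.e. 130 features.
* concatenation (object then part, 185 features) → dense 20 ReLU →
  dense 4 softmax over {Q, R, S, non-QRS}.

Training minimises the summed squared error between the softmax posterior
and the one-hot target (the gradient is propagated through the full softmax
Jacobian; cross-entropy is available behind a flag for comparison) with
plain SGD at an initial learning rate of 0.005 decayed multiplicatively by
a factor (1 - 1e-6) at every mini-batch iteration.

Convolution here means valid (no-padding) cross-correlation without kernel
flip; with learned kernels the flipped and unflipped conventions are
equivalent up to re-parameterisation, and fixing one keeps runs
reproducible.  Mean pooling averages non-overlapping blocks and discards a
trailing partial block.  The ReLU subgradient at 0 is taken as 0.

Everything is plain NumPy: the forward pass, the gradients and the update
rule are all explicit, so each can be verified independently (brute-force
convolution oracles, central finite differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "NetworkParams",
    "TrainConfig",
    "TrainResult",
    "conv1d_forward",
    "mean_subsample",
    "dense_forward",
    "softmax",
    "relu",
    "forward",
    "forward_batch",
    "loss",
    "backward",
    "sgd_update",
    "init_params",
    "train",
]

_ACTIVATIONS = ("relu", "softmax", "linear")


@dataclass(frozen=True)
class LayerSpec:
    """One layer: a convolution stage, a pooling stage, or a dense stage."""

    kind: str  # conv1d | mean_subsample | dense | softmax_dense
    kernel_length: int = 0
    subsample_factor: int = 1
    n_units: int = 1
    activation: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("conv1d", "mean_subsample", "dense", "softmax_dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and self.kernel_length < 1:
            raise ValueError("conv kernel_length must be >= 1")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be >= 1")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def _branch_feature_count(input_length: int, layers: tuple[LayerSpec, ...]) -> int:
    length = input_length
    maps = 1
    for layer in layers:
        if layer.kind == "conv1d":
            length = length - layer.kernel_length + 1
            maps = layer.n_units
        elif layer.kind == "mean_subsample":
            length = length // layer.subsample_factor
        else:
            raise ValueError("branches may only contain conv1d / mean_subsample layers")
        if length < 1:
            raise ValueError("feature length collapsed below 1 sample")
    return maps * length


def _conv_pool(n_maps: int, k: int, factor: int) -> tuple[LayerSpec, LayerSpec]:
    return (
        LayerSpec("conv1d", kernel_length=k, n_units=n_maps, activation="relu"),
        LayerSpec("mean_subsample", subsample_factor=factor),
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Full architecture; feature lengths are recomputed and audited at
    construction, so a mis-shaped configuration fails immediately."""

    input_length: int = 56
    object_level: tuple[LayerSpec, ...] = field(
        default_factory=lambda: _conv_pool(5, 5, 2) + _conv_pool(5, 5, 2)
    )
    part_level: tuple[LayerSpec, ...] = field(default_factory=lambda: _conv_pool(5, 5, 2))
    mlp: tuple[LayerSpec, ...] = field(
        default_factory=lambda: (
            LayerSpec("dense", n_units=20, activation="relu"),
            LayerSpec("softmax_dense", n_units=4, activation="softmax"),
        )
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "object_level", tuple(self.object_level))
        object.__setattr__(self, "part_level", tuple(self.part_level))
        object.__setattr__(self, "mlp", tuple(self.mlp))
        # audit: force the shape arithmetic through once
        _ = self.n_features

    @property
    def object_features(self) -> int:
        return _branch_feature_count(self.input_length, self.object_level)

    @property
    def part_features(self) -> int:
        return _branch_feature_count(self.input_length, self.part_level)

    @property
    def n_features(self) -> int:
        """Concatenated feature count entering the MLP."""
        return self.object_features + self.part_features

    @property
    def n_classes(self) -> int:
        return self.mlp[-1].n_units

    def to_dict(self) -> dict:
        def layer(spec: LayerSpec) -> dict:
            return {
                "kind": spec.kind,
                "kernel_length": spec.kernel_length,
                "subsample_factor": spec.subsample_factor,
                "n_units": spec.n_units,
                "activation": spec.activation,
            }

        return {
            "input_length": self.input_length,
            "object_level": [layer(s) for s in self.object_level],
            "part_level": [layer(s) for s in self.part_level],
            "mlp": [layer(s) for s in self.mlp],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            input_length=int(d["input_length"]),
            object_level=tuple(LayerSpec(**s) for s in d["object_level"]),
            part_level=tuple(LayerSpec(**s) for s in d["part_level"]),
            mlp=tuple(LayerSpec(**s) for s in d["mlp"]),
        )


class NetworkParams(dict):
    """All kernels, weight matrices and biases, keyed by layer name.

    Convolution kernels have shape ``(n_out_maps, n_in_maps, kernel_length)``
    with a per-map bias vector; dense layers hold ``(n_out, n_in)`` weight
    matrices.  Behaves as a plain dict of ndarrays plus a few conveniences.
    """

    def copy(self) -> "NetworkParams":
        return NetworkParams({k: v.copy() for k, v in self.items()})

    def ravel(self) -> np.ndarray:
        return np.concatenate([self[k].ravel() for k in sorted(self)])

    def with_ravel(self, flat: np.ndarray) -> "NetworkParams":
        out = NetworkParams()
        pos = 0
        for k in sorted(self):
            n = self[k].size
            out[k] = flat[pos : pos + n].reshape(self[k].shape).copy()
            pos += n
        return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _apply_activation(x: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return relu(x)
    if activation == "softmax":
        return softmax(x)
    if activation == "linear":
        return x
    raise ValueError(f"unknown activation {activation!r}")


def conv1d_forward(
    inputs: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray,
    activation: str = "linear",
) -> np.ndarray:
    """Valid 1-D cross-correlation over feature maps.

    Parameters
    ----------
    inputs : (..., n_in, L) array
        Input feature maps (leading batch axes allowed).
    kernels : (n_out, n_in, K) array
    bias : (n_out,) array

    Returns ``(..., n_out, L - K + 1)``: each output map correlates every
    input map with its own kernel, sums over input maps, adds the bias and
    applies the activation.
    """
    x = np.asarray(inputs, dtype=float)
    w = np.asarray(kernels, dtype=float)
    if x.ndim < 2 or w.ndim != 3:
        raise ValueError("inputs must be (..., n_in, L); kernels (n_out, n_in, K)")
    n_out, n_in, k = w.shape
    if x.shape[-2] != n_in:
        raise ValueError(f"expected {n_in} input maps, got {x.shape[-2]}")
    if x.shape[-1] < k:
        raise ValueError("input shorter than the kernel")
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)
    out = np.einsum("...ilk,oik->...ol", windows, w) + np.asarray(bias)[:, None]
    return _apply_activation(out, activation)


def mean_subsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean of non-overlapping blocks along the last axis; the trailing
    partial block is discarded."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("subsampling factor must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < factor:
        raise ValueError("sequence shorter than the subsampling factor")
    n_blocks = x.shape[-1] // factor
    trimmed = x[..., : n_blocks * factor]
    return trimmed.reshape(*x.shape[:-1], n_blocks, factor).mean(axis=-1)


def dense_forward(
    x: np.ndarray, weights: np.ndarray, bias: np.ndarray, activation: str = "linear"
) -> np.ndarray:
    """Affine map ``W x + b`` through an activation; batch axes allowed."""
    w = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != w.shape[1]:
        raise ValueError(f"expected input size {w.shape[1]}, got {x.shape[-1]}")
    return _apply_activation(x @ w.T + np.asarray(bias), activation)


# ---------------------------------------------------------------------------
# parameter initialisation and the full forward/backward pass
# ---------------------------------------------------------------------------

def _branch_param_names(branch: str, layers: tuple[LayerSpec, ...]):
    idx = 0
    for layer in layers:
        if layer.kind == "conv1d":
            yield f"{branch}_conv{idx}", layer
            idx += 1


def init_params(spec: NetworkSpec, seed: int = 0) -> NetworkParams:
    """He-style Gaussian initialisation (zero-mean, sd sqrt(2/fan_in)),
    zero biases, fully seeded."""
    rng = np.random.default_rng(seed)
    params = NetworkParams()

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    for branch, layers in (("obj", spec.object_level), ("part", spec.part_level)):
        n_in = 1
        for name, layer in _branch_param_names(branch, layers):
            k = layer.kernel_length
            params[f"{name}_w"] = he((layer.n_units, n_in, k), n_in * k)
            params[f"{name}_b"] = np.zeros(layer.n_units)
            n_in = layer.n_units
    n_in = spec.n_features
    for j, layer in enumerate(spec.mlp):
        params[f"mlp{j}_w"] = he((layer.n_units, n_in), n_in)
        params[f"mlp{j}_b"] = np.zeros(layer.n_units)
        n_in = layer.n_units
    return params


def _branch_forward(x, branch, layers, params, cache):
    """x: (B, 1, L). Stores pre-activation conv outputs for backprop."""
    conv_idx = 0
    for li, layer in enumerate(layers):
        if layer.kind == "conv1d":
            name = f"{branch}_conv{conv_idx}"
            cache[f"{name}_in"] = x
            pre = conv1d_forward(x, params[f"{name}_w"], params[f"{name}_b"], "linear")
            cache[f"{name}_pre"] = pre
            x = _apply_activation(pre, layer.activation)
            conv_idx += 1
        else:
            cache[f"{branch}_pool{li}_inlen"] = x.shape[-1]
            x = mean_subsample(x, layer.subsample_factor)
    return x


def forward_batch(
    spec: NetworkSpec,
    params: NetworkParams,
    part: np.ndarray,
    objects: np.ndarray,
    return_cache: bool = False,
):
    """Posteriors for a batch of window pairs.

    ``part`` and ``objects`` are (B, 56) matrices.  Returns (B, 4)
    posteriors (and the intermediate cache when requested).
    """
    part = np.atleast_2d(np.asarray(part, dtype=float))
    objects = np.atleast_2d(np.asarray(objects, dtype=float))
    if part.shape[1] != spec.input_length or objects.shape[1] != spec.input_length:
        raise ValueError(f"window pairs must be (B, {spec.input_length})")
    cache: dict = {}
    obj_out = _branch_forward(objects[:, None, :], "obj", spec.object_level, params, cache)
    part_out = _branch_forward(part[:, None, :], "part", spec.part_level, params, cache)
    feats = np.concatenate(
        [obj_out.reshape(obj_out.shape[0], -1), part_out.reshape(part_out.shape[0], -1)],
        axis=1,
    )
    cache["obj_out_shape"] = obj_out.shape
    cache["part_out_shape"] = part_out.shape
    x = feats
    for j, layer in enumerate(spec.mlp):
        cache[f"mlp{j}_in"] = x
        pre = x @ params[f"mlp{j}_w"].T + params[f"mlp{j}_b"]
        cache[f"mlp{j}_pre"] = pre
        x = _apply_activation(pre, layer.activation)
    if return_cache:
        return x, cache
    return x


def forward(spec: NetworkSpec, params: NetworkParams, pair) -> np.ndarray:
    """Posterior over {Q, R, S, non-QRS} for a single segment pair."""
    y = forward_batch(spec, params, pair.part_window[None, :], pair.object_window[None, :])
    return y[0]


def loss(y: np.ndarray, t: np.ndarray) -> float:
    """Summed squared error between posterior and one-hot target."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValueError("posterior and target must have equal shapes")
    hot = (t == 1.0).sum(axis=-1)
    if not np.all((hot == 1) & np.all((t == 0.0) | (t == 1.0), axis=-1)):
        raise ValueError("targets must be one-hot vectors")
    return float(np.sum((t - y) ** 2))


def _pool_backward(d_out: np.ndarray, factor: int, in_len: int) -> np.ndarray:
    """Gradient of mean pooling: 1/factor broadcast into each block, zero
    into any discarded tail."""
    d_in = np.zeros(d_out.shape[:-1] + (in_len,))
    n_blocks = d_out.shape[-1]
    d_in[..., : n_blocks * factor] = np.repeat(d_out / factor, factor, axis=-1)
    return d_in


def _conv_backward(d_out, x_in, kernels):
    """Gradients of a valid cross-correlation.

    d_out: (B, n_out, Lout); x_in: (B, n_in, L); kernels: (n_out, n_in, K).
    Returns (d_w, d_b, d_x).
    """
    n_out, n_in, k = kernels.shape
    windows = np.lib.stride_tricks.sliding_window_view(x_in, k, axis=-1)
    d_w = np.einsum("bol,bilk->oik", d_out, windows)
    d_b = d_out.sum(axis=(0, 2))
    pad = np.pad(d_out, [(0, 0), (0, 0), (k - 1, k - 1)])
    pad_windows = np.lib.stride_tricks.sliding_window_view(pad, k, axis=-1)
    d_x = np.einsum("bonk,oik->bin", pad_windows, kernels[:, :, ::-1])
    return d_w, d_b, d_x


def _branch_backward(d_out, branch, layers, params, cache):
    grads = {}
    conv_idx = sum(1 for l in layers if l.kind == "conv1d")
    for li in range(len(layers) - 1, -1, -1):
        layer = layers[li]
        if layer.kind == "mean_subsample":
            d_out = _pool_backward(
                d_out, layer.subsample_factor, cache[f"{branch}_pool{li}_inlen"]
            )
        else:
            conv_idx -= 1
            name = f"{branch}_conv{conv_idx}"
            if layer.activation == "relu":
                d_out = d_out * (cache[f"{name}_pre"] > 0)
            d_w, d_b, d_out = _conv_backward(d_out, cache[f"{name}_in"], params[f"{name}_w"])
            grads[f"{name}_w"] = d_w
            grads[f"{name}_b"] = d_b
    return grads


def backward(
    spec: NetworkSpec,
    params: NetworkParams,
    part: np.ndarray,
    objects: np.ndarray,
    targets: np.ndarray,
    objective: str = "squared_error",
):
    """Mean-over-batch loss and its exact gradients for every parameter.

    ``targets`` is a (B, 4) one-hot matrix.  For the squared-error
    objective the gradient runs through the full softmax Jacobian; the
    optional cross-entropy objective uses the usual ``y - t`` shortcut.
    """
    part = np.atleast_2d(part)
    objects = np.atleast_2d(objects)
    targets = np.atleast_2d(targets)
    y, cache = forward_batch(spec, params, part, objects, return_cache=True)
    batch = y.shape[0]

    if objective == "squared_error":
        loss_value = float(np.mean(np.sum((targets - y) ** 2, axis=1)))
        d_y = -2.0 * (targets - y) / batch
        # softmax Jacobian: dz_j = y_j (g_j - sum_k g_k y_k)
        d_pre = y * (d_y - np.sum(d_y * y, axis=1, keepdims=True))
    elif objective == "cross_entropy":
        eps = 1e-12
        loss_value = float(-np.mean(np.sum(targets * np.log(y + eps), axis=1)))
        d_pre = (y - targets) / batch
    else:
        raise ValueError(f"unknown objective {objective!r}")

    grads = NetworkParams()
    d_x = d_pre
    for j in range(len(spec.mlp) - 1, -1, -1):
        layer = spec.mlp[j]
        if j < len(spec.mlp) - 1 and layer.activation == "relu":
            d_x = d_x * (cache[f"mlp{j}_pre"] > 0)
        x_in = cache[f"mlp{j}_in"]
        grads[f"mlp{j}_w"] = d_x.T @ x_in
        grads[f"mlp{j}_b"] = d_x.sum(axis=0)
        d_x = d_x @ params[f"mlp{j}_w"]

    n_obj = spec.object_features
    obj_shape = cache["obj_out_shape"]
    part_shape = cache["part_out_shape"]
    d_obj = d_x[:, :n_obj].reshape(obj_shape)
    d_part = d_x[:, n_obj:].reshape(part_shape)
    grads.update(_branch_backward(d_obj, "obj", spec.object_level, params, cache))
    grads.update(_branch_backward(d_part, "part", spec.part_level, params, cache))
    return loss_value, grads


def sgd_update(params: NetworkParams, grads: NetworkParams, eta: float) -> NetworkParams:
    """One plain gradient-descent step ``p <- p - eta * dE/dp``."""
    return NetworkParams({k: params[k] - eta * grads[k] for k in params})


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """SGD regimen.

    ``eta0`` and the per-iteration multiplicative decay implement an initial
    learning rate of 0.005 reduced by 0.0001 % at every mini-batch step,
    i.e. eta_t = eta0 * (1 - 1e-6)**t.
    """

    eta0: float = 0.005
    decay_per_iter: float = 1.0 - 1e-6
    max_epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 20
    objective: str = "squared_error"

    def __post_init__(self) -> None:
        if not self.eta0 > 0:
            raise ValueError("eta0 must be positive")
        if not 0 < self.decay_per_iter <= 1:
            raise ValueError("decay_per_iter must lie in (0, 1]")

    def eta_at(self, iteration: int) -> float:
        """Closed-form learning rate after ``iteration`` mini-batch steps."""
        return self.eta0 * self.decay_per_iter**iteration


@dataclass
class TrainResult:
    """Fitted parameters plus the training log.

    ``log`` is a list of per-epoch dicts (epoch, lr, train_loss, val_loss,
    val_acc); ``params`` are the best-validation-loss parameters seen.
    """

    params: NetworkParams
    spec: NetworkSpec
    config: TrainConfig
    log: list[dict]
    best_epoch: int

    def summary(self) -> str:
        last = self.log[-1]
        best = self.log[self.best_epoch]
        lines = [
            "Two-level 1-D CNN training summary",
            f"  epochs run          : {len(self.log)}",
            f"  best epoch (val)    : {self.best_epoch + 1}",
            f"  final train loss    : {last['train_loss']:.6f}",
            f"  best val loss       : {best['val_loss']:.6f}",
            f"  best val accuracy   : {best['val_acc']:.4f}",
            f"  final learning rate : {last['lr']:.6g}",
        ]
        return "\n".join(lines)


def train(dataset, spec: NetworkSpec, config: TrainConfig) -> TrainResult:
    """Mini-batch SGD on a labelled segment dataset.

    The dataset must contain every one of the four classes.  A stratified
    ``val_fraction`` split monitors generalisation; training stops early
    after ``patience`` epochs without validation improvement and the
    best-validation parameters are returned.
    """
    labels = dataset.labels
    present = set(int(v) for v in np.unique(labels))
    if present != {0, 1, 2, 3}:
        missing = sorted({0, 1, 2, 3} - present)
        raise ValueError(f"dataset is missing class indices {missing}")

    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    # stratified validation split
    val_idx: list[int] = []
    for lab in sorted(present):
        idx = np.flatnonzero(labels == lab)
        n_val = max(1, int(round(config.val_fraction * idx.size)))
        val_idx.extend(rng.permutation(idx)[:n_val])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[np.asarray(val_idx)] = True
    tr = np.flatnonzero(~val_mask)
    va = np.flatnonzero(val_mask)

    one_hot = dataset.one_hot
    params = init_params(spec, seed=config.seed)
    best_params = params.copy()
    best_val = np.inf
    best_epoch = 0
    log: list[dict] = []
    iteration = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            eta = config.eta_at(iteration)
            loss_value, grads = backward(
                spec,
                params,
                dataset.part[batch],
                dataset.objects[batch],
                one_hot[batch],
                objective=config.objective,
            )
            params = sgd_update(params, grads, eta)
            epoch_losses.append(loss_value)
            iteration += 1

        y_val = forward_batch(spec, params, dataset.part[va], dataset.objects[va])
        val_loss = float(np.mean(np.sum((one_hot[va] - y_val) ** 2, axis=1)))
        val_acc = float(np.mean(np.argmax(y_val, axis=1) == labels[va]))
        log.append(
            {
                "epoch": epoch + 1,
                "lr": config.eta_at(iteration),
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break

    return TrainResult(params=best_params, spec=spec, config=config, log=log, best_epoch=best_epoch)
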