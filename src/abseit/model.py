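"""Rotation-aware reconstruction network, its losses, and the training loop.

Architecture: a stack of stride-1, circularly padded convolutions (the map is
periodic along both axes, so circular padding is the physically correct
boundary) with layer normalisation, followed by a per-injection-row dense
head whose weights are *shared* across the 16 rows.  Row k's feature block is
cyclically un-rotated by k columns ("canonicalised") before the head, each
row's head output is a full canonical image that is rotated back by k * 22.5
degrees, and the 16 rotated images are averaged.  Because the convolutional
front end is exactly equivariant to diagonal cyclic shifts of the input map
and quarter-turn image rotations are exact pixel permutations, shifting the
input map by n in {4, 8, 12} rotates the output by exactly n * 22.5 degrees.

Everything (forward, backprop, Adam) is plain NumPy: the hot paths are
BLAS-batched matrix products, which keeps desk-scale training tractable on a
single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eim import EIM_SIZE
from .rotation import rotation_operators

_LEAK = 0.01
_LN_EPS = 1e-5


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    The default reproduces the printed constants: five 5x5 convolutions give
    a 21x21 receptive field, 128 final channels give the 16 x 2048 head
    input, and the head widens 2048 -> 2048 -> 4096 = 64*64.
    """

    conv_channels: tuple = (32, 64, 128, 128, 128)
    kernel_sizes: tuple = (5, 5, 5, 5, 5)
    out_size: int = 64
    dropout: float = 0.1
    aggregation: str = "rotate_mean"   # or "mean" (no per-row rotation)
    canonicalize_rows: bool = True
    out_activation: str = "softplus"   # keeps conductivities positive

    def __post_init__(self):
        if len(self.conv_channels) != len(self.kernel_sizes):
            raise ValueError("one kernel size per conv layer")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")
        if self.aggregation in ("rotate_sum",):
            object.__setattr__(self, "aggregation", "rotate_mean")
        if self.aggregation not in ("rotate_mean", "mean"):
            raise ValueError("aggregation must be 'rotate_mean' or 'mean'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def channels_final(self) -> int:
        return self.conv_channels[-1]

    @property
    def row_feature_width(self) -> int:
        return EIM_SIZE * self.channels_final

    @property
    def head_widths(self) -> tuple:
        return (self.row_feature_width, self.out_size * self.out_size)


#: scaled-down configuration for CPU smoke training; same receptive field
#: (21) and output size, narrower channels (head input 16 x 256).
SMOKE_CONFIG = NetConfig(conv_channels=(8, 16, 16, 16, 16))


def receptive_field(config: NetConfig) -> int:
    """Receptive-field side of the stride-1 conv stack: 1 + sum(k - 1)."""
    return 1 + sum(k - 1 for k in config.kernel_sizes)


@dataclass(frozen=True)
class LossWeights:
    """Composite-loss weights, as printed: total = Lw2 + l1*TV + l2*MSLE."""

    lambda1: float = 0.1    # total-variation weight
    lambda2: float = 1e-6   # MSLE weight

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


#: training presets: coefficients (c_w2, c_tv, c_msle) on the three terms.
#: "as_printed" follows the published equation literally; with it the weight
#: penalty (coefficient 1) dwarfs the 1e-6-weighted data term and training
#: collapses toward zero weights, so the "sane" preset swaps the two.
LOSS_PRESETS = {
    "as_printed": (1.0, 0.1, 1e-6),
    "sane": (1e-6, 0.1, 1.0),
}


# --------------------------------------------------------------------------
# primitive layers (forward + vjp)

def _kernel_spectrum(W: np.ndarray, h: int, w: int) -> np.ndarray:
    """rfft2 of the kernel embedded on the full (circular) grid.

    Offset m in [-k//2, k//2] of the cross-correlation lands at index m mod h,
    so the embedded kernel is the k x k block rolled to the origin.
    """
    cout, cin, k, _ = W.shape
    p = k // 2
    full = np.zeros((cout, cin, h, w))
    full[:, :, :k, :k] = W
    full = np.roll(full, (-p, -p), axis=(-2, -1))
    return np.fft.rfft2(full)


def _circ_conv(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Stride-1 cross-correlation with circular padding on both axes.

    Circular boundary conditions make the convolution exactly diagonal in
    the Fourier domain: y^ = x^ * conj(w^) (cross-correlation theorem).
    """
    h, w = x.shape[-2:]
    xf = np.fft.rfft2(x)
    wf = _kernel_spectrum(W, h, w)
    yf = np.einsum("bcxy,ocxy->boxy", xf, wf.conj(), optimize=True)
    return np.fft.irfft2(yf, s=(h, w))


def _circ_conv_backward(x: np.ndarray, W: np.ndarray, dy: np.ndarray):
    h, w = x.shape[-2:]
    k = W.shape[-1]
    p = k // 2
    xf = np.fft.rfft2(x)
    wf = _kernel_spectrum(W, h, w)
    dyf = np.fft.rfft2(dy)
    dxf = np.einsum("boxy,ocxy->bcxy", dyf, wf, optimize=True)
    dx = np.fft.irfft2(dxf, s=(h, w))
    dwf = np.einsum("boxy,bcxy->ocxy", dyf.conj(), xf, optimize=True)
    dw_full = np.roll(np.fft.irfft2(dwf, s=(h, w)), (p, p), axis=(-2, -1))
    dW = dw_full[:, :, :k, :k]
    db = dy.sum(axis=(0, 2, 3))
    return dx, dW, db


def _layernorm(z: np.ndarray, g: np.ndarray, b: np.ndarray):
    """Normalise over (C, H, W) per sample; per-channel affine."""
    mu = z.mean(axis=(1, 2, 3), keepdims=True)
    var = z.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (z - mu) * inv
    y = g[None, :, None, None] * xhat + b[None, :, None, None]
    return y, (xhat, inv)


def _layernorm_backward(cache, g: np.ndarray, dy: np.ndarray):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=(0, 2, 3))
    db = dy.sum(axis=(0, 2, 3))
    dxh = dy * g[None, :, None, None]
    m1 = dxh.mean(axis=(1, 2, 3), keepdims=True)
    m2 = (dxh * xhat).mean(axis=(1, 2, 3), keepdims=True)
    dz = inv * (dxh - m1 - xhat * m2)
    return dz, dg, db


def _leaky(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, _LEAK * x)


def _dleaky(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0, _LEAK)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# parameters and forward/backward

def init_network(config: NetConfig, seed: int = 0) -> dict:
    """He-initialised parameter set; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    params = {}
    cin = 1
    for i, (cout, k) in enumerate(zip(config.conv_channels, config.kernel_sizes)):
        fan = cin * k * k
        params[f"conv{i}_W"] = rng.normal(0, np.sqrt(2.0 / fan), (cout, cin, k, k))
        params[f"conv{i}_b"] = np.zeros(cout)
        params[f"ln{i}_g"] = np.ones(cout)
        params[f"ln{i}_b"] = np.zeros(cout)
        cin = cout
    d, out = config.head_widths
    params["fc1_W"] = rng.normal(0, np.sqrt(2.0 / d), (d, d))
    params["fc1_b"] = np.zeros(d)
    params["fc2_W"] = rng.normal(0, np.sqrt(2.0 / d), (d, out))
    params["fc2_b"] = np.zeros(out)
    return params


def weight_keys(params: dict) -> list:
    """Parameter names counted as 'weights' by the L2 penalty (no biases,
    no normalisation gains)."""
    return [k for k in params if k.endswith("_W")]


def _canonical_rows(x: np.ndarray, canonicalize: bool) -> np.ndarray:
    """(B, C, 16, 16) features -> (B, 16, C*16) per-row vectors."""
    xr = x.transpose(0, 2, 1, 3)  # (B, rows, C, cols)
    if canonicalize:
        xr = np.stack([np.roll(xr[:, k], -k, axis=-1) for k in range(EIM_SIZE)],
                      axis=1)
    b = x.shape[0]
    return xr.reshape(b, EIM_SIZE, -1)


def _canonical_rows_backward(drows: np.ndarray, c: int,
                             canonicalize: bool) -> np.ndarray:
    b = drows.shape[0]
    dxr = drows.reshape(b, EIM_SIZE, c, EIM_SIZE)
    if canonicalize:
        dxr = np.stack([np.roll(dxr[:, k], k, axis=-1) for k in range(EIM_SIZE)],
                       axis=1)
    return dxr.transpose(0, 2, 1, 3)


def forward_pass(params: dict, eim: np.ndarray, config: NetConfig,
                 train: bool = False, rng: np.random.Generator | None = None,
                 cache: dict | None = None) -> np.ndarray:
    """Reconstruct a batch of maps into images.

    ``eim`` may be (16, 16) or (B, 16, 16); the output matches ((64, 64) or
    (B, 64, 64)).  With ``train=True`` dropout is active (needs ``rng``) and,
    if a dict is passed as ``cache``, intermediates for ``backward_pass`` are
    stored in it.
    """
    single = eim.ndim == 2
    x = np.asarray(eim, dtype=float)
    if single:
        x = x[None]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in the input map")
    if x.shape[1:] != (EIM_SIZE, EIM_SIZE):
        raise ValueError("input maps must be 16x16")
    B = x.shape[0]
    n = config.out_size
    store = cache is not None
    acts = []
    h = x[:, None]  # (B, 1, 16, 16)
    for i in range(len(config.conv_channels)):
        z = _circ_conv(h, params[f"conv{i}_W"]) \
            + params[f"conv{i}_b"][None, :, None, None]
        y, ln_cache = _layernorm(z, params[f"ln{i}_g"], params[f"ln{i}_b"])
        if store:
            acts.append((h, ln_cache, y))
        h = _leaky(y)
    rows = _canonical_rows(h, config.canonicalize_rows)   # (B, 16, D)
    h1 = rows @ params["fc1_W"] + params["fc1_b"]
    a1 = _leaky(h1)
    if train and config.dropout > 0:
        if rng is None:
            raise ValueError("training-mode forward pass needs an rng for dropout")
        keep = 1.0 - config.dropout
        dmask = (rng.random(a1.shape) < keep) / keep
        a1d = a1 * dmask
    else:
        dmask = None
        a1d = a1
    maps = a1d @ params["fc2_W"] + params["fc2_b"]        # (B, 16, n*n)
    if config.aggregation == "rotate_mean":
        ops = rotation_operators(n)
        pre = np.zeros((B, n * n))
        for k in range(EIM_SIZE):
            pre += maps[:, k] @ ops[k].T
        pre /= EIM_SIZE
    else:
        pre = maps.mean(axis=1)
    pre = pre.reshape(B, n, n)
    out = _softplus(pre) if config.out_activation == "softplus" else pre
    if store:
        cache.update(acts=acts, rows=rows, h1=h1, a1=a1, dmask=dmask,
                     a1d=a1d, pre=pre, B=B)
    return out[0] if single else out


def backward_pass(params: dict, config: NetConfig, cache: dict,
                  dout: np.ndarray) -> dict:
    """Vector-Jacobian product of ``forward_pass`` w.r.t. all parameters."""
    B = cache["B"]
    n = config.out_size
    if dout.ndim == 2:
        dout = dout[None]
    if config.out_activation == "softplus":
        dpre = dout * _sigmoid(cache["pre"])
    else:
        dpre = dout
    dpre = dpre.reshape(B, n * n)
    dmaps = np.empty((B, EIM_SIZE, n * n))
    if config.aggregation == "rotate_mean":
        ops = rotation_operators(n)
        for k in range(EIM_SIZE):
            dmaps[:, k] = (dpre @ ops[k]) / EIM_SIZE
    else:
        dmaps[:] = (dpre / EIM_SIZE)[:, None]
    grads = {}
    a1d = cache["a1d"]
    grads["fc2_W"] = np.einsum("bkd,bko->do", a1d, dmaps, optimize=True)
    grads["fc2_b"] = dmaps.sum(axis=(0, 1))
    da1d = dmaps @ params["fc2_W"].T
    if cache["dmask"] is not None:
        da1d = da1d * cache["dmask"]
    dh1 = da1d * _dleaky(cache["h1"])
    rows = cache["rows"]
    grads["fc1_W"] = np.einsum("bkd,bke->de", rows, dh1, optimize=True)
    grads["fc1_b"] = dh1.sum(axis=(0, 1))
    drows = dh1 @ params["fc1_W"].T
    dh = _canonical_rows_backward(drows, config.channels_final,
                                  config.canonicalize_rows)
    for i in reversed(range(len(config.conv_channels))):
        hin, ln_cache, y = cache["acts"][i]
        dy = dh * _dleaky(y)
        dz, dg, db_ln = _layernorm_backward(ln_cache, params[f"ln{i}_g"], dy)
        grads[f"ln{i}_g"] = dg
        grads[f"ln{i}_b"] = db_ln
        dh, dW, db = _circ_conv_backward(hin, params[f"conv{i}_W"], dz)
        grads[f"conv{i}_W"] = dW
        grads[f"conv{i}_b"] = db
    return grads


# --------------------------------------------------------------------------
# losses

def loss_w2(params: dict, squared: bool = True) -> float:
    """Weight penalty: sum of squared weights (literal plain sum via flag)."""
    total = 0.0
    for k in weight_keys(params):
        w = params[k]
        total += float((w * w).sum() if squared else w.sum())
    return total


def loss_tv(image: np.ndarray) -> float:
    """Anisotropic total variation, summed over in-grid forward neighbours."""
    image = np.asarray(image, dtype=float)
    return float(np.abs(np.diff(image, axis=-2)).sum()
                 + np.abs(np.diff(image, axis=-1)).sum())


def _tv_grad(image: np.ndarray) -> np.ndarray:
    g = np.zeros_like(image)
    d = np.sign(np.diff(image, axis=-2))
    g[..., 1:, :] += d
    g[..., :-1, :] -= d
    d = np.sign(np.diff(image, axis=-1))
    g[..., :, 1:] += d
    g[..., :, :-1] -= d
    return g


def loss_msle(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared logarithmic error over all pixels."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.any(pred <= -1) or np.any(target <= -1):
        raise ValueError("MSLE requires all values > -1")
    d = np.log1p(pred) - np.log1p(target)
    return float(np.mean(d * d))


def _msle_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    d = np.log1p(pred) - np.log1p(target)
    return 2.0 * d / (d.size * (1.0 + pred))


def compose_total(w2: float, tv: float, msle: float,
                  weights: LossWeights = LossWeights()) -> float:
    """The composite-loss formula on already-computed component values."""
    return w2 + weights.lambda1 * tv + weights.lambda2 * msle


def loss_total(params: dict, pred: np.ndarray, target: np.ndarray,
               weights: LossWeights = LossWeights(),
               squared_w2: bool = True) -> float:
    """Composite loss exactly as printed: Lw2 + l1*TV + l2*MSLE."""
    return compose_total(loss_w2(params, squared=squared_w2),
                         loss_tv(pred), loss_msle(pred, target), weights)


# --------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    plateau_patience: int = 10
    lr_factor: float = 0.3
    val_frac: float = 0.1
    alpha_blending: bool = True
    preset: str = "sane"
    seed: int = 0

    def coefficients(self) -> tuple:
        return LOSS_PRESETS[self.preset]


class Adam:
    """Standard Adam with bias correction; state keyed like the params."""

    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _batch_loss_and_grads(params, config, eims, targets, coeffs, rng):
    c_w2, c_tv, c_msle = coeffs
    cache = {}
    pred = forward_pass(params, eims, config, train=True, rng=rng, cache=cache)
    msle = loss_msle(pred, targets)
    # per-pair-normalised TV so lambda1 is comparable across image sizes
    n_pairs = 2 * pred.shape[-1] * (pred.shape[-1] - 1) * pred.shape[0]
    tv = loss_tv(pred) / n_pairs
    dpred = c_msle * _msle_grad(pred, targets) + (c_tv / n_pairs) * _tv_grad(pred)
    grads = backward_pass(params, config, cache, dpred)
    if c_w2:
        for k in weight_keys(params):
            grads[k] = grads[k] + 2.0 * c_w2 * params[k]
    w2 = loss_w2(params) if c_w2 else 0.0
    return c_w2 * w2 + c_tv * tv + c_msle * msle, grads


def train(params: dict, dataset: tuple, config: NetConfig,
          train_config: TrainConfig = TrainConfig()) -> tuple:
    """Adam training with alpha-blended pairs and plateau LR decay.

    ``dataset`` is ``(eims (N, 16, 16), targets (N, 64, 64))``.  Returns
    ``(params, history)``; history carries per-epoch training loss,
    validation MSLE, the monotone best-so-far validation MSLE, and the
    learning rate.  Fully deterministic for a given seed.
    """
    from .augment import blend_voltages  # local import avoids a cycle

    eims, targets = (np.asarray(a, dtype=float) for a in dataset)
    n = eims.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(train_config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(train_config.val_frac * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    coeffs = train_config.coefficients()
    opt = Adam(params, train_config.lr)
    history = {"train_loss": [], "val_msle": [], "best_val_msle": [], "lr": []}
    best = np.inf
    stall = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(tr_idx))
        partner = rng.permutation(len(tr_idx))
        epoch_loss = 0.0
        nb = 0
        for start in range(0, len(tr_idx), train_config.batch_size):
            sel = tr_idx[order[start:start + train_config.batch_size]]
            be, bt = eims[sel], targets[sel]
            if train_config.alpha_blending:
                mate = tr_idx[partner[start:start + train_config.batch_size]]
                alphas = rng.uniform(0, 1, size=len(sel))
                be = np.stack([blend_voltages(e1, e2, a) for e1, e2, a
                               in zip(be, eims[mate], alphas)])
                bt = alphas[:, None, None] * bt \
                    + (1 - alphas)[:, None, None] * targets[mate]
            loss, grads = _batch_loss_and_grads(
                params, config, be, bt, coeffs, rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {nb}")
            opt.step(params, grads)
            epoch_loss += loss
            nb += 1
        if n_val:
            vp = forward_pass(params, eims[val_idx], config)
            val = loss_msle(vp, targets[val_idx])
        else:
            val = float("nan")
        if val < best - 1e-12:
            best = val
            stall = 0
        else:
            stall += 1
            if stall > train_config.plateau_patience:
                opt.lr *= train_config.lr_factor
                stall = 0
        history["train_loss"].append(epoch_loss / max(nb, 1))
        history["val_msle"].append(val)
        history["best_val_msle"].append(best)
        history["lr"].append(opt.lr)
    return params, history


def save_checkpoint(path: str, params: dict, config: NetConfig,
                    seed: int | None = None) -> None:
    """Parameters + architecture in one .npz (config serialised as JSON)."""
    import json

    meta = {"config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(config).items()},
            "seed": seed}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **params)


def load_checkpoint(path: str) -> tuple:
    """Returns ``(params, NetConfig, seed)`` from ``save_checkpoint`` output."""
    import json

    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        params = {k: f[k] for k in f.files if k != "__meta__"}
    cfg_kv = {k: tuple(v) if isinstance(v, list) else v
              for k, v in meta["config"].items()}
    return params, NetConfig(**cfg_kv), meta["seed"]
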