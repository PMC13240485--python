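"""Channel-and-Spatial Parallel Attention (CSPA) and baseline attention modules.

An attention module follows a three-step contract:

    extract   X -> E      pooled descriptors of the feature map
    transform E -> T      attention factors in (0, 1) via learned maps + sigmoid
    fuse      (X, T) -> X  multiplicative (or additive) recalibration

CSPA runs two branches *in parallel from the same input*:

* channel branch — global max pooling and global average pooling collapse
  each channel's H x W plane to a scalar; a 1D convolution of size k slides
  along the channel axis of each pooled vector (no dimensionality
  reduction, as in efficient channel attention); the two responses are
  summed and squashed:  Wc = sigmoid(C1D(GMP(X)) + C1D(GAP(X))).
* spatial branch — max and mean over the channel axis give two H x W
  planes; stacked, they pass through parallel 1x1 and 3x3 convolutions
  (2 -> 1 channel each); those two outputs are stacked again and a final
  7x7 convolution (2 -> 1) plus sigmoid gives the per-location factor map.

Fusion is elementwise:  out[h, w, c] = X[h, w, c] * Wc[c] * Ws[h, w].

Two layers of API live here:

* pure-NumPy functional forms (``channel_attention``, ``spatial_attention``,
  ``apply_cspa``) on single H x W x C arrays — convenient for analysis and
  verification against explicit-loop references;
* autograd ``Module`` classes on batched N x C x H x W tensors
  (``CSPAAttention``, ``SEAttention``, ``ECAAttention``, ``CBAMAttention``)
  obtained through the ``build_attention`` registry and consumed by the
  network's bottleneck blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor
from .errors import ConfigurationError, InputError

__all__ = [
    "AttentionConfig", "adaptive_kernel_size",
    "channel_attention", "spatial_attention", "apply_cspa",
    "build_attention", "attention_names",
    "IdentityAttention", "SEAttention", "ECAAttention",
    "CBAMAttention", "CSPAAttention",
]

SPATIAL_KERNELS = (1, 3, 7)  # fixed: parallel 1x1 / 3x3, then final 7x7


@dataclass(frozen=True)
class AttentionConfig:
    """Hyperparameters shared by the attention modules.

    channel_kernel_size: size k of the 1D channel convolution, or "auto"
        to derive it from the channel count (see ``adaptive_kernel_size``).
    share_channel_conv: apply one shared kernel to both pooled vectors
        (the default, matching the single C1D operator in the channel
        branch) or learn separate kernels per pooled path.
    use_bias: include bias terms in the attention convolutions. Off by
        default, so zero-initialized weights give factors of exactly 0.5.
    weight_init_scheme: "zeros" (analytic, factors 0.5 everywhere at init)
        or "uniform-scaled" (He-style fan-in scaled uniform, for training).
    se_reduction: bottleneck reduction ratio of the SE / CBAM channel MLPs.
    """

    channel_kernel_size: int | str = "auto"
    share_channel_conv: bool = True
    use_bias: bool = False
    spatial_kernels: tuple = SPATIAL_KERNELS
    weight_init_scheme: str = "uniform-scaled"
    seed: int = 0
    se_reduction: int = 16

    def __post_init__(self):
        k = self.channel_kernel_size
        if k != "auto" and (not isinstance(k, int) or k < 1 or k % 2 == 0):
            raise ConfigurationError(
                f"channel_kernel_size must be an odd integer >= 1 or 'auto', got {k!r}")
        if tuple(self.spatial_kernels) != SPATIAL_KERNELS:
            raise ConfigurationError(
                f"spatial_kernels is fixed at {SPATIAL_KERNELS}, got {self.spatial_kernels!r}")
        if self.weight_init_scheme not in ("zeros", "uniform-scaled"):
            raise ConfigurationError(
                f"unknown weight_init_scheme {self.weight_init_scheme!r}")

    def resolve_kernel_size(self, channels: int) -> int:
        if self.channel_kernel_size == "auto":
            return adaptive_kernel_size(channels)
        return self.channel_kernel_size


def adaptive_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Channel-count-adaptive size of the 1D channel-attention kernel.

    Returns the odd integer >= 1 nearest to |log2(C)/gamma + b/gamma|,
    resolving ties toward the smaller kernel. This is the efficient-
    channel-attention sizing policy: wider channel dimensions get a
    (logarithmically) wider local interaction window.
    """
    if channels < 1:
        raise InputError(f"channels must be >= 1, got {channels}")
    t = abs(math.log2(channels) / gamma + b / gamma)
    lo = max(1, 2 * math.floor((t - 1) / 2) + 1)  # nearest odd <= t (>= 1)
    hi = lo + 2
    return lo if (t - lo) <= (hi - t) else hi


# ---------------------------------------------------------------------------
# Functional forms (single feature map, H x W x C, plain NumPy)
# ---------------------------------------------------------------------------

def _validate_feature_map(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or min(X.shape) < 1:
        raise InputError(f"feature map must be rank-3 (H, W, C), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError("feature map contains non-finite entries")
    return X


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _conv1d_same(v: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    k = kernel.shape[0]
    p = (k - 1) // 2
    vp = np.pad(v, p)
    return np.convolve(vp, kernel[::-1], mode="valid") + bias


def channel_attention(X, kernel, cfg: AttentionConfig = AttentionConfig(),
                      kernel_avg=None, bias: float = 0.0) -> np.ndarray:
    """Per-channel attention factors Wc = sigmoid(C1D(GMP(X)) + C1D(GAP(X))).

    ``kernel`` is the learned 1D kernel applied to the max-pooled vector;
    with ``cfg.share_channel_conv`` (default) the same kernel also serves
    the average-pooled path, otherwise ``kernel_avg`` must be supplied.
    Zero padding (k-1)/2 keeps the output length at C.
    """
    X = _validate_feature_map(X)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.shape[0] % 2 == 0:
        raise ConfigurationError(f"channel kernel must be 1D of odd length, got shape {kernel.shape}")
    k = cfg.resolve_kernel_size(X.shape[2])
    if kernel.shape[0] != k:
        raise ConfigurationError(
            f"channel kernel length {kernel.shape[0]} does not match configured k={k}")
    if cfg.share_channel_conv:
        kernel_avg = kernel
    elif kernel_avg is None:
        raise ConfigurationError("share_channel_conv=False requires kernel_avg")
    else:
        kernel_avg = np.asarray(kernel_avg, dtype=float)
        if kernel_avg.shape != kernel.shape:
            raise ConfigurationError("kernel_avg must match kernel length")
    gmp = X.max(axis=(0, 1))
    gap = X.mean(axis=(0, 1))
    b = bias if cfg.use_bias else 0.0
    return _sigmoid(_conv1d_same(gmp, kernel, b) + _conv1d_same(gap, kernel_avg, b))


def _conv2d_same(plane2: np.ndarray, w: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """'Same' cross-correlation of a (H, W, Cin) stack with one (k, k, Cin) kernel."""
    k = w.shape[0]
    p = (k - 1) // 2
    H, W, Cin = plane2.shape
    xp = np.pad(plane2, ((p, p), (p, p), (0, 0)))
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(xp, (k, k), axis=(0, 1))  # (H, W, Cin, k, k)
    return np.einsum("hwcij,ijc->hw", win, w) + bias


def spatial_attention(X, weights: dict, cfg: AttentionConfig = AttentionConfig(),
                      biases: dict | None = None) -> np.ndarray:
    """Per-location attention factors (H x W) from channel-pooled planes.

    ``weights`` maps kernel size to its array: {1: (1,1,2), 3: (3,3,2),
    7: (7,7,2)}; each convolution takes a 2-channel stack to 1 channel,
    with zero padding preserving H x W throughout.
    """
    X = _validate_feature_map(X)
    if set(weights) != set(SPATIAL_KERNELS):
        raise ConfigurationError(f"spatial weights must have kernel sizes {SPATIAL_KERNELS}")
    ws = {}
    for k in SPATIAL_KERNELS:
        w = np.asarray(weights[k], dtype=float)
        if w.shape != (k, k, 2):
            raise ConfigurationError(
                f"spatial kernel {k} must have shape {(k, k, 2)}, got {w.shape}")
        ws[k] = w
    biases = biases or {}
    bz = {k: (biases.get(k, 0.0) if cfg.use_bias else 0.0) for k in SPATIAL_KERNELS}
    pooled = np.stack([X.max(axis=2), X.mean(axis=2)], axis=2)  # (H, W, 2)
    p1 = _conv2d_same(pooled, ws[1], bz[1])
    p3 = _conv2d_same(pooled, ws[3], bz[3])
    restacked = np.stack([p1, p3], axis=2)
    return _sigmoid(_conv2d_same(restacked, ws[7], bz[7]))


def apply_cspa(X, Wc, Ws) -> np.ndarray:
    """Parallel fusion: out[h, w, c] = X[h, w, c] * Wc[c] * Ws[h, w].

    Both factor sets are computed from the *original* input, so the two
    branches commute; fusion is a single elementwise product.
    """
    X = np.asarray(X, dtype=float)
    Wc = np.asarray(Wc, dtype=float)
    Ws = np.asarray(Ws, dtype=float)
    if X.ndim != 3:
        raise InputError(f"feature map must be rank-3, got shape {X.shape}")
    if Wc.shape != (X.shape[2],):
        raise InputError(f"channel factors must have length C={X.shape[2]}, got {Wc.shape}")
    if Ws.shape != X.shape[:2]:
        raise InputError(f"spatial factors must be {X.shape[:2]}, got {Ws.shape}")
    return X * Wc[None, None, :] * Ws[:, :, None]


# ---------------------------------------------------------------------------
# Trainable modules (batched N x C x H x W, autograd)
# ---------------------------------------------------------------------------

def _init(shape, rng, scheme: str, fan_in: int, dtype=np.float32) -> Parameter:
    if scheme == "zeros":
        return Parameter(np.zeros(shape, dtype=dtype))
    bound = math.sqrt(6.0 / max(fan_in, 1))
    return Parameter(rng.uniform(-bound, bound, size=shape).astype(dtype))


class AttentionBase(Module):
    """extract / transform / fuse contract shared by all attention modules."""

    fusion_op = "multiply"

    def extract(self, x: Tensor):
        raise NotImplementedError

    def transform(self, e):
        raise NotImplementedError

    def fuse(self, x: Tensor, t) -> Tensor:
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(x, self.transform(self.extract(x)))


class IdentityAttention(AttentionBase):
    """The 'none' entry of the registry: a pass-through operator."""

    def __init__(self, channels: int = 0, cfg: AttentionConfig | None = None,
                 rng=None):
        pass

    def extract(self, x):
        return x

    def transform(self, e):
        return None

    def fuse(self, x, t):
        return x


class SEAttention(AttentionBase):
    """Squeeze-and-excitation: GAP -> bottleneck MLP -> sigmoid -> scale."""

    def __init__(self, channels: int, cfg: AttentionConfig, rng):
        self.channels = channels
        hidden = max(channels // cfg.se_reduction, 1)
        self.w1 = _init((channels, hidden), rng, cfg.weight_init_scheme, channels)
        self.w2 = _init((hidden, channels), rng, cfg.weight_init_scheme, hidden)

    def extract(self, x):
        return ag.reduce_mean(x, axis=(2, 3))  # (N, C)

    def transform(self, e):
        return ag.sigmoid(ag.linear(ag.relu(ag.linear(e, self.w1)), self.w2))

    def fuse(self, x, t):
        N, C = t.shape
        return ag.mul(x, ag.reshape(t, (N, C, 1, 1)))


class ECAAttention(AttentionBase):
    """Efficient channel attention: GAP -> 1D conv of size k -> sigmoid."""

    def __init__(self, channels: int, cfg: AttentionConfig, rng):
        self.channels = channels
        k = cfg.resolve_kernel_size(channels)
        self.kernel = _init((k,), rng, cfg.weight_init_scheme, k)

    def extract(self, x):
        return ag.reduce_mean(x, axis=(2, 3))

    def transform(self, e):
        return ag.sigmoid(ag.conv1d_channels(e, self.kernel))

    def fuse(self, x, t):
        N, C = t.shape
        return ag.mul(x, ag.reshape(t, (N, C, 1, 1)))


class CBAMAttention(AttentionBase):
    """Convolutional block attention: sequential channel then spatial gates.

    Channel gate: shared two-layer MLP on GAP and GMP descriptors, summed,
    sigmoid. Spatial gate: 7x7 convolution over the stacked channel-max /
    channel-mean planes of the channel-refined map, sigmoid. Unlike CSPA
    the second gate sees the already-recalibrated features.
    """

    def __init__(self, channels: int, cfg: AttentionConfig, rng):
        self.channels = channels
        hidden = max(channels // cfg.se_reduction, 1)
        self.w1 = _init((channels, hidden), rng, cfg.weight_init_scheme, channels)
        self.w2 = _init((hidden, channels), rng, cfg.weight_init_scheme, hidden)
        self.w_sp = _init((1, 2, 7, 7), rng, cfg.weight_init_scheme, 2 * 49)

    def extract(self, x):
        return (ag.reduce_mean(x, axis=(2, 3)), ag.reduce_max(x, axis=(2, 3)))

    def _mlp(self, v):
        return ag.linear(ag.relu(ag.linear(v, self.w1)), self.w2)

    def transform(self, e):
        avg, mx = e
        return ag.sigmoid(ag.add(self._mlp(avg), self._mlp(mx)))

    def fuse(self, x, t):
        N, C = t.shape
        xc = ag.mul(x, ag.reshape(t, (N, C, 1, 1)))
        planes = ag.concat([ag.reduce_max(xc, axis=1, keepdims=True),
                            ag.reduce_mean(xc, axis=1, keepdims=True)], axis=1)
        ws = ag.sigmoid(ag.conv2d(planes, self.w_sp, padding=3))
        return ag.mul(xc, ws)


class CSPAAttention(AttentionBase):
    """Channel-and-spatial parallel attention (the module under study).

    Both branches read the original input; their factors multiply it
    jointly (parallel fusion), unlike CBAM's sequential refinement.
    """

    def __init__(self, channels: int, cfg: AttentionConfig, rng):
        self.channels = channels
        self.cfg = cfg
        k = cfg.resolve_kernel_size(channels)
        self.kernel_size = k
        scheme = cfg.weight_init_scheme
        self.ch_kernel = _init((k,), rng, scheme, k)
        if not cfg.share_channel_conv:
            self.ch_kernel_avg = _init((k,), rng, scheme, k)
        self.w1 = _init((1, 2, 1, 1), rng, scheme, 2)
        self.w3 = _init((1, 2, 3, 3), rng, scheme, 2 * 9)
        self.w7 = _init((1, 2, 7, 7), rng, scheme, 2 * 49)
        if cfg.use_bias:
            self.b_ch = Parameter(np.zeros((), dtype=np.float32))
            self.b1 = Parameter(np.zeros(1, dtype=np.float32))
            self.b3 = Parameter(np.zeros(1, dtype=np.float32))
            self.b7 = Parameter(np.zeros(1, dtype=np.float32))

    def extract(self, x):
        gmp = ag.reduce_max(x, axis=(2, 3))    # (N, C)
        gap = ag.reduce_mean(x, axis=(2, 3))   # (N, C)
        smax = ag.reduce_max(x, axis=1, keepdims=True)    # (N, 1, H, W)
        savg = ag.reduce_mean(x, axis=1, keepdims=True)   # (N, 1, H, W)
        return gmp, gap, ag.concat([smax, savg], axis=1)

    def transform(self, e):
        gmp, gap, planes = e
        k_avg = self.ch_kernel if self.cfg.share_channel_conv else self.ch_kernel_avg
        b_ch = getattr(self, "b_ch", None)
        zc = ag.add(ag.conv1d_channels(gmp, self.ch_kernel, b_ch),
                    ag.conv1d_channels(gap, k_avg, b_ch))
        wc = ag.sigmoid(zc)                                    # (N, C)
        p1 = ag.conv2d(planes, self.w1, getattr(self, "b1", None), padding=0)
        p3 = ag.conv2d(planes, self.w3, getattr(self, "b3", None), padding=1)
        restacked = ag.concat([p1, p3], axis=1)                # (N, 2, H, W)
        ws = ag.sigmoid(ag.conv2d(restacked, self.w7, getattr(self, "b7", None),
                                  padding=3))                  # (N, 1, H, W)
        return wc, ws

    def fuse(self, x, t):
        wc, ws = t
        N, C = wc.shape
        return ag.mul(ag.mul(x, ag.reshape(wc, (N, C, 1, 1))), ws)


_REGISTRY = {
    "none": IdentityAttention,
    "se": SEAttention,
    "eca": ECAAttention,
    "cbam": CBAMAttention,
    "cspa": CSPAAttention,
}


def attention_names():
    return tuple(_REGISTRY)


def build_attention(name: str, channels: int,
                    cfg: AttentionConfig | None = None, rng=None) -> AttentionBase:
    """Instantiate a registered attention operator for ``channels`` channels."""
    if name not in _REGISTRY:
        raise ConfigurationError(
            f"unknown attention {name!r}; valid names: {', '.join(sorted(_REGISTRY))}")
    cfg = cfg or AttentionConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return _REGISTRY[name](channels, cfg, rng)
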