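"""CSPANet: a residual bottleneck CNN with pluggable attention.

Architecture: a Stem of three convolutions with shrinking kernels
(7x7 -> 5x5 -> 3x3, the "inverted triangle"), six residual bottleneck
blocks (1x1 reduce -> 3x3 -> 1x1 expand, attention applied to the main
path before the residual addition), global average pooling, and a dense
softmax head. With the attention operator set to "cspa" in every block
this is the full CSPANet; with "none" and the Stem collapsed to a single
7x7 convolution it is the plain ResNet20-style baseline; the two toggles
span the four ablation arms.

Channel widths and strides of the six blocks are configurable; the
defaults follow standard residual staging (three stages of two blocks,
expansion 4, stride 2 at the first block of each stage). A quarter-width
"desk" preset at 256 x 128 input makes the whole stack trainable on a
single CPU.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor
from .attention import AttentionConfig, build_attention, attention_names
from .errors import ConfigurationError, InputError

__all__ = [
    "StemConfig", "BottleneckConfig", "NetworkConfig", "ClassifierOutput",
    "Stem", "Bottleneck", "CSPANet",
    "default_network_config", "count_parameters", "parameter_breakdown",
    "save_checkpoint", "load_checkpoint", "architecture_summary",
]

CHECKPOINT_FORMAT_VERSION = "1"
STEM_KERNELS = (7, 5, 3)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StemConfig:
    """Three-convolution entry stack (kernels fixed at 7, 5, 3).

    When ``enabled`` is False the stack is replaced by a single 7x7
    convolution with the same output width and the combined stride, the
    ResNet20-style ablation arm.
    """
    channel_widths: tuple = (32, 48, 64)
    strides: tuple = (2, 2, 2)
    enabled: bool = True
    kernel_sizes: tuple = STEM_KERNELS

    def __post_init__(self):
        if tuple(self.kernel_sizes) != STEM_KERNELS:
            raise ConfigurationError(f"stem kernel sizes are fixed at {STEM_KERNELS}")
        if len(self.channel_widths) != 3 or len(self.strides) != 3:
            raise ConfigurationError("stem needs exactly 3 channel widths and 3 strides")
        if min(self.channel_widths) < 1 or min(self.strides) < 1:
            raise ConfigurationError("stem widths and strides must be positive")

    @property
    def total_stride(self) -> int:
        return int(np.prod(self.strides))

    @property
    def out_channels(self) -> int:
        return self.channel_widths[-1]


@dataclass(frozen=True)
class BottleneckConfig:
    """One residual bottleneck block: 1x1 reduce -> 3x3 -> 1x1 expand."""
    in_channels: int
    mid_channels: int
    out_channels: int
    stride: int = 1
    attention_name: str = "cspa"
    shortcut: str = "auto"  # identity | projection | auto

    def __post_init__(self):
        if min(self.in_channels, self.mid_channels, self.out_channels, self.stride) < 1:
            raise ConfigurationError("bottleneck channel counts and stride must be positive")
        if self.attention_name not in attention_names():
            raise ConfigurationError(
                f"unknown attention {self.attention_name!r}; valid: {attention_names()}")
        identity_ok = self.in_channels == self.out_channels and self.stride == 1
        resolved = ("identity" if identity_ok else "projection") \
            if self.shortcut == "auto" else self.shortcut
        if resolved == "identity" and not identity_ok:
            raise ConfigurationError(
                "identity shortcut requires in_channels == out_channels and stride 1")
        if resolved not in ("identity", "projection"):
            raise ConfigurationError(f"unknown shortcut {self.shortcut!r}")
        object.__setattr__(self, "shortcut", resolved)


@dataclass(frozen=True)
class NetworkConfig:
    """Complete architectural description of a classifier instance."""
    stem: StemConfig
    blocks: tuple  # exactly six BottleneckConfig
    num_classes: int = 3
    input_size: tuple = (1600, 800)  # (W, H)
    input_channels: int = 1
    seed: int = 0
    attention: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        if len(self.blocks) != 6:
            raise ConfigurationError(f"exactly six bottleneck blocks required, got {len(self.blocks)}")
        if self.blocks[0].in_channels != self.stem.out_channels:
            raise ConfigurationError(
                f"block 0 expects {self.blocks[0].in_channels} input channels "
                f"but the stem produces {self.stem.out_channels}")
        for i in range(5):
            if self.blocks[i].out_channels != self.blocks[i + 1].in_channels:
                raise ConfigurationError(
                    f"block {i} outputs {self.blocks[i].out_channels} channels but "
                    f"block {i + 1} expects {self.blocks[i + 1].in_channels}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stem"]["kernel_sizes"] = list(self.stem.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        stem = StemConfig(**{**d["stem"], "kernel_sizes": tuple(d["stem"].get("kernel_sizes", STEM_KERNELS)),
                             "channel_widths": tuple(d["stem"]["channel_widths"]),
                             "strides": tuple(d["stem"]["strides"])})
        blocks = tuple(BottleneckConfig(**b) for b in d["blocks"])
        att = AttentionConfig(**{**d.get("attention", {}),
                                 "spatial_kernels": tuple(d.get("attention", {}).get("spatial_kernels", (1, 3, 7)))})
        return cls(stem=stem, blocks=blocks, num_classes=d["num_classes"],
                   input_size=tuple(d["input_size"]), input_channels=d["input_channels"],
                   seed=d["seed"], attention=att)


def default_network_config(attention: str = "cspa", stem_enabled: bool = True,
                           desk: bool = False, seed: int = 0,
                           attention_cfg: AttentionConfig | None = None) -> NetworkConfig:
    """The paper-scale architecture, or its quarter-width desk preset.

    Paper scale: input 1600 x 800 grayscale, stem widths (32, 48, 64),
    block output widths (256, 256, 512, 512, 1024, 1024) with expansion 4
    and stride 2 at the first block of each two-block stage. The desk
    preset divides every width by 4 and uses a 256 x 128 input.
    """
    div = 4 if desk else 1
    stem = StemConfig(channel_widths=tuple(w // div for w in (32, 48, 64)),
                      strides=(2, 2, 2), enabled=stem_enabled)
    outs = tuple(w // div for w in (256, 256, 512, 512, 1024, 1024))
    blocks = []
    in_ch = stem.out_channels
    for i, out in enumerate(outs):
        blocks.append(BottleneckConfig(
            in_channels=in_ch, mid_channels=out // 4, out_channels=out,
            stride=2 if i % 2 == 0 else 1, attention_name=attention))
        in_ch = out
    return NetworkConfig(stem=stem, blocks=tuple(blocks),
                         input_size=(256, 128) if desk else (1600, 800),
                         seed=seed,
                         attention=attention_cfg or AttentionConfig(seed=seed))


@dataclass
class ClassifierOutput:
    """Softmax probabilities, raw logits, and argmax class per sample."""
    probabilities: np.ndarray  # (N, num_classes)
    logits: np.ndarray
    predicted_class: np.ndarray  # (N,) int; ties resolve to the lowest index

    def __post_init__(self):
        if not np.allclose(self.probabilities.sum(axis=-1), 1.0, atol=1e-6):
            raise InputError("probabilities must sum to 1 per sample")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _he_uniform(shape, fan_in, rng, dtype=np.float32):
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    """Convolution without bias (batch norm follows every convolution)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None, scheme="uniform-scaled"):
        pad = (kernel - 1) // 2
        fan_in = in_ch * kernel * kernel
        shape = (out_ch, in_ch, kernel, kernel)
        if scheme == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        else:
            w = _he_uniform(shape, fan_in, rng)
        self.weight = Parameter(w)
        self.stride = stride
        self.padding = pad

    def forward(self, x):
        return ag.conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return ag.batch_norm(x, self.gamma, self.beta,
                             self._buffers["running_mean"], self._buffers["running_var"],
                             training=self.training, momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel, stride, rng, scheme="uniform-scaled",
                 activate=True):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, rng, scheme)
        self.bn = BatchNorm2d(out_ch)
        self.activate = activate

    def forward(self, x):
        y = self.bn(self.conv(x))
        return ag.relu(y) if self.activate else y


class Linear(Module):
    def __init__(self, in_f, out_f, rng, scheme="uniform-scaled"):
        if scheme == "zeros":
            w = np.zeros((in_f, out_f), dtype=np.float32)
        else:
            w = _he_uniform((in_f, out_f), in_f, rng)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32))

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


# ---------------------------------------------------------------------------
# Network blocks
# ---------------------------------------------------------------------------

class Stem(Module):
    """Inverted-triangle entry stack, or a single 7x7 conv when disabled."""

    def __init__(self, cfg: StemConfig, in_channels: int, rng, scheme="uniform-scaled"):
        self.cfg = cfg
        if cfg.enabled:
            widths = cfg.channel_widths
            chans = (in_channels,) + tuple(widths)
            self.layers = [
                ConvBNReLU(chans[i], chans[i + 1], k, s, rng, scheme)
                for i, (k, s) in enumerate(zip(cfg.kernel_sizes, cfg.strides))
            ]
        else:
            self.layers = [ConvBNReLU(in_channels, cfg.out_channels, 7,
                                      cfg.total_stride, rng, scheme)]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Bottleneck(Module):
    """Residual bottleneck with attention on the main path pre-addition."""

    def __init__(self, cfg: BottleneckConfig, att_cfg: AttentionConfig, rng,
                 scheme="uniform-scaled"):
        self.cfg = cfg
        self.reduce = ConvBNReLU(cfg.in_channels, cfg.mid_channels, 1, 1, rng, scheme)
        self.conv3 = ConvBNReLU(cfg.mid_channels, cfg.mid_channels, 3, cfg.stride, rng, scheme)
        self.expand = ConvBNReLU(cfg.mid_channels, cfg.out_channels, 1, 1, rng, scheme,
                                 activate=False)
        self.attention = build_attention(cfg.attention_name, cfg.out_channels,
                                         att_cfg, rng)
        if cfg.shortcut == "projection":
            self.proj = ConvBNReLU(cfg.in_channels, cfg.out_channels, 1, cfg.stride,
                                   rng, scheme, activate=False)

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise InputError(
                f"bottleneck expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        main = self.expand(self.conv3(self.reduce(x)))
        main = self.attention(main)
        short = self.proj(x) if self.cfg.shortcut == "projection" else x
        return ag.relu(ag.add(main, short))


class CSPANet(Module):
    """Stem -> six bottlenecks -> global average pooling -> dense softmax head."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        scheme = cfg.attention.weight_init_scheme
        self.stem = Stem(cfg.stem, cfg.input_channels, rng, scheme)
        self.blocks = [Bottleneck(b, cfg.attention, rng, scheme) for b in cfg.blocks]
        self.head = Linear(cfg.blocks[-1].out_channels, cfg.num_classes, rng, scheme)

    def forward(self, x) -> Tensor:
        """Logits for a (N, C, H, W) batch; raises on a wrong input size."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        W, H = self.cfg.input_size
        expected = (self.cfg.input_channels, H, W)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise InputError(
                f"expected input batch of shape (N, {expected[0]}, {expected[1]}, "
                f"{expected[2]}) for input_size (W={W}, H={H}), got {tuple(x.shape)}")
        y = self.stem(x)
        for block in self.blocks:
            y = block(y)
        pooled = ag.reduce_mean(y, axis=(2, 3))
        return self.head(pooled)

    def predict(self, x) -> ClassifierOutput:
        """Deterministic inference: probabilities, logits, argmax class."""
        self.set_training(False)
        logits = self.forward(x).data
        probs = ag.softmax(logits)
        return ClassifierOutput(probabilities=probs, logits=logits,
                                predicted_class=np.argmax(probs, axis=-1))


# ---------------------------------------------------------------------------
# Parameter accounting, checkpointing, summaries
# ---------------------------------------------------------------------------

def count_parameters(cfg_or_model) -> int:
    """Exact trainable-parameter count of a config or built model."""
    model = cfg_or_model if isinstance(cfg_or_model, Module) else CSPANet(cfg_or_model)
    return int(sum(p.data.size for p in model.parameters()))


def parameter_breakdown(cfg_or_model) -> dict:
    """Per-component parameter counts: stem, each block, head; and conv-only
    subtotals (normalization scale/shift parameters reported separately)."""
    model = cfg_or_model if isinstance(cfg_or_model, Module) else CSPANet(cfg_or_model)

    def split(mod):
        conv = sum(p.data.size for n, p in mod.named_parameters()
                   if n.endswith(("weight", "kernel", "w1", "w3", "w7", "ch_kernel",
                                  "ch_kernel_avg", "w2", "w_sp")) and "bn" not in n)
        total = sum(p.data.size for p in mod.parameters())
        return {"total": int(total), "conv": int(conv), "other": int(total - conv)}

    out = {"stem": split(model.stem)}
    for i, b in enumerate(model.blocks):
        out[f"block{i}"] = split(b)
    out["head"] = split(model.head)
    out["total"] = count_parameters(model)
    return out


def save_checkpoint(path, model: CSPANet, seed: int | None = None, extra: dict | None = None):
    """Single-file checkpoint: config JSON, all weights and BN statistics."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "network_config": model.cfg.to_dict(),
        "seed": model.cfg.seed if seed is None else seed,
        "extra": extra or {},
    }
    arrays = {f"param/{n}": p.data for n, p in model.named_parameters()}
    arrays.update({f"buffer/{n}": b for n, b in model.named_buffers()})
    arrays["__meta__"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple:
    """Rebuild the model from a checkpoint; returns (model, metadata dict)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint format {meta.get('format_version')!r}")
        cfg = NetworkConfig.from_dict(meta["network_config"])
        model = CSPANet(cfg)
        params = dict(model.named_parameters())
        for key in z.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                if name not in params:
                    raise ConfigurationError(f"checkpoint has unknown parameter {name!r}")
                if params[name].data.shape != z[key].shape:
                    raise ConfigurationError(f"shape mismatch for parameter {name!r}")
                params[name].data = z[key].copy()
        buffers = dict(model.named_buffers())
        for key in z.files:
            if key.startswith("buffer/"):
                name = key[len("buffer/"):]
                buffers[name][...] = z[key]
    return model, meta


def architecture_summary(model: CSPANet, batch_size: int = 1) -> str:
    """Plain-text per-stage table: name, output shape, parameter count."""
    W, H = model.cfg.input_size
    x = Tensor(np.zeros((batch_size, model.cfg.input_channels, H, W), dtype=np.float32))
    model.set_training(False)
    rows = [("input", tuple(x.shape), 0)]
    y = model.stem(x)
    rows.append(("stem", tuple(y.shape), sum(p.data.size for p in model.stem.parameters())))
    for i, block in enumerate(model.blocks):
        y = block(y)
        rows.append((f"block{i}[{block.cfg.attention_name}]", tuple(y.shape),
                     sum(p.data.size for p in block.parameters())))
    pooled = ag.reduce_mean(y, axis=(2, 3))
    logits = model.head(pooled)
    rows.append(("head", tuple(logits.shape),
                 sum(p.data.size for p in model.head.parameters())))
    buf = io.StringIO()
    buf.write(f"{'layer':<20}{'output shape':<24}{'params':>10}\n")
    for name, shape, n in rows:
        buf.write(f"{name:<20}{str(shape):<24}{n:>10}\n")
    buf.write(f"{'total':<20}{'':<24}{count_parameters(model):>10}\n")
    return buf.getvalue()
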