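"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops and index
arithmetic, deliberately sharing no code with the package, so agreement
between the two is evidence of correctness rather than tautology.
"""

import math

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def loop_channel_attention(X, kernel, kernel_avg=None):
    """Explicit-loop channel attention on an (H, W, C) map."""
    H, W, C = X.shape
    k = len(kernel)
    p = (k - 1) // 2
    if kernel_avg is None:
        kernel_avg = kernel
    gmp = np.empty(C)
    gap = np.empty(C)
    for c in range(C):
        mx, total = -math.inf, 0.0
        for h in range(H):
            for w in range(W):
                v = X[h, w, c]
                mx = max(mx, v)
                total += v
        gmp[c] = mx
        gap[c] = total / (H * W)
    out = np.empty(C)
    for c in range(C):
        z = 0.0
        for j in range(k):
            src = c + j - p
            if 0 <= src < C:
                z += kernel[j] * gmp[src] + kernel_avg[j] * gap[src]
        out[c] = sigmoid(z)
    return out


def loop_conv2d_same(stack, w):
    """'Same' zero-padded cross-correlation, (H, W, Cin) x (k, k, Cin) -> (H, W)."""
    H, W, Cin = stack.shape
    k = w.shape[0]
    p = (k - 1) // 2
    out = np.zeros((H, W))
    for h in range(H):
        for x in range(W):
            z = 0.0
            for i in range(k):
                for j in range(k):
                    hh, ww = h + i - p, x + j - p
                    if 0 <= hh < H and 0 <= ww < W:
                        for c in range(Cin):
                            z += stack[hh, ww, c] * w[i, j, c]
            out[h, x] = z
    return out


def loop_spatial_attention(X, weights):
    """Explicit-loop spatial attention on an (H, W, C) map."""
    H, W, C = X.shape
    pooled = np.empty((H, W, 2))
    for h in range(H):
        for x in range(W):
            mx, total = -math.inf, 0.0
            for c in range(C):
                v = X[h, x, c]
                mx = max(mx, v)
                total += v
            pooled[h, x, 0] = mx
            pooled[h, x, 1] = total / C
    p1 = loop_conv2d_same(pooled, weights[1])
    p3 = loop_conv2d_same(pooled, weights[3])
    restacked = np.stack([p1, p3], axis=2)
    return sigmoid(loop_conv2d_same(restacked, weights[7]))


def loop_apply_cspa(X, wc, ws):
    H, W, C = X.shape
    out = np.empty_like(X, dtype=float)
    for h in range(H):
        for w in range(W):
            for c in range(C):
                out[h, w, c] = X[h, w, c] * wc[c] * ws[h, w]
    return out


def nearest_odd_oracle(t):
    """Enumerate odd candidates and pick the closest (ties -> smaller)."""
    best, best_d = None, math.inf
    for cand in range(1, 65, 2):
        d = abs(cand - t)
        if d < best_d - 1e-12:
            best, best_d = cand, d
    return best


def loop_macro_metrics(counts):
    """Per-class enumeration of the four macro metrics from a 3x3 tally."""
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    acc = sum(counts[i, i] for i in range(3)) / total
    sens, spec, prec = [], [], []
    for i in range(3):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            sens.append(tp / (tp + fn))
        if tn + fp > 0:
            spec.append(tn / (tn + fp))
        if tp + fp > 0:
            prec.append(tp / (tp + fp))
    mean = lambda v: sum(v) / len(v) if v else float("nan")
    return acc, mean(sens), mean(spec), mean(prec)


def pair_count_auc(scores, labels, class_index):
    """Mann-Whitney probability-of-correct-ranking with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == class_index]
    neg = [s for s, l in zip(scores, labels) if l != class_index]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def count_conv_params(in_ch, out_ch, k, bias=False):
    return k * k * in_ch * out_ch + (out_ch if bias else 0)


def expected_network_params(cfg):
    """Closed-form parameter count for a NetworkConfig, by per-layer arithmetic."""
    def bn(c):
        return 2 * c

    def attention_params(name, c, k_auto):
        if name == "none":
            return 0
        if name == "eca":
            return k_auto(c)
        if name == "se":
            h = max(c // 16, 1)
            return c * h + h * c
        if name == "cbam":
            h = max(c // 16, 1)
            return c * h + h * c + count_conv_params(2, 1, 7)
        if name == "cspa":
            return (k_auto(c) + count_conv_params(2, 1, 1)
                    + count_conv_params(2, 1, 3) + count_conv_params(2, 1, 7))
        raise ValueError(name)

    def k_auto(c):
        t = abs(math.log2(c) / 2 + 0.5)
        return nearest_odd_oracle(t)

    total = 0
    if cfg.stem.enabled:
        chans = (cfg.input_channels,) + tuple(cfg.stem.channel_widths)
        for i, k in enumerate((7, 5, 3)):
            total += count_conv_params(chans[i], chans[i + 1], k) + bn(chans[i + 1])
    else:
        total += count_conv_params(cfg.input_channels, cfg.stem.out_channels, 7)
        total += bn(cfg.stem.out_channels)
    for b in cfg.blocks:
        total += count_conv_params(b.in_channels, b.mid_channels, 1) + bn(b.mid_channels)
        total += count_conv_params(b.mid_channels, b.mid_channels, 3) + bn(b.mid_channels)
        total += count_conv_params(b.mid_channels, b.out_channels, 1) + bn(b.out_channels)
        total += attention_params(b.attention_name, b.out_channels, k_auto)
        if b.shortcut == "projection":
            total += count_conv_params(b.in_channels, b.out_channels, 1) + bn(b.out_channels)
    total += cfg.blocks[-1].out_channels * cfg.num_classes + cfg.num_classes
    return total
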