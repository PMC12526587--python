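"""Trainable components of the adaptation model.

Three networks play the adversarial game:

* ``FeatureExtractor`` (G) — a dual-branch 1-D spectral encoder: a
  self-attention branch over linearly embedded spectral patches, and a
  multi-scale convolution branch (parallel kernels, several widths), fused by
  one fully connected layer into a fixed-size feature vector.
* ``Classifier`` (C) — a single linear layer + softmax producing class
  probabilities from G's features.
* ``Discriminator`` (D) — an MLP with dropout and sigmoid output that receives
  multilinear feature x prediction vectors and scores the domain of origin.

All parameters are Xavier/Glorot initialized (uniform) with zero biases, and
every forward pass is a pure function of (parameters, input) in evaluation
mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "FeatureExtractor",
    "Classifier",
    "Discriminator",
    "ModelBundle",
    "build_feature_extractor",
    "build_classifier",
    "build_discriminator",
    "build_bundle",
    "xavier_init",
    "grad_reverse",
    "save_bundle",
    "load_bundle",
]


def grad_reverse(x: Tensor, lam: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-lam``.

    This is the gradient-reversal construct realizing the min-max game: the
    discriminator loss backpropagates normally into D but reversed (scaled by
    ``-lam``) into the feature extractor.
    """
    out = x._make(x.data, (x,), None)
    out._backward = lambda g: (-lam * g,)
    return out


class Module:
    """Tiny module base: parameter registration + traversal."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def xavier_init(self, rng: np.random.Generator) -> None:
        """Re-draw weight matrices Glorot-uniform, zero the biases.

        Recurses into submodules so that overrides (e.g. per-bank fans of the
        fused multi-scale convolution) take effect.
        """
        for name, val in vars(self).items():
            if isinstance(val, Tensor):
                self._init_param(name, val, rng)
            elif isinstance(val, Module):
                val.xavier_init(rng)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.xavier_init(rng)

    @staticmethod
    def _init_param(name: str, p: Tensor, rng: np.random.Generator) -> None:
        if name.startswith("b") or name == "beta":
            p.data[...] = 0.0
        elif name == "gamma":
            p.data[...] = 1.0
        elif name == "pos":
            # positional table: small Xavier-style draw over (tokens, dim)
            fan_in, fan_out = p.data.shape[-2], p.data.shape[-1]
            a = np.sqrt(6.0 / (fan_in + fan_out))
            p.data[...] = rng.uniform(-a, a, size=p.data.shape)
        else:
            shape = p.data.shape
            if p.data.ndim == 2:
                fan_in, fan_out = shape
            elif p.data.ndim == 3:  # conv (out, in, k)
                fan_out = shape[0] * shape[2]
                fan_in = shape[1] * shape[2]
            else:
                fan_in = fan_out = p.data.size
            a = np.sqrt(6.0 / (fan_in + fan_out))
            p.data[...] = rng.uniform(-a, a, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int):
        self.W = Tensor(np.zeros((n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 3:  # flatten token batches into one 2-D BLAS call
            B, T, D = x.shape
            return (x.reshape(B * T, D) @ self.W + self.b).reshape(B, T, -1)
        return x @ self.W + self.b


class Conv1d(Module):
    """1-D convolution with 'same' zero padding (odd kernel), stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.W = Tensor(np.zeros((c_out, c_in, kernel)))
        self.b = Tensor(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        # x: (batch, c_in, length); computed as a short loop over kernel
        # offsets — each offset is one small tensordot, avoiding large im2col
        # buffers (kernels here are <= 15 wide)
        W, b, k = self.W, self.b, self.kernel
        B, c_in, L = x.shape
        c_out = W.shape[0]
        pad = (k - 1) // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
        val = np.empty((B, c_out, L))
        val[:] = b.data[None, :, None]
        for j in range(k):
            # val[b,o,l] += sum_c xp[b,c,l+j] * W[o,c,j]
            val += np.tensordot(W.data[:, :, j], xp[:, :, j:j + L], axes=([1], [1])
                                ).transpose(1, 0, 2)
        out = x._make(val, (x, W, b), None)

        def backward(g):
            gb = g.sum(axis=(0, 2))
            gW = np.empty_like(W.data)
            gxp = np.zeros_like(xp)
            for j in range(k):
                xs = xp[:, :, j:j + L]
                gW[:, :, j] = np.tensordot(g, xs, axes=([0, 2], [0, 2]))
                gxp[:, :, j:j + L] += np.tensordot(g, W.data[:, :, j],
                                                   axes=([1], [0])).transpose(0, 2, 1)
            gx = gxp[:, :, pad: pad + L] if pad else gxp
            return (gx, gW, gb)

        out._backward = backward
        return out


class MultiScaleConv1d(Module):
    """Parallel 1-D convolutions at several kernel widths, fused into one op.

    Each kernel bank is stored center-aligned inside a max-width weight array
    under a fixed binary mask, so one im2col matmul computes all scales at
    once while keeping every bank's receptive field at its own width.
    Output channels are ordered bank by bank, matching a concatenation of the
    individual convolutions.
    """

    def __init__(self, c_in: int, channels: int, kernels: tuple):
        if any(k % 2 == 0 for k in kernels):
            raise ValueError("kernel sizes must be odd for 'same' padding")
        self.kernels = tuple(kernels)
        self.channels = channels
        self.c_in = c_in
        kmax = max(kernels)
        self.kmax = kmax
        c_total = channels * len(kernels)
        self.W = Tensor(np.zeros((c_total, c_in, kmax)))
        self.b = Tensor(np.zeros(c_total))
        mask = np.zeros_like(self.W.data)
        for i, k in enumerate(kernels):
            start = (kmax - k) // 2
            mask[i * channels:(i + 1) * channels, :, start:start + k] = 1.0
        self._mask = mask

    def xavier_init(self, rng: np.random.Generator) -> None:
        # per-bank Glorot fans: fan_in = c_in * k, fan_out = channels * k
        self.W.data[...] = 0.0
        self.b.data[...] = 0.0
        kmax = self.kmax
        for i, k in enumerate(self.kernels):
            a = np.sqrt(6.0 / (self.c_in * k + self.channels * k))
            start = (kmax - k) // 2
            bank = rng.uniform(-a, a, size=(self.channels, self.c_in, k))
            self.W.data[i * self.channels:(i + 1) * self.channels, :, start:start + k] = bank

    def __call__(self, x: Tensor) -> Tensor:
        W, b, kmax = self.W, self.b, self.kmax
        B, c_in, L = x.shape
        c_total = W.shape[0]
        pad = (kmax - 1) // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(xp, kmax, axis=2)  # (B, c_in, L, kmax)
        col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, c_in * kmax)
        Wm = (W.data * self._mask).reshape(c_total, c_in * kmax)
        val = (col @ Wm.T).reshape(B, L, c_total).transpose(0, 2, 1) + b.data[None, :, None]
        out = x._make(val, (x, W, b), None)

        def backward(g):
            gflat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * L, c_total)
            gW = (gflat.T @ col).reshape(W.shape) * self._mask
            gb = g.sum(axis=(0, 2))
            gcol = (gflat @ Wm).reshape(B, L, c_in, kmax)
            gxp = np.zeros_like(xp)
            for j in range(kmax):  # col2im: short loop over kernel offsets
                gxp[:, :, j:j + L] += gcol[:, :, :, j].transpose(0, 2, 1)
            gx = gxp[:, :, pad: pad + L] if pad else gxp
            return (gx, gW, gb)

        out._backward = backward
        return out


class LayerNorm(Module):
    """Normalization over the last axis, fused into one tape node."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        mu = x.data.mean(axis=-1, keepdims=True)
        xc = x.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        out = x._make(xhat * gamma.data + beta.data, (x, gamma, beta), None)

        def backward(g):
            axes = tuple(range(g.ndim - 1))
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            dxhat = g * gamma.data
            dx = inv * (
                dxhat
                - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
            )
            return (dx, dgamma, dbeta)

        out._backward = backward
        return out


class SelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.Wqkv = Linear(d_model, 3 * d_model)
        self.Wo = Linear(d_model, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.Wqkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, B, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.Wo(out)


class EncoderLayer(Module):
    """Pre-norm transformer encoder block."""

    def __init__(self, d_model: int, n_heads: int, mlp_ratio: int = 2):
        self.ln1 = LayerNorm(d_model)
        self.attn = SelfAttention(d_model, n_heads)
        self.ln2 = LayerNorm(d_model)
        self.fc1 = Linear(d_model, mlp_ratio * d_model)
        self.fc2 = Linear(mlp_ratio * d_model, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


@dataclass
class ExtractorConfig:
    patch: int = 16
    d_model: int = 64
    depth: int = 2
    n_heads: int = 4
    conv_kernels: tuple = (3, 7, 15)
    conv_channels: int = 16
    feature_dim: int = 64


class FeatureExtractor(Module):
    """Dual-branch spectral encoder G.

    Branch 1 tokenizes the spectrum into non-overlapping patches, embeds them
    linearly, adds a learned positional table and runs a small self-attention
    encoder; the token mean is the branch output.  Branch 2 runs parallel 1-D
    convolutions at several kernel widths, keeps the per-position feature maps
    (used by Grad-CAM) and global-average-pools each channel.  The two branch
    vectors are concatenated and fused by one fully connected layer, a ReLU
    and a LayerNorm into ``feature_dim`` dimensions.
    """

    def __init__(self, input_len: int, config: ExtractorConfig | None = None):
        cfg = config or ExtractorConfig()
        if input_len < min(cfg.conv_kernels):
            raise ValueError(
                f"input_len={input_len} shorter than smallest conv kernel "
                f"{min(cfg.conv_kernels)}"
            )
        if input_len < cfg.patch:
            raise ValueError(f"input_len={input_len} shorter than patch size {cfg.patch}")
        self.input_len = input_len
        self.config = cfg
        self.n_tokens = int(np.ceil(input_len / cfg.patch))
        self.pad_to = self.n_tokens * cfg.patch
        self.embed = Linear(cfg.patch, cfg.d_model)
        self.pos = Tensor(np.zeros((self.n_tokens, cfg.d_model)))
        self.layers = [EncoderLayer(cfg.d_model, cfg.n_heads) for _ in range(cfg.depth)]
        self.conv = MultiScaleConv1d(1, cfg.conv_channels, cfg.conv_kernels)
        fused_in = cfg.d_model + cfg.conv_channels * len(cfg.conv_kernels)
        self.fuse = Linear(fused_in, cfg.feature_dim)
        self.ln_out = LayerNorm(cfg.feature_dim)

    @property
    def feature_dim(self) -> int:
        return self.config.feature_dim

    def __call__(self, x: Tensor, return_conv_maps: bool = False):
        if x.ndim != 2 or x.shape[1] != self.input_len:
            raise ValueError(f"expected (batch, {self.input_len}) input, got {x.shape}")
        B, L = x.shape
        # token branch
        if self.pad_to != L:
            xt = x._make(np.pad(x.data, ((0, 0), (0, self.pad_to - L))), (x,), None)
            xt._backward = lambda g: (g[:, :L],)
        else:
            xt = x
        tokens = xt.reshape(B, self.n_tokens, self.config.patch)
        t = self.embed(tokens) + self.pos
        for layer in self.layers:
            t = layer(t)
        token_feat = t.mean(axis=1)  # (B, d_model)
        # multi-scale conv branch
        xc = x.reshape(B, 1, L)
        maps = self.conv(xc).relu()
        conv_feat = maps.mean(axis=2)  # global average pool -> (B, channels)
        fused = self.ln_out(self.fuse(concatenate([token_feat, conv_feat], axis=1)).relu())
        if return_conv_maps:
            return fused, maps
        return fused


class Classifier(Module):
    """Class head C: one linear layer; ``probs`` applies the softmax."""

    def __init__(self, feature_dim: int, n_classes: int):
        if feature_dim <= 0 or n_classes < 2:
            raise ValueError("feature_dim must be positive and n_classes >= 2")
        self.n_classes = n_classes
        self.fc = Linear(feature_dim, n_classes)

    def __call__(self, f: Tensor) -> Tensor:  # logits
        return self.fc(f)

    def probs(self, f: Tensor) -> Tensor:
        return self.fc(f).softmax(axis=-1)


class Discriminator(Module):
    """Domain head D on multilinear vectors: 2 hidden layers, dropout, sigmoid."""

    def __init__(self, in_dim: int, hidden: int = 128, dropout: float = 0.5):
        if in_dim <= 0:
            raise ValueError("in_dim must be positive")
        self.in_dim = in_dim
        self.p_drop = dropout
        self.fc1 = Linear(in_dim, hidden)
        self.fc2 = Linear(hidden, hidden)
        self.fc3 = Linear(hidden, 1)
        self.training = False
        self.rng: np.random.Generator | None = None

    def _dropout(self, x: Tensor) -> Tensor:
        if not self.training or self.p_drop <= 0:
            return x
        rng = self.rng or np.random.default_rng(0)
        keep = (rng.random(x.shape) >= self.p_drop) / (1.0 - self.p_drop)
        return x * Tensor(keep, requires_grad=False)

    def __call__(self, phi: Tensor) -> Tensor:
        if phi.shape[-1] != self.in_dim:
            raise ValueError(f"expected multilinear vectors of dim {self.in_dim}")
        h = self._dropout(self.fc1(phi).relu())
        h = self._dropout(self.fc2(h).relu())
        return self.fc3(h).sigmoid().reshape(-1)


@dataclass
class ModelBundle:
    """The three-network parameter bundle (G, C, D)."""

    G: FeatureExtractor
    C: Classifier
    D: Discriminator
    feature_dim: int
    n_classes: int
    meta: dict = field(default_factory=dict)

    def parameters(self) -> list[Tensor]:
        return self.G.parameters() + self.C.parameters() + self.D.parameters()

    def named_parameters(self):
        yield from self.G.named_parameters("G.")
        yield from self.C.named_parameters("C.")
        yield from self.D.named_parameters("D.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train_mode(self, rng: np.random.Generator | None = None) -> None:
        self.D.training = True
        if rng is not None:
            self.D.rng = rng

    def eval_mode(self) -> None:
        self.D.training = False


def build_feature_extractor(
    input_len: int, feature_dim: int = 64, config: ExtractorConfig | None = None
) -> FeatureExtractor:
    cfg = config or ExtractorConfig()
    cfg.feature_dim = feature_dim
    return FeatureExtractor(input_len, cfg)


def build_classifier(feature_dim: int, n_classes: int) -> Classifier:
    return Classifier(feature_dim, n_classes)


def build_discriminator(in_dim: int, hidden: int = 128, dropout: float = 0.5) -> Discriminator:
    return Discriminator(in_dim, hidden=hidden, dropout=dropout)


def build_bundle(
    input_len: int,
    n_classes: int = 2,
    feature_dim: int = 64,
    config: ExtractorConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    G = build_feature_extractor(input_len, feature_dim, config)
    C = build_classifier(G.feature_dim, n_classes)
    D = build_discriminator(G.feature_dim * n_classes)
    bundle = ModelBundle(G=G, C=C, D=D, feature_dim=G.feature_dim, n_classes=n_classes)
    return xavier_init(bundle, seed)


def xavier_init(bundle: ModelBundle, seed: int) -> ModelBundle:
    """Re-draw every weight Glorot-uniform under `seed`; biases become zero."""
    rng = np.random.default_rng(seed)
    bundle.G.xavier_init(rng)
    bundle.C.xavier_init(rng)
    bundle.D.xavier_init(rng)
    bundle.meta["init_seed"] = seed
    return bundle


def save_bundle(bundle: ModelBundle, path: str) -> None:
    """Save parameters + a JSON config echo to one NPZ archive."""
    cfg = bundle.G.config
    manifest = {
        "input_len": bundle.G.input_len,
        "n_classes": bundle.n_classes,
        "feature_dim": bundle.feature_dim,
        "extractor": {
            "patch": cfg.patch,
            "d_model": cfg.d_model,
            "depth": cfg.depth,
            "n_heads": cfg.n_heads,
            "conv_kernels": list(cfg.conv_kernels),
            "conv_channels": cfg.conv_channels,
            "feature_dim": cfg.feature_dim,
        },
        "meta": bundle.meta,
    }
    arrays = {name: p.data for name, p in bundle.named_parameters()}
    arrays["__manifest__"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_bundle(path: str) -> ModelBundle:
    with np.load(path) as archive:
        manifest = json.loads(archive["__manifest__"].tobytes().decode())
        ecfg = ExtractorConfig(**{
            k: tuple(v) if k == "conv_kernels" else v
            for k, v in manifest["extractor"].items()
        })
        bundle = build_bundle(
            manifest["input_len"],
            n_classes=manifest["n_classes"],
            feature_dim=manifest["feature_dim"],
            config=ecfg,
        )
        for name, p in bundle.named_parameters():
            p.data[...] = archive[name]
    bundle.meta.update(manifest.get("meta", {}))
    return bundle
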