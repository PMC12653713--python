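"""The color-correction networks: TococoNet and the shallow DCCN baseline.

TococoNet is a fully convolutional image-to-image regressor built from two
encoder–decoder U-Blocks bridged by a constant-resolution M-Block, with
channel-concatenation fusion between blocks and an output head of
BatchNorm → 1×1 conv (64 filters) → 3×3 conv (3 filters).  The default
configuration instantiates exactly 26 convolutional layers, which
:func:`audit_architecture` verifies structurally.

* **U-Block** — a two-level symmetric encoder–decoder: two 3×3 convs per
  level, 2×2 max-pool downsampling, ×2 bilinear upsampling, concatenation
  skips between matching levels, and a parameter-free identity shortcut
  from block input to block output (channels zero-padded or truncated so no
  extra projection conv enters the layer budget).  The deepest features sit
  at 1/4 of the input resolution; two upsampling passes restore it.
* **M-Block** — 8 stacked 3×3 convs at constant resolution; the features
  are concatenated with the block input before the eighth conv, which acts
  as the fusion projection.
* **DCCN** — the 5-conv baseline: no pooling, no batch norm; three scalar
  color-adjustment parameters enter as constant extra input channels.

Images are processed as [0, 1] floats in N×H×W×C layout; quantization to
8 bits happens only at the image boundary in :func:`correct_image`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..image import quantize, validate_rgb
from .layers import BatchNorm2d, BilinearUpsample2x, Conv2d, MaxPool2x2, Module, ReLU

__all__ = [
    "NetworkConfig",
    "DccnConfig",
    "UBlock",
    "MBlock",
    "TococoNet",
    "DCCN",
    "audit_architecture",
    "correct_image",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Structural description of a TococoNet instance.

    The defaults are the published architecture; ``reduced()`` gives the
    small variant used for CPU-scale experiments.
    """

    ublock_mid_filters: int = 32
    ublock_out_channels: int = 64
    mblock_filters: int = 32
    mblock_out_channels: int = 64
    head_filters: int = 64
    total_conv_layers: int = 26

    @classmethod
    def reduced(cls) -> "NetworkConfig":
        return cls(
            ublock_mid_filters=8,
            ublock_out_channels=16,
            mblock_filters=8,
            mblock_out_channels=16,
            head_filters=16,
        )


@dataclass(frozen=True)
class DccnConfig:
    """Structural description of the DCCN baseline."""

    conv_layers: int = 5
    hidden_filters: int = 32
    patch_size: int = 40
    n_adjustment_params: int = 3


def _identity_shortcut(x: np.ndarray, out_channels: int) -> np.ndarray:
    """Parameter-free channel-matching identity: zero-pad or truncate."""
    c = x.shape[-1]
    if c == out_channels:
        return x
    if c < out_channels:
        pad = np.zeros(x.shape[:3] + (out_channels - c,), dtype=x.dtype)
        return np.concatenate([x, pad], axis=-1)
    return x[..., :out_channels]


def _shortcut_grad(grad: np.ndarray, in_channels: int) -> np.ndarray:
    """Gradient of :func:`_identity_shortcut` w.r.t. its input."""
    c = grad.shape[-1]
    if in_channels == c:
        return grad
    if in_channels < c:
        return grad[..., :in_channels]
    pad = np.zeros(grad.shape[:3] + (in_channels - c,), dtype=grad.dtype)
    return np.concatenate([grad, pad], axis=-1)


class UBlock(Module):
    """Two-level encoder–decoder block with skips and an identity shortcut."""

    def __init__(self, in_channels: int, mid_filters: int, out_channels: int,
                 rng: np.random.Generator, name: str = "ublock"):
        m = mid_filters
        self.in_channels, self.out_channels = in_channels, out_channels
        self.e1a = Conv2d(in_channels, m, 3, rng, f"{name}.e1a")
        self.e1b = Conv2d(m, m, 3, rng, f"{name}.e1b")
        self.e2a = Conv2d(m, m, 3, rng, f"{name}.e2a")
        self.e2b = Conv2d(m, m, 3, rng, f"{name}.e2b")
        self.d2a = Conv2d(2 * m, m, 3, rng, f"{name}.d2a")
        self.d2b = Conv2d(m, m, 3, rng, f"{name}.d2b")
        self.d1a = Conv2d(2 * m, m, 3, rng, f"{name}.d1a")
        self.d1b = Conv2d(m, out_channels, 3, rng, f"{name}.d1b")
        self.relus = [ReLU() for _ in range(8)]
        self.pool1, self.pool2 = MaxPool2x2(), MaxPool2x2()
        self.up2, self.up1 = BilinearUpsample2x(), BilinearUpsample2x()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ValueError(
                f"U-Block input spatial dims must be divisible by 4, got {x.shape[1:3]}"
            )
        r = self.relus
        a = r[1](self.e1b(r[0](self.e1a(x, train), train), train), train)   # full res
        b = r[3](self.e2b(r[2](self.e2a(self.pool1(a, train), train), train), train), train)
        deep = self.pool2(b, train)                                          # 1/4 res
        c = np.concatenate([self.up2(deep, train), b], axis=-1)
        d = r[5](self.d2b(r[4](self.d2a(c, train), train), train), train)
        e = np.concatenate([self.up1(d, train), a], axis=-1)
        f = r[7](self.d1b(r[6](self.d1a(e, train), train), train), train)
        return f + _identity_shortcut(x, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        r = self.relus
        m = self.e1a.out_channels
        gf = self.d1a.backward(r[6].backward(self.d1b.backward(r[7].backward(grad))))
        g_up1, ga = gf[..., :m], gf[..., m:]
        gd = self.up1.backward(g_up1)
        gc = self.d2a.backward(r[4].backward(self.d2b.backward(r[5].backward(gd))))
        g_up2, gb = gc[..., :m], gc[..., m:]
        g_deep = self.up2.backward(g_up2)
        gb = gb + self.pool2.backward(g_deep)
        g_p1 = self.e2a.backward(r[2].backward(self.e2b.backward(r[3].backward(gb))))
        ga = ga + self.pool1.backward(g_p1)
        gx = self.e1a.backward(r[0].backward(self.e1b.backward(r[1].backward(ga))))
        return gx + _shortcut_grad(grad, self.in_channels)


class MBlock(Module):
    """Eight constant-resolution 3×3 convs; input re-fused before the last."""

    def __init__(self, in_channels: int, filters: int, out_channels: int,
                 rng: np.random.Generator, name: str = "mblock"):
        f = filters
        self.in_channels, self.out_channels = in_channels, out_channels
        convs = [Conv2d(in_channels, f, 3, rng, f"{name}.c1")]
        convs += [Conv2d(f, f, 3, rng, f"{name}.c{i}") for i in range(2, 8)]
        self.convs = convs
        self.fuse = Conv2d(f + in_channels, out_channels, 3, rng, f"{name}.c8")
        self.relus = [ReLU() for _ in range(8)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = x
        for conv, relu in zip(self.convs, self.relus[:7]):
            h = relu(conv(h, train), train)
        fused = np.concatenate([h, x], axis=-1)
        return self.relus[7](self.fuse(fused, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.fuse.backward(self.relus[7].backward(grad))
        f = self.convs[-1].out_channels
        gh, gx = g[..., :f], g[..., f:]
        for conv, relu in zip(reversed(self.convs), reversed(self.relus[:7])):
            gh = conv.backward(relu.backward(gh))
        return gh + gx


class TococoNet(Module):
    """U-Block → concat → M-Block → concat → U-Block → BN → 1×1 → 3×3 head."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.u1 = UBlock(3, cfg.ublock_mid_filters, cfg.ublock_out_channels, rng, "u1")
        m_in = cfg.ublock_out_channels + 3
        self.m = MBlock(m_in, cfg.mblock_filters, cfg.mblock_out_channels, rng, "m")
        u2_in = cfg.mblock_out_channels + m_in
        self.u2 = UBlock(u2_in, cfg.ublock_mid_filters, cfg.ublock_out_channels, rng, "u2")
        self.bn = BatchNorm2d(cfg.ublock_out_channels, "head.bn")
        self.head1 = Conv2d(cfg.ublock_out_channels, cfg.head_filters, 1, rng, "head.c1x1")
        self.head_relu = ReLU()
        self.head2 = Conv2d(cfg.head_filters, 3, 3, rng, "head.c3x3")
        audit_architecture(self)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        u1 = self.u1(x, train)
        m_in = np.concatenate([u1, x], axis=-1)
        m = self.m(m_in, train)
        u2_in = np.concatenate([m, m_in], axis=-1)
        u2 = self.u2(u2_in, train)
        h = self.head_relu(self.head1(self.bn(u2, train), train), train)
        return self.head2(h, train)  # final conv: no nonlinearity (regression head)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.bn.backward(self.head1.backward(self.head_relu.backward(
            self.head2.backward(grad))))
        g_u2in = self.u2.backward(g)
        cm = self.m.out_channels
        gm, g_min = g_u2in[..., :cm], g_u2in[..., cm:]
        g_min = g_min + self.m.backward(gm)
        cu = self.u1.out_channels
        gu1, gx = g_min[..., :cu], g_min[..., cu:]
        return gx + self.u1.backward(gu1)


class DCCN(Module):
    """Five-conv baseline; no pooling, no batch norm, 3 adjustment scalars.

    The adjustment scalars are broadcast to three constant feature planes
    appended to the RGB input, giving a 6-channel first conv.
    """

    def __init__(self, config: DccnConfig | None = None, seed: int = 0):
        self.config = config or DccnConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        f = cfg.hidden_filters
        chans = [3 + cfg.n_adjustment_params] + [f] * (cfg.conv_layers - 1) + [3]
        self.convs = [
            Conv2d(chans[i], chans[i + 1], 3, rng, f"dccn.c{i + 1}")
            for i in range(cfg.conv_layers)
        ]
        self.relus = [ReLU() for _ in range(cfg.conv_layers - 1)]
        audit_architecture(self)

    def forward(self, x: np.ndarray, train: bool = True,
                adjustments: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
        n, h, w, _ = x.shape
        adj = np.empty((n, h, w, len(adjustments)), dtype=x.dtype)
        for i, a in enumerate(adjustments):
            adj[..., i] = a
        h_ = np.concatenate([x, adj], axis=-1)
        for conv, relu in zip(self.convs[:-1], self.relus):
            h_ = relu(conv(h_, train), train)
        return self.convs[-1](h_, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.convs[-1].backward(grad)
        for conv, relu in zip(reversed(self.convs[:-1]), reversed(self.relus)):
            g = conv.backward(relu.backward(g))
        return g[..., :3]  # drop the constant adjustment planes


def audit_architecture(model: Module) -> dict[str, int]:
    """Count structural node types and check them against the model's config.

    Returns ``{"conv_layers": ..., "pooling": ..., "batch_norm": ...}``;
    raises ``ValueError`` naming the count found when the graph disagrees
    with its configuration.
    """
    mods = model.submodules()
    counts = {
        "conv_layers": sum(isinstance(m, Conv2d) for m in mods),
        "pooling": sum(isinstance(m, MaxPool2x2) for m in mods),
        "batch_norm": sum(isinstance(m, BatchNorm2d) for m in mods),
    }
    if isinstance(model, TococoNet):
        expected = model.config.total_conv_layers
        if counts["conv_layers"] != expected:
            raise ValueError(
                f"architecture audit failed: found {counts['conv_layers']} conv layers, "
                f"config requires {expected}"
            )
    if isinstance(model, DCCN):
        if counts["conv_layers"] != model.config.conv_layers:
            raise ValueError(
                f"architecture audit failed: found {counts['conv_layers']} conv layers, "
                f"config requires {model.config.conv_layers}"
            )
        if counts["pooling"] or counts["batch_norm"]:
            raise ValueError(
                "architecture audit failed: DCCN must contain no pooling or batch-norm nodes"
            )
    return counts


def state_dict(model: Module) -> dict[str, np.ndarray]:
    state = {p.name: p.data.copy() for p in model.parameters()}
    for mod in [model, *model.submodules()]:
        if isinstance(mod, BatchNorm2d):
            state[mod.gamma.name.rsplit(".", 1)[0] + ".running_mean"] = mod.running_mean.copy()
            state[mod.gamma.name.rsplit(".", 1)[0] + ".running_var"] = mod.running_var.copy()
    return state


def load_state_dict(model: Module, state: dict[str, np.ndarray]) -> None:
    for p in model.parameters():
        if p.name not in state:
            raise KeyError(f"checkpoint is missing parameter {p.name}")
        if state[p.name].shape != p.data.shape:
            raise ValueError(
                f"parameter {p.name}: checkpoint shape {state[p.name].shape} "
                f"!= model shape {p.data.shape}"
            )
        p.data = state[p.name].astype(p.data.dtype).copy()
    for mod in [model, *model.submodules()]:
        if isinstance(mod, BatchNorm2d):
            base = mod.gamma.name.rsplit(".", 1)[0]
            mod.running_mean = state[base + ".running_mean"].astype(mod.running_mean.dtype).copy()
            mod.running_var = state[base + ".running_var"].astype(mod.running_var.dtype).copy()


def fingerprint(model: Module) -> dict:
    """Architecture identity: config plus the ordered (name, shape) list."""
    return {
        "model": type(model).__name__,
        "config": asdict(model.config),
        "parameters": [[p.name, list(p.data.shape)] for p in model.parameters()],
    }


def save_checkpoint(model: Module, path: str) -> None:
    """Serialize parameters plus an embedded architecture fingerprint."""
    state = state_dict(model)
    state["__fingerprint__"] = np.frombuffer(
        json.dumps(fingerprint(model)).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_checkpoint(model: Module, path: str) -> Module:
    """Load a checkpoint into ``model``; refuse on fingerprint mismatch."""
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    stored = json.loads(bytes(state.pop("__fingerprint__")).decode())
    if stored != fingerprint(model):
        raise ValueError(
            "checkpoint fingerprint does not match the model architecture; "
            f"checkpoint was written for {stored['model']} {stored['config']}"
        )
    load_state_dict(model, state)
    return model


def correct_image(model: Module, img: np.ndarray) -> np.ndarray:
    """Whole-image inference: normalize, forward in eval mode, re-quantize.

    Spatial dims not divisible by 4 are reflect-padded up to the next
    multiple and the output cropped back.
    """
    img = validate_rgb(img)
    for p in model.parameters():
        if not np.all(np.isfinite(p.data)):
            raise ValueError(f"model parameter {p.name} contains non-finite values")
    h, w = img.shape[:2]
    ph, pw = (-h) % 4, (-w) % 4
    dtype = model.parameters()[0].data.dtype
    x = img.astype(dtype) / 255.0
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    y = model.forward(x[None], train=False)[0][:h, :w]
    return quantize(np.clip(y, 0.0, 1.0) * 255.0)
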