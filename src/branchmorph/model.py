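"""Attention-augmented UNet for background / trunk / branch segmentation.

Architecture
------------
The encoder is a VGG16-style stack: 13 3x3 convolutions in blocks of
[2, 2, 3, 3, 3] with ReLU, and a 2x2/stride-2 max pool after each of
the first four blocks (channel widths c, 2c, 4c, 8c, 8c).  A
squeeze-and-excitation (SE) channel-attention module sits before each
of the four pooling layers, and a residual attention module (RAM) sits
immediately after the first SE site.  The decoder mirrors the encoder
with four 2x2 transpose-convolution upsampling stages; each stage
concatenates the matching encoder skip tensor and refines with two 3x3
convolutions.  SE modules occupy five decoding-path sites: the
bottleneck plus each of the four post-concatenation tensors.  A 1x1
convolution and a softmax produce per-pixel class probabilities, so the
output spatial size equals the input's.

SE module: each channel is squeezed to its spatial mean, the resulting
vector passes through a two-layer bottleneck (ReLU then Sigmoid, width
reduced by ``se_reduction``), and the input channels are rescaled by
the resulting gates.  RAM: the input is convolved and ReLU-activated
into f; channel attention pools f to its per-channel spatial variance,
spatial attention applies a depthwise 3x3 convolution to f; the two
maps are broadcast-summed, sigmoid-gated, multiplied with a second
convolution of f, and added back onto the input (a pure residual path
when all weights are zero).

Training follows a two-phase fine-tuning schedule: the encoder backbone
is frozen for the first ``freeze_epochs`` epochs, then released.  Adam
with an initial learning rate of 1e-4 decayed by a half-cosine over the
epoch count, pixelwise cross-entropy loss, batch size 4, 300 epochs are
the defaults.  Weights use He initialization.  All computation is
NumPy (see :mod:`branchmorph.nn`), so a fixed seed gives a bitwise
reproducible loss history on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "SEBlock",
    "RAMBlock",
    "AttentionUNet",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "ram_forward",
    "build_model",
    "train",
    "predict_mask",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

# ---------------------------------------------------------------------------
# Functional SE operations


def se_squeeze(u: np.ndarray) -> np.ndarray:
    """Squeeze a (C, H, W) feature map to per-channel spatial means."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 3 or u.size == 0:
        raise ValueError("se_squeeze expects a non-empty (C, H, W) feature map")
    if not np.isfinite(u).all():
        raise ValueError("feature map contains non-finite values")
    return u.mean(axis=(1, 2))


def se_excite(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Excitation: s = Sigmoid(w2 @ ReLU(w1 @ z)); every s_m in (0, 1).

    ``w1`` has shape (C/r, C) and ``w2`` shape (C, C/r).
    """
    z = np.asarray(z, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape[1] != z.shape[0] or w2.shape[1] != w1.shape[0] or w2.shape[0] != z.shape[0]:
        raise ValueError(
            f"inconsistent SE shapes: z {z.shape}, w1 {w1.shape}, w2 {w2.shape}"
        )
    hidden = np.maximum(w1 @ z, 0.0)
    return nn.sigmoid(w2 @ hidden)


def se_scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale each channel of ``u`` by its excitation weight."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.ndim != 3 or s.shape != (u.shape[0],):
        raise ValueError(f"excitation length {s.shape} does not match channels {u.shape[0]}")
    return u * s[:, None, None]


# ---------------------------------------------------------------------------
# Attention modules


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention on NCHW tensors."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "se"):
        if channels % reduction != 0:
            raise ValueError(
                f"SE reduction {reduction} does not divide channel count {channels}"
            )
        self.channels = channels
        self.fc1 = nn.Dense(channels, channels // reduction, rng, dtype, f"{name}.fc1")
        self.fc2 = nn.Dense(channels // reduction, channels, rng, dtype, f"{name}.fc2")
        self._cache = None
        self.force_identity = False  # diagnostic switch: gates pinned to 1

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()

    def forward(self, x):
        if self.force_identity:
            self._cache = None
            return x
        n, c, h, w = x.shape
        z = x.mean(axis=(2, 3))
        a = self.fc1(z)
        relu_mask = a > 0
        a = np.where(relu_mask, a, 0)
        s = nn.sigmoid(self.fc2(a))
        self._cache = (x, s, relu_mask, h * w)
        return x * s[:, :, None, None]

    def backward(self, dy):
        if self._cache is None:
            return dy
        x, s, relu_mask, hw = self._cache
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        da = self.fc2.backward(ds * s * (1.0 - s))
        dz = self.fc1.backward(np.where(relu_mask, da, 0))
        dx += (dz / hw)[:, :, None, None]
        return dx


class RAMBlock(nn.Module):
    """Residual attention: parallel channel (variance-pool) and spatial
    (depthwise conv) attention gating a convolved feature map, with a
    residual connection to the input."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "ram"):
        self.conv1 = nn.Conv2d(channels, channels, kernel, rng, dtype, f"{name}.conv1")
        self.conv2 = nn.Conv2d(channels, channels, kernel, rng, dtype, f"{name}.conv2")
        self.dw = nn.DepthwiseConv2d(channels, kernel, rng, dtype, f"{name}.dw")
        self._cache = None

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters() + self.dw.parameters()

    def forward(self, x):
        if not np.isfinite(x).all():
            raise ValueError("RAM input contains non-finite values")
        a = self.conv1(x)
        relu_mask = a > 0
        f = np.where(relu_mask, a, 0)
        ca = f.var(axis=(2, 3), keepdims=True)  # population variance per channel
        sa = self.dw(f)
        g = nn.sigmoid(ca + sa)
        h = self.conv2(f)
        self._cache = (relu_mask, f, g, h)
        return x + g * h

    def backward(self, dy):
        relu_mask, f, g, h = self._cache
        hw = f.shape[2] * f.shape[3]
        dx = dy.copy()
        dh = dy * g
        dpre = dy * h * g * (1.0 - g)
        df = self.conv2.backward(dh)
        df += self.dw.backward(dpre)
        dca = dpre.sum(axis=(2, 3), keepdims=True)
        df += (2.0 / hw) * (f - f.mean(axis=(2, 3), keepdims=True)) * dca
        dx += self.conv1.backward(np.where(relu_mask, df, 0))
        return dx


def ram_forward(x: np.ndarray, block: RAMBlock | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a RAM block to a single (C, H, W) feature map.

    A fresh randomly initialized block is created when none is given.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("ram_forward expects a (C, H, W) feature map")
    if block is None:
        block = RAMBlock(x.shape[0], 3, rng or np.random.default_rng(0))
    return block.forward(x[None])[0]


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class UNetConfig:
    """Hyperparameters of the attention UNet.

    ``base_channels`` is 64 for the full-size network; smaller values
    scale every stage proportionally and are used for CPU-scale runs.
    """

    in_channels: int = 3
    num_classes: int = 3
    base_channels: int = 64
    se_reduction: int = 16
    ram_kernel: int = 3
    encoder_se: bool = True
    decoder_se: bool = True  # bottleneck + the 4 post-concatenation sites
    use_ram: bool = True
    dtype: str = "float32"

    #: convolutions per encoder block (VGG16 layout, 13 in total)
    block_layout: tuple[int, ...] = (2, 2, 3, 3, 3)

    def channel_widths(self) -> tuple[int, ...]:
        b = self.base_channels
        return (b, 2 * b, 4 * b, 8 * b, 8 * b)

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        for c in self.channel_widths():
            if c % self.se_reduction != 0:
                raise ValueError(
                    f"se_reduction {self.se_reduction} does not divide channel width {c}"
                )

    def as_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "num_classes": self.num_classes,
            "base_channels": self.base_channels,
            "se_reduction": self.se_reduction,
            "ram_kernel": self.ram_kernel,
            "encoder_se": self.encoder_se,
            "decoder_se": self.decoder_se,
            "use_ram": self.use_ram,
            "dtype": self.dtype,
            "block_layout": list(self.block_layout),
        }


@dataclass(frozen=True)
class TrainConfig:
    """Two-phase fine-tuning schedule (defaults: Adam, lr 1e-4 with
    half-cosine decay, batch 4, 300 epochs, encoder frozen for 150)."""

    lr0: float = 1e-4
    batch_size: int = 4
    epochs: int = 300
    freeze_epochs: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.freeze_epochs > self.epochs:
            raise ValueError("freeze_epochs must not exceed epochs")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")

    def lr_at(self, epoch: int) -> float:
        """Half-cosine decay: lr0 * 0.5 * (1 + cos(pi * t / epochs))."""
        return self.lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / self.epochs))


# ---------------------------------------------------------------------------
# Network


class AttentionUNet:
    """The assembled network; build via :func:`build_model`."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        widths = cfg.channel_widths()

        self.enc_blocks: list[list[tuple[nn.Conv2d, nn.ReLU]]] = []
        c_prev = cfg.in_channels
        for bi, n_convs in enumerate(cfg.block_layout):
            block = []
            for ci in range(n_convs):
                conv = nn.Conv2d(c_prev, widths[bi], 3, rng, dtype,
                                 f"enc{bi + 1}.conv{ci + 1}")
                block.append((conv, nn.ReLU()))
                c_prev = widths[bi]
            self.enc_blocks.append(block)

        self.enc_se = [
            SEBlock(widths[i], cfg.se_reduction, rng, dtype, f"enc{i + 1}.se")
            if cfg.encoder_se else None
            for i in range(4)
        ]
        self.ram = (RAMBlock(widths[0], cfg.ram_kernel, rng, dtype, "enc1.ram")
                    if cfg.use_ram else None)
        self.pools = [nn.MaxPool2d() for _ in range(4)]

        self.bottleneck_se = (SEBlock(widths[4], cfg.se_reduction, rng, dtype, "bott.se")
                              if cfg.decoder_se else None)

        self.ups: list[nn.ConvTranspose2d] = []
        self.dec_se: list[SEBlock | None] = []
        self.dec_blocks: list[list[tuple[nn.Conv2d, nn.ReLU]]] = []
        c_prev = widths[4]
        for j, skip_idx in enumerate((3, 2, 1, 0)):
            c_skip = widths[skip_idx]
            self.ups.append(nn.ConvTranspose2d(c_prev, c_skip, rng, dtype, f"dec{j + 1}.up"))
            cat = 2 * c_skip
            self.dec_se.append(
                SEBlock(cat, cfg.se_reduction, rng, dtype, f"dec{j + 1}.se")
                if cfg.decoder_se else None
            )
            self.dec_blocks.append([
                (nn.Conv2d(cat, c_skip, 3, rng, dtype, f"dec{j + 1}.conv1"), nn.ReLU()),
                (nn.Conv2d(c_skip, c_skip, 3, rng, dtype, f"dec{j + 1}.conv2"), nn.ReLU()),
            ])
            c_prev = c_skip
        self.head = nn.Conv2d(widths[0], cfg.num_classes, 1, rng, dtype, "head")
        self._cat_split: list[int] = []

    # -- parameter bookkeeping ------------------------------------------------

    def encoder_parameters(self) -> list[nn.Parameter]:
        """Backbone parameters frozen during the first training phase."""
        params = []
        for block in self.enc_blocks:
            for conv, _ in block:
                params.extend(conv.parameters())
        return params

    def parameters(self) -> list[nn.Parameter]:
        params = self.encoder_parameters()
        for se in self.enc_se:
            if se is not None:
                params.extend(se.parameters())
        if self.ram is not None:
            params.extend(self.ram.parameters())
        if self.bottleneck_se is not None:
            params.extend(self.bottleneck_se.parameters())
        for up, se, block in zip(self.ups, self.dec_se, self.dec_blocks):
            params.extend(up.parameters())
            if se is not None:
                params.extend(se.parameters())
            for conv, _ in block:
                params.extend(conv.parameters())
        params.extend(self.head.parameters())
        return params

    # -- forward / backward ---------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Logits for a NCHW batch whose spatial dims are multiples of 16."""
        h = x
        skips = []
        for i in range(5):
            for conv, act in self.enc_blocks[i]:
                h = act(conv(h))
            if i < 4:
                if self.enc_se[i] is not None:
                    h = self.enc_se[i](h)
                if i == 0 and self.ram is not None:
                    h = self.ram(h)
                skips.append(h)
                h = self.pools[i](h)
        if self.bottleneck_se is not None:
            h = self.bottleneck_se(h)
        self._cat_split = []
        for j, skip_idx in enumerate((3, 2, 1, 0)):
            u = self.ups[j](h)
            skip = skips[skip_idx]
            self._cat_split.append(skip.shape[1])
            h = np.concatenate([skip, u], axis=1)
            if self.dec_se[j] is not None:
                h = self.dec_se[j](h)
            for conv, act in self.dec_blocks[j]:
                h = act(conv(h))
        return self.head(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        for j in reversed(range(4)):
            skip_idx = (3, 2, 1, 0)[j]
            for conv, act in reversed(self.dec_blocks[j]):
                d = conv.backward(act.backward(d))
            if self.dec_se[j] is not None:
                d = self.dec_se[j].backward(d)
            c_skip = self._cat_split[j]
            dskips[skip_idx] = d[:, :c_skip]
            d = self.ups[j].backward(d[:, c_skip:])
        if self.bottleneck_se is not None:
            d = self.bottleneck_se.backward(d)
        for i in reversed(range(5)):
            if i < 4:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
                if i == 0 and self.ram is not None:
                    d = self.ram.backward(d)
                if self.enc_se[i] is not None:
                    d = self.enc_se[i].backward(d)
            for conv, act in reversed(self.enc_blocks[i]):
                d = conv.backward(act.backward(d))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities for an NCHW batch (pads and
        crops internally, so any spatial size is accepted)."""
        xp, (h, w) = _pad_to_multiple(x, 16)
        probs = nn.softmax(self.forward_logits(xp), axis=1)
        return probs[:, :, :h, :w]


def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad NCHW spatial dims up to the next multiple of ``m``."""
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    return x, (h, w)


def build_model(cfg: UNetConfig | None = None, seed: int = 0) -> AttentionUNet:
    """Construct an attention UNet with He-initialized weights."""
    return AttentionUNet(cfg or UNetConfig(), np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Training and inference


def _to_batch(images: np.ndarray, dtype) -> np.ndarray:
    """HWC uint8 (or NHWC stack) -> normalized NCHW float batch."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] not in (1, 3):
        raise ValueError(f"expected (N, H, W, C) images, got shape {arr.shape}")
    return (arr.astype(dtype) / 255.0).transpose(0, 3, 1, 2)


def train(net: AttentionUNet, dataset, tc: TrainConfig | None = None,
          progress: bool = False) -> list[float]:
    """Train a network on (image, mask) pairs; returns per-epoch losses.

    ``dataset`` is a sequence of (HWC uint8 image, HW integer mask)
    pairs.  The encoder backbone is frozen for the first
    ``tc.freeze_epochs`` epochs.  Deterministic for a fixed
    ``tc.seed``.
    """
    tc = tc or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    dtype = np.dtype(net.cfg.dtype).type
    images = np.stack([img for img, _ in dataset])
    masks = np.stack([np.asarray(m) for _, m in dataset]).astype(np.int64)
    if masks.max() >= net.cfg.num_classes or masks.min() < 0:
        raise ValueError(
            f"mask labels exceed the configured {net.cfg.num_classes} classes"
        )
    x_all = _to_batch(images, dtype)
    x_all, _ = _pad_to_multiple(x_all, 16)
    masks_p = np.pad(
        masks,
        ((0, 0), (0, x_all.shape[2] - masks.shape[1]), (0, x_all.shape[3] - masks.shape[2])),
        mode="reflect",
    )

    rng = np.random.default_rng(tc.seed)
    params = net.parameters()
    opt = nn.Adam(params, lr=tc.lr0)
    frozen = {id(p) for p in net.encoder_parameters()}
    n = x_all.shape[0]
    history: list[float] = []
    for epoch in range(tc.epochs):
        opt.lr = tc.lr_at(epoch)
        active_frozen = frozen if epoch < tc.freeze_epochs else set()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            opt.zero_grad()
            logits = net.forward_logits(x_all[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, masks_p[idx])
            net.backward(dlogits.astype(dtype))
            opt.step(frozen=active_frozen)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if progress:  # pragma: no cover - cosmetic
            print(f"epoch {epoch + 1}/{tc.epochs}  loss {history[-1]:.4f}")
    return history


def predict_proba(net: AttentionUNet, images: np.ndarray) -> np.ndarray:
    """Class probabilities, (N, K, H, W), for HWC or NHWC uint8 input."""
    arr = np.asarray(images)
    if arr.ndim not in (3, 4):
        raise ValueError(f"expected an image or batch of images, got shape {arr.shape}")
    if arr.shape[-1] != net.cfg.in_channels:
        raise ValueError(
            f"input has {arr.shape[-1]} channels, model expects {net.cfg.in_channels}"
        )
    x = _to_batch(arr, np.dtype(net.cfg.dtype).type)
    return net.forward(x)


def predict_mask(net: AttentionUNet, images: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class mask(s) for one image or a batch.

    Returns (H, W) for a single HWC image, (N, H, W) for a batch;
    input order is preserved.
    """
    single = np.asarray(images).ndim == 3
    masks = predict_proba(net, images).argmax(axis=1).astype(np.uint8)
    return masks[0] if single else masks


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(net: AttentionUNet, path: str | Path) -> None:
    """Serialize weights (.npz) with a JSON config sidecar."""
    path = Path(path)
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(net.parameters())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(net.cfg.as_dict(), indent=2) + "\n")


def load_checkpoint(path: str | Path) -> AttentionUNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg_dict = json.loads(sidecar.read_text())
    cfg_dict["block_layout"] = tuple(cfg_dict["block_layout"])
    net = build_model(UNetConfig(**cfg_dict))
    with np.load(path) as data:
        for i, p in enumerate(net.parameters()):
            stored = data[f"p{i:04d}"]
            if stored.shape != p.value.shape:
                raise ValueError("checkpoint does not match the configured architecture")
            p.value[...] = stored
    return net
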