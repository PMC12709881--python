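"""CSFTU-Net: an attention-augmented U-Net for endosperm segmentation.

The architecture is a 5-level U-Net encoder–decoder segmenting each CT
slice into background / starchy / vitreous endosperm, with two kinds of
attention grafted on:

* a **CBAM** (convolutional block attention module) at the end of every
  encoder level, immediately before max pooling — sequential channel
  attention (shared two-layer MLP over global average- and max-pooled
  channel descriptors, sigmoid-combined) followed by spatial attention
  (7×7 convolution over the channel-wise mean and max maps);
* an **SE** (squeeze-and-excitation) block after the convolution pair of
  every decoder level — global-average-pool squeeze, two-layer gating
  excitation, per-channel rescale.

A 1×1 convolution head maps the final feature map to the three class
logits.  Both attention families can be switched off independently,
which reduces the network to the plain U-Net baseline.

Channel widths double per level from ``base_filters`` (64, 128, 256,
512, 1024 at 5 levels), with an optional cap at 512.  Upsampling is a
2×2 transposed convolution by default; nearest-neighbour interpolation
is available by flag.  All convolutions are 'same'-padded so skip
connections concatenate without cropping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .io_formats import CTVolume, LabelVolume
from .nn import (
    Tensor, concat, max_pool2d, no_grad,
    upsample2x_conv, upsample2x_nearest,
    Conv2d, ConvBNReLU, Linear, Module,
)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the segmentation network."""

    levels: int = 5
    base_filters: int = 64
    cap_filters: int | None = None        # e.g. 512 to cap the doubling rule
    cbam_reduction_r: int = 16
    se_reduction_r: int = 16
    spatial_kernel: int = 7
    num_classes: int = 3
    in_channels: int = 1
    use_cbam: bool = True
    use_se: bool = True
    cbam_at_bottleneck: bool = False
    upsample: str = "transposed"          # or "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        if self.upsample not in ("transposed", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        for name, r in (("cbam_reduction_r", self.cbam_reduction_r),
                        ("se_reduction_r", self.se_reduction_r)):
            for ch in self.filters_per_level:
                if ch % r != 0:
                    raise ValueError(
                        f"{name}={r} does not divide channel count {ch}; "
                        "adjust base_filters or the reduction ratio"
                    )

    @property
    def filters_per_level(self) -> list[int]:
        """Channel widths per level: doubling from base, optionally capped."""
        widths = [self.base_filters * 2 ** i for i in range(self.levels)]
        if self.cap_filters is not None:
            widths = [min(w, self.cap_filters) for w in widths]
        return widths

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.levels - 1)


# ---------------------------------------------------------------------------
# attention blocks
# ---------------------------------------------------------------------------

class ChannelAttention(Module):
    """CBAM channel attention: σ(MLP(avgpool F) + MLP(maxpool F)).

    Global average and max pooling over H×W each yield a length-C
    descriptor; both pass through one *shared* two-layer MLP
    (C → C/r, ReLU, C/r → C), are summed, and squashed by a sigmoid to
    one weight per channel in (0, 1).
    """

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        super().__init__()
        if channels % r != 0:
            raise ValueError(f"reduction r={r} does not divide C={channels}")
        self.fc1 = Linear(channels, channels // r, rng)
        self.fc2 = Linear(channels // r, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))                 # (N, C)
        mx = x.max(axis=3).max(axis=2)            # (N, C)
        mlp = lambda v: self.fc2(self.fc1(v).relu())
        return (mlp(avg) + mlp(mx)).sigmoid()     # (N, C)


class SpatialAttention(Module):
    """CBAM spatial attention: σ(f_{k×k}([mean_c F ; max_c F]))."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)       # (N,1,H,W)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()


class CBAM(Module):
    """Channel-then-spatial attention: F' = (F ⊗ M_c) ⊗ M_s."""

    def __init__(self, channels: int, r: int, spatial_kernel: int, rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, r, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        mc = self.channel(x)
        n, c = mc.shape
        xw = x * mc.reshape(n, c, 1, 1)
        ms = self.spatial(xw)
        return xw * ms


class SEBlock(Module):
    """Squeeze-and-excitation: z = spatial mean, s = σ(W₂ δ(W₁ z)), U_c ← s_c·U_c."""

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        super().__init__()
        if channels % r != 0:
            raise ValueError(f"reduction r={r} does not divide C={channels}")
        self.fc1 = Linear(channels, channels // r, rng)
        self.fc2 = Linear(channels // r, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                   # squeeze (N, C)
        s = self.fc2(self.fc1(z).relu()).sigmoid()
        n, c = s.shape
        return x * s.reshape(n, c, 1, 1)


# functional forms used by the oracle tests --------------------------------

def channel_attention(x: Tensor | np.ndarray, block: ChannelAttention) -> np.ndarray:
    """Per-channel CBAM weights of a feature map, as an (N, C) array."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    with no_grad():
        return block(t).numpy()


def spatial_attention(x: Tensor | np.ndarray, block: SpatialAttention) -> np.ndarray:
    """Per-position CBAM weights of a feature map, as an (N,1,H,W) array."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    with no_grad():
        return block(t).numpy()


def cbam_apply(x: Tensor | np.ndarray, block: CBAM) -> np.ndarray:
    """Feature map rescaled by channel then spatial attention."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    with no_grad():
        return block(t).numpy()


def se_apply(x: Tensor | np.ndarray, block: SEBlock) -> np.ndarray:
    """Feature map rescaled by squeeze-and-excitation gating."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    with no_grad():
        return block(t).numpy()


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class _Upsample(Module):
    """2× spatial upsampling, transposed-conv (learned) or nearest."""

    def __init__(self, in_ch: int, out_ch: int, mode: str, rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        self.out_ch = out_ch
        if mode == "transposed":
            self.weight = Tensor(
                np.sqrt(2.0 / in_ch) * rng.normal(0, 1, size=(in_ch, out_ch * 4)).astype(np.float32),
                requires_grad=True,
            )
            self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        else:
            self.proj = Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "transposed":
            return upsample2x_conv(x, self.weight, self.bias)
        return self.proj(upsample2x_nearest(x))


class CSFTUNet(Module):
    """The attention U-Net; see the module docstring for the layout."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.filters_per_level
        n_enc = config.levels - 1

        in_ch = config.in_channels
        for i in range(n_enc):
            setattr(self, f"enc{i}_a", ConvBNReLU(in_ch, f[i], rng))
            setattr(self, f"enc{i}_b", ConvBNReLU(f[i], f[i], rng))
            att = (CBAM(f[i], config.cbam_reduction_r, config.spatial_kernel, rng)
                   if config.use_cbam else _Identity())
            setattr(self, f"enc{i}_att", att)
            in_ch = f[i]

        self.bottleneck_a = ConvBNReLU(f[n_enc - 1], f[n_enc], rng)
        self.bottleneck_b = ConvBNReLU(f[n_enc], f[n_enc], rng)
        self.bottleneck_att = (
            CBAM(f[n_enc], config.cbam_reduction_r, config.spatial_kernel, rng)
            if (config.use_cbam and config.cbam_at_bottleneck) else _Identity()
        )

        for i in reversed(range(n_enc)):
            up_in = f[i + 1]
            setattr(self, f"up{i}", _Upsample(up_in, f[i], config.upsample, rng))
            setattr(self, f"dec{i}_a", ConvBNReLU(f[i] * 2, f[i], rng))
            setattr(self, f"dec{i}_b", ConvBNReLU(f[i], f[i], rng))
            att = (SEBlock(f[i], config.se_reduction_r, rng)
                   if config.use_se else _Identity())
            setattr(self, f"dec{i}_att", att)

        self.head = Conv2d(f[0], config.num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        h, w = x.shape[2], x.shape[3]
        d = cfg.downsample_factor
        if h % d or w % d:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by {d} "
                f"({cfg.levels} levels = {cfg.levels - 1} downsamplings)"
            )
        skips = []
        n_enc = cfg.levels - 1
        for i in range(n_enc):
            x = getattr(self, f"enc{i}_b")(getattr(self, f"enc{i}_a")(x))
            x = getattr(self, f"enc{i}_att")(x)
            skips.append(x)
            x = max_pool2d(x)
        x = self.bottleneck_att(self.bottleneck_b(self.bottleneck_a(x)))
        for i in reversed(range(n_enc)):
            x = getattr(self, f"up{i}")(x)
            x = concat([skips[i], x], axis=1)
            x = getattr(self, f"dec{i}_b")(getattr(self, f"dec{i}_a")(x))
            x = getattr(self, f"dec{i}_att")(x)
        return self.head(x)

    def parameter_checksum(self) -> str:
        """SHA-256 over all parameter and buffer bytes, in registry order."""
        h = hashlib.sha256()
        for name, p in self.named_parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def build_model(config: NetworkConfig | None = None, **overrides) -> CSFTUNet:
    """Construct a CSFTU-Net; parameter init is deterministic in config.seed."""
    if config is None:
        config = NetworkConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    return CSFTUNet(config)


def predict_slices(model: CSFTUNet, images: np.ndarray, batch: int = 4) -> np.ndarray:
    """Argmax class maps for a stack of slices.

    ``images``: (n, H, W) float array in [0, 1].  Returns (n, H, W)
    uint8 class codes in {0, 1, 2}.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    model.eval()
    out = np.empty(images.shape, dtype=np.uint8)
    with no_grad():
        for i in range(0, images.shape[0], batch):
            chunk = images[i:i + batch]
            logits = model(Tensor(chunk[:, None])).numpy()
            out[i:i + chunk.shape[0]] = np.argmax(logits, axis=1).astype(np.uint8)
    return out


def predict_volume(model: CSFTUNet, volume: CTVolume) -> LabelVolume:
    """Segment a standardized CT volume slice by slice.

    Slices must already be sized for the model (H, W divisible by the
    downsample factor).  Intensities on the 8-bit scale are rescaled to
    [0, 1]; slice order is preserved and inference is deterministic.
    """
    images = volume.data.astype(np.float32)
    if images.max() > 1.0:
        images = images / 255.0
    labels = predict_slices(model, images)
    return LabelVolume(data=labels, voxel_edge_um=volume.voxel_edge_um)
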