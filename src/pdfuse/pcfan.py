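"""Pyramid Channel-based Feature Attention Network (PCFAN).

A three-scale encoder (32/64/128 channels at full/half/quarter resolution,
each stage a 3×3 convolution plus two residual blocks), a pyramid fusion
stage (PCFA) that combines all three scales through exactly four
channel-attention blocks, two ×2 upsamplings and two concatenations, and a
single-convolution reconstruction head mapping the fused features back to a
[0,1] image.

Channel attention is squeeze-excitation style: the per-channel global-average
descriptor mu is reduced C -> C/r, passed through ReLU, expanded back to C and
squashed by a sigmoid; the resulting gate in (0,1)^C multiplies the feature
map elementwise, so |output| <= |input| everywhere.

Without clean/corrupted image pairs the network is pretrained by
self-supervised reconstruction (target = input) under the MSE loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import nn

__all__ = [
    "PCFANConfig",
    "FeaturePyramid",
    "ChannelAttention",
    "ResBlock",
    "PCFAN",
    "mse_loss",
    "pretrain_pcfan",
]


@dataclass
class PCFANConfig:
    stage_channels: tuple[int, int, int] = (32, 64, 128)
    resblocks_per_stage: int = 2
    attention_reduction: int = 8
    upsample_mode: str = "bilinear"
    output_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        c1, c2, c3 = self.stage_channels
        if not c1 < c2 < c3:
            raise ValueError("stage_channels must be strictly increasing")
        mid = c2 + c3
        for c in (c1, c2, c3, mid):
            if c % self.attention_reduction != 0:
                raise ValueError(
                    f"attention_reduction {self.attention_reduction} must divide "
                    f"every attended channel count (violated by {c})")


@dataclass
class FeaturePyramid:
    f1: np.ndarray  # (B, c1, H, W)
    f2: np.ndarray  # (B, c2, H/2, W/2)
    f3: np.ndarray  # (B, c3, H/4, W/4)


class ChannelAttention(nn.Module):
    """Squeeze (GAP) -> reduce -> ReLU -> expand -> sigmoid -> scale."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction != 0:
            raise ValueError(
                f"channel count {channels} not divisible by reduction {reduction}")
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)
        self._cache = None

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        mu = x.mean(axis=(2, 3))                       # (B, C)
        z = self.fc1.forward(mu)
        a = np.maximum(z, 0.0)
        logits = self.fc2.forward(a)
        gate = expit(logits)                           # (B, C) in (0, 1)
        out = x * gate[:, :, None, None]
        self._cache = (x, z, gate, (H, W))
        return out

    def backward(self, dout):
        x, z, gate, (H, W) = self._cache
        dgate = (dout * x).sum(axis=(2, 3))
        dlogits = dgate * gate * (1.0 - gate)
        da = self.fc2.backward(dlogits)
        dz = da * (z > 0)
        dmu = self.fc1.backward(dz)
        dx = dout * gate[:, :, None, None] + dmu[:, :, None, None] / (H * W)
        return dx


class ResBlock(nn.Module):
    """conv3x3 -> ReLU -> conv3x3 with identity skip."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv2d(channels, channels, 3, rng=rng)

    def forward(self, x, train: bool = False):
        h = self.conv2.forward(self.relu.forward(self.conv1.forward(x)))
        return x + h

    def backward(self, dout):
        dh = self.conv1.backward(self.relu.backward(self.conv2.backward(dout)))
        return dout + dh


class _Stage(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, n_blocks: int,
                 rng: np.random.Generator):
        self.conv = nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.relu = nn.ReLU()
        self.blocks = [ResBlock(out_ch, rng) for _ in range(n_blocks)]

    def forward(self, x, train: bool = False):
        x = self.relu.forward(self.conv.forward(x))
        for b in self.blocks:
            x = b.forward(x)
        return x

    def backward(self, dout):
        for b in reversed(self.blocks):
            dout = b.backward(dout)
        return self.conv.backward(self.relu.backward(dout))


class PCFAN(nn.Module):
    """Encoder + PCFA fusion + one-layer reconstruction."""

    def __init__(self, config: PCFANConfig | None = None):
        self.config = config or PCFANConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.stage_channels
        nb = cfg.resblocks_per_stage
        self.stage1 = _Stage(1, c1, 1, nb, rng)
        self.stage2 = _Stage(c1, c2, 2, nb, rng)
        self.stage3 = _Stage(c2, c3, 2, nb, rng)
        # PCFA: exactly four channel-attention blocks, two upsamples, two concats.
        r = cfg.attention_reduction
        self.ca1 = ChannelAttention(c1, r, rng)
        self.ca2 = ChannelAttention(c2, r, rng)
        self.ca3 = ChannelAttention(c3, r, rng)
        self.ca_mid = ChannelAttention(c2 + c3, r, rng)
        self.up1 = nn.Upsample2x(cfg.upsample_mode)
        self.up2 = nn.Upsample2x(cfg.upsample_mode)
        self.fuse_conv = nn.Conv2d(c1 + c2 + c3, c1, 1, rng=rng)
        self.recon_conv = nn.Conv2d(c1, cfg.output_channels, 3, rng=rng)
        self.recon_sigmoid = nn.Sigmoid()
        self._pad = None

    @property
    def attention_blocks(self) -> list[ChannelAttention]:
        return [self.ca1, self.ca2, self.ca3, self.ca_mid]

    @property
    def upsample_blocks(self) -> list[nn.Upsample2x]:
        return [self.up1, self.up2]

    n_concats = 2

    # -- encoder ------------------------------------------------------------
    def _pad_to_multiple(self, x: np.ndarray) -> np.ndarray:
        H, W = x.shape[2:]
        ph, pw = (-H) % 4, (-W) % 4
        self._pad = (ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x

    def encode(self, image: np.ndarray, train: bool = False) -> FeaturePyramid:
        """image: (B, 1, H, W) with H, W >= 8; returns the three-scale pyramid."""
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        if x.shape[2] < 8 or x.shape[3] < 8:
            raise ValueError(f"input spatial dims must be >= 8, got {x.shape[2:]}")
        x = self._pad_to_multiple(x)
        f1 = self.stage1.forward(x, train=train)
        f2 = self.stage2.forward(f1, train=train)
        f3 = self.stage3.forward(f2, train=train)
        return FeaturePyramid(f1=f1, f2=f2, f3=f3)

    # -- PCFA ---------------------------------------------------------------
    def pcfa_fuse(self, pyr: FeaturePyramid, train: bool = False) -> np.ndarray:
        c1, c2, c3 = self.config.stage_channels
        if pyr.f1.shape[1] != c1 or pyr.f2.shape[1] != c2 or pyr.f3.shape[1] != c3:
            raise ValueError("pyramid channel counts do not match the config")
        if (pyr.f1.shape[2] != 2 * pyr.f2.shape[2]
                or pyr.f2.shape[2] != 2 * pyr.f3.shape[2]):
            raise ValueError("pyramid spatial dims must halve between stages")
        a3 = self.ca3.forward(pyr.f3, train=train)
        u3 = self.up1.forward(a3)
        a2 = self.ca2.forward(pyr.f2, train=train)
        cat23 = np.concatenate([u3, a2], axis=1)
        mid = self.ca_mid.forward(cat23, train=train)
        umid = self.up2.forward(mid)
        a1 = self.ca1.forward(pyr.f1, train=train)
        cat = np.concatenate([umid, a1], axis=1)
        return self.fuse_conv.forward(cat)

    def _pcfa_backward(self, dout):
        c1, c2, c3 = self.config.stage_channels
        dcat = self.fuse_conv.backward(dout)
        dumid, da1 = dcat[:, : c2 + c3], dcat[:, c2 + c3:]
        df1 = self.ca1.backward(da1)
        dmid = self.up2.backward(dumid)
        dcat23 = self.ca_mid.backward(dmid)
        du3, da2 = dcat23[:, :c3], dcat23[:, c3:]
        df2 = self.ca2.backward(da2)
        df3 = self.ca3.backward(self.up1.backward(du3))
        return df1, df2, df3

    # -- reconstruction -----------------------------------------------------
    def reconstruct(self, fused: np.ndarray) -> np.ndarray:
        out = self.recon_sigmoid.forward(self.recon_conv.forward(fused))
        ph, pw = self._pad if self._pad else (0, 0)
        if ph or pw:
            out = out[:, :, : out.shape[2] - ph, : out.shape[3] - pw]
            self._crop = (ph, pw)
        else:
            self._crop = (0, 0)
        return out

    def forward(self, image, train: bool = False):
        pyr = self.encode(image, train=train)
        fused = self.pcfa_fuse(pyr, train=train)
        return self.reconstruct(fused)

    def backward(self, dout):
        ph, pw = self._crop
        if ph or pw:
            dout = np.pad(dout, ((0, 0), (0, 0), (0, ph), (0, pw)))
        dfused = self.recon_conv.backward(self.recon_sigmoid.backward(dout))
        df1, df2, df3 = self._pcfa_backward(dfused)
        df2 = df2 + self.stage3.backward(df3)
        df1 = df1 + self.stage2.backward(df2)
        return self.stage1.backward(df1)


def mse_loss(clear: np.ndarray, extracted: np.ndarray) -> float:
    """Mean over channels × width × height of squared differences."""
    clear = np.asarray(clear, dtype=np.float64)
    extracted = np.asarray(extracted, dtype=np.float64)
    if clear.shape != extracted.shape:
        raise ValueError(f"shape mismatch: {clear.shape} vs {extracted.shape}")
    return float(np.mean((clear - extracted) ** 2))


def pretrain_pcfan(
    images: np.ndarray,
    config: PCFANConfig | None = None,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 8,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[PCFAN, pd.DataFrame]:
    """Self-supervised reconstruction pretraining (target = input image).

    images: (N, H, W) or (N, 1, H, W) array, N >= 1.  Inputs are optionally
    noise-corrupted while the target stays clean.  Returns the trained model
    and a per-epoch loss history frame.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.size == 0:
        raise ValueError("empty pretraining dataset")
    if images.ndim == 3:
        images = images[:, None]
    config = config or PCFANConfig()
    model = PCFAN(config)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    n = images.shape[0]
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = images[order[start:start + batch_size]]
            inp = batch
            if noise_sigma > 0:
                inp = np.clip(batch + rng.normal(0, noise_sigma, batch.shape), 0, 1)
            out = model.forward(inp, train=True)
            loss, dout = nn.mse_loss_grad(out, batch)
            model.zero_grad()
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses))})
    return model, pd.DataFrame(history)
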