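"""Scale-configurable encoder–ViT–decoder segmentation network.

The architecture mirrors the hybrid design used for multi-metastasis
segmentation: a convolutional encoder downsamples the T1c volume to an 8x8x8
bottleneck grid, a vision transformer applies self-attention over the
L = 512 bottleneck tokens, and a convolutional decoder with skip connections
upsamples back to a two-class (lesion / background) per-voxel softmax.

Training proceeds in two stages with complementary freezing:

* ``pretrain``  — encoder + ViT trainable, decoder frozen (contrastive
  latent pretraining);
* ``finetune``  — decoder trainable, encoder + ViT frozen (supervised
  segmentation fine-tuning);
* ``inference`` — everything frozen.

``extract_latent`` exposes the ViT output tokens ``z`` with shape (d, L) in
C-order raster over the bottleneck grid — the same order used when the lesion
mask is subsampled onto that grid, so token ``l`` and mask entry ``l`` refer
to the same spatial cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .layers import (Module, ConvBlock, Conv3d, Linear, TransformerBlock,
                     concat_channels)

BOTTLENECK = (8, 8, 8)
N_TOKENS = 512

STAGES = ("pretrain", "finetune", "inference")


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``input_shape`` divided by ``2**n_down`` must equal the 8x8x8 bottleneck
    grid, so the token count is always L = 512.
    """

    input_shape: tuple[int, int, int] = (64, 64, 64)
    n_down: int = 3
    base_channels: int = 8
    vit_layers: int = 6
    vit_dim: int = 32
    vit_heads: int = 4
    out_classes: int = 2

    def __post_init__(self):
        self.input_shape = tuple(int(s) for s in self.input_shape)
        for s in self.input_shape:
            if s % (2 ** self.n_down) or s // (2 ** self.n_down) != 8:
                raise ValueError(
                    f"input shape {self.input_shape} with {self.n_down} "
                    f"downsamplings does not reach the 8x8x8 bottleneck")
        if self.vit_dim % self.vit_heads:
            raise ValueError("vit_dim must be divisible by vit_heads")


class Network(Module):
    """Encoder–ViT–decoder with stage-wise parameter freezing."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        widths = [min(c * 2 ** i, 8 * c) for i in range(config.n_down + 1)]

        # encoder: full-resolution stem, then strided double blocks
        self.enc_stem = [ConvBlock(rng, 1, widths[0]),
                         ConvBlock(rng, widths[0], widths[0])]
        self.enc_stages = []
        for i in range(config.n_down):
            self.enc_stages.append([
                ConvBlock(rng, widths[i], widths[i + 1], stride=2),
                ConvBlock(rng, widths[i + 1], widths[i + 1]),
            ])
        cb = widths[-1]                       # bottleneck channels

        # ViT over the 8^3 token grid
        self.vit_in = Linear(rng, cb, config.vit_dim)
        self.pos_embed = Tensor(
            rng.normal(0.0, 0.02,
                       size=(1, N_TOKENS, config.vit_dim)).astype(np.float32),
            requires_grad=True)
        self.vit_blocks = [TransformerBlock(rng, config.vit_dim,
                                            config.vit_heads)
                           for _ in range(config.vit_layers)]
        self.vit_out = Linear(rng, config.vit_dim, cb)

        # decoder: upsample + skip concat + double block, then 1x1x1 head
        self.dec_stages = []
        for i in reversed(range(config.n_down)):
            self.dec_stages.append([
                ConvBlock(rng, widths[i + 1] + widths[i], widths[i]),
                ConvBlock(rng, widths[i], widths[i]),
            ])
        self.head = Conv3d(rng, widths[0], config.out_classes, k=1)

        self.stage = "inference"
        self.set_stage("inference")

    # ------------------------------------------------------------ groups
    def encoder_params(self) -> list[Tensor]:
        return Module.parameters(_Holder([self.enc_stem, self.enc_stages]))

    def vit_params(self) -> list[Tensor]:
        return Module.parameters(_Holder(
            [self.vit_in, self.pos_embed, self.vit_blocks, self.vit_out]))

    def decoder_params(self) -> list[Tensor]:
        return Module.parameters(_Holder([self.dec_stages, self.head]))

    def trainable_params(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def set_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected {STAGES}")
        self.stage = stage
        for p in self.encoder_params() + self.vit_params():
            p.requires_grad = stage == "pretrain"
        for p in self.decoder_params():
            p.requires_grad = stage == "finetune"

    # ----------------------------------------------------------- forward
    def _check_shape(self, vol: np.ndarray) -> None:
        if tuple(vol.shape[-3:]) != self.config.input_shape:
            raise ValueError(
                f"volume shape {vol.shape[-3:]} != configured "
                f"{self.config.input_shape}")

    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run encoder + ViT. Returns (skip features, ViT tokens (B, L, d))."""
        h = x
        for blk in self.enc_stem:
            h = blk(h)
        skips = [h]
        for stage in self.enc_stages:
            for blk in stage:
                h = blk(h)
            skips.append(h)
        B, cb = h.shape[0], h.shape[1]
        tokens = h.reshape(B, cb, N_TOKENS).transpose(0, 2, 1)   # B L cb
        tokens = self.vit_in(tokens) + self.pos_embed
        for blk in self.vit_blocks:
            tokens = blk(tokens)
        return skips, tokens

    def decode(self, skips: list[Tensor], tokens: Tensor) -> Tensor:
        """Map ViT tokens + skips to per-voxel class probabilities.

        Tokens are normalised per position (parameter-free layer norm)
        before the decoder projection: contrastive pretraining is free to
        grow the latent scale, and the decoder should not have to re-learn
        that scale."""
        B = tokens.shape[0]
        cb = skips[-1].shape[1]
        mu = tokens.mean(axis=-1, keepdims=True)
        centred = tokens - mu
        var = (centred ** 2).mean(axis=-1, keepdims=True)
        tokens = centred * ((var + 1e-5) ** -0.5)
        h = self.vit_out(tokens).transpose(0, 2, 1).reshape(B, cb, *BOTTLENECK)
        for stage, skip in zip(self.dec_stages, reversed(skips[:-1])):
            h = concat_channels(h.upsample3d(2), skip)
            for blk in stage:
                h = blk(h)
        return self.head(h).softmax(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        skips, tokens = self.encode(x)
        return self.decode(skips, tokens)

    # ------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"stage": self.stage, "config": asdict(self.config)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = NetConfig(**{**meta["config"],
                           "input_shape": tuple(meta["config"]["input_shape"])})
        net = cls(cfg, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(net.parameters()):
                p.data = data[f"p{i}"]
        net.set_stage(meta["stage"])
        return net


class _Holder(Module):
    def __init__(self, items):
        self.items = items


# ---------------------------------------------------------------- public API
def build_network(config: NetConfig, seed: int = 0) -> Network:
    """Construct a network with deterministic, seeded initialisation."""
    return Network(config, seed=seed)


def forward_segment(net: Network, vol: np.ndarray) -> np.ndarray:
    """Per-voxel foreground (lesion) probability for one volume.

    ``vol`` is a raw (D, H, W) array; it is z-scored internally, matching the
    normalisation used during training.
    """
    net._check_shape(vol)
    x = Tensor(normalize_volume(vol)[None, None])
    probs = net.forward(x)
    return probs.data[0, 1]


def extract_latent(net: Network, vol: np.ndarray) -> np.ndarray:
    """ViT output tokens z with shape (d, L=512), C-order over the 8^3 grid."""
    net._check_shape(vol)
    x = Tensor(normalize_volume(vol)[None, None])
    _, tokens = net.encode(x)
    return tokens.data[0].T.copy()


def set_stage(net: Network, stage: str) -> None:
    net.set_stage(stage)


def normalize_volume(vol: np.ndarray) -> np.ndarray:
    """Per-volume z-scoring (zero mean, unit SD); float32 network input."""
    vol = np.asarray(vol, dtype=np.float64)
    sd = vol.std()
    return ((vol - vol.mean()) / (sd if sd > 0 else 1.0)).astype(np.float32)
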