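"""The SegResDeiT network and its ablation variants.

A shared SegNet-style encoder (3x3 conv -> batch norm -> ReLU blocks, each
closed by 2x2 max pooling that records argmax indices) feeds a residual
bottleneck bridge (ResNet-style 1x1 -> 3x3 -> 1x1 stages at stride 1).  Two
heads consume the bridge output:

* segmentation — a decoder mirroring the encoder, upsampling by index-guided
  unpooling followed by convolutional refinement, closed by a 1x1 conv and
  sigmoid per-pixel probability map;
* classification — a DeiT-style transformer: the bridge map is cut into
  non-overlapping patches, linearly embedded, prepended with learnable class
  and distillation tokens plus positional embeddings, passed through
  pre-norm attention blocks, and read out by an MLP head with sigmoid.

Without a distillation teacher the distillation token is supervised by the
same ground-truth label as the class token and the two logits are averaged
at inference.

Ablation variants (factory :func:`build_model`):
  ``segnet_mlp``          encoder only, global-average-pool MLP classifier
  ``segnet_resnet_mlp``   + residual bridge, MLP classifier
  ``segnet_resnet_vit``   + transformer classifier, class token only
  ``segresdeit``          full model (class + distillation tokens)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Linear,
    Module,
    TransformerBlock,
    max_pool_with_indices,
    max_unpool,
)
from .tensor import Tensor, concat

VARIANTS = ("segnet_mlp", "segnet_resnet_mlp", "segnet_resnet_vit", "segresdeit")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    `encoder_blocks` lists (convs_per_block, channels); channels double by
    default.  Input H and W must be divisible by 2^len(encoder_blocks), and
    the bridge feature map by `patch_size`.
    """

    input_size: tuple[int, int, int] = (256, 256, 3)  # (H, W, C)
    encoder_blocks: tuple[tuple[int, int], ...] = ((2, 32), (2, 64), (2, 128))
    bridge_stages: int = 2
    patch_size: int = 2
    embed_dim: int = 192
    depth: int = 4
    heads: int = 3
    mlp_ratio: float = 4.0
    dropout_rate: float = 0.3
    variant: str = "segresdeit"
    use_additive_skips: bool = False

    def validate(self) -> "ModelConfig":
        h, w, c = self.input_size
        stages = len(self.encoder_blocks)
        if h % (1 << stages) or w % (1 << stages):
            raise ValueError(
                f"input {h}x{w} must be divisible by 2^{stages} (pooling stages)"
            )
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant in ("segnet_resnet_vit", "segresdeit"):
            bh, bw = h >> stages, w >> stages
            if bh % self.patch_size or bw % self.patch_size:
                raise ValueError(
                    f"bridge map {bh}x{bw} not divisible by patch size {self.patch_size}"
                )
        return self

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "encoder_blocks": [list(b) for b in self.encoder_blocks],
            "bridge_stages": self.bridge_stages,
            "patch_size": self.patch_size,
            "embed_dim": self.embed_dim,
            "depth": self.depth,
            "heads": self.heads,
            "mlp_ratio": self.mlp_ratio,
            "dropout_rate": self.dropout_rate,
            "variant": self.variant,
            "use_additive_skips": self.use_additive_skips,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            input_size=tuple(d["input_size"]),
            encoder_blocks=tuple(tuple(b) for b in d["encoder_blocks"]),
            bridge_stages=d["bridge_stages"],
            patch_size=d["patch_size"],
            embed_dim=d["embed_dim"],
            depth=d["depth"],
            heads=d["heads"],
            mlp_ratio=d["mlp_ratio"],
            dropout_rate=d["dropout_rate"],
            variant=d["variant"],
            use_additive_skips=d["use_additive_skips"],
        )


@dataclass
class EncoderState:
    """Encoder output: final map, per-stage pooling indices, pre-pool maps."""

    feature_map: Tensor
    pooling_indices: list[np.ndarray]
    skip_features: list[Tensor]


@dataclass
class SegClsOutput:
    """Dual-head forward contract: per-pixel and per-image probabilities."""

    mask_probability: Tensor  # (N, 1, H, W) in (0, 1)
    class_probability: Tensor  # (N,) in (0, 1)
    class_logits: list[Tensor] = field(default_factory=list)  # per supervised token


class _ConvBNReLU(Module):
    def __init__(self, in_ch: int, out_ch: int, rng, kernel: int = 3):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        in_ch = cfg.input_size[2]
        self.blocks = []
        for n_convs, out_ch in cfg.encoder_blocks:
            layers = []
            for j in range(n_convs):
                layers.append(_ConvBNReLU(in_ch if j == 0 else out_ch, out_ch, rng))
            self.blocks.append(layers)
            in_ch = out_ch
        self.out_channels = in_ch

    def forward(self, x: Tensor) -> EncoderState:
        indices, skips = [], []
        for layers in self.blocks:
            for layer in layers:
                x = layer(x)
            skips.append(x)
            x, idx = max_pool_with_indices(x)
            indices.append(idx)
        return EncoderState(feature_map=x, pooling_indices=indices, skip_features=skips)


class BottleneckStage(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand with identity/projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng, reduction: int = 4):
        super().__init__()
        mid = max(out_ch // reduction, 4)
        self.reduce = Conv2d(in_ch, mid, 1, rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv = Conv2d(mid, mid, 3, rng)
        self.bn2 = BatchNorm2d(mid)
        self.expand = Conv2d(mid, out_ch, 1, rng)
        self.bn3 = BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.shortcut = Conv2d(in_ch, out_ch, 1, rng)
            self.bn_short = BatchNorm2d(out_ch)
        else:
            self.shortcut = None
            self.bn_short = None

    def forward(self, x: Tensor) -> Tensor:
        branch = self.bn1(self.reduce(x)).relu()
        branch = self.bn2(self.conv(branch)).relu()
        branch = self.bn3(self.expand(branch))
        short = x if self.shortcut is None else self.bn_short(self.shortcut(x))
        return (branch + short).relu()


class ResNetBridge(Module):
    """Stride-1 residual bottleneck stack between encoder and the heads."""

    def __init__(self, in_ch: int, rng, stages: int = 2):
        super().__init__()
        self.proj = _ConvBNReLU(in_ch, in_ch, rng, kernel=1)
        self.stages = [BottleneckStage(in_ch, in_ch, rng) for _ in range(stages)]
        self.out_channels = in_ch

    def forward(self, x: Tensor) -> Tensor:
        x = self.proj(x)
        for stage in self.stages:
            x = stage(x)
        return x


class Decoder(Module):
    """Mirror of the encoder: unpool with recorded indices, then refine."""

    def __init__(self, cfg: ModelConfig, in_ch: int, rng):
        super().__init__()
        self.use_additive_skips = cfg.use_additive_skips
        self.stages = []
        blocks = list(cfg.encoder_blocks)[::-1]
        for i, (n_convs, ch) in enumerate(blocks):
            out_ch = blocks[i + 1][1] if i + 1 < len(blocks) else blocks[-1][1]
            layers = []
            for j in range(n_convs):
                layers.append(_ConvBNReLU(in_ch if j == 0 else out_ch, out_ch, rng))
            self.stages.append(layers)
            in_ch = out_ch
        self.dropout = Dropout(cfg.dropout_rate)
        self.final = Conv2d(in_ch, 1, 1, rng)

    def forward(self, x: Tensor, state: EncoderState) -> Tensor:
        if len(self.stages) != len(state.pooling_indices):
            raise ValueError("decoder stage count does not match encoder index sets")
        for i, layers in enumerate(self.stages):
            idx = state.pooling_indices[-(i + 1)]
            skip = state.skip_features[-(i + 1)]
            out_dims = (skip.shape[2], skip.shape[3])
            x = max_unpool(x, idx, out_dims)
            if self.use_additive_skips and x.shape == skip.shape:
                x = x + skip
            for layer in layers:
                x = layer(x)
        x = self.dropout(x)
        return self.final(x).sigmoid()


class MLPHead(Module):
    """Global-average-pool -> hidden MLP -> single logit."""

    def __init__(self, in_ch: int, rng, hidden: int = 64, dropout: float = 0.3):
        super().__init__()
        self.fc1 = Linear(in_ch, hidden, rng)
        self.dropout = Dropout(dropout)
        self.fc2 = Linear(hidden, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # (N, C)
        h = self.dropout(self.fc1(pooled).relu())
        return self.fc2(h).reshape(-1)  # logits (N,)


class DeiTHead(Module):
    """Patch-token transformer classifier with class (+distillation) token."""

    def __init__(self, in_ch: int, feat_hw: tuple[int, int], cfg: ModelConfig,
                 rng, use_distillation: bool = True):
        super().__init__()
        self.patch = cfg.patch_size
        fh, fw = feat_hw
        if fh % self.patch or fw % self.patch:
            raise ValueError("feature map not divisible by patch size")
        self.grid = (fh // self.patch, fw // self.patch)
        self.n_patches = self.grid[0] * self.grid[1]
        self.use_distillation = use_distillation
        patch_dim = in_ch * self.patch * self.patch
        self.embed = Linear(patch_dim, cfg.embed_dim, rng)
        n_special = 2 if use_distillation else 1
        self.cls_token = Tensor(rng.normal(0, 0.02, (1, 1, cfg.embed_dim)),
                                requires_grad=True)
        self.dist_token = (
            Tensor(rng.normal(0, 0.02, (1, 1, cfg.embed_dim)), requires_grad=True)
            if use_distillation else None
        )
        self.pos_embed = Tensor(
            rng.normal(0, 0.02, (1, self.n_patches + n_special, cfg.embed_dim)),
            requires_grad=True,
        )
        self.blocks = [
            TransformerBlock(cfg.embed_dim, cfg.heads, cfg.mlp_ratio, rng)
            for _ in range(cfg.depth)
        ]
        from .nn import LayerNorm  # local import to avoid cycle noise

        self.norm = LayerNorm(cfg.embed_dim)
        self.dropout = Dropout(cfg.dropout_rate)
        self.head_cls = Linear(cfg.embed_dim, 1, rng)
        self.head_dist = Linear(cfg.embed_dim, 1, rng) if use_distillation else None

    def patchify(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, T, C*p*p) non-overlapping patch rows."""
        n, c, h, w = x.shape
        p = self.patch
        gh, gw = h // p, w // p
        x = x.reshape(n, c, gh, p, gw, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)  # n, gh, gw, c, p, p
        return x.reshape(n, gh * gw, c * p * p)

    def forward_sequence(self, patch_tokens: Tensor) -> list[Tensor]:
        """Run the transformer on embedded patch tokens; returns token logits."""
        n = patch_tokens.shape[0]
        tokens = self.embed(patch_tokens)
        ones = Tensor(np.ones((n, 1, 1)))
        specials = [self.cls_token * ones]
        if self.use_distillation:
            specials.append(self.dist_token * ones)
        x = concat(specials + [tokens], axis=1)
        x = x + self.pos_embed
        for block in self.blocks:
            x = block(x)
        x = self.norm(x)
        cls = self.dropout(x[:, 0, :])
        logits = [self.head_cls(cls).reshape(-1)]
        if self.use_distillation:
            dist = self.dropout(x[:, 1, :])
            logits.append(self.head_dist(dist).reshape(-1))
        return logits

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.shape[2] % self.patch or x.shape[3] % self.patch:
            raise ValueError("feature map not divisible by patch size")
        return self.forward_sequence(self.patchify(x))


class SegResDeiT(Module):
    """Multi-task network: shared encoder, dual segmentation/classification heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        h, w, _ = config.input_size
        stages = len(config.encoder_blocks)
        feat_hw = (h >> stages, w >> stages)

        self.encoder = Encoder(config, rng)
        ch = self.encoder.out_channels
        self.bridge = (
            ResNetBridge(ch, rng, config.bridge_stages)
            if config.variant != "segnet_mlp" else None
        )
        self.decoder = Decoder(config, ch, rng)
        if config.variant in ("segnet_mlp", "segnet_resnet_mlp"):
            self.cls_head = MLPHead(ch, rng, dropout=config.dropout_rate)
        else:
            self.cls_head = DeiTHead(
                ch, feat_hw, config, rng,
                use_distillation=(config.variant == "segresdeit"),
            )

    # -- per-component forward surface ------------------------------------

    def encoder_forward(self, x: Tensor) -> EncoderState:
        return self.encoder(x)

    def resnet_bridge_forward(self, state: EncoderState) -> Tensor:
        if self.bridge is None:
            return state.feature_map
        return self.bridge(state.feature_map)

    def decoder_forward(self, features: Tensor, state: EncoderState) -> Tensor:
        return self.decoder(features, state)

    def deit_head_forward(self, features: Tensor) -> list[Tensor]:
        return self.cls_head(features)

    def forward(self, x: Tensor) -> SegClsOutput:
        state = self.encoder_forward(x)
        features = self.resnet_bridge_forward(state)
        mask_prob = self.decoder_forward(features, state)
        logits = self.cls_head(features)
        if not isinstance(logits, list):
            logits = [logits]
        mean_logit = logits[0]
        for extra in logits[1:]:
            mean_logit = mean_logit + extra
        mean_logit = mean_logit * (1.0 / len(logits))
        return SegClsOutput(
            mask_probability=mask_prob,
            class_probability=mean_logit.sigmoid(),
            class_logits=logits,
        )


def build_model(config: ModelConfig, seed: int = 0) -> SegResDeiT:
    """Construct a variant with seeded He initialisation."""
    return SegResDeiT(config, seed=seed)
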