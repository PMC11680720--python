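"""The dual-supervised U-Net: a standard encoder-decoder backbone with two
independent auxiliary output paths used as training constraints.

The backbone is a plain U-Net (two 3x3 conv + ReLU per level, 2x2 max
pooling, nearest-neighbor upsampling with skip concatenation). On top of the
main full-resolution segmentation head it exposes:

* a geometric head — a 1x1 convolution on the final decoder features that
  regresses the signed distance transform of the femoral-head boundary;
* pixel-level deep-supervision heads — 1x1 convolutions emitting a
  downsampled probability map at every coarser decoder resolution.

Both auxiliary paths read the decoder features but feed only the loss, so
setting their loss weights to zero reduces training exactly to a plain
U-Net.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from .layers import F32, Adam, Conv2d, ConvBlock, MaxPool2, Upsample2


@dataclass
class SegModelConfig:
    """Architecture and training configuration.

    ``depth`` is the number of encoder levels; channel width doubles per
    level from ``base_channels`` up to ``max_channels`` (a cap that keeps CPU
    training tractable). ``loss_weights`` is (w_main, w_geometric, w_pixel).
    """

    depth: int = 4
    base_channels: int = 16
    max_channels: int = 64
    loss_weights: tuple[float, float, float] = (1.0, 0.5, 0.5)
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise ValidationError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 4:
            raise ValidationError(f"base_channels must be >= 4, got {self.base_channels}")
        if self.max_channels < self.base_channels:
            raise ValidationError("max_channels must be >= base_channels")
        w = self.loss_weights
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValidationError("loss_weights must be three non-negative reals")
        if w[0] <= 0:
            raise ValidationError("the main loss weight must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate, batch_size and epochs must be positive")

    def channels(self) -> list[int]:
        """Channel width at each level, encoder top to bottleneck."""
        return [min(self.base_channels * 2**i, self.max_channels) for i in range(self.depth + 1)]


class ForwardState:
    """Raw network outputs plus the caches needed for one backward pass."""

    def __init__(self) -> None:
        self.main_logits: np.ndarray | None = None
        self.geo: np.ndarray | None = None
        self.ds_logits: list[np.ndarray] = []


class DualSupervisedUNet:
    """U-Net with geometric and pixel-level auxiliary supervision heads."""

    def __init__(self, config: SegModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels()
        d = config.depth

        self.enc = [ConvBlock(1 if i == 0 else ch[i - 1], ch[i], rng) for i in range(d)]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = ConvBlock(ch[d - 1], ch[d], rng)
        self.ups = [Upsample2() for _ in range(d)]
        # decoder level i consumes concat(upsampled deeper features, skip_i)
        self.dec = [ConvBlock(ch[i + 1] + ch[i], ch[i], rng) for i in range(d)]
        self.head_main = Conv2d(ch[0], 1, 1, rng)
        self.head_geo = Conv2d(ch[0], 1, 1, rng)
        # deep supervision at every coarser decoder resolution (levels 1..d-1)
        self.heads_ds = [Conv2d(ch[i], 1, 1, rng) for i in range(1, d)]
        self._skip_channels = ch

    # ---- parameter plumbing -------------------------------------------------

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs: list[tuple[np.ndarray, np.ndarray]] = []
        for block in [*self.enc, self.bottleneck, *self.dec]:
            pairs.extend(block.params())
        for head in [self.head_main, self.head_geo, *self.heads_ds]:
            pairs.extend(head.params())
        return pairs

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params()):
            src = arrays[f"p{i}"]
            if src.shape != p.shape:
                raise ValidationError(f"checkpoint parameter p{i} shape mismatch")
            p[...] = src

    def checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p, _ in self.params()))

    # ---- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        stride = 2**self.config.depth
        if x.ndim != 4 or x.shape[3] != 1:
            raise ValidationError("input must be (N, H, W, 1)")
        if x.shape[1] % stride or x.shape[2] % stride or min(x.shape[1:3]) < 2 * stride:
            raise ValidationError(
                f"spatial size {x.shape[1:3]} must be a multiple of {stride} and at least {2 * stride}"
            )

    def forward(self, x: np.ndarray) -> ForwardState:
        """Run the network on a channels-last (N, H, W, 1) float32 batch."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=F32)
        d = self.config.depth
        skips = []
        h = x
        for i in range(d):
            s = self.enc[i].forward(h)
            skips.append(s)
            h = self.pools[i].forward(s)
        h = self.bottleneck.forward(h)

        state = ForwardState()
        feats: list[np.ndarray | None] = [None] * d
        for i in reversed(range(d)):
            up = self.ups[i].forward(h)
            h = self.dec[i].forward(np.concatenate([up, skips[i]], axis=-1))
            feats[i] = h
        state.main_logits = self.head_main.forward(feats[0])[..., 0]
        state.geo = self.head_geo.forward(feats[0])[..., 0]
        state.ds_logits = [
            self.heads_ds[i - 1].forward(feats[i])[..., 0] for i in range(1, d)
        ]
        self._skips = skips
        return state

    def backward(
        self,
        d_main_logits: np.ndarray,
        d_geo: np.ndarray,
        d_ds_logits: list[np.ndarray],
    ) -> None:
        """Backpropagate loss gradients through heads, decoder and encoder."""
        d = self.config.depth
        ch = self._skip_channels

        d_feat = self.head_main.backward(d_main_logits[..., None].astype(F32))
        d_feat += self.head_geo.backward(d_geo[..., None].astype(F32))

        d_skips: list[np.ndarray | None] = [None] * d
        d_deeper = None  # gradient wrt the features one level deeper
        for i in range(d):
            if i > 0:
                d_feat = d_deeper
                d_feat += self.heads_ds[i - 1].backward(d_ds_logits[i - 1][..., None].astype(F32))
            d_in = self.dec[i].backward(d_feat)
            c_up = ch[i + 1]
            d_up, d_skip = d_in[..., :c_up], d_in[..., c_up:]
            d_skips[i] = np.ascontiguousarray(d_skip)
            d_deeper = self.ups[i].backward(d_up)

        h_grad = self.bottleneck.backward(d_deeper)
        for i in reversed(range(d)):
            g = self.pools[i].backward(h_grad) + d_skips[i]
            h_grad = self.enc[i].backward(g)

    def make_optimizer(self) -> Adam:
        return Adam(self.params(), lr=self.config.learning_rate)
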