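"""Femoral-head segmentation with a dual-supervised U-Net.

Training combines the main segmentation loss with two independent auxiliary
constraints — regression of the boundary signed distance transform
(geometric supervision) and deep per-pixel supervision at every decoder
resolution (pixel-level supervision). At inference the probability map is
thresholded at 0.5 and post-processed by keeping the largest connected
component and filling holes, since each image contains exactly one femoral
head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label

from .datatypes import RegionMask, Slice, TrainReport, validate_mask
from .errors import ValidationError
from .nn.layers import F32
from .nn.losses import LossComponents, composite_components
from .nn.unet import DualSupervisedUNet, ForwardState, SegModelConfig

__all__ = [
    "SegModelConfig",
    "SegOutput",
    "build_model",
    "composite_loss",
    "train",
    "segment",
    "save_checkpoint",
    "load_checkpoint",
]

PROB_THRESHOLD = 0.5


@dataclass
class SegOutput:
    """Network outputs for one slice."""

    probability_map: np.ndarray  # (H, W) in [0, 1]
    head_mask: RegionMask  # probability >= 0.5, largest component, holes filled
    geometric_map: np.ndarray  # predicted signed distance to the head boundary, px
    ds_probability_maps: list[np.ndarray] | None = None  # deep-supervision maps


def build_model(config: SegModelConfig | None = None) -> DualSupervisedUNet:
    """Construct a dual-supervised U-Net with seeded initialization."""
    return DualSupervisedUNet(config or SegModelConfig())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def composite_loss(
    output: SegOutput,
    truth: RegionMask,
    weights: tuple[float, float, float] = (1.0, 0.5, 0.5),
) -> LossComponents:
    """Evaluate the composite loss of one prediction against a true mask.

    Components: main = per-pixel binary cross-entropy + soft Dice of the
    probability map; geometric = mean absolute error against the clipped
    signed distance transform of the true boundary; pixel = mean
    cross-entropy of the deep-supervision maps against block-downsampled
    truth (zero when no auxiliary maps are present).
    """
    truth = validate_mask(truth, name="truth")
    if output.probability_map.shape != truth.shape:
        raise ValidationError(
            f"shape mismatch: prediction {output.probability_map.shape} vs truth {truth.shape}"
        )
    if output.geometric_map.shape != truth.shape:
        raise ValidationError("geometric map must share the input shape")
    ds = output.ds_probability_maps or []
    return composite_components(
        output.probability_map[None],
        output.geometric_map[None],
        [m[None] for m in ds],
        truth[None],
        weights,
    )


def _as_batch(samples: list[tuple[Slice, np.ndarray]], idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([samples[i][0].pixels for i in idx]).astype(F32)[..., None]
    ts = np.stack([np.asarray(samples[i][1], dtype=bool) for i in idx])
    return xs, ts


def train(
    model: DualSupervisedUNet,
    samples: list[tuple[Slice, RegionMask]],
    config: SegModelConfig | None = None,
    progress: bool = False,
) -> TrainReport:
    """Train the model in place on (slice, head-mask) pairs.

    Deterministic for a fixed config seed: batch shuffling uses a dedicated
    generator and all arithmetic is single-threaded NumPy. Returns the
    per-epoch trajectory of every loss component.
    """
    config = config or model.config
    config.validate()
    if len(samples) < 2:
        raise ValidationError("training requires at least 2 samples")
    for slc, mask in samples:
        if slc.pixels.shape != np.asarray(mask).shape:
            raise ValidationError("each slice and its mask must share a shape")

    rng = np.random.default_rng(config.seed + 1)  # decoupled from init seed
    opt = model.make_optimizer()
    n = len(samples)
    history: dict[str, list[float]] = {k: [] for k in ("total", "main", "geometric", "pixel")}

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = {k: 0.0 for k in history}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x, t = _as_batch(samples, idx)
            state = model.forward(x)
            main_p = _sigmoid(state.main_logits)
            ds_p = [_sigmoid(z) for z in state.ds_logits]
            comps, g_main, g_geo, g_ds = composite_components(
                main_p, state.geo, ds_p, t, config.loss_weights, with_grads=True
            )
            model.backward(g_main, g_geo, g_ds)
            opt.step()
            for key in sums:
                sums[key] += getattr(comps, key)
            n_batches += 1
        for key in sums:
            history[key].append(sums[key] / n_batches)
        if progress:
            print(
                f"epoch {epoch + 1}/{config.epochs}: total={history['total'][-1]:.4f} "
                f"main={history['main'][-1]:.4f} geo={history['geometric'][-1]:.4f} "
                f"pixel={history['pixel'][-1]:.4f}"
            )

    return TrainReport(
        epochs_run=config.epochs,
        final_train_loss=history["total"][-1],
        history=history,
        seed=config.seed,
    )


def _postprocess(binary: np.ndarray) -> np.ndarray:
    """Keep the largest connected component and fill its holes."""
    if not binary.any():
        return binary
    labels = label(binary, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == counts.argmax()
    return binary_fill_holes(keep)


def segment(model: DualSupervisedUNet, slc: Slice) -> SegOutput:
    """Segment the femoral head in one preprocessed slice.

    The head mask may be empty when the network finds no head-like region;
    downstream stages treat that as "no femoral head found".
    """
    x = slc.pixels.astype(F32)[None, ..., None]
    state: ForwardState = model.forward(x)
    prob = _sigmoid(state.main_logits[0])
    binary = prob >= PROB_THRESHOLD
    return SegOutput(
        probability_map=prob,
        head_mask=_postprocess(binary),
        geometric_map=np.asarray(state.geo[0], dtype=np.float64),
        ds_probability_maps=[_sigmoid(z[0]) for z in state.ds_logits],
    )


def save_checkpoint(model: DualSupervisedUNet, path: str | Path) -> Path:
    """Save weights plus the full config manifest to an .npz checkpoint."""
    path = Path(path)
    cfg = model.config
    manifest = json.dumps(
        {
            "depth": cfg.depth,
            "base_channels": cfg.base_channels,
            "max_channels": cfg.max_channels,
            "loss_weights": list(cfg.loss_weights),
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "epochs": cfg.epochs,
            "seed": cfg.seed,
        }
    )
    np.savez(path, __config__=np.frombuffer(manifest.encode(), dtype=np.uint8),
             **model.state_arrays())
    return path


def load_checkpoint(path: str | Path) -> DualSupervisedUNet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(Path(path)) as data:
        manifest = json.loads(bytes(data["__config__"]).decode())
        config = SegModelConfig(
            depth=manifest["depth"],
            base_channels=manifest["base_channels"],
            max_channels=manifest["max_channels"],
            loss_weights=tuple(manifest["loss_weights"]),
            learning_rate=manifest["learning_rate"],
            batch_size=manifest["batch_size"],
            epochs=manifest["epochs"],
            seed=manifest["seed"],
        )
        model = DualSupervisedUNet(config)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
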