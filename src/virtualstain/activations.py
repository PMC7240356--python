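"""Layer-by-layer activation maps of the staining generator.

For a given input patch, every tracked convolutional layer's post-activation
feature maps are captured in forward order.  A layer's "consolidated" map is
the per-pixel mean over its channels, min-max scaled to [0, 255] (channel
max available as an alternative); channel maps can be ranked by mean scaled
activation and tiled into a near-square montage for visual inspection.
Two stacks from matched inputs are compared with a per-layer normalised
mean-square error (MSE divided by the squared 255 dynamic range of the
scaled maps), giving a layer profile of where the network's responses to
the two inputs diverge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gan import TrainedModel, Tensor, to_unit
from .imaging import RGBImage


@dataclass
class LayerActivation:
    """One tracked layer: its channel maps and consolidated map."""

    index: int  # 1-based, forward order
    channel_maps: np.ndarray  # (C, H, W) raw post-activation values
    consolidated: np.ndarray  # (H, W) in [0, 255]


@dataclass
class LayerActivationStack:
    image_id: str
    direction: str
    layers: list[LayerActivation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.layers)

    def layer(self, index: int) -> LayerActivation:
        if not 1 <= index <= len(self.layers):
            raise IndexError(
                f"layer {index} out of range 1..{len(self.layers)}"
            )
        return self.layers[index - 1]


def _minmax255(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x, dtype=np.float64)
    return np.clip((x.astype(np.float64) - lo) * (255.0 / (hi - lo)), 0.0,
                   255.0)


def capture(model: TrainedModel, patch, consolidation: str = "mean",
            image_id: str = "") -> LayerActivationStack:
    """Run a patch through the generator, recording every tracked layer.

    Deterministic given weights and input.  ``consolidation`` is "mean"
    (default) or "max" across channels.
    """
    if consolidation not in ("mean", "max"):
        raise ValueError("consolidation must be 'mean' or 'max'")
    pixels = patch.pixels if hasattr(patch, "pixels") else np.asarray(patch)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an HxWx3 patch")
    if pixels.shape[0] % (2 ** model.spec.depth):
        raise ValueError(
            f"patch size {pixels.shape[0]} incompatible with generator "
            f"depth {model.spec.depth}"
        )
    record: list[Tensor] = []
    model.generator.forward(Tensor(to_unit(pixels)[None]), record=record)
    stack = LayerActivationStack(
        image_id=image_id or getattr(patch, "slide_id", ""),
        direction=model.direction,
    )
    for i, tensor in enumerate(record, start=1):
        maps = tensor.data[0]  # (C, H, W)
        combined = maps.mean(axis=0) if consolidation == "mean" else maps.max(axis=0)
        stack.layers.append(
            LayerActivation(
                index=i,
                channel_maps=maps.copy(),
                consolidated=_minmax255(combined),
            )
        )
    return stack


@dataclass
class RankedMaps:
    """Channel maps of one layer ordered by activation strength."""

    layer: int
    channel_order: list[int]  # descending mean scaled activation
    maps: list[np.ndarray]  # scaled to [0, 255], same order
    hot_channels: list[int]  # max scaled activation > threshold
    truncated: bool = False  # True when k exceeded the channel count


def rank_maps(stack: LayerActivationStack, layer: int, k: int = 5,
              hot_threshold: float = 200.0) -> RankedMaps:
    """Top-k channel maps of a layer, strongest first.

    Channel maps are min-max scaled to [0, 255] jointly across the layer so
    channels are comparable; ranking is by descending mean scaled
    activation with ties broken by ascending channel index.  The hot list
    collects channels whose maximum scaled activation exceeds
    ``hot_threshold``.  Asking for more maps than the layer has returns
    them all, flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    la = stack.layer(layer)
    scaled = _minmax255(la.channel_maps)
    means = scaled.mean(axis=(1, 2))
    # stable sort on negated means -> descending, ties by ascending index
    order = np.argsort(-means, kind="stable")
    hot = [int(c) for c in range(scaled.shape[0])
           if scaled[c].max() > hot_threshold]
    truncated = k > scaled.shape[0]
    top = [int(c) for c in order[:k]]
    return RankedMaps(
        layer=layer,
        channel_order=top,
        maps=[scaled[c] for c in top],
        hot_channels=hot,
        truncated=truncated,
    )


def concat_grid(maps: list[np.ndarray], separator_value: int = 255) -> RGBImage:
    """Tile grayscale maps into a near-square row-major montage.

    One-pixel separators between cells; missing cells in the last row are
    left black; grayscale values are replicated to RGB.
    """
    if not maps:
        raise ValueError("no maps to tile")
    h, w = maps[0].shape
    n = len(maps)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    height = nrows * h + (nrows - 1)
    width = ncols * w + (ncols - 1)
    canvas = np.zeros((height, width), dtype=np.uint8)
    for r in range(nrows):  # separators
        if r > 0:
            canvas[r * (h + 1) - 1, :] = separator_value
    for c in range(ncols):
        if c > 0:
            canvas[:, c * (w + 1) - 1] = separator_value
    for i, m in enumerate(maps):
        if m.shape != (h, w):
            raise ValueError("all maps must share one shape")
        r, c = divmod(i, ncols)
        tile = np.clip(np.floor(np.asarray(m, dtype=np.float64) + 0.5), 0,
                       255).astype(np.uint8)
        canvas[r * (h + 1) : r * (h + 1) + h, c * (w + 1) : c * (w + 1) + w] = tile
    return RGBImage(np.repeat(canvas[:, :, None], 3, axis=2))


@dataclass
class NMSEProfile:
    """Per-layer normalised MSE between two activation stacks."""

    values: np.ndarray  # length = tracked layer count
    cohort_a: str = ""
    cohort_b: str = ""

    def __len__(self) -> int:
        return len(self.values)


def nmse_profile(stack_a: LayerActivationStack,
                 stack_b: LayerActivationStack) -> NMSEProfile:
    """Layerwise MSE between consolidated maps, normalised by 255^2.

    Symmetric in its arguments; all values are >= 0 and 0 for identical
    stacks.
    """
    if len(stack_a) != len(stack_b):
        raise ValueError(
            f"layer counts differ: {len(stack_a)} vs {len(stack_b)}"
        )
    values = np.empty(len(stack_a))
    for i, (la, lb) in enumerate(zip(stack_a.layers, stack_b.layers)):
        if la.consolidated.shape != lb.consolidated.shape:
            raise ValueError(f"layer {i + 1}: consolidated map shapes differ")
        diff = la.consolidated - lb.consolidated
        values[i] = float(np.mean(diff * diff)) / (255.0 * 255.0)
    return NMSEProfile(values=values, cohort_a=stack_a.image_id,
                       cohort_b=stack_b.image_id)


def cohort_profile(stacks_a: list[LayerActivationStack],
                   stacks_b: list[LayerActivationStack],
                   cohort_a: str = "", cohort_b: str = "") -> NMSEProfile:
    """Mean NMSE profile over matched stack pairs of two image cohorts."""
    if len(stacks_a) != len(stacks_b) or not stacks_a:
        raise ValueError("cohorts must be matched and non-empty")
    profiles = [nmse_profile(a, b).values for a, b in zip(stacks_a, stacks_b)]
    return NMSEProfile(values=np.mean(profiles, axis=0), cohort_a=cohort_a,
                       cohort_b=cohort_b)
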