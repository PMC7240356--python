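"""Image and patch data model: patch-grid extraction, pairing, stitching, I/O.

Whole-slide images are handled as flat 8-bit RGB rasters.  Slides too large
for the translation network are tiled into square patches on a regular grid
(reflect-padding the slide so the grid covers it exactly), pushed through the
model patch by patch, and stitched back; where patches overlap, the stitched
pixel is the rounded mean of all contributors.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left corner
and half-open extents.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image as _PILImage

log = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 1024


class StainState(str, enum.Enum):
    """Provenance of an image's colouring."""

    NONSTAINED = "nonstained"
    DYE_STAINED = "dye_stained"
    COMP_STAINED = "comp_stained"
    COMP_DESTAINED = "comp_destained"


def _validate_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(
            f"expected a height x width x 3 array, got shape {pixels.shape}"
        )
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("zero-area image")
    if pixels.dtype != np.uint8:
        if pixels.min() < 0 or pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        pixels = pixels.astype(np.uint8)
    return pixels


@dataclass
class RGBImage:
    """An 8-bit 3-channel raster with a stain-state tag."""

    pixels: np.ndarray
    stain_state: StainState = StainState.NONSTAINED
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels)
        self.stain_state = StainState(self.stain_state)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class ImagePatch:
    """A square tile of a slide, tagged with its top-left origin."""

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    slide_id: str = ""
    stain_state: StainState = StainState.NONSTAINED

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels)
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("patches must be square")
        self.origin = (int(self.origin[0]), int(self.origin[1]))
        self.stain_state = StainState(self.stain_state)

    @property
    def patch_size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PatchGrid:
    """Bookkeeping for a tiling: slide shape, tile geometry and padding.

    ``pad`` is (top, bottom, left, right) applied to the slide before tiling;
    the padded shape is covered exactly by the grid.
    """

    slide_shape: tuple[int, int]
    patch_size: int
    stride: int
    pad: tuple[int, int, int, int] = (0, 0, 0, 0)

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if not (1 <= self.stride <= self.patch_size):
            raise ValueError(
                "stride must satisfy 1 <= stride <= patch_size "
                "(a larger stride would leave gaps)"
            )

    @property
    def padded_shape(self) -> tuple[int, int]:
        h, w = self.slide_shape
        t, b, l, r = self.pad
        return h + t + b, w + l + r

    @property
    def n_rows(self) -> int:
        return (self.padded_shape[0] - self.patch_size) // self.stride + 1

    @property
    def n_cols(self) -> int:
        return (self.padded_shape[1] - self.patch_size) // self.stride + 1

    def origins(self) -> list[tuple[int, int]]:
        """Row-major list of patch origins in padded-slide coordinates."""
        return [
            (r * self.stride, c * self.stride)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]


@dataclass
class RegisteredPair:
    """A coordinate-matched (model input, ground-truth output) patch pair."""

    source: ImagePatch
    target: ImagePatch
    registered: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.source.origin != self.target.origin:
            raise ValueError("source/target origins differ; pair not registered")
        if self.source.slide_id != self.target.slide_id:
            raise ValueError("source/target come from different slides")
        if self.source.pixels.shape != self.target.pixels.shape:
            raise ValueError("source/target shapes differ")


def _axis_padding(extent: int, patch_size: int, stride: int) -> int:
    """Bottom/right padding that makes a stride-grid of patch_size tiles
    cover ``extent`` pixels exactly."""
    if extent <= patch_size:
        return patch_size - extent
    n = -(-(extent - patch_size) // stride)  # ceil division
    return patch_size + n * stride - extent


def _reflect_pad(pixels: np.ndarray, pad: tuple[int, int, int, int]) -> np.ndarray:
    """Reflect-pad, iterating so pads larger than the image size work."""
    t, b, l, r = pad
    out = pixels
    while t or b or l or r:
        h, w = out.shape[:2]
        ct, cb = min(t, h - 1), min(b, h - 1)
        cl, cr = min(l, w - 1), min(r, w - 1)
        if max(ct, cb, cl, cr) == 0:  # 1-pixel image: fall back to edge mode
            out = np.pad(out, ((t, b), (l, r), (0, 0)), mode="edge")
            break
        out = np.pad(out, ((ct, cb), (cl, cr), (0, 0)), mode="reflect")
        t, b, l, r = t - ct, b - cb, l - cl, r - cr
    return out


def patchify(
    image: RGBImage,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stride: int | None = None,
) -> tuple[list[ImagePatch], PatchGrid]:
    """Tile an image into square patches on a regular grid.

    The image is reflect-padded on the bottom and right so that the grid
    covers every pixel; padding is recorded on the returned
    :class:`PatchGrid` and removed again by :func:`stitch`.  Patches are
    emitted row-major.  The default stride equals ``patch_size``
    (non-overlapping tiling).
    """
    if stride is None:
        stride = patch_size
    h, w = image.shape
    pad = (0, _axis_padding(h, patch_size, stride),
           0, _axis_padding(w, patch_size, stride))
    grid = PatchGrid((h, w), patch_size, stride, pad)
    padded = _reflect_pad(image.pixels, pad)
    patches = [
        ImagePatch(
            padded[r : r + patch_size, c : c + patch_size],
            origin=(r, c),
            slide_id=image.slide_id,
            stain_state=image.stain_state,
        )
        for r, c in grid.origins()
    ]
    return patches, grid


def stitch(patches: list[ImagePatch], grid: PatchGrid) -> RGBImage:
    """Reassemble a slide from its patches.

    Overlapping contributions are averaged (unweighted mean, rounded half
    away from zero); the padding recorded on the grid is cropped away so the
    result has the original slide shape.
    """
    by_origin = {p.origin: p for p in patches}
    missing = [o for o in grid.origins() if o not in by_origin]
    if missing:
        raise ValueError(f"missing patches for grid cells at origins {missing[:5]}")

    ph, pw = grid.padded_shape
    acc = np.zeros((ph, pw, 3), dtype=np.float64)
    cnt = np.zeros((ph, pw, 1), dtype=np.float64)
    ps = grid.patch_size
    for (r, c) in grid.origins():
        acc[r : r + ps, c : c + ps] += by_origin[(r, c)].pixels
        cnt[r : r + ps, c : c + ps] += 1.0
    mean = acc / cnt
    out = np.floor(mean + 0.5).astype(np.uint8)  # round half away from zero
    t, _b, l, _r = grid.pad
    h, w = grid.slide_shape
    out = out[t : t + h, l : l + w]
    state = patches[0].stain_state if patches else StainState.NONSTAINED
    slide_id = patches[0].slide_id if patches else ""
    return RGBImage(out, stain_state=state, slide_id=slide_id)


def pair_patches(
    source_patches: list[ImagePatch],
    target_patches: list[ImagePatch],
) -> tuple[list[RegisteredPair], dict[str, list[tuple[int, int]]]]:
    """Match source and target patches by origin.

    Returns the matched pairs (in source order) plus a report of origins
    present on one side only, keyed ``source_only`` / ``target_only``.
    """
    for name, patches in (("source", source_patches), ("target", target_patches)):
        origins = [p.origin for p in patches]
        if len(set(origins)) != len(origins):
            raise ValueError(f"duplicate origins in {name} patch list")
    tgt = {p.origin: p for p in target_patches}
    src = {p.origin: p for p in source_patches}
    pairs = [
        RegisteredPair(p, tgt[p.origin]) for p in source_patches if p.origin in tgt
    ]
    unmatched = {
        "source_only": sorted(o for o in src if o not in tgt),
        "target_only": sorted(o for o in tgt if o not in src),
    }
    return pairs, unmatched


def read_image(path, stain_state: StainState = StainState.NONSTAINED,
               slide_id: str = "") -> RGBImage:
    """Read an 8-bit RGB PNG or TIFF.

    An alpha channel is dropped with a warning; grayscale and non-8-bit
    inputs are rejected.
    """
    with _PILImage.open(path) as im:
        mode = im.mode
        if mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise ValueError(
                f"{path}: unsupported bit depth (mode {mode}); "
                "only 8-bit RGB images are handled — convert to 8 bits first"
            )
        if mode in ("L", "1"):
            raise ValueError(
                f"{path}: grayscale image; stack it to 3 identical channels "
                "or provide an RGB scan"
            )
        if mode == "P":
            im = im.convert("RGBA" if "transparency" in im.info else "RGB")
            mode = im.mode
        if mode == "RGBA":
            warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
            log.warning("%s: dropping alpha channel", path)
            im = im.convert("RGB")
        elif mode != "RGB":
            raise ValueError(f"{path}: unsupported image mode {mode}")
        pixels = np.asarray(im, dtype=np.uint8)
    return RGBImage(pixels, stain_state=stain_state, slide_id=slide_id)


def write_image(image: RGBImage, path) -> None:
    """Write an image losslessly as PNG or TIFF (by file extension)."""
    _PILImage.fromarray(image.pixels, mode="RGB").save(path)
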