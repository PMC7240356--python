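"""Synthetic prostate-biopsy phantoms: registered stain/nonstain pairs with
exact ground truth.

A phantom is procedurally drawn geometric "tissue": elliptical glands with
epithelial rims and lumens embedded in stroma, nuclei as small disks, on a
background margin.  Architectural patterns follow Gleason grading intuition:
grade 3 draws discrete well-separated glands, grade 4 fused/cribriform gland
clusters with multiple lumens, grade 5 sheets of nuclei without lumens, and
benign tissue large glands with sparse nuclei.  Because every pixel's class
is known, the stained and nonstained renders are deterministic per-class
colour maps plus Gaussian noise — so a trained translator has a knowable
target, metric values have analytic references, and simulated raters can be
scored against exact masks.

Everything is a pure function of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box as _box
from shapely.ops import unary_union

from .agreement import LABEL_TO_CODE, AnnotationSet, Region, rasterize
from .imaging import ImagePatch, RegisteredPair, StainState

#: Phantom tissue-class codes for ``PhantomSlide.class_map``.
BACKGROUND, STROMA, EPITHELIUM, LUMEN, NUCLEUS = 0, 1, 2, 3, 4

GRADES = ("benign", "G3", "G4", "G5")


@dataclass
class StainPalette:
    """Per-class base colours for the stained and nonstained renders.

    The stained palette mimics H&E hues (nuclei blue-purple, epithelium and
    stroma pink, lumens near-white); the nonstained palette is a dim,
    low-contrast gray-green as in autofluorescence-style scans of
    deparaffinized tissue.  By construction the nonstained render is darker
    than the stained one on the red and blue channels — matching the
    direction of the intensity shift real H&E staining produces — while the
    green channel barely moves.
    """

    stained: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: {
            BACKGROUND: (244, 242, 244),
            STROMA: (231, 159, 183),
            EPITHELIUM: (196, 120, 190),
            LUMEN: (250, 246, 250),
            NUCLEUS: (64, 40, 122),
        }
    )
    nonstained: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: {
            BACKGROUND: (146, 188, 140),
            STROMA: (118, 166, 112),
            EPITHELIUM: (102, 148, 100),
            LUMEN: (136, 178, 130),
            NUCLEUS: (84, 118, 86),
        }
    )
    noise_sd: float = 3.0

    def lut(self, which: str) -> np.ndarray:
        table = self.stained if which == "stained" else self.nonstained
        lut = np.zeros((5, 3), dtype=np.float64)
        for cls, rgb in table.items():
            if not all(0 <= v <= 255 for v in rgb):
                raise ValueError("palette colours must lie in [0, 255]")
            lut[cls] = rgb
        return lut


@dataclass
class PhantomSlide:
    """Ground truth for one synthetic slide."""

    shape: tuple[int, int]
    class_map: np.ndarray  # per-pixel code over the 5 tissue classes
    tumor_regions: list[tuple[np.ndarray, str]]  # (polygon (x,y) Nx2, grade)
    grade: str
    seed: int

    def truth_annotation(self) -> AnnotationSet:
        """The ground-truth outlines as an annotation set (rater 'truth')."""
        ann = AnnotationSet(rater_id="truth", image_id=f"phantom-{self.seed}",
                            modality="dye_stained")
        ann.regions = [Region(polygon=poly, label=grade)
                       for poly, grade in self.tumor_regions]
        return ann

    def truth_mask(self) -> np.ndarray:
        """Rasterized ground-truth label mask."""
        return rasterize(self.truth_annotation(), self.shape)


def _ellipse_mask(shape, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _disk(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _gland_outline(cy, cx, ry, rx, theta, margin=2.0, n_pts=24) -> np.ndarray:
    """Polygon (x, y) just outside an ellipse, for the tumor outline."""
    t = np.linspace(0.0, 2.0 * np.pi, n_pts, endpoint=False)
    u = (rx + margin) * np.cos(t)
    v = (ry + margin) * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    x = cx + u * ct - v * st
    y = cy + u * st + v * ct
    return np.column_stack([x, y])


def generate_phantom(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    grade: str = "G3",
    n_glands_range: tuple[int, int] = (5, 8),
) -> PhantomSlide:
    """Draw one phantom slide; deterministic per (seed, parameters).

    Grade-3 glands are mutually disjoint (their count equals the number of
    connected gland components); grade-4 clusters fuse several lumens into
    one epithelial mass; grade 5 has no lumens at all.
    """
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}; expected one of {GRADES}")
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("phantom shape must be at least 64x64")
    rng = np.random.default_rng(seed)
    cmap = np.zeros(shape, dtype=np.uint8)

    margin = max(4, int(0.05 * min(h, w)))
    cmap[margin : h - margin, margin : w - margin] = STROMA
    tissue = cmap == STROMA

    n_glands = int(rng.integers(n_glands_range[0], n_glands_range[1] + 1))
    scale = min(h, w)
    regions: list[tuple[np.ndarray, str]] = []

    def place_disjoint(n, radius, min_gap):
        """Rejection-sample n centres whose circles stay disjoint and inside
        tissue."""
        centres = []
        for _ in range(4000):
            if len(centres) == n:
                break
            cy = rng.uniform(margin + radius, h - margin - radius)
            cx = rng.uniform(margin + radius, w - margin - radius)
            if all((cy - oy) ** 2 + (cx - ox) ** 2
                   >= (2 * radius + min_gap) ** 2 for oy, ox in centres):
                centres.append((cy, cx))
        return centres

    if grade in ("G3", "benign"):
        base_r = scale / (10.0 if grade == "benign" else 16.0)
        centres = place_disjoint(n_glands, base_r * 1.25, max(3, scale // 40))
        for cy, cx in centres:
            ry = base_r * rng.uniform(0.75, 1.1)
            rx = base_r * rng.uniform(0.75, 1.1)
            theta = rng.uniform(0, np.pi)
            gland = _ellipse_mask(shape, cy, cx, ry, rx, theta) & tissue
            lumen = _ellipse_mask(shape, cy, cx, 0.55 * ry, 0.55 * rx, theta)
            cmap[gland] = EPITHELIUM
            cmap[lumen & gland] = LUMEN
            _sprinkle_nuclei(
                cmap, rng, cy, cx, ry, rx, theta,
                n=(6 if grade == "benign" else 14),
            )
            label = "benign" if grade == "benign" else "G3"
            regions.append((_gland_outline(cy, cx, ry, rx, theta), label))
    elif grade == "G4":
        n_clusters = max(2, n_glands // 3)
        base_r = scale / 18.0
        centres = place_disjoint(n_clusters, base_r * 2.6, max(3, scale // 30))
        for cy, cx in centres:
            cluster = np.zeros(shape, dtype=bool)
            n_sub = int(rng.integers(3, 6))
            for _ in range(n_sub):  # touching ellipses -> fused mass
                dy = rng.uniform(-base_r, base_r)
                dx = rng.uniform(-base_r, base_r)
                ry = base_r * rng.uniform(0.7, 1.0)
                rx = base_r * rng.uniform(0.7, 1.0)
                theta = rng.uniform(0, np.pi)
                sub = _ellipse_mask(shape, cy + dy, cx + dx, ry, rx, theta)
                cluster |= sub
                lumen = _ellipse_mask(
                    shape, cy + dy, cx + dx, 0.4 * ry, 0.4 * rx, theta
                )
                cmap[sub & tissue] = EPITHELIUM
                cmap[lumen & sub & tissue] = LUMEN
            _sprinkle_nuclei(cmap, rng, cy, cx, 2.2 * base_r, 2.2 * base_r,
                             0.0, n=24)
            regions.append(
                (_gland_outline(cy, cx, 2.2 * base_r, 2.2 * base_r, 0.0,
                                margin=4.0), "G4")
            )
    else:  # G5: sheets of nuclei, no lumens
        n_sheets = max(2, n_glands // 3)
        base_r = scale / 10.0
        centres = place_disjoint(n_sheets, base_r * 1.2, max(3, scale // 40))
        for cy, cx in centres:
            ry = base_r * rng.uniform(0.8, 1.1)
            rx = base_r * rng.uniform(0.8, 1.1)
            theta = rng.uniform(0, np.pi)
            sheet = _ellipse_mask(shape, cy, cx, ry, rx, theta) & tissue
            cmap[sheet] = EPITHELIUM
            n_nuc = max(20, int(sheet.sum() / 40))
            for _ in range(n_nuc):
                t = rng.uniform(0, 2 * np.pi)
                rad = np.sqrt(rng.uniform(0, 1))
                ny = cy + rad * ry * np.sin(t)
                nx = cx + rad * rx * np.cos(t)
                cmap[_disk(shape, ny, nx, rng.uniform(1.5, 2.5)) & sheet] = NUCLEUS
            regions.append((_gland_outline(cy, cx, ry, rx, theta), "G5"))

    # scattered stromal fibroblast nuclei
    stroma_now = cmap == STROMA
    n_stromal = int(stroma_now.sum() / 2500) + 3
    for _ in range(n_stromal):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        d = _disk(shape, cy, cx, rng.uniform(1.0, 1.8))
        cmap[d & stroma_now] = NUCLEUS

    return PhantomSlide(shape=shape, class_map=cmap, tumor_regions=regions,
                        grade=grade, seed=seed)


def _sprinkle_nuclei(cmap, rng, cy, cx, ry, rx, theta, n):
    """Place small nuclear disks along an ellipse's epithelial rim."""
    shape = cmap.shape
    ct, st = np.cos(theta), np.sin(theta)
    for _ in range(n):
        t = rng.uniform(0, 2 * np.pi)
        u = 0.8 * rx * np.cos(t)
        v = 0.8 * ry * np.sin(t)
        ny = cy + u * st + v * ct
        nx = cx + u * ct - v * st
        d = _disk(shape, ny, nx, rng.uniform(1.2, 2.2))
        cmap[d & (cmap == EPITHELIUM)] = NUCLEUS


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_pair(
    phantom: PhantomSlide,
    palette: StainPalette | None = None,
    seed: int = 0,
) -> RegisteredPair:
    """Render the registered (nonstained, stained) image pair of a phantom.

    Each pixel's class determines its base colour per render; independent
    zero-mean Gaussian noise of sd ``palette.noise_sd`` is added and clipped
    to [0, 255].  The pair is registered by construction.  Square phantoms
    only (the pair is exchanged as a patch pair at origin (0, 0)).
    """
    palette = palette or StainPalette()
    if phantom.shape[0] != phantom.shape[1]:
        raise ValueError("render_pair requires a square phantom")
    rng = np.random.default_rng(seed)
    slide_id = f"phantom-{phantom.seed}"
    images = {}
    for which, state in (
        ("nonstained", StainState.NONSTAINED),
        ("stained", StainState.DYE_STAINED),
    ):
        img = palette.lut(which)[phantom.class_map]
        if palette.noise_sd > 0:
            img = img + rng.normal(0.0, palette.noise_sd, img.shape)
        img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
        images[which] = ImagePatch(img, origin=(0, 0), slide_id=slide_id,
                                   stain_state=state)
    return RegisteredPair(source=images["nonstained"], target=images["stained"])


def analytic_render(phantom: PhantomSlide, palette: StainPalette | None = None,
                    which: str = "stained") -> np.ndarray:
    """The noise-free render: the exact target a perfect translator hits."""
    palette = palette or StainPalette()
    return palette.lut(which)[phantom.class_map].astype(np.uint8)


def make_training_set(
    n_pairs: int,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    grades=("benign", "G3", "G4", "G5"),
    palette: StainPalette | None = None,
    n_glands_range: tuple[int, int] = (2, 4),
) -> list[RegisteredPair]:
    """A list of rendered phantom pairs cycling through the given grades."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        grade = grades[i % len(grades)]
        sub = int(rng.integers(0, 2**31 - 1))
        ph = generate_phantom(sub, shape=shape, grade=grade,
                              n_glands_range=n_glands_range)
        pairs.append(render_pair(ph, palette, seed=sub))
    return pairs


# ---------------------------------------------------------------------------
# simulated raters
# ---------------------------------------------------------------------------

_polygon_cache: dict = {}


def _mask_region_polygons(mask: np.ndarray) -> list[tuple[np.ndarray, str]]:
    """Exact pixel-boundary polygon of every labelled connected component.

    Each component's outline is the boundary of the union of its pixel
    squares (pixel (r, c) occupying [c, c+1] x [r, r+1]), so rasterizing the
    polygon with the pixel-centre rule reproduces the component exactly.
    Interior holes are ignored.
    """
    key = (mask.shape, mask.tobytes())
    if key in _polygon_cache:
        return _polygon_cache[key]
    out: list[tuple[np.ndarray, str]] = []
    for label, code in LABEL_TO_CODE.items():
        binary = mask == code
        if not binary.any():
            continue
        comp, n = ndimage.label(binary)
        for i in range(1, n + 1):
            sel = comp == i
            rows = np.nonzero(sel.any(axis=1))[0]
            boxes = []
            for r in rows:  # merge pixel runs into row rectangles
                cols = np.nonzero(sel[r])[0]
                splits = np.split(cols, np.nonzero(np.diff(cols) > 1)[0] + 1)
                for run in splits:
                    boxes.append(_box(run[0], r, run[-1] + 1, r + 1))
            geom = unary_union(boxes).simplify(0)
            geoms = getattr(geom, "geoms", [geom])
            for g in geoms:
                coords = np.asarray(g.exterior.coords)[:-1]
                out.append((coords, label))
    if len(_polygon_cache) > 64:
        _polygon_cache.clear()
    _polygon_cache[key] = out
    return out


def simulate_rater(
    mask: np.ndarray,
    seed: int,
    boundary_jitter_px: float = 0.0,
    label_dropout: float = 0.0,
    dilation_px: float = 0.0,
    image_id: str = "",
    modality: str = "comp_stained",
) -> AnnotationSet:
    """Simulate a pathologist's free-form outlines from a ground-truth mask.

    Region boundaries are traced exactly from the mask, optionally dilated
    uniformly by ``dilation_px`` (square-cornered, so a square of side s
    becomes side s + 2r), then each vertex is displaced by zero-mean
    Gaussian noise of sd ``boundary_jitter_px``; each region is
    independently dropped with probability ``label_dropout``.  With zero
    jitter, dilation and dropout the rasterized annotations reproduce the
    mask exactly.  Deterministic per seed; an empty mask yields an empty
    annotation set.
    """
    if boundary_jitter_px < 0:
        raise ValueError("boundary_jitter_px must be >= 0")
    if not (0.0 <= label_dropout < 1.0):
        raise ValueError("label_dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ann = AnnotationSet(rater_id=f"sim-{seed}", image_id=image_id,
                        modality=modality)
    for coords, label in _mask_region_polygons(mask):
        drop = rng.random() < label_dropout
        jitter = (
            rng.normal(0.0, boundary_jitter_px, coords.shape)
            if boundary_jitter_px > 0
            else 0.0
        )
        if drop:
            continue
        poly = coords
        if dilation_px > 0:
            from shapely.geometry import Polygon

            buffered = Polygon(poly).buffer(
                dilation_px, join_style=2, mitre_limit=10.0
            )
            poly = np.asarray(buffered.exterior.coords)[:-1]
            if boundary_jitter_px > 0:  # re-draw jitter for the new vertex count
                jitter = rng.normal(0.0, boundary_jitter_px, poly.shape)
        poly = poly + jitter
        ann.regions.append(Region(polygon=poly, label=label))
    return ann
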