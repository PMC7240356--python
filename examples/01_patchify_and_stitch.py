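"""Tile a slide-scale image into model-sized patches and stitch it back.

Whole-slide scans are too large to push through the translation network in
one piece, so they are cut into square tiles on a regular grid (the slide
is reflect-padded so the grid covers it exactly) and reassembled afterwards.
"""

import numpy as np

from virtualstain import RGBImage, patchify, stitch

rng = np.random.default_rng(0)
slide = RGBImage(rng.integers(0, 256, (1500, 1500, 3), dtype=np.uint8),
                 slide_id="demo")

patches, grid = patchify(slide, patch_size=1024, stride=1024)
print(f"slide {slide.shape} -> {len(patches)} patches of "
      f"{grid.patch_size}px, padding (top,bottom,left,right)={grid.pad}")

reconstructed = stitch(patches, grid)
exact = np.array_equal(reconstructed.pixels, slide.pixels)
print(f"stitched back to {reconstructed.shape}; bit-exact round trip: {exact}")
# With stride == patch_size the tiling is non-overlapping, so stitching
# loses nothing: the round trip must be exact.
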