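"""Topology-preserving reduction of a root mask to a 1-pixel skeleton.

Two stages: parallel thinning (Zhang's two-subiteration method, via
scikit-image) followed by a sequential simple-point reduction that deletes
remaining deletable pixels — corner pixels of staircases and clumps around
junctions — in raster order until the pixel set is irreducible. Working to
an irreducible set is what makes the operation idempotent: no thinning rule
can remove anything further, so a skeleton fed back in comes out unchanged.

Foreground connectivity is 8, background 4, the image border is background.
A pixel is *simple* (deletable without changing topology) iff its 8-neighbour
foreground falls in exactly one 8-connected component and the 4-adjacent
background of its neighbourhood in exactly one 4-connected component; both
conditions are precomputed for all 256 neighbourhood configurations.
Endpoints (single foreground neighbour) and isolated pixels are never
deleted, so root tips survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_thin

from .mask_io import STRUCT8, BinaryRootMask

__all__ = ["Skeleton", "skeletonize"]

#: neighbour bit order: (dy, dx) for bits 0..7
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class Skeleton:
    """1-px-wide skeleton grid; inherits the mask's mm-per-pixel scale."""

    grid: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise ValueError("skeleton grid must be 2-D")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        object.__setattr__(self, "grid", g)

    def as_mask(self) -> BinaryRootMask:
        return BinaryRootMask(self.grid, scale=self.scale)

    def pixels(self) -> list[tuple[int, int]]:
        """Skeleton pixels as (x, y), in raster (y, x) order."""
        ys, xs = np.nonzero(self.grid)
        return [(int(x), int(y)) for y, x in zip(ys, xs)]

    def save_png(self, path) -> None:
        """Persist as an 8-bit mask image (skeleton = 255)."""
        import imageio.v3 as iio

        iio.imwrite(path, self.grid.astype(np.uint8) * 255)

    def save_csv(self, path) -> None:
        """Persist the pixel list as CSV with columns x,y."""
        with open(path, "w") as fh:
            fh.write("x,y\n")
            for x, y in self.pixels():
                fh.write(f"{x},{y}\n")


def _build_luts() -> tuple[np.ndarray, np.ndarray]:
    """simple[code] and degree[code] for all 256 neighbourhood configs."""
    simple = np.zeros(256, dtype=bool)
    degree = np.zeros(256, dtype=np.int8)
    bit_pos = [(dy + 1, dx + 1) for dy, dx in NEIGHBOR_OFFSETS]
    s4 = ndi.generate_binary_structure(2, 1)
    for code in range(256):
        nb = np.zeros((3, 3), dtype=bool)
        for i, (r, c) in enumerate(bit_pos):
            nb[r, c] = bool((code >> i) & 1)
        degree[code] = int(nb.sum())
        if nb.sum() == 0:
            continue
        if ndi.label(nb, structure=STRUCT8)[1] != 1:
            continue
        bg = ~nb
        bg[1, 1] = False
        lab, _ = ndi.label(bg, structure=s4)
        adj = {lab[0, 1], lab[1, 0], lab[1, 2], lab[2, 1]} - {0}
        simple[code] = len(adj) == 1
    return simple, degree


_SIMPLE_LUT, _DEGREE_LUT = _build_luts()
_BIT_WEIGHT = np.array([1 << i for i in range(8)])


def _neighbor_codes(grid: np.ndarray) -> np.ndarray:
    """Per-pixel 8-bit neighbourhood code (border treated as background)."""
    padded = np.pad(grid, 1).astype(np.int64)
    code = np.zeros(grid.shape, dtype=np.int64)
    for i, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        code += padded[1 + dy:1 + dy + grid.shape[0],
                       1 + dx:1 + dx + grid.shape[1]] << i
    return code


def _reduce_to_irreducible(grid: np.ndarray) -> np.ndarray:
    """Sequentially delete simple non-endpoint pixels in raster order."""
    g = np.pad(grid, 1)  # border padding: neighbourhood reads need no bounds
    H, W = g.shape
    changed = True
    while changed:
        changed = False
        ys, xs = np.nonzero(g)
        for y, x in zip(ys.tolist(), xs.tolist()):
            if not g[y, x]:
                continue
            code = 0
            for i, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
                if g[y + dy, x + dx]:
                    code |= 1 << i
            if _DEGREE_LUT[code] >= 2 and _SIMPLE_LUT[code]:
                g[y, x] = False
                changed = True
    return g[1:-1, 1:-1]


def skeletonize(mask: BinaryRootMask) -> Skeleton:
    """Thin a root mask to an irreducible 1-px, topology-preserving skeleton.

    Preserves the number of 8-connected foreground components and of
    4-connected background holes; the result is a subset of the mask and a
    fixed point of this function.
    """
    grid = mask.grid
    if not grid.any():
        return Skeleton(np.zeros_like(grid), scale=mask.scale)
    thin = _sk_thin(grid)
    thin = _reduce_to_irreducible(thin)
    return Skeleton(thin, scale=mask.scale)
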