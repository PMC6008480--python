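"""Binary input patterns: fixtures, synthetic contour images, edge
detection and fragmentation.

A pattern is a binary pixel grid whose active pixels select the neurons
that receive external drive (one neuron per pixel, row-major).  The
network experiments use either the two canonical 3x3 patterns of the
9-neuron runs or 32x32 black/white contour images.  Photographic inputs
are reduced to such contours by a neighbour-difference edge detector;
the synthetic generator draws simple closed shapes directly, as a
stand-in for external photograph sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import circle_perimeter, polygon_perimeter
from skimage.transform import resize

__all__ = [
    "Pattern",
    "make_grid_patterns",
    "synth_contour_image",
    "edge_detect",
    "fragment_pattern",
    "center_pattern",
    "load_grayscale",
    "save_pbm",
    "load_pbm",
]


@dataclass
class Pattern:
    """Binary pixel grid, stored row-major as a flat 0/1 vector."""

    width: int
    height: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels).astype(np.uint8).ravel()
        if px.size != self.width * self.height:
            raise ValueError("pixel count does not match grid dimensions")
        if not np.all(np.isin(px, (0, 1))):
            raise ValueError("pattern pixels must be 0/1")
        self.pixels = px

    @classmethod
    def from_grid(cls, grid) -> "Pattern":
        g = np.asarray(grid)
        return cls(width=g.shape[1], height=g.shape[0], pixels=g.ravel())

    def grid(self) -> np.ndarray:
        return self.pixels.reshape(self.height, self.width)

    @property
    def n(self) -> int:
        return self.pixels.size

    def active(self) -> np.ndarray:
        """Indices of active pixels (the pattern's target neurons)."""
        return np.flatnonzero(self.pixels)

    @property
    def n_active(self) -> int:
        return int(self.pixels.sum())


def make_grid_patterns() -> tuple[Pattern, Pattern]:
    """The two canonical, partially overlapping 3x3 fixtures.

    Pattern 1 is the top row plus centre, pattern 2 the bottom row plus
    centre; they share the centre pixel.
    """
    p1 = Pattern.from_grid([[1, 1, 1], [0, 1, 0], [0, 0, 0]])
    p2 = Pattern.from_grid([[0, 0, 0], [0, 1, 0], [1, 1, 1]])
    return p1, p2


def center_pattern(p: Pattern) -> Pattern:
    """Shift the active pixels so their centroid sits at the grid centre."""
    g = p.grid()
    ys, xs = np.nonzero(g)
    if ys.size == 0:
        return p
    dy = int(round((p.height - 1) / 2.0 - ys.mean()))
    dx = int(round((p.width - 1) / 2.0 - xs.mean()))
    out = np.zeros_like(g)
    ys2 = np.clip(ys + dy, 0, p.height - 1)
    xs2 = np.clip(xs + dx, 0, p.width - 1)
    out[ys2, xs2] = 1
    return Pattern.from_grid(out)


def synth_contour_image(
    shape: str = "circle", size: int = 32, seed: int | None = None
) -> Pattern:
    """Render a 1-pixel-wide closed shape outline onto a binary grid.

    Shapes: ``circle``, ``polygon`` (random convex polygon) or ``blob``
    (random star-convex outline).  The contour is centred on the grid and
    reproducible under the seed.  Synthetic stand-in for photograph-derived
    contour images.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size), dtype=np.uint8)
    c = (size - 1) / 2.0
    if shape == "circle":
        r = int(rng.integers(size // 4, size // 2 - 1)) if seed is not None else size // 3
        rr, cc = circle_perimeter(size // 2, size // 2, r, shape=img.shape)
        img[rr, cc] = 1
    elif shape in ("polygon", "blob"):
        k = int(rng.integers(3, 7)) if shape == "polygon" else int(rng.integers(6, 12))
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=k))
        radii = (
            np.full(k, size * 0.35)
            if shape == "polygon"
            else rng.uniform(size * 0.2, size * 0.45, size=k)
        )
        ys = c + radii * np.sin(angles)
        xs = c + radii * np.cos(angles)
        if np.ptp(ys) < 1 or np.ptp(xs) < 1:
            raise ValueError("degenerate shape")
        rr, cc = polygon_perimeter(ys, xs, shape=img.shape, clip=True)
        img[rr, cc] = 1
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return center_pattern(Pattern.from_grid(img))


def edge_detect(image, threshold: float) -> Pattern:
    """Binary contour: 1 wherever a 4-neighbour intensity step exceeds the
    threshold, then centred.

    An all-zero result (threshold too high) is returned as an empty
    pattern, not raised.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D grayscale grid")
    edges = np.zeros(img.shape, dtype=np.uint8)
    dv = np.abs(np.diff(img, axis=0)) > threshold
    dh = np.abs(np.diff(img, axis=1)) > threshold
    edges[:-1, :] |= dv
    edges[1:, :] |= dv
    edges[:, :-1] |= dh
    edges[:, 1:] |= dh
    return center_pattern(Pattern.from_grid(edges))


def fragment_pattern(p: Pattern, fraction: float, seed: int | None = None) -> Pattern:
    """Keep ``ceil(fraction * n_active)`` active pixels, chosen uniformly
    without replacement; everything else goes dark."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    act = p.active()
    keep = int(np.ceil(fraction * act.size))
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(act)[:keep]
    px = np.zeros(p.n, dtype=np.uint8)
    px[chosen] = 1
    return Pattern(p.width, p.height, px)


def load_grayscale(path, out_size: int | None = 32) -> np.ndarray:
    """Load a raster image as grayscale in [0, 1], block-mean resized."""
    from PIL import Image

    img = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    if out_size is not None and img.shape != (out_size, out_size):
        img = resize(img, (out_size, out_size), anti_aliasing=True)
    return img


# -- plain-text P1 (ASCII PBM) import/export --------------------------------
def save_pbm(p: Pattern, path) -> None:
    """Write the pattern as an ASCII P1 bitmap."""
    rows = "\n".join(" ".join(str(v) for v in row) for row in p.grid())
    with open(path, "w") as fh:
        fh.write(f"P1\n{p.width} {p.height}\n{rows}\n")


def load_pbm(path) -> Pattern:
    """Read an ASCII P1 bitmap (comments allowed)."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError("not an ASCII P1 bitmap")
    w, h = int(tokens[1]), int(tokens[2])
    bits = np.array([int(t) for t in "".join(tokens[3:])], dtype=np.uint8)
    if bits.size != w * h:
        raise ValueError("pixel count mismatch in P1 file")
    return Pattern(width=w, height=h, pixels=bits)
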