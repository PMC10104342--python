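"""Shape-image simulator: metadata scalars control shapes in an image.

Four scalar variables V, C, R, H give the probabilities that,
respectively, a Vertical bar, a Circle, a Rectangle, and a Horizontal bar
are overlaid (pixel value 1.0) on a black (all-zero) background grid at
randomized positions and sizes. The returned :class:`ShapeImage` records
which shapes fired and their geometry so downstream analyses have ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DomainError

DEFAULT_SIZE = 64

#: draw order is fixed so output is deterministic given the rng stream
SHAPE_ORDER = ("vertical_bar", "circle", "rectangle", "horizontal_bar")


@dataclass
class ShapeImage:
    """A simulated image plus its ground-truth annotation.

    ``pixels`` is a float grid with background exactly 0.0 and shape pixels
    exactly 1.0; ``fired`` says which shapes were drawn; ``geometry`` holds
    each drawn shape's parameters (e.g. circle center and radius).
    """

    pixels: np.ndarray
    fired: dict[str, bool]
    geometry: dict[str, dict] = field(default_factory=dict)


def _draw_vertical_bar(img: np.ndarray, rng) -> dict:
    size = img.shape[0]
    width = int(rng.integers(2, 6))
    x0 = int(rng.integers(0, size - width + 1))
    img[:, x0:x0 + width] = 1.0
    return {"x0": x0, "width": width}


def _draw_horizontal_bar(img: np.ndarray, rng) -> dict:
    size = img.shape[0]
    height = int(rng.integers(2, 6))
    y0 = int(rng.integers(0, size - height + 1))
    img[y0:y0 + height, :] = 1.0
    return {"y0": y0, "height": height}


def _draw_circle(img: np.ndarray, rng) -> dict:
    size = img.shape[0]
    radius = int(rng.integers(4, size // 4 + 1))
    cy = int(rng.integers(radius, size - radius + 1))
    cx = int(rng.integers(radius, size - radius + 1))
    rows, cols = np.ogrid[:size, :size]
    # pixel-center rasterization: a pixel is inside iff its integer
    # coordinate lies within the radius
    mask = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius ** 2
    img[mask] = 1.0
    return {"cy": cy, "cx": cx, "radius": radius}


def _draw_rectangle(img: np.ndarray, rng) -> dict:
    size = img.shape[0]
    height = int(rng.integers(4, size // 3 + 1))
    width = int(rng.integers(4, size // 3 + 1))
    y0 = int(rng.integers(0, size - height + 1))
    x0 = int(rng.integers(0, size - width + 1))
    img[y0:y0 + height, x0:x0 + width] = 1.0
    return {"y0": y0, "x0": x0, "height": height, "width": width}


_DRAWERS = {
    "vertical_bar": _draw_vertical_bar,
    "circle": _draw_circle,
    "rectangle": _draw_rectangle,
    "horizontal_bar": _draw_horizontal_bar,
}


def shape_image(
    v: float,
    c: float,
    r: float,
    h: float,
    rng: np.random.Generator,
    size: int = DEFAULT_SIZE,
) -> ShapeImage:
    """Simulate one image conditioned on shape probabilities ``v, c, r, h``.

    Each shape fires independently with its probability; fired shapes are
    overlaid in the fixed order vertical bar, circle, rectangle,
    horizontal bar. Probabilities outside [0, 1] raise
    :class:`DomainError`.
    """
    probs = {"vertical_bar": v, "circle": c, "rectangle": r, "horizontal_bar": h}
    for shape, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"probability for {shape} is {p}, outside [0, 1]")
    img = np.zeros((size, size), dtype=float)
    fired = {shape: bool(rng.random() < probs[shape]) for shape in SHAPE_ORDER}
    geometry = {}
    for shape in SHAPE_ORDER:
        if fired[shape]:
            geometry[shape] = _DRAWERS[shape](img, rng)
    return ShapeImage(pixels=img, fired=fired, geometry=geometry)


def shape_image_pixels(
    v: float, c: float, r: float, h: float, rng: np.random.Generator,
    size: int = DEFAULT_SIZE,
) -> np.ndarray:
    """Like :func:`shape_image` but returns only the pixel grid — the form
    used as a node function in the shipped YAML model (the grid is written
    to an ``.npy`` sidecar per sample)."""
    return shape_image(v, c, r, h, rng, size=size).pixels
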