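"""Raster I/O, CIELAB conversion, and the resize-and-pad canvas protocol.

Wound photographs arrive as 8-bit sRGB rasters (consumer-camera JPEGs,
typically 3600x2700).  Region-based labeling operates in CIELAB, where
Euclidean distance approximates perceptual color difference, and on a
reduced 1000-px-long-side raster padded with black to a square canvas so
that every image presents the same geometry downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from PIL import Image
from skimage import color as _skcolor

if TYPE_CHECKING:  # pragma: no cover
    from .analysis import CameraParams

__all__ = [
    "WoundImage",
    "LabImage",
    "AffineRecord",
    "rgb_to_lab",
    "lab_to_rgb",
    "resize_and_pad",
    "read_image",
    "write_image",
]


@dataclass
class WoundImage:
    """An 8-bit RGB wound photograph plus optional capture metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, sRGB channel order.
    id
        Opaque identifier (usually the source filename stem).
    camera
        Optional :class:`~ulcerlab.analysis.CameraParams` describing the
        capture geometry, needed for metric wound-size estimation.
    """

    pixels: np.ndarray
    id: str = ""
    camera: "CameraParams | None" = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 RGB raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("pixel values must be 8-bit (0..255)")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[:2]


@dataclass
class LabImage:
    """Per-channel CIELAB representation of a :class:`WoundImage`.

    ``l`` is luminance in [0, 100]; ``a`` and ``b`` are the opponent
    chroma axes (unbounded in practice, roughly [-128, 127]).
    """

    l: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.l.shape == self.a.shape == self.b.shape):
            raise ValueError("l, a, b channels must share one raster grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.l.shape

    def stack(self) -> np.ndarray:
        """Return an (H, W, 3) float array with channels (l, a, b)."""
        return np.stack([self.l, self.a, self.b], axis=-1)


def rgb_to_lab(image: WoundImage | np.ndarray) -> LabImage:
    """Convert an 8-bit sRGB raster to CIELAB (D65 white point).

    The conversion is the standard sRGB companding -> linear RGB ->
    XYZ (D65) -> L*a*b* chain; deterministic and vectorized.
    """
    px = image.pixels if isinstance(image, WoundImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB raster, got shape {px.shape}")
    lab = _skcolor.rgb2lab(px)
    return LabImage(l=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def lab_to_rgb(lab: LabImage) -> WoundImage:
    """Inverse of :func:`rgb_to_lab`; out-of-gamut values are clipped."""
    rgb = _skcolor.lab2rgb(lab.stack())
    return WoundImage(pixels=np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8))


@dataclass
class AffineRecord:
    """Scale/offset bookkeeping for :func:`resize_and_pad`.

    Masks drawn on the padded canvas can be mapped back to the source
    raster (and vice versa) with :meth:`to_canvas` / :meth:`to_source`.
    The content is always anchored at the canvas origin (top-left), so
    the offset is identically zero and only the scale matters.
    """

    scale: float
    source_shape: tuple[int, int]
    content_shape: tuple[int, int]
    canvas_shape: tuple[int, int]
    offset: tuple[int, int] = (0, 0)

    def to_canvas(self, mask: np.ndarray) -> np.ndarray:
        """Map a source-raster binary mask onto the padded canvas (nearest)."""
        if mask.shape != self.source_shape:
            raise ValueError("mask shape does not match the source raster")
        out = np.zeros(self.canvas_shape, dtype=bool)
        ch, cw = self.content_shape
        rr = np.minimum((np.arange(ch) / self.scale).astype(int), mask.shape[0] - 1)
        cc = np.minimum((np.arange(cw) / self.scale).astype(int), mask.shape[1] - 1)
        out[: ch, : cw] = mask[np.ix_(rr, cc)]
        return out

    def to_source(self, mask: np.ndarray) -> np.ndarray:
        """Map a canvas binary mask back to the source raster (nearest)."""
        if mask.shape != self.canvas_shape:
            raise ValueError("mask shape does not match the canvas")
        sh, sw = self.source_shape
        rr = np.minimum(np.rint(np.arange(sh) * self.scale).astype(int), self.content_shape[0] - 1)
        cc = np.minimum(np.rint(np.arange(sw) * self.scale).astype(int), self.content_shape[1] - 1)
        return mask[np.ix_(rr, cc)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scale": self.scale,
            "source_shape": list(self.source_shape),
            "content_shape": list(self.content_shape),
            "canvas_shape": list(self.canvas_shape),
            "offset": list(self.offset),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            scale=d["scale"],
            source_shape=tuple(d["source_shape"]),
            content_shape=tuple(d["content_shape"]),
            canvas_shape=tuple(d["canvas_shape"]),
            offset=tuple(d["offset"]),
        )


def resize_and_pad(
    image: WoundImage,
    content_long_side: int = 1000,
    canvas: tuple[int, int] = (1000, 1000),
) -> tuple[WoundImage, AffineRecord]:
    """Scale the longest side to ``content_long_side`` and pad with black.

    A 3600x2700 photograph becomes 1000x750 content on a 1000x1000 black
    canvas.  Aspect ratio is preserved; the content sits at the top-left;
    every remaining canvas pixel is exactly (0, 0, 0).  Bilinear
    interpolation is used for rescaling; an identity scale leaves the
    content bit-identical.
    """
    h, w = image.shape
    if h == 0 or w == 0:
        raise ValueError("cannot resize a zero-sized image")
    scale = content_long_side / max(h, w)
    new_h, new_w = int(round(h * scale)), int(round(w * scale))
    if new_h > canvas[0] or new_w > canvas[1]:
        raise ValueError(
            f"scaled content {new_h}x{new_w} does not fit canvas {canvas[0]}x{canvas[1]}"
        )
    if (new_h, new_w) == (h, w):
        content = image.pixels
    else:
        content = np.asarray(
            Image.fromarray(image.pixels).resize((new_w, new_h), Image.BILINEAR)
        )
    out = np.zeros((canvas[0], canvas[1], 3), dtype=np.uint8)
    out[:new_h, :new_w] = content
    record = AffineRecord(
        scale=scale,
        source_shape=(h, w),
        content_shape=(new_h, new_w),
        canvas_shape=canvas,
    )
    return WoundImage(pixels=out, id=image.id, camera=image.camera), record


def read_image(path: str | Path) -> WoundImage:
    """Read a JPEG/PNG raster as a :class:`WoundImage` (forced to RGB)."""
    path = Path(path)
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return WoundImage(pixels=px, id=path.stem)


def write_image(image: WoundImage, path: str | Path) -> None:
    """Write a :class:`WoundImage` as JPEG or PNG depending on suffix."""
    Image.fromarray(image.pixels).save(str(path))
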