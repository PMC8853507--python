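"""Annotation workflows: boundary (polygon) and region (superpixel) labeling.

Two labeling styles coexist.  Boundary-based ("pizza-making") labeling
draws the ulceration outline first, then tissue outlines inside it, the
way pizza toppings are layered onto the dough; region-based labeling
assigns a tissue class to each SLIC superpixel.  Both reduce to the
same canonical representation, :class:`LabelMasks`: per-class binary
masks on one grid, where the inner classes (granulation, slough,
eschar, undefined) are pairwise disjoint, their union is the
ulceration, and the peri-wound re-epithelialization rim never overlaps
the ulceration.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .image_io import WoundImage
from .superpixels import SuperpixelSegmentation

__all__ = [
    "TissueClass",
    "INSIDE_CLASSES",
    "PolygonShape",
    "BoundaryAnnotation",
    "RegionAnnotation",
    "LabelMasks",
    "rasterize",
    "compose_ulceration",
    "from_regions",
    "combine_classes",
    "split_dataset",
    "threefold_cv",
    "augment",
    "assignment_from_truth",
    "MODEL1_CLASSES",
    "MODEL2_CLASSES",
    "CATEGORICAL_CLASSES",
    "PALETTE",
    "read_labelme",
    "write_labelme",
    "read_region_csv",
    "write_region_csv",
    "write_label_png",
    "read_label_png",
]


class TissueClass(str, enum.Enum):
    """Tissue taxonomy: four inside classes, one peri-wound, background.

    Granulation is healthy beefy-red healing tissue; slough is yellowish
    partially necrotic tissue; eschar is black-brown desiccated necrotic
    tissue; "undefined" is the residual wound bed not assigned to a
    named tissue; re_ep is peri-wound re-epithelialization, the earliest
    sign of healing; ulceration is the whole wound (union of the inside
    classes).
    """

    GRANULATION = "granulation"
    SLOUGH = "slough"
    ESCHAR = "eschar"
    UNDEFINED = "undefined"
    ULCERATION = "ulceration"
    RE_EP = "re_ep"
    BACKGROUND = "background"


INSIDE_CLASSES = (
    TissueClass.GRANULATION,
    TissueClass.SLOUGH,
    TissueClass.ESCHAR,
    TissueClass.UNDEFINED,
)

#: categorical encoding used for single-layer label maps and transforms
CATEGORICAL_CLASSES = (
    TissueClass.BACKGROUND,
    TissueClass.GRANULATION,
    TissueClass.SLOUGH,
    TissueClass.ESCHAR,
    TissueClass.UNDEFINED,
    TissueClass.RE_EP,
)

MODEL1_CLASSES = (TissueClass.BACKGROUND, TissueClass.ULCERATION, TissueClass.RE_EP)
MODEL2_CLASSES = (
    TissueClass.BACKGROUND,
    TissueClass.GRANULATION,
    TissueClass.SLOUGH,
    TissueClass.ESCHAR,
    TissueClass.RE_EP,
)

#: display palette (granulation red, slough yellow, eschar blue)
PALETTE = {
    TissueClass.BACKGROUND: (0, 0, 0),
    TissueClass.GRANULATION: (255, 0, 0),
    TissueClass.SLOUGH: (255, 255, 0),
    TissueClass.ESCHAR: (0, 0, 255),
    TissueClass.UNDEFINED: (128, 128, 128),
    TissueClass.RE_EP: (255, 160, 200),
    TissueClass.ULCERATION: (200, 0, 200),
}


@dataclass
class PolygonShape:
    """One drawn outline: a tissue class and its vertex list [(x, y), ...]."""

    label: TissueClass
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.label = TissueClass(self.label)
        if len(self.points) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        self.points = [(float(x), float(y)) for x, y in self.points]


@dataclass
class BoundaryAnnotation:
    """Pizza-making annotation: ordered polygons, ulceration drawn first."""

    image_id: str
    shapes: list[PolygonShape]

    def __post_init__(self) -> None:
        seen_inner = False
        for s in self.shapes:
            if s.label in INSIDE_CLASSES:
                seen_inner = True
            elif s.label is TissueClass.ULCERATION and seen_inner:
                raise ValueError("ulceration outline must precede inner-tissue outlines")


@dataclass
class RegionAnnotation:
    """Region-based annotation: superpixel id -> inside tissue class.

    Unmapped superpixels default to background.
    """

    image_id: str
    segmentation: SuperpixelSegmentation
    assignment: dict[int, TissueClass]

    def __post_init__(self) -> None:
        self.assignment = {int(k): TissueClass(v) for k, v in self.assignment.items()}
        bad = [k for k in self.assignment if not 0 <= k < self.segmentation.k_actual]
        if bad:
            raise ValueError(f"assignment references unknown superpixel ids: {bad[:5]}")


@dataclass
class LabelMasks:
    """Per-class binary masks on one raster grid; the canonical labels.

    Invariants (enforced at construction): the four inside masks are
    pairwise disjoint; re_ep is disjoint from the ulceration; the
    ulceration is, by definition here, the union of the inside masks.
    """

    granulation: np.ndarray
    slough: np.ndarray
    eschar: np.ndarray
    undefined: np.ndarray
    re_ep: np.ndarray

    def __post_init__(self) -> None:
        masks = [self.granulation, self.slough, self.eschar, self.undefined, self.re_ep]
        shape = masks[0].shape
        for m in masks:
            if m.shape != shape:
                raise ValueError("all masks must share one raster grid")
        for name in ("granulation", "slough", "eschar", "undefined", "re_ep"):
            setattr(self, name, getattr(self, name).astype(bool))
        self.validate()

    def validate(self) -> None:
        inner = [self.granulation, self.slough, self.eschar, self.undefined]
        total = sum(m.astype(np.uint8) for m in inner)
        if (total > 1).any():
            raise ValueError("inside-class masks overlap")
        if (self.re_ep & self.ulceration).any():
            raise ValueError("re_ep overlaps the ulceration")

    @property
    def shape(self) -> tuple[int, int]:
        return self.granulation.shape

    @property
    def ulceration(self) -> np.ndarray:
        """The whole wound: union of the four inside-class masks."""
        return self.granulation | self.slough | self.eschar | self.undefined

    def __getitem__(self, cls: TissueClass) -> np.ndarray:
        cls = TissueClass(cls)
        if cls is TissueClass.ULCERATION:
            return self.ulceration
        if cls is TissueClass.BACKGROUND:
            return ~(self.ulceration | self.re_ep)
        return getattr(self, cls.value)

    def pixel_counts(self) -> dict[str, int]:
        out = {c.value: int(self[c].sum()) for c in CATEGORICAL_CLASSES}
        out["ulceration"] = int(self.ulceration.sum())
        return out

    def to_categorical(self) -> np.ndarray:
        """Single-layer encoding, indices per :data:`CATEGORICAL_CLASSES`."""
        out = np.zeros(self.shape, dtype=np.uint8)
        for i, cls in enumerate(CATEGORICAL_CLASSES):
            if cls is TissueClass.BACKGROUND:
                continue
            out[getattr(self, cls.value)] = i
        return out

    @classmethod
    def from_categorical(cls, cat: np.ndarray) -> "LabelMasks":
        idx = {c: i for i, c in enumerate(CATEGORICAL_CLASSES)}
        return cls(
            granulation=cat == idx[TissueClass.GRANULATION],
            slough=cat == idx[TissueClass.SLOUGH],
            eschar=cat == idx[TissueClass.ESCHAR],
            undefined=cat == idx[TissueClass.UNDEFINED],
            re_ep=cat == idx[TissueClass.RE_EP],
        )

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LabelMasks":
        z = np.zeros(shape, dtype=bool)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


def polygon_mask(points: list[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of one polygon at pixel centers.

    Pixel (r, c) has its center at (x=c, y=r); a center on a left/top
    edge is inside, on a right/bottom edge outside (half-open crossing
    rule), so abutting polygons never double-claim a pixel.
    """
    pts = np.asarray(points, dtype=float)
    h, w = shape
    yy = np.arange(h, dtype=float)[:, None]
    xx = np.arange(w, dtype=float)[None, :]
    inside = np.zeros(shape, dtype=bool)
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for xa, ya, xb, yb in zip(x1, y1, x2, y2):
        if ya == yb:
            continue
        cond = (ya > yy) != (yb > yy)
        xint = xa + (yy - ya) * (xb - xa) / (yb - ya)
        inside ^= cond & (xx < xint)
    return inside


def _warn_if_self_intersecting(shape_: PolygonShape) -> None:
    try:
        from shapely.geometry import Polygon
        if not Polygon(shape_.points).is_valid:
            warnings.warn(
                f"self-intersecting {shape_.label.value} polygon; using even-odd fill",
                stacklevel=3,
            )
    except Exception:  # pragma: no cover - shapely hiccups must not block fills
        pass


def rasterize(annotation: BoundaryAnnotation, shape: tuple[int, int]) -> LabelMasks:
    """Rasterize a boundary annotation into :class:`LabelMasks`.

    The layering follows the draw order: ulceration outlines define the
    wound, later inner-tissue polygons overwrite earlier ones inside the
    wound, the residual wound bed becomes "undefined", and re_ep is
    clipped to the wound's complement.
    """
    ulcer = np.zeros(shape, dtype=bool)
    re_ep = np.zeros(shape, dtype=bool)
    inner = np.zeros(shape, dtype=np.uint8)  # 0 none, 1 gran, 2 slough, 3 eschar
    inner_code = {TissueClass.GRANULATION: 1, TissueClass.SLOUGH: 2, TissueClass.ESCHAR: 3}
    for s in annotation.shapes:
        _warn_if_self_intersecting(s)
        m = polygon_mask(s.points, shape)
        if s.label is TissueClass.ULCERATION:
            ulcer |= m
        elif s.label is TissueClass.RE_EP:
            re_ep |= m
        elif s.label in inner_code:
            inner[m] = inner_code[s.label]
        elif s.label is TissueClass.UNDEFINED:
            inner[m] = 0  # explicit reset to the residual class
    inner[~ulcer] = 0
    re_ep &= ~ulcer
    return LabelMasks(
        granulation=(inner == 1),
        slough=(inner == 2),
        eschar=(inner == 3),
        undefined=ulcer & (inner == 0),
        re_ep=re_ep,
    )


def compose_ulceration(masks: LabelMasks) -> np.ndarray:
    """Union of the inside-class masks — the whole wound.

    The inside masks must be pairwise disjoint (a pixel is one tissue).
    """
    inner = [masks.granulation, masks.slough, masks.eschar, masks.undefined]
    total = sum(m.astype(np.uint8) for m in inner)
    if (total > 1).any():
        raise ValueError("inside-class masks overlap; cannot compose ulceration")
    return total > 0


def from_regions(
    annotation: RegionAnnotation,
    ulcer_boundary: BoundaryAnnotation | None = None,
    re_ep_mask: np.ndarray | None = None,
) -> LabelMasks:
    """Expand a superpixel class assignment into :class:`LabelMasks`.

    Every pixel of a mapped superpixel takes the superpixel's class;
    unmapped superpixels stay background.  Region labeling covers only
    the inside tissues; the peri-wound rim comes from boundary labeling,
    supplied either as a :class:`BoundaryAnnotation` whose re_ep
    outlines are rasterized, or directly as ``re_ep_mask`` (both are
    clipped to the wound's complement).
    """
    labels = annotation.segmentation.labels
    shape = labels.shape
    per_class: dict[TissueClass, list[int]] = {}
    for sp_id, cls in annotation.assignment.items():
        if cls is TissueClass.BACKGROUND:
            continue
        if cls not in INSIDE_CLASSES:
            raise ValueError(f"region assignment must use inside classes, got {cls}")
        per_class.setdefault(cls, []).append(sp_id)

    def mask_for(cls: TissueClass) -> np.ndarray:
        ids = per_class.get(cls, [])
        return np.isin(labels, ids) if ids else np.zeros(shape, dtype=bool)

    re_ep = np.zeros(shape, dtype=bool)
    if ulcer_boundary is not None:
        b = rasterize(ulcer_boundary, shape)
        re_ep |= b.re_ep
    if re_ep_mask is not None:
        re_ep |= np.asarray(re_ep_mask, dtype=bool)
    masks = LabelMasks(
        granulation=mask_for(TissueClass.GRANULATION),
        slough=mask_for(TissueClass.SLOUGH),
        eschar=mask_for(TissueClass.ESCHAR),
        undefined=mask_for(TissueClass.UNDEFINED),
        re_ep=np.zeros(shape, dtype=bool),
    )
    masks.re_ep = re_ep & ~masks.ulceration
    masks.validate()
    return masks


def assignment_from_truth(
    segmentation: SuperpixelSegmentation,
    truth: LabelMasks,
    refine: bool = True,
) -> RegionAnnotation:
    """Build the region assignment a perfect labeler would produce.

    With ``refine=True`` superpixels are first split along the
    ground-truth class boundaries (each superpixel/class intersection
    becomes its own region), so expanding the assignment reproduces the
    truth losslessly; with ``refine=False`` each superpixel takes its
    majority truth class, quantizing the truth to superpixel resolution.
    """
    cat = truth.to_categorical()
    # fold re_ep into background for the inside-tissue assignment
    idx_re = CATEGORICAL_CLASSES.index(TissueClass.RE_EP)
    cat = np.where(cat == idx_re, 0, cat)
    labels = segmentation.labels
    if refine:
        combined = labels.astype(np.int64) * len(CATEGORICAL_CLASSES) + cat
        uniq, inv = np.unique(combined, return_inverse=True)
        new_labels = inv.reshape(labels.shape).astype(np.int32)
        seg = SuperpixelSegmentation(
            labels=new_labels,
            k_actual=len(uniq),
            params=segmentation.params,
            s=segmentation.s,
        )
        assignment = {
            i: CATEGORICAL_CLASSES[int(u % len(CATEGORICAL_CLASSES))]
            for i, u in enumerate(uniq)
            if u % len(CATEGORICAL_CLASSES) != 0
        }
        return RegionAnnotation(image_id="", segmentation=seg, assignment=assignment)
    assignment = {}
    for sp in range(segmentation.k_actual):
        vals = cat[labels == sp]
        maj = int(np.bincount(vals, minlength=len(CATEGORICAL_CLASSES)).argmax())
        if maj != 0:
            assignment[sp] = CATEGORICAL_CLASSES[maj]
    return RegionAnnotation(image_id="", segmentation=segmentation, assignment=assignment)


def combine_classes(masks: LabelMasks, mode: str) -> np.ndarray:
    """Collapse masks into one categorical map for a training target.

    ``model1`` trains the wound outline: {background, ulceration,
    re_ep}.  ``model2`` trains the inside tissues alongside re_ep:
    {background, granulation, slough, eschar, re_ep}; the residual
    "undefined" wound bed has no slot in model 2 and maps to background.
    Indices follow :data:`MODEL1_CLASSES` / :data:`MODEL2_CLASSES`.
    """
    if mode == "model1":
        out = np.zeros(masks.shape, dtype=np.uint8)
        out[masks.ulceration] = 1
        out[masks.re_ep] = 2
        return out
    if mode == "model2":
        out = np.zeros(masks.shape, dtype=np.uint8)
        out[masks.granulation] = 1
        out[masks.slough] = 2
        out[masks.eschar] = 3
        out[masks.re_ep] = 4
        return out
    raise ValueError(f"unknown mode {mode!r}; expected 'model1' or 'model2'")


def split_dataset(ids: list, seed: int) -> tuple[list, list, list]:
    """Deterministic 7:2:1 train/validation/test split.

    Sizes are floor(0.7 n) / floor(0.2 n) / remainder; partitions are
    disjoint and exhaustive, reproducible under ``seed``.
    """
    if len(ids) == 0:
        raise ValueError("cannot split an empty id list")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train, n_val = int(np.floor(0.7 * n)), int(np.floor(0.2 * n))
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def threefold_cv(ids: list, seed: int) -> list[list]:
    """Three disjoint, exhaustive folds over the train+validation ids."""
    if len(ids) == 0:
        raise ValueError("cannot fold an empty id list")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    shuffled = [ids[i] for i in order]
    return [list(part) for part in np.array_split(np.array(shuffled, dtype=object), 3)]


_AUGMENT_OPS = ("rotate", "shift", "scale", "gaussian_blur", "contrast")


def _geometric(cat: np.ndarray, op: str, p: dict, order: int) -> np.ndarray:
    if op == "rotate":
        angle = float(p["angle"])
        if angle % 90 == 0:
            return np.ascontiguousarray(np.rot90(cat, k=int(angle // 90) % 4))
        return ndimage.rotate(cat, angle, reshape=False, order=order, mode="constant", cval=0)
    if op == "shift":
        dy, dx = float(p.get("dy", 0)), float(p.get("dx", 0))
        shift = (dy, dx) if cat.ndim == 2 else (dy, dx, 0)
        return ndimage.shift(cat, shift, order=order, mode="constant", cval=0)
    if op == "scale":
        f = float(p["factor"])
        h, w = cat.shape[:2]
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        mat = np.eye(cat.ndim)
        mat[0, 0] = mat[1, 1] = 1.0 / f
        off = np.zeros(cat.ndim)
        off[:2] = center - center / f
        return ndimage.affine_transform(
            cat, mat, offset=off, order=order, mode="constant", cval=0
        )
    raise AssertionError(op)


def augment(
    image: WoundImage,
    masks: LabelMasks,
    spec: list[dict],
    seed: int = 0,
) -> tuple[WoundImage, LabelMasks]:
    """Mask-consistent augmentation: rotate, shift, scale, blur, contrast.

    Geometric ops transform the image (bilinear) and the categorical
    label map (nearest) identically; photometric ops (gaussian_blur,
    contrast normalization) touch the image only, so the masks come back
    bitwise unchanged.  Missing op parameters are sampled from typical
    ranges with ``seed``.  An empty spec is the identity.
    """
    rng = np.random.default_rng(seed)
    img = image.pixels.astype(float)
    cat = masks.to_categorical()
    for step in spec:
        op = step.get("op")
        if op not in _AUGMENT_OPS:
            raise ValueError(f"unsupported transform {op!r}; expected one of {_AUGMENT_OPS}")
        p = dict(step)
        if op == "rotate":
            p.setdefault("angle", float(rng.uniform(-25, 25)))
            img = _geometric(img, op, p, order=1)
            cat = _geometric(cat, op, p, order=0)
        elif op == "shift":
            p.setdefault("dy", float(rng.uniform(-0.1, 0.1)) * img.shape[0])
            p.setdefault("dx", float(rng.uniform(-0.1, 0.1)) * img.shape[1])
            img = _geometric(img, op, p, order=1)
            cat = _geometric(cat, op, p, order=0)
        elif op == "scale":
            p.setdefault("factor", float(rng.uniform(0.9, 1.1)))
            img = _geometric(img, op, p, order=1)
            cat = _geometric(cat, op, p, order=0)
        elif op == "gaussian_blur":
            sigma = float(p.get("sigma", rng.uniform(0.5, 1.5)))
            img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
        elif op == "contrast":
            gain = float(p.get("gain", rng.uniform(0.8, 1.2)))
            img = (img - 127.5) * gain + 127.5
    out_img = WoundImage(
        pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        id=image.id,
        camera=image.camera,
    )
    return out_img, LabelMasks.from_categorical(cat)


# ---------------------------------------------------------------------------
# serialization


def read_labelme(path: str | Path) -> BoundaryAnnotation:
    """Read a LabelMe-dialect JSON annotation file."""
    d = json.loads(Path(path).read_text())
    shapes = [
        PolygonShape(label=s["label"], points=[tuple(p) for p in s["points"]])
        for s in d.get("shapes", [])
        if s.get("shape_type", "polygon") == "polygon"
    ]
    image_id = Path(d.get("imagePath", Path(path).stem)).stem
    return BoundaryAnnotation(image_id=image_id, shapes=shapes)


def write_labelme(
    annotation: BoundaryAnnotation, path: str | Path, shape: tuple[int, int] | None = None
) -> None:
    """Write a LabelMe-dialect JSON annotation file."""
    d = {
        "imagePath": f"{annotation.image_id}.png",
        "imageHeight": shape[0] if shape else None,
        "imageWidth": shape[1] if shape else None,
        "shapes": [
            {
                "label": s.label.value,
                "points": [[x, y] for x, y in s.points],
                "shape_type": "polygon",
            }
            for s in annotation.shapes
        ],
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_region_csv(path: str | Path, segmentation: SuperpixelSegmentation) -> RegionAnnotation:
    """Read a superpixel_id,class CSV into a :class:`RegionAnnotation`."""
    df = pd.read_csv(path)
    assignment = {
        int(r.superpixel_id): TissueClass(r["class"]) for _, r in df.iterrows()
    }
    return RegionAnnotation(
        image_id=Path(path).stem, segmentation=segmentation, assignment=assignment
    )


def write_region_csv(annotation: RegionAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        sorted((k, v.value) for k, v in annotation.assignment.items()),
        columns=["superpixel_id", "class"],
    ).to_csv(path, index=False)


def write_label_png(cat: np.ndarray, path: str | Path, classes=CATEGORICAL_CLASSES) -> None:
    """Write a categorical label map as a paletted PNG."""
    im = Image.fromarray(cat.astype(np.uint8), mode="P")
    palette = []
    for cls in classes:
        palette.extend(PALETTE[cls])
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(str(path))


def read_label_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path))).astype(np.uint8)
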