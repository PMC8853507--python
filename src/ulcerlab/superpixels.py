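"""SLIC superpixel segmentation in the 5-D (l, a, b, x, y) space.

Simple linear iterative clustering seeds cluster centers on a regular
grid with interval S = sqrt(N/K), then alternates a localized
nearest-center assignment with a center update until the centers stop
moving.  The distance between a pixel and a center combines the CIELAB
color distance with the spatial distance weighted by the compactness m:

    D = D_color + (m / S) * D_xy

with both sub-distances Euclidean.  (The classical variant
sqrt(D_color^2 + (D_xy / S)^2 m^2) is available via
``SlicParams.original_distance`` for comparison.)  After convergence,
stray fragments are absorbed into their largest neighbor so every
region is 4-connected — labelers annotate regions, so each must be a
single contiguous patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from .image_io import LabImage

__all__ = [
    "SlicParams",
    "ClusterCenter",
    "SuperpixelSegmentation",
    "init_centers",
    "slic_distance",
    "slic_segment",
    "enforce_connectivity",
    "boundary_mask",
    "boundary_recall",
    "save_labels",
    "load_labels",
]


@dataclass(frozen=True)
class SlicParams:
    """Parameters of one SLIC run.

    k is the desired superpixel count; m the compactness weighting the
    spatial term (larger m -> squarer regions); iteration stops when the
    mean center displacement drops to ``tol`` pixels or after
    ``max_iter`` sweeps.  ``seed`` only matters when k is drawn from the
    default per-image range [800, 1000].
    """

    k: int
    m: float = 10.0
    max_iter: int = 10
    tol: float = 0.1
    seed: int = 0
    original_distance: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.m <= 0:
            raise ValueError("compactness m must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")


class ClusterCenter(NamedTuple):
    """A 5-D SLIC cluster center (color + continuous pixel position)."""

    l: float
    a: float
    b: float
    x: float
    y: float


@dataclass
class SuperpixelSegmentation:
    """A total, connected partition of the raster into superpixels.

    ``labels`` maps every pixel to a region id in [0, k_actual);
    regions are 4-connected and labels consecutive.  ``s`` is the grid
    interval sqrt(N/K) the run was seeded with.
    """

    labels: np.ndarray
    k_actual: int
    params: SlicParams
    s: float

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.k_actual:
            raise ValueError("labels must lie in [0, k_actual)")


def default_k(rng: np.random.Generator, low: int = 800, high: int = 1000) -> int:
    """Draw a per-image superpixel count from the labeling protocol's range."""
    return int(rng.integers(low, high + 1))


def _gradient_magnitude(lab: LabImage) -> np.ndarray:
    g = np.zeros(lab.shape)
    for ch in (lab.l, lab.a, lab.b):
        gy, gx = np.gradient(ch)
        g += gy * gy + gx * gx
    return g


def init_centers(lab: LabImage, params: SlicParams) -> list[ClusterCenter]:
    """Seed ~k centers on a regular grid, then nudge each off local edges.

    The grid has ``nx * ny`` cells chosen so nx*ny is within rounding of
    k, with a center at each cell midpoint.  Each center moves to the
    strictly lowest-gradient position in its 3x3 neighborhood so that no
    seed sits on a color edge; on a uniform image nothing moves.
    """
    h, w = lab.shape
    n = h * w
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds pixel count {n}")
    nx = max(1, int(round(np.sqrt(params.k * w / h))))
    ny = max(1, int(round(params.k / nx)))
    nx, ny = min(nx, w), min(ny, h)
    # snap seeds to pixel positions: avoids systematic half-pixel ties
    xs = ((np.arange(nx) + 0.5) * w / nx).astype(int).astype(float)
    ys = ((np.arange(ny) + 0.5) * h / ny).astype(int).astype(float)
    grad = _gradient_magnitude(lab)
    centers: list[ClusterCenter] = []
    for cy in ys:
        for cx in xs:
            r, c = int(cy), int(cx)
            best_r, best_c = r, c
            best_g = grad[r, c]
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and grad[rr, cc] < best_g:
                        best_g, best_r, best_c = grad[rr, cc], rr, cc
            if (best_r, best_c) == (r, c):
                yy, xx = cy, cx  # keep the sub-pixel grid position
            else:
                yy, xx = float(best_r), float(best_c)
            rr, cc = int(yy), int(xx)
            centers.append(
                ClusterCenter(
                    l=float(lab.l[rr, cc]),
                    a=float(lab.a[rr, cc]),
                    b=float(lab.b[rr, cc]),
                    x=float(xx),
                    y=float(yy),
                )
            )
    return centers


def slic_distance(
    pixel: tuple[float, float, float, float, float],
    center: ClusterCenter,
    m: float,
    s: float,
    original: bool = False,
) -> float:
    """5-D SLIC distance between one pixel (l,a,b,x,y) and one center."""
    if s <= 0:
        raise ValueError("grid interval S must be positive")
    dl, da, db = pixel[0] - center.l, pixel[1] - center.a, pixel[2] - center.b
    dx, dy = pixel[3] - center.x, pixel[4] - center.y
    d_color = float(np.sqrt(dl * dl + da * da + db * db))
    d_xy = float(np.sqrt(dx * dx + dy * dy))
    if original:
        return float(np.sqrt(d_color**2 + (d_xy / s) ** 2 * m**2))
    return d_color + (m / s) * d_xy


def slic_segment(lab: LabImage, params: SlicParams) -> SuperpixelSegmentation:
    """Run SLIC to convergence and return a connected, total label map.

    Each sweep assigns pixels to the minimum-D center searched within a
    2S x 2S window around it (ties go to the lowest center index), then
    re-centers every cluster on the mean of its pixels.  Pixels left
    outside every window (possible once centers drift) are attached to
    the spatially nearest center.  Fragments smaller than (N/K)/4 are
    then merged into their largest 4-adjacent neighbor.
    """
    h, w = lab.shape
    n = h * w
    if n == 0:
        raise ValueError("empty image")
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds pixel count {n}")
    s = float(np.sqrt(n / params.k))
    centers = np.array(init_centers(lab, params), dtype=float)  # (nc, 5) l,a,b,x,y
    nc = len(centers)
    feat = np.stack([lab.l, lab.a, lab.b], axis=-1).astype(float)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    weight = params.m / s

    labels = np.full((h, w), -1, dtype=np.int32)
    for _ in range(params.max_iter):
        best = np.full((h, w), np.inf)
        labels.fill(-1)
        for ci in range(nc):
            cl, ca, cb, cx, cy = centers[ci]
            r0, r1 = max(0, int(cy - s)), min(h, int(cy + s) + 1)
            c0, c1 = max(0, int(cx - s)), min(w, int(cx + s) + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            patch = feat[r0:r1, c0:c1]
            d_color = np.sqrt(
                (patch[..., 0] - cl) ** 2
                + (patch[..., 1] - ca) ** 2
                + (patch[..., 2] - cb) ** 2
            )
            d_xy = np.sqrt(
                (xx[r0:r1, c0:c1] - cx) ** 2 + (yy[r0:r1, c0:c1] - cy) ** 2
            )
            if params.original_distance:
                d = np.sqrt(d_color**2 + (d_xy / s) ** 2 * params.m**2)
            else:
                d = d_color + weight * d_xy
            win_best = best[r0:r1, c0:c1]
            # ties (within fp noise of the center-mean update) keep the
            # lower center index
            better = d < win_best - 1e-9
            win_best[better] = d[better]
            labels[r0:r1, c0:c1][better] = ci

        if (labels < 0).any():
            miss = labels < 0
            my, mx = yy[miss], xx[miss]
            d2 = (my[:, None] - centers[None, :, 4]) ** 2 + (
                mx[:, None] - centers[None, :, 3]
            ) ** 2
            labels[miss] = np.argmin(d2, axis=1)

        flat = labels.ravel()
        counts = np.bincount(flat, minlength=nc).astype(float)
        counts[counts == 0] = np.nan
        new_centers = centers.copy()
        for dim, arr in enumerate((feat[..., 0], feat[..., 1], feat[..., 2], xx, yy)):
            sums = np.bincount(flat, weights=arr.ravel(), minlength=nc)
            new_centers[:, dim] = sums / counts
        stale = np.isnan(new_centers).any(axis=1)
        new_centers[stale] = centers[stale]
        shift = np.sqrt(
            (new_centers[:, 3] - centers[:, 3]) ** 2
            + (new_centers[:, 4] - centers[:, 4]) ** 2
        ).mean()
        centers = new_centers
        if shift <= params.tol:
            break

    min_size = max(1, int((n / params.k) / 4))
    final = enforce_connectivity(labels, min_size)
    return SuperpixelSegmentation(
        labels=final, k_actual=int(final.max()) + 1, params=params, s=s
    )


def enforce_connectivity(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Absorb sub-``min_size`` fragments and renumber labels consecutively.

    Connected components (4-connectivity) of the label map are computed;
    each component smaller than ``min_size`` is relabeled to its largest
    4-adjacent neighboring component (ties to the lowest component id).
    A map with a single region is returned unchanged (renumbered to 0).
    """
    comp = measure.label(labels, connectivity=1, background=labels.min() - 1)
    comp -= 1  # measure.label starts at 1
    ncomp = comp.max() + 1
    sizes = np.bincount(comp.ravel(), minlength=ncomp)
    objects = ndimage.find_objects(comp + 1)
    parent = np.arange(ncomp)

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(sizes, kind="stable")
    h, w = comp.shape
    for ci in order:
        if sizes[root(ci)] >= min_size or root(ci) != ci:
            continue
        sl = objects[ci]
        r0 = max(0, sl[0].start - 1)
        r1 = min(h, sl[0].stop + 1)
        c0 = max(0, sl[1].start - 1)
        c1 = min(w, sl[1].stop + 1)
        sub = comp[r0:r1, c0:c1]
        mask = np.zeros(sub.shape, dtype=bool)
        mask[sub == ci] = True
        # 4-adjacent neighbors of the fragment
        dil = ndimage.binary_dilation(
            mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
        )
        neigh = np.unique(sub[dil & ~mask])
        neigh = np.array([root(x) for x in neigh if root(x) != ci])
        if neigh.size == 0:
            continue  # single-region map: nothing to merge into
        neigh = np.unique(neigh)
        target = neigh[np.argmax(sizes[neigh])]
        sizes[target] += sizes[ci]
        parent[ci] = target

    roots = np.array([root(i) for i in range(ncomp)])
    merged = roots[comp]
    # renumber consecutively by first appearance (row-major): deterministic
    uniq, inv = np.unique(merged, return_inverse=True)
    first_pos = np.full(uniq.size, merged.size, dtype=np.int64)
    flat_inv = inv.ravel()
    np.minimum.at(first_pos, flat_inv, np.arange(flat_inv.size))
    rank = np.argsort(np.argsort(first_pos))
    return rank[inv].reshape(labels.shape).astype(np.int32)


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels whose right or lower 4-neighbor carries a different label."""
    b = np.zeros(labels.shape, dtype=bool)
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    return b


def boundary_recall(
    truth_labels: np.ndarray, pred_labels: np.ndarray, tol_px: float = 2.0
) -> float:
    """Fraction of true boundary pixels within ``tol_px`` of a predicted one."""
    tb = boundary_mask(truth_labels)
    pb = boundary_mask(pred_labels)
    if not tb.any():
        return 1.0
    if not pb.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~pb)
    return float((dist[tb] <= tol_px).mean())


def save_labels(seg: SuperpixelSegmentation, path: str | Path) -> None:
    """Write the label map as 16-bit PNG with a params sidecar JSON."""
    if seg.k_actual > 65535:
        raise ValueError("more than 65535 regions cannot be stored as 16-bit PNG")
    path = Path(path)
    Image.fromarray(seg.labels.astype(np.uint16)).save(str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "k": seg.params.k,
        "m": seg.params.m,
        "max_iter": seg.params.max_iter,
        "tol": seg.params.tol,
        "seed": seg.params.seed,
        "original_distance": seg.params.original_distance,
        "k_actual": seg.k_actual,
        "s": seg.s,
    }, indent=2))


def load_labels(path: str | Path) -> SuperpixelSegmentation:
    """Read a label map written by :func:`save_labels`."""
    path = Path(path)
    labels = np.asarray(Image.open(str(path))).astype(np.int32)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = SlicParams(
        k=meta["k"], m=meta["m"], max_iter=meta["max_iter"], tol=meta["tol"],
        seed=meta["seed"], original_distance=meta["original_distance"],
    )
    return SuperpixelSegmentation(
        labels=labels, k_actual=meta["k_actual"], params=params, s=meta["s"]
    )
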