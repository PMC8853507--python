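"""Synthetic wound scenes with exact ground truth.

The generator emulates the photographic population the labeling
protocol was designed for: a skin-toned background, one organically
shaped ulceration covering ~41.8% of the frame on average, inside
tissue blobs (granulation / slough / eschar) with characteristic
colors, a narrow peri-wound re-epithelialization rim, a smooth
illumination gradient and sensor noise.  Masks record the pre-noise
geometry exactly, so every downstream module can be tested without any
external data.

Shapes come from thresholded low-pass-filtered seeded noise biased
toward the frame center; the threshold is the score quantile that
yields the requested ulceration pixel count, so the area fraction is
exact up to rounding.  Tissue blobs partition the wound by ranking its
pixels on a second smooth field, hitting the mixture weights exactly
while staying spatially coherent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .analysis import ClinicalRecord
from .annotation import LabelMasks
from .image_io import WoundImage

__all__ = ["SceneSpec", "generate_scene", "generate_dataset", "write_dataset"]

import datetime as _dt

#: RGB palette anchors per tissue appearance: granulation beefy red,
#: slough yellow, eschar black-brown, re-ep light pink, skin tone.
DEFAULT_PALETTE = {
    "granulation": (180, 40, 50),
    "slough": (200, 180, 80),
    "eschar": (60, 40, 30),
    "re_ep": (220, 170, 180),
    "skin": (225, 185, 160),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic wound scene.

    ``ulcer_fraction`` is the target wound share of the frame (study
    average 0.418); ``tissue_weights`` the granulation/slough/eschar
    mixture inside the wound; ``rim_width`` the re-ep band in pixels;
    ``noise_sigma`` the 8-bit sensor-noise standard deviation;
    ``illumination`` the relative strength of the linear lighting
    ramp.  Setting noise and illumination to 0 yields piecewise-
    constant scenes for boundary-adherence tests.
    """

    size: tuple[int, int] = (256, 256)
    seed: int = 0
    ulcer_fraction: float = 0.418
    tissue_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    rim_width: int = 6
    noise_sigma: float = 6.0
    illumination: float = 0.15
    color_jitter: int = 10
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))

    def __post_init__(self) -> None:
        if not 0 < self.ulcer_fraction < 1:
            raise ValueError("ulcer_fraction must lie in (0, 1)")
        w = np.asarray(self.tissue_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("tissue_weights must be non-negative and sum to 1")
        if self.rim_width < 0 or self.noise_sigma < 0:
            raise ValueError("rim_width and noise_sigma must be non-negative")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _separated_colors(
    rng: np.random.Generator,
    spec: SceneSpec,
    names: tuple[str, ...],
    min_lab_dist: float,
    max_tries: int = 50,
) -> dict[str, np.ndarray]:
    """Jitter the palette anchors, keeping all class pairs >= min_lab_dist
    apart in CIELAB (redraw on violation; deterministic under the rng)."""
    from skimage import color as _skcolor

    for _ in range(max_tries):
        cols = {
            n: np.clip(
                np.array(spec.palette[n], float)
                + rng.integers(-spec.color_jitter, spec.color_jitter + 1, 3),
                0, 255,
            )
            for n in names
        }
        stacked = np.stack([cols[n] for n in names])[None] / 255.0
        lab = _skcolor.rgb2lab(stacked)[0]
        d = np.linalg.norm(lab[:, None] - lab[None, :], axis=-1)
        d[np.diag_indices(len(names))] = np.inf
        if d.min() >= min_lab_dist:
            return cols
    return {n: np.array(spec.palette[n], float) for n in names}  # pragma: no cover


def generate_scene(spec: SceneSpec) -> tuple[WoundImage, LabelMasks, ClinicalRecord]:
    """Generate one scene: image, exact masks, sampled clinical record.

    Deterministic under ``spec.seed`` (bitwise-identical outputs).
    """
    h, w = spec.size
    n = h * w
    rng = np.random.default_rng(spec.seed)

    # wound shape: smooth noise + central bias, thresholded at the exact quantile
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h / 2 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    r2 = ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2
    score = 0.45 * _smooth_field(rng, (h, w), sigma=min(h, w) / 8) - r2 / r2.std()
    k = int(round(spec.ulcer_fraction * n))
    if k < 1:
        raise ValueError("ulcer_fraction too small for this canvas")
    order = np.argsort(score, axis=None, kind="stable")[::-1]
    ulcer = np.zeros(n, dtype=bool)
    ulcer[order[:k]] = True
    ulcer = ulcer.reshape(h, w)

    # partition the wound into tissue blobs by ranking on a second field
    tissue_field = _smooth_field(rng, (h, w), sigma=min(h, w) / 10)
    inner_vals = tissue_field[ulcer]
    rank = np.argsort(inner_vals, kind="stable")
    wg, ws, we = spec.tissue_weights
    n_g = int(round(wg * k))
    n_s = int(round(ws * k))
    codes = np.zeros(k, dtype=np.uint8)  # 0 gran, 1 slough, 2 eschar
    codes[rank[n_g : n_g + n_s]] = 1
    codes[rank[n_g + n_s :]] = 2
    gran = np.zeros((h, w), dtype=bool)
    slough = np.zeros((h, w), dtype=bool)
    eschar = np.zeros((h, w), dtype=bool)
    gran[ulcer] = codes == 0
    slough[ulcer] = codes == 1
    eschar[ulcer] = codes == 2

    # peri-wound re-epithelialization rim
    if spec.rim_width > 0:
        ry, rx = np.mgrid[-spec.rim_width : spec.rim_width + 1, -spec.rim_width : spec.rim_width + 1]
        disk = ry * ry + rx * rx <= spec.rim_width * spec.rim_width
        re_ep = ndimage.binary_dilation(ulcer, structure=disk) & ~ulcer
    else:
        re_ep = np.zeros((h, w), dtype=bool)

    masks = LabelMasks(
        granulation=gran,
        slough=slough,
        eschar=eschar,
        undefined=np.zeros((h, w), dtype=bool),
        re_ep=re_ep,
    )

    # paint: flat per-class colors with per-scene jitter; redraw until every
    # class pair stays clearly separated in CIELAB so color boundaries in the
    # scene remain well-posed for segmentation
    names = ("skin", "re_ep", "granulation", "slough", "eschar")
    colors = _separated_colors(rng, spec, names, min_lab_dist=12.0)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = colors["skin"]
    for name, m in (
        ("re_ep", re_ep), ("granulation", gran), ("slough", slough), ("eschar", eschar)
    ):
        img[m] = colors[name]

    if spec.illumination > 0:
        theta = rng.uniform(0, 2 * np.pi)
        ramp = ((yy - h / 2) * np.sin(theta) + (xx - w / 2) * np.cos(theta)) / max(h, w)
        img *= (1.0 + spec.illumination * 2 * ramp)[..., None]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # clinical context sampled alongside the scene
    wbc = float(np.round(rng.lognormal(np.log(9_000), 0.3)))
    start = _dt.date(2024, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 365)))
    base_ratio = rng.uniform(0.1, 0.6)
    slope = rng.uniform(-0.08, 0.12)  # per week
    obs = [
        (start + _dt.timedelta(weeks=i),
         float(np.clip(base_ratio + slope * i + rng.normal(0, 0.02), 0.0, 1.0)))
        for i in range(4)
    ]
    clinical = ClinicalRecord(
        wbc=wbc,
        fever=bool(rng.random() < 0.15),
        local_infection_signs=bool(rng.random() < 0.2),
        dressing_change_ongoing=bool(rng.random() < 0.7),
        observations=obs,
    )
    return WoundImage(pixels=pixels, id=f"scene-{spec.seed}"), masks, clinical


def generate_dataset(
    n: int, spec: SceneSpec = SceneSpec(), seed: int = 0
) -> tuple[list[tuple[WoundImage, LabelMasks, ClinicalRecord]], pd.DataFrame]:
    """Generate ``n`` independently seeded scenes plus a manifest.

    The manifest records per-scene seeds and mask pixel counts.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    scenes = []
    rows = []
    for i, s in enumerate(child_seeds):
        sc = dataclasses.replace(spec, seed=int(s))
        image, masks, clinical = generate_scene(sc)
        scenes.append((image, masks, clinical))
        row = {"scene": image.id, "seed": int(s)}
        row.update(masks.pixel_counts())
        rows.append(row)
    return scenes, pd.DataFrame(rows)


def write_dataset(
    n: int, outdir: str | Path, spec: SceneSpec = SceneSpec(), seed: int = 0
) -> pd.DataFrame:
    """Generate and write scenes (PNG + label-map PNG + clinical JSON)."""
    from .annotation import write_label_png
    from .image_io import write_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenes, manifest = generate_dataset(n, spec, seed)
    for i, (image, masks, clinical) in enumerate(scenes):
        stem = outdir / f"{i:04d}"
        write_image(image, stem.with_suffix(".png"))
        write_label_png(masks.to_categorical(), Path(f"{stem}_labels.png"))
        clinical.to_json(Path(f"{stem}_clinical.json"))
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
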