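"""Wound-size estimation, healing indicators, and debridement decision logic.

Size estimation uses the pinhole projection: an image captured at
distance D with sensor side ``sensor_size`` and focal distance f covers
a physical length

    Length = D * sensor_size / f,        A = Length^2 * aspect_ratio

on the object plane, and the wound area is the wound's pixel fraction
of that projection, A_wound = (P_wound / P_image) * A_x.  Healing is
tracked by the presence of re-epithelialization adjacent to the wound
and by the granulation-to-ulceration area ratio (G/U) and its trend.
The debridement recommendation combines three boolean checks —
necrotic tissue on segmentation, infection from clinical data
(WBC > 12 000/mm^3, fever, or local signs), and a stalled G/U trend
under ongoing dressing changes — through a configurable rule table.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotation import LabelMasks

__all__ = [
    "CameraParams",
    "ClinicalRecord",
    "DecisionConfig",
    "DiagnosisReport",
    "image_projection_area",
    "rescale_area",
    "wound_area",
    "gu_ratio",
    "gu_trend",
    "detect_healing",
    "suggest_debridement",
    "diagnose",
]

IMPROVING, STABLE, WORSENING = "improving", "stable", "worsening"
CONTINUE, REVIEW, DEBRIDE = "continue_dressing", "clinical_review", "debride"


@dataclass(frozen=True)
class CameraParams:
    """Capture geometry: all lengths in millimetres.

    ``distance`` is camera-to-wound distance D; ``sensor_size`` the
    sensor extent along the measured (long) side; ``focal_distance``
    the lens focal distance; ``aspect_ratio`` the frame height/width
    fraction (0.75 for 4:3).
    """

    distance: float
    sensor_size: float
    focal_distance: float
    aspect_ratio: float = 0.75

    def __post_init__(self) -> None:
        for name in ("distance", "sensor_size", "focal_distance", "aspect_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ClinicalRecord:
    """Clinical context for one patient/wound; None means not recorded."""

    wbc: float | None = None  # cells per mm^3
    fever: bool | None = None
    local_infection_signs: bool | None = None
    dressing_change_ongoing: bool | None = None
    observations: list[tuple[_dt.date, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.wbc is not None and self.wbc < 0:
            raise ValueError("wbc must be non-negative")
        dates = [d for d, _ in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("observations must be strictly increasing in date")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "wbc": self.wbc,
            "fever": self.fever,
            "local_infection_signs": self.local_infection_signs,
            "dressing_change_ongoing": self.dressing_change_ongoing,
            "observations": [[d.isoformat(), r] for d, r in self.observations],
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClinicalRecord":
        d = json.loads(Path(path).read_text())
        obs = [(_dt.date.fromisoformat(x), float(r)) for x, r in d.get("observations", [])]
        return cls(
            wbc=d.get("wbc"),
            fever=d.get("fever"),
            local_infection_signs=d.get("local_infection_signs"),
            dressing_change_ongoing=d.get("dressing_change_ongoing"),
            observations=obs,
        )


def image_projection_area(camera: CameraParams) -> float:
    """Physical area (mm^2) covered by the full frame at the object plane."""
    length = camera.distance * camera.sensor_size / camera.focal_distance
    return length * length * camera.aspect_ratio


def rescale_area(a: float, d: float, dx: float, exponent: int = 2) -> float:
    """Rescale a projection area from capture distance d to distance dx.

    The pinhole model implies area scales with distance squared
    (exponent 2, the default); exponent 1 gives the literal linear
    rescaling A_x = A * Dx / D.
    """
    if d <= 0 or dx <= 0:
        raise ValueError("distances must be strictly positive")
    if exponent not in (1, 2):
        raise ValueError("exponent must be 1 or 2")
    return a * (dx / d) ** exponent


def wound_area(p_wound: int, p_image: int, a_x: float) -> float:
    """A_wound = (P_wound / P_image) * A_x in mm^2."""
    if p_image <= 0:
        raise ValueError("p_image must be positive")
    if not 0 <= p_wound <= p_image:
        raise ValueError("p_wound must lie in [0, p_image]")
    return (p_wound / p_image) * a_x


def gu_ratio(masks: LabelMasks) -> float:
    """Granulation/ulceration area fraction; NaN if the wound is empty."""
    u = int(masks.ulceration.sum())
    if u == 0:
        return float("nan")
    return int(masks.granulation.sum()) / u


def gu_trend(
    observations: Sequence[tuple[_dt.date, float]] | Sequence[tuple[float, float]],
    window: int | None = None,
    delta: float = 0.01,
) -> str | None:
    """Classify the G/U time course by its least-squares slope per week.

    ``observations`` are (date, ratio) pairs (dates or day offsets).
    Slope > +delta per week -> improving; < -delta -> worsening; else
    stable.  Returns None (insufficient data) with fewer than two
    points.
    """
    obs = list(observations)
    if window is not None:
        if window < 2:
            raise ValueError("window must be at least 2")
        obs = obs[-window:]
    if len(obs) < 2:
        return None
    t0 = obs[0][0]
    if isinstance(t0, (_dt.date, _dt.datetime)):
        weeks = np.array([(d - t0).days / 7.0 for d, _ in obs])
    else:
        weeks = np.array([float(d) / 7.0 for d, _ in obs])
    ratios = np.array([r for _, r in obs], dtype=float)
    slope = float(np.polyfit(weeks, ratios, 1)[0])
    if slope > delta:
        return IMPROVING
    if slope < -delta:
        return WORSENING
    return STABLE


def detect_healing(
    masks: LabelMasks, min_pixels: int = 50, adjacency_radius: int = 5
) -> bool:
    """True iff enough re-ep lies adjacent to the wound.

    Adjacency is a morphological dilation of the ulceration by a disk
    of ``adjacency_radius`` pixels; at least ``min_pixels`` re-ep
    pixels must fall inside the dilated band.
    """
    if not masks.re_ep.any() or not masks.ulceration.any():
        return False
    yy, xx = np.mgrid[-adjacency_radius : adjacency_radius + 1, -adjacency_radius : adjacency_radius + 1]
    disk = yy * yy + xx * xx <= adjacency_radius * adjacency_radius
    near = ndimage.binary_dilation(masks.ulceration, structure=disk)
    return int((masks.re_ep & near).sum()) >= min_pixels


@dataclass(frozen=True)
class DecisionConfig:
    """Thresholds and rule table for the debridement recommendation.

    The rule table maps the boolean triple (necrotic, infection,
    stalled) to a recommendation; the default encodes: debride iff
    necrotic and (infection or stalled); clinical review iff infection
    without necrosis; otherwise continue dressing changes.
    """

    wbc_threshold: float = 12_000.0
    necrosis_threshold: float = 0.05
    trend_delta: float = 0.01
    adjacency_radius: int = 5
    min_re_ep_pixels: int = 50
    area_exponent: int = 2
    rules: tuple = ()  # ((necrotic, infection, stalled) -> recommendation)

    def rule_table(self) -> dict[tuple[bool, bool, bool], str]:
        if self.rules:
            return {tuple(k): v for k, v in self.rules}
        table = {}
        for nec, inf, sta in product((False, True), repeat=3):
            if nec and (inf or sta):
                table[(nec, inf, sta)] = DEBRIDE
            elif inf and not nec:
                table[(nec, inf, sta)] = REVIEW
            else:
                table[(nec, inf, sta)] = CONTINUE
        return table


@dataclass
class DiagnosisReport:
    """Aggregate wound-status output for one image + clinical record."""

    healing_initiated: bool
    gu_ratio: float
    gu_trend: str | None
    wound_area_mm2: float | None
    recommendation: str
    reasons: list[str]

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["gu_ratio"], float) and math.isnan(d["gu_ratio"]):
            d["gu_ratio"] = None
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        lines = [
            f"healing initiated : {'yes' if self.healing_initiated else 'no'}",
            f"G/U ratio         : {self.gu_ratio:.3f}" if not math.isnan(self.gu_ratio)
            else "G/U ratio         : undefined (no wound)",
            f"G/U trend         : {self.gu_trend or 'insufficient data'}",
            f"wound area        : "
            + (f"{self.wound_area_mm2:.0f} mm^2" if self.wound_area_mm2 is not None
               else "unknown (no camera metadata)"),
            f"recommendation    : {self.recommendation}",
            f"reasons           : {', '.join(self.reasons) or 'none'}",
        ]
        return "\n".join(lines)


def _checks(
    masks: LabelMasks, clinical: ClinicalRecord, config: DecisionConfig
) -> tuple[dict[str, bool | None], list[str]]:
    reasons: list[str] = []
    u = int(masks.ulceration.sum())
    necrotic_px = int(masks.eschar.sum()) + int(masks.slough.sum())
    necrotic: bool | None
    if u == 0:
        necrotic = False
    else:
        necrotic = necrotic_px / u > config.necrosis_threshold
    if necrotic:
        reasons.append(f"necrotic: eschar+slough {necrotic_px / max(u, 1):.0%} of ulceration")

    flags = []
    if clinical.wbc is not None:
        flags.append(clinical.wbc > config.wbc_threshold)
        if clinical.wbc > config.wbc_threshold:
            reasons.append(f"infection: WBC {clinical.wbc:.0f}/mm^3 > {config.wbc_threshold:.0f}")
    else:
        flags.append(None)
    for name, val in (("fever", clinical.fever), ("local signs", clinical.local_infection_signs)):
        flags.append(val)
        if val:
            reasons.append(f"infection: {name}")
    if any(f is True for f in flags):
        infection: bool | None = True
    elif any(f is None for f in flags):
        infection = None
        reasons.append("unknown_infection: incomplete clinical data")
    else:
        infection = False

    trend = gu_trend(clinical.observations, delta=config.trend_delta)
    if clinical.dressing_change_ongoing is None or trend is None:
        stalled: bool | None = None
        reasons.append("unknown_stalled: dressing status or G/U history missing")
    else:
        stalled = bool(clinical.dressing_change_ongoing) and trend in (STABLE, WORSENING)
        if stalled:
            reasons.append(f"stalled: G/U {trend} under ongoing dressing change")
    return {"necrotic": necrotic, "infection": infection, "stalled": stalled}, reasons


def suggest_debridement(
    masks: LabelMasks,
    clinical: ClinicalRecord,
    config: DecisionConfig = DecisionConfig(),
) -> DiagnosisReport:
    """Map the three checks through the rule table to a recommendation.

    Unknown checks (missing clinical fields) are propagated, never
    treated as false: every completion of the unknowns is evaluated,
    and if the recommendation is not invariant the report escalates to
    clinical review with the unknowns listed among the reasons.
    """
    checks, reasons = _checks(masks, clinical, config)
    table = config.rule_table()
    options = [
        (True, False) if v is None else (bool(v),) for v in
        (checks["necrotic"], checks["infection"], checks["stalled"])
    ]
    outcomes = {table[combo] for combo in product(*options)}
    recommendation = outcomes.pop() if len(outcomes) == 1 else REVIEW
    trend = gu_trend(clinical.observations, delta=config.trend_delta)
    return DiagnosisReport(
        healing_initiated=detect_healing(
            masks, config.min_re_ep_pixels, config.adjacency_radius
        ),
        gu_ratio=gu_ratio(masks),
        gu_trend=trend,
        wound_area_mm2=None,
        recommendation=recommendation,
        reasons=reasons,
    )


def diagnose(
    masks: LabelMasks,
    clinical: ClinicalRecord,
    camera: CameraParams | None = None,
    config: DecisionConfig = DecisionConfig(),
) -> DiagnosisReport:
    """Full wound-status report; adds the metric wound size when camera
    metadata is available."""
    report = suggest_debridement(masks, clinical, config)
    if camera is not None:
        a = image_projection_area(camera)
        a_x = rescale_area(a, camera.distance, camera.distance, config.area_exponent)
        report.wound_area_mm2 = wound_area(
            int(masks.ulceration.sum()), int(np.prod(masks.shape)), a_x
        )
    return report
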