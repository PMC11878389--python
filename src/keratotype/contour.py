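"""Examiner-style contours of the colored corneal relief.

In clinical use the examiner traces the bow-tie (or, for a spherical
cornea, a peripheral ring) on the touch screen, following one color shade
through both semimeridians.  For synthetic data an automatic "examiner
oracle" stands in: iso-power level-set polylines extracted from the
ground-truth power map at half the peak elevation above the base power,
which by construction follows the same color shade through both lobes.
Geometric bow-tie descriptors (lobe lengths, widths, steep axis,
inter-meridian angle, symmetry ratio) feed a rule-based reference
classifier that anchors synthetic label quality independently of the CNN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import skimage.measure

from . import synth
from .synth import ClassLabel, PowerMap, SurfaceParams

PERIPHERAL_RING_FRACTION = 0.95  # of the 7-mm zone radius
MIN_VERTICES = 8
MIN_LOBE_AREA_MM2 = 0.02
MINOR_LOBE_AREA_FRACTION = 0.08  # below this fraction of the largest lobe: ignore


class DegeneratePatternError(ValueError):
    """Pattern amplitude below one color step; iso-contour is undefined."""


@dataclass
class Contour:
    """Closed polylines (mm, canonical frame, +y superior) with the iso level."""

    polylines: List[np.ndarray]
    level: Optional[float] = None
    kind: str = "iso"  # "iso" or "peripheral"

    def to_json(self) -> str:
        return json.dumps(
            {
                "level": self.level,
                "kind": self.kind,
                "polylines": [p.tolist() for p in self.polylines],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Contour":
        d = json.loads(text)
        return cls(
            polylines=[np.asarray(p, dtype=float) for p in d["polylines"]],
            level=d.get("level"),
            kind=d.get("kind", "iso"),
        )


@dataclass
class RuleThresholds:
    """Decision thresholds for the rule-based reference classifier."""

    symmetry_ratio: float = 0.75  # >= : symmetric tie
    irregular_ratio_floor: float = 0.35  # < : rudimentary half, irregular
    perpendicularity_tol_deg: float = 15.0  # |angle - 90| beyond: skewed axes
    reach_mm: float = 2.5  # ties confined to the 5-mm zone: irregular


@dataclass
class ShapeFeatures:
    """Geometric descriptors of a traced contour."""

    lobe_count: int
    lobe_lengths: List[float] = field(default_factory=list)  # mm, max radial reach
    base_widths: List[float] = field(default_factory=list)  # mm
    steep_axis: float = 0.0  # degrees mod 180
    inter_meridian_angle: float = 90.0  # degrees; 90 = perpendicular meridians
    symmetry_ratio: float = 1.0  # min/max paired lobe length
    reach_zone: str = "7"  # "3" | "5" | "7"
    peripheral_only: bool = False


# ---------------------------------------------------------------------------
# Polygon helpers
# ---------------------------------------------------------------------------


def _polygon_area(p: np.ndarray) -> float:
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _perimeter(p: np.ndarray) -> float:
    return float(np.sum(np.hypot(*(np.diff(np.vstack([p, p[:1]]), axis=0).T))))


def circularity(p: np.ndarray) -> float:
    """4 * pi * area / perimeter^2; 1 for a circle."""
    per = _perimeter(p)
    return 4.0 * math.pi * _polygon_area(p) / max(per**2, 1e-12)


def _centroid(p: np.ndarray) -> np.ndarray:
    return p.mean(axis=0)


def _is_peripheral_ring(p: np.ndarray) -> bool:
    c = _centroid(p)
    radii = np.hypot(p[:, 0], p[:, 1])
    return (
        float(np.hypot(*c)) < 0.5
        and float(radii.mean()) > 2.8
        and circularity(p) > 0.85
    )


# ---------------------------------------------------------------------------
# Oracle contour
# ---------------------------------------------------------------------------


def _px_to_mm(rc: np.ndarray, grid_n: int, mm_per_px: float) -> np.ndarray:
    c = (grid_n - 1) / 2.0
    x = (rc[:, 1] - c) * mm_per_px
    y = (c - rc[:, 0]) * mm_per_px
    return np.column_stack([x, y])


def peripheral_ring(radius_mm: Optional[float] = None, n_vertices: int = 180) -> np.ndarray:
    if radius_mm is None:
        radius_mm = PERIPHERAL_RING_FRACTION * synth.ZONE_RADII_MM[-1]
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([radius_mm * np.cos(t), radius_mm * np.sin(t)])


def oracle_contour(
    pm: PowerMap, label: Optional[ClassLabel] = None, min_level_step: float = None
) -> Contour:
    """Automatic examiner-oracle contour of a ground-truth power map.

    For the tie/cone classes the iso-power level is k0 + half the peak
    elevation, so both semimeridian lobes are traced at one color shade;
    for a spherical pattern the examiner's peripheral outline is a circle
    at 95% of the 7-mm zone radius.  Deterministic.
    """
    if pm.params is None:
        raise ValueError("power map carries no generating params")
    params: SurfaceParams = pm.params
    label = ClassLabel(label) if label is not None else params.label
    if min_level_step is None:
        min_level_step = synth.ColorScale().step

    if label is ClassLabel.SPHERICAL:
        return Contour(polylines=[peripheral_ring()], level=None, kind="peripheral")

    peak = params.peak_amplitude()
    if peak < min_level_step:
        raise DegeneratePatternError(
            f"peak amplitude {peak:.2f} D below one color step ({min_level_step} D)"
        )
    level = params.k0 + 0.5 * peak
    raw = skimage.measure.find_contours(pm.values, level)
    polys = []
    for rc in raw:
        closed = np.allclose(rc[0], rc[-1])
        if not closed or len(rc) < MIN_VERTICES:
            continue
        p = _px_to_mm(rc[:-1], pm.grid_n, pm.mm_per_px)
        if _polygon_area(p) < MIN_LOBE_AREA_MM2:
            continue
        polys.append(p)
    if not polys:
        raise DegeneratePatternError("iso-power level set is empty")
    return Contour(polylines=polys, level=level, kind="iso")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize(
    c: Contour, n: int, thickness_px: int = 2, fill: bool = False, mm_per_px: float = None
) -> np.ndarray:
    """Burn a contour into an n x n binary raster (canonical frame).

    Stroke of ``thickness_px``; ``fill=True`` additionally fills each
    closed polyline.  Deterministic.
    """
    import skimage.draw
    import skimage.morphology

    if mm_per_px is None:
        mm_per_px = 2.0 * synth.DISC_RADIUS_MM / n
    mask = np.zeros((n, n), dtype=bool)
    cc = (n - 1) / 2.0
    for p in c.polylines:
        col = p[:, 0] / mm_per_px + cc
        row = cc - p[:, 1] / mm_per_px
        if fill:
            rr, ccol = skimage.draw.polygon(row, col, shape=(n, n))
            mask[rr, ccol] = True
        ri = np.round(row).astype(int)
        ci = np.round(col).astype(int)
        for i in range(len(p)):
            j = (i + 1) % len(p)
            rr, ccol = skimage.draw.line(ri[i], ci[i], ri[j], ci[j])
            keep = (rr >= 0) & (rr < n) & (ccol >= 0) & (ccol < n)
            mask[rr[keep], ccol[keep]] = True
    if thickness_px > 1:
        mask = skimage.morphology.dilation(mask, skimage.morphology.disk(thickness_px // 2))
    return mask


# ---------------------------------------------------------------------------
# Shape features and rule classifier
# ---------------------------------------------------------------------------


def _lobe_direction_deg(p: np.ndarray) -> float:
    c = _centroid(p)
    return math.degrees(math.atan2(c[1], c[0])) % 360.0


def _lobe_width(p: np.ndarray, direction_deg: float) -> float:
    a = math.radians(direction_deg)
    perp = np.array([-math.sin(a), math.cos(a)])
    proj = p @ perp
    return float(proj.max() - proj.min())


def shape_features(c: Contour) -> ShapeFeatures:
    """Bow-tie geometry of a contour.

    Lobes are the closed polylines excluding a spherical peripheral ring;
    minor blobs below 8% of the largest lobe's area are ignored (they are
    noise wiggles or a rudimentary remnant, which the lobe count already
    reflects).  Degenerate situations are flagged in the fields rather
    than raised.
    """
    rings = [p for p in c.polylines if c.kind == "peripheral" or _is_peripheral_ring(p)]
    lobes = [p for p in c.polylines if not any(p is q for q in rings)]
    if lobes:
        areas = np.array([_polygon_area(p) for p in lobes])
        keep = areas >= MINOR_LOBE_AREA_FRACTION * areas.max()
        lobes = [p for p, k in zip(lobes, keep) if k]
        lobes.sort(key=_polygon_area, reverse=True)

    f = ShapeFeatures(lobe_count=len(lobes), peripheral_only=bool(rings) and not lobes)
    if not lobes:
        return f
    f.lobe_lengths = [float(np.hypot(p[:, 0], p[:, 1]).max()) for p in lobes]
    dirs = [_lobe_direction_deg(p) for p in lobes]
    f.base_widths = [_lobe_width(p, d) for p, d in zip(lobes, dirs)]
    longest = int(np.argmax(f.lobe_lengths))
    f.steep_axis = dirs[longest] % 180.0
    max_len = max(f.lobe_lengths)
    f.reach_zone = "3" if max_len <= 1.5 else ("5" if max_len <= 2.5 else "7")
    if len(lobes) >= 2:
        l1, l2 = sorted(f.lobe_lengths, reverse=True)[:2]
        f.symmetry_ratio = float(min(l1, l2) / max(l1, l2))
        d = abs(dirs[0] - dirs[1]) % 360.0
        d = min(d, 360.0 - d)  # angle between the two lobe directions
        # a perfect tie has opposed lobes (180 apart) => meridians at 90
        f.inter_meridian_angle = d / 2.0
    return f


def rule_classify(f: ShapeFeatures, thresholds: Optional[RuleThresholds] = None) -> ClassLabel:
    """Decision-list reference classifier over contour shape features.

    Peripheral-only (or empty) trace: spherical.  A single lobe, skewed
    radial axes, a rudimentary second half (length ratio below the floor)
    or a small tie confined to the 5-mm zone: irregular.  Otherwise a
    two-lobe tie is symmetric when the length ratio reaches the symmetry
    threshold (ties break toward the less severe class), else asymmetric.
    """
    t = thresholds or RuleThresholds()
    if f.lobe_count == 0 or f.peripheral_only:
        return ClassLabel.SPHERICAL
    if f.lobe_count == 1:
        return ClassLabel.IRREGULAR
    if abs(f.inter_meridian_angle - 90.0) > t.perpendicularity_tol_deg:
        return ClassLabel.IRREGULAR
    if f.symmetry_ratio < t.irregular_ratio_floor:
        return ClassLabel.IRREGULAR
    if max(f.lobe_lengths) <= t.reach_mm:
        return ClassLabel.IRREGULAR
    if f.symmetry_ratio >= t.symmetry_ratio:
        return ClassLabel.SYMMETRIC
    return ClassLabel.ASYMMETRIC
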