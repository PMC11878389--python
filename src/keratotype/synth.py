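"""Synthetic corneal topogram generation.

Generates labeled axial-power maps for the four diagnostic pattern classes
(spherical, regular symmetric astigmatism, regular asymmetric astigmatism,
irregular astigmatism / keratoconus), renders them as color-coded topograms
with 3/5/7-mm reference zone rings, and simulates perspective-distorted
"smartphone captures" with known ground-truth corner quads.

The axial power surface is

    K(r, theta) = k0
                + sum over semimeridian lobes i of
                      A_i * max(cos(theta - a_i), 0)^2 * w(r / extent_i)
                + cone_dk * exp(-d((r,theta), cone center)^2 / (2 sigma^2))
                + central_dk * exp(-r^2 / (2 central_sigma^2))
                + smooth noise field (seeded random Fourier features)

with w(x) = x^2 * exp(1 - x^2), a radial window that is 0 at the apex,
peaks (value 1) at r = extent and decays smoothly beyond, so a bow-tie lobe
"reaches" roughly 1.6 * extent at the half-amplitude color shade.  Lobe
directions are a_sup = phi and a_inf = phi + 180 + skew, so skew_deg != 0
produces the skewed-radial-axes (loss of perpendicularity) morphology.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

DISC_RADIUS_MM = 4.5
ZONE_RADII_MM = (1.5, 2.5, 3.5)  # 3-, 5-, 7-mm zones (diameters / 2)
CANONICAL_N = 256
DEFAULT_K0_LOW, DEFAULT_K0_HIGH = 42.8, 44.2
DEFAULT_NOISE_SD = 0.15  # diopters


class ClassLabel(str, enum.Enum):
    """The four diagnostic topographic pattern classes."""

    SPHERICAL = "SPHERICAL"
    SYMMETRIC = "SYMMETRIC"
    ASYMMETRIC = "ASYMMETRIC"
    IRREGULAR = "IRREGULAR"  # keratoconus; the screening-positive class


CLASS_ORDER = (
    ClassLabel.SPHERICAL,
    ClassLabel.SYMMETRIC,
    ClassLabel.ASYMMETRIC,
    ClassLabel.IRREGULAR,
)


class Variant(str, enum.Enum):
    """Sub-patterns within a class.

    Post-refractive-surgery variants are spherical-pattern differential
    diagnoses (flatter/colder center after myopic ablation, steeper/warmer
    after hyperopic).  The five irregular variants follow the classic
    keratoconus presentations: localized inferior steepening, skewed radial
    axes, pellucid marginal degeneration (inferior arc), a small symmetric
    tie confined to the 5-mm zone, and a rudimentary ("amputated") superior
    semimeridian.
    """

    NONE = "NONE"
    POST_MYOPIC = "POST_MYOPIC"
    POST_HYPEROPIC = "POST_HYPEROPIC"
    CLASSIC_INFERIOR = "CLASSIC_INFERIOR"
    SKEWED = "SKEWED"
    PELLUCID = "PELLUCID"
    INCOMPLETE_TIE = "INCOMPLETE_TIE"
    RUDIMENTARY_TIE = "RUDIMENTARY_TIE"


VARIANTS_BY_LABEL = {
    ClassLabel.SPHERICAL: (Variant.NONE, Variant.POST_MYOPIC, Variant.POST_HYPEROPIC),
    ClassLabel.SYMMETRIC: (Variant.NONE,),
    ClassLabel.ASYMMETRIC: (Variant.NONE,),
    ClassLabel.IRREGULAR: (
        Variant.CLASSIC_INFERIOR,
        Variant.SKEWED,
        Variant.PELLUCID,
        Variant.INCOMPLETE_TIE,
        Variant.RUDIMENTARY_TIE,
    ),
}

# Default variant mix per class.  The irregular mix weights the classic
# inferior cone most heavily, with the four rarer presentations equal.
DEFAULT_VARIANT_POLICY = {
    ClassLabel.SPHERICAL: {
        Variant.NONE: 0.70,
        Variant.POST_MYOPIC: 0.15,
        Variant.POST_HYPEROPIC: 0.15,
    },
    ClassLabel.SYMMETRIC: {Variant.NONE: 1.0},
    ClassLabel.ASYMMETRIC: {Variant.NONE: 1.0},
    ClassLabel.IRREGULAR: {
        Variant.CLASSIC_INFERIOR: 0.40,
        Variant.SKEWED: 0.15,
        Variant.PELLUCID: 0.15,
        Variant.INCOMPLETE_TIE: 0.15,
        Variant.RUDIMENTARY_TIE: 0.15,
    },
}

# Minimum relative lobe difference for a well-posed ASYMMETRIC label, and
# minimum skew for the loss-of-perpendicularity irregular variant.
MIN_ASYMMETRY = 0.25
MIN_SKEW_DEG = 30.0


class ConfigError(ValueError):
    """Invalid generator configuration (e.g. variant unknown for a label)."""


class DomainError(ValueError):
    """Coordinate outside the corneal disc."""


@dataclass
class SurfaceParams:
    """Ground-truth parameters of one synthetic corneal surface."""

    label: ClassLabel
    variant: Variant = Variant.NONE
    k0: float = 43.5  # base power, diopters
    amp_sup: float = 0.0  # superior semimeridian astigmatic amplitude, D
    amp_inf: float = 0.0  # inferior semimeridian amplitude, D
    axis_phi: float = 90.0  # steep-meridian axis, degrees in [0, 180)
    radial_extent_sup: float = 2.0  # mm, superior lobe reach scale
    radial_extent_inf: float = 2.0  # mm
    cone_dk: float = 0.0  # cone peak elevation above k0, D
    cone_r: float = 0.0  # cone center radius, mm
    cone_theta: float = 270.0  # cone center angle, degrees
    cone_sigma: float = 1.0  # cone radial width, mm
    cone_arc_mm: Optional[float] = None  # tangential smear for arc cones (pellucid)
    central_dk: float = 0.0  # post-refractive central power change, D
    central_sigma: float = 1.5  # mm
    skew_deg: float = 0.0  # inferior-lobe axis deviation from phi+180
    noise_sd: float = DEFAULT_NOISE_SD  # D
    noise_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["label"] = self.label.value
        d["variant"] = self.variant.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceParams":
        d = dict(d)
        d["label"] = ClassLabel(d["label"])
        d["variant"] = Variant(d["variant"])
        return cls(**d)

    def peak_amplitude(self) -> float:
        """Largest positive elevation above k0 (drives the contour level)."""
        return max(self.amp_sup, self.amp_inf, self.cone_dk)


@dataclass
class PowerMap:
    """Axial power sampled on a centered Cartesian grid.

    ``values`` is finite everywhere; ``mask`` marks pixels inside the
    corneal disc (radius 4.5 mm).  ``params`` keeps the generating ground
    truth so downstream stages (examiner-oracle contour) can use it.
    """

    values: np.ndarray
    mask: np.ndarray
    grid_n: int
    mm_per_px: float
    params: Optional[SurfaceParams] = None

    def mm_grid(self):
        """(x, y) coordinate grids in mm; +y is superior (image top)."""
        c = (self.grid_n - 1) / 2.0
        idx = np.arange(self.grid_n)
        x = (idx[None, :] - c) * self.mm_per_px
        y = (c - idx[:, None]) * self.mm_per_px
        return np.broadcast_to(x, self.values.shape), np.broadcast_to(y, self.values.shape)


@dataclass
class ColorScale:
    """Absolute diopter-to-color lookup, cold (blue) to warm (red)."""

    k_min: float = 35.0
    k_max: float = 52.0
    step: float = 1.5
    colors: Sequence[tuple] = field(default_factory=list)

    def __post_init__(self):
        n = self.n_bins
        if not self.colors:
            import colorsys

            cols = []
            for i in range(n):
                hue = 240.0 * (1.0 - i / (n - 1)) / 360.0  # blue -> red
                r, g, b = colorsys.hsv_to_rgb(hue, 1.0, 1.0)
                cols.append((int(round(r * 255)), int(round(g * 255)), int(round(b * 255))))
            self.colors = tuple(cols)
        if len(self.colors) != n:
            raise ConfigError(f"need {n} colors, got {len(self.colors)}")

    @property
    def n_bins(self) -> int:
        return int(math.ceil((self.k_max - self.k_min) / self.step))

    def bin_of(self, k) -> np.ndarray:
        """Bin index of power k after clipping to the scale span."""
        k = np.asarray(k, dtype=float)
        b = np.floor((k - self.k_min) / self.step).astype(int)
        return np.clip(b, 0, self.n_bins - 1)

    def lut(self) -> np.ndarray:
        return np.asarray(self.colors, dtype=np.uint8)


@dataclass
class Topogram:
    """Rendered color topogram plus its ground-truth sidecar metadata."""

    image: np.ndarray  # (n, n, 3) uint8
    zones_px: tuple  # 3/5/7-mm ring radii in pixels (floats, exact 3:5:7)
    sidecar: dict


# ---------------------------------------------------------------------------
# Surface model
# ---------------------------------------------------------------------------


def _noise_field(params: SurfaceParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth seeded noise as random Fourier features (a pure function of x,y).

    Approximates a Gaussian random field with ~0.8 mm correlation length and
    marginal s.d. ``noise_sd``.
    """
    if params.noise_sd <= 0:
        return np.zeros_like(x)
    m = 12
    rng = np.random.default_rng(params.noise_seed)
    omega = rng.normal(0.0, 1.0 / 0.8, size=(m, 2))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
    out = np.zeros_like(x, dtype=float)
    for j in range(m):
        out += np.cos(omega[j, 0] * x + omega[j, 1] * y + phase[j])
    return params.noise_sd * math.sqrt(2.0 / m) * out


def _radial_window(r: np.ndarray, extent: float) -> np.ndarray:
    xr = r / max(extent, 1e-9)
    return xr**2 * np.exp(1.0 - xr**2)


def _power_unchecked(params: SurfaceParams, r, theta_deg) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    k = np.full(np.broadcast_shapes(r.shape, th.shape), params.k0, dtype=float)
    r, th = np.broadcast_to(r, k.shape), np.broadcast_to(th, k.shape)

    lobes = []
    if params.amp_sup > 0:
        lobes.append((params.amp_sup, math.radians(params.axis_phi), params.radial_extent_sup))
    if params.amp_inf > 0:
        a_inf = math.radians(params.axis_phi + 180.0 + params.skew_deg)
        lobes.append((params.amp_inf, a_inf, params.radial_extent_inf))
    for amp, a, ext in lobes:
        c = np.maximum(np.cos(th - a), 0.0)
        k = k + amp * c * c * _radial_window(r, ext)

    if params.cone_dk > 0:
        thc = math.radians(params.cone_theta)
        if params.cone_arc_mm is None:
            xc, yc = params.cone_r * math.cos(thc), params.cone_r * math.sin(thc)
            x, y = r * np.cos(th), r * np.sin(th)
            d2 = ((x - xc) ** 2 + (y - yc) ** 2) / (2.0 * params.cone_sigma**2)
        else:
            dth = np.angle(np.exp(1j * (th - thc)))
            d2 = (r - params.cone_r) ** 2 / (2.0 * params.cone_sigma**2) + (
                params.cone_r * dth
            ) ** 2 / (2.0 * params.cone_arc_mm**2)
        k = k + params.cone_dk * np.exp(-d2)

    if params.central_dk != 0:
        k = k + params.central_dk * np.exp(-(r**2) / (2.0 * params.central_sigma**2))

    if params.noise_sd > 0:
        x, y = r * np.cos(th), r * np.sin(th)
        k = k + _noise_field(params, x, y)
    return k


def eval_power(params: SurfaceParams, r, theta_deg):
    """Axial power K(r, theta) in diopters; r in mm, theta in degrees.

    Deterministic given ``params`` (the noise field is a fixed seeded
    function of position).  Raises :class:`DomainError` outside the
    4.5-mm-radius disc.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > DISC_RADIUS_MM):
        raise DomainError(f"r must lie in [0, {DISC_RADIUS_MM}] mm")
    out = _power_unchecked(params, r_arr, theta_deg)
    if np.isscalar(r) and np.isscalar(theta_deg):
        return float(out)
    return out


def make_power_map(
    params: SurfaceParams, grid_n: int = CANONICAL_N, mm_per_px: Optional[float] = None
) -> PowerMap:
    """Sample the surface on a centered grid; pixels beyond 4.5 mm are masked."""
    if grid_n < 64:
        raise ConfigError("grid_n must be >= 64")
    if mm_per_px is None:
        mm_per_px = 2.0 * DISC_RADIUS_MM / grid_n
    c = (grid_n - 1) / 2.0
    idx = np.arange(grid_n)
    x = (idx[None, :] - c) * mm_per_px
    y = (c - idx[:, None]) * mm_per_px
    r = np.hypot(x, y)
    theta = np.rad2deg(np.arctan2(y, x))
    values = _power_unchecked(params, r, theta)
    mask = r <= DISC_RADIUS_MM
    return PowerMap(values=values, mask=mask, grid_n=grid_n, mm_per_px=mm_per_px, params=params)


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------


def _choose_variant(label: ClassLabel, policy, rng: np.random.Generator) -> Variant:
    if isinstance(policy, Variant):
        if policy not in VARIANTS_BY_LABEL[label]:
            raise ConfigError(f"variant {policy.value} not valid for {label.value}")
        return policy
    table = DEFAULT_VARIANT_POLICY[label]
    if isinstance(policy, dict) and label in policy:
        table = policy[label]
    variants, probs = zip(*table.items())
    for v in variants:
        if v not in VARIANTS_BY_LABEL[label]:
            raise ConfigError(f"variant {Variant(v).value} not valid for {label.value}")
    probs = np.asarray(probs, dtype=float)
    return variants[int(rng.choice(len(variants), p=probs / probs.sum()))]


def sample_params(
    label: ClassLabel, variant_policy=None, rng_seed: int = 0
) -> SurfaceParams:
    """Draw ground-truth surface parameters for one labeled example.

    ``variant_policy`` may be None (default mix), a Variant (forced), or a
    dict mapping labels to {variant: probability}.  The same seed always
    yields identical parameters.
    """
    label = ClassLabel(label)
    rng = np.random.default_rng(rng_seed)
    variant = _choose_variant(label, variant_policy, rng)
    p = SurfaceParams(label=label, variant=variant)
    p.k0 = float(rng.uniform(DEFAULT_K0_LOW, DEFAULT_K0_HIGH))
    p.noise_seed = int(rng.integers(0, 2**31))
    p.axis_phi = float(rng.uniform(0.0, 180.0))

    if label is ClassLabel.SPHERICAL:
        if variant is Variant.POST_MYOPIC:
            p.central_dk = float(rng.uniform(-4.5, -2.5))
            p.central_sigma = float(rng.uniform(1.2, 1.8))
        elif variant is Variant.POST_HYPEROPIC:
            p.central_dk = float(rng.uniform(2.0, 3.5))
            p.central_sigma = float(rng.uniform(1.0, 1.5))
    elif label is ClassLabel.SYMMETRIC:
        amp = float(rng.uniform(2.0, 4.5))
        ext = float(rng.uniform(1.8, 2.1))
        p.amp_sup = p.amp_inf = amp
        p.radial_extent_sup = p.radial_extent_inf = ext
    elif label is ClassLabel.ASYMMETRIC:
        amp = float(rng.uniform(2.0, 4.5))
        ext = float(rng.uniform(1.8, 2.1))
        ratio = float(rng.uniform(0.55, 1.0 - MIN_ASYMMETRY))
        amp_ratio = float(rng.uniform(0.80, 1.0))
        small_sup = bool(rng.random() < 0.5)  # which semimeridian is the short one
        p.amp_sup, p.amp_inf = (amp * amp_ratio, amp) if small_sup else (amp, amp * amp_ratio)
        p.radial_extent_sup = ext * ratio if small_sup else ext
        p.radial_extent_inf = ext if small_sup else ext * ratio
    else:  # IRREGULAR
        if variant is Variant.CLASSIC_INFERIOR:
            p.cone_dk = float(rng.uniform(3.0, 6.5))
            p.cone_r = float(rng.uniform(1.2, 2.2))
            p.cone_theta = float(rng.uniform(200.0, 340.0))  # inferior half-plane
            p.cone_sigma = float(rng.uniform(0.7, 1.0))
        elif variant is Variant.SKEWED:
            amp = float(rng.uniform(2.5, 4.5))
            p.amp_sup = p.amp_inf = amp
            p.radial_extent_sup = p.radial_extent_inf = float(rng.uniform(1.8, 2.1))
            p.skew_deg = float(rng.uniform(max(MIN_SKEW_DEG, 35.0), 60.0)) * (
                1.0 if rng.random() < 0.5 else -1.0
            )
        elif variant is Variant.PELLUCID:
            p.cone_dk = float(rng.uniform(3.0, 5.5))
            p.cone_r = float(rng.uniform(2.0, 2.6))
            p.cone_theta = float(rng.uniform(255.0, 285.0))
            p.cone_sigma = float(rng.uniform(0.45, 0.65))
            p.cone_arc_mm = float(rng.uniform(1.8, 2.8))
        elif variant is Variant.INCOMPLETE_TIE:
            amp = float(rng.uniform(2.5, 4.0))
            p.amp_sup = p.amp_inf = amp
            p.radial_extent_sup = p.radial_extent_inf = float(rng.uniform(0.9, 1.35))
        elif variant is Variant.RUDIMENTARY_TIE:
            amp = float(rng.uniform(2.8, 5.0))
            p.amp_inf = amp
            p.amp_sup = amp * float(rng.uniform(0.55, 0.70))
            p.radial_extent_inf = float(rng.uniform(1.8, 2.1))
            p.radial_extent_sup = p.radial_extent_inf * float(rng.uniform(0.25, 0.34))
        else:
            raise ConfigError(f"variant {variant.value} not valid for IRREGULAR")
    return p


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

BACKGROUND_RGB = (255, 255, 255)
OVERLAY_RGB = (0, 0, 0)


def zone_radii_px(grid_n: int, mm_per_px: float) -> tuple:
    return tuple(z / mm_per_px for z in ZONE_RADII_MM)


def render_topogram(
    pm: PowerMap, scale: Optional[ColorScale] = None, zones_px: Optional[tuple] = None
) -> Topogram:
    """Render a power map as a color topogram with zone rings and axis ticks.

    Per-pixel color is the scale bin of the (clipped) power; pixels outside
    the disc are white; the 3/5/7-mm rings and four axis ticks on the outer
    ring are drawn in black.  Deterministic.
    """
    scale = scale or ColorScale()
    if zones_px is None:
        zones_px = zone_radii_px(pm.grid_n, pm.mm_per_px)
    n = pm.grid_n
    bins = scale.bin_of(pm.values)
    img = scale.lut()[bins]
    img[~pm.mask] = BACKGROUND_RGB

    c = (n - 1) / 2.0
    idx = np.arange(n)
    dist = np.hypot(idx[None, :] - c, idx[:, None] - c)
    ring = np.zeros((n, n), dtype=bool)
    for rz in zones_px:
        ring |= np.abs(dist - rz) <= 0.6
    # axis ticks at 0/90/180/270 degrees crossing the outer ring
    xpx = idx[None, :] - c
    ypx = c - idx[:, None]
    on_axis = (np.abs(xpx) <= 0.6) | (np.abs(np.broadcast_to(ypx, (n, n))) <= 0.6)
    tick = on_axis & (np.abs(dist - zones_px[-1]) <= 4.0)
    img[ring | tick] = OVERLAY_RGB

    sidecar = {
        "mm_per_px": pm.mm_per_px,
        "grid_n": pm.grid_n,
        "zones_px": list(zones_px),
        "params": pm.params.to_dict() if pm.params is not None else None,
    }
    return Topogram(image=img, zones_px=tuple(zones_px), sidecar=sidecar)


def invert_colors_to_bins(image: np.ndarray, scale: ColorScale) -> np.ndarray:
    """Map rendered colors back to scale bins; overlay/background pixels -> -1."""
    lut = scale.lut()
    out = np.full(image.shape[:2], -1, dtype=int)
    for b, col in enumerate(lut):
        out[np.all(image == col, axis=-1)] = b
    return out


# ---------------------------------------------------------------------------
# Capture distortion
# ---------------------------------------------------------------------------


def frame_corners(n: int) -> np.ndarray:
    """TL, TR, BR, BL corners of an n x n frame in (x, y) pixel coords."""
    return np.array(
        [[0.0, 0.0], [n - 1.0, 0.0], [n - 1.0, n - 1.0], [0.0, n - 1.0]], dtype=float
    )


def _cross2(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _is_convex(quad: np.ndarray) -> bool:
    z = []
    for i in range(4):
        a, b, c = quad[i], quad[(i + 1) % 4], quad[(i + 2) % 4]
        z.append(_cross2(b - a, c - b))
    z = np.asarray(z)
    return bool(np.all(z > 0) or np.all(z < 0))


def distort_capture(
    t: Topogram,
    corner_jitter_px: float = 18.0,
    photometric: Optional[dict] = None,
    rng_seed: int = 0,
):
    """Simulate a hand-held capture: projective warp + mild photometrics.

    The canonical frame is mapped onto a random convex quad (corners pulled
    inward by up to ``corner_jitter_px``); the true quad is returned so the
    rectification stage can be tested against ground truth.  Fully seeded.

    Returns ``(image, true_quad)`` with the quad ordered TL, TR, BR, BL.
    """
    from . import rectify  # local import; rectify has no dependency on synth

    n = t.image.shape[0]
    base = frame_corners(n)
    rng = np.random.default_rng(rng_seed)

    if corner_jitter_px == 0:
        quad = base.copy()
        img = t.image.copy()
    else:
        inward = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
        quad = None
        for _ in range(32):
            cand = base + inward * rng.uniform(0.0, corner_jitter_px, size=(4, 2))
            if _is_convex(cand):
                quad = cand
                break
        if quad is None:
            raise RuntimeError("could not draw a convex capture quad")
        H = rectify.estimate_homography(base, quad)
        img = rectify.warp_image(t.image, np.linalg.inv(H), (n, n), cval=255.0)

    photometric = {"brightness": True, "blur": True} if photometric is None else photometric
    out = img.astype(float)
    if photometric.get("brightness"):
        out = out * rng.uniform(0.92, 1.08)
    if photometric.get("blur"):
        sigma = rng.uniform(0.0, 0.5)
        if sigma > 0.05:
            from scipy.ndimage import gaussian_filter

            out = gaussian_filter(out, sigma=(sigma, sigma, 0))
    return np.clip(np.round(out), 0, 255).astype(np.uint8), quad


# ---------------------------------------------------------------------------
# Bank generation
# ---------------------------------------------------------------------------

TRAIN_PER_CLASS = 240


def _image_seed(bank_seed: int, class_idx: int, i: int) -> int:
    ss = np.random.SeedSequence(bank_seed, spawn_key=(class_idx, i))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def generate_bank(
    per_class_counts: dict,
    seed: int = 0,
    out_dir=None,
    grid_n: int = CANONICAL_N,
    train_per_class: int = TRAIN_PER_CLASS,
    variant_policy=None,
    write_images: bool = True,
) -> list:
    """Generate a labeled topogram bank and its train/test manifest.

    Writes ``<stem>.png`` + ``<stem>.json`` sidecars plus ``manifest.tsv``
    under ``out_dir`` (when given) and returns the manifest rows.  Within
    each class, ``train_per_class`` images are assigned to the train split
    (seeded draw without replacement) and the remainder to test; classes
    with fewer images are all train.  Deterministic per seed: all per-image
    randomness derives from one seed through counter-based seed spawning.
    """
    from .pipeline import write_manifest

    scale = ColorScale()
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for class_idx, label in enumerate(CLASS_ORDER):
        count = int(per_class_counts.get(label, per_class_counts.get(label.value, 0)) or 0)
        if count < 0:
            raise ConfigError("per-class counts must be >= 0")
        if count == 0:
            continue
        split_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(class_idx, 1 << 20))
        )
        if count > train_per_class:
            train_idx = set(
                split_rng.choice(count, size=train_per_class, replace=False).tolist()
            )
        else:
            train_idx = set(range(count))
        for i in range(count):
            img_seed = _image_seed(seed, class_idx, i)
            params = sample_params(label, variant_policy, rng_seed=img_seed)
            stem = f"{label.value.lower()}_{i:04d}"
            if out_dir is not None and write_images:
                pm = make_power_map(params, grid_n=grid_n)
                topo = render_topogram(pm, scale)
                Image.fromarray(topo.image).save(out_dir / f"{stem}.png")
                sidecar = dict(topo.sidecar)
                sidecar["seed"] = img_seed
                sidecar["label"] = label.value
                sidecar["variant"] = params.variant.value
                (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
            rows.append(
                {
                    "file": f"{stem}.png",
                    "label": label.value,
                    "variant": params.variant.value,
                    "split": "train" if i in train_idx else "test",
                    "seed": str(img_seed),
                }
            )
    if out_dir is not None:
        write_manifest(rows, out_dir / "manifest.tsv")
    return rows


def manifest_digest(rows: list) -> str:
    payload = json.dumps(rows, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
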