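"""Capture rectification: 4-point homography, canonical warp, HSV conversion.

At capture time the printed topogram is seen under perspective; given the
four corner points of the topogram frame in the photograph, a planar
homography maps the capture into the canonical zone-aligned frame so the
3/5/7-mm rings coincide with their reference positions.  The rectified RGB
image is then converted to HSV, whose hue channel isolates the diopter
color band from illumination.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import synth


class DegenerateGeometryError(ValueError):
    """Corner quad is degenerate (collinear triple / zero area / concave)."""


class QualityCheckError(RuntimeError):
    """Rectified frame fails the zone-alignment quality check; recapture."""


def order_corners(pts) -> np.ndarray:
    """Canonicalize four corner points to TL, TR, BR, BL order.

    Points are sorted by angle around their centroid, then rotated so the
    first point is the one closest to the top-left; user input order is
    therefore forgiving.
    """
    pts = np.asarray(pts, dtype=float).reshape(4, 2)
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    pts = pts[np.argsort(ang)]  # counter-clockwise in image coords = TL,TR,BR,BL
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def _check_quad(pts: np.ndarray) -> None:
    for i in range(4):
        a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        if abs(float(cross)) < 1e-9:
            raise DegenerateGeometryError("collinear corner triple")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if area <= 0:
        raise DegenerateGeometryError("zero-area quad")


def estimate_homography(src, dst) -> np.ndarray:
    """Direct linear estimate of the 3x3 homography H with H @ src_i ~ dst_i.

    Four point correspondences give eight linear equations in the eight
    unknowns (h33 fixed to 1); the exact solve maps each source corner to
    its target corner to numerical precision.
    """
    src = np.asarray(src, dtype=float).reshape(4, 2)
    dst = np.asarray(dst, dtype=float).reshape(4, 2)
    _check_quad(src)
    _check_quad(dst)
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i], b[2 * i + 1] = u, v
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise DegenerateGeometryError(f"homography system singular: {e}") from e
    H = np.append(h, 1.0).reshape(3, 3)
    return H


def apply_homography(H: np.ndarray, pts) -> np.ndarray:
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    ph = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    return ph[:, :2] / ph[:, 2:3]


def warp_image(
    image: np.ndarray, H_inv: np.ndarray, out_shape: tuple, cval: float = 0.0
) -> np.ndarray:
    """Inverse-map warp with bilinear interpolation.

    ``H_inv`` maps output (x, y) to source (x, y).  Output dtype matches the
    input (uint8 rounded).  Deterministic.
    """
    from scipy.ndimage import map_coordinates

    h, w = out_shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = apply_homography(H_inv, np.column_stack([xs.ravel(), ys.ravel()]))
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])  # (row, col)
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    out = np.empty((h, w, img.shape[2]))
    for ch in range(img.shape[2]):
        out[..., ch] = map_coordinates(img[..., ch], coords, order=1, mode="constant", cval=cval)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    if np.asarray(image).ndim == 2:
        out = out[..., 0]
    return out


def warp_to_canonical(image: np.ndarray, src_corners, n: int = synth.CANONICAL_N) -> np.ndarray:
    """Rectify a captured image into the n x n canonical frame.

    ``src_corners`` are the four frame-corner points in the capture (any
    order; canonicalized internally).  Raises DomainError when corners fall
    outside the image.
    """
    image = np.asarray(image)
    src = order_corners(src_corners)
    h, w = image.shape[:2]
    if (src[:, 0] < -0.5).any() or (src[:, 0] > w - 0.5).any() or (
        src[:, 1] < -0.5
    ).any() or (src[:, 1] > h - 0.5).any():
        raise synth.DomainError("corner points outside the capture image")
    dst = synth.frame_corners(n)
    H = estimate_homography(src, dst)  # capture -> canonical
    return warp_image(image, np.linalg.inv(H), (n, n), cval=255.0)


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Per-pixel hexcone conversion of 8-bit RGB to (hue deg, sat, value).

    Hue is in [0, 360) with the gray (zero-saturation) convention hue = 0;
    saturation and value are in [0, 1].
    """
    import skimage.color

    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input")
    hsv = skimage.color.rgb2hsv(img)
    hsv[..., 0] = hsv[..., 0] * 360.0
    return hsv


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`, back to 8-bit RGB."""
    import skimage.color

    h = np.asarray(hsv, dtype=float).copy()
    h[..., 0] = h[..., 0] / 360.0
    rgb = skimage.color.hsv2rgb(h)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def detect_ring_pixels(canonical: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of dark overlay pixels in a canonical frame."""
    img = np.asarray(canonical)
    dark = np.all(img < 80, axis=-1)
    return np.argwhere(dark)


def zone_alignment_error(
    canonical: np.ndarray, expected_zones_px: Optional[tuple] = None
) -> float:
    """Mean radial distance (px) of detected ring pixels from the 3/5/7-mm radii.

    Each dark overlay pixel is matched to its nearest expected ring; axis
    ticks near the outer ring contribute little.  A perfectly rectified
    synthetic render scores ~0.  Raises QualityCheckError when no ring
    pixels are detectable (signal to recapture).
    """
    img = np.asarray(canonical)
    n = img.shape[0]
    if expected_zones_px is None:
        expected_zones_px = synth.zone_radii_px(n, 2.0 * synth.DISC_RADIUS_MM / n)
    pix = detect_ring_pixels(img)
    if len(pix) < 20:
        raise QualityCheckError("zone rings not detectable; recapture required")
    c = (n - 1) / 2.0
    rad = np.hypot(pix[:, 0] - c, pix[:, 1] - c)
    d = np.min(
        np.abs(rad[:, None] - np.asarray(expected_zones_px, dtype=float)[None, :]), axis=1
    )
    return float(d.mean())
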