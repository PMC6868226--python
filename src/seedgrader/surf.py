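"""From-scratch SURF: interest points, orientation, 64-d descriptors.

Speeded-Up Robust Features detect blob-like structures as local maxima of
an integer-box approximation to the determinant of the Hessian, computed in
constant time per filter via an integral image.  Each interest point is
tagged with the sign of the Laplacian (the Hessian trace): +1 for dark
structures on a bright background, -1 for the reverse, which lets matching
distinguish the two cheaply.  A dominant orientation is estimated from Haar
wavelet responses in a circular neighbourhood (sliding 60-degree window of
maximal summed response), and the descriptor is built from Haar responses
on an oriented 12 x 12 sample grid over a window of side 20 * scale: the
grid is divided into 4 x 4 subregions, each summarising its 3 x 3 samples
as (sum dx, sum dy, sum |dx|, sum |dy|); the 64-vector is L2-normalized.

This variant uses 3 x 3 samples per subregion (12 x 12 total) rather than
the more common 5 x 5 (20 x 20); it keeps the standard 0.9^2 weight on the
mixed second-derivative term and the standard 3-octave, 4-level box-filter
schedule.  Scale-space maxima are taken on the sampled grid without
sub-pixel interpolation, so detections are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "InterestPoint",
    "to_grayscale",
    "integral_image",
    "box_sum",
    "detect_interest_points",
    "assign_orientation",
    "compute_descriptor",
    "extract_surf",
]

#: Luminance weights = Y row of the RGB->XYZ matrix used by the color module.
GRAY_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

#: Default determinant-of-Hessian threshold for images scaled to [0, 1];
#: on kernel images it yields on the order of tens of points.
DEFAULT_THRESHOLD = 5e-5


@dataclass
class InterestPoint:
    """A detected scale-space blob with orientation and Laplacian sign."""

    x: float
    y: float
    scale: float
    response: float
    laplacian_sign: int
    orientation: float = 0.0


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance of an RGB image in [0, 1] (Y-row weights 0.2126/0.7152/0.0722)."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    return image @ GRAY_WEIGHTS


def integral_image(gray: np.ndarray) -> np.ndarray:
    """(H+1) x (W+1) zero-padded cumulative-sum table of a grayscale image."""
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    ii = np.zeros((gray.shape[0] + 1, gray.shape[1] + 1))
    np.cumsum(np.cumsum(gray, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _box(ii, r0, c0, r1, c1):
    """Sum of pixels in rows [r0, r1), cols [c0, c1); clipped to the image."""
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    r0 = np.clip(r0, 0, h)
    r1 = np.clip(r1, 0, h)
    c0 = np.clip(c0, 0, w)
    c1 = np.clip(c1, 0, w)
    r1 = np.maximum(r1, r0)
    c1 = np.maximum(c1, c0)
    return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]


def box_sum(ii: np.ndarray, rect: tuple[int, int, int, int]) -> float:
    """Sum of pixels in ``rect = (row, col, height, width)`` via 4 lookups.

    Rectangles extending past the image are clipped to it.
    """
    r, c, h, w = rect
    return float(_box(ii, r, c, r + h, c + w))


def _hessian_maps(ii, rr, cc, lobe):
    """Box-filter Dxx, Dyy, Dxy at the grid (rr, cc) for lobe size ``lobe``.

    The filter side is L = 3 * lobe; responses are normalized by 1 / L^2.
    """
    l = lobe
    L = 3 * l
    b = (L - 1) // 2
    m = (l - 1) // 2
    inv = 1.0 / (L * L)
    # Dyy: full L x (2l-1) strip minus 3x the middle l x (2l-1) lobe
    whole = _box(ii, rr - b, cc - (l - 1), rr + b + 1, cc + l)
    mid = _box(ii, rr - m, cc - (l - 1), rr + m + 1, cc + l)
    dyy = (whole - 3.0 * mid) * inv
    whole = _box(ii, rr - (l - 1), cc - b, rr + l, cc + b + 1)
    mid = _box(ii, rr - (l - 1), cc - m, rr + l, cc + m + 1)
    dxx = (whole - 3.0 * mid) * inv
    tl = _box(ii, rr - l, cc - l, rr, cc)
    br = _box(ii, rr + 1, cc + 1, rr + l + 1, cc + l + 1)
    tr = _box(ii, rr - l, cc + 1, rr, cc + l + 1)
    bl = _box(ii, rr + 1, cc - l, rr + l + 1, cc)
    dxy = (tl + br - tr - bl) * inv
    return dxx, dyy, dxy


def detect_interest_points(
    gray: np.ndarray,
    hessian_threshold: float = DEFAULT_THRESHOLD,
    octaves: int = 3,
    levels: int = 4,
) -> list[InterestPoint]:
    """Scale-space maxima of the approximated determinant of the Hessian.

    Candidate pixels must exceed ``hessian_threshold`` and be 3x3x3 local
    maxima across position and level within an octave (the outer levels
    serve only as comparison layers).  Each point carries the sign of the
    box-filter Laplacian Dxx + Dyy at its location: +1 marks dark blobs on
    a bright background.  Points whose filter support would leave the image
    are discarded.  The returned list is sorted by descending response.

    A constant image produces no points (zero response everywhere).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    h, w = gray.shape
    if h < 32 or w < 32:
        raise ValueError("image must be at least 32 x 32 for detection")
    ii = integral_image(gray)
    points: list[InterestPoint] = []
    for o in range(octaves):
        stride = 2**o
        rows = np.arange(0, h, stride)
        cols = np.arange(0, w, stride)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        resp = np.full((levels,) + rr.shape, -np.inf)
        laps = np.zeros((levels,) + rr.shape)
        lobes = [2 ** (o + 1) * (i + 1) + 1 for i in range(levels)]
        for i, lobe in enumerate(lobes):
            dxx, dyy, dxy = _hessian_maps(ii, rr, cc, lobe)
            det = dxx * dyy - 0.81 * dxy * dxy
            border = (3 * lobe - 1) // 2 + 1
            valid = (
                (rr >= border)
                & (rr < h - border)
                & (cc >= border)
                & (cc < w - border)
            )
            resp[i] = np.where(valid, det, -np.inf)
            laps[i] = dxx + dyy
        localmax = ndimage.maximum_filter(
            resp, size=3, mode="constant", cval=-np.inf
        )
        for i in range(1, levels - 1):
            hit = (resp[i] >= localmax[i]) & (resp[i] > hessian_threshold)
            for ri, ci in zip(*np.nonzero(hit)):
                points.append(
                    InterestPoint(
                        x=float(cols[ci]),
                        y=float(rows[ri]),
                        scale=1.2 * (3 * lobes[i]) / 9.0,
                        response=float(resp[i, ri, ci]),
                        laplacian_sign=1 if laps[i, ri, ci] >= 0 else -1,
                    )
                )
    points.sort(key=lambda p: -p.response)
    return points


def _haar(ii, px, py, hs):
    """Axis-aligned Haar responses (dx, dy) of side ``2*hs`` at integer centers."""
    px = np.asarray(px, dtype=int)
    py = np.asarray(py, dtype=int)
    dx = _box(ii, py - hs, px, py + hs, px + hs) - _box(
        ii, py - hs, px - hs, py + hs, px
    )
    dy = _box(ii, py, px - hs, py + hs, px + hs) - _box(
        ii, py - hs, px - hs, py, px + hs
    )
    return dx, dy


def assign_orientation(ii: np.ndarray, point: InterestPoint) -> float:
    """Dominant orientation of an interest point, in [0, 2*pi).

    Haar responses of side 4s are sampled on a disc of radius 6s (step s)
    around the point, Gaussian-weighted (sigma = 2.5s), and a 60-degree
    window slides over their angles in a fixed scan order; the orientation
    is the angle of the largest summed response vector.  Ties keep the
    first window encountered.  A featureless neighbourhood returns 0.
    """
    s = point.scale
    hs = max(1, round(2 * s))
    offs = np.arange(-6, 7)
    oi, oj = np.meshgrid(offs, offs, indexing="ij")
    disc = oi**2 + oj**2 <= 36
    oi, oj = oi[disc], oj[disc]
    px = np.round(point.x + oj * s).astype(int)
    py = np.round(point.y + oi * s).astype(int)
    dx, dy = _haar(ii, px, py, hs)
    wgt = np.exp(-(oi**2 + oj**2) / (2.0 * 2.5**2))
    dx = dx * wgt
    dy = dy * wgt
    ang = np.arctan2(dy, dx) % (2 * np.pi)
    best = -1.0
    best_angle = 0.0
    for start in np.arange(0.0, 2 * np.pi, np.pi / 32):
        rel = (ang - start) % (2 * np.pi)
        sel = rel < np.pi / 3
        sx, sy = dx[sel].sum(), dy[sel].sum()
        norm = sx * sx + sy * sy
        if norm > best:
            best = norm
            best_angle = np.arctan2(sy, sx) % (2 * np.pi)
    if best <= 0.0:
        return 0.0
    return float(best_angle)


def compute_descriptor(
    ii: np.ndarray, point: InterestPoint
) -> np.ndarray | None:
    """64-d oriented SURF descriptor, or None if the window leaves the image.

    Haar responses (side 2s) are taken at 12 x 12 regularly spaced sample
    points of an orientation-aligned square window of side 20s, weighted by
    a Gaussian (sigma = 3.3s) centred on the point, and rotated into the
    point's frame.  Each of the 4 x 4 subregions sums its 3 x 3 samples
    into (sum dx, sum dy, sum |dx|, sum |dy|); the concatenation is
    L2-normalized.  A perfectly flat window yields the all-zero vector.
    """
    s = point.scale
    theta = point.orientation
    hs = max(1, round(s))
    step = 20.0 * s / 12.0
    grid = (np.arange(12) + 0.5) * step - 10.0 * s
    u, v = np.meshgrid(grid, grid, indexing="ij")  # u: rows, v: cols
    ct, st = np.cos(theta), np.sin(theta)
    px = np.round(point.x + v * ct - u * st).astype(int)
    py = np.round(point.y + v * st + u * ct).astype(int)
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    if (
        px.min() - hs < 0
        or py.min() - hs < 0
        or px.max() + hs > w
        or py.max() + hs > h
    ):
        return None
    dx, dy = _haar(ii, px, py, hs)
    wgt = np.exp(-(u**2 + v**2) / (2.0 * (3.3 * s) ** 2))
    dx = dx * wgt
    dy = dy * wgt
    # rotate the axis-aligned responses into the descriptor frame
    du = dx * ct + dy * st
    dv = -dx * st + dy * ct
    desc = np.empty(64)
    k = 0
    for bi in range(4):
        for bj in range(4):
            su = du[3 * bi : 3 * bi + 3, 3 * bj : 3 * bj + 3]
            sv = dv[3 * bi : 3 * bi + 3, 3 * bj : 3 * bj + 3]
            desc[k : k + 4] = (
                su.sum(),
                sv.sum(),
                np.abs(su).sum(),
                np.abs(sv).sum(),
            )
            k += 4
    norm = np.linalg.norm(desc)
    # cutoff sits above integral-image cumsum rounding noise so flat
    # windows come back as exact zeros rather than normalized residue
    if norm < 1e-7:
        return np.zeros(64)
    return desc / norm


def extract_surf(
    image: np.ndarray,
    hessian_threshold: float = DEFAULT_THRESHOLD,
    octaves: int = 3,
    levels: int = 4,
    max_points: int | None = None,
) -> tuple[list[InterestPoint], np.ndarray]:
    """Detect, orient and describe SURF points of an RGB or grayscale image.

    Points whose descriptor window does not fit inside the image are
    skipped.  Returns the retained points (orientation filled in) and the
    matching (n, 64) descriptor matrix.
    """
    gray = to_grayscale(image)
    ii = integral_image(gray)
    pts = detect_interest_points(gray, hessian_threshold, octaves, levels)
    if max_points is not None:
        pts = pts[:max_points]
    kept: list[InterestPoint] = []
    descs: list[np.ndarray] = []
    for p in pts:
        p.orientation = assign_orientation(ii, p)
        d = compute_descriptor(ii, p)
        if d is not None:
            kept.append(p)
            descs.append(d)
    mat = np.array(descs) if descs else np.empty((0, 64))
    return kept, mat
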