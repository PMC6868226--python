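"""Color-space conversions and spatial color-patch features.

RGB kernel images are converted to CIE L*a*b* in two steps: a fixed linear
RGB -> XYZ map, then the nonlinear XYZ -> L*a*b* transform relative to a
reference white.  The constants used here (the 3x3 matrix, the piecewise
break point 0.0089 and the linear-branch coefficients 7.7870 t + 0.1379)
deliberately follow the grading method's printed values rather than the
higher-precision CIE standard ones (0.008856, 7.787 t + 16/116); the two
differ by well under the quantization noise of 8-bit imagery.

The spatial color feature for the bag-of-features stage is a 5-vector per
non-overlapping 16x16-pixel tile: the three per-tile channel means plus the
tile-center coordinates normalized to [0, 1] by image width and height, so
the layout information is scale invariant.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "XYZ_FROM_RGB",
    "REFERENCE_WHITE",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "rgb_to_hsi",
    "extract_color_patch_features",
]

#: Linear sRGB-primaries RGB -> CIE XYZ matrix (D65 primaries, as printed).
XYZ_FROM_RGB = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: Reference white: the image of RGB = (1, 1, 1) under ``XYZ_FROM_RGB``.
#: Chosen so that pure white maps to L* = 100 under the matrix above
#: (the method states no white point of its own).
REFERENCE_WHITE = XYZ_FROM_RGB.sum(axis=1)  # (0.9505, 1.0000, 1.0890)

# Piecewise L*a*b* companding function constants, as printed.
LAB_BREAK = 0.0089
LAB_SLOPE = 7.7870
LAB_OFFSET = 0.1379


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim < 1 or image.shape[-1] != 3:
        raise ValueError(
            f"expected a 3-channel array with a trailing axis of size 3, "
            f"got shape {image.shape}"
        )
    return image


def rgb_to_xyz(image: np.ndarray, linearize: bool = False) -> np.ndarray:
    """Map RGB intensities in [0, 1] to CIE XYZ.

    The map is exactly linear: each pixel is multiplied by the fixed 3x3
    matrix ``XYZ_FROM_RGB``.  By default the matrix is applied to the raw
    [0, 1] values; ``linearize=True`` first undoes the sRGB gamma encoding,
    for comparison (off by default to match the grading method as printed).

    Parameters
    ----------
    image : array, shape (..., 3)
        RGB values in [0, 1].
    linearize : bool
        Apply the sRGB electro-optical transfer function before the matrix.
    """
    rgb = _check_rgb(image)
    if linearize:
        rgb = np.where(
            rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4
        )
    return rgb @ XYZ_FROM_RGB.T


def xyz_to_lab(
    xyz: np.ndarray, white: np.ndarray | tuple = REFERENCE_WHITE
) -> np.ndarray:
    """Map CIE XYZ to L*a*b* relative to a reference white.

    L* = 116 f(Y/Yn) - 16, a* = 500 (f(X/Xn) - f(Y/Yn)),
    b* = 200 (f(Y/Yn) - f(Z/Zn)), with f the cube root for arguments above
    0.0089 and the linear branch 7.7870 t + 0.1379 otherwise.

    Raises
    ------
    ValueError
        If any reference-white component is not strictly positive.
    """
    xyz = _check_rgb(xyz)  # same shape contract: trailing axis of 3
    white = np.asarray(white, dtype=float)
    if white.shape != (3,) or np.any(white <= 0):
        raise ValueError("reference white must be 3 strictly positive values")
    t = xyz / white
    f = np.where(t > LAB_BREAK, np.cbrt(t), LAB_SLOPE * t + LAB_OFFSET)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def rgb_to_lab(
    image: np.ndarray,
    white: np.ndarray | tuple = REFERENCE_WHITE,
    linearize: bool = False,
) -> np.ndarray:
    """Convenience composition of :func:`rgb_to_xyz` and :func:`xyz_to_lab`."""
    return xyz_to_lab(rgb_to_xyz(image, linearize=linearize), white=white)


def rgb_to_hsi(image: np.ndarray) -> np.ndarray:
    """Convert RGB in [0, 1] to HSI (hue, saturation, intensity).

    Standard geometric conversion: I is the channel mean, S = 1 - min/I,
    and H is the angle (normalized to [0, 1)) of the pixel's chromaticity
    around the achromatic axis.  Achromatic pixels (S = 0 or I = 0) get
    H = 0 by convention.
    """
    rgb = _check_rgb(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    intensity = rgb.mean(axis=-1)
    cmin = rgb.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(intensity > 0, 1.0 - cmin / intensity, 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arccos(np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0))
    hue = np.where(b <= g, theta, 2.0 * np.pi - theta) / (2.0 * np.pi)
    hue = np.where((den > 0) & (sat > 0), hue, 0.0)
    # guard the half-open interval: 2*pi wraps back to 0
    hue = np.where(hue >= 1.0, 0.0, hue)
    return np.stack([hue, np.clip(sat, 0.0, 1.0), intensity], axis=-1)


def extract_color_patch_features(
    image: np.ndarray, tile: int = 16
) -> np.ndarray:
    """Per-tile channel means plus normalized tile-center coordinates.

    The image is cut into non-overlapping ``tile`` x ``tile`` pixel blocks
    (partial blocks at the right/bottom edges are dropped).  Each block
    yields a 5-vector ``(c1_mean, c2_mean, c3_mean, x, y)`` where (x, y) is
    the block center divided by the image width and height.

    Works for any 3-channel representation (L*a*b*, RGB, HSI).

    Returns
    -------
    array, shape (n_tiles, 5) with ``n_tiles = (H // tile) * (W // tile)``.

    Raises
    ------
    ValueError
        If the image is smaller than one tile in either dimension.
    """
    img = _check_rgb(image)
    if img.ndim != 3:
        raise ValueError("expected an H x W x 3 image")
    h, w = img.shape[:2]
    nh, nw = h // tile, w // tile
    if nh == 0 or nw == 0:
        raise ValueError(
            f"image of size {h}x{w} is smaller than one {tile}x{tile} tile"
        )
    block = img[: nh * tile, : nw * tile].reshape(nh, tile, nw, tile, 3)
    means = block.mean(axis=(1, 3))  # (nh, nw, 3)
    ys = (np.arange(nh) + 0.5) * tile / h
    xs = (np.arange(nw) + 0.5) * tile / w
    xg, yg = np.meshgrid(xs, ys)
    feats = np.concatenate(
        [means, xg[..., None], yg[..., None]], axis=-1
    ).reshape(-1, 5)
    return feats
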