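"""Synthetic seed-kernel image generator with grade-dependent defects.

The original grading study was run on scanner photographs of real dry
soybean kernels on a black absorption cover; that dataset is not public.
This module emulates its three appearance grades so the whole pipeline is
exercisable and testable end to end:

* ``good`` — an intact, smooth kernel: an anti-aliased ellipse with a
  yellowish seed-coat color, gentle radial shading and mild speckle, on a
  near-black background.
* ``moderate`` — the same kernel plus 1-2 thin dark crack curves, or a
  coat-break patch exposing the brighter cotyledon.
* ``unhealthy`` — a decayed coat color (luminance-preserving shift toward
  green-brown, plus mild dulling) and at least two of: dense shrivel
  ridges (sinusoidal luminance modulation), dark mold blobs, a bite notch
  carved from the outline, or a strongly deformed outline.  The texture
  defects resemble the moderate grade's cracks in gradient structure,
  while the discoloration is visible only to color features — so the two
  modalities carry complementary information, as they do on real seeds.

Every defect is parametric and the drawn parameters are logged per image
(``SeedImage.meta``) so pipeline failures are debuggable.  Generation is
fully deterministic given the configuration seed: image i of grade g is
drawn from an RNG seeded by (seed, grade_index, i).

What this emulates — and what it does not: the images reproduce the
coarse photometric cues that distinguish the grades (smoothness, local
dark structures, outline damage) but not scanner optics, specular
highlights, hilum detail, dust, or the full variability of biological
seed coats; results on synthetic data bound the pipeline's correctness,
not its field performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import SeedImage, save_image

__all__ = ["GRADES", "SynthConfig", "generate_seed_image", "generate_dataset"]

GRADES = ("good", "moderate", "unhealthy")


@dataclass
class SynthConfig:
    """Parameters of the synthetic kernel-image population.

    Sizes are pixels, colors are RGB in [0, 1], amplitudes are fractions
    of the local luminance.
    """

    counts: tuple = (60, 60, 60)  # images per grade, (good, moderate, unhealthy)
    size: int = 128
    base_color: tuple = (0.82, 0.66, 0.33)
    color_jitter: float = 0.025
    radius_range: tuple = (0.27, 0.33)  # semi-major axis, fraction of size
    eccentricity_range: tuple = (0.68, 0.88)  # semi-minor / semi-major
    shading: float = 0.25
    speckle: float = 0.02
    # moderate-grade defects
    crack_count_range: tuple = (1, 2)
    crack_width_range: tuple = (0.9, 1.8)
    crack_darkness_range: tuple = (0.5, 0.75)  # fraction of luminance removed
    coat_break_prob: float = 0.3
    coat_break_color: tuple = (0.93, 0.85, 0.55)
    # unhealthy-grade defects
    # fine ridges: dark stripes comparable in width and depth to cracks
    shrivel_freq_range: tuple = (0.15, 0.25)  # cycles per pixel
    shrivel_amp_range: tuple = (0.12, 0.20)
    mold_count_range: tuple = (2, 5)
    mold_radius_range: tuple = (3.0, 7.0)
    # early surface mold: a green bloom at nearly the coat's luminance
    mold_color: tuple = (0.45, 0.50, 0.25)
    mold_lum_factor: float = 0.85
    notch_radius_frac: float = 0.25  # of the semi-major axis
    deform_amp_range: tuple = (0.09, 0.16)
    dull_factor_range: tuple = (0.88, 0.97)  # mild coat dulling, unhealthy
    # luminance-preserving discoloration toward a decayed green-brown:
    # visible to color features, invisible to intensity-based gradients
    decay_color: tuple = (0.50, 0.47, 0.28)
    decay_mix_range: tuple = (0.60, 0.85)
    background: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if len(self.counts) != len(GRADES) or any(c < 0 for c in self.counts):
            raise ValueError("counts must be 3 non-negative integers")
        if self.size < 64:
            raise ValueError("image size must be at least 64")


def _smooth_noise(rng, size, sigma=2.0):
    """Unit-std spatially correlated noise field."""
    n = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    return n / n.std()


def _crack_mask(rng, size, cx, cy, a, width):
    """Soft mask of a thin dark crack: a jittered quadratic curve."""
    ang = rng.uniform(0, 2 * np.pi)
    t = np.array([np.cos(ang), np.sin(ang)])
    perp = np.array([-t[1], t[0]])
    length = rng.uniform(0.9, 1.3) * a
    # anchor near the kernel center so the crack crosses visible coat
    p0 = np.array([cx, cy]) + rng.uniform(-0.2, 0.2, 2) * a - t * length / 2
    p1 = p0 + t * length / 2 + perp * rng.uniform(-0.25, 0.25) * a
    p2 = p0 + t * length + perp * rng.uniform(-0.2, 0.2) * a
    u = np.linspace(0, 1, 80)[:, None]
    pts = (1 - u) ** 2 * p0 + 2 * u * (1 - u) * p1 + u**2 * p2  # (80, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = np.min(
        (xx[..., None] - pts[:, 0]) ** 2 + (yy[..., None] - pts[:, 1]) ** 2,
        axis=-1,
    )
    return np.exp(-d2 / (2.0 * width**2))


def _disc_mask(size, px, py, radius, softness=1.5):
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.sqrt((xx - px) ** 2 + (yy - py) ** 2)
    return np.clip((radius - d) / softness + 0.5, 0.0, 1.0)


def generate_seed_image(
    grade: str, config: SynthConfig, rng: np.random.Generator
) -> SeedImage:
    """Draw one labeled kernel image of the given grade.

    Deterministic: the same generator state and configuration always
    produce a bit-identical image.  The defects actually drawn, with
    their parameters, are recorded in ``meta["defects"]``.
    """
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}; expected one of {GRADES}")
    size = config.size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    a = rng.uniform(*config.radius_range) * size
    b = a * rng.uniform(*config.eccentricity_range)
    phi = rng.uniform(0, np.pi)
    xr = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    yr = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    theta = np.arctan2(yr / b, xr / a)
    d = np.hypot(xr / a, yr / b)

    defects: list[dict] = []
    if grade == "unhealthy":
        n_def = int(rng.integers(2, 4))  # 2 or 3 distinct structures
        chosen = list(
            rng.choice(["shrivel", "mold", "notch", "deform"], n_def, False)
        )
    else:
        chosen = []

    # outline: mild waviness for every seed, strong low-order deformation
    # only for the unhealthy "deform" defect
    amp = (
        rng.uniform(*config.deform_amp_range)
        if "deform" in chosen
        else rng.uniform(0.0, 0.015)
    )
    phases = rng.uniform(0, 2 * np.pi, 3)
    r_out = np.ones_like(theta)
    for k in range(3):
        r_out += (amp / (k + 1)) * np.cos((k + 2) * theta + phases[k])
    if "deform" in chosen:
        defects.append({"type": "deform", "amplitude": float(amp)})
    dd = d / np.maximum(r_out, 0.2)
    alpha = np.clip((1.0 - dd) * a / 1.5, 0.0, 1.0)

    if "notch" in chosen:
        th = rng.uniform(0, 2 * np.pi)
        bx = cx + a * np.cos(th) * np.cos(phi) - b * np.sin(th) * np.sin(phi)
        by = cy + a * np.cos(th) * np.sin(phi) + b * np.sin(th) * np.cos(phi)
        rn = config.notch_radius_frac * a * rng.uniform(0.8, 1.2)
        alpha *= 1.0 - _disc_mask(size, bx, by, rn)
        defects.append({"type": "notch", "radius": float(rn)})

    base = np.clip(
        np.asarray(config.base_color) + rng.normal(0, config.color_jitter, 3),
        0.05,
        0.98,
    )
    if grade == "unhealthy":
        # decayed coats discolor toward green-brown at nearly constant
        # luminance (gradient features cannot see this), plus mild dulling
        w = np.array([0.2126, 0.7152, 0.0722])
        t = rng.uniform(*config.decay_mix_range)
        shifted = (1 - t) * base + t * np.asarray(config.decay_color)
        shifted *= (w @ base) / (w @ shifted)  # restore luminance
        base = np.clip(shifted, 0.02, 0.98) * rng.uniform(
            *config.dull_factor_range
        )
        defects.append({"type": "decay_color", "mix": float(t)})
    lum = 1.0 - config.shading * np.clip(dd, 0, 1.2) ** 2
    lum += config.speckle * _smooth_noise(rng, size)

    if grade == "moderate":
        if rng.uniform() < config.coat_break_prob:
            pr = rng.uniform(0.15, 0.25) * a
            pth = rng.uniform(0, 2 * np.pi)
            prad = rng.uniform(0.2, 0.6)
            px = cx + prad * a * np.cos(pth)
            py = cy + prad * b * np.sin(pth)
            patch = _disc_mask(size, px, py, pr) * (dd < 0.9)
            defects.append({"type": "coat_break", "radius": float(pr)})
        else:
            patch = None
            n_cracks = int(
                rng.integers(
                    config.crack_count_range[0],
                    config.crack_count_range[1] + 1,
                )
            )
            for _ in range(n_cracks):
                wdt = rng.uniform(*config.crack_width_range)
                dark = rng.uniform(*config.crack_darkness_range)
                cm = _crack_mask(rng, size, cx, cy, a, wdt) * (dd < 0.92)
                lum *= 1.0 - dark * cm
                defects.append(
                    {"type": "crack", "width": float(wdt), "depth": float(dark)}
                )
    else:
        patch = None

    if "shrivel" in chosen:
        f = rng.uniform(*config.shrivel_freq_range)
        samp = rng.uniform(*config.shrivel_amp_range)
        psi = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        ridges = np.sin(
            2 * np.pi * f * (xx * np.cos(psi) + yy * np.sin(psi)) + phase
        )
        taper = np.clip(1.1 - dd, 0.0, 1.0)
        lum *= 1.0 + samp * ridges * taper
        lum *= 0.93  # shriveled coats read slightly darker overall
        defects.append(
            {"type": "shrivel", "freq": float(f), "amplitude": float(samp)}
        )

    kernel = base[None, None, :] * np.clip(lum, 0.0, 1.4)[..., None]

    if patch is not None:
        kernel = kernel * (1 - patch[..., None]) + np.asarray(
            config.coat_break_color
        )[None, None, :] * patch[..., None] * np.clip(lum, 0.4, 1.2)[..., None]

    if "mold" in chosen:
        n_mold = int(
            rng.integers(
                config.mold_count_range[0], config.mold_count_range[1] + 1
            )
        )
        w = np.array([0.2126, 0.7152, 0.0722])
        mold_rgb = np.asarray(config.mold_color)
        # match the bloom's luminance to the local coat so it reads as a
        # color change, not an intensity edge
        mold_rgb = mold_rgb * (
            config.mold_lum_factor * (w @ base) / (w @ mold_rgb)
        )
        mold_rgb = np.clip(mold_rgb, 0.0, 1.0)
        for _ in range(n_mold):
            mr = rng.uniform(*config.mold_radius_range)
            mth = rng.uniform(0, 2 * np.pi)
            mrad = rng.uniform(0, 0.65)
            mx = cx + mrad * a * np.cos(mth)
            my = cy + mrad * b * np.sin(mth)
            m = _disc_mask(size, mx, my, mr, softness=2.5) * 0.9
            kernel = kernel * (1 - m[..., None]) + mold_rgb[
                None, None, :
            ] * np.clip(lum, 0.3, 1.2)[..., None] * m[..., None]
        defects.append({"type": "mold", "count": n_mold})

    bg = config.background + 0.012 * _smooth_noise(rng, size, 3.0)
    img = bg[..., None] * (1 - alpha[..., None]) + kernel * alpha[..., None]
    img = np.clip(img, 0.0, 1.0)
    # quantize to 8 bits so in-memory and PNG round-tripped pixels agree
    img = np.round(img * 255.0) / 255.0
    return SeedImage(
        pixels=img,
        id="",
        label=grade,
        meta={
            "grade": grade,
            "defects": defects,
            "center": (float(cx), float(cy)),
            "axes": (float(a), float(b)),
            "angle": float(phi),
        },
    )


def generate_dataset(
    config: SynthConfig, out_dir=None
) -> tuple[list[SeedImage], pd.DataFrame]:
    """Generate the full labeled population, optionally writing it to disk.

    Returns the images plus a manifest with one row per image (id, grade,
    defect summary).  With ``out_dir`` set, images go to one PNG per file
    under a subdirectory per grade, alongside ``manifest.csv``.
    """
    images: list[SeedImage] = []
    rows = []
    for gi, (grade, n) in enumerate(zip(GRADES, config.counts)):
        for i in range(n):
            rng = np.random.default_rng([config.seed, gi, i])
            img = generate_seed_image(grade, config, rng)
            img.id = f"{grade}/{grade}_{i:04d}"
            images.append(img)
            rows.append(
                {
                    "id": img.id,
                    "grade": grade,
                    "n_defects": len(img.meta["defects"]),
                    "defects": ";".join(
                        d["type"] for d in img.meta["defects"]
                    ),
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for grade in GRADES:
            (out / grade).mkdir(exist_ok=True)
        for img in images:
            save_image(img, out / f"{img.id}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest
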