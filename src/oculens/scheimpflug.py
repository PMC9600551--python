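"""Scheimpflug-style lens densitometry on a 0-100% opacity scale.

Three manual methods are provided, mirroring common clinical practice on
rotating-Scheimpflug cross-sections: a linear reading along the optical
axis, a regular octagonal ROI inside the nucleus, and a 3D method that
applies one manually placed ellipse to every meridian image of a radial
series, averaging over the resulting ellipsoid volume.  0% represents
ocular-media clarity and 100% complete lenticular opacity; since the
vendor mapping from sensor counts to percent is undocumented, intensities
are mapped linearly from the 0-255 pixel scale (all downstream use is
correlation, which is invariant to monotone linear maps).

Radial series are first restricted to images on, or next to, the vertical
axis for between-patient comparability; ROI placement itself is an input
(the methods are manual), never inferred from the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .imgio import BScan
from .ssoct import EllipseROI


@dataclass
class ScheimpflugDensity:
    """A percent-scale opacity reading and how it was obtained."""

    value_pct: float
    method: Literal["linear", "roi", "ellipsoid"]
    meridians_used: list[float]

    def __post_init__(self) -> None:
        if not 0 <= self.value_pct <= 100:
            raise ValueError(f"opacity percent out of range: {self.value_pct}")


def to_percent(intensity: float) -> float:
    """Map a 0-255 pixel intensity to the 0-100% opacity scale."""
    if not 0 <= intensity <= 255:
        raise ValueError(f"intensity {intensity} outside [0, 255]")
    return intensity / 255.0 * 100.0


def linear_density_pct(
    image: BScan, axis_column: int, lens_rows: tuple[int, int]
) -> ScheimpflugDensity:
    """Mean intensity along the optical-axis column through the lens.

    ``lens_rows`` is the inclusive (top, bottom) row range of the lens on
    that column.
    """
    H, W = image.shape
    top, bottom = lens_rows
    if not 0 <= axis_column < W:
        raise ValueError(f"axis column {axis_column} outside image width {W}")
    if not 0 <= top <= bottom < H:
        raise ValueError(f"invalid lens row range {lens_rows} for height {H}")
    values = image.pixels[top: bottom + 1, axis_column]
    return ScheimpflugDensity(
        value_pct=to_percent(float(values.mean())),
        method="linear",
        meridians_used=[image.meridian_deg],
    )


def octagon_mask(
    shape: tuple[int, int], center: tuple[float, float], circumradius_px: float
) -> np.ndarray:
    """Pixel mask of a regular flat-top octagon.

    The octagon with circumradius ``R`` has inradius ``r = R cos(pi/8)``;
    flat-top orientation means its bounding half-planes are ``|x| <= r``,
    ``|y| <= r`` and ``|x| + |y| <= sqrt(2) r`` about the center.
    """
    cy, cx = float(center[1]), float(center[0])
    r = circumradius_px * np.cos(np.pi / 8)
    yy = np.arange(shape[0], dtype=float)[:, None] - cy
    xx = np.arange(shape[1], dtype=float)[None, :] - cx
    return (
        (np.abs(xx) <= r)
        & (np.abs(yy) <= r)
        & (np.abs(xx) + np.abs(yy) <= np.sqrt(2) * r)
    )


def octagon_density(
    image: BScan, center: tuple[float, float], circumradius_px: float
) -> ScheimpflugDensity:
    """Mean intensity over a regular octagonal nuclear ROI, in percent."""
    H, W = image.shape
    cx, cy = center
    r = circumradius_px * np.cos(np.pi / 8)
    if cx - r < 0 or cx + r > W - 1 or cy - r < 0 or cy + r > H - 1:
        raise ValueError("octagon exceeds image bounds")
    mask = octagon_mask(image.shape, center, circumradius_px)
    return ScheimpflugDensity(
        value_pct=to_percent(float(image.pixels[mask].mean())),
        method="roi",
        meridians_used=[image.meridian_deg],
    )


def ellipsoid_density(
    series: Sequence[BScan], ellipse: EllipseROI
) -> ScheimpflugDensity:
    """3D method: one ellipse applied to all meridians, pooled mean.

    The manually placed ellipse (encompassing nucleus and cortex) is
    applied unchanged to every image of the series, which sweeps out an
    ellipsoid volume in the rotating-section geometry; the returned value
    is the mean over all in-ellipse pixels of all images.
    """
    series = list(series)
    if not series:
        raise ValueError("ellipsoid_density requires at least one image")
    total, count = 0.0, 0
    meridians = []
    for image in series:
        H, W = image.shape
        cx, cy = ellipse.center
        if (
            cx - ellipse.semi_axis_lateral < 0
            or cx + ellipse.semi_axis_lateral > W - 1
            or cy - ellipse.semi_axis_axial < 0
            or cy + ellipse.semi_axis_axial > H - 1
        ):
            raise ValueError(f"ellipse out of bounds on image {image.source_id!r}")
        mask = ellipse.pixel_mask(image.shape)
        total += float(image.pixels[mask].sum())
        count += int(mask.sum())
        meridians.append(image.meridian_deg)
    return ScheimpflugDensity(
        value_pct=to_percent(total / count), method="ellipsoid", meridians_used=meridians
    )


def select_meridians(
    series: Sequence[BScan], target_axis_deg: float = 90.0, tolerance_deg: float = 15.0
) -> list[BScan]:
    """Images on, or next to, a target axis (vertical by default).

    Meridian distance is circular modulo 180 degrees.  All images within
    the tolerance are returned; if none qualify, the single closest image
    is returned, so the selection is never empty.
    """
    series = list(series)
    if not series:
        raise ValueError("empty series")

    def dist(m: float) -> float:
        d = abs(m - target_axis_deg) % 180.0
        return min(d, 180.0 - d)

    within = [s for s in series if dist(s.meridian_deg) <= tolerance_deg]
    if within:
        return within
    return [min(series, key=lambda s: dist(s.meridian_deg))]
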