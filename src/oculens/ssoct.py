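"""Automatic SS-OCT lens densitometry.

The pipeline follows the image-analysis recipe for anterior-segment
B-scans: contrast adjustment, global-threshold binarization, noise
removal and morphological closing, edge extraction of the lens surfaces,
4th-order polynomial fits with outlier correction, then densitometry.
Lens opacity is the mean pixel intensity (0-255 scale) of the segmented
lens; the background-corrected value subtracts the mean intensity of an
anterior-chamber region bounded by the cornea's posterior border (found
by Canny edge detection) and the lens anterior surface.  Nuclear opacity
uses an elliptical ROI at the lens center sized to a configurable
fraction of the lens area (default 14%).  Per-scan values are averaged
over the radial series to counteract scan-to-scan intensity variation.

A third, linear opacity reads a device-exported axial profile: the four
specular interface peaks are detected, and the mean intensity between the
lens anterior and posterior capsule peaks (peaks excluded) is reported in
normalized [0, 1] units.

Contrast adjustment serves segmentation only -- every density is computed
on the original pixel values, since stretching intensities would bias
opacity readings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks
from skimage import feature, filters, measure, morphology

from .imgio import AScanProfile, BScan


class SegmentationError(RuntimeError):
    """Raised when a stage of the segmentation pipeline finds no usable structure."""


@dataclass
class SsoctConfig:
    """Tunable knobs of the SS-OCT pipeline, with phantom-scale defaults.

    clip_percentiles
        Percentile window for the contrast stretch used by segmentation;
        ``(0, 100)`` stretches the full range.
    threshold_override
        Absolute binarization threshold in PIU; ``None`` selects Otsu's
        histogram criterion on the preprocessed image.
    min_object_px
        Connected components smaller than this are treated as noise.
    closing_radius_px
        Radius of the disk structuring element for morphological closing.
    deviation_threshold_px
        Edge points whose residual from the first quartic fit exceeds this
        are replaced by the curve value before a single refit.
    chamber_margin_px
        Erosion margin keeping the chamber ROI clear of the cornea border
        and the lens anterior surface.
    canny_sigma
        Gaussian sigma of the Canny detector used for the cornea border.
    central_column_margin_px
        Half-width of a central column band excluded from densitometry
        (the specular apex reflex in clinical scans; 0 for phantoms).
    nucleus_area_fraction
        Elliptical nuclear ROI area as a fraction of the lens area.
    ascan_smooth_sigma
        Gaussian smoothing (in samples) before A-scan peak detection.
    ascan_peak_prominence
        Minimum prominence (in [0,1] units) for interface peaks.
    capsule_margin_samples
        Samples excluded on each side of the capsule peaks when averaging
        the lens interior, so specular peak tails do not inflate the mean.
    min_contrast_piu
        Minimum intensity range of the original scan; blank or near-blank
        images are rejected before segmentation rather than letting the
        contrast stretch amplify noise into spurious structure.
    """

    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    threshold_override: float | None = None
    min_object_px: int = 50
    closing_radius_px: int = 5
    deviation_threshold_px: float = 10.0
    chamber_margin_px: int = 3
    canny_sigma: float = 2.0
    central_column_margin_px: int = 0
    nucleus_area_fraction: float = 0.14
    ascan_smooth_sigma: float = 3.0
    ascan_peak_prominence: float = 0.05
    capsule_margin_samples: int = 15
    min_contrast_piu: float = 15.0


DEFAULT_CONFIG = SsoctConfig()


@dataclass
class QuarticCurve:
    """4th-order polynomial lateral-px -> axial-px, coefficients c0..c4."""

    coef: np.ndarray

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (5,):
            raise ValueError("a quartic needs exactly 5 coefficients")
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("quartic coefficients must be finite")

    def __call__(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coef)


@dataclass
class LensSegmentation:
    """Fitted lens surfaces plus the pixel mask between them."""

    anterior: QuarticCurve
    posterior: QuarticCurve
    lateral_extent: tuple[int, int]
    mask: np.ndarray
    n_corrected_points: int = 0


@dataclass
class ChamberROI:
    """Anterior-chamber background region between cornea and lens."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise SegmentationError("chamber ROI is empty")


@dataclass
class EllipseROI:
    """Axis-aligned elliptical ROI, pixel coordinates."""

    center: tuple[float, float]  # (x, y)
    semi_axis_lateral: float
    semi_axis_axial: float
    area_fraction: float

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy = np.arange(shape[0], dtype=float)[:, None]
        xx = np.arange(shape[1], dtype=float)[None, :]
        cx, cy = self.center
        return ((xx - cx) / self.semi_axis_lateral) ** 2 + (
            (yy - cy) / self.semi_axis_axial
        ) ** 2 <= 1.0


@dataclass
class DensityResult:
    """Per-scan and series-averaged opacity readings.

    Raw per-scan means are in PIU on the 0-255 scale; the corrected values
    subtract the per-scan chamber mean before averaging over the series.
    ``linear_au`` (optional) is the axial-profile lens mean in [0, 1]
    arbitrary units.
    """

    per_scan_lens_mean: list[float]
    per_scan_chamber_mean: list[float]
    per_scan_nucleus_mean: list[float]
    lens_corrected: float
    nucleus_corrected: float
    n_scans: int
    linear_au: float | None = None


# ---------------------------------------------------------------------------
# segmentation stages
# ---------------------------------------------------------------------------

def preprocess(bscan: BScan, config: SsoctConfig = DEFAULT_CONFIG) -> BScan:
    """Contrast-stretch a copy of the scan for segmentation.

    The returned image spans [0, 255] between the configured percentiles.
    Densitometry must keep reading the original scan; this output feeds
    thresholding and edge detection only.
    """
    px = bscan.pixels
    if np.ptp(px) == 0:
        warnings.warn("constant image: contrast stretch skipped", stacklevel=2)
        return replace(bscan, pixels=px.copy())
    lo, hi = np.percentile(px, config.clip_percentiles)
    if hi <= lo:
        lo, hi = px.min(), px.max()
    stretched = np.clip((px - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return replace(bscan, pixels=stretched)


def binarize(image: np.ndarray | BScan, config: SsoctConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Foreground mask from a single global histogram threshold.

    The anterior-segment histogram has a heavy dark mass (background plus
    aqueous chamber) against mid-to-bright tissue (cornea, cortex,
    nucleus).  The default criterion is the ISODATA / Ridler-Calvard
    iteration -- the threshold equidistant from the two class means -- whose
    fixed point for this scene sits between the chamber and the tissue
    modes; plain Otsu can land a histogram bin below the chamber level and
    pull the whole chamber into the foreground.  ``threshold_override``
    bypasses the histogram criterion entirely.
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image, dtype=float)
    thr = (
        config.threshold_override
        if config.threshold_override is not None
        else filters.threshold_isodata(px)
    )
    return px > thr


def clean_mask(mask: np.ndarray, config: SsoctConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Remove small components, then close small gaps and holes."""
    cleaned = morphology.remove_small_objects(
        mask.astype(bool), max_size=config.min_object_px - 1
    )
    if config.closing_radius_px > 0:
        cleaned = morphology.closing(cleaned, morphology.disk(config.closing_radius_px))
    if not cleaned.any():
        raise SegmentationError("no lens candidate found")
    return cleaned


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationError("no lens candidate found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def extract_surfaces(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First/last foreground row per column of the dominant component.

    Returns ``(anterior_points, posterior_points)``, each an (n, 2) array
    of ``(x, y)`` pixel coordinates.
    """
    comp = _largest_component(np.asarray(mask, dtype=bool))
    cols = np.nonzero(comp.any(axis=0))[0]
    if len(cols) < 5:
        raise SegmentationError(
            f"component spans {len(cols)} columns; a quartic fit needs at least 5"
        )
    sub = comp[:, cols]
    top = sub.argmax(axis=0)
    bottom = sub.shape[0] - 1 - sub[::-1].argmax(axis=0)
    anterior = np.column_stack([cols, top]).astype(float)
    posterior = np.column_stack([cols, bottom]).astype(float)
    return anterior, posterior


def fit_quartic_with_correction(
    points: np.ndarray, deviation_threshold_px: float = 10.0
) -> tuple[QuarticCurve, int]:
    """Least-squares quartic with one outlier-correction pass.

    Points whose residual from the initial fit exceeds the threshold are
    flagged as local segmentation errors and the fit is re-run exactly
    once without them, which snaps the corrected points onto the smooth
    lens surface described by the refit curve.  (Re-using the first,
    outlier-contaminated curve as a replacement value would leak part of
    the error back into the refit.)
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    if len(pts) < 5:
        raise ValueError(f"quartic fit needs >= 5 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    fit = Polynomial.fit(x, y, 4)
    residuals = np.abs(y - fit(x))
    outliers = residuals > deviation_threshold_px
    n_corrected = int(outliers.sum())
    if n_corrected and (~outliers).sum() >= 5:
        fit = Polynomial.fit(x[~outliers], y[~outliers], 4)
    coef = fit.convert().coef
    if len(coef) < 5:
        coef = np.pad(coef, (0, 5 - len(coef)))
    return QuarticCurve(coef), n_corrected


def segment_lens(bscan: BScan, config: SsoctConfig = DEFAULT_CONFIG) -> LensSegmentation:
    """Full lens segmentation: stretch, threshold, clean, trace, fit."""
    if np.ptp(bscan.pixels) < config.min_contrast_piu:
        raise SegmentationError(
            "no lens candidate found: image contrast below "
            f"{config.min_contrast_piu} PIU"
        )
    pre = preprocess(bscan, config)
    mask = binarize(pre, config)
    mask = clean_mask(mask, config)
    anterior_pts, posterior_pts = extract_surfaces(mask)
    ant, n_ant = fit_quartic_with_correction(anterior_pts, config.deviation_threshold_px)
    post, n_post = fit_quartic_with_correction(posterior_pts, config.deviation_threshold_px)

    cols = anterior_pts[:, 0].astype(int)
    x_min, x_max = int(cols.min()), int(cols.max())
    H, W = bscan.shape
    xs = np.arange(x_min, x_max + 1)
    ya, yp = ant(xs), post(xs)
    rows = np.arange(H, dtype=float)[:, None]
    lens_mask = np.zeros((H, W), dtype=bool)
    valid = yp > ya
    lens_mask[:, xs[valid]] = (rows >= ya[valid]) & (rows <= yp[valid])
    if not lens_mask.any():
        raise SegmentationError("fitted lens surfaces enclose no pixels")
    return LensSegmentation(
        anterior=ant,
        posterior=post,
        lateral_extent=(x_min, x_max),
        mask=lens_mask,
        n_corrected_points=n_ant + n_post,
    )


def segment_chamber(
    bscan: BScan,
    lens_anterior: QuarticCurve,
    config: SsoctConfig = DEFAULT_CONFIG,
    lateral_extent: tuple[int, int] | None = None,
) -> ChamberROI:
    """Anterior-chamber background ROI below the cornea's posterior border.

    Canny edges are computed on the contrast-stretched image; per column,
    the deepest edge clearly anterior to the lens surface is taken as the
    cornea's posterior border (median-filtered across columns for
    coherence).  The ROI is the band strictly between that border and the
    lens anterior curve, eroded axially by ``chamber_margin_px``.
    """
    H, W = bscan.shape
    pre = preprocess(bscan, config)
    edges = feature.canny(pre.pixels / 255.0, sigma=config.canny_sigma)

    if lateral_extent is None:
        ya_all = lens_anterior(np.arange(W))
        ok = (ya_all > 0) & (ya_all < H)
        if not ok.any():
            raise SegmentationError("lens anterior curve lies outside the image")
        lateral_extent = (int(np.nonzero(ok)[0].min()), int(np.nonzero(ok)[0].max()))
    x_min, x_max = lateral_extent
    xs = np.arange(x_min, x_max + 1)
    ya = lens_anterior(xs)

    # Deepest edge at least one margin above the lens surface, per column.
    gap = config.chamber_margin_px + 2
    border = np.full(len(xs), -1.0)
    for i, x in enumerate(xs):
        rows_with_edges = np.nonzero(edges[:, x])[0]
        cand = rows_with_edges[rows_with_edges < ya[i] - gap]
        if len(cand):
            border[i] = cand.max()
    found = border >= 0
    if not found.any():
        raise SegmentationError("no cornea edge found anterior to the lens")
    border[~found] = np.median(border[found])
    border = median_filter(border, size=min(15, len(border)))

    rows = np.arange(H, dtype=float)[:, None]
    m = config.chamber_margin_px
    roi = np.zeros((H, W), dtype=bool)
    roi[:, xs] = (rows > border + m) & (rows < ya - m)
    return ChamberROI(mask=roi)


# ---------------------------------------------------------------------------
# densitometry (always on ORIGINAL pixels)
# ---------------------------------------------------------------------------

def _apply_central_margin(mask: np.ndarray, config: SsoctConfig) -> np.ndarray:
    if config.central_column_margin_px <= 0:
        return mask
    W = mask.shape[1]
    c = W // 2
    out = mask.copy()
    out[:, max(0, c - config.central_column_margin_px): c + config.central_column_margin_px + 1] = False
    return out


def lens_density(
    bscan: BScan, seg: LensSegmentation, config: SsoctConfig = DEFAULT_CONFIG
) -> float:
    """Mean original pixel intensity (PIU) inside the lens mask."""
    mask = _apply_central_margin(seg.mask, config)
    if not mask.any():
        raise SegmentationError("empty lens mask")
    return float(bscan.pixels[mask].mean())


def chamber_density(
    bscan: BScan, roi: ChamberROI, config: SsoctConfig = DEFAULT_CONFIG
) -> float:
    """Mean original pixel intensity (PIU) inside the chamber ROI."""
    mask = _apply_central_margin(roi.mask, config)
    if not mask.any():
        raise SegmentationError("empty chamber ROI")
    return float(bscan.pixels[mask].mean())


def corrected_density(raw_mean: float, chamber_mean: float) -> float:
    """Background-corrected opacity: lens mean minus chamber mean.

    Negative values are allowed (and flagged), since clamping would bias
    series averages; a negative corrected density usually indicates a
    segmentation failure.
    """
    if not np.isfinite(raw_mean) or not np.isfinite(chamber_mean):
        raise ValueError("density inputs must be finite")
    value = raw_mean - chamber_mean
    if value < 0:
        warnings.warn(
            f"negative corrected density ({value:.2f} PIU): possible segmentation failure",
            stacklevel=2,
        )
    return value


def nucleus_roi(seg: LensSegmentation, area_fraction: float = 0.14) -> EllipseROI:
    """Elliptical nuclear ROI at the lens centroid.

    The aspect ratio copies the lens proportions (half-width over central
    half-thickness) and the axes are scaled so the ellipse covers
    ``area_fraction`` of the lens mask area, then shrunk if necessary to
    stay strictly inside the mask.
    """
    if not 0 < area_fraction <= 0.5:
        raise ValueError("area_fraction must lie in (0, 0.5]")
    mask = seg.mask
    lens_area = int(mask.sum())
    ys, xs = np.nonzero(mask)
    cy, cx = float(ys.mean()), float(xs.mean())
    x_min, x_max = seg.lateral_extent
    half_width = (x_max - x_min) / 2.0
    xc = (x_min + x_max) / 2.0
    half_thickness = float(seg.posterior(xc) - seg.anterior(xc)) / 2.0
    if half_thickness <= 1 or half_width <= 1:
        raise SegmentationError("lens too thin to contain a nuclear ROI")
    ratio = half_width / half_thickness
    b = np.sqrt(area_fraction * lens_area / (np.pi * ratio))
    a = ratio * b

    for _ in range(120):
        roi = EllipseROI((cx, cy), a, b, area_fraction)
        pm = roi.pixel_mask(mask.shape)
        if pm.any() and not np.any(pm & ~mask):
            return roi
        a *= 0.97
        b *= 0.97
    raise SegmentationError("lens too thin to contain a valid nuclear ellipse")


def nucleus_density(
    bscan: BScan,
    roi: EllipseROI,
    chamber_mean: float,
    config: SsoctConfig = DEFAULT_CONFIG,
) -> float:
    """Background-corrected mean intensity inside the nuclear ellipse."""
    mask = _apply_central_margin(roi.pixel_mask(bscan.shape), config)
    if not mask.any():
        raise SegmentationError("empty nucleus ROI")
    return corrected_density(float(bscan.pixels[mask].mean()), chamber_mean)


def series_density(per_scan_values) -> float:
    """Series-level opacity: arithmetic mean of per-scan values."""
    values = np.asarray(per_scan_values, dtype=float)
    if values.size == 0:
        raise ValueError("series_density requires at least one value")
    return float(values.mean())


# ---------------------------------------------------------------------------
# A-scan (linear) densitometry
# ---------------------------------------------------------------------------

def detect_lens_range(
    profile: AScanProfile, config: SsoctConfig = DEFAULT_CONFIG
) -> tuple[int, int]:
    """Indices of the lens anterior and posterior capsule peaks.

    The profile is Gaussian-smoothed, prominent local maxima are ranked,
    and the four most prominent peaks ordered by depth are taken as the
    cornea anterior/posterior surfaces and the two lens capsules.  Returns
    the indices of the 3rd and 4th peak.
    """
    smooth = gaussian_filter1d(profile.intensity_au, config.ascan_smooth_sigma)
    peaks, props = find_peaks(smooth, prominence=config.ascan_peak_prominence)
    if len(peaks) < 4:
        raise SegmentationError(
            f"capsule interfaces not detected: {len(peaks)} peak(s) found, need 4"
        )
    strongest = peaks[np.argsort(props["prominences"])[-4:]]
    strongest.sort()
    return int(strongest[2]), int(strongest[3])


def linear_density(profile: AScanProfile, config: SsoctConfig = DEFAULT_CONFIG) -> float:
    """Mean normalized intensity between the two capsule peaks.

    The capsule peaks are specular interface reflections, not lens
    opacity, so the mean is taken over the open interval between them with
    ``capsule_margin_samples`` additionally excluded on each side.
    """
    i_ant, i_post = detect_lens_range(profile, config)
    lo = i_ant + config.capsule_margin_samples + 1
    hi = i_post - config.capsule_margin_samples
    if hi <= lo:
        raise SegmentationError("capsule peaks too close: no interior samples to average")
    return float(profile.intensity_au[lo:hi].mean())


# ---------------------------------------------------------------------------
# series orchestration
# ---------------------------------------------------------------------------

def analyze_series(
    scans,
    config: SsoctConfig = DEFAULT_CONFIG,
    profile: AScanProfile | None = None,
) -> DensityResult:
    """Run the full densitometry on a radial series of B-scans.

    Per scan: segment the lens, build the chamber ROI, read the raw lens,
    chamber and nucleus means from the original pixels.  Corrected lens
    and nucleus opacity subtract the per-scan chamber mean and then
    average over the series (equivalent, for equal weights, to averaging
    first and subtracting the averaged background).  If an axial profile
    is supplied, the linear density is computed as well.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("analyze_series requires at least one scan")
    lens_means, chamber_means, nucleus_means = [], [], []
    for scan in scans:
        seg = segment_lens(scan, config)
        chamber = segment_chamber(scan, seg.anterior, config, seg.lateral_extent)
        lens_means.append(lens_density(scan, seg, config))
        chamber_means.append(chamber_density(scan, chamber, config))
        roi = nucleus_roi(seg, config.nucleus_area_fraction)
        mask = _apply_central_margin(roi.pixel_mask(scan.shape), config)
        nucleus_means.append(float(scan.pixels[mask].mean()))
    lens_corr = series_density(
        [corrected_density(l, c) for l, c in zip(lens_means, chamber_means)]
    )
    nucleus_corr = series_density(
        [corrected_density(nm, c) for nm, c in zip(nucleus_means, chamber_means)]
    )
    return DensityResult(
        per_scan_lens_mean=lens_means,
        per_scan_chamber_mean=chamber_means,
        per_scan_nucleus_mean=nucleus_means,
        lens_corrected=lens_corr,
        nucleus_corrected=nucleus_corr,
        n_scans=len(scans),
        linear_au=None if profile is None else linear_density(profile, config),
    )
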