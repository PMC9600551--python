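"""Synthetic anterior-segment phantoms with known ground truth.

The generator emulates a swept-source anterior-segment acquisition: a
radial pattern of B-scans centered on the optical axis (15 scans of 14 mm
by default), each showing background, a corneal band, the optically clear
anterior chamber, and a crystalline lens bounded by two 4th-order
polynomial surfaces with a denser elliptical nucleus at its center.  Every
scan is returned together with exact region masks and the true surface
coefficients, so segmentation and densitometry can be scored against
ground truth.

Speckle is modelled as multiplicative Gaussian noise,
``pixel = region_value * (1 + eps)`` with ``eps ~ N(0, speckle_sd)``,
clipped to the 8-bit range.  The model is mean-preserving, so empirical
region means converge to the configured intensities as region area grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial

from .imgio import AScanProfile, BScan
from .stats import CohortRecord


class PhantomGeometryError(ValueError):
    """Raised when configured lens surfaces are geometrically impossible."""


# Snellen decimal acuity ladder, best to worst, used to discretize CDVA.
_SNELLEN_DECIMAL_STEPS = (1.0, 0.8, 0.63, 0.5, 0.4, 0.32, 0.25, 0.2, 0.16, 0.125, 0.1)


@dataclass
class PhantomParams:
    """Geometry, intensity and noise settings of the phantom scene.

    Depth ordering is anatomical: the corneal band starts at
    ``cornea_anterior_depth_px``, the chamber spans ``chamber_depth_px``
    below the cornea, and the lens apex sits at the bottom of the chamber.
    The two lens surfaces are quartic polynomials mapping lateral pixel
    column to axial row; when ``anterior_quartic``/``posterior_quartic``
    are left as ``None`` they are derived from the scalar geometry fields
    (apex depths plus typical sagittal rise/drop over the lens half-width).

    All intensities are on the 0-255 PIU scale.  ``nucleus_area_fraction``
    defaults to 0.14: on average the nucleus occupies 14% of the lens
    cross-sectional area.
    """

    image_height_px: int = 768
    image_width_px: int = 1024
    scan_width_mm: float = 14.0
    axial_px_mm: float = 64.0
    n_scans: int = 15
    cornea_anterior_depth_px: int = 60
    cornea_thickness_px: int = 35
    chamber_depth_px: int = 185
    lens_thickness_px: int = 280
    lens_width_px: int = 600
    anterior_quartic: tuple[float, ...] | None = None
    posterior_quartic: tuple[float, ...] | None = None
    intensity_background: float = 5.0
    intensity_cornea: float = 90.0
    intensity_chamber: float = 20.0
    intensity_cortex: float = 100.0
    intensity_nucleus: float = 140.0
    nucleus_area_fraction: float = 0.14
    speckle_sd: float = 0.1
    ascan_lens_plateau_au: float = 0.102
    ascan_peak_sigma_mm: float = 0.03
    seed: int = 0

    @property
    def lateral_px_mm(self) -> float:
        return self.image_width_px / self.scan_width_mm

    def __post_init__(self) -> None:
        for name in (
            "intensity_background",
            "intensity_cornea",
            "intensity_chamber",
            "intensity_cortex",
            "intensity_nucleus",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValueError("nucleus_area_fraction must lie in (0, 1)")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.lens_width_px < 8 or self.lens_thickness_px < 8:
            raise ValueError("lens must span at least 8 px in each direction")

    def surfaces(self) -> tuple[Polynomial, Polynomial]:
        """Anterior/posterior quartics in absolute pixel coordinates."""
        if self.anterior_quartic is not None and self.posterior_quartic is not None:
            return (
                Polynomial(np.asarray(self.anterior_quartic, dtype=float)),
                Polynomial(np.asarray(self.posterior_quartic, dtype=float)),
            )
        cx = self.image_width_px / 2.0
        h = self.lens_width_px / 2.0
        apex_ant = float(
            self.cornea_anterior_depth_px + self.cornea_thickness_px + self.chamber_depth_px
        )
        apex_post = apex_ant + self.lens_thickness_px
        # Sagittal rise/drop at the lens equator; the 20% quartic term gives
        # the surfaces genuinely 4th-order (non-parabolic) shape.
        rise = 0.40 * self.lens_thickness_px
        drop = 0.52 * self.lens_thickness_px
        x_shift = Polynomial([-cx, 1.0])
        ant_u = Polynomial([apex_ant, 0.0, 0.8 * rise / h**2, 0.0, 0.2 * rise / h**4])
        post_u = Polynomial([apex_post, 0.0, -0.8 * drop / h**2, 0.0, -0.2 * drop / h**4])
        return ant_u(x_shift), post_u(x_shift)


@dataclass
class PhantomTruth:
    """Exact ground truth for one rendered B-scan.

    Masks are boolean grids matching the image; ``nucleus_mask`` is a
    subset of ``lens_mask`` and the three top-level regions (lens, chamber)
    are pairwise disjoint.  ``region_means`` holds the noise-free mean
    intensity of each region.
    """

    anterior_curve: np.ndarray
    posterior_curve: np.ndarray
    lens_mask: np.ndarray
    nucleus_mask: np.ndarray
    chamber_mask: np.ndarray
    region_means: dict[str, float]
    seed: int


def _render_scene(params: PhantomParams) -> tuple[np.ndarray, PhantomTruth]:
    H, W = params.image_height_px, params.image_width_px
    ant, post = params.surfaces()
    cx = W / 2.0
    half = params.lens_width_px / 2.0
    cols = np.arange(W, dtype=float)
    ya = ant(cols)
    yp = post(cols)

    in_extent = np.abs(cols - cx) <= half
    if np.any(yp[in_extent] <= ya[in_extent]):
        raise PhantomGeometryError(
            "posterior lens surface not strictly deeper than anterior across the lens width"
        )
    if ya[in_extent].min() < params.cornea_anterior_depth_px + params.cornea_thickness_px:
        raise PhantomGeometryError("lens anterior surface intersects the cornea")

    rows = np.arange(H, dtype=float)[:, None]
    cornea_top = params.cornea_anterior_depth_px
    cornea_bot = cornea_top + params.cornea_thickness_px
    cornea_mask = (rows >= cornea_top) & (rows < cornea_bot) & np.ones(W, bool)

    lens_mask = in_extent & (rows >= ya) & (rows < yp)
    # Chamber: everything between the corneal posterior border and the lens
    # anterior surface (the quartic extended across the full width, clipped
    # to the image) -- the concave/convex region the background estimate uses.
    chamber_mask = (rows >= cornea_bot) & (rows < np.clip(ya, cornea_bot, H))

    # Nucleus: ellipse at the lens centroid, area = fraction of lens area,
    # aspect ratio matching the lens half-width : central half-thickness.
    lens_area = int(lens_mask.sum())
    if lens_area == 0:
        raise PhantomGeometryError("lens mask is empty for the configured geometry")
    ys, xs = np.nonzero(lens_mask)
    cyl, cxl = ys.mean(), xs.mean()
    central_half_thickness = (post(cx) - ant(cx)) / 2.0
    ratio = half / central_half_thickness
    b = np.sqrt(params.nucleus_area_fraction * lens_area / (np.pi * ratio))
    a = ratio * b
    X = np.arange(W, dtype=float)[None, :]
    nucleus_mask = ((X - cxl) / a) ** 2 + ((rows - cyl) / b) ** 2 <= 1.0
    nucleus_mask &= lens_mask

    img = np.full((H, W), params.intensity_background, dtype=float)
    img[cornea_mask] = params.intensity_cornea
    img[chamber_mask] = params.intensity_chamber
    img[lens_mask] = params.intensity_cortex
    img[nucleus_mask] = params.intensity_nucleus

    truth = PhantomTruth(
        anterior_curve=ant.coef.copy(),
        posterior_curve=post.coef.copy(),
        lens_mask=lens_mask,
        nucleus_mask=nucleus_mask,
        chamber_mask=chamber_mask,
        region_means={
            "background": params.intensity_background,
            "cornea": params.intensity_cornea,
            "chamber": params.intensity_chamber,
            "cortex": params.intensity_cortex,
            "nucleus": params.intensity_nucleus,
            "lens": float(
                np.mean(
                    np.where(nucleus_mask, params.intensity_nucleus, params.intensity_cortex)[
                        lens_mask
                    ]
                )
            ),
        },
        seed=params.seed,
    )
    return img, truth


def generate_bscan(
    params: PhantomParams, meridian_deg: float = 0.0
) -> tuple[BScan, PhantomTruth]:
    """Render one phantom B-scan at the given meridian.

    The phantom scene is rotationally symmetric, so geometry is identical
    across meridians; the speckle realization is independent per meridian
    but fully determined by ``(params.seed, meridian_deg)``.
    """
    img, truth = _render_scene(params)
    if params.speckle_sd > 0:
        rng = np.random.default_rng([params.seed, int(round(meridian_deg * 1000)) % 2**31])
        img = img * (1.0 + rng.normal(0.0, params.speckle_sd, size=img.shape))
        img = np.clip(img, 0.0, 255.0)
    bscan = BScan(
        pixels=img,
        axial_px_mm=params.axial_px_mm,
        lateral_px_mm=params.lateral_px_mm,
        meridian_deg=meridian_deg,
        source_id=f"phantom-seed{params.seed}-m{meridian_deg:g}",
    )
    return bscan, truth


def generate_radial_series(params: PhantomParams) -> list[tuple[BScan, PhantomTruth]]:
    """Render a radial series: ``n_scans`` meridians equally spaced over 0-180 deg.

    Half-turn B-scans cover the full circle, so 15 scans at 12-degree
    spacing emulate the acquisition protocol's radial pattern.
    """
    meridians = np.arange(params.n_scans) * (180.0 / params.n_scans)
    return [generate_bscan(params, m) for m in meridians]


def generate_ascan(
    params: PhantomParams, noise_sd: float = 0.0
) -> tuple[AScanProfile, np.ndarray]:
    """Synthesize an axial profile along the optical axis.

    The profile is on the normalized [0, 1] arbitrary-unit scale and shows
    four specular interface peaks -- corneal anterior/posterior surface and
    lens anterior/posterior capsule -- superimposed on tissue plateaus.
    The lens plateau defaults to 0.102 au, the magnitude of device-normalized
    lens backscatter.  Returns the profile and the four true interface
    depths (mm, strictly increasing).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    step_mm = 0.01
    total_mm = params.image_height_px / params.axial_px_mm
    depth = np.arange(step_mm, total_mm, step_mm)

    ax = params.axial_px_mm
    d_cornea_ant = params.cornea_anterior_depth_px / ax
    d_cornea_post = (params.cornea_anterior_depth_px + params.cornea_thickness_px) / ax
    d_lens_ant = d_cornea_post + params.chamber_depth_px / ax
    d_lens_post = d_lens_ant + params.lens_thickness_px / ax
    interfaces = np.array([d_cornea_ant, d_cornea_post, d_lens_ant, d_lens_post])

    prof = np.full_like(depth, params.intensity_background / 255.0 / 2.0)
    cornea_band = (depth >= d_cornea_ant) & (depth < d_cornea_post)
    prof[cornea_band] = params.intensity_cornea / 255.0 * 0.8
    chamber_band = (depth >= d_cornea_post) & (depth < d_lens_ant)
    prof[chamber_band] = params.intensity_chamber / 255.0 / 2.0
    lens_band = (depth >= d_lens_ant) & (depth < d_lens_post)
    prof[lens_band] = params.ascan_lens_plateau_au

    sigma = params.ascan_peak_sigma_mm
    for d, height in zip(interfaces, (0.90, 0.55, 0.50, 0.45)):
        prof = prof + height * np.exp(-0.5 * ((depth - d) / sigma) ** 2)

    if noise_sd > 0:
        rng = np.random.default_rng([params.seed, 2**20])
        prof = prof + rng.normal(0.0, noise_sd, size=prof.shape)
    prof = np.clip(prof, 0.0, 1.0)
    return AScanProfile(depth_mm=depth, intensity_au=prof), interfaces


@dataclass
class CohortModel:
    """Latent-severity model behind the simulated clinical cohort.

    Each eye draws a standard-normal latent cataract severity ``s``.  Every
    densitometry column is an affine transform of a noisy view of ``s``:

        column = mean + sd * (loading * s + sqrt(1 - loading^2) * eps)

    with ``eps ~ N(0, 1)`` independent per column, so the population
    correlation between any two columns is the product of their loadings
    and each column keeps its configured marginal mean and sd.  Defaults
    reproduce the magnitude of clinically reported densitometry scales
    (SS-OCT lens ~45 +/- 7 PIU, Scheimpflug ~12 +/- 3 %, linear ~0.10 au).

    Cumulative dissipated energy is a monotone (linear) function of
    severity plus noise, floored at zero and recorded only for eyes
    operated without the femtosecond laser; CDVA is a deterministic
    decreasing ordinal function of severity on the Snellen decimal ladder;
    the ordinal grade bins severity into sextiles 0-5 (a severity-quantile
    surrogate, not the proprietary nucleus-staging algorithm).
    """

    means: dict[str, float] = field(
        default_factory=lambda: {
            "lens_ssoct_piu": 44.78,
            "nucleus_ssoct_piu": 39.08,
            "linear_ssoct_au": 0.102,
            "lens_scheimpflug_pct": 12.3,
            "nucleus_scheimpflug_pct": 11.9,
            "linear_scheimpflug_pct": 12.5,
        }
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {
            "lens_ssoct_piu": 6.68,
            "nucleus_ssoct_piu": 12.91,
            "linear_ssoct_au": 0.017,
            "lens_scheimpflug_pct": 2.9,
            "nucleus_scheimpflug_pct": 4.1,
            "linear_scheimpflug_pct": 3.3,
        }
    )
    loadings: dict[str, float] = field(
        default_factory=lambda: {
            "lens_ssoct_piu": 0.9,
            "nucleus_ssoct_piu": 0.9,
            "linear_ssoct_au": 0.8,
            "lens_scheimpflug_pct": 0.7,
            "nucleus_scheimpflug_pct": 0.8,
            "linear_scheimpflug_pct": 0.7,
        }
    )
    cde_mean: float = 3.26
    cde_sd: float = 1.79
    cde_loading: float = 0.75
    femto_fraction: float = 0.2

    def validate(self) -> None:
        for col, lam in self.loadings.items():
            if not 0 < lam <= 1:
                raise ValueError(f"loading for {col} must lie in (0, 1], got {lam}")
        for col, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"sd for {col} must be positive, got {sd}")
        if not 0 < self.cde_loading <= 1:
            raise ValueError("cde_loading must lie in (0, 1]")
        if self.cde_sd <= 0:
            raise ValueError("cde_sd must be positive")
        if not 0 <= self.femto_fraction < 1:
            raise ValueError("femto_fraction must lie in [0, 1)")
        if set(self.means) != set(self.sds) or set(self.means) != set(self.loadings):
            raise ValueError("means, sds and loadings must cover the same columns")


def _cdva_from_severity(s: float) -> float:
    """Map latent severity to decimal Snellen acuity (decreasing in s)."""
    idx = int(np.clip((s + 2.5) / 5.0 * len(_SNELLEN_DECIMAL_STEPS), 0,
                      len(_SNELLEN_DECIMAL_STEPS) - 1))
    return _SNELLEN_DECIMAL_STEPS[idx]


# Sextile boundaries of N(0,1): severity -> ordinal grade 0..5.
_GRADE_BINS = (-0.9674, -0.4307, 0.0, 0.4307, 0.9674)


def generate_cohort(
    n_eyes: int, latent_model: CohortModel | None = None, seed: int = 0
) -> list[CohortRecord]:
    """Simulate a cohort of eyes with correlated densitometry columns."""
    if n_eyes < 3:
        raise ValueError("n_eyes must be >= 3")
    model = latent_model if latent_model is not None else CohortModel()
    model.validate()
    rng = np.random.default_rng([seed, 2**21])
    severity = rng.normal(0.0, 1.0, size=n_eyes)

    # Physical scale bounds per column; clipping affects only rare >3-sd
    # tail draws, so configured population correlations are preserved to
    # well below sampling error.
    bounds = {
        "lens_ssoct_piu": (0.0, 255.0),
        "nucleus_ssoct_piu": (0.0, 255.0),
        "linear_ssoct_au": (0.0, 1.0),
        "lens_scheimpflug_pct": (0.0, 100.0),
        "nucleus_scheimpflug_pct": (0.0, 100.0),
        "linear_scheimpflug_pct": (0.0, 100.0),
    }
    columns: dict[str, np.ndarray] = {}
    for col, lam in model.loadings.items():
        eps = rng.normal(0.0, 1.0, size=n_eyes)
        z = lam * severity + np.sqrt(1.0 - lam**2) * eps
        vals = model.means[col] + model.sds[col] * z
        lo, hi = bounds.get(col, (-np.inf, np.inf))
        columns[col] = np.clip(vals, lo, hi)

    femto = rng.random(n_eyes) < model.femto_fraction
    cde_eps = rng.normal(0.0, 1.0, size=n_eyes)
    cde_z = model.cde_loading * severity + np.sqrt(1.0 - model.cde_loading**2) * cde_eps
    cde = np.maximum(model.cde_mean + model.cde_sd * cde_z, 0.0)

    grades = np.digitize(severity, _GRADE_BINS)

    records = []
    for i in range(n_eyes):
        records.append(
            CohortRecord(
                eye_id=f"eye{i:04d}",
                lens_ssoct_piu=float(columns["lens_ssoct_piu"][i]),
                nucleus_ssoct_piu=float(columns["nucleus_ssoct_piu"][i]),
                linear_ssoct_au=float(columns["linear_ssoct_au"][i]),
                lens_scheimpflug_pct=float(columns["lens_scheimpflug_pct"][i]),
                nucleus_scheimpflug_pct=float(columns["nucleus_scheimpflug_pct"][i]),
                linear_scheimpflug_pct=float(columns["linear_scheimpflug_pct"][i]),
                grade_ordinal=int(grades[i]),
                cde_pcts=None if femto[i] else float(cde[i]),
                cdva=_cdva_from_severity(float(severity[i])),
                femto_flag=bool(femto[i]),
            )
        )
    return records
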