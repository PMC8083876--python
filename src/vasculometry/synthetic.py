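"""Synthetic cross-sections, vessel tables, TSS series and area pairs.

Every generator returns its ground truth alongside the artifact, so each
downstream stage (segmentation, morphometry, hydraulics, ripening kinetics,
allocation) can be tested against a known answer.  The derived truths
(idealized diameters, d_h, vessel density, relative lumen area, K) are
computed by the very morphometry and hydraulics operations used downstream,
applied to the true geometry -- the truth is self-consistent by
construction, not a parallel formula.

Vessel placement is rejection sampling: an ellipse is drawn from the
diameter distribution, rasterized at the working pixel size, dilated by the
minimum-gap radius, and accepted only if it stays inside the region and
touches no previously placed lumen.  Placement is capped at a hard attempt
budget so an infeasibly dense request fails loudly instead of looping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from vasculometry.morphometry import (
    VesselGeometry,
    VesselPopulation,
    idealized_diameter,
    hydraulically_weighted_diameter,
    relative_lumen_area,
    vessel_density,
)
from vasculometry.hydraulics import HydraulicConstants, conductivity

SIDECAR_COLUMNS = ["vessel_id", "cx_px", "cy_px", "a_um", "b_um", "theta_rad"]

#: working pixel size (um/px) for placement rasters and default rendering;
#: source imagery magnification is study-specific, this is a plausible
#: high-magnification light-microscopy scale
DEFAULT_PIXEL_SIZE_UM = 0.2


@dataclass(frozen=True)
class VesselSpec:
    """Distributional description of a vessel population.

    diameter_dist : dict
        Either ``{"name": "lognormal", "mu": ..., "sigma": ...}`` (mu, sigma
        on the log scale, diameters in um) or ``{"name": "class_mixture",
        "edges": [...], "weights": [...]}`` -- a mixture of uniforms over
        contiguous diameter classes, mirroring size-class abundance
        profiles.
    aspect_ratio_range : (lo, hi]
        Range of b/a sampled uniformly; 1.0 means circular.
    n_vessels : int
    min_gap_px : int
        Minimum boundary separation between lumina, in working pixels.
    """

    diameter_dist: dict = field(
        default_factory=lambda: {"name": "lognormal", "mu": float(np.log(7.0)), "sigma": 0.35}
    )
    aspect_ratio_range: tuple[float, float] = (0.7, 1.0)
    n_vessels: int = 250
    min_gap_px: int = 2
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        lo, hi = self.aspect_ratio_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("aspect_ratio_range must satisfy 0 < lo <= hi <= 1")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if self.min_gap_px < 0:
            raise ValueError("min_gap_px must be non-negative")


@dataclass(frozen=True)
class ImageSpec:
    """Rendering parameters for a synthetic cross-section."""

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    background_level: float = 0.15
    lumen_level: float = 0.85
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.lumen_level == self.background_level:
            raise ValueError("lumen_level must differ from background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """True geometry plus the derived morphometric/hydraulic truths.

    ``vessels`` columns: vessel_id, cx_px, cy_px, cx_um, cy_um, a_um, b_um,
    theta_rad, d_um, lumen_area_um2.  Derived scalars are the morphometry /
    hydraulics operations applied to the true geometry.
    """

    vessels: pd.DataFrame
    region_area_um2: float
    pixel_size_um: float
    d_h: float
    VD: float
    A_lumen_rel: float
    K: float

    def sidecar_frame(self) -> pd.DataFrame:
        return self.vessels[SIDECAR_COLUMNS].copy()

    def to_population(self, **labels) -> VesselPopulation:
        """True geometry as a VesselPopulation (manual-mode vessels)."""
        vessels = [
            VesselGeometry(
                vessel_id=int(r.vessel_id),
                a=float(r.a_um),
                b=float(r.b_um),
                lumen_area=float(np.pi * r.a_um * r.b_um),
                centroid=(float(r.cx_um), float(r.cy_um)),
                mode="manual",
            )
            for r in self.vessels.itertuples(index=False)
        ]
        return VesselPopulation(vessels, self.region_area_um2, **labels)


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested vessels."""


def _sample_diameters(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    name = dist.get("name", "lognormal")
    if name == "lognormal":
        d = rng.lognormal(mean=dist["mu"], sigma=dist["sigma"], size=n)
    elif name == "class_mixture":
        edges = np.asarray(dist["edges"], dtype=float)
        weights = np.asarray(dist["weights"], dtype=float)
        if len(weights) != len(edges) - 1:
            raise ValueError("class_mixture needs len(weights) == len(edges) - 1")
        weights = weights / weights.sum()
        cls = rng.choice(len(weights), size=n, p=weights)
        d = rng.uniform(edges[cls], edges[cls + 1])
    else:
        raise ValueError(f"unknown diameter distribution {name!r}")
    if np.any(d <= 0):
        raise ValueError("diameter distribution produced non-positive samples")
    return d


def _axes_from_diameter(d: float, q: float) -> tuple[float, float]:
    """Invert the idealized-diameter formula for given aspect ratio q = b/a."""
    a = d / (32.0 * q**3 / (1.0 + q**2)) ** 0.25
    return a, q * a


def _ellipse_mask_px(
    cx_px: float, cy_px: float, a_px: float, b_px: float, theta: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    # skimage rotates the ellipse clockwise in (row, col); using one helper
    # for placement and rendering keeps the two rasters identical
    return draw_ellipse(cy_px, cx_px, b_px, a_px, shape=shape, rotation=theta)


def generate_vessel_population(
    spec: VesselSpec,
    region_area_um2: float,
    seed: int,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    constants: HydraulicConstants | None = None,
) -> GroundTruth:
    """Place non-overlapping elliptical lumina in a square xylem region.

    The region is the square of area ``region_area_um2``; the placement
    raster works at ``pixel_size_um``.  Raises :class:`PlacementError` when
    the attempt budget is exhausted, naming the requested density.
    """
    if region_area_um2 <= 0:
        raise ValueError("region_area_um2 must be positive")
    rng = np.random.default_rng(seed)
    side_um = float(np.sqrt(region_area_um2))
    side_px = max(int(round(side_um / pixel_size_um)), 1)
    shape = (side_px, side_px)
    occupied = np.zeros(shape, dtype=bool)
    gap_structure = None
    if spec.min_gap_px > 0:
        gap_structure = ndimage.generate_binary_structure(2, 2)

    rows = []
    attempts = 0
    placed = 0
    while placed < spec.n_vessels:
        if attempts >= spec.max_attempts:
            raise PlacementError(
                f"placed only {placed}/{spec.n_vessels} vessels in "
                f"{spec.max_attempts} attempts: requested vessel density is too "
                f"high for region area {region_area_um2:g} um^2"
            )
        attempts += 1
        d = float(_sample_diameters(spec.diameter_dist, 1, rng)[0])
        q = float(rng.uniform(*spec.aspect_ratio_range))
        a_um, b_um = _axes_from_diameter(d, q)
        theta = float(rng.uniform(0.0, np.pi))
        a_px = a_um / pixel_size_um
        margin = a_px + spec.min_gap_px + 1
        if 2 * margin >= side_px:
            continue  # vessel cannot fit at all
        cx = float(rng.uniform(margin, side_px - margin))
        cy = float(rng.uniform(margin, side_px - margin))
        # rasterize and gap-test inside the local bounding window only
        r_lo = max(int(cy - margin) - 1, 0)
        c_lo = max(int(cx - margin) - 1, 0)
        r_hi = min(int(cy + margin) + 2, side_px)
        c_hi = min(int(cx + margin) + 2, side_px)
        win = (r_hi - r_lo, c_hi - c_lo)
        rr, cc = _ellipse_mask_px(
            cx - c_lo, cy - r_lo, a_px, b_um / pixel_size_um, theta, win
        )
        if rr.size == 0:
            continue
        cand = np.zeros(win, dtype=bool)
        cand[rr, cc] = True
        if spec.min_gap_px > 0:
            cand_test = ndimage.binary_dilation(
                cand, structure=gap_structure, iterations=spec.min_gap_px
            )
        else:
            cand_test = cand
        if np.any(cand_test & occupied[r_lo:r_hi, c_lo:c_hi]):
            continue
        occupied[r_lo:r_hi, c_lo:c_hi] |= cand
        placed += 1
        rows.append(
            {
                "vessel_id": placed,
                "cx_px": cx,
                "cy_px": cy,
                "cx_um": cx * pixel_size_um,
                "cy_um": cy * pixel_size_um,
                "a_um": a_um,
                "b_um": b_um,
                "theta_rad": theta,
                "d_um": idealized_diameter(a_um, b_um),
                "lumen_area_um2": np.pi * a_um * b_um,
            }
        )

    vessels = pd.DataFrame(rows)
    d_true = vessels["d_um"].to_numpy()
    return GroundTruth(
        vessels=vessels,
        region_area_um2=region_area_um2,
        pixel_size_um=pixel_size_um,
        d_h=hydraulically_weighted_diameter(d_true),
        VD=vessel_density(len(vessels), region_area_um2),
        A_lumen_rel=relative_lumen_area(vessels["lumen_area_um2"].tolist(), region_area_um2),
        K=conductivity(d_true, region_area_um2, constants),
    )


def render_cross_section(
    truth: GroundTruth, image_spec: ImageSpec
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a vessel population into a grayscale image.

    Lumina are filled ellipses at ``lumen_level`` over ``background_level``;
    i.i.d. Gaussian noise of sd ``noise_sd`` is added and the image clipped
    to [0, 1].  Returns the float image and the sidecar ground-truth table
    with pixel coordinates at the rendering pixel size.

    Raises ValueError naming the first vessel whose extent leaves the frame.
    """
    shape = (image_spec.height_px, image_spec.width_px)
    img = np.full(shape, image_spec.background_level, dtype=float)
    px = image_spec.pixel_size_um
    sidecar_rows = []
    for r in truth.vessels.itertuples(index=False):
        cx_px = r.cx_um / px
        cy_px = r.cy_um / px
        a_px = r.a_um / px
        if (
            cx_px - a_px < 0
            or cy_px - a_px < 0
            or cx_px + a_px > image_spec.width_px
            or cy_px + a_px > image_spec.height_px
        ):
            raise ValueError(
                f"vessel {r.vessel_id} extends outside the {image_spec.width_px}x"
                f"{image_spec.height_px} frame at {px} um/px"
            )
        rr, cc = _ellipse_mask_px(cx_px, cy_px, a_px, r.b_um / px, r.theta_rad, shape)
        img[rr, cc] = image_spec.lumen_level
        sidecar_rows.append(
            {
                "vessel_id": r.vessel_id,
                "cx_px": cx_px,
                "cy_px": cy_px,
                "a_um": r.a_um,
                "b_um": r.b_um,
                "theta_rad": r.theta_rad,
            }
        )
    if image_spec.noise_sd > 0:
        rng = np.random.default_rng(image_spec.seed)
        img = img + rng.normal(0.0, image_spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return img, pd.DataFrame(sidecar_rows, columns=SIDECAR_COLUMNS)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] float image as 16-bit grayscale TIFF (or PNG via imageio)."""
    path = Path(path)
    arr16 = np.round(np.clip(image, 0.0, 1.0) * 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr16)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr16)


def logistic_curve(x, Y0: float, YM: float, k: float):
    """Constrained logistic: Y(x) = YM*Y0 / ((YM-Y0) e^(-k x) + Y0)."""
    x = np.asarray(x, dtype=float)
    return YM * Y0 / ((YM - Y0) * np.exp(-k * x) + Y0)


def generate_tss_series(
    Y0: float,
    YM: float,
    k: float,
    timepoints: Sequence[float],
    noise_sd: float,
    seed: int,
    cultivar: str = "synthetic",
) -> pd.DataFrame:
    """Logistic TSS trajectory sampled at ``timepoints`` (days after anthesis)
    with additive i.i.d. Gaussian noise; columns ``cultivar, daa, brix``."""
    if not (0 < Y0 < YM):
        raise ValueError("require 0 < Y0 < YM (degenerate logistic otherwise)")
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    x = np.asarray(timepoints, dtype=float)
    if x.size == 0:
        raise ValueError("timepoints must be non-empty")
    y = logistic_curve(x, Y0, YM, k)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame({"cultivar": cultivar, "daa": x, "brix": y})


#: mean A_phloem/A_xylem by regime: receptacle xylem ~5x phloem, brush zone
#: phloem ~2x xylem
RATIO_REGIMES = {"receptacle": 0.2, "brush": 2.0}
_XYLEM_CV = 0.25


def generate_area_pairs(
    n: int,
    mean_axylem: float,
    ratio_regime: str,
    target_r: float,
    noise: float,
    seed: int,
) -> pd.DataFrame:
    """Bivariate (A_xylem, A_phloem) pairs with controlled Pearson correlation.

    The pair is bivariate normal: A_xylem around ``mean_axylem`` with a
    fixed 25% coefficient of variation, A_phloem around the regime mean with
    relative spread ``noise`` (its total coefficient of variation), and
    population correlation exactly ``target_r`` -- so the sample r converges
    to the target as n grows.  The regime sets E[A_phloem]/E[A_xylem] below
    1 (receptacle) or above 1 (brush).  The rare non-positive draw is
    resampled, which perturbs the correlation negligibly at these CVs.
    """
    if ratio_regime not in RATIO_REGIMES:
        raise ValueError(f"ratio_regime must be one of {sorted(RATIO_REGIMES)}")
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("target_r must be in [-1, 1]")
    if mean_axylem <= 0:
        raise ValueError("mean_axylem must be positive")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if noise == 0 and abs(target_r) < 1.0:
        raise ValueError("noise=0 is only feasible for |target_r| = 1 (collinear)")

    rng = np.random.default_rng(seed)
    mu_x = mean_axylem
    mu_p = RATIO_REGIMES[ratio_regime] * mean_axylem
    sd_x = _XYLEM_CV * mu_x
    sd_p = noise * mu_p

    def draw(m: int) -> tuple[np.ndarray, np.ndarray]:
        z1 = rng.standard_normal(m)
        x = mu_x + sd_x * z1
        if abs(target_r) == 1.0:
            p = mu_p + np.sign(target_r) * (mu_p / mu_x) * (x - mu_x)
        else:
            z2 = target_r * z1 + np.sqrt(1.0 - target_r**2) * rng.standard_normal(m)
            p = mu_p + sd_p * z2
        return x, p

    x, p = draw(n)
    bad = (x <= 0) | (p <= 0)
    guard = 0
    while np.any(bad):
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not generate positive area pairs")
        x_new, p_new = draw(int(bad.sum()))
        x[bad] = x_new
        p[bad] = p_new
        bad = (x <= 0) | (p <= 0)
    return pd.DataFrame({"a_xylem_um2": x, "a_phloem_um2": p})
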