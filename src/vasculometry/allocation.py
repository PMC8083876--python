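"""Xylem/phloem tissue-area allocation from traced masks.

Tissue regions are hand-traced upstream and arrive as binary masks; areas
are pixel counts times the pixel area.  When only a quadrant of a large
section fits the field of view, both areas are multiplied by 4 to estimate
the full transverse section (and flagged, since the extrapolation assumes
radial symmetry).  Ratios and Pearson correlations between phloem and xylem
areas are unaffected by the x4 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TissueAreas:
    """Xylem and phloem cross-sectional areas for one section (um^2)."""

    A_xylem: float
    A_phloem: float
    position: str = "receptacle"
    cultivar: str = ""
    stage: str = "post"  # pre- or post-veraison
    quadrant_extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.A_xylem <= 0 or self.A_phloem <= 0:
            raise ValueError("tissue areas must be positive")


def measure_tissue_areas(
    xylem_mask: np.ndarray,
    phloem_mask: np.ndarray,
    pixel_size_um: float,
    quadrant: bool = False,
    **labels,
) -> TissueAreas:
    """Pixel-count areas of disjoint xylem and phloem masks.

    Raises on overlapping masks (reporting the overlap pixel count) and on
    an empty mask, since every downstream ratio needs positive areas.
    """
    xylem_mask = np.asarray(xylem_mask).astype(bool)
    phloem_mask = np.asarray(phloem_mask).astype(bool)
    if xylem_mask.shape != phloem_mask.shape:
        raise ValueError("masks must have the same shape")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    overlap = int(np.sum(xylem_mask & phloem_mask))
    if overlap:
        raise ValueError(f"xylem and phloem masks overlap on {overlap} pixels")
    px2 = pixel_size_um**2
    ax = float(xylem_mask.sum()) * px2
    ap = float(phloem_mask.sum()) * px2
    if ax <= 0 or ap <= 0:
        raise ValueError("empty tissue mask: areas must be positive")
    scale = 4.0 if quadrant else 1.0
    return TissueAreas(
        A_xylem=ax * scale,
        A_phloem=ap * scale,
        quadrant_extrapolated=quadrant,
        **labels,
    )


def allocation_ratio(areas: TissueAreas) -> float:
    """A_phloem / A_xylem; below 1 indicates xylem-dominated allocation."""
    if areas.A_xylem <= 0:
        raise ValueError("A_xylem must be positive")
    return areas.A_phloem / areas.A_xylem


def area_correlation(pairs) -> tuple[float, float, int]:
    """Pearson correlation between phloem and xylem areas.

    ``pairs`` is a list of TissueAreas or a DataFrame with columns
    ``a_xylem_um2, a_phloem_um2``.  Returns (r, two-sided p, n); the
    headline contract is the estimate and n, with p reported alongside.
    """
    if isinstance(pairs, pd.DataFrame):
        x = np.asarray(pairs["a_xylem_um2"], dtype=float)
        y = np.asarray(pairs["a_phloem_um2"], dtype=float)
    else:
        x = np.array([p.A_xylem for p in pairs], dtype=float)
        y = np.array([p.A_phloem for p in pairs], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def ratio_table(frame: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Group summary of A_phloem/A_xylem ratios from an areas table.

    ``frame`` columns: ``a_xylem_um2, a_phloem_um2`` plus the grouping
    columns in ``by``.
    """
    out = frame.copy()
    out["ratio"] = out["a_phloem_um2"] / out["a_xylem_um2"]
    return (
        out.groupby(by, as_index=False)["ratio"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "ratio_mean", "std": "ratio_sd", "count": "n"})
    )
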