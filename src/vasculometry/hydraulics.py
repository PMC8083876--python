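"""Hagen-Poiseuille area-specific hydraulic conductivity.

Potential conductivity of a vessel population, normalized to the xylem
region area:

    K = (pi * rho / (128 * eta * A)) * sum(d^4)

with diameters converted um -> m and the region area um^2 -> m^2, viscosity
in MPa s, density in kg m^-3, giving K in kg m^-1 MPa^-1 s^-1.  The fourth
power makes the unit-conversion chain the dominant hazard (a factor-of-10
slip in d shifts K by 10^4), so conversion happens in this module only, via
two named constants.

The decomposition over 4-um diameter classes assigns each vessel to one
right-open bin and recomputes K per class against the SAME region area, so
class conductivities sum exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

UM_TO_M = 1e-6
UM2_TO_M2 = 1e-12

#: default 4-um class edges; five classes, vessels >= 20 um go to an
#: overflow class and are flagged
DEFAULT_CLASS_EDGES = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)


@dataclass(frozen=True)
class HydraulicConstants:
    """Physical constants for water at the reference temperature.

    eta : dynamic viscosity, MPa s (1.002e-9 MPa s = 1.002e-3 Pa s at 20 C)
    rho : density, kg m^-3
    """

    eta: float = 1.002e-9
    rho: float = 998.2
    reference_temp_c: float = 20.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass
class SizeClassTable:
    """Per-diameter-class vessel counts and conductivity contributions.

    ``table`` columns: class_label, d_lo_um, d_hi_um, n, abundance_pct,
    K_class, K_share_pct, overflow.  Abundances and K shares each sum to
    100%; class K values sum to the total K exactly.
    """

    table: pd.DataFrame
    edges: tuple[float, ...]
    n_overflow: int = 0

    @property
    def has_overflow(self) -> bool:
        return self.n_overflow > 0


@dataclass
class HydraulicSummary:
    K_total: float
    size_class_table: SizeClassTable
    constants: HydraulicConstants


def conductivity(
    d: Sequence[float],
    A_c_xylem: float,
    constants: HydraulicConstants | None = None,
) -> float:
    """Area-specific potential conductivity K (kg m^-1 MPa^-1 s^-1).

    Parameters
    ----------
    d : sequence of float
        Idealized vessel diameters, um.
    A_c_xylem : float
        Reference xylem area, um^2.
    """
    constants = constants or HydraulicConstants()
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("all diameters must be positive")
    if A_c_xylem <= 0:
        raise ValueError("A_c_xylem must be positive")
    d_m = d * UM_TO_M
    area_m2 = A_c_xylem * UM2_TO_M2
    prefactor = np.pi * constants.rho / (128.0 * constants.eta * area_m2)
    return float(prefactor * np.sum(d_m**4))


def size_class_decomposition(
    d: Sequence[float],
    A_c_xylem: float,
    edges: Sequence[float] | None = None,
    constants: HydraulicConstants | None = None,
) -> SizeClassTable:
    """Decompose K and vessel abundance over contiguous diameter classes.

    Bins are right-open [lo, hi); a vessel at or beyond the last edge is
    assigned to an overflow class (flagged) rather than dropped, preserving
    exact additivity of K over the partition.
    """
    constants = constants or HydraulicConstants()
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    edges_arr = np.asarray(edges if edges is not None else DEFAULT_CLASS_EDGES, dtype=float)
    if edges_arr.size < 2 or np.any(np.diff(edges_arr) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    if np.any(d < edges_arr[0]):
        raise ValueError("vessel diameter below the first bin edge")

    n_total = d.size
    K_total = conductivity(d, A_c_xylem, constants)
    rows = []
    for lo, hi in zip(edges_arr[:-1], edges_arr[1:]):
        in_class = (d >= lo) & (d < hi)
        n = int(in_class.sum())
        K_class = conductivity(d[in_class], A_c_xylem, constants) if n else 0.0
        rows.append(
            {
                "class_label": f"{lo:g}-{hi:g}",
                "d_lo_um": lo,
                "d_hi_um": hi,
                "n": n,
                "abundance_pct": 100.0 * n / n_total,
                "K_class": K_class,
                "K_share_pct": 100.0 * K_class / K_total,
                "overflow": False,
            }
        )
    over = d >= edges_arr[-1]
    n_over = int(over.sum())
    if n_over:
        K_over = conductivity(d[over], A_c_xylem, constants)
        rows.append(
            {
                "class_label": f">={edges_arr[-1]:g}",
                "d_lo_um": edges_arr[-1],
                "d_hi_um": np.inf,
                "n": n_over,
                "abundance_pct": 100.0 * n_over / n_total,
                "K_class": K_over,
                "K_share_pct": 100.0 * K_over / K_total,
                "overflow": True,
            }
        )
    return SizeClassTable(pd.DataFrame(rows), tuple(edges_arr), n_overflow=n_over)


def hydraulic_summary(
    d: Sequence[float],
    A_c_xylem: float,
    edges: Sequence[float] | None = None,
    constants: HydraulicConstants | None = None,
) -> HydraulicSummary:
    constants = constants or HydraulicConstants()
    return HydraulicSummary(
        K_total=conductivity(d, A_c_xylem, constants),
        size_class_table=size_class_decomposition(d, A_c_xylem, edges, constants),
        constants=constants,
    )


def conductivity_cov(K_values: Sequence[float]) -> float:
    """Coefficient of variation of replicate conductivities, percent.

    Sample (n-1) standard deviation over the mean, x100 -- appropriate for
    the small replicate counts (3-4) typical of anatomical studies.
    """
    K = np.asarray(K_values, dtype=float)
    if K.size < 2:
        raise ValueError("need at least 2 replicates for a CoV")
    mean = K.mean()
    if mean <= 0:
        raise ValueError("mean conductivity must be positive")
    return float(K.std(ddof=1) / mean * 100.0)
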