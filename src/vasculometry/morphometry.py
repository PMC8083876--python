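"""Per-vessel and per-population xylem morphometry.

A vessel lumen is treated as an ellipse with semi-major axis ``a`` and
semi-minor axis ``b`` (um).  From these the module derives the idealized
(hydraulic-equivalent circle) diameter ``d``, the conductance-weighted mean
diameter ``d_h = sum(d^5)/sum(d^4)``, vessel density (vessels per mm^2 of
xylem area), and the relative lumen area (total lumen area over xylem region
area).

All lengths are in um and areas in um^2; unit conversion to SI happens only
in :mod:`vasculometry.hydraulics` and at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

MeasureMode = Literal["feret", "moment", "manual"]

VESSEL_CSV_COLUMNS = ["vessel_id", "a_um", "b_um", "area_um2", "cx_um", "cy_um", "mode"]


@dataclass(frozen=True)
class VesselGeometry:
    """One vessel lumen.

    Parameters
    ----------
    vessel_id : int
        Identifier, unique within a population.
    a, b : float
        Semi-major and semi-minor axes in um.  In ``feret`` mode these are
        half the Feret and half the minimum-Feret caliper widths of the
        segmented region, matching the hand-drawn-ellipse convention.
    lumen_area : float
        Lumen cross-sectional area in um^2.  For segmented regions this is
        the pixel-count area; for manual ellipses it is ``pi*a*b``.
    centroid : tuple of float
        (x, y) position in um.
    mode : {"feret", "moment", "manual"}
        How the axes were measured.
    """

    vessel_id: int
    a: float
    b: float
    lumen_area: float
    centroid: tuple[float, float] = (0.0, 0.0)
    mode: MeasureMode = "feret"

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(
                f"vessel {self.vessel_id}: require a >= b > 0, got a={self.a}, b={self.b}"
            )
        if not self.lumen_area > 0:
            raise ValueError(f"vessel {self.vessel_id}: lumen_area must be > 0")


@dataclass
class VesselPopulation:
    """Vessels measured within one xylem region of one section.

    ``A_c_xylem`` is the reference xylem area (um^2) against which density,
    relative lumen area and area-specific conductivity are normalized.
    """

    vessels: list[VesselGeometry]
    A_c_xylem: float
    position: str = "receptacle"
    cultivar: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.A_c_xylem <= 0:
            raise ValueError("A_c_xylem must be positive")

    @property
    def n(self) -> int:
        return len(self.vessels)

    def diameters(self) -> np.ndarray:
        """Idealized diameter of every vessel (um)."""
        if not self.vessels:
            raise ValueError("population has no vessels")
        return np.array([idealized_diameter(v.a, v.b) for v in self.vessels])

    def total_lumen_area(self) -> float:
        return float(sum(v.lumen_area for v in self.vessels))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "vessel_id": v.vessel_id,
                "a_um": v.a,
                "b_um": v.b,
                "area_um2": v.lumen_area,
                "cx_um": v.centroid[0],
                "cy_um": v.centroid[1],
                "mode": v.mode,
            }
            for v in self.vessels
        ]
        return pd.DataFrame(rows, columns=VESSEL_CSV_COLUMNS)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        A_c_xylem: float,
        position: str = "receptacle",
        cultivar: str = "",
        replicate_id: str = "",
    ) -> "VesselPopulation":
        vessels = [
            VesselGeometry(
                vessel_id=int(r.vessel_id),
                a=float(r.a_um),
                b=float(r.b_um),
                lumen_area=float(r.area_um2),
                centroid=(float(getattr(r, "cx_um", 0.0)), float(getattr(r, "cy_um", 0.0))),
                mode=getattr(r, "mode", "feret"),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(vessels, A_c_xylem, position, cultivar, replicate_id)


@dataclass(frozen=True)
class MorphometrySummary:
    """Population-level descriptors.

    ``A_lumen_rel`` is stored as a dimensionless fraction; ``A_lumen_pct``
    exposes the same quantity x100.  Both readings are kept because summary
    tables in the field label this column "%" while printing values of
    fraction magnitude.
    """

    d_h: float
    VD: float
    A_lumen_rel: float
    n_vessels: int

    @property
    def A_lumen_pct(self) -> float:
        return self.A_lumen_rel * 100.0


def idealized_diameter(a: float, b: float) -> float:
    """Hydraulic-equivalent circle diameter of an elliptical lumen (um).

    d = (32 (a b)^3 / (a^2 + b^2))^(1/4).  For a circle (a == b == r) this
    reduces to 2r; for any ellipse it is at most the geometric-mean diameter
    2*sqrt(ab), with equality only in the circular case.
    """
    a = float(a)
    b = float(b)
    if a <= 0 or b <= 0:
        raise ValueError(f"semi-axes must be positive, got a={a}, b={b}")
    return float((32.0 * (a * b) ** 3 / (a**2 + b**2)) ** 0.25)


def hydraulically_weighted_diameter(d: Sequence[float]) -> float:
    """Conductance-weighted mean conduit diameter d_h = sum(d^5)/sum(d^4) (um).

    Weights each vessel by its fourth-power (Hagen-Poiseuille) contribution,
    so d_h >= mean(d) with equality only for uniform populations.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("all diameters must be positive")
    return float(np.sum(d**5) / np.sum(d**4))


def vessel_density(n: int, A_c_xylem: float) -> float:
    """Vessels per mm^2 of xylem area: VD = n / (A_c_xylem * 1e-6)."""
    if n < 0:
        raise ValueError("vessel count must be non-negative")
    if A_c_xylem <= 0:
        raise ValueError("A_c_xylem must be positive")
    return float(n) / (A_c_xylem * 1e-6)


def relative_lumen_area(
    vessels: Sequence[VesselGeometry] | Sequence[float], A_c_xylem: float
) -> float:
    """Total lumen area over xylem region area, as a fraction in (0, 1].

    Accepts either VesselGeometry objects or raw lumen areas in um^2.
    """
    if A_c_xylem <= 0:
        raise ValueError("A_c_xylem must be positive")
    areas = [v.lumen_area if isinstance(v, VesselGeometry) else float(v) for v in vessels]
    total = float(sum(areas))
    if total <= 0:
        raise ValueError("total lumen area must be positive")
    if total > A_c_xylem * (1 + 1e-12):
        raise ValueError(
            f"total lumen area {total:.4g} um^2 exceeds A_c_xylem {A_c_xylem:.4g} um^2; "
            "inconsistent region"
        )
    return min(total / A_c_xylem, 1.0)


def summarize_population(population: VesselPopulation) -> MorphometrySummary:
    """d_h, VD and relative lumen area for one vessel population."""
    d = population.diameters()
    return MorphometrySummary(
        d_h=hydraulically_weighted_diameter(d),
        VD=vessel_density(population.n, population.A_c_xylem),
        A_lumen_rel=relative_lumen_area(population.vessels, population.A_c_xylem),
        n_vessels=population.n,
    )


def summary_frame(populations: Sequence[VesselPopulation]) -> pd.DataFrame:
    """Tidy summary table, one row per population."""
    rows = []
    for p in populations:
        s = summarize_population(p)
        mode = p.vessels[0].mode if p.vessels else "feret"
        rows.append(
            {
                "cultivar": p.cultivar,
                "replicate": p.replicate_id,
                "position": p.position,
                "mode": mode,
                "n": s.n_vessels,
                "d_h_um": s.d_h,
                "VD_per_mm2": s.VD,
                "A_lumen_frac": s.A_lumen_rel,
            }
        )
    return pd.DataFrame(rows)
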