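"""Xylem anatomical traits and Hagen-Poiseuille theoretical conductivity.

From vessel lumen areas measured on a stem cross-section:

* equivalent circle diameter  D = 2*sqrt(area/pi)  (um),
* hydraulically weighted diameter  D_H = sum(D^5)/sum(D^4)  (um),
* vessel density  V_D = n / xylem area  (vessels mm^-2),
* theoretical specific hydraulic conductivity

      k_th = sum( pi * D^4 * rho / (128 * eta) ) / A_xyl

  with D in metres, rho = 998.2 kg m^-3 and eta = 1.002e-9 MPa s (water at
  20 C), giving k_th in kg s^-1 m^-1 MPa^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import VesselSet

#: Density of water at 20 C, kg m^-3.
RHO_WATER = 998.2
#: Dynamic viscosity of water at 20 C, in MPa s (equals 1.002e-3 Pa s).
ETA_WATER_MPA_S = 1.002e-9


@dataclass
class AnatomyTraits:
    """Anatomical traits for one cross-section."""

    section_id: str
    variety: str
    diameters_um: np.ndarray
    d_mean_um: float
    d_hydraulic_um: float
    vessel_density_mm2: float
    xylem_area_m2: float
    k_th: float | None = None


def vessel_metrics(vs: VesselSet) -> AnatomyTraits:
    """Diameters, hydraulically weighted diameter and vessel density.

    D_H = sum(d^5)/sum(d^4) weights each vessel by its conductive
    importance (Hagen-Poiseuille flow scales with d^4), so D_H always lies
    between the mean and the maximum diameter.
    """
    areas = vs.vessel_areas_um2
    d = 2.0 * np.sqrt(areas / np.pi)
    d_h = float(np.sum(d**5) / np.sum(d**4))
    v_d = len(d) / (vs.xylem_area_m2 * 1e6)  # m^2 -> mm^2
    return AnatomyTraits(
        section_id=vs.section_id,
        variety=vs.variety,
        diameters_um=d,
        d_mean_um=float(d.mean()),
        d_hydraulic_um=d_h,
        vessel_density_mm2=float(v_d),
        xylem_area_m2=vs.xylem_area_m2,
    )


def compute_kth(diameters_um: np.ndarray, xylem_area_m2: float) -> float:
    """Theoretical specific conductivity from the Hagen-Poiseuille law.

    Diameters are taken in um (the measurement unit) and converted to
    metres inside the summation.
    """
    if xylem_area_m2 <= 0:
        raise ValueError("xylem area must be positive")
    d_m = np.asarray(diameters_um, dtype=float) * 1e-6
    return float(np.sum(np.pi * d_m**4 * RHO_WATER / (128.0 * ETA_WATER_MPA_S)) / xylem_area_m2)


def analyze_section(vs: VesselSet) -> AnatomyTraits:
    """Full trait set for one cross-section, k_th included."""
    traits = vessel_metrics(vs)
    traits.k_th = compute_kth(traits.diameters_um, vs.xylem_area_m2)
    return traits


def traits_to_frame(traits: list[AnatomyTraits]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            section_id=t.section_id, variety=t.variety,
            d_mean_um=t.d_mean_um, d_hydraulic_um=t.d_hydraulic_um,
            vessel_density_mm2=t.vessel_density_mm2,
            xylem_area_m2=t.xylem_area_m2, k_th=t.k_th,
        )
        for t in traits
    )


def correlate_traits(
    anatomy: pd.DataFrame,
    fits: pd.DataFrame,
    anatomy_cols: tuple[str, ...] = ("d_mean_um", "d_hydraulic_um", "vessel_density_mm2", "k_th"),
    fit_cols: tuple[str, ...] = ("psi12_mean", "psi50_mean", "psi88_mean"),
) -> pd.DataFrame:
    """Pearson correlation screen between anatomical and hydraulic traits.

    Tables are matched on ``variety``; the report lists r, p and n for
    every (anatomy, hydraulic) column pair.  This is a descriptive screen,
    not a mixed-model analysis.
    """
    merged = anatomy.merge(fits, on="variety", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched varieties for a correlation screen")
    rows = []
    for ac in anatomy_cols:
        for fc in fit_cols:
            if ac not in merged.columns or fc not in merged.columns:
                continue
            r, p = stats.pearsonr(merged[ac], merged[fc])
            rows.append(dict(anatomy_trait=ac, hydraulic_trait=fc,
                             r=float(r), p=float(p), n=len(merged)))
    return pd.DataFrame(rows)
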