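"""Vulnerability-curve computation and sigmoid fitting.

A vulnerability curve (VC) describes the percentage loss of hydraulic
conductivity (PLC) of a xylem segment as a function of the xylem pressure
(water potential, MPa, negative) imposed on it.  The flow-centrifuge
protocol measures conductivity ``k_i`` at a series of increasingly negative
pressures starting at -0.8 MPa; PLC is expressed relative to the
conductivity at that first pressure::

    PLC_i = 100 * (1 - k_i / k_max)

The curve is summarised by the Pammenter sigmoid

    PLC(psi) = 100 / (1 + exp(S/25 * (psi - psi50)))

where ``psi50`` (MPa) is the pressure inducing 50% conductivity loss and
``S`` (% MPa^-1) is the slope at the inflexion point.  The onset and
lethal thresholds follow analytically:

    psi12 = psi50 + 50/S        psi88 = psi50 - 50/S

at which the sigmoid evaluates to 100/(1+e^2) ~ 11.92% and
100/(1+e^-2) ~ 88.08% respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


class UnusableSweepError(ValueError):
    """Raised when a conductivity sweep cannot yield a PLC curve."""


class FitError(ValueError):
    """Raised when a PLC curve is refused for fitting (too few points,
    insufficient PLC span, or a degenerate flat curve)."""


def pammenter(psi: np.ndarray | float, psi50: float, slope: float) -> np.ndarray | float:
    """Pammenter sigmoid: PLC (%) at xylem pressure ``psi`` (MPa)."""
    return 100.0 / (1.0 + np.exp(slope / 25.0 * (np.asarray(psi, dtype=float) - psi50)))


@dataclass
class ConductivitySweep:
    """One plant's (pressure, conductivity) measurements from a centrifuge run.

    ``psi`` must be strictly decreasing (the rotor only spins faster); the
    first reading, at -0.8 MPa under the standard protocol, provides the
    maximum-conductivity reference k_max.
    """

    plant_id: str
    psi: np.ndarray
    k: np.ndarray
    variety: str = ""
    season: str = ""
    organ: str = "stem"

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.psi.shape != self.k.shape:
            raise ValueError("psi and k must have the same length")
        if np.any(np.diff(self.psi) >= 0):
            raise ValueError("pressures must be strictly decreasing")
        if np.any(self.k < 0):
            raise ValueError("conductivities must be non-negative")


@dataclass
class PLCCurve:
    """Percent loss of conductivity at each pressure; first point is 0 by
    construction.  Negative values (noise pushing k_i above k_max) are
    retained for unbiased least squares and flagged via ``has_negative``."""

    plant_id: str
    psi: np.ndarray
    plc: np.ndarray
    variety: str = ""
    season: str = ""
    organ: str = "stem"

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.plc < 0))


@dataclass
class VulnerabilityFit:
    """Fitted sigmoid parameters with derived thresholds and diagnostics."""

    psi50: float
    slope: float
    psi12: float
    psi88: float
    sse: float
    converged: bool
    n_points: int
    plant_id: str = ""
    variety: str = ""
    season: str = ""
    organ: str = "stem"

    def predict(self, psi: np.ndarray | float) -> np.ndarray | float:
        return pammenter(psi, self.psi50, self.slope)


def compute_plc(sweep: ConductivitySweep) -> PLCCurve:
    """PLC relative to the first-pressure conductivity.

    k_max is always the reading at the first (least negative) pressure,
    never the maximum over the sweep: the protocol fixes the reference at
    -0.8 MPa.
    """
    k_max = sweep.k[0]
    if k_max == 0:
        raise UnusableSweepError(
            f"sweep {sweep.plant_id!r}: conductivity at the reference pressure is zero"
        )
    plc = 100.0 * (1.0 - sweep.k / k_max)
    return PLCCurve(
        plant_id=sweep.plant_id,
        psi=sweep.psi.copy(),
        plc=plc,
        variety=sweep.variety,
        season=sweep.season,
        organ=sweep.organ,
    )


def derive_thresholds(psi50: float, slope: float) -> tuple[float, float]:
    """(psi12, psi88) from the fitted parameters.

    psi12 = 50/S + psi50 and psi88 = -50/S + psi50; with S > 0 the ordering
    psi88 < psi50 < psi12 always holds.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    return 50.0 / slope + psi50, -50.0 / slope + psi50


def _init_psi50(psi: np.ndarray, plc: np.ndarray) -> float:
    """Initial psi50: pressure at PLC=50 by linear interpolation along the
    sweep, falling back to the median pressure when the curve never
    crosses 50."""
    below = plc < 50.0
    above = plc >= 50.0
    if below.any() and above.any():
        # first index where PLC crosses 50 going down-pressure
        for i in range(1, len(plc)):
            lo, hi = plc[i - 1], plc[i]
            if (lo - 50.0) * (hi - 50.0) <= 0 and hi != lo:
                frac = (50.0 - lo) / (hi - lo)
                return float(psi[i - 1] + frac * (psi[i] - psi[i - 1]))
    return float(np.median(psi))


def fit_pammenter(
    curve: PLCCurve | None = None,
    *,
    psi: Sequence[float] | None = None,
    plc: Sequence[float] | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-10.0, 0.0), (1e-6, 500.0)),
    slope_init: float = 50.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    min_points: int = 4,
    min_span: float = 30.0,
) -> VulnerabilityFit:
    """Least-squares fit of the Pammenter sigmoid to a PLC (or PEP) curve.

    Parameters
    ----------
    curve
        A :class:`PLCCurve`; alternatively pass raw ``psi`` and ``plc``
        arrays as keywords.
    bounds
        ``((psi50_lo, psi50_hi), (S_lo, S_hi))`` box constraints.
    min_points, min_span
        Curves with fewer points or a PLC range narrower than ``min_span``
        units are refused rather than silently fitted.

    Returns
    -------
    VulnerabilityFit
        With an honest ``converged`` flag; non-converged fits should be
        excluded from aggregation.
    """
    if curve is not None:
        x = np.asarray(curve.psi, dtype=float)
        y = np.asarray(curve.plc, dtype=float)
        meta = dict(
            plant_id=curve.plant_id, variety=curve.variety,
            season=curve.season, organ=curve.organ,
        )
    else:
        if psi is None or plc is None:
            raise TypeError("pass a PLCCurve or both psi= and plc=")
        x = np.asarray(psi, dtype=float)
        y = np.asarray(plc, dtype=float)
        meta = {}

    if len(x) < min_points:
        raise FitError(f"need at least {min_points} points, got {len(x)}")
    span = float(y.max() - y.min())
    if span < min_span:
        raise FitError(f"PLC span {span:.1f} < {min_span}: curve too flat to constrain the sigmoid")

    p50_0 = float(np.clip(_init_psi50(x, y), bounds[0][0], bounds[0][1]))
    s_0 = float(np.clip(slope_init, bounds[1][0], bounds[1][1]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return pammenter(x, theta[0], theta[1]) - y

    result = optimize.least_squares(
        residuals,
        x0=[p50_0, s_0],
        bounds=([bounds[0][0], bounds[1][0]], [bounds[0][1], bounds[1][1]]),
        ftol=tol, xtol=tol, gtol=tol,
        max_nfev=max_iter,
    )
    psi50_hat, slope_hat = float(result.x[0]), float(result.x[1])
    sse = float(np.sum(result.fun**2))
    psi12, psi88 = derive_thresholds(psi50_hat, slope_hat)
    return VulnerabilityFit(
        psi50=psi50_hat,
        slope=slope_hat,
        psi12=psi12,
        psi88=psi88,
        sse=sse,
        converged=bool(result.success),
        n_points=len(x),
        **meta,
    )


def fits_to_frame(fits: Iterable[VulnerabilityFit]) -> pd.DataFrame:
    """Tabulate fits (one row per plant) for aggregation and export."""
    rows = [
        dict(
            plant_id=f.plant_id, variety=f.variety, season=f.season, organ=f.organ,
            psi12=f.psi12, psi50=f.psi50, psi88=f.psi88, slope=f.slope,
            sse=f.sse, converged=f.converged, n_points=f.n_points,
        )
        for f in fits
    ]
    return pd.DataFrame(rows)


PARAM_COLUMNS = ("psi12", "psi50", "psi88", "slope")


def aggregate_variety(
    fits: pd.DataFrame | Iterable[VulnerabilityFit],
    by: Sequence[str] = ("variety", "season", "organ"),
) -> pd.DataFrame:
    """Mean and standard error of the fitted parameters per group.

    Only converged fits enter the means.  SE is NaN for single-plant
    groups (it is undefined, not zero).
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    if "converged" in df.columns:
        df = df[df["converged"]]
    if df.empty:
        raise ValueError("no converged fits to aggregate")
    by = [b for b in by if b in df.columns]
    grouped = df.groupby(list(by), sort=True)
    out = grouped[list(PARAM_COLUMNS)].agg(["mean", "sem", "count"])
    out.columns = [f"{p}_{s}" if s != "count" else "n_plants" for p, s in out.columns]
    # count is identical across params; keep a single n_plants column
    n = grouped.size().rename("n_plants")
    out = out.loc[:, ~out.columns.duplicated()]
    out["n_plants"] = n
    return out.reset_index()


def compare_groups(
    group_a: Sequence[VulnerabilityFit] | Sequence[float],
    group_b: Sequence[VulnerabilityFit] | Sequence[float],
    param: str = "psi50",
) -> tuple[float, float, float]:
    """Two-sided pooled-variance Student's t-test on one fitted parameter.

    Returns ``(delta, t, p)`` with ``delta = mean(b) - mean(a)``.  When the
    pooled variance is zero the statistic is degenerate: identical groups
    give (0, 0, 1); distinct constant groups give an infinite t.
    """

    def values(group) -> np.ndarray:
        arr = [getattr(g, param) if isinstance(g, VulnerabilityFit) else g for g in group]
        return np.asarray(arr, dtype=float)

    a, b = values(group_a), values(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    delta = float(b.mean() - a.mean())
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        if delta == 0.0:
            return 0.0, 0.0, 1.0
        return delta, math.inf if delta > 0 else -math.inf, 0.0
    t = delta / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return delta, float(t), float(p)


@dataclass
class SegmentationResult:
    """Hydraulic vulnerability segmentation: leaf minus stem thresholds.

    Positive values mean the leaf embolizes at less negative potentials
    than the stem — the leaf acts as a hydraulic fuse."""

    variety: str
    season: str
    leaf_position: str
    hvs_psi12: float
    hvs_psi50: float


def compute_hvs(
    leaf: dict | pd.Series,
    stem: dict | pd.Series,
    leaf_position: str = "",
) -> SegmentationResult:
    """HVS_psiX = psiX(leaf) - psiX(stem) for matched variety and season.

    ``leaf`` and ``stem`` are summary rows (from :func:`aggregate_variety`)
    carrying ``variety``, ``season``, ``psi12_mean`` and ``psi50_mean``.
    """
    lv, sv = leaf["variety"], stem["variety"]
    ls, ss = leaf["season"], stem["season"]
    if lv != sv or ls != ss:
        raise ValueError(f"variety/season mismatch: leaf ({lv}, {ls}) vs stem ({sv}, {ss})")
    return SegmentationResult(
        variety=str(lv),
        season=str(ls),
        leaf_position=leaf_position or str(leaf.get("leaf_position", "")),
        hvs_psi12=float(leaf["psi12_mean"] - stem["psi12_mean"]),
        hvs_psi50=float(leaf["psi50_mean"] - stem["psi50_mean"]),
    )
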