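"""Regional risk index of drought vulnerability.

Each wine region's winegrape bearing area is split by variety; varieties
carry a vulnerability-cluster label with weight 0.125 (low), 0.375
(low-to-medium), 0.625 (medium-to-high) or 0.875 (high).  With cluster
bearing areas expressed as percent of the total regional winegrape area,

    RI = 0.125*area[low] + 0.375*area[low-to-medium]
       + 0.625*area[medium-to-high] + 0.875*area[high]

so RI ranges from 0 to 87.5.  Area planted with varieties outside the
panel contributes nothing to RI (it dilutes the index), and the index is
only reported for regions where the panel covers at least 40% of the
regional bearing area.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clustering import CLUSTER_LABELS, CLUSTER_WEIGHTS

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 40.0


def cluster_areas(
    bearing: pd.DataFrame,
    assignment: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region bearing area (%) of each vulnerability cluster.

    ``bearing`` is the long-format table (region, country, variety,
    bearing_percent); ``assignment`` maps variety -> cluster.  Varieties
    absent from the assignment are logged and treated as uncovered area:
    they enter the regional denominator (the percents are already relative
    to the total regional area) but no cluster.  Coverage is the summed
    percent over panel varieties.
    """
    if (bearing["bearing_percent"] < 0).any():
        raise ValueError("bearing_percent must be non-negative")
    cluster_of = dict(zip(assignment["variety"], assignment["cluster"]))
    unknown = sorted(set(bearing["variety"]) - cluster_of.keys())
    if unknown:
        logger.info("varieties without cluster label treated as uncovered: %s", unknown)
    df = bearing.copy()
    df["cluster"] = df["variety"].map(cluster_of)
    covered = df.dropna(subset=["cluster"])
    pivot = (
        covered.pivot_table(
            index=["region", "country"], columns="cluster",
            values="bearing_percent", aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=list(CLUSTER_LABELS), fill_value=0.0)
        .reset_index()
    )
    # regions whose every variety is unknown still get a (zero) row
    all_regions = bearing[["region", "country"]].drop_duplicates()
    pivot = all_regions.merge(pivot, on=["region", "country"], how="left").fillna(0.0)
    pivot["coverage_percent"] = pivot[list(CLUSTER_LABELS)].sum(axis=1)
    return pivot


def compute_ri(cluster_area: np.ndarray | pd.Series | dict) -> float:
    """Risk index from a (low, low-to-medium, medium-to-high, high) area
    vector in percent of the regional winegrape area."""
    if isinstance(cluster_area, dict):
        areas = np.array([cluster_area[c] for c in CLUSTER_LABELS], dtype=float)
    elif isinstance(cluster_area, pd.Series):
        areas = cluster_area.reindex(list(CLUSTER_LABELS)).to_numpy(dtype=float)
    else:
        areas = np.asarray(cluster_area, dtype=float)
    if areas.shape != (4,):
        raise ValueError("expected a 4-component cluster-area vector")
    if (areas < 0).any() or areas.sum() > 100.0 + 1e-9:
        raise ValueError("cluster areas must be non-negative and sum to at most 100%")
    weights = np.array([CLUSTER_WEIGHTS[c] for c in CLUSTER_LABELS])
    return float(weights @ areas)


def filter_regions(risks: pd.DataFrame, min_coverage: float = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Mark regions whose panel coverage reaches the reporting threshold.

    The threshold is inclusive: coverage of exactly ``min_coverage``
    percent is reported.  Excluded regions stay in the table with
    ``included=False``.
    """
    out = risks.copy()
    out["included"] = out["coverage_percent"] >= min_coverage
    return out


def regional_risk(
    bearing: pd.DataFrame,
    assignment: pd.DataFrame,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Full chain: cluster areas -> RI -> coverage filter, one row per region."""
    areas = cluster_areas(bearing, assignment)
    areas["ri"] = [
        compute_ri(row[list(CLUSTER_LABELS)]) for _, row in areas.iterrows()
    ]
    return filter_regions(areas, min_coverage)


def ri_report(
    risks: pd.DataFrame,
    band: tuple[float, float] = (20.0, 40.0),
) -> tuple[pd.DataFrame, dict]:
    """Map-ready per-region table plus distribution summary.

    The summary gives min, max, n_regions and the share of included
    regions whose RI falls in the inclusive ``band`` (the mid-risk band
    used to characterise the global distribution).
    """
    included = risks[risks["included"]]
    if included.empty:
        raise ValueError("no region passes the coverage filter")
    ri = included["ri"]
    in_band = ((ri >= band[0]) & (ri <= band[1])).mean()
    summary = dict(
        n_regions=int(len(included)),
        ri_min=float(ri.min()),
        ri_max=float(ri.max()),
        band=list(band),
        band_share_percent=float(100.0 * in_band),
    )
    cols = ["region", "country", "coverage_percent", *CLUSTER_LABELS, "ri", "included"]
    return risks[cols].copy(), summary
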