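"""Plain-text and TIFF I/O for pipeline artefacts.

Tabular data travel as CSV with documented headers, image stacks as
multi-page TIFF, and everything else (truth logs, QC, manifests) as JSON.

CSV schemas
-----------
sweeps.csv   : plant_id, variety, season, organ, psi_mpa, k
vessels.csv  : section_id, variety, vessel_area_um2, xylem_area_m2
psi.csv      : time_min, psi_mpa
bearing.csv  : region, country, variety, bearing_percent
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .synthetic import ImageStack, VesselSet, WaterPotentialTimeline
from .vcfit import ConductivitySweep


def write_sweeps(sweeps: Iterable[ConductivitySweep], path: str | Path) -> None:
    rows = []
    for s in sweeps:
        for psi, k in zip(s.psi, s.k):
            rows.append(dict(plant_id=s.plant_id, variety=s.variety, season=s.season,
                             organ=s.organ, psi_mpa=psi, k=k))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sweeps(path: str | Path) -> list[ConductivitySweep]:
    df = pd.read_csv(path)
    sweeps = []
    for pid, g in df.groupby("plant_id", sort=False):
        g = g.sort_values("psi_mpa", ascending=False)
        sweeps.append(
            ConductivitySweep(
                plant_id=str(pid),
                psi=g["psi_mpa"].to_numpy(),
                k=g["k"].to_numpy(),
                variety=str(g["variety"].iloc[0]),
                season=str(g["season"].iloc[0]),
                organ=str(g["organ"].iloc[0]),
            )
        )
    return sweeps


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.frames, photometric="minisblack", metadata=dict(
        timestamps_min=stack.timestamps.tolist(),
        variety=stack.variety, leaf_position=stack.leaf_position, season=stack.season,
    ))


def read_stack(path: str | Path, frame_interval_min: float = 5.0) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    ts = meta.get("timestamps_min")
    timestamps = np.asarray(ts, dtype=float) if ts is not None else (
        frame_interval_min * np.arange(frames.shape[0], dtype=float)
    )
    return ImageStack(
        frames=frames, timestamps=timestamps,
        variety=str(meta.get("variety", "")),
        leaf_position=str(meta.get("leaf_position", "basal")),
        season=str(meta.get("season", "")),
    )


def write_timeline(tl: WaterPotentialTimeline, path: str | Path) -> None:
    pd.DataFrame(dict(time_min=tl.time_min, psi_mpa=tl.psi)).to_csv(path, index=False)


def read_timeline(path: str | Path) -> WaterPotentialTimeline:
    df = pd.read_csv(path)
    return WaterPotentialTimeline(time_min=df["time_min"].to_numpy(),
                                  psi=df["psi_mpa"].to_numpy())


def write_vessels(sets: Iterable[VesselSet], path: str | Path) -> None:
    rows = []
    for vs in sets:
        for a in vs.vessel_areas_um2:
            rows.append(dict(section_id=vs.section_id, variety=vs.variety,
                             vessel_area_um2=a, xylem_area_m2=vs.xylem_area_m2))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vessels(path: str | Path) -> list[VesselSet]:
    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("section_id", sort=False):
        out.append(VesselSet(
            section_id=str(sid),
            vessel_areas_um2=g["vessel_area_um2"].to_numpy(),
            xylem_area_m2=float(g["xylem_area_m2"].iloc[0]),
            variety=str(g["variety"].iloc[0]),
        ))
    return out


def read_bearing(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"region", "country", "variety", "bearing_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bearing table missing columns: {sorted(missing)}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
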