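"""Synthetic-data generators for every pipeline input.

Raw centrifuge sweeps, leaf dehydration image stacks, psychrometer
timelines, vessel tables and regional bearing-area tables are generated
with the statistical structure the downstream analysis assumes, so every
stage is testable without access to laboratory data.  Each generator is
deterministic for a given seed and returns, alongside its output, a
machine-readable truth log sufficient for parameter- and event-recovery
tests.

Conventions
-----------
* Sweeps follow the centrifuge protocol: pressures start at -0.8 MPa and
  step by -0.5 MPa (default grid of 10 points down to -5.3 MPa).
* Conductivity noise is multiplicative Gaussian with a coefficient of
  variation ``noise_cv`` — measurement error scales with the magnitude of
  the flow being measured.
* Image-stack events are contiguous disc-shaped blobs whose intensity step
  is well above the background noise by default, so detector threshold
  behaviour is controllable in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .vcfit import ConductivitySweep, pammenter

#: Standard centrifuge pressure grid: -0.8 MPa start, -0.5 MPa steps, 10 points.
DEFAULT_PRESSURES: tuple[float, ...] = tuple(np.round(-0.8 + -0.5 * np.arange(10), 10))


@dataclass
class VarietyTruth:
    """Generative ground truth for one variety.

    ``true_psi50`` (MPa, negative) and ``true_slope`` (% MPa^-1, positive)
    are the variety-level sigmoid parameters; plants within the variety
    draw their own parameters from Normal(truth, plant_sd).
    """

    variety_name: str
    true_psi50: float
    true_slope: float
    plant_sd_psi50: float = 0.0
    plant_sd_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.true_psi50 >= 0:
            raise ValueError("true_psi50 must be negative (a xylem tension)")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")
        if self.plant_sd_psi50 < 0 or self.plant_sd_slope < 0:
            raise ValueError("plant-level standard deviations must be non-negative")


@dataclass
class WaterPotentialTimeline:
    """Stem water potential readings: (time since start in minutes, MPa)."""

    time_min: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ImageStack:
    """Ordered 8-bit grayscale frames at fixed (5-min) spacing."""

    frames: np.ndarray          # (n_frames, h, w) uint8
    timestamps: np.ndarray      # minutes since start
    variety: str = ""
    leaf_position: str = "basal"
    season: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames of constant shape")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_sweep(
    truth: VarietyTruth,
    pressures: Sequence[float] | None = None,
    noise_cv: float = 0.05,
    seed=None,
    plant_id: str = "plant-1",
    season: str = "summer",
    organ: str = "stem",
    k_max: float = 2.0,
) -> tuple[ConductivitySweep, dict]:
    """One plant's conductivity sweep drawn from variety truth.

    Conductivities follow ``k(psi) = k_max * (1 - PLC(psi)/100) * (1 + eps)``
    with ``eps ~ Normal(0, noise_cv)``; negative draws are clipped at zero
    (a flow meter cannot read a negative flow).  Returns the sweep and a
    truth record with the plant-level (psi50, S) actually drawn.
    """
    rng = _rng(seed)
    psi = np.asarray(pressures if pressures is not None else DEFAULT_PRESSURES, dtype=float)
    if np.any(np.diff(psi) >= 0):
        raise ValueError("pressure grid must be strictly decreasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    psi50 = truth.true_psi50 + rng.normal(0.0, truth.plant_sd_psi50) if truth.plant_sd_psi50 else truth.true_psi50
    slope = truth.true_slope + rng.normal(0.0, truth.plant_sd_slope) if truth.plant_sd_slope else truth.true_slope
    slope = max(slope, 1.0)  # a vulnerability curve cannot have a flat or inverted slope
    plc_true = pammenter(psi, psi50, slope)
    k = k_max * (1.0 - plc_true / 100.0)
    if noise_cv > 0:
        k = k * (1.0 + rng.normal(0.0, noise_cv, size=k.shape))
        k = np.clip(k, 0.0, None)
        if k[0] <= 0:  # reference reading must stay usable
            k[0] = k_max * 1e-6
    sweep = ConductivitySweep(
        plant_id=plant_id, psi=psi, k=k,
        variety=truth.variety_name, season=season, organ=organ,
    )
    truth_rec = dict(
        plant_id=plant_id, variety=truth.variety_name, season=season, organ=organ,
        psi50=float(psi50), slope=float(slope), k_max=float(k_max), noise_cv=float(noise_cv),
    )
    return sweep, truth_rec


def gen_cohort(
    varieties: Sequence[VarietyTruth],
    n_plants_per_variety: int = 6,
    pressures: Sequence[float] | None = None,
    noise_cv: float = 0.05,
    seed=None,
    season: str = "summer",
    organ: str = "stem",
) -> tuple[list[ConductivitySweep], pd.DataFrame]:
    """A cohort of sweeps across varieties, with the per-plant truth table."""
    if n_plants_per_variety < 1:
        raise ValueError("need at least one plant per variety")
    rng = _rng(seed)
    sweeps: list[ConductivitySweep] = []
    records: list[dict] = []
    for vt in varieties:
        for j in range(n_plants_per_variety):
            pid = f"{vt.variety_name}-{season}-{j + 1:02d}"
            sweep, rec = gen_sweep(
                vt, pressures=pressures, noise_cv=noise_cv, seed=rng,
                plant_id=pid, season=season, organ=organ,
            )
            sweeps.append(sweep)
            records.append(rec)
    return sweeps, pd.DataFrame(records)


def _disc_mask(shape: tuple[int, int], center: tuple[int, int], area_px: int) -> np.ndarray:
    """Boolean mask of the ``area_px`` in-bounds pixels nearest to ``center``
    (a filled quasi-disc; contiguous under 8-connectivity)."""
    h, w = shape
    r0, c0 = center
    rr, cc = np.mgrid[0:h, 0:w]
    dist = (rr - r0) ** 2 + (cc - c0) ** 2
    order = np.argsort(dist.ravel(), kind="stable")[:area_px]
    mask = np.zeros(h * w, dtype=bool)
    mask[order] = True
    return mask.reshape(h, w)


def gen_dehydration_stack(
    n_frames: int,
    frame_shape: tuple[int, int],
    events: Sequence[tuple[int, int, tuple[int, int]]],
    background_noise_sd: float = 0.0,
    seed=None,
    base_intensity: int = 120,
    event_step: int = 40,
    frame_interval_min: float = 5.0,
    **stack_meta,
) -> tuple[ImageStack, dict]:
    """Leaf dehydration stack with injected embolism events.

    Each event ``(frame_index, area_px, (row, col))`` permanently brightens
    a contiguous blob of ``area_px`` pixels starting at ``frame_index`` —
    an abrupt light-transmission change between consecutive scans, which is
    what the optical method detects.  Additive Gaussian background noise is
    applied independently per frame.  Overlapping same-frame events are
    allowed; the truth log records the *new* pixels each event contributes.
    """
    rng = _rng(seed)
    h, w = frame_shape
    base = np.full((h, w), float(base_intensity))
    cum_mask = np.zeros((h, w), dtype=bool)
    event_log: list[dict] = []
    overlaps = 0

    per_frame_new = [np.zeros((h, w), dtype=bool) for _ in range(n_frames)]
    for frame_idx, area_px, (r, c) in events:
        if not (0 <= frame_idx < n_frames):
            raise ValueError(f"event frame {frame_idx} outside stack of {n_frames} frames")
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"event position ({r}, {c}) outside frame {frame_shape}")
        if area_px < 1:
            raise ValueError("event area must be at least 1 px")
        mask = _disc_mask((h, w), (r, c), area_px)
        new = mask & ~cum_mask & ~per_frame_new[frame_idx]
        if new.sum() < mask.sum():
            overlaps += 1
        per_frame_new[frame_idx] |= new
        cum_mask |= mask
        event_log.append(dict(frame=int(frame_idx), area_px=int(new.sum()),
                              requested_px=int(area_px), centroid=[int(r), int(c)]))

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    lit = np.zeros((h, w), dtype=bool)
    for i in range(n_frames):
        lit |= per_frame_new[i]
        img = base + event_step * lit
        if background_noise_sd > 0:
            img = img + rng.normal(0.0, background_noise_sd, size=(h, w))
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    timestamps = frame_interval_min * np.arange(n_frames, dtype=float)
    stack = ImageStack(frames=frames, timestamps=timestamps, **stack_meta)
    truth = dict(
        events=event_log,
        n_events=len(event_log),
        total_px=int(sum(e["area_px"] for e in event_log)),
        overlapping_events=overlaps,
        event_step=event_step,
        background_noise_sd=background_noise_sd,
    )
    return stack, truth


def gen_psi_timeline(
    psi_start: float = -0.5,
    psi_end: float = -2.5,
    duration_h: float = 130.0,
    interval_min: float = 30.0,
    shape: str = "linear",
    seed=None,
) -> WaterPotentialTimeline:
    """Monotone non-increasing stem water potential drydown.

    Defaults emulate a summer dehydration: psychrometer logging every
    30 min over ~130 h (a spring drydown is closer to 80 h).  ``shape`` is
    ``"linear"`` or ``"exponential"`` (asymptotic approach to ``psi_end``).
    """
    if psi_start <= psi_end:
        raise ValueError("psi_start must be less negative than psi_end")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration_h * 60.0 + 0.5 * interval_min, interval_min)
    frac = t / t[-1]
    if shape == "linear":
        psi = psi_start + (psi_end - psi_start) * frac
    elif shape == "exponential":
        # ~95% of the drop completed by the end of the record
        rate = 3.0
        psi = psi_end + (psi_start - psi_end) * (np.exp(-rate * frac) - math.exp(-rate)) / (1 - math.exp(-rate))
    else:
        raise ValueError(f"unknown drydown shape {shape!r}")
    return WaterPotentialTimeline(time_min=t, psi=psi)


def gen_sigmoid_stack(
    truth_psi50: float,
    truth_slope: float,
    timeline: WaterPotentialTimeline,
    n_frames: int = 150,
    total_px: int = 4000,
    min_event_px: int = 25,
    frame_shape: tuple[int, int] = (256, 256),
    background_noise_sd: float = 0.0,
    seed=None,
    frame_interval_min: float = 5.0,
    **stack_meta,
) -> tuple[ImageStack, dict]:
    """Dehydration stack whose cumulative embolized area follows a known
    sigmoid along the supplied drydown.

    The target cumulative pixel count at each frame is the Pammenter
    sigmoid of the interpolated water potential, scaled to ``total_px``;
    per-frame increments of at least ``min_event_px`` become events.
    Events are placed on a disjoint spatial grid so that no two blobs
    touch: the injected event count and pixel total are then exactly
    recoverable by the detection chain.  Increments smaller than
    ``min_event_px`` are rolled into the next event, so the injected total
    matches the sigmoid target.
    """
    rng = _rng(seed)
    frame_t = frame_interval_min * np.arange(n_frames)
    if frame_t[-1] > timeline.time_min[-1]:
        raise ValueError("timeline does not span the stack duration")
    frame_psi = np.interp(frame_t, timeline.time_min, timeline.psi)
    cum_target = np.round(pammenter(frame_psi, truth_psi50, truth_slope)
                          / 100.0 * total_px).astype(int)
    inc = np.diff(cum_target, prepend=0)

    # events occupy disjoint grid cells sized for the largest plausible blob
    max_area = int(inc.max()) if inc.max() > 0 else min_event_px
    cell = 2 * int(math.ceil(math.sqrt(max_area / math.pi))) + 4
    h, w = frame_shape
    cells = [(r, c) for r in range(cell // 2, h - cell // 2, cell)
             for c in range(cell // 2, w - cell // 2, cell)]
    events: list[tuple[int, int, tuple[int, int]]] = []
    carry = 0
    for f in range(1, n_frames):
        carry += int(inc[f])
        if carry >= min_event_px:
            events.append((f, carry, (0, 0)))  # position assigned below
            carry = 0
    if len(events) > len(cells):
        raise ValueError(
            f"{len(events)} events need more than the {len(cells)} disjoint "
            f"cells available on a {frame_shape} frame; enlarge the frame or "
            "raise min_event_px"
        )
    order = rng.permutation(len(cells))[: len(events)]
    events = [(f, a, cells[i]) for (f, a, _), i in zip(events, order)]
    return gen_dehydration_stack(
        n_frames, frame_shape, events,
        background_noise_sd=background_noise_sd, seed=rng,
        frame_interval_min=frame_interval_min, **stack_meta,
    )


@dataclass
class VesselSet:
    """Vessel lumen areas (um^2) measured over one stem cross-section."""

    section_id: str
    vessel_areas_um2: np.ndarray
    xylem_area_m2: float
    variety: str = ""

    def __post_init__(self) -> None:
        self.vessel_areas_um2 = np.asarray(self.vessel_areas_um2, dtype=float)
        if len(self.vessel_areas_um2) == 0:
            raise ValueError("vessel set is empty")
        if np.any(self.vessel_areas_um2 <= 0) or self.xylem_area_m2 <= 0:
            raise ValueError("areas must be positive")


def gen_vessels(
    n: int,
    diameter_lognormal_params: tuple[float, float] = (math.log(50.0), 0.3),
    xylem_area_mm2: float = 1.0,
    seed=None,
    section_id: str = "section-1",
    variety: str = "",
) -> tuple[VesselSet, dict]:
    """Vessel table with lognormal equivalent-circle diameters (um).

    Defaults give a median diameter of 50 um, typical of grapevine stem
    metaxylem.  Lumen areas are pi*(d/2)^2, so the diameter is exactly
    recoverable downstream.
    """
    if n < 1:
        raise ValueError("need at least one vessel")
    rng = _rng(seed)
    mu, sigma = diameter_lognormal_params
    diameters = rng.lognormal(mu, sigma, size=n)
    areas = math.pi * (diameters / 2.0) ** 2
    vs = VesselSet(
        section_id=section_id,
        vessel_areas_um2=areas,
        xylem_area_m2=xylem_area_mm2 * 1e-6,
        variety=variety,
    )
    truth = dict(section_id=section_id, diameters_um=diameters.tolist(),
                 xylem_area_mm2=xylem_area_mm2)
    return vs, truth


def gen_bearing_table(
    regions: Sequence[str] | int,
    varieties: Sequence[str],
    share_concentration: float = 1.0,
    uncovered_fraction_range: tuple[float, float] = (0.0, 0.3),
    seed=None,
    country: str = "Synthland",
) -> tuple[pd.DataFrame, dict]:
    """Long-format regional bearing-area table (region, country, variety,
    bearing_percent).

    Per region a fraction of the winegrape area is 'uncovered' (planted
    with varieties outside the panel) and the remainder is split across the
    panel varieties with a symmetric Dirichlet of the given concentration.
    The truth log records each region's covered fraction and shares.
    """
    rng = _rng(seed)
    if isinstance(regions, int):
        regions = [f"Region-{i + 1:02d}" for i in range(regions)]
    lo, hi = uncovered_fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("uncovered_fraction_range must lie within [0, 1]")
    rows: list[dict] = []
    truth_regions: dict[str, dict] = {}
    for region in regions:
        uncovered = rng.uniform(lo, hi)
        covered_pct = 100.0 * (1.0 - uncovered)
        shares = rng.dirichlet(np.full(len(varieties), share_concentration)) * covered_pct
        if np.any(shares < 0):
            raise ValueError("negative share drawn — invalid concentration")
        for v, s in zip(varieties, shares):
            rows.append(dict(region=region, country=country, variety=v,
                             bearing_percent=float(s)))
        truth_regions[region] = dict(covered_percent=float(covered_pct),
                                     shares={v: float(s) for v, s in zip(varieties, shares)})
    return pd.DataFrame(rows), dict(regions=truth_regions)


def reference_varieties() -> list[VarietyTruth]:
    """A small panel of variety truths spanning the vulnerability range
    reported for Vitis: from very vulnerable (psi50 near -1.9 MPa, like
    Sultanine) to resistant rootstock-like genotypes (near -3.4 MPa)."""
    return [
        VarietyTruth("Sultanine", -1.9, 90.0, 0.15, 8.0),
        VarietyTruth("Chardonnay", -2.3, 95.0, 0.15, 8.0),
        VarietyTruth("Ugni blanc", -2.5, 100.0, 0.15, 8.0),
        VarietyTruth("Syrah", -3.0, 110.0, 0.15, 8.0),
        VarietyTruth("Pinot noir", -3.3, 110.0, 0.15, 8.0),
        VarietyTruth("110R", -3.4, 70.0, 0.15, 8.0),
    ]
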