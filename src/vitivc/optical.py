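"""Optical vulnerability analysis of leaf dehydration image stacks.

A dehydrating leaf is scanned every few minutes; air entry into a vein
(an embolism event) changes light transmission abruptly between two
consecutive scans.  The analysis chain is:

1. subtract consecutive frames (absolute difference),
2. threshold the difference images and filter small connected components
   (noise) from the binary masks,
3. accumulate embolized pixels over time and normalise to the dehydration
   total (PEP, percent of embolized pixels),
4. map each frame onto stem water potential by interpolating the
   psychrometer timeline,
5. fit the Pammenter sigmoid to PEP versus water potential to obtain an
   optical vulnerability curve.

The defaults (threshold 5 gray levels, minimum blob 20 px, 8-connected
components) follow common open-source optical-vulnerability practice and
are all configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import ImageStack, WaterPotentialTimeline
from .vcfit import VulnerabilityFit, fit_pammenter

#: 8-connectivity structuring element for component labelling.
_STRUCTURE_8 = np.ones((3, 3), dtype=int)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class EmbolismEventSeries:
    """Per-frame embolism record with cumulative pixel accounting.

    ``frames`` holds one row per difference frame: frame_index, time_min,
    event_count, embolized_px, cumulative_px, pep (%), and (after
    :func:`map_psi`) psi (MPa).
    """

    frames: pd.DataFrame
    total_px: int

    @property
    def event_frames(self) -> pd.DataFrame:
        return self.frames[self.frames["embolized_px"] > 0]


def subtract_stack(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Absolute differences of consecutive frames.

    Returns ``(diffs, timestamps)`` where ``diffs[i] = |frame[i+1] - frame[i]|``
    and each difference is stamped with the *later* frame's time (the event
    is first visible then).
    """
    frames = stack.frames.astype(np.int16)
    diffs = np.abs(frames[1:] - frames[:-1])
    return diffs, stack.timestamps[1:].copy()


def detect_events(
    diffs: np.ndarray,
    intensity_threshold: float = 5.0,
    min_area_px: int = 20,
    connectivity: int = 8,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Threshold difference frames and count noise-filtered events.

    Pixels brighter than ``intensity_threshold`` are candidate embolism;
    connected components smaller than ``min_area_px`` are treated as sensor
    noise and removed (the particle-filter step).  Returns the cleaned
    binary masks and a per-frame table of event and pixel counts.
    """
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be positive")
    if min_area_px < 1:
        raise ValueError("min_area_px must be at least 1")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    masks: list[np.ndarray] = []
    rows: list[dict] = []
    for i, d in enumerate(diffs):
        binary = d > intensity_threshold
        labels, n = ndimage.label(binary, structure=structure)
        kept = np.zeros_like(binary)
        n_kept = 0
        if n:
            sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
            for lab, size in enumerate(sizes, start=1):
                if size >= min_area_px:
                    kept |= labels == lab
                    n_kept += 1
        masks.append(kept)
        rows.append(dict(frame_index=i, event_count=n_kept, embolized_px=int(kept.sum())))
    return masks, pd.DataFrame(rows)


def accumulate(embolized_px: np.ndarray | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative embolized pixels and PEP (% of the dehydration total).

    PEP is undefined when no pixel ever embolized; that case raises, since
    normalising by zero would silently fabricate a flat curve.
    """
    px = np.asarray(embolized_px, dtype=float)
    cum = np.cumsum(px)
    total = cum[-1] if len(cum) else 0.0
    if total <= 0:
        raise ValueError("no embolized pixels: PEP normalisation undefined")
    return cum, 100.0 * cum / total


def clean_timeline(timeline: WaterPotentialTimeline) -> WaterPotentialTimeline:
    """Running-minimum cleaning of a raw psychrometer series.

    Embolism cannot reverse during a drydown, but sensor blips can make the
    raw series locally increase, which would fold the PEP-psi mapping back
    on itself.  The cleaned series is the running minimum of the raw one.
    """
    return WaterPotentialTimeline(
        time_min=timeline.time_min.copy(),
        psi=np.minimum.accumulate(timeline.psi),
    )


def map_psi(
    times_min: np.ndarray,
    timeline: WaterPotentialTimeline,
    clean: bool = True,
) -> np.ndarray:
    """Stem water potential at each frame time by linear interpolation.

    The timeline must span every requested time; extrapolation beyond the
    psychrometer record is refused.
    """
    t = np.asarray(times_min, dtype=float)
    if t.min() < timeline.time_min[0] or t.max() > timeline.time_min[-1]:
        raise ValueError(
            f"frame times [{t.min():g}, {t.max():g}] min exceed the timeline span "
            f"[{timeline.time_min[0]:g}, {timeline.time_min[-1]:g}] min"
        )
    tl = clean_timeline(timeline) if clean else timeline
    return np.interp(t, tl.time_min, tl.psi)


def check_registration(stack: ImageStack, max_shift_px: float = 2.0) -> list[tuple[int, float]]:
    """QC for frame-to-frame translation jitter.

    The protocol clamps the leaf, so frames should be registered; a global
    shift above ``max_shift_px`` (estimated by phase cross-correlation)
    triggers a warning and is reported as (frame_index, shift)."""
    from skimage.registration import phase_cross_correlation

    offenders: list[tuple[int, float]] = []
    for i in range(1, stack.frames.shape[0]):
        shift, _, _ = phase_cross_correlation(
            stack.frames[i - 1].astype(float), stack.frames[i].astype(float),
        )
        mag = float(np.hypot(*shift))
        if mag > max_shift_px:
            offenders.append((i, mag))
    if offenders:
        warnings.warn(
            f"{len(offenders)} frame pair(s) shifted by more than {max_shift_px} px; "
            "the stack may need registration", stacklevel=2,
        )
    return offenders


def analyze_stack(
    stack: ImageStack,
    timeline: WaterPotentialTimeline,
    intensity_threshold: float = 5.0,
    min_area_px: int = 20,
    connectivity: int = 8,
) -> EmbolismEventSeries:
    """Run the detection chain on a stack and attach water potentials."""
    diffs, times = subtract_stack(stack)
    _, table = detect_events(diffs, intensity_threshold, min_area_px, connectivity)
    table = table.copy()
    table["time_min"] = times
    cum, pep = accumulate(table["embolized_px"].to_numpy())
    table["cumulative_px"] = cum.astype(int)
    table["pep"] = pep
    table["psi"] = map_psi(times, timeline)
    return EmbolismEventSeries(frames=table, total_px=int(cum[-1]))


def optical_vc(series: EmbolismEventSeries, **fit_kwargs) -> VulnerabilityFit:
    """Fit the Pammenter sigmoid to the optical PEP-psi curve.

    Only frames at or after the first event carry information about the
    embolism trajectory; earlier all-zero frames are retained (PEP = 0 is a
    genuine observation of an intact leaf).
    """
    df = series.frames
    if df["psi"].nunique() < 4:
        raise ValueError("need at least 4 distinct water-potential values")
    return fit_pammenter(psi=df["psi"].to_numpy(), plc=df["pep"].to_numpy(), **fit_kwargs)
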