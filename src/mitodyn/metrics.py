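"""Trajectory, chemotaxis, focal-adhesion and cortical-localization metrics.

Trajectory metrics summarise a single tracked object: mean frame-to-frame
speed, cumulative path length, net (Euclidean) displacement, and
processivity — the fraction of frame intervals spent in motion, with a
mitochondrion classified as high-processivity when strictly more than 70%
of intervals are moving. Because automated centroids are subpixel, "in
motion" means a per-interval displacement above a small epsilon (default
0.5 px) rather than a literal nonzero.

Chemotaxis metrics apply the same geometry to whole-cell trajectories and
add directionality = Euclidean / accumulated distance. Focal adhesions are
classified from their presence at the first and last frame of a movie into
decaying, newly formed, stable sliding and stable mature, with assembly and
decay rates expressed per hour. Cortical quantification measures
mitochondrial signal inside a belt eroded inward from the cell boundary,
normalized to the total per-cell signal and to area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.morphology import disk

from .tracking import Track

__all__ = [
    "TrajectoryMetrics",
    "ChemotaxisSummary",
    "FAClassification",
    "CorticalMeasure",
    "track_metrics",
    "chemotaxis_summary",
    "classify_fa",
    "cortical_quantify",
]

PROCESSIVITY_CUTOFF = 0.70  # strict '>' separates high from low

FA_CLASSES = ("decaying", "newly_formed", "stable_sliding", "stable_mature")


@dataclass
class TrajectoryMetrics:
    mean_speed_um_s: float
    cumulative_distance_um: float
    euclidean_distance_um: float
    processivity: float
    processivity_class: str  # "high" | "low"


@dataclass
class ChemotaxisSummary:
    """Cohort summary over cells: per-cell table plus mean ± s.d. aggregates."""

    per_cell: pd.DataFrame
    mean_speed_um_min: float
    sd_speed_um_min: float
    mean_accumulated_um: float
    sd_accumulated_um: float
    mean_euclidean_um: float
    sd_euclidean_um: float
    mean_directionality: float
    sd_directionality: float


@dataclass
class FAClassification:
    counts: dict
    decay_rate_per_h: float
    assembly_rate_per_h: float
    movie_duration_h: float


@dataclass
class CorticalMeasure:
    cortical_intensity: float
    total_intensity: float
    cell_area_px: int
    cortical_area_px: int
    cortical_fraction: float
    density_ratio: float
    mass_per_area: float
    saturation_flag: bool
    belt_covers_cell: bool


def _positions(track) -> np.ndarray:
    if isinstance(track, Track):
        return track.positions()
    return np.asarray(track, dtype=np.float64)


def track_metrics(
    track,
    pixel_size_um: float,
    frame_interval_s: float,
    motion_eps_px: float = 0.5,
) -> TrajectoryMetrics:
    """Per-track trafficking metrics.

    ``track`` is a :class:`~mitodyn.tracking.Track` or an (L, 2) array of
    (x, y) centroids at consecutive frames; L must be >= 2. Per-interval
    speed is displacement × pixel size / frame interval; an interval counts
    as "in motion" when its displacement exceeds ``motion_eps_px``.
    """
    pos = _positions(track)
    if len(pos) < 2:
        raise ValueError("track must have at least 2 observations")
    steps_px = np.hypot(*np.diff(pos, axis=0).T)
    speeds = steps_px * pixel_size_um / frame_interval_s
    cumulative = float(steps_px.sum() * pixel_size_um)
    euclidean = float(np.hypot(*(pos[-1] - pos[0])) * pixel_size_um)
    processivity = float(np.mean(steps_px > motion_eps_px))
    return TrajectoryMetrics(
        mean_speed_um_s=float(speeds.mean()),
        cumulative_distance_um=cumulative,
        euclidean_distance_um=euclidean,
        processivity=processivity,
        processivity_class="high" if processivity > PROCESSIVITY_CUTOFF else "low",
    )


def chemotaxis_summary(
    cell_tracks,
    pixel_size_um: float,
    frame_interval_s: float,
    motion_eps_px: float = 0.0,
) -> ChemotaxisSummary:
    """Per-cell chemotaxis metrics and cohort mean ± s.d.

    Speed is reported in μm/min (the conventional unit for cell migration);
    the headline per-cell speed is the mean of instantaneous frame-to-frame
    speeds. Directionality = Euclidean / accumulated distance, in [0, 1],
    NaN (flagged) for a cell that did not move at all.
    """
    if not len(cell_tracks):
        raise ValueError("need at least one cell track")
    rows = []
    for i, tr in enumerate(cell_tracks):
        tid = tr.track_id if isinstance(tr, Track) else i
        m = track_metrics(tr, pixel_size_um, frame_interval_s, motion_eps_px)
        directionality = (
            m.euclidean_distance_um / m.cumulative_distance_um
            if m.cumulative_distance_um > 0
            else np.nan
        )
        rows.append(
            (tid, m.mean_speed_um_s * 60.0, m.cumulative_distance_um,
             m.euclidean_distance_um, directionality)
        )
    per_cell = pd.DataFrame(
        rows,
        columns=["cell_id", "speed_um_min", "accumulated_um", "euclidean_um",
                 "directionality"],
    )

    def agg(col):
        v = per_cell[col].to_numpy()
        return float(np.nanmean(v)), float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0

    ms, ss = agg("speed_um_min")
    ma, sa = agg("accumulated_um")
    me, se = agg("euclidean_um")
    md, sd_ = agg("directionality")
    return ChemotaxisSummary(per_cell, ms, ss, ma, sa, me, se, md, sd_)


def classify_fa(
    fa_presence,
    slide_radius_px: float,
    movie_duration_h: float,
    frame_range: tuple[int, int] | None = None,
) -> FAClassification:
    """Classify focal adhesions by presence at the movie endpoints.

    ``fa_presence`` maps fa_id -> list of (frame, x_px, y_px), or is a
    DataFrame with columns (fa_id, frame, x_px, y_px). ``frame_range`` is the
    movie's (first, last) frame; by default the extremes over all FAs.

    Classes: present at start & absent at end -> decaying; absent at start &
    present at end -> newly formed; present at both with net displacement
    beyond ``slide_radius_px`` -> stable sliding; present at both otherwise
    -> stable mature. An FA absent at both endpoints assembled and fully
    disassembled within the movie; it is counted as decaying. Rates are
    class counts divided by the movie duration in hours.
    """
    if movie_duration_h <= 0:
        raise ValueError("movie duration must be positive")
    if isinstance(fa_presence, pd.DataFrame):
        fa_presence = {
            fid: [(int(r.frame), float(r.x_px), float(r.y_px)) for r in grp.itertuples()]
            for fid, grp in fa_presence.groupby("fa_id")
        }
    if not fa_presence or any(len(v) == 0 for v in fa_presence.values()):
        raise ValueError("every FA needs at least one observation")

    if frame_range is None:
        all_frames = [f for obs in fa_presence.values() for (f, _x, _y) in obs]
        frame_range = (min(all_frames), max(all_frames))
    first, last = frame_range

    counts = {c: 0 for c in FA_CLASSES}
    for obs in fa_presence.values():
        obs = sorted(obs)
        frames = {f for (f, _x, _y) in obs}
        at_start, at_end = first in frames, last in frames
        if at_start and not at_end:
            counts["decaying"] += 1
        elif at_end and not at_start:
            counts["newly_formed"] += 1
        elif at_start and at_end:
            p0 = np.array(obs[0][1:])
            p1 = np.array(obs[-1][1:])
            if np.hypot(*(p1 - p0)) > slide_radius_px:
                counts["stable_sliding"] += 1
            else:
                counts["stable_mature"] += 1
        else:  # transient: formed and decayed within the movie
            counts["decaying"] += 1
    return FAClassification(
        counts=counts,
        decay_rate_per_h=counts["decaying"] / movie_duration_h,
        assembly_rate_per_h=counts["newly_formed"] / movie_duration_h,
        movie_duration_h=movie_duration_h,
    )


def cortical_quantify(
    mito_image: np.ndarray,
    cell_polygon,
    pixel_size_um: float,
    belt_width_um: float = 2.0,
    bit_depth: int = 8,
) -> CorticalMeasure:
    """Quantify cortical versus total mitochondrial signal in one cell.

    ``cell_polygon`` is an ordered list of (x_px, y_px) vertices of the cell
    boundary. The cell mask is the filled polygon; the cortical mask is the
    belt between the boundary and the mask's inward erosion by
    ``belt_width_um``. If the belt is wider than the cell inradius the
    cortical mask degenerates to the whole cell and ``belt_covers_cell`` is
    flagged. ``saturation_flag`` is set when any in-cell pixel reaches the
    bit-depth maximum (e.g. 255 for 8-bit — the acquisition monitored
    max intensity < 256).
    """
    if belt_width_um <= 0:
        raise ValueError("belt_width_um must be > 0")
    img = np.asarray(mito_image, dtype=np.float64)
    poly = np.asarray(cell_polygon, dtype=np.float64)
    cell_mask = polygon2mask(img.shape, poly[:, ::-1])  # polygon2mask wants (row, col)
    if not cell_mask.any():
        raise ValueError("cell polygon does not cover any pixel")

    belt_px = max(1, int(round(belt_width_um / pixel_size_um)))
    interior = ndimage.binary_erosion(cell_mask, structure=disk(belt_px))
    cortical_mask = cell_mask & ~interior
    belt_covers_cell = not interior.any()
    if belt_covers_cell:
        cortical_mask = cell_mask

    total = float(img[cell_mask].sum())
    cortical = float(img[cortical_mask].sum())
    cell_area = int(cell_mask.sum())
    cortical_area = int(cortical_mask.sum())
    fraction = cortical / total if total > 0 else np.nan
    if total > 0 and cortical_area > 0:
        density_ratio = (cortical / cortical_area) / (total / cell_area)
    else:
        density_ratio = np.nan
    return CorticalMeasure(
        cortical_intensity=cortical,
        total_intensity=total,
        cell_area_px=cell_area,
        cortical_area_px=cortical_area,
        cortical_fraction=fraction,
        density_ratio=density_ratio,
        mass_per_area=total / cell_area,
        saturation_flag=bool(img[cell_mask].max() >= 2**bit_depth - 1),
        belt_covers_cell=belt_covers_cell,
    )
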