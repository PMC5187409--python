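"""Fission/fusion event calling, normalization and condition comparison.

A fusion is called when a mitochondrial track ends in a spatiotemporal
neighbourhood of another existing track (the two organelles merged, so one
track terminates next to the survivor). A fission is called when a track
appears in such a neighbourhood (a new fragment splits off an existing
organelle). The neighbourhood defaults to the tracking velocity gate in
space (25 px) and one frame in time. Terminations/appearances within a
margin of the image border are not called, since those are field-of-view
exits and entries rather than dynamics. Per-frame event counts are
normalized to the number of foreground mitochondrial pixels so that cells
of different size and mitochondrial content are comparable, and the
resulting per-frame rates are compared between conditions with two-sample
Kolmogorov–Smirnov (distribution) and Wilcoxon rank-sum (median) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import Track

__all__ = [
    "EventConfig",
    "DynamicsEvent",
    "detect_events",
    "normalize_events",
    "compare_conditions",
    "events_to_dataframe",
]

EVENT_COLUMNS = [
    "type",
    "frame",
    "x_px",
    "y_px",
    "focal_track",
    "partner_track",
    "partner_distance_px",
]


@dataclass
class EventConfig:
    """Spatiotemporal association region for event calling.

    ``assoc_radius_px``: maximal distance between a track end/start and a
    partner observation (default: the 25 px tracking gate).
    ``assoc_window_frames``: how many frames around the end/start to search.
    ``border_margin_px``: ends/starts closer than this to the image edge are
    suppressed (default: the association radius). Set to 0 to disable.
    """

    assoc_radius_px: float = 25.0
    assoc_window_frames: int = 1
    border_margin_px: float | None = None

    def __post_init__(self) -> None:
        if self.assoc_radius_px <= 0:
            raise ValueError("assoc_radius_px must be > 0")
        if self.assoc_window_frames < 1:
            raise ValueError("assoc_window_frames must be >= 1")
        if self.border_margin_px is None:
            self.border_margin_px = self.assoc_radius_px


@dataclass
class DynamicsEvent:
    """One fission or fusion call."""

    type: str  # "fission" | "fusion"
    frame: int
    x_px: float
    y_px: float
    focal_track: int
    partner_track: int
    partner_distance_px: float


def _frame_index(tracks: list[Track]) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """frame -> (track_ids, (N,2) positions) over all observations."""
    buckets: dict[int, list[tuple[int, float, float]]] = {}
    for tr in tracks:
        for (f, _oid, x, y, _a) in tr.observations:
            buckets.setdefault(f, []).append((tr.track_id, x, y))
    return {
        f: (
            np.array([r[0] for r in rows], dtype=int),
            np.array([[r[1], r[2]] for r in rows], dtype=np.float64),
        )
        for f, rows in buckets.items()
    }


def _nearest_partner(
    index, frames: range, pos: np.ndarray, focal_id: int, radius: float
) -> tuple[int, float] | None:
    best: tuple[float, int] | None = None
    for f in frames:
        if f not in index:
            continue
        ids, xy = index[f]
        keep = ids != focal_id
        if not keep.any():
            continue
        d = np.hypot(*(xy[keep] - pos).T)
        j = int(np.argmin(d))
        if d[j] <= radius:
            cand = (float(d[j]), int(ids[keep][j]))
            # nearest wins; distance ties broken toward the lower track id
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return best[1], best[0]


def detect_events(
    tracks: list[Track],
    cfg: EventConfig | None = None,
    frame_shape: tuple[int, int] | None = None,
    frame_range: tuple[int, int] | None = None,
) -> list[DynamicsEvent]:
    """Call fission and fusion events from filtered tracks.

    ``frame_shape`` (H, W) is required when border suppression is enabled
    (``border_margin_px > 0``). ``frame_range`` is the (first, last) movie
    frame; by default it is inferred from the tracks. Track ends at the last
    movie frame and starts at the first are never called (the movie boundary
    is not an event), and a single termination or appearance yields at most
    one call, with the nearest qualifying track as partner.
    """
    cfg = cfg or EventConfig()
    if not tracks:
        return []
    if cfg.border_margin_px > 0 and frame_shape is None:
        raise ValueError("frame_shape required when border filtering is enabled")
    if frame_range is None:
        frame_range = (
            min(t.start_frame for t in tracks),
            max(t.end_frame for t in tracks),
        )
    first, last = frame_range
    index = _frame_index(tracks)

    def near_border(x: float, y: float) -> bool:
        if cfg.border_margin_px <= 0:
            return False
        h, w = frame_shape
        m = cfg.border_margin_px
        return x < m or y < m or x > w - 1 - m or y > h - 1 - m

    events: list[DynamicsEvent] = []
    for tr in tracks:
        # fusion: track ends next to a surviving track
        t_end = tr.end_frame
        if t_end < last:
            _f, _o, x, y, _a = tr.observations[-1]
            if not near_border(x, y):
                hit = _nearest_partner(
                    index,
                    range(t_end, t_end + cfg.assoc_window_frames + 1),
                    np.array([x, y]),
                    tr.track_id,
                    cfg.assoc_radius_px,
                )
                if hit is not None:
                    events.append(
                        DynamicsEvent("fusion", t_end, x, y, tr.track_id, hit[0], hit[1])
                    )
        # fission: track appears next to an existing track
        t_start = tr.start_frame
        if t_start > first:
            _f, _o, x, y, _a = tr.observations[0]
            if not near_border(x, y):
                hit = _nearest_partner(
                    index,
                    range(t_start - cfg.assoc_window_frames, t_start + 1),
                    np.array([x, y]),
                    tr.track_id,
                    cfg.assoc_radius_px,
                )
                if hit is not None:
                    events.append(
                        DynamicsEvent("fission", t_start, x, y, tr.track_id, hit[0], hit[1])
                    )
    events.sort(key=lambda e: (e.frame, e.type, e.focal_track))
    return events


def events_to_dataframe(events: list[DynamicsEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.type, e.frame, e.x_px, e.y_px, e.focal_track, e.partner_track,
             e.partner_distance_px)
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def normalize_events(
    events: list[DynamicsEvent] | pd.DataFrame,
    per_frame_foreground_px,
) -> pd.DataFrame:
    """Per-frame event counts normalized by foreground mitochondrial pixels.

    ``per_frame_foreground_px`` maps frame -> foreground pixel count (dict,
    Series, or DataFrame with columns frame, foreground_px) and must cover
    every frame to report. Returns a DataFrame with columns (frame,
    n_fission, n_fusion, foreground_px, fission_rate_per_px,
    fusion_rate_per_px). Rates are 0 when the count is 0 and NaN (flagged
    undefined) when foreground_px is 0.
    """
    if isinstance(per_frame_foreground_px, pd.DataFrame):
        fg = per_frame_foreground_px.set_index("frame")["foreground_px"]
    else:
        fg = pd.Series(per_frame_foreground_px)
    fg = fg.astype(float).sort_index()
    if (fg < 0).any():
        raise ValueError("foreground pixel counts must be non-negative")

    if isinstance(events, pd.DataFrame):
        edf = events
    else:
        edf = events_to_dataframe(events)

    out = pd.DataFrame({"frame": fg.index.to_numpy(), "foreground_px": fg.to_numpy()})
    for etype, col in (("fission", "n_fission"), ("fusion", "n_fusion")):
        counts = (
            edf.loc[edf["type"] == etype, "frame"].value_counts()
            if len(edf)
            else pd.Series(dtype=int)
        )
        out[col] = out["frame"].map(counts).fillna(0).astype(int)
    for col, rate in (("n_fission", "fission_rate_per_px"), ("n_fusion", "fusion_rate_per_px")):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(out[col] == 0, 0.0, out[col] / out["foreground_px"])
        r = np.where((out["foreground_px"] == 0) & (out[col] > 0), np.nan, r)
        out[rate] = np.where(out["foreground_px"] == 0, np.where(out[col] == 0, 0.0, np.nan), r)
    return out[["frame", "n_fission", "n_fusion", "foreground_px",
                "fission_rate_per_px", "fusion_rate_per_px"]]


def compare_conditions(rates_a, rates_b) -> dict:
    """Compare two samples of per-frame event rates.

    Returns a dict with the two-sample Kolmogorov–Smirnov statistic and
    p-value (exact when sample sizes permit, asymptotic otherwise), the
    two-sided Wilcoxon rank-sum p-value (exact for small tie-free samples),
    and the sample medians. Raises ``ValueError`` for samples of size < 2.
    """
    a = np.asarray(rates_a, dtype=np.float64)
    b = np.asarray(rates_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    ks = stats.ks_2samp(a, b, method="auto")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    mw = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "ranksum_p": float(mw.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
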