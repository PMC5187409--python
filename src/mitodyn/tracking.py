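"""Frame-to-frame object linking and track construction.

Objects detected in consecutive frames are associated by solving a minimum
cost linear assignment (Hungarian algorithm) over an augmented cost matrix:
the cost of linking two objects is the Euclidean distance between their
centroids, pairs farther apart than a maximal-velocity gate are inadmissible,
and every object may instead take a birth/death pseudo-assignment at a fixed
cost. The gate defaults to 25 pixels per frame, the empirically estimated
maximal mitochondrial velocity. Tracks are formed by chaining links across
the movie (pairwise linking only, no gap closing), and tracks shorter than
three frames are removed before any downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "TrackingConfig",
    "Track",
    "link_frames",
    "build_tracks",
    "filter_tracks",
    "tracks_to_dataframe",
    "tracks_from_dataframe",
]

TRACK_COLUMNS = ["frame", "track_id", "x_px", "y_px", "area_px"]


@dataclass
class TrackingConfig:
    """Linking parameters.

    ``max_disp_px_per_frame`` is the velocity gate: candidate links with a
    centroid displacement above it are inadmissible. ``birth_death_cost_px``
    is the cost of starting/ending a track instead of linking; by default it
    equals the gate, so a link is preferred over a birth+death exactly when
    it is admissible. ``min_track_len_frames`` is the minimum track length
    (in frames) retained by :func:`filter_tracks`.
    """

    max_disp_px_per_frame: float = 25.0
    min_track_len_frames: int = 3
    birth_death_cost_px: float | None = None

    def __post_init__(self) -> None:
        if self.max_disp_px_per_frame <= 0:
            raise ValueError("max_disp_px_per_frame must be > 0")
        if self.min_track_len_frames < 1:
            raise ValueError("min_track_len_frames must be >= 1")
        if self.birth_death_cost_px is None:
            self.birth_death_cost_px = self.max_disp_px_per_frame


@dataclass
class Track:
    """Ordered observations of one mitochondrion.

    ``observations`` is a list of (frame, object_id, x_px, y_px, area_px)
    tuples at strictly consecutive frames (pairwise linking admits no gaps).
    """

    track_id: int
    observations: list[tuple[int, int, float, float, float]] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.observations[0][0]

    @property
    def end_frame(self) -> int:
        return self.observations[-1][0]

    @property
    def length(self) -> int:
        return len(self.observations)

    def positions(self) -> np.ndarray:
        """(L, 2) array of (x, y) centroids in pixel units."""
        return np.array([(o[2], o[3]) for o in self.observations], dtype=np.float64)

    def position_at(self, frame: int) -> tuple[float, float] | None:
        if frame < self.start_frame or frame > self.end_frame:
            return None
        o = self.observations[frame - self.start_frame]
        return (o[2], o[3])


def _as_objects(objects) -> pd.DataFrame:
    if isinstance(objects, pd.DataFrame):
        return objects
    return pd.DataFrame(objects, columns=["object_id", "x_px", "y_px"])


def link_frames(
    objects_t, objects_t1, cfg: TrackingConfig | None = None
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Associate objects between two consecutive frames.

    Parameters
    ----------
    objects_t, objects_t1
        DataFrames with columns ``object_id, x_px, y_px`` (extra columns
        ignored). Either may be empty.

    Returns
    -------
    links
        List of (object_id_t, object_id_t1, distance_px).
    deaths
        Object ids in frame t that were not linked forward.
    births
        Object ids in frame t+1 that were not linked backward.

    The assignment minimises total cost over the augmented matrix; equal-cost
    solutions are resolved toward the lexicographically smallest
    (object_id_t, object_id_t1) pairs via an infinitesimal perturbation, so
    the result is invariant to the input row order.
    """
    cfg = cfg or TrackingConfig()
    a = _as_objects(objects_t)
    b = _as_objects(objects_t1)
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return [], [], []
    ids_a = a["object_id"].to_numpy()
    ids_b = b["object_id"].to_numpy()
    if n == 0:
        return [], [], list(ids_b)
    if m == 0:
        return [], list(ids_a), []

    pa = a[["x_px", "y_px"]].to_numpy(dtype=np.float64)
    pb = b[["x_px", "y_px"]].to_numpy(dtype=np.float64)
    dist = cdist(pa, pb)
    bd = float(cfg.birth_death_cost_px)
    large = 1e6 * (bd + dist.max() + 1.0) * (n + m + 1)

    cost = np.where(dist <= cfg.max_disp_px_per_frame, dist, large)
    # Deterministic tie-break: prefer lexicographically smallest id pairs.
    rank_a = np.argsort(np.argsort(ids_a, kind="stable"))
    rank_b = np.argsort(np.argsort(ids_b, kind="stable"))
    eps = 1e-9 * max(bd, 1.0)
    pert = eps * (rank_a[:, None] * (m + 1) + rank_b[None, :] + 1) / ((n + 1) * (m + 1))
    cost = cost + pert

    full = np.full((n + m, n + m), large, dtype=np.float64)
    full[:n, :m] = cost
    full[:n, m:][np.diag_indices(n)] = bd
    full[n:, :m][np.diag_indices(m)] = bd
    full[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(full)

    links, deaths, births = [], [], []
    linked_b = set()
    for r, c in zip(rows, cols):
        if r < n and c < m:
            links.append((int(ids_a[r]), int(ids_b[c]), float(dist[r, c])))
            linked_b.add(c)
        elif r < n:
            deaths.append(int(ids_a[r]))
    births = [int(ids_b[j]) for j in range(m) if j not in linked_b]
    return links, deaths, births


def build_tracks(segmentations, cfg: TrackingConfig | None = None) -> list[Track]:
    """Chain pairwise links over a movie into tracks.

    ``segmentations`` is the per-frame sequence from
    :func:`mitodyn.imaging.segment_stack` (or any sequence of objects whose
    ``.objects`` attribute / value is a DataFrame with object_id, x_px, y_px,
    area_px). A death terminates a track, a birth starts a new one; track ids
    are unique and never reused.
    """
    cfg = cfg or TrackingConfig()
    frames = [getattr(s, "objects", s) for s in segmentations]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to build tracks")

    tracks: list[Track] = []
    next_id = 0
    active: dict[int, Track] = {}  # object_id in current frame -> track

    def _obs(df: pd.DataFrame, oid: int, frame: int):
        row = df.loc[df["object_id"] == oid].iloc[0]
        area = float(row["area_px"]) if "area_px" in df.columns else np.nan
        return (frame, int(oid), float(row["x_px"]), float(row["y_px"]), area)

    for oid in frames[0]["object_id"] if len(frames[0]) else []:
        tr = Track(next_id, [_obs(frames[0], oid, 0)])
        active[int(oid)] = tr
        tracks.append(tr)
        next_id += 1

    for t in range(len(frames) - 1):
        links, deaths, births = link_frames(frames[t], frames[t + 1], cfg)
        new_active: dict[int, Track] = {}
        for oid_t, oid_t1, _ in links:
            tr = active[oid_t]
            tr.observations.append(_obs(frames[t + 1], oid_t1, t + 1))
            new_active[oid_t1] = tr
        for oid in births:
            tr = Track(next_id, [_obs(frames[t + 1], oid, t + 1)])
            new_active[int(oid)] = tr
            tracks.append(tr)
            next_id += 1
        active = new_active
    return tracks


def filter_tracks(tracks: list[Track], cfg: TrackingConfig | None = None) -> list[Track]:
    """Remove tracks shorter than ``cfg.min_track_len_frames``; retained
    tracks are returned unmodified."""
    cfg = cfg or TrackingConfig()
    return [t for t in tracks if t.length >= cfg.min_track_len_frames]


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Long-format export: one row per observation."""
    rows = [
        (f, t.track_id, x, y, area)
        for t in tracks
        for (f, _oid, x, y, area) in t.observations
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`tracks_to_dataframe`."""
    tracks = []
    for tid, grp in df.sort_values("frame").groupby("track_id"):
        obs = [
            (int(r.frame), -1, float(r.x_px), float(r.y_px),
             float(getattr(r, "area_px", np.nan)))
            for r in grp.itertuples()
        ]
        tracks.append(Track(int(tid), obs))
    return tracks
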