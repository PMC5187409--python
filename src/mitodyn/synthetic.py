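"""Synthetic time-lapse movies, trajectories and screen reads with ground truth.

The generator emulates the acquisition regimes of the live-cell experiments
the pipeline was built for: 120 nm pixels, frame intervals of 10 s (LN229,
1,000 s movies) or 1 s (PC3, 300 s movies), mitochondria rendered as
anisotropic Gaussian blobs on a smooth additive background with Poisson
(shot) noise applied last. Motion follows a persistent random walk: each
organelle draws a mean speed from a configured range and a heading that
diffuses from frame to frame, which reproduces the mix of high- and
low-processivity behaviour seen in manual tracking.

Fission and fusion are scheduled explicitly. At a fission the parent object
is replaced by two children placed symmetrically about its position, each
carrying half the parent's integrated intensity (intensity is conserved
exactly before noise). For a fusion, the second partner steers toward the
first so the two blobs are at contact distance one frame before the
scheduled merge frame, at which they are replaced by a single object with
the summed intensity. Object ids are never recycled, so the per-frame object
count equals the initial count plus fissions minus fusions so far.

Amplicon reads for the pooled shRNA screen are generated with the fixed
half-hairpin pattern (TCGAG + 21-nt insert + vector sequence + random tail)
and a configurable per-read substitution error rate.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageStack
from .screen import INSERT_LEN, READ_PREFIX, VECTOR_SUFFIX, Library

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tracks",
    "simulate_movie",
    "simulate_screen_reads",
    "write_fastq",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration (e.g. schedule references a
    nonexistent object)."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated acquisition.

    Defaults follow the LN229 regime: 120 nm pixels, 10 s frame interval.
    ``speed_range_um_s`` bounds the per-object mean speeds (drawn uniformly);
    ``size_range_px`` bounds blob major axes. ``fission_schedule`` is a list
    of (frame, track_id); ``fusion_schedule`` a list of
    (track_a, track_b, frame). Scheduled frames must lie in
    [1, n_frames - 1]. ``shot_noise`` scales the Poisson photon count
    (0 disables noise); ``peak_intensity`` is the blob peak in photons, so
    the peak signal-to-noise ratio is sqrt(peak_intensity * shot_noise).
    """

    n_frames: int = 100
    height: int = 200
    width: int = 200
    pixel_size_um: float = 0.12
    frame_interval_s: float = 10.0
    n_mito: int = 10
    speed_range_um_s: tuple[float, float] = (0.005, 0.012)
    size_range_px: tuple[float, float] = (10.0, 13.0)
    fission_schedule: list = field(default_factory=list)
    fusion_schedule: list = field(default_factory=list)
    background_gradient_amp: float = 5.0
    shot_noise: float = 0.0
    psf_sigma_px: float = 0.0
    peak_intensity: float = 200.0
    heading_sigma_rad: float = 0.4
    min_spacing_px: float = 50.0
    border_margin_px: float = 20.0
    fission_offset_px: float = 5.0
    fission_recoil_px_per_frame: float = 1.5
    fission_recoil_frames: int = 10
    fusion_standoff_px: float = 16.0
    min_separation_px: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.n_mito < 0:
            raise ConfigurationError("n_mito must be >= 0")
        lo, hi = self.speed_range_um_s
        if lo < 0 or hi < lo:
            raise ConfigurationError("invalid speed range")
        for f, _tid in self.fission_schedule:
            if not 1 <= f <= self.n_frames - 1:
                raise ConfigurationError(f"fission frame {f} outside [1, n_frames-1]")
        for _a, _b, f in self.fusion_schedule:
            if not 1 <= f <= self.n_frames - 1:
                raise ConfigurationError(f"fusion frame {f} outside [1, n_frames-1]")


@dataclass
class GroundTruth:
    """Per-frame truth trajectories and the scheduled-event log.

    ``tracks``: DataFrame (frame, track_id, x_px, y_px, area_px).
    ``events``: DataFrame (type, frame, x_px, y_px, parent_ids, child_ids)
    where the id fields are tuples. ``per_frame_foreground_px`` is filled by
    :func:`simulate_movie` (None for trajectory-only simulation).
    ``object_speeds`` maps track_id -> configured mean speed (μm/s).
    """

    tracks: pd.DataFrame
    events: pd.DataFrame
    per_frame_foreground_px: pd.Series | None = None
    object_speeds: dict = field(default_factory=dict)

    def n_objects_at(self, frame: int) -> int:
        return int((self.tracks["frame"] == frame).sum())


class _Obj:
    __slots__ = ("oid", "pos", "step_px", "heading", "sigma_major", "intensity", "speed_um_s")

    def __init__(self, oid, pos, step_px, heading, sigma_major, intensity, speed_um_s):
        self.oid = oid
        self.pos = np.asarray(pos, dtype=np.float64)
        self.step_px = step_px
        self.heading = heading
        self.sigma_major = sigma_major
        self.intensity = intensity
        self.speed_um_s = speed_um_s


_ASPECT = 0.6  # minor/major axis ratio of rendered blobs
EVENT_COLUMNS = ["type", "frame", "x_px", "y_px", "parent_ids", "child_ids"]


def _place_initial(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample initial positions with pairwise spacing >= min_spacing."""
    m = cfg.border_margin_px
    lo = np.array([m, m])
    hi = np.array([cfg.width - 1 - m, cfg.height - 1 - m])
    if np.any(hi <= lo):
        raise ConfigurationError("border margin leaves no interior")
    positions: list[np.ndarray] = []
    placed = True
    for _ in range(cfg.n_mito):
        for _attempt in range(2_000):
            p = rng.uniform(lo, hi)
            if all(np.hypot(*(p - q)) >= cfg.min_spacing_px for q in positions):
                positions.append(p)
                break
        else:
            placed = False
            break
    if placed:
        return np.array(positions) if positions else np.empty((0, 2))

    # Dense regime: random sequential placement jams well below the lattice
    # capacity, so fall back to a jittered square lattice.
    pitch = cfg.min_spacing_px + 2.0
    nx = int((hi[0] - lo[0]) // pitch) + 1
    ny = int((hi[1] - lo[1]) // pitch) + 1
    if nx * ny < cfg.n_mito:
        raise ConfigurationError(
            "could not place objects at the requested spacing; reduce n_mito "
            "or min_spacing_px"
        )
    nodes = np.array(
        [[lo[0] + ix * pitch, lo[1] + iy * pitch] for iy in range(ny) for ix in range(nx)]
    )
    chosen = rng.choice(len(nodes), size=cfg.n_mito, replace=False)
    jitter = rng.uniform(-0.9, 0.9, size=(cfg.n_mito, 2))
    return nodes[chosen] + jitter


def _simulate_state(cfg: SimulationConfig):
    """Core motion/event simulation. Returns (per-frame object snapshots,
    truth rows, event rows, speeds); snapshots keep rendering state."""
    rng = np.random.default_rng(cfg.seed)
    init = _place_initial(cfg, rng)
    px_per_frame = cfg.frame_interval_s / cfg.pixel_size_um

    objs: dict[int, _Obj] = {}
    for i in range(cfg.n_mito):
        speed = rng.uniform(*cfg.speed_range_um_s)
        major = rng.uniform(*cfg.size_range_px)
        sigma = major / 4.0
        intensity = cfg.peak_intensity * 2 * np.pi * sigma * (sigma * _ASPECT)
        objs[i] = _Obj(i, init[i], speed * px_per_frame, rng.uniform(0, 2 * np.pi),
                       sigma, intensity, speed)
    next_id = cfg.n_mito
    speeds = {o.oid: o.speed_um_s for o in objs.values()}

    fissions = {}
    for f, tid in cfg.fission_schedule:
        fissions.setdefault(f, []).append(tid)
    fusions_by_frame = {}
    pending_fusions = []
    for a, b, f in cfg.fusion_schedule:
        fusions_by_frame.setdefault(f, []).append((a, b))
        pending_fusions.append((a, b, f))
    # later fusions steer first, so a chain (a fuses with the survivor of an
    # earlier fusion) places the chaser after its target has moved
    pending_fusions.sort(key=lambda x: -x[2])

    m = cfg.border_margin_px
    lo = np.array([m, m])
    hi = np.array([cfg.width - 1 - m, cfg.height - 1 - m])

    def advance(o: _Obj) -> None:
        o.heading += rng.normal(0.0, cfg.heading_sigma_rad)
        step = o.step_px * np.array([np.cos(o.heading), np.sin(o.heading)])
        new = o.pos + step
        # specular reflection at the interior margin
        if new[0] < lo[0] or new[0] > hi[0]:
            new[0] = np.clip(2 * lo[0] - new[0] if new[0] < lo[0] else 2 * hi[0] - new[0],
                             lo[0], hi[0])
            o.heading = np.pi - o.heading
        if new[1] < lo[1] or new[1] > hi[1]:
            new[1] = np.clip(2 * lo[1] - new[1] if new[1] < lo[1] else 2 * hi[1] - new[1],
                             lo[1], hi[1])
            o.heading = -o.heading
        o.pos = new

    snapshots = []  # frame -> list of (oid, pos, sigma_major, intensity, heading, area)
    truth_rows = []
    event_rows = []
    recoiling: list[list] = []  # [child_a, child_b, axis, frames_left]

    def area_of(o: _Obj) -> float:
        return float(np.pi * (2 * o.sigma_major) * (2 * o.sigma_major * _ASPECT))

    def record(frame: int) -> None:
        snap = []
        for o in objs.values():
            truth_rows.append((frame, o.oid, o.pos[0], o.pos[1], area_of(o)))
            snap.append((o.oid, o.pos.copy(), o.sigma_major, o.intensity, o.heading))
        snapshots.append(snap)

    fusion_pairs = {frozenset((a, b)) for (a, b, _f) in cfg.fusion_schedule}

    def repel() -> None:
        """Soft volume exclusion: organelles that drift closer than
        min_separation_px are pushed apart (scheduled fusion partners are
        exempt, since they are meant to touch)."""
        if cfg.min_separation_px <= 0:
            return
        ids = list(objs)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                if frozenset((a, b)) in fusion_pairs:
                    continue
                vec = objs[b].pos - objs[a].pos
                d = float(np.hypot(*vec))
                if 1e-9 < d < cfg.min_separation_px:
                    push = (cfg.min_separation_px - d) / 2.0
                    u = vec / d
                    objs[a].pos = np.clip(objs[a].pos - u * push, lo, hi)
                    objs[b].pos = np.clip(objs[b].pos + u * push, lo, hi)

    record(0)
    for frame in range(1, cfg.n_frames):
        for o in objs.values():
            advance(o)
        # recently split fragments recoil apart so the fission is persistent
        for rec in recoiling:
            ca, cb, axis, left = rec
            if left > 0 and ca in objs and cb in objs:
                objs[ca].pos = np.clip(objs[ca].pos + cfg.fission_recoil_px_per_frame * axis, lo, hi)
                objs[cb].pos = np.clip(objs[cb].pos - cfg.fission_recoil_px_per_frame * axis, lo, hi)
                rec[3] -= 1
        recoiling = [r for r in recoiling if r[3] > 0]

        # steer pending fusion partners toward each other: close to a
        # standoff distance first, and only jump to contact in the last two
        # frames so the pair stays resolvable until the merge
        for (a, b, f) in pending_fusions:
            if frame < f and a in objs and b in objs:
                oa, ob = objs[a], objs[b]
                vec = oa.pos - ob.pos
                dist = float(np.hypot(*vec))
                # close in to a standoff distance at which both partners are
                # still resolvable, and hold it until the merge frame
                r = f - 1 - frame
                standoff = cfg.fusion_standoff_px
                target = standoff + max(0.0, dist - standoff) * (r / (r + 1))
                if dist > 1e-9:
                    ob.pos = oa.pos - vec / dist * target
        repel()

        for tid in fissions.get(frame, []):
            if tid not in objs:
                raise ConfigurationError(
                    f"fission schedule references object {tid}, not alive at frame {frame}"
                )
            parent = objs.pop(tid)
            perp = parent.heading + np.pi / 2
            offset = cfg.fission_offset_px * np.array([np.cos(perp), np.sin(perp)])
            for sign in (+1, -1):
                # children recoil along the split axis so the fragments
                # separate instead of travelling together
                child = _Obj(
                    next_id,
                    np.clip(parent.pos + sign * offset, lo, hi),
                    parent.step_px,
                    perp if sign > 0 else perp + np.pi,
                    parent.sigma_major / np.sqrt(2),
                    parent.intensity / 2.0,
                    parent.speed_um_s,
                )
                objs[next_id] = child
                speeds[next_id] = child.speed_um_s
                next_id += 1
            axis = np.array([np.cos(perp), np.sin(perp)])
            recoiling.append([next_id - 2, next_id - 1, axis, cfg.fission_recoil_frames])
            event_rows.append(
                ("fission", frame, parent.pos[0], parent.pos[1], (tid,),
                 (next_id - 2, next_id - 1))
            )

        for (a, b) in fusions_by_frame.get(frame, []):
            if a not in objs or b not in objs:
                missing = a if a not in objs else b
                raise ConfigurationError(
                    f"fusion schedule references object {missing}, not alive at frame {frame}"
                )
            oa = objs[a]
            ob = objs.pop(b)
            # merged organelle: modestly larger footprint at the same peak
            # brightness, so the product stays sharply peaked rather than
            # becoming a broad flat ridge twice as bright as its neighbours
            oa.sigma_major = float(max(oa.sigma_major, ob.sigma_major) * 2 ** 0.25)
            oa.intensity = float(
                cfg.peak_intensity * 2 * np.pi * oa.sigma_major * (oa.sigma_major * _ASPECT)
            )
            event_rows.append(("fusion", frame, oa.pos[0], oa.pos[1], (a, b), (a,)))

        record(frame)

    tracks = pd.DataFrame(
        truth_rows, columns=["frame", "track_id", "x_px", "y_px", "area_px"]
    )
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    return snapshots, tracks, events, speeds, rng


def simulate_tracks(cfg: SimulationConfig) -> GroundTruth:
    """Trajectory-only simulation (no rendering), same motion model as
    :func:`simulate_movie`."""
    _snap, tracks, events, speeds, _rng = _simulate_state(cfg)
    return GroundTruth(tracks=tracks, events=events, object_speeds=speeds)


def _render_frame(cfg: SimulationConfig, snap) -> np.ndarray:
    """Sum of anisotropic Gaussian blobs oriented along each object's heading."""
    img = np.zeros((cfg.height, cfg.width), dtype=np.float64)
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for (_oid, pos, sigma, intensity, heading) in snap:
        sx, sy = sigma, sigma * _ASPECT
        half = int(np.ceil(4 * sx)) + 1
        x0, y0 = pos
        c0, c1 = int(round(x0)), int(round(y0))
        xs = slice(max(0, c0 - half), min(cfg.width, c0 + half + 1))
        ys = slice(max(0, c1 - half), min(cfg.height, c1 + half + 1))
        dx = xx[ys, xs] - x0
        dy = yy[ys, xs] - y0
        ca, sa = np.cos(heading), np.sin(heading)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        amp = intensity / (2 * np.pi * sx * sy)
        img[ys, xs] += amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    return img


def simulate_movie(cfg: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a movie with ground truth.

    Blobs are rendered per frame from the simulated state; a linear
    background plane of amplitude ``background_gradient_amp`` is added, the
    optical blur ``psf_sigma_px`` is applied to the signal, and Poisson noise
    is applied last when ``shot_noise > 0``. The ground-truth per-frame
    foreground pixel count is measured on the clean signal (pixels above 5%
    of the nominal blob peak).
    """
    snapshots, tracks, events, speeds, rng = _simulate_state(cfg)
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    background = cfg.background_gradient_amp * (
        xx / max(cfg.width - 1, 1) + yy / max(cfg.height - 1, 1)
    ) / 2.0

    frames = np.empty((cfg.n_frames, cfg.height, cfg.width), dtype=np.float64)
    fg_px = []
    for t, snap in enumerate(snapshots):
        signal = _render_frame(cfg, snap)
        if cfg.psf_sigma_px > 0:
            signal = ndimage.gaussian_filter(signal, cfg.psf_sigma_px)
        fg_px.append(int((signal > 0.05 * cfg.peak_intensity).sum()))
        clean = signal + background
        if cfg.shot_noise > 0:
            frames[t] = rng.poisson(clean * cfg.shot_noise) / cfg.shot_noise
        else:
            frames[t] = clean

    stack = ImageStack(
        frames=frames,
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_s=cfg.frame_interval_s,
        bit_depth=16,
    )
    truth = GroundTruth(
        tracks=tracks,
        events=events,
        per_frame_foreground_px=pd.Series(fg_px, index=range(cfg.n_frames), name="foreground_px"),
        object_speeds=speeds,
    )
    return stack, truth


def simulate_screen_reads(
    library: Library,
    abundances: dict,
    error_rate: float = 0.0,
    seed: int = 0,
    tail_length: int = 25,
    quality: int = 40,
):
    """Generate amplicon reads for a pooled screen.

    ``abundances`` maps shrna_id -> expected (exact) read count. Each read is
    TCGAG + 21-mer + the fixed vector sequence + a random tail, with uniform
    Phred quality. A fraction ``error_rate`` of reads carries one random
    substitution inside the insert; truth counts tally error-free reads only.

    Returns (reads, truth_counts) where reads is a list of
    (read_id, sequence, quality_string).
    """
    if error_rate < 0 or error_rate > 1:
        raise ConfigurationError("error_rate must be in [0, 1]")
    if library.records["sequence21"].duplicated().any():
        raise ConfigurationError("duplicate 21-mer sequences in library")
    if any(v < 0 for v in abundances.values()):
        raise ConfigurationError("abundances must be non-negative")
    rng = np.random.default_rng(seed)
    seq_of = dict(zip(library.records["shrna_id"], library.records["sequence21"]))
    unknown = set(abundances) - set(seq_of)
    if unknown:
        raise ConfigurationError(f"abundances reference unknown shRNAs: {sorted(unknown)}")

    bases = np.array(list("ACGT"))
    reads = []
    truth = {sid: 0 for sid in abundances}
    i = 0
    for sid, n in abundances.items():
        insert = seq_of[sid]
        for _ in range(int(n)):
            ins = insert
            erroneous = rng.random() < error_rate
            if erroneous:
                pos = int(rng.integers(INSERT_LEN))
                alt = rng.choice([b for b in "ACGT" if b != ins[pos]])
                ins = ins[:pos] + alt + ins[pos + 1 :]
            else:
                truth[sid] += 1
            tail = "".join(rng.choice(bases, size=tail_length))
            seq = READ_PREFIX + ins + VECTOR_SUFFIX + tail
            reads.append((f"read_{i}_{sid}", seq, chr(quality + 33) * len(seq)))
            i += 1
    return reads, truth


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence, quality_string) records as 4-line FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
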