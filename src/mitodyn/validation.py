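"""Independent oracles and end-to-end recovery experiments.

This module hosts two kinds of code. The *oracles* are deliberately naive
reimplementations used to cross-check the production code paths: exhaustive
enumeration of all gated matchings for the frame-linking assignment,
a plain-loop version of the screen hit rule, and an exact permutation
enumeration for the rank-sum test. The *experiments* run the full pipeline
(simulate -> denoise -> segment -> track -> call events) on synthetic movies
with known ground truth and score event recovery, speed recovery and gate
compliance. Both the test suite and the reproduction script drive these.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pandas as pd

from . import events as ev
from . import imaging, screen, synthetic, tracking

__all__ = [
    "brute_force_assignment_cost",
    "assignment_cost",
    "brute_force_hits",
    "exact_ranksum_p",
    "random_count_table",
    "score_events",
    "event_recovery_experiment",
    "speed_recovery_experiment",
    "tracking_oracle_experiment",
    "hit_rule_experiment",
]


# ---------------------------------------------------------------------------
# oracles

def brute_force_assignment_cost(
    pos_a: np.ndarray, pos_b: np.ndarray, gate: float, birth_death_cost: float
) -> float:
    """Minimum total cost over every gated matching with births/deaths,
    by exhaustive enumeration (feasible for <= ~6 objects per frame)."""
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 2)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 2)
    n, m = len(pos_a), len(pos_b)
    dist = np.hypot(
        pos_a[:, None, 0] - pos_b[None, :, 0], pos_a[:, None, 1] - pos_b[None, :, 1]
    ) if n and m else np.empty((n, m))
    best = (n + m) * birth_death_cost  # everything dies / is born
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in permutations(range(m), k):
                d = dist[list(rows), list(cols)]
                if np.any(d > gate):
                    continue
                cost = d.sum() + (n - k + m - k) * birth_death_cost
                if cost < best:
                    best = cost
    return float(best)


def assignment_cost(links, deaths, births, pos_of, birth_death_cost: float) -> float:
    """Total cost of a link_frames result (sum of link distances plus the
    birth/death penalties)."""
    total = sum(d for (_a, _b, d) in links)
    return float(total + (len(deaths) + len(births)) * birth_death_cost)


def brute_force_hits(
    table: pd.DataFrame, gene_of: dict, min_reads: int = 500, min_shrnas: int = 3
) -> set:
    """Hit genes by a plain loop over the count table (independent of
    :func:`mitodyn.screen.call_hits`)."""
    genes: dict[str, list] = {}
    for sid in table.index:
        genes.setdefault(gene_of[sid], []).append(sid)
    hits = set()
    for gene, sids in genes.items():
        ok = True
        for rep in table.columns:
            n_over = sum(1 for sid in sids if table.at[sid, rep] >= min_reads)
            if n_over < min_shrnas:
                ok = False
        if ok:
            hits.add(gene)
    return hits


def exact_ranksum_p(a, b) -> float:
    """Two-sided rank-sum p-value by enumerating all C(n_a+n_b, n_a)
    labelings of the pooled (tie-free) sample."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    extreme = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def random_count_table(
    rng: np.random.Generator, n_genes: int = 50, shrnas_per_gene: int = 5
):
    """Random two-replicate count table concentrated around the 500-read
    decision boundary, plus its gene map and Library."""
    rows = []
    for g in range(n_genes):
        gene = f"GENE{g:03d}"
        for s in range(shrnas_per_gene):
            sid = f"sh{g:03d}_{s}"
            rows.append((sid, gene))
    gene_of = dict(rows)
    index = [r[0] for r in rows]
    counts = pd.DataFrame(
        {
            "exp1": rng.integers(0, 1200, size=len(index)),
            "exp2": rng.integers(0, 1200, size=len(index)),
        },
        index=pd.Index(index, name="shrna_id"),
    )
    lib = screen.Library(
        pd.DataFrame(
            {
                "shrna_id": index,
                "gene": [gene_of[s] for s in index],
                "sequence21": [
                    "".join(rng.choice(list("ACGT"), size=21)) for _ in index
                ],
            }
        )
    )
    return counts, gene_of, lib


# ---------------------------------------------------------------------------
# ground-truth scoring

def score_events(
    truth: synthetic.GroundTruth,
    detected: list,
    tracks: list | None = None,
    frame_tol: int = 1,
    dist_tol_px: float = 20.0,
) -> dict:
    """Match detected fission/fusion calls to scheduled ground-truth events.

    A detected event matches a truth event of the same type when their frames
    differ by at most ``frame_tol`` and their locations by at most
    ``dist_tol_px``; matching is one-to-one, nearest first. When ``tracks``
    (the detected Track list) is given, the detected partner track must also
    lie within ``dist_tol_px`` of one of the truth event's participating
    objects near the matched frame. Returns recall, precision and tallies.
    """
    te = truth.events
    track_of = {t.track_id: t for t in tracks} if tracks is not None else {}
    pos = {
        (int(r.frame), int(r.track_id)): (float(r.x_px), float(r.y_px))
        for r in truth.tracks.itertuples()
    }

    candidates = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(te.itertuples()):
            if d.type != t.type or abs(d.frame - t.frame) > frame_tol:
                continue
            dd = np.hypot(d.x_px - t.x_px, d.y_px - t.y_px)
            if dd > dist_tol_px:
                continue
            candidates.append((dd, di, ti))
    candidates.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _dd, di, ti in candidates:
        if di in used_d or ti in used_t:
            continue
        if track_of:
            d = detected[di]
            t = te.iloc[ti]
            participants = tuple(t["parent_ids"]) + tuple(t["child_ids"])
            q = _partner_position(track_of.get(d.partner_track), d.frame)
            ok = False
            if q is not None:
                for df_ in range(-frame_tol, frame_tol + 1):
                    for pid in participants:
                        p = pos.get((d.frame + df_, pid))
                        if p is not None and np.hypot(p[0] - q[0], p[1] - q[1]) <= dist_tol_px:
                            ok = True
            if not ok:
                continue
        used_d.add(di)
        used_t.add(ti)
        matched += 1
    n_true = len(te)
    n_det = len(detected)
    return {
        "n_true": n_true,
        "n_detected": n_det,
        "n_matched": matched,
        "recall": matched / n_true if n_true else 1.0,
        "precision": matched / n_det if n_det else 1.0,
    }


def _partner_position(track, frame):
    if track is None:
        return None
    for df_ in (0, 1, -1):
        p = track.position_at(frame + df_)
        if p is not None:
            return p
    return None


# ---------------------------------------------------------------------------
# pipeline experiments

def _event_config_movie(seed: int, shot_noise: float) -> synthetic.SimulationConfig:
    """Study conditions for event-recovery benchmarks: 200x200 px, 100
    frames (LN229 regime), 10 sparse organelles (nearest-neighbour spacing
    above 50 px), 5 scheduled fissions and 3 fusions."""
    return synthetic.SimulationConfig(
        n_frames=100,
        height=200,
        width=200,
        n_mito=10,
        speed_range_um_s=(0.002, 0.006),
        size_range_px=(10.0, 13.0),
        fission_schedule=[(20, 0), (30, 1), (45, 2), (60, 3), (75, 4)],
        fusion_schedule=[(5, 6, 40), (7, 8, 55), (9, 5, 85)],
        background_gradient_amp=2.0,
        shot_noise=shot_noise,
        psf_sigma_px=0.8,
        peak_intensity=25.0,  # with shot_noise=1 the peak SNR is sqrt(25)=5
        heading_sigma_rad=0.5,
        min_spacing_px=51.0,
        border_margin_px=20.0,
        seed=seed,
    )


def run_pipeline(stack: imaging.ImageStack, event_border_margin_px: float = 15.0):
    """Denoise, segment, track, filter and call events on a movie."""
    segs = imaging.segment_stack(stack)
    tcfg = tracking.TrackingConfig()
    tracks = tracking.filter_tracks(tracking.build_tracks(segs, tcfg), tcfg)
    ecfg = ev.EventConfig(border_margin_px=event_border_margin_px)
    detected = ev.detect_events(
        tracks, ecfg, frame_shape=stack.frame_shape,
        frame_range=(0, stack.n_frames - 1),
    )
    return segs, tracks, detected


def event_recovery_experiment(seed: int, shot_noise: float = 0.0) -> dict:
    """Simulate one movie, run the full pipeline and score event recovery."""
    cfg = _event_config_movie(seed, shot_noise)
    stack, truth = synthetic.simulate_movie(cfg)
    _segs, tracks, detected = run_pipeline(stack)
    return score_events(truth, detected, tracks)


def speed_recovery_experiment(seed: int, n_mito: int = 8) -> dict:
    """Noise-free simulation without scheduled events; tracks each organelle
    through the pipeline and compares estimated against configured mean
    speeds. Also counts gate violations over all linked intervals."""
    cfg = synthetic.SimulationConfig(
        n_frames=80,
        height=220,
        width=220,
        n_mito=n_mito,
        speed_range_um_s=(0.006, 0.012),
        size_range_px=(10.0, 13.0),
        background_gradient_amp=2.0,
        shot_noise=0.0,
        psf_sigma_px=0.8,
        heading_sigma_rad=0.4,
        min_spacing_px=55.0,
        border_margin_px=25.0,
        seed=seed,
    )
    stack, truth = synthetic.simulate_movie(cfg)
    _segs, tracks, _detected = run_pipeline(stack)
    gate = tracking.TrackingConfig().max_disp_px_per_frame

    violations = 0
    rel_errors = []
    matched = 0
    for tr in tracks:
        steps = np.hypot(*np.diff(tr.positions(), axis=0).T)
        violations += int((steps > gate + 1e-9).sum())
        if tr.length < cfg.n_frames:  # compare full-length tracks only
            continue
        # identify the ground-truth object by the starting position
        t0 = truth.tracks[truth.tracks["frame"] == tr.start_frame]
        d = np.hypot(
            t0["x_px"].to_numpy() - tr.observations[0][2],
            t0["y_px"].to_numpy() - tr.observations[0][3],
        )
        tid = int(t0["track_id"].to_numpy()[d.argmin()])
        est = track_mean_speed(tr, cfg.pixel_size_um, cfg.frame_interval_s)
        true_speed = truth.object_speeds[tid]
        rel_errors.append(abs(est - true_speed) / true_speed)
        matched += 1
    return {
        "n_objects": matched,
        "max_rel_error": float(max(rel_errors)) if rel_errors else np.nan,
        "mean_rel_error": float(np.mean(rel_errors)) if rel_errors else np.nan,
        "gate_violations": violations,
    }


def track_mean_speed(track, pixel_size_um: float, frame_interval_s: float) -> float:
    steps = np.hypot(*np.diff(track.positions(), axis=0).T)
    return float(steps.mean() * pixel_size_um / frame_interval_s)


def tracking_oracle_experiment(seed: int, n_pairs: int = 500, max_objects: int = 6) -> dict:
    """Random frame pairs: the gated Hungarian assignment cost must equal
    the exhaustive-enumeration minimum on every pair."""
    rng = np.random.default_rng(seed)
    cfg = tracking.TrackingConfig()
    exact = 0
    for _ in range(n_pairs):
        n = int(rng.integers(0, max_objects + 1))
        m = int(rng.integers(0, max_objects + 1))
        pa = rng.uniform(0, 100, size=(n, 2))
        pb = rng.uniform(0, 100, size=(m, 2))
        oa = pd.DataFrame({"object_id": range(n), "x_px": pa[:, 0], "y_px": pa[:, 1]})
        ob = pd.DataFrame({"object_id": range(m), "x_px": pb[:, 0], "y_px": pb[:, 1]})
        links, deaths, births = tracking.link_frames(oa, ob, cfg)
        got = assignment_cost(links, deaths, births, None, cfg.birth_death_cost_px)
        want = brute_force_assignment_cost(
            pa, pb, cfg.max_disp_px_per_frame, cfg.birth_death_cost_px
        )
        if abs(got - want) <= 1e-6 * max(1.0, want):
            exact += 1
    return {"n_pairs": n_pairs, "n_exact": exact, "fraction_exact": exact / n_pairs}


def hit_rule_experiment(seed: int, n_tables: int = 1000) -> dict:
    """Randomized toy count tables: the vectorised hit rule must agree with
    the brute-force loop on every table."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_tables):
        counts, gene_of, lib = random_count_table(rng, n_genes=50, shrnas_per_gene=5)
        hits_df = screen.call_hits(counts, lib)
        got = set(hits_df.loc[hits_df["is_hit"], "gene"])
        want = brute_force_hits(counts, gene_of)
        if got == want:
            agree += 1
    return {"n_tables": n_tables, "n_agree": agree, "fraction_agree": agree / n_tables}
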