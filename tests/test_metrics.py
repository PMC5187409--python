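import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mitodyn.metrics import (
    FA_CLASSES,
    chemotaxis_summary,
    classify_fa,
    cortical_quantify,
    track_metrics,
)
from mitodyn.synthetic import SimulationConfig, simulate_tracks

from conftest import gaussian_blob

CAL = dict(pixel_size_um=0.12, frame_interval_s=10.0)


def straight_track(step_px, n):
    return np.column_stack([np.arange(n) * step_px, np.zeros(n)])


class TestTrackMetrics:
    def test_constant_velocity_arithmetic(self):
        m = track_metrics(straight_track(2.0, 11), **CAL)
        assert m.mean_speed_um_s == pytest.approx(2 * 0.12 / 10)
        assert m.cumulative_distance_um == pytest.approx(10 * 2 * 0.12)
        assert m.euclidean_distance_um == pytest.approx(m.cumulative_distance_um)
        assert m.processivity == 1.0
        assert m.processivity_class == "high"

    def test_stationary_track(self):
        m = track_metrics(np.zeros((8, 2)), **CAL)
        assert m.mean_speed_um_s == 0.0
        assert m.processivity == 0.0
        assert m.processivity_class == "low"

    @pytest.mark.parametrize(
        "moving,expected_class", [(8, "high"), (7, "low")], ids=["0.8", "0.7-strict"]
    )
    def test_processivity_cutoff_is_strict(self, moving, expected_class):
        """>70% of intervals in motion means high; exactly 70% is low."""
        pos = [np.zeros(2)]
        for i in range(10):
            step = np.array([2.0, 0.0]) if i < moving else np.zeros(2)
            pos.append(pos[-1] + step)
        m = track_metrics(np.array(pos), **CAL)
        assert m.processivity == pytest.approx(moving / 10)
        assert m.processivity_class == expected_class

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            track_metrics(np.zeros((1, 2)), **CAL)

    @settings(max_examples=60, deadline=None)
    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 40), st.just(2)),
            elements=st.floats(-100, 100),
        )
    )
    def test_euclidean_never_exceeds_cumulative(self, pos):
        m = track_metrics(pos, **CAL)
        assert m.euclidean_distance_um <= m.cumulative_distance_um + 1e-9

    def test_speeds_recovered_from_trajectory_simulation(self):
        """Per-object mean speed measured on clean simulated trajectories
        agrees with each object's configured speed within 5%."""
        cfg = SimulationConfig(
            n_frames=60, height=400, width=400, n_mito=12,
            speed_range_um_s=(0.004, 0.012), min_spacing_px=40,
            border_margin_px=30, seed=3,
        )
        truth = simulate_tracks(cfg)
        for tid, grp in truth.tracks.groupby("track_id"):
            pos = grp.sort_values("frame")[["x_px", "y_px"]].to_numpy()
            m = track_metrics(pos, **CAL)
            assert m.mean_speed_um_s == pytest.approx(
                truth.object_speeds[tid], rel=0.05
            )


class TestChemotaxis:
    def test_straight_path_has_unit_directionality(self):
        s = chemotaxis_summary([straight_track(3.0, 20)], **CAL)
        assert s.per_cell["directionality"].iloc[0] == pytest.approx(1.0)

    def test_closed_loop_has_zero_directionality(self):
        theta = np.linspace(0, 2 * np.pi, 33)
        loop = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        s = chemotaxis_summary([loop], **CAL)
        assert s.per_cell["euclidean_um"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert s.per_cell["directionality"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_random_walks_lose_directionality_with_length(self):
        """Mean directionality of unbiased random walks is < 1 and decreases
        as paths get longer."""
        rng = np.random.default_rng(0)

        def walks(n_steps, n=300):
            steps = rng.normal(size=(n, n_steps, 2))
            return [np.vstack([np.zeros(2), np.cumsum(s, axis=0)]) for s in steps]

        short = chemotaxis_summary(walks(8), **CAL).mean_directionality
        long = chemotaxis_summary(walks(64), **CAL).mean_directionality
        assert short < 1.0
        assert long < short

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            chemotaxis_summary([], **CAL)


class TestFocalAdhesions:
    def test_rule_examples(self):
        fas = {
            "only_first": [(0, 10, 10)],
            "appears_last": [(9, 5, 5)],
            "slides": [(0, 0, 0), (9, 30, 0)],
            "mature": [(0, 0, 0), (9, 1, 0)],
        }
        res = classify_fa(fas, slide_radius_px=8.0, movie_duration_h=2.0,
                          frame_range=(0, 9))
        assert res.counts == {
            "decaying": 1, "newly_formed": 1, "stable_sliding": 1, "stable_mature": 1
        }
        assert res.assembly_rate_per_h == pytest.approx(0.5)

    def test_decay_rate_per_hour(self):
        fas = {f"d{i}": [(0, i, i)] for i in range(6)}
        fas["keeper"] = [(0, 50, 50), (9, 50, 50)]
        res = classify_fa(fas, 8.0, movie_duration_h=2.0, frame_range=(0, 9))
        assert res.counts["decaying"] == 6
        assert res.decay_rate_per_h == pytest.approx(3.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sets(st.integers(0, 5), min_size=1), min_size=1, max_size=8))
    def test_classes_exhaustive_and_exclusive(self, presence_sets):
        fas = {
            i: [(f, float(i), 0.0) for f in sorted(frames)]
            for i, frames in enumerate(presence_sets)
        }
        res = classify_fa(fas, 2.0, movie_duration_h=1.0, frame_range=(0, 5))
        assert set(res.counts) == set(FA_CLASSES)
        assert sum(res.counts.values()) == len(fas)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_fa({"a": [(0, 0, 0)]}, 1.0, movie_duration_h=0.0)


def square_cell(x0, y0, side):
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


class TestCortical:
    def test_uniform_cell_fraction_equals_belt_area_fraction(self):
        img = np.full((120, 120), 50.0)
        side = 80
        res = cortical_quantify(
            img, square_cell(20, 20, side), pixel_size_um=0.12, belt_width_um=1.2,
        )
        belt_frac = res.cortical_area_px / res.cell_area_px
        assert res.cortical_fraction == pytest.approx(belt_frac, rel=1e-9)
        assert res.density_ratio == pytest.approx(1.0)

    def test_signal_confined_to_belt_gives_unit_fraction(self):
        img = np.zeros((120, 120))
        img[20:30, 20:100] = 80.0  # a strip hugging the cell's top edge
        res = cortical_quantify(
            img, square_cell(20, 20, 80), pixel_size_um=0.12, belt_width_um=1.2,
        )
        assert res.cortical_fraction == pytest.approx(1.0)

    def test_known_sixty_forty_split_recovered(self):
        """Constructed cell with 60% of intensity in the belt and 40% inside
        is recovered within rasterization tolerance (2%)."""
        img = np.zeros((140, 140))
        poly = square_cell(20, 20, 100)
        belt_px = round(1.2 / 0.12)
        inner = slice(20 + belt_px, 121 - belt_px)
        cell = np.zeros_like(img, dtype=bool)
        cell[20:121, 20:121] = True
        interior = np.zeros_like(cell)
        interior[inner, inner] = True
        belt = cell & ~interior
        img[belt] = 60.0 / belt.sum()
        img[interior] = 40.0 / interior.sum()
        res = cortical_quantify(img, poly, pixel_size_um=0.12, belt_width_um=1.2)
        assert res.cortical_fraction == pytest.approx(0.60, abs=0.02)

    def test_invariance_to_intensity_scaling(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 9, size=(120, 120))
        poly = square_cell(25, 25, 70)
        r1 = cortical_quantify(img, poly, 0.12, belt_width_um=2.0)
        r2 = cortical_quantify(7.0 * img, poly, 0.12, belt_width_um=2.0)
        assert r1.cortical_fraction == pytest.approx(r2.cortical_fraction)
        assert r1.density_ratio == pytest.approx(r2.density_ratio)

    def test_saturation_flag_follows_bit_depth(self):
        img = np.full((60, 60), 100.0)
        poly = square_cell(10, 10, 40)
        assert not cortical_quantify(img, poly, 0.12, 1.2, bit_depth=8).saturation_flag
        img[20, 20] = 255.0
        assert cortical_quantify(img, poly, 0.12, 1.2, bit_depth=8).saturation_flag

    def test_belt_wider_than_cell_flagged_not_error(self):
        img = np.ones((60, 60))
        res = cortical_quantify(img, square_cell(20, 20, 10), 0.12, belt_width_um=5.0)
        assert res.belt_covers_cell
        assert res.cortical_fraction == pytest.approx(1.0)
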