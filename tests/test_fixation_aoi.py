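"""AOI polygons, fixation assignment, metrics, density and persistence."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilpipe import (
    AOIError,
    assign_aoi,
    compute_aoi_statistics,
    fixation_density,
    load_aois,
    point_in_polygon,
    save_aois,
)
from pupilpipe.fixation_aoi import points_in_polygon, validate_aois
from pupilpipe.synthetic import generate_fixations

from oracles import ray_cast_contains


def random_polygon(rng, n_verts=12, center=(500, 500), radius=300):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_verts))
    r = rng.uniform(0.3 * radius, radius, n_verts)
    pts = [(center[0] + ri * np.cos(a), center[1] + ri * np.sin(a))
           for a, ri in zip(angles, r)]
    return pts + [pts[0]]


class TestPointInPolygon:
    def test_inside_unit_square(self, unit_square):
        assert point_in_polygon((0.5, 0.5), unit_square) is True

    def test_outside_unit_square(self, unit_square):
        assert point_in_polygon((2.0, 2.0), unit_square) is False

    def test_boundary_edge_and_vertex_inclusive(self, unit_square):
        assert point_in_polygon((0.5, 0.0), unit_square) is True
        assert point_in_polygon((0.0, 0.0), unit_square) is True
        assert point_in_polygon((1.0, 1.0), unit_square) is True

    def test_open_polygon_rejected(self):
        with pytest.raises(AOIError, match="closed"):
            point_in_polygon((0.5, 0.5), [(0, 0), (1, 0), (1, 1), (0, 1)])

    def test_concave_polygon(self):
        # arrowhead: the notch is outside
        poly = [(0, 0), (4, 0), (2, 1), (4, 4), (0, 4), (0, 0)]
        assert point_in_polygon((1.0, 2.0), poly) is True
        assert point_in_polygon((3.5, 2.0), poly) is False

    def test_agrees_with_ray_casting_oracle(self):
        rng = np.random.default_rng(0)
        poly = random_polygon(rng)
        x = rng.uniform(0, 1000, 10_000)
        y = rng.uniform(0, 1000, 10_000)
        got = points_in_polygon(x, y, [(float(a), float(b)) for a, b in poly])
        expected = ray_cast_contains(x, y, poly)
        # the oracle is only authoritative off-boundary; random floats are
        # off-boundary almost surely
        assert (got == expected).all()

    # coordinates on a 1e-3 grid: keeps points well off the boundary (or
    # exactly on it), so float rounding cannot flip the verdict
    _grid = st.integers(-3000, 3000).map(lambda v: v / 1000.0)
    _shift = st.integers(-100_000, 100_000).map(lambda v: v / 1000.0)

    @settings(max_examples=50, deadline=None)
    @given(x=_grid, y=_grid, dx=_shift, dy=_shift)
    def test_translation_invariance(self, x, y, dx, dy):
        square = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0), (0.0, 0.0)]
        shifted = [(a + dx, b + dy) for a, b in square]
        assert point_in_polygon((x, y), square) == point_in_polygon((x + dx, y + dy), shifted)


class TestAssignAoi:
    def _aois(self):
        return {
            "left": [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)],
            "right": [(200, 0), (300, 0), (300, 100), (200, 100), (200, 0)],
        }

    def _fix(self, pts):
        return pd.DataFrame({"trial": 1, "x": [p[0] for p in pts], "y": [p[1] for p in pts],
                             "duration": 100})

    def test_single_containment(self):
        out = assign_aoi(self._fix([(50, 50), (250, 50)]), self._aois())
        assert out["aoi"].tolist() == ["left", "right"]

    def test_outside(self):
        out = assign_aoi(self._fix([(150, 50)]), self._aois())
        assert out["aoi"].tolist() == ["outside"]

    def test_overlap_first_declared_wins(self):
        aois = {
            "a": [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)],
            "b": [(50, 0), (150, 0), (150, 100), (50, 100), (50, 0)],
        }
        out = assign_aoi(self._fix([(75, 50)]), aois)
        assert out["aoi"].tolist() == ["a"]

    def test_nested_per_trial(self):
        aois = {
            "1": {"only": [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]},
            "2": {"only": [(20, 20), (30, 20), (30, 30), (20, 30), (20, 20)]},
        }
        fix = pd.DataFrame({"trial": [1, 2], "x": [5.0, 5.0], "y": [5.0, 5.0]})
        out = assign_aoi(fix, aois, trial_cols="trial")
        assert out["aoi"].tolist() == ["only", "outside"]

    def test_nested_missing_trial_key_errors(self):
        aois = {"1": {"a": [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]}}
        fix = pd.DataFrame({"trial": [2], "x": [0.5], "y": [0.5]})
        with pytest.raises(AOIError, match="trial '2'"):
            assign_aoi(fix, aois, trial_cols="trial")

    def test_translation_of_everything_is_invariant(self):
        fix = self._fix([(50, 50), (150, 50), (250, 50)])
        base = assign_aoi(fix, self._aois())["aoi"].tolist()
        dx, dy = 37.5, -12.25
        fix2 = fix.assign(x=fix["x"] + dx, y=fix["y"] + dy)
        aois2 = {k: [(x + dx, y + dy) for x, y in v] for k, v in self._aois().items()}
        assert assign_aoi(fix2, aois2)["aoi"].tolist() == base


class TestAoiStatistics:
    def test_counts_and_durations(self):
        aois = {"left": [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)]}
        fix = pd.DataFrame({
            "trial": [1, 1, 1], "x": [10.0, 20.0, 30.0], "y": [10.0, 20.0, 30.0],
            "duration": [100, 200, 300],
        })
        stats = compute_aoi_statistics(fix, aois)
        row = stats.set_index("aoi").loc["left"]
        assert row["n_fixations"] == 3 and row["total_duration"] == 600.0

    def test_zero_row_for_empty_aoi(self):
        aois = {"left": [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)],
                "right": [(200, 0), (300, 0), (300, 100), (200, 100), (200, 0)]}
        fix = pd.DataFrame({"trial": [1], "x": [10.0], "y": [10.0], "duration": [50]})
        stats = compute_aoi_statistics(fix, aois).set_index("aoi")
        assert stats.loc["right", "n_fixations"] == 0
        assert stats.loc["right", "total_duration"] == 0.0

    def test_conservation_counts_and_durations(self):
        rng = np.random.default_rng(0)
        aois = {"a": [(0, 0), (200, 0), (200, 200), (0, 200), (0, 0)],
                "b": [(300, 0), (600, 0), (600, 200), (300, 200), (300, 0)]}
        fix = pd.DataFrame({
            "trial": rng.integers(1, 4, 60),
            "x": rng.uniform(0, 800, 60), "y": rng.uniform(0, 300, 60),
            "duration": rng.integers(50, 500, 60),
        })
        stats = compute_aoi_statistics(fix, aois)
        for trial, g in fix.groupby("trial"):
            sub = stats[stats["trial"] == trial]
            assert sub["n_fixations"].sum() == len(g)
            assert sub["total_duration"].sum() == pytest.approx(g["duration"].sum())

    def test_counts_only_without_duration_column(self):
        aois = {"a": [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]}
        fix = pd.DataFrame({"trial": [1], "x": [5.0], "y": [5.0]})
        stats = compute_aoi_statistics(fix, aois)
        assert "total_duration" not in stats.columns


class TestFixationDensity:
    def test_mode_at_single_fixation(self):
        fix = pd.DataFrame({"x": [320.0], "y": [240.0]})
        grid = fixation_density(fix, canvas=(640, 480), bandwidth=10.0)
        assert np.unravel_index(grid.argmax(), grid.shape) == (240, 320)

    def test_symmetry_about_midline(self):
        # odd width so columns 200 and 400 mirror exactly about column 300
        fix = pd.DataFrame({"x": [200.0, 400.0], "y": [240.0, 240.0]})
        grid = fixation_density(fix, canvas=(601, 480), bandwidth=15.0)
        np.testing.assert_allclose(grid, grid[:, ::-1], atol=1e-12)

    def test_mass_equals_total_duration(self):
        fix = pd.DataFrame({"x": [300.0, 350.0], "y": [240.0, 260.0],
                            "duration": [100.0, 250.0]})
        grid = fixation_density(fix, canvas=(640, 480), bandwidth=12.0)
        assert grid.sum() == pytest.approx(350.0, rel=0.01)

    def test_empty_set_zero_grid(self):
        grid = fixation_density(pd.DataFrame({"x": [], "y": []}), canvas=(100, 100))
        assert grid.shape == (100, 100) and not grid.any()

    def test_invalid_bandwidth(self):
        fix = pd.DataFrame({"x": [10.0], "y": [10.0]})
        with pytest.raises(ValueError, match="bandwidth"):
            fixation_density(fix, canvas=(100, 100), bandwidth=0.0)


class TestPersistence:
    def test_flat_round_trip(self, tmp_path):
        aois = {"left": [[0, 0], [100, 0], [100, 100], [0, 100], [0, 0]],
                "right": [[200, 0], [300, 0], [300, 100], [200, 100], [200, 0]]}
        path = tmp_path / "aois.json"
        save_aois(aois, path)
        assert load_aois(path) == validate_aois(aois)

    def test_nested_round_trip(self, tmp_path):
        aois = {"A|1": {"face": [[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]},
                "A|2": {"face": [[5, 5], [15, 5], [15, 15], [5, 15], [5, 5]]}}
        path = tmp_path / "nested.json"
        save_aois(aois, path)
        loaded = load_aois(path)
        assert set(loaded) == {"A|1", "A|2"}
        assert loaded == validate_aois(aois)

    def test_unclosed_polygon_named_on_load(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"open_one": [[0, 0], [1, 0], [1, 1], [0, 1]]}))
        with pytest.raises(AOIError, match="open_one"):
            load_aois(path)

    def test_malformed_json_names_path(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(AOIError, match="broken.json"):
            load_aois(path)


class TestGenerateFixations:
    def test_labels_recovered_exactly(self):
        aois = {"A": [(0, 0), (300, 0), (300, 300), (0, 300), (0, 0)],
                "B": [(600, 0), (900, 0), (900, 300), (600, 300), (600, 0)]}
        fix, labels = generate_fixations(aois, {"A": 5, "B": 3}, outside_count=2, seed=4)
        assert len(fix) == 10
        out = assign_aoi(fix, aois)
        assert out["aoi"].tolist() == labels

    def test_zero_counts_empty(self):
        aois = {"A": [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]}
        fix, labels = generate_fixations(aois, {"A": 0})
        assert fix.empty and labels == []

    def test_determinism(self):
        aois = {"A": [(0, 0), (50, 0), (50, 50), (0, 50), (0, 0)]}
        f1, l1 = generate_fixations(aois, {"A": 8}, outside_count=3, seed=99)
        f2, l2 = generate_fixations(aois, {"A": 8}, outside_count=3, seed=99)
        pd.testing.assert_frame_equal(f1, f2)
        assert l1 == l2

    def test_degenerate_aoi_errors(self):
        # thin diagonal band: near-zero area relative to its bounding box
        sliver = [(0, 0), (1000, 1000), (1000, 1000 + 1e-9), (0, 1e-9), (0, 0)]
        with pytest.raises(ValueError, match="rejection sampling"):
            generate_fixations({"S": sliver}, {"S": 1}, max_attempts=50)
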