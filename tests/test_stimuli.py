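"""Unit and property tests for controlled stimulus generation."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from skinnertank import stimuli as st


def brute_force_hull_area(points):
    """Independent oracle: the convex hull is the maximum-area polygon with
    vertices drawn from the point set (subsets sorted angularly)."""
    pts = np.asarray(points, dtype=float)
    best = 0.0
    for k in range(3, len(pts) + 1):
        for sub in itertools.combinations(range(len(pts)), k):
            p = pts[list(sub)]
            c = p.mean(axis=0)
            order = np.argsort(np.arctan2(p[:, 1] - c[1], p[:, 0] - c[0]))
            p = p[order]
            x, y = p[:, 0], p[:, 1]
            area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            best = max(best, area)
    return best


def make_array(centers, radii, field=(6.0, 5.0)):
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    return st.DotArray(len(radii), centers, radii, field)


class TestMetrics:
    def test_single_dot_closed_form(self):
        a = make_array([[3.0, 2.5]], [0.40])
        assert st.cumulative_area(a) == pytest.approx(math.pi * 0.16, rel=1e-12)

    def test_identical_arrays_area_ratio_one(self, small_set):
        p = small_set.pairs[0]
        assert st.cumulative_area(p.small) / st.cumulative_area(p.small) == 1.0

    def test_two_vs_three_dot_arithmetic(self):
        a = make_array([[1, 1], [4, 4]], [0.45, 0.45])
        b = make_array([[1, 1], [3, 3], [5, 1]], [0.375] * 3)
        ratio = st.cumulative_area(a) / st.cumulative_area(b)
        assert st.cumulative_area(a) == pytest.approx(1.2723, abs=2e-4)
        assert st.cumulative_area(b) == pytest.approx(1.3254, abs=2e-4)
        assert ratio == pytest.approx(0.96, abs=5e-3)

    def test_empty_array_rejected(self):
        with pytest.raises(st.ConstraintError):
            a = make_array(np.empty((0, 2)), [])
            st.cumulative_area(a)

    def test_hull_unit_square(self):
        assert st.convex_hull_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(1.0)

    def test_hull_collinear_degenerate(self):
        assert st.convex_hull_area([(0, 0), (1, 1), (2, 2)]) == 0.0

    def test_hull_matches_brute_force_oracle(self, rng):
        for n in (4, 5, 6, 7, 8):
            pts = rng.uniform(0, 5, size=(n, 2))
            assert st.convex_hull_area(pts) == pytest.approx(
                brute_force_hull_area(pts), rel=1e-9)

    def test_density_unit_square(self):
        a = make_array([[1, 1], [2, 1], [2, 2], [1, 2]], [0.1] * 4)
        assert st.density(a) == pytest.approx(4.0)

    def test_density_needs_three_noncollinear(self):
        with pytest.raises(st.ConstraintError):
            st.density(make_array([[1, 1], [2, 2]], [0.1, 0.1]))
        with pytest.raises(st.ConstraintError):
            st.density(make_array([[1, 1], [2, 2], [3, 3]], [0.1] * 3))

    @given(s=st_h.floats(min_value=0.5, max_value=2.0))
    @settings(max_examples=25, deadline=None)
    def test_scaling_laws(self, s):
        rng = np.random.default_rng(7)
        centers = rng.uniform(1, 4, size=(5, 2))
        a = make_array(centers, [0.2] * 5, field=(12, 12))
        b = make_array(centers * s, np.full(5, 0.2 * s), field=(24.1, 24.1))
        assert st.cumulative_area(b) == pytest.approx(
            st.cumulative_area(a) * s * s, rel=1e-9)
        assert st.density(b) == pytest.approx(st.density(a) / (s * s), rel=1e-9)


class TestGeneration:
    def test_pair_postconditions_mid_band_hull(self):
        p = st.generate_pair(2, 3, "mid", "hull_matched", seed=1)
        assert 0.86 <= p.area_ratio() <= 0.95
        m = st.matching_metrics(p)
        assert abs(m["hull_small"] - m["hull_large"]) / m["hull_large"] <= 0.05
        p.verify()

    def test_pair_density_no_band(self):
        p = st.generate_pair(3, 12, None, "density_matched", seed=2)
        m = st.matching_metrics(p)
        assert abs(m["density_small"] - m["density_large"]) / m["density_large"] <= 0.05
        assert p.area_band is None

    def test_equal_numerosities_rejected(self):
        with pytest.raises(st.ConstraintError):
            st.generate_pair(3, 3, "mid", "hull_matched", seed=1)

    def test_deterministic_given_seed(self):
        p1 = st.generate_pair(3, 4, "low", "density_matched", seed=42)
        p2 = st.generate_pair(3, 4, "low", "density_matched", seed=42)
        assert np.array_equal(p1.small.centers, p2.small.centers)
        assert np.array_equal(p1.large.radii, p2.large.radii)

    def test_geometry_invariants_from_raw_arrays(self, small_set):
        for p in small_set.pairs:
            p.small.validate()
            p.large.validate()
            ratio = (np.pi * (p.small.radii ** 2).sum()) / \
                (np.pi * (p.large.radii ** 2).sum())
            lo, hi = st.AREA_BANDS[p.area_band]
            assert lo - 1e-9 <= ratio <= hi + 1e-9

    def test_set_composition_2v3(self, small_set):
        comp = small_set.composition
        assert len(small_set.pairs) == 24
        assert comp["bands"] == {"low": 8, "mid": 8, "high": 8}
        assert comp["controls"] == {"hull_matched": 12, "density_matched": 12}

    def test_set_composition_3v12(self, sparse_set):
        comp = sparse_set.composition
        assert len(sparse_set.pairs) == 18
        assert comp["bands"] == {None: 18}
        assert comp["controls"] == {"hull_matched": 9, "density_matched": 9}

    def test_unknown_contrast_rejected(self):
        with pytest.raises(st.ConstraintError):
            st.build_stimulus_set("7v9", seed=0)

    def test_packing_relaxation_on_manual_card(self):
        (lo, hi), relaxed = st.effective_diameter_range(12, st.MANUAL_CARD)
        assert relaxed
        s = math.sqrt(0.4 / (12 * math.pi * 0.425 ** 2 / 9.0))
        assert lo == pytest.approx(0.75 * s)
        assert hi == pytest.approx(0.95 * s)
        (_, _), relaxed_disp = st.effective_diameter_range(12, st.DISPLAY_WINDOW)
        assert not relaxed_disp

    def test_manual_card_hull_matching_infeasible_for_3v12(self):
        # 12 relaxed dots cannot contract their center hull below the
        # largest triangle 3 dots can span on the 3 x 3 cm card; the
        # generator must name the violated constraint
        with pytest.raises(st.ConstraintError) as exc:
            st.generate_pair(3, 12, None, "hull_matched",
                             field_size=st.MANUAL_CARD, seed=5)
        assert exc.value.constraint == "hull"

    def test_manual_card_density_matching_feasible_for_3v12(self):
        p = st.generate_pair(3, 12, None, "density_matched",
                             field_size=st.MANUAL_CARD, seed=5)
        p.verify()
        assert p.small.relaxed and p.large.relaxed


class TestPositioning:
    def test_fixed_scheme_single_placement(self, small_set):
        assert len(st.position_variants(small_set.pairs[0], "fixed")) == 1

    def test_varied18_distinct_in_window(self, small_set):
        placements = st.position_variants(small_set.pairs[0], "varied18")
        assert len(placements) == 18
        assert len({(p.dx, p.dy, p.separation) for p in placements}) == 18

    def test_rotation_over_36_trials_uses_each_twice(self):
        order = st.rotation_order(36)
        counts = {i: order.count(i) for i in range(18)}
        assert all(c == 2 for c in counts.values())

    def test_unknown_scheme_rejected(self, small_set):
        with pytest.raises(ValueError):
            st.position_variants(small_set.pairs[0], "varied7")


class TestSerializationAndRendering:
    def test_json_roundtrip(self, small_set):
        text = st.set_to_json(small_set)
        back = st.set_from_json(text)
        assert back.contrast == small_set.contrast
        for a, b in zip(back.pairs, small_set.pairs):
            assert np.allclose(a.small.centers, b.small.centers)
            assert np.allclose(a.large.radii, b.large.radii)
            assert a.control_type == b.control_type
        json.loads(text)  # stays valid JSON

    def test_raster_marks_dot_centers(self, small_set):
        arr = small_set.pairs[0].large
        img = st.render_array(arr, dots_per_cm=20)
        w, h = arr.field_size
        assert img.shape == (int(h * 20), int(w * 20))
        for c in arr.centers:
            col = int(c[0] * 20)
            row = int((h - c[1]) * 20)
            assert img[row, col] == 0  # dot centers are black
        assert img[0, 0] == 255  # corners are background

    def test_svg_contains_all_dots(self, small_set):
        arr = small_set.pairs[0].small
        svg = st.array_to_svg(arr)
        assert svg.count("<circle") == arr.numerosity
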