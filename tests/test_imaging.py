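"""Shape-factor geometry against closed forms, and segmentation against
the synthetic generator's polygon-exact ground truth."""

import numpy as np
import pytest

from powdermorph import imaging, synthetic
from powdermorph.imaging import (
    SegmentationConfig,
    feret_diameters,
    process_micrographs,
    segment_particles,
    shape_factors,
)

from conftest import regular_polygon


def brute_force_feret(polygon: np.ndarray, n_angles: int = 3600):
    """Oracle: caliper widths over a fine angular grid of projections."""
    p = np.asarray(polygon, float)
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = dirs @ p.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    return widths.max(), widths.min()


class TestFeret:
    @pytest.mark.parametrize(
        "polygon, expected",
        [
            (np.array([[0, 0], [10, 0], [10, 10], [0, 10.0]]), (np.sqrt(200), 10.0)),
            (np.array([[0, 0], [10, 0], [10, 4], [0, 4.0]]), (np.sqrt(116), 4.0)),
        ],
        ids=["square10", "rect10x4"],
    )
    def test_rectangles_closed_form(self, polygon, expected):
        max_f, min_f = feret_diameters(polygon)
        assert max_f == pytest.approx(expected[0], abs=1e-9)
        assert min_f == pytest.approx(expected[1], abs=1e-9)
        # and agrees with the angular-grid oracle
        bf_max, bf_min = brute_force_feret(polygon)
        assert max_f == pytest.approx(bf_max, rel=1e-5)
        assert min_f == pytest.approx(bf_min, rel=1e-5)

    def test_circle_symmetry(self):
        poly = regular_polygon(360, radius=30.0)
        max_f, min_f = feret_diameters(poly)
        assert max_f == pytest.approx(60.0, rel=0.005)
        assert min_f == pytest.approx(60.0, rel=0.005)

    def test_degenerate_collinear(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            feret_diameters(line)


class TestShapeFactors:
    def test_square_closed_form(self, square):
        s = shape_factors(square)
        assert s.circularity == pytest.approx(np.pi / 4, abs=1e-12)
        assert s.solidity == pytest.approx(1.0, abs=1e-12)
        assert s.convexity == pytest.approx(1.0, abs=1e-12)
        assert s.elongation == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert s.area == pytest.approx(100.0)
        assert s.perimeter == pytest.approx(40.0)
        assert s.equivalent_diameter == pytest.approx(np.sqrt(400 / np.pi), abs=1e-9)

    def test_circle_is_extremal(self, fine_circle):
        s = shape_factors(fine_circle)
        for value in (s.circularity, s.solidity, s.convexity, s.elongation):
            assert value >= 0.99

    def test_equivalent_diameter_from_area(self):
        # area 100 regardless of shape: sqrt(400/pi) = 11.2838
        s = shape_factors(np.array([[0, 0], [20, 0], [20, 5], [0, 5.0]]))
        assert s.area == pytest.approx(100.0)
        assert s.equivalent_diameter == pytest.approx(11.283791, abs=1e-5)

    def test_zero_area_polygon_raises(self):
        degenerate = np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 10.0]])
        with pytest.raises(ValueError):
            shape_factors(degenerate)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(42)
        dist = synthetic.ShapeDistribution(100, 0.1, 0.7, 0.05, 0.15, 2)
        poly = synthetic.sample_outline(dist, rng)
        base = shape_factors(poly)
        for angle in (0.3, 1.1, 2.5):
            R = np.array(
                [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
            )
            rot = shape_factors(poly @ R.T)
            for name, b, r in zip(
                imaging.FACTOR_NAMES, base.as_dict().values(), rot.as_dict().values()
            ):
                assert r == pytest.approx(b, rel=1e-9), name

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        dist = synthetic.ShapeDistribution(80, 0.1, 0.8, 0.05, 0.1, 1)
        poly = synthetic.sample_outline(dist, rng)
        s1, s2 = shape_factors(poly), shape_factors(poly * 2.0)
        assert s2.area == pytest.approx(4 * s1.area, rel=1e-9)
        for attr in ("perimeter", "equivalent_diameter", "max_feret", "min_feret"):
            assert getattr(s2, attr) == pytest.approx(2 * getattr(s1, attr), rel=1e-9)
        for attr in ("elongation", "solidity", "convexity", "circularity"):
            assert getattr(s2, attr) == pytest.approx(getattr(s1, attr), rel=1e-9)


class TestSegmentation:
    def test_blank_image(self):
        assert segment_particles(np.full((64, 64), 200, dtype=np.uint8)) == []

    def test_matches_scene_truth(self):
        rng = np.random.default_rng(0)
        dist = synthetic.ShapeDistribution(110, 0.1, 0.8, 0.05, 0.12, 2)
        outlines = [synthetic.sample_outline(dist, rng) for _ in range(5)]
        img, truth = synthetic.render_scene(
            outlines, image_size=640, intensity_noise=0.0, rng_seed=rng
        )
        polys = segment_particles(img)
        assert len(polys) == len(truth.particles) == 5
        found = sorted(polys, key=lambda p: tuple(np.round(p.mean(axis=0), 1)))
        true = sorted(truth.particles, key=lambda r: tuple(np.round(r["center"], 1)))
        for t, f in zip(true, found):
            st, sf = t["shape"], shape_factors(f)
            assert sf.area == pytest.approx(st.area, rel=0.02)
            assert sf.perimeter == pytest.approx(st.perimeter, rel=0.03)
            assert sf.max_feret == pytest.approx(st.max_feret, rel=0.02)
            assert sf.min_feret == pytest.approx(st.min_feret, rel=0.02)
            for attr in ("elongation", "solidity", "convexity", "circularity"):
                assert getattr(sf, attr) == pytest.approx(getattr(st, attr), abs=0.03)

    def test_image_scale_equivariance(self):
        rng = np.random.default_rng(5)
        dist = synthetic.ShapeDistribution(70, 0.0, 0.8, 0.0, 0.1, 1)
        outline = synthetic.sample_outline(dist, rng)
        img, _ = synthetic.render_scene(
            [outline], image_size=256, intensity_noise=0.0, rng_seed=rng
        )
        big = np.kron(img, np.ones((2, 2), dtype=np.uint8))
        s1 = shape_factors(segment_particles(img)[0])
        s2 = shape_factors(segment_particles(big)[0])
        assert s2.area == pytest.approx(4 * s1.area, rel=0.03)
        assert s2.perimeter == pytest.approx(2 * s1.perimeter, rel=0.03)
        assert s2.max_feret == pytest.approx(2 * s1.max_feret, rel=0.02)
        for attr in ("elongation", "solidity", "convexity", "circularity"):
            assert getattr(s2, attr) == pytest.approx(getattr(s1, attr), abs=0.03)

    def test_min_area_filter_dominates(self):
        rng = np.random.default_rng(1)
        dist = synthetic.ShapeDistribution(60, 0.0, 0.9, 0.0, 0.0, 0)
        outlines = [synthetic.sample_outline(dist, rng) for _ in range(3)]
        img, _ = synthetic.render_scene(outlines, image_size=400, rng_seed=rng)
        config = SegmentationConfig(min_area=1e6)
        assert segment_particles(img, config) == []

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            segment_particles(np.zeros((8, 8, 3)))


class TestProcessMicrographs:
    def _scene(self, seed, n=4):
        rng = np.random.default_rng(seed)
        dist = synthetic.ShapeDistribution(80, 0.1, 0.8, 0.05, 0.1, 1)
        outlines = [synthetic.sample_outline(dist, rng) for _ in range(n)]
        img, truth = synthetic.render_scene(outlines, image_size=512, rng_seed=rng)
        return img, truth

    def test_pooling_counts(self):
        batch, total = [], 0
        for i in range(3):
            img, truth = self._scene(seed=i)
            total += len(truth.particles)
            tags = {"sample_id": "s1", "size_class": "fine", "slide": i, "image_id": f"i{i}"}
            batch.append((tags, img))
        table = process_micrographs(batch)
        assert len(table) == total
        assert set(table.columns) >= set(imaging.FACTOR_NAMES)
        assert table.notna().all().all()

    def test_duplicate_image_doubles_rows(self):
        img, truth = self._scene(seed=9)
        tags = {"sample_id": "s", "size_class": "fine", "slide": 0, "image_id": "a"}
        once = process_micrographs([(tags, img)])
        twice = process_micrographs([(tags, img), (tags, img)])
        assert len(twice) == 2 * len(once) == 2 * len(truth.particles)

    def test_blank_group_flagged(self):
        blank = np.full((64, 64), 255, dtype=np.uint8)
        batch = [
            ({"sample_id": "s", "size_class": "fine", "slide": s, "image_id": f"{s}_{i}"}, blank)
            for s in range(3)
            for i in range(20)
        ]
        with pytest.warns(UserWarning, match="no particles"):
            table = process_micrographs(batch)
        assert table.empty
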