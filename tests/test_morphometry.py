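import math
import warnings

import numpy as np
import pytest

from seedmorph.calibration import Calibration
from seedmorph.errors import NoSeedFoundError, ShortContourListWarning
from seedmorph.imaging import BinaryMask, ThresholdSpec, threshold, to_grayscale
from seedmorph.morphometry import (
    MeasureConfig,
    SeedMeasurement,
    bounding_rectangle,
    find_contours,
    measure_seeds,
    projected_area_px,
    select_max_area_contour,
    select_top_n_contours,
)
from seedmorph.synthetic import (
    ShapeSpec,
    SyntheticScene,
    add_speckles,
    ground_truth,
    random_scene,
    render,
)

from .conftest import brute_force_label_count, random_mask


def mask_from(arr) -> BinaryMask:
    a = np.asarray(arr, dtype=np.uint8) * 255
    return BinaryMask(a, maxval=255)


def disk_mask(radius: int, pad: int = 5) -> BinaryMask:
    side = 2 * (radius + pad) + 1
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    ctr = radius + pad
    inside = (rr - ctr) ** 2 + (cc - ctr) ** 2 <= radius**2
    return BinaryMask(np.where(inside, 255, 0).astype(np.uint8))


class TestFindContours:
    def test_empty_mask(self):
        assert find_contours(mask_from(np.zeros((10, 10)))) == []

    def test_filled_square(self):
        arr = np.zeros((20, 20))
        arr[5:15, 5:15] = 1
        contours = find_contours(mask_from(arr))
        assert len(contours) == 1
        assert contours[0].area_px == 100
        assert len(contours[0].boundary) >= 3

    def test_two_disjoint_disks(self):
        m = np.zeros((60, 120))
        for ctr in ((30, 30), (30, 90)):
            rr, cc = np.meshgrid(np.arange(60), np.arange(120), indexing="ij")
            m[(rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2 <= 100] = 1
        assert len(find_contours(mask_from(m))) == 2

    def test_diagonal_pixels_are_one_region(self):
        # 8-connectivity joins diagonal neighbours
        arr = np.eye(5)
        contours = find_contours(mask_from(arr))
        assert len(contours) == 1 and contours[0].area_px == 5

    def test_areas_sum_to_foreground(self, rng):
        for _ in range(20):
            mask = random_mask(rng, (32, 32), p=rng.uniform(0.1, 0.5))
            contours = find_contours(mask)
            assert sum(c.area_px for c in contours) == int(np.count_nonzero(mask.pixels))

    def test_count_matches_brute_force_labelling(self, rng):
        for _ in range(25):
            mask = random_mask(rng, (32, 32), p=rng.uniform(0.05, 0.6))
            assert len(find_contours(mask)) == brute_force_label_count(mask.foreground())

    def test_region_touching_border(self):
        arr = np.zeros((8, 8))
        arr[0:3, 0:3] = 1
        contours = find_contours(mask_from(arr))
        assert len(contours) == 1 and contours[0].area_px == 9


class TestSelectContours:
    def _contours(self, areas):
        arr = np.zeros((40, 30 * len(areas)))
        col = 0
        for a in areas:  # squares of given areas, left to right
            side = int(math.isqrt(a))
            arr[1:1 + side, col + 1:col + 1 + side] = 1
            col += 30
        return find_contours(mask_from(arr))

    def test_max_area_selected(self):
        contours = self._contours([400, 9, 4])
        assert select_max_area_contour(contours).area_px == 400

    def test_single_contour_identity(self):
        contours = self._contours([25])
        assert select_max_area_contour(contours) is contours[0]

    def test_tie_breaks_to_first(self):
        contours = self._contours([49, 49])
        assert select_max_area_contour(contours) is contours[0]

    def test_empty_raises(self):
        with pytest.raises(NoSeedFoundError):
            select_max_area_contour([])

    def test_permutation_stable(self):
        contours = self._contours([100, 225, 16])
        best = select_max_area_contour(contours)
        assert select_max_area_contour(contours[::-1]).area_px == best.area_px

    def test_top_n_full_selection(self):
        contours = self._contours([9, 400, 49, 225, 100])
        top = select_top_n_contours(contours, 5)
        assert [c.area_px for c in top] == [400, 225, 100, 49, 9]

    def test_top_n_slice(self):
        contours = self._contours([400, 361, 9])
        top = select_top_n_contours(contours, 2)
        assert [c.area_px for c in top] == [400, 361]

    def test_short_list_warns(self):
        contours = self._contours([25])
        with pytest.warns(ShortContourListWarning):
            top = select_top_n_contours(contours, 3)
        assert len(top) == 1


class TestBoundingRectangle:
    def test_axis_aligned_rectangle(self):
        arr = np.zeros((60, 80))
        arr[5:35, 10:60] = 1  # 30 rows x 50 cols
        (c,) = find_contours(mask_from(arr))
        length, width = bounding_rectangle(c)
        assert length == pytest.approx(50, abs=1)
        assert width == pytest.approx(30, abs=1)

    def test_rotated_rectangle_recovered(self):
        scene = SyntheticScene(
            shapes=(ShapeSpec("rectangle", (150.0, 150.0), (2.0, 1.2), rotation_deg=37.0),),
            px_per_mm=25.0,
            image_size=(300, 300),
        )
        mask = threshold(to_grayscale(render(scene)), ThresholdSpec(140, 255))
        (c,) = find_contours(mask)
        length, width = bounding_rectangle(c)
        assert length == pytest.approx(50, rel=0.02)
        assert width == pytest.approx(30, rel=0.02)

    def test_disk_square_box(self):
        (c,) = find_contours(disk_mask(40))
        length, width = bounding_rectangle(c)
        assert length == pytest.approx(80, rel=0.02)
        assert width == pytest.approx(80, rel=0.02)
        assert 1.0 <= length / width <= 1.02

    def test_single_pixel(self):
        (c,) = find_contours(mask_from(np.eye(1)))
        assert bounding_rectangle(c) == (1.0, 1.0)

    def test_axis_aligned_mode(self):
        arr = np.zeros((40, 40))
        arr[10:20, 5:35] = 1
        (c,) = find_contours(mask_from(arr))
        assert bounding_rectangle(c, rotated=False) == (30.0, 10.0)

    def test_rotation_invariance_of_rotated_fit(self):
        sides = []
        for deg in (0, 15, 37, 60, 85):
            scene = SyntheticScene(
                shapes=(ShapeSpec("ellipse", (150.0, 150.0), (6.0, 4.0), rotation_deg=deg),),
                px_per_mm=25.0,
                image_size=(300, 300),
            )
            mask = threshold(to_grayscale(render(scene)), ThresholdSpec(140, 255))
            (c,) = find_contours(mask)
            sides.append(bounding_rectangle(c))
        lengths = [s[0] for s in sides]
        widths = [s[1] for s in sides]
        assert max(lengths) - min(lengths) < 0.02 * 150
        assert max(widths) - min(widths) < 0.02 * 100


class TestProjectedArea:
    def test_empty(self):
        assert projected_area_px(mask_from(np.zeros((5, 5)))) == 0

    def test_filled_square(self):
        arr = np.zeros((30, 30))
        arr[5:25, 5:25] = 1
        assert projected_area_px(mask_from(arr)) == 400

    def test_disk_near_pi_r_squared(self):
        area = projected_area_px(disk_mask(50))
        assert area == pytest.approx(math.pi * 50**2, rel=0.01)

    def test_matches_brute_force_count(self, rng):
        for _ in range(20):
            mask = random_mask(rng, (48, 48), p=rng.uniform(0.05, 0.7))
            brute = sum(
                1 for r in range(48) for c in range(48) if mask.pixels[r, c] != 0
            )
            assert projected_area_px(mask) == brute


class TestMeasureSeeds:
    CAL = Calibration(px_per_mm=25.0)

    def test_known_ellipse(self, single_ellipse_image):
        (m,) = measure_seeds(single_ellipse_image, MeasureConfig(), self.CAL)
        assert m.length_mm == pytest.approx(6.0, rel=0.02)
        assert m.width_mm == pytest.approx(4.0, rel=0.02)
        assert m.aspect_ratio == pytest.approx(1.5, rel=0.02)
        assert m.area_mm2 == pytest.approx(6 * math.pi, rel=0.02)

    def test_disk_aspect_ratio_near_one(self):
        scene = SyntheticScene(
            shapes=(ShapeSpec("disk", (100.0, 100.0), (5.0, 5.0)),),
            px_per_mm=25.0,
            image_size=(200, 200),
        )
        (m,) = measure_seeds(render(scene), MeasureConfig(), self.CAL)
        assert 1.0 <= m.aspect_ratio <= 1.02

    def test_five_ellipse_scene_recovers_truth(self, rng):
        scene = random_scene(rng, n_shapes=5, kinds=("ellipse",))
        cfg = MeasureConfig(n_seeds=5)
        measured = measure_seeds(render(scene), cfg, self.CAL)
        truth = ground_truth(scene)
        assert len(measured) == 5
        for m in measured:  # match by nearest centre, not list order
            t = min(truth, key=lambda t: (t.centroid_rc[0] - m.centroid_rc[0]) ** 2
                    + (t.centroid_rc[1] - m.centroid_rc[1]) ** 2)
            assert m.length_mm == pytest.approx(t.length_mm, rel=0.02)
            assert m.width_mm == pytest.approx(t.width_mm, rel=0.02)
            assert m.aspect_ratio == pytest.approx(t.aspect_ratio, rel=0.02)
            assert m.area_mm2 == pytest.approx(t.area_mm2, rel=0.02)

    def test_length_ge_width_invariant(self, rng):
        for _ in range(5):
            scene = random_scene(rng, n_shapes=3)
            for m in measure_seeds(render(scene), MeasureConfig(n_seeds=3), self.CAL):
                assert m.length_px >= m.width_px
                assert m.aspect_ratio >= 1.0

    def test_blank_image_raises(self):
        scene = SyntheticScene(shapes=(), px_per_mm=25.0, image_size=(50, 50))
        with pytest.raises(NoSeedFoundError):
            measure_seeds(render(scene), MeasureConfig())

    def test_no_calibration_leaves_mm_none(self, single_ellipse_image):
        (m,) = measure_seeds(single_ellipse_image, MeasureConfig())
        assert m.length_mm is None and m.width_mm is None and m.area_mm2 is None
        assert m.length_px > 0

    def test_speckle_noise_changes_nothing(self, single_ellipse_scene):
        base = measure_seeds(render(single_ellipse_scene), MeasureConfig(), self.CAL)
        noisy_scene = add_speckles(single_ellipse_scene, 20, rng_seed=99)
        noisy = measure_seeds(render(noisy_scene), MeasureConfig(), self.CAL)
        assert noisy == base

    def test_pa_whole_mask_vs_contour_interior_agree(self, single_ellipse_image):
        # for one clean seed on black, per-contour PA equals the whole-mask count
        (m,) = measure_seeds(single_ellipse_image, MeasureConfig(), self.CAL)
        gray = to_grayscale(single_ellipse_image)
        whole = projected_area_px(threshold(gray, ThresholdSpec(170, 255)))
        assert m.area_px == whole

    def test_disk_area_converges(self):
        # relative error of rasterized disk area < 2% for r >= 30 px
        for r_mm in (1.2, 2.0, 3.0):  # radii 30..75 px at 25 px/mm
            scene = SyntheticScene(
                shapes=(ShapeSpec("disk", (120.0, 120.0), (2 * r_mm, 2 * r_mm)),),
                px_per_mm=25.0,
                image_size=(240, 240),
            )
            (m,) = measure_seeds(render(scene), MeasureConfig(), self.CAL)
            r_px = r_mm * 25
            assert m.area_px == pytest.approx(math.pi * r_px**2, rel=0.02)


class TestSeedMeasurementInvariants:
    def test_rejects_width_over_length(self):
        with pytest.raises(Exception):
            SeedMeasurement(length_px=3, width_px=5, area_px=10, aspect_ratio=0.6)

    def test_rejects_zero_area(self):
        with pytest.raises(Exception):
            SeedMeasurement(length_px=5, width_px=3, area_px=0, aspect_ratio=5 / 3)
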