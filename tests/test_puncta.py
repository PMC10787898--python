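"""Puncta detection, area fractions, colocalization, pair distances."""

import numpy as np
import pytest

from memfluct.puncta import (
    PunctaParams,
    area_fraction,
    colocalization_overlap,
    detect_puncta,
    manders_coefficients,
    nearest_pair_distances,
)
from memfluct.synthetic import render_puncta_pair


def square_image(corners, side=10, shape=(100, 100), amp=100.0):
    """Bright axis-aligned squares with exact pixel areas (side x side)."""
    img = np.zeros(shape)
    for (r, c) in corners:
        img[r:r + side, c:c + side] = amp
    return img


class TestDetect:
    def test_single_square_exact(self):
        img = square_image([(45, 45)])
        ps = detect_puncta(img)
        assert ps.n_objects == 1
        assert ps.objects[0]["area_px"] == 100

    def test_two_separated_squares(self):
        img = square_image([(25, 25), (65, 65)])
        ps = detect_puncta(img)
        assert ps.n_objects == 2

    def test_isolated_single_pixels_removed(self):
        img = square_image([(25, 25)])
        img[80, 80] = 100.0
        img[10, 85] = 100.0
        ps = detect_puncta(img)
        assert ps.n_objects == 1

    def test_all_zero_image_empty_set(self):
        ps = detect_puncta(np.zeros((50, 50)))
        assert ps.n_objects == 0
        assert ps.total_area_px == 0

    def test_affine_intensity_invariance(self):
        img = square_image([(35, 55)])
        a = detect_puncta(img)
        b = detect_puncta(3.0 * img + 500.0)
        assert np.array_equal(a.mask, b.mask)

    def test_roi_mask_restricts_detection(self):
        img = square_image([(20, 20), (70, 70)])
        roi = np.zeros((100, 100), dtype=bool)
        roi[:50, :50] = True
        ps = detect_puncta(img, roi_mask=roi)
        assert ps.n_objects == 1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PunctaParams(blur_sigma=0.0)
        with pytest.raises(ValueError):
            PunctaParams(threshold=1.5)


class TestAreaFraction:
    def test_hundred_pixels_in_ten_thousand(self):
        ps = detect_puncta(square_image([(45, 45)]))
        frac, _ = area_fraction(ps)
        assert frac == pytest.approx(0.01)

    def test_empty_set_zero(self):
        ps = detect_puncta(np.zeros((100, 100)))
        frac, inten = area_fraction(ps)
        assert frac == 0.0 and inten == 0.0

    def test_union_additivity_for_disjoint_sets(self):
        a = detect_puncta(square_image([(20, 20)]))
        b = detect_puncta(square_image([(70, 70)]))
        both = detect_puncta(square_image([(20, 20), (70, 70)]))
        fa, _ = area_fraction(a)
        fb, _ = area_fraction(b)
        fab, _ = area_fraction(both)
        assert fab == pytest.approx(fa + fb)

    def test_programmed_rising_density(self):
        """A schedule of growing object counts yields a monotone area
        fraction matching the painted ground truth within 5%."""
        rng = np.random.default_rng(0)
        previous = 0.0
        for n_obj in (2, 5, 9):
            centers = [(int(r), int(c)) for r, c in
                       zip(rng.integers(10, 90, n_obj) // 1,
                           np.linspace(12, 88, n_obj).astype(int))]
            objs = [{"center": c, "half_side": 2.5} for c in centers]
            img, _, gt = render_puncta_pair(objs, [], (100, 100))
            ps = detect_puncta(img, params=PunctaParams(blur_sigma=3.0))
            frac, _ = area_fraction(ps)
            assert frac == pytest.approx(gt.values["area_fraction_a"],
                                         rel=0.05)
            assert frac >= previous
            previous = frac


class TestColocalization:
    def test_identical_masks_full_coloc(self):
        a = detect_puncta(square_image([(35, 35)]))
        res = colocalization_overlap(a, a)
        assert res.percent_coloc_a == pytest.approx(100.0)
        assert res.percent_coloc_b == pytest.approx(100.0)

    def test_disjoint_masks_zero(self):
        a = detect_puncta(square_image([(20, 20)]))
        b = detect_puncta(square_image([(70, 70)]))
        res = colocalization_overlap(a, b)
        assert res.overlap_area_px == 0
        assert res.coloc_area_fraction == 0.0

    def test_half_overlap_percentage(self):
        """Channel b covers exactly half of channel a's square."""
        a = detect_puncta(square_image([(45, 45)]))
        img_b = np.zeros((100, 100))
        img_b[45:55, 45:50] = 100.0       # left half (10x5)
        b = detect_puncta(img_b)
        res = colocalization_overlap(a, b)
        assert res.percent_coloc_a == pytest.approx(50.0)

    def test_overlap_area_symmetric(self):
        a = detect_puncta(square_image([(45, 43)]))
        b = detect_puncta(square_image([(45, 49)]))
        r1 = colocalization_overlap(a, b)
        r2 = colocalization_overlap(b, a)
        assert r1.overlap_area_px == r2.overlap_area_px


class TestManders:
    def test_b_positive_everywhere_gives_one(self):
        img_a = square_image([(45, 45)])
        m1, _ = manders_coefficients(img_a, np.ones((100, 100)),
                                     img_a > 0, np.ones((100, 100), bool))
        assert m1 == pytest.approx(1.0)

    def test_empty_b_region_gives_zero(self):
        img_a = square_image([(45, 45)])
        m1, _ = manders_coefficients(img_a, np.zeros((100, 100)),
                                     img_a > 0,
                                     np.zeros((100, 100), bool))
        assert m1 == 0.0

    def test_half_intensity_in_b_positive(self):
        img_a = np.zeros((100, 100))
        img_a[40:50, 40:60] = 10.0        # uniform intensity block
        mask_b = np.zeros((100, 100), bool)
        mask_b[40:50, 40:50] = True       # covers exactly half of it
        m1, _ = manders_coefficients(img_a, img_a, img_a > 0, mask_b)
        assert m1 == pytest.approx(0.5)


class TestPairDistances:
    def test_nearest_within_cutoff(self):
        a = [(0.0, 0.0)]
        b = [(0.0, 100.0), (1000.0, 0.0)]
        d = nearest_pair_distances(a, b, cutoffs_nm=[525.0])
        assert d[525.0].tolist() == [100.0]

    def test_empty_when_nothing_in_range(self):
        d = nearest_pair_distances([(0.0, 0.0)], [(900.0, 0.0)],
                                   cutoffs_nm=[525.0])
        assert d[525.0].size == 0
        assert d[None].tolist() == [900.0]

    def test_lattice_spacing(self):
        spacing = 200.0
        a = [(i * spacing, 0.0) for i in range(5)]
        b = [(i * spacing + spacing / 2, 0.0) for i in range(5)]
        d = nearest_pair_distances(a, b, cutoffs_nm=[525.0, 150.0])
        assert np.allclose(d[None], spacing / 2)
        assert d[150.0].size == 5
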