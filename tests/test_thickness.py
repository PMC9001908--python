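"""Largest-inscribed-circle thickness: oracle values, equivalence, geometry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from endoseg.exceptions import EmptyMaskError, ValidationError
from endoseg.thickness import (
    inscribed_circle_exhaustive,
    inscribed_circle_fast,
    largest_connected_component,
    measure_thickness,
)

from conftest import random_blob_mask


def strip(height: int, width: int, total: tuple[int, int] = (20, 50)) -> np.ndarray:
    mask = np.zeros(total, dtype=bool)
    r0 = (total[0] - height) // 2
    c0 = (total[1] - width) // 2
    mask[r0 : r0 + height, c0 : c0 + width] = True
    return mask


def disk(radius: int, pad: int = 3) -> np.ndarray:
    side = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:side, :side] - (radius + pad)
    return yy * yy + xx * xx <= radius * radius


def donut(outer: int, inner: int) -> np.ndarray:
    side = 2 * outer + 5
    yy, xx = np.mgrid[:side, :side] - (outer + 2)
    r2 = yy * yy + xx * xx
    return (r2 <= outer * outer) & (r2 > inner * inner)


class TestInscribedCircle:
    def test_single_pixel_has_radius_one(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 4] = True
        for fn in (inscribed_circle_exhaustive, inscribed_circle_fast):
            c = fn(mask)
            assert (c.center_row, c.center_col) == (3, 4)
            assert c.radius_px == 1.0

    def test_five_px_strip_measures_five(self):
        mask = strip(5, 40)
        for fn in (inscribed_circle_exhaustive, inscribed_circle_fast):
            c = fn(mask)
            assert c.radius_px == 3.0
        m = measure_thickness(mask, spacing_mm_per_px=1.0)
        assert m.thickness_px == 5.0
        assert m.thickness_mm == 5.0

    def test_filled_disk_thickness_near_diameter(self):
        m = measure_thickness(disk(10), spacing_mm_per_px=1.0)
        assert 19.0 <= m.thickness_px <= 21.0

    def test_thickness_arithmetic_in_mm(self):
        # 39-px-tall strip -> radius 20 -> thickness 39 px -> 3.9 mm at 0.1 mm/px
        mask = strip(39, 45, total=(45, 50))
        m = measure_thickness(mask, spacing_mm_per_px=0.1)
        assert m.circle.radius_px == 20.0
        assert m.thickness_mm == pytest.approx(3.9)

    def test_empty_mask_raises(self):
        empty = np.zeros((5, 5), dtype=bool)
        with pytest.raises(EmptyMaskError):
            inscribed_circle_fast(empty)
        with pytest.raises(EmptyMaskError):
            inscribed_circle_exhaustive(empty)
        with pytest.raises(EmptyMaskError):
            measure_thickness(empty, 1.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValidationError):
            measure_thickness(strip(5, 10), 0.0)
        with pytest.raises(ValidationError):
            measure_thickness(strip(5, 10), -1.0)

    def test_border_touching_region_counts_exterior_as_background(self):
        # Full-frame foreground: the circle cannot extend past the frame.
        mask = np.ones((9, 9), dtype=bool)
        for fn in (inscribed_circle_exhaustive, inscribed_circle_fast):
            c = fn(mask)
            assert (c.center_row, c.center_col) == (4, 4)
            assert c.radius_px == 5.0

    def test_tie_broken_row_major_first(self):
        # Two identical pixels equally far from background; first in raster wins.
        mask = np.zeros((5, 9), dtype=bool)
        mask[1:4, 1:4] = True
        mask[1:4, 5:8] = True
        for fn in (inscribed_circle_exhaustive, inscribed_circle_fast):
            c = fn(mask)
            assert (c.center_row, c.center_col) == (2, 2)


EDGE_CASES = [
    strip(1, 30),  # 1-px line
    strip(5, 40),
    strip(4, 40),  # even width: measured one below
    disk(6),
    donut(8, 4),
    np.ones((6, 11), dtype=bool),  # border-touching everywhere
    np.eye(9, dtype=bool),  # diagonal line
]


@pytest.mark.parametrize("mask", EDGE_CASES, ids=range(len(EDGE_CASES)))
def test_fast_equals_exhaustive_on_edge_cases(mask):
    e = inscribed_circle_exhaustive(mask)
    f = inscribed_circle_fast(mask)
    assert (e.center_row, e.center_col) == (f.center_row, f.center_col)
    assert e.radius_px == f.radius_px


def test_fast_equals_exhaustive_on_random_sweep():
    rng = np.random.default_rng(2024)
    for _ in range(60):
        mask = random_blob_mask(rng)
        e = inscribed_circle_exhaustive(mask)
        f = inscribed_circle_fast(mask)
        assert (e.center_row, e.center_col, e.radius_px) == (
            f.center_row,
            f.center_col,
            f.radius_px,
        )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        dtype=bool,
        shape=st.tuples(st.integers(1, 12), st.integers(1, 12)),
    )
)
def test_fast_equals_exhaustive_property(mask):
    if not mask.any():
        return
    e = inscribed_circle_exhaustive(mask)
    f = inscribed_circle_fast(mask)
    assert (e.center_row, e.center_col, e.radius_px) == (
        f.center_row,
        f.center_col,
        f.radius_px,
    )


def test_dilation_never_decreases_thickness(rng):
    for _ in range(20):
        mask = random_blob_mask(rng, max_side=40)
        t0 = measure_thickness(mask, 1.0).thickness_px
        dilated = ndimage.binary_dilation(mask)
        t1 = measure_thickness(dilated, 1.0).thickness_px
        assert t1 >= t0


def test_thickness_invariant_under_rotation_and_flip(rng):
    for _ in range(15):
        mask = random_blob_mask(rng, max_side=40)
        t0 = measure_thickness(mask, 1.0).thickness_px
        for transformed in (np.rot90(mask), np.rot90(mask, 2), mask[::-1], mask[:, ::-1]):
            assert measure_thickness(transformed, 1.0).thickness_px == t0


class TestLargestConnectedComponent:
    def test_keeps_the_larger_of_two_components(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :5] = True  # 5 px
        mask[5, :3] = True  # 3 px
        out = largest_connected_component(mask)
        assert out.values.sum() == 5
        assert out.values[0, :5].all()

    def test_single_component_is_identity(self):
        mask = strip(3, 10)
        out = largest_connected_component(mask)
        assert (out.values == mask).all()

    def test_connectivity_flag_changes_diagonal_linking(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        mask[0, 3] = True
        assert largest_connected_component(mask, connectivity=8).values.sum() == 3
        # 4-connected: the diagonal splits into 1-px components; tie -> first pixel
        out4 = largest_connected_component(mask, connectivity=4)
        assert out4.values.sum() == 1
        assert out4.values[0, 0]

    def test_size_tie_broken_by_first_pixel_row_major(self):
        mask = np.zeros((3, 9), dtype=bool)
        mask[1, 6:8] = True
        mask[1, 1:3] = True
        out = largest_connected_component(mask)
        assert out.values[1, 1] and out.values[1, 2]
        assert out.values.sum() == 2

    def test_empty_and_bad_connectivity(self):
        with pytest.raises(EmptyMaskError):
            largest_connected_component(np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValidationError):
            largest_connected_component(np.ones((3, 3), dtype=bool), connectivity=6)
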