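"""Vertical projection, gap-candidate selection, line tilt optimization
(vs. exhaustive enumeration) and region pairing/trimming."""
import numpy as np
import pytest

from periseg.phantom import PhantomSpec, generate_phantom
from periseg.preprocess import redistribute_bright
from periseg.segment import (ProjectionProfile, SegLine, find_gap_candidates,
                             pair_lines_for_tooth, rotate_tangent,
                             trim_outer_endpoint, vertical_projection)
from periseg.threshold import adaptive_threshold, binarize
from periseg.util import line_columns


def oracle_line_cost(binary, x_top, x_bottom):
    """Per-row python loop over the shared rasterization rule."""
    H = binary.shape[0]
    cols = line_columns(x_top, x_bottom, H)
    return sum(int(binary[r, cols[r]]) for r in range(H))


class TestVerticalProjection:
    def test_all_white(self):
        p = vertical_projection(np.ones((10, 10), dtype=np.uint8))
        assert (p.sums == 10).all() and p.width == 10

    def test_all_black(self):
        p = vertical_projection(np.zeros((10, 10), dtype=np.uint8))
        assert (p.sums == 0).all()

    def test_matches_double_loop(self, rng):
        b = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        p = vertical_projection(b)
        for x in range(16):
            assert p.sums[x] == sum(int(b[r, x]) for r in range(16))


class TestFindGapCandidates:
    def test_global_minimum_selected_first(self):
        sums = np.full(20, 9)
        sums[5] = 0
        got = find_gap_candidates(ProjectionProfile(sums, 20), min_gap=3)
        assert 5 in got

    def test_spacing_discards_near_ties(self):
        sums = np.full(30, 9)
        sums[10] = 0
        sums[12] = 0
        got = find_gap_candidates(ProjectionProfile(sums, 30),
                                  max_lines=5, min_gap=5)
        assert 10 in got and 12 not in got

    def test_selected_pairwise_spaced(self, rng):
        sums = rng.integers(0, 50, size=60)
        got = find_gap_candidates(ProjectionProfile(sums, 60),
                                  max_lines=5, min_gap=10)
        assert got == sorted(got)
        for i, a in enumerate(got):
            for b in got[i + 1:]:
                assert abs(a - b) >= 10

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            find_gap_candidates(ProjectionProfile(np.array([]), 0))

    def test_noise_free_phantom_gaps_recovered(self):
        spec = PhantomSpec(noise_sd=0.0, illumination_slope=0.0)
        img, truth = generate_phantom(spec)
        res = adaptive_threshold(redistribute_bright(img))
        binary = binarize(img, res.T)
        got = find_gap_candidates(vertical_projection(binary))
        for g in truth.gap_x:
            assert any(abs(x - g) <= 2 for x in got)


class TestRotateTangent:
    def test_vertical_black_gap_zero_cost(self):
        b = np.ones((20, 30), dtype=np.uint8)
        b[:, 12] = 0
        line = rotate_tangent(b, 12, shift_range=4)
        assert (line.x_top, line.x_bottom, line.cost) == (12, 12, 0)

    def test_all_white_tie_break_to_vertical(self):
        b = np.ones((15, 30), dtype=np.uint8)
        line = rotate_tangent(b, 10, shift_range=3)
        assert (line.x_top, line.x_bottom) == (10, 10)
        assert line.cost == 15

    def test_slanted_band_found_and_globally_minimal(self):
        H, W = 40, 60
        b = np.ones((H, W), dtype=np.uint8)
        x0 = 30
        cols = line_columns(x0 - 5, x0 + 5, H)
        b[np.arange(H), cols] = 0                   # black band of slope a=-5,b=+5
        line = rotate_tangent(b, x0, shift_range=6)
        assert line.cost == 0
        assert (line.x_top, line.x_bottom) == (x0 - 5, x0 + 5)

    def test_cost_not_worse_than_vertical(self, rng):
        b = (rng.random((24, 40)) < 0.5).astype(np.uint8)
        for x0 in (5, 20, 34):
            line = rotate_tangent(b, x0, shift_range=4)
            assert line.cost <= oracle_line_cost(b, x0, x0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            b = (rng.random((20, 32)) < 0.4).astype(np.uint8)
            x0 = int(rng.integers(4, 28))
            sr = 3
            line = rotate_tangent(b, x0, shift_range=sr)
            best = None
            for a in range(-sr, sr + 1):
                for bb in range(-sr, sr + 1):
                    xt, xb = x0 + a, x0 + bb
                    if not (0 <= xt < 32 and 0 <= xb < 32):
                        continue
                    cost = oracle_line_cost(b, xt, xb)
                    key = (cost, abs(a) + abs(bb), a, bb)
                    if best is None or key < best:
                        best = key
            assert (line.cost, abs(line.x_top - x0) + abs(line.x_bottom - x0),
                    line.x_top - x0, line.x_bottom - x0) == best

    def test_out_of_bounds_x0_raises(self):
        with pytest.raises(ValueError):
            rotate_tangent(np.ones((5, 5), dtype=np.uint8), 7, 1)


class TestPairLines:
    def test_region_counts(self):
        lines = [SegLine(10, 10), SegLine(30, 30)]
        for i in range(3):
            pair_lines_for_tooth(lines, i, 50)
        with pytest.raises(IndexError):
            pair_lines_for_tooth(lines, 3, 50)

    def test_no_lines_single_region_spans_image(self):
        left, right = pair_lines_for_tooth([], 0, 40)
        assert (left.x_top, right.x_top) == (0, 39)

    def test_each_phantom_tooth_in_exactly_one_region(self):
        spec = PhantomSpec(n_teeth=4, roots_per_tooth=[1, 1, 2, 1],
                           lesion_flags=[False] * 4, width=320,
                           noise_sd=0.0, illumination_slope=0.0)
        img, truth = generate_phantom(spec)
        lines = [SegLine(g, g) for g in truth.gap_x]
        W = spec.width
        for r0, c0, r1, c1 in truth.tooth_boxes:
            containing = []
            for i in range(len(lines) + 1):
                left, right = pair_lines_for_tooth(lines, i, W)
                if left.mean_x <= c0 and c1 - 1 <= right.mean_x:
                    containing.append(i)
            assert len(containing) == 1


class TestTrimOuterEndpoint:
    def test_vertical_line_unchanged(self):
        line = SegLine(25, 25, 3)
        assert trim_outer_endpoint(line, 100) == line

    def test_left_line_trims_to_leftmost(self):
        got = trim_outer_endpoint(SegLine(40, 50), tooth_center_x=100)
        assert (got.x_top, got.x_bottom) == (40, 40)

    def test_right_line_trims_to_rightmost(self):
        got = trim_outer_endpoint(SegLine(140, 150), tooth_center_x=100)
        assert (got.x_top, got.x_bottom) == (150, 150)

    def test_trimmed_region_contains_truth_columns(self, rng):
        """Random slanted lines around a phantom tooth: after trimming, the
        region between the lines covers the full truth tooth columns."""
        spec = PhantomSpec(noise_sd=0.0, illumination_slope=0.0)
        img, truth = generate_phantom(spec)
        H = spec.height
        for r0, c0, r1, c1 in truth.tooth_boxes:
            cx = (c0 + c1) / 2
            for _ in range(10):
                jl = int(rng.integers(0, 6))
                jr = int(rng.integers(0, 6))
                left = trim_outer_endpoint(SegLine(c0 - 1 - jl, c0 - 1), cx)
                right = trim_outer_endpoint(SegLine(c1 + jr, c1), cx)
                lcols = line_columns(left.x_top, left.x_bottom, H)
                rcols = line_columns(right.x_top, right.x_bottom, H)
                assert (lcols <= c0 - 1).all() and (rcols >= c1).all()
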