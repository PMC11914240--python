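"""Segment metrics: volumes, burden indices, maxLCBI_4mm, HU classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plaquekit.data_model import SpreadoutPlot, Tissue
from plaquekit.plaque_metrics import (
    HuCutoffConfig,
    InsufficientDataError,
    build_spreadout,
    burden_index,
    ca_arc_from_cabi,
    classify_hu,
    compute_volumes,
    max_lcbi_4mm,
    mean_ca_area,
)
from conftest import make_frame, make_segment


def brute_trapezoid(xs, ys):
    total = 0.0
    for i in range(len(xs) - 1):
        total += 0.5 * (ys[i] + ys[i + 1]) * (xs[i + 1] - xs[i])
    return total


def brute_max_lcbi(grid, positions, window=4.0):
    """Exhaustive enumeration over all maximal windows of span <= 4 mm."""
    n_bins, n = grid.shape
    lipid = (grid & int(Tissue.LIPID)) > 0
    if positions[-1] - positions[0] <= window:
        return 1000.0 * lipid.sum() / grid.size
    best = 0.0
    for j in range(n):
        e = j
        while e + 1 < n and positions[e + 1] - positions[j] <= window:
            e += 1
        cells = (e - j + 1) * n_bins
        best = max(best, 1000.0 * lipid[:, j : e + 1].sum() / cells)
    return best


class TestVolumes:
    def test_constant_area_integral(self):
        seg = make_segment(np.arange(11.0), [5.0] * 11, [10.0] * 11)
        lumen, vessel, tav, pav = compute_volumes(seg)
        assert (lumen, vessel, tav, pav) == pytest.approx((50.0, 100.0, 50.0, 50.0))

    def test_no_plaque_gives_zero_tav_and_pav(self):
        seg = make_segment([0, 1, 2], [7, 7, 7], [7, 7, 7])
        _, _, tav, pav = compute_volumes(seg)
        assert tav == pytest.approx(0.0)
        assert pav == pytest.approx(0.0)

    def test_irregular_spacing_matches_trapezoid_oracle(self, rng):
        pos = np.sort(rng.uniform(0, 30, 25))
        lum = np.linspace(3, 8, 25) * rng.uniform(0.9, 1.1, 25)
        ves = lum + np.linspace(1, 6, 25)
        seg = make_segment(pos, lum, ves)
        lumen, vessel, tav, pav = compute_volumes(seg)
        assert lumen == pytest.approx(brute_trapezoid(pos, lum))
        assert vessel == pytest.approx(brute_trapezoid(pos, ves))
        assert tav == pytest.approx(vessel - lumen)

    def test_pav_scale_invariance(self, rng):
        pos = np.arange(10.0)
        lum = rng.uniform(3, 6, 10)
        ves = lum + rng.uniform(1, 5, 10)
        _, _, _, pav1 = compute_volumes(make_segment(pos, lum, ves))
        _, _, _, pav2 = compute_volumes(make_segment(pos, 3.7 * lum, 3.7 * ves))
        assert pav1 == pytest.approx(pav2)

    def test_single_frame_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            compute_volumes(make_segment([0.0], [5], [10]))


class TestSpreadout:
    def test_empty_flags_give_empty_grid(self):
        seg = make_segment([0, 1], [5, 5], [10, 10])
        plot = build_spreadout(seg)
        assert plot.grid.shape == (360, 2)
        assert not plot.grid.any()

    def test_identity_mapping_of_bins(self):
        bins = np.zeros(360, dtype=np.uint8)
        bins[0:90] = int(Tissue.LIPID)
        seg = make_segment([0, 1], [5, 5], [10, 10])
        seg.frames[1].tissue_bins = bins
        plot = build_spreadout(seg)
        assert ((plot.grid[:, 1] & int(Tissue.LIPID)) > 0).sum() == 90
        assert not plot.grid[:, 0].any()

    def test_overlapping_tissues_are_multilabel(self):
        bins = np.zeros(360, dtype=np.uint8)
        bins[0:180] |= int(Tissue.LIPID)
        bins[90:270] |= int(Tissue.CA)
        seg = make_segment([0.0], [5], [10])
        seg.frames[0].tissue_bins = bins
        plot = build_spreadout(seg)
        both = (plot.grid[:, 0] & int(Tissue.LIPID | Tissue.CA)) == int(
            Tissue.LIPID | Tissue.CA
        )
        assert both[90:180].all() and both.sum() == 90

    def test_mixed_resolution_raises(self):
        seg = make_segment([0, 1], [5, 5], [10, 10])
        seg.frames[1].tissue_bins = np.zeros(180, dtype=np.uint8)
        with pytest.raises(ValueError, match="resolution"):
            build_spreadout(seg)


class TestBurdenIndex:
    def test_full_chemogram_is_1000(self):
        grid = np.full((360, 5), int(Tissue.LIPID), dtype=np.uint8)
        plot = SpreadoutPlot(grid, np.arange(5.0))
        assert burden_index(plot, Tissue.LIPID) == 1000.0

    def test_absent_tissue_is_zero(self):
        grid = np.full((360, 5), int(Tissue.LIPID), dtype=np.uint8)
        plot = SpreadoutPlot(grid, np.arange(5.0))
        assert burden_index(plot, Tissue.CA) == 0.0

    def test_cell_count_oracle(self):
        grid = np.zeros((360, 20), dtype=np.uint8)
        flat = grid.reshape(-1)
        flat[:1800] = int(Tissue.LIPID)
        plot = SpreadoutPlot(flat.reshape(360, 20), np.arange(20.0))
        assert burden_index(plot, Tissue.LIPID) == pytest.approx(250.0)

    def test_column_permutation_invariance(self, rng):
        grid = (rng.random((36, 30)) < 0.3).astype(np.uint8) * int(Tissue.LIPID)
        pos = np.arange(30.0)
        a = burden_index(SpreadoutPlot(grid, pos), Tissue.LIPID)
        perm = rng.permutation(30)
        b = burden_index(SpreadoutPlot(grid[:, perm], pos), Tissue.LIPID)
        assert a == pytest.approx(b)


class TestMaxLcbi4mm:
    def test_uniform_fraction_equals_whole_lcbi(self):
        grid = np.zeros((360, 21), dtype=np.uint8)
        grid[:90, :] = int(Tissue.LIPID)
        plot = SpreadoutPlot(grid, np.arange(21) * 0.5)
        assert max_lcbi_4mm(plot) == pytest.approx(burden_index(plot, Tissue.LIPID))

    def test_empty_chemogram_is_zero(self):
        plot = SpreadoutPlot(np.zeros((360, 41), dtype=np.uint8), np.arange(41) * 0.5)
        assert max_lcbi_4mm(plot) == 0.0

    def test_single_block_matches_exhaustive_oracle(self):
        grid = np.zeros((360, 41), dtype=np.uint8)
        grid[:, 18:23] = int(Tissue.LIPID)  # 2 mm full-circumference block
        pos = np.arange(41) * 0.5
        plot = SpreadoutPlot(grid, pos)
        assert max_lcbi_4mm(plot) == pytest.approx(brute_max_lcbi(grid, pos))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_random_grids_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 100))
        grid = (r.random((24, n)) < r.uniform(0, 0.6)).astype(np.uint8) * int(
            Tissue.LIPID
        )
        pos = np.cumsum(r.uniform(0.2, 1.0, n))
        plot = SpreadoutPlot(grid, pos)
        assert max_lcbi_4mm(plot) == pytest.approx(brute_max_lcbi(grid, pos))

    def test_reversal_invariance(self, rng):
        grid = (rng.random((36, 50)) < 0.25).astype(np.uint8) * int(Tissue.LIPID)
        pos = np.cumsum(rng.uniform(0.3, 0.8, 50))
        fwd = max_lcbi_4mm(SpreadoutPlot(grid, pos))
        rev_pos = pos[-1] - pos[::-1]
        rev = max_lcbi_4mm(SpreadoutPlot(grid[:, ::-1], rev_pos))
        assert fwd == pytest.approx(rev)

    def test_short_segment_returns_whole_lcbi_with_warning(self):
        grid = np.zeros((360, 4), dtype=np.uint8)
        grid[:180, :] = int(Tissue.LIPID)
        plot = SpreadoutPlot(grid, np.arange(4) * 0.5)
        with pytest.warns(UserWarning, match="window"):
            val = max_lcbi_4mm(plot)
        assert val == pytest.approx(500.0)


class TestCaMetrics:
    def test_constant_ca_area(self):
        seg = make_segment(np.arange(11.0), [5] * 11, [10] * 11)
        for f in seg.frames:
            f.tissue_areas = {"CA": 2.0}
        assert mean_ca_area(seg) == pytest.approx(2.0)

    def test_zero_ca(self):
        seg = make_segment(np.arange(5.0), [5] * 5, [10] * 5)
        for f in seg.frames:
            f.tissue_areas = {"CA": 0.0}
        assert mean_ca_area(seg) == 0.0

    def test_triangular_profile_matches_trapezoid_oracle(self):
        pos = np.arange(9.0)
        ca = np.concatenate([np.linspace(0, 4, 5), np.linspace(3, 0, 4)])
        seg = make_segment(pos, [5] * 9, [12] * 9)
        for f, c in zip(seg.frames, ca):
            f.tissue_areas = {"CA": float(c)}
        assert mean_ca_area(seg) == pytest.approx(brute_trapezoid(pos, ca) / 8.0)

    def test_missing_ca_without_fallback_raises(self):
        seg = make_segment(np.arange(3.0), [5] * 3, [10] * 3)
        with pytest.raises(InsufficientDataError):
            mean_ca_area(seg, fallback_from_bins=False)

    @pytest.mark.parametrize("cabi,expected", [(1000, 360.0), (0, 0.0), (500, 180.0)])
    def test_ca_arc_linearity(self, cabi, expected):
        assert ca_arc_from_cabi(cabi) == pytest.approx(expected)

    def test_ca_arc_domain_error(self):
        with pytest.raises(ValueError):
            ca_arc_from_cabi(1200)

    @given(st.floats(0, 360))
    @settings(max_examples=50, deadline=None)
    def test_ca_arc_roundtrip_identity(self, arc):
        assert ca_arc_from_cabi(1000.0 * arc / 360.0) == pytest.approx(arc)


class TestHuClassifier:
    def test_interval_membership(self):
        cfg = HuCutoffConfig(nc_ff=76, ff_ft=131, ft_ca=351)
        out = classify_hu([400.0, -10.0, 100.0, 200.0], cfg)
        assert list(out) == ["CA", "NC", "FF", "FT"]

    def test_boundary_joins_upper_class(self):
        cfg = HuCutoffConfig(nc_ff=76, ff_ft=131, ft_ca=351)
        assert list(classify_hu([76.0, 131.0, 351.0], cfg)) == ["FF", "FT", "CA"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_hu([np.nan])

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            HuCutoffConfig(nc_ff=200, ff_ft=131, ft_ca=351)
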