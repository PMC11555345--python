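"""Segmentation, per-cell records, classification and statistics."""

import numpy as np
import pytest
from scipy import stats

from carsense.indicators import ratio_map, subtraction_map
from carsense.quantify import (
    CellRecord,
    classify_cell,
    extract_cell_records,
    group_comparison,
    segment_regions,
    size_ratio_regression,
)
from carsense.synthetic import (
    NUCLEOLUS,
    PhantomLayout,
    ch_intensity_image,
    make_phantom,
    synthesize_cube,
)
from test_indicators import fitmaps_from


class TestSegmentRegions:
    def test_all_zero_image_is_all_background(self):
        assert not segment_regions(np.zeros((16, 16))).any()

    def test_constant_nonzero_image_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            segment_regions(np.full((16, 16), 3.0))

    def test_separable_phantom_levels_recovered_exactly(self):
        layout = PhantomLayout(shape=(96, 96), n_control=4, n_senescent=0)
        phantom = make_phantom(layout, seed=3)
        img = ch_intensity_image(phantom)  # 4 well-separated levels
        labels = segment_regions(img)
        assert np.array_equal(labels, phantom.label_image)

    def test_two_nucleoli_in_one_nucleus_are_distinct_components(self):
        from scipy import ndimage

        from carsense.quantify import FOUR_CONNECTED

        layout = PhantomLayout(
            shape=(64, 64), n_control=1, n_senescent=0,
            cell_radius=20.0, nucleus_radius_control=12.0,
            nucleolus_radius_control=2.0, nucleoli_per_nucleus=2, margin=8,
        )
        phantom = make_phantom(layout, seed=5)
        _, n = ndimage.label(phantom.label_image == NUCLEOLUS, structure=FOUR_CONNECTED)
        assert n == 2


class TestExtractCellRecords:
    def _single_cell(self):
        label = np.zeros((20, 20), dtype=int)
        cells = np.zeros((20, 20), dtype=int)
        label[2:18, 2:18] = 1
        cells[2:18, 2:18] = 1
        label[5:15, 5:15] = 2  # nucleus 100 px
        label[6:9, 6:16][:, :4] = 3  # nucleolus A: rows 6-8, cols 6-9 (12 px)
        label[11:13, 6:11] = 3  # nucleolus B: 2x5 = 10 px
        return label, cells

    def test_largest_nucleolus_and_constant_mean(self):
        label, cells = self._single_cell()
        fm = fitmaps_from(np.full((20, 20), 0.4), np.full((20, 20), 0.6))
        maps = subtraction_map(fm, np.ones((20, 20), bool))
        (rec,) = extract_cell_records(label, cells, maps, pixel_size_um=0.5)
        assert rec.largest_nucleolus_px == 12
        assert rec.largest_nucleolus_mean_ratio == pytest.approx(0.6)
        assert rec.largest_nucleolus_mean_subtraction == pytest.approx(0.2)

    def test_area_arithmetic_exact(self):
        label, cells = self._single_cell()
        fm = fitmaps_from(np.ones((20, 20)), np.ones((20, 20)))
        maps = ratio_map(fm)
        (rec,) = extract_cell_records(label, cells, maps, pixel_size_um=0.5)
        # nucleus extent = 100 px (nucleoli included) at 0.25 um^2/px
        assert rec.largest_nucleus_area_um2 == pytest.approx(100 * 0.25)
        assert rec.phenotype_class == "control"

    def test_cell_without_nucleus_flagged_invalid(self):
        label = np.zeros((8, 8), dtype=int)
        cells = np.zeros((8, 8), dtype=int)
        label[2:6, 2:6] = 1
        cells[2:6, 2:6] = 1
        fm = fitmaps_from(np.ones((8, 8)), np.ones((8, 8)))
        (rec,) = extract_cell_records(label, cells, ratio_map(fm), 0.5)
        assert not rec.valid

    def test_phantom_truth_round_trip(self, small_phantom):
        """Ground-truth masks + noiseless cube reproduce the composition
        beta fractions as largest-nucleolus mean ratios."""
        from carsense.amide import fit_cube

        cube, truth = synthesize_cube(small_phantom, seed=0)
        maps = ratio_map(fit_cube(cube))
        records = extract_cell_records(
            small_phantom.label_image,
            small_phantom.cell_ids,
            maps,
            small_phantom.pixel_size_um,
            phenotype_truth=small_phantom.phenotype,
        )
        tbl = truth.beta_fraction.set_index(["cell_id", "region"]).beta_fraction
        for rec in records:
            expected = tbl.loc[(rec.cell_id, "nucleolus")]
            assert rec.largest_nucleolus_mean_ratio == pytest.approx(expected, abs=1e-6)


class TestClassifyCell:
    def _rec(self, nuclei, area):
        return CellRecord(1, nuclei, area, 10, 0.3, 0.0)

    @pytest.mark.parametrize(
        "nuclei,area,expected",
        [
            (1, 117.9, "control"),
            (1, 118.0, "large_nucleus"),  # strict < 118 boundary
            (1, 300.0, "large_nucleus"),
            (2, 50.0, "binucleate"),
            (3, 500.0, "binucleate"),
        ],
    )
    def test_classification_rules(self, nuclei, area, expected):
        assert classify_cell(self._rec(nuclei, area)) == expected

    def test_no_nucleus_rejected(self):
        with pytest.raises(ValueError, match="no nucleus"):
            classify_cell(self._rec(0, 0.0))

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            rec = self._rec(int(rng.integers(1, 4)), float(rng.uniform(0, 300)))
            assert classify_cell(rec) in {"control", "binucleate", "large_nucleus"}


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        comp = group_comparison({"a": v, "b": v.copy()}, design="ttest_scheme")
        assert comp.location_p == pytest.approx(1.0)
        assert not comp.significant

    def test_pooled_t_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
        # closed-form pooled-variance t with df = 8
        sp2 = (4 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 8
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert t == pytest.approx(-2.0)
        p = 2 * stats.t.sf(abs(t), 8)
        comp = group_comparison({"a": a, "b": b}, design="ttest_scheme")
        assert comp.location_p == pytest.approx(p, rel=1e-10)
        assert comp.location_p == pytest.approx(0.08052, abs=5e-5)
        assert not comp.significant

    def test_dunnett_scheme_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        ctl = rng.normal(0, 1, 10)
        g1 = rng.normal(1.2, 1, 10)
        g2 = rng.normal(0.1, 1, 10)
        comp = group_comparison(
            {"control": ctl, "t1": g1, "t2": g2}, design="dunnett_scheme"
        )
        ref = stats.dunnett(g1, g2, control=ctl, rng=0)
        assert comp.location_p["t1"] == pytest.approx(float(ref.pvalue[0]))
        assert comp.variance_test == "bartlett"
        assert set(comp.shapiro_p) == {"control", "t1", "t2"}

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n="):
            group_comparison({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})

    def test_null_permutation_false_positive_rate(self):
        """Shuffling labels on null data keeps the t-test size near alpha."""
        rng = np.random.default_rng(99)
        values = rng.normal(0, 1, 20)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(values)
            p = stats.ttest_ind(perm[:10], perm[10:], equal_var=True).pvalue
            hits += p < 0.05
        assert hits / n_perm <= 0.07


class TestSizeRatioRegression:
    def _rec(self, size, ratio):
        return CellRecord(1, 1, 50.0, size, ratio, 0.0)

    def test_collinear_points_exact(self):
        records = [self._rec(s, 0.1 + 0.002 * s) for s in (10, 20, 30, 40)]
        res = size_ratio_regression(records)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.002)
        assert res.intercept == pytest.approx(0.1)

    def test_five_points_match_normal_equations(self):
        sizes = np.array([12.0, 25.0, 31.0, 44.0, 58.0])
        ratios = np.array([0.22, 0.31, 0.28, 0.41, 0.47])
        # closed-form OLS oracle
        sx, sy = sizes.mean(), ratios.mean()
        slope = np.sum((sizes - sx) * (ratios - sy)) / np.sum((sizes - sx) ** 2)
        intercept = sy - slope * sx
        res = size_ratio_regression(
            [self._rec(int(s), r) for s, r in zip(sizes, ratios)]
        )
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert 0.0 <= res.r_squared <= 1.0

    def test_zero_size_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            size_ratio_regression([self._rec(10, r) for r in (0.1, 0.2, 0.3)])
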