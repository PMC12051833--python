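"""tCPI, immCPI and band profiles: exact cases, invariants, transforms."""

import numpy as np
import pytest
import shapely.affinity
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from cpindex.geometry import LesionGeometry
from cpindex.io import CellTable
from cpindex.metrics import (
    MetricError,
    NoCellsError,
    border_depths,
    compute_immcpi,
    compute_tcpi,
    infiltration_bands,
    median_depth,
)
from cpindex.synthetic import (
    LesionShapeSpec,
    MarkerSpec,
    RadialProfile,
    assign_markers,
    make_lesion,
    sample_cells,
)


def table(points, classification=None):
    pts = np.asarray(points, dtype=float)
    cls = (
        np.asarray(classification, dtype=object)
        if classification is not None
        else np.full(len(pts), "", dtype=object)
    )
    return CellTable(x=pts[:, 0], y=pts[:, 1], classification=cls)


@pytest.fixture(scope="module")
def square_lesion():
    """20x20 µm square lesion inside a generous tissue box."""
    return LesionGeometry.build(box(0, 0, 20, 20), box(-10, -10, 30, 30), name="sq")


class TestBorderDepths:
    def test_known_depths_in_square(self, square_lesion):
        cells = table([(1, 10), (2, 10), (9, 10)])
        bd = border_depths(cells, square_lesion)
        np.testing.assert_allclose(np.sort(bd.depths), [1, 2, 9])
        assert bd.n_excluded == 0

    def test_boundary_cell_included_at_zero(self, square_lesion):
        bd = border_depths(table([(0, 10), (5, 5)]), square_lesion)
        assert np.min(bd.depths) == 0
        assert bd.depths.size == 2

    def test_outside_cells_excluded_and_counted(self, square_lesion):
        bd = border_depths(table([(5, 5), (25, 25)]), square_lesion)
        assert bd.depths.size == 1
        assert bd.n_excluded == 1

    def test_no_cells_in_lesion_is_an_error(self, square_lesion):
        with pytest.raises(NoCellsError):
            border_depths(table([(25, 25)]), square_lesion)


class TestMedianDepth:
    @pytest.mark.parametrize(
        "depths,expected",
        [([1, 2, 9], 2), ([1, 3], 2), ([5], 5), ([4, 1, 3, 2], 2.5), ([2, 2, 7], 2)],
    )
    def test_sorted_middle_and_even_mean(self, depths, expected):
        assert median_depth(depths) == expected

    def test_empty_rejected(self):
        with pytest.raises(MetricError):
            median_depth([])


class TestTcpi:
    def test_areas_partition_the_lesion(self, square_lesion):
        rng = np.random.default_rng(0)
        cells = table(rng.uniform(0, 20, size=(500, 2)))
        res = compute_tcpi(cells, square_lesion)
        assert res.central_area + res.peripheral_area == pytest.approx(
            res.total_area, rel=1e-6
        )
        assert 0 <= res.tcpi <= 1

    def test_square_median_depth_erosion_is_exact(self, square_lesion):
        # two cells at depth 5: erode 20x20 by 5 -> 10x10 central square
        res = compute_tcpi(table([(5, 10), (15, 10)]), square_lesion)
        assert res.median_border_depth == pytest.approx(5)
        assert res.central_area == pytest.approx(100)
        assert res.tcpi == pytest.approx(300 / 400)

    def test_center_packed_cells_fully_erode_to_tcpi_one(self, square_lesion):
        with pytest.warns(UserWarning, match="fully erodes"):
            res = compute_tcpi(table([(10, 10), (10, 10)]), square_lesion)
        assert res.tcpi == 1
        assert res.central_area == 0

    def test_fewer_than_two_cells_rejected(self, square_lesion):
        with pytest.raises(MetricError):
            compute_tcpi(table([(5, 5)]), square_lesion)

    def test_edge_lesion_uses_clipped_area(self):
        # lesion half off-tissue: total area is the on-tissue half
        lg = LesionGeometry.build(box(0, 0, 20, 20), box(10, -10, 40, 30), name="edge")
        res = compute_tcpi(table([(12, 10), (18, 10)]), lg)
        assert res.total_area == pytest.approx(200)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0, 360),
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
        scale=st.floats(0.05, 20),
    )
    def test_invariant_under_similarity_transforms(self, angle, dx, dy, scale):
        """tCPI is unchanged by rotating, translating and scaling all inputs."""
        shape = LesionShapeSpec(kind="star", radius=80, amplitudes=(0.2,),
                                harmonics=(3,), n_vertices=48, seed=4)
        lesion, tissue = make_lesion(shape)
        cells = sample_cells(lesion, 300, RadialProfile("uniform"), seed=4, shape=shape)
        lg = LesionGeometry.build(lesion.geometry, tissue.geometry, name="s")
        base = compute_tcpi(cells, lg).tcpi

        def tf(geom):
            g = shapely.affinity.rotate(geom, angle, origin=(0, 0))
            g = shapely.affinity.scale(g, scale, scale, origin=(0, 0))
            return shapely.affinity.translate(g, dx, dy)

        rad = np.deg2rad(angle)
        x = scale * (cells.x * np.cos(rad) - cells.y * np.sin(rad)) + dx
        y = scale * (cells.x * np.sin(rad) + cells.y * np.cos(rad)) + dy
        moved_cells = CellTable(x=x, y=y, classification=cells.classification)
        moved_lg = LesionGeometry.build(tf(lesion.geometry), tf(tissue.geometry), name="s")
        assert compute_tcpi(moved_cells, moved_lg).tcpi == pytest.approx(base, abs=1e-6)


class TestImmcpi:
    def test_marker_equal_to_all_cells_is_exactly_one(self, square_lesion):
        cells = table([(3, 3), (5, 9), (11, 4), (16, 16)], ["CD3"] * 4)
        assert compute_immcpi(cells, square_lesion, "CD3").immcpi == 1.0

    def test_substring_matches_composite_classifications(self, square_lesion):
        cells = table(
            [(5, 10), (15, 10), (10, 5)],
            ["Opal 690: Opal 570", "Opal 690", "Opal 540"],
        )
        res = compute_immcpi(cells, square_lesion, "Opal 570")
        assert res.n_marker_cells == 1

    def test_exact_mode_does_not_match_partial_tokens(self, square_lesion):
        cells = table([(5, 10), (15, 10)], ["CD34", "CD3"])
        assert compute_immcpi(cells, square_lesion, "CD3", match_mode="substring").n_marker_cells == 2
        assert compute_immcpi(cells, square_lesion, "CD3", match_mode="exact").n_marker_cells == 1

    def test_missing_marker_warns_and_reports_nan(self, square_lesion):
        cells = table([(5, 10), (15, 10)], ["CD8", "CD8"])
        with pytest.warns(UserWarning, match="CD3"):
            res = compute_immcpi(cells, square_lesion, "CD3")
        assert np.isnan(res.immcpi)
        assert res.mean_depth_marker is None
        assert res.n_marker_cells == 0

    def test_all_cells_on_border_undefined(self, square_lesion):
        cells = table([(0, 10), (20, 10)], ["CD3", "CD3"])
        with pytest.raises(MetricError):
            compute_immcpi(cells, square_lesion, "CD3")

    def test_ratio_sign_matches_depth_comparison(self, square_lesion):
        # central marker cells -> deeper than average -> immCPI > 1
        cells = table([(10, 10), (1, 10), (2, 10), (19, 10)], ["CD3", "", "", ""])
        res = compute_immcpi(cells, square_lesion, "CD3")
        assert (res.immcpi > 1) == (res.mean_depth_marker > res.mean_depth_all)
        assert res.immcpi > 1

    def test_uniform_thinning_leaves_immcpi_at_one(self, disk_lesion):
        """A position-independent subsample has the same depth distribution."""
        shape, lesion, tissue, lg = disk_lesion
        cells = sample_cells(lesion, 20_000, RadialProfile("uniform"), seed=5, shape=shape)
        cells = assign_markers(cells, lesion, [MarkerSpec("CD3", "uniform_p", p=0.3)],
                               seed=5, shape=shape)
        res = compute_immcpi(cells, lg, "CD3")
        assert res.immcpi == pytest.approx(1.0, abs=0.05)


class TestInfiltrationBands:
    def test_uniform_disk_band_densities_equal(self, disk_lesion):
        shape, lesion, tissue, lg = disk_lesion
        cells = sample_cells(lesion, 20_000, RadialProfile("uniform"), seed=6, shape=shape)
        prof = infiltration_bands(cells, lg, band_width=50, n_bands=10)
        overall = prof.counts.sum() / prof.band_areas.sum()
        for cnt, a in zip(prof.counts, prof.band_areas):
            se = np.sqrt(max(cnt, 1)) / a
            assert cnt / a == pytest.approx(overall, abs=3 * se)

    def test_single_depth_concentrates_in_first_band(self, square_lesion):
        cells = table([(5, 10), (5, 5), (15, 15)])  # all at depth 5
        prof = infiltration_bands(cells, square_lesion, band_width=10, n_bands=2)
        # edges ascend from deepest; the band [-10, 0) is the last entry
        assert prof.counts[-1] == 3
        assert prof.counts[:-1].sum() == 0

    def test_boundary_cell_forced_into_peripheral_band(self, square_lesion):
        prof = infiltration_bands(table([(0, 10), (5, 5)]), square_lesion,
                                  band_width=2, n_bands=1)
        assert prof.counts[-1] == 1  # depth 0 in [0, 2)
        assert prof.remainder_count == 1  # depth 5 beyond the single band

    def test_counts_plus_remainder_conserve_cells(self, disk_lesion):
        shape, lesion, tissue, lg = disk_lesion
        cells = sample_cells(lesion, 5_000, RadialProfile("uniform"), seed=7, shape=shape)
        prof = infiltration_bands(cells, lg, band_width=30, n_bands=5)
        assert prof.counts.sum() + prof.remainder_count == 5_000

    def test_outward_bands_count_peritumoral_cells(self, square_lesion):
        cells = table([(5, 10), (25, 10), (23, 10)])  # one inside, two 3-5 µm outside
        prof = infiltration_bands(cells, square_lesion, band_width=4, n_bands=2,
                                  direction="outward")
        assert prof.counts.tolist() == [1, 1]
        assert prof.n_cells == 2

    def test_both_directions_concatenate(self, square_lesion):
        cells = table([(5, 10), (23, 10)])
        prof = infiltration_bands(cells, square_lesion, band_width=4, n_bands=2,
                                  direction="both")
        assert len(prof.counts) == 4
        assert prof.band_edges[0] == -8 and prof.band_edges[-1] == 8
        assert prof.counts.sum() == 2

    def test_invalid_parameters_rejected(self, square_lesion):
        cells = table([(5, 10)])
        with pytest.raises(ValueError):
            infiltration_bands(cells, square_lesion, band_width=0, n_bands=3)
        with pytest.raises(ValueError):
            infiltration_bands(cells, square_lesion, band_width=10, n_bands=0)
        with pytest.raises(ValueError):
            infiltration_bands(cells, square_lesion, band_width=10, n_bands=3,
                               direction="sideways")
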