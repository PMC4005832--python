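import numpy as np
import pytest

from ldmkit import (
    LDM,
    compute_indices,
    consecutive_distances,
    coverage_areas,
    delta0,
    deltaz,
    mu,
    nearest_neighbor_distances,
    synthesize_ldm,
    upsilon,
)
from ldmkit.exceptions import (
    DegenerateConfigurationError,
    InsufficientSpotsError,
)

from conftest import EXAMPLE_DIMS, EXAMPLE_TEMPLATE
from reference import indices_reference


class TestCoverageAreas:
    def test_worked_example_census(self, worked_ldm):
        prof = coverage_areas(worked_ldm)
        assert prof.A0 == 156
        assert prof.A.tolist() == [58, 15, 2]
        assert prof.alpha == 3

    def test_all_zero_ldm(self):
        prof = coverage_areas(LDM(grid=np.zeros((13, 12), dtype=int)))
        assert prof.A0 == 156 and prof.A.tolist() == []

    def test_single_interior_spot(self):
        prof = coverage_areas(synthesize_ldm([(6.0, 5.0)], (13, 12), 5))
        assert prof.A.tolist() == [25]

    def test_census_sum_equals_grid_sum(self, worked_ldm):
        prof = coverage_areas(worked_ldm)
        assert int(prof.A.sum()) == int(worked_ldm.grid.sum()) == 75


class TestErrorIndices:
    def test_worked_example_values(self, worked_ldm):
        prof = coverage_areas(worked_ldm)
        assert delta0(prof) == pytest.approx(62.82, abs=5e-3)
        assert deltaz(prof) == pytest.approx(10.90, abs=5e-3)

    def test_empty_map_is_fully_untreated(self):
        prof = coverage_areas(LDM(grid=np.zeros((5, 5), dtype=int)))
        assert delta0(prof) == 100.0
        assert deltaz(prof) == 0.0

    def test_full_single_coverage(self):
        prof = coverage_areas(LDM(grid=np.ones((5, 5), dtype=int)))
        assert delta0(prof) == 0.0
        assert deltaz(prof) == 0.0

    def test_two_coincident_spots_redundancy(self):
        ldm = synthesize_ldm([(6.0, 5.0), (6.0, 5.0)], (13, 12), 5)
        assert deltaz(coverage_areas(ldm)) == pytest.approx(25 / 156 * 100)

    def test_delta0_complement_identity(self, worked_ldm):
        prof = coverage_areas(worked_ldm)
        assert delta0(prof) + prof.A[0] / prof.A0 * 100 == pytest.approx(100.0)


class TestDistances:
    def test_worked_example_distances(self, worked_spots):
        dc = consecutive_distances(worked_spots)
        dn = nearest_neighbor_distances(worked_spots)
        assert np.round(dc, 2).tolist() == [3.61, 4.12]
        assert np.round(dn, 2).tolist() == [2.83, 3.61, 2.83]

    def test_two_spots(self):
        spots = [(0.0, 0.0), (3.0, 4.0)]
        assert consecutive_distances(spots).tolist() == [5.0]
        assert nearest_neighbor_distances(spots).tolist() == [5.0, 5.0]

    def test_collinear_equal_spacing(self):
        spots = [(0.0, 0.0), (0.0, 2.0), (0.0, 4.0)]
        assert consecutive_distances(spots).tolist() == [2.0, 2.0]
        assert nearest_neighbor_distances(spots).tolist() == [2.0, 2.0, 2.0]

    def test_dn_bounds_dc(self, rng):
        spots = rng.uniform(0, 50, size=(12, 2))
        dc = consecutive_distances(spots)
        dn = nearest_neighbor_distances(spots)
        assert (dn[:-1] <= dc + 1e-12).all()
        assert (dn[1:] <= dc + 1e-12).all()

    def test_dn_reorder_invariant_dc_not(self, rng, worked_spots):
        reordered = [worked_spots[i] for i in (2, 0, 1)]
        assert sorted(nearest_neighbor_distances(worked_spots)) == pytest.approx(
            sorted(nearest_neighbor_distances(reordered))
        )
        assert not np.allclose(
            consecutive_distances(worked_spots), consecutive_distances(reordered)
        )

    def test_single_spot_raises(self):
        with pytest.raises(InsufficientSpotsError):
            consecutive_distances([(1.0, 1.0)])


class TestMu:
    def test_worked_example_full_precision(self, worked_spots):
        # (sqrt(13) + sqrt(17)) / 2; the printed 3.87 averages 2-dp distances
        assert mu(worked_spots, 1.0) == pytest.approx(
            (np.sqrt(13) + np.sqrt(17)) / 2
        )

    def test_single_pair_with_conversion(self):
        assert mu([(0.0, 0.0), (0.0, 10.0)], 0.35) == pytest.approx(3.5)

    def test_ideal_operator_hits_window_size(self, bed_calibration):
        # grid traversal at pitch == template side, C chosen so pitch*C = 12
        pitch = bed_calibration.template_side
        spots = [(10.0, 10.0 + i * pitch) for i in range(5)]
        C = 12.0 / pitch
        assert mu(spots, C) == pytest.approx(12.0)

    def test_scales_linearly_with_conversion(self, worked_spots):
        assert mu(worked_spots, 2.0) == pytest.approx(2 * mu(worked_spots, 1.0))


class TestUpsilon:
    def test_worked_example_ratio(self, worked_spots):
        pct, ratio = upsilon(worked_spots)
        assert round(ratio, 2) == 0.15
        assert pct == pytest.approx(14.5321, abs=1e-3)
        assert ratio == pytest.approx(
            indices_reference([[0]], list(worked_spots), 1.0)["upsilon_ratio"],
            rel=1e-12,
        )

    def test_all_equal_nearest_distances(self):
        # 2x2 square: every spot's nearest neighbour is at the same distance
        spots = [(0.0, 0.0), (0.0, 3.0), (3.0, 0.0), (3.0, 3.0)]
        assert upsilon(spots) == (0.0, 0.0)

    def test_rigid_motion_and_scale_invariance(self, rng, worked_spots):
        arr = np.asarray(worked_spots)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = 3.0 * arr @ rot.T + np.array([11.0, -4.0])
        assert upsilon(moved)[1] == pytest.approx(upsilon(arr)[1], rel=1e-9)

    def test_coincident_spots_degenerate(self):
        with pytest.raises(DegenerateConfigurationError):
            upsilon([(1.0, 1.0), (1.0, 1.0)])


class TestComputeIndices:
    def test_worked_example_bundle(self, worked_ldm):
        idx = compute_indices(worked_ldm, 1.0)
        assert idx.alpha == 3 and idx.beta == 3
        assert idx.delta0 == pytest.approx(62.82, abs=5e-3)
        assert idx.deltaz == pytest.approx(10.90, abs=5e-3)
        assert round(idx.upsilon_ratio, 2) == 0.15
        assert idx.upsilon_pct == pytest.approx(100 * idx.upsilon_ratio)

    def test_perfect_tiling_scores_zero_errors(self):
        # 3x3 abutting 5x5 templates covering a 15x15 target exactly
        spots = [(2.0 + 5 * r, 2.0 + 5 * c) for r in range(3) for c in range(3)]
        idx = compute_indices(synthesize_ldm(spots, (15, 15), 5), 1.0)
        assert idx.delta0 == 0.0
        assert idx.deltaz == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        beta = int(rng.integers(2, 15))
        spots = np.column_stack(
            [rng.uniform(4, 55, beta), rng.uniform(4, 45, beta)]
        )
        ldm = synthesize_ldm(spots, (60, 50), 7)
        idx = compute_indices(ldm, 0.35)
        ref = indices_reference(ldm.grid.tolist(), spots.tolist(), 0.35)
        for key in ("delta0", "deltaz", "mu", "upsilon_ratio"):
            ours = idx.as_dict()[key] if key != "mu" else idx.mu_mm
            assert ours == pytest.approx(ref[key], rel=1e-9)
        assert idx.alpha == ref["alpha"] and idx.beta == ref["beta"]

    def test_insufficient_spots_propagates(self):
        ldm = synthesize_ldm([(6.0, 5.0)], (13, 12), 5)
        with pytest.raises(InsufficientSpotsError):
            compute_indices(ldm, 1.0)
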