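import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxadapt.adaptation import (
    AdaptationParams,
    compute_penalty_scale,
    delta_p,
    phi_naive,
    phi_suppressed,
    suppression,
)
from voxadapt.distance import DistanceMap
from voxadapt.fluence import ConstraintSet, VoiConstraint
from voxadapt.grid import Structure, StructureSet, VoxelGrid

PARAMS = AdaptationParams()  # alpha=1, d_T=35, delta_delta=12, sigma_p=3.2
BODY_C = VoiConstraint(d_max=25.0, p_max=8000.0)


class TestPhiNaive:
    def test_unity_at_threshold_dose(self):
        assert phi_naive(35.0, BODY_C, PARAMS) == pytest.approx(1.0)

    def test_hand_value_above_threshold(self):
        # (45-25)^2 / (35-25)^2 = 4
        assert phi_naive(45.0, BODY_C, PARAMS) == pytest.approx(4.0)

    def test_clamped_below_threshold(self):
        assert phi_naive(20.0, BODY_C, PARAMS) == 1.0

    def test_unclamped_literal_form(self):
        p = AdaptationParams(clamp_low=False)
        assert phi_naive(30.0, BODY_C, p) == pytest.approx(0.25)
        assert phi_naive(20.0, BODY_C, p) == 0.0

    def test_alpha_scales_exponent(self):
        p = AdaptationParams(alpha=2.0)
        assert phi_naive(45.0, BODY_C, p) == pytest.approx(16.0)

    def test_threshold_must_exceed_dmax(self):
        with pytest.raises(ValueError, match="exceed"):
            phi_naive(30.0, VoiConstraint(d_max=40.0, p_max=1.0), PARAMS)


class TestDeltaP:
    def test_zero_at_95_percent(self):
        assert delta_p(0.95 * 70.0, 70.0, 3.2) == pytest.approx(0.0, abs=1e-9)

    def test_half_prescription_value(self):
        # sqrt(2)*3.2*(erfcinv(1) + 1.16309) = sqrt(2)*3.2*1.16309
        assert delta_p(35.0, 70.0, 3.2) == pytest.approx(5.2636, abs=2e-4)

    def test_clamped_band_above_95_percent(self):
        assert delta_p(0.97 * 70.0, 70.0, 3.2) == 0.0

    def test_vanishing_dose_capped(self):
        assert delta_p(0.0, 70.0, 3.2, cap=500.0) == 500.0
        assert delta_p(1e-15, 70.0, 3.2, cap=500.0) == 500.0

    def test_monotone_non_increasing_in_dose(self):
        d = np.linspace(1e-3, 69.0, 500)
        dp = delta_p(d, 70.0, 3.2, cap=1e3)
        assert np.all(np.diff(dp) <= 1e-12)


class TestSuppression:
    def test_full_inside_allowed_distance(self):
        d = 30.0
        dp = delta_p(d, 70.0, PARAMS.sigma_p)
        assert suppression(d, 0.5 * dp, 70.0, PARAMS) == 1.0

    def test_quadratic_falloff_in_zero_dp_band(self):
        d = 0.97 * 70.0  # delta_p = 0 here
        s = suppression(d, PARAMS.delta_delta / 2.0, 70.0, PARAMS)
        assert s == pytest.approx(0.75)

    def test_zero_beyond_release_margin(self):
        d = 30.0
        dp = delta_p(d, 70.0, PARAMS.sigma_p)
        assert suppression(d, dp + PARAMS.delta_delta, 70.0, PARAMS) == 0.0

    def test_high_dose_clamped_to_zero(self):
        assert suppression(140.0, PARAMS.delta_delta, 70.0, PARAMS) == 0.0

    def test_continuity_at_prescription(self):
        s = suppression(70.0, PARAMS.delta_delta / 2.0, 70.0, PARAMS)
        assert s == pytest.approx(0.75)

    @given(
        d=st.floats(0.0, 210.0),
        delta=st.floats(0.0, 80.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_between_zero_and_one(self, d, delta):
        s = suppression(d, delta, 70.0, PARAMS)
        assert 0.0 <= s <= 1.0


class TestPhiSuppressed:
    def test_full_suppression_gives_unit_scale(self):
        assert phi_suppressed(7.3, 1.0) == pytest.approx(1.0)

    def test_no_suppression_keeps_naive_scale(self):
        assert phi_suppressed(7.3, 0.0) == pytest.approx(7.3)

    def test_hand_value(self):
        assert phi_suppressed(4.0, 0.75) == pytest.approx(1.75)

    @given(
        phi_o=st.floats(1.0, 100.0),
        s=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_between_one_and_phi_o(self, phi_o, s):
        phi = phi_suppressed(phi_o, s)
        assert 1.0 - 1e-12 <= phi <= phi_o + 1e-12


SURFACE_DPRES = 70.0


@pytest.fixture(scope="module")
def surface():
    d = np.linspace(0.0, 2.0 * SURFACE_DPRES, 500)
    delta = np.linspace(0.0, 60.0, 500)
    dd, tt = np.meshgrid(d, delta, indexing="ij")
    s = suppression(dd, tt, SURFACE_DPRES, PARAMS)
    phi_o = phi_naive(dd, BODY_C, PARAMS)
    return d, delta, s, phi_suppressed(phi_o, s)


class TestSurfaceProperties:
    """Shape of phi_S(d, delta) on a fine grid: S = 1 plateau at small
    distances, S = 0 at large distances, continuous band between, and
    monotone growth with dose."""

    DPRES = SURFACE_DPRES

    def test_plateaus(self, surface):
        d, delta, s, _ = surface
        below = d < self.DPRES
        dp = delta_p(d, self.DPRES, PARAMS.sigma_p, cap=1e3)
        inside = below[:, None] & (delta[None, :] <= dp[:, None])
        outside = below[:, None] & (delta[None, :] >= dp[:, None] + PARAMS.delta_delta)
        assert np.all(s[inside] == 1.0)
        assert np.all(s[outside] == 0.0)

    def test_continuous_across_branch_joins(self):
        """phi_S has no jump at d = dpres (quadratic band meets the
        exponential high-dose branch) nor at the edges of the delta_P = 0
        band (d = 0.95 dpres)."""
        eps = 1e-8
        delta = np.linspace(0.0, 60.0, 500)
        for d_join in (self.DPRES, 0.95 * self.DPRES):
            lo = phi_suppressed(
                phi_naive(d_join - eps, BODY_C, PARAMS),
                suppression(d_join - eps, delta, self.DPRES, PARAMS),
            )
            hi = phi_suppressed(
                phi_naive(d_join + eps, BODY_C, PARAMS),
                suppression(d_join + eps, delta, self.DPRES, PARAMS),
            )
            assert np.max(np.abs(hi - lo) / np.maximum(np.abs(lo), 1.0)) < 1e-6

    def test_monotone_non_decreasing_in_dose(self, surface):
        _, _, _, phi = surface
        assert np.all(np.diff(phi, axis=0) >= -1e-9)

    def test_phi_s_never_exceeds_phi_o(self, surface):
        d, delta, s, phi = surface
        phi_o = phi_naive(d, BODY_C, PARAMS)[:, None]
        assert np.all(phi <= phi_o + 1e-12)
        assert np.all(phi[s == 1.0] == pytest.approx(1.0))


def _line_case(doses, dpres=(70.0,)):
    """1D structure set whose target(s) sit at the left end, with given
    normal-tissue doses."""
    n = len(doses) + len(dpres)
    grid = VoxelGrid((n, 1, 1))
    body = np.ones(grid.shape, bool)
    structures = [Structure("body", body, "body")]
    for i, dp in enumerate(dpres):
        m = np.zeros(grid.shape, bool)
        m[i] = True
        structures.append(Structure(f"t{i}", m, "target", dpres=dp))
    ss = StructureSet(grid, structures)
    dose = np.zeros(grid.shape)
    dose[len(dpres):, 0, 0] = doses
    return ss, dose


class TestComputePenaltyScale:
    CONS = ConstraintSet({"body": BODY_C})

    def test_uniform_threshold_dose_gives_unit_cube(self):
        ss, dose = _line_case([35.0] * 5)
        dose[:] = 35.0
        maps = {70.0: DistanceMap(np.arange(6, dtype=float).reshape(6, 1, 1), 70.0)}
        phi = compute_penalty_scale(dose, ss, maps, PARAMS, self.CONS)
        assert np.all(phi == 1.0)

    def test_single_group_matches_per_voxel_formulas(self):
        doses = [50.0, 40.0, 80.0, 20.0]
        ss, dose = _line_case(doses)
        delta = np.array([0.0, 5.0, 20.0, 40.0, 12.0]).reshape(5, 1, 1)
        maps = {70.0: DistanceMap(delta, 70.0)}
        phi = compute_penalty_scale(dose, ss, maps, PARAMS, self.CONS)
        region = ss.adaptation_region()
        for i, d in enumerate(doses, start=1):
            expected = phi_suppressed(
                phi_naive(d, BODY_C, PARAMS),
                suppression(d, delta[i, 0, 0], 70.0, PARAMS),
            )
            assert phi[i, 0, 0] == pytest.approx(expected)
        assert np.all(phi[~region] == 1.0)

    def test_naive_mode_ignores_distance(self):
        ss, dose = _line_case([50.0, 45.0])
        maps = {70.0: DistanceMap(np.zeros((3, 1, 1)), 70.0)}
        params = AdaptationParams(mode="naive")
        phi = compute_penalty_scale(dose, ss, maps, params, self.CONS)
        assert phi[1, 0, 0] == pytest.approx(phi_naive(50.0, BODY_C, PARAMS))

    def test_group_selection_smallest_excess_wins(self):
        d = 40.0
        ss, dose = _line_case([d], dpres=(46.0, 70.0))
        # group 70: delta chosen far outside; group 46: inside its allowed
        # distance (d < 0.95*46 is false -> d >= dpres? 40 < 46 so band).
        delta70 = np.full((3, 1, 1), 30.0)
        delta46 = np.full((3, 1, 1), 1.0)
        maps = {
            70.0: DistanceMap(delta70, 70.0),
            46.0: DistanceMap(delta46, 46.0),
        }
        phi = compute_penalty_scale(dose, ss, maps, PARAMS, self.CONS)
        expected = phi_suppressed(
            phi_naive(d, BODY_C, PARAMS), suppression(d, 1.0, 46.0, PARAMS)
        )
        assert phi[2, 0, 0] == pytest.approx(expected)

    def test_tie_break_prefers_lower_prescription(self):
        d = 50.0
        # engineer an exact tie in delta - delta_p between the two groups
        dp70 = delta_p(d, 70.0, PARAMS.sigma_p)
        assert dp70 > 0
        dp46 = delta_p(d, 46.0, PARAMS.sigma_p)  # d >= dpres -> 0
        assert dp46 == 0.0
        delta46 = 20.0 - dp70  # excess46 = excess70
        ss, dose = _line_case([d], dpres=(46.0, 70.0))
        maps = {
            70.0: DistanceMap(np.full((3, 1, 1), 20.0), 70.0),
            46.0: DistanceMap(np.full((3, 1, 1), delta46), 46.0),
        }
        phi = compute_penalty_scale(dose, ss, maps, PARAMS, self.CONS)
        expected = phi_suppressed(
            phi_naive(d, BODY_C, PARAMS),
            suppression(d, delta46, 46.0, PARAMS),
        )
        assert phi[2, 0, 0] == pytest.approx(expected)

    def test_requires_groups_and_body_constraint(self):
        ss, dose = _line_case([40.0])
        with pytest.raises(ValueError, match="group"):
            compute_penalty_scale(dose, ss, {}, PARAMS, self.CONS)
        maps = {70.0: DistanceMap(np.zeros((2, 1, 1)), 70.0)}
        with pytest.raises(KeyError):
            compute_penalty_scale(dose, ss, maps, PARAMS, ConstraintSet())
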