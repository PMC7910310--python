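import numpy as np
import pytest

from cdcpol.model_core import ModelParams, q0_homogeneous, reaction_f
from cdcpol.homogeneous import find_steady_states, select_patterning_state
from cdcpol.turing import (
    CLASSIC,
    NONCLASSIC,
    NONE,
    classify,
    classify_params,
    dispersion,
    homogeneous_jacobian,
    local_jacobian,
    map_parameter_plane,
    mode_matrix,
)

from conftest import random_positive_params


def fd_jacobian(u, v, params, h=1e-6):
    """Central finite differences of (gamma*f, gamma*(-f + q0))."""
    def rhs(uu, vv):
        f = float(reaction_f(uu, vv, params))
        q0 = float(q0_homogeneous(uu, vv, params))
        return np.array([params.gamma * f, params.gamma * (-f + q0)])

    J = np.empty((2, 2))
    J[:, 0] = (rhs(u + h, v) - rhs(u - h, v)) / (2 * h)
    J[:, 1] = (rhs(u, v + h) - rhs(u, v - h)) / (2 * h)
    return J


class TestJacobians:
    def test_homogeneous_jacobian_vs_finite_differences(self, classic_params):
        ss = select_patterning_state(classic_params)
        J = homogeneous_jacobian(ss, classic_params)
        J_fd = fd_jacobian(ss.u_star, ss.v_star, classic_params)
        np.testing.assert_allclose(J, J_fd, atol=1e-5 * np.abs(J).max())

    def test_analytic_f_derivatives(self, classic_params):
        ss = select_patterning_state(classic_params)
        J = homogeneous_jacobian(ss, classic_params) / classic_params.gamma
        u, v = ss.u_star, ss.v_star
        assert J[0, 0] == pytest.approx(2 * u * v - 1)
        assert J[0, 1] == pytest.approx(classic_params.c2 + u * u)

    def test_classic_state_is_stable_node(self, classic_params):
        """The patterning steady state must be stable without diffusion."""
        ss = select_patterning_state(classic_params)
        J = homogeneous_jacobian(ss, classic_params)
        assert np.trace(J) < 0
        assert np.linalg.det(J) > 0

    def test_local_flux_derivative_structure(self, classic_params):
        """q_u = q_v + c_minus1 at fixed V (both equal -c1*V* up to c_minus1)."""
        ss = select_patterning_state(classic_params)
        J = local_jacobian(ss, classic_params)
        f_u = 2 * ss.u_star * ss.v_star - 1
        f_v = classic_params.c2 + ss.u_star**2
        q_u = J[1, 0] + f_u
        q_v = J[1, 1] + f_v
        assert q_u == pytest.approx(q_v + classic_params.c_minus1)
        assert q_u == pytest.approx(-classic_params.c1 * ss.V_star)

    def test_mass_coupling_distinguishes_jacobians(self, classic_params):
        """The l=0 Jacobian carries the conservation coupling that the
        inhomogeneous modes do not feel."""
        ss = select_patterning_state(classic_params)
        J_hom = homogeneous_jacobian(ss, classic_params)
        M0 = mode_matrix(ss, classic_params, k2=0.0)
        assert not np.allclose(J_hom, M0)
        assert np.allclose(M0, classic_params.gamma * local_jacobian(ss, classic_params))


class TestModeMatrix:
    def test_eigenvalues_match_dense_solver(self, classic_params):
        ss = select_patterning_state(classic_params)
        disp = dispersion(ss, classic_params, l_max=20)
        for l in (1, 3, 7, 20):
            M = mode_matrix(ss, classic_params, k2=l * (l + 1.0))
            expected = np.max(np.linalg.eigvals(M).real)
            assert disp.growth_rate_by_degree[l] == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_k2(self, classic_params):
        ss = select_patterning_state(classic_params)
        with pytest.raises(ValueError):
            mode_matrix(ss, classic_params, k2=-1.0)


class TestDispersion:
    def test_pure_diffusion_decay_without_reactions(self, classic_params):
        """gamma -> 0: growth rates tend to -min(1, d)*l(l+1) < 0."""
        p = classic_params.replace(gamma=1e-12)
        ss = select_patterning_state(p)
        disp = dispersion(ss, p, l_max=10)
        for l in range(1, 11):
            assert disp.growth_rate_by_degree[l] == pytest.approx(
                -l * (l + 1.0), rel=1e-6
            )
        assert disp.classification == NONE

    def test_unstable_band_is_contiguous(self, classic_params):
        """Instability from det(M(k2)) < 0 occupies one contiguous k2 band,
        verified against the quadratic-in-k2 determinant roots."""
        ss = select_patterning_state(classic_params)
        p = classic_params
        disp = dispersion(ss, p, l_max=50)
        J = p.gamma * local_jacobian(ss, p)
        # det(M) = d*k2^2 - k2*(d*J11 + J22) + det(J)
        coeffs = [p.d, -(p.d * J[0, 0] + J[1, 1]), np.linalg.det(J)]
        roots = np.roots(coeffs)
        lo, hi = np.sort(roots.real)
        unstable = set(int(l) for l in disp.unstable_degrees)
        for l in range(1, 51):
            k2 = l * (l + 1.0)
            assert (lo < k2 < hi) == (l in unstable)
        assert unstable, "classic fixture must have unstable degrees"

    def test_homogeneous_instability_yields_none(self):
        """A parameter point whose selected state is l=0 unstable cannot be
        classified as a pattern-forming instability."""
        rng = np.random.default_rng(5)
        found = 0
        for _ in range(400):
            p = random_positive_params(rng)
            for ss in find_steady_states(p):
                if ss.satisfies_necessary_condition and not ss.homogeneous_stable:
                    disp = dispersion(ss, p, l_max=20)
                    assert disp.classification == NONE
                    found += 1
        assert found > 0


class TestClassify:
    @pytest.mark.parametrize(
        "c_minus1, c2, expected",
        [
            (0.02, 0.45, CLASSIC),
            (0.04, 0.45, CLASSIC),
            (0.01, 0.20, NONCLASSIC),
            (0.03, 0.15, NONCLASSIC),
        ],
    )
    def test_reference_parameter_sets(self, c_minus1, c2, expected):
        p = ModelParams(c1=0.05, c_minus1=c_minus1, c2=c2, c_max=3.0, V0=6.0,
                        gamma=25.0, d=10.0)
        assert classify_params(p) == expected
        assert classify_params(p, l_max=50) == expected

    def test_equal_diffusion_never_classic(self):
        """With d = 1 the classic Turing conditions cannot be met."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            p = random_positive_params(rng).replace(d=1.0)
            assert classify_params(p) != CLASSIC

    def test_classified_points_satisfy_necessary_condition(self):
        """Every classic/non-classic point has a steady state passing the
        necessary condition (cross-module consistency)."""
        from cdcpol.homogeneous import necessary_condition

        fixed = ModelParams(c1=0.05, c_minus1=0.05, c2=0.45, d=10.0)
        for c_minus1 in np.linspace(0.005, 0.1, 8):
            for c2 in np.linspace(0.05, 1.0, 8):
                p = fixed.replace(c_minus1=float(c_minus1), c2=float(c2))
                label = classify_params(p)
                if label in (CLASSIC, NONCLASSIC):
                    ss = select_patterning_state(p)
                    assert ss is not None
                    assert necessary_condition(p, ss)


@pytest.fixture(scope="module")
def small_map():
    fixed = ModelParams(c1=0.05, c_minus1=0.05, c2=0.45, d=10.0)
    grid = (np.linspace(0.0005, 0.1, 30), np.linspace(0.005, 1.0, 30))
    return map_parameter_plane(
        ("c_minus1", "c2"), grid, fixed, d_list=(5.0, 10.0, 30.0)
    )


class TestRegionMap:
    def test_classic_regions_nested_in_d(self, small_map):
        c5 = small_map.classic[5.0]
        c10 = small_map.classic[10.0]
        c30 = small_map.classic[30.0]
        assert np.all(~c5 | c10)
        assert np.all(~c10 | c30)
        assert c5.sum() < c30.sum()

    def test_nonclassic_flag_independent_of_d(self):
        fixed = ModelParams(c1=0.05, c_minus1=0.05, c2=0.45, d=10.0)
        grid = (np.linspace(0.0005, 0.1, 20), np.linspace(0.005, 1.0, 20))
        flags = [
            map_parameter_plane(("c_minus1", "c2"), grid, fixed, d_list=(d,)).nonclassic
            for d in (1.0, 5.0, 30.0)
        ]
        assert np.array_equal(flags[0], flags[1])
        assert np.array_equal(flags[0], flags[2])
        assert flags[0].any()

    def test_classification_constant_along_c1(self):
        """Inside the classic band the label does not depend on the relative
        influx c1."""
        base = ModelParams(c1=0.05, c_minus1=0.05, c2=0.45, d=10.0)
        labels = {
            classify_params(base.replace(c1=float(c1)))
            for c1 in (0.05, 0.1, 0.5, 2.0, 10.0)
        }
        assert labels == {CLASSIC}

    def test_refinement_stability_of_region_areas(self):
        """Doubling the grid resolution changes the classic area by < 5%."""
        fixed = ModelParams(c1=0.05, c_minus1=0.05, c2=0.45, d=10.0)
        areas = []
        for n in (25, 50):
            grid = (np.linspace(0.0005, 0.1, n), np.linspace(0.005, 1.0, n))
            rmap = map_parameter_plane(("c_minus1", "c2"), grid, fixed,
                                       d_list=(10.0,))
            areas.append(rmap.classic[10.0].mean())
        assert abs(areas[1] - areas[0]) / areas[0] < 0.05

    def test_long_format_export(self, small_map):
        df = small_map.to_dataframe()
        assert set(df.columns) == {"c_minus1", "c2", "d", "label"}
        assert len(df) == 30 * 30 * 3
        assert set(df["label"].unique()) <= {CLASSIC, NONCLASSIC, NONE}
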