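"""Laminate plate mechanics: reduced stiffness, ABD assembly, hygro solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hygrocap.laminate import (
    ElasticLayer,
    Laminate,
    ModelParams,
    StiffnessError,
    assemble_abd,
    effective_fiber_moduli,
    hygro_resultants,
    isotropic_layer,
    reduced_stiffness,
    solve_free_hygro,
    timoshenko_bilayer_curvature,
)
from hygrocap.profile import ThicknessProfile, station_laminate


def rotate_stiffness_tensor(q: np.ndarray, theta_deg: float) -> np.ndarray:
    """Independent oracle: brute-force 4th-order tensor rotation of Q."""
    c_t = np.zeros((2, 2, 2, 2))
    idx = {(0, 0): 0, (1, 1): 1, (0, 1): 2, (1, 0): 2}
    for (i, j), a in idx.items():
        for (k, l), b in idx.items():
            c_t[i, j, k, l] = q[a, b]
    th = np.deg2rad(theta_deg)
    # rotate material axes into laminate axes
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c_rot = np.einsum("ia,jb,kc,ld,abcd->ijkl", r, r, r, r, c_t)
    out = np.zeros((3, 3))
    for (i, j), a in idx.items():
        for (k, l), b in idx.items():
            out[a, b] = c_rot[i, j, k, l]
    return out


layers_strategy = st.lists(
    st.tuples(
        st.floats(0.1, 2.0),      # thickness
        st.floats(0.0, 180.0),    # orientation
        st.floats(0.05, 5.0),     # E_perp
        st.floats(1.0, 30.0),     # anisotropy ratio
        st.floats(0.0, 0.45),     # nu12
        st.floats(-0.9, 0.5),     # hygro strain
    ),
    min_size=1,
    max_size=5,
).map(
    lambda rows: Laminate(
        ElasticLayer(
            thickness=t,
            orientation_deg=ang,
            E_parallel=e2 * ratio,
            E_perp=e2,
            nu12=nu,
            hygro_strain=eps,
        )
        for (t, ang, e2, ratio, nu, eps) in rows
    )
)


def quadrature_abd_and_hygro(lam: Laminate) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre through-thickness integration oracle (exact for polys)."""
    nodes, weights = np.polynomial.legendre.leggauss(6)
    z = lam.z_interfaces
    abd = np.zeros((6, 6))
    nh = np.zeros(6)
    for k, layer in enumerate(lam.layers):
        qbar = reduced_stiffness(layer)
        beta = qbar @ np.array([layer.hygro_strain, layer.hygro_strain, 0.0])
        mid, half = (z[k] + z[k + 1]) / 2.0, (z[k + 1] - z[k]) / 2.0
        for node, w in zip(nodes, weights):
            zz = mid + half * node
            abd[:3, :3] += w * half * qbar
            abd[:3, 3:] += w * half * qbar * zz
            abd[3:, 3:] += w * half * qbar * zz * zz
            nh[:3] += w * half * beta
            nh[3:] += w * half * beta * zz
    abd[3:, :3] = abd[:3, 3:]
    return abd, nh


class TestReducedStiffness:
    @pytest.mark.parametrize("angle", [0.0, 17.0, 45.0, 90.0, 133.0])
    def test_isotropic_layer_rotation_invariant(self, angle):
        E, nu = 2.0, 0.3
        layer = ElasticLayer(1.0, angle, E, E, nu, G12=E / (2 * (1 + nu)))
        q = reduced_stiffness(layer)
        assert q[0, 0] == pytest.approx(E / (1 - nu**2), rel=1e-12)
        q0 = reduced_stiffness(ElasticLayer(1.0, 0.0, E, E, nu, G12=E / (2 * (1 + nu))))
        np.testing.assert_allclose(q, q0, rtol=1e-10, atol=1e-12)

    def test_0_and_90_swap_normal_entries(self):
        l0 = ElasticLayer(1.0, 0.0, 20.0, 5.0, 0.3)
        l90 = ElasticLayer(1.0, 90.0, 20.0, 5.0, 0.3)
        q0, q90 = reduced_stiffness(l0), reduced_stiffness(l90)
        assert q0[0, 0] == pytest.approx(q90[1, 1], rel=1e-12)
        assert q0[1, 1] == pytest.approx(q90[0, 0], rel=1e-12)
        assert q0[0, 1] == pytest.approx(q90[0, 1], rel=1e-12)

    @pytest.mark.parametrize("angle", [30.0, 45.0, 60.0, 120.0])
    def test_matches_tensor_rotation_oracle(self, angle):
        base = ElasticLayer(1.0, 0.0, 20.0, 5.0, 0.3)
        rotated = ElasticLayer(1.0, angle, 20.0, 5.0, 0.3)
        expected = rotate_stiffness_tensor(reduced_stiffness(base), angle)
        np.testing.assert_allclose(reduced_stiffness(rotated), expected, rtol=1e-10)

    def test_symmetric_positive_definite(self):
        q = reduced_stiffness(ElasticLayer(1.0, 37.0, 20.0, 5.0, 0.3))
        np.testing.assert_allclose(q, q.T, rtol=1e-12)
        assert np.all(np.linalg.eigvalsh(q) > 0)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(StiffnessError):
            ElasticLayer(1.0, 0.0, 1.0, 1.0, nu12=1.0)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(StiffnessError):
            ElasticLayer(0.0, 0.0, 1.0, 1.0)


class TestRuleOfMixtures:
    @pytest.mark.parametrize(
        "vf,expected",
        [
            (1.0, (100.0, 100.0)),
            (0.0, (1.0, 1.0)),
            (0.5, (50.5, 100.0 / 50.5)),
        ],
    )
    def test_voigt_reuss_values(self, vf, expected):
        e_par, e_perp = effective_fiber_moduli(100.0, 1.0, vf)
        assert e_par == pytest.approx(expected[0], rel=1e-12)
        assert e_perp == pytest.approx(expected[1], rel=1e-12)

    def test_volume_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            effective_fiber_moduli(10.0, 1.0, 1.5)


class TestABD:
    def test_single_layer_closed_form(self):
        E, nu, h = 3.0, 0.25, 0.7
        lam = Laminate([isotropic_layer(h, E, nu)])
        abd = assemble_abd(lam)
        a11 = h * E / (1 - nu**2)
        assert abd[0, 0] == pytest.approx(a11, rel=1e-12)
        assert abd[3, 3] == pytest.approx(a11 * h**2 / 12, rel=1e-12)
        np.testing.assert_allclose(abd[:3, 3:], 0.0, atol=1e-15)

    def test_empty_laminate_rejected(self):
        with pytest.raises(ValueError):
            Laminate([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(lam=layers_strategy)
    def test_matches_quadrature_oracle(self, lam):
        abd_expected, nh_expected = quadrature_abd_and_hygro(lam)
        abd = assemble_abd(lam)
        nh = hygro_resultants(lam)
        np.testing.assert_allclose(abd, abd_expected, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(nh, nh_expected, rtol=1e-9, atol=1e-12)


class TestHygroSolve:
    def test_zero_hygro_strain_zero_state(self):
        lam = Laminate(
            [
                ElasticLayer(0.3, 90.0, 20.0, 5.0, 0.3),
                ElasticLayer(0.3, 0.0, 20.0, 5.0, 0.3),
            ]
        )
        state = solve_free_hygro(lam)
        np.testing.assert_allclose(state.midplane_strains, 0.0, atol=1e-15)
        np.testing.assert_allclose(state.curvatures, 0.0, atol=1e-15)

    def test_single_isotropic_layer_no_moment(self):
        lam = Laminate([isotropic_layer(1.0, 2.0, 0.3, hygro_strain=-0.5)])
        nh = hygro_resultants(lam)
        np.testing.assert_allclose(nh[3:], 0.0, atol=1e-15)
        state = solve_free_hygro(lam)
        np.testing.assert_allclose(state.curvatures, 0.0, atol=1e-14)
        # free shrinkage: midplane strain equals the hygro strain
        np.testing.assert_allclose(state.midplane_strains[:2], -0.5, rtol=1e-12)

    @pytest.mark.parametrize("m", [0.3, 1.0, 3.0])
    @pytest.mark.parametrize("n", [0.2, 1.0, 5.0])
    def test_bilayer_matches_timoshenko(self, m, n):
        h2, e2, eps = 0.8, 1.7, -0.7
        h1, e1 = m * h2, n * e2
        lam = Laminate(
            [
                isotropic_layer(h1, e1, 0.3, hygro_strain=eps, name="active"),
                isotropic_layer(h2, e2, 0.3, name="passive"),
            ]
        )
        kappa = solve_free_hygro(lam).kappa_L
        expected = timoshenko_bilayer_curvature(h1, h2, e1, e2, eps)
        assert kappa == pytest.approx(expected, rel=1e-9)

    def test_linearity_in_hygro_strain(self):
        def capsule(eps):
            return Laminate(
                [
                    ElasticLayer(0.3, 90.0, 20.0, 5.0, 0.3),
                    ElasticLayer(0.2, 0.0, 20.0, 5.0, 0.3),
                    isotropic_layer(0.5, 0.1, 0.3, hygro_strain=eps),
                ]
            )

        k1 = solve_free_hygro(capsule(-0.7)).kappa_L
        k2 = solve_free_hygro(capsule(-0.35)).kappa_L
        k3 = solve_free_hygro(capsule(0.7)).kappa_L
        assert k2 == pytest.approx(0.5 * k1, rel=1e-12)
        assert k3 == pytest.approx(-k1, rel=1e-12)

    def test_symmetric_stack_zero_curvature(self):
        sym = Laminate(
            [
                isotropic_layer(0.2, 1.0, 0.3, hygro_strain=-0.4),
                ElasticLayer(0.3, 30.0, 20.0, 5.0, 0.3, hygro_strain=-0.1),
                isotropic_layer(0.1, 5.0, 0.3),
                ElasticLayer(0.3, 30.0, 20.0, 5.0, 0.3, hygro_strain=-0.1),
                isotropic_layer(0.2, 1.0, 0.3, hygro_strain=-0.4),
            ]
        )
        state = solve_free_hygro(sym)
        np.testing.assert_allclose(state.curvatures, 0.0, atol=1e-12)

    def test_reference_plane_does_not_change_curvature(self):
        layers = [
            ElasticLayer(0.3, 90.0, 20.0, 5.0, 0.3),
            ElasticLayer(0.2, 0.0, 20.0, 5.0, 0.3),
            isotropic_layer(0.5, 0.1, 0.3, hygro_strain=-0.7),
        ]
        k_mid = solve_free_hygro(Laminate(layers)).curvatures
        k_bottom = solve_free_hygro(Laminate(layers, z_ref=0.0)).curvatures
        k_odd = solve_free_hygro(Laminate(layers, z_ref=0.37)).curvatures
        np.testing.assert_allclose(k_mid, k_bottom, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(k_mid, k_odd, rtol=1e-9, atol=1e-12)

    def test_drying_bends_capsule_outward(self, params):
        """Shrinking outer parenchyma must give positive kappa_L."""
        profile = ThicknessProfile(
            s=[0.5], X_M=[0.5], X_L=[0.2], X_T=[0.3]
        )
        state = solve_free_hygro(station_laminate(profile, 0, params))
        assert state.kappa_L > 0

    def test_longitudinal_fibers_resist_bending(self, params):
        """|kappa_L| strictly decreases as the longitudinal-fiber layer thickens."""
        kappas = []
        for x_l in [0.05, 0.15, 0.3, 0.5]:
            lam = Laminate(
                [
                    ElasticLayer(0.2, 90.0, 20.0, 5.0, 0.3),
                    ElasticLayer(x_l, 0.0, 20.0, 5.0, 0.3),
                    isotropic_layer(0.4, 0.1, 0.3, hygro_strain=-0.7),
                ]
            )
            kappas.append(abs(solve_free_hygro(lam).kappa_L))
        assert all(a > b for a, b in zip(kappas, kappas[1:]))


class TestTimoshenkoFormula:
    def test_zero_strain(self):
        assert timoshenko_bilayer_curvature(1.0, 1.0, 2.0, 3.0, 0.0) == 0.0

    def test_equal_layers_hand_value(self):
        # m = n = 1, h = 1: denominator = 3*4 + 2*2 = 16; 6*eps*4/16 = 1.5 eps
        eps = -0.7
        assert timoshenko_bilayer_curvature(0.5, 0.5, 1.0, 1.0, eps) == pytest.approx(
            1.5 * eps, rel=1e-12
        )

    def test_rigid_passive_layer_suppresses_bending(self):
        kappas = [
            abs(timoshenko_bilayer_curvature(1.0, 1.0, 1.0, e2, -0.7))
            for e2 in [1.0, 1e3, 1e6, 1e9]
        ]
        assert all(a > b for a, b in zip(kappas, kappas[1:]))
        assert kappas[-1] < 1e-8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            timoshenko_bilayer_curvature(0.0, 1.0, 1.0, 1.0, -0.5)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(stiffness_triplet=(20.0, 5.0, 0.0))
    with pytest.raises(ValueError):
        ModelParams(eps_parenchyma=-1.5)
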