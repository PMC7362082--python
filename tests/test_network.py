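"""Protofibril network: derived counts, topology, equilibrium, fiber curve."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fibrinet.force_laws import SpringKind, invert_fibrinogen_force
from fibrinet.network import (
    NodeRole,
    assemble_residual,
    build_element_topology,
    derive_cross_section_count,
    derive_element_count,
    fiber_curve,
    jacobian,
    molecule_curve,
    solve_equilibrium,
    total_energy,
)
from fibrinet.params import FiberGeometry, SimulationControls, ValidationError


# -- derived counts ---------------------------------------------------------


@pytest.mark.parametrize(
    "diameter, fraction, radius, expected",
    [
        (330.0, 0.30, 2.25, 1614),  # reference fiber
        (50.0, 0.30, 2.25, 38),  # ceil(37.04)
        (30.0, 1.0, 7.5, 4),  # exactly integral: ceiling is a no-op
    ],
)
def test_cross_section_count(diameter, fraction, radius, expected):
    g = FiberGeometry(
        fiber_diameter=diameter, protein_fraction=fraction, monomer_radius=radius
    )
    assert derive_cross_section_count(g) == expected


@pytest.mark.parametrize(
    "length, expected",
    [(12_000.0, 261), (46.0, 1), (500.0, 11), (92.0, 2)],
)
def test_element_count(length, expected):
    g = FiberGeometry(fiber_length=length)
    assert derive_element_count(g) == expected


def test_invalid_geometry_rejected():
    with pytest.raises(ValidationError):
        derive_cross_section_count(FiberGeometry(fiber_diameter=-1.0))
    with pytest.raises(ValidationError):
        derive_element_count(FiberGeometry(element_rest_length=-1.0))


def test_cross_section_scales_with_radius_squared():
    g1 = FiberGeometry(fiber_diameter=165.0)
    g2 = FiberGeometry(fiber_diameter=330.0)
    ratio = derive_cross_section_count(g2) / derive_cross_section_count(g1)
    assert 3.99 <= ratio <= 4.01


# -- topology ---------------------------------------------------------------


def test_single_element_matches_reference_schematic(geometry):
    t = build_element_topology(geometry, 1)
    physical = [n for n in t.nodes if n.role is not NodeRole.DUMMY]
    dummies = [n for n in t.nodes if n.role is NodeRole.DUMMY]
    assert len(physical) == 7 and len(dummies) == 2
    roles = sorted(n.role.value for n in physical)
    assert roles.count("D") == 4 and roles.count("E") == 3
    # both strand ends at x=0 are fixed, and only those
    fixed = [n for n in t.nodes if n.fixed]
    assert len(fixed) == 2 and all(n.rest_position == 0.0 for n in fixed)
    kinds = [s.kind for s in t.springs]
    assert kinds.count(SpringKind.MONOMER_HALF) == 4
    assert kinds.count(SpringKind.KNOB_HOLE) == 4  # 2 center + 2 boundary
    assert kinds.count(SpringKind.GAMMA_GAMMA) == 1
    assert kinds.count(SpringKind.BINDING) == 1
    assert kinds.count(SpringKind.RIGID_TIE) == 3


def test_chain_shares_boundary_nodes(geometry):
    t1 = build_element_topology(geometry, 1)
    t2 = build_element_topology(geometry, 2)
    # each extra element adds 3 center nodes + 2 boundary nodes
    assert t2.n_nodes == t1.n_nodes + 5
    # free dof count: 5 per element, minus merged end yoke, see topology module
    assert t2.n_dof == t1.n_dof + 5


def test_chain_rest_span(geometry):
    t = build_element_topology(geometry, 261)
    assert t.rest_span == pytest.approx(261 * 46.0)
    assert t.rest_span == pytest.approx(12_006.0)


def test_rest_positions_within_fiber(geometry):
    t = build_element_topology(geometry, 3)
    for n in t.nodes:
        assert 0.0 <= n.rest_position <= t.rest_span


# -- residual / energy ------------------------------------------------------


def test_rest_state_is_equilibrium(params, geometry):
    t = build_element_topology(geometry, 2)
    u = np.zeros(t.n_nodes)
    np.testing.assert_array_equal(assemble_residual(t, u, 0.0, params), 0.0)
    assert total_energy(t, u, 0.0, params) == 0.0
    assert total_energy(t, u, 50.0, params) == 0.0  # no displacement against load


def test_residual_at_rest_is_pure_external_load(params, geometry):
    t = build_element_topology(geometry, 1)
    r = assemble_residual(t, np.zeros(t.n_nodes), 5.0, params)
    # the rigid yoke merges both loaded strand ends into one dof carrying 2F
    loaded = np.nonzero(r)[0]
    assert len(loaded) == 1
    assert r[loaded[0]] == pytest.approx(10.0)


def test_dimension_mismatch_rejected(params, geometry):
    t = build_element_topology(geometry, 1)
    with pytest.raises(ValueError, match="node displacements"):
        assemble_residual(t, np.zeros(3), 0.0, params)


@pytest.mark.parametrize("n_elements", [1, 3])
def test_residual_is_negative_energy_gradient(n_elements, params, geometry, rng):
    t = build_element_topology(geometry, n_elements)
    h = 1e-4
    for _ in range(10):
        dofs = rng.normal(0.0, 5.0, t.n_dof)
        r = assemble_residual(t, t.expand_dofs(dofs), 30.0, params)
        fd = np.empty(t.n_dof)
        for i in range(t.n_dof):
            up, um = dofs.copy(), dofs.copy()
            up[i] += h
            um[i] -= h
            fd[i] = -(
                total_energy(t, t.expand_dofs(up), 30.0, params)
                - total_energy(t, t.expand_dofs(um), 30.0, params)
            ) / (2 * h)
        np.testing.assert_allclose(fd, r, rtol=1e-5, atol=1e-7)


def test_jacobian_matches_residual_differences(params, geometry, rng):
    t = build_element_topology(geometry, 2)
    dofs = rng.normal(0.0, 3.0, t.n_dof)
    J = jacobian(t, t.expand_dofs(dofs), params, sparse=False)
    h = 1e-6
    for i in range(t.n_dof):
        up, um = dofs.copy(), dofs.copy()
        up[i] += h
        um[i] -= h
        col = (
            assemble_residual(t, t.expand_dofs(up), 0.0, params)
            - assemble_residual(t, t.expand_dofs(um), 0.0, params)
        ) / (2 * h)
        np.testing.assert_allclose(J[:, i], col, rtol=1e-5, atol=1e-6)


# -- equilibrium solve ------------------------------------------------------


def test_zero_force_solution_is_zero(params, geometry, controls):
    t = build_element_topology(geometry, 2)
    st = solve_equilibrium(t, 0.0, params, controls=controls)
    assert st.converged
    np.testing.assert_allclose(st.displacements, 0.0, atol=1e-12)


def test_converged_state_satisfies_tolerance(params, geometry, controls):
    t = build_element_topology(geometry, 1)
    st = solve_equilibrium(t, 80.0, params, controls=controls)
    assert st.converged
    assert st.residual_norm <= controls.solver_tolerance
    # fixed nodes exactly zero
    for n, u in zip(t.nodes, st.displacements):
        if n.fixed:
            assert u == 0.0


@pytest.mark.parametrize("F", [10.0, 50.0])
def test_solver_matches_derivative_free_energy_minimum(F, params, geometry, controls):
    t = build_element_topology(geometry, 1)
    st = solve_equilibrium(t, F, params, controls=controls)
    res = minimize(
        lambda x: total_energy(t, t.expand_dofs(x), F, params),
        np.zeros(t.n_dof),
        method="Powell",
        options=dict(xtol=1e-12, ftol=1e-15, maxiter=10_000, maxfev=200_000),
    )
    assert res.success
    np.testing.assert_allclose(res.x, st.dofs, atol=1e-4)


def test_rigid_crosslink_limit_reduces_to_series_monomer(params, geometry, controls):
    # near-rigid D-E and D-D bonds, binding off: each strand is two monomer
    # halves in series, so the element extension inverts the monomer law
    pr = params.replace(k3=params.k3 * 1e6, k4=params.k4 * 1e6, k5=0.0, k6=0.0)
    t = build_element_topology(geometry, 1)
    for F in (25.0, 100.0, 180.0):
        st = solve_equilibrium(t, F, pr, controls=controls)
        assert st.converged
        expected = invert_fibrinogen_force(F, params)
        assert t.end_displacement(st.displacements) == pytest.approx(expected, rel=1e-6)


# -- fiber curve ------------------------------------------------------------


def test_fiber_curve_shape_and_scaling(params, geometry, fast_controls):
    crv = fiber_curve(params, geometry, fast_controls)
    assert crv.scale == "fiber"
    assert crv.x[0] == 1.0
    assert crv.force[0] == 0.0
    # fiber force is the per-monomer force scaled by the cross-section count
    np.testing.assert_allclose(crv.force, 1614 * crv.extra["per_monomer_force_pN"])
    assert crv.metadata["monomers_per_cross_section"] == 1614
    assert crv.metadata["n_elements"] == 261


def test_fiber_curve_strictly_increasing(params, geometry, fast_controls):
    crv = fiber_curve(params, geometry, fast_controls)
    assert crv.break_index is None
    assert np.all(np.diff(crv.x) > 0)
    assert np.all(np.diff(crv.force) > 0)


def test_binding_force_stiffens_fiber(params, geometry, fast_controls):
    with_binding = fiber_curve(params, geometry, fast_controls)
    without = fiber_curve(params.without_binding(), geometry, fast_controls)
    # parallel binding springs reduce stretch at every force level
    assert np.all(with_binding.x[1:] <= without.x[1:])
    assert np.any(with_binding.x[1:] < without.x[1:])


def test_full_chain_equals_replication_small(params, fast_controls):
    g = FiberGeometry(fiber_length=3 * 46.0)
    fast = fiber_curve(params, g, fast_controls)
    full = fiber_curve(params, g, fast_controls, full_chain=True)
    np.testing.assert_allclose(full.x, fast.x, rtol=1e-8)


def test_break_extension_factor_truncates(params, geometry):
    c = SimulationControls(n_steps=60, break_extension_factor=1.5)
    crv = fiber_curve(params, geometry, c)
    assert crv.break_index is not None
    assert crv.n_samples < 60
    assert crv.x[-2] <= 1.5 or crv.x[-1] > 1.5


def test_molecule_curve_samples_monomer_law(params):
    crv = molecule_curve(params, x_max=56.0, n_points=3)
    np.testing.assert_allclose(crv.x, [0.0, 28.0, 56.0])
    np.testing.assert_allclose(crv.force, [0.0, 42.0, 84.3])
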