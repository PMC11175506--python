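import math

import numpy as np
import pytest

from histomech import (
    ConnectionSet,
    SimParams,
    TissueMesh,
    bending_torque,
    connection_force,
    edge_force,
    foundation_force,
    solve_equilibrium,
    total_energy,
)
from histomech.mechanics import energy_and_forces


class TestEdgeForce:
    def test_published_worked_value(self):
        # Stretch to twice the rest length at the table's boundary stiffness.
        assert edge_force(2.0, 1.0, 0.2) == pytest.approx(0.2)

    def test_unstressed_spring(self):
        assert edge_force(1.0, 1.0, 0.2) == 0.0

    def test_compression(self):
        assert edge_force(0.5, 1.0, 0.2) == pytest.approx(-0.1)

    def test_zero_rest_length_rejected(self):
        with pytest.raises(ValueError):
            edge_force(1.0, 0.0, 0.2)


class TestBendingTorque:
    def test_at_rest(self):
        assert bending_torque(math.pi, math.pi, 5e-4) == 0.0

    def test_linear(self):
        assert bending_torque(math.pi + 0.1, math.pi, 5e-4) == pytest.approx(5e-5)


class TestFoundationForce:
    def test_coincident(self):
        f = foundation_force([1.0, 2.0], [1.0, 2.0], 0.1)
        assert np.allclose(f, 0.0)

    def test_unit_displacement_magnitude(self):
        f = foundation_force([0.0, 0.0], [1.0, 0.0], 0.1)
        assert np.allclose(f, [0.1, 0.0])

    def test_antisymmetric(self):
        a, b = np.array([0.3, 0.4]), np.array([1.1, -0.2])
        assert np.allclose(
            foundation_force(a, b, 0.1), -foundation_force(b, a, 0.1)
        )


class TestConnectionForce:
    def test_no_force_when_longer(self):
        assert connection_force(1.2, 1.0, 0.1) == 0.0

    def test_repulsive_when_compressed(self):
        assert connection_force(0.5, 1.0, 0.1) == pytest.approx(-0.05)

    def test_boundary_case(self):
        assert connection_force(1.0, 1.0, 0.1) == 0.0


def _random_chain_mesh(rng, n=8, fix_ends=True):
    pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    pos += rng.normal(0, 0.15, size=pos.shape)
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    rest_angles = np.full(n, np.nan)
    rest_angles[1:-1] = math.pi
    fixed = np.zeros(n, dtype=bool)
    if fix_ends:
        fixed[[0, -1]] = True
    return TissueMesh(
        positions=pos,
        foundation=pos + rng.normal(0, 0.1, size=pos.shape),
        edges=edges,
        rest_lengths=np.full(n - 1, 0.9),
        rest_angles=rest_angles,
        faces=[],
        fixed=fixed,
    )


class TestEnergyGradientConsistency:
    """Forces must equal minus the finite-difference gradient of the energy."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_check_chain(self, seed):
        rng = np.random.default_rng(seed)
        mesh = _random_chain_mesh(rng)
        params = SimParams()
        conns = ConnectionSet(
            pairs=np.array([[0, 4], [1, 6]]),
            rest_lengths=np.array([10.0, 10.0]),  # strongly active
            stiffness=params.k_connect,
        )
        e0, forces = energy_and_forces(mesh, conns, params)
        h = 1e-6
        num = np.zeros_like(forces)
        for v in range(mesh.n_vertices):
            for c in range(2):
                pp = mesh.positions.copy()
                pp[v, c] += h
                ep = energy_and_forces(mesh, conns, params, positions=pp)[0]
                pp[v, c] -= 2 * h
                em = energy_and_forces(mesh, conns, params, positions=pp)[0]
                num[v, c] = -(ep - em) / (2 * h)
        scale = max(np.abs(forces).max(), 1e-12)
        assert np.abs(forces - num).max() / scale < 1e-6

    def test_gradient_check_with_junction_bending(self):
        rng = np.random.default_rng(3)
        # star: center 0 with 3 arms of 2 vertices each
        pos = np.array(
            [[0, 0], [1, 0.1], [2, 0], [-0.5, 0.9], [-1, 1.8], [-0.4, -1], [-0.9, -2]],
            dtype=float,
        )
        edges = np.array([[0, 1], [1, 2], [0, 3], [3, 4], [0, 5], [5, 6]])
        rest_angles = np.full(7, np.nan)
        rest_angles[0] = 2 * math.pi / 3
        rest_angles[[1, 3, 5]] = math.pi
        mesh = TissueMesh(
            positions=pos,
            foundation=pos + rng.normal(0, 0.05, pos.shape),
            edges=edges,
            rest_lengths=np.full(6, 0.8),
            rest_angles=rest_angles,
            faces=[],
            fixed=np.zeros(7, dtype=bool),
        )
        params = SimParams(junction_bending=True)
        _, forces = energy_and_forces(mesh, None, params)
        h = 1e-6
        num = np.zeros_like(forces)
        for v in range(7):
            for c in range(2):
                pp = pos.copy()
                pp[v, c] += h
                ep = energy_and_forces(mesh, None, params, positions=pp)[0]
                pp[v, c] -= 2 * h
                em = energy_and_forces(mesh, None, params, positions=pp)[0]
                num[v, c] = -(ep - em) / (2 * h)
        scale = max(np.abs(forces).max(), 1e-12)
        assert np.abs(forces - num).max() / scale < 1e-6

    def test_newtons_third_law_free_chain(self):
        """Internal stretch/bending forces sum to zero net force and torque."""
        rng = np.random.default_rng(4)
        mesh = _random_chain_mesh(rng, fix_ends=False)
        params = SimParams(k_foundation=0.0)
        _, forces = energy_and_forces(mesh, None, params)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-12)
        torque = np.sum(
            mesh.positions[:, 0] * forces[:, 1] - mesh.positions[:, 1] * forces[:, 0]
        )
        assert abs(torque) < 1e-12


class TestTotalEnergy:
    def test_rest_state_zero(self, nest16, default_params):
        assert total_energy(nest16, None, default_params) < 1e-12

    def test_stretched_edge_positive(self):
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        mesh = TissueMesh(
            positions=pos, foundation=pos.copy(),
            edges=np.array([[0, 1]]), rest_lengths=np.array([1.0]),
            rest_angles=np.full(2, np.nan), faces=[],
            fixed=np.array([True, False]),
        )
        e = total_energy(mesh, None, SimParams(k_foundation=0.0))
        assert e == pytest.approx(0.5 * 0.2 * 1.0 * 1.0)  # k/2 * l_rest * eps^2


class TestSolveEquilibrium:
    def test_already_at_equilibrium(self, nest16, default_params):
        relaxed, report = solve_equilibrium(nest16, None, default_params)
        assert report.converged
        assert report.n_iter == 0
        assert np.array_equal(relaxed.positions, nest16.positions)

    def test_single_spring_closed_form(self):
        # One free vertex on a stretched spring: settles at l_rest from anchor
        # (with the foundation off).
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        mesh = TissueMesh(
            positions=pos, foundation=pos.copy(),
            edges=np.array([[0, 1]]), rest_lengths=np.array([1.0]),
            rest_angles=np.full(2, np.nan), faces=[],
            fixed=np.array([True, False]),
        )
        params = SimParams(k_foundation=0.0, solver_tol=1e-10)
        relaxed, report = solve_equilibrium(mesh, None, params)
        assert report.converged
        assert np.hypot(*relaxed.positions[1]) == pytest.approx(1.0, abs=1e-6)

    def test_three_spring_star_symmetric(self):
        anchors = np.array([[1.0, 0.0], [-0.5, math.sqrt(3) / 2], [-0.5, -math.sqrt(3) / 2]])
        pos = np.vstack([anchors, [[0.3, 0.2]]])
        mesh = TissueMesh(
            positions=pos, foundation=pos.copy(),
            edges=np.array([[0, 3], [1, 3], [2, 3]]),
            rest_lengths=np.array([0.5, 0.5, 0.5]),
            rest_angles=np.full(4, np.nan), faces=[],
            fixed=np.array([True, True, True, False]),
        )
        params = SimParams(k_foundation=0.0, solver_tol=1e-10)
        relaxed, _ = solve_equilibrium(mesh, None, params)
        assert np.allclose(relaxed.positions[3], [0.0, 0.0], atol=1e-5)

    def test_energy_monotone_during_relaxation(self):
        rng = np.random.default_rng(7)
        mesh = _random_chain_mesh(rng, n=12)
        mesh.positions[1:-1] += rng.normal(0, 0.3, size=(10, 2))
        _, report = solve_equilibrium(mesh, None, SimParams())
        trace = np.array(report.energy_trace)
        assert np.all(np.diff(trace) <= 1e-12 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_fixed_vertices_never_move(self, nest16, default_params):
        mesh = nest16.copy()
        mesh.rest_lengths = mesh.rest_lengths * 1.1  # growth-like stress
        relaxed, _ = solve_equilibrium(mesh, None, default_params)
        assert np.array_equal(
            relaxed.positions[mesh.fixed], mesh.positions[mesh.fixed]
        )
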