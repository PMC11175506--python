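import math

import numpy as np
import pytest

from histomech import (
    SimParams,
    TissueMesh,
    boundary_self_crossings,
    grow_rest_lengths,
    place_connections,
    run_simulation,
    shrink_domain,
    simulation_step,
    update_foundation,
)


def _parallel_chains(gap, n=7, spacing=1.0):
    """Two horizontal chains separated vertically by ``gap``."""
    xs = np.arange(n) * spacing
    pos = np.vstack(
        [np.column_stack([xs, np.zeros(n)]), np.column_stack([xs, np.full(n, gap)])]
    )
    edges = np.vstack(
        [
            np.column_stack([np.arange(n - 1), np.arange(1, n)]),
            np.column_stack([np.arange(n, 2 * n - 1), np.arange(n + 1, 2 * n)]),
        ]
    )
    rest_angles = np.full(2 * n, np.nan)
    rest_angles[1 : n - 1] = math.pi
    rest_angles[n + 1 : 2 * n - 1] = math.pi
    fixed = np.zeros(2 * n, dtype=bool)
    fixed[[0, n - 1, n, 2 * n - 1]] = True
    return TissueMesh(
        positions=pos,
        foundation=pos.copy(),
        edges=edges,
        rest_lengths=np.full(len(edges), spacing),
        rest_angles=rest_angles,
        faces=[],
        fixed=fixed,
    )


class TestPlaceConnections:
    def test_far_chains_no_connections(self):
        mesh = _parallel_chains(3.0)
        assert len(place_connections(mesh, SimParams())) == 0

    def test_close_chains_connect_with_tangent_circle_rest(self):
        mesh = _parallel_chains(0.5)
        conns = place_connections(mesh, SimParams())
        assert len(conns) > 0
        # perpendicular closest pairs: alpha = pi/2, rest = Th_sub * sin = 1
        d = mesh.positions[conns.pairs[:, 1]] - mesh.positions[conns.pairs[:, 0]]
        perp = np.isclose(d[:, 0], 0.0)
        assert perp.any()
        assert np.allclose(conns.rest_lengths[perp], 1.0)
        assert np.all(conns.rest_lengths <= 1.0 + 1e-12)

    def test_single_short_chain_excluded_topologically(self):
        pos = np.array([[0, 0], [0.4, 0.0], [0.8, 0.0]], dtype=float)
        mesh = TissueMesh(
            positions=pos, foundation=pos.copy(),
            edges=np.array([[0, 1], [1, 2]]),
            rest_lengths=np.array([0.4, 0.4]),
            rest_angles=np.array([np.nan, math.pi, np.nan]),
            faces=[], fixed=np.zeros(3, dtype=bool),
        )
        assert len(place_connections(mesh, SimParams())) == 0

    def test_visibility_blocks_occluded_pairs(self):
        # three chains stacked: top and bottom see only the middle one
        mesh3 = _parallel_chains(0.6)
        n = 7
        xs = np.arange(n) * 1.0 + 0.3  # offset so crossings are proper
        extra = np.column_stack([xs, np.full(n, 1.2)])
        pos = np.vstack([mesh3.positions, extra])
        edges = np.vstack(
            [mesh3.edges, np.column_stack([np.arange(2 * n, 3 * n - 1), np.arange(2 * n + 1, 3 * n)])]
        )
        rest_angles = np.concatenate([mesh3.rest_angles, np.full(n, np.nan)])
        rest_angles[2 * n + 1 : 3 * n - 1] = math.pi
        fixed = np.concatenate([mesh3.fixed, np.zeros(n, dtype=bool)])
        fixed[[2 * n, 3 * n - 1]] = True
        mesh = TissueMesh(
            positions=pos, foundation=pos.copy(), edges=edges,
            rest_lengths=np.full(len(edges), 1.0), rest_angles=rest_angles,
            faces=[], fixed=fixed,
        )
        conns = place_connections(mesh, SimParams())
        rows = conns.pairs // n  # chain index of each endpoint
        occluded = np.abs(rows[:, 0] - rows[:, 1]) == 2
        # interior vertices of the outer chains cannot see each other through
        # the middle chain (chain ends may still connect around its corner)
        interior = ~(fixed[conns.pairs[:, 0]] | fixed[conns.pairs[:, 1]])
        assert not np.any(occluded & interior)
        assert len(conns) > 0


class TestGrowShrinkFoundation:
    def test_no_growth(self, nest16):
        out = grow_rest_lengths(nest16, SimParams(g_b=0.0))
        assert np.array_equal(out.rest_lengths, nest16.rest_lengths)

    def test_single_step_factor(self, nest16, default_params):
        out = grow_rest_lengths(nest16, default_params)
        assert np.allclose(out.rest_lengths, nest16.rest_lengths * 1.005)

    def test_compounding_exact(self, nest16, default_params):
        mesh = nest16
        for _ in range(100):
            mesh = grow_rest_lengths(mesh, default_params)
        expected = nest16.rest_lengths * 1.005**100
        assert np.allclose(mesh.rest_lengths, expected, rtol=1e-12)
        assert mesh.rest_lengths.sum() == pytest.approx(
            nest16.rest_lengths.sum() * 1.005**100, rel=1e-12
        )

    def test_shrink_identity_at_zero_rate(self, nest16):
        out = shrink_domain(nest16, SimParams(g_axis=0.0))
        assert np.array_equal(out.positions, nest16.positions)

    def test_shrink_scale_0997(self, nest16, default_params):
        out = shrink_domain(nest16, default_params)
        cx = 0.5 * (
            nest16.positions[nest16.fixed, 0].min()
            + nest16.positions[nest16.fixed, 0].max()
        )
        assert np.allclose(out.positions[:, 0] - cx, (nest16.positions[:, 0] - cx) * 0.997)

    def test_shrink_leaves_other_axis_bit_identical(self, nest16, default_params):
        out = shrink_domain(nest16, default_params)
        assert np.array_equal(out.positions[:, 1], nest16.positions[:, 1])
        assert np.array_equal(out.foundation[:, 1], nest16.foundation[:, 1])

    def test_shrink_rejects_runaway_rate(self, nest16):
        with pytest.raises(ValueError):
            shrink_domain(nest16, SimParams(g_axis=0.6, dt=2.0))

    def test_foundation_full_reset(self, nest16):
        mesh = nest16.copy()
        mesh.foundation = mesh.foundation + 1.0
        out = update_foundation(mesh, SimParams(dt_foundation=1.0))
        assert np.allclose(out.foundation, mesh.positions)

    def test_foundation_frozen(self, nest16):
        mesh = nest16.copy()
        mesh.foundation = mesh.foundation + 1.0
        out = update_foundation(mesh, SimParams(dt_foundation=0.0))
        assert np.array_equal(out.foundation, mesh.foundation)

    def test_foundation_closes_exact_fraction(self, nest16, default_params):
        mesh = nest16.copy()
        mesh.foundation = mesh.foundation + np.array([1.0, 0.0])
        out = update_foundation(mesh, default_params)
        gaps = np.hypot(*(out.positions - out.foundation).T)
        assert np.allclose(gaps, 0.99)


class TestSimulationStep:
    def test_fixpoint_without_growth_or_shrink(self, nest16):
        params = SimParams(g_b=0.0, g_axis=0.0)
        out, entry = simulation_step(nest16, params)
        assert np.allclose(out.positions, nest16.positions, atol=1e-9)
        assert entry.converged

    def test_step_log_fields(self, nest16, default_params):
        _, entry = simulation_step(nest16, default_params)
        assert entry.n_connections >= 0
        assert np.isfinite(entry.energy)
        assert 0 < entry.mean_circularity <= 1.0
        assert entry.template_width < 20.0


class TestRunSimulation:
    def test_zero_steps(self, nest16, default_params):
        snaps, log = run_simulation(nest16, default_params, 0)
        assert len(snaps) == 1
        assert len(log) == 0

    def test_determinism(self, nest16, default_params, tmp_path):
        _, log1 = run_simulation(nest16, default_params, 5)
        _, log2 = run_simulation(nest16, default_params, 5)
        assert log1.equals(log2)

    def test_short_run_circularity_decreases_no_crossing(self, nest16, default_params):
        snaps, log = run_simulation(nest16, default_params, 40)
        circ = log["mean_circularity"]
        assert circ.iloc[-1] < circ.iloc[0]
        assert boundary_self_crossings(snaps[-1]) == 0
        assert np.isfinite(log["energy"]).all()

    def test_snapshots_written(self, nest16, default_params, tmp_path):
        run_simulation(nest16, default_params, 4, snapshot_every=2, out_dir=tmp_path)
        assert (tmp_path / "run_log.csv").exists()
        assert (tmp_path / "snapshot_000000.txt").exists()
        assert (tmp_path / "snapshot_000004.txt").exists()
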