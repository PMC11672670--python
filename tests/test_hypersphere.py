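"""Hypersphere point distributions: energies, minimization, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.stats import ortho_group

from nmsphere import (
    DivergenceError,
    InvalidArgumentError,
    MinimizationConfig,
    PointSet,
    UnsupportedDimensionError,
    init_points,
    kissing_preset,
    mdist,
    minimize,
    minimize_mirrored,
    neighbor_counts,
    riesz_energy,
)


def hexagon() -> PointSet:
    ang = np.pi * np.arange(6) / 3.0
    return PointSet(dim=2, points=np.column_stack([np.cos(ang), np.sin(ang)]))


def icosahedron() -> PointSet:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    raw = []
    for a, b in [(1.0, phi), (-1.0, phi), (1.0, -phi), (-1.0, -phi)]:
        raw += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    pts = np.array(raw)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return PointSet(dim=3, points=pts)


def brute_force_mdist(points: np.ndarray) -> float:
    best = np.inf
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            best = min(best, float(np.linalg.norm(points[i] - points[j])))
    return best


def brute_force_energy(points: np.ndarray, alpha: float, s: float) -> float:
    total = 0.0
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            total += np.linalg.norm(points[i] - points[j]) ** (-s)
    return alpha * total


class TestInitPoints:
    def test_unit_norms_and_reproducibility(self):
        ps = init_points(6, 2, seed=1)
        assert ps.n == 6
        np.testing.assert_allclose(np.linalg.norm(ps.points, axis=1), 1.0, atol=1e-12)
        ps2 = init_points(6, 2, seed=1)
        np.testing.assert_array_equal(ps.points, ps2.points)

    def test_single_point_is_valid(self):
        ps = init_points(1, 3, seed=0)
        assert ps.n == 1

    def test_large_set_has_positive_mdist(self):
        ps = init_points(240, 8, seed=7)
        assert brute_force_mdist(ps.points) > 0

    @pytest.mark.parametrize("n,dim", [(0, 3), (-2, 3), (5, 1), (5, 0)])
    def test_invalid_arguments(self, n, dim):
        with pytest.raises(InvalidArgumentError):
            init_points(n, dim, seed=0)


class TestRieszEnergy:
    def test_antipodal_pair(self):
        ps = PointSet(dim=2, points=np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert riesz_energy(ps, alpha=1.0, s=1.0) == pytest.approx(0.5)

    def test_hexagon_matches_brute_force(self):
        ps = hexagon()
        expected = 6.0 / 1.0 + 6.0 / np.sqrt(3.0) + 3.0 / 2.0
        assert expected == pytest.approx(10.9641, abs=1e-4)
        assert riesz_energy(ps, 1.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert riesz_energy(ps, 1.0, 3.0) == pytest.approx(
            brute_force_energy(ps.points, 1.0, 3.0), rel=1e-12
        )

    def test_linear_in_alpha(self):
        ps = init_points(10, 4, seed=3)
        assert riesz_energy(ps, 2.0, 2.0) == pytest.approx(
            2.0 * riesz_energy(ps, 1.0, 2.0), rel=1e-12
        )

    def test_coincident_points_raise_naming_pair(self):
        pts = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        ps = PointSet(dim=2, points=pts)
        with pytest.raises(DivergenceError, match="0 and 2"):
            riesz_energy(ps, 1.0, 1.0)


class TestMdistAndNeighbors:
    def test_hexagon_mdist_is_one(self):
        assert mdist(hexagon()) == pytest.approx(1.0, abs=1e-12)

    def test_icosahedron_closed_form_and_scan(self):
        ps = icosahedron()
        closed = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))
        assert closed == pytest.approx(1.05146, abs=1e-5)
        assert mdist(ps) == pytest.approx(closed, rel=1e-12)
        assert mdist(ps) == pytest.approx(brute_force_mdist(ps.points), rel=1e-12)

    def test_duplicate_point_gives_zero(self):
        pts = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert mdist(PointSet(dim=2, points=pts)) == 0.0

    def test_mdist_needs_two_points(self):
        with pytest.raises(InvalidArgumentError):
            mdist(init_points(1, 2, seed=0))

    def test_hexagon_neighbor_count(self):
        assert np.all(neighbor_counts(hexagon()) == 2)

    def test_tetrahedron_all_equidistant(self):
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
        assert np.all(neighbor_counts(PointSet(dim=3, points=pts)) == 3)

    def test_neighbor_counts_match_scan(self):
        ps = init_points(20, 3, seed=5)
        counts = neighbor_counts(ps, rel_tol=0.05)
        m = brute_force_mdist(ps.points)
        for i in range(ps.n):
            expected = sum(
                1
                for j in range(ps.n)
                if j != i
                and np.linalg.norm(ps.points[i] - ps.points[j]) <= m * 1.05
            )
            assert counts[i] == expected


class TestKissingPreset:
    @pytest.mark.parametrize(
        "dim,expected", [(2, 6), (3, 12), (4, 24), (5, 40), (6, 72), (7, 126), (8, 240)]
    )
    def test_preset_values(self, dim, expected):
        assert kissing_preset(dim) == expected

    @pytest.mark.parametrize("dim", [1, 9, 0])
    def test_unsupported_dimension(self, dim):
        with pytest.raises(UnsupportedDimensionError):
            kissing_preset(dim)


class TestMinimize:
    def test_two_points_become_antipodal(self):
        ps, trace = minimize(init_points(2, 2, seed=9), MinimizationConfig(seed=9))
        assert trace.final_mdist == pytest.approx(2.0, abs=1e-6)

    def test_four_points_form_tetrahedron(self):
        ps, trace = minimize(init_points(4, 3, seed=1), MinimizationConfig(seed=1))
        assert trace.final_mdist == pytest.approx(np.sqrt(8.0 / 3.0), abs=1e-6)
        assert trace.final_mdist == pytest.approx(brute_force_mdist(ps.points), rel=1e-12)

    @pytest.mark.parametrize("n", [3, 6, 9, 12])
    def test_circle_optimum_attained(self, n):
        ps, trace = minimize(init_points(n, 2, seed=n), MinimizationConfig(seed=n))
        optimum = 2.0 * np.sin(np.pi / n)
        assert trace.final_mdist <= optimum + 1e-9
        assert trace.final_mdist == pytest.approx(optimum, abs=1e-6)

    def test_unit_norm_preserved_and_trace_invariants(self):
        ps, trace = minimize(init_points(10, 3, seed=4), MinimizationConfig(seed=4))
        np.testing.assert_allclose(np.linalg.norm(ps.points, axis=1), 1.0, atol=1e-12)
        records = trace.records
        assert records[-1]["mdist"] >= records[0]["mdist"]
        # log-energy never increases within a cycle across accepted steps
        for cycle in {r["cycle"] for r in records}:
            les = [r["log_energy"] for r in records if r["cycle"] == cycle]
            assert all(b <= a + 1e-12 for a, b in zip(les, les[1:]))

    def test_restarts_return_best(self):
        cfg = MinimizationConfig(seed=42)
        _, tr1 = minimize(init_points(24, 4, seed=42), cfg, restarts=1)
        _, tr5 = minimize(init_points(24, 4, seed=42), cfg, restarts=5)
        assert tr5.final_mdist >= tr1.final_mdist - 1e-12


class TestMinimizeMirrored:
    def test_output_closed_under_negation(self):
        ps, _ = minimize_mirrored(6, 3, MinimizationConfig(seed=2))
        n = ps.n // 2
        np.testing.assert_array_equal(ps.points[:n], -ps.points[n:])
        assert ps.is_mirrored()

    def test_icosahedron_recovered(self):
        ps, trace = minimize_mirrored(6, 3, MinimizationConfig(seed=5))
        assert trace.final_mdist == pytest.approx(1.0514622, abs=2e-3)

    def test_d4_24_cell(self):
        ps, trace = minimize_mirrored(12, 4, MinimizationConfig(seed=7))
        assert trace.final_mdist == pytest.approx(1.0, abs=1e-3)
        assert np.all(neighbor_counts(ps) == 8)

    def test_mirrored_reliability_d4(self):
        ok = sum(
            minimize_mirrored(12, 4, MinimizationConfig(seed=s))[1].final_mdist >= 0.999
            for s in range(20)
        )
        assert ok == 20

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            minimize_mirrored(0, 3, MinimizationConfig())
        with pytest.raises(InvalidArgumentError):
            minimize_mirrored(4, 1, MinimizationConfig())


class TestRotationInvariance:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st_.integers(0, 10_000))
    def test_energy_and_mdist_invariant(self, seed):
        ps = init_points(8, 3, seed=seed)
        rng = np.random.default_rng(seed)
        q = ortho_group.rvs(3, random_state=rng)
        rotated = PointSet(dim=3, points=ps.points @ q.T)
        assert riesz_energy(rotated, 1.0, 2.0) == pytest.approx(
            riesz_energy(ps, 1.0, 2.0), abs=1e-10
        )
        assert mdist(rotated) == pytest.approx(mdist(ps), abs=1e-10)


class TestConfigAndSerialization:
    def test_schedule_must_increase(self):
        with pytest.raises(InvalidArgumentError):
            MinimizationConfig(s_schedule=(1.0, 4.0, 2.0))
        with pytest.raises(InvalidArgumentError):
            MinimizationConfig(grad_tol=-1.0)
        with pytest.raises(InvalidArgumentError):
            MinimizationConfig(max_cycles=0)

    def test_default_schedule_doubles(self):
        cfg = MinimizationConfig(max_cycles=4)
        assert cfg.resolved_schedule() == (1.0, 2.0, 4.0, 8.0)

    def test_pointset_csv_round_trip(self, tmp_path):
        ps = init_points(5, 3, seed=8)
        path = tmp_path / "points.csv"
        ps.to_csv(path)
        back = PointSet.from_csv(path)
        assert back.dim == 3
        np.testing.assert_allclose(back.points, ps.points, atol=1e-12)

    def test_trace_csv_columns(self, tmp_path):
        _, trace = minimize(init_points(4, 2, seed=1), MinimizationConfig(seed=1))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "cycle,iter,s,energy,mdist"
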