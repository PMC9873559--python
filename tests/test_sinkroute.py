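from dataclasses import replace

import numpy as np
import pytest

import oracles
from seatea import grids, production, sinkroute
from seatea.grids import EnvLayers, OceanGrid, YieldEnsemble
from seatea.sinkroute import optimal_sink_assignment, weighted_distance_transform


def _open_row(n=10):
    """Single row of open water, non-global (no longitude wrap)."""
    return OceanGrid(np.array([0.0, 1.0]), np.linspace(0, n, n + 1), np.zeros((1, n), bool))


def _toy_world(n=6, f_lo=0.2, f_hi=0.9, barrier=True):
    """6x6 toy: two sequestration-fraction plateaus and an L-shaped barrier."""
    land = np.zeros((n, n), bool)
    if barrier:
        land[1:4, 3] = True
        land[3, 3:5] = True
    grid = OceanGrid(np.linspace(0, n, n + 1), np.linspace(0, n, n + 1), land)
    f_seq = np.full((n, n), f_lo)
    f_seq[:, 4:] = f_hi
    port = np.zeros((n, n), bool)
    port[0, 0] = True
    d_port = weighted_distance_transform(grid, port).distance
    ocean = grid.ocean_mask
    nanland = lambda a: np.where(ocean, a, np.nan)
    env = EnvLayers(
        depth=nanland(np.full((n, n), 1000.0)),
        swh=nanland(np.full((n, n), 2.0)),
        d_port=nanland(np.where(np.isfinite(d_port), d_port, np.nan)),
        f_seq=nanland(f_seq),
        port_mask=port,
        shipping_mask=np.zeros((n, n), bool),
        mpa_mask=np.zeros((n, n), bool),
    )
    mults = np.array([0.5, 0.8, 1.0, 1.2, 1.5])
    s = 2000.0 * mults[None, None, :, None, None] * np.ones((1, 2, 5, n, n))
    s = np.where(ocean[None, None, None], s, np.nan)
    yields = YieldEnsemble(
        s_dw=s,
        type_names=("toy",),
        scenarios=("ambient", "limited"),
        percentiles=(5, 25, 50, 75, 95),
        n_harv=np.array([4.0]),
        line_spacing_m=np.array([1.0]),
        preferred_type=np.where(ocean, 0, -1),
    )
    return grid, env, yields


class TestWeightedDistanceTransform:
    def test_source_cell_is_zero(self):
        g = _open_row()
        src = np.zeros((1, 10), bool)
        src[0, 0] = True
        d = weighted_distance_transform(g, src).distance
        assert d[0, 0] == 0.0

    def test_open_row_accumulates_cell_pitches(self):
        g = _open_row()
        src = np.zeros((1, 10), bool)
        src[0, 0] = True
        d = weighted_distance_transform(g, src).distance
        lat, lon = g.lat_centers, g.lon_centers
        pitch = grids.haversine_km(lat[0], lon[0], lat[0], lon[1])
        np.testing.assert_allclose(d[0], pitch * np.arange(10), rtol=1e-12)

    def test_l_shaped_barrier_matches_dijkstra_oracle(self):
        land = np.zeros((12, 12), bool)
        land[2:9, 5] = True
        land[8, 5:10] = True
        g = OceanGrid(np.linspace(0, 12, 13), np.linspace(0, 12, 13), land)
        src = np.zeros((12, 12), bool)
        src[0, 0] = True
        d = weighted_distance_transform(g, src).distance
        oracle = oracles.dijkstra_distances(g, src)
        np.testing.assert_allclose(d, oracle, rtol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("trial", range(10))
    def test_random_grids_match_dijkstra_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_lat = int(rng.integers(6, 21))
        n_lon = int(rng.integers(6, 21))
        land = rng.random((n_lat, n_lon)) < 0.3
        if land.all():
            land[0, 0] = False
        wrap = bool(trial % 2)
        lon_edges = np.linspace(-180, 180, n_lon + 1) if wrap else np.linspace(0, n_lon, n_lon + 1)
        g = OceanGrid(np.linspace(-40, 40, n_lat + 1), lon_edges, land)
        ocean_idx = np.argwhere(g.ocean_mask)
        src = np.zeros((n_lat, n_lon), bool)
        for k in rng.choice(len(ocean_idx), size=min(3, len(ocean_idx)), replace=False):
            src[tuple(ocean_idx[k])] = True
        d = weighted_distance_transform(g, src).distance
        oracle = oracles.dijkstra_distances(g, src)
        np.testing.assert_allclose(d, oracle, rtol=1e-9, equal_nan=True)

    def test_empty_source_set_rejected(self):
        g = _open_row()
        with pytest.raises(ValueError, match="empty source"):
            weighted_distance_transform(g, np.zeros((1, 10), bool))


def brute_force_assignment(grid, env, yields, mean_sample, q_step=0.01):
    """Exhaustive (cell x q) enumeration with networkx distances."""
    ocean = grid.ocean_mask
    s_dw = yields.preferred_map("ambient", 50)
    p_sline = yields.preferred_p_sline()
    n_harv = yields.preferred_n_harv()
    f_snap = np.floor((env.f_seq + 1e-9) / q_step) * q_step
    best = {}
    for k in range(1, int(round(1 / q_step)) + 1):
        q = round(k * q_step, 9)
        src = ocean & (np.nan_to_num(f_snap, nan=-1) >= q - 1e-9)
        if not src.any():
            continue
        dist = oracles.dijkstra_distances(grid, src)
        for i, j in np.argwhere(ocean):
            d = dist[i, j]
            if not np.isfinite(d):
                continue
            cost = oracles.one_shot_sinking(
                mean_sample,
                s_dw[i, j],
                env.depth[i, j],
                env.swh[i, j],
                env.d_port[i, j],
                d,
                q,
                p_sline[i, j],
                n_harv[i, j],
            )
            if np.isnan(cost):
                continue
            cur = best.get((i, j))
            if cur is None or cost < cur[0] - 1e-9 or (
                abs(cost - cur[0]) <= 1e-9
                and (d < cur[1] - 1e-9 or (abs(d - cur[1]) <= 1e-9 and q > cur[2]))
            ):
                best[(i, j)] = (cost, d, q)
    return best


class TestOptimalSinkAssignment:
    def test_matches_exhaustive_enumeration_on_toy(self, mean_sample):
        grid, env, yields = _toy_world()
        asg = optimal_sink_assignment(grid, env, yields, mean_sample)
        best = brute_force_assignment(grid, env, yields, mean_sample)
        assert best  # oracle found candidates
        for (i, j), (_, d, q) in best.items():
            assert asg.q_assigned[i, j] == pytest.approx(q, abs=1e-9), (i, j)
            assert asg.d_sink[i, j] == pytest.approx(d, rel=1e-9, abs=1e-6), (i, j)

    def test_uniform_fraction_sinks_in_place(self, mean_sample):
        grid, env, yields = _toy_world(f_lo=0.5, f_hi=0.5, barrier=False)
        asg = optimal_sink_assignment(grid, env, yields, mean_sample)
        ocean = grid.ocean_mask
        assert (asg.d_sink[ocean] == 0).all()
        np.testing.assert_allclose(asg.q_assigned[ocean], 0.5)

    def test_free_transport_targets_global_maximum_fraction(self, mean_sample):
        grid, env, yields = _toy_world(barrier=False)
        free = replace(mean_sample, c_transbase=0.0, e_transbase=0.0)
        asg = optimal_sink_assignment(grid, env, yields, free)
        ocean = grid.ocean_mask
        np.testing.assert_allclose(asg.q_assigned[ocean], 0.9)

    def test_never_worse_than_sinking_in_place(self, world, mean_sample):
        from seatea import sinking as sk

        grid, env, yields = world
        asg = optimal_sink_assignment(grid, env, yields, mean_sample)
        s_dw = yields.preferred_map("ambient", 50)
        layout = production.FarmLayout(
            yields.preferred_p_sline(), s_dw, yields.preferred_n_harv()
        )
        prod = production.evaluate_production(
            mean_sample, layout, env.depth, env.swh, env.d_port
        )
        chosen = sk.evaluate_sinking(
            mean_sample, s_dw, asg.d_sink, env.d_port, asg.q_assigned,
            prod.c_prod, prod.e_prod,
        )
        in_place = sk.evaluate_sinking(
            mean_sample, s_dw, np.zeros_like(s_dw), env.d_port,
            sinkroute.snap_fraction_down(env.f_seq), prod.c_prod, prod.e_prod,
        )
        both = chosen.valid_mask & in_place.valid_mask
        tol = 1e-9 * np.abs(in_place.c_perton[both]) + 1e-6
        assert (chosen.c_perton[both] <= in_place.c_perton[both] + tol).all()

    def test_deterministic(self, mean_sample):
        grid, env, yields = _toy_world()
        a = optimal_sink_assignment(grid, env, yields, mean_sample)
        b = optimal_sink_assignment(grid, env, yields, mean_sample)
        np.testing.assert_array_equal(a.d_sink, b.d_sink)
        np.testing.assert_array_equal(a.q_assigned, b.q_assigned)
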