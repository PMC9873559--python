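"""Over-water shortest paths and cost-optimal sinking-site assignment.

The sequestration fraction of sunk carbon varies in space, so the cheapest
place to sink a harvest is not necessarily the farm cell. The weighted
distance transform computes, for every ocean cell, the shortest over-water
distance to a set of target cells on an 8-connected grid with great-circle
edge weights (land is impassable). The sink assignment sweeps candidate
sequestration fractions q = 0.01 ... 1.00, computes the distance to the
nearest cell offering at least q, evaluates the full sinking cost chain
with a fixed mean parameter set, and keeps the q that minimizes the cost
per ton of CO2 removed. Sinking in place is always a candidate because the
local fraction is snapped down onto the q grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from . import production, sinking
from .grids import EnvLayers, OceanGrid, YieldEnsemble, haversine_km
from .params import Constants, EconomicSample


@dataclass
class DistanceField:
    """Shortest over-water distances (km) from a set of source cells.

    ``distance`` is 0 at sources, +inf on ocean cells disconnected from all
    sources, and NaN on land.
    """

    distance: np.ndarray
    n_sources: int


@dataclass
class SinkAssignment:
    """Per-cell optimal sinking distance and assigned sequestration fraction."""

    d_sink: np.ndarray  # km; 0 = sink in place
    q_assigned: np.ndarray  # sequestration fraction at the sink site
    in_place: np.ndarray  # bool, sink-in-place cells
    has_candidate: np.ndarray  # bool, False where no q gave positive removal


class OceanGraph:
    """8-connected graph over ocean cells with great-circle edge weights.

    Built once per land mask; reused across many multi-source transforms.
    Longitude wraps when the grid spans 360 degrees.
    """

    def __init__(self, grid: OceanGrid, land_mask: np.ndarray | None = None):
        self.grid = grid
        land = grid.land_mask if land_mask is None else np.asarray(land_mask, bool)
        self.ocean = ~land
        shape = land.shape
        self.node_index = np.full(shape, -1, dtype=np.int64)
        self.n_nodes = int(self.ocean.sum())
        self.node_index[self.ocean] = np.arange(self.n_nodes)

        lat_c = grid.lat_centers
        lon_c = grid.lon_centers
        n_lat, n_lon = shape
        I, J = np.indices(shape)
        rows, cols, weights = [], [], []
        # four forward offsets; symmetry gives the full 8-neighbourhood
        for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
            I2, J2 = I + di, J + dj
            inside = (I2 >= 0) & (I2 < n_lat)
            if grid.wraps_lon:
                J2 = J2 % n_lon
            else:
                inside &= (J2 >= 0) & (J2 < n_lon)
            J2c = np.clip(J2, 0, n_lon - 1)
            I2c = np.clip(I2, 0, n_lat - 1)
            ok = inside & self.ocean & self.ocean[I2c, J2c]
            if not ok.any():
                continue
            i1, j1 = I[ok], J[ok]
            i2, j2 = I2c[ok], J2c[ok]
            w = haversine_km(lat_c[i1], lon_c[j1], lat_c[i2], lon_c[j2])
            rows.append(self.node_index[i1, j1])
            cols.append(self.node_index[i2, j2])
            weights.append(w)
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
            w = np.concatenate(weights)
            self.csr = coo_matrix(
                (np.concatenate([w, w]), (np.concatenate([r, c]), np.concatenate([c, r]))),
                shape=(self.n_nodes, self.n_nodes),
            ).tocsr()
        else:
            self.csr = coo_matrix((self.n_nodes, self.n_nodes)).tocsr()

    def distances(self, source_mask: np.ndarray) -> np.ndarray:
        """Multi-source shortest distance field; NaN on land, inf unreachable."""
        src = self.node_index[np.asarray(source_mask, bool) & self.ocean]
        if src.size == 0:
            raise ValueError("empty source set")
        d = dijkstra(self.csr, directed=False, indices=src, min_only=True)
        out = np.full(self.ocean.shape, np.nan)
        out[self.ocean] = d
        return out


def weighted_distance_transform(
    grid: OceanGrid,
    source_mask: np.ndarray,
    land_mask: np.ndarray | None = None,
) -> DistanceField:
    """Shortest ocean distance from every cell to the nearest source cell."""
    graph = OceanGraph(grid, land_mask)
    distance = graph.distances(source_mask)
    return DistanceField(distance=distance, n_sources=int(np.count_nonzero(source_mask)))


def snap_fraction_down(f_seq: np.ndarray, q_step: float = 0.01) -> np.ndarray:
    """Snap local sequestration fractions down onto the candidate q grid."""
    steps = np.floor((np.asarray(f_seq, dtype=float) + 1e-9) / q_step)
    return np.round(steps * q_step, 9)


def optimal_sink_assignment(
    grid: OceanGrid,
    env: EnvLayers,
    yields: YieldEnsemble,
    mean_sample: EconomicSample,
    scenario: str = "ambient",
    q_step: float = 0.01,
    constants: Constants = Constants(),
    graph: OceanGraph | None = None,
) -> SinkAssignment:
    """Choose, per cell, the sequestration fraction and distance to sink at.

    For each candidate fraction q the source set is every ocean cell whose
    (snapped) local fraction reaches q; the cost per tCO2 removed is then
    evaluated with d_sink equal to the distance to that set and k_fseq = q,
    using the median yield map and the mean parameter set. Ties are broken
    toward smaller d_sink, then larger q. Cells for which no candidate
    yields positive net removal fall back to sinking in place.
    """
    if graph is None:
        graph = OceanGraph(grid)
    ocean = grid.ocean_mask

    s_dw = yields.preferred_map(scenario, 50)
    layout = production.FarmLayout(
        p_sline=yields.preferred_p_sline(),
        s_dw=s_dw,
        n_harv=yields.preferred_n_harv(),
    )
    prod = production.evaluate_production(
        mean_sample, layout, env.depth, env.swh, env.d_port, constants
    )

    f_snap = snap_fraction_down(env.f_seq, q_step)
    n_q = int(round(1.0 / q_step))
    qs = np.round(np.arange(1, n_q + 1) * q_step, 9)

    shape = ocean.shape
    best_cost = np.full(shape, np.inf)
    best_d = np.full(shape, np.inf)
    best_q = np.full(shape, np.nan)

    for q in qs:
        src = ocean & (f_snap >= q - 1e-9)
        if not src.any():
            continue  # q exceeds every local fraction: no viable target
        dist = graph.distances(src)
        res = sinking.evaluate_sinking(
            mean_sample,
            s_dw,
            d_sink=np.where(np.isfinite(dist), dist, np.nan),
            d_port=env.d_port,
            k_fseq=np.full(shape, q),
            c_prod=prod.c_prod,
            e_prod=prod.e_prod,
            constants=constants,
        )
        cost = np.where(res.valid_mask & np.isfinite(dist), res.c_perton, np.inf)
        better = cost < best_cost
        tie = np.isfinite(cost) & np.isclose(cost, best_cost, rtol=1e-12, atol=1e-9)
        tie_break = tie & (
            (dist < best_d - 1e-9)
            | (np.isclose(dist, best_d, rtol=1e-12, atol=1e-9) & (q > np.nan_to_num(best_q, nan=-1.0)))
        )
        upd = (better | tie_break) & ocean
        best_cost[upd] = cost[upd]
        best_d[upd] = dist[upd]
        best_q[upd] = q

    has_candidate = np.isfinite(best_cost) & ocean
    # fall back to sinking in place where nothing produced positive removal
    d_sink = np.where(has_candidate, best_d, 0.0)
    q_assigned = np.where(has_candidate, best_q, f_snap)
    d_sink = np.where(ocean, d_sink, np.nan)
    q_assigned = np.where(ocean, q_assigned, np.nan)
    in_place = ocean & (d_sink == 0.0)
    return SinkAssignment(
        d_sink=d_sink,
        q_assigned=q_assigned,
        in_place=in_place,
        has_candidate=has_candidate,
    )
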