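"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own composition: shortest paths go
through networkx, quantiles through explicit nearest-rank arithmetic, and
the cost chains are written as monolithic scalar formulas.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from seatea.grids import OceanGrid, haversine_km

CO2_PER_C = 44.0 / 12.0
CARBON_FRACTION = 0.30
WET_DRY = 10.0


def grid_graph(grid: OceanGrid) -> nx.Graph:
    """8-connected ocean graph with great-circle weights, built by hand.

    Shares the package's haversine so edge weights are identical and the
    path-finding algorithms can be compared to float precision.
    """
    G = nx.Graph()
    lat, lon = grid.lat_centers, grid.lon_centers
    n_lat, n_lon = grid.n_lat, grid.n_lon
    ocean = grid.ocean_mask
    for i in range(n_lat):
        for j in range(n_lon):
            if ocean[i, j]:
                G.add_node((i, j))
    for i in range(n_lat):
        for j in range(n_lon):
            if not ocean[i, j]:
                continue
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    i2, j2 = i + di, j + dj
                    if not 0 <= i2 < n_lat:
                        continue
                    if grid.wraps_lon:
                        j2 %= n_lon
                    elif not 0 <= j2 < n_lon:
                        continue
                    if ocean[i2, j2]:
                        w = float(haversine_km(lat[i], lon[j], lat[i2], lon[j2]))
                        G.add_edge((i, j), (i2, j2), weight=w)
    return G


def dijkstra_distances(grid: OceanGrid, source_mask: np.ndarray) -> np.ndarray:
    """Multi-source shortest over-water distances via networkx."""
    G = grid_graph(grid)
    sources = [tuple(ij) for ij in np.argwhere(np.asarray(source_mask, bool))]
    lengths = nx.multi_source_dijkstra_path_length(G, sources)
    out = np.full((grid.n_lat, grid.n_lon), np.inf)
    for (i, j), d in lengths.items():
        out[i, j] = d
    out[grid.land_mask] = np.nan
    return out


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Inverse-CDF (nearest-rank) percentile of finite values."""
    vals = np.sort(values[np.isfinite(values)])
    if vals.size == 0:
        return np.nan
    k = max(1, math.ceil(q / 100.0 * vals.size))
    return float(vals[k - 1])


def one_shot_sinking(p, s_dw, depth, swh, d_port, d_sink, k_fseq, p_sline, n_harv):
    """$ per tCO2 removed, written as one monolithic formula."""
    c_prod = (
        p.c_capbase * (1 + p.k_d * (depth > 500) + p.k_w * (swh > 3))
        + p.c_slbase * p_sline
        + p.c_ins + p.c_lic + p.c_lab + p.c_opbase
        + p.c_harvbase * n_harv
        + p.c_transbase * p.m_eq * d_port
    ) / s_dw
    e_prod = (
        p.e_transbase * p.m_eq * d_port
        + 2 * d_port * p.e_mntbase * p.n_mnt / p.a_mnt
        + p.e_mntbase * p.d_mnt
    ) / s_dw
    v_sink = (
        p.v_cprice
        - (
            p.c_transbase * d_sink * WET_DRY * s_dw
            + p.c_transbase * (2 * d_sink + d_port) * p.m_eq
        )
    ) / s_dw
    e_rem = (
        p.k_atm * k_fseq * CARBON_FRACTION * CO2_PER_C * s_dw
        - (
            p.e_transbase * d_sink * WET_DRY * s_dw
            + p.e_transbase * (2 * d_sink + d_port) * p.m_eq
        )
    ) / s_dw
    e_net = e_rem - e_prod
    if e_net <= 0:
        return math.nan
    return (c_prod - v_sink) / e_net


def one_shot_product(p, category, s_dw, depth, swh, d_port, p_sline, n_harv):
    """$ per tCO2-eq avoided, written as one monolithic formula."""
    pp = p.products[category]
    c_prod = (
        p.c_capbase * (1 + p.k_d * (depth > 500) + p.k_w * (swh > 3))
        + p.c_slbase * p_sline
        + p.c_ins + p.c_lic + p.c_lab + p.c_opbase
        + p.c_harvbase * n_harv
        + p.c_transbase * p.m_eq * d_port
    ) / s_dw
    e_prod = (
        p.e_transbase * p.m_eq * d_port
        + 2 * d_port * p.e_mntbase * p.n_mnt / p.a_mnt
        + p.e_mntbase * p.d_mnt
    ) / s_dw
    v_product = pp.v_mkt - (
        p.c_transbase * d_port * (WET_DRY * s_dw + p.m_eq) / s_dw + pp.c_conv
    )
    e_av = pp.e_subprod - (
        p.e_transbase * d_port * (WET_DRY * s_dw + p.m_eq) / s_dw + pp.e_conv
    )
    e_net = e_av - e_prod
    if e_net <= 0:
        return math.nan
    return (c_prod - v_product) / e_net


def single_cell_world(
    s_dw=2000.0,
    depth=1200.0,
    swh=2.0,
    d_port=300.0,
    d_sink=80.0,
    f_seq=0.6,
    n_harv=4.0,
    spacing_m=0.5,
):
    """One-cell grid/env/yields/assignment for composed-pipeline checks."""
    from seatea import grids, sinkroute

    ones = np.ones((1, 1))
    grid = grids.OceanGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.zeros((1, 1), bool))
    env = grids.EnvLayers(
        depth=depth * ones,
        swh=swh * ones,
        d_port=d_port * ones,
        f_seq=f_seq * ones,
        port_mask=np.zeros((1, 1), bool),
        shipping_mask=np.zeros((1, 1), bool),
        mpa_mask=np.zeros((1, 1), bool),
    )
    mults = np.array([0.5, 0.8, 1.0, 1.2, 1.5])
    s = s_dw * mults[None, None, :, None, None] * np.ones((1, 2, 5, 1, 1))
    s[:, 1] *= 0.7  # limited scenario below ambient
    yields = grids.YieldEnsemble(
        s_dw=s,
        type_names=("toy",),
        scenarios=("ambient", "limited"),
        percentiles=(5, 25, 50, 75, 95),
        n_harv=np.array([n_harv]),
        line_spacing_m=np.array([spacing_m]),
        preferred_type=np.zeros((1, 1), int),
    )
    assignment = sinkroute.SinkAssignment(
        d_sink=d_sink * ones,
        q_assigned=f_seq * ones,
        in_place=(d_sink == 0) * np.ones((1, 1), bool),
        has_candidate=np.ones((1, 1), bool),
    )
    return grid, env, yields, assignment
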