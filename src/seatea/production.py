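"""Farm-gate seaweed production costs and emissions per ton dry weight.

Annualized costs per km^2 of farm comprise capital (with multipliers for
deep water and high waves), seeded line, operating, harvest, and equipment
transport; dividing by annual harvest yield gives $ per tDW. Emissions per
km^2 come from equipment transport and maintenance-vessel trips. All
functions are vectorized over grid fields and mask cells with zero yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Constants, EconomicSample


@dataclass
class FarmLayout:
    """Per-cell farming geometry of the preferred seaweed type."""

    p_sline: np.ndarray  # seeded-line length per km^2 (m km^-2)
    s_dw: np.ndarray  # annual harvest, tDW km^-2 yr^-1
    n_harv: np.ndarray  # harvests per year


@dataclass
class ProductionResult:
    """Per-cell production cost/emission fields ($ km^-2 yr^-1 unless noted)."""

    c_cap: np.ndarray
    c_sl: np.ndarray
    c_op: np.ndarray
    c_harv: np.ndarray
    c_eqtrans: np.ndarray
    c_prod: np.ndarray  # $ tDW^-1, NaN where s_dw == 0
    e_eqtrans: np.ndarray  # tCO2 km^-2 yr^-1
    e_mnt: np.ndarray
    e_prod: np.ndarray  # tCO2 tDW^-1, NaN where s_dw == 0
    shares: dict[str, np.ndarray]  # component shares of total cost, sum to 1


def capital_cost(
    sample: EconomicSample,
    layout: FarmLayout,
    depth: np.ndarray,
    swh: np.ndarray,
    constants: Constants = Constants(),
) -> np.ndarray:
    """Annualized capital cost per km^2, including seeded line.

    The depth and wave multipliers k_d/k_w scale the base capital cost only
    on cells strictly deeper than 500 m or wavier than 3 m significant wave
    height.
    """
    depth = np.asarray(depth, dtype=float)
    swh = np.asarray(swh, dtype=float)
    if np.any(depth[np.isfinite(depth)] < 0) or np.any(swh[np.isfinite(swh)] < 0):
        raise ValueError("depth and significant wave height must be non-negative")
    mult = sample.k_d * (depth > constants.depth_threshold_m) + sample.k_w * (
        swh > constants.swh_threshold_m
    )
    c_sl = sample.c_slbase * layout.p_sline
    return sample.c_capbase * (1.0 + mult) + c_sl


def seeded_line_cost(sample: EconomicSample, layout: FarmLayout) -> np.ndarray:
    return sample.c_slbase * layout.p_sline


def annual_costs(
    sample: EconomicSample, layout: FarmLayout, d_port: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Operating, harvest and one-way equipment-transport costs per km^2."""
    if np.any(np.asarray(layout.n_harv)[np.isfinite(layout.n_harv)] < 0):
        raise ValueError("n_harv must be non-negative")
    c_op = sample.c_ins + sample.c_lic + sample.c_lab + sample.c_opbase
    c_op = np.broadcast_to(np.asarray(c_op, dtype=float), np.shape(d_port)).copy()
    c_harv = sample.c_harvbase * np.asarray(layout.n_harv, dtype=float)
    c_eqtrans = sample.c_transbase * sample.m_eq * np.asarray(d_port, dtype=float)
    return c_op, c_harv, c_eqtrans


def production_cost(
    c_cap: np.ndarray,
    c_op: np.ndarray,
    c_harv: np.ndarray,
    c_eqtrans: np.ndarray,
    s_dw: np.ndarray,
) -> np.ndarray:
    """Total production cost in $ per tDW; NaN where nothing is harvested."""
    total = c_cap + c_op + c_harv + c_eqtrans
    s_dw = np.asarray(s_dw, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s_dw > 0, total / s_dw, np.nan)


def production_emissions(
    sample: EconomicSample, d_port: np.ndarray, s_dw: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equipment-transport and maintenance emissions; e_prod in tCO2/tDW.

    Maintenance emissions combine round trips from port (2 * d_port per
    trip, n_mnt/a_mnt trips per km^2) and the fixed distance d_mnt travelled
    around each km^2 of farm.
    """
    d_port = np.asarray(d_port, dtype=float)
    s_dw = np.asarray(s_dw, dtype=float)
    e_eqtrans = sample.e_transbase * sample.m_eq * d_port
    e_mnt = (2.0 * d_port) * sample.e_mntbase * (sample.n_mnt / sample.a_mnt) + (
        sample.e_mntbase * sample.d_mnt
    )
    e_mnt = np.broadcast_to(np.asarray(e_mnt, dtype=float), d_port.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_prod = np.where(s_dw > 0, (e_eqtrans + e_mnt) / s_dw, np.nan)
    return e_eqtrans, e_mnt, e_prod


def evaluate_production(
    sample: EconomicSample,
    layout: FarmLayout,
    depth: np.ndarray,
    swh: np.ndarray,
    d_port: np.ndarray,
    constants: Constants = Constants(),
) -> ProductionResult:
    """Full production chain on grid fields, with component cost shares."""
    c_sl = seeded_line_cost(sample, layout)
    c_cap = capital_cost(sample, layout, depth, swh, constants)
    c_op, c_harv, c_eqtrans = annual_costs(sample, layout, d_port)
    c_prod = production_cost(c_cap, c_op, c_harv, c_eqtrans, layout.s_dw)
    e_eqtrans, e_mnt, e_prod = production_emissions(sample, d_port, layout.s_dw)

    total = c_cap + c_op + c_harv + c_eqtrans
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = {
            "seeded_line": c_sl / total,
            "capital_ex_line": (c_cap - c_sl) / total,
            "harvest": c_harv / total,
            "other": (c_op + c_eqtrans) / total,
        }
    return ProductionResult(
        c_cap=c_cap,
        c_sl=c_sl,
        c_op=c_op,
        c_harv=c_harv,
        c_eqtrans=c_eqtrans,
        c_prod=c_prod,
        e_eqtrans=e_eqtrans,
        e_mnt=e_mnt,
        e_prod=e_prod,
        shares=shares,
    )
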