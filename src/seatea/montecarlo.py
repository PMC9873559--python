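"""Monte Carlo orchestration over the full technoeconomic chain.

Each simulation draws one set of technoeconomic parameters (including the
yield-percentile map), evaluates production, the sinking pathway and every
product pathway on the grid, and records per-cell costs plus per-simulation
scalar summaries (average costs in the cheapest 1% / 2% ocean areas). The
sink-site assignment is computed once with the mean parameter set and
shared across simulations. Child seeds are spawned per simulation index,
so ensembles are reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import aggregate, production, products, sinking
from .grids import EnvLayers, OceanGrid, YieldEnsemble
from .params import (
    PRODUCT_CATEGORIES,
    Constants,
    EconomicSample,
    ParameterRange,
    sample as draw_sample,
)
from .sinkroute import SinkAssignment


@dataclass
class SimulationResult:
    """Per-cell pathway fields for one parameter draw."""

    sample: EconomicSample
    c_prod: np.ndarray
    e_prod: np.ndarray
    prod: production.ProductionResult
    sink: sinking.SinkingResult
    products: dict[str, products.ProductResult]


@dataclass
class EnsembleResult:
    """Stacked per-cell cost distributions and per-sim summaries.

    ``fields`` maps a field name (``c_prod``, ``c_perton_sinking``,
    ``c_perton_<category>``) to an (n_sims, n_ocean_cells) float32 array
    with NaN where the pathway is invalid for that simulation.
    """

    scenario: str
    n_sims: int
    ocean_mask: np.ndarray
    cell_area: np.ndarray
    fields: dict[str, np.ndarray]
    params: pd.DataFrame
    summaries: pd.DataFrame

    def quantile_map(self, field_name: str, q: float) -> np.ndarray:
        """Per-cell empirical quantile map (NaN on land / never-valid cells)."""
        flat = summarize_percentiles(self.fields[field_name], q)
        out = np.full(self.ocean_mask.shape, np.nan)
        out[self.ocean_mask] = flat
        return out


def summarize_percentiles(values: np.ndarray, q: float) -> np.ndarray:
    """Empirical inverse-CDF (nearest-rank) quantile across simulations.

    Invalid (NaN) simulations contribute nothing to a cell's distribution;
    cells invalid in every simulation return NaN.
    """
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanpercentile(values, q, axis=0, method="inverted_cdf")


def run_simulation(
    sample_: EconomicSample,
    grid: OceanGrid,
    env: EnvLayers,
    yields: YieldEnsemble,
    assignment: SinkAssignment,
    scenario: str = "ambient",
    categories: Iterable[str] = PRODUCT_CATEGORIES,
    constants: Constants = Constants(),
) -> SimulationResult:
    """Evaluate every pathway on the grid for one parameter draw."""
    s_dw = yields.preferred_map(scenario, sample_.yield_percentile)
    layout = production.FarmLayout(
        p_sline=yields.preferred_p_sline(),
        s_dw=s_dw,
        n_harv=yields.preferred_n_harv(),
    )
    prod = production.evaluate_production(
        sample_, layout, env.depth, env.swh, env.d_port, constants
    )
    sink = sinking.evaluate_sinking(
        sample_,
        s_dw,
        d_sink=assignment.d_sink,
        d_port=env.d_port,
        k_fseq=assignment.q_assigned,
        c_prod=prod.c_prod,
        e_prod=prod.e_prod,
        constants=constants,
    )
    prods = {
        cat: products.evaluate_product(
            sample_, cat, s_dw, sink.s_ww, env.d_port, prod.c_prod, prod.e_prod
        )
        for cat in categories
    }
    return SimulationResult(
        sample=sample_,
        c_prod=prod.c_prod,
        e_prod=prod.e_prod,
        prod=prod,
        sink=sink,
        products=prods,
    )


def _sim_summaries(
    sim: SimulationResult,
    s_dw: np.ndarray,
    cell_area: np.ndarray,
    total_area: float,
    fractions: tuple[float, ...],
) -> dict[str, float]:
    """Average costs within the cheapest-fraction areas of one simulation.

    Production cost is area-weighted ($/tDW); per-ton-of-climate-benefit
    costs are benefit-weighted (total dollars over total tons).
    """
    out: dict[str, float] = {}

    def _safe(cost, benefit, label):
        for f in fractions:
            key = f"{label}_cheapest{int(round(100 * f))}"
            try:
                mask = aggregate.cheapest_fraction(cost, cell_area, f, total_area)
                out[key] = aggregate.average_cost(mask, cost, cell_area, benefit)
            except ValueError:
                out[key] = np.nan

    _safe(sim.c_prod, None, "c_prod")
    benefit_sink = np.where(sim.sink.valid_mask, sim.sink.e_sinknet * s_dw, np.nan)
    _safe(sim.sink.c_perton, benefit_sink, "c_perton_sinking")
    for cat, pr in sim.products.items():
        benefit = np.where(pr.valid_mask, pr.e_prodnet * s_dw, np.nan)
        _safe(pr.c_perton, benefit, f"c_perton_{cat}")
    return out


def run_ensemble(
    grid: OceanGrid,
    env: EnvLayers,
    yields: YieldEnsemble,
    assignment: SinkAssignment,
    ranges: Mapping[str, ParameterRange],
    n_sims: int,
    scenario: str = "ambient",
    root_seed: int = 0,
    categories: Iterable[str] = PRODUCT_CATEGORIES,
    constants: Constants = Constants(),
    summary_fractions: tuple[float, ...] = (0.01, 0.02),
) -> EnsembleResult:
    """Run the Monte Carlo ensemble and stack per-cell cost distributions."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    categories = tuple(categories)
    ocean = grid.ocean_mask
    n_cells = int(ocean.sum())
    cell_area = grid.cell_area
    total_area = grid.total_ocean_area_km2

    field_names = ["c_prod", "c_perton_sinking"] + [f"c_perton_{c}" for c in categories]
    fields = {name: np.full((n_sims, n_cells), np.nan, dtype=np.float32) for name in field_names}

    children = np.random.SeedSequence(root_seed).spawn(n_sims)
    rows, summaries = [], []
    for i in range(n_sims):
        rng = np.random.default_rng(children[i])
        smp = draw_sample(ranges, rng, categories)
        sim = run_simulation(
            smp, grid, env, yields, assignment, scenario, categories, constants
        )
        fields["c_prod"][i] = sim.c_prod[ocean]
        fields["c_perton_sinking"][i] = np.where(
            sim.sink.valid_mask, sim.sink.c_perton, np.nan
        )[ocean]
        for cat in categories:
            pr = sim.products[cat]
            fields[f"c_perton_{cat}"][i] = np.where(pr.valid_mask, pr.c_perton, np.nan)[ocean]
        s_dw = yields.preferred_map(scenario, smp.yield_percentile)
        rows.append(smp.to_flat_dict())
        summaries.append(
            _sim_summaries(sim, s_dw, cell_area, total_area, summary_fractions)
        )

    return EnsembleResult(
        scenario=scenario,
        n_sims=n_sims,
        ocean_mask=ocean,
        cell_area=cell_area,
        fields=fields,
        params=pd.DataFrame(rows),
        summaries=pd.DataFrame(summaries),
    )
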