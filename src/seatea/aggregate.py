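"""Area-weighted aggregation: cheapest-area masks, supply curves, growth rates.

The headline statistics of the analysis are defined over the fraction of
global ocean area where costs are lowest: cells are ranked by per-unit
cost, accumulated until the target area is reached, and climate benefit is
integrated over that prefix. Supply curves report cumulative benefit (Gt
per year) against cumulative lowest-cost area with a benefit-weighted
average cost; growth-rate arithmetic converts a target farmed area into
the compound annual expansion it implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GrowthRateResult:
    """Compound annual growth implied by a farmed-area target."""

    target_area_km2: float
    current_area_km2: float
    horizon_years: float
    fold_increase: float
    annual_growth_rate_pct: float


def _valid(cost: np.ndarray) -> np.ndarray:
    return np.isfinite(np.asarray(cost, dtype=float))


def cheapest_fraction(
    cost: np.ndarray,
    cell_area: np.ndarray,
    fraction: float,
    total_area: float | None = None,
) -> np.ndarray:
    """Mask of the lowest-cost cells covering ``fraction`` of the ocean.

    Valid (finite-cost) cells are sorted ascending by cost with a stable
    tie-break on cell index, and accumulated until their area reaches
    ``fraction * total_area`` (the cell that crosses the target is
    included). ``total_area`` defaults to the summed area of valid cells.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    cost = np.asarray(cost, dtype=float)
    cell_area = np.asarray(cell_area, dtype=float)
    valid = _valid(cost)
    if not valid.any():
        raise ValueError("no valid cells to rank")
    if total_area is None:
        total_area = float(cell_area[valid].sum())
    target = fraction * total_area

    flat_idx = np.flatnonzero(valid.ravel())
    order = flat_idx[np.argsort(cost.ravel()[flat_idx], kind="stable")]
    areas = cell_area.ravel()[order]
    started_below = np.cumsum(areas) - areas < target  # include crossing cell
    mask = np.zeros(cost.size, dtype=bool)
    mask[order[started_below]] = True
    return mask.reshape(cost.shape)


def average_cost(
    mask: np.ndarray,
    cost: np.ndarray,
    cell_area: np.ndarray,
    benefit: np.ndarray | None = None,
) -> float:
    """Average cost over a mask: benefit-weighted if a benefit map is given.

    With a benefit density (per-km^2), returns total dollars per total tons
    of benefit, i.e. sum(cost*benefit*area)/sum(benefit*area); without,
    the plain area-weighted mean (used for $ per tDW production cost).
    """
    mask = np.asarray(mask, bool) & _valid(cost)
    if not mask.any():
        raise ValueError("empty mask")
    c = np.asarray(cost, dtype=float)[mask]
    a = np.asarray(cell_area, dtype=float)[mask]
    if benefit is None:
        w = a
    else:
        w = np.asarray(benefit, dtype=float)[mask] * a
    total = w.sum()
    if total == 0:
        raise ValueError("zero total weight")
    return float((c * w).sum() / total)


def supply_curve(
    cost: np.ndarray,
    benefit_density: np.ndarray,
    cell_area: np.ndarray,
    max_fraction: float = 0.01,
    total_area: float | None = None,
) -> pd.DataFrame:
    """Cumulative climate benefit vs lowest-cost area.

    Cells are ordered by ascending cost; the curve reports, per prefix,
    cumulative area (km^2 and fraction of ocean), cumulative benefit
    (Gt yr^-1, from a per-km^2 benefit density in t km^-2 yr^-1), the
    marginal cost of the last cell added, and the benefit-weighted average
    cost so far. Truncated at ``max_fraction`` of the ocean area.
    """
    cost = np.asarray(cost, dtype=float).ravel()
    benefit = np.asarray(benefit_density, dtype=float).ravel()
    area = np.asarray(cell_area, dtype=float).ravel()
    valid = np.isfinite(cost) & np.isfinite(benefit)
    if total_area is None:
        total_area = float(area[valid].sum())

    flat_idx = np.flatnonzero(valid)
    order = flat_idx[np.argsort(cost[flat_idx], kind="stable")]
    a = area[order]
    cum_area = np.cumsum(a)
    keep = (cum_area - a) < max_fraction * total_area
    order, a, cum_area = order[keep], a[keep], cum_area[keep]

    benefit_per_cell = benefit[order] * a  # t yr^-1
    cum_benefit = np.cumsum(benefit_per_cell)
    cum_dollars = np.cumsum(cost[order] * benefit_per_cell)
    with np.errstate(divide="ignore", invalid="ignore"):
        avg_cost = np.where(cum_benefit > 0, cum_dollars / cum_benefit, np.nan)
    return pd.DataFrame(
        {
            "cell_index": order,
            "marginal_cost": cost[order],
            "area_km2": cum_area,
            "area_fraction": cum_area / total_area,
            "benefit_gt_yr": cum_benefit / 1e9,
            "average_cost": avg_cost,
        }
    )


def farm_growth_rate(
    target_area_km2: float, current_area_km2: float, horizon_years: float
) -> GrowthRateResult:
    """Compound annual growth rate to scale farming to a target area."""
    if target_area_km2 <= 0 or current_area_km2 <= 0 or horizon_years <= 0:
        raise ValueError("areas and horizon must be strictly positive")
    fold = target_area_km2 / current_area_km2
    rate = fold ** (1.0 / horizon_years) - 1.0
    return GrowthRateResult(
        target_area_km2=target_area_km2,
        current_area_km2=current_area_km2,
        horizon_years=horizon_years,
        fold_increase=fold,
        annual_growth_rate_pct=100.0 * rate,
    )


def constraint_overlap(
    mask: np.ndarray,
    shipping_mask: np.ndarray,
    mpa_mask: np.ndarray,
    cell_area: np.ndarray,
) -> dict[str, float]:
    """Area fractions of a cell selection lying in shipping lanes or MPAs."""
    mask = np.asarray(mask, bool)
    area = np.asarray(cell_area, dtype=float)
    total = float(area[mask].sum())
    if total == 0:
        return {"shipping": 0.0, "mpa": 0.0, "either": 0.0}
    ship = float(area[mask & np.asarray(shipping_mask, bool)].sum())
    mpa = float(area[mask & np.asarray(mpa_mask, bool)].sum())
    either = float(
        area[mask & (np.asarray(shipping_mask, bool) | np.asarray(mpa_mask, bool))].sum()
    )
    return {"shipping": ship / total, "mpa": mpa / total, "either": either / total}


def plot_supply_curve(curve: pd.DataFrame, ax=None, **kwargs):
    """Quick matplotlib rendering of a supply curve (benefit vs area)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(
        curve["area_fraction"] * 100,
        curve["benefit_gt_yr"],
        c=curve["average_cost"],
        s=8,
        **kwargs,
    )
    ax.set_xlabel("lowest-cost ocean area (%)")
    ax.set_ylabel("cumulative climate benefit (Gt yr$^{-1}$)")
    plt.colorbar(sc, ax=ax, label="average cost ($ t$^{-1}$)")
    return ax
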