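"""Avoided-emissions pathway: seaweed as food, animal feed or biofuel.

Harvested seaweed is barged straight back to port with the replaced
equipment, converted into a product, and sold at a globally uniform market
value. The climate benefit is the CO2-equivalent (GWP100) emissions of the
displaced conventional product, net of seaweed-chain transport and
conversion emissions; the net cost per tCO2-eq may be negative (a profit)
where product value exceeds production cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .params import PRODUCT_CATEGORIES, EconomicSample, ParameterRange

#: net-avoided-emissions threshold (tCO2-eq/tDW) below which a cell is invalid
NET_AVOIDED_EPS = 1e-9


@dataclass
class ProductResult:
    """Per-cell fields of one product pathway."""

    category: str
    c_transprod: np.ndarray  # $ tDW^-1
    v_product: np.ndarray  # $ tDW^-1
    e_transprod: np.ndarray  # tCO2 tDW^-1
    e_avprod: np.ndarray  # tCO2-eq tDW^-1 avoided before production emissions
    c_prodnet: np.ndarray  # $ tDW^-1
    e_prodnet: np.ndarray  # tCO2-eq tDW^-1, net of production emissions
    c_perton: np.ndarray  # $ per tCO2-eq avoided, NaN outside valid_mask
    valid_mask: np.ndarray


def product_value(
    sample: EconomicSample,
    category: str,
    s_dw: np.ndarray,
    s_ww: np.ndarray,
    d_port: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Transport-to-port cost per tDW and resulting product value."""
    pp = sample.products[category]
    d_port = np.asarray(d_port, dtype=float)
    s_dw = np.asarray(s_dw, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_transprod = np.where(
            s_dw > 0,
            sample.c_transbase * d_port * (s_ww + sample.m_eq) / s_dw,
            np.nan,
        )
    v_product = pp.v_mkt - (c_transprod + pp.c_conv)
    return c_transprod, v_product


def product_emissions(
    sample: EconomicSample,
    category: str,
    s_dw: np.ndarray,
    s_ww: np.ndarray,
    d_port: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Transport emissions per tDW and net avoided emissions per tDW."""
    pp = sample.products[category]
    d_port = np.asarray(d_port, dtype=float)
    s_dw = np.asarray(s_dw, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_transprod = np.where(
            s_dw > 0,
            sample.e_transbase * d_port * (s_ww + sample.m_eq) / s_dw,
            np.nan,
        )
    e_avprod = pp.e_subprod - (e_transprod + pp.e_conv)
    return e_transprod, e_avprod


def substituted_emissions(
    category: str, ranges: Mapping[str, ParameterRange]
) -> tuple[float, float]:
    """Range of CO2-eq emissions avoided per tDW for one product category."""
    if category not in PRODUCT_CATEGORIES:
        raise ValueError(f"unknown product category {category!r}")
    r = ranges[f"e_subprod_{category}"]
    return (r.low, r.high)


def fuel_substitution_range(
    fossil_intensity_low: float = 3.2,
    fossil_intensity_high: float = 3.5,
    biofuel_yield: float = 0.25,
) -> tuple[float, float]:
    """Bottom-up check of the fuel-substitution range.

    Multiplying fossil-fuel combustion intensity (tCO2 per t fuel) by the
    biofuel yield per ton of seaweed dry weight brackets the avoided
    emissions per tDW before energy-density adjustments.
    """
    return (fossil_intensity_low * biofuel_yield, fossil_intensity_high * biofuel_yield)


def product_net(
    c_prod: np.ndarray,
    e_prod: np.ndarray,
    v_product: np.ndarray,
    e_avprod: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Net cost and net avoided emissions per tDW, and $ per tCO2-eq."""
    c_prodnet = np.asarray(c_prod, dtype=float) - v_product
    e_prodnet = e_avprod - np.asarray(e_prod, dtype=float)
    valid = np.isfinite(e_prodnet) & (e_prodnet > NET_AVOIDED_EPS) & np.isfinite(c_prodnet)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_perton = np.where(valid, c_prodnet / e_prodnet, np.nan)
    return c_prodnet, e_prodnet, c_perton, valid


def evaluate_product(
    sample: EconomicSample,
    category: str,
    s_dw: np.ndarray,
    s_ww: np.ndarray,
    d_port: np.ndarray,
    c_prod: np.ndarray,
    e_prod: np.ndarray,
) -> ProductResult:
    """Full product chain from harvest to $ per tCO2-eq avoided."""
    c_transprod, v_product = product_value(sample, category, s_dw, s_ww, d_port)
    e_transprod, e_avprod = product_emissions(sample, category, s_dw, s_ww, d_port)
    c_prodnet, e_prodnet, c_perton, valid = product_net(
        c_prod, e_prod, v_product, e_avprod
    )
    return ProductResult(
        category=category,
        c_transprod=c_transprod,
        v_product=v_product,
        e_transprod=e_transprod,
        e_avprod=e_avprod,
        c_prodnet=c_prodnet,
        e_prodnet=e_prodnet,
        c_perton=c_perton,
        valid_mask=valid,
    )
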