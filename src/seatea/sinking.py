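"""Carbon-sequestration pathway: sinking harvested seaweed to the deep sea.

Harvested wet biomass is barged to a (possibly remote) sinking site chosen
for its 100-yr sequestration fraction, the barge returns via the farm to
port with used equipment in tow, and the removed CO2 is the seaweed carbon
scaled by the atmospheric removal fraction (k_atm) and the site's
sequestration fraction (k_fseq), net of transport-chain emissions. Cells
whose net removal is not positive contribute nothing to the pathway and
are masked out of every downstream aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Constants, EconomicSample

#: net-removal threshold (tCO2/tDW) below which a cell is invalid; strictly
#: positive to keep the cost-per-ton division well conditioned
NET_REMOVAL_EPS = 1e-9


@dataclass
class SinkingResult:
    """Per-cell fields of the sinking pathway."""

    s_ww: np.ndarray  # t WW km^-2 yr^-1
    c_swtsink: np.ndarray  # $ km^-2 yr^-1, seaweed haul to sink site
    c_eqtsink: np.ndarray  # $ km^-2 yr^-1, equipment legs
    v_sink: np.ndarray  # $ tDW^-1 (<= 0 without a carbon price)
    e_seqsink: np.ndarray  # tCO2 km^-2 yr^-1 sequestered
    e_swtsink: np.ndarray  # tCO2 km^-2 yr^-1
    e_eqtsink: np.ndarray  # tCO2 km^-2 yr^-1
    e_remsink: np.ndarray  # tCO2 tDW^-1 removed, net of transport
    c_sinknet: np.ndarray  # $ tDW^-1
    e_sinknet: np.ndarray  # tCO2 tDW^-1, net of production emissions
    c_perton: np.ndarray  # $ per tCO2 removed, NaN outside valid_mask
    valid_mask: np.ndarray  # net removal > 0


def wet_weight(s_dw: np.ndarray, constants: Constants = Constants()) -> np.ndarray:
    """Wet weight from dry weight (seaweed is ~90% water at harvest)."""
    return np.asarray(s_dw, dtype=float) * constants.wet_dry_ratio


def sinking_value(
    sample: EconomicSample,
    s_dw: np.ndarray,
    s_ww: np.ndarray,
    d_sink: np.ndarray,
    d_port: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transport costs of the sinking route and resulting value per tDW.

    The loaded leg carries the wet harvest to the sink site; the equipment
    legs cover the round trip to the sink site plus the return to port.
    Without a carbon price the value is a pure cost (v_sink <= 0).
    """
    d_sink = np.asarray(d_sink, dtype=float)
    d_port = np.asarray(d_port, dtype=float)
    c_swtsink = sample.c_transbase * d_sink * s_ww
    c_eqtsink = (
        sample.c_transbase * (2.0 * d_sink) * sample.m_eq
        + sample.c_transbase * d_port * sample.m_eq
    )
    s_dw = np.asarray(s_dw, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_sink = np.where(
            s_dw > 0, (sample.v_cprice - (c_swtsink + c_eqtsink)) / s_dw, np.nan
        )
    return c_swtsink, c_eqtsink, v_sink


def sinking_removal(
    sample: EconomicSample,
    k_fseq: np.ndarray,
    s_dw: np.ndarray,
    s_ww: np.ndarray,
    d_sink: np.ndarray,
    d_port: np.ndarray,
    constants: Constants = Constants(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gross sequestration, transport emissions, and net removal per tDW."""
    k_fseq = np.asarray(k_fseq, dtype=float)
    if np.any((k_fseq[np.isfinite(k_fseq)] < 0) | (k_fseq[np.isfinite(k_fseq)] > 1)):
        raise ValueError("k_fseq must lie in [0, 1]")
    d_sink = np.asarray(d_sink, dtype=float)
    d_port = np.asarray(d_port, dtype=float)
    s_dw = np.asarray(s_dw, dtype=float)

    e_seqsink = (
        sample.k_atm * k_fseq * constants.carbon_fraction * constants.co2_per_c * s_dw
    )
    e_swtsink = sample.e_transbase * d_sink * s_ww
    e_eqtsink = (
        sample.e_transbase * (2.0 * d_sink) * sample.m_eq
        + sample.e_transbase * d_port * sample.m_eq
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        e_remsink = np.where(
            s_dw > 0, (e_seqsink - (e_swtsink + e_eqtsink)) / s_dw, np.nan
        )
    return e_seqsink, e_swtsink, e_eqtsink, e_remsink


def sinking_net(
    c_prod: np.ndarray,
    e_prod: np.ndarray,
    v_sink: np.ndarray,
    e_remsink: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Net cost and net removal per tDW, and $ per tCO2 on valid cells."""
    c_sinknet = np.asarray(c_prod, dtype=float) - v_sink
    e_sinknet = e_remsink - np.asarray(e_prod, dtype=float)
    valid = np.isfinite(e_sinknet) & (e_sinknet > NET_REMOVAL_EPS) & np.isfinite(c_sinknet)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_perton = np.where(valid, c_sinknet / e_sinknet, np.nan)
    return c_sinknet, e_sinknet, c_perton, valid


def evaluate_sinking(
    sample: EconomicSample,
    s_dw: np.ndarray,
    d_sink: np.ndarray,
    d_port: np.ndarray,
    k_fseq: np.ndarray,
    c_prod: np.ndarray,
    e_prod: np.ndarray,
    constants: Constants = Constants(),
) -> SinkingResult:
    """Full sinking chain from harvest to $ per tCO2 removed."""
    s_ww = wet_weight(s_dw, constants)
    c_swtsink, c_eqtsink, v_sink = sinking_value(sample, s_dw, s_ww, d_sink, d_port)
    e_seqsink, e_swtsink, e_eqtsink, e_remsink = sinking_removal(
        sample, k_fseq, s_dw, s_ww, d_sink, d_port, constants
    )
    c_sinknet, e_sinknet, c_perton, valid = sinking_net(
        c_prod, e_prod, v_sink, e_remsink
    )
    return SinkingResult(
        s_ww=s_ww,
        c_swtsink=c_swtsink,
        c_eqtsink=c_eqtsink,
        v_sink=v_sink,
        e_seqsink=e_seqsink,
        e_swtsink=e_swtsink,
        e_eqtsink=e_eqtsink,
        e_remsink=e_remsink,
        c_sinknet=c_sinknet,
        e_sinknet=e_sinknet,
        c_perton=c_perton,
        valid_mask=valid,
    )
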