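"""Technoeconomic constants, parameter ranges and Monte Carlo sampling.

The economics of open-ocean seaweed farming are only loosely constrained by
the literature: for most inputs only a handful of divergent estimates exist.
The analysis therefore treats every technoeconomic input as a uniform random
variable over a range constructed from published values. Ranges are built by
a fixed set of rules: when two or more literature values exist, their min and
max are taken as the 5th/95th percentiles of the range; a single value is
extended by +/-50%; selected floors are extended (capital cost down to
$10,000 km^-2 for hypothetical autonomous farms, transport and maintenance
emissions down to zero for zero-emission vessels); and the resulting bounds
are rounded to parameter-specific increments.

Seaweed yield uncertainty enters through a discrete draw of one of five
yield-percentile maps (5/25/50/75/95), selected through a standard normal
deviate so that draws concentrate on the median map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.stats import norm

#: conversion from tons of carbon to tons of CO2
CO2_PER_C = 44.0 / 12.0

#: yield-map percentiles available per scenario
PERCENTILE_LEVELS = (5, 25, 50, 75, 95)

#: product end-use categories of the avoided-emissions pathway
PRODUCT_CATEGORIES = ("food", "feed", "fuel")

#: per-category parameter name stems
_PRODUCT_STEMS = ("c_conv", "e_conv", "v_mkt", "e_subprod")

#: scalar (non product-specific) parameters, in sampling order
SCALAR_PARAMS = (
    "c_capbase",
    "k_d",
    "k_w",
    "c_slbase",
    "c_ins",
    "c_lic",
    "c_lab",
    "c_opbase",
    "c_harvbase",
    "c_transbase",
    "e_transbase",
    "e_mntbase",
    "n_mnt",
    "a_mnt",
    "d_mnt",
    "m_eq",
    "k_atm",
    "v_cprice",
)

#: cut points between the five percentile bins on the standard normal axis:
#: midpoint probabilities between the levels (0.15, 0.375, 0.625, 0.85)
PERCENTILE_BIN_EDGES = tuple(norm.ppf([0.15, 0.375, 0.625, 0.85]))


@dataclass(frozen=True)
class Constants:
    """Fixed physical and bookkeeping constants of the analysis."""

    wet_dry_ratio: float = 10.0
    carbon_fraction: float = 0.30
    co2_per_c: float = CO2_PER_C
    ocean_area_total_km2: float = 3.6e8
    current_farm_area_km2: float = 2700.0
    depth_threshold_m: float = 500.0
    swh_threshold_m: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "wet_dry_ratio",
            "carbon_fraction",
            "ocean_area_total_km2",
            "current_farm_area_km2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be strictly positive")


@dataclass(frozen=True)
class ParameterRange:
    """One uniform parameter range with its construction provenance.

    ``low``/``high`` are the final (rounded, extended, possibly overridden)
    Monte Carlo bounds. ``raw_low``/``raw_high`` retain the unrounded
    literature span, which the sink-route optimization averages.
    """

    name: str
    units: str
    low: float
    high: float
    raw_low: float
    raw_high: float
    rounding: float | None = None
    rounding_mode: str = "nearest"
    provenance: str = ""
    placeholder: bool = False
    mean_uses_extended: bool = False
    extend_low_to: float | None = None
    explicit_mean: float | None = None

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.name}: low {self.low} > high {self.high}")
        if self.rounding:
            for bound in (self.low, self.high):
                ratio = bound / self.rounding
                if abs(ratio - round(ratio)) > 1e-6:
                    raise ValueError(
                        f"{self.name}: bound {bound} is not a multiple of "
                        f"rounding increment {self.rounding}"
                    )

    def contains(self, value: float) -> bool:
        return self.low - 1e-12 <= value <= self.high + 1e-12

    @property
    def mean(self) -> float:
        """Midpoint of the unrounded literature span.

        Parameters whose floor was deliberately extended to zero
        (transport/maintenance emissions) average the extended span instead;
        an explicit mean overrides both.
        """
        if self.explicit_mean is not None:
            return self.explicit_mean
        lo = self.raw_low
        if self.mean_uses_extended and self.extend_low_to is not None:
            lo = min(lo, self.extend_low_to)
        return 0.5 * (lo + self.raw_high)


def _round_nearest(x: float, inc: float) -> float:
    # half-away-from-zero, so 0.1125 -> 0.10 and 0.3375 -> 0.35 at inc=0.05
    return math.floor(x / inc + 0.5) * inc


def _round_out(low: float, high: float, inc: float) -> tuple[float, float]:
    return (math.floor(low / inc + 1e-9) * inc, math.ceil(high / inc - 1e-9) * inc)


def default_table_path():
    return resources.files("seatea").joinpath("data/parameter_ranges.yaml")


def load_raw_table(path=None) -> dict:
    """Read the parameter-range configuration (YAML) into a dict."""
    if path is None:
        text = default_table_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def build_range(name: str, entry: Mapping) -> ParameterRange:
    """Construct one ParameterRange from a raw table entry."""
    units = entry.get("units")
    if not units:
        raise ValueError(f"parameter {name} is missing units")
    if "range" in entry:
        raw_low, raw_high = (float(v) for v in entry["range"])
        provenance = "explicit model range"
    elif "literature" in entry:
        values = [float(v) for v in entry["literature"]]
        if not values:
            raise ValueError(f"parameter {name} has an empty literature list")
        if len(values) >= 2:
            raw_low, raw_high = min(values), max(values)
            provenance = "literature min/max as 5th/95th percentiles"
        else:
            raw_low, raw_high = 0.5 * values[0], 1.5 * values[0]
            provenance = "single literature value +/-50%"
    else:
        raise ValueError(f"parameter {name} has neither 'range' nor 'literature'")

    extend_low_to = entry.get("extend_low_to")
    low, high = raw_low, raw_high
    if extend_low_to is not None and float(extend_low_to) < low:
        low = float(extend_low_to)
        provenance += "; floor extended"

    inc = entry.get("rounding")
    mode = entry.get("rounding_mode", "nearest")
    if inc:
        inc = float(inc)
        if mode == "out":
            low, high = _round_out(low, high, inc)
        else:
            low, high = _round_nearest(low, inc), _round_nearest(high, inc)

    if "override" in entry:
        low, high = (float(v) for v in entry["override"])
        provenance += "; final range pinned to published table"

    return ParameterRange(
        name=name,
        units=units,
        low=low,
        high=high,
        raw_low=raw_low,
        raw_high=raw_high,
        rounding=float(inc) if inc else None,
        rounding_mode=mode,
        provenance=provenance,
        placeholder=bool(entry.get("placeholder", False)),
        mean_uses_extended=bool(entry.get("mean_uses_extended", False)),
        extend_low_to=float(extend_low_to) if extend_low_to is not None else None,
        explicit_mean=float(entry["mean"]) if "mean" in entry else None,
    )


def build_ranges(raw_table: Mapping) -> dict[str, ParameterRange]:
    """Apply the range-construction rules to every entry of the raw table."""
    return {
        name: build_range(name, entry)
        for name, entry in raw_table["parameters"].items()
    }


def load_constants(raw_table: Mapping | None = None) -> Constants:
    raw_table = raw_table if raw_table is not None else load_raw_table()
    return Constants(**{k: float(v) for k, v in raw_table.get("constants", {}).items()})


def load_ranges(path=None) -> tuple[Constants, dict[str, ParameterRange]]:
    """Load constants and fully-built parameter ranges from a config file."""
    raw = load_raw_table(path)
    return load_constants(raw), build_ranges(raw)


@dataclass(frozen=True)
class ProductParams:
    """Per-category product-pathway parameters ($ and tCO2-eq per tDW)."""

    c_conv: float
    e_conv: float
    v_mkt: float
    e_subprod: float


@dataclass(frozen=True)
class EconomicSample:
    """One draw of every scalar technoeconomic parameter.

    Monetary units are $ (per km^2 yr, per m, per t km as appropriate);
    emissions are tCO2 (or tCO2-eq for product substitution).
    """

    c_capbase: float
    k_d: float
    k_w: float
    c_slbase: float
    c_ins: float
    c_lic: float
    c_lab: float
    c_opbase: float
    c_harvbase: float
    c_transbase: float
    e_transbase: float
    e_mntbase: float
    n_mnt: float
    a_mnt: float
    d_mnt: float
    m_eq: float
    k_atm: float
    v_cprice: float
    products: Mapping[str, ProductParams]
    yield_percentile: int = 50

    def to_flat_dict(self) -> dict[str, float]:
        """Flatten to one row (product params suffixed by category)."""
        row = {name: getattr(self, name) for name in SCALAR_PARAMS}
        for cat, pp in self.products.items():
            for stem in _PRODUCT_STEMS:
                row[f"{stem}_{cat}"] = getattr(pp, stem)
        row["yield_percentile"] = self.yield_percentile
        return row


def _product_param_names(categories: Iterable[str]) -> list[str]:
    return [f"{stem}_{cat}" for cat in categories for stem in _PRODUCT_STEMS]


def draw_yield_percentile(rng: np.random.Generator) -> int:
    """Draw one of the five yield-percentile levels via a normal deviate.

    A standard normal draw is mapped to {5, 25, 50, 75, 95} through
    probability bins whose edges sit at the midpoints between the levels,
    so the median map is the most likely (P = 0.25) and the tails the least.
    """
    u = rng.standard_normal()
    idx = int(np.searchsorted(PERCENTILE_BIN_EDGES, u))
    return PERCENTILE_LEVELS[idx]


def percentile_bin_probabilities() -> np.ndarray:
    """Theoretical probability of each percentile level under the normal map."""
    edges = np.concatenate([[-np.inf], PERCENTILE_BIN_EDGES, [np.inf]])
    cdf = norm.cdf(edges)
    return np.diff(cdf)


def sample(
    ranges: Mapping[str, ParameterRange],
    rng: np.random.Generator,
    categories: Iterable[str] = PRODUCT_CATEGORIES,
) -> EconomicSample:
    """Draw one EconomicSample: independent uniforms, then the yield map."""
    categories = tuple(categories)
    values: dict[str, float] = {}
    for name in (*SCALAR_PARAMS, *_product_param_names(categories)):
        r = ranges[name]
        values[name] = r.low if r.low == r.high else float(rng.uniform(r.low, r.high))
    products = {
        cat: ProductParams(**{stem: values[f"{stem}_{cat}"] for stem in _PRODUCT_STEMS})
        for cat in categories
    }
    scalars = {name: values[name] for name in SCALAR_PARAMS}
    return EconomicSample(
        **scalars, products=products, yield_percentile=draw_yield_percentile(rng)
    )


def mean_parameter_set(
    ranges: Mapping[str, ParameterRange],
    categories: Iterable[str] = PRODUCT_CATEGORIES,
) -> EconomicSample:
    """Fixed parameter set used for the sink-route optimization.

    Every parameter is the midpoint of its unrounded literature span, except
    transport and maintenance emissions whose floors are first extended to
    zero (see :class:`ParameterRange.mean`). The yield percentile is pinned
    to the median map.
    """
    categories = tuple(categories)
    scalars = {name: ranges[name].mean for name in SCALAR_PARAMS}
    products = {
        cat: ProductParams(
            **{stem: ranges[f"{stem}_{cat}"].mean for stem in _PRODUCT_STEMS}
        )
        for cat in categories
    }
    return EconomicSample(**scalars, products=products, yield_percentile=50)


def with_percentile(sample_: EconomicSample, percentile: int) -> EconomicSample:
    """Copy of a sample with the yield percentile replaced."""
    if percentile not in PERCENTILE_LEVELS:
        raise ValueError(f"unknown yield percentile {percentile}")
    return replace(sample_, yield_percentile=percentile)
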