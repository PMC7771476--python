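"""Domain types for the partial-equilibrium priority-setting simulator.

The model world is a set of regions trading a set of commodities.  One
commodity is the *focus* crop: the one receiving research-induced
productivity shocks and the one on which welfare is measured.  All
calibration data live in dense arrays indexed ``[region, commodity]`` in
the order of :attr:`WorldModel.regions` / :attr:`WorldModel.commodities`.

Units are fixed throughout the package:

====================  =====================
quantity              unit
====================  =====================
harvested area        thousand hectares (kha)
yield                 tonnes per hectare (t/ha)
supply / demand       thousand tonnes (kt)
prices                US$ per tonne
money                 million US$, constant prices
population            millions
====================  =====================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Commodity",
    "Region",
    "MarketCalibration",
    "WorldModel",
    "TargetSpec",
    "TechnologyOption",
    "AdoptionCurve",
    "ScenarioDrivers",
    "MarketTrajectory",
    "validate_world",
    "world_to_dict",
    "world_from_dict",
    "world_to_yaml",
    "world_from_yaml",
]


@dataclass(frozen=True)
class Commodity:
    """A traded commodity; ``is_focus`` marks the crop under study."""

    id: str
    is_focus: bool = False


@dataclass(frozen=True)
class Region:
    """A country-level market region."""

    id: str


@dataclass
class MarketCalibration:
    """Base-year market data and elasticities.

    All 2-D arrays are ``(n_regions, n_commodities)``; the elasticity
    tensors are ``(n_regions, n_commodities, n_commodities)`` with the
    last axis indexing the price whose change is responded to.
    """

    yield_base: np.ndarray          # t/ha
    area_base: np.ndarray           # kha
    demand_base: np.ndarray         # kt
    price_base: np.ndarray          # (C,) world reference producer prices, US$/t
    price_margin: np.ndarray        # (R, C) domestic = world * margin; defaults to 1
    yield_price_elast: np.ndarray   # (R, C) own-price yield response, >= 0
    input_price_elast: np.ndarray   # (R, C) yield response to input prices
    area_elast: np.ndarray          # (R, C, C) area response to producer prices
    demand_elast: np.ndarray        # (R, C, C) demand response to consumer prices
    income_elast: np.ndarray        # (R, C)
    population_base: np.ndarray     # (R,) millions
    income_base: np.ndarray         # (R,) per-capita income index
    input_price_base: float = 1.0   # exogenous input price index PF

    @property
    def supply_base(self) -> np.ndarray:
        """Base-year production, kt: yield x area."""
        return self.yield_base * self.area_base

    @property
    def domestic_price_base(self) -> np.ndarray:
        return self.price_base[None, :] * self.price_margin

    def supply_elasticity(self) -> np.ndarray:
        """Regional own-price supply elasticity: yield response plus area
        own-price response (the country-level analog of aggregating
        yield x area responses)."""
        own_area = np.einsum("rcc->rc", self.area_elast)
        return self.yield_price_elast + own_area


@dataclass
class WorldModel:
    """Regions x commodities with calibration and a simulation horizon."""

    commodities: list[Commodity]
    regions: list[Region]
    calibration: MarketCalibration
    years: np.ndarray  # consecutive calendar years, first..last inclusive

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_commodities(self) -> int:
        return len(self.commodities)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def focus_index(self) -> int:
        idx = [i for i, c in enumerate(self.commodities) if c.is_focus]
        if len(idx) != 1:
            raise ValueError(f"expected exactly one focus commodity, found {len(idx)}")
        return idx[0]

    @property
    def region_ids(self) -> list[str]:
        return [r.id for r in self.regions]

    @property
    def commodity_ids(self) -> list[str]:
        return [c.id for c in self.commodities]

    def region_index(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region {region_id!r}") from None


@dataclass(frozen=True)
class TargetSpec:
    """Per-target-country technology parameters."""

    amax: float      # adoption ceiling, fraction of harvested area
    dyield: float    # maximum expected proportional yield change
    dcost: float     # proportional production cost change
    p_success: float # probability of research success


@dataclass
class TechnologyOption:
    """One research option: lags, targets, and cost parameters."""

    name: str
    research_lag: int                 # years before release
    adoption_lag: int                 # diffusion span after release
    targets: dict[str, TargetSpec]    # region id -> parameters
    annual_rd_cost: float             # million US$ per research year
    dissemination_cost_per_ha: float  # US$ per newly adopted hectare

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not self.targets:
            problems.append(f"{self.name}: empty target set")
        if self.research_lag < 0 or self.adoption_lag <= 0:
            problems.append(f"{self.name}: non-positive lag")
        if self.annual_rd_cost < 0 or self.dissemination_cost_per_ha < 0:
            problems.append(f"{self.name}: negative cost")
        for rid, t in self.targets.items():
            if not (0.0 < t.amax <= 1.0):
                problems.append(f"{self.name}/{rid}: Amax={t.amax} outside (0, 1]")
            if t.dyield <= -1.0:
                problems.append(f"{self.name}/{rid}: yield change {t.dyield} <= -1")
            if not (0.0 <= t.p_success <= 1.0):
                problems.append(f"{self.name}/{rid}: p={t.p_success} outside [0, 1]")
        return problems


@dataclass(frozen=True)
class AdoptionCurve:
    """Logistic diffusion curve A(t) = Amax / (1 + exp(-(alpha + beta t)))."""

    amax: float
    a0: float
    t0: float     # calendar year of initial adoption (rate a0)
    tmid: float   # calendar year of 50% adoption
    alpha: float
    beta: float


@dataclass
class ScenarioDrivers:
    """Exogenous per-year paths for one scenario.

    ``pop_mult`` and ``income_mult`` are ``(T, R)``; the yield paths are
    ``(T, R, C)``.  All are multipliers relative to the base year (first
    row is all ones).  A static driver set has every path constant at 1.
    """

    name: str
    years: np.ndarray
    pop_mult: np.ndarray
    income_mult: np.ndarray
    yint2: np.ndarray   # exogenous yield growth path
    ywat: np.ndarray    # water-stress yield multiplier
    yclim: np.ndarray   # climate-change yield multiplier
    adoption_ceiling_factor: float = 1.0

    @property
    def is_static(self) -> bool:
        return all(
            np.allclose(a, a[0]) for a in (self.pop_mult, self.income_mult,
                                           self.yint2, self.ywat, self.yclim)
        )


@dataclass
class MarketTrajectory:
    """Solved per-year market records for one scenario run."""

    years: np.ndarray
    world_price: np.ndarray  # (T, C)
    price: np.ndarray        # (T, R, C) domestic producer prices
    yields: np.ndarray       # (T, R, C) t/ha
    area: np.ndarray         # (T, R, C) kha
    supply: np.ndarray       # (T, R, C) kt
    demand: np.ndarray       # (T, R, C) kt

    @property
    def net_trade(self) -> np.ndarray:
        """Net exports (supply minus demand), kt; sums to ~0 globally."""
        return self.supply - self.demand

    def to_frame(self, world: WorldModel) -> pd.DataFrame:
        """Long-format table: year, region, commodity, prices, quantities."""
        t, r, c = np.meshgrid(
            np.arange(len(self.years)), np.arange(world.n_regions),
            np.arange(world.n_commodities), indexing="ij")
        return pd.DataFrame({
            "year": self.years[t.ravel()],
            "region": np.asarray(world.region_ids)[r.ravel()],
            "commodity": np.asarray(world.commodity_ids)[c.ravel()],
            "world_price": self.world_price[t.ravel(), c.ravel()],
            "price": self.price.ravel(),
            "yield": self.yields.ravel(),
            "area": self.area.ravel(),
            "supply": self.supply.ravel(),
            "demand": self.demand.ravel(),
            "net_trade": self.net_trade.ravel(),
        })


# ---------------------------------------------------------------------------
# validation

def validate_world(world: WorldModel, clearing_rtol: float = 1e-9) -> list[str]:
    """Check all WorldModel invariants; return a list of violations.

    An empty list means the world is well formed, including base-year
    global market clearing per commodity.  Findings name the offending
    region/commodity/field; callers decide whether to raise.
    """
    problems: list[str] = []
    cal = world.calibration
    R, C = world.n_regions, world.n_commodities

    cids = world.commodity_ids
    if len(set(cids)) != C:
        problems.append("commodity ids not unique")
    rids = world.region_ids
    if len(set(rids)) != R:
        problems.append("region ids not unique")
    n_focus = sum(c.is_focus for c in world.commodities)
    if n_focus != 1:
        problems.append(f"expected exactly one focus commodity, found {n_focus}")

    years = np.asarray(world.years)
    if len(years) < 2 or not np.all(np.diff(years) == 1):
        problems.append("years must be consecutive and span at least two years")

    shapes = {
        "yield_base": (R, C), "area_base": (R, C), "demand_base": (R, C),
        "price_base": (C,), "price_margin": (R, C),
        "yield_price_elast": (R, C), "input_price_elast": (R, C),
        "area_elast": (R, C, C), "demand_elast": (R, C, C),
        "income_elast": (R, C), "population_base": (R,), "income_base": (R,),
    }
    for name, shape in shapes.items():
        arr = np.asarray(getattr(cal, name))
        if arr.shape != shape:
            problems.append(f"{name}: shape {arr.shape}, expected {shape}")
    if problems:
        return problems  # positional checks below assume correct shapes

    def _cells(mask: np.ndarray, field: str, msg: str) -> None:
        for idx in zip(*np.nonzero(mask)):
            r = rids[idx[0]] if len(idx) >= 1 and mask.ndim >= 1 else ""
            c = cids[idx[1]] if len(idx) >= 2 else ""
            problems.append(f"{field}[{r},{c}]: {msg}")

    _cells(cal.yield_base <= 0, "yield_base", "must be strictly positive")
    _cells(cal.area_base <= 0, "area_base", "must be strictly positive")
    _cells(cal.demand_base <= 0, "demand_base", "must be strictly positive")
    _cells(cal.price_margin <= 0, "price_margin", "must be strictly positive")
    for j, p in enumerate(cal.price_base):
        if p <= 0:
            problems.append(f"price_base[{cids[j]}]: must be strictly positive")
    for i, p in enumerate(cal.population_base):
        if p <= 0:
            problems.append(f"population_base[{rids[i]}]: must be strictly positive")
    for i, y in enumerate(cal.income_base):
        if y <= 0:
            problems.append(f"income_base[{rids[i]}]: must be strictly positive")

    own_demand = np.einsum("rcc->rc", cal.demand_elast)
    _cells(own_demand >= 0, "demand_elast(own)", "own-price demand elasticity must be negative")
    _cells(cal.yield_price_elast < 0, "yield_price_elast", "must be non-negative")
    own_area = np.einsum("rcc->rc", cal.area_elast)
    _cells(own_area < 0, "area_elast(own)", "own-price area elasticity must be non-negative")

    supply = cal.supply_base
    for j in range(C):
        s, d = supply[:, j].sum(), np.asarray(cal.demand_base)[:, j].sum()
        if not np.isclose(s, d, rtol=clearing_rtol, atol=0.0):
            problems.append(
                f"market clearing[{cids[j]}]: base global supply {s:.6g} kt "
                f"!= base global demand {d:.6g} kt")
    return problems


# ---------------------------------------------------------------------------
# serialization (structured-text study configuration)

def world_to_dict(world: WorldModel) -> dict:
    cal = world.calibration
    return {
        "commodities": [{"id": c.id, "is_focus": bool(c.is_focus)}
                        for c in world.commodities],
        "regions": [{"id": r.id} for r in world.regions],
        "years": [int(world.years[0]), int(world.years[-1])],
        "calibration": {
            "input_price_base": float(cal.input_price_base),
            **{name: np.asarray(getattr(cal, name)).tolist()
               for name in ("yield_base", "area_base", "demand_base",
                            "price_base", "price_margin", "yield_price_elast",
                            "input_price_elast", "area_elast", "demand_elast",
                            "income_elast", "population_base", "income_base")},
        },
    }


def world_from_dict(data: Mapping) -> WorldModel:
    cal = data["calibration"]
    arrays = {name: np.asarray(cal[name], dtype=float)
              for name in ("yield_base", "area_base", "demand_base",
                           "price_base", "price_margin", "yield_price_elast",
                           "input_price_elast", "area_elast", "demand_elast",
                           "income_elast", "population_base", "income_base")}
    first, last = data["years"]
    return WorldModel(
        commodities=[Commodity(d["id"], bool(d.get("is_focus", False)))
                     for d in data["commodities"]],
        regions=[Region(d["id"]) for d in data["regions"]],
        calibration=MarketCalibration(
            input_price_base=float(cal.get("input_price_base", 1.0)), **arrays),
        years=np.arange(int(first), int(last) + 1),
    )


def world_to_yaml(world: WorldModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(world_to_dict(world), fh, sort_keys=True)


def world_from_yaml(path) -> WorldModel:
    with open(path) as fh:
        return world_from_dict(yaml.safe_load(fh))
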