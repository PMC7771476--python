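"""Seeded generators for worlds, scenario drivers, and technology fixtures.

The generated world emulates a FAOSTAT-like calibration at country
level: a focus root crop (potato-like) traded alongside two larger
staple markets (rice/wheat-like), with the focus crop holding a
configurable share (default ~15%) of three-crop production, reflecting
the smaller size of a root-crop sector relative to cereals.

Regional structure (defaults, ``n_regions = 12``):

* ``maj_exp`` — a large rest-of-world aggregate producing ~30-45% of
  every commodity; the residual demand region that closes base-year
  market balances, hence a net exporter of the focus crop.  Never a
  technology target.
* ``maj_tgt`` — a single large producer (~20-28% of focus production,
  a China-like anchor) eligible as a target only for the most widely
  targeted technology.
* ``sml00..`` — small producers with geometrically decaying sizes
  (country production is heavy-tailed), each a slight net importer of
  the commodities it consumes; most technology targets come from here.

This makes target countries collectively hold a minority of world focus
production and makes non-target countries net exporters of it, the
configuration under which research in target countries depresses world
prices and shifts surplus as observed in global priority studies.

Scenario drivers are ordered by construction: with the same seed,
population growth (SSP3 > SSP2 > SSP1), income growth (SSP1 > SSP2 >
SSP3) and climate yield penalties (RCP8.5 > RCP6.0 > RCP4.5) are drawn
from disjoint-or-nested ranges through common uniform deviates, so the
orderings hold per region-year and not just in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (Commodity, MarketCalibration, Region, TargetSpec,
                    TechnologyOption, WorldModel, validate_world)

__all__ = [
    "GeneratorConfig",
    "generate_world",
    "generate_drivers",
    "build_rtb_technologies",
    "default_target_universe",
    "PATHWAYS",
]

PATHWAYS = ("static", "SSP1-RCP4.5", "SSP2-RCP6.0", "SSP3-RCP8.5")

# Annual growth-rate ranges; ordering across SSPs is by construction.
_POP_GROWTH = {"SSP1": (0.002, 0.008), "SSP2": (0.006, 0.012),
               "SSP3": (0.010, 0.018)}
_INC_GROWTH = {"SSP1": (0.020, 0.030), "SSP2": (0.015, 0.025),
               "SSP3": (0.010, 0.020)}
# End-of-horizon climate yield multipliers (linear decline from 1.0).
_CLIM_END = {"RCP4.5": (0.98, 1.00), "RCP6.0": (0.95, 0.99),
             "RCP8.5": (0.90, 0.97)}
_CEILING_FACTOR = {"SSP1": 1.10, "SSP2": 1.00, "SSP3": 0.90}
# Spread of baseline yield growth around each region's demand growth.
_YIELD_GROWTH_NOISE = 0.006


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    n_regions: int = 12
    focus_commodity: str = "potato"
    other_commodities: tuple[str, ...] = ("rice", "wheat")
    target_share: float = 0.75          # fraction of regions target-eligible
    focus_share: float = 0.15           # focus crop share of total production
    total_production: float = 2.5e6     # kt across all commodities
    # elasticity ranges
    demand_own: tuple[float, float] = (-0.8, -0.2)
    demand_cross: tuple[float, float] = (0.0, 0.1)
    income_elast: tuple[float, float] = (0.1, 0.7)
    yield_price_elast: tuple[float, float] = (0.05, 0.3)
    area_own: tuple[float, float] = (0.1, 0.5)
    area_cross: tuple[float, float] = (-0.1, 0.0)
    # base-magnitude ranges
    focus_yield: tuple[float, float] = (8.0, 25.0)     # t/ha
    staple_yield: tuple[float, float] = (2.0, 6.0)
    focus_price: tuple[float, float] = (150.0, 250.0)  # US$/t
    staple_price: tuple[float, float] = (200.0, 450.0)
    import_imbalance: tuple[float, float] = (0.05, 0.15)
    major_exporter_share: tuple[float, float] = (0.30, 0.45)
    major_target_share: tuple[float, float] = (0.20, 0.28)
    small_share_decay: float = 0.7      # geometric decay of small-producer sizes
    years: tuple[int, int] = (2015, 2040)
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError(f"need at least 2 regions, got {self.n_regions}")
        if not 0.0 < self.focus_share < 1.0:
            raise ValueError(f"focus share must be in (0, 1), got {self.focus_share}")
        for name in ("demand_own", "demand_cross", "income_elast",
                     "yield_price_elast", "area_own", "area_cross",
                     "focus_yield", "staple_yield", "focus_price",
                     "staple_price", "import_imbalance",
                     "major_exporter_share", "major_target_share"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name} not ordered: ({lo}, {hi})")
        if not 0.0 < self.small_share_decay <= 1.0:
            raise ValueError("small_share_decay must be in (0, 1], got "
                             f"{self.small_share_decay}")
        if self.years[0] >= self.years[1]:
            raise ValueError(f"empty horizon {self.years}")


def _region_ids(n: int) -> list[str]:
    ids = ["maj_exp"]
    if n >= 3:
        ids.append("maj_tgt")
    ids += [f"sml{i:02d}" for i in range(n - len(ids))]
    return ids


def generate_world(config: GeneratorConfig | None = None) -> WorldModel:
    """Generate a calibrated world; same seed, same world, bit for bit.

    Base-year market clearing is exact by construction: every region
    except the large exporter demands slightly more than it produces,
    and the large exporter's demand is set residually.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    R = config.n_regions
    cids = [config.focus_commodity, *config.other_commodities]
    C = len(cids)
    rids = _region_ids(R)

    # global production per commodity, kt
    totals = np.empty(C)
    totals[0] = config.focus_share * config.total_production
    w = rng.uniform(0.8, 1.2, C - 1) if C > 1 else np.empty(0)
    if C > 1:
        totals[1:] = (1.0 - config.focus_share) * config.total_production \
            * w / w.sum()

    # regional production shares: big rest-of-world bloc, one large
    # target-eligible producer, small producers for the remainder
    # Country production sizes are heavy-tailed in reality; small
    # producers follow a geometrically decaying size profile (with
    # jitter) rather than near-equal shares.
    shares = np.empty((R, C))
    for c in range(C):
        maj = rng.uniform(*config.major_exporter_share)
        n_small = R - 2 if R >= 3 else R - 1
        small_w = (config.small_share_decay ** np.arange(n_small)
                   * rng.uniform(0.9, 1.1, n_small))
        if R >= 3:
            tgt = rng.uniform(*config.major_target_share)
            shares[:, c] = np.concatenate(
                [[maj, tgt], (1.0 - maj - tgt) * small_w / small_w.sum()])
        else:
            shares[:, c] = np.concatenate(
                [[maj], (1.0 - maj) * small_w / small_w.sum()])
    production = shares * totals[None, :]

    yields = np.empty((R, C))
    yields[:, 0] = rng.uniform(*config.focus_yield, R)
    for c in range(1, C):
        yields[:, c] = rng.uniform(*config.staple_yield, R)
    area = production / yields

    prices = np.empty(C)
    prices[0] = rng.uniform(*config.focus_price)
    for c in range(1, C):
        prices[c] = rng.uniform(*config.staple_price)

    # demand: all regions but the large exporter are slight net importers;
    # the exporter's demand closes the market exactly
    demand = np.empty((R, C))
    imb = rng.uniform(*config.import_imbalance, (R - 1, C))
    demand[1:] = production[1:] * (1.0 + imb)
    demand[0] = production.sum(axis=0) - demand[1:].sum(axis=0)
    if np.any(demand[0] <= 0):
        raise ValueError("infeasible config: residual demand of the major "
                         "exporter is non-positive; reduce import_imbalance "
                         "or raise major_exporter_share")

    # Elasticities: each region stands for an aggregate of roughly one
    # country per 2% of world production, and an aggregate's elasticity
    # is a production-average of its members' — so large regions draw
    # the mean of many uniforms (central values), tiny regions a single
    # uniform (full printed spread).
    region_share = production.sum(axis=1) / production.sum()
    n_agg = np.maximum(1, np.floor(region_share / 0.02).astype(int))

    def elast(lo, hi, *shape):
        out = np.empty((R, *shape))
        for r in range(R):
            out[r] = rng.uniform(lo, hi, (n_agg[r], *shape)).mean(axis=0)
        return out

    demand_elast = elast(*config.demand_cross, C, C)
    demand_elast[:, np.arange(C), np.arange(C)] = elast(*config.demand_own, C)
    area_elast = elast(*config.area_cross, C, C)
    area_elast[:, np.arange(C), np.arange(C)] = elast(*config.area_own, C)

    population = 7000.0 * demand.sum(axis=1) / demand.sum() \
        * rng.uniform(0.8, 1.2, R)

    cal = MarketCalibration(
        yield_base=yields, area_base=area, demand_base=demand,
        price_base=prices, price_margin=np.ones((R, C)),
        yield_price_elast=elast(*config.yield_price_elast, C),
        input_price_elast=np.zeros((R, C)),
        area_elast=area_elast, demand_elast=demand_elast,
        income_elast=elast(*config.income_elast, C),
        population_base=population, income_base=np.ones(R),
    )
    world = WorldModel(
        commodities=[Commodity(cids[0], is_focus=True)]
        + [Commodity(c) for c in cids[1:]],
        regions=[Region(r) for r in rids],
        calibration=cal,
        years=np.arange(config.years[0], config.years[1] + 1),
    )
    problems = validate_world(world)
    if problems:  # construction guarantees this never triggers
        raise AssertionError("generator produced an invalid world: "
                             + "; ".join(problems))
    return world


def generate_drivers(pathway: str, world: WorldModel, seed: int):
    """Exogenous driver paths for one pathway.

    The same seed yields comparable draws across pathways (common
    uniform deviates), so SSP/RCP orderings hold per region and year.
    ``static`` freezes every path at 1 (zero growth in all parameters).
    """
    from .model import ScenarioDrivers

    if pathway not in PATHWAYS:
        raise KeyError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    years = np.asarray(world.years)
    T, R, C = len(years), world.n_regions, world.n_commodities
    t = np.arange(T, dtype=float)
    ones_trc = np.ones((T, R, C))
    if pathway == "static":
        return ScenarioDrivers(
            name="static", years=years.copy(),
            pop_mult=np.ones((T, R)), income_mult=np.ones((T, R)),
            yint2=ones_trc, ywat=ones_trc.copy(), yclim=ones_trc.copy(),
            adoption_ceiling_factor=1.0)

    ssp, rcp = pathway.split("-")
    rng = np.random.default_rng([seed, 202])
    u_pop = rng.uniform(size=R)
    u_inc = rng.uniform(size=R)
    u_clim = rng.uniform(size=(R, C))
    u_yg = rng.uniform(size=(R, C))

    lo, hi = _POP_GROWTH[ssp]
    pop_g = lo + (hi - lo) * u_pop
    lo, hi = _INC_GROWTH[ssp]
    inc_g = lo + (hi - lo) * u_inc
    lo, hi = _CLIM_END[rcp]
    clim_end = lo + (hi - lo) * u_clim
    # Business-as-usual productivity growth is calibrated to track each
    # region's demand growth (population plus income effect), as baseline
    # projections do, so base-year trade positions drift only mildly
    # instead of exploding over the horizon.
    demand_growth = pop_g[:, None] \
        + world.calibration.income_elast * inc_g[:, None]
    yg = demand_growth + _YIELD_GROWTH_NOISE * (u_yg - 0.5)

    frac = t / t[-1]
    return ScenarioDrivers(
        name=pathway, years=years.copy(),
        pop_mult=(1.0 + pop_g[None, :]) ** t[:, None],
        income_mult=(1.0 + inc_g[None, :]) ** t[:, None],
        yint2=(1.0 + yg[None, :, :]) ** t[:, None, None],
        ywat=ones_trc.copy(),
        yclim=1.0 + (clim_end[None, :, :] - 1.0) * frac[:, None, None],
        adoption_ceiling_factor=_CEILING_FACTOR[ssp])


# ---------------------------------------------------------------------------
# technology fixtures

# Printed technology parameters: research lag, adoption lag, annual R&D
# cost (million US$), dissemination cost (US$/ha), probability of
# success, max yield change, production cost change, adoption ceiling.
# Scalars are point values; 2-tuples are across-country ranges.
# Reference target-country counts (out of 32 for the largest program)
# set the relative sizes of the scaled-down target sets.
_TECH_TABLE = {
    "improved_seed_systems": dict(
        research_lag=3, adoption_lag=5, annual_rd_cost=8.0,
        dissemination_cost_per_ha=80.0, p=(0.60, 0.80), dyield=0.20,
        dcost=0.20, amax=(0.03, 0.20), n_countries=27, large=False,
        tail=True),
    "bacterial_wilt_resistance": dict(
        research_lag=10, adoption_lag=10, annual_rd_cost=4.0,
        dissemination_cost_per_ha=50.0, p=0.50, dyield=(0.10, 0.30),
        dcost=0.0, amax=(0.10, 0.60), n_countries=22, large=False),
    "virus_resistance": dict(
        research_lag=2, adoption_lag=10, annual_rd_cost=8.0,
        dissemination_cost_per_ha=50.0, p=0.70, dyield=0.40,
        dcost=-0.05, amax=(0.15, 0.40), n_countries=27, large=False),
    "late_blight_resistance": dict(
        research_lag=2, adoption_lag=10, annual_rd_cost=16.0,
        dissemination_cost_per_ha=50.0, p=0.80, dyield=(0.12, 0.32),
        dcost=(-0.05, -0.02), amax=(0.10, 0.60), n_countries=32, large=True),
}

#: Default seed for fixture draws (chosen once; any seed preserves the
#: qualitative structure because the draws are stratified).
DEFAULT_FIXTURE_SEED = 2019


def default_target_universe(world: WorldModel,
                            target_share: float = 0.75) -> list[str]:
    """Region ids eligible as technology targets.

    The large exporter bloc is never a target, and at least one small
    focus-crop producer is always left non-target.
    """
    n = world.n_regions
    size = min(max(1, round(target_share * n)), n - 2)
    if size < 1:
        raise ValueError("world too small to carry a target set")
    return world.region_ids[1:1 + size]


def _stratified(rng: np.random.Generator, value, m: int) -> np.ndarray:
    """m draws spanning a printed range: one per equal-width stratum,
    randomly placed within it, assigned to targets center-out.

    A printed min-max range across countries means countries span the
    range; stratification reproduces that while keeping the
    across-target mean stable.  Targets are ordered by production
    (largest first) and receive strata by distance from the range
    middle — central estimates for the dominant targets, extremes for
    the smallest — so the *production-weighted* mean also stays near
    the range midpoint regardless of the seed.
    """
    if np.isscalar(value):
        return np.full(m, float(value))
    lo, hi = value
    vals = lo + (hi - lo) * (np.arange(m) + rng.uniform(size=m)) / m
    order = sorted(range(m), key=lambda i: (abs(i - (m - 1) / 2.0), i))
    return vals[order]


def build_rtb_technologies(world: WorldModel,
                           seed: int = DEFAULT_FIXTURE_SEED,
                           target_universe: list[str] | None = None
                           ) -> list[TechnologyOption]:
    """The four root-and-tuber research option fixtures.

    Target-set sizes scale the printed country counts onto the world's
    target universe.  Target-set composition is deterministic given the
    world, reflecting the kind of constraint each option addresses:
    only the most widely targeted option (late blight resistance, the
    most widespread constraint) includes the large producer; the two
    variety options for more localized diseases target the largest
    small producers (nested sets); and the seed-system option targets
    the *smallest* producers, where formal seed systems are weakest.
    Per-target values are stratified draws over the printed ranges (see
    :func:`_stratified`).
    """
    universe = (list(target_universe) if target_universe is not None
                else default_target_universe(world))
    for rid in universe:
        world.region_index(rid)  # raises on unknown id
    focus = world.focus_index
    prod = world.calibration.supply_base[:, focus]
    large_id = max(universe, key=lambda rid: prod[world.region_index(rid)])
    # small producers in descending focus-production order (stable)
    smalls = sorted((rid for rid in universe if rid != large_id),
                    key=lambda rid: -prod[world.region_index(rid)])
    max_count = max(spec["n_countries"] for spec in _TECH_TABLE.values())
    rng = np.random.default_rng([seed, 303])

    techs = []
    for name, spec in _TECH_TABLE.items():
        # floor-scale the printed country counts onto the universe so the
        # most widely targeted option keeps a clear target-share margin
        n_t = max(1, int(spec["n_countries"] * len(universe) / max_count))
        if spec["large"]:
            chosen = [large_id] + smalls[:min(n_t - 1, len(smalls))]
        elif spec.get("tail"):
            chosen = smalls[-min(n_t, len(smalls)):]
        else:
            chosen = smalls[:min(n_t, len(smalls))]
        m = len(chosen)  # chosen is in production-descending order
        amax = _stratified(rng, spec["amax"], m)
        dy = _stratified(rng, spec["dyield"], m)
        dc = _stratified(rng, spec["dcost"], m)
        p = _stratified(rng, spec["p"], m)
        techs.append(TechnologyOption(
            name=name, research_lag=spec["research_lag"],
            adoption_lag=spec["adoption_lag"],
            targets={rid: TargetSpec(amax=float(a), dyield=float(y),
                                     dcost=float(c), p_success=float(pp))
                     for rid, a, y, c, pp in zip(chosen, amax, dy, dc, p)},
            annual_rd_cost=spec["annual_rd_cost"],
            dissemination_cost_per_ha=spec["dissemination_cost_per_ha"]))
    return techs
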