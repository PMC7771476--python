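"""Translate research options into supply shifts and yield-trend shocks.

Two equivalent-but-distinct representations of the same technology:

* ``supply_shift_k`` — the proportional *vertical* supply-curve shift of
  classical economic-surplus analysis,
  ``k_t = (dY/eps_s - dC/(1 + dY)) * p * A_t``;
* ``yield_trend_shift`` — the proportional upward shift of the exogenous
  yield-growth trend fed to the equilibrium simulator,
  ``dYInt2 = (dY - dC/(1 + dY)) * p``,

where ``dY`` is the maximum proportional yield change, ``dC`` the
proportional production-cost change, ``p`` the probability of research
success and ``A_t`` the adoption rate.  The two coincide (times supply
elasticity) at full adoption when ``eps_s = 1``.

In the simulator the trend shift is area-weighted by adoption: the
region-level yield multiplier in year t is ``1 + dYInt2 * A(t)``,
reading ``dYInt2`` as the fully-adopted shift and ``A(t)`` as the area
share planted to the new technology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adoption import adopted_area_path, adoption_rate, build_curve
from .model import (AdoptionCurve, MarketTrajectory, ScenarioDrivers,
                    TechnologyOption, WorldModel)

__all__ = ["ShockSpec", "supply_shift_k", "yield_trend_shift",
           "build_shock", "cost_stream"]


def supply_shift_k(dyield: float, eps_s: float, dcost: float, p: float,
                   a_t) -> float | np.ndarray:
    """Proportional vertical supply shift k_t; zero at zero adoption."""
    if eps_s <= 0:
        raise ValueError(f"supply elasticity must be positive, got {eps_s}")
    if dyield <= -1.0:
        raise ValueError(f"yield change must exceed -1, got {dyield}")
    a_t = np.asarray(a_t, dtype=float)
    if np.any((a_t < 0) | (a_t > 1)):
        raise ValueError("adoption rate outside [0, 1]")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability of success outside [0, 1]: {p}")
    out = (dyield / eps_s - dcost / (1.0 + dyield)) * p * a_t
    return float(out) if out.ndim == 0 else out


def yield_trend_shift(dyield: float, dcost: float, p: float) -> float:
    """Proportional shift of the exogenous yield trend, dYInt2.

    Collapses to ``dY * p`` when costs are unchanged; cost savings
    (negative dC) increase the shift.
    """
    if dyield <= -1.0:
        raise ValueError(f"yield change must exceed -1, got {dyield}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability of success outside [0, 1]: {p}")
    return (dyield - dcost / (1.0 + dyield)) * p


@dataclass
class ShockSpec:
    """Per-(year, region, commodity) technology shock for one option.

    ``multiplier`` (T, R, C) scales yields in the equilibrium model and
    is exactly 1 for non-target regions, non-focus commodities, and
    pre-release years.  ``k`` holds the equivalent classical supply
    shift per cell for audit and for the static surplus oracle.
    """

    technology: str
    release_year: int
    multiplier: np.ndarray
    k: np.ndarray
    curves: dict[str, AdoptionCurve]  # region id -> solved curve

    def to_frame(self, world: WorldModel) -> pd.DataFrame:
        """Audit table of non-trivial shock cells."""
        t, r, c = np.nonzero(self.multiplier != 1.0)
        return pd.DataFrame({
            "year": np.asarray(world.years)[t],
            "region": np.asarray(world.region_ids)[r],
            "commodity": np.asarray(world.commodity_ids)[c],
            "multiplier": self.multiplier[t, r, c],
            "k": self.k[t, r, c],
        })


def build_shock(world: WorldModel, tech: TechnologyOption,
                drivers: ScenarioDrivers) -> ShockSpec:
    """Build the yield-shock specification for one technology.

    Adoption ceilings are scaled by the scenario's adoption-ceiling
    factor (clamped to 1).  The release year is the first simulation
    year plus the research lag.
    """
    problems = tech.validate()
    if problems:
        raise ValueError("; ".join(problems))
    years = np.asarray(world.years)
    release = int(years[0]) + tech.research_lag
    if release > int(years[-1]):
        raise ValueError(
            f"{tech.name}: release year {release} beyond horizon end {years[-1]}")
    T, R, C = world.n_years, world.n_regions, world.n_commodities
    focus = world.focus_index
    mult = np.ones((T, R, C))
    k = np.zeros((T, R, C))
    eps_s = world.calibration.supply_elasticity()
    curves: dict[str, AdoptionCurve] = {}
    after = years >= release
    for rid, spec in tech.targets.items():
        r = world.region_index(rid)
        amax_eff = min(spec.amax * drivers.adoption_ceiling_factor, 1.0)
        curve = build_curve(amax_eff, release, tech.adoption_lag)
        curves[rid] = curve
        a_t = np.where(after, adoption_rate(curve, years), 0.0)
        dyint2 = yield_trend_shift(spec.dyield, spec.dcost, spec.p_success)
        mult[:, r, focus] = 1.0 + dyint2 * a_t
        k[:, r, focus] = supply_shift_k(spec.dyield, eps_s[r, focus],
                                        spec.dcost, spec.p_success, a_t)
    return ShockSpec(technology=tech.name, release_year=release,
                     multiplier=mult, k=k, curves=curves)


def cost_stream(tech: TechnologyOption, world: WorldModel, shock: ShockSpec,
                trajectory: MarketTrajectory) -> np.ndarray:
    """Per-year R&D plus dissemination costs, million US$.

    R&D costs accrue at the annual rate during each year of the research
    lag.  Dissemination costs are the per-hectare figure times the
    marginal (newly) adopted area each year, taken from the realized
    harvested-area path of the given (shocked) trajectory.
    """
    years = np.asarray(world.years)
    stream = np.zeros(len(years))
    stream[: tech.research_lag] += tech.annual_rd_cost
    focus = world.focus_index
    for rid, curve in shock.curves.items():
        r = world.region_index(rid)
        _, marginal_kha = adopted_area_path(
            curve, years, trajectory.area[:, r, focus], shock.release_year)
        # kha * US$/ha: 1 kha = 1e3 ha; 1e6 US$ = 1 million => /1e3
        stream += tech.dissemination_cost_per_ha * marginal_kha / 1e3
    return stream
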