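"""Recursive-dynamic multi-region multi-commodity market simulator.

Each year, supply in every region is yield times harvested area, both
constant-elasticity (log-linear) responses to producer prices around the
base-year calibration point:

    Y = YInt * YInt2(t) * YWat(t) * YClim(t) * (PS/PS0)^eps * (PF/PF0)^eta * shock(t)
    A = A0 * prod_j (P_j/P0_j)^(area elasticity w.r.t. j)

Demand is log-linear in consumer prices with population and income
drivers:

    D = D0 * pop(t) * inc(t)^(income elasticity) * prod_j (P_j/P0_j)^(demand elasticity w.r.t. j)

Regions trade at a single world price per commodity (domestic prices are
the world price times a fixed margin, 1 by default); net trade closes
each region's balance, and the world price vector is solved each year so
global excess demand vanishes per commodity.  Years are coupled only
through the exogenous driver paths and the solver's warm start.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .model import MarketTrajectory, ScenarioDrivers, WorldModel
from .shocks import ShockSpec

__all__ = [
    "ConvergenceError",
    "compute_yield",
    "compute_area",
    "compute_demand",
    "excess_demand",
    "solve_year",
    "run_scenario",
    "SOLVER_TOL",
]

#: Convergence requirement: |excess demand| / base global demand per commodity.
SOLVER_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """World-price solver failed; carries the residual report."""

    def __init__(self, year: int, residuals: np.ndarray, commodities: list[str]):
        self.year = year
        self.residuals = residuals
        report = ", ".join(f"{c}={r:.3e}" for c, r in zip(commodities, residuals))
        super().__init__(
            f"market clearing failed in year {year}: relative excess demand {report}")


def _year_index(world: WorldModel, year: int) -> int:
    years = np.asarray(world.years)
    idx = np.searchsorted(years, year)
    if idx >= len(years) or years[idx] != year:
        raise ValueError(f"year {year} outside horizon {years[0]}..{years[-1]}")
    return int(idx)


def _price_ratio_log(world: WorldModel, domestic_price: np.ndarray) -> np.ndarray:
    base = world.calibration.domestic_price_base
    return np.log(domestic_price / base)


def compute_yield(world: WorldModel, drivers: ScenarioDrivers,
                  shock: ShockSpec | None, year: int,
                  domestic_price: np.ndarray,
                  input_price: float | None = None) -> np.ndarray:
    """Per-(region, commodity) yields, t/ha, at the given prices."""
    if np.any(domestic_price <= 0):
        raise ValueError("prices must be strictly positive")
    cal = world.calibration
    t = _year_index(world, year)
    pf = cal.input_price_base if input_price is None else input_price
    if pf <= 0:
        raise ValueError("input price must be strictly positive")
    logp = _price_ratio_log(world, domestic_price)
    y = (cal.yield_base
         * drivers.yint2[t] * drivers.ywat[t] * drivers.yclim[t]
         * np.exp(cal.yield_price_elast * logp)
         * (pf / cal.input_price_base) ** cal.input_price_elast)
    if shock is not None:
        y = y * shock.multiplier[t]
    return y


def compute_area(world: WorldModel, year: int,
                 domestic_price: np.ndarray) -> np.ndarray:
    """Per-(region, commodity) harvested areas, kha, at the given prices."""
    if np.any(domestic_price <= 0):
        raise ValueError("prices must be strictly positive")
    cal = world.calibration
    _year_index(world, year)  # bounds check; area has no direct time dependence
    logp = _price_ratio_log(world, domestic_price)
    return cal.area_base * np.exp(np.einsum("rcj,rj->rc", cal.area_elast, logp))


def compute_demand(world: WorldModel, drivers: ScenarioDrivers, year: int,
                   domestic_price: np.ndarray) -> np.ndarray:
    """Per-(region, commodity) demand, kt, at the given prices."""
    if np.any(domestic_price <= 0):
        raise ValueError("prices must be strictly positive")
    cal = world.calibration
    t = _year_index(world, year)
    logp = _price_ratio_log(world, domestic_price)
    return (cal.demand_base
            * drivers.pop_mult[t][:, None]
            * drivers.income_mult[t][:, None] ** cal.income_elast
            * np.exp(np.einsum("rcj,rj->rc", cal.demand_elast, logp)))


def excess_demand(world: WorldModel, drivers: ScenarioDrivers,
                  shock: ShockSpec | None, year: int,
                  world_price: np.ndarray) -> np.ndarray:
    """Global demand minus global supply per commodity, kt."""
    ps = world_price[None, :] * world.calibration.price_margin
    supply = (compute_yield(world, drivers, shock, year, ps)
              * compute_area(world, year, ps))
    demand = compute_demand(world, drivers, year, ps)
    return demand.sum(axis=0) - supply.sum(axis=0)


def _trajectory_slice(world, drivers, shock, year, world_price):
    ps = world_price[None, :] * world.calibration.price_margin
    yields = compute_yield(world, drivers, shock, year, ps)
    area = compute_area(world, year, ps)
    demand = compute_demand(world, drivers, year, ps)
    return ps, yields, area, yields * area, demand


def _newton_polish(residual, x, tol, max_iter=60, fd_step=1e-7):
    """Damped Newton iterations with finite-difference Jacobians."""
    n = len(x)
    f = residual(x)
    for _ in range(max_iter):
        if np.all(np.abs(f) <= tol):
            break
        jac = np.empty((n, n))
        for j in range(n):
            xp = x.copy()
            xp[j] += fd_step
            jac[:, j] = (residual(xp) - f) / fd_step
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            break
        damp = 1.0
        for _ in range(30):
            f_new = residual(x + damp * step)
            if np.linalg.norm(f_new) < np.linalg.norm(f):
                x = x + damp * step
                f = f_new
                break
            damp /= 2.0
        else:
            break
    return x, f


def solve_year(world: WorldModel, drivers: ScenarioDrivers,
               shock: ShockSpec | None, year: int,
               prior_world_price: np.ndarray | None = None,
               tol: float = SOLVER_TOL) -> tuple[np.ndarray, tuple]:
    """Solve the world price vector clearing all commodity markets.

    Root-finding runs on log price ratios (guaranteeing positive
    prices), warm-started at the previous year's solution.  Returns the
    world price vector and the (price, yield, area, supply, demand)
    slice; raises :class:`ConvergenceError` with a residual report when
    the relative excess demand cannot be brought below ``tol``.
    """
    cal = world.calibration
    base_price = np.asarray(cal.price_base, dtype=float)
    scale = np.asarray(cal.demand_base).sum(axis=0)  # base global demand, kt

    def residual(x: np.ndarray) -> np.ndarray:
        wp = base_price * np.exp(x)
        return excess_demand(world, drivers, shock, year, wp) / scale

    x0 = (np.zeros(world.n_commodities) if prior_world_price is None
          else np.log(prior_world_price / base_price))
    sol = optimize.root(residual, x0, method="hybr",
                        options={"xtol": 1e-12, "maxfev": 400 * (len(x0) + 1)})
    x, res = sol.x, residual(sol.x)
    if not np.all(np.abs(res) <= tol):
        # hybr's initial trust radius scales with |x0| and can stall on a
        # near-zero warm start; polish with damped Newton (the system is
        # small, smooth and log-linear, so Newton converges quadratically)
        x, res = _newton_polish(residual, x, tol)
    if not np.all(np.abs(res) <= tol):
        raise ConvergenceError(year, res, world.commodity_ids)
    world_price = base_price * np.exp(x)
    return world_price, _trajectory_slice(world, drivers, shock, year, world_price)


def run_scenario(world: WorldModel, drivers: ScenarioDrivers,
                 shock: ShockSpec | None = None) -> MarketTrajectory:
    """Solve every horizon year and assemble the full trajectory.

    With no shock and static drivers every solved year reproduces the
    base-year calibration point (the static counterfactual emulating a
    comparative-static surplus analysis).
    """
    years = np.asarray(world.years)
    if not np.array_equal(np.asarray(drivers.years), years):
        raise ValueError("drivers do not cover the world's horizon")
    T, R, C = world.n_years, world.n_regions, world.n_commodities
    wp = np.empty((T, C))
    price = np.empty((T, R, C))
    yields = np.empty((T, R, C))
    area = np.empty((T, R, C))
    supply = np.empty((T, R, C))
    demand = np.empty((T, R, C))
    prior = None
    for t, year in enumerate(years):
        wp[t], (price[t], yields[t], area[t], supply[t], demand[t]) = \
            solve_year(world, drivers, shock, int(year), prior)
        prior = wp[t]
    return MarketTrajectory(years=years.copy(), world_price=wp, price=price,
                            yields=yields, area=area, supply=supply,
                            demand=demand)
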