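"""Economic-surplus accounting, investment metrics, and ranking.

Welfare changes are measured on the focus commodity only: when a shock
is introduced in one market, the new multi-market equilibrium already
reflects adjustments in related markets, so summing surplus across
markets would double-count.

Surplus accounting linearizes demand and supply at each region's
*baseline* equilibrium point.  Consumer surplus changes integrate the
baseline-linearized demand curve between the baseline and shocked
prices; producer surplus changes compare the untruncated triangles
above parallel supply lines (baseline slope), the shifted one displaced
by the known proportional shift k — the classical parallel-shift
accounting, which reproduces the economic-surplus closed forms exactly
in the linear limit:

    Z   = k * eps_s / (eps_s + eta)
    dCS = P0*Q0 * Z * (1 + 0.5*Z*eta)
    dPS = P0*Q0 * (k - Z) * (1 + 0.5*Z*eta)

with k the proportional vertical supply shift, eta the demand
elasticity magnitude and eps_s the supply elasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MarketTrajectory, TechnologyOption, WorldModel

__all__ = [
    "consumer_surplus", "producer_surplus", "alston_oracle",
    "WelfareStreams", "welfare_change",
    "npv", "irr", "mirr",
    "WelfareReport", "build_report", "rank_technologies",
]

DEFAULT_DISCOUNT_RATE = 0.10


# ---------------------------------------------------------------------------
# surplus levels and changes

def consumer_surplus(price: float, quantity: float, demand_elast: float) -> float:
    """Triangle under the linearized demand through (Q, P): Q*P / (2|eps|)."""
    if demand_elast >= 0:
        raise ValueError(f"demand own-price elasticity must be negative, got {demand_elast}")
    if price <= 0 or quantity <= 0:
        raise ValueError("price and quantity must be strictly positive")
    return quantity * price / (2.0 * abs(demand_elast))


def producer_surplus(price: float, quantity: float, supply_elast: float) -> float:
    """Surplus above the linearized supply through (Q, P), truncated at P=0.

    ``Q*P/(2*eps_s)`` when the supply line meets the price axis
    (eps_s >= 1); otherwise the trapezoid ``P*(Q - eps_s*Q/2)``.
    """
    if supply_elast <= 0:
        raise ValueError(f"supply elasticity must be positive, got {supply_elast}")
    if price <= 0 or quantity <= 0:
        raise ValueError("price and quantity must be strictly positive")
    if supply_elast >= 1.0:
        return quantity * price / (2.0 * supply_elast)
    return price * (quantity - supply_elast * quantity / 2.0)


def _delta_cs(p0, q0, p1, demand_elast):
    """CS change along the baseline-linearized demand curve (vectorized)."""
    q_on_line = q0 * (1.0 + demand_elast * (p1 - p0) / p0)
    return (p0 - p1) * (q0 + q_on_line) / 2.0


def _delta_ps(p0, q0s, p1, k, supply_elast):
    """PS change along the baseline-linearized supply, shifted by k (vectorized).

    The supply line through the baseline point, with slope
    b = eps_s*Q0/P0, shifts down by k*P0 in the price direction.  The
    untruncated triangle difference Q^2/(2b) between the shifted and
    unshifted lines reduces to a trapezoid in the price direction,

        dPS = (P1 - P0 + k*P0) * (Q0 + Q1_line) / 2,

    with Q1_line = Q0 * (1 + eps_s*((P1 - P0)/P0 + k)) the post-change
    quantity on the shifted line.  For a vertical shift of a linear
    supply this equals the classical (k - Z)(1 + 0.5*Z*eta) result for
    any supply elasticity.  Using the known shift k (zero where no
    technology is adopted) rather than backing it out of simulated
    quantities keeps the accounting insensitive to small cross-market
    quantity adjustments, which the triangle-difference form would
    otherwise magnify by 1/eps_s.
    """
    q_on_line = q0s * (1.0 + supply_elast * ((p1 - p0) / p0 + k))
    return (p1 - p0 + k * p0) * (q0s + q_on_line) / 2.0


def alston_oracle(k: float, p0: float, q0: float, eta: float,
                  eps_s: float) -> tuple[float, float, float]:
    """Closed-form single-market surplus changes for a supply shift k.

    ``eta`` is the demand elasticity magnitude (> 0).  Guards against
    shifts large enough to push the linear model outside its domain.
    """
    if min(p0, q0, eta, eps_s) <= 0:
        raise ValueError("p0, q0, eta and eps_s must all be positive")
    if not 0.0 <= k < eps_s / (1.0 + eta):
        raise ValueError(
            f"shift k={k} outside the safeguard [0, {eps_s / (1 + eta):.3f})")
    z = k * eps_s / (eps_s + eta)
    dcs = p0 * q0 * z * (1.0 + 0.5 * z * eta)
    dps = p0 * q0 * (k - z) * (1.0 + 0.5 * z * eta)
    return dcs, dps, dcs + dps


@dataclass
class WelfareStreams:
    """Per-year focus-market surplus changes by country group, million US$."""

    years: np.ndarray
    dcs: dict[str, np.ndarray]  # group -> (T,)
    dps: dict[str, np.ndarray]

    @property
    def groups(self) -> list[str]:
        return list(self.dcs)


def welfare_change(world: WorldModel, baseline: MarketTrajectory,
                   shocked: MarketTrajectory,
                   target_regions: set[str] | list[str],
                   supply_shift: np.ndarray | None = None) -> WelfareStreams:
    """Focus-market surplus change streams for target / non-target / all.

    ``supply_shift`` is the proportional vertical supply shift k per
    (year, region) in the focus market (``ShockSpec.k`` sliced at the
    focus commodity); ``None`` means no shift anywhere.  Per
    region-year, quantities are in kt and prices in US$/t, so the raw
    surplus product is thousand US$; results are converted to million
    US$.  Aggregation is additive: ``all = target + non_target`` per
    year, exactly.
    """
    if not np.array_equal(baseline.years, shocked.years):
        raise ValueError("trajectories do not share a horizon")
    cal = world.calibration
    f = world.focus_index
    eta = np.einsum("rcc->rc", cal.demand_elast)[:, f]     # negative
    eps_s = cal.supply_elasticity()[:, f]
    p0 = baseline.price[:, :, f]
    p1 = shocked.price[:, :, f]
    if supply_shift is None:
        supply_shift = np.zeros_like(p0)
    elif np.shape(supply_shift) != p0.shape:
        raise ValueError(f"supply_shift must have shape {p0.shape}, "
                         f"got {np.shape(supply_shift)}")

    dcs = _delta_cs(p0, baseline.demand[:, :, f], p1, eta[None, :]) / 1e3
    dps = _delta_ps(p0, baseline.supply[:, :, f], p1,
                    supply_shift, eps_s[None, :]) / 1e3

    target_regions = set(target_regions)
    unknown = target_regions - set(world.region_ids)
    if unknown:
        raise KeyError(f"unknown target regions: {sorted(unknown)}")
    is_target = np.array([r in target_regions for r in world.region_ids])
    return WelfareStreams(
        years=baseline.years.copy(),
        dcs={"target": dcs[:, is_target].sum(axis=1),
             "non_target": dcs[:, ~is_target].sum(axis=1),
             "all": dcs.sum(axis=1)},
        dps={"target": dps[:, is_target].sum(axis=1),
             "non_target": dps[:, ~is_target].sum(axis=1),
             "all": dps.sum(axis=1)},
    )


# ---------------------------------------------------------------------------
# investment metrics

def npv(stream, rate: float) -> float:
    """Net present value; t = 0 at the first entry (study launch year)."""
    if rate <= -1.0:
        raise ValueError(f"discount rate must exceed -1, got {rate}")
    stream = np.asarray(stream, dtype=float)
    t = np.arange(len(stream))
    return float(np.sum(stream / (1.0 + rate) ** t))


def irr(stream) -> float:
    """Internal rate of return: the smallest real rate above -1 zeroing NPV.

    Found as a root of the NPV polynomial in the discount factor
    x = 1/(1+r); raises ``ValueError`` when the stream has no sign
    change (IRR undefined).
    """
    stream = np.asarray(stream, dtype=float)
    signs = np.sign(stream[stream != 0])
    if len(signs) == 0 or np.all(signs == signs[0]):
        raise ValueError("IRR undefined: cash-flow stream has no sign change")
    # npv(x) = sum_t c_t x^t; np.roots wants highest power first
    roots = np.roots(stream[::-1])
    real = roots[np.abs(roots.imag) < 1e-9].real
    rates = 1.0 / real[real > 0] - 1.0
    rates = rates[rates > -1.0]
    if len(rates) == 0:
        raise ValueError("IRR undefined: no real root above -1")
    r = float(np.min(rates))
    # polish: np.roots is accurate but polish to the stated tolerance anyway
    for _ in range(60):
        x = 1.0 / (1.0 + r)
        t = np.arange(len(stream))
        f = np.sum(stream * x ** t)
        df = np.sum(stream * t * x ** (t - 1)) * (-(x ** 2))
        if df == 0 or abs(f) < 1e-12:
            break
        r -= f / df
    return r


def mirr(stream, finance_rate: float = DEFAULT_DISCOUNT_RATE,
         reinvest_rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Modified internal rate of return.

    Future value of positive flows compounded at the reinvestment rate
    over |present value of negative flows| discounted at the finance
    rate, annualized over the n periods after the first.
    """
    stream = np.asarray(stream, dtype=float)
    if not (np.any(stream > 0) and np.any(stream < 0)):
        raise ValueError("MIRR undefined: need at least one negative and one "
                         "positive cash flow")
    n = len(stream) - 1
    t = np.arange(len(stream))
    fv_pos = np.sum(np.where(stream > 0, stream, 0.0)
                    * (1.0 + reinvest_rate) ** (n - t))
    pv_neg = np.sum(np.where(stream < 0, -stream, 0.0)
                    / (1.0 + finance_rate) ** t)
    return float((fv_pos / pv_neg) ** (1.0 / n) - 1.0)


# ---------------------------------------------------------------------------
# reports and ranking

@dataclass
class WelfareReport:
    """Benefit-cost results for one technology x scenario x aggregation."""

    technology: str
    scenario: str
    aggregation: str            # "all" or "target"
    dps_npv: float              # million US$
    dcs_npv: float
    cost_npv: float
    net_benefits: float         # NPV(dPS + dCS) - NPV(costs)
    irr: float | None
    mirr: float | None
    discount_rate: float
    # undiscounted per-year streams retained for audit
    years: np.ndarray = field(repr=False, default=None)
    dps_stream: np.ndarray = field(repr=False, default=None)
    dcs_stream: np.ndarray = field(repr=False, default=None)
    cost_stream: np.ndarray = field(repr=False, default=None)

    @property
    def net_stream(self) -> np.ndarray:
        return self.dps_stream + self.dcs_stream - self.cost_stream


def build_report(tech: TechnologyOption, scenario: str, streams: WelfareStreams,
                 costs: np.ndarray, aggregation: str,
                 discount_rate: float = DEFAULT_DISCOUNT_RATE) -> WelfareReport:
    """Assemble benefit-cost metrics from surplus and cost streams.

    ``aggregation`` selects which country group's surplus streams the
    benefits are summed over ("all" or "target"); the full program cost
    stream is charged in both cases.
    """
    if aggregation not in streams.dcs:
        raise KeyError(f"aggregation {aggregation!r} not in {streams.groups}")
    dps_s = streams.dps[aggregation]
    dcs_s = streams.dcs[aggregation]
    net = dps_s + dcs_s - costs
    try:
        irr_val: float | None = irr(net)
    except ValueError:
        irr_val = None
    try:
        mirr_val: float | None = mirr(net, discount_rate, discount_rate)
    except ValueError:
        mirr_val = None
    return WelfareReport(
        technology=tech.name, scenario=scenario, aggregation=aggregation,
        dps_npv=npv(dps_s, discount_rate), dcs_npv=npv(dcs_s, discount_rate),
        cost_npv=npv(costs, discount_rate),
        net_benefits=npv(dps_s + dcs_s, discount_rate) - npv(costs, discount_rate),
        irr=irr_val, mirr=mirr_val, discount_rate=discount_rate,
        years=streams.years, dps_stream=dps_s, dcs_stream=dcs_s,
        cost_stream=costs,
    )


def reports_to_frame(reports: list[WelfareReport]) -> pd.DataFrame:
    """Tabular view of a report set (one row per tech/scenario/aggregation)."""
    return pd.DataFrame([{
        "technology": r.technology, "scenario": r.scenario,
        "aggregation": r.aggregation, "producer_surplus_npv": r.dps_npv,
        "consumer_surplus_npv": r.dcs_npv, "cost_npv": r.cost_npv,
        "net_benefits_npv": r.net_benefits, "irr": r.irr, "mirr": r.mirr,
        "discount_rate": r.discount_rate,
    } for r in reports])


def rank_technologies(reports: list[WelfareReport],
                      metric: str = "npv") -> list[str]:
    """Technologies in descending order of the chosen metric.

    All reports must share one scenario and aggregation.  Ties are
    broken alphabetically by technology name for determinism.
    """
    key = {"npv": lambda r: r.net_benefits,
           "irr": lambda r: r.irr,
           "mirr": lambda r: r.mirr}.get(metric)
    if key is None:
        raise KeyError(f"unknown metric {metric!r}; use npv, irr or mirr")
    if len({(r.scenario, r.aggregation) for r in reports}) != 1:
        raise ValueError("reports must share a common scenario and aggregation")
    values = [key(r) for r in reports]
    if any(v is None for v in values):
        raise ValueError(f"metric {metric!r} undefined for some technology")
    return [r.technology
            for r in sorted(reports, key=lambda r: (-key(r), r.technology))]
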