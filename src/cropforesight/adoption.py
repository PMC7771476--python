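"""Logistic technology diffusion and adopted-area accounting.

Adoption follows the logistic curve

    A(t) = Amax / (1 + exp(-(alpha + beta * t)))

with ``(alpha, beta)`` pinned by two anchor points: the initial adoption
rate ``A0`` at the release year ``t0`` and the half-ceiling rate
``Amax/2`` at ``tmid``.  Closed form:

    beta  = ln(Amax/A0 - 1) / (tmid - t0)
    alpha = -beta * tmid
"""

from __future__ import annotations

import numpy as np

from .model import AdoptionCurve

__all__ = [
    "solve_logistic_params",
    "adoption_rate",
    "build_curve",
    "adopted_area_path",
]

#: Default initial adoption rate as a fraction of the (effective) ceiling.
DEFAULT_A0_FRACTION = 0.005


def solve_logistic_params(a0: float, amax: float, t0: float, tmid: float
                          ) -> tuple[float, float]:
    """Solve (alpha, beta) so the curve passes through (t0, a0) and
    (tmid, amax/2) exactly.

    Raises ``ValueError`` when no rising logistic (beta > 0) can pass
    through both anchors, i.e. when ``a0 >= amax/2`` with ``t0 < tmid``.
    """
    if not (0.0 < a0 < amax <= 1.0):
        raise ValueError(f"need 0 < A0 < Amax <= 1, got A0={a0}, Amax={amax}")
    if not t0 < tmid:
        raise ValueError(f"need t0 < tmid, got t0={t0}, tmid={tmid}")
    if a0 >= amax / 2.0:
        raise ValueError(
            f"A0={a0} >= Amax/2={amax / 2}: a rising logistic cannot pass "
            "through both anchor points")
    beta = np.log(amax / a0 - 1.0) / (tmid - t0)
    alpha = -beta * tmid
    return float(alpha), float(beta)


def adoption_rate(curve: AdoptionCurve, t) -> np.ndarray | float:
    """Adoption rate A(t) in (0, Amax); monotone non-decreasing in t.

    ``t`` is a calendar year (scalar or array) on the same axis the
    curve was solved on.
    """
    t = np.asarray(t, dtype=float)
    out = curve.amax / (1.0 + np.exp(-(curve.alpha + curve.beta * t)))
    return float(out) if out.ndim == 0 else out


def build_curve(amax: float, release_year: int, adoption_lag: int,
                a0_fraction: float = DEFAULT_A0_FRACTION) -> AdoptionCurve:
    """Construct a solved curve from technology lag semantics.

    The curve starts at ``a0_fraction * amax`` in the release year and
    reaches half its ceiling at ``release_year + adoption_lag / 2``, so
    adoption is effectively complete by the end of the adoption lag.
    """
    a0 = a0_fraction * amax
    t0 = float(release_year)
    tmid = release_year + adoption_lag / 2.0
    alpha, beta = solve_logistic_params(a0, amax, t0, tmid)
    return AdoptionCurve(amax=amax, a0=a0, t0=t0, tmid=tmid,
                         alpha=alpha, beta=beta)


def adopted_area_path(curve: AdoptionCurve, years: np.ndarray,
                      harvested_area: np.ndarray, release_year: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Adopted and newly adopted (marginal) area per year, kha.

    ``adopted[t] = A(t) * area[t]`` for years at or after the release
    year, zero before; ``marginal[t] = max(0, adopted[t] - adopted[t-1])``
    (no refunds when total harvested area shrinks).
    """
    years = np.asarray(years)
    harvested_area = np.asarray(harvested_area, dtype=float)
    if harvested_area.shape != years.shape:
        raise ValueError("harvested-area path must cover the horizon")
    if not (years[0] <= release_year <= years[-1]):
        raise ValueError(f"release year {release_year} outside horizon "
                         f"{years[0]}..{years[-1]}")
    rates = np.where(years >= release_year, adoption_rate(curve, years), 0.0)
    adopted = rates * harvested_area
    marginal = np.maximum(0.0, np.diff(adopted, prepend=0.0))
    return adopted, marginal
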