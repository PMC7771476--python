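# Methods

This note records the model equations, the synthetic-world generator's
design rationale, the numerical choices, and the limitations of the
package. Units throughout: area in thousand hectares (kha), yield in
t/ha, quantities in thousand tonnes (kt), prices in US$/t, money in
million US$ at constant prices.

## 1. Market core

The world holds R regions and C commodities, one of which is the
*focus* crop receiving research shocks. Each region's behavior is a
constant-elasticity (log-linear) displacement from a calibrated base
year.

**Supply** is yield times harvested area:

    Y_rc(t) = Y0_rc · YInt2_rc(t) · YWat_rc(t) · YClim_rc(t)
              · (PS_rc / PS0_rc)^eps_rc · (PF / PF0)^theta_rc · M_rc(t)
    A_rc(t) = A0_rc · prod_j (PS_rj / PS0_rj)^gamma_rcj
    S_rc(t) = Y_rc(t) · A_rc(t)

where `YInt2`, `YWat`, `YClim` are exogenous productivity, water and
climate paths (all 1 in the static scenario), `eps` is the own-price
yield elasticity, `theta` the (input-price) elasticity against the
exogenous input price index `PF`, `gamma` the area elasticity tensor,
and `M_rc(t)` the technology yield multiplier (Section 3).

**Demand** is log-linear in consumer prices with population and income
drivers:

    D_rc(t) = D0_rc · pop_r(t) · inc_r(t)^mu_rc · prod_j (PD_rj / PD0_rj)^eta_rcj

**Market clearing.** Regions trade at a single world price per
commodity (domestic prices are the world price times a fixed margin,
1 by default). Each year the world price vector P(t) solves

    sum_r D_rc(t) - sum_r S_rc(t) = 0   for every commodity c.

Years are coupled only through the exogenous driver paths and the
solver's warm start (a recursive-dynamic, not intertemporal, model).
The region-level own-price supply elasticity used in surplus accounting
is `eps_s = eps + gamma_own` (yield plus own-price area response).

With static drivers and no shock, every solved year reproduces the base
year to machine precision — the classical comparative-static baseline
is a special case of the simulator, which is what makes the static vs
foresight comparison internally consistent.

## 2. Adoption

Diffusion is logistic: `A(t) = Amax / (1 + exp(-(alpha + beta·t)))`,
with the two parameters pinned by two anchors — the initial rate
`A0 = 0.005·Amax` in the release year `t0`, and `Amax/2` at
`tmid = t0 + adoption_lag/2` — giving the closed form

    beta  = ln(Amax/A0 - 1) / (tmid - t0)
    alpha = -beta · tmid.

The release year is the first simulation year plus the research lag.
Scenario optimism scales the ceiling (`Amax` times an SSP-dependent
factor, clamped at 1). Adopted area is `A(t)` times realized harvested
area, zero before release; newly adopted (marginal) area is clamped at
zero so a shrinking harvested area never generates negative
dissemination costs.

## 3. Research shocks

A research option is parameterized per target country by the maximum
proportional yield change `dY`, the proportional production-cost change
`dC`, the probability of research success `p`, and the adoption ceiling
`Amax`. Two equivalent representations are kept:

* the classical proportional **vertical supply shift**

      k(t) = (dY/eps_s - dC/(1 + dY)) · p · A(t),

  used for surplus accounting and auditable per cell; and
* the **yield-trend shift** fed to the simulator,

      dYInt2 = (dY - dC/(1 + dY)) · p,

  entering as the multiplier `M(t) = 1 + dYInt2 · A(t)` on the focus
  crop's yield in target regions (adoption-area-weighted, reading
  `dYInt2` as the fully-adopted shift).

Costs: R&D accrues at the annual rate during the research lag;
dissemination costs are per newly adopted hectare along the realized
(shocked) area path.

## 4. Welfare accounting

Welfare is measured on the focus market only: the multi-market
equilibrium already internalizes adjustments in related markets, so
summing surplus across markets would double-count. Per region-year,
demand and supply are linearized at the *baseline* equilibrium point
(P0, Q0):

* **Consumers:** `dCS = (P0 - P1)(Q0 + Q1d)/2` with
  `Q1d = Q0(1 + eta·(P1 - P0)/P0)` — the trapezoid under the
  baseline-linearized demand between the two prices.
* **Producers:** the baseline-slope supply line shifts down by `k·P0`
  (the known shift from Section 3, zero in non-target regions), and

      dPS = (P1 - P0 + k·P0)(Q0 + Q1s)/2,
      Q1s = Q0(1 + eps_s·((P1 - P0)/P0 + k)).

  For a vertical shift of a linear supply this equals the classical
  closed forms exactly for any supply elasticity:

      Z   = k·eps_s / (eps_s + eta)
      dCS = P0·Q0·Z(1 + 0.5·Z·eta)
      dPS = P0·Q0·(k - Z)(1 + 0.5·Z·eta).

  Using the *known* shift rather than backing it out of simulated
  quantities matters in the multi-market setting: cross-commodity price
  adjustments move region-level quantities by small amounts that a
  triangle-difference accounting would misread as supply shifts and
  value at slope `P0/(eps_s·Q0)` — an error amplified by `1/eps_s`.
  With the known shift, a non-target region's welfare reduces to
  `z·P0·(D0 - S0) + O(z²)` (z the relative price fall): consumers gain,
  producers lose, and the net is negative exactly when the region is a
  net exporter.

Aggregation is additive and exact: `all = target + non_target` per
year. Benefit-cost metrics are NPV at a 10% default discount rate,
IRR (smallest real root above −100% of the NPV polynomial, with a
Newton polish) and MIRR (future value of positive flows over present
value of negatives, annualized). Rankings sort by the chosen metric
with alphabetical tie-breaking for determinism.

Because the simulator's curves are log-linear while the closed forms
are linear, the two agree only up to curvature. The acceptance test
compares them after recovering the *realized* vertical shift
`k_eff = (Q1/Q0 - 1)/eps_s + z` from the solved equilibrium, so that
both sides price the same displacement; remaining deviations are pure
curvature and stay under 2% for shifts up to 5% across the tested
elasticity ranges (demand 0.2–0.8, supply 0.15–0.8).

## 5. Synthetic world generator

The generator emulates a FAOSTAT-like country-level calibration whose
structural features drive the study's qualitative findings. Design
choices, all fixed a priori:

* **Commodity structure.** A potato-like focus crop holding ~15% of
  three-crop production, traded alongside two larger staple markets —
  root-crop sectors are small relative to cereals, and the staple
  markets give cross-price effects somewhere to go.
* **Heavy-tailed region sizes.** One rest-of-world exporter bloc
  (30–45% of each commodity), one large target-eligible producer
  (20–28% of the focus crop, a China-like anchor), and ten small
  producers with geometrically decaying shares (ratio 0.7, jittered) —
  country production is heavy-tailed in reality.
* **Trade positions by construction.** Every region except the
  exporter bloc demands slightly more than it produces (5–15% import
  imbalance); the bloc's demand closes the base-year balance exactly.
  This makes non-target countries collectively net exporters of the
  focus crop, the configuration under which target-only accounting
  overstates global benefits.
* **Elasticities as aggregates.** Each region stands for roughly one
  country per 2% of world production; its elasticity is the mean of
  that many uniform draws from the printed range. Large regions thus
  get central values (as production-weighted country aggregates do)
  while tiny regions span the full range.
* **Scenario drivers through common deviates.** Population growth
  (SSP3 > SSP2 > SSP1), income growth (SSP1 > SSP2 > SSP3) and climate
  yield penalties (RCP8.5 > RCP6.0 > RCP4.5) are drawn from ordered
  ranges through shared uniform deviates, so the orderings hold per
  region-year, not just in expectation. Baseline productivity growth
  tracks each region's demand growth so trade positions drift mildly
  instead of exploding over the horizon.
* **Technology fixtures.** Target-set composition is deterministic
  given the world: only the most widely targeted option includes the
  large producer; the variety options for localized diseases target
  the largest small producers (nested sets); the seed-system option
  targets the smallest producers, where formal seed systems are
  weakest. Per-target parameters are stratified draws over printed
  ranges, assigned center-out (central strata to the largest targets)
  so production-weighted means stay near range midpoints for any seed.

## 6. Numerical choices

* **Solver.** Root-finding runs on log world-price ratios (prices stay
  positive by construction), warm-started at the previous year, using
  a hybrid Powell method with a damped-Newton polish fallback (the
  system is small, smooth and log-linear, so Newton converges
  quadratically near the root). Convergence requires relative excess
  demand ≤ 1e-8 per commodity; failures raise with a residual report
  rather than returning unconverged prices.
* **Determinism.** All randomness flows from integer seeds through
  `numpy` generators keyed as `[seed, stream]`, so world, drivers and
  fixtures have independent streams but a single controlling seed.
* **Exactness invariants.** Base-year clearing is exact by
  construction; a zero-probability technology produces multiplier 1
  everywhere and bit-identical trajectories; `all = target +
  non_target` holds exactly per year.

## 7. Limitations

* The model is recursive-dynamic: no storage, no expectations, no
  intertemporal optimization. Years interact only through exogenous
  paths.
* One world price per commodity with fixed margins: no bilateral trade
  flows, tariffs or transport costs, so "who trades with whom" is
  undefined — only net positions.
* Surplus is measured on the focus market only and linearized at the
  baseline point; welfare changes of large shocks inherit linearization
  error, and cross-market welfare effects are deliberately excluded.
* The synthetic calibration is stylized. Magnitudes (NPVs, price
  changes) are illustrative of the mechanism, not estimates for any
  real country set; only the qualitative structure (rankings, signs,
  aggregation effects) is designed to be robust across seeds.
* Technology risk enters only as an expected-value scaling by the
  success probability; no distributional risk analysis is performed.
* Adoption is exogenous logistic diffusion: it does not respond to
  prices or profitability within the simulation.
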