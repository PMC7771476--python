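# cropforesight

A stylized recursive-dynamic, multi-region, multi-commodity
partial-equilibrium simulator for *ex-ante* priority setting among crop
research options. It combines logistic technology adoption,
economic-surplus welfare accounting and NPV/IRR/MIRR investment metrics
to compare research investments under a static counterfactual versus
foresight (SSP-RCP-style) scenarios, and under all-countries versus
target-countries-only welfare aggregation.

## The science in brief

Ex-ante research evaluation asks: if a research program succeeds with
probability *p*, raises yields by *ΔY* and changes production costs by
*ΔC* on the fraction of area that adopts the technology, what are the
discounted benefits, who captures them, and how do candidate programs
rank? Two methodological choices matter and this package makes both
explicit:

1. **Static vs foresight evaluation.** Classical economic-surplus
   analysis holds the world fixed at a base year. A foresight
   evaluation instead projects population, income, productivity and
   climate-driven yield paths forward and evaluates the technology
   against that moving baseline. The package runs both: `static`
   drivers freeze every exogenous path at 1, while the
   `SSP1-RCP4.5` / `SSP2-RCP6.0` / `SSP3-RCP8.5` pathways draw
   internally consistent growth and climate-penalty paths whose
   cross-scenario orderings hold by construction.
2. **Target-only vs global accounting.** Research targeted at a subset
   of countries depresses the world price of the focus crop. Consumers
   everywhere gain; producers in *non-target* countries face the lower
   price without the cost-saving technology and lose. An analysis that
   counts benefits only in target countries therefore overstates net
   global benefits whenever the non-target group is a net exporter.
   Every study reports both aggregations and their ratio.

The market core is a yearly-solved multi-region model: supply is yield
times harvested area, each a constant-elasticity (log-linear) response
to producer prices around a calibrated base year; demand is log-linear
in consumer prices with population and income drivers; one world price
per commodity is solved each year so global excess demand vanishes
(relative residual ≤ 1e-8). Technologies diffuse along a logistic
adoption curve pinned by its release-year start (0.5% of the ceiling)
and its half-ceiling midpoint, and enter the model as adoption-weighted
yield multipliers. Welfare is measured on the focus market with
baseline-linearized surplus accounting that reproduces the classical
closed forms exactly in the linear limit (see
[docs/methods.md](docs/methods.md)).

Because real country-level calibration data cannot ship with the
package, a seeded generator builds FAOSTAT-like synthetic worlds: a
potato-like focus crop (~15% of three-crop production) traded alongside
two staple markets across 12 regions — one large exporter bloc, one
large target-eligible producer, and a heavy tail of small producers.
The four bundled research-option fixtures (late blight resistance,
virus resistance, bacterial wilt resistance, improved seed systems)
span realistic ranges of lags, success probabilities, yield gains,
adoption ceilings and target-set structures.

## Worked example

Running the full study grid (`python examples/04_full_priority_study.py`,
seed 2019, horizon 2015–2040, 10% discount rate) prints:

```
net-benefit NPV ranking per scenario x aggregation:
   scenario aggregation metric                                                                                       ranking
     static         all    npv late_blight_resistance > virus_resistance > bacterial_wilt_resistance > improved_seed_systems
     static      target    npv late_blight_resistance > virus_resistance > bacterial_wilt_resistance > improved_seed_systems
SSP1-RCP4.5         all    npv late_blight_resistance > virus_resistance > bacterial_wilt_resistance > improved_seed_systems
...                                                  (identical ranking in all 8 scenario x aggregation cells)

static scenario, all countries (million US$):
               technology scenario aggregation  producer_surplus_npv  consumer_surplus_npv  cost_npv  net_benefits_npv  irr
    improved_seed_systems   static         all                3279.7                 405.6      50.9            3634.4  1.2
bacterial_wilt_resistance   static         all                3108.2                2180.4      53.9            5234.7  0.6
         virus_resistance   static         all               15812.1               15017.8      69.5           30760.4  2.4
   late_blight_resistance   static         all               23515.5               20303.2     132.6           43686.1  2.1

target-only vs all-countries net benefits:
               technology scenario  net_benefits_target  net_benefits_all  ratio_target_over_all
bacterial_wilt_resistance   static             5330.215          5234.686                  1.018
    improved_seed_systems   static             3648.193          3634.403                  1.004
   late_blight_resistance   static            44846.433         43686.080                  1.027
         virus_resistance   static            31372.311         30760.412                  1.020

end-of-horizon world potato price, static scenario (US$/t):
  baseline: 237.78
  improved_seed_systems: 237.58 (-0.09%)
  bacterial_wilt_resistance: 234.21 (-1.50%)
  virus_resistance: 229.05 (-3.67%)
  late_blight_resistance: 226.02 (-4.95%)
```

The headline findings are visible directly: the NPV ranking is the same
in every scenario and under both aggregations; target-only accounting
overstates net benefits for every option (ratio > 1, because non-target
countries are net exporters whose producers lose from the price fall);
and every technology depresses the world focus-crop price, most for the
most widely adopted option.

The same study is available from the command line:

```bash
cropforesight generate --seed 2019 --out run/        # config + world tables
cropforesight run --config run/study.yaml --out run/ # full grid, all tables
cropforesight report --results run/                  # aggregation comparison
```

Other examples: `examples/01_generate_world.py` (world calibration),
`examples/02_adoption_and_shock.py` (logistic adoption and supply
shifts), `examples/03_surplus_vs_oracle.py` (simulated surplus vs the
closed-form single-market oracle, deviations < 1% at realized shifts up
to 4%).

## Reproduction

All randomness flows from explicit integer seeds; the same seed
reproduces every world, driver path, technology fixture and result bit
for bit. To reproduce the full verification battery:

```bash
python -m pytest tests/ -q                         # unit + acceptance tests
python scripts/acceptance.py --seed 1 --out acc.json
```

`scripts/acceptance.py` writes the headline quantities (net-benefit
NPVs per technology under static and foresight scenarios, target/all
overstatement ratios, world-price effects, the worst market-clearing
residual, and the worst deviation from the closed-form surplus oracle)
as JSON for any seed. `tests/test_acceptance.py` holds one test per
acceptance criterion, from closed-form oracle equivalence through the
qualitative reproduction of the seeded study's findings.

## Layout

```
src/cropforesight/
  model.py        domain types, units, validation, serialization
  synthetic.py    seeded world / driver / technology-fixture generators
  adoption.py     logistic diffusion and adopted-area accounting
  shocks.py       research options -> supply shifts and cost streams
  equilibrium.py  yearly world-price solver (log-linear market core)
  welfare.py      surplus accounting, NPV/IRR/MIRR, reports, ranking
  study.py        the full technology x scenario study driver
  cli.py          thin command-line surface
docs/methods.md   model equations, numerical choices, limitations
examples/         narrative walk-throughs (four scripts)
tests/            unit, property and acceptance tests
```
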