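"""Unit tests for the world, driver and technology-fixture generators."""

import numpy as np
import pytest

from cropforesight.model import validate_world
from cropforesight.synthetic import (PATHWAYS, GeneratorConfig,
                                     build_rtb_technologies,
                                     default_target_universe,
                                     generate_drivers, generate_world)


def test_generated_world_is_valid_and_deterministic():
    a = generate_world(GeneratorConfig(seed=11))
    b = generate_world(GeneratorConfig(seed=11))
    c = generate_world(GeneratorConfig(seed=12))
    assert validate_world(a) == []
    assert np.array_equal(a.calibration.demand_base, b.calibration.demand_base)
    assert np.array_equal(a.calibration.demand_elast, b.calibration.demand_elast)
    assert not np.array_equal(a.calibration.demand_base,
                              c.calibration.demand_base)


def test_regional_structure():
    world = generate_world(GeneratorConfig(seed=5))
    assert world.region_ids[:2] == ["maj_exp", "maj_tgt"]
    assert world.n_regions == 12
    cal = world.calibration
    f = world.focus_index
    shares = cal.supply_base[:, f] / cal.supply_base[:, f].sum()
    # the exporter bloc is the largest producer and the only net exporter
    assert shares[0] == shares.max()
    net = cal.supply_base - cal.demand_base
    assert np.all(net[0] > 0)
    assert np.all(net[1:] < 0)
    # small-producer sizes decay (heavy-tailed country distribution)
    smalls = shares[2:]
    assert smalls[0] > 2.0 * smalls[-1]


def test_focus_share_of_production():
    cfg = GeneratorConfig(seed=3, focus_share=0.15)
    world = generate_world(cfg)
    supply = world.calibration.supply_base
    share = supply[:, world.focus_index].sum() / supply.sum()
    assert share == pytest.approx(0.15, rel=1e-9)


def test_generator_config_validation():
    with pytest.raises(ValueError, match="regions"):
        GeneratorConfig(n_regions=1).validate()
    with pytest.raises(ValueError, match="focus share"):
        GeneratorConfig(focus_share=1.5).validate()
    with pytest.raises(ValueError, match="not ordered"):
        GeneratorConfig(demand_own=(-0.2, -0.8)).validate()
    with pytest.raises(ValueError, match="horizon"):
        GeneratorConfig(years=(2030, 2020)).validate()
    with pytest.raises(ValueError, match="small_share_decay"):
        GeneratorConfig(small_share_decay=0.0).validate()


def test_driver_orderings_hold_per_region_and_year():
    world = generate_world(GeneratorConfig(seed=9))
    seed = 9
    ssp1 = generate_drivers("SSP1-RCP4.5", world, seed)
    ssp2 = generate_drivers("SSP2-RCP6.0", world, seed)
    ssp3 = generate_drivers("SSP3-RCP8.5", world, seed)
    after = slice(1, None)  # base year is all ones in every pathway
    # population growth: SSP3 > SSP2 > SSP1
    assert np.all(ssp3.pop_mult[after] > ssp2.pop_mult[after])
    assert np.all(ssp2.pop_mult[after] > ssp1.pop_mult[after])
    # income growth: SSP1 > SSP2 > SSP3
    assert np.all(ssp1.income_mult[after] > ssp2.income_mult[after])
    assert np.all(ssp2.income_mult[after] > ssp3.income_mult[after])
    # climate yield penalty: RCP8.5 strongest
    assert np.all(ssp3.yclim[after] < ssp2.yclim[after])
    assert np.all(ssp2.yclim[after] < ssp1.yclim[after])
    assert np.all(ssp3.yclim <= 1.0)
    # adoption ceilings: optimistic > middle > pessimistic
    assert ssp1.adoption_ceiling_factor > ssp2.adoption_ceiling_factor \
        > ssp3.adoption_ceiling_factor


def test_static_drivers_are_static():
    world = generate_world(GeneratorConfig(seed=4))
    drv = generate_drivers("static", world, 4)
    assert drv.is_static
    assert not generate_drivers("SSP2-RCP6.0", world, 4).is_static
    with pytest.raises(KeyError, match="unknown pathway"):
        generate_drivers("SSP9-RCP1.0", world, 4)
    assert set(PATHWAYS) == {"static", "SSP1-RCP4.5", "SSP2-RCP6.0",
                             "SSP3-RCP8.5"}


def test_target_universe_excludes_exporter_and_leaves_slack():
    world = generate_world(GeneratorConfig(seed=2))
    universe = default_target_universe(world)
    assert "maj_exp" not in universe
    assert len(universe) <= world.n_regions - 2  # >= 1 small never targeted
    assert "maj_tgt" in universe


def test_technology_fixtures_structure():
    world = generate_world(GeneratorConfig(seed=8))
    techs = build_rtb_technologies(world, seed=8)
    by_name = {t.name: t for t in techs}
    assert set(by_name) == {"improved_seed_systems", "bacterial_wilt_resistance",
                            "virus_resistance", "late_blight_resistance"}
    for t in techs:
        assert t.validate() == []
    # only the most widely targeted option includes the large producer
    assert "maj_tgt" in by_name["late_blight_resistance"].targets
    for name in ("improved_seed_systems", "bacterial_wilt_resistance",
                 "virus_resistance"):
        assert "maj_tgt" not in by_name[name].targets
    # the widest program has the largest target set
    sizes = {n: len(t.targets) for n, t in by_name.items()}
    assert sizes["late_blight_resistance"] == max(sizes.values())
    # the seed-system option targets the smallest producers
    prod = world.calibration.supply_base[:, world.focus_index]
    seed_prod = max(prod[world.region_index(r)]
                    for r in by_name["improved_seed_systems"].targets)
    virus_prod = max(prod[world.region_index(r)]
                     for r in by_name["virus_resistance"].targets)
    assert seed_prod < virus_prod


def test_technology_parameters_within_printed_ranges():
    world = generate_world(GeneratorConfig(seed=8))
    techs = {t.name: t for t in build_rtb_technologies(world, seed=8)}
    lb = techs["late_blight_resistance"]
    assert lb.research_lag == 2 and lb.adoption_lag == 10
    assert lb.annual_rd_cost == 16.0
    for spec in lb.targets.values():
        assert 0.10 <= spec.amax <= 0.60
        assert 0.12 <= spec.dyield <= 0.32
        assert -0.05 <= spec.dcost <= -0.02
        assert spec.p_success == 0.80
    seed_sys = techs["improved_seed_systems"]
    for spec in seed_sys.targets.values():
        assert spec.dyield == 0.20 and spec.dcost == 0.20
        assert 0.60 <= spec.p_success <= 0.80


def test_build_technologies_deterministic_and_seed_sensitive():
    world = generate_world(GeneratorConfig(seed=8))
    a = build_rtb_technologies(world, seed=8)
    b = build_rtb_technologies(world, seed=8)
    c = build_rtb_technologies(world, seed=9)
    assert [t.targets for t in a] == [t.targets for t in b]
    assert [t.targets for t in a] != [t.targets for t in c]
    with pytest.raises(KeyError):
        build_rtb_technologies(world, seed=8, target_universe=["nowhere"])
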