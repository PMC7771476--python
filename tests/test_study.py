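"""Unit tests for the study driver, outputs and command-line surface."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from cropforesight.cli import main
from cropforesight.study import (StudyConfig, compare_aggregations,
                                 load_study_config, run_study)
from cropforesight.welfare import WelfareReport


def _small_config(seed=7):
    return StudyConfig(seed=seed, scenarios=("static",),
                       generator={"n_regions": 6, "years": [2015, 2032]})


def test_run_study_is_deterministic():
    a = run_study(_small_config())
    b = run_study(_small_config())
    pd.testing.assert_frame_equal(a.reports_frame(), b.reports_frame())
    assert a.manifest["config_hash"] == b.manifest["config_hash"]
    c = run_study(_small_config(), seed=8)
    assert c.manifest["seed"] == 8
    assert not a.reports_frame().equals(c.reports_frame())


def test_study_outputs_written(tmp_path):
    out = tmp_path / "run"
    result = run_study(_small_config(), out_dir=out)
    expected = {"welfare_reports.csv", "ranking_npv.csv",
                "aggregation_comparison.csv", "manifest.json",
                "trajectory_static_baseline.csv"}
    names = {p.name for p in out.iterdir()}
    assert expected <= names
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    assert manifest["seed"] == 7
    assert manifest["horizon"] == [2015, 2032]
    assert set(manifest["technologies"]) == set(
        t.name for t in result.technologies)
    reports = pd.read_csv(out / "welfare_reports.csv")
    assert len(reports) == 4 * 1 * 2  # tech x scenario x aggregation
    traj = pd.read_csv(out / "trajectory_static_baseline.csv")
    assert {"year", "region", "commodity", "supply", "demand"} <= set(traj)


def test_study_config_validation():
    with pytest.raises(ValueError, match="unknown scenario"):
        StudyConfig(scenarios=("mystery",)).validate()
    with pytest.raises(ValueError, match="discount_rate"):
        StudyConfig(discount_rate=-1.5).validate()
    with pytest.raises(ValueError, match="unknown fields"):
        StudyConfig(generator={"n_planets": 3}).validate()


def test_load_study_config_round_trip(tmp_path):
    cfg = _small_config()
    path = tmp_path / "study.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    loaded = load_study_config(path)
    assert loaded.to_dict() == cfg.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump({"seed": 1, "bogus": True}, fh)
    with pytest.raises(ValueError, match="unknown study config fields"):
        load_study_config(path)


def _report(tech, scenario, agg, net):
    return WelfareReport(technology=tech, scenario=scenario, aggregation=agg,
                         dps_npv=0.0, dcs_npv=net, cost_npv=0.0,
                         net_benefits=net, irr=None, mirr=None,
                         discount_rate=0.1)


def test_compare_aggregations_guards():
    rows = [_report("a", "static", "all", 10.0),
            _report("a", "static", "target", 12.0),
            _report("b", "static", "all", 0.0),
            _report("b", "static", "target", -5.0)]
    frame = compare_aggregations(rows)
    a = frame[frame.technology == "a"].iloc[0]
    assert a.ratio_target_over_all == pytest.approx(1.2)
    assert not a.ratio_undefined and not a.signs_differ
    b = frame[frame.technology == "b"].iloc[0]
    assert b.ratio_undefined and np.isnan(b.ratio_target_over_all)
    with pytest.raises(ValueError, match="both aggregations"):
        compare_aggregations(rows[:1])


def test_aggregation_comparison_on_fixture(fixture_study):
    frame = compare_aggregations(fixture_study.reports)
    assert len(frame) == 16  # 4 technologies x 4 scenarios
    assert not frame.ratio_undefined.any()
    assert not frame.signs_differ.any()
    assert (frame.ratio_target_over_all > 1.0).all()


def test_ranking_frame(fixture_study):
    frame = fixture_study.ranking("npv")
    assert len(frame) == 8  # 4 scenarios x 2 aggregations
    assert frame.ranking.str.count(">").eq(3).all()


def test_cli_generate_and_run(tmp_path):
    runner = CliRunner()
    gen_dir = tmp_path / "gen"
    res = runner.invoke(main, ["generate", "--seed", "7", "--n-regions", "6",
                               "--out", str(gen_dir)])
    assert res.exit_code == 0, res.output
    assert (gen_dir / "study.yaml").exists()
    assert (gen_dir / "world_base_year.csv").exists()

    run_dir = tmp_path / "run"
    res = runner.invoke(main, ["run", "--config", str(gen_dir / "study.yaml"),
                               "--static", "--seed", "7",
                               "--out", str(run_dir)])
    assert res.exit_code == 0, res.output
    assert (run_dir / "welfare_reports.csv").exists()
    assert "static" in res.output

    res = runner.invoke(main, ["report", "--results", str(run_dir)])
    assert res.exit_code == 0, res.output
    assert "ratio_target_over_all" in res.output


def test_cli_rejects_bad_inputs(tmp_path):
    runner = CliRunner()
    res = runner.invoke(main, ["run", "--discount-rate", "-2.0",
                               "--out", str(tmp_path / "x")])
    assert res.exit_code != 0
    res = runner.invoke(main, ["report", "--results", str(tmp_path)])
    assert res.exit_code != 0
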