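"""I/O validation, pipeline orchestration and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from phenometrics import SpeciesConfig, default_config, generate_woodland
from phenometrics.cli import main as cli_main
from phenometrics.io import (ObservationValidationError, read_observations,
                             read_trees, write_observations)
from phenometrics.pipeline import PipelineConfig, PipelineError, run_pipeline


def tiny_config(seed=3):
    return default_config(
        rng_seed=seed,
        species=[SpeciesConfig("oak", 5, 112.0, 7, 30.0),
                 SpeciesConfig("birch", 5, 104.0, 5, 12.0)],
    )


@pytest.fixture(scope="module")
def tiny_csvs(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny")
    trees, obs, _ = generate_woodland(tiny_config())
    trees.to_csv(out / "trees.csv", index=False, float_format="%.10g")
    write_observations(obs, out / "observations.csv")
    return out, trees, obs


class TestReadObservations:
    def test_valid_rows_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "tree_id": ["a", "a", "a"], "species": "oak", "area": "Great Wood",
            "method": "lai", "day": [100, 103, 106],
            "value": [1.234567890123, 2.0, 3.0], "observer_id": "",
        })
        path = tmp_path / "obs.csv"
        write_observations(df, path)
        back = read_observations(path)
        assert len(back) == 3
        assert np.allclose(back["value"], df["value"], atol=1e-12)

    def test_bad_bud_score_names_row(self, tmp_path):
        df = pd.DataFrame({
            "tree_id": ["b1"], "species": "birch", "area": "Marley",
            "method": "bud_score", "day": [100], "value": [9.0],
            "observer_id": "obs_1",
        })
        trees = pd.DataFrame({"tree_id": ["b1"], "species": ["birch"],
                              "area": ["Marley"], "max_stage": [5]})
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ObservationValidationError, match=r"line 2.*9.0 outside \[1, 5\]"):
            read_observations(path, trees=trees)

    def test_skip_bad_drops_rows(self, tmp_path):
        df = pd.DataFrame({
            "tree_id": ["a", "a"], "species": "oak", "area": "GW",
            "method": ["lai", "nonsense"], "day": [100, 103],
            "value": [1.0, 2.0], "observer_id": "",
        })
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        back = read_observations(path, skip_bad=True)
        assert len(back) == 1

    def test_empty_file_explicit_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("tree_id,species,area,method,day,value,observer_id\n")
        with pytest.raises(ValueError, match="empty observation file"):
            read_observations(path)

    def test_negative_count_rejected(self, tmp_path):
        df = pd.DataFrame({
            "tree_id": ["a"], "species": "oak", "area": "GW",
            "method": "count_total", "day": [140], "value": [-3.0],
            "observer_id": "",
        })
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ObservationValidationError, match="negative value"):
            read_observations(path)

    def test_calendar_dates_converted(self, tmp_path):
        df = pd.DataFrame({
            "tree_id": ["a"] * 3, "species": "oak", "area": "GW",
            "method": "lai", "day": ["2023-04-10", "2023-04-13", "2023-04-16"],
            "value": [1.0, 2.0, 3.0], "observer_id": "",
        })
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        back = read_observations(path)
        assert back["day"].tolist() == [100.0, 103.0, 106.0]
        assert back.attrs["year"] == 2023


class TestPipeline:
    def test_deterministic_manifests(self, tmp_path):
        cfgs = [PipelineConfig(outdir=str(tmp_path / d), seed=5,
                               woodland=tiny_config(5), ensemble_size=10,
                               n_boot=50)
                for d in ("run1", "run2")]
        m1 = run_pipeline(cfgs[0])
        m2 = run_pipeline(cfgs[1])
        h1 = {k: v["sha256"] for k, v in m1["artifacts"].items()}
        h2 = {k: v["sha256"] for k, v in m2["artifacts"].items()}
        assert h1 == h2
        assert (tmp_path / "run1" / "manifest.json").exists()

    def test_zero_caterpillar_tree_flagged_run_succeeds(self, tmp_path):
        trees, obs, _ = generate_woodland(tiny_config(7))
        starved = trees.tree_id.iloc[0]
        mask = (obs.tree_id == starved) & obs.method.isin(
            ["count_total", "count_fwm", "frass_mass_g"])
        obs.loc[mask, "value"] = 0.0
        out = tmp_path / "o"
        out.mkdir()
        trees.to_csv(out / "trees.csv", index=False)
        write_observations(obs, out / "observations.csv")
        cfg = PipelineConfig(outdir=str(out), seed=1, ensemble_size=0)
        run_pipeline(cfg, stages=("fit",))
        hd = pd.read_csv(out / "half_dates.csv")
        starved_rows = hd[(hd.tree_id == starved)
                          & hd.metric.isin(["tc_half_fall", "fwm_half_fall",
                                            "frass_half_fall"])]
        assert (starved_rows.flag == "undefined").all()
        assert starved_rows.half_day.isna().all()

    def test_compare_without_fit_names_missing_file(self, tmp_path, tiny_csvs):
        src, _, _ = tiny_csvs
        cfg = PipelineConfig(outdir=str(tmp_path / "x"),
                             observations=str(src / "observations.csv"),
                             trees=str(src / "trees.csv"), seed=1)
        with pytest.raises(PipelineError, match="half_dates.csv"):
            run_pipeline(cfg, stages=("compare",))


class TestCLI:
    def test_icc_subcommand(self, tmp_path):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        pd.DataFrame({"unit": np.arange(20), "m1": x,
                      "m2": x + 0.1 * rng.normal(size=20)}).to_csv(
            tmp_path / "pairs.csv", index=False)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["icc", str(tmp_path / "pairs.csv"),
                                       "--col-a", "m1", "--col-b", "m2"])
        assert res.exit_code == 0, res.output
        assert "ICC" in res.output and "absolute agreement" in res.output

    def test_simulate_subcommand_writes_artifacts(self, tmp_path):
        runner = CliRunner()
        cfg = tiny_config(2)
        cfg.to_yaml(tmp_path / "wc.yaml")
        res = runner.invoke(cli_main, [
            "simulate", "--outdir", str(tmp_path / "sim"), "--seed", "2",
            "--woodland-config", str(tmp_path / "wc.yaml")])
        assert res.exit_code == 0, res.output
        manifest = json.loads((tmp_path / "sim" / "manifest.json").read_text())
        assert {"trees", "observations", "truth", "config"} <= set(
            manifest["artifacts"])

    def test_compare_dependency_error_is_clean(self, tmp_path, tiny_csvs):
        src, _, _ = tiny_csvs
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "compare", "--outdir", str(tmp_path / "nope"),
            "--observations", str(src / "observations.csv"),
            "--trees", str(src / "trees.csv")])
        assert res.exit_code != 0
        assert "half_dates.csv" in res.output
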