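"""Config validation, end-to-end runner, CLI stages, reproducibility."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import ldu
from ldu.cli import main
from ldu.experiment import ConfigError, load_run_config, run_experiment

DEMO_CONFIG = {
    "data": {"n_per_class": 120, "seed": 0},
    "train_fraction": 0.7,
    "base_spec": {"hidden_layer_sizes": [16, 16], "epochs": 25},
    "defer_spec": {"epochs": 10},
    "K": 3,
    "ldu_alphas": [0.8, 1.3, 2.5],
    "ld_alphas": [1.3],
    "dt_thresholds": [0.0, 0.5],
    "seeds": [0, 1],
    "seed": 5,
}


class TestRunConfig:
    def test_defaults_validate(self):
        config = load_run_config({})
        assert config.K >= 2 and 0 < config.train_fraction < 1

    @pytest.mark.parametrize(
        "patch, field",
        [
            ({"train_fraction": 1.5}, "train_fraction"),
            ({"K": 1}, "K"),
            ({"dt_thresholds": [-0.2]}, "dt_thresholds"),
            ({"seeds": []}, "seeds"),
            ({"data": {"noise_sd": 0}}, "noise_sd"),
            ({"defer_spec": {"alpha": -2}}, "alpha"),
        ],
    )
    def test_errors_name_the_offending_field(self, patch, field):
        with pytest.raises((ConfigError, ValueError), match=field):
            load_run_config({**DEMO_CONFIG, **patch})

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            load_run_config({"not_a_key": 1})

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(DEMO_CONFIG))
        config = load_run_config(path)
        assert config.data.n_per_class == 120
        assert config.ldu_alphas == (0.8, 1.3, 2.5)


class TestRunExperiment:
    @pytest.fixture(scope="class")
    @staticmethod
    def demo_run(tmp_path_factory):
        out = tmp_path_factory.mktemp("run")
        run_experiment(load_run_config(DEMO_CONFIG), out)
        return out

    def test_all_sweep_tables_written_and_non_empty(self, demo_run):
        for name in ("sweep_ldu.csv", "sweep_ld.csv", "sweep_dt.csv"):
            content = (demo_run / name).read_text().strip().splitlines()
            assert len(content) > 1, name

    def test_manifest_records_seeds_and_reference_f1(self, demo_run):
        manifest = json.loads((demo_run / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert manifest["sweep_seeds"] == [0, 1]
        assert 0.0 <= manifest["diagnostic_network_f1"]["LDU"] <= 1.0

    def test_rerun_reproduces_tables_byte_identically(self, demo_run, tmp_path):
        rerun = tmp_path / "rerun"
        run_experiment(load_run_config(DEMO_CONFIG), rerun)
        for name in (
            "cohort.csv", "train.csv", "test.csv", "ensemble_test.csv",
            "uncertainty_test.csv", "sweep_ldu.csv", "sweep_ld.csv", "sweep_dt.csv",
        ):
            assert (rerun / name).read_bytes() == (demo_run / name).read_bytes(), name

    def test_failure_leaves_marker_naming_stage(self, tmp_path, monkeypatch):
        config = load_run_config(DEMO_CONFIG)

        def boom(*args, **kwargs):
            raise RuntimeError("synthetic failure")

        monkeypatch.setattr("ldu.experiment.train_ensemble", boom)
        with pytest.raises(RuntimeError, match="ensemble"):
            run_experiment(config, tmp_path / "failing")
        marker = (tmp_path / "failing" / "FAILED").read_text()
        assert "ensemble" in marker


def test_separable_config_reaches_high_diagnostic_f1(tmp_path):
    config = load_run_config(
        {
            "data": {
                "n_per_class": 150,
                "easy_fraction": 1.0,
                "ambiguous_fraction": 0.0,
                "overconfident_wrong_fraction": 0.0,
                "class_separation": 10.0,
                "noise_sd": 0.5,
            },
            "K": 2,
            "ldu_alphas": [2.0],
            "ld_alphas": [],
            "dt_thresholds": [0.0],
            "seeds": [0],
            "seed": 1,
        }
    )
    run_experiment(config, tmp_path / "sep")
    manifest = json.loads((tmp_path / "sep" / "manifest.json").read_text())
    assert manifest["diagnostic_network_f1"]["LDU"] >= 0.95


class TestCliStages:
    @pytest.fixture(scope="class")
    @staticmethod
    def workspace(tmp_path_factory):
        root = tmp_path_factory.mktemp("cli")
        runner = CliRunner()
        gen_config = root / "gen.yaml"
        gen_config.write_text(
            yaml.safe_dump({"n_per_class": 100, "seed": 3})
        )

        def run(*args):
            result = runner.invoke(main, list(args), catch_exceptions=False)
            assert result.exit_code == 0, result.output
            return result

        run("simulate", "--config", str(gen_config), "--out", str(root / "cohort.csv"))
        run(
            "split", "--data", str(root / "cohort.csv"), "--seed", "3",
            "--train-out", str(root / "train.csv"), "--test-out", str(root / "test.csv"),
        )
        run(
            "train-ensemble", "--train", str(root / "train.csv"), "--k", "3",
            "--seed", "1", "--out", str(root / "ensemble"),
        )
        run(
            "predict", "--model", str(root / "ensemble"),
            "--data", str(root / "test.csv"), "--out", str(root / "preds.csv"),
        )
        run(
            "predict", "--model", str(root / "ensemble"),
            "--data", str(root / "train.csv"), "--out", str(root / "preds_train.csv"),
        )
        return root, run

    def test_uncertainty_stage(self, workspace):
        root, run = workspace
        run("uncertainty", "--predictions", str(root / "preds.csv"),
            "--out", str(root / "unc.csv"))
        header = (root / "unc.csv").read_text().splitlines()[0]
        assert header == "sample_id,u_e,u_d,p_vote_pos"

    def test_defer_training_and_triage(self, workspace):
        root, run = workspace
        run(
            "train-defer", "--predictions", str(root / "preds_train.csv"),
            "--alpha", "1.3", "--seed", "2", "--out", str(root / "defer_net"),
        )
        run(
            "triage", "--model", str(root / "defer_net"),
            "--predictions", str(root / "preds.csv"), "--out", str(root / "triage.csv"),
        )
        run(
            "evaluate", "--triage", str(root / "triage.csv"),
            "--labels", str(root / "test.csv"), "--out", str(root / "metrics.json"),
        )
        metrics = json.loads((root / "metrics.json").read_text())
        assert 0.0 <= metrics["defer_rate"] <= 1.0
        assert set(metrics) >= {"f1", "f1_overall", "accuracy", "flags"}

    def test_dt_and_ld_stages(self, workspace):
        root, run = workspace
        run(
            "triage-dt", "--predictions", str(root / "preds.csv"),
            "--threshold", "0.0", "--out", str(root / "dt.csv"),
        )
        assert (root / "dt.csv").read_text().count("\n") > 1
        run(
            "train-ld", "--train", str(root / "train.csv"), "--alpha", "1.5",
            "--seed", "4", "--out", str(root / "ld_model"),
        )
        run(
            "triage-ld", "--model", str(root / "ld_model"),
            "--data", str(root / "test.csv"), "--out", str(root / "ld.csv"),
        )
        decisions = (root / "ld.csv").read_text()
        assert decisions.splitlines()[0].startswith("sample_id,decision")

    def test_stage_rerun_is_byte_identical(self, workspace):
        root, run = workspace
        run("simulate", "--config", str(root / "gen.yaml"),
            "--out", str(root / "cohort2.csv"))
        assert (root / "cohort.csv").read_bytes() == (root / "cohort2.csv").read_bytes()
        run(
            "predict", "--model", str(root / "ensemble"),
            "--data", str(root / "test.csv"), "--out", str(root / "preds2.csv"),
        )
        assert (root / "preds.csv").read_bytes() == (root / "preds2.csv").read_bytes()
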