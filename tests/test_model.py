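"""Model/Results layer, determinism, cross-validation, and the CLI."""

import os

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import neurotune as nt
from neurotune.cli import main as cli_main
from neurotune.pnds import MockTimer


@pytest.fixture(scope="module")
def fitted(tiny_scene):
    frames, mask = tiny_scene
    tuner = nt.PipelineTuner(frames, mask,
                             config=nt.PsoConfig(max_iterations=4),
                             timer=MockTimer(nt.detection_cost_model),
                             seed=5)
    return tuner.fit()


def test_results_surface(fitted):
    assert 0.0 <= fitted.best_fitness <= 1.0
    assert set(fitted.best_params) == set(nt.ndsep_space().names)
    assert list(fitted.history.columns) == ["iteration", "best_fitness",
                                            "mean_fitness"]
    assert len(fitted.history) == 5  # initial population + 4 iterations
    assert {"fitness", "accuracy", "seconds", "tau",
            "timescale"} <= set(fitted.candidates.columns)


def test_summary_mentions_key_quantities(fitted):
    text = fitted.summary()
    assert "PSO" in text
    assert "Best fitness H" in text
    assert "threshold_step" in text


def test_score_on_heldout(fitted, tiny_scene):
    frames, mask = tiny_scene
    scores = fitted.score(frames, mask)
    assert {"odc", "precision", "recall", "f1", "fps"} <= set(scores)
    assert 0.0 <= scores["odc"] <= 1.0


def test_save_writes_artifacts(fitted, tmp_path):
    out = tmp_path / "run"
    fitted.save(str(out))
    assert (out / "best_params.txt").read_text().count("=") >= 7
    diag = pd.read_csv(out / "diagnostics.csv")
    assert list(diag.columns) == ["iteration", "best_fitness", "mean_fitness"]
    assert len(pd.read_csv(out / "candidates.csv")) == fitted.n_evaluations


def test_identical_seed_and_mock_timer_reproduce_run(tiny_scene):
    frames, mask = tiny_scene
    def run():
        return nt.PipelineTuner(
            frames, mask, config=nt.PsoConfig(max_iterations=3),
            timer=MockTimer(nt.detection_cost_model), seed=9,
        ).fit()

    a, b = run(), run()
    assert a.best_params == b.best_params
    pd.testing.assert_frame_equal(a.candidates, b.candidates)
    pd.testing.assert_frame_equal(a.history, b.history)


def test_firing_log_written(tiny_scene, tmp_path, landscape):
    log_path = str(tmp_path / "firings.tsv")
    nt.PipelineTuner(pnds=landscape, config=nt.PsoConfig(max_iterations=1),
                     seed=0, log_path=log_path).fit()
    lines = open(log_path).read().strip().split("\n")
    assert lines[0] == "actor\tmode\ttokens_in\ttokens_out"
    assert any("initialize-write\t0\t24" in line for line in lines)


def test_invalid_inputs_rejected(tiny_scene):
    frames, mask = tiny_scene
    with pytest.raises(ValueError):
        nt.PipelineTuner(frames, mask, strategy="annealing")
    with pytest.raises(ValueError):
        nt.PipelineTuner()  # neither dataset nor wrapper


def test_cross_validated_runs_layout(tiny_scene, landscape):
    frames, mask = tiny_scene
    table, agg = nt.cross_validated_runs(
        frames, mask, k=3, repetitions=1, seed=0,
        config=nt.PsoConfig(max_iterations=2),
        timer=MockTimer(nt.detection_cost_model),
    )
    assert len(table) == 3 * 1 * 2  # folds x repetitions x {train, test}
    assert set(table["split"]) == {"train", "test"}
    assert np.isfinite(float(agg.loc["test", ("odc", "std")]))
    # a single run within one fold has zero dispersion, reported as 0
    one = table[(table["split"] == "test") & (table["fold"] == 0)]
    assert one["odc"].std() == 0.0 or len(one) == 1


# -- command-line interface --------------------------------------------------

@pytest.fixture(scope="module")
def cli_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("cli-data")
    runner = CliRunner()
    result = runner.invoke(cli_main, [
        "generate", "--out", str(root), "--height", "32", "--width", "32",
        "--neurons", "5", "--frames", "40", "--seed", "3",
    ])
    assert result.exit_code == 0, result.output
    return root


def test_cli_generate_writes_dataset(cli_dataset):
    assert (cli_dataset / "frames.tif").exists()
    assert (cli_dataset / "mask.tif").exists()
    assert (cli_dataset / "scene.yaml").exists()


def test_cli_optimize_score_round_trip(cli_dataset, tmp_path):
    out = tmp_path / "opt"
    runner = CliRunner()
    config = tmp_path / "run.yaml"
    config.write_text(
        "strategy: pso\nmock_timer: true\npso:\n  max_iterations: 2\n"
    )
    result = runner.invoke(cli_main, [
        "optimize", "--config", str(config),
        "--frames", str(cli_dataset / "frames.tif"),
        "--mask", str(cli_dataset / "mask.tif"),
        "--seed", "1", "--out", str(out),
    ])
    assert result.exit_code == 0, result.output
    for name in ("best_params.txt", "diagnostics.csv", "summary.csv",
                 "candidates.csv", "firings.tsv"):
        assert (out / name).exists()
    scored = runner.invoke(cli_main, [
        "score", "--frames", str(cli_dataset / "frames.tif"),
        "--mask", str(cli_dataset / "mask.tif"),
        "--params", str(out / "best_params.txt"),
    ])
    assert scored.exit_code == 0, scored.output
    assert "odc" in scored.output


def test_cli_rejects_bad_config(cli_dataset, tmp_path):
    config = tmp_path / "bad.yaml"
    config.write_text("strategy: pso\npso:\n  warp_speed: 9\n")
    runner = CliRunner()
    result = runner.invoke(cli_main, [
        "optimize", "--config", str(config),
        "--frames", str(cli_dataset / "frames.tif"),
        "--mask", str(cli_dataset / "mask.tif"),
        "--out", str(tmp_path / "x"),
    ])
    assert result.exit_code != 0
    assert "warp_speed" in result.output


def test_cli_sweep_writes_front(cli_dataset, tmp_path):
    out = tmp_path / "sweep"
    runner = CliRunner()
    result = runner.invoke(cli_main, [
        "sweep", "--frames", str(cli_dataset / "frames.tif"),
        "--mask", str(cli_dataset / "mask.tif"),
        "--mock-timer", "--seed", "2", "--out", str(out),
        "--weights", "0.2,0.8",
        "--config", str(_tiny_cfg(tmp_path)),
    ])
    assert result.exit_code == 0, result.output
    front = pd.read_csv(out / "pareto.csv")
    assert len(front) == 2
    assert (out / "pareto.png").exists()
    assert "AUC=" in result.output


def _tiny_cfg(tmp_path):
    path = tmp_path / "tiny.yaml"
    path.write_text("pso:\n  max_iterations: 2\n")
    return path
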