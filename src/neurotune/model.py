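"""Model/Results interface over the optimization dataflow graph.

:class:`PipelineTuner` is the front door of the package: it binds a
dataset (or any PNDS wrapper), a parameter space and a search strategy,
builds the four-actor optimization loop

    core (PSO/GA)  ->  set-params  ->  PNDS  ->  fitness  ->  core

and :meth:`PipelineTuner.fit` runs the loop to completion, returning a
:class:`TuningResults` carrying the best parameter settings (all ties),
the per-iteration and per-candidate diagnostics, and a ``summary()``
table.  All randomness — swarm/population initialization, stochastic
operators, tie-breaks — flows from the single ``seed``.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataflow import Edge, Graph
from .ga import GaConfig, GaCoreActor
from .metrics import frame_rate, score_masks
from .params import ParamSpace, ndsep_space
from .pareto import OutcomePoint, pareto_auc, pareto_front, weight_sweep
from .pnds import (
    FitnessEvaluationActor,
    PndsActor,
    PndsWrapper,
    ReferencePnds,
    SetParamsActor,
    WallClockTimer,
)
from .pso import PsoConfig, PsoCoreActor, write_result_files

__all__ = ["PipelineTuner", "TuningResults", "evaluate_params",
           "cross_validated_runs"]


def evaluate_params(frames: np.ndarray, truth: np.ndarray,
                    params: Mapping[str, float | int],
                    t_dice: float = 0.5) -> dict[str, float]:
    """Run the reference detector with fixed parameters on a dataset and
    report segmentation metrics plus throughput."""
    wrapper = ReferencePnds(frames, truth)
    result = wrapper.evaluate_at(params, WallClockTimer())
    mask = wrapper.detect(params)
    scores = score_masks(mask, truth, t_dice)
    scores["seconds"] = result.seconds
    scores["fps"] = frame_rate(wrapper.n_frames, result.seconds)
    return scores


class TuningResults:
    """Outcome of one optimization run."""

    def __init__(self, *, strategy: str, space: ParamSpace, config,
                 seed: int, a1: float, t_dice: float, core_result: dict,
                 candidates: pd.DataFrame):
        self.strategy = strategy
        self.space = space
        self.config = config
        self.seed = seed
        self.a1 = a1
        self.t_dice = t_dice
        self.best_fitness: float = core_result["best_fitness"]
        self.best_params_all: list[dict] = core_result["best_params"]
        self.best_params: dict = self.best_params_all[0]
        self.iterations: int = core_result["iterations"]
        self.history = pd.DataFrame(core_result["history"])
        self.candidates = candidates
        self._core_result = core_result

    @property
    def n_evaluations(self) -> int:
        return len(self.candidates)

    def score(self, frames: np.ndarray, truth: np.ndarray) -> dict[str, float]:
        """Evaluate the best parameter setting on a (held-out) dataset."""
        return evaluate_params(frames, truth, self.best_params, self.t_dice)

    def save(self, output_dir: str) -> None:
        """best_params.txt, diagnostics.csv and per-candidate scores."""
        os.makedirs(output_dir, exist_ok=True)
        write_result_files(output_dir, self._core_result)
        self.candidates.to_csv(
            os.path.join(output_dir, "candidates.csv"), index=False
        )

    def summary(self) -> str:
        best_rows = self.candidates[
            self.candidates["fitness"] == self.best_fitness
        ]
        lines = [
            "              Pipeline Parameter Optimization Results",
            "=" * 66,
            f"Strategy:              {self.strategy.upper():<10}"
            f"Seed:                 {self.seed}",
            f"Iterations:            {self.iterations:<10}"
            f"Candidate evaluations: {self.n_evaluations}",
            f"Accuracy weight a1:    {self.a1:<10.2f}"
            f"Time weight a2:        {1 - self.a1:.2f}",
            f"Best fitness H:        {self.best_fitness:<10.4f}"
            f"Loss 1 - H:            {1 - self.best_fitness:.4f}",
        ]
        if len(best_rows):
            row = best_rows.iloc[0]
            lines.append(
                f"Best accuracy D:       {row['accuracy']:<10.4f}"
                f"Best TimeScale:        {row['timescale']:.4f}"
            )
        lines.append("-" * 66)
        n_sol = len(self.best_params_all)
        for i, params in enumerate(self.best_params_all, start=1):
            lines.append(f"best parameters (solution {i} of {n_sol})")
            for name, value in params.items():
                shown = f"{value:.4f}" if isinstance(value, float) else value
                lines.append(f"    {name:<24}{shown}")
        lines.append("=" * 66)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<TuningResults {self.strategy} best_fitness="
                f"{self.best_fitness:.4f} iterations={self.iterations}>")


class PipelineTuner:
    """Configure-and-fit model for pipeline parameter search.

    Parameters
    ----------
    frames, ground_truth
        The calcium-imaging stack and its label mask.  May be omitted
        when an explicit ``pnds`` wrapper is supplied.
    space
        The parameter box to search; defaults to the bundled reference
        detector's seven-parameter space.
    strategy
        ``"pso"`` or ``"ga"``.
    config
        A :class:`PsoConfig` or :class:`GaConfig`; defaults carry the
        standard experiment settings (population 24, 50 iterations).
    a1
        Accuracy weight of the harmonic fitness aggregate (a2 = 1 - a1).
    timer
        Wall-time source; inject a :class:`neurotune.pnds.MockTimer` for
        bit-reproducible runs.
    n_threads
        Candidate evaluations per concurrent block (default 1; the
        platform core count is a sensible production setting).
    """

    def __init__(self, frames: np.ndarray | None = None,
                 ground_truth: np.ndarray | None = None, *,
                 space: ParamSpace | None = None,
                 strategy: str = "pso",
                 config: PsoConfig | GaConfig | None = None,
                 a1: float = 0.8, t_dice: float = 0.5,
                 n_threads: int = 1, timer=None,
                 pnds: PndsWrapper | None = None,
                 seed: int = 0, log_path: str | None = None):
        if strategy not in ("pso", "ga"):
            raise ValueError("strategy must be 'pso' or 'ga'")
        if pnds is None:
            if frames is None or ground_truth is None:
                raise ValueError(
                    "provide frames and ground_truth, or a pnds wrapper"
                )
            pnds = ReferencePnds(frames, ground_truth)
            space = space or ndsep_space()
        if space is None:
            space = getattr(pnds, "space", None) or ndsep_space()
        if config is None:
            config = PsoConfig() if strategy == "pso" else GaConfig()
        self.pnds = pnds
        self.space = space
        self.strategy = strategy
        self.config = config
        self.a1 = float(a1)
        self.t_dice = float(t_dice)
        self.n_threads = int(n_threads)
        self.timer = timer if timer is not None else WallClockTimer()
        self.seed = int(seed)
        self.log_path = log_path

    @classmethod
    def from_files(cls, frames_path: str, mask_path: str, **kwargs):
        from .synthetic import read_dataset

        frames, mask = read_dataset(frames_path, mask_path)
        return cls(frames, mask, **kwargs)

    def build_graph(self, output_dir: str | None = None,
                    log=None) -> tuple[Graph, object, FitnessEvaluationActor]:
        """Assemble the four-actor loop; exposed for instrumented tests."""
        rng = np.random.default_rng(self.seed)
        if self.strategy == "pso":
            core = PsoCoreActor(self.space, self.config, rng,
                                output_dir=output_dir)
        else:
            core = GaCoreActor(self.space, self.config, rng,
                               output_dir=output_dir)
        setp = SetParamsActor(self.pnds, self.space)
        pnds_actor = PndsActor(self.pnds, self.timer, self.n_threads)
        fitness = FitnessEvaluationActor(self.a1)
        edges = [
            Edge((core.name, "out"), (setp.name, "in")),
            Edge((setp.name, "out"), (pnds_actor.name, "in")),
            Edge((pnds_actor.name, "out"), (fitness.name, "in")),
            Edge((fitness.name, "out"), (core.name, "in")),
        ]
        graph = Graph([core, setp, pnds_actor, fitness], edges, log=log)
        return graph, core, fitness

    def fit(self, output_dir: str | None = None) -> TuningResults:
        """Run the optimization loop to write-output and collect results."""
        log_fh = None
        log = None
        if self.log_path is not None:
            log_fh = open(self.log_path, "w")
            log_fh.write("actor\tmode\ttokens_in\ttokens_out\n")
            log = lambda line: log_fh.write(line + "\n")  # noqa: E731
        try:
            graph, core, fitness = self.build_graph(output_dir, log)
            graph.run(lambda: core.terminated)
            graph.check_conservation()
        finally:
            if log_fh is not None:
                log_fh.close()
        candidates = pd.DataFrame(
            {
                "evaluation": np.arange(len(fitness.records)),
                "fitness": [r.value for r in fitness.records],
                "accuracy": [r.accuracy for r in fitness.records],
                "seconds": [r.seconds for r in fitness.records],
                "tau": [r.tau for r in fitness.records],
                "timescale": [r.timescale for r in fitness.records],
            }
        )
        return TuningResults(
            strategy=self.strategy, space=self.space, config=self.config,
            seed=self.seed, a1=self.a1, t_dice=self.t_dice,
            core_result=core.result, candidates=candidates,
        )

    # -- multiobjective sweep -------------------------------------------------
    def sweep(self, weights: Iterable[float]) -> list[OutcomePoint]:
        """Re-fit once per accuracy weight a1, collecting the best
        solution's (D, TimeScale) outcome for Pareto analysis."""

        def runner(a1: float) -> OutcomePoint:
            tuner = PipelineTuner(
                space=self.space, strategy=self.strategy,
                config=self.config, a1=a1, t_dice=self.t_dice,
                n_threads=self.n_threads, timer=self.timer, pnds=self.pnds,
                seed=self.seed,
            )
            res = tuner.fit()
            best = res.candidates[
                res.candidates["fitness"] == res.best_fitness
            ]
            row = (best.iloc[0] if len(best)
                   else res.candidates.iloc[res.candidates["fitness"].idxmax()])
            return OutcomePoint(
                accuracy=float(row["accuracy"]),
                timescale=float(row["timescale"]),
                provenance={"a1": a1, "seed": self.seed},
            )

        return weight_sweep(runner, weights)


def cross_validated_runs(frames: np.ndarray, truth: np.ndarray, *,
                         k: int = 3, repetitions: int = 1, seed: int = 0,
                         strategy: str = "pso", config=None, a1: float = 0.8,
                         t_dice: float = 0.5, n_threads: int = 1,
                         timer=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-fold cross-validated optimization with repeated seeded runs.

    Frames are split into k random folds (temporal order retained); each
    group trains on k-1 folds and tests on the held-out fold, repeated
    ``repetitions`` times with seeds derived as seed + repetition index.
    Returns (per-run rows, mean/std aggregate over runs x folds).
    """
    from .synthetic import kfold_split

    folds = kfold_split(frames.shape[0], k, seed)
    rows = []
    for fold_i in range(k):
        test_idx = folds[fold_i]
        train_idx = np.sort(
            np.concatenate([folds[j] for j in range(k) if j != fold_i])
        )
        for rep in range(repetitions):
            rep_seed = seed + rep
            tuner = PipelineTuner(
                frames[train_idx], truth, strategy=strategy, config=config,
                a1=a1, t_dice=t_dice, n_threads=n_threads, timer=timer,
                seed=rep_seed,
            )
            res = tuner.fit()
            for split, idx in (("train", train_idx), ("test", test_idx)):
                scores = evaluate_params(frames[idx], truth,
                                         res.best_params, t_dice)
                rows.append({
                    "fold": fold_i, "repetition": rep, "seed": rep_seed,
                    "split": split, "fitness": res.best_fitness, **scores,
                })
    table = pd.DataFrame(rows)
    metrics = ["odc", "precision", "recall", "f1", "seconds", "fps"]
    agg = table.groupby("split")[metrics].agg(["mean", "std"]).fillna(0.0)
    return table, agg
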