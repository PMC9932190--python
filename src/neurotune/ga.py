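"""Genetic algorithm over real/integer-coded chromosomes as an eight-mode
CFDF actor.

Chromosomes carry one gene per pipeline parameter (real-coded; integer
dimensions rounded only on materialization).  Each generation the actor
emits CP - EL offspring built by selection + crossover + mutation, then
P - CP selection-only survivors, while the top EL individuals are carried
over unconditionally (elitism) without re-evaluation; per-generation
evaluation cost is therefore P - EL.

Six selection schemes (RWS, SUS, RNK, RSP, TNT, TRS), three crossover
operators (P1XO, P2XO, UXO) and three mutation operators (BDM, SPM, UNM)
are provided under their conventional abbreviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .dataflow import CfdfActor
from .params import ParamSpace
from .pso import write_result_files

__all__ = [
    "GaConfig",
    "selection_probabilities",
    "select_indices",
    "select_parents",
    "crossover",
    "mutate",
    "apply_elitism",
    "GaCoreActor",
]

SELECTION_METHODS = ("RWS", "SUS", "RNK", "RSP", "TNT", "TRS")
CROSSOVER_METHODS = ("P1XO", "P2XO", "UXO")
MUTATION_METHODS = ("BDM", "SPM", "UNM")


@dataclass
class GaConfig:
    """GA settings.  Defaults are the experiment configuration this
    package reproduces: population 24, mating population 24, elite 1,
    roulette-wheel selection, one-point crossover at rate 0.5,
    single-point mutation at rate 0.05, selective pressure 1.5."""

    population_size: int = 24          # P
    mating_size: int = 24              # CP
    elite_size: int = 1                # EL
    selection: str = "RWS"
    crossover: str = "P1XO"
    mutation: str = "SPM"
    crossover_rate: float = 0.5
    mutation_rate: float = 0.05
    selective_pressure: float = 1.5
    tournament_size: int = 2
    max_iterations: int = 50
    max_error: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.elite_size <= self.mating_size <= self.population_size:
            raise ValueError("need 0 <= EL <= CP <= P")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.selection not in SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.selection!r}")
        if self.crossover not in CROSSOVER_METHODS:
            raise ValueError(f"unknown crossover method {self.crossover!r}")
        if self.mutation not in MUTATION_METHODS:
            raise ValueError(f"unknown mutation method {self.mutation!r}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def selection_probabilities(method: str, fitnesses, sp: float = 1.5,
                            p_total: int | None = None) -> np.ndarray:
    """Analytic selection probabilities for the wheel/rank methods.

    RWS: p_i = f_i / sum(f) (uniform fallback when the total is 0).
    RNK: p_i proportional to rank (rank 1 = worst).
    RSP: p_i = (2-SP)/P + 2 (rank_i - 1)(SP - 1) / (P (P - 1)).
    TRS: p_i proportional to rank^SP.
    Tied fitnesses share averaged ranks, so equal fitnesses always give a
    uniform distribution.
    """
    f = np.asarray(fitnesses, dtype=float)
    n = p_total or len(f)
    if method == "RWS" or method == "SUS":
        if np.any(f < 0):
            raise ValueError("RWS/SUS require non-negative fitnesses")
        total = f.sum()
        return np.full(len(f), 1.0 / len(f)) if total == 0 else f / total
    ranks = rankdata(f, method="average")  # 1 = worst
    if method == "RNK":
        return ranks / ranks.sum()
    if method == "RSP":
        if n < 2:
            return np.ones(len(f))
        p = (2.0 - sp) / n + 2.0 * (ranks - 1.0) * (sp - 1.0) / (n * (n - 1.0))
        return p
    if method == "TRS":
        powered = ranks**sp
        return powered / powered.sum()
    raise ValueError(f"no analytic probabilities for method {method!r}")


def select_indices(method: str, fitnesses, m: int, rng: np.random.Generator,
                   sp: float = 1.5, tournament_size: int = 2) -> np.ndarray:
    """Draw ``m`` parent indices with the given scheme."""
    f = np.asarray(fitnesses, dtype=float)
    if method == "TNT":
        winners = np.empty(m, dtype=int)
        for i in range(m):
            entrants = rng.integers(0, len(f), size=tournament_size)
            winners[i] = entrants[int(np.argmax(f[entrants]))]
        return winners
    probs = selection_probabilities(method, f, sp)
    if method == "SUS":
        # one spin, m equally spaced pointers over the wheel
        cum = np.cumsum(probs)
        start = rng.random() / m
        points = start + np.arange(m) / m
        return np.searchsorted(cum, points, side="right").clip(0, len(f) - 1)
    return rng.choice(len(f), size=m, p=probs)


def select_parents(method: str, fitnesses, n_pairs: int,
                   rng: np.random.Generator, sp: float = 1.5,
                   tournament_size: int = 2) -> list[tuple[int, int]]:
    """``n_pairs`` parent index pairs.  SUS draws all parents in a single
    spin (then shuffles before pairing, so wheel order does not mate
    neighbors); the other methods draw independently."""
    idx = select_indices(method, fitnesses, 2 * n_pairs, rng, sp,
                         tournament_size)
    if method == "SUS":
        idx = rng.permutation(idx)
    return [(int(idx[2 * i]), int(idx[2 * i + 1])) for i in range(n_pairs)]


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def crossover(method: str, parent_a: np.ndarray, parent_b: np.ndarray,
              rate: float, rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray]:
    """Two offspring from two parents; with probability 1 - rate the
    parents are copied unchanged.  P1XO/P2XO fall back to copying when the
    chromosome is too short for interior cut points."""
    a = np.asarray(parent_a, dtype=float).copy()
    b = np.asarray(parent_b, dtype=float).copy()
    if a.shape != b.shape:
        raise ValueError("parents must have the same dimension")
    n = len(a)
    if rng.random() >= rate:
        return a, b
    if method == "P1XO":
        if n < 2:
            return a, b
        k = int(rng.integers(1, n))
        a[k:], b[k:] = b[k:].copy(), a[k:].copy()
        return a, b
    if method == "P2XO":
        if n < 3:
            return a, b
        k1, k2 = sorted(rng.choice(np.arange(1, n), size=2, replace=False))
        a[k1:k2], b[k1:k2] = b[k1:k2].copy(), a[k1:k2].copy()
        return a, b
    if method == "UXO":
        mask = rng.random(n) < 0.5
        a[mask], b[mask] = b[mask].copy(), a[mask].copy()
        return a, b
    raise ValueError(f"unknown crossover method {method!r}")


def _resample_gene(space: ParamSpace, i: int,
                   rng: np.random.Generator) -> float:
    d = space.descriptors[i]
    if d.kind == "integer":
        return float(rng.integers(int(d.min), int(d.max) + 1))
    return float(rng.uniform(d.min, d.max))


def mutate(method: str, genes: np.ndarray, rate: float, space: ParamSpace,
           rng: np.random.Generator) -> np.ndarray:
    """BDM: each gene with probability ``rate`` snaps to its min or max
    bound (fair coin).  SPM: with probability ``rate`` one uniformly
    chosen gene is resampled in its range.  UNM: each gene independently
    resampled with probability ``rate``.  The result is repaired."""
    x = np.asarray(genes, dtype=float).copy()
    n = len(x)
    if method == "BDM":
        for i in range(n):
            if rng.random() < rate:
                d = space.descriptors[i]
                x[i] = d.max if rng.random() < 0.5 else d.min
    elif method == "SPM":
        if rng.random() < rate:
            i = int(rng.integers(n))
            x[i] = _resample_gene(space, i, rng)
    elif method == "UNM":
        for i in range(n):
            if rng.random() < rate:
                x[i] = _resample_gene(space, i, rng)
    else:
        raise ValueError(f"unknown mutation method {method!r}")
    return space.repair(x)


def apply_elitism(fitnesses, elite_size: int) -> list[int]:
    """Indices of the ``elite_size`` highest-fitness individuals (stable
    under ties: lower index first)."""
    f = np.asarray(fitnesses, dtype=float)
    if elite_size > len(f):
        raise ValueError("elite size exceeds population size")
    order = np.argsort(-f, kind="stable")
    return [int(i) for i in order[:elite_size]]


# ---------------------------------------------------------------------------
# The GA Core actor
# ---------------------------------------------------------------------------

class GaCoreActor(CfdfActor):
    """The GA search engine wired as a CFDF actor (eight modes)."""

    def __init__(self, space: ParamSpace, config: GaConfig,
                 rng: np.random.Generator, name: str = "ga-core",
                 output_dir: str | None = None):
        config.validate()
        p, cp, el = (config.population_size, config.mating_size,
                     config.elite_size)
        table = {
            "initialize-write": {"out": p},
            "initialize-read": {"in": -p},
            "stopping-evaluation": {},
            "update-population-crossover-write": {"out": cp - el},
            "update-population-crossover-read": {"in": -(cp - el)},
            "update-population-complete-write": {"out": p - cp},
            "update-population-complete-read": {"in": -(p - cp)},
            "write-output": {},
        }
        super().__init__(name, table, "initialize-write")
        self.space = space
        self.config = config
        self.rng = rng
        self.output_dir = output_dir
        self.genes: list[np.ndarray] = []
        self.fitness = np.full(p, -np.inf)
        self.best_fitness = -np.inf
        self.best_positions: list[np.ndarray] = []
        self.iteration = 0
        self.history: list[dict] = []
        self.result: dict | None = None
        self._elite_idx: list[int] = []
        self._offspring: list[np.ndarray] = []
        self._offspring_fitness: np.ndarray | None = None
        self._completes: list[np.ndarray] = []

    # -- helpers --------------------------------------------------------------
    def _update_best(self) -> None:
        best = float(self.fitness.max())
        if best >= self.best_fitness:
            self.best_fitness = best
            ties = np.flatnonzero(self.fitness == best)
            self.best_positions = [self.genes[int(i)].copy() for i in ties]

    def _record(self) -> None:
        self.history.append({
            "iteration": self.iteration,
            "best_fitness": self.best_fitness,
            "mean_fitness": float(self.fitness.mean()),
        })

    def _make_offspring(self, count: int) -> list[np.ndarray]:
        cfg = self.config
        out: list[np.ndarray] = []
        while len(out) < count:
            (i, j) = select_parents(
                cfg.selection, self.fitness, 1, self.rng,
                cfg.selective_pressure, cfg.tournament_size,
            )[0]
            child_a, child_b = crossover(
                cfg.crossover, self.genes[i], self.genes[j],
                cfg.crossover_rate, self.rng,
            )
            for child in (child_a, child_b):
                out.append(mutate(cfg.mutation, child, cfg.mutation_rate,
                                  self.space, self.rng))
        return out[:count]  # truncate the last pair's second offspring

    # -- modes ----------------------------------------------------------------
    def mode_initialize_write(self, consumed):
        self.genes = [
            self.space.sample_uniform(self.rng)
            for _ in range(self.config.population_size)
        ]
        return {"out": [g.copy() for g in self.genes]}, "initialize-read"

    def mode_initialize_read(self, consumed):
        self.fitness = np.array([rec.value for rec in consumed["in"]])
        self.iteration = 0
        self._update_best()
        self._record()
        return {}, "stopping-evaluation"

    def mode_stopping_evaluation(self, consumed):
        cfg = self.config
        done = self.iteration >= cfg.max_iterations or (
            cfg.max_error > 0 and (1.0 - self.best_fitness) <= cfg.max_error
        )
        next_mode = ("write-output" if done
                     else "update-population-crossover-write")
        return {}, next_mode

    def mode_update_population_crossover_write(self, consumed):
        cfg = self.config
        self._elite_idx = apply_elitism(self.fitness, cfg.elite_size)
        self._offspring = self._make_offspring(cfg.mating_size
                                               - cfg.elite_size)
        out = [g.copy() for g in self._offspring]
        return {"out": out}, "update-population-crossover-read"

    def mode_update_population_crossover_read(self, consumed):
        self._offspring_fitness = np.array(
            [rec.value for rec in consumed["in"]]
        )
        return {}, "update-population-complete-write"

    def mode_update_population_complete_write(self, consumed):
        cfg = self.config
        n_fill = cfg.population_size - cfg.mating_size
        if n_fill > 0:
            idx = select_indices(
                cfg.selection, self.fitness, n_fill, self.rng,
                cfg.selective_pressure, cfg.tournament_size,
            )
            self._completes = [self.genes[int(i)].copy() for i in idx]
        else:
            self._completes = []
        out = [g.copy() for g in self._completes]
        return {"out": out}, "update-population-complete-read"

    def mode_update_population_complete_read(self, consumed):
        fill_fitness = [rec.value for rec in consumed.get("in", [])]
        elites = [self.genes[i].copy() for i in self._elite_idx]
        elite_fitness = [float(self.fitness[i]) for i in self._elite_idx]
        self.genes = elites + self._offspring + self._completes
        self.fitness = np.array(
            elite_fitness
            + list(self._offspring_fitness)
            + fill_fitness
        )
        self.iteration += 1
        self._update_best()
        self._record()
        return {}, "stopping-evaluation"

    def mode_write_output(self, consumed):
        self.result = {
            "best_fitness": self.best_fitness,
            "best_positions": [p.copy() for p in self.best_positions],
            "best_params": [
                self.space.materialize(p) for p in self.best_positions
            ],
            "iterations": self.iteration,
            "history": list(self.history),
        }
        if self.output_dir is not None:
            write_result_files(self.output_dir, self.result)
        self.terminated = True
        return {}, "write-output"
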