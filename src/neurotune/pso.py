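"""Particle swarm optimization as a six-mode CFDF actor.

The swarm searches the parameter box with the local-best (neighborhood)
velocity rule

    v' = w*v + c1*r1 .* (pbest - x) + c2*r2 .* (lbest - x)
    x' = repair(x + v')

where ``lbest`` is the best personal-best among a particle's neighbors
(including itself) under the configured topology — fully connected, ring
lattice, or a randomly rewired informant graph that is re-randomized
whenever an iteration brings no improvement of the global best.  Inertia
``w`` decreases linearly from ``w_max`` to ``w_min`` over the run.  Ties
for the best particle are broken uniformly at random.

The actor's six modes (initialize-write/read, update-population-write/read,
stopping-evaluation, write-output) carry fixed dataflow rates: the write
modes emit one candidate token per particle, the read modes consume one
fitness token per particle, and the bookkeeping modes move no tokens.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .dataflow import CfdfActor
from .params import ParamSpace

__all__ = [
    "PsoConfig",
    "Particle",
    "inertia_at",
    "neighbors",
    "select_best",
    "update_velocity_position",
    "random_informants",
    "maybe_rewire",
    "PsoCoreActor",
]

TOPOLOGIES = ("fully_connected", "ring", "random")


@dataclass
class PsoConfig:
    """Swarm settings.  Defaults are the configuration used throughout the
    experiments this package reproduces: 24 particles, ring topology with
    10 informants, c1 = c2 = 1.496, inertia 0.7298 -> 0.3, 50 iterations.
    ``max_error`` > 0 enables early stopping once (1 - best fitness) drops
    to that level."""

    n_particles: int = 24
    c1: float = 1.496
    c2: float = 1.496
    w_min: float = 0.3
    w_max: float = 0.7298
    topology: str = "ring"
    neighborhood_size: int = 10
    max_iterations: int = 50
    max_error: float = 0.0

    def validate(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0 < self.w_min <= self.w_max:
            raise ValueError("need 0 < w_min <= w_max")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray | None = None
    pbest_fitness: float = -np.inf
    fitness: float = -np.inf


def inertia_at(iteration: int, max_iterations: int, w_min: float,
               w_max: float) -> float:
    """Linearly decreasing inertia: w_max at iteration 0 down to w_min at
    the final iteration; w_max when there are no iterations."""
    if max_iterations <= 0:
        return w_max
    frac = min(max(iteration / max_iterations, 0.0), 1.0)
    return w_max - (w_max - w_min) * frac


def neighbors(topology: str, n: int, i: int, k: int = 2,
              graph: list[set[int]] | None = None) -> set[int]:
    """Neighbor index set of particle ``i``.

    fully_connected: all other particles.  ring: the ``k`` cyclically
    nearest indices, split evenly on each side (the extra one on the right
    when ``k`` is odd).  random: the current informant graph edges.
    """
    if topology == "fully_connected":
        return set(range(n)) - {i}
    if topology == "ring":
        left = k // 2
        right = k - left
        out = {(i - d) % n for d in range(1, left + 1)}
        out |= {(i + d) % n for d in range(1, right + 1)}
        out.discard(i)
        return out
    if topology == "random":
        if graph is None:
            raise ValueError("random topology requires an informant graph")
        return set(graph[i])
    raise ValueError(f"unknown topology {topology!r}")


def select_best(fitnesses, rng: np.random.Generator) -> int:
    """Index of a maximal fitness; ties broken uniformly at random."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty fitness list")
    ties = np.flatnonzero(f == f.max())
    return int(ties[0] if len(ties) == 1 else rng.choice(ties))


def update_velocity_position(particle: Particle, lbest: np.ndarray,
                             w: float, c1: float, c2: float,
                             rng: np.random.Generator,
                             space: ParamSpace) -> None:
    """In-place velocity/position update with fresh uniform[0,1] draw
    vectors; the new position is repaired into the box."""
    r1 = rng.random(space.n)
    r2 = rng.random(space.n)
    particle.velocity = (
        w * particle.velocity
        + c1 * r1 * (particle.pbest_position - particle.position)
        + c2 * r2 * (lbest - particle.position)
    )
    particle.position = space.repair(particle.position + particle.velocity)


def random_informants(n: int, k: int,
                      rng: np.random.Generator) -> list[set[int]]:
    """Randomly rewired informant graph: each particle informs itself plus
    ``k`` uniformly chosen particles.  neighbors(i) = particles informing
    i, so every particle has at least one neighbor (itself)."""
    neigh: list[set[int]] = [{i} for i in range(n)]
    for j in range(n):
        for t in rng.integers(0, n, size=k):
            neigh[int(t)].add(j)
    return neigh


def maybe_rewire(informants: list[set[int]], improved: bool, n: int, k: int,
                 rng: np.random.Generator) -> list[set[int]]:
    """Random-topology step: keep the informant graph when the global
    best improved this iteration, otherwise re-randomize it."""
    if improved:
        return informants
    return random_informants(n, k, rng)


class PsoCoreActor(CfdfActor):
    """The PSO search engine wired as a CFDF actor (six modes)."""

    def __init__(self, space: ParamSpace, config: PsoConfig,
                 rng: np.random.Generator, name: str = "pso-core",
                 output_dir: str | None = None):
        config.validate()
        p = config.n_particles
        table = {
            "initialize-write": {"out": p},
            "initialize-read": {"in": -p},
            "stopping-evaluation": {},
            "update-population-write": {"out": p},
            "update-population-read": {"in": -p},
            "write-output": {},
        }
        super().__init__(name, table, "initialize-write")
        self.space = space
        self.config = config
        self.rng = rng
        self.output_dir = output_dir
        self.particles: list[Particle] = []
        self.gbest_fitness = -np.inf
        self.gbest_positions: list[np.ndarray] = []
        self.iteration = 0
        self.informants: list[set[int]] | None = None
        self.history: list[dict] = []
        self.result: dict | None = None

    # -- helpers --------------------------------------------------------------
    def _neighbors(self, i: int) -> set[int]:
        return neighbors(self.config.topology, self.config.n_particles, i,
                         self.config.neighborhood_size, self.informants)

    def _local_best(self, i: int) -> np.ndarray:
        idx = sorted(self._neighbors(i) | {i})
        pbf = [self.particles[j].pbest_fitness for j in idx]
        return self.particles[idx[select_best(pbf, self.rng)]].pbest_position

    def _update_gbest(self) -> bool:
        """Refresh the global best from personal bests; returns True when
        it improved.  All tied-for-best positions are retained."""
        pbf = np.array([p.pbest_fitness for p in self.particles])
        best = float(pbf.max())
        improved = best > self.gbest_fitness
        if best >= self.gbest_fitness:
            self.gbest_fitness = best
            ties = np.flatnonzero(pbf == best)
            self.gbest_positions = [
                self.particles[int(i)].pbest_position.copy() for i in ties
            ]
        return improved

    def _record(self) -> None:
        fit = np.array([p.fitness for p in self.particles])
        self.history.append({
            "iteration": self.iteration,
            "best_fitness": self.gbest_fitness,
            "mean_fitness": float(fit.mean()),
        })

    # -- modes ----------------------------------------------------------------
    def mode_initialize_write(self, consumed):
        cfg = self.config
        self.particles = [
            Particle(
                position=self.space.sample_uniform(self.rng),
                velocity=np.zeros(self.space.n),
            )
            for _ in range(cfg.n_particles)
        ]
        if cfg.topology == "random":
            self.informants = random_informants(
                cfg.n_particles, cfg.neighborhood_size, self.rng
            )
        out = [p.position.copy() for p in self.particles]
        return {"out": out}, "initialize-read"

    def mode_initialize_read(self, consumed):
        for particle, rec in zip(self.particles, consumed["in"]):
            particle.fitness = rec.value
            particle.pbest_fitness = rec.value
            particle.pbest_position = particle.position.copy()
        self.iteration = 0
        self._update_gbest()
        self._record()
        return {}, "stopping-evaluation"

    def mode_stopping_evaluation(self, consumed):
        cfg = self.config
        done = self.iteration >= cfg.max_iterations or (
            cfg.max_error > 0
            and (1.0 - self.gbest_fitness) <= cfg.max_error
        )
        return {}, "write-output" if done else "update-population-write"

    def mode_update_population_write(self, consumed):
        cfg = self.config
        w = inertia_at(self.iteration, cfg.max_iterations, cfg.w_min,
                       cfg.w_max)
        out = []
        for i, p in enumerate(self.particles):
            lbest = self._local_best(i)
            update_velocity_position(p, lbest, w, cfg.c1, cfg.c2, self.rng,
                                     self.space)
            out.append(p.position.copy())
        return {"out": out}, "update-population-read"

    def mode_update_population_read(self, consumed):
        for particle, rec in zip(self.particles, consumed["in"]):
            particle.fitness = rec.value
            if rec.value > particle.pbest_fitness:
                particle.pbest_fitness = rec.value
                particle.pbest_position = particle.position.copy()
        improved = self._update_gbest()
        self.iteration += 1
        if self.config.topology == "random":
            self.informants = maybe_rewire(
                self.informants, improved, self.config.n_particles,
                self.config.neighborhood_size, self.rng,
            )
        self._record()
        return {}, "stopping-evaluation"

    def mode_write_output(self, consumed):
        self.result = {
            "best_fitness": self.gbest_fitness,
            "best_positions": [p.copy() for p in self.gbest_positions],
            "best_params": [
                self.space.materialize(p) for p in self.gbest_positions
            ],
            "iterations": self.iteration,
            "history": list(self.history),
        }
        if self.output_dir is not None:
            write_result_files(self.output_dir, self.result)
        self.terminated = True
        return {}, "write-output"


def write_result_files(output_dir: str, result: dict) -> None:
    """best_params.txt (key=value blocks, one per tied-for-best solution)
    plus a per-iteration diagnostics.csv."""
    os.makedirs(output_dir, exist_ok=True)
    with open(os.path.join(output_dir, "best_params.txt"), "w") as fh:
        fh.write(f"# best_fitness={result['best_fitness']:.6f}\n")
        for i, params in enumerate(result["best_params"]):
            fh.write(f"# solution {i + 1} of {len(result['best_params'])}\n")
            for key, value in params.items():
                fh.write(f"{key}={value}\n")
    with open(os.path.join(output_dir, "diagnostics.csv"), "w",
              newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["iteration", "best_fitness", "mean_fitness"]
        )
        writer.writeheader()
        writer.writerows(result["history"])
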