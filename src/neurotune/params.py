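"""Heterogeneous continuous/integer parameter search spaces.

A :class:`ParamSpace` declares the box the optimizers search: an ordered
sequence of named dimensions, each either continuous or integer with finite
bounds.  Candidate solutions are carried as real-valued position vectors
(one entry per dimension, integer dimensions included); integer dimensions
are materialized (rounded) only when a candidate is handed to the detection
pipeline, so the optimizer dynamics stay in ordinary real arithmetic.

Out-of-range values produced by swarm motion or mutation are repaired by
clamping (round-then-clamp on integer dimensions); no reflection or
wrap-around is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParamDescriptor",
    "ParamSpace",
    "ndsep_space",
    "cellsort_space",
]


@dataclass(frozen=True)
class ParamDescriptor:
    """One search dimension: a named parameter with kind and bounds."""

    name: str
    kind: str  # "continuous" | "integer"
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if not self.min <= self.max:
            raise ValueError(f"{self.name}: min {self.min} > max {self.max}")
        if self.kind == "integer" and (
            self.min != int(self.min) or self.max != int(self.max)
        ):
            raise ValueError(f"{self.name}: integer bounds must be integral")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


class ParamSpace:
    """An ordered, named box of continuous and integer parameters."""

    def __init__(self, descriptors: Iterable[ParamDescriptor]):
        self.descriptors = tuple(descriptors)
        if not self.descriptors:
            raise ValueError("parameter space must have at least one dimension")
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        self.names = tuple(names)
        self.lo = np.array([d.min for d in self.descriptors], dtype=float)
        self.hi = np.array([d.max for d in self.descriptors], dtype=float)
        self.is_integer = np.array(
            [d.kind == "integer" for d in self.descriptors], dtype=bool
        )

    @property
    def n(self) -> int:
        return len(self.descriptors)

    @property
    def range(self) -> np.ndarray:
        return self.hi - self.lo

    def sample_uniform(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a position uniformly: continuous dims U[min, max], integer
        dims uniform over the integers in range (carried as floats)."""
        x = rng.uniform(self.lo, self.hi)
        if self.is_integer.any():
            ints = rng.integers(
                self.lo[self.is_integer].astype(int),
                self.hi[self.is_integer].astype(int) + 1,
            )
            x[self.is_integer] = ints.astype(float)
        return x

    def repair(self, position: Sequence[float]) -> np.ndarray:
        """Clamp into the box; integer dims are rounded (half away from
        zero) before clamping.  Idempotent."""
        x = np.asarray(position, dtype=float).copy()
        if x.shape != (self.n,):
            raise ValueError(
                f"position has shape {x.shape}, expected ({self.n},)"
            )
        x[self.is_integer] = _round_half_away(x[self.is_integer])
        return np.clip(x, self.lo, self.hi)

    def materialize(self, position: Sequence[float]) -> dict[str, float | int]:
        """Repair and convert to a {name: value} dict with native ints on
        integer dimensions — the form handed to a detection pipeline."""
        x = self.repair(position)
        out: dict[str, float | int] = {}
        for i, d in enumerate(self.descriptors):
            out[d.name] = int(x[i]) if d.kind == "integer" else float(x[i])
        return out

    def midpoint(self) -> np.ndarray:
        """Center of the box (integer dims rounded into range)."""
        return self.repair((self.lo + self.hi) / 2.0)

    def to_config(self) -> list[dict]:
        return [
            {"name": d.name, "kind": d.kind, "min": d.min, "max": d.max}
            for d in self.descriptors
        ]

    @classmethod
    def from_config(cls, entries: Iterable[dict]) -> "ParamSpace":
        return cls(
            ParamDescriptor(e["name"], e["kind"], float(e["min"]), float(e["max"]))
            for e in entries
        )

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        dims = ", ".join(f"{d.name}[{d.min},{d.max}]" for d in self.descriptors)
        return f"ParamSpace({dims})"


def ndsep_space() -> ParamSpace:
    """Search space of the bundled reference neuron detector: threshold
    sweep step, three blob-shape filters, and three smoothing settings."""
    return ParamSpace(
        [
            ParamDescriptor("threshold_step", "continuous", 10.0, 100.0),
            ParamDescriptor("min_circularity", "continuous", 0.0, 1.0),
            ParamDescriptor("min_convexity", "continuous", 0.0, 1.0),
            ParamDescriptor("min_inertia_ratio", "continuous", 0.0, 1.0),
            ParamDescriptor("gaussian_blur_size", "integer", 1, 60),
            ParamDescriptor("gaussian_std", "continuous", 0.0, 1.0),
            ParamDescriptor("median_blur_size", "integer", 1, 60),
        ]
    )


def cellsort_space() -> ParamSpace:
    """Parameter box of the PCA/ICA segmentation tool (accepted by the
    config format; no engine for it ships with this package)."""
    return ParamSpace(
        [
            ParamDescriptor("PCl", "integer", 1, 60),
            ParamDescriptor("PCf", "integer", 61, 150),
            ParamDescriptor("mu", "continuous", 0.0, 1.0),
            ParamDescriptor("smwidth", "continuous", 0.0, 10.0),
            ParamDescriptor("areal", "integer", 50, 500),
            ParamDescriptor("areah", "integer", 501, 2000),
            ParamDescriptor("thresh", "continuous", 1.5, 10.0),
        ]
    )
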