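"""Weight sweeps, Pareto-front extraction and the dominated-area metric.

A weight sweep re-runs the optimizer for each accuracy weight a1 in a
grid (a2 = 1 - a1), collecting the best solution's accuracy/speed outcome
(D, TimeScale), both maximized on the unit square.  The Pareto front is
the non-dominated subset of those outcomes; its quality is summarized by
the AUC — the area of the unit square dominated by the front (the 2-D
hypervolume with reference point (0, 0))."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["OutcomePoint", "weight_sweep", "pareto_front", "pareto_auc"]

DEFAULT_WEIGHTS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass(frozen=True)
class OutcomePoint:
    """One optimization outcome on the accuracy/speed plane."""

    accuracy: float
    timescale: float
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    def dominates(self, other: "OutcomePoint") -> bool:
        ge = (self.accuracy >= other.accuracy
              and self.timescale >= other.timescale)
        gt = (self.accuracy > other.accuracy
              or self.timescale > other.timescale)
        return ge and gt


def weight_sweep(runner: Callable[[float], OutcomePoint],
                 weights: Iterable[float] = DEFAULT_WEIGHTS
                 ) -> list[OutcomePoint]:
    """One optimization run per accuracy weight a1 (a2 = 1 - a1); the
    runner returns the best solution's outcome point."""
    points = []
    for a1 in weights:
        if not 0.0 < a1 < 1.0:
            raise ValueError(f"a1 must lie in (0, 1), got {a1}")
        point = runner(float(a1))
        point.provenance.setdefault("a1", float(a1))
        points.append(point)
    return points


def pareto_front(points: Sequence[OutcomePoint]) -> list[OutcomePoint]:
    """Maximal non-dominated subset, sorted by ascending accuracy.
    Duplicate coordinates collapse to one representative."""
    if not points:
        raise ValueError("empty outcome set")
    unique: dict[tuple[float, float], OutcomePoint] = {}
    for p in points:
        unique.setdefault((p.accuracy, p.timescale), p)
    kept = [
        p for p in unique.values()
        if not any(q.dominates(p) for q in unique.values())
    ]
    return sorted(kept, key=lambda p: (p.accuracy, p.timescale))


def pareto_auc(front: Sequence[OutcomePoint]) -> float:
    """Area of the unit square dominated by the front (staircase
    integration of the attainment surface)."""
    if not front:
        raise ValueError("empty front")
    # on a non-dominated front sorted by ascending accuracy, timescale is
    # non-increasing, so the rectangle over (prev, acc_i] has height ts_i
    pts = sorted(front, key=lambda p: (p.accuracy, -p.timescale))
    area = 0.0
    prev_acc = 0.0
    for p in pts:
        if p.accuracy > prev_acc:
            area += (p.accuracy - prev_acc) * p.timescale
            prev_acc = p.accuracy
    return area
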