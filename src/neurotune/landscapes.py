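"""Mock detection systems with known fitness landscapes.

These stand-ins implement the PNDS wrapper contract but compute accuracy
from a closed-form function of the parameters instead of segmenting
images.  They make optimizer behavior testable: the optimum is known, the
landscape is smooth and unimodal, and the reported wall time is a
deterministic function of the candidate, so whole optimization
trajectories are reproducible bit-for-bit.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .params import ParamSpace
from .pnds import EvalResult, PndsWrapper

__all__ = ["UnimodalLandscapePnds", "TradeoffLandscapePnds",
           "recovery_error"]


def recovery_error(params: Mapping[str, float | int], peak: np.ndarray,
                   space: ParamSpace) -> float:
    """Range-normalized RMS distance of a parameter setting from a known
    optimum: ||(x - peak) / range||_2 / sqrt(n).  0 at the optimum; 1 is
    one full parameter range off on every dimension."""
    x = np.array([float(params[name]) for name in space.names])
    z = (x - peak) / np.where(space.range > 0, space.range, 1.0)
    return float(np.sqrt(np.mean(z**2)))

# Fixed interior peak, expressed as fractions of each dimension's range.
DEFAULT_PEAK_FRACTIONS = (0.30, 0.62, 0.55, 0.41, 0.70, 0.35, 0.52)


class UnimodalLandscapePnds(PndsWrapper):
    """Accuracy is a single Gaussian bump inside the parameter box.

    D(x) = floor + (1 - floor) * exp(-sum_i ((x_i - peak_i) / (width * range_i))^2)

    The reported wall time decreases toward the peak (faster where more
    accurate), so the harmonic fitness aggregate shares the same optimum
    for every weighting.  ``peak_fractions`` places the optimum at fixed
    fractions of each dimension's range.
    """

    def __init__(self, space: ParamSpace,
                 peak_fractions=None, width: float = 0.25,
                 floor: float = 0.1, base_seconds: float = 1.0):
        super().__init__()
        self.space = space
        self.param_names = space.names
        fracs = np.asarray(
            peak_fractions
            if peak_fractions is not None
            else DEFAULT_PEAK_FRACTIONS[: space.n],
            dtype=float,
        )
        if len(fracs) != space.n:
            raise ValueError("one peak fraction per dimension required")
        self.peak = space.lo + fracs * space.range
        self.width = width
        self.floor = floor
        self.base_seconds = base_seconds

    def _vector(self, values: Mapping[str, float | int]) -> np.ndarray:
        return np.array([float(values[name]) for name in self.param_names])

    def accuracy(self, values: Mapping[str, float | int]) -> float:
        x = self._vector(values)
        scale = np.where(self.space.range > 0,
                         self.width * self.space.range, 1.0)
        z = ((x - self.peak) / scale) ** 2
        return self.floor + (1.0 - self.floor) * float(np.exp(-z.sum()))

    def seconds(self, values: Mapping[str, float | int]) -> float:
        return self.base_seconds * (2.0 - self.accuracy(values))

    def evaluate_at(self, values, timer=None) -> EvalResult:
        return EvalResult(self.accuracy(values), self.seconds(values))


class TradeoffLandscapePnds(PndsWrapper):
    """A strict accuracy/time trade-off on the first parameter.

    Accuracy increases and speed decreases along the dimension, so the
    best attainable (D, TimeScale) pairs trace a known Pareto curve; a
    higher accuracy weight a1 must pull the optimum toward the accurate,
    slow end.  Used to exercise weight sweeps and front extraction.
    """

    def __init__(self, space: ParamSpace, w_slow: float = 10.0,
                 w_fast: float = 1.0):
        super().__init__()
        self.space = space
        self.param_names = space.names
        self.w_slow = w_slow
        self.w_fast = w_fast

    def _t(self, values: Mapping[str, float | int]) -> float:
        d = self.space.descriptors[0]
        span = d.max - d.min
        return (float(values[d.name]) - d.min) / span if span else 0.0

    def accuracy(self, values) -> float:
        return 0.05 + 0.95 * self._t(values)

    def seconds(self, values) -> float:
        return self.w_fast + (self.w_slow - self.w_fast) * self._t(values)

    def evaluate_at(self, values, timer=None) -> EvalResult:
        return EvalResult(self.accuracy(values), self.seconds(values))
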