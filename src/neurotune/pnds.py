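"""Pluggable neuron-detection systems and their dataflow wrappers.

A *parameterized neuron-detection system* (PNDS) is any detector whose
tunable parameters are exposed through the small wrapper contract below:
``set_params`` updates named parameter slots, ``evaluate`` runs detection
on the wrapper's bound dataset and returns an accuracy/wall-time pair.
The optimizers only ever talk to this contract, so third-party detectors
can be plugged in without touching the search code.

The module also ships a reference detector: a classical multi-level
thresholding blob pipeline over the temporal max-projection of a calcium
imaging stack (Gaussian + median smoothing, an intensity-threshold sweep,
connected components merged across levels by centroid proximity, and
circularity/convexity/inertia shape filters).  Its seven parameters form
the bundled search space (:func:`neurotune.params.ndsep_space`).

Wall time is measured through an injectable timer so tests and repeatable
experiments can substitute a deterministic cost model for the real clock.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

from .dataflow import CfdfActor
from .metrics import aggregate_fitness, overall_dice, time_scale

__all__ = [
    "EvalResult",
    "FitnessRecord",
    "WallClockTimer",
    "MockTimer",
    "PndsWrapper",
    "ReferencePnds",
    "reference_detect",
    "detection_cost_model",
    "SetParamsActor",
    "PndsActor",
    "FitnessEvaluationActor",
]


@dataclass(frozen=True)
class EvalResult:
    """Per-candidate evaluation outcome: detection accuracy D(p) in [0,1]
    and measured single-threaded wall time W(p) in seconds."""

    accuracy: float
    seconds: float


@dataclass(frozen=True)
class FitnessRecord:
    """Fitness token payload: the maximized harmonic aggregate plus the
    components it was built from, for diagnostics."""

    value: float
    accuracy: float
    seconds: float
    tau: float
    timescale: float


class WallClockTimer:
    """Measures real elapsed time with a monotonic clock."""

    def measure(self, fn: Callable[[], object],
                params: Mapping | None = None):
        t0 = time.perf_counter()
        out = fn()
        return out, max(time.perf_counter() - t0, 1e-9)


class MockTimer:
    """Deterministic timer: runs the computation but reports a wall time
    computed from the candidate's parameters, so optimization trajectories
    are bit-reproducible and independent of machine load or threading."""

    def __init__(self, cost_fn: Callable[[Mapping], float]):
        self.cost_fn = cost_fn

    def measure(self, fn: Callable[[], object],
                params: Mapping | None = None):
        out = fn()
        return out, max(float(self.cost_fn(params or {})), 1e-9)


class PndsWrapper:
    """Contract every pluggable detector implements.

    Parameter slots are named; setting a parameter and then evaluating
    uses the new value, and evaluation is deterministic given parameters
    and dataset.  ``evaluate_at`` is the pure form (no shared state) used
    for concurrent block evaluation.
    """

    param_names: tuple[str, ...] = ()

    def __init__(self):
        self._params: dict[str, float | int] = {}

    def set_params(self, values: Mapping[str, float | int]) -> None:
        for name, value in values.items():
            if name not in self.param_names:
                raise KeyError(f"unknown PNDS parameter {name!r}")
            self._params[name] = value

    def get_params(self) -> dict[str, float | int]:
        return dict(self._params)

    def evaluate_at(self, values: Mapping[str, float | int],
                    timer) -> EvalResult:
        raise NotImplementedError

    def evaluate(self, timer) -> EvalResult:
        return self.evaluate_at(self.get_params(), timer)


# ---------------------------------------------------------------------------
# Reference detector
# ---------------------------------------------------------------------------

def _odd(k: int) -> int:
    """Even smoothing kernel sizes are promoted to the next odd integer."""
    k = int(k)
    return k if k % 2 == 1 else k + 1


def _region_passes(region, min_circularity: float, min_convexity: float,
                   min_inertia_ratio: float) -> bool:
    area = region.area
    perim = region.perimeter
    circularity = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    if circularity < min_circularity:
        return False
    hull = region.area_convex
    convexity = area / hull if hull > 0 else 1.0
    if convexity < min_convexity:
        return False
    major = region.axis_major_length
    minor = region.axis_minor_length
    inertia = minor / major if major > 0 else 1.0
    return inertia >= min_inertia_ratio


def reference_detect(frames: np.ndarray,
                     params: Mapping[str, float | int]) -> np.ndarray:
    """Run the reference blob pipeline; returns a label mask.

    Steps: temporal max-projection rescaled to [0, 255]; Gaussian blur
    (kernel ``gaussian_blur_size``, sigma ``gaussian_std``); median blur
    (``median_blur_size``); an absolute-intensity threshold sweep with
    spacing ``threshold_step``; per-level connected components filtered by
    circularity 4*pi*A/perimeter^2, convexity A/convex-area and inertia
    ratio minor/major axis; surviving blobs merged across levels when a
    centroid falls within one blob radius of an already-kept blob (the
    lowest-threshold version is kept).  Components under 3 px are ignored
    (shape measures are degenerate there).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    img = frames.max(axis=0)
    return _detect_projection(img, params)


def _detect_projection(img: np.ndarray,
                       params: Mapping[str, float | int]) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    out = np.zeros(img.shape, dtype=np.int32)
    if hi <= lo:
        return out
    work = (img - lo) * (255.0 / (hi - lo))

    sigma = float(params["gaussian_std"])
    ksize = _odd(int(params["gaussian_blur_size"]))
    if sigma > 0 and ksize > 1:
        truncate = ((ksize - 1) / 2) / sigma
        work = ndi.gaussian_filter(work, sigma=sigma, truncate=truncate,
                                   mode="nearest")

    msize = _odd(int(params["median_blur_size"]))
    if msize > 1:
        u8 = np.clip(np.round(work), 0, 255).astype(np.uint8)
        work = rank.median(
            u8, footprint=footprint_rectangle((msize, msize))
        ).astype(float)

    step = float(params["threshold_step"])
    wlo, whi = float(work.min()), float(work.max())
    levels = np.arange(wlo + step, whi, step)

    kept: list[dict] = []  # each: centroid, radius, coords
    for level in levels:
        labels = measure.label(work >= level, connectivity=2)
        for region in measure.regionprops(labels):
            if region.area < 3:
                continue
            if not _region_passes(
                region,
                float(params["min_circularity"]),
                float(params["min_convexity"]),
                float(params["min_inertia_ratio"]),
            ):
                continue
            cy, cx = region.centroid
            merged = False
            for blob in kept:
                by, bx = blob["centroid"]
                if np.hypot(cy - by, cx - bx) < blob["radius"]:
                    merged = True
                    break
            if not merged:
                kept.append({
                    "centroid": (cy, cx),
                    "radius": region.equivalent_diameter_area / 2.0,
                    "coords": region.coords,
                })

    for i, blob in enumerate(kept, start=1):
        out[blob["coords"][:, 0], blob["coords"][:, 1]] = i
    # drop labels fully overwritten by later blobs, keep ids contiguous
    present = np.unique(out[out > 0])
    if len(present) and present[-1] != len(present):
        remap = {old: new for new, old in enumerate(present, start=1)}
        out = np.vectorize(lambda v: remap.get(v, 0))(out).astype(np.int32)
    return out


def detection_cost_model(params: Mapping[str, float | int]) -> float:
    """Deterministic surrogate wall time (seconds) for the reference
    detector: smoothing cost grows with the blur kernels, sweep cost with
    the number of threshold levels.  Used by the mock timer."""
    gauss = float(params.get("gaussian_blur_size", 1))
    med = float(params.get("median_blur_size", 1))
    step = float(params.get("threshold_step", 50.0))
    levels = 255.0 / max(step, 1e-6)
    return 1e-3 * (1.0 + 0.05 * (gauss + med) + 0.2 * levels)


class ReferencePnds(PndsWrapper):
    """The bundled reference detector bound to one dataset.

    The pipeline segments the temporal max-projection once per evaluation
    (a single overall detection result for the dataset); accuracy is the
    ODC against the bound ground-truth mask.  Only the detection
    computation is timed — scoring is excluded from W(p).
    """

    param_names = (
        "threshold_step",
        "min_circularity",
        "min_convexity",
        "min_inertia_ratio",
        "gaussian_blur_size",
        "gaussian_std",
        "median_blur_size",
    )

    def __init__(self, frames: np.ndarray, truth: np.ndarray):
        super().__init__()
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.size == 0:
            raise ValueError("empty dataset")
        self.frames = frames
        self.truth = np.asarray(truth)
        self.n_frames = frames.shape[0]
        # the projection depends only on the dataset; cache it
        self._projection = frames.max(axis=0)

    def detect(self, values: Mapping[str, float | int]) -> np.ndarray:
        return _detect_projection(self._projection, values)

    def evaluate_at(self, values: Mapping[str, float | int],
                    timer) -> EvalResult:
        mask, seconds = timer.measure(lambda: self.detect(values),
                                      params=values)
        return EvalResult(overall_dice(mask, self.truth), seconds)


# ---------------------------------------------------------------------------
# Dataflow actors around the PNDS
# ---------------------------------------------------------------------------

class SetParamsActor(CfdfActor):
    """Receives candidate-position tokens, pushes the values into the PNDS
    wrapper through its parameter-slot interface (a callback channel, not
    a token edge), and forwards the bound snapshot as the PNDS trigger."""

    def __init__(self, wrapper: PndsWrapper, space, name: str = "set-params"):
        super().__init__(name, {"set": {"in": -1, "out": 1}}, "set")
        self.wrapper = wrapper
        self.space = space

    def mode_set(self, consumed):
        position = consumed["in"][0]
        values = self.space.materialize(position)
        self.wrapper.set_params(values)
        return {"out": [values]}, "set"


class PndsActor(CfdfActor):
    """Fires the detector once per candidate snapshot, emitting an
    accuracy/time pair.  Marked block-capable: the scheduler may execute a
    backlog of firings concurrently (results stay in candidate order)."""

    supports_block = True

    def __init__(self, wrapper: PndsWrapper, timer, n_threads: int = 1,
                 name: str = "pnds"):
        super().__init__(name, {"evaluate": {"in": -1, "out": 1}}, "evaluate")
        self.wrapper = wrapper
        self.timer = timer
        self.n_threads = max(int(n_threads), 1)

    def block_evaluate(self, values: Mapping) -> EvalResult:
        return self.wrapper.evaluate_at(values, self.timer)

    def mode_evaluate(self, consumed):
        return {"out": [self.block_evaluate(consumed["in"][0])]}, "evaluate"


class FitnessEvaluationActor(CfdfActor):
    """Linear/harmonic aggregation of each evaluation pair into a single
    fitness token.  Maintains the running maximum wall time W_max across
    all evaluations so far; earlier fitness values are never rescored."""

    def __init__(self, a1: float = 0.8, name: str = "fitness"):
        super().__init__(name, {"aggregate": {"in": -1, "out": 1}},
                         "aggregate")
        if not 0.0 < a1 < 1.0:
            raise ValueError("a1 must be in (0, 1)")
        self.a1 = a1
        self.w_max = 0.0
        self.records: list[FitnessRecord] = []

    def mode_aggregate(self, consumed):
        result: EvalResult = consumed["in"][0]
        self.w_max = max(self.w_max, result.seconds)
        tau, ts = time_scale(result.seconds, self.w_max)
        value = aggregate_fitness(result.accuracy, ts, self.a1)
        rec = FitnessRecord(value, result.accuracy, result.seconds, tau, ts)
        self.records.append(rec)
        return {"out": [rec]}, "aggregate"
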