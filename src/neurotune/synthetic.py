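"""Synthetic calcium-imaging stacks with exact ground-truth masks.

The generator emulates the role of a two-photon calcium-imaging recording
with a dataset-level neuron mask: fluorescent neurons are filled ellipses
placed without overlap; each neuron's brightness over time is a constant
baseline plus Poisson-timed calcium transients with an instantaneous rise
and exponential decay; frames carry additive Gaussian read noise.  The
returned label mask marks exactly the planted ellipses, so segmentation
scores against it are exact by construction.

Also provides the random k-fold frame split in which the temporal order of
frames is retained inside every fold and training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.draw import ellipse

__all__ = ["SceneSpec", "generate_dataset", "kfold_split",
           "write_dataset", "read_dataset"]


@dataclass
class SceneSpec:
    """Scene description for one synthetic recording.

    Intensities are arbitrary fluorescence units on a 0-255-like scale.
    ``event_rate`` is expected transients per frame per neuron;
    ``decay_frames`` the exponential decay constant of a transient.
    """

    height: int = 64
    width: int = 64
    n_neurons: int = 10
    n_frames: int = 300
    radius_range: tuple[float, float] = (3.0, 6.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.5)
    event_rate: float = 0.02
    decay_frames: float = 10.0
    amplitude: float = 120.0
    baseline: float = 40.0
    noise_std: float = 4.0
    min_gap: float = 2.0  # minimum blank pixels between neuron borders
    seed: int = 0

    def validate(self) -> None:
        if min(self.height, self.width, self.n_neurons, self.n_frames) < 1:
            raise ValueError("scene dimensions must be positive")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("invalid radius range")
        if not 0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1:
            raise ValueError("eccentricity range must lie in [0, 1)")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


def _place_neurons(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Plant non-overlapping rotated ellipses; returns the label mask.

    Shapes are drawn up front and placed largest-first (the standard
    packing order), each with a bounded number of position proposals;
    separation is enforced on outer radii plus ``min_gap``.
    """
    mask = np.zeros((spec.height, spec.width), dtype=np.uint16)
    shapes = []
    for _ in range(spec.n_neurons):
        r = rng.uniform(*spec.radius_range)
        ecc = rng.uniform(*spec.eccentricity_range)
        a, b = r * (1.0 + ecc), max(r * (1.0 - ecc), 1.0)
        shapes.append((a, b, rng.uniform(0, np.pi)))
    shapes.sort(key=lambda s: -s[0])
    centers: list[tuple[float, float, float]] = []  # (y, x, outer radius)
    for label, (a, b, theta) in enumerate(shapes, start=1):
        if 2 * (a + 1) >= min(spec.height, spec.width):
            raise ValueError(
                f"neuron of outer radius {a:.1f} cannot fit in a "
                f"{spec.height}x{spec.width} image"
            )
        for _ in range(5000):
            cy = rng.uniform(a + 1, spec.height - a - 1)
            cx = rng.uniform(a + 1, spec.width - a - 1)
            if all(
                np.hypot(cy - y0, cx - x0) >= a + r0 + spec.min_gap
                for y0, x0, r0 in centers
            ):
                break
        else:
            raise ValueError(
                f"could not place {spec.n_neurons} neurons of radius "
                f"{spec.radius_range} in a {spec.height}x{spec.width} image"
            )
        rr, cc = ellipse(cy, cx, a, b, shape=mask.shape, rotation=theta)
        mask[rr, cc] = label
        centers.append((cy, cx, a))
    return mask


def _transient_traces(spec: SceneSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-neuron brightness over time: baseline + sum of exponentially
    decaying transients with Poisson-distributed counts per frame."""
    t = np.arange(spec.n_frames)
    traces = np.full((spec.n_neurons, spec.n_frames), spec.baseline)
    for i in range(spec.n_neurons):
        counts = rng.poisson(spec.event_rate, size=spec.n_frames)
        for onset in np.flatnonzero(counts):
            kick = spec.amplitude * counts[onset] * np.exp(
                -(t[onset:] - onset) / spec.decay_frames
            )
            traces[i, onset:] += kick
    return traces


def generate_dataset(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Returns ``(frames, mask)``: a float32 stack of shape
    (n_frames, height, width) and the uint16 ground-truth label mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = _place_neurons(spec, rng)
    traces = _transient_traces(spec, rng)
    frames = np.zeros((spec.n_frames, spec.height, spec.width),
                      dtype=np.float32)
    for i in range(spec.n_neurons):
        ys, xs = np.nonzero(mask == i + 1)
        frames[:, ys, xs] = traces[i][:, None]
    if spec.noise_std > 0:
        frames += rng.normal(0.0, spec.noise_std, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return frames, mask


def kfold_split(n_frames: int, k: int, seed: int) -> list[np.ndarray]:
    """Random k-fold frame partition with temporal order retained.

    Frames are assigned to folds uniformly at random (fold sizes differ by
    at most one) and each fold is then sorted ascending so the temporal
    order of retained frames is intact.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_frames:
        raise ValueError(f"k={k} exceeds frame count {n_frames}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_frames)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def write_dataset(frames: np.ndarray, mask: np.ndarray, frames_path: str,
                  mask_path: str) -> None:
    """Frames as a multi-page TIFF stack, mask as a 16-bit label image."""
    tifffile.imwrite(frames_path, np.asarray(frames, dtype=np.float32))
    tifffile.imwrite(mask_path, np.asarray(mask, dtype=np.uint16))


def read_dataset(frames_path: str,
                 mask_path: str) -> tuple[np.ndarray, np.ndarray]:
    frames = tifffile.imread(frames_path)
    mask = tifffile.imread(mask_path)
    return np.asarray(frames, dtype=np.float32), np.asarray(mask)
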