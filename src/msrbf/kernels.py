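"""Gaussian activation functions and candidate-pool construction.

Each hidden node carries one isotropic Gaussian activation function (AF)
parameterized by a center in input space, a positive width sigma and an
amplitude:  ``A * exp(-||x - c||^2 / (2 sigma^2))``.

Candidate pools are built differently per task.  For waveform regression
the pool is data-anchored: every bin whose amplitude exceeds the noise
floor contributes its (position, amplitude) as a candidate center and
peak height, crossed with a grid of widths spanning ``(0, T/6]`` where
``T`` is the record length.  For classification, candidate centers are
drawn from training points with widths sampled uniformly; the amplitude
is fixed to 1 because the output-layer least squares absorbs scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import Dataset, Waveform
from .errors import ValidationError

__all__ = [
    "GaussianAF",
    "CandidatePool",
    "evaluate",
    "receptive_field_mask",
    "build_pool_regression",
    "build_pool_classification",
]

DEFAULT_RADIUS_FACTOR = 3.0  # ~99.7% of the kernel's mass


@dataclass(frozen=True)
class GaussianAF:
    """One radial activation function: center, width (sigma), amplitude."""

    center: tuple[float, ...]
    width: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        object.__setattr__(self, "center", tuple(float(v) for v in c))
        if not self.width > 0:
            raise ValidationError(f"width must be positive, got {self.width}")
        if not np.isfinite(self.amplitude):
            raise ValidationError("amplitude must be finite")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "width": float(self.width),
            "amplitude": float(self.amplitude),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianAF":
        return cls(tuple(d["center"]), float(d["width"]), float(d["amplitude"]))


def _sq_dist(X: np.ndarray, center: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diff = X - center[None, :]
    return np.einsum("ij,ij->i", diff, diff)


def evaluate(af: GaussianAF, X: np.ndarray) -> np.ndarray:
    """Kernel responses ``A exp(-||x-c||^2 / (2 w^2))`` for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    return af.amplitude * np.exp(-_sq_dist(X, af.center_array) / (2.0 * af.width**2))


def receptive_field_mask(
    af: GaussianAF, X: np.ndarray, radius_factor: float = DEFAULT_RADIUS_FACTOR
) -> np.ndarray:
    """Boolean mask of points within ``radius_factor * width`` of the center."""
    if not radius_factor > 0:
        raise ValidationError("radius_factor must be positive")
    r = radius_factor * af.width
    return _sq_dist(X, af.center_array) <= r * r


@dataclass
class CandidatePool:
    """Ordered list of candidate AFs plus a provenance tag."""

    candidates: list[GaussianAF]
    provenance: str = "random"  # random | data-anchored | exhaustive-width

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValidationError("candidate pool is empty")

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __getitem__(self, i: int) -> GaussianAF:
        return self.candidates[i]

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "candidates": [af.to_dict() for af in self.candidates],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "CandidatePool":
        d = json.loads(s)
        return cls(
            [GaussianAF.from_dict(c) for c in d["candidates"]], d["provenance"]
        )


def width_grid(span: float, n_widths: int) -> np.ndarray:
    """``n_widths`` widths evenly spaced over the half-open interval (0, span/6].

    Zero is excluded because a kernel width must be positive, so the grid is
    ``span/6 * j / n_widths`` for j = 1..n_widths.
    """
    if n_widths < 1:
        raise ValidationError("n_widths must be >= 1")
    wmax = span / 6.0
    return wmax * np.arange(1, n_widths + 1) / n_widths


def build_pool_regression(
    waveform: Waveform, n_widths: int = 50, noise_floor: float = 0.0
) -> CandidatePool:
    """Data-anchored pool: supra-floor bins x an even width grid over (0, T/6]."""
    above = waveform.amplitudes > noise_floor
    if not np.any(above):
        raise ValidationError("no waveform bin exceeds the noise floor")
    widths = width_grid(waveform.span, n_widths)
    cands = [
        GaussianAF((float(p),), float(w), float(a))
        for p, a in zip(waveform.positions[above], waveform.amplitudes[above])
        for w in widths
    ]
    return CandidatePool(cands, provenance="data-anchored")


def build_pool_classification(
    dataset: Dataset,
    pool_size: int,
    width_range: tuple[float, float],
    rng: np.random.Generator,
) -> CandidatePool:
    """Random pool: centers on training points, widths uniform, amplitude 1."""
    if dataset.n == 0:
        raise ValidationError("dataset is empty")
    if pool_size < 1:
        raise ValidationError("pool_size must be >= 1")
    lo, hi = width_range
    if not (lo > 0 and hi >= lo):
        raise ValidationError(f"width_range must be positive, got {width_range}")
    idx = rng.integers(0, dataset.n, size=pool_size)
    widths = rng.uniform(lo, hi, size=pool_size)
    cands = [
        GaussianAF(tuple(dataset.X[i]), float(w), 1.0)
        for i, w in zip(idx, widths)
    ]
    return CandidatePool(cands, provenance="random")
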