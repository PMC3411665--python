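"""The blocking-layer network algebra.

A trained network is a linear combination of Gaussian node responses,
gated by a binary blocking layer.  For n sample points and k nodes:

* ``Phi`` (n x k) records every point's response to every node.
* ``B`` (n x k) is binary.  When node j's neighborhood is declared
  successfully mapped, a blocking node is activated for it: every point
  inside node j's receptive field has its entries zeroed in all *later*
  columns (j+1..k), never in column j itself.  Activated blocks act
  cumulatively by multiplication of the per-node indicators, and the
  first column is all ones since no earlier node exists.
* ``H = Phi * B`` element-wise is the effective design matrix; output
  weights (and optional bias) solve ``min ||[H 1](W,b) - y||_2`` by
  least squares, with the minimum-norm solution when H is
  rank-deficient.

The network output is ``f(X) = H(X) W + b``; classification additionally
takes the sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .kernels import DEFAULT_RADIUS_FACTOR, GaussianAF, evaluate, receptive_field_mask

__all__ = [
    "ModelState",
    "response_matrix",
    "blocking_matrix",
    "effective_matrix",
    "solve_weights",
    "predict",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class ModelState:
    """Ordered accepted AFs, blocking flags, output weights and bias."""

    afs: list[GaussianAF] = field(default_factory=list)
    block_active: list[bool] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bias: float = 0.0
    task: str = "regress"
    fit_bias: bool = False
    radius_factor: float = DEFAULT_RADIUS_FACTOR
    trace: list[dict] = field(default_factory=list)
    blocked_train_masks: list[list[int]] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.block_active) != len(self.afs):
            raise ValidationError("one blocking flag required per node")
        if self.weights.size and self.weights.size != len(self.afs):
            raise ValidationError("weight vector length must equal node count")

    @property
    def n_nodes(self) -> int:
        return len(self.afs)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "task": self.task,
                "fit_bias": self.fit_bias,
                "radius_factor": self.radius_factor,
                "afs": [af.to_dict() for af in self.afs],
                "block_active": [bool(b) for b in self.block_active],
                "weights": self.weights.tolist(),
                "bias": float(self.bias),
                "trace": self.trace,
                "blocked_train_masks": self.blocked_train_masks,
                "config_echo": self.config_echo,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelState":
        d = json.loads(s)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format {d.get('format_version')!r}"
            )
        return cls(
            afs=[GaussianAF.from_dict(a) for a in d["afs"]],
            block_active=list(d["block_active"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            task=d["task"],
            fit_bias=bool(d["fit_bias"]),
            radius_factor=float(d["radius_factor"]),
            trace=d.get("trace", []),
            blocked_train_masks=d.get("blocked_train_masks", []),
            config_echo=d.get("config_echo", {}),
        )


def response_matrix(afs: list[GaussianAF], X: np.ndarray) -> np.ndarray:
    """Phi[i, j] = response of point i to node j."""
    if not afs:
        raise ValidationError("need at least one AF")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([evaluate(af, X) for af in afs])


def blocking_matrix(model: ModelState, X: np.ndarray) -> np.ndarray:
    """Binary B: cumulative product of activated nodes' block indicators.

    A block caused by node j covers its receptive field and zeroes
    columns j+1..k for the covered points; column j itself is untouched
    and column 1 is all ones.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape[0], model.n_nodes
    B = np.ones((n, k))
    blocked = np.zeros(n, dtype=bool)  # points covered by any activated block so far
    for j in range(k):
        if j > 0:
            B[blocked, j] = 0.0
        if model.block_active[j]:
            blocked |= receptive_field_mask(model.afs[j], X, model.radius_factor)
    return B


def effective_matrix(Phi: np.ndarray, B: np.ndarray) -> np.ndarray:
    """H = Phi * B element-wise."""
    Phi = np.asarray(Phi, dtype=float)
    B = np.asarray(B, dtype=float)
    if Phi.shape != B.shape:
        raise ValidationError(f"shape mismatch {Phi.shape} vs {B.shape}")
    return Phi * B


def solve_weights(
    H: np.ndarray, y: np.ndarray, fit_bias: bool = False
) -> tuple[np.ndarray, float]:
    """Least-squares output weights (minimum-norm under rank deficiency)."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite inputs to solve_weights")
    if H.shape[0] != y.shape[0]:
        raise ValidationError("H rows and y length differ")
    A = np.column_stack([H, np.ones(H.shape[0])]) if fit_bias else H
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    if fit_bias:
        return sol[:-1], float(sol[-1])
    return sol, 0.0


def predict(
    model: ModelState, X: np.ndarray, return_labels: bool | None = None
) -> np.ndarray:
    """Network output f(X) = H(X) W + b; signed labels in classify mode."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = len(model.afs[0].center) if model.afs else X.shape[1]
    if X.shape[1] != d:
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match model dimension {d}"
        )
    if not model.afs:
        out = np.full(X.shape[0], model.bias)
    else:
        H = effective_matrix(
            response_matrix(model.afs, X), blocking_matrix(model, X)
        )
        out = H @ model.weights + model.bias
    if return_labels is None:
        return_labels = model.task == "classify"
    if return_labels:
        labels = np.where(out > 0, 1.0, -1.0)
        labels[out == 0] = 0.0  # ambiguous output; counted as error upstream
        return labels
    return out
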