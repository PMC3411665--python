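"""Global/local error statistics and waveform fit metrics.

The node-selection loop scores every candidate by a *global error* (GE,
over the whole training set) and a *local error* (LE, the same statistic
restricted to the candidate's receptive field).  For classification the
statistic is the misclassification ratio of the signed network output;
for regression it is the mean absolute error.

Waveform fits are summarized by amplitude-normalized errors: relMAE is
the mean of ``|sim_i - ref_i| / ref_i`` and relSDE its standard
deviation over the return points, so both are invariant under a joint
positive rescaling of the two signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Waveform
from .errors import ValidationError

__all__ = [
    "ErrorPair",
    "global_error",
    "local_error",
    "relative_mae_sde",
    "estimate_noise_floor",
]

NOISE_PREFIX_BINS = 150  # leading bins assumed signal-free


@dataclass(frozen=True)
class ErrorPair:
    """Global error, local error, and local support count for one candidate.

    ``local_defined`` is False when the receptive field holds no points;
    the stored ``local_error`` is then a sentinel, never a silent NaN.
    """

    global_error: float
    local_error: float
    local_support: int
    local_defined: bool = True


def _check_lengths(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"length mismatch: {y_true.shape[0]} vs {y_pred.shape[0]}"
        )
    return y_true, y_pred


def global_error(y_true, y_pred, task: str) -> float:
    """Misclassification ratio (classification) or MAE (regression).

    Classification predictions are the sign of the network output; an
    exactly-zero output counts as a misclassification.
    """
    y_true, y_pred = _check_lengths(y_true, y_pred)
    if y_true.size == 0:
        raise ValidationError("empty input")
    if task == "classify":
        correct = np.sign(y_pred) == y_true  # sign(0)=0 never equals +/-1
        return float(np.mean(~correct))
    if task == "regress":
        return float(np.mean(np.abs(y_true - y_pred)))
    raise ValidationError(f"unknown task {task!r}")


def local_error(y_true, y_pred, mask, task: str) -> tuple[float, int, bool]:
    """GE restricted to masked points; returns (error, support, defined).

    An all-false mask yields ``(nan, 0, False)`` so callers can apply a
    deterministic worst-case substitute.
    """
    y_true, y_pred = _check_lengths(y_true, y_pred)
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.shape != y_true.shape:
        raise ValidationError("mask length mismatch")
    support = int(mask.sum())
    if support == 0:
        return float("nan"), 0, False
    return global_error(y_true[mask], y_pred[mask], task), support, True


def relative_mae_sde(
    simulated,
    reference,
    noise_floor: float = 0.0,
    normalize_by: str = "per_point",
) -> tuple[float, float]:
    """Amplitude-normalized mean and standard deviation of absolute errors.

    ``normalize_by="per_point"`` divides each absolute error by that
    return's reference amplitude, skipping bins at or below
    ``noise_floor`` to avoid division blow-up; ``"max"`` divides every
    error by the waveform's maximum reference amplitude instead.  The
    standard deviation uses the population denominator n.
    """
    sim, ref = _check_lengths(simulated, reference)
    if np.all(ref == 0):
        raise ValidationError("reference signal is identically zero")
    if normalize_by == "per_point":
        keep = ref > noise_floor
        if not np.any(keep):
            raise ValidationError("no reference bin exceeds the noise floor")
        rel = np.abs(sim[keep] - ref[keep]) / ref[keep]
    elif normalize_by == "max":
        rel = np.abs(sim - ref) / np.max(np.abs(ref))
    else:
        raise ValidationError(f"unknown normalize_by {normalize_by!r}")
    return float(np.mean(rel)), float(np.std(rel))


def estimate_noise_floor(
    waveform: Waveform | np.ndarray, prefix_bins: int = NOISE_PREFIX_BINS
) -> float:
    """Background level: the maximum amplitude among the leading bins."""
    amps = (
        waveform.amplitudes
        if isinstance(waveform, Waveform)
        else np.asarray(waveform, dtype=float).ravel()
    )
    if amps.size < prefix_bins:
        raise ValidationError(
            f"waveform has {amps.size} bins, fewer than the {prefix_bins}-bin "
            "noise prefix; pass a smaller prefix_bins"
        )
    return float(np.max(amps[:prefix_bins]))
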