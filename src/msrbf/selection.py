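"""Candidate scoring, local-weight schedules and winner selection.

Each training iteration scores every candidate AF by the weighted sum

    S = w_local * LE + (1 - w_local) * GE + R

where the local weight follows a per-iteration schedule and R is an
optional penalty that discourages kernels whose receptive field holds
too few training points (it only engages when the local error already
beats the target, i.e. when blocking would otherwise trigger on a
near-empty neighborhood).  The candidate with the lowest S wins; a
candidate whose *global* error already beats the global target is
selected immediately and ends training.

Schedules
---------
``power_decay``      w(k) = w0 * (1 - (k-1)/K_max)^m — classification
                     default: local accuracy dominates early and decays
                     at a user-controlled rate m.
``regression_ramp``  w(k) = min(1, w0 * (K_max - k + 1)/K_max) — the
                     waveform variant, largest at the first node.
``constant``         w(k) = w0.

Both families satisfy w in [0, 1] with the global weight 1 - w; they
are deliberately pluggable so other local/global trade-offs can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .metrics import ErrorPair

__all__ = [
    "WeightSchedule",
    "SelectionConfig",
    "local_weight",
    "weighted_score",
    "support_condition",
    "select_winner",
]

SCHEDULE_FAMILIES = ("power_decay", "regression_ramp", "constant")


@dataclass(frozen=True)
class WeightSchedule:
    """Local-weight schedule over training iterations k = 1..K_max."""

    w0: float = 0.9
    K_max: int = 7
    m: float = 2.0
    family: str = "power_decay"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w0 <= 1.0:
            raise ValidationError(f"w0 must be in [0,1], got {self.w0}")
        if self.K_max < 1:
            raise ValidationError("K_max must be >= 1")
        if not self.m > 0:
            raise ValidationError("m must be > 0")
        if self.family not in SCHEDULE_FAMILIES:
            raise ValidationError(f"unknown schedule family {self.family!r}")


@dataclass(frozen=True)
class SelectionConfig:
    """Targets and the small-neighborhood penalty for winner selection."""

    schedule: WeightSchedule = field(default_factory=WeightSchedule)
    target_error_global: float = 0.0
    target_error_local: float = 0.0
    min_support: int = 0
    R_penalty_scale: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_error_global):
            raise ValidationError("target_error_global must be finite")
        if not np.isfinite(self.target_error_local):
            raise ValidationError("target_error_local must be finite")
        if self.min_support < 0:
            raise ValidationError("min_support must be >= 0")
        if self.R_penalty_scale < 0:
            raise ValidationError("R_penalty_scale must be >= 0")


def local_weight(schedule: WeightSchedule, k: int) -> float:
    """Local weight at iteration k (1-based), always in [0, 1]."""
    if not 1 <= k <= schedule.K_max:
        raise ValidationError(
            f"iteration k={k} outside [1, {schedule.K_max}]"
        )
    if schedule.family == "power_decay":
        return schedule.w0 * (1.0 - (k - 1) / schedule.K_max) ** schedule.m
    if schedule.family == "regression_ramp":
        return min(1.0, schedule.w0 * (schedule.K_max - k + 1) / schedule.K_max)
    return schedule.w0  # constant


def weighted_score(err: ErrorPair, w_local: float, R: float = 0.0) -> float:
    """S = w_local*LE + (1-w_local)*GE + R; lower is better."""
    if not 0.0 <= w_local <= 1.0:
        raise ValidationError(f"w_local must be in [0,1], got {w_local}")
    le = err.local_error
    if not err.local_defined:
        raise ValidationError(
            "LE undefined (empty support); substitute a worst-case LE before scoring"
        )
    return w_local * le + (1.0 - w_local) * err.global_error + R


def support_condition(err: ErrorPair, config: SelectionConfig) -> float:
    """Penalty R against tiny well-fitted neighborhoods.

    Engages only when LE < local target (blocking imminent): then
    R = scale * max(0, 1 - support/min_support), so a kernel fitting a
    single low-magnitude point cannot win on local error alone.
    """
    if config.min_support <= 0:
        return 0.0
    if not err.local_defined or not err.local_error < config.target_error_local:
        return 0.0
    if err.local_support >= config.min_support:
        return 0.0
    return config.R_penalty_scale * (1.0 - err.local_support / config.min_support)


def select_winner(
    scores: list[tuple[int, float, ErrorPair]], config: SelectionConfig
) -> tuple[int, bool]:
    """Pick the winning candidate; returns (index, terminate).

    Any candidate whose GE already beats the global target is returned
    immediately (lowest GE among such) with the termination flag set.
    Otherwise the lowest weighted sum wins; ties break on lower GE then
    lower candidate index.
    """
    if not scores:
        raise ValidationError("empty score list")
    below = [t for t in scores if t[2].global_error < config.target_error_global]
    if below:
        winner = min(below, key=lambda t: (t[2].global_error, t[0]))
        return winner[0], True
    winner = min(scores, key=lambda t: (t[1], t[2].global_error, t[0]))
    return winner[0], False
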