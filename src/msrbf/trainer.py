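"""Greedy training loop for the multi-scale network and its baselines.

One node is added per iteration.  Every remaining candidate AF is
tentatively appended (rebuilding the effective matrix and re-solving the
output weights), scored by the weighted global/local error sum at the
iteration's local weight, and the winner committed.  If the winner's
local error beats the local target over a sufficiently populated
receptive field, its blocking node is activated: points inside the
winner's receptive field are frozen out of all later columns.  Training
stops early when the global error beats the global target, and always
ends with a joint least-squares fine-tune of all node weights.

Three modes share this loop:

* ``msrbf`` — local weights per schedule, blocking enabled;
* ``mkrbf`` — the multi-kernel baseline: identical except the local
  weight is identically zero and blocking is off;
* ``skrbf`` — single shared kernel width, global-error-only selection,
  centers free to sit anywhere on a grid plus the training points.

For waveform regression, :func:`train_regression_grid` wraps the loop in
an exhaustive search over initial local weights 1.0, 0.9, ..., 0.0 and
returns the model with the lowest amplitude-normalized MAE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .data import Dataset, Waveform
from .errors import ConfigurationError, ValidationError
from .kernels import (
    DEFAULT_RADIUS_FACTOR,
    CandidatePool,
    GaussianAF,
    build_pool_classification,
    build_pool_regression,
    evaluate,
    receptive_field_mask,
)
from .metrics import (
    ErrorPair,
    estimate_noise_floor,
    global_error,
    local_error,
    relative_mae_sde,
)
from .network import (
    ModelState,
    blocking_matrix,
    effective_matrix,
    predict,
    response_matrix,
    solve_weights,
)
from .selection import (
    SelectionConfig,
    WeightSchedule,
    local_weight,
    select_winner,
    support_condition,
    weighted_score,
)

__all__ = [
    "TrainConfig",
    "evaluate_candidate",
    "train",
    "train_regression_grid",
    "train_skrbf",
]

MODES = ("msrbf", "mkrbf", "skrbf")
W0_GRID = tuple(round(w, 1) for w in np.arange(10, -1, -1) / 10.0)  # 1.0 .. 0.0


@dataclass(frozen=True)
class TrainConfig:
    """Everything one training run needs besides the data and the pool."""

    mode: str = "msrbf"
    task: str = "regress"
    K_max: int = 7
    target_error_global: float = 0.0
    target_error_local: float = 0.05
    min_support: int = 0
    R_penalty_scale: float = 1.0
    w0: float = 0.9
    m: float = 2.0
    schedule_family: str | None = None  # default: by task
    radius_factor: float = DEFAULT_RADIUS_FACTOR
    fit_bias: bool | None = None  # default: classify on, regress off
    blocking: bool | None = None  # default: msrbf only
    exact_refit: bool = True
    # pool settings
    n_widths: int = 50
    noise_prefix_bins: int = 150
    pool_size: int = 200
    width_range: tuple[float, float] = (0.5, 5.0)
    skrbf_widths: tuple[float, ...] = ()
    skrbf_grid_points: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.task not in ("classify", "regress"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.K_max < 1:
            raise ConfigurationError("K_max must be >= 1")

    # -- derived settings ------------------------------------------------
    @property
    def effective_family(self) -> str:
        if self.schedule_family is not None:
            return self.schedule_family
        return "power_decay" if self.task == "classify" else "regression_ramp"

    @property
    def effective_w0(self) -> float:
        # the baselines ignore local error by definition
        return 0.0 if self.mode in ("mkrbf", "skrbf") else self.w0

    @property
    def effective_blocking(self) -> bool:
        if self.blocking is not None and self.mode == "msrbf":
            return self.blocking
        return self.mode == "msrbf" if self.blocking is None else False

    @property
    def effective_fit_bias(self) -> bool:
        return self.task == "classify" if self.fit_bias is None else self.fit_bias

    def schedule(self) -> WeightSchedule:
        return WeightSchedule(
            w0=self.effective_w0,
            K_max=self.K_max,
            m=self.m,
            family=self.effective_family,
        )

    def selection(self) -> SelectionConfig:
        return SelectionConfig(
            schedule=self.schedule(),
            target_error_global=self.target_error_global,
            target_error_local=self.target_error_local,
            min_support=self.min_support,
            R_penalty_scale=self.R_penalty_scale,
        )

    def echo(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["width_range"] = list(self.width_range)
        d["skrbf_widths"] = list(self.skrbf_widths)
        return d


def evaluate_candidate(
    state: ModelState, candidate: GaussianAF, data: Dataset
) -> ErrorPair:
    """Score one candidate against the current model without mutating it.

    The candidate is tentatively appended (its column gated by the
    blocks already active), all output weights are re-solved, and the
    global error plus the local error over the candidate's receptive
    field are returned.
    """
    trial = ModelState(
        afs=state.afs + [candidate],
        block_active=list(state.block_active) + [False],
        weights=np.zeros(state.n_nodes + 1),
        task=state.task,
        fit_bias=state.fit_bias,
        radius_factor=state.radius_factor,
    )
    Phi = response_matrix(trial.afs, data.X)
    B = blocking_matrix(trial, data.X)
    H = effective_matrix(Phi, B)
    W, b = solve_weights(H, data.y, fit_bias=state.fit_bias)
    pred = H @ W + b
    ge = global_error(data.y, pred, data.task)
    mask = receptive_field_mask(candidate, data.X, state.radius_factor)
    le, support, defined = local_error(data.y, pred, mask, data.task)
    return ErrorPair(ge, le, support, defined)


class _FastScorer:
    """Vectorized candidate scoring for one training run.

    Precomputes every candidate's response column and receptive-field
    mask once; per iteration each candidate costs one small least
    squares (exact refit) or one residual projection (shortcut).
    """

    def __init__(self, data: Dataset, pool: CandidatePool, config: TrainConfig):
        self.data = data
        self.cands = list(pool.candidates)
        self.cols = np.column_stack(
            [evaluate(af, data.X) for af in self.cands]
        )  # n x n_cand
        self.masks = np.column_stack(
            [
                receptive_field_mask(af, data.X, config.radius_factor)
                for af in self.cands
            ]
        )
        self.alive = np.ones(len(self.cands), dtype=bool)
        self.config = config

    def score_all(
        self,
        H_cols: list[np.ndarray],
        blocked: np.ndarray,
        current_pred: np.ndarray,
    ) -> list[tuple[int, ErrorPair]]:
        data, cfg = self.data, self.config
        idx = np.flatnonzero(self.alive)
        y = data.y
        cols = self.cols[:, idx] * (~blocked)[:, None].astype(float)
        masks = self.masks[:, idx]
        nc = idx.size
        if cfg.exact_refit:
            # batched normal equations; pinv of the Gram gives the same
            # minimum-norm least-squares solution as a direct lstsq
            parts = list(H_cols)
            if cfg.effective_fit_bias:
                parts = parts + [np.ones(data.n)]
            base = np.column_stack(parts) if parts else np.zeros((data.n, 0))
            p = base.shape[1]
            G = np.empty((nc, p + 1, p + 1))
            G[:, :p, :p] = base.T @ base
            Bth = base.T @ cols  # p x nc
            G[:, :p, p] = Bth.T
            G[:, p, :p] = Bth.T
            G[:, p, p] = np.einsum("ij,ij->j", cols, cols)
            rhs = np.empty((nc, p + 1))
            rhs[:, :p] = base.T @ y
            rhs[:, p] = cols.T @ y
            sol = np.linalg.pinv(G, hermitian=True) @ rhs[:, :, None]
            pred = base @ sol[:, :p, 0].T + cols * sol[:, p, 0]
        else:
            r = y - current_pred
            hh = np.einsum("ij,ij->j", cols, cols)
            coef = np.divide(
                cols.T @ r, hh, out=np.zeros(nc), where=hh > 0
            )
            pred = current_pred[:, None] + cols * coef
        if data.task == "classify":
            err = np.sign(pred) != y[:, None]
        else:
            err = np.abs(y[:, None] - pred)
        ge = err.mean(axis=0)
        support = masks.sum(axis=0)
        le_num = (err * masks).sum(axis=0)
        out: list[tuple[int, ErrorPair]] = []
        for t, j in enumerate(idx):
            s = int(support[t])
            if s == 0:
                out.append((int(j), ErrorPair(float(ge[t]), float("nan"), 0, False)))
            else:
                out.append(
                    (int(j), ErrorPair(float(ge[t]), float(le_num[t] / s), s, True))
                )
        return out


def _substitute_undefined(
    pairs: list[tuple[int, ErrorPair]], task: str
) -> list[tuple[int, ErrorPair]]:
    """Give empty-support candidates a deterministic worst-case LE."""
    if all(p.local_defined for _, p in pairs):
        return pairs
    worst = 1.0 if task == "classify" else max(p.global_error for _, p in pairs)
    return [
        (j, p if p.local_defined else ErrorPair(p.global_error, worst, 0, True))
        for j, p in pairs
    ]


def train(
    data: Dataset,
    config: TrainConfig,
    pool: CandidatePool | None = None,
    pool_provider: Callable[[ModelState, int], CandidatePool] | None = None,
) -> ModelState:
    """Run the greedy node-selection loop and return the trained model.

    Exactly one of ``pool`` (fixed pool, winners removed after
    selection) or ``pool_provider`` (fresh pool per iteration, e.g. from
    the genetic search) must be given; with neither, a default pool is
    built from the data and the config's pool settings.
    """
    if pool is None and pool_provider is None:
        pool = _default_pool(data, config)
    selcfg = config.selection()
    schedule = selcfg.schedule
    model = ModelState(
        task=data.task,
        fit_bias=config.effective_fit_bias,
        radius_factor=config.radius_factor,
        config_echo=config.echo(),
    )
    blocked = np.zeros(data.n, dtype=bool)
    H_cols: list[np.ndarray] = []
    current_pred = np.zeros(data.n)
    scorer = (
        _FastScorer(data, pool, config) if pool is not None else None
    )

    for k in range(1, config.K_max + 1):
        if scorer is not None:
            if not np.any(scorer.alive):
                model.trace.append({"k": k, "event": "pool_exhausted"})
                break
            pairs = scorer.score_all(H_cols, blocked, current_pred)
            cands = scorer.cands
        else:
            it_pool = pool_provider(model, k)
            it_scorer = _FastScorer(data, it_pool, config)
            pairs = it_scorer.score_all(H_cols, blocked, current_pred)
            cands = it_scorer.cands
        pairs = _substitute_undefined(pairs, data.task)
        w = local_weight(schedule, k)
        scores = [
            (j, weighted_score(p, w, support_condition(p, selcfg)), p)
            for j, p in pairs
        ]
        winner, terminate = select_winner(scores, selcfg)
        werr = next(p for j, p in pairs if j == winner)
        wS = next(s for j, s, _ in scores if j == winner)
        waf = cands[winner]

        # commit the winner
        gate = (~blocked).astype(float)
        col = evaluate(waf, data.X) * gate
        H_cols.append(col)
        model.afs.append(waf)
        model.block_active.append(False)
        A = (
            np.column_stack(H_cols + [np.ones(data.n)])
            if config.effective_fit_bias
            else np.column_stack(H_cols)
        )
        sol, *_ = np.linalg.lstsq(A, data.y, rcond=None)
        if config.effective_fit_bias:
            model.weights, model.bias = sol[:-1], float(sol[-1])
        else:
            model.weights, model.bias = sol, 0.0
        current_pred = A @ sol

        entry = {
            "k": k,
            "w_local": w,
            "winner_center": list(waf.center),
            "winner_width": waf.width,
            "GE": werr.global_error,
            "LE": werr.local_error,
            "support": werr.local_support,
            "S": wS,
            "terminated": bool(terminate),
            "block_activated": False,
            "n_blocked_total": int(blocked.sum()),
        }

        if scorer is not None:
            scorer.alive[winner] = False

        if terminate or werr.global_error < config.target_error_global:
            entry["terminated"] = True
            model.trace.append(entry)
            break

        # blocking test: skipped on the final node
        if (
            k < config.K_max
            and config.effective_blocking
            and werr.local_defined
            and werr.local_error < config.target_error_local
            and werr.local_support >= config.min_support
        ):
            model.block_active[-1] = True
            mask = receptive_field_mask(waf, data.X, config.radius_factor)
            model.blocked_train_masks.append(
                [int(i) for i in np.flatnonzero(mask)]
            )
            blocked |= mask
            entry["block_activated"] = True
        model.trace.append(entry)

    # final fine-tune: joint least squares over the committed structure
    if model.afs:
        Phi = response_matrix(model.afs, data.X)
        B = blocking_matrix(model, data.X)
        H = effective_matrix(Phi, B)
        model.weights, model.bias = solve_weights(
            H, data.y, fit_bias=config.effective_fit_bias
        )
        final_pred = H @ model.weights + model.bias
        model.trace.append(
            {
                "event": "final_solve",
                "GE": global_error(data.y, final_pred, data.task),
                "ssr": float(np.sum((data.y - final_pred) ** 2)),
            }
        )
    return model


def _default_pool(data: Dataset, config: TrainConfig) -> CandidatePool:
    if data.task == "regress" and data.d == 1:
        wf = Waveform(data.X[:, 0], data.y)
        try:
            floor = estimate_noise_floor(wf, config.noise_prefix_bins)
        except ValidationError:
            floor = 0.0
        if not np.any(wf.amplitudes > floor):
            floor = 0.0
        return build_pool_regression(wf, config.n_widths, floor)
    rng = np.random.default_rng(config.seed)
    return build_pool_classification(
        data, config.pool_size, config.width_range, rng
    )


def train_regression_grid(
    waveform: Waveform, config: TrainConfig
) -> tuple[ModelState, list[dict]]:
    """Exhaustive initial-local-weight search for one waveform.

    Runs the training loop once per w0 in {1.0, 0.9, ..., 0.0} (the zero
    entry degenerates to the multi-kernel baseline, since a zero local
    weight means local statistics never influence selection) and returns
    the model minimizing relMAE, ties broken by lower relSDE.
    """
    floor = estimate_noise_floor(waveform, config.noise_prefix_bins)
    pool = build_pool_regression(waveform, config.n_widths, floor)
    data = waveform.as_dataset()
    best: tuple[float, float, int] | None = None
    best_model: ModelState | None = None
    trace: list[dict] = []
    for i, w0 in enumerate(W0_GRID):
        run_cfg = replace(
            config, w0=w0, mode="mkrbf" if w0 == 0.0 else "msrbf", task="regress"
        )
        model = train(data, run_cfg, pool=pool)
        pred = predict(model, data.X, return_labels=False)
        relmae, relsde = relative_mae_sde(pred, waveform.amplitudes, floor)
        trace.append(
            {
                "w0": w0,
                "relMAE": relmae,
                "relSDE": relsde,
                "n_nodes": model.n_nodes,
            }
        )
        key = (relmae, relsde, i)
        if best is None or key < best:
            best, best_model = key, model
    assert best_model is not None
    return best_model, trace


def train_skrbf(data: Dataset, config: TrainConfig) -> ModelState:
    """Single-width baseline: shared width, free centers, global error only.

    Centers come from the training points plus an even grid over the
    input bounding box; the shared width is either given or searched
    over a small grid, keeping the run with the lowest training error.
    """
    widths = config.skrbf_widths or _skrbf_width_grid(data)
    best_ge, best_model = np.inf, None
    for wshare in widths:
        pool = _skrbf_pool(data, float(wshare), config.skrbf_grid_points)
        model = train(data, replace(config, mode="skrbf"), pool=pool)
        pred = predict(model, data.X, return_labels=False)
        ge = global_error(data.y, pred, data.task)
        if ge < best_ge:
            best_ge, best_model = ge, model
    assert best_model is not None
    return best_model


def _skrbf_width_grid(data: Dataset) -> tuple[float, ...]:
    span = float(np.max(data.X) - np.min(data.X))
    return tuple(span * f for f in (0.02, 0.05, 0.1, 0.2, 0.4))


def _skrbf_pool(data: Dataset, width: float, grid_points: int) -> CandidatePool:
    centers = [tuple(x) for x in data.X]
    lo, hi = data.X.min(axis=0), data.X.max(axis=0)
    if data.d == 1:
        grid = np.linspace(lo[0], hi[0], grid_points)[:, None]
    else:
        side = max(2, int(round(grid_points ** (1.0 / data.d))))
        axes = [np.linspace(lo[j], hi[j], side) for j in range(data.d)]
        grid = np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, data.d)
    centers += [tuple(g) for g in grid]
    return CandidatePool(
        [GaussianAF(c, width, 1.0) for c in centers], provenance="exhaustive-width"
    )
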