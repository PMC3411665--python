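"""Genetic search over candidate activation functions (classification).

For the classification task the candidate pool is not enumerable the way
waveform bins are, so each training iteration evolves a small population
of (center index, width) genomes against the *current* network state.
A genome's fitness is the same weighted global/local error sum used for
winner selection, minus a receptive-field occupancy bonus: rewarding
kernels whose neighborhood holds many training points steers the search
toward larger widths and away from overfitting single points.  The final
population is handed back as an ordinary candidate pool, so winner
selection and blocking proceed unchanged.

Operators are deliberately plain — tournament selection, one-point
crossover on the two-gene genome, Gaussian mutation on the width and a
re-draw mutation on the center index — with one elite genome carried
over unchanged, so the best fitness never worsens across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .errors import ConfigurationError, ValidationError
from .kernels import CandidatePool, GaussianAF
from .metrics import ErrorPair
from .network import ModelState
from .selection import local_weight, weighted_score
from .trainer import TrainConfig, evaluate_candidate, train

__all__ = ["GAConfig", "ga_propose", "train_classification_ga"]


@dataclass(frozen=True)
class GAConfig:
    """Knobs for the per-iteration genetic candidate search."""

    population_size: int = 24
    generations: int = 8
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    tournament_size: int = 3
    fitness_error_weight: float = 1.0
    fitness_support_weight: float = 0.1
    width_range: tuple[float, float] | None = None  # default from data bounds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.generations < 0:
            raise ConfigurationError("generations must be >= 0")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.tournament_size < 1:
            raise ConfigurationError("tournament_size must be >= 1")


def _width_bounds(data: Dataset, config: GAConfig) -> tuple[float, float]:
    if config.width_range is not None:
        lo, hi = config.width_range
    else:
        span = float(np.max(data.X.max(axis=0) - data.X.min(axis=0)))
        lo, hi = 0.02 * span, 0.6 * span
    if not (np.isfinite(lo) and lo > 0 and hi >= lo):
        raise ValidationError(f"degenerate data bounds give width range ({lo}, {hi})")
    return lo, hi


def _genome_af(data: Dataset, idx: int, width: float) -> GaussianAF:
    return GaussianAF(tuple(data.X[idx]), float(width), 1.0)


def ga_propose(
    data: Dataset,
    state: ModelState,
    config: GAConfig,
    w_local: float = 0.5,
    rng: np.random.Generator | None = None,
    trace_out: list | None = None,
) -> CandidatePool:
    """Evolve candidate AFs against the current model; return the population.

    fitness(genome) = error_weight * S(GE, LE; w_local)
                      - support_weight * (receptive-field count / n),
    minimized.  ``generations=0`` returns the untouched random initial
    population.  Seed-deterministic given the same rng state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = _width_bounds(data, config)
    n = data.n
    pop_idx = rng.integers(0, n, size=config.population_size)
    pop_w = rng.uniform(lo, hi, size=config.population_size)

    def fitness(idx: int, width: float) -> float:
        err = evaluate_candidate(state, _genome_af(data, idx, width), data)
        if not err.local_defined:
            err = ErrorPair(err.global_error, 1.0, 0, True)
        s = weighted_score(err, w_local)
        return (
            config.fitness_error_weight * s
            - config.fitness_support_weight * err.local_support / n
        )

    fits = np.array([fitness(i, w) for i, w in zip(pop_idx, pop_w)])
    if trace_out is not None:
        trace_out.append(
            {"gen": 0, "best": float(fits.min()), "mean": float(fits.mean())}
        )
    for gen in range(config.generations):
        elite = int(np.argmin(fits))
        new_idx = [int(pop_idx[elite])]
        new_w = [float(pop_w[elite])]
        while len(new_idx) < config.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size,
                                          size=config.tournament_size)
                parents.append(contenders[int(np.argmin(fits[contenders]))])
            p1, p2 = parents
            ci, cw = int(pop_idx[p1]), float(pop_w[p1])
            if rng.random() < config.crossover_rate:
                cw = float(pop_w[p2])  # one-point crossover on the 2-gene genome
            if rng.random() < config.mutation_rate:
                ci = int(rng.integers(0, n))  # center re-draw
            if rng.random() < config.mutation_rate:
                cw = float(np.clip(cw + rng.normal(0.0, 0.1 * (hi - lo)), lo, hi))
            new_idx.append(ci)
            new_w.append(cw)
        pop_idx = np.array(new_idx)
        pop_w = np.array(new_w)
        fits = np.array([fitness(i, w) for i, w in zip(pop_idx, pop_w)])
        if trace_out is not None:
            trace_out.append(
                {
                    "gen": gen + 1,
                    "best": float(fits.min()),
                    "mean": float(fits.mean()),
                }
            )
    pool = CandidatePool(
        [_genome_af(data, int(i), float(w)) for i, w in zip(pop_idx, pop_w)],
        provenance="random",
    )
    return pool


def train_classification_ga(
    data: Dataset, config: TrainConfig, ga_config: GAConfig
) -> ModelState:
    """MSRBF training with a fresh GA-evolved pool per node iteration."""
    schedule = config.schedule()

    def provider(state: ModelState, k: int) -> CandidatePool:
        rng = np.random.default_rng([ga_config.seed, k])
        return ga_propose(
            data, state, ga_config, w_local=local_weight(schedule, k), rng=rng
        )

    return train(data, config, pool_provider=provider)
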