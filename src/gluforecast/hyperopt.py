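"""Genetic hyperparameter search with validation-MSE fitness.

Canonical operator set: tournament selection, uniform crossover, per-gene
resampling mutation, and elitism (which makes the best-so-far fitness
curve nonincreasing by construction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SamplingError

_MAX_RESAMPLE = 1000


# ----------------------------------------------------------------------
# Search space
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[rng.integers(len(self.choices))]

    def __contains__(self, v) -> bool:
        return v in self.choices


@dataclass(frozen=True)
class IntRange:
    lo: int
    hi: int  # inclusive

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.lo, self.hi + 1))

    def __contains__(self, v) -> bool:
        return self.lo <= v <= self.hi


@dataclass(frozen=True)
class FloatRange:
    lo: float
    hi: float
    log: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        return float(rng.uniform(self.lo, self.hi))

    def __contains__(self, v) -> bool:
        return self.lo <= v <= self.hi


def _divisibility_ok(candidate: dict) -> bool:
    d, h = candidate.get("d_model"), candidate.get("n_heads")
    return d is None or h is None or d % h == 0


@dataclass
class SearchSpace:
    """Named hyperparameter domains plus structural constraints."""

    domains: dict[str, Categorical | IntRange | FloatRange]

    def __post_init__(self):
        if not self.domains:
            raise ParameterError("search space must be non-empty")
        for name, dom in self.domains.items():
            if isinstance(dom, Categorical) and len(dom.choices) == 0:
                raise ParameterError(f"empty domain for {name}")

    def sample(self, rng: np.random.Generator) -> dict:
        for _ in range(_MAX_RESAMPLE):
            cand = {k: d.sample(rng) for k, d in self.domains.items()}
            if _divisibility_ok(cand):
                return cand
        raise SamplingError("could not draw a feasible candidate")

    def mutate_gene(self, cand: dict, gene: str, rng: np.random.Generator) -> dict:
        for _ in range(_MAX_RESAMPLE):
            new = dict(cand)
            new[gene] = self.domains[gene].sample(rng)
            if _divisibility_ok(new):
                return new
        raise SamplingError(f"could not mutate gene {gene!r} feasibly")

    def is_feasible(self, cand: dict) -> bool:
        return all(cand[k] in d for k, d in self.domains.items()) and _divisibility_ok(
            cand
        )


def default_search_space() -> SearchSpace:
    return SearchSpace(
        {
            "d_model": Categorical((8, 16, 32)),
            "n_heads": Categorical((1, 2, 4)),
            "n_encoder_layers": IntRange(1, 3),
            "lstm_hidden": Categorical((16, 32, 64)),
            "dropout": FloatRange(0.0, 0.3),
            "lr": FloatRange(1e-4, 1e-2, log=True),
            "lookback": Categorical((6, 12, 18)),
        }
    )


# ----------------------------------------------------------------------
# GA machinery
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 8
    n_iter: int = 10
    elite_k: int = 2
    tournament_k: int = 2
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15

    def __post_init__(self):
        if self.pop_size < 2:
            raise ParameterError("pop_size must be >= 2 for crossover")
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")
        if not 0 < self.elite_k <= self.pop_size:
            raise ParameterError("elite_k must be in [1, pop_size]")
        if self.tournament_k < 1:
            raise ParameterError("tournament_k must be >= 1")


def candidate_digest(cand: dict) -> str:
    return hashlib.sha256(
        json.dumps(cand, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class IterationRecord:
    fitnesses: list[float]
    best_fitness: float
    best_candidate_digest: str


@dataclass
class FitnessHistory:
    iterations: list[IterationRecord] = field(default_factory=list)
    evaluations: list[tuple[str, float]] = field(default_factory=list)

    def record_eval(self, cand: dict, fitness: float) -> None:
        self.evaluations.append((candidate_digest(cand), fitness))

    @property
    def best_fitness_per_iter(self) -> list[float]:
        return [rec.best_fitness for rec in self.iterations]


def best_so_far(history: FitnessHistory | list[float]) -> np.ndarray:
    """Running minimum of per-iteration best fitness."""
    values = (
        history.best_fitness_per_iter
        if isinstance(history, FitnessHistory)
        else list(history)
    )
    if len(values) == 0:
        raise ParameterError("empty fitness history")
    return np.minimum.accumulate(np.asarray(values, dtype=np.float64))


def genetic_search(
    space: SearchSpace,
    fitness,
    ga: GAConfig = GAConfig(),
    seed: int = 0,
) -> tuple[dict, FitnessHistory]:
    """Minimize ``fitness(candidate)`` over the space.

    ``fitness`` is any callable mapping a candidate dict to a float — for
    model tuning use :func:`make_validation_fitness`; tests may plant a
    synthetic objective.  Fully seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    history = FitnessHistory()
    cache: dict[str, float] = {}

    def evaluate(cand: dict) -> float:
        key = candidate_digest(cand)
        if key not in cache:
            cache[key] = float(fitness(cand))
            history.record_eval(cand, cache[key])
        return cache[key]

    population = [space.sample(rng) for _ in range(ga.pop_size)]
    fits = [evaluate(c) for c in population]

    def record_iteration():
        k = int(np.argmin(fits))
        history.iterations.append(
            IterationRecord(
                fitnesses=list(fits),
                best_fitness=fits[k],
                best_candidate_digest=candidate_digest(population[k]),
            )
        )

    record_iteration()

    def tournament() -> dict:
        idx = rng.integers(0, ga.pop_size, size=ga.tournament_k)
        best = min(idx, key=lambda i: fits[i])
        return population[best]

    for _ in range(ga.n_iter):
        elite_order = np.argsort(fits, kind="stable")[: ga.elite_k]
        next_pop = [dict(population[i]) for i in elite_order]
        while len(next_pop) < ga.pop_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < ga.crossover_rate:
                child = {
                    k: (p1[k] if rng.random() < 0.5 else p2[k]) for k in p1
                }
                if not space.is_feasible(child):
                    child = dict(p1)
            else:
                child = dict(p1)
            for gene in list(child):
                if rng.random() < ga.mutation_rate:
                    child = space.mutate_gene(child, gene, rng)
            next_pop.append(child)
        population = next_pop
        fits = [evaluate(c) for c in population]
        record_iteration()

    best_idx = int(np.argmin(fits))
    curve = best_so_far(history)
    assert np.all(np.diff(curve) <= 0), "elitism must keep best-so-far nonincreasing"
    return population[best_idx], history


def make_validation_fitness(
    cohort,
    kind: str = "transformer_lstm",
    horizon_min: int = 15,
    interval_min: int = 5,
    train_frac: float = 0.8,
    search_epochs: int = 30,
    base_train_cfg=None,
    seed: int = 0,
):
    """Fitness = best validation MSE (scaled units) of a shortened training
    run with the candidate's hyperparameters."""
    from dataclasses import replace

    from .dataset import WindowSpec
    from .evaluation import prepare_splits
    from .models import HybridConfig, build_model
    from .training import TrainConfig, train as train_model

    base_train_cfg = base_train_cfg or TrainConfig(seed=seed)

    def fitness(cand: dict) -> float:
        lookback = int(cand.get("lookback", 12))
        spec = WindowSpec(lookback, horizon_min // interval_min, interval_min)
        train_s, _, _, _ = prepare_splits(cohort, spec, train_frac)
        model_kwargs = {
            k: cand[k]
            for k in ("d_model", "n_heads", "n_encoder_layers", "lstm_hidden", "dropout")
            if k in cand
        }
        cfg = HybridConfig(lookback=lookback, **model_kwargs)
        tcfg = replace(
            base_train_cfg,
            max_epochs=search_epochs,
            lr=float(cand.get("lr", base_train_cfg.lr)),
            seed=seed,
        )
        model = build_model(kind, cfg, seed=seed)
        _, log = train_model(model, train_s, tcfg)
        return min(log.val_losses)

    return fitness
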