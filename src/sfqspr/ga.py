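"""Genetic-algorithm descriptor selection with elitism and adaptive mutation.

Three variants are implemented over fixed-length bit genomes (one bit per
descriptor, 1 = selected):

* ``O``   -- plain GA: roulette-wheel selection proportional to fitness,
  single-point crossover, single-point mutation.
* ``RE``  -- adds elite retention: if the best offspring is inferior to the
  best parent, it is replaced by that parent, so the best fitness per
  generation never decreases.
* ``REC`` -- additionally replaces the fixed single-point mutation with
  per-gene mutation probabilities derived from the evolutionary history: for
  each gene, the fitness-weighted mean over the recent per-generation elites
  that carried it is min-max normalized across genes (genes absent from every
  recent elite score 0.5), and the normalized vector is affinely mapped into
  a configurable probability range before use.

Fitness of a genome is the mean per-fold R-squared of a 5-fold
cross-validation of the chosen regressor on the training partition restricted
to the selected descriptors.  Folds are drawn once per run from the run seed
and reused for every genome, so individuals compete on identical folds.

After the run, descriptors are ranked by how often they appear in the
per-generation elites (a Monte-Carlo frequency ranking), and prefixes of that
ranking are swept to choose the final subset size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .data_io import DescriptorTable
from .modeling import ModelSpec, UndefinedMetricError, build_pipeline, cross_validate, r_squared

logger = logging.getLogger(__name__)

SENTINEL_FITNESS = float("-inf")


class PopulationCollapseError(RuntimeError):
    """Every individual carries the sentinel fitness; selection is impossible."""


@dataclass
class Individual:
    """A bit genome over descriptors with (lazily) cached fitness."""

    genome: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genome = np.asarray(self.genome, dtype=np.uint8)

    def copy(self) -> "Individual":
        return Individual(self.genome.copy(), self.fitness)

    @property
    def n_selected(self) -> int:
        return int(self.genome.sum())


@dataclass
class GAConfig:
    """GA run parameters.

    Defaults follow the standard small-population setup for descriptor
    selection: 50 chromosomes, 200 generations, crossover probability 0.5,
    mutation probability 0.01, 5-fold CV fitness.  ``init_prob`` is the
    Bernoulli rate at which genes are switched on in the initial population;
    sparse initialization (0.1) reflects that useful descriptor subsets are
    small relative to the pool.
    """

    population_size: int = 50
    generations: int = 200
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    cv_folds: int = 5
    variant: str = "O"
    history_window: int = 50
    adaptive_pm_range: tuple[float, float] = (0.001, 0.05)
    init_prob: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.variant = self.variant.upper()
        if self.variant not in ("O", "RE", "REC"):
            raise ValueError(f"variant must be O, RE or REC, got {self.variant!r}")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.history_window < 1:
            raise ValueError("history_window must be >= 1")
        lo, hi = self.adaptive_pm_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("adaptive_pm_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class RouletteState:
    """Selection probabilities and their cumulative intervals."""

    probabilities: np.ndarray
    cumulative: np.ndarray  # NP_1..NP_N with implicit NP_0 = 0


@dataclass
class EliteHistory:
    """Rolling window (capacity W) of per-generation best (genome, fitness)."""

    capacity: int
    genomes: list[np.ndarray] = field(default_factory=list)
    fitnesses: list[float] = field(default_factory=list)

    def push(self, genome: np.ndarray, fitness: float) -> None:
        self.genomes.append(np.asarray(genome, dtype=np.uint8).copy())
        self.fitnesses.append(float(fitness))
        if len(self.genomes) > self.capacity:
            del self.genomes[0]
            del self.fitnesses[0]

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class SelectionReport:
    """Everything a GA run produces: trace, elites, ranking inputs, curve."""

    descriptor_names: list[str]
    best_fitness_trace: list[float]
    elite_genomes: list[np.ndarray]
    elite_fitnesses: list[float]
    config: GAConfig | None = None
    curve: list[dict] = field(default_factory=list)
    chosen_subset: list[str] = field(default_factory=list)

    def descriptor_frequencies(self) -> np.ndarray:
        """Per-descriptor count of appearances in the per-generation elites."""
        if not self.elite_genomes:
            return np.zeros(len(self.descriptor_names), dtype=int)
        return np.sum(np.stack(self.elite_genomes), axis=0).astype(int)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def make_cv_folds(n: int, folds: int, rng_seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold partition, computed once per run and reused."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    return list(kf.split(np.arange(n)))


def evaluate_fitness(
    genome: np.ndarray,
    data: DescriptorTable,
    model: ModelSpec,
    folds: int = 5,
    rng_seed: int = 0,
    fold_indices: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Mean per-fold CV R-squared of the model on the selected descriptors.

    The all-zero genome gets the -inf sentinel (it can never win selection)
    instead of raising, so the GA loop stays total.  An isolated CV failure is
    retried once with a fallback fold seed; a second failure also yields the
    sentinel.
    """
    genome = np.asarray(genome, dtype=np.uint8)
    if genome.sum() == 0:
        return SENTINEL_FITNESS
    if data.target is None:
        raise ValueError("fitness needs a table with targets")
    cols = np.flatnonzero(genome)
    sub = DescriptorTable(
        molecule_ids=list(data.molecule_ids),
        descriptor_names=[data.descriptor_names[j] for j in cols],
        values=data.values[:, cols],
        target=data.target.copy(),
    )
    fast = model.family == "pls" and model.pca_components is None
    try:
        cv_r2, _, _ = cross_validate(
            model, sub, folds=folds, rng_seed=rng_seed,
            fold_indices=fold_indices, fast_pls=fast,
        )
        return cv_r2
    except UndefinedMetricError:
        raise
    except Exception as exc:  # isolated numerical failure: retry on fresh folds
        logger.warning("CV failed (%s); retrying with fallback fold seed", exc)
        try:
            cv_r2, _, _ = cross_validate(
                model, sub, folds=folds, rng_seed=rng_seed + 1, fast_pls=fast
            )
            return cv_r2
        except Exception:
            return SENTINEL_FITNESS


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------

def roulette_probabilities(fitnesses: Sequence[float], eps: float = 1e-9) -> RouletteState:
    """Selection probabilities proportional to (shifted) fitness.

    CV R-squared can be negative while roulette weights must not be, so finite
    fitnesses are shifted by ``-min + eps`` first; the shift preserves the
    ordering.  Sentinel (-inf) individuals get probability exactly zero.
    """
    f = np.asarray(fitnesses, dtype=float)
    finite = np.isfinite(f)
    if not finite.any():
        raise PopulationCollapseError("no individual has a finite fitness")
    shifted = np.zeros_like(f)
    fmin = f[finite].min()
    shifted[finite] = f[finite] - fmin + eps
    p = shifted / shifted.sum()
    return RouletteState(probabilities=p, cumulative=np.cumsum(p))


def spin_roulette(state: RouletteState, r: float) -> int:
    """Index i with NP_{i-1} <= r <= NP_i."""
    return int(np.searchsorted(state.cumulative, r, side="left"))


def select_next_generation(
    population: list[Individual], state: RouletteState, rng: np.random.Generator
) -> list[Individual]:
    """Draw N offspring with replacement by the cumulative-interval rule."""
    n = len(population)
    draws = rng.random(n)
    return [population[spin_roulette(state, r)].copy() for r in draws]


def single_point_cross(a: np.ndarray, b: np.ndarray, cut: int) -> tuple[np.ndarray, np.ndarray]:
    """Swap tails after position ``cut`` (1 <= cut <= L-1)."""
    ca = np.concatenate([a[:cut], b[cut:]])
    cb = np.concatenate([b[:cut], a[cut:]])
    return ca, cb


def crossover(
    parent_a: Individual, parent_b: Individual, pc: float, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """With probability Pc, single-point crossover; else parents pass through."""
    if len(parent_a.genome) != len(parent_b.genome):
        raise ValueError("genome lengths differ")
    if rng.random() < pc and len(parent_a.genome) > 1:
        cut = int(rng.integers(1, len(parent_a.genome)))
        ga, gb = single_point_cross(parent_a.genome, parent_b.genome, cut)
        return Individual(ga), Individual(gb)
    return parent_a.copy(), parent_b.copy()


def mutate_fixed(individual: Individual, pm: float, rng: np.random.Generator) -> Individual:
    """With probability Pm, flip one uniformly chosen gene."""
    if rng.random() < pm:
        g = individual.genome.copy()
        j = int(rng.integers(0, len(g)))
        g[j] ^= 1
        return Individual(g)
    return individual.copy()


def adaptive_mutation_scores(history: EliteHistory, d: int) -> np.ndarray:
    """History-based per-gene scores in [0, 1] (before range mapping).

    For gene j carried by at least one elite in the window the raw score is
    the fitness-weighted mean  sum_i a_i b_ij / sum_i b_ij  over the window's
    elites; raw scores are then min-max normalized across genes.  Genes absent
    from every elite get 0.5 exactly.  If all raw scores coincide the min-max
    map is degenerate and every gene gets 0.5.
    """
    if len(history) == 0:
        raise ValueError("history is empty")
    B = np.stack(history.genomes).astype(float)  # (w, d)
    a = np.asarray(history.fitnesses, dtype=float)
    counts = B.sum(axis=0)
    selected = counts > 0
    scores = np.full(d, 0.5)
    if selected.any():
        raw = (a @ B)[selected] / counts[selected]
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            scores[selected] = (raw - lo) / (hi - lo)
        else:
            scores[selected] = 0.5
    return scores


def adaptive_mutation_probs(
    history: EliteHistory,
    d: int,
    pm_range: tuple[float, float] = (0.001, 0.05),
    fallback_pm: float = 0.01,
) -> np.ndarray:
    """Per-gene flip probabilities: scores mapped affinely into ``pm_range``.

    An empty history (before the first generation completes) falls back to a
    uniform vector at the fixed mutation probability.
    """
    lo, hi = pm_range
    if len(history) == 0:
        return np.full(d, fallback_pm)
    scores = adaptive_mutation_scores(history, d)
    return lo + scores * (hi - lo)


def mutate_adaptive(
    individual: Individual, probs: np.ndarray, rng: np.random.Generator
) -> Individual:
    """Independent per-gene Bernoulli flips with per-gene probabilities."""
    flips = rng.random(len(individual.genome)) < probs
    if flips.any():
        g = individual.genome.copy()
        g[flips] ^= 1
        return Individual(g)
    return individual.copy()


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

def _init_population(d: int, config: GAConfig, rng: np.random.Generator) -> list[Individual]:
    pop = []
    for _ in range(config.population_size):
        g = (rng.random(d) < config.init_prob).astype(np.uint8)
        if g.sum() == 0:
            g[rng.integers(0, d)] = 1
        pop.append(Individual(g))
    return pop


def run_ga(data: DescriptorTable, model: ModelSpec, config: GAConfig) -> SelectionReport:
    """Run one GA variant over the training table and collect the elites.

    ``data`` must already be the training partition; fitness is never computed
    on held-out rows.  Identical config (including the seed) reproduces the
    run exactly.
    """
    if data.target is None:
        raise ValueError("run_ga needs a table with targets")
    d = data.n_descriptors
    rng = np.random.default_rng(config.rng_seed)
    folds = make_cv_folds(data.n_samples, config.cv_folds, config.rng_seed)
    cache: dict[bytes, float] = {}

    def fitness_of(ind: Individual) -> float:
        if ind.fitness is not None:
            return ind.fitness
        key = ind.genome.tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(
                ind.genome, data, model, folds=config.cv_folds,
                rng_seed=config.rng_seed, fold_indices=folds,
            )
        ind.fitness = cache[key]
        return ind.fitness

    pop = _init_population(d, config, rng)
    for ind in pop:
        fitness_of(ind)

    history = EliteHistory(capacity=config.history_window)
    trace: list[float] = []
    elite_genomes: list[np.ndarray] = []
    elite_fitnesses: list[float] = []

    for gen in range(config.generations):
        fits = [ind.fitness for ind in pop]
        state = roulette_probabilities(fits)
        parents = select_next_generation(pop, state, rng)

        offspring: list[Individual] = []
        for i in range(0, len(parents) - 1, 2):
            ca, cb = crossover(parents[i], parents[i + 1], config.crossover_prob, rng)
            offspring.extend([ca, cb])
        if len(parents) % 2:
            offspring.append(parents[-1].copy())

        if config.variant == "REC":
            probs = adaptive_mutation_probs(
                history, d, pm_range=config.adaptive_pm_range,
                fallback_pm=config.mutation_prob,
            )
            offspring = [mutate_adaptive(ind, probs, rng) for ind in offspring]
        else:
            offspring = [mutate_fixed(ind, config.mutation_prob, rng) for ind in offspring]

        for ind in offspring:
            fitness_of(ind)

        # the generation's optimal individual enters the Monte-Carlo sample
        # before elite retention, so each generation contributes a freshly
        # generated genome rather than a frozen copy of the incumbent
        off_best = max(offspring, key=lambda x: x.fitness)
        if np.isfinite(off_best.fitness):
            history.push(off_best.genome, off_best.fitness)
            elite_genomes.append(off_best.genome.copy())
            elite_fitnesses.append(off_best.fitness)

        if config.variant in ("RE", "REC"):
            parent_best = max(pop, key=lambda x: x.fitness)
            off_best_idx = int(np.argmax([x.fitness for x in offspring]))
            if offspring[off_best_idx].fitness < parent_best.fitness:
                offspring[off_best_idx] = parent_best.copy()

        pop = offspring
        best = max(pop, key=lambda x: x.fitness)
        trace.append(best.fitness)
        logger.info(
            "gen %d: best=%.4f mean=%.4f selected=%d",
            gen, best.fitness,
            float(np.mean([f for f in (x.fitness for x in pop) if np.isfinite(f)])),
            best.n_selected,
        )

    return SelectionReport(
        descriptor_names=list(data.descriptor_names),
        best_fitness_trace=trace,
        elite_genomes=elite_genomes,
        elite_fitnesses=elite_fitnesses,
        config=config,
    )


def rank_descriptors(
    report: SelectionReport, n_keep: int, values: np.ndarray | None = None
) -> list[str]:
    """Top descriptors by elite-selection frequency.

    Ties are broken by the mean fitness of the elites containing the
    descriptor (descending), then by name (ascending).

    When the descriptor matrix ``values`` is supplied, columns with exactly
    identical values are treated as one descriptor: no regressor can tell
    them apart, so their elite appearances are pooled (an elite counts once
    if it selects any copy) and only the alphabetically first copy of each
    group is reported.  Without ``values`` every column is ranked on its own
    raw frequency.
    """
    d = len(report.descriptor_names)
    if n_keep > d:
        raise ValueError(f"n_keep={n_keep} exceeds descriptor count {d}")
    names = report.descriptor_names

    if values is not None:
        groups: dict[bytes, list[int]] = {}
        for j in range(d):
            groups.setdefault(np.ascontiguousarray(values[:, j]).tobytes(), []).append(j)
        members = [sorted(idxs, key=lambda j: names[j]) for idxs in groups.values()]
    else:
        members = [[j] for j in range(d)]

    if report.elite_genomes:
        B = np.stack(report.elite_genomes).astype(float)
        a = np.asarray(report.elite_fitnesses, dtype=float)
    else:
        B = np.zeros((0, d))
        a = np.zeros(0)

    ranked: list[tuple[float, float, str]] = []
    for idxs in members:
        present = B[:, idxs].sum(axis=1) > 0 if len(B) else np.zeros(0, bool)
        freq = float(present.sum())
        mean_fit = float(a[present].mean()) if freq else float("-inf")
        ranked.append((-freq, -mean_fit, names[idxs[0]]))
    ranked.sort()
    return [nm for _, _, nm in ranked[:n_keep]]


def sweep_subset_sizes(
    ranked: Sequence[str],
    train: DescriptorTable,
    model: ModelSpec,
    sizes: Sequence[int],
    test: DescriptorTable | None = None,
    folds: int = 5,
    rng_seed: int = 0,
) -> list[dict]:
    """Fit top-k prefixes of the ranking; report tr/cv/test R-squared per k.

    Duplicate sizes are dropped with a warning.  The conventional choice of
    the final size is the argmax of cv_r2, ties resolved toward the smaller
    subset (see :func:`choose_subset_size`).
    """
    seen: set[int] = set()
    cleaned: list[int] = []
    for s in sizes:
        if s in seen:
            warnings.warn(f"duplicate subset size {s} ignored")
            continue
        if s > len(ranked):
            raise ValueError(f"size {s} exceeds ranked list length {len(ranked)}")
        if s < 1:
            raise ValueError("subset sizes must be >= 1")
        seen.add(s)
        cleaned.append(s)

    from .modeling import fit_predict  # local import avoids cycle at module load

    curve = []
    for s in cleaned:
        names = list(ranked[:s])
        sub_train = train.subset_columns(names)
        pred_tr, pipe = fit_predict(model, sub_train, sub_train)
        tr_r2 = r_squared(sub_train.target, pred_tr)
        cv_r2, _, _ = cross_validate(model, sub_train, folds=folds, rng_seed=rng_seed)
        te_r2 = None
        if test is not None and test.target is not None:
            sub_test = test.subset_columns(names)
            pred_te = np.asarray(pipe.predict(sub_test.values), dtype=float).ravel()
            te_r2 = r_squared(sub_test.target, pred_te)
        curve.append({"size": s, "tr_r2": tr_r2, "cv_r2": cv_r2, "te_r2": te_r2})
    return curve


def choose_subset_size(curve: Sequence[dict]) -> int:
    """Smallest size attaining the maximal cv_r2 on the sweep curve."""
    if not curve:
        raise ValueError("empty sweep curve")
    best = max(c["cv_r2"] for c in curve)
    return min(c["size"] for c in curve if c["cv_r2"] == best)
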