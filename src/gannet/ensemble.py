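"""Genetic-algorithm SNP-subset search and the neural-network ensemble.

A chromosome is a fixed-size set of k SNP ids (k in {3, 10, 16} in the
study design). Fitness of a subset is the sum of the training and
validation binary cross-entropy of the fixed ANN trained on that subset's
dosage columns — lower is better. The search space is combinatorial
(C(92,10) is about 7.2e12), so the GA seeds one individual with the top-k
SNPs from the association analysis to start near a good basin.

The final predictor is a six-member ensemble: the best individual from each
of five independent GA runs plus the association top-k subset, one trained
ANN per member, predictions averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .assoc import SNPSubsetSpec
from .classifiers import ANNSpec, TrainedANN, train_ann
from .genotype_data import GenotypeMatrix

__all__ = [
    "Individual", "GAConfig", "EnsembleModel", "FitnessEvaluator",
    "init_population", "evolve", "run_gannet", "ensemble_predict",
    "search_space_size",
]


def search_space_size(n_snps: int = 92, k: int = 10) -> int:
    """Exact number of size-k SNP subsets: the binomial coefficient C(n, k)."""
    return math.comb(n_snps, k)


@dataclass
class Individual:
    """A fixed-size SNP subset with (optionally) its evaluated fitness."""

    snp_ids: frozenset[str]
    fitness: float | None = None

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def sorted_ids(self) -> list[str]:
        return sorted(self.snp_ids)


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; population and cycle counts default to 30."""

    subset_size: int = 10
    population_size: int = 30
    cycles: int = 30
    tournament_size: int = 2
    crossover_rate: float = 0.9
    mutation_rate_per_gene: float = 0.05
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate_per_gene"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


class FitnessEvaluator:
    """Trains the ANN on a subset's columns; memoizes by subset.

    Fitness = train BCE + validation BCE at the restored checkpoint (lower
    is better). One fixed ANN seed per evaluator, so fitness differences
    reflect subsets rather than initialization noise. A training abort maps
    to fitness +inf with a warning.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        train_ids: list[str],
        val_ids: list[str],
        *,
        ann_seed: int = 0,
        epochs: int = 100,
        hidden_width: int | None = None,
    ):
        self._matrix = matrix
        pos = {sid: i for i, sid in enumerate(matrix.sample_ids)}
        self._train_rows = [pos[s] for s in train_ids]
        self._val_rows = [pos[s] for s in val_ids]
        self.ann_seed = ann_seed
        self.epochs = epochs
        self.hidden_width = hidden_width
        self._cache: dict[frozenset, float] = {}
        self.n_trainings = 0

    def columns(self, snp_ids: list[str], rows: list[int]) -> np.ndarray:
        return self._matrix.select(snp_ids)[rows, :]

    def train_member(self, snp_ids: frozenset[str], seed: int | None = None) -> TrainedANN:
        ids = sorted(snp_ids)
        spec = ANNSpec(n_inputs=len(ids), hidden_width=self.hidden_width,
                       epochs=self.epochs)
        self.n_trainings += 1
        return train_ann(
            spec,
            self.columns(ids, self._train_rows),
            self._matrix.phenotypes[self._train_rows],
            self.columns(ids, self._val_rows),
            self._matrix.phenotypes[self._val_rows],
            self.ann_seed if seed is None else seed,
        )

    def __call__(self, individual: Individual) -> float:
        key = individual.snp_ids
        if key not in self._cache:
            try:
                net = self.train_member(key)
                self._cache[key] = net.train_loss + net.val_loss
            except RuntimeError as exc:
                warnings.warn(f"fitness evaluation aborted: {exc}")
                self._cache[key] = float("inf")
        individual.fitness = self._cache[key]
        return individual.fitness


# ---------------------------------------------------------------------------
# GA operators
# ---------------------------------------------------------------------------

def init_population(
    config: GAConfig, snp_pool: list[str], seeded_subset: SNPSubsetSpec,
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """Population of k-subsets; individual #1 is the association top-k."""
    k = config.subset_size
    if len(snp_pool) < k:
        raise ValueError(f"SNP pool ({len(snp_pool)}) smaller than subset size {k}")
    if len(seeded_subset.snp_ids) < k:
        raise ValueError("seeded subset has fewer than k members")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = [Individual(frozenset(seeded_subset.snp_ids[:k]))]
    pool = np.asarray(sorted(snp_pool))
    for _ in range(config.population_size - 1):
        pick = rng.choice(pool, size=k, replace=False)
        population.append(Individual(frozenset(pick.tolist())))
    return population


def _tournament(population, rng, size: int) -> Individual:
    idx = rng.integers(0, len(population), size=size)
    return min((population[i] for i in idx), key=lambda ind: ind.fitness)


def _crossover(a: Individual, b: Individual, rng) -> Individual:
    """Child = shared SNPs + uniform fill from the symmetric difference."""
    k = a.k
    shared = a.snp_ids & b.snp_ids
    diff = sorted(a.snp_ids ^ b.snp_ids)
    need = k - len(shared)
    fill = rng.choice(np.asarray(diff), size=need, replace=False).tolist() if need else []
    child = frozenset(shared | set(fill))
    assert len(child) == k
    return Individual(child)


def _mutate(ind: Individual, pool: list[str], rng, rate: float) -> Individual:
    genes = ind.sorted_ids()
    unused = sorted(set(pool) - ind.snp_ids)
    out = set(genes)
    for g in genes:
        if unused and rng.random() < rate:
            repl = unused[int(rng.integers(0, len(unused)))]
            out.discard(g)
            out.add(repl)
            unused.remove(repl)
            unused.append(g)
            unused.sort()
    child = frozenset(out)
    assert len(child) == len(genes)
    return Individual(child)


def evolve(
    population: list[Individual],
    config: GAConfig,
    fitness: FitnessEvaluator,
    rng: np.random.Generator | None = None,
    trajectory: list | None = None,
) -> Individual:
    """Run the GA for ``config.cycles`` generations; return the best ever.

    Per cycle: elitism carries the best individual unchanged; parents are
    chosen by size-2 tournaments; subset-preserving crossover (rate 0.9)
    builds children; per-gene replacement mutation (rate 0.05) draws from
    the unused pool. Best-ever fitness is non-increasing by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pool = sorted({sid for ind in population for sid in ind.snp_ids} |
                  set(fitness._matrix.snp_ids))
    for ind in population:
        fitness(ind)
    best = min(population, key=lambda i: i.fitness)
    if trajectory is not None:
        trajectory.append({"cycle": 0, "best_fitness": best.fitness,
                           "mean_fitness": float(np.mean([i.fitness for i in population]))})

    for cycle in range(1, config.cycles + 1):
        elite = sorted(population, key=lambda i: (i.fitness, tuple(i.sorted_ids())))
        next_pop = [Individual(e.snp_ids, e.fitness) for e in elite[:config.elitism]]
        while len(next_pop) < config.population_size:
            p1 = _tournament(population, rng, config.tournament_size)
            p2 = _tournament(population, rng, config.tournament_size)
            if rng.random() < config.crossover_rate:
                child = _crossover(p1, p2, rng)
            else:
                child = Individual(p1.snp_ids)
            child = _mutate(child, pool, rng, config.mutation_rate_per_gene)
            next_pop.append(child)
        population = next_pop
        for ind in population:
            fitness(ind)
        gen_best = min(population, key=lambda i: i.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best
        if trajectory is not None:
            trajectory.append({
                "cycle": cycle, "best_fitness": best.fitness,
                "mean_fitness": float(np.mean([i.fitness for i in population]))})
    return Individual(best.snp_ids, best.fitness)


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Six trained nets (five GA-selected subsets + the association subset)."""

    members: list[TrainedANN]
    member_subsets: list[Individual]
    subset_size: int
    trajectories: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.member_subsets):
            raise ValueError("one subset per member required")
        for net, ind in zip(self.members, self.member_subsets):
            if net.spec.n_inputs != self.subset_size or ind.k != self.subset_size:
                raise ValueError("member input dimension != subset size")

    @property
    def association_member(self) -> Individual:
        """The association-analysis subset is always the last member."""
        return self.member_subsets[-1]

    def snp_union(self) -> set[str]:
        return set().union(*(ind.snp_ids for ind in self.member_subsets))


def run_gannet(
    matrix: GenotypeMatrix,
    split,
    assoc_subset: SNPSubsetSpec,
    *,
    config: GAConfig | None = None,
    n_ga_runs: int = 5,
    epochs: int = 100,
    seed: int = 0,
) -> EnsembleModel:
    """Build the six-member ensemble for subset size k = config.subset_size.

    Five independent GA searches (seed offsets 0..4) each contribute their
    best-ever individual; the association top-k subset is appended as the
    sixth member. Each member's net is then (re)trained with the run seed.
    """
    if config is None:
        config = GAConfig(seed=seed)
    k = config.subset_size
    if len(assoc_subset.snp_ids) < k:
        raise ValueError("association subset has fewer than k SNPs")

    members: list[Individual] = []
    trajectories = []
    for run in range(n_ga_runs):
        run_seed = seed + run
        fitness = FitnessEvaluator(
            matrix, split.train_ids, split.val_ids,
            ann_seed=run_seed, epochs=epochs)
        cfg = replace(config, seed=run_seed)
        rng = np.random.default_rng(run_seed)
        population = init_population(cfg, list(matrix.snp_ids), assoc_subset, rng)
        traj: list = []
        best = evolve(population, cfg, fitness, rng, trajectory=traj)
        members.append(best)
        trajectories.append(traj)
    members.append(Individual(frozenset(assoc_subset.snp_ids[:k])))

    trainer = FitnessEvaluator(matrix, split.train_ids, split.val_ids,
                               ann_seed=seed, epochs=epochs)
    nets = [trainer.train_member(ind.snp_ids) for ind in members]
    return EnsembleModel(members=nets, member_subsets=members,
                         subset_size=k, trajectories=trajectories)


def ensemble_predict(model: EnsembleModel, matrix: GenotypeMatrix) -> np.ndarray:
    """Unweighted mean of the members' predicted case probabilities.

    Classification uses probability >= 0.5 as "case". Raises if the matrix
    lacks any member's SNPs.
    """
    preds = []
    for net, ind in zip(model.members, model.member_subsets):
        x = matrix.select(ind.sorted_ids())
        preds.append(net.predict_proba(x))
    return np.mean(preds, axis=0)
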