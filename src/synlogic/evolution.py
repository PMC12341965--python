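"""Genetic-algorithm calibration of Boolean model ensembles.

A model's fitness against a partial steady-state observation *ss* with m
specified nodes is

    fitness = (1 / (m n)) * sum_i sum_j I[fix_ij == ss_j]

over its n fixed points — the average fraction of specified entries each
stable state matches.  Models without a stable state get fitness 0, and
models with several disagreeing stable states are penalized by the average.

One *evolution* runs from the default-assembled model to a halting
condition: each generation, offspring are built by per-equation crossover
of the selected parents ("including itself, thus also enabling asexual
reproduction"), mutated, scored, and the best ``selection_count`` models
kept.  Until the first generation in which any population member has a
stable state, the mutation counts are boosted (x ``burst_multiplier`` link
-operator flips; the larger initial topology-mutation count), which makes
the opening generations near-uniform draws from the 2^n parameterization
space.  Training repeats ``evolutions`` times and pools the kept models,
so the default schedule yields 3 x 50 = 150 models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean, pstdev
from typing import Callable, Sequence

import numpy as np

from .attractors import AttractorSet, FixedPointOverflowError, fixed_points
from .logic import (
    BooleanModel,
    assemble_default_model,
    mutate_link_operators,
    mutate_topology,
)
from .network import CalibrationProfile, PriorKnowledgeNetwork

logger = logging.getLogger(__name__)

PARAMETERIZATION = "parameterization"
TOPOLOGY = "topology"
BOTH = "both"

ProfileSource = CalibrationProfile | Callable[[int], CalibrationProfile]


@dataclass(frozen=True)
class GAConfig:
    """Knobs of the genetic algorithm; defaults are the published schedule."""

    population: int = 20
    generations_max: int = 20
    selection_count: int = 3
    mutations_per_model: int = 3
    burst_multiplier: int = 1000
    topology_mutations_init: int = 50
    topology_mutations_after: int = 10
    fitness_threshold: float = 0.99
    evolutions: int = 50
    mutation_mode: str = PARAMETERIZATION
    seed: int = 0
    crossover: str = "uniform"  # or "single_point"
    elitism: bool = True
    max_fixed_points: int = 64

    def __post_init__(self) -> None:
        if self.selection_count > self.population:
            raise ValueError("selection_count must be <= population")
        if not (0 < self.fitness_threshold <= 1):
            raise ValueError("fitness_threshold must be in (0, 1]")
        if self.mutation_mode not in (PARAMETERIZATION, TOPOLOGY, BOTH):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")
        if self.crossover not in ("uniform", "single_point"):
            raise ValueError(f"unknown crossover {self.crossover!r}")


@dataclass
class Ensemble:
    """Pooled best models of all evolutions, with their fitness values."""

    models: list[BooleanModel]
    config: GAConfig
    calibration: CalibrationProfile | None
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.models:
            if m.fitness is None or not (0.0 <= m.fitness <= 1.0):
                raise ValueError("ensemble models must carry a fitness in [0,1]")

    @property
    def mean_fitness(self) -> float:
        return fmean(m.fitness for m in self.models)


def compute_fitness(attractors: AttractorSet, profile: CalibrationProfile) -> float:
    """Average match fraction of the profile over all fixed points; 0 if none."""
    if profile.m < 1:
        raise ValueError("profile must specify at least one node (m >= 1)")
    n = attractors.n
    if n == 0:
        return 0.0
    specified = profile.specified
    index = {v: i for i, v in enumerate(attractors.nodes)}
    matches = 0
    for fp in attractors.fixed_points:
        for node, want in specified.items():
            if fp[index[node]] == want:
                matches += 1
    return matches / (profile.m * n)


def _score(model: BooleanModel, profile: CalibrationProfile, cap: int
           ) -> tuple[BooleanModel, int]:
    """Attach fitness; returns (scored model, fixed-point count)."""
    try:
        attrs = fixed_points(model, max_fixed_points=cap)
    except FixedPointOverflowError:
        logger.warning("fixed-point cap exceeded; assigning fitness 0")
        return model.with_fitness(0.0), cap + 1
    return model.with_fitness(compute_fitness(attrs, profile)), attrs.n


def _crossover(parents: Sequence[BooleanModel], config: GAConfig,
               rng: np.random.Generator) -> BooleanModel:
    p1 = parents[rng.integers(0, len(parents))]
    p2 = parents[rng.integers(0, len(parents))]
    n = len(p1.equations)
    if config.crossover == "uniform":
        take_first = rng.random(n) < 0.5
    else:
        cut = int(rng.integers(0, n + 1))
        take_first = np.arange(n) < cut
    eqs = tuple(
        p1.equations[i] if take_first[i] else p2.equations[i] for i in range(n)
    )
    return BooleanModel(eqs, provenance="offspring")


def next_generation(
    parents: Sequence[BooleanModel],
    config: GAConfig,
    network: PriorKnowledgeNetwork,
    rng: np.random.Generator,
    *,
    burst: bool = False,
) -> list[BooleanModel]:
    """Produce ``config.population`` offspring by crossover then mutation.

    With ``mutation_mode='both'`` topology mutations are applied before
    link-operator mutations within each offspring.
    """
    if not parents:
        raise ValueError("parents must be non-empty")
    offspring = []
    for _ in range(config.population):
        child = _crossover(parents, config, rng)
        if config.mutation_mode in (TOPOLOGY, BOTH):
            k = (config.topology_mutations_init if burst
                 else config.topology_mutations_after)
            child = mutate_topology(child, network, k, rng)
        if config.mutation_mode in (PARAMETERIZATION, BOTH):
            k = config.mutations_per_model * (config.burst_multiplier if burst else 1)
            child = mutate_link_operators(child, k, rng)
        offspring.append(child)
    return offspring


def evolve(
    network: PriorKnowledgeNetwork,
    profile: ProfileSource,
    config: GAConfig,
) -> Ensemble:
    """Run the full schedule: ``evolutions`` independent GA runs, pooled.

    ``profile`` may be a single calibration profile or a callable mapping
    the evolution index to a profile (used to train the random-proliferative
    baseline ensemble against a fresh target per evolution).  Each evolution
    draws from its own seed stream ``[config.seed, evolution_index]`` so
    runs are reproducible independently.
    """
    profile_for = profile if callable(profile) else (lambda _e: profile)
    # fail fast on bad profiles before any training
    probe = profile_for(0)
    probe.validate_against(network)
    if probe.m < 1:
        raise ValueError("calibration profile must specify at least one node")

    base = assemble_default_model(network)
    kept_all: list[BooleanModel] = []
    log: list[dict] = []
    last_profile: CalibrationProfile | None = None
    for e in range(config.evolutions):
        rng = np.random.default_rng([config.seed, e])
        prof = profile_for(e)
        prof.validate_against(network)
        last_profile = prof
        parents: list[BooleanModel] = [base]
        burst = True
        top: list[tuple[float, int, BooleanModel]] = []
        creation = 0
        for gen in range(config.generations_max):
            offspring = next_generation(parents, config, network, rng, burst=burst)
            pool: list[tuple[float, int, BooleanModel]] = (
                list(top) if config.elitism else []
            )
            any_stable = False
            for child in offspring:
                scored, n_fp = _score(child, prof, config.max_fixed_points)
                if n_fp >= 1:
                    any_stable = True
                pool.append((scored.fitness, creation, scored))
                creation += 1
            if burst and any_stable:
                burst = False  # boosted mutation counts end permanently
            pool.sort(key=lambda t: (-t[0], t[1]))
            top = pool[: config.selection_count]
            parents = [t[2] for t in top]
            fits = [t[0] for t in pool]
            log.append({
                "evolution": e,
                "generation": gen,
                "best_fitness": max(fits),
                "mean_fitness": fmean(fits),
                "sd_fitness": pstdev(fits),
                "burst": burst,
            })
            if min(t[0] for t in top) >= config.fitness_threshold:
                break
        kept_all.extend(t[2] for t in top)
    calibration = last_profile if not callable(profile) else None
    return Ensemble(kept_all, config, calibration, log)
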