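"""Genetic algorithm over host internal-node orderings.

One gene per non-root internal host node, holding its proposed depth; the
admissible range of each gene is fixed by the topology alone (ancestors
push the lower bound up, internal descendants pull the upper bound down).
Fitness of a chromosome is the cost of the collapsed-and-pushed mapping
under the decoded ordering.  Operators are standard and declared, not
inherited from any reference tool: tournament selection (size 2), uniform
crossover, per-gene resampling mutation, single-individual elitism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .collapse import CollapseConfig, tree_collapse
from .model import (
    CophyloMapping,
    CostScheme,
    InputError,
    JUNGLE,
    NodeOrdering,
    PhyloTree,
    Tanglegram,
    default_ordering,
    validate_ordering,
)
from .rightpush import right_push

__all__ = [
    "GAConfig",
    "Chromosome",
    "gene_range",
    "random_chromosome",
    "decode",
    "fitness",
    "run_ga",
]

_REPAIR_ATTEMPTS = 20


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 100
    mutation_rate: Optional[float] = None  # default: 1 / number of genes
    tournament_size: int = 2
    elitism_count: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InputError("population_size must be >= 2")
        if self.generations < 0:
            raise InputError("generations must be >= 0")


@dataclass(frozen=True)
class Chromosome:
    """Depth gene per non-root internal host node, in pre-order."""

    genes: Tuple[int, ...]
    nodes: Tuple[int, ...]

    def as_dict(self) -> Dict[int, int]:
        return dict(zip(self.nodes, self.genes))


def _gene_nodes(host: PhyloTree) -> Tuple[int, ...]:
    return tuple(
        v for v in host.preorder() if not host.is_leaf(v) and v != host.root
    )


def gene_range(host: PhyloTree, node: int) -> Tuple[int, int]:
    """Admissible depth range ``[i, j]`` for a non-root internal node."""
    if host.is_leaf(node) or node == host.root:
        raise InputError("gene ranges exist only for non-root internal nodes")
    i = host.topo_depth(node)  # ancestors between node and root, root included
    internal_desc = 0
    stack = list(host.children[node])
    while stack:
        v = stack.pop()
        if not host.is_leaf(v):
            internal_desc += 1
            stack.extend(host.children[v])
    j = host.n_internal - internal_desc - 1
    assert i <= j
    return i, j


def decode(host: PhyloTree, chromosome: Chromosome) -> NodeOrdering:
    depth = {host.root: 0}
    depth.update(chromosome.as_dict())
    n_internal = host.n_internal
    for leaf in host.leaves():
        depth[leaf] = n_internal
    return NodeOrdering(depth=depth, n_internal=n_internal)


def _violating(host: PhyloTree, nodes: Sequence[int], genes: Sequence[int]) -> List[int]:
    depth = {host.root: 0}
    depth.update(zip(nodes, genes))
    counts: Dict[int, int] = {}
    for v in depth.values():
        counts[v] = counts.get(v, 0) + 1
    bad = []
    for idx, v in enumerate(nodes):
        if counts[depth[v]] > 1 or depth[v] <= depth[host.parent[v]]:
            bad.append(idx)
    return bad


def _repair(
    host: PhyloTree,
    nodes: Tuple[int, ...],
    genes: List[int],
    ranges: Sequence[Tuple[int, int]],
    rng: random.Random,
) -> Chromosome:
    """Resample conflicting genes; deterministic fallback to pre-order ranks."""
    for _ in range(_REPAIR_ATTEMPTS):
        bad = _violating(host, nodes, genes)
        if not bad:
            return Chromosome(genes=tuple(genes), nodes=nodes)
        for idx in bad:
            lo, hi = ranges[idx]
            genes[idx] = rng.randint(lo, hi)
    fallback = default_ordering(host)
    return Chromosome(genes=tuple(fallback.depth[v] for v in nodes), nodes=nodes)


def random_chromosome(host: PhyloTree, rng: random.Random) -> Chromosome:
    nodes = _gene_nodes(host)
    ranges = [gene_range(host, v) for v in nodes]
    genes = [rng.randint(lo, hi) for lo, hi in ranges]
    return _repair(host, nodes, genes, ranges, rng)


def fitness(
    tg: Tanglegram,
    chromosome: Chromosome,
    scheme: CostScheme = JUNGLE,
    config: CollapseConfig = CollapseConfig(),
    use_right_push: bool = True,
) -> float:
    ordering = decode(tg.host, chromosome)
    if not validate_ordering(tg.host, ordering):
        raise InputError("chromosome decodes to an invalid ordering")
    mapping = tree_collapse(tg, ordering, scheme, config)
    if use_right_push:
        mapping = right_push(mapping)
    return mapping.cost(scheme)


def run_ga(
    tg: Tanglegram,
    config: GAConfig = GAConfig(),
    scheme: CostScheme = JUNGLE,
    collapse_config: CollapseConfig = CollapseConfig(),
    use_right_push: bool = True,
) -> Tuple[CophyloMapping, float, List[float]]:
    """Search orderings; returns (best mapping, best cost, best-so-far history).

    ``history[g]`` is the best cost seen up to and including generation
    ``g`` (entry 0 covers the initial population); elitism makes it
    monotone non-increasing.  Fully reproducible from ``config.rng_seed``.
    """
    rng = random.Random(config.rng_seed)
    host = tg.host
    nodes = _gene_nodes(host)
    ranges = [gene_range(host, v) for v in nodes]
    n_genes = len(nodes)
    mut_rate = (
        config.mutation_rate if config.mutation_rate is not None
        else (1.0 / n_genes if n_genes else 0.0)
    )

    def evaluate(ch: Chromosome) -> float:
        return fitness(tg, ch, scheme, collapse_config, use_right_push)

    population = [random_chromosome(host, rng) for _ in range(config.population_size)]
    scores = [evaluate(ch) for ch in population]

    def best_index() -> int:
        return min(range(len(scores)), key=lambda i: scores[i])

    bi = best_index()
    best_ch, best_cost = population[bi], scores[bi]
    history = [best_cost]

    def tournament() -> Chromosome:
        picks = [rng.randrange(len(population)) for _ in range(config.tournament_size)]
        return population[min(picks, key=lambda i: scores[i])]

    for _ in range(config.generations):
        next_pop: List[Chromosome] = []
        elite = sorted(range(len(scores)), key=lambda i: scores[i])
        for i in elite[: config.elitism_count]:
            next_pop.append(population[i])
        while len(next_pop) < config.population_size:
            a, b = tournament(), tournament()
            genes = [
                (a.genes[i] if rng.random() < 0.5 else b.genes[i])
                for i in range(n_genes)
            ]
            for i in range(n_genes):
                if rng.random() < mut_rate:
                    lo, hi = ranges[i]
                    genes[i] = rng.randint(lo, hi)
            next_pop.append(_repair(host, nodes, genes, ranges, rng))
        population = next_pop
        scores = [evaluate(ch) for ch in population]
        bi = best_index()
        if scores[bi] < best_cost:
            best_ch, best_cost = population[bi], scores[bi]
        history.append(best_cost)

    ordering = decode(host, best_ch)
    best_mapping = tree_collapse(tg, ordering, scheme, collapse_config)
    if use_right_push:
        best_mapping = right_push(best_mapping)
    return best_mapping, best_cost, history
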