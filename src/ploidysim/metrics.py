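"""Summary statistics, the exact segregation-load enumerator, and analytic
rate calculators.

Segregation load is the probability that a viable parent produces an
unviable daughter under amitotic random segregation: each chromosome is
replicated and the 2P copies are partitioned P / P uniformly at random.
The exact enumerator walks all C(2P, P) equally likely daughter genomes
(each unordered daughter pair contributes its two daughters); the
Monte-Carlo companion samples random partitions and reports a
Clopper-Pearson confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .core import Cell, Population
from .fitness import VIABILITY_THRESHOLD, population_fitness, potential_fitness
from .recombination import expected_segment_length

__all__ = [
    "GenerationRecord",
    "population_stats",
    "segregation_counts",
    "segregation_load",
    "segregation_load_mc",
    "expected_conversion_probability",
    "chromosome_specialization",
    "mean_pairwise_identity",
]

#: Largest ploidy accepted by the exact enumerator (C(20, 10) = 184756).
MAX_EXACT_PLOIDY = 10


@dataclass
class GenerationRecord:
    """Per-generation summary statistics (taken after selection)."""

    generation: int
    n_alive: int
    mean_f: float = float("nan")
    min_f: float = float("nan")
    max_f: float = float("nan")
    mean_ploidy: float = float("nan")
    monoploid_fraction: float = float("nan")
    ploidy_histogram: dict[int, int] = field(default_factory=dict)
    lineage_counts: dict[str, int] = field(default_factory=dict)
    mean_identity: float = float("nan")

    @property
    def extinct(self) -> bool:
        return self.n_alive == 0


def mean_pairwise_identity(pop: Population, sample: int | None = None) -> float:
    """Mean within-cell pairwise chromosome identity (fraction of loci with
    exactly equal values), averaged over cells with ploidy >= 2.

    ``sample`` caps the number of cells considered (an evenly spaced,
    deterministic subsample); NaN if no cell has two chromosomes.
    """
    idx = np.nonzero(pop.ploidy >= 2)[0]
    if len(idx) == 0:
        return float("nan")
    if sample is not None and len(idx) > sample:
        idx = idx[np.linspace(0, len(idx) - 1, sample).astype(int)]
    vals = []
    for i in idx:
        genes = pop.cell_genes(int(i))
        p = genes.shape[0]
        acc = 0.0
        npairs = 0
        for a in range(p):
            for b in range(a + 1, p):
                acc += float((genes[a] == genes[b]).mean())
                npairs += 1
        vals.append(acc / npairs)
    return float(np.mean(vals))


def population_stats(
    pop: Population, f0: float = 1.0, F: np.ndarray | None = None,
    sample_identity: int | None = 0,
) -> GenerationRecord:
    """Compute a :class:`GenerationRecord` for the current population.

    ``sample_identity``: number of cells used for the pairwise-identity
    statistic (0 skips it entirely, ``None`` uses every cell).
    """
    if pop.n_cells == 0:
        return GenerationRecord(generation=pop.generation, n_alive=0)
    if F is None:
        F = population_fitness(pop, f0)
    ploidies, counts = np.unique(pop.ploidy, return_counts=True)
    labels = pop.lineage_labels()
    lin_counts = {
        labels[i]: int((pop.lineage == i).sum()) for i in range(len(labels))
    }
    identity = float("nan")
    if sample_identity != 0:
        identity = mean_pairwise_identity(pop, sample=sample_identity)
    return GenerationRecord(
        generation=pop.generation,
        n_alive=pop.n_cells,
        mean_f=float(F.mean()),
        min_f=float(F.min()),
        max_f=float(F.max()),
        mean_ploidy=float(pop.ploidy.mean()),
        monoploid_fraction=float((pop.ploidy == 1).mean()),
        ploidy_histogram={int(p): int(c) for p, c in zip(ploidies, counts)},
        lineage_counts=lin_counts,
        mean_identity=identity,
    )


# ---------------------------------------------------------------------------
# Segregation load
# ---------------------------------------------------------------------------


def segregation_counts(cell: Cell, f0: float = 1.0) -> tuple[int, int]:
    """Exact enumeration: ``(viable, total)`` daughter genomes.

    Each chromosome is duplicated and every choice of P of the 2P copies
    for one daughter is enumerated (replicas distinguishable, duplicates
    counted with multiplicity); the complementary daughter appears as its
    own choice, so ``total = C(2P, P)`` covers all daughters exactly once.
    """
    p = cell.ploidy
    if p > MAX_EXACT_PLOIDY:
        raise ValueError(
            f"ploidy {p} too large for exact enumeration (max {MAX_EXACT_PLOIDY}); "
            "use segregation_load_mc"
        )
    pool = np.repeat(cell.genes, 2, axis=0)
    viable = 0
    total = comb(2 * p, p)
    for pick in combinations(range(2 * p), p):
        daughter = pool[list(pick)]
        if potential_fitness(daughter, f0) >= VIABILITY_THRESHOLD:
            viable += 1
    return viable, total


def segregation_load(cell: Cell, f0: float = 1.0) -> float:
    """Exact probability that amitotic division yields an unviable daughter."""
    viable, total = segregation_counts(cell, f0)
    return (total - viable) / total


def segregation_load_mc(
    cell: Cell, n_samples: int, rng: np.random.Generator,
    f0: float = 1.0, ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo segregation load with a Clopper-Pearson ``ci`` interval.

    Samples daughters by shuffling the 2P replicated copies and taking the
    first P; returns ``(estimate, (lo, hi))``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = cell.ploidy
    pool = np.repeat(cell.genes, 2, axis=0)
    unviable = 0
    for _ in range(n_samples):
        pick = rng.permutation(2 * p)[:p]
        if potential_fitness(pool[pick], f0) < VIABILITY_THRESHOLD:
            unviable += 1
    est = unviable / n_samples
    alpha = 1.0 - ci
    lo = 0.0 if unviable == 0 else float(stats.beta.ppf(alpha / 2, unviable, n_samples - unviable + 1))
    hi = 1.0 if unviable == n_samples else float(
        stats.beta.ppf(1 - alpha / 2, unviable + 1, n_samples - unviable)
    )
    return est, (lo, hi)


# ---------------------------------------------------------------------------
# Analytic rates and specialization
# ---------------------------------------------------------------------------


def expected_conversion_probability(r: float, g: int) -> float:
    """Expected per-gene per-generation probability of being overwritten by
    gene conversion at rate coefficient ``r``: ``r * E[segment length] / g``."""
    if r < 0:
        raise ValueError("rate must be >= 0")
    if g < 1:
        raise ValueError("g must be >= 1")
    return r * expected_segment_length(g) / g


def chromosome_specialization(obj: Cell | Population, f0: float) -> float:
    """Fraction of loci whose best allele is well preserved (>= f0) on
    exactly one chromosome, averaged over cells.

    In a long mitotic run chromosomes diversify so that each gene is well
    preserved on a single chromosome; this statistic approaches 1.
    """
    cells = [obj] if isinstance(obj, Cell) else [
        Cell(obj.cell_genes(i)) for i in range(obj.n_cells)
    ]
    if not cells:
        return float("nan")
    vals = [float(((c.genes >= f0).sum(axis=0) == 1).mean()) for c in cells]
    return float(np.mean(vals))
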