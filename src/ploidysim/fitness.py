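"""Potential fitness F, effective fitness F_e, and viability culling.

Potential fitness of a cell is the product over loci of the *best* allele
at that locus (full dominance of the better allele), normalized by the
initial quality ``f0``::

    F = prod_i  max_j(f_g[j, i]) / f0

so a clonal all-``f0`` genome has F = 1 and any locus with only lethal
(0.0) copies drives F to 0.  Cells with F < 0.5 are unviable and are
removed; the inequality is strict (F = 0.5 survives).

Effective fitness blends the cell's relative rank with a uniform draw::

    F_e = (1 - S) * (F - F_min) / (F_max - F_min) + S * Rnd

S = 0 gives strict truncation selection; S = 1 pure drift.  When the
candidate pool is degenerate (F_max == F_min) the deterministic term is
defined as 0, so ranking is purely random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Cell, Population

__all__ = [
    "FitnessContext",
    "potential_fitness",
    "population_fitness",
    "effective_fitness",
    "cull_unviable",
    "VIABILITY_THRESHOLD",
]

#: Cells with potential fitness strictly below this are unviable.
VIABILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class FitnessContext:
    """Candidate-pool summary needed to turn F into F_e."""

    f_min: float
    f_max: float
    s: float

    def __post_init__(self):
        if self.f_min > self.f_max:
            raise ValueError("f_min must not exceed f_max")


def potential_fitness(cell: Cell | np.ndarray, f0: float = 1.0) -> float:
    """Potential fitness F of one cell (best copy of each gene is used)."""
    genes = cell.genes if isinstance(cell, Cell) else np.asarray(cell, dtype=float)
    if genes.ndim == 1:
        genes = genes[None, :]
    return float(np.prod(genes.max(axis=0) / f0))


def population_fitness(pop: Population, f0: float = 1.0) -> np.ndarray:
    """Vector of potential fitnesses for every cell of a population.

    Cells are processed per ploidy class so the per-locus max reduces over
    a fixed axis of a dense block (much faster than a segmented reduce).
    """
    if pop.n_cells == 0:
        return np.empty(0, dtype=float)
    offsets = pop.offsets
    F = np.empty(pop.n_cells, dtype=float)
    for p in np.unique(pop.ploidy):
        sel = np.nonzero(pop.ploidy == p)[0]
        p = int(p)
        rows = (offsets[sel][:, None] + np.arange(p)).ravel()
        block = pop.genes[rows].reshape(len(sel), p, pop.n_genes)
        F[sel] = np.prod(block.max(axis=1) / f0, axis=1)
    return F


def effective_fitness(F, ctx: FitnessContext, rnd):
    """Effective fitness F_e for scalar or array ``F`` and uniform draw(s)."""
    span = ctx.f_max - ctx.f_min
    if span == 0:
        det = np.zeros_like(np.asarray(F, dtype=float))
    else:
        det = (np.asarray(F, dtype=float) - ctx.f_min) / span
    out = (1.0 - ctx.s) * det + ctx.s * np.asarray(rnd, dtype=float)
    return float(out) if np.isscalar(F) else out


def cull_unviable(pop: Population, f0: float = 1.0) -> Population:
    """Remove every cell with F < 0.5 (strict); may return an empty population."""
    F = population_fitness(pop, f0)
    keep = np.nonzero(F >= VIABILITY_THRESHOLD)[0]
    if len(keep) == pop.n_cells:
        return pop
    return pop.subset(keep)
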