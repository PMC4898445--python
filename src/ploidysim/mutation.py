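"""Per-gene mutation process.

In each generation every gene copy mutates independently with probability
``m``; a mutating gene is beneficial with probability ``b``, else
deleterious.  Effects are multiplicative and bounded::

    deleterious:  f -> f * (1 - k_d)
    beneficial:   f -> 1 - (1 - f) * (1 - k_b)

so 0 and 1 are fixed points of the two branches respectively and values
stay inside [0, 1].  Mutation is applied to parent cells before chromosome
replication, which makes the per-gene-copy mutation probability per
generation exactly ``m`` regardless of division mode.
"""

from __future__ import annotations

import numpy as np

from .core import Population, SimParams

__all__ = ["mutate_gene", "mutate_population"]


def mutate_gene(f_old: float, is_beneficial: bool, k_d: float, k_b: float) -> float:
    """Apply one mutation to a gene quality value."""
    if is_beneficial:
        return 1.0 - (1.0 - f_old) * (1.0 - k_b)
    return f_old * (1.0 - k_d)


def mutate_population(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Mutate every gene copy in place with probability ``params.m``.

    Draw order (fixed for reproducibility): one uniform per gene copy in
    row-major order to decide mutation, then one uniform per mutating gene
    to decide beneficial/deleterious.
    """
    if params.m == 0 or pop.n_chromosomes == 0:
        return pop
    mask = rng.random(pop.genes.shape) < params.m
    k = int(mask.sum())
    if k == 0:
        return pop
    beneficial = rng.random(k) < params.b
    old = pop.genes[mask]
    new = np.where(
        beneficial,
        1.0 - (1.0 - old) * (1.0 - params.k_b),
        old * (1.0 - params.k_d),
    )
    pop.genes[mask] = new
    return pop
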