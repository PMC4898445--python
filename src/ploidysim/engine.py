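"""Selection and the per-generation simulation loop.

One generation proceeds in a fixed order:

1. cull cells with F < 0.5 (start-of-step viability check);
2. genetic-exchange events (:func:`ploidysim.recombination.run_exchange_phase`);
3. mutation of every gene copy;
4. binary fission of every cell according to its lineage's division mode;
5. cull unviable offspring;
6. selection: the ``min(n, pool)`` offspring with the highest effective
   fitness survive.

Effective fitness uses F_min / F_max of the post-cull offspring pool of the
current generation.  Ties in F_e are broken by one extra uniform draw per
cell.  Extinction is an empty population after either cull or selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Population, SimParams, init_population, validate_params
from .fitness import VIABILITY_THRESHOLD, population_fitness
from .metrics import GenerationRecord, population_stats
from .mutation import mutate_population
from .recombination import run_exchange_phase
from .reproduction import divide_population

__all__ = [
    "RunResult",
    "select_indices",
    "select",
    "run_generation",
    "run_simulation",
    "run_replicates",
]


@dataclass
class RunResult:
    """Outcome of one simulation run."""

    records: list[GenerationRecord]
    extinction_generation: int | None
    final_population: Population | None
    seed: int
    params: SimParams

    @property
    def extinct(self) -> bool:
        return self.extinction_generation is not None

    @property
    def n_generations(self) -> int:
        """Number of completed generation steps."""
        return len(self.records) - 1


def select_indices(F: np.ndarray, n: int, s: float, rng: np.random.Generator) -> np.ndarray:
    """Indices (sorted) of the ``min(n, len(F))`` candidates with highest F_e.

    Draw order: one uniform per candidate (the Rnd term), then one uniform
    per candidate as tie-breaker.
    """
    m = len(F)
    rnd = rng.random(m)
    tie = rng.random(m)
    f_min, f_max = F.min(), F.max()
    if f_max == f_min:
        det = np.zeros(m)
    else:
        det = (F - f_min) / (f_max - f_min)
    fe = (1.0 - s) * det + s * rnd
    order = np.lexsort((tie, fe))
    return np.sort(order[m - min(n, m):])


def select(pop: Population, F: np.ndarray, params: SimParams,
           rng: np.random.Generator) -> tuple[Population, np.ndarray]:
    """Apply survival selection to a (pre-culled) candidate population."""
    idx = select_indices(F, params.n, params.s, rng)
    if len(idx) == pop.n_cells:
        return pop, F
    return pop.subset(idx), F[idx]


def _cull(pop: Population, f0: float) -> tuple[Population, np.ndarray]:
    F = population_fitness(pop, f0)
    keep = np.nonzero(F >= VIABILITY_THRESHOLD)[0]
    if len(keep) < pop.n_cells:
        pop = pop.subset(keep)
        F = F[keep]
    return pop, F


def run_generation(
    pop: Population, params: SimParams, rng: np.random.Generator,
    sample_identity: int | None = 0,
    pre_culled: bool = False,
) -> tuple[Population, GenerationRecord]:
    """Advance the population by one generation.

    Raises ``ValueError`` on extinct input.  Returns the post-selection
    population (generation counter incremented) and its summary record;
    if every cell dies the returned population is empty and the record has
    ``n_alive == 0``.

    ``pre_culled=True`` skips the start-of-step viability cull; it is valid
    whenever the input is the unmodified output of a previous selection
    step (every survivor already has F >= 0.5), and changes nothing else.
    """
    if pop.is_extinct:
        raise ValueError("cannot step an extinct population")
    gen = pop.generation + 1

    if not pre_culled:
        pop, _ = _cull(pop, params.f0)
        if pop.is_extinct:
            pop.generation = gen
            return pop, population_stats(pop, params.f0)

    run_exchange_phase(pop, params, rng)
    mutate_population(pop, params, rng)
    offspring = divide_population(pop, params, rng)

    # Offspring cull and selection composed into a single subset.
    F = population_fitness(offspring, params.f0)
    viable = np.nonzero(F >= VIABILITY_THRESHOLD)[0]
    if len(viable) == 0:
        empty = offspring.subset(viable)
        empty.generation = gen
        return empty, population_stats(empty, params.f0)
    Fv = F[viable]
    surv = viable[select_indices(Fv, params.n, params.s, rng)]
    survivors = offspring.subset(surv) if len(surv) < offspring.n_cells else offspring
    survivors.generation = gen
    record = population_stats(
        survivors, params.f0, F=F[surv], sample_identity=sample_identity
    )
    return survivors, record


def run_simulation(params: SimParams, sample_identity: int | None = 0) -> RunResult:
    """Run a full simulation: deterministic given ``(params, params.seed)``.

    ``sample_identity`` caps the number of cells used for the within-cell
    chromosome-identity statistic (0 disables it; None means all cells).
    """
    params = validate_params(params)
    rng = np.random.default_rng(params.seed)
    pop = init_population(params)
    records = [population_stats(pop, params.f0, sample_identity=sample_identity)]
    extinction = None
    first = True
    while pop.generation < params.max_generations:
        pop, rec = run_generation(
            pop, params, rng, sample_identity=sample_identity, pre_culled=not first
        )
        first = False
        records.append(rec)
        if pop.is_extinct:
            extinction = pop.generation
            break
    return RunResult(
        records=records,
        extinction_generation=extinction,
        final_population=None if pop.is_extinct else pop,
        seed=params.seed,
        params=params,
    )


def run_replicates(
    params: SimParams, n_reps: int, base_seed: int | None = None,
    burn_in: int = 50,
) -> pd.DataFrame:
    """Run ``n_reps`` independent replicates with seeds ``base_seed + i``.

    Returns one row per replicate: extinction generation (NaN if the run
    survived to the cap), generations completed, final population size and
    mean F, and time-averaged ploidy composition (monoploid fraction and
    mean ploidy averaged over generations after ``burn_in``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    rows = []
    for i in range(n_reps):
        res = run_simulation(params.replace(seed=int(base_seed) + i))
        alive = [r for r in res.records if r.n_alive > 0]
        tail = [r for r in alive if r.generation >= burn_in] or alive
        rows.append(
            {
                "seed": int(base_seed) + i,
                "extinction_generation": (
                    np.nan if res.extinction_generation is None else res.extinction_generation
                ),
                "n_generations": res.n_generations,
                "final_n_alive": res.records[-1].n_alive,
                "final_mean_f": res.records[-1].mean_f,
                "time_avg_monoploid_fraction": float(
                    np.mean([r.monoploid_fraction for r in tail])
                ),
                "time_avg_mean_ploidy": float(np.mean([r.mean_ploidy for r in tail])),
            }
        )
    return pd.DataFrame(rows)
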