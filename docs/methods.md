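# Methods

## Model

`ploidysim` simulates a finite population of unicellular organisms in
discrete, non-overlapping generations.  The unit of selection is the cell;
the unit of inheritance is the chromosome.  A cell carries `P ≥ 1`
circular chromosomes of `G` genes each, and a gene is reduced to a single
quality value `f_g ∈ [0, 1]`.  The model deliberately has no sequence,
no linkage map beyond gene adjacency on the circle, and no explicit
DNA-repair mechanics: it isolates the population-genetic consequences of
how chromosomes are copied, shuffled, exchanged and distributed.

### Fitness

Potential fitness is multiplicative across loci and fully dominant within
a locus: `F = Π_i max_j(f_g[j,i]) / f0`.  Full dominance means a single
intact copy of a gene masks any number of damaged copies — this is the
regime in which polyploidy buys mutation tolerance and accumulates hidden
recessive load.  The alternative (incomplete dominance) makes a polyploid
equivalent to a monoploid with a G·P-gene genome and is not implemented.

Viability is a hard threshold: cells with `F < 0.5` die regardless of the
competition (strictly below — `F = 0.5` exactly survives).  Survival of
viable cells is by rank in effective fitness

    F_e = (1 − S)·(F − F_min)/(F_max − F_min) + S·Rnd,

with `F_min`/`F_max` taken over the current post-cull offspring pool and
`Rnd ~ U[0,1)` drawn per cell per generation.  `S = 0` is strict
truncation selection; for `S < 0.5` the best cell always outranks the
worst, so drift cannot remove the best genotype at the cell level.  When
the pool is degenerate (`F_max = F_min`) the deterministic term is defined
as 0 and ranking is purely random; ties in `F_e` are broken by one extra
uniform draw per cell.

### Generation cycle

Fixed order, frozen for reproducibility: (1) viability cull, (2)
genetic-exchange events, (3) mutation, (4) division of every cell, (5)
offspring cull, (6) selection of the top `min(N, pool)` by `F_e`.
Mutating *parents* (after exchange, before replication) makes the
per-gene-copy mutation probability exactly `M` per generation independent
of the exchange rates and division mode.  Since survivors of step (6)
always satisfy `F ≥ 0.5`, step (1) only has an effect on a freshly
constructed (or externally modified) population; the engine skips it when
the input is the unmodified output of the previous step, which is
semantically identical.

### Mutation

Each gene copy mutates independently with probability `M`; a mutating
gene is beneficial with probability `B` (two-stage Bernoulli).  Effects
are deterministic and bounded: deleterious `f → f(1−K_d)`, beneficial
`f → 1−(1−f)(1−K_b)`; 0 and 1 are the respective fixed points, so values
never leave `[0, 1]`.  All deleterious mutations are equally deleterious
and all beneficial mutations equally beneficial.

### Genetic exchange

Five operators, all parameterized by per-chromosome per-generation rate
coefficients; each generation `round(R·C)` events fire, with `C` the
*realized* chromosome count (so per-chromosome rates stay constant while
a population dwindles).  Segments are runs of `1 + ⌊G/20⌋ + Ri(⌊G/10⌋+1)`
adjacent genes (`Ri(X)` uniform on `[0, X)`), capped at `G`, starting at
a uniform position, wrapping circularly; at `G = 100` the mean length is
11, giving the analytic per-gene conversion probability `R·11/100`.

* conversion — segment of one chromosome overwritten by the homologous
  segment of another chromosome of the same cell (asymmetric);
* crossing over — the same but swapped (symmetric);
* LGT — conversion whose donor chromosome belongs to another cell;
* exchange — two cells swap whole chromosomes;
* pairing — exchange followed by crossing over between the two
  chromosomes involved.

With `homology=true` the partner chromosome of a between-cell event is
the one sharing the most exactly-identical gene values with the first
chromosome (ties to the lowest index).  Exact equality is meaningful
because alleles arise only by copying or by identical deterministic
mutation effects; no similarity tolerance is needed.  Event schedules are
drawn in a fixed kind order (lgt, exchange, pairing, conversion,
crossing) against the phase-start state, then applied sequentially; a
within-cell event that lands on a monoploid cell is consumed without
effect.  A cell may participate in any number of events per generation,
but never partners with itself.

### Division

* constant ploidy: replicate every chromosome, shuffle the 2P copies
  uniformly, split P/P;
* mitotic: each daughter receives one replica of every chromosome
  (mitosis is mutually exclusive with ploidy changes);
* variable ploidy: with probability `D` divide without replication
  (reductional division, ⌈P/2⌉/⌊P/2⌋ split); otherwise replicate, then
  with probability `Q` split unequally — `min(P+1, P_max)` and
  `max(P−1, 1)` — else equally.

Two corners of the unequal split are undefined by the clamps and resolved
as follows: at `P = 1` the demands (2 and 1) exceed the pool of 2 copies,
so one uniformly chosen copy is duplicated; at `P = P_max` the leftover
copy is discarded (a uniformly random one, via the shuffle).  Reductional
division at `P = 1` would produce a 0-chromosome daughter; a monoploid
drawing that branch instead divides normally (ploidy cannot fall below
one).  We also examined the literal alternative — treating the empty
daughter as dead, i.e. a fecundity cost — and found it drives frequently
ploidy-cycling populations (`D = 0.5`) extinct, contradicting the
rescuing effect of frequent reductional divisions that this regime is
known for; see Limitations.

### Segregation load

For a cell of ploidy P, the exact enumerator duplicates every chromosome
and walks all `C(2P, P)` equally likely daughter genomes (replicas
distinguishable, duplicates counted with multiplicity; each unordered
daughter pair contributes both members), reporting the unviable fraction.
It is exact up to `P = 10` (184 756 daughters); beyond that a Monte-Carlo
estimator with a Clopper–Pearson 95 % interval is provided.  For the
reference triploid `1100101;1100101;0011010` the enumerator gives
4/20 = 0.2, doubling to 0.4 when a lethal allele is converted onto the
redundant chromosome — the arithmetic of why gene conversion inflates
polyploid segregation load far more easily than it relieves it.

## Default parameters

`N = 4000` cells, `G = 100` genes, `f0 = 0.99`, `M = 0.007` (so
`U_chr = 0.7` per chromosome per generation), `B = 0.01`, `K_d = 0.05`,
`K_b = 0.1`, `S = 0.3`.  This is a deliberately stressful regime — a
small local population under high mutation pressure and intense
within-population competition — in which a monoploid population reaches
mutation–selection balance and persists, while amitotic polyploids enjoy
a transient fitness advantage and then degenerate.  All experiment
configurations in the tests and the acceptance script are expressed as
deviations from this set.

## Randomness and reproducibility

One `numpy` PCG64 generator per run, seeded from `SimParams.seed`; every
stochastic step draws from it in a documented fixed order (exchange
schedule block-wise per kind; mutation mask then beneficial flags;
division branch uniforms in cell order then per-group shuffles; selection
`Rnd` then tie-breaks).  Identical `(params, seed)` reproduce a run
bit-for-bit.  Replicate runners derive seeds as `base_seed + i`; the
acceptance script spawns independent child seeds from its `--seed` via
`numpy.random.SeedSequence`.

## Problem sizes used in the tests and acceptance script

The exact and analytic quantities are instant.  For stochastic
experiments the package's own study sizes are:

* acceptance script: full `N = 4000` for the ploidy-cycle monoploid
  fraction (500 generations, burn-in 50) and the three extinction-time
  experiments (10 replicates each, capped at 1500/1200/900 generations).
* test suite: extinction-time medians at full `N = 4000` with 5
  replicates; qualitative rescue patterns (LGT, operator synergies,
  mitosis, homologous pairing) at `N = 300–500` with 3 replicates and a
  majority-of-replicates vote, justified by the rank-based selection
  regime (`S < 0.5`) making the qualitative behavior insensitive to `N`.

## What the simulations do and do not show

The generator *is* the study system: there is no external data, and every
population is initialized clonal at `f_g = f0`.  Conclusions are about
the model dynamics — masking, segregation load, chromosome-level Muller's
ratchet, and the rescuing value of exchange operators — not about any
particular organism.  Real prokaryotic genomes have variable mutation
effects, neutral sites, gene order structure, insertion-type LGT that
grows genomes, and regulated (not memoryless) ploidy cycles; none of
these are modeled.

## Numerical and design notes

* Populations are stored as one `(C, G)` float array with cells owning
  contiguous row blocks; fitness reduces per ploidy class over dense
  blocks, and division gathers daughter rows per (mode, branch, ploidy)
  group.  This keeps full-size runs at tens of milliseconds per
  generation on one CPU.
* `F` is a product of ~`G` terms near 1; with `f0 = 0.99` and `G = 100`
  double precision is ample (underflow would need thousands of lethal
  loci, at which point the cell is dead anyway).
* Extinction is an empty population after either cull or selection; the
  recorded extinction generation is the generation whose processing
  emptied the population (generation counters start at 0 for the initial
  state).
* The within-cell pairwise-identity statistic is estimated on a
  deterministic, evenly spaced subsample of at most `sample_identity`
  cells when requested; the engine skips it by default.

## Known limitations

* Replicate extinction times under this parameter regime vary by tens of
  percent between seeds of the *same* configuration (e.g. 421–687 over
  seven replicates of the `D = 0` ploidy-cycle collapse at `N = 4000`).
  Single-run reference figures should therefore be compared with the
  replicate spread, not at face value; the package reports medians with
  replicate counts for this reason.
* In the frequent-ploidy-cycle regime (`D = 0.5`) the model maintains a
  substantially *larger* standing monoploid fraction (~75 % time-averaged
  at `N = 4000`) than the 35–40 % sometimes quoted for this regime;
  the monoploid-fraction results should be read as "at least this much",
  which is also how the acceptance bound is phrased.  The fraction is
  sensitive to how reductional division is defined for monoploids (see
  Division above), a corner on which reasonable conventions differ.
* The incomplete-dominance variant and variable mutation-effect sizes are
  out of scope, as are spatial structure, resource dynamics, and modifier
  alleles for the exchange rates themselves.
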