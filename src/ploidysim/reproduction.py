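"""Cell division: amitotic constant-ploidy, variable-ploidy, and mitotic.

Every surviving cell divides exactly once per generation (binary fission).

* ``constant``: each chromosome is replicated; the 2P copies are uniformly
  shuffled and split P / P between the daughters.
* ``mitotic``: each daughter receives one replica of every parental
  chromosome (both daughters are exact copies of the parent).
* ``variable``: with probability ``d`` the cell divides *without* prior
  replication (reductional division): the P chromosomes are shuffled and
  split ceil(P/2) / floor(P/2).  Otherwise it replicates; with probability
  ``q`` the split is unequal -- one daughter receives ``min(P+1, p_max)``
  copies and the other ``max(P-1, 1)`` -- else equal P / P.

Clamping corner cases of the unequal split (the pool of 2P copies cannot
always satisfy the clamped demands):

* P = 1: demands are 2 and 1 but only 2 copies exist; one uniformly chosen
  copy is duplicated so the daughters have ploidy 2 and 1.
* P = p_max: demands are p_max and p_max - 1; the single leftover copy is
  discarded (a uniformly random one, via the shuffle).

Reductional division is undefined at P = 1 (the odd-P rule would give a
0-chromosome daughter, which is not a cell).  A monoploid that draws the
reduction branch divides as usual (replication, then equal or -- with
probability ``q`` -- unequal split): ploidy simply cannot be reduced below
one.  The alternative reading (a single surviving daughter, i.e. a
fecundity cost) makes frequent ploidy cycles lethal to the whole
population, which contradicts their observed rescuing effect.
"""

from __future__ import annotations

import numpy as np

from .core import Cell, Population, SimParams, row_indices

__all__ = [
    "divide_constant",
    "divide_mitotic",
    "divide_variable",
    "divide_population",
]


def _split_cell(genes: np.ndarray, pool_rows: np.ndarray, a: int, b: int,
                rng: np.random.Generator, tag: str) -> tuple[Cell, Cell]:
    perm = rng.permutation(len(pool_rows))
    shuffled = pool_rows[perm]
    d1 = Cell(genes[shuffled[:a]].copy(), tag)
    d2 = Cell(genes[shuffled[a : a + b]].copy(), tag)
    return d1, d2


def divide_constant(cell: Cell, rng: np.random.Generator) -> tuple[Cell, Cell]:
    """Replicate every chromosome, shuffle the 2P copies, split P / P."""
    p = cell.ploidy
    pool = np.repeat(np.arange(p), 2)
    return _split_cell(cell.genes, pool, p, p, rng, cell.lineage_tag)


def divide_mitotic(cell: Cell) -> tuple[Cell, Cell]:
    """Each daughter receives one replica of every parental chromosome."""
    return cell.copy(), cell.copy()


def divide_variable(
    cell: Cell, q: float, d: float, p_max: int, rng: np.random.Generator
) -> tuple[Cell, ...]:
    """Variable-ploidy division; returns 2 daughters, or 1 for a
    reductional division of a monoploid.  Draw order: reduction uniform,
    unequal uniform (always consumed), then shuffles/choices as needed."""
    p = cell.ploidy
    u_reduce = rng.random()
    u_unequal = rng.random()
    if u_reduce < d and p > 1:
        pool = np.arange(p)
        a, b = (p + 1) // 2, p // 2
        return _split_cell(cell.genes, pool, a, b, rng, cell.lineage_tag)
    pool = np.repeat(np.arange(p), 2)
    if u_unequal < q:
        a, b = min(p + 1, p_max), max(p - 1, 1)
        if a + b > len(pool):  # only P=1: duplicate one uniformly chosen copy
            extra = pool[int(rng.integers(len(pool)))]
            pool = np.append(pool, extra)
    else:
        a, b = p, p
    return _split_cell(cell.genes, pool, a, b, rng, cell.lineage_tag)


# ---------------------------------------------------------------------------
# Vectorized whole-population division
# ---------------------------------------------------------------------------

_MODE_CODE = {"constant": 0, "variable": 1, "mitotic": 2}
# Branch codes within variable mode.
_EQUAL, _UNEQUAL, _REDUCE = 0, 1, 2


def _group_split(
    genes: np.ndarray,
    rows: np.ndarray,  # (m, P) parent chromosome rows
    replicate: bool,
    a: int,
    b: int,
    rng: np.random.Generator,
    extend_to: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle each cell's copy pool and return daughter source rows.

    Returns ``(src, ploidies)`` where ``src`` is the flat list of parent
    rows feeding the daughters (daughter pairs adjacent, a-then-b) and
    ``ploidies`` alternates ``a, b`` per parent.
    """
    m, p = rows.shape
    pool = np.repeat(rows, 2, axis=1) if replicate else rows
    if extend_to is not None and extend_to > pool.shape[1]:
        extra_cols = extend_to - pool.shape[1]
        picks = rng.integers(pool.shape[1], size=(m, extra_cols))
        pool = np.concatenate([pool, np.take_along_axis(pool, picks, axis=1)], axis=1)
    perm = np.argsort(rng.random(pool.shape), axis=1)
    shuffled = np.take_along_axis(pool, perm, axis=1)
    src = np.concatenate([shuffled[:, :a], shuffled[:, a : a + b]], axis=1).ravel()
    ploidies = np.tile([a, b], m)
    return src, ploidies


def divide_population(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> Population:
    """Divide every cell once, returning the offspring population.

    Cells are processed in groups of identical (mode, branch, ploidy) so the
    shuffles vectorize; groups are visited in a fixed order.  Draw order:
    first the two branch uniforms for every variable-mode cell (in cell
    order), then per-group shuffle draws.
    """
    n = pop.n_cells
    if n == 0:
        return pop
    offsets = pop.offsets
    modes = np.array([_MODE_CODE[m] for m in pop.lineage_modes], dtype=np.intp)[pop.lineage]

    branch = np.zeros(n, dtype=np.intp)
    var = np.nonzero(modes == 1)[0]
    if len(var):
        u = rng.random((len(var), 2))
        pv = pop.ploidy[var]
        reduce_mask = (u[:, 0] < params.d) & (pv > 1)
        unequal_mask = ~reduce_mask & (u[:, 1] < params.q)
        branch[var[reduce_mask]] = _REDUCE
        branch[var[unequal_mask]] = _UNEQUAL

    src_parts: list[np.ndarray] = []
    ploidy_parts: list[np.ndarray] = []
    lineage_parts: list[np.ndarray] = []

    # Fixed group order: mode code, then branch, then ploidy.
    for code in (0, 1, 2):
        sel_mode = np.nonzero(modes == code)[0]
        if not len(sel_mode):
            continue
        branches = (0,) if code != 1 else (_EQUAL, _UNEQUAL, _REDUCE)
        for br in branches:
            sel_br = sel_mode[branch[sel_mode] == br] if code == 1 else sel_mode
            if not len(sel_br):
                continue
            for p in np.unique(pop.ploidy[sel_br]):
                sel = sel_br[pop.ploidy[sel_br] == p]
                p = int(p)
                rows = offsets[sel][:, None] + np.arange(p)[None, :]
                if code == 2:  # mitotic: both daughters copy the parent
                    src = np.concatenate([rows, rows], axis=1).ravel()
                    ploidies = np.tile([p, p], len(sel))
                elif code == 1 and br == _REDUCE:
                    src, ploidies = _group_split(
                        pop.genes, rows, False, (p + 1) // 2, p // 2, rng
                    )
                elif code == 1 and br == _UNEQUAL:
                    a, b = min(p + 1, params.p_max), max(p - 1, 1)
                    src, ploidies = _group_split(
                        pop.genes, rows, True, a, b, rng,
                        extend_to=a + b if a + b > 2 * p else None,
                    )
                else:  # constant mode or variable equal split
                    src, ploidies = _group_split(pop.genes, rows, True, p, p, rng)
                src_parts.append(src)
                ploidy_parts.append(ploidies)
                lineage_parts.append(np.repeat(pop.lineage[sel], 2))

    all_src = np.concatenate(src_parts)
    return Population(
        pop.genes[all_src],
        np.concatenate(ploidy_parts),
        np.concatenate(lineage_parts),
        pop.lineage_modes,
        pop.generation,
    )
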