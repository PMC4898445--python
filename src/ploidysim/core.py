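"""Domain types, parameter validation and population construction.

The model population consists of ``n`` unicellular individuals.  Each cell
carries one or more circular chromosomes (its ploidy ``P``), and each
chromosome carries ``g`` genes.  A gene is described by a single real-valued
performance quality ``f_g`` in ``[0, 1]``; initially every gene equals
``f0``.  Deleterious alleles are fully recessive: a cell's potential fitness
is computed from the best copy of every gene across its chromosomes (see
:mod:`ploidysim.fitness`).

Populations are stored column-major by cell: the chromosomes of cell ``i``
occupy a contiguous block of rows of a single ``(C, g)`` float array, which
keeps whole-population operations (mutation, fitness, division) vectorized.
:class:`Cell` is a light wrapper around one such block, used by the
fixture/oracle API and by the recombination operators' functional wrappers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLOIDY_MODES",
    "ParameterError",
    "FixtureParseError",
    "SimParams",
    "validate_params",
    "Cell",
    "Population",
    "init_population",
    "build_fixture_genome",
    "parse_fixture_file",
    "row_indices",
]

#: Recognized cell-division modes.
#:
#: * ``constant`` -- amitotic division at fixed ploidy: chromosomes are
#:   replicated and the 2P copies are randomly partitioned P/P.
#: * ``variable`` -- amitotic division with occasional unequal distribution
#:   (probability ``q``) and reductional division without replication
#:   (probability ``d``); ploidy wanders between 1 and ``p_max``.
#: * ``mitotic`` -- each daughter receives exactly one replica of every
#:   parental chromosome.
PLOIDY_MODES = ("constant", "variable", "mitotic")


class ParameterError(ValueError):
    """Raised when a simulation parameter is out of range or inconsistent."""


class FixtureParseError(ValueError):
    """Raised when a bitstring genome specification cannot be parsed."""


@dataclass(frozen=True)
class SimParams:
    """Complete parameterization of one simulation run.

    Field names follow the model's conventional symbols (lower-cased); the
    plain-text configuration format of :func:`ploidysim.io.read_config` uses
    exactly these names as keys.

    Parameters
    ----------
    n
        Maximum population size (cells); also the initial size.
    g
        Genes per chromosome.
    f0
        Initial gene quality, in ``(0, 1]``.
    m
        Per-gene per-generation mutation probability.
    b
        Fraction of mutations that are beneficial.
    k_d, k_b
        Effect coefficients of deleterious / beneficial mutations:
        ``f -> f*(1-k_d)`` and ``f -> 1-(1-f)*(1-k_b)``.
    s
        Drift weight in effective fitness (0 = strict truncation selection,
        1 = pure drift).
    ploidy_mode
        One of :data:`PLOIDY_MODES`.
    p
        Ploidy (initial ploidy in ``variable`` mode).
    p_max
        Ploidy ceiling (``variable`` mode only).
    q
        Probability of unequal chromosome distribution (``variable`` mode).
    d
        Probability of reductional division without prior replication
        (``variable`` mode).
    r_conv, r_cross, r_lgt, r_ex, r_pair
        Per-chromosome per-generation event-rate coefficients of the five
        genetic-exchange operators.
    homology
        If true, the partner chromosome in between-cell operators is the
        most similar chromosome of the partner cell rather than a random one.
    max_generations
        Run length cap.
    seed
        RNG seed; a run is fully determined by ``(params, seed)``.
    initial_composition
        Optional tuple of ``(count, mode)`` groups for mixed-population
        experiments; counts must sum to ``n``.  ``None`` means a single
        group of ``n`` cells in ``ploidy_mode``.
    """

    n: int = 4000
    g: int = 100
    f0: float = 0.99
    m: float = 0.007
    b: float = 0.01
    k_d: float = 0.05
    k_b: float = 0.1
    s: float = 0.3
    ploidy_mode: str = "constant"
    p: int = 1
    p_max: int = 6
    q: float = 0.0
    d: float = 0.0
    r_conv: float = 0.0
    r_cross: float = 0.0
    r_lgt: float = 0.0
    r_ex: float = 0.0
    r_pair: float = 0.0
    homology: bool = False
    max_generations: int = 2000
    seed: int = 0
    initial_composition: tuple[tuple[int, str], ...] | None = None

    # -- derived quantities (never stored) --------------------------------
    @property
    def u_chr(self) -> float:
        """Mutation rate per chromosome, ``m * g``."""
        return self.m * self.g

    @property
    def u_genome(self) -> float:
        """Mutation rate per (initial) polyploid genome, ``m * g * p``."""
        return self.m * self.g * self.p

    def composition(self) -> tuple[tuple[int, str], ...]:
        """The effective ``(count, mode)`` groups of the initial population."""
        if self.initial_composition is None:
            return ((self.n, self.ploidy_mode),)
        return tuple(self.initial_composition)

    def validated(self) -> "SimParams":
        return validate_params(self)

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def _check_range(name: str, value, lo, hi, lo_open=False, hi_open=False) -> None:
    bad = (
        value < lo
        or value > hi
        or (lo_open and value == lo)
        or (hi_open and value == hi)
    )
    if bad:
        lob, hib = "(" if lo_open else "[", ")" if hi_open else "]"
        raise ParameterError(f"{name}={value!r} out of {lob}{lo}, {hi}{hib}")


def validate_params(raw: SimParams) -> SimParams:
    """Validate a :class:`SimParams`, returning it unchanged if acceptable.

    Raises :class:`ParameterError` naming the offending field otherwise.
    """
    for name in ("n", "g", "p", "p_max"):
        v = getattr(raw, name)
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ParameterError(f"{name}={v!r} must be an integer >= 1")
    if not isinstance(raw.max_generations, (int, np.integer)) or raw.max_generations < 0:
        raise ParameterError(f"max_generations={raw.max_generations!r} must be an integer >= 0")
    for name in ("m", "b", "q", "d", "s"):
        _check_range(name, getattr(raw, name), 0.0, 1.0)
    for name in ("k_d", "k_b"):
        _check_range(name, getattr(raw, name), 0.0, 1.0, hi_open=True)
    _check_range("f0", raw.f0, 0.0, 1.0, lo_open=True)
    for name in ("r_conv", "r_cross", "r_lgt", "r_ex", "r_pair"):
        if getattr(raw, name) < 0:
            raise ParameterError(f"{name}={getattr(raw, name)!r} must be >= 0")
    if raw.ploidy_mode not in PLOIDY_MODES:
        raise ParameterError(
            f"ploidy_mode={raw.ploidy_mode!r} not one of {PLOIDY_MODES}"
        )

    comp = raw.composition()
    for count, mode in comp:
        if mode not in PLOIDY_MODES:
            raise ParameterError(f"initial_composition mode {mode!r} not one of {PLOIDY_MODES}")
        if not isinstance(count, (int, np.integer)) or count < 1:
            raise ParameterError(f"initial_composition count {count!r} must be an integer >= 1")
    total = sum(c for c, _ in comp)
    if total != raw.n:
        raise ParameterError(
            f"initial_composition counts sum to {total}, expected n={raw.n}"
        )

    modes = {mode for _, mode in comp}
    # Mitosis is mutually exclusive with changes of ploidy.
    if "mitotic" in modes and ("variable" in modes or raw.q > 0 or raw.d > 0):
        raise ParameterError(
            "mitotic mode is mutually exclusive with variable ploidy (q/d must be 0)"
        )
    if "variable" in modes and raw.p > raw.p_max:
        raise ParameterError(f"p={raw.p} exceeds p_max={raw.p_max} in variable mode")
    return raw


# ---------------------------------------------------------------------------
# Cells and populations
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """One individual: an ordered collection of chromosomes.

    ``genes`` has shape ``(P, g)``; row order is meaningful only as an
    identity for the exchange operators (fitness is row-order invariant).
    """

    genes: np.ndarray
    lineage_tag: str = "constant"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        if self.genes.ndim != 2 or self.genes.shape[0] < 1 or self.genes.shape[1] < 1:
            raise ValueError("cell genome must be a (P, g) array with P, g >= 1")

    @property
    def ploidy(self) -> int:
        return self.genes.shape[0]

    @property
    def n_genes(self) -> int:
        return self.genes.shape[1]

    def copy(self) -> "Cell":
        return Cell(self.genes.copy(), self.lineage_tag)


def row_indices(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Expand block starts/lengths into a flat array of row indices.

    ``row_indices([3, 10], [2, 3]) -> [3, 4, 10, 11, 12]``.
    """
    starts = np.asarray(starts, dtype=np.intp)
    counts = np.asarray(counts, dtype=np.intp)
    if len(counts) == 0:
        return np.empty(0, dtype=np.intp)
    total = int(counts.sum())
    shift = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.repeat(starts - shift, counts) + np.arange(total, dtype=np.intp)


class Population:
    """A collection of cells stored as one flat chromosome array.

    Attributes
    ----------
    genes : (C, g) float array
        All chromosomes; cell ``i`` owns rows ``offsets[i] : offsets[i] +
        ploidy[i]``.
    ploidy : (n_cells,) int array
    lineage : (n_cells,) int array
        Index of each cell's division-mode group (inherited by daughters).
    lineage_modes : tuple of str
        Division mode of each group.
    generation : int
    """

    __slots__ = ("genes", "ploidy", "lineage", "lineage_modes", "generation")

    def __init__(self, genes, ploidy, lineage, lineage_modes=("constant",), generation=0):
        self.genes = np.asarray(genes, dtype=float)
        self.ploidy = np.asarray(ploidy, dtype=np.intp)
        self.lineage = np.asarray(lineage, dtype=np.intp)
        self.lineage_modes = tuple(lineage_modes)
        self.generation = int(generation)

    # -- basic queries ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.ploidy)

    @property
    def n_chromosomes(self) -> int:
        return self.genes.shape[0]

    @property
    def n_genes(self) -> int:
        return self.genes.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.ploidy)[:-1])).astype(np.intp)

    @property
    def is_extinct(self) -> bool:
        return self.n_cells == 0

    def lineage_labels(self) -> tuple[str, ...]:
        """Human-readable label per lineage group (mode, disambiguated)."""
        out = []
        for i, mode in enumerate(self.lineage_modes):
            if sum(1 for m in self.lineage_modes if m == mode) > 1:
                out.append(f"{mode}#{list(self.lineage_modes[: i + 1]).count(mode)}")
            else:
                out.append(mode)
        return tuple(out)

    # -- views and conversions --------------------------------------------
    def cell_genes(self, i: int) -> np.ndarray:
        """Writable (P, g) view of cell ``i``'s chromosomes."""
        start = int(self.offsets[i])
        return self.genes[start : start + int(self.ploidy[i])]

    def cell(self, i: int) -> Cell:
        return Cell(self.cell_genes(i).copy(), self.lineage_labels()[self.lineage[i]])

    def cells(self):
        return [self.cell(i) for i in range(self.n_cells)]

    @classmethod
    def from_cells(cls, cells, lineage_modes=None, generation=0) -> "Population":
        cells = list(cells)
        if not cells:
            g = 1
            return cls(np.empty((0, g)), np.empty(0, int), np.empty(0, int),
                       lineage_modes or ("constant",), generation)
        tags = []
        for c in cells:
            if c.lineage_tag not in tags:
                tags.append(c.lineage_tag)
        if lineage_modes is None:
            lineage_modes = tuple(tags)
        genes = np.concatenate([c.genes for c in cells], axis=0)
        ploidy = np.array([c.ploidy for c in cells])
        lineage = np.array([tags.index(c.lineage_tag) for c in cells])
        return cls(genes, ploidy, lineage, lineage_modes, generation)

    def subset(self, cell_idx) -> "Population":
        """New population containing the given cells (genes copied)."""
        cell_idx = np.asarray(cell_idx, dtype=np.intp)
        rows = row_indices(self.offsets[cell_idx], self.ploidy[cell_idx])
        return Population(
            self.genes[rows],
            self.ploidy[cell_idx].copy(),
            self.lineage[cell_idx].copy(),
            self.lineage_modes,
            self.generation,
        )

    def copy(self) -> "Population":
        return Population(
            self.genes.copy(), self.ploidy.copy(), self.lineage.copy(),
            self.lineage_modes, self.generation,
        )


def init_population(params: SimParams) -> Population:
    """Build the clonal initial population: every gene equals ``f0``.

    Deterministic (consumes no random numbers).  Every cell starts with
    ploidy ``p``; lineage tags follow ``initial_composition``.
    """
    params = validate_params(params)
    comp = params.composition()
    genes = np.full((params.n * params.p, params.g), params.f0, dtype=float)
    ploidy = np.full(params.n, params.p, dtype=np.intp)
    lineage = np.concatenate(
        [np.full(count, i, dtype=np.intp) for i, (count, _) in enumerate(comp)]
    )
    modes = tuple(mode for _, mode in comp)
    return Population(genes, ploidy, lineage, modes, generation=0)


# ---------------------------------------------------------------------------
# Fixture genomes (bitstring specs)
# ---------------------------------------------------------------------------


def build_fixture_genome(spec: str, f0: float = 1.0, lineage_tag: str = "constant") -> Cell:
    """Parse a bitstring genome spec into a :class:`Cell`.

    ``spec`` is a semicolon-separated list of equal-length bitstrings, one
    per chromosome.  ``'1'`` maps to gene quality ``f0`` (intact), ``'0'``
    to exactly ``0.0`` (recessive lethal): any locus with no intact copy
    drives the cell's potential fitness to 0.

    >>> build_fixture_genome("1100101;1100101;0011010").ploidy
    3
    """
    parts = [s.strip() for s in spec.strip().split(";") if s.strip()]
    if not parts:
        raise FixtureParseError("empty genome spec")
    length = len(parts[0])
    rows = []
    for s in parts:
        if len(s) != length:
            raise FixtureParseError(
                f"chromosome bitstrings have unequal lengths ({len(s)} vs {length})"
            )
        if set(s) - {"0", "1"}:
            raise FixtureParseError(f"non-binary character in bitstring {s!r}")
        rows.append([f0 if ch == "1" else 0.0 for ch in s])
    return Cell(np.array(rows, dtype=float), lineage_tag)


def parse_fixture_file(text: str, f0: float = 1.0) -> list[Cell]:
    """Parse a fixture file: one cell spec per line, ``#`` comments allowed."""
    cells = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            cells.append(build_fixture_genome(line, f0=f0))
    return cells
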