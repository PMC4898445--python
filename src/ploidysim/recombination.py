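"""The five genetic-exchange operators and per-generation event scheduling.

Within-cell operators:

* **gene conversion** (rate ``r_conv``): a random segment of a recipient
  chromosome is overwritten by a copy of the homologous segment of another
  chromosome of the same cell (asymmetric).
* **crossing over** (``r_cross``): two chromosomes of one cell swap a
  segment (symmetric; conserves the cell's per-locus allele multiset).

Between-cell operators:

* **lateral gene transfer** (``r_lgt``): like conversion, but donor and
  recipient chromosomes belong to two different cells; the donor is
  unchanged.
* **chromosome exchange** (``r_ex``): two cells swap whole chromosomes.
* **exchange with crossing over** (``r_pair``): reciprocal chromosome
  exchange followed by crossing over between the two chromosomes.

Chromosomes are circular: segments wrap modulo ``g``.  A segment covers
``1 + g//20 + Ri(g//10 + 1)`` adjacent genes (``Ri(X)`` a random integer in
``[0, X)``), capped at ``g``.  With ``homology=True`` the partner
chromosome of a between-cell event is the one most similar to the first
chromosome (maximum count of exactly identical gene values) instead of a
uniform choice.

In each generation ``round(R * C)`` events of each kind occur, where ``C``
is the realized chromosome count of the population.  The whole schedule is
drawn against the phase-start population state and then applied
sequentially, in a fixed kind order (lgt, exchange, pairing, conversion,
crossing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Cell, Population, SimParams

__all__ = [
    "Segment",
    "ExchangeEvent",
    "sample_segment",
    "expected_segment_length",
    "segment_indices",
    "gene_conversion",
    "crossing_over",
    "lateral_gene_transfer",
    "chromosome_exchange",
    "exchange_with_crossing",
    "most_similar_chromosome",
    "schedule_events",
    "apply_event",
    "run_exchange_phase",
]

#: Fixed application order of event kinds within one generation.
KIND_ORDER = ("lgt", "exchange", "pairing", "conversion", "crossing")


@dataclass(frozen=True)
class Segment:
    """A run of adjacent genes on a circular chromosome (wraps modulo g)."""

    start: int
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("segment length must be >= 1")

    def indices(self, g: int) -> np.ndarray:
        """Gene indices covered by the segment on a chromosome of g genes."""
        return (self.start + np.arange(min(self.length, g))) % g


@dataclass(frozen=True)
class ExchangeEvent:
    """One scheduled genetic-exchange event.

    ``cell_b``/``chr_b`` are ``None`` for within-cell kinds; ``segment`` is
    ``None`` for whole-chromosome exchange.
    """

    kind: str
    cell_a: int
    chr_a: int
    cell_b: int | None = None
    chr_b: int | None = None
    segment: Segment | None = None


def segment_length_bounds(g: int) -> tuple[int, int]:
    """Inclusive (min, max) segment length for a chromosome of g genes."""
    base = 1 + g // 20
    return min(base, g), min(base + g // 10, g)


def expected_segment_length(g: int) -> float:
    """Mean segment length: ``1 + g//20 + (g//10)/2`` (capped lengths ignored)."""
    return 1 + g // 20 + (g // 10) / 2.0


def sample_segment(g: int, rng: np.random.Generator) -> Segment:
    """Draw a segment: uniform start, length ``1 + g//20 + Ri(g//10 + 1)``.

    Draw order: start first, then the length increment.  Length is capped
    at ``g`` (relevant only for very short chromosomes).
    """
    start = int(rng.integers(g))
    length = 1 + g // 20 + int(rng.integers(g // 10 + 1))
    return Segment(start, min(length, g))


# ---------------------------------------------------------------------------
# In-place array primitives (operate on (P, g) genome views)
# ---------------------------------------------------------------------------


def _convert(genome: np.ndarray, donor: int, recipient: int, seg: Segment) -> None:
    idx = seg.indices(genome.shape[1])
    genome[recipient, idx] = genome[donor, idx]


def _cross(genome_a: np.ndarray, i: int, genome_b: np.ndarray, j: int, seg: Segment) -> None:
    idx = seg.indices(genome_a.shape[1])
    tmp = genome_a[i, idx].copy()
    genome_a[i, idx] = genome_b[j, idx]
    genome_b[j, idx] = tmp


def _swap_rows(genome_a: np.ndarray, i: int, genome_b: np.ndarray, j: int) -> None:
    tmp = genome_a[i].copy()
    genome_a[i] = genome_b[j]
    genome_b[j] = tmp


# ---------------------------------------------------------------------------
# Functional Cell-level operators (copy-on-write; used by tests and oracles)
# ---------------------------------------------------------------------------


def _check_pair(n: int, i: int, j: int) -> None:
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"chromosome index out of range (ploidy {n})")
    if i == j:
        raise ValueError("the two chromosome indices must be distinct")


def gene_conversion(cell: Cell, donor_idx: int, recipient_idx: int, seg: Segment) -> Cell:
    """Overwrite the recipient's segment with a copy of the donor's."""
    _check_pair(cell.ploidy, donor_idx, recipient_idx)
    out = cell.copy()
    _convert(out.genes, donor_idx, recipient_idx, seg)
    return out


def crossing_over(cell: Cell, idx_a: int, idx_b: int, seg: Segment) -> Cell:
    """Swap a segment between two chromosomes of one cell."""
    _check_pair(cell.ploidy, idx_a, idx_b)
    out = cell.copy()
    _cross(out.genes, idx_a, out.genes, idx_b, seg)
    return out


def lateral_gene_transfer(
    recipient_cell: Cell, donor_cell: Cell, recipient_chr: int, donor_chr: int, seg: Segment
) -> Cell:
    """Overwrite a segment of the recipient cell's chromosome with the
    homologous segment of a chromosome of the donor cell (donor unchanged)."""
    if not 0 <= recipient_chr < recipient_cell.ploidy:
        raise IndexError("recipient chromosome index out of range")
    if not 0 <= donor_chr < donor_cell.ploidy:
        raise IndexError("donor chromosome index out of range")
    out = recipient_cell.copy()
    idx = seg.indices(out.n_genes)
    out.genes[recipient_chr, idx] = donor_cell.genes[donor_chr, idx]
    return out


def chromosome_exchange(cell_a: Cell, cell_b: Cell, idx_a: int, idx_b: int) -> tuple[Cell, Cell]:
    """Two cells swap whole chromosomes; ploidies unchanged."""
    if not 0 <= idx_a < cell_a.ploidy or not 0 <= idx_b < cell_b.ploidy:
        raise IndexError("chromosome index out of range")
    out_a, out_b = cell_a.copy(), cell_b.copy()
    _swap_rows(out_a.genes, idx_a, out_b.genes, idx_b)
    return out_a, out_b


def exchange_with_crossing(
    cell_a: Cell, cell_b: Cell, idx_a: int, idx_b: int, seg: Segment
) -> tuple[Cell, Cell]:
    """Reciprocal chromosome exchange followed by crossing over between the
    two participating chromosomes: each cell ends with a recombinant."""
    if not 0 <= idx_a < cell_a.ploidy or not 0 <= idx_b < cell_b.ploidy:
        raise IndexError("chromosome index out of range")
    out_a, out_b = cell_a.copy(), cell_b.copy()
    _swap_rows(out_a.genes, idx_a, out_b.genes, idx_b)
    _cross(out_a.genes, idx_a, out_b.genes, idx_b, seg)
    return out_a, out_b


def most_similar_chromosome(query: np.ndarray, genome: Cell | np.ndarray) -> int:
    """Index of the chromosome with the maximum count of exactly identical
    gene values; ties broken by lowest index."""
    genes = genome.genes if isinstance(genome, Cell) else np.asarray(genome)
    if genes.shape[0] == 0:
        raise ValueError("genome is empty")
    matches = (genes == np.asarray(query)).sum(axis=1)
    return int(np.argmax(matches))


# ---------------------------------------------------------------------------
# Per-generation scheduling
# ---------------------------------------------------------------------------


def _event_count(rate: float, n_chromosomes: int) -> int:
    return int(np.floor(rate * n_chromosomes + 0.5))


def _distinct_pair(rng: np.random.Generator, n: int) -> tuple[int, int]:
    a = int(rng.integers(n))
    b = int(rng.integers(n - 1))
    if b >= a:
        b += 1
    return a, b


def schedule_events(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> list[ExchangeEvent]:
    """Draw the full exchange schedule for one generation.

    For each kind with rate R > 0, ``round(R * C)`` events are drawn (C =
    realized chromosome count).  Kinds are drawn in :data:`KIND_ORDER`;
    within each kind the draws are block-wise: cells first, then
    chromosomes, then segment starts and lengths, each as one vector over
    the kind's events.  A within-cell event that lands on a monoploid cell
    is consumed without effect and omitted from the schedule; between-cell
    kinds require at least two cells.  With ``homology=True`` the partner
    chromosome of a between-cell event is resolved by similarity against
    the current state (no chromosome draw is consumed for the partner).
    """
    C = pop.n_chromosomes
    n = pop.n_cells
    g = pop.n_genes
    ploidy = pop.ploidy
    offsets = pop.offsets
    genes = pop.genes
    events: list[ExchangeEvent] = []
    rates = {
        "lgt": params.r_lgt,
        "exchange": params.r_ex,
        "pairing": params.r_pair,
        "conversion": params.r_conv,
        "crossing": params.r_cross,
    }
    seg_extra = g // 10 + 1
    seg_base = 1 + g // 20
    for kind in KIND_ORDER:
        k = _event_count(rates[kind], C)
        if k == 0:
            continue
        if kind in ("lgt", "exchange", "pairing"):
            if n < 2:
                continue
            cells_a = rng.integers(n, size=k)
            cells_b = rng.integers(n - 1, size=k)
            cells_b += cells_b >= cells_a
            chrs_a = (rng.random(k) * ploidy[cells_a]).astype(np.intp)
            if not params.homology:
                chrs_b = (rng.random(k) * ploidy[cells_b]).astype(np.intp)
            if kind != "exchange":
                starts = rng.integers(g, size=k)
                lengths = seg_base + rng.integers(seg_extra, size=k)
            for e in range(k):
                a, b, ca = int(cells_a[e]), int(cells_b[e]), int(chrs_a[e])
                if params.homology:
                    ob = offsets[b]
                    block = genes[ob : ob + ploidy[b]]
                    cb = int(
                        np.argmax((block == genes[offsets[a] + ca]).sum(axis=1))
                    )
                else:
                    cb = int(chrs_b[e])
                seg = (
                    None
                    if kind == "exchange"
                    else Segment(int(starts[e]), min(int(lengths[e]), g))
                )
                events.append(ExchangeEvent(kind, a, ca, b, cb, seg))
        else:
            cells_a = rng.integers(n, size=k)
            p_a = ploidy[cells_a]
            chrs_i = (rng.random(k) * p_a).astype(np.intp)
            chrs_j = (rng.random(k) * (p_a - 1)).astype(np.intp)
            chrs_j += chrs_j >= chrs_i
            starts = rng.integers(g, size=k)
            lengths = seg_base + rng.integers(seg_extra, size=k)
            for e in range(k):
                if p_a[e] < 2:
                    continue  # event consumed, no second chromosome
                seg = Segment(int(starts[e]), min(int(lengths[e]), g))
                events.append(
                    ExchangeEvent(kind, int(cells_a[e]), int(chrs_i[e]), None,
                                  int(chrs_j[e]), seg)
                )
    return events


def _apply_event_rows(genes: np.ndarray, offsets: np.ndarray, g: int,
                      ev: ExchangeEvent) -> None:
    row_a = offsets[ev.cell_a] + ev.chr_a
    if ev.kind == "conversion":
        # chr_a is the recipient ("a length of a randomly chosen chromosome
        # is replaced"), chr_b the donor.
        idx = ev.segment.indices(g)
        genes[row_a, idx] = genes[offsets[ev.cell_a] + ev.chr_b, idx]
    elif ev.kind == "crossing":
        row_b = offsets[ev.cell_a] + ev.chr_b
        idx = ev.segment.indices(g)
        tmp = genes[row_a, idx].copy()
        genes[row_a, idx] = genes[row_b, idx]
        genes[row_b, idx] = tmp
    elif ev.kind == "lgt":
        idx = ev.segment.indices(g)
        genes[row_a, idx] = genes[offsets[ev.cell_b] + ev.chr_b, idx]
    elif ev.kind == "exchange":
        row_b = offsets[ev.cell_b] + ev.chr_b
        tmp = genes[row_a].copy()
        genes[row_a] = genes[row_b]
        genes[row_b] = tmp
    elif ev.kind == "pairing":
        row_b = offsets[ev.cell_b] + ev.chr_b
        tmp = genes[row_a].copy()
        genes[row_a] = genes[row_b]
        genes[row_b] = tmp
        idx = ev.segment.indices(g)
        tmp = genes[row_a, idx].copy()
        genes[row_a, idx] = genes[row_b, idx]
        genes[row_b, idx] = tmp
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {ev.kind!r}")


def apply_event(pop: Population, ev: ExchangeEvent) -> None:
    """Apply one event in place on the population's flat genome array."""
    _apply_event_rows(pop.genes, pop.offsets, pop.n_genes, ev)


def run_exchange_phase(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Draw and apply one generation's worth of exchange events in place."""
    if (
        params.r_conv == 0
        and params.r_cross == 0
        and params.r_lgt == 0
        and params.r_ex == 0
        and params.r_pair == 0
    ):
        return pop
    offsets = pop.offsets  # ploidies never change during the exchange phase
    g = pop.n_genes
    genes = pop.genes
    for ev in schedule_events(pop, params, rng):
        _apply_event_rows(genes, offsets, g, ev)
    return pop
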