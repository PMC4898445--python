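import numpy as np
import pytest

from ploidysim import (
    Cell,
    Population,
    Segment,
    SimParams,
    build_fixture_genome,
    chromosome_exchange,
    crossing_over,
    exchange_with_crossing,
    gene_conversion,
    init_population,
    lateral_gene_transfer,
    most_similar_chromosome,
    potential_fitness,
    sample_segment,
    schedule_events,
    segregation_load,
)
from ploidysim.recombination import (
    apply_event,
    expected_segment_length,
    run_exchange_phase,
    segment_length_bounds,
)


class TestSegments:
    def test_lengths_g100(self, rng):
        lengths = {sample_segment(100, rng).length for _ in range(2000)}
        assert lengths == set(range(6, 17))

    def test_lengths_g20(self, rng):
        # 1 + 20//20 + Ri(20//10 + 1) = 2 + Ri(3)
        lengths = {sample_segment(20, rng).length for _ in range(500)}
        assert lengths == {2, 3, 4}

    def test_expected_length_g100(self):
        assert expected_segment_length(100) == pytest.approx(11.0)

    def test_bounds(self):
        assert segment_length_bounds(100) == (6, 16)
        assert segment_length_bounds(20) == (2, 4)

    def test_wraps_circularly(self):
        seg = Segment(start=5, length=4)
        assert seg.indices(7).tolist() == [5, 6, 0, 1]

    def test_starts_cover_chromosome(self, rng):
        starts = {sample_segment(10, rng).start for _ in range(500)}
        assert starts == set(range(10))


class TestGeneConversion:
    def test_identical_chromosomes_noop(self, rng):
        cell = Cell(np.tile(rng.random(8), (3, 1)))
        out = gene_conversion(cell, 0, 1, Segment(2, 3))
        assert np.array_equal(out.genes, cell.genes)

    def test_worked_example_doubles_segregation_load(self, triploid):
        """Copying the lethal allele at locus 5 from chromosome 3 onto
        chromosome 2 makes it 1100001 and doubles the load to 0.4."""
        out = gene_conversion(triploid, donor_idx=2, recipient_idx=1, seg=Segment(4, 1))
        assert out.genes[1].tolist() == [1, 1, 0, 0, 0, 0, 1]
        assert segregation_load(triploid) == pytest.approx(0.2)
        assert segregation_load(out) == pytest.approx(0.4)

    def test_full_segment_copies_whole_chromosome(self, rng):
        cell = Cell(rng.random((2, 6)))
        out = gene_conversion(cell, 0, 1, Segment(3, 6))
        assert np.array_equal(out.genes[1], out.genes[0])

    def test_donor_unchanged_and_asymmetric(self, rng):
        cell = Cell(rng.random((2, 10)))
        out = gene_conversion(cell, 0, 1, Segment(0, 4))
        assert np.array_equal(out.genes[0], cell.genes[0])

    def test_same_index_rejected(self, triploid):
        with pytest.raises(ValueError):
            gene_conversion(triploid, 1, 1, Segment(0, 2))


class TestCrossingOver:
    def test_involution(self, rng):
        cell = Cell(rng.random((4, 10)))
        seg = Segment(7, 5)
        twice = crossing_over(crossing_over(cell, 1, 3, seg), 1, 3, seg)
        assert np.array_equal(twice.genes, cell.genes)

    def test_conserves_per_locus_multiset(self, rng):
        cell = Cell(rng.random((3, 10)))
        out = crossing_over(cell, 0, 2, Segment(8, 4))
        for locus in range(10):
            assert sorted(out.genes[:, locus]) == pytest.approx(
                sorted(cell.genes[:, locus])
            )

    def test_potential_fitness_invariant(self, rng):
        for _ in range(10):
            cell = Cell(rng.random((3, 12)))
            seg = sample_segment(12, rng)
            out = crossing_over(cell, 0, 1, seg)
            assert potential_fitness(out) == pytest.approx(potential_fitness(cell))


class TestBetweenCellOperators:
    def test_lgt_repairs_lethal_locus(self):
        rec = build_fixture_genome("1101")
        don = build_fixture_genome("1111")
        out = lateral_gene_transfer(rec, don, 0, 0, Segment(2, 1))
        assert out.genes[0].tolist() == [1, 1, 1, 1]
        assert don.genes[0].tolist() == [1, 1, 1, 1]

    def test_lgt_donor_bitwise_unchanged(self, rng):
        rec, don = Cell(rng.random((2, 10))), Cell(rng.random((3, 10)))
        before = don.genes.copy()
        lateral_gene_transfer(rec, don, 1, 2, Segment(5, 6))
        assert np.array_equal(don.genes, before)

    def test_exchange_swap_then_swap_back(self, rng):
        a, b = Cell(rng.random((2, 8))), Cell(rng.random((3, 8)))
        a2, b2 = chromosome_exchange(a, b, 1, 0)
        a3, b3 = chromosome_exchange(a2, b2, 1, 0)
        assert np.array_equal(a3.genes, a.genes)
        assert np.array_equal(b3.genes, b.genes)

    def test_exchange_conserves_chromosomes(self, rng):
        a, b = Cell(rng.random((2, 8))), Cell(rng.random((3, 8)))
        a2, b2 = chromosome_exchange(a, b, 0, 2)
        assert a2.ploidy == 2 and b2.ploidy == 3
        pool_before = np.vstack([a.genes, b.genes])
        pool_after = np.vstack([a2.genes, b2.genes])
        assert sorted(map(tuple, pool_before)) == sorted(map(tuple, pool_after))

    def test_pairing_identical_chromosomes_noop(self, rng):
        shared = rng.random(8)
        a, b = Cell(np.vstack([shared, rng.random(8)])), Cell(shared[None, :].copy())
        a2, b2 = exchange_with_crossing(a, b, 0, 0, Segment(1, 3))
        assert np.array_equal(a2.genes, a.genes)
        assert np.array_equal(b2.genes, b.genes)

    def test_pairing_full_segment_is_identity(self, rng):
        """Swapping chromosomes and then swapping the full-length segment
        returns each chromosome to its original cell."""
        a, b = Cell(rng.random((2, 6))), Cell(rng.random((2, 6)))
        a2, b2 = exchange_with_crossing(a, b, 1, 0, Segment(4, 6))
        assert np.array_equal(a2.genes, a.genes)
        assert np.array_equal(b2.genes, b.genes)

    def test_pairing_conserves_two_cell_multiset(self, rng):
        a, b = Cell(rng.random((3, 9))), Cell(rng.random((2, 9)))
        a2, b2 = exchange_with_crossing(a, b, 2, 1, Segment(7, 4))
        for locus in range(9):
            before = sorted(np.concatenate([a.genes[:, locus], b.genes[:, locus]]))
            after = sorted(np.concatenate([a2.genes[:, locus], b2.genes[:, locus]]))
            assert before == pytest.approx(after)


class TestMostSimilar:
    def test_exact_copy_wins(self, rng):
        genome = Cell(rng.random((4, 10)))
        q = genome.genes[2].copy()
        assert most_similar_chromosome(q, genome) == 2

    def test_worked_bitstrings(self):
        genome = build_fixture_genome("0011010;1100101")
        q = build_fixture_genome("1100101").genes[0]
        assert most_similar_chromosome(q, genome) == 1

    def test_tie_breaks_to_lowest_index(self):
        genome = Cell(np.zeros((3, 5)))
        assert most_similar_chromosome(np.ones(5), genome) == 0


class TestScheduling:
    def _pop(self, n, p, g=20):
        return init_population(SimParams(n=n, p=p, g=g))

    def test_event_count_rounds_rate_times_chromosomes(self, rng):
        pop = self._pop(40, 2)
        params = SimParams(n=40, p=2, g=20, r_conv=0.1)
        events = schedule_events(pop, params, rng)
        assert len(events) == round(0.1 * 80)
        assert all(e.kind == "conversion" for e in events)

    def test_all_rates_zero_empty_schedule(self, rng):
        events = schedule_events(self._pop(10, 2), SimParams(n=10, p=2, g=20), rng)
        assert events == []

    def test_monoploid_within_cell_events_consumed(self, rng):
        pop = self._pop(10, 1)
        params = SimParams(n=10, p=1, g=20, r_conv=1.0)
        assert schedule_events(pop, params, rng) == []

    def test_homology_changes_partner_not_counts(self):
        pop = self._pop(20, 3)
        base = dict(n=20, p=3, g=20, r_lgt=0.5, r_ex=0.2)
        n_hom = len(schedule_events(pop, SimParams(**base, homology=True),
                                    np.random.default_rng(0)))
        n_rand = len(schedule_events(pop, SimParams(**base, homology=False),
                                     np.random.default_rng(0)))
        assert n_hom == n_rand == round(0.5 * 60) + round(0.2 * 60)

    def test_between_cell_events_use_distinct_cells(self, rng):
        pop = self._pop(5, 2)
        params = SimParams(n=5, p=2, g=20, r_ex=2.0, r_lgt=1.0, r_pair=1.0)
        for ev in schedule_events(pop, params, rng):
            assert ev.cell_a != ev.cell_b

    def test_no_operator_changes_ploidy(self, rng):
        params = SimParams(
            n=30, p=3, g=20, r_conv=0.5, r_cross=0.5, r_lgt=0.5, r_ex=0.5, r_pair=0.5
        )
        pop = init_population(params)
        # make genomes distinct so swaps are observable
        pop.genes[:] = rng.random(pop.genes.shape)
        before = pop.ploidy.copy()
        run_exchange_phase(pop, params, rng)
        assert np.array_equal(pop.ploidy, before)

    def test_symmetric_operators_conserve_global_multiset(self, rng):
        params = SimParams(n=20, p=3, g=10, r_cross=1.0, r_ex=1.0, r_pair=1.0)
        pop = init_population(params)
        pop.genes[:] = rng.random(pop.genes.shape)
        before = np.sort(pop.genes, axis=None).copy()
        run_exchange_phase(pop, params, rng)
        assert np.allclose(np.sort(pop.genes, axis=None), before)

    def test_conversion_and_lgt_conserve_gene_count_only(self, rng):
        params = SimParams(n=20, p=3, g=10, r_conv=1.0, r_lgt=1.0)
        pop = init_population(params)
        pop.genes[:] = rng.random(pop.genes.shape)
        shape = pop.genes.shape
        run_exchange_phase(pop, params, rng)
        assert pop.genes.shape == shape

    def test_measured_conversion_probability(self, rng):
        """Empirical per-gene overwrite frequency in a neutral setting
        matches R_conv * E[len]/G."""
        g = 100
        params = SimParams(n=200, p=2, g=g, r_conv=0.1)
        pop = init_population(params)
        # distinct values per chromosome so an overwrite is detectable
        pop.genes[:] = np.arange(pop.n_chromosomes)[:, None] + np.arange(g) / g
        overwritten = 0
        gens = 30
        total = gens * pop.genes.size
        for _ in range(gens):
            before = pop.genes.copy()
            for ev in schedule_events(pop, params, rng):
                apply_event(pop, ev)
            overwritten += int((pop.genes != before).sum())
            pop.genes[:] = np.arange(pop.n_chromosomes)[:, None] + np.arange(g) / g
        expected = 0.1 * expected_segment_length(g) / g
        rate = overwritten / total
        assert rate == pytest.approx(expected, rel=0.15)
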