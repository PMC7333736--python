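"""Binarisation, the memetic operators, and planted-bicluster recovery."""

import numpy as np
import pandas as pd
import pytest

from dyncomplex import biclustering as bc
from dyncomplex.aggregation import jaccard


def matrix(rows, proteins=None, timepoints=None):
    rows = np.asarray(rows, dtype=float)
    m, n = rows.shape
    return pd.DataFrame(
        rows,
        index=proteins or [f"P{i}" for i in range(m)],
        columns=timepoints or [f"T{j}" for j in range(n)],
    )


def chromosome(protein_bits, time_bits):
    bits = np.concatenate([np.asarray(protein_bits, bool), np.asarray(time_bits, bool)])
    return bc.Chromosome(bits=bits, m=len(protein_bits))


class TestBinarize:
    def test_row_1_2_3_at_zero_epsilon(self):
        nge = bc.binarize(matrix([[1, 2, 3]]), epsilon=0.0)
        assert nge.nge.tolist() == [[0, 1, 1]]  # threshold |μ| = 2

    def test_constant_nonnegative_row_all_active(self):
        nge = bc.binarize(matrix([[2.5, 2.5, 2.5]]), epsilon=0.8)
        assert nge.nge.tolist() == [[1, 1, 1]]  # σ=0 → threshold |c|, ties active

    def test_hand_computed_row(self):
        # μ=0.5, σ=0.4, threshold |0.5−0.4·0.6|=0.26
        nge = bc.binarize(matrix([[0.1, 0.9, 0.9, 0.1]]), epsilon=0.6)
        assert nge.nge.tolist() == [[0, 1, 1, 0]]
        assert nge.sigma[0] == pytest.approx(0.4)

    def test_population_sd_used(self):
        nge = bc.binarize(matrix([[1.0, 3.0]]), epsilon=1.0)
        assert nge.sigma[0] == pytest.approx(1.0)  # ddof=0, not 2/√2

    def test_rows_independent(self):
        a = bc.binarize(matrix([[0.1, 0.9, 0.5, 0.3]]), 0.6).nge
        b = bc.binarize(matrix([[0.1, 0.9, 0.5, 0.3], [9, 1, 4, 4]]), 0.6).nge
        assert (b[0] == a[0]).all()

    def test_per_row_prescaling_is_noop(self, bundle):
        plain = bc.binarize(bundle.ge, 0.6).nge
        scaled = bc.binarize(bundle.ge, 0.6, prescale=True).nge
        assert (plain == scaled).all()

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            bc.binarize(matrix([[1.0]]), -0.1)


class TestFitness:
    def test_all_active_block_is_one(self):
        nge = bc.binarize(matrix([[1, 1], [1, 1]]), 0.0)
        assert bc.fitness(chromosome([1, 1], [1, 1]), nge) == 1.0

    def test_empty_selection_is_zero(self):
        nge = bc.binarize(matrix([[1, 1], [1, 1]]), 0.0)
        assert bc.fitness(chromosome([0, 0], [1, 1]), nge) == 0.0
        assert bc.fitness(chromosome([1, 1], [0, 0]), nge) == 0.0

    def test_three_quarters(self):
        nge = bc.BinaryActivityMatrix(
            nge=np.array([[1, 1], [1, 0]], dtype=np.uint8),
            mu=np.zeros(2), sigma=np.zeros(2), epsilon=0.0,
            proteins=["P0", "P1"], timepoints=["T0", "T1"],
        )
        assert bc.fitness(chromosome([1, 1], [1, 1]), nge) == 0.75

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        raw = (rng.random((12, 7)) < 0.4).astype(np.uint8)
        nge = bc.BinaryActivityMatrix(
            nge=raw, mu=np.zeros(12), sigma=np.zeros(12), epsilon=0.0,
            proteins=[f"P{i}" for i in range(12)], timepoints=[f"T{j}" for j in range(7)],
        )
        for _ in range(1000):
            bits = rng.random(19) < 0.5
            chrom = bc.Chromosome(bits=bits, m=12)
            I = np.flatnonzero(bits[:12])
            J = np.flatnonzero(bits[12:])
            expected = 0.0
            if I.size and J.size:
                count = sum(int(raw[i, j] == 1) for i in I for j in J)
                expected = count / (I.size * J.size)
            assert bc.fitness(chrom, nge) == pytest.approx(expected)


class TestTournament:
    def _population(self, fitnesses):
        pop = []
        for f in fitnesses:
            c = chromosome([1, 0], [1])
            c.fitness = f
            pop.append(c)
        return pop

    def test_fitter_contestant_wins(self):
        pop = self._population([0.9, 0.1])
        rng = np.random.default_rng(0)
        for _ in range(20):
            p1, p2 = bc.tournament_select(pop, rng)
            assert p1.fitness == 0.9 and p2.fitness == 0.9

    def test_uniform_marginal_under_equal_fitness(self):
        from scipy.stats import chisquare

        pop = self._population([0.5] * 8)
        rng = np.random.default_rng(1)
        counts = np.zeros(8)
        for _ in range(5000):
            p1, p2 = bc.tournament_select(pop, rng)
            counts[pop.index(p1)] += 1
            counts[pop.index(p2)] += 1
        assert chisquare(counts).pvalue > 1e-3

    def test_population_too_small(self):
        with pytest.raises(ValueError):
            bc.tournament_select(self._population([0.5]), np.random.default_rng(0))


class TestCrossover:
    def test_time_part_never_crossed(self):
        rng = np.random.default_rng(2)
        a = chromosome([1, 0, 1, 0, 1], [1, 0, 1])
        b = chromosome([0, 1, 0, 1, 0], [0, 1, 0])
        for _ in range(50):
            c1, c2 = bc.two_point_crossover(a, b, rng)
            assert (c1.time_part == a.time_part).all()
            assert (c2.time_part == b.time_part).all()

    def test_identical_parents_yield_identical_children(self):
        rng = np.random.default_rng(3)
        a = chromosome([1, 0, 1, 1], [0, 1])
        c1, c2 = bc.two_point_crossover(a, a.copy(), rng)
        assert (c1.bits == a.bits).all() and (c2.bits == a.bits).all()

    def test_protein_bit_multiset_conserved(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            pa = rng.random(20) < 0.5
            pb = rng.random(20) < 0.5
            a = chromosome(pa, [1, 0])
            b = chromosome(pb, [0, 1])
            c1, c2 = bc.two_point_crossover(a, b, rng)
            assert (
                c1.protein_part.sum() + c2.protein_part.sum()
                == pa.sum() + pb.sum()
            )
            assert ((c1.protein_part | c2.protein_part) == (pa | pb)).all()

    def test_no_crossover_probability_zero_clones(self):
        rng = np.random.default_rng(5)
        a = chromosome([1, 1, 0, 0], [1])
        b = chromosome([0, 0, 1, 1], [0])
        c1, c2 = bc.two_point_crossover(a, b, rng, p_crossover=0.0)
        assert (c1.bits == a.bits).all() and (c2.bits == b.bits).all()


class TestMutate:
    def test_zero_probability_is_identity(self):
        rng = np.random.default_rng(6)
        a = chromosome([1, 0, 1], [0, 1])
        out = bc.mutate(a, rng, p_protein=0.0, p_time=0.0)
        assert (out.bits == a.bits).all()

    def test_unit_probability_is_complement(self):
        rng = np.random.default_rng(7)
        a = chromosome([1, 0, 1], [0, 1])
        out = bc.mutate(a, rng, p_protein=1.0, p_time=1.0)
        assert (out.bits == ~a.bits).all()

    def test_empirical_flip_rates_within_3_sigma(self):
        rng = np.random.default_rng(8)
        m, n, reps = 1000, 100, 100
        a = bc.Chromosome(bits=np.zeros(m + n, bool), m=m)
        p_flips = t_flips = 0
        for _ in range(reps):
            out = bc.mutate(a, rng, p_protein=0.001, p_time=0.1)
            p_flips += out.protein_part.sum()
            t_flips += out.time_part.sum()
        for flips, p, total in ((p_flips, 0.001, m * reps), (t_flips, 0.1, n * reps)):
            sigma = np.sqrt(total * p * (1 - p))
            assert abs(flips - total * p) < 3 * sigma


class TestLocalSearch:
    def _nge(self, raw):
        raw = np.asarray(raw, dtype=np.uint8)
        return bc.BinaryActivityMatrix(
            nge=raw, mu=np.zeros(raw.shape[0]), sigma=np.zeros(raw.shape[0]),
            epsilon=0.0, proteins=[f"P{i}" for i in range(raw.shape[0])],
            timepoints=[f"T{j}" for j in range(raw.shape[1])],
        )

    def test_perfect_chromosome_unchanged(self):
        nge = self._nge(np.ones((4, 3)))
        chrom = chromosome([1, 1, 1, 1], [1, 1, 1])
        chrom.fitness = bc.fitness(chrom, nge)
        out = bc.local_search(chrom, nge, np.random.default_rng(0), p_bit=1.0)
        assert (out.bits == chrom.bits).all() and out.fitness == 1.0

    def test_inactive_protein_cleared_when_always_tested(self):
        raw = np.ones((4, 3), dtype=np.uint8)
        raw[3] = 0  # one fully inactive protein selected
        nge = self._nge(raw)
        chrom = chromosome([1, 1, 1, 1], [1, 1, 1])
        out = bc.local_search(chrom, nge, np.random.default_rng(0), p_bit=1.0)
        assert not out.protein_part[3]
        assert out.fitness == 1.0

    def test_never_decreases_fitness(self):
        rng = np.random.default_rng(9)
        raw = (rng.random((30, 8)) < 0.5).astype(np.uint8)
        nge = self._nge(raw)
        for _ in range(1000):
            bits = rng.random(38) < 0.5
            chrom = bc.Chromosome(bits=bits, m=30)
            before = bc.fitness(chrom, nge)
            out = bc.local_search(chrom, nge, rng)
            assert out.fitness >= before - 1e-12
            assert out.fitness == pytest.approx(bc.fitness(out, nge))


class TestRunMemetic:
    def test_population_size_invariant_and_best_monotone(self):
        """Steady-state bookkeeping: +2 children, −2 worst, elitist best."""
        rng = np.random.default_rng(10)
        raw = (rng.random((40, 8)) < 0.4).astype(np.uint8)
        nge = bc.BinaryActivityMatrix(
            nge=raw, mu=np.zeros(40), sigma=np.zeros(40), epsilon=0.0,
            proteins=[f"P{i}" for i in range(40)], timepoints=[f"T{j}" for j in range(8)],
        )
        pop = [bc.Chromosome(bits=rng.random(48) < 0.5, m=40) for _ in range(20)]
        for c in pop:
            c.fitness = bc.fitness(c, nge)
        best_trace = []
        for _ in range(150):
            p1, p2 = bc.tournament_select(pop, rng)
            c1, c2 = bc.two_point_crossover(p1, p2, rng)
            children = [bc.mutate(c, rng) for c in (c1, c2)]
            for c in children:
                c.fitness = bc.fitness(c, nge)
            children = [bc.local_search(c, nge, rng) for c in children]
            pop.extend(children)
            pop.sort(key=bc._rank_key, reverse=True)
            del pop[-2:]
            assert len(pop) == 20
            best_trace.append(pop[0].fitness)
        assert all(b >= a for a, b in zip(best_trace, best_trace[1:]))

    def test_deterministic_given_seed(self, bundle):
        nge = bc.binarize(bundle.ge, 0.6)
        config = bc.MemeticConfig(
            population_size=30, max_iterations=150, n_biclusters=3,
            restarts_per_bicluster=1, rng_seed=5,
        )
        r1 = bc.run_memetic(nge, config)
        r2 = bc.run_memetic(nge, config)
        assert [(b.proteins, b.timepoints, b.fitness) for b in r1] == [
            (b.proteins, b.timepoints, b.fitness) for b in r2
        ]

    def test_returns_sorted_distinct_nondegenerate(self, memetic_result):
        fits = [b.fitness for b in memetic_result]
        assert all(b >= a for a, b in zip(fits[1:], fits))  # descending
        assert all(b.proteins and b.timepoints for b in memetic_result)
        keys = [(frozenset(b.proteins), frozenset(b.timepoints)) for b in memetic_result]
        assert len(keys) == len(set(keys))

    def test_recovers_planted_blocks(self, bundle, memetic_result):
        """Each planted bicluster matched at protein-set Jaccard ≥ 0.9."""
        for truth in bundle.truth_biclusters:
            best = max(
                jaccard(set(truth.proteins), set(b.proteins)) for b in memetic_result
            )
            assert best >= 0.9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            bc.MemeticConfig(population_size=2).validate()
        with pytest.raises(ValueError):
            bc.MemeticConfig(p_crossover=1.5).validate()


class TestExtractSubnetwork:
    def test_unknown_proteins_give_empty_subnetwork(self, bundle, go_weight_fn):
        from dyncomplex.weighting import build_weighted_network

        net = build_weighted_network(
            bundle.ppi, go_weight_fn, bundle.tap_lcms, bundle.tap_maldi, 0.4
        )
        bic = bc.Bicluster(proteins=["ZZZ1", "ZZZ2"], timepoints=["T00"], fitness=1.0)
        sub = bc.extract_subnetwork(bic, net)
        assert sub.graph.number_of_nodes() == 0

    def test_all_proteins_returns_whole_network(self, bundle, go_weight_fn):
        from dyncomplex.weighting import build_weighted_network

        net = build_weighted_network(
            bundle.ppi, go_weight_fn, bundle.tap_lcms, bundle.tap_maldi, 0.4
        )
        bic = bc.Bicluster(proteins=bundle.proteins, timepoints=["T00"], fitness=1.0)
        sub = bc.extract_subnetwork(bic, net)
        assert sub.graph.number_of_edges() == net.graph.number_of_edges()
        assert sub.graph.number_of_nodes() == net.graph.number_of_nodes()

    def test_induced_edges_match_pair_enumeration(self, bundle, go_weight_fn):
        from dyncomplex.weighting import build_weighted_network

        net = build_weighted_network(
            bundle.ppi, go_weight_fn, bundle.tap_lcms, bundle.tap_maldi, 0.4
        )
        members = bundle.proteins[:30]
        bic = bc.Bicluster(proteins=members, timepoints=["T00"], fitness=1.0)
        sub = bc.extract_subnetwork(bic, net)
        expected = sum(
            1
            for i, a in enumerate(members)
            for b in members[i + 1 :]
            if net.graph.has_edge(a, b)
        )
        assert sub.graph.number_of_edges() == expected
        # isolated nodes retained
        assert sub.graph.number_of_nodes() == 30
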