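import numpy as np
import pytest

from rnajoint.dotmatrix import Category, SubDiagonal, SubDiagonalSet, build_matrix, extract_subdiagonals
from rnajoint.energy import SimpleNearestNeighborModel
from rnajoint.ga import (
    GaConfig,
    NoComplementarityError,
    StopReason,
    crossover_pair,
    init_population,
    mutate,
    next_generation,
    prepare_search_space,
    random_genotype,
    run,
)
from rnajoint.genotype import Genotype
from rnajoint.sequences import concatenate, normalize_sequence

MODEL = SimpleNearestNeighborModel()


class FlatModel:
    """Stub energy backend: every structure scores 0.

    Used where tests build synthetic sub-diagonals whose pairs are not
    tied to real complementary bases, to exercise genotype mechanics
    independently of energetics.
    """

    name = "flat"

    def evaluate_intra(self, seq, pairs):
        return 0.0

    def evaluate_hybrid(self, first, second, hybrid):
        return 0.0


def joint(first, second):
    return concatenate(
        normalize_sequence(first, "a"), normalize_sequence(second, "b")
    )


def search_space(first, second, **kw):
    cfg = GaConfig(**kw)
    js = joint(first, second)
    diags = extract_subdiagonals(
        build_matrix(js), js, cfg.min_pairs, cfg.min_hairpin_loop
    )
    return js, diags, cfg


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"population_size": 1},
            {"crossover_rate": 1.5},
            {"mutation_rate": -0.1},
            {"max_generations": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            GaConfig(**kw)


class TestInitPopulation:
    def test_deterministic_per_seed(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        pops = [
            init_population(
                cfg, diags, js, np.random.default_rng(5), MODEL
            )
            for _ in range(2)
        ]
        assert [i.genotype.bits for i in pops[0].individuals] == [
            i.genotype.bits for i in pops[1].individuals
        ]

    def test_sorted_by_fitness(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        pop = init_population(cfg, diags, js, np.random.default_rng(1), MODEL)
        fits = [i.fitness for i in pop.individuals]
        assert fits == sorted(fits)
        assert len(pop.individuals) == cfg.population_size

    def test_single_diagonal_space(self):
        js, diags, cfg = search_space("GC", "GC", population_size=2)
        assert len(diags) == 1
        pop = init_population(cfg, diags, js, np.random.default_rng(0), MODEL)
        for ind in pop.individuals:
            assert ind.genotype.bits == (1,)  # at least one active bit

    def test_no_complementarity_errors(self):
        with pytest.raises(NoComplementarityError):
            run(GaConfig(), normalize_sequence("AAA"), normalize_sequence("AAA"))

    def test_active_cap_respected_at_init(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            g = random_genotype(rng, num_diagonals=20, active_cap=5)
            assert 1 <= g.num_active <= 5


class TestCrossover:
    def test_single_point_exchange(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        assert len(diags) >= 4
        pad = (0,) * (len(diags) - 4)
        p1 = Genotype((1, 1, 0, 0) + pad)
        p2 = Genotype((0, 0, 1, 1) + pad)
        c1, c2 = crossover_pair(p1, p2, 2, diags, js, MODEL)
        assert c1.genotype.bits == (1, 1, 1, 1) + pad
        assert c2.genotype.bits == (0, 0, 0, 0) + pad

    def test_cut_at_end_reproduces_parents(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        rng = np.random.default_rng(2)
        bits = tuple(int(b) for b in rng.integers(0, 2, len(diags)))
        other = tuple(int(b) for b in rng.integers(0, 2, len(diags)))
        c1, c2 = crossover_pair(
            Genotype(bits), Genotype(other), len(diags), diags, js, MODEL
        )
        assert c1.genotype.bits == bits
        assert c2.genotype.bits == other

    def test_identical_parents_fixed_point(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        bits = Genotype((1, 0) * (len(diags) // 2) + (0,) * (len(diags) % 2))
        c1, c2 = crossover_pair(bits, bits, 3, diags, js, MODEL)
        assert c1.genotype.bits == bits.bits == c2.genotype.bits


class TestMutate:
    def _two_diag_space(self):
        js = joint("A" * 12, "A")
        d1 = SubDiagonal(
            pairs=((1, 10), (2, 9)),
            category=Category.INTRA_FIRST,
            gu_flags=(False, False),
            size=js.length,
        )
        d2 = SubDiagonal(
            pairs=((3, 8), (4, 7)),
            category=Category.INTRA_FIRST,
            gu_flags=(False, False),
            size=js.length,
        )
        return js, SubDiagonalSet((d1, d2))

    def test_forced_swap_on_two_bits(self):
        js, diags = self._two_diag_space()
        cfg = GaConfig()
        from rnajoint.ga import _build

        ind = _build(Genotype((1, 0)), diags, js, FlatModel())
        out = mutate(ind, cfg, np.random.default_rng(0), diags, js, FlatModel())
        assert out.genotype.bits == (0, 1)

    def test_degenerate_genotypes_identity(self):
        js, diags = self._two_diag_space()
        cfg = GaConfig()
        from rnajoint.ga import _build

        all_on = _build(Genotype((1, 1)), diags, js, FlatModel())
        out = mutate(all_on, cfg, np.random.default_rng(0), diags, js, FlatModel())
        assert out is all_on  # no 0-bit available: identity

    def test_retry_prefers_contributing_diagonal(self):
        # d2 fully overlaps d1, d3 is free: activating d2 while d1 is
        # on contributes nothing, so the retry must land on d3.
        js = joint("A" * 20, "A")
        mk = lambda pairs: SubDiagonal(
            pairs=pairs,
            category=Category.INTRA_FIRST,
            gu_flags=(False,) * len(pairs),
            size=js.length,
        )
        d1 = mk(((1, 10), (2, 9)))
        d2 = mk(((1, 10), (2, 9)))
        d3 = mk(((12, 20), (13, 19)))
        diags = SubDiagonalSet((d1, d2, d3))
        from rnajoint.ga import _build

        ind = _build(Genotype((1, 1, 0)), diags, js, FlatModel())
        for seed in range(5):
            out = mutate(
                ind, GaConfig(), np.random.default_rng(seed), diags, js, FlatModel()
            )
            # whichever 1-bit was cleared, the result has two active
            # bits and its phenotype is never empty
            assert out.genotype.num_active == 2
            assert out.components


class TestNextGeneration:
    def test_zero_crossover_rate_transfers_everyone(self):
        js, diags, cfg = search_space(
            "GCGCAAAAGCGC", "CGCAAAAACGCG", crossover_rate=0.0
        )
        rng = np.random.default_rng(4)
        pop = init_population(cfg, diags, js, rng, MODEL)
        after = next_generation(pop, cfg, rng, diags, js, MODEL)
        assert [i.genotype.bits for i in after.individuals] == [
            i.genotype.bits for i in pop.individuals
        ]

    def test_elitism_never_worsens_best(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        rng = np.random.default_rng(8)
        pop = init_population(cfg, diags, js, rng, MODEL)
        for _ in range(5):
            new = next_generation(pop, cfg, rng, diags, js, MODEL)
            assert new.best.fitness <= pop.best.fitness
            pop = new

    def test_population_invariants_every_generation(self):
        js, diags, cfg = search_space("GCGCAAAAGCGC", "CGCAAAAACGCG")
        rng = np.random.default_rng(8)
        pop = init_population(cfg, diags, js, rng, MODEL)
        for _ in range(3):
            pop = next_generation(pop, cfg, rng, diags, js, MODEL)
            fits = [i.fitness for i in pop.individuals]
            assert fits == sorted(fits)
            for ind in pop.individuals:
                ind.structure.validate()


class TestRun:
    def test_max_generations_stop(self, example_pair):
        res = run(GaConfig(max_generations=1, seed=1), *example_pair)
        assert res.generations_run == 1
        assert res.stop_reason is StopReason.MAX_GENERATIONS
        assert len(res.history) == 2  # initial + one generation

    def test_flat_landscape_converges_quickly(self):
        res = run(
            GaConfig(patience=1, seed=0),
            normalize_sequence("GC"),
            normalize_sequence("GC"),
        )
        assert res.stop_reason is StopReason.CONVERGED
        assert res.generations_run == 1

    def test_best_fitness_monotone_in_history(self, example_pair):
        res = run(GaConfig(seed=13), *example_pair)
        best = [h.best_fitness for h in res.history]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))

    def test_identical_seed_identical_result(self, example_pair):
        a = run(GaConfig(seed=21), *example_pair)
        b = run(GaConfig(seed=21), *example_pair)
        assert a.best.genotype.bits == b.best.genotype.bits
        assert a.best.fitness == b.best.fitness
        assert a.history == b.history
        assert a.stop_reason == b.stop_reason

    def test_gu_filter_applied_in_pipeline(self, example_pair):
        cfg = GaConfig()
        js, diags = prepare_search_space(*example_pair, cfg)
        for d in diags:
            assert not (d.gu_fraction > cfg.gu_threshold and any(d.gu_flags))
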