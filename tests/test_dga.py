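from collections import Counter, deque

import numpy as np
import pytest

from hsqcmatch import (
    GAConfig,
    Matching,
    OperatorInapplicableError,
    Spectrum,
    crossover_combine,
    crossover_mask,
    dga_similarity,
    evolve,
    init_population,
    mutate,
    optimal_assignment,
)

from conftest import random_spectrum


def matching(j, n_target):
    j = np.asarray(j)
    return Matching(p_id="p", q_id="q", assignment=j,
                    n_source=j.size, n_target=n_target)


class TestConfig:
    @pytest.mark.parametrize(
        "preset,k,mult", [("small", 2, 5), ("medium", 5, 10), ("large", 20, 50)]
    )
    def test_presets(self, preset, k, mult):
        cfg = GAConfig(preset=preset)
        assert (cfg.k_population, cfg.gmax_multiplier) == (k, mult)
        assert cfg.gmax(20) == mult * 20

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(preset="huge")
        with pytest.raises(ValueError):
            GAConfig(k_population=1)
        with pytest.raises(ValueError):
            GAConfig(gmax_multiplier=0)


class TestInitPopulation:
    def test_single_slot_population_is_forced(self, rng):
        p = random_spectrum(rng, 1, "p")
        q = random_spectrum(rng, 1, "q")
        pop = init_population(p, q, GAConfig(seed=0))
        assert all(m.assignment.tolist() == [0] for m in pop.members)
        assert pop.nfe == 5

    def test_seed_determinism(self, rng):
        p, q = random_spectrum(rng, 5, "p"), random_spectrum(rng, 7, "q")
        a = init_population(p, q, GAConfig(seed=11))
        b = init_population(p, q, GAConfig(seed=11))
        for ma, mb in zip(a.members, b.members):
            assert ma.assignment.tolist() == mb.assignment.tolist()

    def test_uniform_over_injections(self, rng):
        # N=2, M=3: six injections, each expected 1/6 of 10^4 draws
        p, q = random_spectrum(rng, 2, "p"), random_spectrum(rng, 3, "q")
        counts = Counter()
        draws = 10_000
        pop = init_population(
            p, q, GAConfig(k_population=draws, gmax_multiplier=1, seed=99)
        )
        for m in pop.members:
            counts[tuple(m.assignment)] += 1
        assert len(counts) == 6
        expected = draws / 6
        sigma = np.sqrt(draws * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - expected) <= 3 * sigma


class TestMutations:
    def test_exc_swaps_two_positions(self, rng):
        m = matching([0, 1, 2, 3], 4)
        for _ in range(50):
            out = mutate(m, "EXC", rng).assignment
            diff = np.nonzero(out != m.assignment)[0]
            assert diff.size == 2
            i, k = diff
            assert out[i] == m.assignment[k] and out[k] == m.assignment[i]

    def test_l3o_deranges_three_positions(self, rng):
        m = matching([0, 1, 2], 3)
        seen = set()
        for _ in range(100):
            out = tuple(mutate(m, "L3O", rng).assignment)
            seen.add(out)
            # derangement on all three positions: nothing stays put
            assert all(a != b for a, b in zip(out, m.assignment))
        assert seen == {(1, 2, 0), (2, 0, 1)}  # the only derangements of 3

    def test_l4o_deranges_four_positions(self, rng):
        m = matching([3, 1, 0, 2], 4)
        for _ in range(100):
            out = mutate(m, "L4O", rng).assignment
            diff = np.nonzero(out != m.assignment)[0]
            assert diff.size == 4
            assert sorted(out) == sorted(m.assignment)

    def test_exon_uniform_over_outside_nodes(self, rng):
        # N=1, M=4, current value 1: replacements 0, 2, 3 each ~1/3
        m = matching([1], 4)
        counts = Counter(int(mutate(m, "EXON", rng).assignment[0])
                         for _ in range(10_000))
        assert set(counts) == {0, 2, 3}
        sigma = np.sqrt(10_000 * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - 10_000 / 3) <= 3 * sigma

    @pytest.mark.parametrize(
        "kind,j,m_target",
        [("EXC", [0], 1), ("L3O", [0, 1], 2), ("L4O", [0, 1, 2], 3),
         ("EXON", [0, 1, 2], 3)],
    )
    def test_inapplicable_operators_signal(self, rng, kind, j, m_target):
        with pytest.raises(OperatorInapplicableError):
            mutate(matching(j, m_target), kind, rng)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown mutation"):
            mutate(matching([0, 1], 2), "FLIP", rng)


class TestCrossoverMasks:
    def test_singleburst_n3_forced_all_ones(self, rng):
        for _ in range(20):
            assert crossover_mask("SINGLEBURST", 3, rng).tolist() == [1, 1, 1]

    def test_singleburst_is_cyclic_block(self, rng):
        lengths = set()
        wrapped = 0
        for _ in range(500):
            mask = crossover_mask("SINGLEBURST", 7, rng)
            ones = int(mask.sum())
            lengths.add(ones)
            assert 3 <= ones <= 7
            # a cyclic block has at most one 1->0 transition around the ring
            trans = sum(
                mask[i] == 1 and mask[(i + 1) % 7] == 0 for i in range(7)
            )
            assert trans <= 1
            if mask[0] == 1 and mask[-1] == 1 and ones < 7:
                wrapped += 1
        assert lengths == {3, 4, 5, 6, 7}
        assert wrapped > 0  # roll-over actually occurs

    def test_burstrand_adjacent_disagreement_rate(self, rng):
        n, draws = 20, 100_000
        disagreements = 0
        for _ in range(draws):
            mask = crossover_mask("BURSTRAND", n, rng)
            disagreements += int(np.sum(mask[1:] != mask[:-1]))
        total = draws * (n - 1)
        p = 2.0 / n
        sigma = np.sqrt(total * p * (1 - p))
        assert abs(disagreements - total * p) <= 3 * sigma

    def test_rx_bits_are_fair(self, rng):
        bits = np.concatenate(
            [crossover_mask("RX", 16, rng) for _ in range(2000)]
        )
        assert abs(bits.mean() - 0.5) <= 3 * np.sqrt(0.25 / bits.size)

    def test_singleburst_too_short_signals(self, rng):
        with pytest.raises(OperatorInapplicableError):
            crossover_mask("SINGLEBURST", 2, rng)


class TestCrossoverCombine:
    def test_all_ones_returns_first_parent(self, rng):
        a, b = matching([2, 0, 1], 3), matching([0, 1, 2], 3)
        out = crossover_combine(a, b, np.ones(3, dtype=np.uint8))
        assert out.assignment.tolist() == [2, 0, 1]

    def test_all_zeros_returns_second_parent(self, rng):
        a, b = matching([2, 0, 1], 3), matching([0, 1, 2], 3)
        out = crossover_combine(a, b, np.zeros(3, dtype=np.uint8))
        assert out.assignment.tolist() == [0, 1, 2]

    def test_hand_fill_example(self):
        # keep a's first value, fill the rest from b skipping the value
        # already present
        a, b = matching([0, 1, 2], 3), matching([2, 1, 0], 3)
        out = crossover_combine(a, b, np.array([1, 0, 0], dtype=np.uint8))
        assert out.assignment.tolist() == [0, 2, 1]

    def test_child_always_valid(self, rng):
        for _ in range(200):
            n, mt = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            universe = max(n, mt)
            a = matching(rng.permutation(universe)[:n], mt)
            b = matching(rng.permutation(universe)[:n], mt)
            mask = (rng.random(n) < 0.5).astype(np.uint8)
            crossover_combine(a, b, mask)  # constructor validates


class TestEvolve:
    def test_identical_spectra_reach_zero(self, rng):
        hits = 0
        for seed in range(100):
            p = random_spectrum(rng, 5, "p")
            _, pop = evolve(p, p, GAConfig(preset="small", seed=seed))
            hits += pop.best_cost == 0.0
        assert hits >= 99

    def test_single_peak_pair_trivial(self, rng):
        p, q = random_spectrum(rng, 1, "p"), random_spectrum(rng, 1, "q")
        best, pop = evolve(p, q, GAConfig(preset="medium", seed=0))
        assert best.assignment.tolist() == [0]

    def test_nfe_closed_form_without_early_exit(self, rng):
        p, q = random_spectrum(rng, 5, "p"), random_spectrum(rng, 7, "q")
        cfg = GAConfig(preset="medium", seed=4)
        _, pop = evolve(p, q, cfg)
        gmax = cfg.gmax(7)
        assert pop.generations == gmax  # random spectra: cost 0 unreachable
        k, sweeps = cfg.k_population, cfg.mutation_sweeps
        assert pop.nfe == k + gmax * (sweeps * k + k)

    def test_best_cost_monotone_in_generations(self, rng):
        # same seed means longer runs extend the same trajectory, so the
        # best cost after more generations can never be worse
        p, q = random_spectrum(rng, 8, "p"), random_spectrum(rng, 8, "q")
        costs = []
        for mult in (1, 2, 5, 10, 20):
            cfg = GAConfig(k_population=5, gmax_multiplier=mult, seed=7)
            _, pop = evolve(p, q, cfg)
            costs.append(pop.best_cost)
        assert costs == sorted(costs, reverse=True)

    def test_population_members_always_valid(self, rng):
        for seed in range(10):
            n, mt = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            p, q = random_spectrum(rng, n, "p"), random_spectrum(rng, mt, "q")
            _, pop = evolve(p, q, GAConfig(preset="small", seed=seed))
            assert len(pop.members) == 2  # constructor validated each one

    def test_medium_preset_matches_oracle_mostly(self, rng):
        hits = 0
        for seed in range(20):
            p = random_spectrum(rng, 6, "p")
            q = random_spectrum(rng, 6, "q")
            _, opt = optimal_assignment(p, q)
            _, pop = evolve(p, q, GAConfig(preset="medium", seed=seed))
            hits += abs(pop.best_cost - opt) < 1e-12
        assert hits >= 18

    def test_exchange_moves_reach_every_injection(self):
        # EXC alone spans all permutations at N=M; with EXON it spans all
        # injections at N<M. BFS over deterministic neighbour enumeration
        # (independent of the stochastic operators) on N=3, M=4.
        start = (0, 1, 2)
        seen = {start}
        frontier = deque([start])
        while frontier:
            j = frontier.popleft()
            neighbours = []
            for a in range(3):
                for b in range(a + 1, 3):  # all EXC swaps
                    jj = list(j)
                    jj[a], jj[b] = jj[b], jj[a]
                    neighbours.append(tuple(jj))
                unused = set(range(4)) - set(j)
                for v in unused:  # all EXON replacements
                    jj = list(j)
                    jj[a] = v
                    neighbours.append(tuple(jj))
            for nb in neighbours:
                if nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        assert len(seen) == 24  # all 4*3*2 injections of 3 slots into 4


class TestDGASimilarity:
    def test_identical_spectra_score_zero(self, rng):
        p = random_spectrum(rng, 6)
        res = dga_similarity(p, p, GAConfig(preset="small", seed=1))
        assert res.final_score == 0.0

    def test_seeded_runs_bit_reproducible(self, rng):
        p, q = random_spectrum(rng, 8, "p"), random_spectrum(rng, 10, "q")
        cfg = GAConfig(preset="medium", seed=123)
        a = dga_similarity(p, q, cfg)
        b = dga_similarity(p, q, cfg)
        assert a.final_score == b.final_score
        assert a.matching.assignment.tolist() == b.matching.assignment.tolist()
        assert a.nfe == b.nfe

    def test_matches_refined_oracle_when_optimum_reached(self, rng):
        from hsqcmatch import refine_matching

        found = 0
        for seed in range(10):
            p = random_spectrum(rng, 5, "p")
            q = random_spectrum(rng, 6, "q")
            m_opt, opt = optimal_assignment(p, q)
            res = dga_similarity(p, q, GAConfig(preset="medium", seed=seed))
            if abs(res.evaluation.epsilon_s - opt) < 1e-12:
                found += 1
                assert res.final_score == pytest.approx(
                    refine_matching(p, q, m_opt).final_score, abs=1e-9
                )
        assert found > 0
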