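import numpy as np
import pytest

from ecvmate.selection import (
    CrossingPlan,
    InfeasibleSelectionError,
    PartialPlanError,
    SelectionConfig,
    _enumerate_all_pairs,
    _feasibility,
    _lex_solve_explicit,
    _lex_solve_fast,
    _lex_solve_ilp,
    select_best_pair,
    select_best_pair_exhaustive,
    select_best_pair_ilp,
    select_pairs_by_score,
    select_pairs_iterative,
    select_pairs_lexicographic,
)

from conftest import make_pop, single_trait_arch


def pop_with_counts(counts, n_loci):
    """Population whose single-trait allele counts equal ``counts``."""
    K = len(counts)
    alleles = np.zeros((K, n_loci, 2), dtype=np.int8)
    for k, c in enumerate(counts):
        flat = alleles[k].reshape(-1)
        flat[:c] = 1
    return make_pop(alleles)


def pop_with_two_trait_counts(c1, c2, n1, n2):
    """Two disjoint trait blocks with prescribed per-individual counts."""
    from ecvmate.population import TraitArchitecture

    K = len(c1)
    alleles = np.zeros((K, n1 + n2, 2), dtype=np.int8)
    for k in range(K):
        alleles[k, :n1].reshape(-1)[: c1[k]] = 1
        alleles[k, n1:].reshape(-1)[: c2[k]] = 1
    pop = make_pop(alleles)
    arch = TraitArchitecture(
        trait_ids=("t1", "t2"),
        qtl_indices={"t1": np.arange(n1), "t2": np.arange(n1, n1 + n2)},
        desirable_allele={
            "t1": np.ones(n1, dtype=np.int8),
            "t2": np.ones(n2, dtype=np.int8),
        },
    )
    return pop, arch


class TestSingleBestPair:
    def setup_method(self):
        self.pop = pop_with_counts([8, 6, 2], n_loci=4)
        self.arch = single_trait_arch(4)

    @pytest.mark.parametrize("solve", [select_best_pair_ilp, select_best_pair_exhaustive])
    def test_unconstrained_optimum(self, solve):
        G = np.zeros((3, 3))
        cfg = SelectionConfig(epsilon=0.2)
        pair, obj = solve(self.pop, self.arch, "t", G, cfg)
        assert pair == (0, 1) and obj == 3.5

    @pytest.mark.parametrize("solve", [select_best_pair_ilp, select_best_pair_exhaustive])
    def test_relatedness_cap_excludes_top_pair(self, solve):
        G = np.zeros((3, 3))
        G[0, 1] = G[1, 0] = 0.5
        pair, obj = solve(self.pop, self.arch, "t", G, SelectionConfig(epsilon=0.2))
        assert pair == (0, 2) and obj == 2.5

    def test_no_cap_picks_two_highest_counts(self):
        pair, obj = select_best_pair_exhaustive(
            self.pop, self.arch, "t", None, SelectionConfig(epsilon=None)
        )
        assert pair == (0, 1) and obj == 3.5

    def test_infeasible_names_binding_constraint(self):
        G = np.full((3, 3), 0.9)
        with pytest.raises(InfeasibleSelectionError, match="epsilon"):
            select_best_pair_exhaustive(self.pop, self.arch, "t", G, SelectionConfig(epsilon=0.2))

    def test_single_admissible_pair(self):
        forb = [(0, 1), (0, 2)]
        pair, _ = select_best_pair_exhaustive(
            self.pop, self.arch, "t", None, SelectionConfig(epsilon=None), forbidden=forb
        )
        assert pair == (1, 2)


class TestRouteEquivalence:
    """The three exact routes must agree pair-for-pair, including ties."""

    def test_randomized_instances_with_constraints(self, rng):
        mismatches = 0
        solved = 0
        for _ in range(60):
            K = int(rng.integers(5, 40))
            M = int(rng.integers(1, 4))
            n1 = int(rng.integers(3, 7))
            counts = rng.integers(0, 4 * n1 + 1, (K, M))
            G = rng.uniform(0, 0.5, (K, K))
            G = (G + G.T) / 2
            eps = float(rng.uniform(0.2, 0.5))
            taus = tuple(float(t) for t in rng.uniform(0, 0.4, M - 1)) + (0.0,)
            forbidden = set()
            for _ in range(int(rng.integers(0, 5))):
                a, b = sorted(map(int, rng.integers(0, K, 2)))
                if a != b:
                    forbidden.add((a, b))
            cfg = SelectionConfig(epsilon=eps, tolerances=taus,
                                  trait_priority=tuple(f"x{j}" for j in range(M)))
            feas = _feasibility(G, cfg, forbidden)
            k1, k2 = _enumerate_all_pairs(K, False)
            try:
                res_exh = _lex_solve_explicit(k1, k2, counts, taus, feas)
            except InfeasibleSelectionError:
                with pytest.raises(InfeasibleSelectionError):
                    _lex_solve_ilp(counts, taus, G, cfg, forbidden)
                continue
            res_ilp = _lex_solve_ilp(counts, taus, G, cfg, forbidden)
            res_fast = _lex_solve_fast(counts, taus, feas, False, enum_guard=2)
            solved += 1
            if not (res_exh == res_ilp == res_fast):
                mismatches += 1
        assert solved >= 40
        assert mismatches == 0

    def test_tie_breaking_smallest_index_pair(self):
        pop = pop_with_counts([4, 4, 4, 4], n_loci=2)
        arch = single_trait_arch(2)
        for solve in (select_best_pair_ilp, select_best_pair_exhaustive):
            pair, _ = solve(pop, arch, "t", None, SelectionConfig(epsilon=None))
            assert pair == (0, 1)


class TestIterative:
    def test_two_slots(self):
        pop = pop_with_counts([8, 6, 2], n_loci=4)
        plan = select_pairs_iterative(
            pop, single_trait_arch(4), "t", np.zeros((3, 3)),
            SelectionConfig(epsilon=0.2, n_pairs=2), solver="exhaustive",
        )
        assert plan.pairs == [(0, 1), (0, 2)]
        assert [e.ecv[0] for e in plan] == [3.5, 2.5]

    def test_single_slot_matches_best_pair(self):
        pop = pop_with_counts([8, 6, 2], n_loci=4)
        arch = single_trait_arch(4)
        plan = select_pairs_iterative(
            pop, arch, "t", None, SelectionConfig(epsilon=None, n_pairs=1)
        )
        pair, obj = select_best_pair_exhaustive(pop, arch, "t", None, SelectionConfig(epsilon=None))
        assert plan.pairs == [pair] and plan.entries[0].ecv[0] == obj

    def test_full_enumeration_ranks_all_pairs(self, rng):
        K = 6
        pop = pop_with_counts(list(rng.integers(0, 17, K)), n_loci=4)
        n_all = K * (K - 1) // 2
        plan = select_pairs_iterative(
            pop, single_trait_arch(4), "t", None,
            SelectionConfig(epsilon=None, n_pairs=n_all),
        )
        objs = [e.ecv[0] for e in plan]
        assert len(set(plan.pairs)) == n_all
        assert all(a >= b for a, b in zip(objs, objs[1:]))

    def test_partial_plan_error_carries_found_pairs(self):
        pop = pop_with_counts([8, 6, 2], n_loci=4)
        with pytest.raises(PartialPlanError) as err:
            select_pairs_iterative(
                pop, single_trait_arch(4), "t", None,
                SelectionConfig(epsilon=None, n_pairs=5),
            )
        assert len(err.value.plan) == 3  # only 3 distinct pairs exist


class TestLexicographic:
    def test_single_trait_reduction(self):
        pop = pop_with_counts([8, 6, 2, 5], n_loci=4)
        arch = single_trait_arch(4)
        cfg = SelectionConfig(epsilon=None, n_pairs=3, tolerances=(0.0,), trait_priority=("t",))
        lex = select_pairs_lexicographic(pop, arch, None, cfg)
        it = select_pairs_iterative(pop, arch, "t", None, cfg)
        assert lex.pairs == it.pairs

    def test_zero_tolerance_keeps_stage_one_winner(self):
        # unique stage-1 optimum + tau = 0: later traits cannot override it
        pop, arch = pop_with_two_trait_counts([8, 6, 2, 1], [0, 2, 8, 8], n1=4, n2=4)
        cfg = SelectionConfig(
            epsilon=None, n_pairs=1, tolerances=(0.0, 0.0), trait_priority=("t1", "t2")
        )
        plan = select_pairs_lexicographic(pop, arch, None, cfg)
        assert plan.pairs == [(0, 1)]

    @pytest.mark.parametrize("tau1,winner", [(0.2, (2, 3)), (0.05, (0, 1))])
    def test_degradation_tolerance_trades_traits(self, tau1, winner):
        # pair P=(0,1): ECV = (4.0, 1.0); pair Q=(2,3): ECV = (3.5, 3.0);
        # cross pairs are blocked by the relatedness cap
        pop, arch = pop_with_two_trait_counts([8, 8, 7, 7], [2, 2, 6, 6], n1=4, n2=3)
        G = np.ones((4, 4))
        G[0, 1] = G[1, 0] = G[2, 3] = G[3, 2] = 0.0
        cfg = SelectionConfig(
            epsilon=0.5, n_pairs=1, tolerances=(tau1, 0.0), trait_priority=("t1", "t2")
        )
        plan = select_pairs_lexicographic(pop, arch, G, cfg)
        assert plan.pairs == [winner]

    def test_tolerance_contract_on_random_instances(self, rng):
        # every achieved earlier-stage ECV stays within its (1 - tau) factor
        for _ in range(20):
            K = int(rng.integers(6, 20))
            c1 = list(rng.integers(0, 17, K))
            c2 = list(rng.integers(0, 13, K))
            pop, arch = pop_with_two_trait_counts(c1, c2, n1=4, n2=3)
            G = rng.uniform(0, 0.4, (K, K))
            G = (G + G.T) / 2
            tau1 = float(rng.uniform(0, 0.5))
            cfg = SelectionConfig(
                epsilon=0.3, n_pairs=2, tolerances=(tau1, 0.0), trait_priority=("t1", "t2")
            )
            try:
                plan = select_pairs_lexicographic(pop, arch, G, cfg)
            except (InfeasibleSelectionError, PartialPlanError):
                continue
            for entry in plan:
                opt1 = entry.stage_optima[0]
                assert entry.ecv[0] >= (1 - tau1) * opt1 - 1e-9
                assert G[entry.parent1, entry.parent2] <= 0.3

    def test_shrinking_epsilon_never_improves_optimum(self, rng):
        pop = pop_with_counts(list(rng.integers(0, 17, 12)), n_loci=4)
        arch = single_trait_arch(4)
        G = rng.uniform(0, 0.5, (12, 12))
        G = (G + G.T) / 2
        prev = np.inf
        for eps in (0.5, 0.3, 0.2, 0.1):
            try:
                _, obj = select_best_pair_exhaustive(
                    pop, arch, "t", G, SelectionConfig(epsilon=eps)
                )
            except InfeasibleSelectionError:
                obj = -np.inf
            assert obj <= prev
            prev = obj


class TestScoreBaseline:
    def test_rank_sum_example(self):
        plan = select_pairs_by_score(
            np.array([5.0, 3.0, 1.0]), SelectionConfig(epsilon=None, n_pairs=2)
        )
        assert plan.pairs == [(0, 1), (0, 2)]

    def test_all_equal_scores_take_index_order(self):
        plan = select_pairs_by_score(np.ones(5), SelectionConfig(epsilon=None, n_pairs=3))
        assert plan.pairs == [(0, 1), (0, 2), (0, 3)]

    def test_multitrait_sum_invariance(self):
        s = np.array([5.0, 3.0, 1.0, 4.0])
        single = select_pairs_by_score(2 * s, SelectionConfig(epsilon=None, n_pairs=3))
        multi = select_pairs_by_score(
            np.column_stack([s, s]), SelectionConfig(epsilon=None, n_pairs=3)
        )
        assert single.pairs == multi.pairs

    def test_requires_enough_distinct_pairs(self):
        with pytest.raises(InfeasibleSelectionError):
            select_pairs_by_score(np.array([1.0, 2.0]), SelectionConfig(epsilon=None, n_pairs=2))

    def test_matches_full_enumeration_ranking(self, rng):
        for _ in range(20):
            K = int(rng.integers(4, 15))
            s = rng.normal(size=K)
            n_c = int(rng.integers(1, K * (K - 1) // 2 + 1))
            plan = select_pairs_by_score(s, SelectionConfig(epsilon=None, n_pairs=n_c))
            a, b = np.triu_indices(K, k=1)
            order = np.lexsort((b, a, -(s[a] + s[b])))
            expected = [(int(a[i]), int(b[i])) for i in order[:n_c]]
            assert plan.pairs == expected


class TestPlanInvariants:
    def test_no_duplicates_no_self_and_cap_respected(self, rng):
        K = 15
        pop = pop_with_counts(list(rng.integers(0, 17, K)), n_loci=4)
        G = rng.uniform(0, 0.4, (K, K))
        G = (G + G.T) / 2
        plan = select_pairs_iterative(
            pop, single_trait_arch(4), "t", G, SelectionConfig(epsilon=0.25, n_pairs=6)
        )
        assert len(set(plan.pairs)) == 6
        for e in plan:
            assert e.parent1 != e.parent2
            assert G[e.parent1, e.parent2] <= 0.25
        assert isinstance(plan, CrossingPlan)
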