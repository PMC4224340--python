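"""Sankoff reconstruction: exact small-case values, oracle equivalence, invariants."""

import pytest

from archevo import (
    build_universe,
    count_by_type,
    extract_events,
    parse_profile,
    read_newick,
    sankoff,
)
from archevo.model import enumerate_events
from archevo.parsimony import UniverseError, transition_costs

from oracles import exhaustive_min_cost, induced_pair_costs


class TestBuildUniverse:
    def test_depth_zero_is_distinct_tips(self):
        tips = {"A": parse_profile("K-P"), "B": parse_profile("K-P")}
        u = build_universe(tips, depth=0)
        assert set(u.profiles) == {parse_profile("K-P")}

    def test_depth_nesting(self, folate):
        tips = folate.amorphea_tips
        sets = []
        for depth in (0, 1, 2):
            sets.append(set(build_universe(tips, depth=depth).profiles))
        assert sets[0] <= sets[1] <= sets[2]
        assert sets[0] < sets[1] < sets[2]

    def test_depth_two_matches_independent_closure(self, folate):
        """The closure equals a plain BFS over grammar neighbourhoods."""
        tips = set(folate.amorphea_tips.values())
        closure = set(tips)
        frontier = set(tips)
        for _ in range(2):
            new = set()
            for p in frontier:
                for _e, n in enumerate_events(p):
                    if n not in closure:
                        new.add(n)
            closure |= new
            frontier = new
        u = build_universe(folate.amorphea_tips, depth=2)
        assert set(u.profiles) == closure
        for text in [".", "B-K-P", "B-B-K-P", "B-B;K-P", "B;K-P", "K-P"]:
            assert parse_profile(text) in u

    def test_size_guard(self, folate):
        with pytest.raises(UniverseError, match="states"):
            build_universe(folate.amorphea_tips, depth=2, max_states=20)

    def test_depth_guard(self, folate):
        with pytest.raises(UniverseError):
            build_universe(folate.amorphea_tips, depth=4)


class TestSankoffSmall:
    def test_two_identical_tips_cost_zero(self):
        tree = read_newick("(A,B);")
        tips = {n: parse_profile("K-P") for n in "AB"}
        result = sankoff(tree, tips)
        assert result.total_cost == 0.0
        assert len(result.reconstructions) == 1
        assert result.optimal_root_profiles == (parse_profile("K-P"),)

    def test_three_tip_minimal_cost_one(self, three_tip_tree):
        """One domain loss on the internal branch explains {K-P,K-P,B-K-P}."""
        tips = {
            "A": parse_profile("K-P"),
            "B": parse_profile("K-P"),
            "C": parse_profile("B-K-P"),
        }
        result = sankoff(three_tip_tree, tips, universe_depth=1)
        assert result.total_cost == 1.0
        events = [e for rec in result for e in extract_events(rec)]
        for rec in result:
            evs = extract_events(rec)
            assert len(evs) == 1
            counts = count_by_type(evs)
            assert counts["fissions_total"] + counts["domain_duplication"] == 1

    def test_missing_tip_profile_raises(self, three_tip_tree):
        with pytest.raises(KeyError):
            sankoff(three_tip_tree, {"A": parse_profile("K-P")})

    def test_constraint_outside_universe_raises(self, three_tip_tree):
        tips = {n: parse_profile("K-P") for n in "ABC"}
        u = build_universe(tips, depth=0)
        with pytest.raises(UniverseError):
            sankoff(three_tip_tree, tips, universe=u, root_constraint=parse_profile("B-B-K-P"))

    def test_constraint_monotonicity(self, three_tip_tree):
        tips = {
            "A": parse_profile("K-P"),
            "B": parse_profile("B-K-P"),
            "C": parse_profile("B-B-K-P"),
        }
        free = sankoff(three_tip_tree, tips)
        for state in ["K-P", "B-K-P", "B-B-K-P"]:
            pinned = sankoff(three_tip_tree, tips, root_constraint=parse_profile(state))
            assert pinned.total_cost >= free.total_cost - 1e-9

    def test_all_mprs_share_total_cost(self, three_tip_tree):
        tips = {
            "A": parse_profile("B-B;K-P"),
            "B": parse_profile("B-K-P"),
            "C": parse_profile("K-P"),
        }
        result = sankoff(three_tip_tree, tips)
        assert len(result.reconstructions) >= 1
        for rec in result:
            assert abs(rec.total_cost - result.total_cost) < 1e-9

    def test_mpr_cap_flags_truncation(self, folate):
        result = sankoff(folate.amorphea_tree, folate.amorphea_tips, max_mprs=2)
        assert len(result.reconstructions) == 2
        assert result.truncated


class TestOracleEquivalence:
    TOPOLOGIES = [
        "((A,B),(C,D));",
        "(((A,B),C),(D,E));",
        "((((A,B),C),D),E);",
        "(A,B,C,D);",  # polytomy
        "(((A,B),(C,D)),E);",
    ]

    def test_matches_exhaustive_enumeration(self, case_profiles):
        """DP minimum equals brute-force enumeration over all assignments."""
        import random

        rng = random.Random(42)
        universe = tuple(sorted(case_profiles, key=lambda p: p.text))
        D = induced_pair_costs(universe)
        from archevo.parsimony import StateUniverse

        su = StateUniverse(universe)
        for topology in self.TOPOLOGIES:
            tree = read_newick(topology)
            for _ in range(3):
                tips = {name: rng.choice(universe) for name in tree.tip_names()}
                expected = exhaustive_min_cost(tree, tips, universe, D)
                result = sankoff(tree, tips, universe=su)
                assert abs(result.total_cost - expected) < 1e-9, (topology, tips)

    def test_transition_matrix_matches_independent_relaxation(self, case_profiles):
        from archevo.parsimony import StateUniverse

        universe = tuple(sorted(case_profiles, key=lambda p: p.text))
        su = StateUniverse(universe)
        tc = transition_costs(su)
        D = induced_pair_costs(universe)
        for i in range(len(universe)):
            for j in range(len(universe)):
                a, b = tc.cost(i, j), D[i][j]
                assert (a == b) or abs(a - b) < 1e-9


class TestInvariances:
    def test_uniform_clade_permutation(self, folate):
        """Permuting the topology inside the uniform amoebozoan clade changes nothing."""
        base = sankoff(folate.amorphea_tree, folate.amorphea_tips, max_mprs=64)
        alt_newick = None
        from archevo import write_newick

        text = write_newick(folate.amorphea_tree)
        swapped = text.replace(
            "((Acanthamoeba_castellanii,Copromyxa_protea),"
            "(Dictyostelium_discoideum,Dictyostelium_purpureum))Amoebozoa",
            "(Acanthamoeba_castellanii,(Copromyxa_protea,"
            "(Dictyostelium_discoideum,Dictyostelium_purpureum)))Amoebozoa",
        )
        assert swapped != text
        alt = sankoff(read_newick(swapped), folate.amorphea_tips, max_mprs=64)
        assert abs(alt.total_cost - base.total_cost) < 1e-9

        def count_set(result):
            return sorted(
                tuple(sorted(count_by_type(extract_events(rec)).items()))
                for rec in result
            )

        assert count_set(alt) == count_set(base)

    def test_branch_paths_cost_consistent(self, three_tip_tree):
        tips = {
            "A": parse_profile("K-P"),
            "B": parse_profile("K-P"),
            "C": parse_profile("B-B-K-P"),
        }
        result = sankoff(three_tip_tree, tips)
        for rec in result:
            total = sum(p.total_cost for p in rec.branch_paths.values())
            assert abs(total - rec.total_cost) < 1e-9


class TestCountByType:
    def test_empty(self):
        counts = count_by_type([])
        assert counts["fissions_total"] == 0
        assert all(v == 0 for k, v in counts.items())
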