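"""Seed sets, competition scores and dependency scans."""

import random

import pytest

from symbionet.competition import (
    competition_matrix,
    competition_score,
    dependency_scan,
    dependency_table,
    seed_set,
)
from symbionet.reaction_universe import (
    DirectedReaction,
    MetabolicNetwork,
    TargetSet,
    network_from_ecs,
)
from symbionet.synthetic_data import (
    make_random_universe,
    plant_shared_seeds,
    thiamine_toy,
    tryptophan_toy,
)


def _rxn(rid, sub, prod):
    return DirectedReaction(rid, frozenset({"1.1.1.1"}),
                            frozenset(sub), frozenset(prod))


def _net(org, *reactions):
    return MetabolicNetwork(org, frozenset(reactions))


def _seed_oracle(network):
    """Independent seed predicate via pairwise reachability.

    A compound is a seed iff no reaction produces it from a substrate
    outside its own strongly connected component, where SCC membership is
    decided by mutual BFS reachability on the compound graph.
    """
    edges: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for r in network.reactions:
        nodes |= r.substrates | r.products
        for s in r.substrates:
            edges.setdefault(s, set()).update(r.products)

    def reachable(src):
        seen = {src}
        stack = [src]
        while stack:
            n = stack.pop()
            for m in edges.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return seen

    reach = {n: reachable(n) for n in nodes}
    seeds = set()
    for c in nodes:
        scc = {d for d in nodes if d in reach[c] and c in reach[d]}
        # the whole component must lack incoming edges from outside itself
        incoming_outside = any(
            (r.products & scc) and any(s not in scc for s in r.substrates)
            for r in network.reactions
        )
        if not incoming_outside:
            seeds.add(c)
    return frozenset(seeds)


class TestSeedSet:
    def test_single_reaction(self):
        ss = seed_set(_net("o", _rxn("r", ["A"], ["B"])))
        assert ss.seeds == {"A"}

    def test_cycle_forms_one_source_component(self):
        ss = seed_set(_net("o", _rxn("r1", ["A"], ["B"]), _rxn("r2", ["B"], ["A"]),
                           _rxn("r3", ["B"], ["C"])))
        assert ss.seeds == {"A", "B"}
        assert frozenset({"A", "B"}) in ss.seed_components
        assert "C" not in ss.seeds

    def test_disconnected_chains_both_heads(self):
        ss = seed_set(_net("o", _rxn("r1", ["A"], ["B"]), _rxn("r2", ["X"], ["Y"])))
        assert ss.seeds == {"A", "X"}
        assert len(ss.seed_components) == 2

    def test_empty_network_warns_empty(self):
        ss = seed_set(_net("o"))
        assert ss.seeds == frozenset()

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_reachability_oracle(self, seed):
        u = make_random_universe(
            n_compounds=random.Random(seed).randint(4, 20),
            n_reactions=random.Random(seed + 1).randint(1, 25),
            reversible_fraction=0.3, seed=seed)
        net = MetabolicNetwork("all", frozenset(u.reactions.values()))
        assert seed_set(net).seeds == _seed_oracle(net)


class TestCompetitionScore:
    def test_disjoint_seed_sets_zero(self):
        row = _net("row", _rxn("r1", ["A"], ["T"]))
        col = _net("col", _rxn("r2", ["X"], ["Y"]))
        targets = TargetSet(frozenset({"T"}))
        assert competition_score(row, col, targets) == 0.0

    def test_identical_seed_dependent_networks_one(self):
        r = _rxn("r1", ["A"], ["T"])
        targets = TargetSet(frozenset({"T"}))
        assert competition_score(_net("a", r), _net("b", r), targets) == 1.0

    def test_half_overlap_gives_half(self):
        row = _net("row", _rxn("r1", ["s1"], ["t1"]), _rxn("r2", ["s2"], ["t2"]))
        col = _net("col", _rxn("r3", ["s1"], ["x"]))
        targets = TargetSet(frozenset({"t1", "t2"}))
        assert competition_score(row, col, targets) == pytest.approx(0.5)

    def test_no_producible_targets_scores_zero(self):
        row = _net("row", _rxn("r1", ["A"], ["B"]))
        col = _net("col", _rxn("r2", ["A"], ["C"]))
        assert competition_score(row, col, TargetSet(frozenset({"Z"}))) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_scores_bounded_on_random_networks(self, seed):
        u = make_random_universe(15, 20, seed=seed)
        reactions = sorted(u.reactions.values(), key=lambda r: r.id)
        a = MetabolicNetwork("a", frozenset(reactions[: len(reactions) // 2]))
        b = MetabolicNetwork("b", frozenset(reactions[len(reactions) // 3:]))
        targets = TargetSet(frozenset(sorted(u.compounds)[:6]))
        for row, col in [(a, b), (b, a)]:
            if not row.reactions or not col.reactions:
                continue
            s = competition_score(row, col, targets)
            assert 0.0 <= s <= 1.0


class TestCompetitionMatrix:
    def test_identical_networks_symmetric(self):
        r = _rxn("r1", ["A"], ["T"])
        m = competition_matrix([_net("a", r), _net("b", r)],
                               TargetSet(frozenset({"T"})))
        assert m["a", "b"] == m["b", "a"] == 1.0

    def test_matches_per_cell_evaluation(self):
        fix = plant_shared_seeds(4, 2, 2, 3, seed=11)
        nets = [network_from_ecs(fix.universe, a) for a in fix.annotations]
        m = competition_matrix(nets, fix.targets)
        for row in nets:
            for col in nets:
                if row.organism_id == col.organism_id:
                    continue
                assert m[row.organism_id, col.organism_id] == pytest.approx(
                    competition_score(row, col, fix.targets))

    def test_planted_shared_seed_scores_exact(self):
        fix = plant_shared_seeds(3, 1, 1, 2, seed=1)
        nets = [network_from_ecs(fix.universe, a) for a in fix.annotations]
        m = competition_matrix(nets, fix.targets)
        for a in m.organism_ids:
            for b in m.organism_ids:
                if a != b:
                    assert m[a, b] == pytest.approx(fix.expected_scores.loc[a, b])

    def test_zero_shared_seeds_all_zero(self):
        fix = plant_shared_seeds(3, 0, 2, 2, seed=2)
        nets = [network_from_ecs(fix.universe, a) for a in fix.annotations]
        m = competition_matrix(nets, fix.targets)
        for a in m.organism_ids:
            for b in m.organism_ids:
                if a != b:
                    assert m[a, b] == 0.0


class TestDependencyScan:
    def test_unconsumed_source_scores_zero(self):
        toy = tryptophan_toy()
        from symbionet.reaction_universe import Environment
        env = Environment("host", toy.env_host.source_metabolites | {"UNUSED"})
        row = dependency_scan(toy.networks["Portiera"], env, toy.targets)
        assert row["UNUSED"] == 0

    def test_tryptophan_precursors_each_cost_one_target(self, trp):
        row = dependency_scan(trp.networks["Portiera"], trp.env_host, trp.targets)
        for precursor in ("R5P", "E4P", "PEP"):
            assert row[precursor] == 1
        assert row["HCY"] == 1  # methionine from homocysteine

    def test_thiamine_affects_only_kinase_carrier(self, thiamine):
        table = dependency_table(
            [thiamine.networks["Wolbachia"], thiamine.networks["Rickettsia"]],
            thiamine.env_host, thiamine.targets)
        assert table.loc["Wolbachia", "THI"] == 1
        assert table.loc["Rickettsia", "THI"] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_removal_never_increases_counts(self, seed):
        u = make_random_universe(15, 25, seed=seed)
        net = MetabolicNetwork("all", frozenset(u.reactions.values()))
        from symbionet.reaction_universe import Environment
        env = Environment("e", frozenset(sorted(u.compounds)[:6]))
        targets = TargetSet(frozenset(sorted(u.compounds)[6:12]))
        row = dependency_scan(net, env, targets)
        assert (row >= 0).all()
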