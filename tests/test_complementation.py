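"""Complementary-metabolite detection, masking, profiles and PCA."""

import numpy as np
import pandas as pd
import pytest

from symbionet.complementation import (
    MASK_BOTH,
    MASK_HOST_ONLY,
    ComplementationProfile,
    ComplementationResult,
    build_profile,
    complementary_metabolites,
    kwise_complementary,
    masking_classify,
    pca_cluster_profiles,
)
from symbionet.environments import derive_host_portiera
from symbionet.expansion import expand
from symbionet.reaction_universe import (
    DirectedReaction,
    Environment,
    MetabolicNetwork,
    merge_networks,
)
from symbionet.synthetic_data import (
    lysine_toy,
    make_linear_pathway,
    plant_split_pathway,
)
from symbionet.reaction_universe import network_from_ecs


def _net(org, *reactions):
    return MetabolicNetwork(org, frozenset(reactions))


def _rxn(rid, sub, prod):
    return DirectedReaction(rid, frozenset({"1.1.1.1"}),
                            frozenset(sub), frozenset(prod))


ENV_S = Environment("host", frozenset({"S"}))


class TestPairwise:
    def test_identical_networks_yield_nothing(self):
        r = _rxn("r", ["S"], ["X"])
        a, b = _net("a", r), _net("b", r)
        assert complementary_metabolites(a, b, ENV_S).complementary == frozenset()

    def test_split_linear_pathway(self):
        a = _net("a", _rxn("r1", ["S"], ["X"]))
        b = _net("b", _rxn("r2", ["X"], ["T"]))
        res = complementary_metabolites(a, b, ENV_S)
        assert res.complementary == {"T"}
        assert res.complementary == complementary_metabolites(b, a, ENV_S).complementary

    def test_same_organism_rejected(self):
        a = _net("a", _rxn("r1", ["S"], ["X"]))
        with pytest.raises(ValueError):
            complementary_metabolites(a, a, ENV_S)

    def test_superadditivity_excess(self):
        a = _net("a", _rxn("r1", ["S"], ["X"]))
        b = _net("b", _rxn("r2", ["X"], ["T"]))
        sa = expand(ENV_S, a).scope
        sb = expand(ENV_S, b).scope
        sab = expand(ENV_S, merge_networks([a, b])).scope
        assert sa | sb <= sab
        assert complementary_metabolites(a, b, ENV_S).complementary == sab - (sa | sb)

    def test_lysine_toy_pair(self):
        toy = lysine_toy()
        res = complementary_metabolites(
            toy.networks["Wolbachia"], toy.networks["Hamiltonella"], toy.env_host)
        assert "LYS" in res.complementary


class TestKwise:
    def _three_way(self):
        u = make_linear_pathway(3, "K")
        return plant_split_pathway(u, [1, 2], ["g1", "g2", "g3"], "K")

    def test_k2_reduces_to_pairwise(self):
        fix = self._three_way()
        nets = {a.organism_id: network_from_ecs(fix.universe, a)
                for a in fix.annotations}
        pairwise = complementary_metabolites(nets["g1"], nets["g2"], fix.environment)
        k2 = kwise_complementary([nets["g1"], nets["g2"]], fix.environment)
        assert pairwise.complementary == k2.complementary

    def test_three_way_split(self):
        fix = self._three_way()
        nets = {a.organism_id: network_from_ecs(fix.universe, a)
                for a in fix.annotations}
        triple = kwise_complementary(list(nets.values()), fix.environment)
        assert triple.complementary == {"K_c3"}
        assert kwise_complementary(
            [nets["g1"], nets["g3"]], fix.environment).complementary == frozenset()

    def test_pair_completing_pathway_voids_triple(self):
        # g1 and g2 span the whole chain; adding g3 brings nothing new
        u = make_linear_pathway(2, "Q")
        fix = plant_split_pathway(u, [1], ["g1", "g2"], "Q")
        nets = {a.organism_id: network_from_ecs(fix.universe, a)
                for a in fix.annotations}
        extra = MetabolicNetwork("g3", frozenset())
        triple = kwise_complementary(
            [nets["g1"], nets["g2"], extra], fix.environment)
        assert triple.complementary == frozenset()

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            kwise_complementary([MetabolicNetwork("a", frozenset())], ENV_S)


class TestMasking:
    def test_lysine_masked_once_obligate_enriches(self):
        toy = lysine_toy()
        pair = [toy.networks["Wolbachia"], toy.networks["Hamiltonella"]]
        env_hp = derive_host_portiera(toy.env_host, toy.networks["Portiera"])
        labels = masking_classify(pair, toy.env_host, env_hp)
        assert labels["LYS"] == MASK_HOST_ONLY

    def test_both_envs_label(self):
        a = _net("a", _rxn("r1", ["S"], ["X"]))
        b = _net("b", _rxn("r2", ["X"], ["T"]))
        env2 = Environment("host+P", frozenset({"S", "U"}))
        labels = masking_classify([a, b], ENV_S, env2)
        assert labels == {"T": MASK_BOTH}

    def test_empty_complementary_sets_vacuous(self):
        r = _rxn("r", ["S"], ["X"])
        labels = masking_classify([_net("a", r), _net("b", r)], ENV_S,
                                  Environment("e2", frozenset({"S"})))
        assert labels == {}

    def test_environment_growth_can_remove_complementarity(self):
        # scopes grow with the environment, complementary sets need not
        toy = lysine_toy()
        pair = [toy.networks["Wolbachia"], toy.networks["Hamiltonella"]]
        env_hp = derive_host_portiera(toy.env_host, toy.networks["Portiera"])
        assert toy.env_host.source_metabolites < env_hp.source_metabolites
        comp_host = kwise_complementary(pair, toy.env_host).complementary
        comp_hp = kwise_complementary(pair, env_hp).complementary
        assert "LYS" in comp_host and "LYS" not in comp_hp


class TestProfile:
    def _result(self, label, env, mets):
        return ComplementationResult(tuple(label.split("+")), env, frozenset(mets))

    def test_single_result_all_ones(self):
        p = build_profile([self._result("a+b", "host", {"m1", "m2", "m3"})])
        assert p.incidence.shape == (1, 3)
        assert (p.incidence.to_numpy() == 1).all()

    def test_disjoint_results_block_structure(self):
        p = build_profile([
            self._result("a+b", "host", {"m1", "m2"}),
            self._result("c+d", "host", {"n1", "n2", "n3"}),
        ])
        assert p.incidence.shape == (2, 5)
        assert list(p.incidence.columns) == sorted(p.incidence.columns)
        assert p.incidence.to_numpy().sum() == 5
        assert (p.incidence.loc["a+b@host"] == 0).sum() == 3

    def test_row_sums_are_complementary_counts(self):
        results = [
            self._result("a+b", "host", {"m1", "m2"}),
            self._result("a+c", "host", {"m2"}),
            self._result("b+c", "host", set()),
        ]
        p = build_profile(results)
        sums = p.incidence.sum(axis=1)
        assert sums["a+b@host"] == 2 and sums["a+c@host"] == 1 and sums["b+c@host"] == 0


class TestPCACluster:
    def test_identical_rows_zero_coordinates(self):
        inc = pd.DataFrame([[1, 0, 1]] * 3, index=list("abc"),
                           columns=["m1", "m2", "m3"])
        profile = ComplementationProfile(inc, {})
        with pytest.warns(UserWarning, match="zero variance"):
            coords, clusters = pca_cluster_profiles(profile, n_clusters=1)
        assert np.allclose(coords.to_numpy(), 0)

    def test_orthogonal_groups_separate_on_pc1(self):
        inc = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=["r1", "r2", "r3", "r4"], columns=list("wxyz"))
        profile = ComplementationProfile(inc, {})
        coords, clusters = pca_cluster_profiles(profile, n_clusters=2)
        pc1 = coords["PC1"]
        assert np.sign(pc1["r1"]) == np.sign(pc1["r2"])
        assert np.sign(pc1["r3"]) == np.sign(pc1["r4"])
        assert np.sign(pc1["r1"]) != np.sign(pc1["r3"])
        assert clusters["r1"] == clusters["r2"]
        assert clusters["r3"] == clusters["r4"]
        assert clusters["r1"] != clusters["r3"]

    def test_deterministic_sign_convention(self):
        inc = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
            index=list("abcd"), columns=["m1", "m2", "m3"])
        profile = ComplementationProfile(inc, {})
        c1, _ = pca_cluster_profiles(profile, n_clusters=2)
        c2, _ = pca_cluster_profiles(profile, n_clusters=2)
        pd.testing.assert_frame_equal(c1, c2)
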