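"""Randomization, enrichment, supergene, subtype and spectrum analyses."""

import numpy as np
import pytest

from bewith.evaluation import (cosmic_contexts, decompose_spectrum,
                               driver_enrichment, empirical_pvalue,
                               randomize_network, subtype_enrichment,
                               supergene_me)
from bewith.mutnet import PairNetwork
from bewith.pair_stats import fisher_exact_2x2


def degree_sequence(weight_map):
    deg = {}
    for a, b in weight_map:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg


@pytest.fixture
def net():
    w_me = {("a", "b"): 0.5, ("c", "d"): 0.6, ("a", "c"): 0.7,
            ("b", "d"): 0.8, ("a", "d"): 0.9}
    w_co = {("e", "f"): 0.4, ("f", "g"): 0.3}
    w_f = {("a", "e"): 0.9, ("b", "f"): 0.8, ("c", "g"): 0.7}
    return PairNetwork(nodes=set("abcdefg"), w_me=w_me, w_co=w_co, w_f=w_f)


class TestRandomizeNetwork:
    def test_degree_sequence_preserved(self, net):
        out = randomize_network(net, which="ME", seed=1)
        assert degree_sequence(out.w_me) == degree_sequence(net.w_me)

    def test_unselected_sets_untouched(self, net):
        out = randomize_network(net, which="ME", seed=1)
        assert out.w_co == net.w_co and out.w_f == net.w_f

    def test_weights_travel_with_edges(self, net):
        out = randomize_network(net, which="all", seed=2)
        assert sorted(out.w_me.values()) == sorted(net.w_me.values())

    def test_reproducible(self, net):
        a = randomize_network(net, which="all", seed=5)
        b = randomize_network(net, which="all", seed=5)
        assert a.w_me == b.w_me and a.w_co == b.w_co and a.w_f == b.w_f

    def test_tiny_edge_set_returned_unchanged(self):
        tiny = PairNetwork(nodes={"a", "b"}, w_me={("a", "b"): 1.0})
        with pytest.warns(UserWarning, match="too small"):
            out = randomize_network(tiny, which="ME", seed=0)
        assert out.w_me == tiny.w_me

    def test_four_cycle_reachable_rewirings(self):
        # a 4-cycle admits exactly the three 2-regular pairings of 4 nodes;
        # double-edge swaps keep 2-regularity, so every rewiring is one of
        # the three perfect pairings (the cycle itself included)
        cycle = PairNetwork(nodes=set("abcd"),
                            w_me={("a", "b"): 1, ("b", "c"): 1,
                                  ("c", "d"): 1, ("a", "d"): 1})
        seen = set()
        for seed in range(40):
            out = randomize_network(cycle, which="ME", seed=seed)
            seen.add(frozenset(out.w_me))
            assert degree_sequence(out.w_me) == {g: 2 for g in "abcd"}
        # both 4-cycles on {a,b,c,d} are reachable (the "diagonal" pairing
        # K2+K2 has multi-edges and is excluded by simple-graph swaps)
        assert len(seen) >= 2

    def test_unknown_selection_rejected(self, net):
        with pytest.raises(ValueError):
            randomize_network(net, which="bogus")


class TestEmpiricalPvalue:
    def test_real_above_all_hundred_nulls(self):
        nulls = np.linspace(0.0, 50.0, 100).tolist()
        assert empirical_pvalue(57.60, nulls) == pytest.approx(1 / 101)

    def test_real_below_all(self):
        assert empirical_pvalue(-1.0, [0.0, 1.0]) == 1.0

    def test_ties_count_against(self):
        assert empirical_pvalue(5.0, [5.0] * 10) == 1.0

    def test_monotone_in_real_value(self):
        nulls = [0.1, 0.5, 0.9]
        ps = [empirical_pvalue(v, nulls) for v in (0.0, 0.4, 0.8, 1.2)]
        assert ps == sorted(ps, reverse=True)


class TestEvaluateRun:
    def test_zero_randomizations_gives_real_row_only(self, net):
        from bewith.evaluation import evaluate_run
        from bewith.ilp_core import BeWithConfig

        cfg = BeWithConfig(k_modules=2, max_module_size=3, use_density=False,
                           use_between_edge=False)
        table = evaluate_run(net, "beme-withfun", cfg, n_random=0, seed=0)
        assert len(table) == 1 and table.iloc[0].features == "Real data"

    def test_me_only_scheme_preserves_other_relations(self, net):
        from bewith.evaluation import randomize_network

        out = randomize_network(net, which="ME", seed=3)
        assert out.w_f == net.w_f and out.w_co == net.w_co


class TestDriverEnrichment:
    def test_closed_form_two_of_two(self):
        p = driver_enrichment(["g1", "g2"], [f"g{i}" for i in range(1, 5)],
                              [f"g{i}" for i in range(1, 11)])
        assert p == pytest.approx(6 / 45 + 0.0, rel=1e-12) or p == pytest.approx(
            (6 / 45), rel=1e-9)

    def test_zero_driver_module_p_is_one(self):
        p = driver_enrichment(["x"], ["d1"], ["x", "d1", "y"])
        assert p == pytest.approx(1.0)

    def test_module_equals_universe(self):
        p = driver_enrichment(["a", "b"], ["a"], ["a", "b"])
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            driver_enrichment([], [], [])


class TestSupergeneMe:
    def test_single_gene_module_reports_nothing(self, matrix_factory):
        m = matrix_factory({"A": [0, 1], "B": [2, 3], "C": [0, 2]}, 4)
        out = supergene_me(m, ["A"], n_draws=200, seed=0)
        assert out.empty

    def test_merged_module_beats_members(self, matrix_factory):
        # two rare module genes; candidate exclusive with their union
        m = matrix_factory({"m1": [0], "m2": [1], "cand": [2, 3, 4, 5],
                            "bg1": [0, 2, 4], "bg2": [1, 3, 5]}, 6)
        out = supergene_me(m, ["m1", "m2"], candidate_genes=["cand"],
                           alpha=0.6, n_draws=4000, seed=1)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.supergene_p < row.best_member_p

    def test_cooccurring_candidate_excluded(self, matrix_factory):
        m = matrix_factory({"m1": [0, 1], "m2": [2, 3], "cand": [0, 1, 2, 3],
                            "bg": [4, 5]}, 6)
        out = supergene_me(m, ["m1", "m2"], candidate_genes=["cand"],
                           alpha=0.05, n_draws=1000, seed=2)
        assert out.empty

    def test_reported_pairs_respect_alpha(self, matrix_factory):
        rng = np.random.default_rng(0)
        profiles = {f"g{i}": sorted(rng.choice(8, size=3, replace=False).tolist())
                    for i in range(6)}
        m = matrix_factory(profiles, 8)
        out = supergene_me(m, ["g0", "g1"], alpha=0.2, n_draws=500, seed=3)
        assert (out["supergene_p"] <= 0.2).all()


class TestSubtypeEnrichment:
    def test_concentrated_module_matches_fisher_tail(self, matrix_factory):
        m = matrix_factory({"A": [0, 1, 2, 3], "B": [4]}, 8)
        labels = {f"s{i+1}": ("lumA" if i < 4 else "basal") for i in range(8)}
        out = subtype_enrichment(m, [["A"]], labels)
        row = out[(out.subtype == "lumA")].iloc[0]
        expected = fisher_exact_2x2([[4, 0], [0, 4]], alternative="greater")
        assert row.p_value == pytest.approx(expected)
        assert row.stars == "***" if expected < 0.01 else True

    def test_uniform_module_not_enriched(self, matrix_factory):
        m = matrix_factory({"A": [0, 1, 4, 5]}, 8)
        labels = {f"s{i+1}": ("x" if i < 4 else "y") for i in range(8)}
        out = subtype_enrichment(m, [["A"]], labels)
        assert (out.p_value > 0.5).all()

    def test_single_subtype_gives_p_one(self, matrix_factory):
        m = matrix_factory({"A": [0, 1]}, 4)
        labels = {f"s{i+1}": "only" for i in range(4)}
        out = subtype_enrichment(m, [["A"]], labels)
        assert (out.p_value == 1.0).all()

    def test_unlabeled_sample_rejected(self, matrix_factory):
        m = matrix_factory({"A": [0]}, 2)
        with pytest.raises(ValueError, match="without subtype"):
            subtype_enrichment(m, [["A"]], {"s1": "x"})


class TestDecomposeSpectrum:
    @pytest.fixture
    def signatures(self):
        rng = np.random.default_rng(4)
        sig = rng.random((96, 3))
        return sig / sig.sum(axis=0)

    def test_pure_signature_recovered(self, signatures):
        out = decompose_spectrum(signatures[:, 1] * 1000, signatures)
        assert out["error"] == pytest.approx(0.0, abs=1e-8)
        assert out["exposures"][1] == pytest.approx(1.0, abs=1e-8)
        assert out["decomposable"]

    def test_mixture_recovered(self, signatures):
        mix = 0.6 * signatures[:, 0] + 0.4 * signatures[:, 2]
        out = decompose_spectrum(mix, signatures)
        assert out["exposures"] == pytest.approx([0.6, 0.0, 0.4], abs=1e-6)
        assert out["error"] < 1e-8

    def test_noise_flagged_not_decomposable(self, signatures):
        rng = np.random.default_rng(8)
        # spectrum concentrated on channels where the signatures are smallest
        weight = signatures.sum(axis=1)
        noise = np.zeros(96)
        noise[np.argsort(weight)[:5]] = rng.random(5) + 1.0
        out = decompose_spectrum(noise, signatures)
        assert not out["decomposable"]

    def test_dimension_mismatch_rejected(self, signatures):
        with pytest.raises(ValueError, match="incompatible"):
            decompose_spectrum(np.ones(95), signatures)

    def test_context_labels(self):
        labels = cosmic_contexts()
        assert len(labels) == 96 and labels[0] == "A[C>A]A" and labels[-1] == "T[T>G]T"
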