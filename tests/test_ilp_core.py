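"""Optimizer correctness: oracle equivalence, integrality, constraints."""

import numpy as np
import pytest

from bewith.ilp_core import (BeWithConfig, ConfigError, add_symmetry_breaking,
                             brute_force_optimum, build_model, solve)
from bewith.mutnet import WeightFunctions


def toy_two_modules():
    """4 genes, two natural 2-gene modules, all cross pairs rewarded."""
    within = {("a", "b"): 1.0, ("c", "d"): 1.0}
    between = {("a", "c"): 1.0, ("a", "d"): 1.0, ("b", "c"): 1.0,
               ("b", "d"): 1.0}
    return WeightFunctions(between_map=between, within_map=within)


class TestBuildModel:
    def test_variable_accounting(self):
        wf = toy_two_modules()
        cfg = BeWithConfig(k_modules=2, max_module_size=2, use_density=False,
                           use_between_edge=False)
        model = build_model(wf, ["a", "b", "c", "d"], cfg)
        n_pairs = len(wf.scored_pairs())
        # y: n*(K+1); per scored pair: K x-vars + u + z
        assert model.n_vars == 4 * 3 + n_pairs * (2 + 2)
        assert int(model.integrality.sum()) == 4 * 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            BeWithConfig(k_modules=0)
        with pytest.raises(ConfigError):
            BeWithConfig(max_module_size=0)
        with pytest.raises(ConfigError):
            BeWithConfig(density=1.5)

    def test_zero_density_is_vacuous(self):
        wf = toy_two_modules()
        genes = ["a", "b", "c", "d"]
        cfg_off = BeWithConfig(k_modules=2, max_module_size=2,
                               use_density=False, use_between_edge=False)
        cfg_zero = BeWithConfig(k_modules=2, max_module_size=2, density=0.0,
                                use_density=True, use_between_edge=False)
        a = solve(build_model(wf, genes, cfg_off))
        b = solve(build_model(wf, genes, cfg_zero))
        assert a.objective == pytest.approx(b.objective)

    def test_empty_ey_with_between_edge_forces_all_unselected(self):
        wf = toy_two_modules()  # e_y empty by default
        cfg = BeWithConfig(k_modules=2, max_module_size=2, use_density=False,
                           use_between_edge=True)
        res = solve(build_model(wf, ["a", "b", "c", "d"], cfg))
        assert res.nonempty_modules() == []
        assert res.objective == pytest.approx(0.0)


class TestSolve:
    def test_toy_optimum(self):
        cfg = BeWithConfig(k_modules=2, max_module_size=2, use_density=False,
                           use_between_edge=False)
        res = solve(build_model(toy_two_modules(), list("abcd"), cfg))
        assert res.objective == pytest.approx(6.0)
        assert res.module_sets() == {frozenset("ab"), frozenset("cd")}

    def test_all_zero_weights(self):
        wf = WeightFunctions()
        cfg = BeWithConfig(k_modules=2, max_module_size=3, use_density=False,
                           use_between_edge=False)
        res = solve(build_model(wf, list("abc"), cfg))
        assert res.objective == pytest.approx(0.0)

    def test_negative_within_leaves_genes_apart(self):
        within = {(a, b): -1.0 for a, b in
                  [("a", "b"), ("a", "c"), ("b", "c")]}
        wf = WeightFunctions(within_map=within)
        cfg = BeWithConfig(k_modules=2, max_module_size=3, use_density=False,
                           use_between_edge=False)
        res = solve(build_model(wf, list("abc"), cfg))
        assert res.objective == pytest.approx(0.0)
        for mod in res.nonempty_modules():
            assert len(mod) == 1

    def test_empty_universe(self):
        res = solve(build_model(WeightFunctions(), [], BeWithConfig()))
        assert res.objective == 0.0 and res.unselected == []


class TestSymmetryBreaking:
    def test_objective_preserved_on_random_instances(self, instance_factory):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            wf = instance_factory(rng, n)
            cfg = BeWithConfig(k_modules=int(rng.integers(1, 4)),
                               max_module_size=int(rng.integers(2, 5)),
                               use_density=False, use_between_edge=False)
            genes = sorted({g for p in wf.scored_pairs() for g in p})
            if not genes:
                continue
            plain = solve(build_model(wf, genes, cfg))
            broken = solve(add_symmetry_breaking(build_model(wf, genes, cfg)))
            assert broken.objective == pytest.approx(plain.objective, abs=1e-6)

    def test_k1_is_effectively_noop(self):
        wf = toy_two_modules()
        cfg = BeWithConfig(k_modules=1, max_module_size=2, use_density=False,
                           use_between_edge=False)
        model = add_symmetry_breaking(build_model(wf, list("abcd"), cfg))
        res = solve(model)
        assert res.objective == pytest.approx(1.0)  # one best pair


class TestBruteForceOracle:
    def test_toy_matches_definition(self):
        cfg = BeWithConfig(k_modules=2, max_module_size=2, use_density=False,
                           use_between_edge=False)
        res = brute_force_optimum(toy_two_modules(), list("abcd"), cfg)
        assert res.objective == pytest.approx(6.0)

    def test_single_gene_scores_zero(self):
        res = brute_force_optimum(WeightFunctions(), ["a"],
                                  BeWithConfig(k_modules=1, max_module_size=1,
                                               use_density=False,
                                               use_between_edge=False))
        assert res.objective == 0.0

    def test_refuses_huge_instances(self):
        genes = [f"g{i}" for i in range(30)]
        with pytest.raises(ValueError, match="too large"):
            brute_force_optimum(WeightFunctions(), genes, BeWithConfig(k_modules=3))

    @pytest.mark.parametrize("use_density,use_between_edge",
                             [(False, False), (True, False), (False, True),
                              (True, True)])
    def test_solver_agrees_with_enumeration(self, instance_factory,
                                            use_density, use_between_edge):
        rng = np.random.default_rng(7 + use_density + 2 * use_between_edge)
        for _ in range(10):
            n = int(rng.integers(3, 7))
            wf = instance_factory(rng, n)
            cfg = BeWithConfig(
                k_modules=int(rng.integers(1, 3)),
                max_module_size=int(rng.integers(2, 5)),
                density=float(rng.choice([0.3, 0.5, 1.0])),
                use_density=use_density, use_between_edge=use_between_edge)
            genes = [chr(ord("a") + i) for i in range(n)]
            exact = brute_force_optimum(wf, genes, cfg)
            got = solve(add_symmetry_breaking(build_model(wf, genes, cfg)))
            assert got.objective == pytest.approx(exact.objective, abs=1e-6)


class TestConnectivity:
    def test_dense_modules_connected_in_ex(self, instance_factory):
        import networkx as nx

        rng = np.random.default_rng(99)
        for _ in range(15):
            wf = instance_factory(rng, int(rng.integers(4, 8)))
            cfg = BeWithConfig(k_modules=2, max_module_size=4, density=0.5,
                               use_density=True, use_between_edge=False)
            genes = sorted({g for p in wf.scored_pairs() for g in p} |
                           {g for p in wf.e_x for g in p})
            if len(genes) < 2:
                continue
            res = solve(add_symmetry_breaking(build_model(wf, genes, cfg)))
            for mod in res.nonempty_modules():
                sub = nx.Graph()
                sub.add_nodes_from(mod)
                sub.add_edges_from(
                    (a, b) for a, b in wf.e_x if a in set(mod) and b in set(mod))
                assert nx.is_connected(sub)


class TestLpExport:
    def test_export_mentions_all_variable_families(self, tmp_path):
        cfg = BeWithConfig(k_modules=2, max_module_size=2, use_density=False,
                           use_between_edge=False)
        model = build_model(toy_two_modules(), list("abcd"), cfg)
        path = tmp_path / "model.lp"
        model.export_lp(path)
        text = path.read_text()
        for tag in ("y[", "x[", "u[", "z[", "Maximize", "Binaries"):
            assert tag in text
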