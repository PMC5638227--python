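"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: the
weighted-sampling null is evaluated by exhaustive enumeration over all
subset placements (summing sequential-draw probabilities over permutations),
and small optimization instances are checked by direct search over labelings
in ``bewith.ilp_core.brute_force_optimum`` (itself solver-free).
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest

from bewith.io_formats import MutationMatrix
from bewith.mutnet import WeightFunctions


def make_matrix(profiles: dict[str, list[int]], n_samples: int) -> MutationMatrix:
    """Matrix from gene -> list of mutated sample indices."""
    genes = sorted(profiles)
    values = np.zeros((len(genes), n_samples), dtype=np.int8)
    for i, g in enumerate(genes):
        values[i, profiles[g]] = 1
    samples = [f"s{i+1}" for i in range(n_samples)]
    return MutationMatrix(genes=genes, samples=samples, values=values)


def subset_probability(weights: np.ndarray, subset: tuple[int, ...]) -> float:
    """P(drawing exactly this subset) under sequential weighted sampling
    without replacement, summed over all draw orders."""
    total = weights.sum()
    prob = 0.0
    for order in permutations(subset):
        p = 1.0
        remaining = total
        for idx in order:
            p *= weights[idx] / remaining
            remaining -= weights[idx]
        prob += p
    return prob


def enumeration_null_pvalue(matrix: MutationMatrix, gene_i: str, gene_j: str,
                            statistic: str) -> float:
    """Exact tail probability of the weighted-sampling null.

    Enumerates every pair of placements of the two genes' mutated-sample
    sets; ``statistic`` is ``"coverage"`` (exclusivity, upper tail) or
    ``"overlap"`` (co-occurrence, upper tail).
    """
    weights = matrix.freq.astype(float)
    n = matrix.n_samples
    n_i = int(matrix.row(gene_i).sum())
    n_j = int(matrix.row(gene_j).sum())
    row_i = matrix.row(gene_i).astype(bool)
    row_j = matrix.row(gene_j).astype(bool)
    if statistic == "coverage":
        observed = int((row_i ^ row_j).sum())
    else:
        observed = int((row_i & row_j).sum())
    tail = 0.0
    sets_i = [(s, subset_probability(weights, s))
              for s in combinations(range(n), n_i)]
    sets_j = [(s, subset_probability(weights, s))
              for s in combinations(range(n), n_j)]
    for si, pi in sets_i:
        for sj, pj in sets_j:
            overlap = len(set(si) & set(sj))
            stat = n_i + n_j - 2 * overlap if statistic == "coverage" else overlap
            if stat >= observed:
                tail += pi * pj
    return min(tail, 1.0)  # guard accumulated rounding above 1


def random_weight_instance(rng: np.random.Generator, n_genes: int,
                           edge_prob: float = 0.6) -> WeightFunctions:
    """Random dense-ish weights in [-1, 1] with random E_X/E_Y edge sets."""
    genes = [chr(ord("a") + i) for i in range(n_genes)]
    between, within = {}, {}
    e_x, e_y = set(), set()
    for a, b in combinations(genes, 2):
        if rng.random() < edge_prob:
            within[(a, b)] = float(rng.uniform(-1, 1))
        if rng.random() < edge_prob:
            between[(a, b)] = float(rng.uniform(-1, 1))
        if rng.random() < edge_prob:
            e_x.add((a, b))
        if rng.random() < edge_prob:
            e_y.add((a, b))
    return WeightFunctions(between_map=between, within_map=within,
                           e_x=e_x, e_y=e_y)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def null_oracle():
    return enumeration_null_pvalue


@pytest.fixture
def instance_factory():
    return random_weight_instance


@pytest.fixture
def uniform4(matrix_factory):
    """4 uniform-frequency samples: two disjoint 2-sample genes."""
    return matrix_factory({"gA": [0, 1], "gB": [2, 3]}, 4)
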