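"""Per-gene-pair statistics on binary mutation matrices.

Two families of tests are provided:

* closed-form tests — upper-tail hypergeometric co-occurrence and Fisher's
  exact test on a 2x2 table;
* weighted-sampling permutation tests for mutual exclusivity (WeSME) and
  co-occurrence (WeSCO).  The null redraws each gene's mutated-sample set
  independently, without replacement, with per-sample inclusion weight
  proportional to the sample's total mutation count ``freq[s]``.  This
  conditions on the heterogeneity of mutation burden across patients: a pair
  of genes concentrated in heavily mutated samples is not called co-occurring
  merely because those samples are mutated everywhere.

The ME statistic is the coverage (samples mutated in exactly one of the two
genes, large when exclusive); the CO statistic is the overlap (samples mutated
in both).  p-values use the add-one permutation estimator
``(1 + #{null >= observed}) / (1 + n_draws)`` and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "PairTestResult",
    "hypergeom_cooccurrence",
    "fisher_exact_2x2",
    "wesme_pvalue",
    "wesco_pvalue",
    "all_pairs_test",
]


@dataclass(frozen=True)
class PairTestResult:
    """Outcome of one pairwise test."""

    gene_i: str
    gene_j: str
    overlap: int  # samples mutated in both genes
    coverage: int  # samples mutated in exactly one gene
    p_value: float
    test_name: str
    n_draws: int | None = None  # only for sampling tests

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def hypergeom_cooccurrence(k_overlap: int, n_i: int, n_j: int, n_samples: int) -> float:
    """Upper-tail hypergeometric co-occurrence p-value, P(X >= k_overlap).

    X is the overlap of two random sample sets of sizes ``n_i`` and ``n_j``
    drawn uniformly from ``n_samples`` patients.
    """
    if not (0 <= k_overlap <= min(n_i, n_j) <= n_samples):
        raise ValueError(
            f"require 0 <= k ({k_overlap}) <= min(n_i, n_j) "
            f"({min(n_i, n_j)}) <= n_samples ({n_samples})"
        )
    return float(stats.hypergeom.sf(k_overlap - 1, n_samples, n_i, n_j))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be nonnegative")
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def _sample_weights(matrix) -> np.ndarray:
    freq = matrix.freq.astype(float)
    total = freq.sum()
    if total == 0:
        raise ValueError("matrix has no mutations")
    return freq / total


def _null_member_sets(weights: np.ndarray, n_mut: int, n_draws: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Null mutated-sample sets: ``n_draws`` x ``n_samples`` boolean array.

    Each row is a weighted sample without replacement of ``n_mut`` samples.
    Uses the Gumbel top-k construction, equivalent to successive draws with
    probability proportional to the remaining weight.  Samples with zero
    weight are never drawn.
    """
    n = weights.size
    logw = np.full(n, -np.inf)
    pos = weights > 0
    logw[pos] = np.log(weights[pos])
    keys = logw[None, :] + rng.gumbel(size=(n_draws, n))
    top = np.argpartition(-keys, n_mut - 1, axis=1)[:, :n_mut]
    out = np.zeros((n_draws, n), dtype=bool)
    np.put_along_axis(out, top, True, axis=1)
    return out


def _check_testable(matrix, gene: str) -> np.ndarray:
    row = matrix.row(gene).astype(bool)
    if not row.any():
        raise ValueError(f"untestable gene {gene!r}: 0 mutations")
    return row


def _sampling_pvalue(matrix, gene_i: str, gene_j: str, n_draws: int, seed,
                     tail: str) -> PairTestResult:
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    row_i = _check_testable(matrix, gene_i)
    row_j = _check_testable(matrix, gene_j)
    obs_overlap = int((row_i & row_j).sum())
    obs_coverage = int((row_i ^ row_j).sum())
    weights = _sample_weights(matrix)
    rng = np.random.default_rng(seed)
    null_i = _null_member_sets(weights, int(row_i.sum()), n_draws, rng)
    null_j = _null_member_sets(weights, int(row_j.sum()), n_draws, rng)
    null_overlap = (null_i & null_j).sum(axis=1)
    if tail == "coverage":  # mutual exclusivity
        null_stat = int(row_i.sum()) + int(row_j.sum()) - 2 * null_overlap
        observed, name = obs_coverage, "wesme"
    else:  # co-occurrence
        null_stat, observed, name = null_overlap, obs_overlap, "wesco"
    b = int((null_stat >= observed).sum())
    return PairTestResult(
        gene_i=gene_i,
        gene_j=gene_j,
        overlap=obs_overlap,
        coverage=obs_coverage,
        p_value=(1 + b) / (1 + n_draws),
        test_name=name,
        n_draws=n_draws,
    )


def wesme_pvalue(matrix, gene_i: str, gene_j: str, n_draws: int = 10000,
                 seed=None) -> PairTestResult:
    """Weighted-sampling mutual-exclusivity test (statistic: coverage)."""
    return _sampling_pvalue(matrix, gene_i, gene_j, n_draws, seed, tail="coverage")


def wesco_pvalue(matrix, gene_i: str, gene_j: str, n_draws: int = 10000,
                 seed=None) -> PairTestResult:
    """Weighted-sampling co-occurrence test (statistic: overlap)."""
    return _sampling_pvalue(matrix, gene_i, gene_j, n_draws, seed, tail="overlap")


def all_pairs_test(matrix, test: str = "wesme", alpha: float = 1.0,
                   n_draws: int = 10000, seed=None,
                   min_mut: int = 3) -> list[PairTestResult]:
    """Test all unordered pairs of sufficiently mutated genes.

    Genes with fewer than ``min_mut`` mutated samples are skipped.  Only pairs
    with ``p <= alpha`` are returned.  For the sampling tests the per-gene
    null sample sets are drawn once and shared across pairs, so the run is
    deterministic given ``seed`` and independent of gene enumeration order.

    Parameters
    ----------
    test
        ``"wesme"``, ``"wesco"`` or ``"hypergeom"`` (upper-tail co-occurrence).
    """
    if test not in {"wesme", "wesco", "hypergeom"}:
        raise ValueError(f"unknown test {test!r}")
    counts = matrix.gene_counts()
    genes = [g for g in matrix.genes if counts[g] >= min_mut]
    if alpha <= 0 or len(genes) < 2:
        return []

    results: list[PairTestResult] = []
    if test == "hypergeom":
        sub = np.stack([matrix.row(g) for g in genes]).astype(np.int64)
        overlap = sub @ sub.T
        n = matrix.n_samples
        for a, b in combinations(range(len(genes)), 2):
            gi, gj = genes[a], genes[b]
            p = hypergeom_cooccurrence(int(overlap[a, b]), int(counts[gi]),
                                       int(counts[gj]), n)
            if p <= alpha:
                cov = int(counts[gi] + counts[gj] - 2 * overlap[a, b])
                results.append(PairTestResult(gi, gj, int(overlap[a, b]), cov,
                                              p, "hypergeom"))
        return results

    # sampling tests: one packed null array per gene, popcount per pair
    weights = _sample_weights(matrix)
    rng = np.random.default_rng(seed)
    packed = {}
    for g in genes:  # draw order fixed by matrix gene order
        null = _null_member_sets(weights, int(counts[g]), n_draws, rng)
        packed[g] = np.packbits(null, axis=1)
    for gi, gj in combinations(genes, 2):
        null_overlap = np.bitwise_count(packed[gi] & packed[gj]).sum(axis=1)
        row_i, row_j = matrix.row(gi).astype(bool), matrix.row(gj).astype(bool)
        obs_overlap = int((row_i & row_j).sum())
        obs_coverage = int((row_i ^ row_j).sum())
        n_i, n_j = int(counts[gi]), int(counts[gj])
        if test == "wesme":
            null_stat = n_i + n_j - 2 * null_overlap
            observed = obs_coverage
        else:
            null_stat = null_overlap
            observed = obs_overlap
        b = int((null_stat >= observed).sum())
        p = (1 + b) / (1 + n_draws)
        if p <= alpha:
            results.append(PairTestResult(gi, gj, obs_overlap, obs_coverage,
                                          p, test, n_draws))
    return results


def write_pair_results(results, path) -> None:
    """Write pair results as TSV: gene_i, gene_j, test, statistic, p_value."""
    import pandas as pd

    rows = [
        {
            "gene_i": r.gene_i,
            "gene_j": r.gene_j,
            "test": r.test_name,
            "statistic": r.coverage if r.test_name == "wesme" else r.overlap,
            "p_value": r.p_value,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "test", "statistic",
                                "p_value"]).to_csv(path, sep="\t", index=False)
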