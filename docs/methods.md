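# Methods

## The between/within module-finding problem

Given a gene set $V$ and two pairwise score functions, $\mathrm{within}(i,j)$
and $\mathrm{between}(i,j)$, the tool partitions genes into at most $K$
modules plus a catch-all unselected cluster $K' = K+1$, maximizing

$$\max \sum_{ij} \mathrm{between}(i,j)\, z_{ij} \;+\; \sum_{ij}\sum_{k=1}^{K} \mathrm{within}(i,j)\, x_{ijk}$$

where $y_{ik}\in\{0,1\}$ assigns gene $i$ to cluster $k$, $x_{ijk}=1$ iff $i$
and $j$ share module $k$, $u_{ij}=1$ iff either gene is unselected, and
$z_{ij} = 1 - u_{ij} - \sum_k x_{ijk}$ marks pairs spanning two modules.
Constraints: each gene sits in exactly one cluster; each module holds at most
$M$ genes; linking inequalities tie $x$ and $u$ to $y$; optionally

* **density** — every gene of a module of size $s$ must have at least
  $D\,(s-1)$ neighbours inside the module via an edge set $E_X$ (for
  $D \ge 0.5$ any two non-adjacent members share a neighbour, so each module
  induces a connected $E_X$ subgraph);
* **between-edge** — every selected gene needs at least one between pair in
  an edge set $E_Y$. The formulation states this per module $k$ with
  right-hand side $y_{ik}$; because each gene occupies exactly one cluster
  the $K$ rows are equivalent to the single row
  $\sum_{j: ij\in E_Y} z_{ij} \ge 1 - y_{iK'}$, which is what the model
  emits.

The problem generalizes Max-Cut and is NP-hard, but only $y$ must be declared
integer: for any binary $y$ the linking constraints *force* $x$, $u$, $z$ to
binary values, so they are left continuous in $[0,1]$. The solver audit
re-checks integrality (tolerance $10^{-6}$) on every returned optimum.
Pair variables are instantiated only for pairs with a nonzero objective
coefficient or membership in $E_Y$; all other pairs contribute nothing to the
objective and appear in no constraint, so the reduction is exact.

Models are solved with the HiGHS branch-and-bound backend
(`scipy.optimize.milp`) at zero relative gap; the returned objective is
recomputed from the membership alone and every constraint is re-audited
outside the solver. A solver-free exhaustive enumerator
(`brute_force_optimum`) provides the independent optimum on instances up to
$10^7$ assignments and backs the oracle-equivalence tests.

**Symmetry breaking.** Module labels are interchangeable, which bloats
branch-and-bound trees. We add $y_{ik} \le \sum_{j<i} y_{j,k-1}$ for
$k \ge 2$ (gene order = sorted universe): a gene may enter module $k$ only if
an earlier gene occupies module $k-1$. Relabeling modules by their minimum
member makes any family of module sets feasible, so the optimal objective is
untouched (verified by paired solves on random instances).

## The three settings

| setting | within(i,j) | between(i,j) | E_X | E_Y |
|---|---|---|---|---|
| BeME-WithFun | $w_F$ | $w_{ME}-w_F$ | $E_F$ | $E_{ME}$ |
| BeME-WithCo | $w_{CO}-w_{ME}$ | $w_{ME}-w_{CO}$ | $E_{CO}$ | $E_{ME}$ |
| BeCo-WithMEFun | $w_{ME}-w_{CO}+w_F$ | $w_{CO}-w_{ME}-w_F$ | $E_F$ | $E_{CO}$ |

BeME-WithFun deliberately keeps mutual exclusivity out of the within score —
functional coherence alone decides module membership. The other two settings
satisfy $\mathrm{within} = -\mathrm{between}$ identically.

## Pair tests and edge weights

The mutual-exclusivity (WeSME) and co-occurrence (WeSCO) tests draw, for each
gene, null mutated-sample sets of the observed size by weighted sampling
without replacement with per-sample weight $\mathrm{freq}[s]/\sum
\mathrm{freq}$ (Gumbel top-$k$, equivalent to successive draws proportional
to remaining weight). The ME statistic is the coverage (samples mutated in
exactly one gene, upper tail); the CO statistic is the overlap (both genes,
upper tail). The add-one estimator $p = (1+b)/(1+n_\text{draws})$ keeps $p >
0$. With uniform frequencies the null reduces to uniform subset placement
(checked against the closed-form hypergeometric overlap law). The exact
null is also available by enumeration for small cohorts and anchors the
calibration tests. Genes mutated in fewer than 3 samples (configurable) are
not tested.

Network edges retain pairs at $p \le \alpha$ and carry weight
$\min(-\log_{10} p,\ c)/c$ with cap $c = 6$, so all three weight families are
commensurable on $[0,1]$; functional edges carry their confidence score
directly (STRING-style 0–1000 scores are auto-rescaled). Which test builds
$E_{CO}$ depends on the setting: the hypergeometric test by default (it
deliberately lets burden-driven, mutagenic-process co-occurrence through);
the burden-corrected WeSCO for BeCo-WithMEFun, configurable per run.

## Synthetic cohorts

`generate_instance` plants modules in a binary matrix of `n_genes` × 
`n_samples`: each module owns a patient block (disjoint blocks ⇒
between-module exclusivity; one shared block ⇒ between-module co-occurrence).
Within a module, `co` mutates every member across the whole block with
probability `q_in`; `me` splits the block into per-gene sub-blocks; a `fun`
component adds a functional clique at confidence 0.9. Background mutation
rate `q_bg` applies elsewhere, sparse Erdős–Rényi noise edges (density 0.05,
confidence U[0.4, 0.9]) populate the functional network, and each matrix cell
is finally flipped with probability ε.

Defaults — two 3-gene modules, 200 samples, blocks of 40, `q_in` 0.8,
`q_bg` 0.02 — give planted genes ≈35 mutated samples, comparable to
moderately mutated drivers in a mid-size cohort, and leave the planted
optimum well separated from background at low ε. What the generator does
*not* emulate: gene-length effects, panel/coverage artefacts, subclonality,
and correlated background (mutations are independent Bernoulli given the
planted blocks). Passing recovery tests therefore demonstrates correctness
of the statistics-to-optimizer chain under the stated generative model, not
performance on real cohorts.

**Recovery protocol.** The recovery experiment runs the full pipeline with
the true $K$ and $M$, density $D = 0.5$ on and the between-edge constraint
on. Its edge-retention threshold is α = 0.05: under the frequency-weighted
null, block-planted genes are *expected* to overlap little (the null piles
placements onto the heavily mutated blocks), so attainable between-module
exclusivity p-values sit around $10^{-4}$–$10^{-2}$ at these cohort sizes; a
stricter retention would discard true between edges, while the ≈20 false
edges expected among 435 pairs at 0.05 carry near-zero log-weights and
cannot displace the planted structure. Exact recovery requires the returned
module sets to equal the planted sets; the graded score is the mean best
Jaccard index.

## Evaluation machinery

* **Randomization protocol** — selected edge sets are rewired by
  degree-preserving double-edge swaps (10·|E| attempts; weights travel with
  edges), the optimizer is re-run per null instance, and the empirical
  p-value is $(1+\#\{\text{null} \ge \text{real}\})/(1+n)$ with ties counted
  against the real value. Rewiring schemes default to the edge types a
  setting actually reads — rewiring an unused edge type leaves the objective
  unchanged by construction. For schemes that tend to produce singleton
  modules (functional- or CO-only rewiring), driver statistics use modules
  of size > 1 only.
* **Driver enrichment** — upper-tail hypergeometric test of known drivers
  among selected genes against the network's gene universe. The driver list
  is user-supplied; none is bundled.
* **Supergene exclusivity** — a module's rows are OR-merged; candidates are
  reported when the supergene ME p-value passes α *and* beats the
  candidate's best p-value against every individual member.
* **Subtype enrichment** — per module and subtype, a one-sided Fisher test
  on mutated-sample counts (a sample counts once per module) inside vs
  outside the subtype; stars at 0.01/0.05/0.1.
* **Signature decomposition** — the normalized 96-channel spectrum is fit by
  non-negative least squares against the signature matrix; exposures are
  renormalized to sum to 1, and the relative L2 residual above 0.1 flags the
  spectrum as not decomposable.

## Numerical choices and degenerate inputs

Float comparisons at $10^{-6}$; solver gap 0; the empty universe yields the
empty assignment at objective 0; an all-hypermutated cohort filters to zero
samples with a warning; edge sets with fewer than two edges are returned
un-rewired with a warning; p-value weights reject $p \le 0$. HiGHS is
deterministic, so `solve` accepts a seed only for interface uniformity; all
stochastic components (tests, generator, rewiring) are driven by explicit
NumPy generators.

## Problem sizes used in the shipped experiments

The bundled tests and the acceptance script run the solver-vs-enumeration
comparison on 100 random instances with up to 7 genes and $K \le 2$, the
recovery experiment on 100 generated cohorts (30 genes × 200 samples,
10 000 null draws per pair test), and the randomization protocol at 19 nulls
per scheme — sizes chosen so the full suite runs on a laptop-class single
core in minutes while every claim is still computed, never asserted.

## Known limitations

The WeSME/WeSCO implementation follows the documented contract of the
original tests (frequency-weighted sampling null) without their pooling and
binning speedups, so very large cohorts will be slower than the original
implementation. Gene symbols are taken verbatim (no alias mapping). CNV,
expression and subtype-stratified tests are out of scope. Reproducing the
published cohort analyses requires the external TCGA/STRING/COSMIC inputs;
the file readers support them but no such data ships with the package.
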