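"""Exact solution of the between/within module-finding problem.

Genes are assigned to one of K modules or to a catch-all "unselected"
cluster K' = K + 1.  With binary membership variables y_ik and derived pair
variables

* x_ijk = 1 iff genes i and j are both in module k (a *within* pair),
* u_ij  = 1 iff i or j is unselected,
* z_ij  = 1 iff i and j sit in two different modules (a *between* pair),

the problem maximizes

    sum_ij between(i,j) * z_ij  +  sum_ij sum_k within(i,j) * x_ijk

subject to: each gene in exactly one cluster; module sizes at most M;
linking constraints tying x, u, z to y; optionally a module-density
constraint (each member of a module of size s must have at least D*(s-1)
neighbours inside the module via the edge set E_X — D >= 0.5 forces every
module to induce a connected E_X subgraph); and optionally a between-edge
constraint (every selected gene needs at least one between pair in E_Y).

Only y is declared integer: the linking constraints force x, u, z to binary
values in any optimum, so they are left continuous in [0, 1], which shrinks
the branch-and-bound tree.  Pair variables are instantiated only for pairs
with a nonzero objective coefficient or membership in E_Y; all other pairs
contribute nothing and appear in no constraint.

The model is solved to proven optimality (zero gap) with the HiGHS
branch-and-bound backend behind :func:`scipy.optimize.milp`.  A brute-force
enumerator over all feasible assignments doubles as an independent oracle for
small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .io_formats import _pair
from .mutnet import WeightFunctions

__all__ = [
    "BeWithConfig",
    "ModuleAssignment",
    "BeWithModel",
    "build_model",
    "add_symmetry_breaking",
    "solve",
    "brute_force_optimum",
]

FLOAT_TOL = 1e-6


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BeWithConfig:
    """Structural parameters of one optimization run.

    Parameters
    ----------
    k_modules
        Target number of modules K (the solver may leave some empty).
    max_module_size
        Maximum genes per module M.
    density
        Minimum within-module neighbour fraction D in [0, 1] (used when
        ``use_density``).
    use_density, use_between_edge
        Toggle constraints (density / at-least-one-between-edge).
    time_limit
        Solver wall-clock limit in seconds (None = unlimited).
    """

    k_modules: int = 7
    max_module_size: int = 6
    density: float = 0.5
    use_density: bool = True
    use_between_edge: bool = True
    time_limit: float | None = None

    def __post_init__(self):
        if self.k_modules < 1:
            raise ConfigError("k_modules must be >= 1")
        if self.max_module_size < 1:
            raise ConfigError("max_module_size must be >= 1")
        if not 0.0 <= self.density <= 1.0:
            raise ConfigError("density must lie in [0, 1]")


@dataclass
class ModuleAssignment:
    """A solved partition: K modules plus the unselected cluster."""

    modules: list[list[str]]
    unselected: list[str]
    objective: float
    optimal: bool = True
    #: largest distance of any returned (continuous) x/u/z variable from
    #: {0, 1}; filled by :func:`solve`
    max_aux_integrality_gap: float = 0.0

    def nonempty_modules(self) -> list[list[str]]:
        return [m for m in self.modules if m]

    def module_sets(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.modules if m}

    def membership(self) -> dict[str, int]:
        """Gene -> module index (1-based; 0 means unselected)."""
        out = {g: 0 for g in self.unselected}
        for k, mod in enumerate(self.modules, start=1):
            for g in mod:
                out[g] = k
        return out

    def pair_label(self, a: str, b: str) -> str:
        """'within', 'between' or 'unselected' for a gene pair."""
        mem = self.membership()
        ka, kb = mem[a], mem[b]
        if ka == 0 or kb == 0:
            return "unselected"
        return "within" if ka == kb else "between"

    def recompute_objective(self, weights: WeightFunctions) -> float:
        genes = sorted(set(self.unselected) | {g for m in self.modules for g in m})
        total = 0.0
        for a, b in combinations(genes, 2):
            label = self.pair_label(a, b)
            if label == "within":
                total += weights.within(a, b)
            elif label == "between":
                total += weights.between(a, b)
        return total

    def report(self) -> dict:
        return {
            "objective": self.objective,
            "optimal": self.optimal,
            "modules": [
                {"module": k, "genes": list(m)}
                for k, m in enumerate(self.modules, start=1)
                if m
            ],
            "unselected": list(self.unselected),
        }


@dataclass
class BeWithModel:
    """The assembled MILP: variable index maps plus constraint rows."""

    genes: list[str]
    config: BeWithConfig
    weights: WeightFunctions
    n_vars: int
    y_index: dict[tuple[str, int], int]  # (gene, cluster 1..K+1) -> column
    x_index: dict[tuple[str, str, int], int]  # (i, j, module k) -> column
    u_index: dict[tuple[str, str], int]
    z_index: dict[tuple[str, str], int]
    objective: np.ndarray  # maximization coefficients
    integrality: np.ndarray
    rows: list[tuple[dict[int, float], float, float]] = field(default_factory=list)
    symmetry_broken: bool = False

    def add_row(self, coeffs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append((coeffs, lb, ub))

    @property
    def n_constraints(self) -> int:
        return len(self.rows)

    def constraint_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        data, ri, ci = [], [], []
        lb = np.empty(len(self.rows))
        ub = np.empty(len(self.rows))
        for r, (coeffs, lo, hi) in enumerate(self.rows):
            lb[r], ub[r] = lo, hi
            for c, v in coeffs.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
        mat = sparse.csr_matrix((data, (ri, ci)), shape=(len(self.rows), self.n_vars))
        return mat, lb, ub

    def export_lp(self, path) -> None:
        """Write the model in a plain LP-like text format for debugging."""
        names = [""] * self.n_vars
        for (g, k), c in self.y_index.items():
            names[c] = f"y[{g},{k}]"
        for (a, b, k), c in self.x_index.items():
            names[c] = f"x[{a},{b},{k}]"
        for (a, b), c in self.u_index.items():
            names[c] = f"u[{a},{b}]"
        for (a, b), c in self.z_index.items():
            names[c] = f"z[{a},{b}]"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Maximize\n obj: ")
            terms = [f"{v:+g} {names[c]}" for c, v in enumerate(self.objective) if v]
            fh.write(" ".join(terms) + "\nSubject To\n")
            for r, (coeffs, lo, hi) in enumerate(self.rows):
                expr = " ".join(f"{v:+g} {names[c]}" for c, v in coeffs.items())
                fh.write(f" c{r}: {lo} <= {expr} <= {hi}\n")
            fh.write("Binaries\n " + " ".join(
                names[c] for c in range(self.n_vars) if self.integrality[c]) + "\n")


def build_model(weights: WeightFunctions, genes, config: BeWithConfig) -> BeWithModel:
    """Assemble the MILP for a gene universe and a setting's weights."""
    genes = sorted(set(genes))
    K = config.k_modules
    clusters = range(1, K + 2)  # K' = K + 1 is the unselected cluster
    pairs = sorted(p for p in weights.scored_pairs()
                   if p[0] in set(genes) and p[1] in set(genes))

    y_index: dict[tuple[str, int], int] = {}
    for g in genes:
        for k in clusters:
            y_index[(g, k)] = len(y_index)
    n = len(y_index)
    x_index: dict[tuple[str, str, int], int] = {}
    u_index: dict[tuple[str, str], int] = {}
    z_index: dict[tuple[str, str], int] = {}
    for a, b in pairs:
        for k in range(1, K + 1):
            x_index[(a, b, k)] = n
            n += 1
        u_index[(a, b)] = n
        n += 1
        z_index[(a, b)] = n
        n += 1

    objective = np.zeros(n)
    for a, b in pairs:
        w_in = weights.within(a, b)
        if w_in:
            for k in range(1, K + 1):
                objective[x_index[(a, b, k)]] = w_in
        w_bet = weights.between(a, b)
        if w_bet:
            objective[z_index[(a, b)]] = w_bet

    integrality = np.zeros(n, dtype=np.int8)
    for col in y_index.values():
        integrality[col] = 1

    model = BeWithModel(
        genes=genes, config=config, weights=weights, n_vars=n,
        y_index=y_index, x_index=x_index, u_index=u_index, z_index=z_index,
        objective=objective, integrality=integrality,
    )

    # (2) every gene in exactly one cluster
    for g in genes:
        model.add_row({y_index[(g, k)]: 1.0 for k in clusters}, 1.0, 1.0)
    # (3) module capacity
    for k in range(1, K + 1):
        model.add_row({y_index[(g, k)]: 1.0 for g in genes}, -np.inf, config.max_module_size)
    # (4)-(6) x linking; (7)-(9) u linking; (10) z definition
    for a, b in pairs:
        kp = K + 1
        for k in range(1, K + 1):
            x = x_index[(a, b, k)]
            model.add_row({x: 1.0, y_index[(a, k)]: -1.0}, -np.inf, 0.0)
            model.add_row({x: 1.0, y_index[(b, k)]: -1.0}, -np.inf, 0.0)
            model.add_row(
                {x: 1.0, y_index[(a, k)]: -1.0, y_index[(b, k)]: -1.0}, -1.0, np.inf
            )
        u = u_index[(a, b)]
        model.add_row({u: 1.0, y_index[(a, kp)]: -1.0}, 0.0, np.inf)
        model.add_row({u: 1.0, y_index[(b, kp)]: -1.0}, 0.0, np.inf)
        model.add_row(
            {u: 1.0, y_index[(a, kp)]: -1.0, y_index[(b, kp)]: -1.0}, -np.inf, 0.0
        )
        coeffs = {z_index[(a, b)]: 1.0, u: 1.0}
        for k in range(1, K + 1):
            coeffs[x_index[(a, b, k)]] = 1.0
        model.add_row(coeffs, 1.0, 1.0)

    # (11) per-gene module density over E_X:
    #   sum_{j in N_X(i)} y_jk  >=  D(M-1)(y_ik - 1) + D(sum_j y_jk - 1)
    if config.use_density and config.density > 0:
        D, M = config.density, config.max_module_size
        nbrs: dict[str, set[str]] = {g: set() for g in genes}
        gene_set = set(genes)
        for a, b in weights.e_x:
            if a in gene_set and b in gene_set:
                nbrs[a].add(b)
                nbrs[b].add(a)
        for g in genes:
            for k in range(1, K + 1):
                coeffs: dict[int, float] = {}
                for j in nbrs[g]:
                    coeffs[y_index[(j, k)]] = 1.0
                coeffs[y_index[(g, k)]] = coeffs.get(y_index[(g, k)], 0.0) - D * (M - 1)
                for j in genes:
                    coeffs[y_index[(j, k)]] = coeffs.get(y_index[(j, k)], 0.0) - D
                model.add_row(coeffs, -D * (M - 1) - D, np.inf)

    # (12) every selected gene needs a between pair in E_Y.  Stated per
    # module k in the formulation; because each gene occupies exactly one
    # cluster the K rows collapse to sum_{j: ij in E_Y} z_ij >= 1 - y_{i,K'}.
    if config.use_between_edge:
        gene_set = set(genes)
        ynbrs: dict[str, set[str]] = {g: set() for g in genes}
        for a, b in weights.e_y:
            if a in gene_set and b in gene_set:
                ynbrs[a].add(b)
                ynbrs[b].add(a)
        for g in genes:
            coeffs = {z_index[_pair(g, j)]: 1.0 for j in ynbrs[g]}
            coeffs[y_index[(g, K + 1)]] = 1.0
            model.add_row(coeffs, 1.0, np.inf)

    return model


def add_symmetry_breaking(model: BeWithModel) -> BeWithModel:
    """Anchor module labels to kill relabeling symmetry.

    Gene ``i`` may enter module ``k >= 2`` only if some earlier gene (in the
    sorted universe order) occupies module ``k - 1``.  Every family of module
    sets admits exactly one surviving labeling — order modules by their
    minimum gene — so the optimal objective is unchanged while equivalent
    branch-and-bound subtrees disappear.
    """
    K = model.config.k_modules
    if K >= 2:
        for idx, g in enumerate(model.genes):
            earlier = model.genes[:idx]
            for k in range(2, K + 1):
                coeffs = {model.y_index[(j, k - 1)]: 1.0 for j in earlier}
                coeffs[model.y_index[(g, k)]] = coeffs.get(
                    model.y_index[(g, k)], 0.0) - 1.0
                model.add_row(coeffs, 0.0, np.inf)
    model.symmetry_broken = True
    return model


def _audit(assignment: ModuleAssignment, weights: WeightFunctions,
           config: BeWithConfig) -> None:
    """Re-check every structural invariant independently of the solver."""
    seen: set[str] = set()
    for mod in assignment.modules + [assignment.unselected]:
        for g in mod:
            if g in seen:
                raise AssertionError(f"gene {g} assigned twice")
            seen.add(g)
    for mod in assignment.modules:
        if len(mod) > config.max_module_size:
            raise AssertionError("module exceeds size cap")
    if config.use_density and config.density > 0:
        for mod in assignment.modules:
            s = len(mod)
            for g in mod:
                deg = sum(1 for j in mod if j != g and _pair(g, j) in weights.e_x)
                if deg + FLOAT_TOL < config.density * (s - 1):
                    raise AssertionError(f"density violated for {g}")
    if config.use_between_edge:
        mem = assignment.membership()
        for mod in assignment.modules:
            for g in mod:
                ok = any(
                    mem.get(j, 0) not in (0, mem[g])
                    for j in seen
                    if j != g and _pair(g, j) in weights.e_y
                )
                if not ok:
                    raise AssertionError(f"between-edge constraint violated for {g}")
    recomputed = assignment.recompute_objective(weights)
    if abs(recomputed - assignment.objective) > 1e-6 * max(1.0, abs(recomputed)):
        raise AssertionError(
            f"objective mismatch: solver {assignment.objective}, "
            f"recomputed {recomputed}"
        )


def solve(model: BeWithModel, seed: int | None = None,
          integrality_tol: float = FLOAT_TOL) -> ModuleAssignment:
    """Solve the model to proven optimality and audit the solution.

    The HiGHS backend is deterministic; ``seed`` is accepted for interface
    uniformity and is not consumed.  The returned continuous pair variables
    are checked to be integral within ``integrality_tol`` and the objective is
    recomputed from the membership alone.
    """
    del seed
    K = model.config.k_modules
    if not model.genes:
        return ModuleAssignment(modules=[[] for _ in range(K)], unselected=[],
                                objective=0.0)
    mat, lb, ub = model.constraint_matrix()
    options = {"mip_rel_gap": 0.0}
    if model.config.time_limit is not None:
        options["time_limit"] = float(model.config.time_limit)
    res = milp(
        c=-model.objective,  # HiGHS minimizes
        constraints=LinearConstraint(mat, lb, ub),
        integrality=model.integrality,
        bounds=Bounds(0.0, 1.0),
        options=options,
    )
    if res.x is None:
        raise RuntimeError(f"solver failed: {res.message}")
    optimal = res.status == 0
    xvals = res.x
    modules: list[list[str]] = [[] for _ in range(K)]
    unselected: list[str] = []
    for g in model.genes:
        k = max(range(1, K + 2), key=lambda kk: xvals[model.y_index[(g, kk)]])
        if k == K + 1:
            unselected.append(g)
        else:
            modules[k - 1].append(g)
    gap = 0.0
    for cols in (model.x_index, model.u_index, model.z_index):
        for col in cols.values():
            v = xvals[col]
            gap = max(gap, min(abs(v), abs(1 - v)))
    if gap > integrality_tol:
        raise AssertionError(
            f"auxiliary variable not integral in optimum: gap {gap}")
    assignment = ModuleAssignment(
        modules=[sorted(m) for m in modules],
        unselected=sorted(unselected),
        objective=float(-res.fun),
        optimal=optimal,
        max_aux_integrality_gap=gap,
    )
    if optimal:
        _audit(assignment, model.weights, model.config)
    return assignment


def _feasible(labels, genes, weights: WeightFunctions, config: BeWithConfig) -> bool:
    K = config.k_modules
    members: dict[int, list[int]] = {}
    for i, k in enumerate(labels):
        if k <= K:
            members.setdefault(k, []).append(i)
    for mod in members.values():
        if len(mod) > config.max_module_size:
            return False
    if config.use_density and config.density > 0:
        for mod in members.values():
            s = len(mod)
            for i in mod:
                deg = sum(
                    1 for j in mod if j != i and _pair(genes[i], genes[j]) in weights.e_x
                )
                if deg + FLOAT_TOL < config.density * (s - 1):
                    return False
    if config.use_between_edge:
        for k, mod in members.items():
            for i in mod:
                # per-module statement of (12): some z_ij = 1 with ij in E_Y
                ok = any(
                    labels[j] <= K and labels[j] != k
                    and _pair(genes[i], genes[j]) in weights.e_y
                    for j in range(len(genes))
                    if j != i
                )
                if not ok:
                    return False
    return True


def brute_force_optimum(weights: WeightFunctions, genes,
                        config: BeWithConfig) -> ModuleAssignment:
    """Exhaustive search over all feasible cluster assignments.

    Independent of the MILP path; used as the correctness oracle on small
    instances.  Refuses instances with more than 10^7 assignments.  Ties are
    broken toward the canonically smallest set of modules.
    """
    genes = sorted(set(genes))
    K = config.k_modules
    n_assign = (K + 1) ** len(genes)
    if n_assign > 10**7:
        raise ValueError(f"instance too large for brute force ({n_assign} assignments)")
    pair_within = {}
    pair_between = {}
    for a, b in combinations(genes, 2):
        pair_within[(a, b)] = weights.within(a, b)
        pair_between[(a, b)] = weights.between(a, b)

    best = None
    for labels in product(range(1, K + 2), repeat=len(genes)):
        if not _feasible(labels, genes, weights, config):
            continue
        obj = 0.0
        for ia, ib in combinations(range(len(genes)), 2):
            ka, kb = labels[ia], labels[ib]
            if ka == K + 1 or kb == K + 1:
                continue
            key = (genes[ia], genes[ib])
            if ka == kb:
                obj += pair_within[key]
            else:
                obj += pair_between[key]
        mods = [sorted(genes[i] for i in range(len(genes)) if labels[i] == k)
                for k in range(1, K + 1)]
        canon = tuple(sorted(tuple(m) for m in mods if m))
        key_t = (obj, canon)
        if best is None or obj > best[0] + FLOAT_TOL or (
                abs(obj - best[0]) <= FLOAT_TOL and canon < best[1]):
            best = (obj, canon, labels)
    assert best is not None  # the all-unselected assignment is always feasible
    obj, _, labels = best
    modules = [sorted(genes[i] for i in range(len(genes)) if labels[i] == k)
               for k in range(1, K + 1)]
    unselected = sorted(genes[i] for i in range(len(genes)) if labels[i] == K + 1)
    return ModuleAssignment(modules=modules, unselected=unselected,
                            objective=obj)
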