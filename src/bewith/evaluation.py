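"""Downstream evaluation of solved module sets.

Covers the validation machinery used around the optimizer: degree-preserving
edge randomization with empirical p-values, hypergeometric driver enrichment,
module-level ("supergene") mutual exclusivity, subtype enrichment, and
non-negative decomposition of module mutational spectra into predefined
signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import MutationMatrix, _pair
from .ilp_core import BeWithConfig, add_symmetry_breaking, build_model, solve
from .mutnet import PairNetwork
from .pair_stats import fisher_exact_2x2, wesme_pvalue
from .settings import get_setting

__all__ = [
    "RandomizationSummary",
    "randomize_network",
    "empirical_pvalue",
    "driver_enrichment",
    "supergene_me",
    "subtype_enrichment",
    "cosmic_contexts",
    "decompose_spectrum",
    "evaluate_run",
]


@dataclass
class RandomizationSummary:
    """Observed statistic vs its randomized-instance null distribution."""

    real_value: float
    null_values: list[float]

    @property
    def empirical_p(self) -> float:
        return empirical_pvalue(self.real_value, self.null_values)


def empirical_pvalue(real: float, nulls) -> float:
    """Permutation p-value ``(1 + #{null >= real}) / (1 + #nulls)``.

    Ties count against the real value (conservative).
    """
    nulls = list(nulls)
    if not nulls:
        raise ValueError("need at least one null value")
    b = sum(1 for v in nulls if v >= real)
    return (1 + b) / (1 + len(nulls))


def _rewire(weighted_edges: dict, rng: np.random.Generator,
            n_attempts: int | None = None) -> dict:
    """Degree-preserving double-edge swaps; weights travel with edge slots."""
    edges = [list(p) for p in weighted_edges]
    weights = list(weighted_edges.values())
    m = len(edges)
    if m < 2:
        warnings.warn("edge set too small to rewire; returned unchanged",
                      stacklevel=3)
        return dict(weighted_edges)
    if n_attempts is None:
        n_attempts = 10 * m
    present = {frozenset(e) for e in edges}
    for _ in range(n_attempts):
        i, j = rng.choice(m, size=2, replace=False)
        (a, b), (c, d) = edges[i], edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, c), (b, d)
        if a == c or b == d:
            continue
        new1, new2 = frozenset((a, c)), frozenset((b, d))
        if new1 in present or new2 in present or new1 == new2:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(new1)
        present.add(new2)
        edges[i] = [a, c]
        edges[j] = [b, d]
    return {_pair(*e): w for e, w in zip(edges, weights)}


def randomize_network(net: PairNetwork, which: str = "all",
                      seed: int | None = None) -> PairNetwork:
    """Rewire selected edge set(s) of the network, preserving degrees.

    ``which`` is one of ``all``, ``functional``, ``ME``, ``CO`` (case
    insensitive).  Unselected edge sets are returned untouched.
    """
    choice = which.lower()
    selections = {
        "all": ("me", "co", "functional"),
        "functional": ("functional",),
        "me": ("me",),
        "co": ("co",),
    }
    if choice not in selections:
        raise ValueError(f"unknown selection {which!r}")
    rng = np.random.default_rng(seed)
    maps = {"me": net.w_me, "co": net.w_co, "functional": net.w_f}
    out = {}
    for name, w in maps.items():
        out[name] = _rewire(w, rng) if name in selections[choice] else dict(w)
    return PairNetwork(nodes=set(net.nodes), w_me=out["me"], w_co=out["co"],
                       w_f=out["functional"])


def driver_enrichment(module_genes, driver_list, universe) -> float:
    """Upper-tail hypergeometric enrichment of known drivers in a module."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    module_genes = set(module_genes)
    if not module_genes <= universe:
        raise ValueError("module genes must lie inside the universe")
    drivers = set(driver_list) & universe
    k = len(module_genes & drivers)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(drivers),
                                    len(module_genes)))


def supergene_me(matrix: MutationMatrix, module_genes, candidate_genes=None,
                 alpha: float = 0.05, n_draws: int = 10000,
                 seed: int | None = None) -> pd.DataFrame:
    """Module-level mutual exclusivity via a merged "supergene" row.

    The supergene is mutated in a patient iff any module member is.  For each
    candidate gene outside the module, the weighted-sampling ME test is run
    against the supergene; a pair is reported when its p-value passes
    ``alpha`` *and* improves on the candidate's best ME p-value against any
    individual module member.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("module must be nonempty")
    if candidate_genes is None:
        candidate_genes = [g for g in matrix.genes if g not in set(module_genes)]
    super_row = np.zeros(matrix.n_samples, dtype=np.int8)
    for g in module_genes:
        super_row |= matrix.row(g)
    super_name = "super:" + "+".join(module_genes)
    while super_name in set(matrix.genes):
        super_name += "_"
    aug = MutationMatrix(
        genes=list(matrix.genes) + [super_name],
        samples=list(matrix.samples),
        values=np.vstack([matrix.values, super_row[None, :]]),
    )
    rows = []
    rng = np.random.default_rng(seed)
    for cand in candidate_genes:
        if cand in set(module_genes):
            continue
        if not matrix.row(cand).any():
            continue
        sub_seed = int(rng.integers(2**31 - 1))
        res = wesme_pvalue(aug, super_name, cand, n_draws=n_draws, seed=sub_seed)
        if res.p_value > alpha:
            continue
        member_ps = [
            wesme_pvalue(matrix, g, cand, n_draws=n_draws,
                         seed=int(rng.integers(2**31 - 1))).p_value
            for g in module_genes
            if matrix.row(g).any()
        ]
        if member_ps and res.p_value < min(member_ps):
            rows.append({
                "module": super_name,
                "gene": cand,
                "supergene_p": res.p_value,
                "best_member_p": min(member_ps),
            })
    return pd.DataFrame(rows, columns=["module", "gene", "supergene_p",
                                       "best_member_p"])


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def subtype_enrichment(matrix: MutationMatrix, modules, subtype_labels: dict
                       ) -> pd.DataFrame:
    """Per (module, subtype) enrichment of module mutations in the subtype.

    A sample counts once per module if any member gene is mutated.  For each
    subtype the one-sided Fisher's exact test compares the module's
    mutated-sample count inside the subtype against its count elsewhere,
    relative to the subtype's share of the cohort — i.e. enrichment relative
    to the module's overall mutation distribution.
    """
    unknown = [s for s in matrix.samples if s not in subtype_labels]
    if unknown:
        raise ValueError(f"samples without subtype label, e.g. {unknown[0]!r}")
    labels = pd.Series([subtype_labels[s] for s in matrix.samples],
                       index=matrix.samples)
    subtypes = sorted(labels.unique())
    rows = []
    for k, module in enumerate(modules, start=1):
        hit = np.zeros(matrix.n_samples, dtype=bool)
        for g in module:
            hit |= matrix.row(g).astype(bool)
        for st in subtypes:
            in_st = (labels == st).to_numpy()
            if len(subtypes) == 1:
                p = 1.0
            else:
                a = int((hit & in_st).sum())
                b = int((hit & ~in_st).sum())
                table = [[a, int(in_st.sum()) - a],
                         [b, int((~in_st).sum()) - b]]
                p = fisher_exact_2x2(table, alternative="greater")
            rows.append({"module": k, "subtype": st, "mutated_in_subtype":
                         int((hit & in_st).sum()), "p_value": p,
                         "stars": _stars(p)})
    return pd.DataFrame(rows)


def cosmic_contexts() -> list[str]:
    """The 96 trinucleotide substitution context labels, in COSMIC order."""
    subs = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
    return [
        f"{five}[{ref}>{alt}]{three}"
        for ref, alt in subs
        for five, three in product("ACGT", repeat=2)
    ]


def decompose_spectrum(spectrum, signatures, error_threshold: float = 0.1
                       ) -> dict:
    """Non-negative decomposition of a 96-channel spectrum into signatures.

    Finds nonnegative exposures minimizing the squared error between the
    normalized spectrum and ``signatures @ exposures`` (NNLS), then
    renormalizes exposures to sum to 1.  The reported error is the relative
    L2 residual of the fit; spectra with error above ``error_threshold`` are
    flagged not decomposable.
    """
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    signatures = np.asarray(signatures, dtype=float)
    if signatures.ndim != 2 or signatures.shape[0] != spectrum.size:
        raise ValueError(
            f"signature matrix shape {signatures.shape} incompatible with "
            f"spectrum of length {spectrum.size}"
        )
    if spectrum.sum() <= 0:
        raise ValueError("spectrum must contain at least one count")
    if (signatures < 0).any():
        raise ValueError("signatures must be nonnegative")
    target = spectrum / spectrum.sum()
    raw, _ = optimize.nnls(signatures, target)
    residual = float(np.linalg.norm(signatures @ raw - target))
    error = residual / float(np.linalg.norm(target))
    total = raw.sum()
    exposures = raw / total if total > 0 else raw
    return {
        "exposures": exposures,
        "error": error,
        "decomposable": error <= error_threshold,
    }


#: Randomization rows of the evaluation protocol, per setting: only edge
#: types a setting's objective or constraints read are informative nulls.
DEFAULT_SCHEMES = {
    "beme-withfun": ("all", "functional", "ME"),
    "beme-withco": ("all", "CO", "ME"),
    "beco-withmefun": ("all", "functional", "CO", "ME"),
}

#: Schemes whose nulls tend to produce many singleton modules; driver
#: statistics for them use non-trivial modules (size > 1) only.
_NONTRIVIAL_SCHEMES = {"functional", "CO"}


def _driver_stats(assignment, drivers, universe, nontrivial_only: bool):
    modules = assignment.nonempty_modules()
    if nontrivial_only:
        modules = [m for m in modules if len(m) > 1]
    selected = [g for m in modules for g in m]
    n_drivers = len(set(selected) & set(drivers))
    p = driver_enrichment(selected, drivers, universe) if selected else 1.0
    return n_drivers, p


def evaluate_run(net: PairNetwork, setting: str, config: BeWithConfig,
                 n_random: int = 100, seed: int | None = None,
                 drivers=None, schemes=None) -> pd.DataFrame:
    """Solve on the real networks and on randomized instances per scheme.

    Returns one row for the real run plus one per randomization scheme, with
    the objective value, empirical p-value of the real objective against the
    scheme's nulls, and (when a driver list is given) the number of known
    drivers selected and their enrichment p, with empirical p-values for both.
    """
    if schemes is None:
        schemes = DEFAULT_SCHEMES.get(setting, ("all",))
    drivers = set(drivers) if drivers else set()
    universe = set(net.nodes)
    setting_fn = get_setting(setting)

    def run(network: PairNetwork):
        weights = setting_fn(network)
        model = add_symmetry_breaking(build_model(weights, network.nodes, config))
        return solve(model)

    real = run(net)
    n_real_drivers, real_enrich = _driver_stats(real, drivers, universe, False)
    rows = [{
        "features": "Real data",
        "objective": real.objective,
        "objective_p": np.nan,
        "n_drivers": n_real_drivers if drivers else np.nan,
        "driver_enrichment_p": real_enrich if drivers else np.nan,
        "n_drivers_p": np.nan,
        "modules": [list(m) for m in real.nonempty_modules()],
    }]
    rng = np.random.default_rng(seed)
    for scheme in (schemes if n_random > 0 else ()):
        nontrivial = scheme in _NONTRIVIAL_SCHEMES
        real_d, real_e = _driver_stats(real, drivers, universe, nontrivial)
        null_obj, null_drv, null_enr = [], [], []
        for _ in range(n_random):
            null_net = randomize_network(net, which=scheme,
                                         seed=int(rng.integers(2**31 - 1)))
            null = run(null_net)
            null_obj.append(null.objective)
            if drivers:
                d, e = _driver_stats(null, drivers, universe, nontrivial)
                null_drv.append(d)
                null_enr.append(e)
        rows.append({
            "features": f"Randomization of {scheme} edges"
                        if scheme != "all" else "Randomization of all edges",
            "objective": float(np.mean(null_obj)) if null_obj else np.nan,
            "objective_p": empirical_pvalue(real.objective, null_obj)
                           if null_obj else np.nan,
            "n_drivers": float(np.mean(null_drv)) if null_drv else np.nan,
            # enrichment p: smaller is better, so the empirical comparison
            # counts nulls with p <= the real p
            "driver_enrichment_p": float(np.mean(null_enr)) if null_enr else np.nan,
            "n_drivers_p": empirical_pvalue(real_d, null_drv)
                           if null_drv else np.nan,
            "modules": None,
        })
    return pd.DataFrame(rows)
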