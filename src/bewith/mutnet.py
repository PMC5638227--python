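"""Weighted pairwise networks and the between/within weight functions.

Three symmetric edge-weighted relations live on a common gene universe:

* ``E_ME`` — significantly mutually exclusive pairs, weight ``w_ME``;
* ``E_CO`` — significantly co-occurring pairs, weight ``w_CO``;
* ``E_F``  — functional interactions, weight ``w_F`` (the confidence score).

Test p-values are mapped onto [0, 1] by a capped, normalized -log10
transform (``pvalue_to_weight``), making the three weight families
commensurable.  Absent pairs have weight 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import FunctionalEdgeList, _pair

__all__ = ["PairNetwork", "WeightFunctions", "pvalue_to_weight", "build_networks"]

Pair = tuple[str, str]


def pvalue_to_weight(p: float, cap: float = 6.0) -> float:
    """Map a p-value to a weight in [0, 1]: ``min(-log10 p, cap) / cap``.

    p-values at or below ``10**-cap`` saturate at weight 1.
    """
    if p <= 0:
        raise ValueError("p must be in (0, 1]")
    if cap <= 0:
        raise ValueError("cap must be positive")
    import math

    return min(-math.log10(p), cap) / cap


@dataclass
class PairNetwork:
    """The three weighted relations on a shared gene universe ``nodes``."""

    nodes: set[str] = field(default_factory=set)
    w_me: dict[Pair, float] = field(default_factory=dict)
    w_co: dict[Pair, float] = field(default_factory=dict)
    w_f: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in (("w_me", self.w_me), ("w_co", self.w_co), ("w_f", self.w_f)):
            for (a, b), v in w.items():
                if a == b:
                    raise ValueError(f"self-pair ({a}, {b}) in {name}")
                if (a, b) != _pair(a, b):
                    raise ValueError(f"pair ({a}, {b}) not in canonical order")
                if v < 0:
                    raise ValueError(f"negative weight {v} in {name}")

    @property
    def e_me(self) -> set[Pair]:
        return set(self.w_me)

    @property
    def e_co(self) -> set[Pair]:
        return set(self.w_co)

    @property
    def e_f(self) -> set[Pair]:
        return set(self.w_f)

    def me(self, a: str, b: str) -> float:
        return self.w_me.get(_pair(a, b), 0.0)

    def co(self, a: str, b: str) -> float:
        return self.w_co.get(_pair(a, b), 0.0)

    def f(self, a: str, b: str) -> float:
        return self.w_f.get(_pair(a, b), 0.0)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """One edge-list DataFrame per relation (gene_i, gene_j, weight)."""
        out = {}
        for name, w in (("me", self.w_me), ("co", self.w_co), ("functional", self.w_f)):
            out[name] = pd.DataFrame(
                [(a, b, v) for (a, b), v in sorted(w.items())],
                columns=["gene_i", "gene_j", "weight"],
            )
        return out

    def write(self, prefix: str) -> None:
        for name, frame in self.to_frames().items():
            frame.to_csv(f"{prefix}.{name}.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str) -> "PairNetwork":
        weights = {}
        for name in ("me", "co", "functional"):
            frame = pd.read_csv(f"{prefix}.{name}.tsv", sep="\t")
            weights[name] = {
                _pair(str(r.gene_i), str(r.gene_j)): float(r.weight)
                for r in frame.itertuples()
            }
        nodes = {g for w in weights.values() for pair in w for g in pair}
        return cls(nodes=nodes, w_me=weights["me"], w_co=weights["co"],
                   w_f=weights["functional"])


@dataclass
class WeightFunctions:
    """A setting's between/within scores plus its constraint edge sets.

    ``between(i, j)`` and ``within(i, j)`` are total on gene pairs (0 where no
    relation exists).  ``e_x`` feeds the module-density constraint; ``e_y``
    feeds the between-edge requirement.
    """

    between_map: dict[Pair, float] = field(default_factory=dict)
    within_map: dict[Pair, float] = field(default_factory=dict)
    e_x: set[Pair] = field(default_factory=set)
    e_y: set[Pair] = field(default_factory=set)
    name: str = "custom"

    def between(self, a: str, b: str) -> float:
        return self.between_map.get(_pair(a, b), 0.0)

    def within(self, a: str, b: str) -> float:
        return self.within_map.get(_pair(a, b), 0.0)

    def scored_pairs(self) -> set[Pair]:
        """Pairs that can contribute to the objective or constraint (12)."""
        nonzero = {p for p, v in self.between_map.items() if v != 0.0}
        nonzero |= {p for p, v in self.within_map.items() if v != 0.0}
        return nonzero | self.e_y


def build_networks(matrix, me_results, co_results, func_edges: FunctionalEdgeList | None,
                   alpha_me: float = 0.001, alpha_co: float = 0.001,
                   cap: float = 6.0) -> PairNetwork:
    """Assemble the three relations from test results and functional edges.

    ``E_ME``/``E_CO`` retain pairs at ``p <= alpha``, weighted by
    :func:`pvalue_to_weight`; ``E_F`` carries the raw confidences.  The gene
    universe is the union of genes incident to at least one retained edge —
    isolated genes cannot contribute to any module score.
    """
    w_me = {
        _pair(r.gene_i, r.gene_j): pvalue_to_weight(r.p_value, cap)
        for r in me_results
        if r.p_value <= alpha_me
    }
    w_co = {
        _pair(r.gene_i, r.gene_j): pvalue_to_weight(r.p_value, cap)
        for r in co_results
        if r.p_value <= alpha_co
    }
    w_f = dict(func_edges.conf) if func_edges is not None else {}
    nodes = {g for w in (w_me, w_co, w_f) for pair in w for g in pair}
    return PairNetwork(nodes=nodes, w_me=w_me, w_co=w_co, w_f=w_f)
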