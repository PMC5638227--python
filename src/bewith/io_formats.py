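"""Readers and writers for the external formats the tool touches.

Mutation data enters either as a TCGA-style MAF (one variant per row) or as a
binary gene x sample TSV, and is normalized into a :class:`MutationMatrix`.
Functional interactions enter as a STRING-style edge list (gene1, gene2,
combined score on the 0-1000 scale or already in [0, 1]).  Module solutions are
written as a JSON report plus a flat TSV.

All TSVs are UTF-8 and lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


#: Variant classes excluded when reading a MAF (non-silent convention).
SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


@dataclass
class MutationMatrix:
    """Binary gene x sample mutation indicator matrix.

    Parameters
    ----------
    genes
        Ordered, unique gene symbols (rows).
    samples
        Ordered, unique sample identifiers (columns).
    values
        Array of shape ``(len(genes), len(samples))`` with entries in {0, 1}.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary entry at gene {self.genes[g]!r}, sample {self.samples[s]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def freq(self) -> np.ndarray:
        """Per-sample mutation count (column sums), recomputed on access."""
        return self.values.sum(axis=0).astype(int)

    def row(self, gene: str) -> np.ndarray:
        """Binary mutation profile of one gene across samples."""
        return self.values[self._gene_index[gene]]

    def gene_counts(self) -> pd.Series:
        """Number of mutated samples per gene."""
        return pd.Series(self.values.sum(axis=1), index=self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutationMatrix":
        return cls(
            genes=[str(g) for g in frame.index],
            samples=[str(s) for s in frame.columns],
            values=frame.to_numpy(),
        )


@dataclass
class FunctionalEdgeList:
    """Undirected functional-interaction edges with confidences in [0, 1]."""

    conf: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), c in self.conf.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} for ({a}, {b}) outside [0, 1]")

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.conf)

    def genes(self) -> set[str]:
        return {g for pair in self.conf for g in pair}

    def __len__(self) -> int:
        return len(self.conf)


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) unordered gene pair."""
    return (a, b) if a <= b else (b, a)


def read_maf(path, variant_classes=None) -> MutationMatrix:
    """Read a MAF file into a binary mutation matrix.

    A gene/sample cell is 1 iff the sample carries at least one retained
    variant of the gene.  ``variant_classes`` gives the retained
    Variant_Classification values; by default every class except the silent
    set (:data:`SILENT_CLASSES`) is kept.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    for col in _MAF_REQUIRED:
        if col not in table.columns:
            raise FormatError(f"MAF is missing required column {col!r}")
    if variant_classes is None:
        keep = ~table["Variant_Classification"].isin(SILENT_CLASSES)
    else:
        keep = table["Variant_Classification"].isin(set(variant_classes))
    table = table.loc[keep]
    if table.empty:
        return MutationMatrix(genes=[], samples=[], values=np.zeros((0, 0)))
    # crosstab then clip: multiple retained variants of a gene in a sample
    # collapse to a single indicator
    counts = pd.crosstab(table["Hugo_Symbol"], table["Tumor_Sample_Barcode"])
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    return MutationMatrix.from_frame((counts > 0).astype(np.int8))


def read_matrix_tsv(path) -> MutationMatrix:
    """Read a binary gene x sample TSV (gene rows, sample columns)."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    arr = frame.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary entry {arr[r, c]!r} at gene {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r}"
        )
    return MutationMatrix.from_frame(frame.astype(np.int8))


def write_matrix_tsv(matrix: MutationMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def filter_hypermutated(matrix: MutationMatrix, max_mutations: int = 500) -> MutationMatrix:
    """Drop ultra-mutated samples (those with more than ``max_mutations``).

    Genes are kept even if their row becomes all-zero.
    """
    if max_mutations <= 0:
        raise ValueError("max_mutations must be positive")
    keep = matrix.freq <= max_mutations
    if not keep.any():
        warnings.warn("all samples exceed the hypermutation cutoff", stacklevel=2)
    return MutationMatrix(
        genes=list(matrix.genes),
        samples=[s for s, k in zip(matrix.samples, keep) if k],
        values=matrix.values[:, keep],
    )


def read_functional_edges(path, min_conf: float = 0.0) -> FunctionalEdgeList:
    """Read a STRING-style edge TSV (gene1, gene2, score).

    Scores on the 0-1000 STRING scale are auto-detected (any score > 1) and
    divided by 1000.  Duplicate orientations keep the maximum confidence;
    self-loops are dropped with a warning; edges below ``min_conf`` are
    discarded.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    if table.shape[1] < 3:
        raise FormatError("edge list needs at least 3 columns: gene1, gene2, score")
    g1, g2, score = (table.iloc[:, i] for i in range(3))
    score = score.astype(float)
    if (score > 1).any():
        score = score / 1000.0
    conf: dict[tuple[str, str], float] = {}
    n_loops = 0
    for a, b, c in zip(g1.astype(str), g2.astype(str), score):
        if a == b:
            n_loops += 1
            continue
        key = _pair(a, b)
        conf[key] = max(conf.get(key, 0.0), float(c))
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop edge(s)", stacklevel=2)
    conf = {k: c for k, c in conf.items() if c >= min_conf}
    return FunctionalEdgeList(conf=conf)


def write_functional_edges(edges: FunctionalEdgeList, path) -> None:
    frame = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(edges.conf.items())],
        columns=["gene1", "gene2", "confidence"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_modules(assignment, path, network=None) -> None:
    """Write a solved :class:`~bewith.ilp_core.ModuleAssignment` as JSON.

    The report lists, per module, the member genes (and, when a
    :class:`~bewith.mutnet.PairNetwork` is supplied, the within edges by
    relation type with their weights); the between pairs with type and
    weight; the unselected genes; and the objective value.  A sibling
    ``.tsv`` flat listing is written next to the JSON for spreadsheet use.
    """
    path = str(path)
    report = assignment.report()
    if network is not None:
        from itertools import combinations

        relations = (("me", network.w_me), ("co", network.w_co),
                     ("functional", network.w_f))
        for rec in report["modules"]:
            rec["within_edges"] = {
                name: [[a, b, w[_pair(a, b)]]
                       for a, b in combinations(sorted(rec["genes"]), 2)
                       if _pair(a, b) in w]
                for name, w in relations
            }
        mods = [rec["genes"] for rec in report["modules"]]
        between = []
        for m1, m2 in combinations(mods, 2):
            for a in m1:
                for b in m2:
                    for name, w in relations:
                        if _pair(a, b) in w:
                            between.append([a, b, name, w[_pair(a, b)]])
        report["between_pairs"] = between
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    rows = []
    for rec in report["modules"]:
        for gene in rec["genes"]:
            rows.append({"module": rec["module"], "gene": gene})
    for gene in report["unselected"]:
        rows.append({"module": "unselected", "gene": gene})
    tsv_path = path[:-5] + ".tsv" if path.endswith(".json") else path + ".tsv"
    pd.DataFrame(rows, columns=["module", "gene"]).to_csv(tsv_path, sep="\t", index=False)


def read_modules(path):
    """Read a module-report JSON back into a ModuleAssignment."""
    from .ilp_core import ModuleAssignment

    with open(path, encoding="utf-8") as fh:
        report = json.load(fh)
    return ModuleAssignment(
        modules=[sorted(rec["genes"]) for rec in report["modules"]],
        unselected=sorted(report["unselected"]),
        objective=float(report["objective"]),
        optimal=bool(report.get("optimal", True)),
    )
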