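"""Validated domain containers shared across the pipeline.

The containers are thin wrappers over :class:`pandas.DataFrame` /
:class:`networkx.DiGraph` that enforce the structural invariants the
method relies on (binary adjacency, symmetric unit-interval similarity,
acyclic disease ontology).  They validate eagerly at construction so that
downstream numerical code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-10

#: contribution decay per ontology generation
DAG_DECAY = 0.5


class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix.

    Rows are indexed by miRNA identifiers, columns by disease identifiers.
    Row ``i`` is the interaction profile of miRNA ``i`` over diseases;
    column ``j`` is the interaction profile of disease ``j`` over miRNAs.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("AssociationMatrix expects a pandas DataFrame")
        arr = values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"adjacency must be binary; entry at row "
                f"{values.index[bad[0]]!r}, column {values.columns[bad[1]]!r} "
                f"is {arr[bad[0], bad[1]]!r}"
            )
        if values.index.has_duplicates:
            raise ValueError("duplicate miRNA identifiers in adjacency rows")
        if values.columns.has_duplicates:
            raise ValueError("duplicate disease identifiers in adjacency columns")
        self.values = values.astype(np.int8)

    @property
    def mirna_ids(self) -> list:
        return list(self.values.index)

    @property
    def disease_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (miRNA row, disease column) of the known associations."""
        rows, cols = np.nonzero(self.values.to_numpy())
        return list(zip(rows.tolist(), cols.tolist()))

    def zero_pairs(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.values.to_numpy() == 0)
        return list(zip(rows.tolist(), cols.tolist()))

    def __repr__(self) -> str:  # pragma: no cover
        nm, nd = self.shape
        return f"AssociationMatrix({nm} miRNAs x {nd} diseases, {int(self.values.sum().sum())} links)"


class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1].

    ``kind`` names the view: ``FS`` (miRNA functional similarity), ``SS``
    (disease semantic similarity), ``GS_m`` / ``GS_d`` (Gaussian
    interaction-profile kernels).  For every kind except ``FS`` the
    diagonal must be exactly 1 (FS matrices distributed upstream
    occasionally zero the diagonal; we accept 0-or-1 there).
    """

    KINDS = ("FS", "SS", "GS_m", "GS_d")

    def __init__(self, values: pd.DataFrame, kind: str = "FS"):
        if kind not in self.KINDS:
            raise ValueError(f"unknown similarity kind {kind!r}; expected one of {self.KINDS}")
        if list(values.index) != list(values.columns):
            raise ValueError("similarity matrix row and column identifiers differ")
        arr = values.to_numpy(dtype=float)
        asym = np.abs(arr - arr.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.abs(arr - arr.T).argmax(), arr.shape)
            raise ValueError(
                f"similarity matrix asymmetric beyond {SYMMETRY_TOL:g}: "
                f"({values.index[i]!r}, {values.columns[j]!r}) differs by {asym:g}"
            )
        lo, hi = (arr.min(initial=0.0), arr.max(initial=1.0)) if arr.size else (0.0, 1.0)
        if lo < -SYMMETRY_TOL or hi > 1 + SYMMETRY_TOL:
            i, j = np.unravel_index(arr.argmax() if hi > 1 else arr.argmin(), arr.shape)
            raise ValueError(
                f"similarity value {arr[i, j]!r} at ({values.index[i]!r}, "
                f"{values.columns[j]!r}) outside [0, 1]"
            )
        arr = np.clip((arr + arr.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
        if kind != "FS" and arr.size:
            diag = np.diag(arr)
            if not np.allclose(diag, 1.0, atol=1e-8):
                k = int(np.argmax(np.abs(diag - 1.0)))
                raise ValueError(
                    f"{kind} diagonal must be 1; entry for {values.index[k]!r} is {diag[k]!r}"
                )
        self.values = pd.DataFrame(arr, index=values.index, columns=values.columns)
        self.kind = kind

    @property
    def ids(self) -> list:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def align(self, ids: Iterable) -> "SimilarityMatrix":
        """Reorder rows/columns to ``ids``; error on missing identifiers."""
        ids = list(ids)
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise KeyError(f"identifiers missing from {self.kind} matrix: {missing}")
        return SimilarityMatrix(self.values.loc[ids, ids], kind=self.kind)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SimilarityMatrix(kind={self.kind}, n={len(self.values)})"


@dataclass
class DiseaseDAG:
    """Rooted acyclic ancestor graph of ontology terms with disease annotations.

    ``parent_edges`` is a child -> parents relation over term identifiers;
    ``annotation`` maps each disease identifier to the term node(s) it
    occupies (MeSH-style terms may occupy several tree positions).
    Ancestor contributions decay by :data:`DAG_DECAY` per generation.
    """

    nodes: set = field(default_factory=set)
    parent_edges: Mapping[str, Iterable[str]] = field(default_factory=dict)
    annotation: Mapping[str, Iterable[str]] = field(default_factory=dict)
    decay: float = DAG_DECAY

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, parents in self.parent_edges.items():
            for p in ([parents] if isinstance(parents, str) else parents):
                g.add_edge(child, p)  # edge direction: child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease ontology contains a cycle: {cycle}")
        self.graph = g
        self.nodes = set(g.nodes)
        norm: dict[str, frozenset] = {}
        for dis, terms in self.annotation.items():
            terms = frozenset([terms] if isinstance(terms, str) else terms)
            if not terms:
                raise ValueError(f"disease {dis!r} has an empty annotation")
            missing = terms - self.nodes
            if missing:
                raise ValueError(f"disease {dis!r} annotated to unknown nodes {sorted(missing)}")
            norm[dis] = terms
        self.annotation = norm

    def is_annotated(self, disease) -> bool:
        return disease in self.annotation

    def ancestors(self, node) -> set:
        """The node itself plus all its ancestors (root-ward closure)."""
        return {node} | nx.descendants(self.graph, node)

    def children_in(self, node, subset: set) -> list:
        """Children of ``node`` (one generation leaf-ward) restricted to ``subset``."""
        return [c for c, _ in self.graph.in_edges(node) if c in subset]
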