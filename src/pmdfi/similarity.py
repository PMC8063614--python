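"""Similarity views over the miRNA-disease network.

Two similarity constructions are computed here, and a third is loaded
from disk:

* **Gaussian interaction-profile (GIP) kernel** — a radial-basis
  similarity between the binary interaction profiles of two miRNAs (rows
  of the adjacency matrix) or two diseases (columns).  The bandwidth is
  normalised by the mean squared profile norm, so the kernel adapts to
  network density:

  ``GS(u, v) = exp(-gamma * ||IP(u) - IP(v)||^2)``,
  ``gamma = lambda' / mean_i ||IP(i)||^2``.

* **Disease semantic similarity** — each disease is a node set in a
  MeSH-style ontology; an ancestor ``g`` generations above a disease
  contributes ``0.5**g`` (taking the max over paths), the semantic value
  ``DV`` is the sum of contributions, and the pairwise score is the
  shared-ancestor contribution sum normalised by ``DV(i) + DV(j)``.

* **miRNA functional similarity (FS)** — consumed as a precomputed
  labelled table (the MISIM algorithm that produces it is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from ._types import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "GIPParams",
    "gip_kernel",
    "dag_contribution",
    "semantic_value",
    "semantic_similarity",
    "load_similarity_table",
]


@dataclass(frozen=True)
class GIPParams:
    """Kernel bandwidth regulariser lambda' (> 0, default 1)."""

    lambda_prime: float = 1.0

    def __post_init__(self):
        if not self.lambda_prime > 0:
            raise ValueError(f"lambda_prime must be positive, got {self.lambda_prime}")


_AXIS_ALIASES = {
    "mirna": "miRNA", "mi_rna": "miRNA", "m": "miRNA", "miRNA": "miRNA",
    "disease": "disease", "d": "disease",
}


def gip_kernel(
    A: AssociationMatrix,
    axis: str = "miRNA",
    params: GIPParams | None = None,
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one side of the network.

    Parameters
    ----------
    A
        Binary adjacency; miRNA profiles are its rows, disease profiles
        its columns.
    axis
        ``"miRNA"`` for the miRNA-side kernel GS_m, ``"disease"`` for the
        disease-side kernel GS_d.
    params
        Bandwidth regulariser lambda' (default 1, after van Laarhoven's
        convention for interaction-profile kernels).

    Returns
    -------
    SimilarityMatrix
        Symmetric kernel with unit diagonal and entries in (0, 1].

    Raises
    ------
    ValueError
        If the chosen axis has no interactions at all (the bandwidth
        ``gamma = lambda' / mean ||IP||^2`` would divide by zero), or the
        axis label is unknown.
    """
    params = params or GIPParams()
    key = _AXIS_ALIASES.get(str(axis).lower(), None) or _AXIS_ALIASES.get(axis, None)
    if key is None:
        raise ValueError(f"unknown axis {axis!r}; expected 'miRNA' or 'disease'")
    if key == "miRNA":
        profiles, ids, kind = A.to_numpy(), A.mirna_ids, "GS_m"
    else:
        profiles, ids, kind = A.to_numpy().T, A.disease_ids, "GS_d"

    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError(
            f"all {key} interaction profiles are zero; GIP bandwidth for axis "
            f"{key!r} is undefined"
        )
    gamma = params.lambda_prime / mean_sq
    if len(profiles) > 1:
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        d2 = np.zeros((1, 1))
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(pd.DataFrame(K, index=ids, columns=ids), kind=kind)


def _contribution_one_term(dag: DiseaseDAG, term) -> dict:
    """Contribution of every ancestor of ``term`` toward ``term`` itself.

    The annotated node contributes 1; any ancestor contributes
    ``decay * max(child contributions)`` over its children inside the
    ancestor closure — a max, not a sum, so parallel paths do not inflate
    the value.
    """
    closure = dag.ancestors(term)
    contrib = {term: 1.0}
    # iterate root-ward: process nodes in topological order of the
    # child->parent graph restricted to the closure
    import networkx as nx

    sub = dag.graph.subgraph(closure)
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        kids = dag.children_in(node, closure)
        vals = [contrib[c] for c in kids if c in contrib]
        if vals:
            contrib[node] = dag.decay * max(vals)
    return contrib


def dag_contribution(dag: DiseaseDAG, disease) -> dict:
    """Per-node semantic contribution map for ``disease``.

    The disease's own term(s) contribute 1 and every ancestor decays by
    0.5 per generation (max over paths and over multiple annotations).
    All values lie in (0, 1].
    """
    if not dag.is_annotated(disease):
        raise KeyError(f"disease {disease!r} is not annotated in the ontology")
    combined: dict = {}
    for term in dag.annotation[disease]:
        for node, val in _contribution_one_term(dag, term).items():
            combined[node] = max(combined.get(node, 0.0), val)
    return combined


def semantic_value(dag: DiseaseDAG, disease) -> float:
    """Semantic value DV: the sum of contributions over the ancestor set (>= 1)."""
    return float(sum(dag_contribution(dag, disease).values()))


def semantic_similarity(dag: DiseaseDAG, diseases) -> SimilarityMatrix:
    """Pairwise DAG-based semantic similarity over ``diseases``.

    ``SS(i, j) = sum_{t in T(i) & T(j)} (D_i(t) + D_j(t)) / (DV(i) + DV(j))``

    where ``T(d)`` is the ancestor closure and ``D_d`` the contribution
    map.  Self-similarity is exactly 1 and disjoint ancestries score 0.
    """
    diseases = list(diseases)
    missing = [d for d in diseases if not dag.is_annotated(d)]
    if missing:
        raise KeyError(f"diseases not annotated in the ontology: {missing}")
    contribs = {d: dag_contribution(dag, d) for d in diseases}
    dvs = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(diseases)
    S = np.eye(n)
    for i in range(n):
        ci = contribs[diseases[i]]
        for j in range(i + 1, n):
            cj = contribs[diseases[j]]
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                S[i, j] = S[j, i] = num / (dvs[diseases[i]] + dvs[diseases[j]])
    return SimilarityMatrix(pd.DataFrame(S, index=diseases, columns=diseases), kind="SS")


def load_similarity_table(path, expected_ids=None, kind: str = "FS") -> SimilarityMatrix:
    """Load a labelled TSV/CSV similarity table and validate it.

    The file must carry identifiers in its header row and first column,
    with identical row and column identifier sets.  If ``expected_ids``
    is given the matrix is realigned to that ordering; missing
    identifiers raise.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if set(df.index) != set(df.columns):
        only_rows = sorted(set(df.index) - set(df.columns))
        only_cols = sorted(set(df.columns) - set(df.index))
        raise ValueError(
            f"row/column identifier sets differ (rows only: {only_rows[:5]}, "
            f"columns only: {only_cols[:5]})"
        )
    df = df.loc[df.index, df.index]  # order columns like rows
    sim = SimilarityMatrix(df, kind=kind)
    if expected_ids is not None:
        sim = sim.align([str(i) for i in expected_ids])
    return sim
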