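"""Desk-scale synthetic benchmarks with the structure the method assumes.

The generator plants a block (community) structure: miRNAs and diseases
are assigned to latent blocks, associations occur mostly within blocks,
and the surrogate similarity matrices score same-block pairs high — the
"functionally similar miRNAs share diseases" premise of the predictor.
A toy disease ontology (forest of rooted trees) supports the semantic
similarity path.  Everything is deterministic for a fixed seed, so the
entire pipeline is testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "BlockNetworkConfig",
    "simulate_block_network",
    "simulate_similarities",
    "simulate_dag_forest",
]

# same-block vs different-block baseline similarity of the surrogates
BASE_IN = 0.8
BASE_OUT = 0.1


@dataclass
class BlockNetworkConfig:
    """Planted-block bipartite network settings.

    ``p_in``/``p_out`` are association probabilities within/between
    blocks; ``sim_noise`` is the s.d. of the Gaussian jitter on the
    surrogate similarities.
    """

    n_mirna: int = 100
    n_disease: int = 80
    n_blocks: int = 5
    p_in: float = 0.30
    p_out: float = 0.02
    sim_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}")
        if self.n_blocks > min(self.n_mirna, self.n_disease):
            raise ValueError("n_blocks exceeds the smaller side of the network")
        if self.n_blocks < 1 or self.n_mirna < 1 or self.n_disease < 1:
            raise ValueError("sizes must be positive")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be non-negative")


def _block_labels(n: int, k: int) -> np.ndarray:
    # contiguous, near-equal blocks
    return np.sort(np.arange(n) % k)


def simulate_block_network(cfg: BlockNetworkConfig):
    """Draw the planted-block association matrix.

    Returns ``(AssociationMatrix, memberships)`` where ``memberships``
    maps ``"mirna"``/``"disease"`` to per-entity block labels.
    """
    rng = np.random.default_rng(cfg.seed)
    mb = _block_labels(cfg.n_mirna, cfg.n_blocks)
    db = _block_labels(cfg.n_disease, cfg.n_blocks)
    same = mb[:, None] == db[None, :]
    P = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random(P.shape) < P).astype(np.int8)
    mirna_ids = [f"mir-{i:03d}" for i in range(cfg.n_mirna)]
    disease_ids = [f"dis-{j:03d}" for j in range(cfg.n_disease)]
    am = AssociationMatrix(pd.DataFrame(A, index=mirna_ids, columns=disease_ids))
    memberships = {
        "mirna": pd.Series(mb, index=mirna_ids),
        "disease": pd.Series(db, index=disease_ids),
    }
    return am, memberships


def _surrogate_similarity(blocks: pd.Series, noise: float, rng, kind: str) -> SimilarityMatrix:
    b = blocks.to_numpy()
    same = b[:, None] == b[None, :]
    base = np.where(same, BASE_IN, BASE_OUT)
    eps = rng.standard_normal(base.shape)
    eps = np.triu(eps, 1)
    eps = eps + eps.T  # symmetric jitter
    S = np.clip(base + noise * eps, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    ids = list(blocks.index)
    return SimilarityMatrix(pd.DataFrame(S, index=ids, columns=ids), kind=kind)


def simulate_similarities(memberships, cfg: BlockNetworkConfig, informative: bool = True):
    """Surrogate FS (miRNA) and SS (disease) matrices from block labels.

    Same-block pairs score around 0.8, different-block pairs around 0.1,
    jittered by ``sim_noise`` and clamped to [0, 1]; diagonal is 1.
    With ``informative=False`` the block structure is erased (labels
    shuffled independently of the network) — a negative control whose
    similarities carry no signal about the planted associations.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mblocks = memberships["mirna"]
    dblocks = memberships["disease"]
    if not informative:
        mblocks = pd.Series(
            rng.permutation(mblocks.to_numpy()), index=mblocks.index
        )
        dblocks = pd.Series(
            rng.permutation(dblocks.to_numpy()), index=dblocks.index
        )
    FS = _surrogate_similarity(mblocks, cfg.sim_noise, rng, "FS")
    SS = _surrogate_similarity(dblocks, cfg.sim_noise, rng, "SS")
    return FS, SS


def simulate_dag_forest(
    n_diseases: int,
    max_depth: int = 3,
    branching: int = 2,
    seed: int = 0,
) -> DiseaseDAG:
    """Random forest of rooted term trees with one leaf annotation per disease.

    Trees are grown top-down: each node at depth < ``max_depth`` - 1
    spawns ``branching`` children.  Diseases are annotated round-robin
    to the deepest tier of nodes.  With ``branching=1`` each tree is a
    chain, which reproduces the hand-checkable chain arithmetic
    (contributions 1, 0.5, 0.25, ... along the chain).
    """
    if n_diseases < 1 or max_depth < 1 or branching < 1:
        raise ValueError("n_diseases, max_depth and branching must be positive")
    rng = np.random.default_rng(seed)
    n_roots = max(1, int(np.ceil(n_diseases / max(1, branching ** (max_depth - 1)))))
    nodes: set[str] = set()
    parent_edges: dict[str, list[str]] = {}
    leaves: list[str] = []
    for r in range(n_roots):
        tier = [f"t{r}_0"]
        nodes.update(tier)
        for depth in range(1, max_depth):
            nxt = []
            for parent in tier:
                for c in range(branching):
                    child = f"{parent}.{c}" if branching > 1 else f"{parent}>{depth}"
                    nodes.add(child)
                    parent_edges.setdefault(child, []).append(parent)
                    nxt.append(child)
            tier = nxt
        leaves.extend(tier)
    order = rng.permutation(len(leaves))
    annotation = {
        f"dis-{i:03d}": leaves[int(order[i % len(leaves)])] for i in range(n_diseases)
    }
    return DiseaseDAG(nodes=nodes, parent_edges=parent_edges, annotation=annotation)
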