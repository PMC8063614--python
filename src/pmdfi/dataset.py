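"""Training-set assembly: adjacency construction and negative sampling.

Known miRNA-disease associations are the positive class.  Unobserved
pairs (zeros of the adjacency matrix) are not verified negatives, so
negatives are drawn in a cluster-balanced fashion: all zero-pairs are
partitioned into ``k`` clusters by k-means over a per-pair similarity
representation, and an equal-as-possible number is sampled from each
cluster.  This spreads the negative set over the feature space instead
of letting it concentrate near a few hub entities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._types import AssociationMatrix, SimilarityMatrix

__all__ = ["PairSample", "SamplingConfig", "build_adjacency", "pair_representation", "sample_negatives"]


@dataclass(frozen=True)
class PairSample:
    """One (miRNA, disease) pair with a binary association label."""

    mirna_index: int
    disease_index: int
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class SamplingConfig:
    """Negative-sampling settings.

    k_clusters
        Number of k-means clusters over the zero-pairs (default 23).
    n_negatives
        Total negatives to draw; ``None`` means one per positive.
    seed
        Seeds both the k-means initialisation and the per-cluster draws.
    """

    k_clusters: int = 23
    n_negatives: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.n_negatives is not None and self.n_negatives < 1:
            raise ValueError("n_negatives must be >= 1")


def build_adjacency(pairs, mirna_ids, disease_ids) -> AssociationMatrix:
    """Build the binary adjacency matrix from an association list.

    ``pairs`` is an iterable of (miRNA id, disease id); identifiers must
    come from the supplied universes.  Duplicate pairs are counted once
    with a warning.
    """
    mirna_ids = [str(m) for m in mirna_ids]
    disease_ids = [str(d) for d in disease_ids]
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    if len(mi) != len(mirna_ids):
        raise ValueError("duplicate miRNA identifiers in universe")
    if len(di) != len(disease_ids):
        raise ValueError("duplicate disease identifiers in universe")
    A = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    seen = set()
    dups = 0
    for m, d in pairs:
        m, d = str(m), str(d)
        if m not in mi:
            raise KeyError(f"unknown miRNA identifier {m!r} in association list")
        if d not in di:
            raise KeyError(f"unknown disease identifier {d!r} in association list")
        if (m, d) in seen:
            dups += 1
            continue
        seen.add((m, d))
        A[mi[m], di[d]] = 1
    if dups:
        warnings.warn(f"{dups} duplicate association pair(s) counted once", stacklevel=2)
    return AssociationMatrix(pd.DataFrame(A, index=mirna_ids, columns=disease_ids))


def pair_representation(
    A: AssociationMatrix,
    FS: SimilarityMatrix,
    SS: SimilarityMatrix,
    pairs,
    GSm: SimilarityMatrix | None = None,
    GSd: SimilarityMatrix | None = None,
) -> np.ndarray:
    """Per-pair feature rows: concatenated similarity profiles.

    Each pair (i, j) is represented by [FS row of miRNA i | SS row of
    disease j]; if the GIP kernels are supplied their profiles are
    appended as well.  All matrices must be aligned to the adjacency
    identifiers.
    """
    if FS.ids != A.mirna_ids:
        raise ValueError("FS identifiers misaligned with adjacency miRNA ids")
    if SS.ids != A.disease_ids:
        raise ValueError("SS identifiers misaligned with adjacency disease ids")
    m_blocks = [FS.to_numpy()]
    d_blocks = [SS.to_numpy()]
    if GSm is not None:
        if GSm.ids != A.mirna_ids:
            raise ValueError("GS_m identifiers misaligned with adjacency miRNA ids")
        m_blocks.append(GSm.to_numpy())
    if GSd is not None:
        if GSd.ids != A.disease_ids:
            raise ValueError("GS_d identifiers misaligned with adjacency disease ids")
        d_blocks.append(GSd.to_numpy())
    Mside = np.hstack(m_blocks)
    Dside = np.hstack(d_blocks)
    rows = np.asarray([np.concatenate([Mside[i], Dside[j]]) for i, j in pairs])
    return rows


def sample_negatives(
    A: AssociationMatrix,
    pair_repr: np.ndarray,
    cfg: SamplingConfig,
) -> list[PairSample]:
    """Cluster-balanced draw of negative (unobserved) pairs.

    ``pair_repr`` carries one feature row per zero-pair of ``A`` in
    :meth:`AssociationMatrix.zero_pairs` order.  The zero-pairs are
    clustered with k-means and ``n_negatives`` unique pairs are drawn
    with per-cluster quotas as equal as possible: ``floor(n/k)`` from
    each cluster with the remainder assigned to the largest clusters.
    A cluster smaller than its quota hands its deficit to the others.
    Deterministic given ``cfg.seed``.
    """
    zeros = A.zero_pairs()
    n_zero = len(zeros)
    if pair_repr.shape[0] != n_zero:
        raise ValueError(
            f"pair_repr has {pair_repr.shape[0]} rows but adjacency has {n_zero} zero-pairs"
        )
    n = cfg.n_negatives if cfg.n_negatives is not None else int(A.values.sum().sum())
    if n > n_zero:
        raise ValueError(f"requested {n} negatives but only {n_zero} zero-pairs exist")
    k = cfg.k_clusters
    n_distinct = np.unique(pair_repr, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k_clusters={k} exceeds the {n_distinct} distinct zero-pair points")

    rng = np.random.default_rng(cfg.seed)
    if k == 1:
        chosen = rng.choice(n_zero, size=n, replace=False)
    else:
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=cfg.seed)
        labels = km.fit_predict(pair_repr)
        cluster_members = [np.flatnonzero(labels == c) for c in range(k)]
        sizes = np.array([len(m) for m in cluster_members])
        quotas = np.full(k, n // k)
        # remainder goes to the largest clusters
        remainder = n - quotas.sum()
        if remainder:
            order = np.argsort(-sizes, kind="stable")
            quotas[order[:remainder]] += 1
        # clusters smaller than their quota push the deficit elsewhere
        deficit = int(np.maximum(quotas - sizes, 0).sum())
        quotas = np.minimum(quotas, sizes)
        while deficit > 0:
            room = sizes - quotas
            if room.sum() == 0:  # pragma: no cover - guarded by n <= n_zero
                break
            order = np.argsort(-room, kind="stable")
            for c in order:
                if deficit == 0:
                    break
                if room[c] > 0:
                    quotas[c] += 1
                    room[c] -= 1
                    deficit -= 1
        if int(np.maximum(np.full(k, n // k) - sizes, 0).sum()) > 0:
            warnings.warn(
                "some clusters were smaller than their quota; deficit redistributed",
                stacklevel=2,
            )
        chosen = np.concatenate(
            [rng.choice(m, size=q, replace=False) for m, q in zip(cluster_members, quotas) if q]
        )
    chosen = np.sort(chosen)
    return [PairSample(zeros[i][0], zeros[i][1], 0) for i in chosen]
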