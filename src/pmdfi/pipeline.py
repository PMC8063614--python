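"""End-to-end pipeline: similarities -> codes -> cross features -> ensemble.

The stages mirror the method's flow: build the four similarity views
(functional, semantic, and the two interaction-profile kernels), train
one stacked autoencoder per view on that view's similarity rows,
represent each labelled pair by the concatenation of its entity codes,
and evaluate the stacked forest ensemble by cross-validation.

Feature extraction is transductive by default — autoencoders see all
similarity rows, which are entity-level (not pair-label-level) inputs —
matching the reference flow; ``strict`` mode additionally recomputes
the GIP kernels from the training-fold adjacency in each fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import AssociationMatrix, SimilarityMatrix
from .dataset import PairSample, SamplingConfig, pair_representation, sample_negatives
from .ensemble import PMDFIClassifier, rank_mirnas_for_disease
from .evaluation import (
    CVResult,
    _stratified_assignments,
    ablation_cross_features,
    auc_aupr,
    binary_metrics,
    cross_validate,
)
from .representation import CrossFeatureSet, StackedAutoencoder, build_cross_features
from .similarity import gip_kernel
from .synthetic import BlockNetworkConfig, simulate_block_network, simulate_similarities

__all__ = [
    "PipelineConfig",
    "PairFeaturizer",
    "assemble_pairs",
    "run_pipeline",
    "strict_cross_validate",
    "make_benchmark",
]

logger = logging.getLogger("pmdfi")


@dataclass
class PipelineConfig:
    """Serializable snapshot of one run's settings."""

    folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    sae_layers: tuple = (256, 128, 64)
    sae_epochs: int = 500
    sae_lr: float = 0.1
    sae_weight_decay: float = 1e-4
    n_trees: int = 300
    stack_folds: int = 5
    mode: str = "transductive"  # or "strict"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sae_layers"] = list(self.sae_layers)
        return d


class PairFeaturizer:
    """Maps identifier pairs to cross features via fitted per-view encoders.

    Holds the adjacency, the four similarity views aligned to it, and
    one fitted :class:`StackedAutoencoder` per view.  Entity codes are
    computed once; a pair's cross features are concatenations of row
    lookups, so scoring every candidate pair of a disease is cheap.
    """

    VIEW_KINDS = ("FS", "SS", "GS_m", "GS_d")

    def __init__(self, A: AssociationMatrix, FS, SS, GSm, GSd, config: PipelineConfig, seed: int = 0):
        FS = FS.align(A.mirna_ids)
        GSm = GSm.align(A.mirna_ids)
        SS = SS.align(A.disease_ids)
        GSd = GSd.align(A.disease_ids)
        self.A = A
        self.views = {"FS": FS, "SS": SS, "GS_m": GSm, "GS_d": GSd}
        self.config = config
        self._codes: dict[str, np.ndarray] = {}
        self.encoders: dict[str, StackedAutoencoder] = {}
        rng = np.random.default_rng(seed)
        for kind in self.VIEW_KINDS:
            sae = StackedAutoencoder(
                layer_sizes=config.sae_layers,
                weight_decay=config.sae_weight_decay,
                epochs_per_layer=config.sae_epochs,
                learning_rate=config.sae_lr,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            rows = self.views[kind].to_numpy()
            self.encoders[kind] = sae.fit(rows)
            self._codes[kind] = sae.transform(rows)
        self._mi = {m: i for i, m in enumerate(A.mirna_ids)}
        self._di = {d: j for j, d in enumerate(A.disease_ids)}

    @property
    def mirna_ids(self):
        return self.A.mirna_ids

    @property
    def disease_ids(self):
        return self.A.disease_ids

    def known_pairs(self) -> set:
        return {
            (self.A.mirna_ids[i], self.A.disease_ids[j])
            for i, j in self.A.positive_pairs()
        }

    def cross_features_by_index(self, index_pairs) -> CrossFeatureSet:
        mi = np.asarray([p[0] for p in index_pairs], dtype=int)
        di = np.asarray([p[1] for p in index_pairs], dtype=int)
        return build_cross_features(
            D_fs=self._codes["FS"][mi],
            D_ss=self._codes["SS"][di],
            D_gsm=self._codes["GS_m"][mi],
            D_gsd=self._codes["GS_d"][di],
        )

    def cross_features(self, id_pairs) -> CrossFeatureSet:
        index_pairs = [(self._mi[m], self._di[d]) for m, d in id_pairs]
        return self.cross_features_by_index(index_pairs)


def assemble_pairs(
    A: AssociationMatrix,
    FS: SimilarityMatrix,
    SS: SimilarityMatrix,
    sampling: SamplingConfig,
) -> list[PairSample]:
    """Positives (all ones of A) plus cluster-balanced negatives."""
    positives = [PairSample(i, j, 1) for i, j in A.positive_pairs()]
    zeros = A.zero_pairs()
    repr_rows = pair_representation(A, FS, SS, zeros)
    negatives = sample_negatives(A, repr_rows, sampling)
    return positives + negatives


@dataclass
class PipelineResult:
    cv: CVResult
    ablation: dict | None
    featurizer: PairFeaturizer
    samples: list[PairSample]
    labels: np.ndarray
    cross: CrossFeatureSet

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "cv_result.json", "w") as fh:
            json.dump(self.cv.to_dict(), fh, indent=2)
        pd.DataFrame(self.cv.per_fold).to_csv(outdir / "cv_folds.tsv", sep="\t", index=False)
        if self.ablation is not None:
            rows = [
                {"view": k, **r.summary()} for k, r in self.ablation.items()
            ]
            pd.DataFrame(rows).to_csv(outdir / "ablation.tsv", sep="\t", index=False)


def strict_cross_validate(
    A: AssociationMatrix,
    FS: SimilarityMatrix,
    SS: SimilarityMatrix,
    samples: list[PairSample],
    config: PipelineConfig,
    seed: int = 0,
) -> CVResult:
    """Leakage-free k-fold evaluation with per-fold GIP recomputation.

    In each fold, the test positives are removed from the adjacency
    before the interaction-profile kernels are computed, and the
    autoencoders are retrained on the fold's views, so no test-pair
    association information reaches the representations.
    """
    y = np.asarray([s.label for s in samples], dtype=int)
    index_pairs = [(s.mirna_index, s.disease_index) for s in samples]
    assign = _stratified_assignments(y, config.folds, seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=config.folds)
    result = CVResult(folds=config.folds, seed=seed, fold_assignments=assign)
    for f in range(config.folds):
        te = assign == f
        tr = ~te
        A_tr = A.values.to_numpy().copy()
        for s, held_out in zip(samples, te):
            if held_out and s.label == 1:
                A_tr[s.mirna_index, s.disease_index] = 0
        A_fold = AssociationMatrix(
            pd.DataFrame(A_tr, index=A.mirna_ids, columns=A.disease_ids)
        )
        GSm = gip_kernel(A_fold, "miRNA")
        GSd = gip_kernel(A_fold, "disease")
        fz = PairFeaturizer(A_fold, FS, SS, GSm, GSd, config, seed=int(fold_seeds[f]))
        cross = fz.cross_features_by_index(index_pairs)
        model = PMDFIClassifier(
            n_trees=config.n_trees,
            stack_folds=config.stack_folds,
            random_state=int(fold_seeds[f]),
        )
        model.fit(cross.subset(tr), y[tr])
        scores = model.decision_scores(cross.subset(te))
        auc, aupr = auc_aupr(scores, y[te])
        bm = binary_metrics(scores, y[te], config.threshold)
        result.per_fold.append(
            {
                "fold": f,
                "auc": auc,
                "aupr": aupr,
                "precision": bm.precision,
                "recall": bm.recall,
                "f1": bm.f1,
                "n_test": int(te.sum()),
            }
        )
    return result


def run_pipeline(
    A: AssociationMatrix,
    FS: SimilarityMatrix,
    SS: SimilarityMatrix,
    config: PipelineConfig | None = None,
    with_ablation: bool = False,
) -> PipelineResult:
    """Run similarity -> representation -> ensemble -> cross-validation."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    GSm = gip_kernel(A, "miRNA")
    GSd = gip_kernel(A, "disease")
    featurizer = PairFeaturizer(
        A, FS, SS, GSm, GSd, config, seed=int(rng.integers(0, 2**31 - 1))
    )
    sampling = SamplingConfig(
        k_clusters=config.sampling.k_clusters,
        n_negatives=config.sampling.n_negatives,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    samples = assemble_pairs(A, featurizer.views["FS"], featurizer.views["SS"], sampling)
    labels = np.array([s.label for s in samples])
    cross = featurizer.cross_features_by_index(
        [(s.mirna_index, s.disease_index) for s in samples]
    )
    cv_seed = int(rng.integers(0, 2**31 - 1))
    if config.mode == "strict":
        cv = strict_cross_validate(A, FS, SS, samples, config, seed=cv_seed)
        logger.info(
            "strict mode: per-fold GIP/autoencoder recomputation; transductive "
            "results would include test-link information in the kernels"
        )
    elif config.mode == "transductive":
        cv = cross_validate(
            cross,
            labels,
            folds=config.folds,
            seed=cv_seed,
            model_factory=lambda s: PMDFIClassifier(
                n_trees=config.n_trees, stack_folds=config.stack_folds, random_state=s
            ),
            threshold=config.threshold,
        )
    else:
        raise ValueError(f"unknown mode {config.mode!r}; expected 'transductive' or 'strict'")
    cv.config = config.to_dict()
    ablation = None
    if with_ablation:
        ablation = ablation_cross_features(
            cross, labels, folds=config.folds, seed=cv_seed, n_trees=config.n_trees
        )
    return PipelineResult(cv, ablation, featurizer, samples, labels, cross)


def make_benchmark(
    seed: int = 0,
    net_cfg: BlockNetworkConfig | None = None,
    config: PipelineConfig | None = None,
    informative_similarities: bool = True,
):
    """Default planted-block benchmark inputs (A, FS, SS, memberships).

    Network and similarity structure follow :class:`BlockNetworkConfig`
    defaults (100 miRNAs x 80 diseases, 5 blocks, p_in 0.30 / p_out
    0.02, similarity noise 0.1).
    """
    net_cfg = net_cfg or BlockNetworkConfig(seed=seed)
    A, memberships = simulate_block_network(net_cfg)
    FS, SS = simulate_similarities(memberships, net_cfg, informative=informative_similarities)
    return A, FS, SS, memberships
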