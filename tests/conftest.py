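"""Shared fixtures: the planted-block benchmark is built once per session.

The heavy objects (similarity views, autoencoder codes, cross features,
the ablation and permuted-label cross-validation runs) are reused by
both the unit and the acceptance tests, so the expensive forest fits
happen once.
"""

import numpy as np
import pandas as pd
import pytest

from pmdfi import (
    AssociationMatrix,
    DiseaseDAG,
    PMDFIClassifier,
    SamplingConfig,
    ablation_cross_features,
    cross_validate,
    make_benchmark,
)
from pmdfi.pipeline import PairFeaturizer, PipelineConfig, assemble_pairs
from pmdfi.similarity import gip_kernel

BENCH_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    """Default planted-block network: 100 x 80, 5 blocks."""
    A, FS, SS, memberships = make_benchmark(seed=BENCH_SEED)
    return {"A": A, "FS": FS, "SS": SS, "memberships": memberships}


@pytest.fixture(scope="session")
def benchmark_features(benchmark):
    """Featurizer, labelled samples and cross features on the benchmark."""
    A, FS, SS = benchmark["A"], benchmark["FS"], benchmark["SS"]
    GSm = gip_kernel(A, "miRNA")
    GSd = gip_kernel(A, "disease")
    config = PipelineConfig(seed=BENCH_SEED)
    fz = PairFeaturizer(A, FS, SS, GSm, GSd, config, seed=11)
    samples = assemble_pairs(A, fz.views["FS"], fz.views["SS"], SamplingConfig(seed=12))
    labels = np.array([s.label for s in samples])
    cross = fz.cross_features_by_index([(s.mirna_index, s.disease_index) for s in samples])
    return {"featurizer": fz, "samples": samples, "labels": labels, "cross": cross}


@pytest.fixture(scope="session")
def benchmark_ablation(benchmark_features):
    """Per-view and stacked 5-fold CV under identical folds."""
    return ablation_cross_features(
        benchmark_features["cross"], benchmark_features["labels"], folds=5, seed=13
    )


@pytest.fixture(scope="session")
def permuted_cv(benchmark_features):
    """Stacked 5-fold CV after destroying the labels (null control)."""
    rng = np.random.default_rng(14)
    yperm = rng.permutation(benchmark_features["labels"])
    return cross_validate(benchmark_features["cross"], yperm, folds=5, seed=13)


@pytest.fixture(scope="session")
def benchmark_model(benchmark_features):
    """Stacked model fitted on the full benchmark sample set."""
    return PMDFIClassifier(n_trees=100, random_state=3).fit(
        benchmark_features["cross"], benchmark_features["labels"]
    )


@pytest.fixture
def chain_dag():
    """Three-generation chain G -> P -> D with one disease per node."""
    return DiseaseDAG(
        nodes={"G", "P", "D"},
        parent_edges={"D": ["P"], "P": ["G"]},
        annotation={"dD": "D", "dP": "P", "dG": "G"},
    )


@pytest.fixture
def identity_association():
    """2 x 2 identity adjacency (2 miRNAs, 2 diseases)."""
    return AssociationMatrix(
        pd.DataFrame(np.eye(2, dtype=int), index=["m1", "m2"], columns=["d1", "d2"])
    )
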