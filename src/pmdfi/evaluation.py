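"""Cross-validation driver, threshold metrics, AUC/AUPR, and ablation.

Evaluation is transductive by default, matching the pipeline's flow:
similarity matrices and autoencoder codes are computed once on the full
network, and cross-validation partitions only the labelled pair samples.
The alternative (recomputing the GIP kernels per training fold) is
stricter about information leakage; both modes are exposed in the
pipeline layer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .ensemble import PMDFIClassifier
from .representation import CrossFeatureSet

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "CVResult",
    "binary_metrics",
    "f1_from_precision_recall",
    "auc_aupr",
    "cross_validate",
    "ablation_cross_features",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class BinaryMetrics:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    #: True when a zero denominator forced a metric to 0
    degenerate: bool = False


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def binary_metrics(scores, labels, threshold: float = 0.5) -> BinaryMetrics:
    """Thresholded precision, recall and F1 with explicit confusion counts.

    A zero denominator (no predicted positives, or no true positives)
    reports the affected metric as 0 and sets ``degenerate``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.size == 0:
        raise ValueError("cannot compute metrics on empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return BinaryMetrics(
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        counts=ConfusionCounts(tp, fp, tn, fn),
        degenerate=degenerate,
    )


def auc_aupr(scores, labels) -> tuple[float, float]:
    """ROC AUC (midrank tie handling) and step-wise precision-recall AUC."""
    labels = np.asarray(labels).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


@dataclass
class CVResult:
    """Per-fold and mean metrics of one cross-validation run."""

    folds: int
    seed: int
    per_fold: list[dict] = field(default_factory=list)
    fold_assignments: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    METRICS = ("auc", "aupr", "precision", "recall", "f1")

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.per_fold]))

    def summary(self) -> dict:
        return {m: self.mean(m) for m in self.METRICS}

    def fold_hash(self) -> str:
        """Digest of the fold partition — equal hashes mean identical folds."""
        payload = np.asarray(self.fold_assignments, dtype=np.int64).tobytes()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seed": self.seed,
            "mean": self.summary(),
            "per_fold": self.per_fold,
            "fold_hash": self.fold_hash() if self.fold_assignments is not None else None,
            "config": self.config,
        }


def _stratified_assignments(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assign = np.full(y.shape[0], -1, dtype=np.int64)
    for f, (_, te) in enumerate(skf.split(np.zeros((y.shape[0], 1)), y)):
        assign[te] = f
    return assign


def cross_validate(
    cross: CrossFeatureSet,
    labels,
    folds: int = 5,
    seed: int = 0,
    model_factory=None,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold evaluation of the stacked model.

    ``model_factory(fold_seed)`` must return an unfitted estimator with
    ``fit`` and ``decision_scores``; the default builds a
    :class:`PMDFIClassifier` with standard settings.  Deterministic for
    a fixed seed.
    """
    y = np.asarray(labels).astype(int).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if np.unique(y).size < 2:
        raise ValueError("cross-validation needs both classes")
    if model_factory is None:
        def model_factory(fold_seed):
            return PMDFIClassifier(random_state=fold_seed)

    assign = _stratified_assignments(y, folds, seed)
    result = CVResult(folds=folds, seed=seed, fold_assignments=assign)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=folds)
    for f in range(folds):
        te = assign == f
        tr = ~te
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            raise ValueError(f"fold {f} lost a class; use fewer folds or more samples")
        model = model_factory(int(fold_seeds[f]))
        model.fit(cross.subset(tr), y[tr])
        scores = model.decision_scores(cross.subset(te))
        auc, aupr = auc_aupr(scores, y[te])
        bm = binary_metrics(scores, y[te], threshold)
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


class _SingleViewModel:
    """One random forest on a single cross block (ablation baseline)."""

    def __init__(self, view: int, n_trees: int, seed: int):
        from sklearn.ensemble import RandomForestClassifier

        self.view = view
        self.forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", bootstrap=True,
            n_jobs=1, random_state=seed,
        )

    def fit(self, cross: CrossFeatureSet, y):
        self.forest.fit(cross.blocks[self.view], y)
        return self

    def decision_scores(self, cross: CrossFeatureSet) -> np.ndarray:
        return self.forest.predict_proba(cross.blocks[self.view])[:, 1]


def ablation_cross_features(
    cross: CrossFeatureSet,
    labels,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 300,
) -> dict[str, CVResult]:
    """Per-view forests vs. the full stack, under identical folds.

    Returns CV results keyed ``D1``..``D4`` plus ``stacked``; all five
    runs share the same fold partition (verifiable via ``fold_hash``).
    """
    out: dict[str, CVResult] = {}
    for v in range(4):
        out[f"D{v + 1}"] = cross_validate(
            cross, labels, folds=folds, seed=seed,
            model_factory=lambda s, v=v: _SingleViewModel(v, n_trees, s),
        )
    out["stacked"] = cross_validate(
        cross, labels, folds=folds, seed=seed,
        model_factory=lambda s: PMDFIClassifier(n_trees=n_trees, random_state=s),
    )
    return out
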