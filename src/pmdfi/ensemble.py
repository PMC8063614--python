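"""Stacking ensemble: four random forests merged by logistic regression.

Each cross-feature block D1-D4 trains its own random forest (300 trees
by default).  The forests' positive-class probabilities become the
meta-features of a logistic-regression layer that learns how much to
trust each view; the final association score is sigma(w'p + b).

To keep the meta-learner honest, its training meta-features are
out-of-fold: the training set is split into ``stack_folds`` internal
stratified folds, each forest scores the fold it did not see, and the
forests are then refit on all training data for prediction time.  A
``naive`` mode (meta-features = in-sample scores) exists for
comparison but overestimates base-learner reliability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .representation import CrossFeatureSet

__all__ = ["ForestConfig", "PMDFIClassifier", "fit_pmdfi", "predict", "rank_mirnas_for_disease"]

N_VIEWS = 4


@dataclass
class ForestConfig:
    """Hyperparameters shared by the four base forests."""

    n_trees: int = 300
    max_features: str | float = "sqrt"
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class PMDFIClassifier(BaseEstimator, ClassifierMixin):
    """Four cross-feature random forests stacked with logistic regression.

    Parameters
    ----------
    n_trees : int, default 300
        Trees per forest.
    max_features, min_leaf
        Forwarded to each :class:`~sklearn.ensemble.RandomForestClassifier`.
    stack_folds : int, default 5
        Internal stratified folds producing out-of-fold meta-features.
    stacking : {"oof", "naive"}, default "oof"
        ``naive`` feeds in-sample base scores to the meta-learner.
    block_widths : tuple of int or None
        Needed only when ``fit``/``predict`` receive a plain 2-d array
        instead of a :class:`CrossFeatureSet`; the array is split into
        four blocks of these widths.
    random_state : int, default 0
        Master seed; forests and fold shuffling derive from it.

    Attributes
    ----------
    forests_ : list of RandomForestClassifier
        One fitted forest per cross block, refit on all training data.
    meta_ : LogisticRegression
        The fitted meta-learner over the four base probabilities.
    meta_weights_, meta_intercept_ : ndarray, float
        Convenience views of the meta-learner coefficients.
    """

    def __init__(
        self,
        n_trees: int = 300,
        max_features="sqrt",
        min_leaf: int = 1,
        stack_folds: int = 5,
        stacking: str = "oof",
        block_widths=None,
        n_jobs: int = 1,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_leaf = min_leaf
        self.stack_folds = stack_folds
        self.stacking = stacking
        self.block_widths = block_widths
        self.n_jobs = n_jobs
        self.random_state = random_state

    # -- plumbing ---------------------------------------------------------
    def _as_cross(self, X) -> CrossFeatureSet:
        if isinstance(X, CrossFeatureSet):
            return X
        X = np.asarray(X, dtype=float)
        widths = self.block_widths
        if widths is None:
            if X.shape[1] % N_VIEWS:
                raise ValueError(
                    "plain-array input needs block_widths (or a width divisible by 4)"
                )
            w = X.shape[1] // N_VIEWS
            widths = (w,) * N_VIEWS
        return CrossFeatureSet.from_stacked(X, widths)

    def _make_forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            min_samples_leaf=self.min_leaf,
            bootstrap=True,
            n_jobs=self.n_jobs,
            random_state=seed,
        )

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        cross = self._as_cross(X)
        y = np.asarray(y).astype(int).ravel()
        if cross.n_samples != y.shape[0]:
            raise ValueError("sample counts of features and labels disagree")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(f"labels contain a single class {classes.tolist()}; need both 0 and 1")
        if self.stacking not in ("oof", "naive"):
            raise ValueError(f"unknown stacking mode {self.stacking!r}")
        if cross.n_samples < self.stack_folds:
            raise ValueError(
                f"{cross.n_samples} samples cannot be split into {self.stack_folds} stacking folds"
            )
        rng = np.random.default_rng(self.random_state)
        forest_seeds = rng.integers(0, 2**31 - 1, size=N_VIEWS)
        fold_seed = int(rng.integers(0, 2**31 - 1))

        if self.stacking == "oof":
            meta_X = np.zeros((cross.n_samples, N_VIEWS))
            skf = StratifiedKFold(n_splits=self.stack_folds, shuffle=True, random_state=fold_seed)
            for tr, te in skf.split(cross.D1, y):
                for v, block in enumerate(cross.blocks):
                    f = self._make_forest(int(forest_seeds[v]))
                    f.fit(block[tr], y[tr])
                    meta_X[te, v] = f.predict_proba(block[te])[:, 1]
        # refit base forests on everything
        self.forests_ = []
        for v, block in enumerate(cross.blocks):
            f = self._make_forest(int(forest_seeds[v]))
            f.fit(block, y)
            self.forests_.append(f)
        if self.stacking == "naive":
            meta_X = np.column_stack(
                [f.predict_proba(b)[:, 1] for f, b in zip(self.forests_, cross.blocks)]
            )
        self.meta_ = LogisticRegression(max_iter=1000).fit(meta_X, y)
        self.meta_weights_ = self.meta_.coef_.ravel()
        self.meta_intercept_ = float(self.meta_.intercept_[0])
        self.classes_ = self.meta_.classes_
        self.block_widths_ = cross.block_widths
        return self

    def base_scores(self, X) -> np.ndarray:
        """Per-view positive-class probabilities p1..p4, shape (n, 4)."""
        check_is_fitted(self, "forests_")
        cross = self._as_cross(X)
        if cross.block_widths != self.block_widths_:
            raise ValueError(
                f"cross block widths {cross.block_widths} do not match "
                f"training widths {self.block_widths_}"
            )
        return np.column_stack(
            [f.predict_proba(b)[:, 1] for f, b in zip(self.forests_, cross.blocks)]
        )

    def predict_proba(self, X) -> np.ndarray:
        p = self.base_scores(X)
        return self.meta_.predict_proba(p)

    def decision_scores(self, X) -> np.ndarray:
        """Final association scores sigma(w'p + b) in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


# -- functional wrappers ---------------------------------------------------

def fit_pmdfi(
    cross: CrossFeatureSet,
    labels,
    forest_cfg: ForestConfig | None = None,
    stack_folds: int = 5,
    seed: int = 0,
) -> PMDFIClassifier:
    """Fit the full stacked model on a cross-feature set."""
    cfg = forest_cfg or ForestConfig()
    model = PMDFIClassifier(
        n_trees=cfg.n_trees,
        max_features=cfg.max_features,
        min_leaf=cfg.min_leaf,
        stack_folds=stack_folds,
        random_state=seed,
    )
    return model.fit(cross, labels)


def predict(model: PMDFIClassifier, cross: CrossFeatureSet) -> dict[str, np.ndarray]:
    """Base probabilities and final score per sample."""
    p = model.base_scores(cross)
    final = model.meta_.predict_proba(p)[:, 1]
    return {"p1": p[:, 0], "p2": p[:, 1], "p3": p[:, 2], "p4": p[:, 3], "final": final}


def rank_mirnas_for_disease(model, feature_provider, disease_id, k: int = 10):
    """Top-``k`` candidate miRNAs for one disease by final score.

    ``feature_provider`` must expose ``mirna_ids``, ``disease_ids``,
    ``known_pairs()`` (set of associated (miRNA id, disease id)) and
    ``cross_features(pairs)`` returning a :class:`CrossFeatureSet` for a
    list of identifier pairs.  miRNAs already associated with the
    disease are excluded; ties break by miRNA identifier.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if disease_id not in feature_provider.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    known = feature_provider.known_pairs()
    candidates = [m for m in feature_provider.mirna_ids if (m, disease_id) not in known]
    if not candidates:
        return []
    cross = feature_provider.cross_features([(m, disease_id) for m in candidates])
    scores = model.decision_scores(cross)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], str(candidates[i])))
    return [(candidates[i], float(scores[i])) for i in order[:k]]
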