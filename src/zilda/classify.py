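"""Cross-validated disease-state classification on selected features.

The differentially abundant features feed a random-forest classifier
evaluated by stratified k-fold cross-validation.  The headline number is the
pooled out-of-fold AUC: every sample's predicted probability is taken from
the fold in which it was held out, and one ROC curve is computed over all
samples.  Per-fold AUCs are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .tables import CountTable
from .zil import DifferentialTable


class ClassifierError(ValueError):
    """Raised for invalid classifier inputs."""


@dataclass
class CVResult:
    fold_aucs: list[float]
    pooled_auc: float
    n_folds: int
    seed: int
    feature_ids: list[str]

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i + 1, "auc": auc} for i, auc in enumerate(self.fold_aucs)
        ]
        rows.append({"fold": "pooled", "auc": self.pooled_auc})
        return pd.DataFrame(rows)


def select_features_from_differential(
    diff: DifferentialTable | pd.DataFrame, max_features: int = 9
) -> list[str]:
    """Significant features ordered by q-value, truncated to ``max_features``.

    Ties in q are broken by |delta_mu| descending, then feature id.  The
    default of nine features matches the size of a compact genus-level
    biomarker panel.
    """
    frame = diff.frame if isinstance(diff, DifferentialTable) else diff
    sig = frame[frame["significant"].astype(bool)]
    if len(sig) == 0:
        raise ClassifierError(
            "no significant features to select; consider a more permissive FDR level"
        )
    ordered = sig.sort_values(
        by=["q_value", "delta_mu", "feature_id"],
        key=lambda col: -col.abs() if col.name == "delta_mu" else col,
        kind="mergesort",
    )
    return list(ordered["feature_id"].head(max_features))


def crossval_auc(
    table: CountTable,
    labels,
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
) -> CVResult:
    """Stratified k-fold random-forest AUC on a feature-restricted table.

    ``labels`` is a binary vector aligned with ``table.sample_ids`` (1 = the
    disease class).  Reproducible: the seed drives both the fold shuffle and
    the forest.
    """
    y = np.asarray(labels, dtype=int).ravel()
    if y.size != len(table.sample_ids):
        raise ClassifierError("labels must align with table.sample_ids")
    if set(np.unique(y)) != {0, 1}:
        raise ClassifierError("labels must contain both classes coded 0/1")
    if len(table.feature_ids) < 2:
        raise ClassifierError("need at least 2 features")
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ClassifierError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{n_folds} folds; use fewer folds"
        )
    x = table.values.T  # samples x features
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(y.size)
    fold_aucs: list[float] = []
    for train, test in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(x[train], y[train])
        proba = clf.predict_proba(x[test])[:, list(clf.classes_).index(1)]
        oof[test] = proba
        fold_aucs.append(float(roc_auc_score(y[test], proba)))
    pooled = float(roc_auc_score(y, oof))
    return CVResult(
        fold_aucs=fold_aucs,
        pooled_auc=pooled,
        n_folds=n_folds,
        seed=seed,
        feature_ids=list(table.feature_ids),
    )
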