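"""Model-object facade over the evaluation pipeline.

``PresenceClassifier`` is built from a :class:`FeatureTable` (epochs x
181 features with class labels and subject groups); ``fit()`` runs the
leave-one-subject-out evaluation — optionally with nested genetic
feature selection — and returns a :class:`PresenceResults` object
carrying per-fold metrics, aggregate estimates with their fold-to-fold
dispersion, selected masks, and Shapley attributions on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import AttributionResult, ShapleyConfig, attribute_model
from .features import FeatureTable
from .recordings import CLASSES
from .selection import CvResult, GaConfig, ModelSpec, loso_cv


class PresenceClassifier:
    """Three-class presence classifier evaluated subject-wise.

    Parameters
    ----------
    table:
        Assembled feature table.
    family:
        One of ``svm``, ``knn``, ``gradient_boosted_trees``,
        ``random_forest``, ``logistic_regression``, ``mlp``.
    ga:
        Optional :class:`GaConfig`; when given, wrapper feature selection
        runs nested inside every fold.
    """

    def __init__(self, table: FeatureTable, family: str = "mlp",
                 ga: GaConfig | None = None, seed: int = 0,
                 params: dict | None = None):
        self.table = table
        self.spec = ModelSpec(family, params or {})
        self.ga = ga
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, feature_names: list[str],
                       **kwargs) -> "PresenceClassifier":
        return cls(FeatureTable(frame, feature_names), **kwargs)

    def fit(self) -> "PresenceResults":
        cv = loso_cv(self.table, self.spec, ga_cfg=self.ga, seed=self.seed)
        return PresenceResults(self, cv)


@dataclass
class PresenceResults:
    """LOSO evaluation results for one classifier family."""

    model: PresenceClassifier
    cv: CvResult

    @property
    def macro_accuracy(self) -> float:
        return self.cv.macro_accuracy

    @property
    def accuracy_sd(self) -> float:
        return self.cv.accuracy_sd

    def metrics_frame(self) -> pd.DataFrame:
        return self.cv.to_frame()

    def selected_masks(self) -> list[np.ndarray | None]:
        return [f["mask"] for f in self.cv.folds]

    def summary(self) -> str:
        lines = [
            "Presence classification (leave-one-subject-out)",
            "=" * 55,
            f"family:        {self.model.spec.family}",
            f"subjects:      {self.cv.n_folds} (one fold each)",
            f"epochs:        {len(self.model.table.frame)}",
            f"features:      {len(self.model.table.feature_names)}"
            + ("" if self.model.ga is None else " (GA-selected per fold)"),
            "-" * 55,
            f"macro accuracy: {self.macro_accuracy:.3f} "
            f"+/- {self.accuracy_sd:.3f}",
        ]
        for metric in ("f1", "auc"):
            for cls in CLASSES:
                m, s = self.cv.class_metric(metric, cls)
                lines.append(
                    f"{metric.upper():>4s} {cls + ' vs rest:':<16s}"
                    f"{m:.3f} +/- {s:.3f}"
                )
        flagged = [f["subject"] for f in self.cv.folds if f.get("flag")]
        if flagged:
            lines.append(f"flagged folds: {flagged}")
        return "\n".join(lines)

    def attributions(self, target_class: str | None = None,
                     n_instances: int = 16, n_permutations: int = 128,
                     seed: int = 0) -> AttributionResult:
        """Shapley attributions from a model refit on all but one subject.

        The last subject is held out as the instance pool so the
        background (training rows) never includes the explained epochs.
        """
        table = self.model.table
        subjects = table.subjects
        held = subjects[-1]
        train = table.subset(table.groups != held)
        test = table.subset(table.groups == held)
        spec = self.model.spec
        pipe = spec.build(n_train_rows=len(train.frame), seed=self.model.seed)
        from .selection import _encode, _simplex_scores  # shared encoders
        pipe.fit(train.X, _encode(train.y))

        rng = np.random.default_rng(seed)
        pool = test.frame.index.to_numpy()
        if target_class is not None:
            pool = pool[test.y == target_class]
            if pool.size == 0:
                raise ValueError(
                    f"held-out subject has no {target_class!r} epochs"
                )
        take = rng.choice(pool, size=min(n_instances, pool.size),
                          replace=False)
        X_inst = test.frame.loc[take, table.feature_names].to_numpy()

        classes = [target_class] if target_class else list(CLASSES)
        cols = [CLASSES.index(c) for c in classes]

        def proba(M):
            scores = _simplex_scores(pipe, np.asarray(M, dtype=float),
                                     np.arange(len(CLASSES)))
            return scores[:, cols]
        return attribute_model(
            proba, X_inst, train.X, table.feature_names, classes,
            ShapleyConfig(n_permutations=n_permutations, rng_seed=seed),
        )
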