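"""Genetic-algorithm feature selection and leave-one-subject-out evaluation.

Six classifier families are evaluated on the 181-feature table with
leave-one-subject-out cross-validation (one fold per participant) and
one-vs-rest per-class F1 and AUC.  Feature selection is a wrapper genetic
algorithm over feature bitmasks whose fitness is the mean accuracy of a
subject-grouped inner cross-validation on the training side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureTable
from .recordings import CLASSES

MODEL_FAMILIES = ("svm", "knn", "gradient_boosted_trees", "random_forest",
                  "logistic_regression", "mlp")

#: Printed hyperparameters per family (the random-forest minimum leaf is
#: 5 % of the training epochs, resolved at fit time).
FAMILY_PARAMS: dict[str, dict] = {
    "knn": {"n_neighbors": 13, "leaf_size": 1},
    "mlp": {"hidden_layer_sizes": (25,), "activation": "logistic",
            "learning_rate_init": 1e-4, "solver": "lbfgs", "max_iter": 400},
    "gradient_boosted_trees": {"reg_alpha": 1.0, "max_depth": 7,
                               "learning_rate": 0.01, "n_estimators": 100},
    "random_forest": {"max_features": "sqrt", "min_leaf_fraction": 0.05,
                      "n_estimators": 20},
    "svm": {"C": 100.0, "gamma": 0.001, "kernel": "sigmoid"},
    # No penalty: C -> inf is the unpenalised limit (sklearn's preferred
    # spelling of penalty=None), Newton-type solver.
    "logistic_regression": {"C": float("inf"), "solver": "newton-cg",
                            "max_iter": 200},
}


@dataclass
class ModelSpec:
    """A classifier family with its preloaded hyperparameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}"
            )
        merged = dict(FAMILY_PARAMS[self.family])
        merged.update(self.params)
        self.params = merged

    def build(self, n_train_rows: int, seed: int = 0) -> Pipeline:
        p = dict(self.params)
        family = self.family
        if family == "knn":
            est = KNeighborsClassifier(**p)
        elif family == "mlp":
            est = MLPClassifier(random_state=seed, **p)
        elif family == "gradient_boosted_trees":
            est = XGBClassifier(random_state=seed, n_jobs=1,
                                eval_metric="mlogloss", **p)
        elif family == "random_forest":
            frac = p.pop("min_leaf_fraction")
            min_leaf = max(1, int(round(frac * n_train_rows)))
            est = RandomForestClassifier(random_state=seed,
                                         min_samples_leaf=min_leaf,
                                         n_jobs=1, **p)
        elif family == "svm":
            est = SVC(random_state=seed, **p)
        else:
            est = LogisticRegression(**p)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])


def _encode(y: np.ndarray) -> np.ndarray:
    codes = pd.Categorical(y, categories=list(CLASSES)).codes
    if (codes < 0).any():
        bad = sorted(set(y) - set(CLASSES))
        raise ValueError(f"labels outside {CLASSES}: {bad}")
    return codes.astype(int)


def _simplex_scores(fitted: Pipeline, X: np.ndarray,
                    classes_present: np.ndarray) -> np.ndarray:
    """(n, 3) class scores on the probability simplex, in CLASSES order."""
    clf = fitted.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        raw = fitted.predict_proba(X)
    else:
        df = fitted.decision_function(X)
        if df.ndim == 1:
            df = np.column_stack([-df, df])
        shifted = df - df.max(axis=1, keepdims=True)
        raw = np.exp(shifted)
        raw /= raw.sum(axis=1, keepdims=True)
    scores = np.zeros((X.shape[0], len(CLASSES)))
    for j, code in enumerate(fitted.named_steps["clf"].classes_):
        scores[:, int(code)] = raw[:, j]
    totals = scores.sum(axis=1, keepdims=True)
    return scores / totals


def fit_predict(spec: ModelSpec, train: FeatureTable, test: FeatureTable,
                mask: np.ndarray | None = None, seed: int = 0):
    """Fit one multiclass model on the training table, score the test table.

    Returns ``(scores, labels)`` with scores on the probability simplex in
    ``CLASSES`` order and labels the argmax class names.
    """
    if train.feature_names != test.feature_names:
        raise ValueError("train/test feature schemas differ (column order)")
    if mask is None:
        mask = np.ones(len(train.feature_names), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(train.feature_names):
        raise ValueError("mask length does not match the feature schema")
    if not mask.any():
        raise ValueError("empty feature mask")
    y_train = _encode(train.y)
    if len(np.unique(y_train)) < len(CLASSES):
        missing = set(CLASSES) - set(train.y)
        raise ValueError(f"class(es) absent from training data: {missing}")
    model = spec.build(n_train_rows=len(y_train), seed=seed)
    model.fit(train.X[:, mask], y_train)
    scores = _simplex_scores(model, test.X[:, mask], np.arange(len(CLASSES)))
    labels = np.asarray(CLASSES)[scores.argmax(axis=1)]
    return scores, labels


def ovr_auc(y_true: np.ndarray, scores_pos: np.ndarray) -> float | None:
    """One-vs-rest AUC from the rank statistic (Mann-Whitney)."""
    pos = y_true.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores_pos)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def compute_metrics(y_true, scores: np.ndarray) -> dict:
    """Accuracy plus per-class one-vs-rest F1 and AUC.

    ``y_true`` holds class names; ``scores`` is the (n, 3) simplex matrix
    in ``CLASSES`` order.  A class absent from the truth yields ``None``
    AUC/F1 entries (flagged, never silently zero).
    """
    y_true = np.asarray(y_true)
    if len(set(y_true)) < 2:
        raise ValueError("need at least two classes in the truth labels")
    rows_ok = np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
    if not rows_ok:
        raise ValueError("score rows must sum to 1")
    pred = np.asarray(CLASSES)[scores.argmax(axis=1)]
    out = {"accuracy": float(np.mean(pred == y_true)), "f1": {}, "auc": {}}
    for ci, cls in enumerate(CLASSES):
        truth_pos = y_true == cls
        if not truth_pos.any():
            out["f1"][cls] = None
            out["auc"][cls] = None
            continue
        pred_pos = pred == cls
        tp = int((pred_pos & truth_pos).sum())
        fp = int((pred_pos & ~truth_pos).sum())
        fn = int((~pred_pos & truth_pos).sum())
        out["f1"][cls] = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0
        out["auc"][cls] = ovr_auc(truth_pos, scores[:, ci])
    return out


# ---------------------------------------------------------------------------
# Genetic-algorithm wrapper selection
# ---------------------------------------------------------------------------

@dataclass
class GaConfig:
    """Wrapper-GA settings; fitness is grouped inner-CV mean accuracy."""

    population_size: int = 60
    generations: int = 40
    tournament_size: int = 3
    crossover_prob: float = 0.9
    mutation_rate: float | None = None  # default 1 / n_features
    elitism: int = 2
    inner_folds: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size % 2:
            raise ValueError("population_size must be even")
        for name in ("crossover_prob",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")


def _inner_cv_accuracy(spec: ModelSpec, table: FeatureTable,
                       mask: np.ndarray, cfg: GaConfig, seed: int) -> float:
    groups = table.groups
    n_groups = len(np.unique(groups))
    n_splits = min(cfg.inner_folds, n_groups)
    if n_splits < 2:
        raise ValueError("need >= 2 subjects for inner CV fitness")
    X, y = table.X[:, mask], _encode(table.y)
    accs = []
    for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
        if len(np.unique(y[tr])) < len(CLASSES):
            continue
        model = spec.build(n_train_rows=len(tr), seed=seed)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    if not accs:
        raise ValueError("inner CV degenerate: some class missing everywhere")
    return float(np.mean(accs))


def ga_select(table: FeatureTable, spec: ModelSpec,
              cfg: GaConfig | None = None) -> np.ndarray:
    """Evolve a feature bitmask maximising inner grouped-CV accuracy.

    Elitism guarantees a non-decreasing elite fitness trajectory; ties
    break toward fewer active features.  Returns the elite boolean mask.
    """
    cfg = cfg or GaConfig()
    y = table.y
    if len(set(y)) < 2:
        raise ValueError("degenerate table: a single class present")
    d = len(table.feature_names)
    p_mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / d
    rng = np.random.default_rng(cfg.rng_seed)
    cache: dict[bytes, float] = {}

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(d)] = True
        return mask

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = _inner_cv_accuracy(spec, table, mask, cfg,
                                            seed=cfg.rng_seed)
        return cache[key]

    def better(a: tuple, b: tuple) -> bool:
        # (fitness, -n_active): maximise fitness, then prefer fewer features
        return a > b

    pop = [repair(rng.random(d) < 0.5) for _ in range(cfg.population_size)]
    scored = [(fitness(m), -int(m.sum()), m) for m in pop]
    scored.sort(key=lambda s: (s[0], s[1]), reverse=True)
    elite = scored[0]

    for _ in range(cfg.generations):
        next_pop = [s[2].copy() for s in scored[:cfg.elitism]]
        while len(next_pop) < cfg.population_size:
            parents = []
            for _p in range(2):
                idx = rng.integers(len(scored), size=cfg.tournament_size)
                cand = max((scored[i] for i in idx),
                           key=lambda s: (s[0], s[1]))
                parents.append(cand[2])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < cfg.crossover_prob:
                swap = rng.random(d) < 0.5
                a[swap], b[swap] = parents[1][swap], parents[0][swap]
            for child in (a, b):
                flip = rng.random(d) < p_mut
                child[flip] = ~child[flip]
                next_pop.append(repair(child))
        pop = next_pop[:cfg.population_size]
        scored = [(fitness(m), -int(m.sum()), m) for m in pop]
        scored.sort(key=lambda s: (s[0], s[1]), reverse=True)
        if (scored[0][0], scored[0][1]) > (elite[0], elite[1]):
            elite = scored[0]
    return elite[2].copy()


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-fold held-out metrics of a leave-one-subject-out run."""

    family: str
    folds: list[dict]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f["metrics"]["accuracy"] for f in self.folds])

    @property
    def macro_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.n_folds > 1 else 0.0

    def class_metric(self, metric: str, cls: str) -> tuple[float, float]:
        vals = np.array([f["metrics"][metric][cls] for f in self.folds
                         if f["metrics"][metric][cls] is not None])
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), (float(vals.std(ddof=1))
                                    if vals.size > 1 else 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"subject": f["subject"],
                   "accuracy": f["metrics"]["accuracy"],
                   "flag": f.get("flag")}
            for cls in CLASSES:
                row[f"f1_{cls}"] = f["metrics"]["f1"][cls]
                row[f"auc_{cls}"] = f["metrics"]["auc"][cls]
            rows.append(row)
        return pd.DataFrame(rows)


def loso_cv(table: FeatureTable, spec: ModelSpec,
            ga_cfg: GaConfig | None = None, seed: int = 0) -> CvResult:
    """Leave-one-subject-out evaluation; one fold per subject.

    When ``ga_cfg`` is given, GA feature selection runs inside every fold
    on the training subjects only; the selected mask is applied to both
    sides of that fold.
    """
    subjects = table.subjects
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for LOSO")
    folds = []
    for fi, held_out in enumerate(subjects):
        test_mask = table.groups == held_out
        train = table.subset(~test_mask)
        test = table.subset(test_mask)
        flag = None
        if len(set(test.y)) < 2:
            flag = "held-out subject has a single class"
        mask = None
        if ga_cfg is not None:
            fold_cfg = GaConfig(**{**ga_cfg.__dict__,
                                   "rng_seed": ga_cfg.rng_seed + fi})
            mask = ga_select(train, spec, fold_cfg)
        scores, _ = fit_predict(spec, train, test, mask, seed=seed)
        metrics = compute_metrics(test.y, scores) if flag is None else (
            _single_class_metrics(test.y, scores)
        )
        folds.append({"subject": held_out, "metrics": metrics,
                      "mask": mask, "flag": flag})
    return CvResult(family=spec.family, folds=folds)


def _single_class_metrics(y_true, scores) -> dict:
    y_true = np.asarray(y_true)
    pred = np.asarray(CLASSES)[scores.argmax(axis=1)]
    out = {"accuracy": float(np.mean(pred == y_true)), "f1": {}, "auc": {}}
    for ci, cls in enumerate(CLASSES):
        truth_pos = y_true == cls
        if not truth_pos.any():
            out["f1"][cls] = None
            out["auc"][cls] = None
        else:
            pred_pos = pred == cls
            tp = int((pred_pos & truth_pos).sum())
            fn = int((~pred_pos & truth_pos).sum())
            fp = int((pred_pos & ~truth_pos).sum())
            denom = 2 * tp + fp + fn
            out["f1"][cls] = 2 * tp / denom if denom else 0.0
            out["auc"][cls] = None  # undefined without negatives
    return out
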