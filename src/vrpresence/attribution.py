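"""Shapley-value attribution and the self-report / feature statistics.

The Shapley value of feature ``i`` for a model score ``v`` is its average
marginal contribution over orderings of the remaining features, with
absent features imputed from a background reference.  The exact coalition
sum is infeasible beyond a handful of features, so the estimator samples
permutations uniformly; within each sampled ordering the telescoping sum
of marginal contributions equals ``v(x) - v(background)`` exactly, so the
efficiency identity is preserved by construction and the Monte-Carlo
error affects only the per-feature split.

The statistics stage covers the questionnaire analysis (Friedman test
with Dunn-Bonferroni post hoc) and the per-feature repeated-measures
ANOVA with Tukey HSD post hoc.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ShapleyConfig:
    """Monte-Carlo permutation estimator settings."""

    n_permutations: int = 256
    max_background: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


def shapley_permutation(value_fn, x: np.ndarray, background: np.ndarray,
                        cfg: ShapleyConfig | None = None):
    """Permutation-sampling Shapley values for one instance.

    ``value_fn`` maps an (m, d) matrix to m scalar scores; ``background``
    is a (d,) reference vector imputed for absent features.  Returns
    ``(phi, residual)`` where ``phi`` is the (d,) attribution vector and
    ``residual = v(x) - v(background) - sum(phi)`` (zero up to float
    arithmetic).
    """
    cfg = cfg or ShapleyConfig()
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float).ravel()
    d = x.size
    if background.size != d:
        raise ValueError("background length does not match the instance")
    rng = np.random.default_rng(cfg.rng_seed)
    phi = np.zeros(d)
    for _ in range(cfg.n_permutations):
        order = rng.permutation(d)
        grid = np.tile(background, (d + 1, 1))
        for step, j in enumerate(order, start=1):
            grid[step:, j] = x[j]
        values = np.asarray(value_fn(grid), dtype=float)
        phi[order] += np.diff(values)
    phi /= cfg.n_permutations
    v_full = float(np.asarray(value_fn(x[None, :]))[0])
    v_none = float(np.asarray(value_fn(background[None, :]))[0])
    residual = v_full - v_none - phi.sum()
    return phi, residual


def shapley_exact(value_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by enumeration over all 2^d coalitions (d <= 16)."""
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float).ravel()
    d = x.size
    if d > 16:
        raise ValueError("exact enumeration limited to d <= 16")
    rows = np.empty((2 ** d, d))
    for s in range(2 ** d):
        members = [(s >> j) & 1 for j in range(d)]
        rows[s] = np.where(members, x, background)
    values = np.asarray(value_fn(rows), dtype=float)
    phi = np.zeros(d)
    fact = math.factorial
    for i in range(d):
        for s in range(2 ** d):
            if (s >> i) & 1:
                continue
            size = bin(s).count("1")
            weight = fact(size) * fact(d - size - 1) / fact(d)
            phi[i] += weight * (values[s | (1 << i)] - values[s])
    return phi


@dataclass
class AttributionResult:
    """Signed per-(instance, feature, class) contributions and summaries."""

    contributions: pd.DataFrame  # instance, class, feature, phi
    efficiency_residuals: np.ndarray

    def summary(self, target_class: str | None = None) -> pd.DataFrame:
        df = self.contributions
        if target_class is not None:
            df = df[df["class"] == target_class]
        agg = df.groupby("feature")["phi"].agg(
            mean_abs_phi=lambda s: float(np.mean(np.abs(s))),
            mean_phi="mean",
        )
        return agg.sort_values("mean_abs_phi", ascending=False).reset_index()

    def top_feature(self, target_class: str) -> str:
        return str(self.summary(target_class).iloc[0]["feature"])


def attribute_model(predict_proba, X_instances: np.ndarray,
                    background_X: np.ndarray, feature_names: list[str],
                    class_names: list[str],
                    cfg: ShapleyConfig | None = None) -> AttributionResult:
    """Shapley attributions of every instance for every class score.

    ``predict_proba`` maps an (m, d) matrix to (m, n_classes) simplex
    scores.  The background is the feature-wise mean of ``background_X``
    (subsampled to ``max_background`` rows first when larger).
    """
    cfg = cfg or ShapleyConfig()
    background_X = np.asarray(background_X, dtype=float)
    if background_X.shape[0] == 0:
        raise ValueError("background set is empty")
    if background_X.shape[0] > cfg.max_background:
        rng = np.random.default_rng(cfg.rng_seed)
        idx = rng.choice(background_X.shape[0], cfg.max_background,
                         replace=False)
        background_X = background_X[idx]
    background = background_X.mean(axis=0)

    rows, residuals = [], []
    for ii, x in enumerate(np.atleast_2d(X_instances)):
        if x.size != len(feature_names):
            raise ValueError("instance length does not match feature schema")
        for ci, cls in enumerate(class_names):
            fn = lambda M, _ci=ci: predict_proba(M)[:, _ci]
            inst_cfg = ShapleyConfig(cfg.n_permutations, cfg.max_background,
                                     cfg.rng_seed + 7919 * ii + ci)
            phi, resid = shapley_permutation(fn, x, background, inst_cfg)
            residuals.append(resid)
            rows.extend(
                {"instance": ii, "class": cls, "feature": name,
                 "phi": float(p)}
                for name, p in zip(feature_names, phi)
            )
    return AttributionResult(pd.DataFrame(rows), np.array(residuals))


# ---------------------------------------------------------------------------
# Statistics stage
# ---------------------------------------------------------------------------

@dataclass
class StatTestResult:
    statistic: float
    df: tuple
    pvalue: float
    posthoc: pd.DataFrame
    method: str = ""


def _as_matrix(scores) -> np.ndarray:
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("expected a subjects x 3 conditions matrix")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.isfinite(m).all():
        raise ValueError("missing cells are not allowed")
    return m


def friedman_dunn(scores, condition_names=("low", "medium", "high")
                  ) -> StatTestResult:
    """Friedman test across 3 within-subject conditions + Dunn post hoc.

    Within-subject ranks use mid-ranks for ties; pairwise Dunn z tests on
    mean ranks are Bonferroni-adjusted by the 3 comparisons.
    """
    m = _as_matrix(scores)
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    mean_ranks = ranks.mean(axis=0)
    if np.allclose(ranks, ranks[:, :1]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*(m[:, j] for j in range(k)))
    rows = []
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    for i, j in itertools.combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({
            "pair": f"{condition_names[i]} vs {condition_names[j]}",
            "statistic": float(z), "p_raw": float(raw),
            "p_adj": float(min(1.0, 3.0 * raw)),
        })
    return StatTestResult(float(stat), (k - 1,), float(p),
                          pd.DataFrame(rows), method="friedman+dunn-bonferroni")


def rm_anova_tukey(values, condition_names=("low", "medium", "high")
                   ) -> StatTestResult:
    """One-way repeated-measures ANOVA with subject blocking + Tukey HSD."""
    m = _as_matrix(values)
    n, k = m.shape
    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0 or ss_cond <= 1e-12 * max(ss_total, 1.0):
        f_stat = 0.0 if ss_cond <= 1e-12 * max(ss_total, 1.0) else np.inf
        p = 1.0 if f_stat == 0.0 else 0.0
    else:
        f_stat = (ss_cond / df_cond) / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = cond_means[i] - cond_means[j]
        if ms_err > 0:
            q = abs(diff) / np.sqrt(ms_err / n)
            p_pair = float(sps.studentized_range.sf(q, k, df_err))
        else:
            q, p_pair = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
        rows.append({
            "pair": f"{condition_names[i]} vs {condition_names[j]}",
            "statistic": float(q), "p_raw": p_pair,
            "p_adj": p_pair,  # Tukey HSD is already familywise-adjusted
        })
    return StatTestResult(float(f_stat), (df_cond, df_err), float(p),
                          pd.DataFrame(rows), method="rm-anova+tukey")


def shapiro_normality(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (delegated standard routine)."""
    w, p = sps.shapiro(np.asarray(x, dtype=float))
    return float(w), float(p)
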