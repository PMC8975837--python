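"""Behavioral prediction from regional features and model comparison.

Feature vectors concatenate per-region measures computed on the static
correlation and autoregression connectivity matrices: three control
measures (activation energy, average and modal controllability) or three
graph measures (weighted degree, local efficiency, participation
coefficient) on both matrix kinds give a 6N vector per subject; the
combined family concatenates a 3N control block and a 3N graph block.

Prediction uses kernel ridge regression with the cosine kernel and
10-fold cross-validation: held-out predictions are pooled and correlated
with the observed scores (Pearson r, Fisher z).  Models are compared via
the two-correlation difference statistic

    z_d = (z_1 - z_2) / sqrt(1/(N_1 - 3) + 1/(N_2 - 3)),

applied to same-cohort models exactly as commonly printed, even though
it is nominally the independent-samples formula (a conservative reading;
see the methods note).  Region and community importance is the z_d drop
when a unit's feature columns are removed and the full pipeline refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.preprocessing import StandardScaler

from .connectivity import AUTOREGRESSION, STATIC_CORRELATION

__all__ = [
    "CONTROL_MEASURES",
    "GRAPH_MEASURES",
    "PREDICTION_KINDS",
    "FeatureSpec",
    "CorrelationStat",
    "ComparisonStat",
    "assemble_features",
    "krr_cv_predict",
    "fisher_z",
    "compare_correlations",
    "region_importance",
    "subject_shuffle_null",
    "one_sample_t",
]

CONTROL_MEASURES = ("activation_energy", "average_ctrl", "modal_ctrl")
GRAPH_MEASURES = ("degree", "local_eff", "participation")
#: matrix kinds admitted into prediction features (the sliding-window
#: sequence is excluded: per-window graphs are noisy and would unbalance
#: the feature-length comparison)
PREDICTION_KINDS = (STATIC_CORRELATION, AUTOREGRESSION)

_R_CLAMP = 1.0 - 1e-12


@dataclass
class FeatureSpec:
    """Which (measurement, matrix kind) blocks form the feature vector.

    ``family`` is one of ``control`` (3 control measures × 2 kinds, 6N),
    ``graph`` (3 graph measures × 2 kinds, 6N) or ``combined`` (a 3N
    control block plus a 3N graph block).  For the combined family the
    default pairing puts the control measures on the static correlation
    matrix and the graph measures on the autoregression matrix;
    ``combined_pairing`` overrides it.
    """

    family: str = "control"
    matrix_kinds: tuple[str, ...] = PREDICTION_KINDS
    combined_pairing: tuple[str, str] = (STATIC_CORRELATION, AUTOREGRESSION)

    def blocks(self) -> list[tuple[str, str]]:
        for kind in self.matrix_kinds:
            if kind not in PREDICTION_KINDS:
                raise ValueError(
                    f"matrix kind {kind!r} cannot feed prediction; only "
                    f"{PREDICTION_KINDS} are admitted"
                )
        if self.family == "control":
            return [(m, k) for m in CONTROL_MEASURES for k in self.matrix_kinds]
        if self.family == "graph":
            return [(m, k) for m in GRAPH_MEASURES for k in self.matrix_kinds]
        if self.family == "combined":
            ctrl_kind, graph_kind = self.combined_pairing
            return [(m, ctrl_kind) for m in CONTROL_MEASURES] + [
                (m, graph_kind) for m in GRAPH_MEASURES
            ]
        raise ValueError(f"unknown feature family: {self.family!r}")


@dataclass
class CorrelationStat:
    """Pooled held-out prediction performance."""

    r: float
    z: float
    n: int


@dataclass
class ComparisonStat:
    """Two-correlation difference test."""

    z_d: float
    p: float
    N1: int
    N2: int


def assemble_features(
    tables: dict[tuple[str, str], np.ndarray],
    spec: FeatureSpec,
    region_ids: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate per-region measure tables into subject × feature form.

    ``tables`` maps (measurement, matrix_kind) to a subjects × regions
    array.  Ordering is measurement-major, then matrix kind, then region;
    the returned index frame records (measurement, matrix_kind, region)
    per column.
    """
    blocks = spec.blocks()
    missing = [b for b in blocks if b not in tables]
    if missing:
        raise KeyError(f"missing feature table(s): {missing}")
    cols = []
    meta = []
    n_subjects = None
    for meas, kind in blocks:
        tab = np.asarray(tables[(meas, kind)], dtype=float)
        if tab.ndim != 2:
            raise ValueError(f"table for {(meas, kind)} must be subjects × regions")
        if n_subjects is None:
            n_subjects = tab.shape[0]
        elif tab.shape[0] != n_subjects:
            raise ValueError("feature tables disagree on subject count")
        n_regions = tab.shape[1]
        ids = region_ids or [f"r{i:03d}" for i in range(n_regions)]
        cols.append(tab)
        meta.extend((meas, kind, rid) for rid in ids)
    X = np.hstack(cols)
    index = pd.DataFrame(meta, columns=["measurement", "matrix_kind", "region"])
    return X, index


def _default_grid() -> np.ndarray:
    return np.logspace(-3, 3, 7)


def krr_cv_predict(
    features: np.ndarray,
    scores: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    ridge_grid: np.ndarray | None = None,
    inner_folds: int = 5,
) -> tuple[np.ndarray, CorrelationStat]:
    """Cosine-kernel ridge regression with nested cross-validation.

    Outer ``n_folds``-fold CV pools held-out predictions; the ridge
    penalty is selected per outer fold by an inner ``inner_folds``-fold
    grid search.  Features and scores are standardized with
    training-fold statistics only.  Returns the pooled predictions and
    the pooled predicted-vs-observed Pearson correlation with its Fisher
    z.

    Predictions are returned on the training-standardized score scale,
    and each held-out fold's predictions are recentred to zero mean
    before pooling: a fold's prediction mean reflects its training-fold
    score mean, which under exchangeability carries no subject-level
    signal but is anti-correlated with the held-out scores and would
    bias the pooled correlation negative.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(scores, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("features must be subjects × features, scores per subject")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 subjects for nested cross-validation")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in features or scores")
    if np.any(np.linalg.norm(X, axis=1) == 0):
        raise ValueError("zero-norm feature vector; cosine kernel undefined")
    if np.std(y) == 0:
        raise ValueError("constant scores cannot be predicted")
    grid = _default_grid() if ridge_grid is None else np.asarray(ridge_grid, float)

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
    preds = np.empty_like(y)
    for train, test in outer.split(X):
        xs = StandardScaler().fit(X[train])
        y_mean, y_sd = y[train].mean(), y[train].std()
        Xtr = xs.transform(X[train])
        ytr = (y[train] - y_mean) / y_sd
        search = GridSearchCV(
            KernelRidge(kernel="cosine"),
            {"alpha": grid},
            cv=inner,
            scoring="neg_mean_squared_error",
        )
        search.fit(Xtr, ytr)
        p = search.predict(xs.transform(X[test]))
        preds[test] = p - p.mean()
    r = float(np.corrcoef(preds, y)[0, 1])
    return preds, CorrelationStat(r, fisher_z(r), y.size)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = arctanh(r), clamped near ±1."""
    if abs(r) > 1:
        raise ValueError("correlation outside [-1, 1]")
    return float(np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)))


def compare_correlations(r1: float, r2: float, N1: int, N2: int) -> ComparisonStat:
    """Difference of two correlations on the Fisher-z scale."""
    if N1 <= 3 or N2 <= 3:
        raise ValueError("need more than 3 samples per correlation")
    z_d = (fisher_z(r1) - fisher_z(r2)) / np.sqrt(1.0 / (N1 - 3) + 1.0 / (N2 - 3))
    p = 2.0 * stats.norm.sf(abs(z_d))
    return ComparisonStat(float(z_d), float(p), N1, N2)


def region_importance(
    features: np.ndarray,
    scores: np.ndarray,
    index: pd.DataFrame,
    unit: str = "region",
    communities: dict[str, str] | None = None,
    **krr_kwargs,
) -> pd.Series:
    """Importance of each region (or community) for prediction.

    Importance is the performance drop, as a two-correlation z, when the
    unit's feature columns are removed and the whole nested-CV pipeline
    is refit: positive values mean the unit carried predictive signal.
    ``unit='community'`` requires ``communities`` mapping region id to
    community label and removes all member regions' columns together.
    """
    y = np.asarray(scores, dtype=float)
    _, full = krr_cv_predict(features, y, **krr_kwargs)
    if unit == "region":
        labels = index["region"].to_numpy()
    elif unit == "community":
        if communities is None:
            raise ValueError("community importance needs a region->community map")
        labels = index["region"].map(communities).to_numpy()
    else:
        raise ValueError("unit must be 'region' or 'community'")
    out = {}
    for label in pd.unique(labels):
        keep = labels != label
        if not keep.any():
            raise ValueError("cannot remove every feature column")
        _, reduced = krr_cv_predict(features[:, keep], y, **krr_kwargs)
        out[label] = compare_correlations(full.r, reduced.r, full.n, reduced.n).z_d
    return pd.Series(out, name="importance_z")


def subject_shuffle_null(
    features: np.ndarray,
    scores: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    **krr_kwargs,
) -> tuple[float, np.ndarray, float]:
    """Null distribution of prediction r under subject-score shuffling.

    Breaks the correspondence between feature vectors and scores
    ``n_perm`` times, rerunning the full prediction each time.  Returns
    (observed r, null r values, empirical one-sided p).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(scores, dtype=float)
    _, obs = krr_cv_predict(features, y, **krr_kwargs)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for p in range(n_perm):
        _, stat = krr_cv_predict(features, y[rng.permutation(y.size)], **krr_kwargs)
        nulls[p] = stat.r
    p_emp = (1.0 + np.sum(nulls >= obs.r)) / (n_perm + 1.0)
    return obs.r, nulls, float(p_emp)


def one_sample_t(
    values: np.ndarray, mu0: float = 0.0, tail: str = "two"
) -> tuple[float, float]:
    """One-sample t-test against mu0 with a two-sided or greater tail."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    alternative = {"two": "two-sided", "greater": "greater"}.get(tail)
    if alternative is None:
        raise ValueError("tail must be 'two' or 'greater'")
    res = stats.ttest_1samp(values, mu0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
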