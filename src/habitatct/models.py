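"""Diagnostic models: feature ranking, SMOTE, nested LOOCV, cascade.

The classifier throughout is an ensemble of 100 boosted classification
trees (adaptive boosting of depth-2 trees, learning rate 0.5).  Features
are ranked univariately by a chi-square test of the quantile-binned
feature against the class label, scored as -ln(p).  Class imbalance
(pneumonia outnumbers pneumonitis roughly 3:1) is handled with SMOTE —
synthetic minority samples interpolated between nearest minority
neighbors — applied strictly inside each training fold of leave-one-out
cross-validation, after the held-out sample has been removed, so no
test-set information enters ranking, oversampling, or fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.ensemble import AdaBoostClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .bayes import ConfusionMatrix, metrics

__all__ = [
    "ClassifierSpec",
    "chi2_rank",
    "smote_oversample",
    "loocv_evaluate",
    "select_top_k",
    "prepare_benchmark_features",
    "BENCHMARK_COLUMNS",
    "cascade_predict",
    "fit_composite",
    "AMBIGUOUS",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Boosted classification-tree ensemble settings."""

    n_trees: int = 100
    max_depth: int = 2
    learning_rate: float = 0.5

    def build(self, random_state: int) -> AdaBoostClassifier:
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=self.max_depth),
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            random_state=random_state,
        )


def _bin_feature(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin a continuous feature; binary features pass through."""
    uniq = np.unique(values)
    if uniq.size <= 2:
        return np.searchsorted(uniq, values)
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(values, edges)


def chi2_rank(X: pd.DataFrame, y: np.ndarray, n_bins: int = 4) -> pd.DataFrame:
    """Univariate chi-square feature ranking: score = -ln(p), descending.

    Continuous features are quantile-binned (default 4 bins) into a
    contingency table against the label; no continuity correction.
    Constant features get p=1 (score 0); ties break by feature name.
    """
    y = np.asarray(y)
    if min(np.bincount(y, minlength=2)[:2]) < 2:
        raise ValueError("need at least 2 patients per class")
    rows = []
    for name in X.columns:
        v = X[name].to_numpy(dtype=float)
        binned = _bin_feature(v, n_bins)
        if np.unique(binned).size < 2:
            p = 1.0
        else:
            table = pd.crosstab(binned, y).to_numpy()
            _, p, _, _ = chi2_contingency(table, correction=False)
            p = max(float(p), 1e-300)
        rows.append({"feature": name, "p_value": p, "score": -np.log(p)})
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["score", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample the minority class to the majority count by interpolation.

    Each synthetic point lies on the segment between a random minority
    point and one of its k nearest minority neighbors; originals are
    preserved and come first.  ``k_neighbors`` is reduced automatically
    when the minority class is small; a minority class of fewer than 2
    points is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class must have at least 2 samples for SMOTE")
    k = min(k_neighbors, n_min - 1)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    n_new = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=n_new)
    nbr = idx[base, rng.integers(1, k + 1, size=n_new)]
    t = rng.random(size=(n_new, 1))
    synthetic = Xm[base] + t * (Xm[nbr] - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.default_rng([seed, fold]).integers(2**31 - 1))


def loocv_evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    n_top_features: int | None = None,
    seed: int = 0,
    smote_k: int = 5,
) -> tuple[ConfusionMatrix, pd.DataFrame]:
    """SMOTE-nested leave-one-out cross-validation of the boosted ensemble.

    For each of the n folds: the held-out sample is removed first; features
    are ranked (chi-square) on the training fold only and the top
    ``n_top_features`` kept; SMOTE balances the training fold only; the
    ensemble is fit and the held-out sample predicted.  Returns the
    accumulated confusion matrix (pneumonitis=1 positive) and per-patient
    predictions.
    """
    spec = spec or ClassifierSpec()
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples for LOOCV")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        X_tr, y_tr = X.iloc[train], y[train]
        if n_top_features is not None:
            ranking = chi2_rank(X_tr, y_tr)
            keep = ranking["feature"].head(n_top_features).tolist()
            X_tr = X_tr[keep]
            X_te = X.iloc[[i]][keep]
        else:
            X_te = X.iloc[[i]]
        fs = _fold_seed(seed, i)
        Xb, yb = smote_oversample(X_tr.to_numpy(dtype=float), y_tr, smote_k, seed=fs)
        clf = spec.build(random_state=fs)
        clf.fit(Xb, yb)
        preds[i] = int(clf.predict(X_te.to_numpy(dtype=float))[0])
    cm = ConfusionMatrix(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
    )
    pred_df = pd.DataFrame({"index": np.arange(n), "y_true": y, "y_pred": preds})
    return cm, pred_df


def select_top_k(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    k_grid: tuple[int, ...] = (1, 2, 5, 10, 20),
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Grow the model over ``k_grid`` top-ranked features; best k by accuracy.

    Ties break toward the smaller k.  Returns (best_k, per-k report).
    """
    k_grid = tuple(k for k in k_grid)
    if not k_grid:
        raise ValueError("empty k grid")
    if any(k < 1 or k > X.shape[1] for k in k_grid):
        raise ValueError("k_grid must lie within [1, n_features]")
    rows = []
    for k in sorted(k_grid):
        cm, _ = loocv_evaluate(X, y, spec, n_top_features=k, seed=seed)
        acc, sens, spc = metrics(cm)
        rows.append(
            {"k": k, "accuracy": acc, "sensitivity": sens, "specificity": spc,
             "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
        )
    report = pd.DataFrame(rows)
    best = report.loc[report["accuracy"].idxmax()]  # idxmax takes first (smallest k) on ties
    return int(best["k"]), report


BENCHMARK_COLUMNS = [
    "cough_baseline",
    "fever_baseline",
    "dyspnea_baseline",
    "cough_syndrome",
    "fever_syndrome",
    "dyspnea_syndrome",
    "age",
    "sex",
    "log_wbc_baseline",
    "log_wbc_syndrome",
    "anc_baseline",
    "anc_syndrome",
    "alc_baseline",
    "alc_syndrome",
    "log_platelets_baseline",
    "log_platelets_syndrome",
    "blasts_baseline",
]

_LOG_FLOOR = 1e-6


def prepare_benchmark_features(table: pd.DataFrame) -> pd.DataFrame:
    """The 17-column clinical/blood benchmark matrix.

    Eight clinical columns (three symptoms at two timepoints, age, sex)
    and nine blood columns, with WBC and platelets replaced by their
    natural logs at both timepoints (floored at a small positive constant).
    """
    count_cols = [
        "wbc_baseline", "wbc_syndrome", "anc_baseline", "anc_syndrome",
        "alc_baseline", "alc_syndrome", "platelets_baseline",
        "platelets_syndrome", "blasts_baseline",
    ]
    for c in count_cols:
        if (table[c].to_numpy(dtype=float) < 0).any():
            raise ValueError(f"negative counts in {c}")
    out = pd.DataFrame(index=table.index)
    for c in BENCHMARK_COLUMNS:
        if c.startswith("log_"):
            src = c[4:]
            out[c] = np.log(np.maximum(table[src].to_numpy(dtype=float), _LOG_FLOOR))
        else:
            out[c] = table[c].to_numpy(dtype=float)
    return out


AMBIGUOUS = "ambiguous"
_LABEL_NAMES = {0: "pneumonia", 1: "pneumonitis"}


def cascade_predict(pred_benchmark: np.ndarray, pred_habitat: np.ndarray) -> np.ndarray:
    """Agreement rule: diagnose when both models agree, else 'ambiguous'."""
    a = np.asarray(pred_benchmark).astype(int)
    b = np.asarray(pred_habitat).astype(int)
    if a.shape != b.shape:
        raise ValueError("prediction vectors must align")
    out = np.where(a == b, a, -1)
    return np.array([_LABEL_NAMES.get(v, AMBIGUOUS) for v in out])


def fit_composite(
    X_msi: pd.DataFrame,
    X_benchmark: pd.DataFrame,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    k_grid: tuple[int, ...] = (1, 2, 5, 10, 20),
    seed: int = 0,
) -> dict:
    """Concatenate MSI and clinical/blood columns and refit one model.

    Returns a report with the best feature count, its LOOCV confusion
    matrix and metrics, and the pooled univariate importance ranking.
    """
    if len(X_msi) != len(X_benchmark):
        raise ValueError("patient rows misaligned between feature banks")
    X = pd.concat(
        [X_msi.reset_index(drop=True), X_benchmark.reset_index(drop=True)], axis=1
    )
    best_k, report = select_top_k(X, y, spec, k_grid, seed)
    cm, preds = loocv_evaluate(X, y, spec, n_top_features=best_k, seed=seed)
    acc, sens, spc = metrics(cm)
    ranking = chi2_rank(X, np.asarray(y))
    return {
        "best_k": best_k,
        "grid_report": report,
        "confusion": cm,
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spc,
        "predictions": preds,
        "importance": ranking,
    }
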