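"""Machine-learning grading harness with cross-validated ROC evaluation.

Feature triple: true diffusion coefficient D (cellularity), perfusion
fraction f (vascularity) and apparent kurtosis K_app (micro-structural
heterogeneity) — the three parameters that differ between grades and carry
distinct biological meaning.  Four classifier families (logistic
regression, k-nearest neighbours, RBF support vector machine, random
forest) are trained under stratified 5-fold cross-validation with
train-fold-only standardisation; evaluation uses empirical ROC curves
(AUC = pairwise concordance with ties counted ½), Youden-optimal operating
points, per-fold AUC aggregation, and the DeLong test for correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "FEATURES",
    "CLASSIFIERS",
    "RocResult",
    "CvResult",
    "DelongResult",
    "assemble_features",
    "stratified_kfold",
    "train_predict",
    "roc_curve_auc",
    "youden_optimal",
    "cross_validate",
    "delong_test",
    "parameter_roc",
    "performance_table",
]

FEATURES = ("d", "f", "kapp")
CLASSIFIERS = ("LG", "KNN", "SVM", "RF")


def assemble_features(table: pd.DataFrame) -> pd.DataFrame:
    """Build the fixed-order (D, f, K_app, label) feature table.

    ``table`` needs per-patient columns ``d``, ``f``, ``kapp`` and either a
    binary ``label`` column or a ``grade`` column ('low'/'high' → 0/1).
    D_p, D_app and ADC are excluded by construction.
    """
    for col in FEATURES:
        if col not in table.columns:
            raise ValueError(f"missing feature column: {col}")
    if "label" in table.columns:
        label = table["label"].astype(int)
    elif "grade" in table.columns:
        label = (table["grade"] == "high").astype(int)
    else:
        raise ValueError("need a 'label' or 'grade' column")
    out = table.loc[:, list(FEATURES)].copy()
    out["label"] = label.to_numpy()
    if out.isna().any().any():
        raise ValueError("feature table contains missing values")
    if set(out["label"].unique()) != {0, 1}:
        raise ValueError("both classes must be present with binary labels")
    return out.reset_index(drop=True)


def stratified_kfold(labels, k: int = 5, seed: int = 0):
    """Seeded stratified fold assignment (per-fold class counts within ±1)."""
    y = np.asarray(labels)
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls!r} has fewer members ({count}) than folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros((y.size, 1)), y))


def _median_heuristic_gamma(x: np.ndarray) -> float:
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    med = np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)]))
    return 1.0 / (2.0 * med * med) if med > 0 else 1.0


def train_predict(kind: str, x_train: np.ndarray, y_train: np.ndarray,
                  x_test: np.ndarray, seed: int = 0,
                  hyper: dict | None = None) -> np.ndarray:
    """Fit one classifier and return continuous class-1 scores for the test set.

    Features are standardised with training-fold statistics only.  LG is
    unpenalised; KNN uses k = 5 unweighted; SVM an RBF kernel with unit cost
    and median-heuristic bandwidth (decision-function scores); RF 500 seeded
    trees.  Hyperparameters can be overridden via ``hyper``.
    """
    hyper = dict(hyper or {})
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training fold contains a single class")

    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    xtr = (x_train - mu) / sd
    xte = (x_test - mu) / sd

    if kind == "LG":
        # C = inf: plain (unpenalised) maximum-likelihood logistic regression
        model = LogisticRegression(C=float(hyper.get("C", np.inf)),
                                   solver="lbfgs",
                                   max_iter=int(hyper.get("max_iter", 2000)))
        model.fit(xtr, y_train)
        return model.predict_proba(xte)[:, 1]
    if kind == "KNN":
        k = int(hyper.get("n_neighbors", 5))
        model = KNeighborsClassifier(n_neighbors=min(k, len(xtr)),
                                     weights=hyper.get("weights", "uniform"))
        model.fit(xtr, y_train)
        return model.predict_proba(xte)[:, 1]
    if kind == "SVM":
        gamma = hyper.get("gamma", _median_heuristic_gamma(xtr))
        model = SVC(C=float(hyper.get("C", 1.0)), kernel="rbf", gamma=gamma)
        model.fit(xtr, y_train)
        return model.decision_function(xte)
    if kind == "RF":
        model = RandomForestClassifier(
            n_estimators=int(hyper.get("n_estimators", 500)),
            random_state=int(seed) % (2 ** 31))
        model.fit(xtr, y_train)
        return model.predict_proba(xte)[:, 1]
    raise ValueError(f"unknown classifier kind: {kind!r}")


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    sens_at_youden: float
    spec_at_youden: float
    youden_index: float


def roc_curve_auc(scores, labels) -> RocResult:
    """Empirical ROC over the unique score thresholds.

    A case is called positive when its score is >= the threshold.  The AUC
    equals the Mann–Whitney concordance probability with ties counted ½.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC evaluation")

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])

    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    j = sens + spec - 1.0
    best = np.isclose(j, j.max(), rtol=0, atol=1e-12)
    # ties broken toward higher specificity (then the more stringent cut)
    cand = np.flatnonzero(best)
    cand = cand[np.lexsort((-thresholds[cand], -spec[cand]))]
    i = cand[0]
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), youden_threshold=float(thresholds[i]),
        sens_at_youden=float(sens[i]), spec_at_youden=float(spec[i]),
        youden_index=float(sens[i] + spec[i] - 1.0),
    )


def youden_optimal(roc: RocResult) -> tuple[float, float, float, float]:
    """Operating point maximising J = sensitivity + specificity − 1."""
    return (roc.youden_threshold, roc.sens_at_youden,
            roc.spec_at_youden, roc.youden_index)


def parameter_roc(values, labels, direction: str = "auto") -> tuple[RocResult, int]:
    """ROC of a raw parameter value (no training involved).

    Parameters that *decrease* with grade (D, f, ADC, D_app) discriminate
    with a sign flip; ``direction="auto"`` flips when concordance < 0.5 and
    returns the sign used (+1: higher value scores class 1).
    """
    v = np.asarray(values, dtype=float)
    roc = roc_curve_auc(v, labels)
    sign = 1
    if direction == "auto" and roc.auc < 0.5:
        roc = roc_curve_auc(-v, labels)
        sign = -1
    elif direction == "negative":
        roc = roc_curve_auc(-v, labels)
        sign = -1
    return roc, sign


@dataclass(frozen=True)
class CvResult:
    classifier: str
    fold_aucs: tuple[float, ...]
    mean_auc: float
    ci_low: float
    ci_high: float
    sens_at_youden: float
    spec_at_youden: float
    youden_index: float
    youden_threshold: float
    oof_scores: np.ndarray


def aggregate_fold_aucs(fold_aucs) -> tuple[float, float, float]:
    """Mean of the fold AUCs and mean ± 1.96·SD interval clipped to [0, 1]."""
    a = np.asarray(fold_aucs, dtype=float)
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return mean, float(np.clip(mean - 1.96 * sd, 0, 1)), \
        float(np.clip(mean + 1.96 * sd, 0, 1))


def cross_validate(features: pd.DataFrame, kind: str, k: int = 5,
                   seed: int = 0, hyper: dict | None = None) -> CvResult:
    """Stratified k-fold CV of one classifier on the feature table.

    Fold AUCs are computed on each held-out fold; the operating point
    (sensitivity/specificity/Youden) comes from the pooled out-of-fold
    scores.  All randomness (folds, RF) derives from ``seed``.
    """
    x = features.loc[:, list(FEATURES)].to_numpy(float)
    y = features["label"].to_numpy(int)
    folds = stratified_kfold(y, k=k, seed=seed)
    sub_seeds = np.random.SeedSequence(seed).generate_state(k)
    oof = np.empty(y.size, dtype=float)
    fold_aucs = []
    for (train_idx, test_idx), sub in zip(folds, sub_seeds):
        scores = train_predict(kind, x[train_idx], y[train_idx], x[test_idx],
                               seed=int(sub % (2 ** 31)), hyper=hyper)
        oof[test_idx] = scores
        fold_aucs.append(roc_curve_auc(scores, y[test_idx]).auc)
    mean, lo, hi = aggregate_fold_aucs(fold_aucs)
    pooled = roc_curve_auc(oof, y)
    return CvResult(
        classifier=kind, fold_aucs=tuple(fold_aucs), mean_auc=mean,
        ci_low=lo, ci_high=hi, sens_at_youden=pooled.sens_at_youden,
        spec_at_youden=pooled.spec_at_youden,
        youden_index=pooled.youden_index,
        youden_threshold=pooled.youden_threshold, oof_scores=oof,
    )


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = scores[y == 1]
    neg = scores[y == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive placement
    v01 = psi.mean(axis=0)  # per-negative placement
    return v10, v01, float(psi.mean())


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Paired DeLong comparison of two correlated AUCs.

    Uses the structural-component (placement-value) variance estimator and a
    two-sided normal p-value; a degenerate variance (e.g. identical scores)
    yields z = 0, p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("score vectors must match the label vector")
    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return DelongResult(auc_a, auc_b, float(max(var, 0.0)), 0.0, 1.0)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(var), float(z), p)


def performance_table(features: pd.DataFrame, cohort_table: pd.DataFrame,
                      parameters, k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Summary of diagnostic performance for classifiers and raw parameters.

    One row per cross-validated classifier (sensitivity/specificity from
    pooled out-of-fold scores, AUC = mean fold AUC with its interval) and
    one per single parameter (full-cohort ROC, no training involved).
    """
    rows = []
    for kind in CLASSIFIERS:
        cv = cross_validate(features, kind, k=k, seed=seed)
        rows.append({"model": kind, "sensitivity": cv.sens_at_youden,
                     "specificity": cv.spec_at_youden, "auc": cv.mean_auc,
                     "ci_low": cv.ci_low, "ci_high": cv.ci_high,
                     "youden_index": cv.youden_index})
    y = features["label"].to_numpy(int)
    for param in parameters:
        roc, _ = parameter_roc(cohort_table[param].to_numpy(float), y)
        rows.append({"model": param, "sensitivity": roc.sens_at_youden,
                     "specificity": roc.spec_at_youden, "auc": roc.auc,
                     "ci_low": float("nan"), "ci_high": float("nan"),
                     "youden_index": roc.youden_index})
    return pd.DataFrame(rows)
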