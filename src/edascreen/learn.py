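"""Feature ranking by SVM-RFE and the repeated cross-validation experiment.

A linear support-vector machine (C = 1) is trained on the standardized
training fold and the feature with the smallest squared weight is removed,
repeatedly, until one feature remains; the elimination order yields a full
ranking (rank 1 = most relevant).  Four classifiers — linear SVM, CART
decision tree (Gini), 3-nearest-neighbours (Euclidean) and Gaussian Naive
Bayes — are then trained on the top-ranked subsets and evaluated on the
held-out fold of a stratified 5-fold cross-validation repeated many times.
Feature scaling and ranking happen strictly inside each training fold, so
no information from a test fold reaches model fitting.

Reported measures: accuracy, sensitivity, specificity, PPV, NPV (percent,
with the patient group as the positive class) and AUC from the rank
(Mann-Whitney) formulation of the ROC area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .featureset import FEATURE_COLUMNS

CLASSIFIERS = ("svm", "tree", "knn", "nb")
METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ModelConfig:
    """Classifier and cross-validation settings."""

    svm_C: float = 1.0
    knn_k: int = 3
    tree_min_samples_leaf: int = 1
    cv_folds: int = 5
    cv_repeats: int = 200
    subset_sizes: tuple[int, ...] = (1, 5, 11, 15, 20, 25, 30, 35)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if any(s < 1 for s in self.subset_sizes):
            raise ValueError("subset sizes must be >= 1")


def standardize_fit_apply(train: np.ndarray, eval_: np.ndarray):
    """Z-score using training mean/SD only; constant columns scale to 1.

    Returns (scaled train, scaled eval, (mean, sd)).
    """
    train = np.asarray(train, dtype=float)
    eval_ = np.asarray(eval_, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mean) / sd, (eval_ - mean) / sd, (mean, sd)


class SVMRFE(BaseEstimator):
    """Recursive feature elimination with a linear SVM, as a ranker.

    Fitting produces ``ranking_``: a permutation of 1..p where 1 marks the
    last surviving (most relevant) feature.  Elimination removes the feature
    with the smallest squared weight; ties break toward the lowest column
    index, making the ranking deterministic given the input order.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM-RFE needs both classes present in the training data")
        n_features = X.shape[1]
        remaining = list(range(n_features))
        ranking = np.zeros(n_features, dtype=int)
        rank = n_features
        while len(remaining) > 1:
            svc = SVC(kernel="linear", C=self.C)
            svc.fit(X[:, remaining], y)
            w2 = np.ravel(svc.coef_) ** 2
            drop = int(np.argmin(w2))  # argmin takes the lowest index on ties
            ranking[remaining[drop]] = rank
            del remaining[drop]
            rank -= 1
        ranking[remaining[0]] = 1
        self.ranking_ = ranking
        self.n_features_in_ = n_features
        return self

    def top_features(self, k: int) -> np.ndarray:
        """Column indices of the k best-ranked features, best first."""
        order = np.argsort(self.ranking_, kind="stable")
        return order[:k]


def _make_classifier(kind: str, config: ModelConfig):
    if kind == "svm":
        return SVC(kernel="linear", C=config.svm_C)
    if kind == "tree":
        return DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=config.tree_min_samples_leaf,
            random_state=config.rng_seed,
        )
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_k, metric="euclidean")
    if kind == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_predict(
    kind: str,
    train: np.ndarray,
    labels: np.ndarray,
    eval_: np.ndarray,
    config: ModelConfig = ModelConfig(),
):
    """Fit one classifier and return (predicted labels, case scores).

    Labels are 0 (control) / 1 (case).  Scores usable for ROC analysis:
    signed margin for the SVM, case-class probability for the others.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    eval_ = np.atleast_2d(np.asarray(eval_, dtype=float))
    if eval_.shape[1] != train.shape[1]:
        raise ValueError(
            f"eval has {eval_.shape[1]} features but the model was trained on "
            f"{train.shape[1]}"
        )
    clf = _make_classifier(kind, config)
    if kind == "knn" and train.shape[0] < config.knn_k:
        clf.set_params(n_neighbors=train.shape[0])  # degenerate tiny-fold guard
    clf.fit(train, labels)
    pred = clf.predict(eval_)
    if kind == "svm":
        score = clf.decision_function(eval_)
        if clf.classes_[-1] != 1:  # orient the margin toward the case class
            score = -score
    else:
        proba = clf.predict_proba(eval_)
        case_col = int(np.nonzero(clf.classes_ == 1)[0][0])
        score = proba[:, case_col]
    return pred, score


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float | None:
    """ROC area via the rank (Mann-Whitney) formulation with mid-rank ties."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(predictions, scores, truth) -> dict[str, float | None]:
    """Confusion-matrix rates (percent) and AUC, with case (=1) positive."""
    pred = np.asarray(predictions)
    truth = np.asarray(truth)
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    return {
        "accuracy": pct(tp + tn, tp + tn + fp + fn),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
        "auc": rank_auc(scores, truth),
    }


def roc_points(scores: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """ROC curve (FPR, TPR) at every distinct score threshold."""
    truth = np.asarray(truth)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    t = truth[order]
    tps = np.cumsum(t == 1)
    fps = np.cumsum(t == 0)
    n_pos = max(int((truth == 1).sum()), 1)
    n_neg = max(int((truth == 0).sum()), 1)
    return pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps / n_neg],
            "tpr": np.r_[0.0, tps / n_pos],
        }
    )


@dataclass
class CVReport:
    """Aggregated repeated-CV results.

    ``metrics`` has one row per (classifier, subset size) with the mean and
    SD of each rate over all test folds plus pooled train/test AUC;
    ``pooled_scores`` maps (classifier, subset size, split) to the pooled
    (scores, truth) arrays for ROC plotting.
    """

    metrics: pd.DataFrame
    pooled_scores: dict = field(repr=False, default_factory=dict)
    n_rankings: int = 0

    def roc(self, classifier: str, subset_size: int, split: str = "test") -> pd.DataFrame:
        scores, truth = self.pooled_scores[(classifier, subset_size, split)]
        return roc_points(scores, truth)


def encode_labels(groups) -> np.ndarray:
    """Map group labels to 0 (control) / 1 (case, the positive class)."""
    groups = np.asarray(groups)
    out = np.where(groups == "case", 1, 0)
    if set(np.unique(groups)) - {"case", "control"}:
        raise ValueError("groups must be 'case' or 'control'")
    return out


def repeated_cv(
    table: pd.DataFrame, config: ModelConfig = ModelConfig()
) -> tuple[CVReport, pd.DataFrame]:
    """Stratified k-fold CV repeated ``cv_repeats`` times, with SVM-RFE
    ranking and scaling performed inside each training fold.

    Returns the CV report and the rank table (per-feature average rank over
    all folds x repeats, ascending = more relevant).
    """
    feature_cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if not feature_cols:
        feature_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    X = table[feature_cols].to_numpy(dtype=float)
    y = encode_labels(table["group"].to_numpy())
    n_per_class = np.bincount(y, minlength=2)
    if (n_per_class < config.cv_folds).any():
        raise ValueError(
            f"need at least {config.cv_folds} subjects per class, have {n_per_class}"
        )
    p = len(feature_cols)
    sizes = sorted({min(s, p) for s in config.subset_sizes})

    rankings: list[np.ndarray] = []
    fold_metrics: list[dict] = []
    pooled: dict = {}

    def _pool(key, scores, truth):
        if key not in pooled:
            pooled[key] = ([], [])
        pooled[key][0].append(np.asarray(scores, dtype=float))
        pooled[key][1].append(np.asarray(truth))

    for repeat in range(config.cv_repeats):
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.rng_seed + repeat
        )
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[tr])) < 2:  # cannot occur with stratification
                continue
            Xtr, Xte, _ = standardize_fit_apply(X[tr], X[te])
            rfe = SVMRFE(C=config.svm_C).fit(Xtr, y[tr])
            rankings.append(rfe.ranking_)
            for k in sizes:
                cols = rfe.top_features(k)
                for kind in CLASSIFIERS:
                    pred, score = train_predict(kind, Xtr[:, cols], y[tr], Xte[:, cols], config)
                    m = compute_metrics(pred, score, y[te])
                    m.update(
                        {"classifier": kind, "subset_size": k, "repeat": repeat, "fold": fold}
                    )
                    fold_metrics.append(m)
                    _pool((kind, k, "test"), score, y[te])
                    _, tr_score = train_predict(
                        kind, Xtr[:, cols], y[tr], Xtr[:, cols], config
                    )
                    _pool((kind, k, "train"), tr_score, y[tr])

    raw = pd.DataFrame(fold_metrics)
    rows = []
    for (kind, k), grp in raw.groupby(["classifier", "subset_size"]):
        row: dict = {"classifier": kind, "subset_size": int(k)}
        for metric in METRICS:
            row[metric] = float(grp[metric].mean())
            row[f"{metric}_sd"] = float(grp[metric].std(ddof=1)) if len(grp) > 1 else 0.0
        row["auc_fold_mean"] = float(grp["auc"].dropna().mean())
        for split in ("test", "train"):
            scores, truth = pooled[(kind, int(k), split)]
            s, t = np.concatenate(scores), np.concatenate(truth)
            pooled[(kind, int(k), split)] = (s, t)
            row[f"auc_{split}"] = rank_auc(s, t)
        rows.append(row)
    metrics = pd.DataFrame(rows).sort_values(["classifier", "subset_size"]).reset_index(
        drop=True
    )

    rank_matrix = np.vstack(rankings)
    rank_table = pd.DataFrame(
        {
            "feature": feature_cols,
            "average_rank": rank_matrix.mean(axis=0),
        }
    ).sort_values("average_rank").reset_index(drop=True)
    rank_table["dataset"] = [f.split("_")[0] for f in rank_table["feature"]]

    report = CVReport(metrics=metrics, pooled_scores=pooled, n_rankings=len(rankings))
    return report, rank_table
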