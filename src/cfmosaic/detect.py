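"""Stage-1 cancer-vs-healthy detection: tuned base models per feature
group, out-of-fold score generation, exhaustive stacking over all subsets
of the nine groups, a specificity-anchored decision cutoff, and ROC
evaluation utilities (trapezoidal AUC, stratified-bootstrap CI, DeLong
test).

Per feature group, logistic regression, random forest and gradient-boosted
trees are tuned by 5-fold stratified grid search on cross-validated AUC;
the winning algorithm is reported with its 20-fold CV AUC.  The stacked
ensemble is a logistic meta-learner over base-model probability scores;
to avoid optimistic bias, the meta-learner only ever sees out-of-fold
scores (a sample's score always comes from a base model trained without
that sample's fold).  The decision cutoff is the smallest score threshold
achieving a minimum specificity (default 95%) on the selection set.
"""

from __future__ import annotations

import itertools
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from xgboost import XGBClassifier

from cfmosaic.features import FEATURE_GROUPS, MultiFeatureSet

#: default hyperparameter grids, exposed through configuration
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "LR": [
        # l1_ratio 1 = lasso, 0 = ridge; C=inf with l1_ratio 0 = unpenalized
        {"l1_ratio": [1.0, 0.0], "C": [0.01, 0.1, 1, 10], "solver": ["liblinear"]},
        {"l1_ratio": [0.0], "C": [np.inf], "solver": ["lbfgs"]},
    ],
    "RF": [{"n_estimators": [100, 300], "max_depth": [None, 5, 10]}],
    "XGB": [
        {
            "max_depth": [3, 5],
            "learning_rate": [0.05, 0.1],
            "n_estimators": [100, 300],
        }
    ],
}

#: reduced grids for quick runs (smoke tests, examples)
FAST_GRIDS: dict[str, list[dict]] = {
    "LR": [{"l1_ratio": [0.0], "C": [0.1, 1], "solver": ["liblinear"]}],
    "RF": [{"n_estimators": [100], "max_depth": [None, 5]}],
    "XGB": [{"max_depth": [3], "learning_rate": [0.1], "n_estimators": [100]}],
}

#: importance threshold under which tree-model features are dropped
IMPORTANCE_THRESHOLD = 1e-4


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "XGB":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class BaseModelSpec:
    """A tuned single-feature-group model."""

    group: str
    algorithm: str
    params: dict
    estimator: object = field(repr=False)
    cv_auc: float = float("nan")
    cv_auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    cv_fold_aucs: np.ndarray | None = field(default=None, repr=False)
    selected_features: list[str] | None = field(default=None, repr=False)

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        cols = self.selected_features
        data = X[cols] if cols else X
        return self.estimator.predict_proba(data.to_numpy())[:, 1]


def tune_base_model(
    features: pd.DataFrame,
    labels,
    group: str,
    seed: int,
    grids: dict[str, list[dict]] | None = None,
    algorithms=("LR", "RF", "XGB"),
    cv_tune: int = 5,
    cv_report: int = 20,
) -> BaseModelSpec:
    """Grid-search each algorithm, keep the best by 20-fold CV AUC.

    Ties in the tuning grid are broken by first-in-grid order (the
    grid-search keeps the first best parameter set); ties between
    algorithms by the listed order.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    X = features.to_numpy(dtype=float)
    grids = grids or DEFAULT_GRIDS

    best: BaseModelSpec | None = None
    for algorithm in algorithms:
        cv_in = StratifiedKFold(cv_tune, shuffle=True, random_state=seed)
        search = GridSearchCV(
            _make_estimator(algorithm, seed),
            grids[algorithm],
            scoring="roc_auc",
            cv=cv_in,
            n_jobs=1,
        )
        search.fit(X, y)
        tuned = search.best_estimator_

        selected = _select_features(tuned, features.columns, algorithm)
        X_sel = features[selected].to_numpy(dtype=float) if selected else X
        est = clone(tuned)
        max_folds = int(np.bincount(y).min())
        k = min(cv_report, max_folds)
        cv_out = StratifiedKFold(k, shuffle=True, random_state=seed + 1)
        fold_aucs = cross_val_score(est, X_sel, y, scoring="roc_auc", cv=cv_out, n_jobs=1)
        mean_auc = float(fold_aucs.mean())
        half = 1.96 * fold_aucs.std(ddof=1) / np.sqrt(len(fold_aucs))
        spec = BaseModelSpec(
            group=group,
            algorithm=algorithm,
            params=search.best_params_,
            estimator=clone(est).fit(X_sel, y),
            cv_auc=mean_auc,
            cv_auc_ci=(mean_auc - half, mean_auc + half),
            cv_fold_aucs=fold_aucs,
            selected_features=selected,
        )
        if best is None or spec.cv_auc > best.cv_auc:
            best = spec
    return best


def _select_features(estimator, columns, algorithm) -> list[str] | None:
    """Importance-based feature selection for tree models (threshold 1e-4)."""
    if algorithm in ("RF", "XGB"):
        imp = getattr(estimator, "feature_importances_", None)
        if imp is not None:
            keep = [c for c, v in zip(columns, imp) if v >= IMPORTANCE_THRESHOLD]
            if 0 < len(keep) < len(columns):
                return keep
    return None


def out_of_fold_scores(
    specs: dict[str, BaseModelSpec],
    feature_set: MultiFeatureSet,
    labels,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Samples x groups matrix of leakage-free probability scores.

    The score of sample ``i`` for group ``g`` comes from a clone of the
    tuned group-``g`` model trained without sample ``i``'s fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(labels).astype(int)
    n = len(y)
    out = pd.DataFrame(
        np.full((n, len(specs)), np.nan),
        index=feature_set.sample_ids,
        columns=list(specs),
    )
    skf = StratifiedKFold(min(folds, int(np.bincount(y).min())), shuffle=True,
                          random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold lost one of the classes")
        for g, spec in specs.items():
            X = feature_set.matrices[g]
            cols = spec.selected_features
            Xm = (X[cols] if cols else X).to_numpy(dtype=float)
            est = clone(spec.estimator).fit(Xm[train_idx], y[train_idx])
            out.iloc[test_idx, out.columns.get_loc(g)] = est.predict_proba(
                Xm[test_idx]
            )[:, 1]
    return out


@dataclass
class StackResult:
    """Outcome of the exhaustive stacking search."""

    subset: tuple[str, ...]
    meta_model: LogisticRegression = field(repr=False)
    cv_auc: float = float("nan")
    search_table: pd.DataFrame | None = field(default=None, repr=False)

    def scores(self, score_matrix: pd.DataFrame) -> np.ndarray:
        cols = score_matrix[list(self.subset)].to_numpy(dtype=float)
        return self.meta_model.predict_proba(cols)[:, 1]


def exhaustive_stack_search(
    score_matrix: pd.DataFrame,
    labels,
    seed: int = 0,
    cv: int = 5,
) -> StackResult:
    """Evaluate a logistic meta-learner on every non-empty group subset.

    With nine groups this enumerates all 511 combinations.  The winner is
    the subset with the highest cross-validated AUC; ties go to the
    smaller subset, then lexicographic order.
    """
    groups = list(score_matrix.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to stack")
    y = np.asarray(labels).astype(int)
    S = score_matrix.to_numpy(dtype=float)
    skf = StratifiedKFold(cv, shuffle=True, random_state=seed)
    splits = list(skf.split(S, y))

    records = []
    best_key, best_subset, best_auc = None, None, -np.inf
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(range(len(groups)), r):
            cols = S[:, subset]
            aucs = []
            for tr, te in splits:
                meta = LogisticRegression(max_iter=1000)
                meta.fit(cols[tr], y[tr])
                aucs.append(roc_auc(meta.predict_proba(cols[te])[:, 1], y[te]))
            auc = float(np.mean(aucs))
            names = tuple(groups[i] for i in subset)
            records.append({"subset": names, "cv_auc": auc})
            key = (-auc, r, names)
            if best_key is None or key < best_key:
                best_key, best_subset, best_auc = key, names, auc
    meta = LogisticRegression(max_iter=1000)
    meta.fit(score_matrix[list(best_subset)].to_numpy(dtype=float), y)
    return StackResult(
        subset=best_subset,
        meta_model=meta,
        cv_auc=best_auc,
        search_table=pd.DataFrame(records),
    )


def choose_cutoff(scores, labels, min_specificity: float = 0.95) -> float:
    """Smallest threshold with specificity >= target under ``score >= c``.

    If even classifying every sample negative cannot reach the target
    (impossible for targets <= 1), the maximum observed score plus a small
    epsilon is returned, i.e. an all-negative classifier.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    neg = np.sort(s[y == 0])
    eps = 1e-9
    candidates = np.concatenate([np.unique(s), [s.max() + eps]])
    for c in candidates:
        specificity = np.mean(neg < c)
        if specificity >= min_specificity:
            return float(c)
    return float(s.max() + eps)


def roc_auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.where(np.diff(s))[0]
    idx = np.concatenate([distinct, [y.size - 1]])
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]
    if tps[-1] == 0 or fps[-1] == 0:
        raise ValueError("labels must contain both classes")
    tpr = np.concatenate([[0], tps / tps[-1]])
    fpr = np.concatenate([[0], fps / fps[-1]])
    return float(np.trapezoid(tpr, fpr))


@dataclass
class DetectionMetrics:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    cutoff: float
    per_class_sensitivity: dict[str, float] = field(default_factory=dict)


def evaluate_detection(
    scores,
    labels,
    cutoff: float,
    class_labels=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> DetectionMetrics:
    """AUC with stratified-bootstrap 95% CI plus confusion rates at a cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc = roc_auc(s, y)

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        boot[b] = roc_auc(s[idx], y[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])

    called = s >= cutoff
    sensitivity = float(called[y == 1].mean())
    specificity = float((~called)[y == 0].mean())
    per_class = {}
    if class_labels is not None:
        cls = np.asarray(class_labels)
        for label in pd.unique(cls[y == 1]):
            mask = (y == 1) & (cls == label)
            per_class[str(label)] = float(called[mask].mean())
    return DetectionMetrics(
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        sensitivity=sensitivity,
        specificity=specificity,
        cutoff=float(cutoff),
        per_class_sensitivity=per_class,
    )


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p-value of DeLong's paired test for equal AUCs.

    Both score vectors must be computed on the same samples; the paired
    structure-function covariance of the two empirical AUCs is estimated
    with midrank placements.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")

    def placements(s):
        pos, neg = s[y == 1], s[y == 0]
        m, n = pos.size, neg.size
        all_ranks = stats.rankdata(np.concatenate([pos, neg]))
        pos_ranks = stats.rankdata(pos)
        neg_ranks = stats.rankdata(neg)
        v10 = (all_ranks[:m] - pos_ranks) / n           # per-positive placement
        v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m     # per-negative placement
        auc = v10.mean()
        return auc, v10, v01

    auc_a, v10_a, v01_a = placements(sa)
    auc_b, v10_b, v01_b = placements(sb)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class DetectionModelBundle:
    """Everything needed to score new samples for cancer status."""

    base_models: dict[str, BaseModelSpec]
    stack: StackResult
    cutoff: float
    min_specificity: float = 0.95
    training_manifest: dict = field(default_factory=dict)

    def scores(self, feature_set: MultiFeatureSet) -> pd.Series:
        cols = {
            g: self.base_models[g].scores(feature_set.matrices[g])
            for g in self.stack.subset
        }
        score_matrix = pd.DataFrame(cols, index=feature_set.sample_ids)
        return pd.Series(
            self.stack.scores(score_matrix), index=feature_set.sample_ids
        )

    def predict(self, feature_set: MultiFeatureSet) -> pd.Series:
        return self.scores(feature_set) >= self.cutoff

    def save(self, path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path) -> "DetectionModelBundle":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a DetectionModelBundle")
        return obj


def train_detection_model(
    feature_set: MultiFeatureSet,
    labels,
    seed: int = 0,
    grids: dict[str, list[dict]] | None = None,
    min_specificity: float = 0.95,
    oof_folds: int = 10,
    groups: list[str] | None = None,
) -> DetectionModelBundle:
    """End-to-end stage-1 training: tune, stack, anchor the cutoff."""
    y = np.asarray(labels).astype(int)
    groups = groups or FEATURE_GROUPS
    specs = {
        g: tune_base_model(feature_set.matrices[g], y, g, seed=seed, grids=grids)
        for g in groups
    }
    oof = out_of_fold_scores(specs, feature_set, y, folds=oof_folds, seed=seed)
    stack = exhaustive_stack_search(oof, y, seed=seed)
    ensemble_scores = stack.scores(oof)
    cutoff = choose_cutoff(ensemble_scores, y, min_specificity)
    manifest = {
        "seed": seed,
        "oof_folds": oof_folds,
        "n_samples": int(len(y)),
        "n_cancer": int(y.sum()),
        "base_algorithms": {g: s.algorithm for g, s in specs.items()},
        "base_cv_auc": {g: s.cv_auc for g, s in specs.items()},
    }
    return DetectionModelBundle(
        base_models=specs,
        stack=stack,
        cutoff=cutoff,
        min_specificity=min_specificity,
        training_manifest=manifest,
    )
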