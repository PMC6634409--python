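"""LASSO feature selection and the three-classifier evaluation protocol.

The protocol, per run: stratified k-fold split of the labeled dataset; inside
each fold, feature selection by L1-penalized logistic regression on the
training rows only (for the combined set, selected separately per datatype
block and merged), hyperparameters tuned by an inner stratified CV over the
method's grid, the tuned model fitted on the training rows and applied to the
held-out fold.  Out-of-fold class-1 scores are pooled per run for AUC;
accuracy, sensitivity (recall of the high-heterogeneity class) and
specificity come from the pooled out-of-fold hard calls.  Metrics are
averaged over independent fold randomizations ("runs").

Preprocessing is fitted on training rows only: expression features are
log2(count+1)-transformed and standardized (penalized models and RBF kernels
need comparable scales); binary mutation features are left as-is.

Grids follow the standard protocol: SVM-RBF over C in {0.1, 10, 100} and
kernel width gamma in {0.01, 0.25, 0.5, 1}; random forest over
n_trees in {200, 500, 1000, 2000} and minimum terminal-node size in
{2, 3, 4, 5}; naive Bayes has no grid and uses Gaussian likelihoods for
expression features and Bernoulli (Laplace smoothing 1) for mutation
features, with a pure-Gaussian mode available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.svm import SVC

from hetmix.prep import EXPRESSION, MUTATION, FeatureDataset

__all__ = ["ModelSpec", "EvaluationResult", "lasso_select", "select_for_combined", "cross_validate"]

logger = logging.getLogger(__name__)

METHODS = ("naive_bayes", "svm_rbf", "random_forest")


@dataclass
class ModelSpec:
    """Classifier choice plus tuning grids and selection settings."""

    method: str = "svm_rbf"
    svm_C: tuple = (0.1, 10, 100)
    svm_gamma: tuple = (0.01, 0.25, 0.5, 1)
    rf_n_trees: tuple = (200, 500, 1000, 2000)
    rf_min_node: tuple = (2, 3, 4, 5)
    inner_folds: int = 3
    #: internal CV folds and path length of the L1 selection
    lasso_cv: int = 10
    lasso_n_cs: int = 10
    #: replace an empty LASSO selection with the top-k univariate features
    lasso_fallback_k: int = 10
    nb_mode: str = "mixed"  # "mixed" or "gaussian"
    log_expression: bool = True
    standardize: bool = True

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "svm_rbf" and (not self.svm_C or not self.svm_gamma):
            raise ValueError("SVM grids must be non-empty")
        if self.method == "random_forest" and (not self.rf_n_trees or not self.rf_min_node):
            raise ValueError("random forest grids must be non-empty")
        if self.nb_mode not in ("mixed", "gaussian"):
            raise ValueError(f"nb_mode must be 'mixed' or 'gaussian', got {self.nb_mode!r}")


@dataclass
class EvaluationResult:
    """Cross-validation metrics for one method on one dataset kind.

    ``accuracy`` is in percent; sensitivity, specificity and AUC in [0, 1];
    each is the mean over runs, with per-run values in ``per_run`` (which also
    reports the fold-averaged AUC next to the pooled one) and the per-fold
    selected features with coefficients in ``selected``.
    """

    method: str
    set_kind: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_run: pd.DataFrame
    selected: pd.DataFrame
    n_runs: int
    n_folds: int

    def validate(self) -> None:
        if not 0 <= self.accuracy <= 100:
            raise ValueError("accuracy must be in [0, 100] percent")
        for name in ("sensitivity", "specificity", "auc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.per_run) != self.n_runs:
            raise ValueError("per_run must have one row per run")


class _Preprocessor:
    """Train-fold transform: log2(x+1) + standardization of expression columns."""

    def __init__(self, feature_types: np.ndarray, log_expression: bool, standardize: bool):
        self.expr_mask = np.asarray(feature_types) == EXPRESSION
        self.log_expression = log_expression
        self.standardize = standardize

    def fit(self, X: np.ndarray) -> "_Preprocessor":
        Z = X.copy()
        if self.expr_mask.any():
            block = Z[:, self.expr_mask]
            if self.log_expression:
                block = np.log2(block + 1.0)
            self.mean_ = block.mean(axis=0)
            sd = block.std(axis=0)
            sd[sd == 0] = 1.0  # constant-in-train columns pass through centered
            self.sd_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = X.astype(float, copy=True)
        if self.expr_mask.any():
            block = Z[:, self.expr_mask]
            if self.log_expression:
                block = np.log2(block + 1.0)
            if self.standardize:
                block = (block - self.mean_) / self.sd_
            Z[:, self.expr_mask] = block
        return Z


class MixedNaiveBayes:
    """Naive Bayes with Gaussian expression and Bernoulli mutation blocks.

    Feature independence lets the two blocks' joint log-likelihoods simply
    add; the class prior, counted once, comes from the training labels.
    """

    def __init__(self, feature_types: np.ndarray, alpha: float = 1.0):
        types = np.asarray(feature_types)
        self.mut_mask = types == MUTATION
        self.expr_mask = ~self.mut_mask
        self.alpha = alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MixedNaiveBayes":
        self.classes_ = np.unique(y)
        counts = np.array([(y == c).sum() for c in self.classes_], dtype=float)
        self.class_log_prior_ = np.log(counts / counts.sum())
        self._gnb = self._bnb = None
        if self.expr_mask.any():
            self._gnb = GaussianNB().fit(X[:, self.expr_mask], y)
        if self.mut_mask.any():
            self._bnb = BernoulliNB(alpha=self.alpha).fit(X[:, self.mut_mask], y)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        total = np.tile(self.class_log_prior_, (X.shape[0], 1))
        # each sub-model's joint already includes a prior term: strip it
        if self._gnb is not None:
            total += self._gnb.predict_joint_log_proba(X[:, self.expr_mask])
            total -= np.log(self._gnb.class_prior_)[None, :]
        if self._bnb is not None:
            total += self._bnb.predict_joint_log_proba(X[:, self.mut_mask])
            total -= self._bnb.class_log_prior_[None, :]
        return total

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def _univariate_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|point-biserial correlation| of each column with the labels."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    return np.abs(np.nan_to_num(r))


def lasso_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    rng: np.random.Generator,
    feature_ids: list[str] | None = None,
    cv: int = 10,
    n_cs: int = 10,
    fallback_k: int | None = 10,
) -> tuple[list[str], np.ndarray]:
    """Select features by L1-penalized logistic regression on training data.

    The penalty is chosen over a log-spaced path by internal stratified CV
    minimizing deviance; features with nonzero coefficients are returned
    ranked by |coefficient| descending.  An empty selection falls back to the
    top ``fallback_k`` features by univariate association (disabled with
    ``fallback_k=None``, returning the empty set).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    classes, counts = np.unique(y_train, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class; cannot select features")
    if counts.min() < 2:
        raise ValueError("need at least 2 training samples per class")
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X_train.shape[1])]

    path_seed = int(rng.integers(2**31))

    def l1_model(C: float) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=C, max_iter=2000, random_state=path_seed
        )

    # regularization path chosen by internal stratified CV minimizing deviance;
    # ties resolve toward the stronger penalty (smaller C)
    Cs = np.logspace(-2, 2, n_cs)
    folds = min(cv, int(counts.min()))
    skf = StratifiedKFold(folds, shuffle=True, random_state=int(rng.integers(2**31)))
    splits = list(skf.split(X_train, y_train))
    deviances = []
    for C in Cs:
        losses = []
        for tr, te in splits:
            fit = l1_model(C).fit(X_train[tr], y_train[tr])
            losses.append(log_loss(y_train[te], fit.predict_proba(X_train[te])[:, 1], labels=classes))
        deviances.append(float(np.mean(losses)))
    best_c = Cs[int(np.argmin(deviances))]
    coefs = l1_model(best_c).fit(X_train, y_train).coef_.ravel()
    nz = np.flatnonzero(coefs != 0)
    if nz.size == 0:
        if fallback_k is None:
            return [], np.array([])
        logger.warning("LASSO selected no features; falling back to top-%d univariate", fallback_k)
        scores = _univariate_scores(X_train, y_train)
        nz = np.argsort(-scores, kind="mergesort")[: min(fallback_k, X_train.shape[1])]
        coefs = np.zeros_like(coefs)
        coefs[nz] = scores[nz]
    order = nz[np.argsort(-np.abs(coefs[nz]), kind="mergesort")]
    return [feature_ids[i] for i in order], coefs[order]


def select_for_combined(
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_types: np.ndarray,
    rng: np.random.Generator,
    feature_ids: list[str] | None = None,
    **kwargs,
) -> tuple[list[str], dict[str, float]]:
    """Per-datatype LASSO selection on a combined matrix, merged by union.

    Mutation-tagged and expression-tagged blocks are selected independently
    and the selections concatenated (mutation block first; the blocks are
    disjoint so the union is a concatenation).
    """
    feature_types = np.asarray(feature_types)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X_train.shape[1])]
    selected: list[str] = []
    coefs: dict[str, float] = {}
    for tag in (MUTATION, EXPRESSION):
        mask = feature_types == tag
        if not mask.any():
            continue
        ids = [f for f, m in zip(feature_ids, mask) if m]
        got, c = lasso_select(X_train[:, mask], y_train, rng, feature_ids=ids, **kwargs)
        selected.extend(got)
        coefs.update(dict(zip(got, c)))
    return selected, coefs


def _grid_candidates(spec: ModelSpec) -> list[dict]:
    """Grid in a fixed order so score ties resolve toward more regularization."""
    if spec.method == "svm_rbf":
        return [{"C": C, "gamma": g} for C in sorted(spec.svm_C) for g in sorted(spec.svm_gamma)]
    if spec.method == "random_forest":
        return [
            {"n_estimators": t, "min_samples_leaf": s}
            for t in sorted(spec.rf_n_trees)
            for s in sorted(spec.rf_min_node, reverse=True)
        ]
    return [{}]


def _build_model(spec: ModelSpec, params: dict, feature_types: np.ndarray, seed: int):
    if spec.method == "svm_rbf":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"], random_state=seed)
    if spec.method == "random_forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            min_samples_leaf=params["min_samples_leaf"],
            random_state=seed,
            n_jobs=None,
        )
    if spec.nb_mode == "gaussian":
        return GaussianNB()
    return MixedNaiveBayes(feature_types)


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Class-1 score: decision value for SVM, probability otherwise (AUC is rank-based)."""
    if isinstance(model, SVC):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def _fit_model(model, X, y):
    return model.fit(X, y)


def _tune(spec: ModelSpec, X: np.ndarray, y: np.ndarray, feature_types: np.ndarray, seed: int) -> dict:
    """Pick grid parameters by inner stratified CV on classification accuracy.

    Accuracy mirrors the error-rate criterion of the standard tuners for
    these classifiers; the first best candidate wins, and the grid order
    resolves ties toward more regularization.
    """
    candidates = _grid_candidates(spec)
    if len(candidates) == 1:
        return candidates[0]
    counts = np.bincount(y)
    folds = max(2, min(spec.inner_folds, int(counts[counts > 0].min())))
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best, best_score = candidates[0], -np.inf
    for params in candidates:
        scores = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                continue
            model = _build_model(spec, params, feature_types, seed)
            _fit_model(model, X[tr], y[tr])
            scores.append(float((model.predict(X[te]) == y[te]).mean()))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score + 1e-12:
            best, best_score = params, mean
    return best


def pooled_metrics(y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray) -> dict[str, float]:
    """Accuracy (%), sensitivity, specificity and AUC from pooled calls/scores."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = len(y_true)
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "auc": float(roc_auc_score(y_true, y_score)) if len(np.unique(y_true)) == 2 else np.nan,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def cross_validate(
    dataset: FeatureDataset,
    spec: ModelSpec | None = None,
    n_folds: int = 10,
    n_runs: int = 10,
    rng: np.random.Generator | int | None = None,
    select_features: bool = True,
    audit_canary: bool = False,
) -> EvaluationResult:
    """Evaluate one classifier on one dataset by repeated stratified k-fold CV.

    Feature selection and preprocessing are fitted inside each fold on the
    training rows only.  With ``audit_canary`` a leakage tripwire column is
    appended per fold before selection — equal to the label on the held-out
    rows and constant zero on training rows — and recorded if ever selected;
    a selection procedure that only sees training rows can never pick it.
    """
    spec = spec or ModelSpec()
    spec.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("dataset must contain both classes")

    canary_id = "__canary__"
    run_rows = []
    selected_rows = []
    for run in range(n_runs):
        run_seed = int(rng.integers(2**31))
        run_rng = np.random.default_rng(run_seed)
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=run_seed)
        oof_true = np.empty(dataset.n_samples, dtype=int)
        oof_pred = np.empty(dataset.n_samples, dtype=int)
        oof_score = np.empty(dataset.n_samples, dtype=float)
        fold_aucs = []
        for fold, (tr, te) in enumerate(skf.split(dataset.X, dataset.y)):
            if len(np.unique(dataset.y[tr])) < 2:
                raise RuntimeError("stratified split produced a single-class training fold")
            X, y = dataset.X, dataset.y
            feature_ids = list(dataset.feature_ids)
            feature_types = dataset.feature_types
            if audit_canary:
                canary = np.zeros(dataset.n_samples)
                canary[te] = y[te]
                X = np.hstack([X, canary[:, None]])
                feature_ids = feature_ids + [canary_id]
                canary_type = MUTATION if dataset.set_kind == "M" else EXPRESSION
                feature_types = np.concatenate([feature_types, [canary_type]])

            pre = _Preprocessor(feature_types, spec.log_expression, spec.standardize).fit(X[tr])
            Xtr, Xte = pre.transform(X[tr]), pre.transform(X[te])

            if select_features:
                kwargs = dict(cv=spec.lasso_cv, n_cs=spec.lasso_n_cs, fallback_k=spec.lasso_fallback_k)
                if dataset.set_kind == "EM":
                    sel_ids, coefs = select_for_combined(
                        Xtr, y[tr], feature_types, run_rng, feature_ids=feature_ids, **kwargs
                    )
                else:
                    sel_ids, c = lasso_select(Xtr, y[tr], run_rng, feature_ids=feature_ids, **kwargs)
                    coefs = dict(zip(sel_ids, c))
                if not sel_ids:  # fallback disabled and nothing selected: use all features
                    sel_ids = feature_ids
                    coefs = {f: np.nan for f in sel_ids}
            else:
                sel_ids = feature_ids
                coefs = {f: np.nan for f in sel_ids}
            for feat in sel_ids:
                selected_rows.append(
                    {"run": run, "fold": fold, "feature": feat, "coefficient": coefs.get(feat, np.nan)}
                )
            col_index = {f: i for i, f in enumerate(feature_ids)}
            cols = np.array([col_index[f] for f in sel_ids], dtype=int)
            sub_types = feature_types[cols]

            params = _tune(spec, Xtr[:, cols], y[tr], sub_types, seed=int(run_rng.integers(2**31)))
            model = _build_model(spec, params, sub_types, seed=int(run_rng.integers(2**31)))
            _fit_model(model, Xtr[:, cols], y[tr])
            oof_true[te] = y[te]
            oof_pred[te] = model.predict(Xte[:, cols])
            oof_score[te] = _scores(model, Xte[:, cols])
            if len(np.unique(y[te])) == 2:
                fold_aucs.append(roc_auc_score(y[te], oof_score[te]))

        m = pooled_metrics(oof_true, oof_pred, oof_score)
        m["run"] = run
        m["auc_fold_mean"] = float(np.mean(fold_aucs)) if fold_aucs else np.nan
        run_rows.append(m)

    per_run = pd.DataFrame(run_rows)
    selected = pd.DataFrame(selected_rows, columns=["run", "fold", "feature", "coefficient"])
    result = EvaluationResult(
        method=spec.method,
        set_kind=dataset.set_kind,
        accuracy=float(per_run["accuracy"].mean()),
        sensitivity=float(per_run["sensitivity"].mean()),
        specificity=float(per_run["specificity"].mean()),
        auc=float(per_run["auc"].mean()),
        per_run=per_run,
        selected=selected,
        n_runs=n_runs,
        n_folds=n_folds,
    )
    result.validate()
    return result
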