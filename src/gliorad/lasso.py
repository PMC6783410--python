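"""L1-regularized logistic models with repeated nested cross-validation.

Used for two classification problems: predicting the MGMT-promoter
methylation label from radiomic features, and predicting long-term
survival at a sweep of overall-survival cutoffs. The regularization
weight lambda is chosen as the minimizer of the mean k-fold binomial
deviance (lambda_min) over a log-spaced path from lambda_max (the
smallest lambda with an all-zero solution) down to 0.001*lambda_max;
the final model is refit on all data at lambda_min.

Reported performance always comes from *nested* cross-validation: outer
folds are held out, lambda is tuned on the training portion only, and
held-out cases are classified at probability 0.5. Metrics are computed
on the pooled outer-fold predictions of each repeat and averaged over
repeats.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

_EPS = 1e-12


class SingleClassError(ValueError):
    """Labels contain a single class; no model can be fit."""


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if len(classes) < 2:
        raise SingleClassError("both classes must be present")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return X, y


def _effective_k(y, k: int) -> int:
    """Largest stratified fold count the class balance supports (>= 2)."""
    m = int(np.bincount(y).min())
    keff = max(2, min(k, m))
    if keff < k:
        warnings.warn(f"reducing folds from {k} to {keff} (minority class size {m})")
    return keff


def _impute_standardize(X, medians=None, mu=None, sd=None):
    if medians is None:
        medians = np.nanmedian(X, axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
    X = np.where(np.isnan(X), medians, X)
    if mu is None:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
    keep_sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / keep_sd, medians, mu, sd


def lambda_max(Z, y) -> float:
    """Smallest lambda with an all-zero L1-logistic solution (KKT bound)."""
    r = y - y.mean()
    return float(np.max(np.abs(Z.T @ r)) / len(y))


def lambda_path(Z, y, n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(Z, y)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def _fit_at_lambda(Z, y, lam: float) -> tuple:
    """L1 logistic fit at one lambda; returns (coefs, intercept).

    Solved with liblinear at C = 1/(n*lambda); a large intercept scaling
    makes the intercept effectively unpenalized.
    """
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        l1_ratio=1, C=C, solver="liblinear", intercept_scaling=100.0,
        max_iter=500, tol=1e-7,
    )
    clf.fit(Z, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


@dataclass
class LassoFit:
    lambdas: np.ndarray
    lambda_min: float
    coef: np.ndarray             # on the standardized scale
    intercept: float
    feature_names: list
    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    cv_seed: int
    cv_deviance: np.ndarray      # mean k-fold deviance per lambda
    path_coefs: np.ndarray | None = None   # (n_lambda, p), full-data path

    @property
    def selected(self) -> list:
        return [n for n, c in zip(self.feature_names, self.coef) if c != 0.0]

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z, *_ = _impute_standardize(X, self.medians, self.means, self.sds)
        eta = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)


def lasso_cv_fit(X, y, k: int = 10, seed: int = 0, n_lambda: int = 100,
                 lambda_min_ratio: float = 1e-3,
                 store_path: bool = False, feature_names=None) -> LassoFit:
    """Cross-validated L1 logistic fit; lambda_min by minimum mean deviance."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X, y = _validate_xy(X, y)
    if len(y) < 20:
        raise ValueError("need at least 20 cases")
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    const = np.nanstd(X, axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) carry no signal")

    Zfull, medians, mu, sd = _impute_standardize(X)
    lams = lambda_path(Zfull, y, n_lambda, lambda_min_ratio)

    k = _effective_k(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dev = np.zeros((k, len(lams)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        Ztr, med_f, mu_f, sd_f = _impute_standardize(X[tr])
        Zte, *_ = _impute_standardize(X[te], med_f, mu_f, sd_f)
        for li, lam in enumerate(lams):
            coef, b = _fit_at_lambda(Ztr, y[tr], lam)
            p = 1.0 / (1.0 + np.exp(-(Zte @ coef + b)))
            p = np.clip(p, _EPS, 1 - _EPS)
            dev[f, li] = -2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    mean_dev = dev.mean(axis=0)
    lam_min = float(lams[int(np.argmin(mean_dev))])

    coef, intercept = _fit_at_lambda(Zfull, y, lam_min)
    path = None
    if store_path:
        path = np.array([_fit_at_lambda(Zfull, y, lam)[0] for lam in lams])
    return LassoFit(
        lambdas=lams, lambda_min=lam_min, coef=coef, intercept=intercept,
        feature_names=names, medians=medians, means=mu, sds=sd,
        cv_seed=seed, cv_deviance=mean_dev, path_coefs=path,
    )


# ---------------------------------------------------------------------------
# Nested CV metrics


@dataclass
class CvMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    per_repeat: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "sensitivity", "specificity", "ppv", "npv", "prevalence")}


def _binary_metrics(y_true, y_pred) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    div = lambda a, b: a / b if b > 0 else np.nan
    return {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
        "prevalence": (tp + fn) / len(y_true),
    }


def nested_cv_metrics(X, y, outer_k: int = 10, repeats: int = 5, seed: int = 0,
                      inner_k: int = 10, n_lambda: int = 50) -> CvMetrics:
    """Repeated nested cross-validation of the L1 logistic classifier.

    Inner lambda tuning sees only the outer-fold training portion; the
    held-out class is predicted at probability 0.5. Metrics are computed
    on each repeat's pooled outer-fold predictions and averaged over
    repeats.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X, y = _validate_xy(X, y)
    per_repeat = []
    outer_k = _effective_k(y, outer_k)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=outer_k, shuffle=True,
                              random_state=seed + 1000 * r)
        pooled_true = np.empty(len(y), dtype=int)
        pooled_pred = np.empty(len(y), dtype=int)
        for tr, te in skf.split(X, y):
            fit = lasso_cv_fit(X[tr], y[tr], k=inner_k,
                               seed=seed + 1000 * r + 1, n_lambda=n_lambda)
            pooled_true[te] = y[te]
            pooled_pred[te] = fit.predict(X[te])
        per_repeat.append(_binary_metrics(pooled_true, pooled_pred))
    agg = {k: float(np.nanmean([m[k] for m in per_repeat]))
           for k in per_repeat[0]}
    return CvMetrics(per_repeat=per_repeat, **agg)


# ---------------------------------------------------------------------------
# Long-term survivor labeling and sweep


@dataclass
class SurvivorLabeling:
    cutoff_months: float
    labels: np.ndarray            # 1 = long-term, 0 = short-term (labeled cases)
    labeled_idx: np.ndarray
    excluded_idx: np.ndarray      # censored before the cutoff

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels)) if len(self.labels) else 0


def survivor_labels(time, event, cutoff_months: float) -> SurvivorLabeling:
    """Long/short survivor labels at a cutoff.

    Death before the cutoff -> short; observed (event or censoring) time
    at or beyond the cutoff -> long; censored strictly before the cutoff
    -> excluded (survival status at the cutoff unknown).
    """
    if cutoff_months <= 0:
        raise ValueError("cutoff must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    long_ = time >= cutoff_months
    short = (event == 1) & (time < cutoff_months)
    labeled = long_ | short
    labels = long_[labeled].astype(int)
    return SurvivorLabeling(
        cutoff_months=float(cutoff_months),
        labels=labels,
        labeled_idx=np.flatnonzero(labeled),
        excluded_idx=np.flatnonzero(~labeled),
    )


def survivor_sweep(X, time, event, cutoffs, outer_k: int = 10,
                   repeats: int = 5, seed: int = 0,
                   n_lambda: int = 50) -> tuple:
    """Long-term-survivor prediction at each cutoff.

    Returns (metrics table, {cutoff: selected feature names}). A cutoff
    whose labeling is single-class or leaves too few cases is reported as
    not modelable rather than raising.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    rows = []
    selected = {}
    for cutoff in cutoffs:
        lab = survivor_labels(time, event, cutoff)
        n_min_class = min(np.bincount(lab.labels, minlength=2)) if len(lab.labels) else 0
        if lab.n_classes < 2 or len(lab.labels) < 20 or n_min_class < 3:
            rows.append({"cutoff_months": cutoff, "modelable": False,
                         "n_labeled": len(lab.labels),
                         "n_excluded": len(lab.excluded_idx)})
            continue
        Xl = X[lab.labeled_idx]
        try:
            m = nested_cv_metrics(Xl, lab.labels, outer_k=outer_k,
                                  repeats=repeats, seed=seed, n_lambda=n_lambda)
            fit = lasso_cv_fit(Xl, lab.labels, k=outer_k, seed=seed,
                               n_lambda=n_lambda, feature_names=names)
        except ValueError as exc:   # e.g. training folds too small
            rows.append({"cutoff_months": cutoff, "modelable": False,
                         "n_labeled": len(lab.labels),
                         "n_excluded": len(lab.excluded_idx)})
            warnings.warn(f"cutoff {cutoff}: not modelable ({exc})")
            continue
        selected[float(cutoff)] = fit.selected
        rows.append({"cutoff_months": cutoff, "modelable": True,
                     "n_labeled": len(lab.labels),
                     "n_excluded": len(lab.excluded_idx),
                     **m.as_dict()})
    return pd.DataFrame(rows), selected
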