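"""Supervised principal component survival modeling.

The predictor is built in two stages, mirroring the gene-expression
"supervised PCA" recipe applied to radiomic features:

1. *Screening*: each standardized feature gets a univariate Cox score
   statistic (partial-likelihood score at beta = 0 divided by the square
   root of the information, Breslow tie handling). Features with
   |score| above a threshold theta are retained; theta is tuned by
   k-fold cross-validation maximizing the held-out Cox likelihood-ratio
   statistic of the predicted risk score.
2. *Component*: the first principal component of the standardized
   retained submatrix is the continuous risk score; it is oriented so
   that a higher score means higher hazard, and a median split of the
   training scores gives the discrete high/low risk classification.

Feature importance is reported as the Pearson correlation between each
retained standardized feature and the continuous component score.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class SpcaModelFailure(RuntimeError):
    """No feature passed the screening threshold."""


# ---------------------------------------------------------------------------
# Univariate Cox machinery (Breslow ties)


def _prepare_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return time, event


def cox_univariate_scores(X, time, event) -> np.ndarray:
    """Standardized Cox score statistic of every feature column at beta=0.

    ``score_j = U_j / sqrt(I_j)`` with the Breslow convention for tied
    event times; asymptotically standard normal under the null. Features
    are standardized internally; zero-variance columns score 0.
    """
    time, event = _prepare_survival(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 cases")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s) scored 0")
        sd = np.where(zero, 1.0, sd)
    Z = (X - mu) / sd

    order = np.argsort(time, kind="stable")
    t_s, e_s, Z_s = time[order], event[order], Z[order]
    # suffix sums over the risk set {k : t_k >= t}
    s1 = np.cumsum(Z_s[::-1], axis=0)[::-1]
    s2 = np.cumsum((Z_s**2)[::-1], axis=0)[::-1]
    nrisk = np.arange(n, 0, -1)

    U = np.zeros(p)
    I = np.zeros(p)
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        if d > 0:
            m1 = s1[i] / nrisk[i]
            m2 = s2[i] / nrisk[i]
            U += Z_s[i:j][e_s[i:j] == 1].sum(axis=0) - d * m1
            I += d * (m2 - m1**2)
        i = j
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(I > 0, U / np.sqrt(np.maximum(I, 1e-300)), 0.0)
    scores[zero] = 0.0
    return scores


def cox_univariate_fit(x, time, event, max_iter: int = 25, tol: float = 1e-9):
    """One-covariate Cox fit by Newton's method (Breslow ties).

    Returns (beta_hat, log-likelihood-ratio statistic vs beta = 0).
    """
    time, event = _prepare_survival(time, event)
    x = np.asarray(x, dtype=float)
    order = np.argsort(time, kind="stable")
    t_s, e_s, x_s = time[order], event[order], x[order]

    # distinct event times: index of first tied element and event count
    blocks = []
    i = 0
    while i < len(t_s):
        j = i
        while j < len(t_s) and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        if d > 0:
            blocks.append((i, d, float(x_s[i:j][e_s[i:j] == 1].sum())))
        i = j

    def loglik_grad_hess(beta):
        w = np.exp(beta * x_s)
        sw = np.cumsum(w[::-1])[::-1]
        swx = np.cumsum((w * x_s)[::-1])[::-1]
        swx2 = np.cumsum((w * x_s**2)[::-1])[::-1]
        ll = g = h = 0.0
        for i0, d, xsum in blocks:
            ll += beta * xsum - d * np.log(sw[i0])
            m1 = swx[i0] / sw[i0]
            m2 = swx2[i0] / sw[i0]
            g += xsum - d * m1
            h -= d * (m2 - m1**2)
        return ll, g, h

    ll0, _, _ = loglik_grad_hess(0.0)
    beta = 0.0
    for _ in range(max_iter):
        ll, g, h = loglik_grad_hess(beta)
        if h >= 0:
            break
        step = -g / h
        step = np.clip(step, -2.0, 2.0)
        beta += step
        if abs(step) < tol:
            break
    ll_hat, _, _ = loglik_grad_hess(beta)
    return float(beta), float(2.0 * (ll_hat - ll0))


# ---------------------------------------------------------------------------
# Model


@dataclass
class SpcaModel:
    threshold: float
    retained: list
    feature_names: list
    means: np.ndarray          # per retained feature, training mean
    sds: np.ndarray
    medians: np.ndarray        # training medians for imputation
    loadings: np.ndarray       # unit-norm first-PC loadings
    cox_coef: float            # log-HR of the PC score
    cut: float                 # training-score median (discrete split)
    cv_seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "retained": list(self.retained),
            "means": list(map(float, self.means)),
            "sds": list(map(float, self.sds)),
            "medians": list(map(float, self.medians)),
            "loadings": list(map(float, self.loadings)),
            "cox_coef": self.cox_coef,
            "cut": self.cut,
            "cv_seed": self.cv_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SpcaModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            threshold=d["threshold"], retained=d["retained"],
            feature_names=d["retained"],
            means=np.asarray(d["means"]), sds=np.asarray(d["sds"]),
            medians=np.asarray(d["medians"]),
            loadings=np.asarray(d["loadings"]), cox_coef=d["cox_coef"],
            cut=d["cut"], cv_seed=d.get("cv_seed"),
        )


def _as_matrix(features) -> tuple:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _impute_median(X, medians=None):
    if medians is None:
        medians = np.nanmedian(X, axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
    X = np.where(np.isnan(X), medians, X)
    return X, medians


def spca_fit(features, time, event, threshold: float,
             cv_seed: int | None = None) -> SpcaModel:
    """Fit the supervised-PC survival model at a given screening threshold."""
    X, names = _as_matrix(features)
    time, event = _prepare_survival(time, event)
    X, medians = _impute_median(X)
    scores = cox_univariate_scores(X, time, event)
    keep = np.abs(scores) > threshold
    if not keep.any():
        raise SpcaModelFailure(
            f"no feature exceeds screening threshold {threshold:g}"
        )
    idx = np.flatnonzero(keep)
    sub = X[:, idx]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (sub - mu) / sd
    # first right singular vector = first PC loadings
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    pc = Z @ loadings
    beta, _ = cox_univariate_fit(pc, time, event)
    if beta < 0:  # orient: higher score = higher hazard
        loadings = -loadings
        pc = -pc
        beta = -beta
    return SpcaModel(
        threshold=float(threshold),
        retained=[names[i] for i in idx],
        feature_names=names,
        means=mu, sds=sd, medians=medians[idx],
        loadings=loadings, cox_coef=float(beta),
        cut=float(np.median(pc)), cv_seed=cv_seed,
    )


def spca_classify(model: SpcaModel, features):
    """Continuous risk scores and high/low labels for new cases."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.retained if f not in features.columns]
        if missing:
            raise ValueError(f"features missing retained columns: {missing[:5]}")
        sub = features[model.retained].to_numpy(dtype=float)
    else:
        X, names = _as_matrix(features)
        cols = [names.index(f) for f in model.retained]
        sub = X[:, cols]
    all_missing = np.isnan(sub).all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"{int(all_missing.sum())} case(s) have no retained feature observed"
        )
    sub, _ = _impute_median(sub, model.medians)
    Z = (sub - model.means) / model.sds
    score = Z @ model.loadings
    labels = np.where(score > model.cut, "high", "low")
    return score, labels


def spca_importance(model: SpcaModel, features) -> dict:
    """Correlation of each retained standardized feature with the PC score."""
    score, _ = spca_classify(model, features)
    if isinstance(features, pd.DataFrame):
        sub = features[model.retained].to_numpy(dtype=float)
    else:
        X, names = _as_matrix(features)
        sub = X[:, [names.index(f) for f in model.retained]]
    sub, _ = _impute_median(sub, model.medians)
    out = {}
    sc = score - score.mean()
    denom_s = np.sqrt((sc**2).sum())
    for j, name in enumerate(model.retained):
        v = sub[:, j] - sub[:, j].mean()
        denom = np.sqrt((v**2).sum()) * denom_s
        out[name] = float((v * sc).sum() / denom) if denom > 0 else 0.0
    return out


@dataclass
class SpcaCvResult:
    grid: np.ndarray
    mean_statistic: np.ndarray
    best_threshold: float
    fold_seed: int


def default_threshold_grid(scores: np.ndarray, n_points: int = 30) -> np.ndarray:
    """30 thresholds spanning the 50th-99th percentile of |score|."""
    a = np.abs(scores)
    return np.linspace(np.percentile(a, 50), np.percentile(a, 99), n_points)


def spca_cross_validate_threshold(features, time, event, grid=None,
                                  k: int = 10, seed: int = 0) -> SpcaCvResult:
    """Tune the screening threshold by k-fold cross-validation.

    For each candidate theta the screening and PC construction run on the
    training portion of each fold; held-out cases are scored on the
    trained loadings and the fold records the Cox likelihood-ratio
    statistic of the held-out scores. The tuned theta maximizes the mean
    held-out statistic (ties broken toward the larger, sparser theta).
    Folds are stratified by the event indicator.
    """
    X, _ = _as_matrix(features)
    time, event = _prepare_survival(time, event)
    X, _ = _impute_median(X)
    if grid is None:
        grid = default_threshold_grid(cox_univariate_scores(X, time, event))
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    m = int(np.bincount(event).min())
    if m < k:
        warnings.warn(f"reducing folds from {k} to {max(2, m)} "
                      "(event/censor balance)")
        k = max(2, m)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    stats = np.zeros((k, grid.size))
    used = np.zeros(k, dtype=bool)
    for f, (tr, te) in enumerate(skf.split(X, event)):
        if event[tr].sum() < 2 or event[te].sum() < 1:
            warnings.warn(f"fold {f} skipped: too few events")
            continue
        used[f] = True
        tr_scores = cox_univariate_scores(X[tr], time[tr], event[tr])
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Ztr = (X[tr] - mu) / sd
        Zte = (X[te] - mu) / sd
        for gi, theta in enumerate(grid):
            keep = np.abs(tr_scores) > theta
            if not keep.any():
                stats[f, gi] = 0.0
                continue
            _, _, vt = np.linalg.svd(Ztr[:, keep], full_matrices=False)
            held = Zte[:, keep] @ vt[0]
            if held.std() == 0:
                stats[f, gi] = 0.0
                continue
            try:
                _, lr = cox_univariate_fit(held, time[te], event[te])
                stats[f, gi] = lr
            except Exception:
                stats[f, gi] = 0.0
    if not used.any():
        raise RuntimeError("all folds skipped; too few events")
    mean_stat = stats[used].mean(axis=0)
    # argmax; among near-ties prefer the largest (sparsest) theta
    best = grid[np.flatnonzero(mean_stat >= mean_stat.max() - 1e-12).max()]
    return SpcaCvResult(grid, mean_stat, float(best), seed)
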