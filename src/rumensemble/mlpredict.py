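"""Ridge regression with cross-validated greedy feature selection.

The predictor mirrors how microbiome features are screened against a
residual trait: candidate features are ranked by their univariate
correlation with the trait and accepted one at a time into a ridge model
only while the inner 5-fold validation MSE keeps improving beyond its
paired fold-wise standard error; the ridge penalty is re-chosen from a grid
at every step.  Performance is estimated by an outer seeded 10-fold
cross-validation that re-runs the entire selection inside each training
split, so reported R2/MSE/RMSE come from leakage-free out-of-fold
predictions.

Because residual traits split cows into efficient (negative RFI) and
inefficient (positive RFI) halves, prediction quality is also summarized as
a sign-agreement confusion matrix with precision, recall and F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class RidgeModel:
    """Ridge fit with internally standardized columns, intercept unpenalized."""

    coef: np.ndarray          # on the original feature scale
    intercept: float
    lam: float

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.coef + self.intercept


def ridge_fit(X, y, lam: float) -> RidgeModel:
    """Minimize ||y - Xb - b0||^2 + lam * ||b_std||^2 (standardized scale)."""
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if y.std() == 0:
        raise ValueError("constant response")
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    yc = y - y.mean()
    G = Z.T @ Z + lam * np.eye(X.shape[1])
    beta = np.linalg.solve(G, Z.T @ yc)
    coef = beta / sd
    return RidgeModel(coef=coef, intercept=float(y.mean() - coef @ mean), lam=lam)


def _ridge_path(Xtr: np.ndarray, ytr: np.ndarray, lams: np.ndarray):
    """Coefficients for every penalty at once via eigendecomposition.

    Returns (coefs[len(lams), k] on original scale, intercepts[len(lams)]).
    """
    mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xtr - mean) / sd
    yc = ytr - ytr.mean()
    w, Q = np.linalg.eigh(Z.T @ Z)
    qty = Q.T @ (Z.T @ yc)
    betas = Q @ (qty[:, None] / (w[:, None] + lams[None, :]))   # k x L
    coefs = (betas / sd[:, None]).T                              # L x k
    intercepts = ytr.mean() - coefs @ mean
    return coefs, intercepts


def make_folds(n: int, k_folds: int, rng: np.random.Generator,
               stratify_by: np.ndarray | None = None) -> list[np.ndarray]:
    """Seeded fold assignment with sizes differing by <= 1.

    With ``stratify_by`` (e.g. the sign of a residual trait) each stratum is
    dealt round-robin so the folds stay balanced on it.
    """
    if k_folds > n:
        raise ValueError("more folds than observations")
    assign = np.empty(n, int)
    if stratify_by is None:
        order = rng.permutation(n)
        assign[order] = np.arange(n) % k_folds
    else:
        stratify_by = np.asarray(stratify_by)
        start = 0
        for s in np.unique(stratify_by):
            idx = np.flatnonzero(stratify_by == s)
            order = rng.permutation(idx)
            assign[order] = (np.arange(len(idx)) + start) % k_folds
            start += len(idx)
    return [np.flatnonzero(assign == f) for f in range(k_folds)]


@dataclass
class PredictionReport:
    """Outcome of :func:`cv_feature_select`."""

    selected: list                       # feature ids in acceptance order
    lambdas: list                        # final per-fold penalties
    fold_mse: list
    mse: float
    rmse: float
    r2: float
    oof_predictions: pd.Series
    mse_path: list = field(default_factory=list)   # best inner MSE per step


def _inner_cv_score(X: np.ndarray, y: np.ndarray, cols: list[int],
                    inner_folds: list[np.ndarray], lams: np.ndarray):
    """Inner-CV MSE of a column set over the penalty grid.

    Returns (best mean validation MSE, best penalty, per-fold MSEs at the
    best penalty).
    """
    n = len(y)
    fold_mse = np.zeros((len(inner_folds), len(lams)))
    for k, val in enumerate(inner_folds):
        tr = np.setdiff1d(np.arange(n), val)
        if cols:
            coefs, icepts = _ridge_path(X[np.ix_(tr, cols)], y[tr], lams)
            preds = X[np.ix_(val, cols)] @ coefs.T + icepts
        else:
            preds = np.full((len(val), len(lams)), y[tr].mean())
        fold_mse[k] = ((preds - y[val][:, None]) ** 2).mean(axis=0)
    mse = fold_mse.mean(axis=0)
    best = int(np.argmin(mse))
    return float(mse[best]), float(lams[best]), fold_mse[:, best]


def _rank_by_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (Xc.T @ yc) / denom, 0.0)
    return np.argsort(-np.abs(corr), kind="stable")


def _greedy_select(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                   lams: np.ndarray, inner_k: int, max_features: int,
                   patience: int, se_margin: float):
    """Greedy forward selection judged entirely by inner CV on (X, y).

    Candidates are walked in decreasing |correlation| order; one is accepted
    iff it strictly lowers the inner-CV validation MSE by more than
    ``se_margin`` times the paired fold-wise standard error of the
    improvement (penalty re-chosen from the grid at every step).  The walk
    stops after ``patience`` consecutive non-improving candidates.
    Returns (selected column indices, final penalty, MSE path).
    """
    n = len(y)
    inner_folds = make_folds(n, min(inner_k, n), rng)
    ranking = _rank_by_correlation(X, y)
    best_mse, best_lam, best_folds = _inner_cv_score(X, y, [], inner_folds,
                                                     lams)
    selected: list[int] = []
    mse_path = [best_mse]
    fails = 0
    for cand in ranking:
        if len(selected) >= max_features:
            break
        score, lam, score_folds = _inner_cv_score(
            X, y, selected + [int(cand)], inner_folds, lams)
        diff = best_folds - score_folds       # paired per-fold improvements
        se = diff.std(ddof=1) / np.sqrt(len(diff)) if len(diff) > 1 else 0.0
        if score < best_mse and diff.mean() > se_margin * se:
            selected.append(int(cand))
            best_mse, best_lam, best_folds = score, lam, score_folds
            mse_path.append(score)
            fails = 0
        else:
            fails += 1
            if fails >= patience:
                break
    return selected, best_lam, mse_path


def _as_matrix(features):
    """Accept a FeatureMatrix, DataFrame, or ndarray; return (X, ids, index)."""
    inner = getattr(features, "values", None)
    if isinstance(features, pd.DataFrame):
        df = features
    elif isinstance(inner, pd.DataFrame):
        df = inner
    else:
        X = np.asarray(features, float)
        return X, list(range(X.shape[1])), pd.RangeIndex(X.shape[0])
    return df.to_numpy(float), list(df.columns), df.index


def cv_feature_select(features, y, k_folds: int = 10,
                      lambda_grid=DEFAULT_LAMBDA_GRID, seed: int = 0,
                      max_features: int = 50, inner_k: int = 5,
                      patience: int = 10, se_margin: float = 2.0,
                      stratify_sign: bool = True) -> PredictionReport:
    """Nested-CV greedy ridge feature selection.

    ``features`` is a FeatureMatrix or DataFrame (cows x features); ``y`` a
    per-cow trait aligned on the same index.  Performance is estimated by an
    outer ``k_folds`` cross-validation in which the entire selection
    procedure (correlation ranking, greedy acceptance, penalty choice) is
    re-run inside every outer training set, so the pooled out-of-fold
    R2/MSE/RMSE are free of selection leakage.  The reported feature list
    comes from one final selection pass on all cows.
    """
    X, ids, index = _as_matrix(features)
    y_arr = np.asarray(y, float)
    n, p = X.shape
    if p == 0:
        raise ValueError("empty feature matrix")
    if k_folds > n:
        raise ValueError("more folds than cows")
    rng = np.random.default_rng(seed)
    strat = np.sign(y_arr) if stratify_sign else None
    folds = make_folds(n, k_folds, rng, stratify_by=strat)
    lams = np.asarray(lambda_grid, float)

    oof = np.empty(n)
    fold_mse, fold_lams = [], []
    for val_idx in folds:
        tr = np.setdiff1d(np.arange(n), val_idx)
        sel, lam, _ = _greedy_select(X[tr], y_arr[tr], rng, lams, inner_k,
                                     max_features, patience, se_margin)
        if sel:
            coefs, icepts = _ridge_path(X[np.ix_(tr, sel)], y_arr[tr],
                                        np.array([lam]))
            pred = X[np.ix_(val_idx, sel)] @ coefs[0] + icepts[0]
        else:
            pred = np.full(len(val_idx), y_arr[tr].mean())
        oof[val_idx] = pred
        fold_mse.append(float(((pred - y_arr[val_idx]) ** 2).mean()))
        fold_lams.append(lam if sel else float("nan"))

    # reporting pass on all cows (the model a user would deploy)
    selected, _, mse_path = _greedy_select(X, y_arr, rng, lams, inner_k,
                                           max_features, patience, se_margin)

    sse = float(((y_arr - oof) ** 2).sum())
    tss = float(((y_arr - y_arr.mean()) ** 2).sum())
    pooled_mse = float(((y_arr - oof) ** 2).mean())
    return PredictionReport(
        selected=[ids[i] for i in selected],
        lambdas=fold_lams,
        fold_mse=fold_mse,
        mse=pooled_mse,
        rmse=float(np.sqrt(pooled_mse)),
        r2=1.0 - sse / tss,
        oof_predictions=pd.Series(oof, index=index),
        mse_path=mse_path,
    )


@dataclass
class SignConfusion:
    """Sign-agreement confusion matrix over a residual trait."""

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    f1_negative: float
    positive_label: str
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def sign_confusion(observed, predicted,
                   positive_label: str = "+") -> SignConfusion:
    """Confusion matrix from sign agreement of observed vs predicted residuals.

    For RFI the positive (``"+"``) class is the inefficient cow; pass
    ``positive_label="-"`` to score the efficient class instead.  Residuals
    that are exactly zero are assigned to the negative (efficient) class.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must align")
    if positive_label not in ("+", "-"):
        raise ValueError("positive_label must be '+' or '-'")
    if (obs == 0).any() or (pred == 0).any():
        log.info("zero residuals assigned to the negative class")
    obs_pos = obs > 0
    pred_pos = pred > 0
    if positive_label == "-":
        obs_pos, pred_pos = ~obs_pos, ~pred_pos
    tp = int((obs_pos & pred_pos).sum())
    tn = int((~obs_pos & ~pred_pos).sum())
    fp = int((~obs_pos & pred_pos).sum())
    fn = int((obs_pos & ~pred_pos).sum())
    degenerate = obs_pos.all() or (~obs_pos).all()
    if degenerate:
        log.warning("only one observed class: precision/recall partly undefined")

    def _prf(tp_, fp_, fn_):
        prec = tp_ / (tp_ + fp_) if tp_ + fp_ else float("nan")
        rec = tp_ / (tp_ + fn_) if tp_ + fn_ else float("nan")
        if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
            return prec, rec, float("nan") if np.isnan(prec) or np.isnan(rec) else 0.0
        return prec, rec, 2 * prec * rec / (prec + rec)

    precision, recall, f1 = _prf(tp, fp, fn)
    _, _, f1_neg = _prf(tn, fn, fp)
    return SignConfusion(tp=tp, tn=tn, fp=fp, fn=fn,
                         precision=precision, recall=recall, f1=f1,
                         f1_negative=f1_neg, positive_label=positive_label,
                         degenerate=degenerate)
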