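"""Logistic modelling and stepwise signature selection.

The discriminating signature is built by classical forward–backward stepwise
logistic regression over the screen's candidate miRNAs (predictors entered
as −ΔCt): at each step the candidate whose likelihood-ratio test (LRT)
against the current model has the smallest p-value is added if p ≤ α_enter
(default 0.10), and after every addition any included term whose drop-LRT
p-value exceeds α_remove (default 0.15) is removed, largest first.  Ties
break by candidate order, so selection is deterministic for a fixed
candidate ordering.

Maximum-likelihood fits use Newton–Raphson with step halving.  With few
samples and several informative predictors the likelihood can be maximized
at infinity (complete or quasi-complete separation); such fits, and any
non-converging fit, are refit with a small ridge penalty on the slopes and
flagged ``penalized_fallback`` so downstream consumers can report it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortError, ExpressionMatrix

#: ridge weight used when maximum likelihood diverges (separation); the
#: penalty is 0.5 * weight * ||slopes||^2 on the log-likelihood scale
RIDGE_FALLBACK_WEIGHT = 0.05
_MAX_ABS_COEF = 12.0   # beyond this the MLE is de facto diverging (separation)
_MAX_ITER = 60
_TOL = 1e-10

ALPHA_ENTER = 0.10
ALPHA_REMOVE = 0.15


@dataclass
class LogisticFit:
    """A fitted binary logistic model p(y=1|x) = expit(b0 + x·b)."""

    coefficients: np.ndarray        # one slope per input predictor (dropped -> 0)
    intercept: float
    deviance: float                 # -2 log-likelihood (unpenalized part)
    converged: bool
    penalized_fallback: bool
    fitted_probabilities: np.ndarray
    dropped: list[int] = field(default_factory=list)  # constant predictors
    n_iter: int = 0

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _expit(self.linear_predictor(X))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _newton(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Newton–Raphson for logistic regression on a design with intercept.

    Returns (beta, deviance, converged, n_iter, diverged) where ``diverged``
    marks runaway coefficients (separation).  ``ridge`` penalizes slopes
    only, never the intercept.
    """
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    pen = np.zeros(p + 1)
    pen[1:] = ridge
    beta = np.zeros(p + 1)
    prob = _expit(design @ beta)
    obj = _deviance(y, prob) + float(pen @ beta**2)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        w = prob * (1 - prob)
        grad = design.T @ (y - prob) - pen * beta
        hess = (design * w[:, None]).T @ design + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving on the penalized deviance
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            prob_c = _expit(design @ cand)
            obj_c = _deviance(y, prob_c) + float(pen @ cand**2)
            if obj_c <= obj + 1e-14:
                break
            scale *= 0.5
        beta, prob = cand, prob_c
        if p > 0 and ridge == 0.0 and np.max(np.abs(beta[1:])) > _MAX_ABS_COEF:
            return beta, _deviance(y, prob), False, it, True
        if abs(obj - obj_c) < _TOL * (1.0 + abs(obj_c)):
            obj = obj_c
            converged = True
            break
        obj = obj_c
    return beta, _deviance(y, prob), converged, it, False


def fit_logistic(X, y, penalty: float | None = None) -> LogisticFit:
    """Fit a binary logistic regression by maximum likelihood.

    Parameters
    ----------
    X : array-like of shape (n_samples, n_predictors)
        May have zero columns (intercept-only model).  Constant columns are
        dropped with a warning and reported with slope 0.
    y : array-like of 0/1 labels
        Both classes must be present.
    penalty : float, optional
        Explicit ridge weight on the slopes.  When None (default), maximum
        likelihood is attempted first; on separation or non-convergence the
        fit falls back to :data:`RIDGE_FALLBACK_WEIGHT` and sets
        ``penalized_fallback``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise CohortError("X and y have different numbers of samples")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise CohortError("y must contain both classes, coded 0/1")

    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [j for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping constant predictor column(s) {dropped}")
    Xk = X[:, keep]

    fallback = False
    if penalty is not None:
        beta, dev, converged, n_iter, _ = _newton(Xk, y, ridge=penalty)
    else:
        beta, dev, converged, n_iter, diverged = _newton(Xk, y, ridge=0.0)
        if len(beta) > 1 and np.max(np.abs(beta[1:])) > _MAX_ABS_COEF:
            diverged = True      # "converged" onto a separating hyperplane
        if diverged or not converged:
            fallback = True
            beta, dev, converged, n_iter, _ = _newton(
                Xk, y, ridge=RIDGE_FALLBACK_WEIGHT)

    coef = np.zeros(X.shape[1])
    coef[keep] = beta[1:]
    prob = _expit(beta[0] + Xk @ beta[1:])
    return LogisticFit(
        coefficients=coef,
        intercept=float(beta[0]),
        deviance=dev,
        converged=bool(converged),
        penalized_fallback=fallback,
        fitted_probabilities=prob,
        dropped=dropped,
        n_iter=n_iter,
    )


def likelihood_ratio_p(X, y, full_cols: list[int], reduced_cols: list[int]) -> float:
    """LRT p-value for the terms in ``full_cols`` \\ ``reduced_cols``.

    Both models are refit; if either requires the ridge fallback, both are
    refit under the same ridge weight so the deviance difference compares
    like with like.
    """
    X = np.asarray(X, dtype=float)
    df = len(full_cols) - len(reduced_cols)
    if df <= 0:
        raise CohortError("full model must strictly extend the reduced model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_full = fit_logistic(X[:, full_cols], y)
        fit_red = fit_logistic(X[:, reduced_cols], y)
        if fit_full.penalized_fallback or fit_red.penalized_fallback:
            w = RIDGE_FALLBACK_WEIGHT
            fit_full = fit_logistic(X[:, full_cols], y, penalty=w)
            fit_red = fit_logistic(X[:, reduced_cols], y, penalty=w)
    stat = max(fit_red.deviance - fit_full.deviance, 0.0)
    return float(stats.chi2.sf(stat, df))


@dataclass
class SignatureModel:
    """Result of stepwise selection: the signature and how it was reached."""

    mirna_ids: list[str]            # selected, in order of entry
    fit: LogisticFit                # final model over the selected predictors
    trace: list[dict]               # steps: {step, action, term, p}
    candidate_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "selected": list(self.mirna_ids),
            "intercept": self.fit.intercept,
            "coefficients": {m: float(c) for m, c in
                             zip(self.mirna_ids, self.fit.coefficients)},
            "deviance": self.fit.deviance,
            "penalized_fallback": self.fit.penalized_fallback,
            "trace": list(self.trace),
            "candidates": list(self.candidate_ids),
        }


def stepwise_select(
    candidates,
    y,
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
    candidate_ids: list[str] | None = None,
) -> SignatureModel:
    """Forward–backward stepwise logistic selection over candidate miRNAs.

    Parameters
    ----------
    candidates : ExpressionMatrix or array of shape (n_samples, n_candidates)
        Candidate predictors.  An ExpressionMatrix contributes its −ΔCt
        values (higher = more expressed) with its assay names.
    y : binary labels (case=1 / control=0)
    alpha_enter, alpha_remove : float
        Largest acceptable LRT p to add a term; smallest to keep one.
    candidate_ids : list of str, optional
        Names for plain-array input; defaults to ``cand000`` style.
    """
    if isinstance(candidates, ExpressionMatrix):
        X = candidates.minus_delta_ct.T
        ids = list(candidates.mirna_ids)
    else:
        X = np.asarray(candidates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        ids = (list(candidate_ids) if candidate_ids is not None
               else [f"cand{j:03d}" for j in range(X.shape[1])])
    y = np.asarray(y, dtype=float)

    included: list[int] = []
    trace: list[dict] = []
    seen = set()
    step = 0
    if X.shape[1] > 0:
        while True:
            changed = False
            # forward: candidate with the smallest add-LRT p
            best_j, best_p = None, None
            for j in range(X.shape[1]):
                if j in included:
                    continue
                p = likelihood_ratio_p(X, y, included + [j], included)
                if best_p is None or p < best_p:
                    best_j, best_p = j, p
            if best_j is not None and best_p <= alpha_enter:
                included.append(best_j)
                step += 1
                trace.append({"step": step, "action": "add",
                              "term": ids[best_j], "p": float(best_p)})
                changed = True
                # backward: remove worst included term while p > alpha_remove
                while len(included) > 1:
                    worst_j, worst_p = None, None
                    for j in included:
                        rest = [k for k in included if k != j]
                        p = likelihood_ratio_p(X, y, included, rest)
                        if worst_p is None or p > worst_p:
                            worst_j, worst_p = j, p
                    if worst_p is not None and worst_p > alpha_remove:
                        included.remove(worst_j)
                        step += 1
                        trace.append({"step": step, "action": "remove",
                                      "term": ids[worst_j], "p": float(worst_p)})
                    else:
                        break
            key = frozenset(included)
            if not changed or key in seen:
                break
            seen.add(key)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = fit_logistic(X[:, included] if included else np.empty((len(y), 0)), y)
    return SignatureModel(
        mirna_ids=[ids[j] for j in included],
        fit=final,
        trace=trace,
        candidate_ids=ids,
    )
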