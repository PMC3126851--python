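"""Classifier evaluation: LOOCV accuracy, Mann–Whitney AUC, confounder-score
adjustment, and two resampling null distributions.

Two complementary nulls probe the signature's discriminating performance:

* **Label permutation** — keep the signature's features, permute the
  case/control status, and record the resulting AUC.  The observed AUC's
  exceedance count over the null sample gives the permutation significance
  level (reported "< 1/n_perm" when no permuted AUC exceeds it).
* **Random-subset draws** — keep the true status, draw k miRNAs at random
  from the retained pool, fit, and record the *apparent* (training) AUC.
  This characterizes the optimism of a k-predictor model fitted and
  evaluated on the same samples; a genuine signature must beat this band,
  not just 0.5.

Confounder adjustment follows the confounder-score approach: the linear
predictor of a logistic regression of case status on age, sex, education
and smoking enters the model as a single extra covariate, preserving
degrees of freedom at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .cohort import CONFOUNDERS, CohortError, ExpressionMatrix, SampleTable
from .signature import LogisticFit, fit_logistic

SVM_COST = 1.0           # margin-cost constant of the linear-kernel SVM
DEFAULT_CUTOFF = 0.5     # probability cutoff for the "raw accuracy rate"


def auc(scores, y) -> float:
    """Mann–Whitney AUC: P(case score > control score), ties counted half.

    Computed from midranks, which is algebraically identical to brute-force
    pair counting with the 0.5 tie convention.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    case = scores[y == 1]
    ctrl = scores[y == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise CohortError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    rank_sum = ranks[y == 1].sum()
    u = rank_sum - len(case) * (len(case) + 1) / 2.0
    return float(u / (len(case) * len(ctrl)))


def confounder_score(samples: SampleTable, y=None) -> np.ndarray:
    """Miettinen-style confounder score.

    Fits a logistic regression of case status on age, sex, education and
    smoking and returns each sample's linear predictor.  Zero-variance
    confounders are dropped (with a warning) inside the fit.
    """
    y = samples.labels() if y is None else np.asarray(y)
    design = samples.confounder_matrix()
    X = design[CONFOUNDERS].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_logistic(X, y)
    if fit.dropped:
        warnings.warn(
            f"constant confounder(s) dropped from score: "
            f"{[CONFOUNDERS[j] for j in fit.dropped]}")
    score = fit.linear_predictor(X)
    if np.ptp(score) == 0:
        warnings.warn("confounder score has zero variance; adjustment is a no-op")
    return score


@dataclass
class CVResult:
    """Out-of-fold scores and accuracy from leave-one-out cross-validation."""

    scores: np.ndarray          # per-sample out-of-fold probability / decision value
    predictions: np.ndarray     # 0/1 class calls at the cutoff
    accuracy: float
    classifier: str             # "logistic" | "svm_linear"
    adjusted: bool
    cutoff: float


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise CohortError("X and y have different numbers of samples")
    return X, y


def loocv(
    X,
    y,
    classifier: str = "logistic",
    adjust=None,
    cutoff: float = DEFAULT_CUTOFF,
) -> CVResult:
    """Leave-one-out cross-validation of the signature classifier.

    Each sample is scored by a model fitted on the remaining n−1 samples.
    ``adjust`` is an optional per-sample confounder score entered as one
    extra covariate.  For the linear-kernel SVM, features are z-scored with
    the training fold's mean/SD and the decision value is the score (class
    calls threshold at 0); for logistic regression the score is the
    predicted probability, thresholded at ``cutoff``.
    """
    X, y = _check_xy(X, y)
    if adjust is not None:
        adjust = np.asarray(adjust, dtype=float)
        if np.ptp(adjust) > 0:        # constant score carries no information
            X = np.column_stack([X, adjust])
    n = len(y)
    if n < 4 or (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise CohortError("need n >= 4 with >= 2 samples per class")
    if classifier not in ("logistic", "svm_linear"):
        raise CohortError(f"unknown classifier {classifier!r}")

    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if len(np.unique(y_tr)) < 2:
            raise CohortError("training fold with a single class")
        if classifier == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_logistic(X_tr, y_tr)
            scores[i] = fit.predict_proba(X[i:i + 1])[0]
        else:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="linear", C=SVM_COST)
            clf.fit((X_tr - mu) / sd, y_tr)
            scores[i] = clf.decision_function((X[i:i + 1] - mu) / sd)[0]

    threshold = cutoff if classifier == "logistic" else 0.0
    predictions = (scores > threshold).astype(int)
    return CVResult(
        scores=scores,
        predictions=predictions,
        accuracy=float((predictions == y).mean()),
        classifier=classifier,
        adjusted=adjust is not None,
        cutoff=threshold,
    )


@dataclass
class NullDistribution:
    """A resampled AUC null sample with its summary."""

    observed_auc: float
    null_aucs: np.ndarray
    n_resamples: int
    exceed_count: int
    p_value: float | None
    p_report: str
    mean: float
    sd: float
    scheme: str                  # "label_perm" | "subset_draw"
    seed: int | None
    adjusted: bool
    k: int | None = None
    refit: bool = True

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "observed_auc": self.observed_auc,
            "n_resamples": self.n_resamples,
            "exceed_count": self.exceed_count,
            "p_value": self.p_value,
            "p_report": self.p_report,
            "null_mean": self.mean,
            "null_sd": self.sd,
            "adjusted": self.adjusted,
            "k": self.k,
            "seed": self.seed,
        }


def _full_fit_scores(X, y, samples: SampleTable | None, adjusted: bool) -> np.ndarray:
    """Fitted probabilities of the (optionally adjusted) full-data logistic."""
    if adjusted:
        if samples is None:
            raise CohortError("adjusted models need the sample table")
        score = confounder_score(samples, y)
        X = np.column_stack([X, score]) if np.ptp(score) > 0 else X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_logistic(X, y)
    return fit.fitted_probabilities


def full_fit_auc(X, y, samples: SampleTable | None = None,
                 adjusted: bool = False) -> float:
    """Apparent AUC of the logistic model fitted and evaluated on all data."""
    X, y = _check_xy(X, y)
    return auc(_full_fit_scores(X, y, samples, adjusted), y)


def label_permutation_test(
    X_signature,
    y,
    samples: SampleTable | None = None,
    n_perm: int = 10000,
    adjusted: bool = False,
    seed: int | None = None,
    refit: bool = True,
) -> NullDistribution:
    """Permutation significance of the signature's AUC.

    The signature's features are kept fixed while the disease status is
    permuted ``n_perm`` times within the analysis set.  With ``refit``
    (default) each permutation refits the (adjusted) logistic on the
    permuted labels and records its apparent AUC — the same procedure that
    produced the observed AUC, so observed and null values are exchangeable
    under the null.  With ``refit=False`` the fitted scores are frozen and
    only the labels move; the null is then centred at 0.5 exactly.

    The significance level is the count of permuted AUCs strictly exceeding
    the observed one, over ``n_perm``; when the count is zero it is reported
    as "< 1/n_perm".
    """
    if n_perm < 1:
        raise CohortError("n_perm must be >= 1")
    X, y = _check_xy(X_signature, y)
    rng = np.random.default_rng(seed)
    observed_scores = _full_fit_scores(X, y, samples, adjusted)
    observed = auc(observed_scores, y)

    null_aucs = np.empty(n_perm)
    for b in range(n_perm):
        y_p = rng.permutation(y)
        if refit:
            null_aucs[b] = auc(_full_fit_scores(X, y_p, samples, adjusted), y_p)
        else:
            null_aucs[b] = auc(observed_scores, y_p)

    exceed = int((null_aucs > observed).sum())
    p = exceed / n_perm
    p_report = f"< {1.0 / n_perm:g}" if exceed == 0 else f"{p:g}"
    return NullDistribution(
        observed_auc=observed, null_aucs=null_aucs, n_resamples=n_perm,
        exceed_count=exceed, p_value=p, p_report=p_report,
        mean=float(null_aucs.mean()), sd=float(null_aucs.std(ddof=1)),
        scheme="label_perm", seed=seed, adjusted=adjusted, refit=refit,
    )


def subset_draw_null(
    expr_retained,
    y,
    samples: SampleTable | None = None,
    k: int = 7,
    n_draws: int = 10000,
    adjusted: bool = False,
    seed: int | None = None,
    observed_auc: float | None = None,
) -> NullDistribution:
    """Apparent-AUC null from random k-miRNA subsets of the retained pool.

    Keeps the true disease status; each draw selects k distinct miRNAs
    uniformly from the pool, fits the (adjusted) logistic on all samples and
    records the apparent AUC.  The mean of this distribution measures the
    overfitting optimism of a k-predictor model at this sample size; the
    exceedance count of the observed signature AUC (when supplied) is its
    significance against "any random k miRNAs would do".
    """
    if isinstance(expr_retained, ExpressionMatrix):
        pool = expr_retained.minus_delta_ct.T
    else:
        pool = np.asarray(expr_retained, dtype=float)
    pool, y = _check_xy(pool, y)
    m = pool.shape[1]
    if not 1 <= k <= m:
        raise CohortError(f"k={k} outside pool of {m} miRNAs")
    rng = np.random.default_rng(seed)

    adj_col = None
    if adjusted:
        if samples is None:
            raise CohortError("adjusted models need the sample table")
        score = confounder_score(samples, y)
        if np.ptp(score) > 0:
            adj_col = score

    null_aucs = np.empty(n_draws)
    for b in range(n_draws):
        cols = rng.choice(m, size=k, replace=False)
        X = pool[:, cols]
        if adj_col is not None:
            X = np.column_stack([X, adj_col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(X, y)
        null_aucs[b] = auc(fit.fitted_probabilities, y)

    if observed_auc is None:
        exceed, p, p_report = 0, None, "n/a (no observed AUC supplied)"
    else:
        exceed = int((null_aucs > observed_auc).sum())
        p = exceed / n_draws
        p_report = f"< {1.0 / n_draws:g}" if exceed == 0 else f"{p:g}"
    return NullDistribution(
        observed_auc=float("nan") if observed_auc is None else observed_auc,
        null_aucs=null_aucs, n_resamples=n_draws, exceed_count=exceed,
        p_value=p, p_report=p_report,
        mean=float(null_aucs.mean()),
        sd=float(null_aucs.std(ddof=1)) if n_draws > 1 else 0.0,
        scheme="subset_draw", seed=seed, adjusted=adjusted, k=k,
    )
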