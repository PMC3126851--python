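"""Correlation of signature expression with clinical and neurocognitive
phenotypes, plus the signal-detection indices of the Continuous Performance
Test.

Learning- and testing-set samples are profiled on different platforms
(array card vs single-assay qRT-PCR), so their −ΔCt values are not directly
poolable.  Each miRNA's −ΔCt is therefore standardized to mean 0 / SD 1
*within each set* before the sets are concatenated; any per-set affine shift
(the platform effect) cancels, and Spearman correlations — being rank
based — are untouched by the per-set rescaling.

Symptom and ERP instruments (PANSS, MMN, P50) are residualized on age, sex
and education before correlation; the performance-based CPT and WCST scores
are correlated as-is.  Each instrument is correlated over the subjects that
completed it (pairwise-complete deletion), so n varies by instrument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, ExpressionMatrix, SampleTable

#: p-value tiers used to mark the correlation report
SIGNIFICANCE_TIERS = ((0.006, "***"), (0.01, "**"), (0.05, "*"))

#: instrument prefixes residualized on age/sex/education before correlation
ADJUSTED_PREFIXES = ("panss", "mmn", "p50")
ADJUST_COVARIATES = ["age", "sex", "education"]


def standardize_and_pool(expr: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Z-score each miRNA's −ΔCt within each analysis set, then concatenate.

    Returns a samples × miRNAs DataFrame in the input sample order.  A miRNA
    with zero variance inside a set cannot be standardized there; this
    raises an error naming the miRNA.
    """
    meta = samples.frame.loc[list(expr.sample_ids)]
    x = expr.minus_delta_ct  # (mirna, sample)
    out = np.empty_like(x, dtype=float)
    for analysis_set in sorted(set(meta["set"])):
        cols = (meta["set"] == analysis_set).to_numpy()
        if cols.sum() < 2:
            raise CohortError(f"set {analysis_set!r} has fewer than 2 samples")
        block = x[:, cols]
        sd = block.std(axis=1, ddof=0)
        flat = np.where(sd == 0)[0]
        if len(flat):
            raise CohortError(
                f"zero variance in set {analysis_set!r} for miRNA(s): "
                f"{[expr.mirna_ids[i] for i in flat]}")
        out[:, cols] = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out.T, index=expr.sample_ids, columns=expr.mirna_ids)


def adjust_scores(scores, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize scores on covariates by ordinary least squares.

    ``scores`` is a Series or DataFrame indexed like ``covariates``.  Each
    column is regressed (with intercept) on the covariates over its
    complete rows; residuals are returned, missing rows stay missing.
    """
    if isinstance(scores, pd.Series):
        return adjust_scores(scores.to_frame(), covariates).iloc[:, 0]
    cov = covariates.loc[scores.index].to_numpy(dtype=float)
    if np.isnan(cov).any():
        bad = scores.index[np.isnan(cov).any(axis=1)].tolist()
        raise CohortError(f"missing covariate values for: {bad}")
    out = scores.copy().astype(float)
    design = np.column_stack([np.ones(len(cov)), cov])
    for col in scores.columns:
        yv = scores[col].to_numpy(dtype=float)
        ok = ~np.isnan(yv)
        if ok.sum() <= design.shape[1]:
            raise CohortError(
                f"too few complete observations ({ok.sum()}) to adjust {col!r}")
        beta = np.linalg.lstsq(design[ok], yv[ok], rcond=None)[0]
        resid = np.full_like(yv, np.nan)
        resid[ok] = yv[ok] - design[ok] @ beta
        out[col] = resid
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise-complete deletion.

    Midranks for ties; p-value from the t approximation.  Requires ≥ 4
    complete pairs and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise CohortError(f"need >= 4 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CohortError("zero variance in one of the variables")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def tier_marker(p: float) -> str:
    for threshold, marker in SIGNIFICANCE_TIERS:
        if p < threshold:
            return marker
    return ""


def sdt_indices(hit_rate, false_alarm_rate, n_targets, n_nontargets):
    """Signal-detection sensitivity d′ and response criterion ln β.

    d′ = z(H) − z(F) and ln β = (z(F)² − z(H)²)/2 with z the standard-normal
    quantile.  Extreme rates (0 or 1) make z infinite, so they are clamped
    by the 1/(2N) rule: H=1 → 1 − 1/(2·n_targets), H=0 → 1/(2·n_targets),
    and likewise for F with n_nontargets.
    """
    h = float(hit_rate)
    f = float(false_alarm_rate)
    if not (0 <= h <= 1 and 0 <= f <= 1):
        raise CohortError("rates must lie in [0, 1]")

    def clamp(rate, n):
        if rate in (0.0, 1.0):
            if n is None or n <= 0:
                raise CohortError("positive trial count required to clamp extreme rate")
            lo = 1.0 / (2.0 * n)
            return min(max(rate, lo), 1.0 - lo)
        return rate

    zh = stats.norm.ppf(clamp(h, n_targets))
    zf = stats.norm.ppf(clamp(f, n_nontargets))
    d_prime = float(zh - zf)
    ln_beta = float((zf**2 - zh**2) / 2.0)
    return d_prime, ln_beta


def correlation_report(
    pooled_expr: pd.DataFrame,
    clinical: pd.DataFrame,
    samples: SampleTable,
    patients_only: bool = True,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Correlate pooled signature expression with every instrument score.

    Parameters
    ----------
    pooled_expr : DataFrame, samples × miRNAs
        Output of :func:`standardize_and_pool`, typically restricted to the
        signature's miRNAs.
    clinical : DataFrame, samples × scores
        Instrument scores; missing cells mean the subject skipped the
        instrument.
    samples : SampleTable
        Used for the patients-only restriction and the adjustment
        covariates.
    patients_only : bool
        Restrict to cases (clinical correlates of the disease are defined
        within patients).

    Returns a long-format report with one row per (score, miRNA): Spearman
    rho, p, the number of complete pairs, and the tier marker ('' / * / **
    / ***).  Scores from age/sex/education-adjusted instruments are
    residualized first.  Pairs with fewer than ``min_pairs`` complete
    observations are skipped.
    """
    ids = [s for s in pooled_expr.index if s in clinical.index]
    meta = samples.frame.loc[ids]
    if patients_only:
        ids = [s for s in ids if meta.loc[s, "group"] == "case"]
    expr = pooled_expr.loc[ids]
    clin = clinical.loc[ids]

    cov = samples.confounder_matrix(ids)[ADJUST_COVARIATES]
    adjusted_cols = [c for c in clin.columns
                     if c.split("_")[0] in ADJUSTED_PREFIXES]
    if adjusted_cols:
        clin = clin.copy()
        clin[adjusted_cols] = adjust_scores(clin[adjusted_cols], cov)

    rows = []
    for score_name in clin.columns:
        for mirna in expr.columns:
            x = expr[mirna].to_numpy(dtype=float)
            yv = clin[score_name].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(yv))
            if ok.sum() < min_pairs or np.ptp(yv[ok]) == 0 or np.ptp(x[ok]) == 0:
                continue
            rho, p = spearman(x, yv)
            rows.append({"score": score_name, "mirna_id": mirna,
                         "rho": rho, "p": p, "n": int(ok.sum()),
                         "tier": tier_marker(p),
                         "adjusted": score_name in adjusted_cols})
    return pd.DataFrame(rows)


def report_to_table(report: pd.DataFrame, alpha: float | None = 0.05) -> pd.DataFrame:
    """Pivot the long report into a scores × miRNAs display table.

    Cells show rho with the tier marker appended; with ``alpha`` set, cells
    with p ≥ alpha are blanked (the conventional presentation).  Pass
    ``alpha=None`` for the full unfiltered matrix.
    """
    if report.empty:
        return pd.DataFrame()
    disp = report.copy()
    if alpha is not None:
        disp = disp[disp["p"] < alpha]
    disp["cell"] = disp.apply(lambda r: f"{r.rho:.2f}{r.tier}", axis=1)
    return disp.pivot_table(index="score", columns="mirna_id", values="cell",
                            aggfunc="first").fillna("")
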