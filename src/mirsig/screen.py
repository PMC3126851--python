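"""Differential-expression screen: detectability filter, Wilcoxon rank-sum
test, and signed fold change.

The screen works on ΔCt values; the Wilcoxon rank-sum test is invariant to
the monotone map ΔCt → 2^(−ΔCt), so testing on ΔCt is equivalent to testing
on relative expression.  Fold change follows the signed qPCR convention:
the case/control expression ratio r = 2^(mean ΔCt_control − mean ΔCt_case)
is reported as r when r ≥ 1 and as −1/r otherwise, so −1.4 means 1.4-fold
lower in cases.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, CtMatrix, ExpressionMatrix, SampleTable

DETECT_THRESHOLD = 0.30
SCREEN_ALPHA = 0.05


def detectability_filter(
    ct: CtMatrix,
    samples: SampleTable,
    threshold: float = DETECT_THRESHOLD,
) -> tuple[list[str], pd.DataFrame]:
    """Retain assays detected in ≥ ``threshold`` of cases OR of controls.

    The endogenous-control assay is excluded from the candidate list.
    Returns the retained assay names and a per-assay table of detected
    fractions with the ``passed_detect`` flag.
    """
    meta = samples.frame.loc[list(ct.sample_ids)]
    case_cols = (meta["group"] == "case").to_numpy()
    ctrl_cols = (meta["group"] == "control").to_numpy()
    if case_cols.sum() == 0 or ctrl_cols.sum() == 0:
        raise CohortError("both groups must be nonempty for the detectability filter")

    rows = []
    retained = []
    for i, mid in enumerate(ct.mirna_ids):
        if mid == ct.control_id:
            continue
        frac_case = ct.detected[i, case_cols].mean()
        frac_ctrl = ct.detected[i, ctrl_cols].mean()
        passed = bool(frac_case >= threshold or frac_ctrl >= threshold)
        rows.append({"mirna_id": mid, "detect_frac_case": frac_case,
                     "detect_frac_control": frac_ctrl, "passed_detect": passed})
        if passed:
            retained.append(mid)
    return retained, pd.DataFrame(rows).set_index("mirna_id")


def wilcoxon_two_sided(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Midranks handle ties.  With ``method="auto"`` the null distribution is
    enumerated exactly when both groups have ≤ 10 observations and there are
    no ties across the pooled sample; otherwise the normal approximation
    with tie and continuity correction is used.  ``method`` may be forced to
    "exact" or "asymptotic".

    Returns the Mann–Whitney U statistic for the first sample and the
    two-sided p-value.  Identical constant samples yield p = 1.0 with a
    warning (every rank assignment is equally extreme).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise CohortError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; rank test is uninformative")
        return len(x) * len(y) / 2.0, 1.0
    if method == "auto":
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fold_change(delta_ct_case, delta_ct_control) -> float:
    """Signed case/control fold change from group-mean ΔCt.

    r = 2^(mean ΔCt_control − mean ΔCt_case) is the ratio of geometric-mean
    relative expressions (the standard ΔΔCt convention).  Returned as r when
    r ≥ 1, else −1/r (negative = lower expression in cases).
    """
    case = np.asarray(delta_ct_case, dtype=float)
    ctrl = np.asarray(delta_ct_control, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise CohortError("both groups must be nonempty")
    r = float(np.exp2(np.nanmean(ctrl) - np.nanmean(case)))
    return r if r >= 1.0 else -1.0 / r


def run_screen(
    expr: ExpressionMatrix,
    samples: SampleTable,
    ct: CtMatrix | None = None,
    detect_threshold: float = DETECT_THRESHOLD,
    alpha: float = SCREEN_ALPHA,
    method: str = "auto",
    drop_censored: bool = False,
) -> pd.DataFrame:
    """Full screen: detectability filter, per-miRNA rank test, fold change.

    When ``ct`` is given, detected fractions come from its flags; otherwise
    the expression matrix's ``imputed`` flags serve (imputed = undetected).
    With ``drop_censored`` the rank test excludes censoring-imputed cells
    (unequal per-group n) instead of keeping them tied at the detection
    limit; the default keeps them, which preserves n and the censoring
    information.

    Returns a per-assay table: detected fractions, two-sided p, signed fold
    change, ``passed_detect`` and ``passed_alpha`` (significant among
    retained).  Assays failing the detectability filter carry NaN p-values.
    """
    meta = samples.frame.loc[list(expr.sample_ids)]
    case_cols = (meta["group"] == "case").to_numpy()
    ctrl_cols = (meta["group"] == "control").to_numpy()
    if case_cols.sum() == 0 or ctrl_cols.sum() == 0:
        raise CohortError("both groups must be nonempty")

    if ct is not None:
        fractions = detectability_filter(ct, samples, detect_threshold)[1]
        fractions = fractions.loc[expr.mirna_ids]
    else:
        det = ~expr.imputed
        fractions = pd.DataFrame({
            "detect_frac_case": det[:, case_cols].mean(axis=1),
            "detect_frac_control": det[:, ctrl_cols].mean(axis=1),
        }, index=expr.mirna_ids)
        fractions["passed_detect"] = (
            (fractions["detect_frac_case"] >= detect_threshold)
            | (fractions["detect_frac_control"] >= detect_threshold))

    rows = []
    for i, mid in enumerate(expr.mirna_ids):
        rec = {"mirna_id": mid,
               "detect_frac_case": fractions.loc[mid, "detect_frac_case"],
               "detect_frac_control": fractions.loc[mid, "detect_frac_control"],
               "passed_detect": bool(fractions.loc[mid, "passed_detect"]),
               "p_value": np.nan, "fold_change": np.nan, "passed_alpha": False}
        if rec["passed_detect"]:
            keep = ~expr.imputed[i] if drop_censored else np.ones(len(expr.sample_ids), bool)
            xs = expr.delta_ct[i, case_cols & keep]
            ys = expr.delta_ct[i, ctrl_cols & keep]
            if len(xs) >= 2 and len(ys) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = wilcoxon_two_sided(xs, ys, method=method)
                rec["p_value"] = p
                rec["fold_change"] = fold_change(xs, ys)
                rec["passed_alpha"] = bool(p < alpha)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("mirna_id")
    return out


def significant_mirnas(screen_table: pd.DataFrame) -> list[str]:
    """Assay names passing both the detectability filter and the α screen,
    ordered by ascending p-value (the candidate order fed to selection)."""
    sig = screen_table[screen_table["passed_alpha"]]
    return list(sig.sort_values("p_value").index)
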