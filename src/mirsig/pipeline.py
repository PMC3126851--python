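"""End-to-end orchestration of the two-stage discovery design.

Stage 1 (learning set): detectability filter → Wilcoxon screen → stepwise
logistic selection → LOOCV accuracies, apparent AUC, label-permutation and
random-subset nulls.  Stage 2 (testing set): the signature fixed in stage 1
is re-evaluated on independent samples, either by refitting its logistic
coefficients there (default — the testing set's own permutation
significance is then well defined) or by freezing the learning-set
coefficients and scoring the testing samples with them.

Every stochastic step derives its own seed from the run seed and a stage
label, so the run report is reproducible and each null distribution carries
the seed that made it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort import (
    DEFAULT_CONTROL_ID,
    DEFAULT_MAX_CYCLES,
    CohortError,
    CtMatrix,
    ExpressionMatrix,
    SampleTable,
    normalize_delta_ct,
    read_clinical_table,
    read_ct_table,
    read_sample_table,
)
from .evaluate import (
    auc,
    confounder_score,
    full_fit_auc,
    label_permutation_test,
    loocv,
    subset_draw_null,
)
from .phenotype import correlation_report, standardize_and_pool
from .screen import run_screen, significant_mirnas
from .signature import stepwise_select

log = logging.getLogger("mirsig")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_DEGENERATE = 3


@dataclass
class PipelineConfig:
    """Parameter registry for a full two-stage run."""

    seed: int
    ct_path: str | None = None
    samples_path: str | None = None
    clinical_path: str | None = None
    output_dir: str | None = None
    control_id: str = DEFAULT_CONTROL_ID
    max_cycles: float = DEFAULT_MAX_CYCLES
    impute_censored: bool = True
    detect_threshold: float = 0.30
    screen_alpha: float = 0.05
    screen_method: str = "auto"
    alpha_enter: float = 0.10
    alpha_remove: float = 0.15
    classifiers: tuple[str, ...] = ("logistic", "svm_linear")
    cutoff: float = 0.5
    adjust: bool = True              # also compute confounder-adjusted variants
    n_perm: int = 10000
    subset_k: tuple[int, ...] = (7,)
    n_draws: int = 10000
    testing_mode: str = "refit"      # "refit" | "frozen"

    def __post_init__(self) -> None:
        for name, value, lo, hi in [
            ("detect_threshold", self.detect_threshold, 0.0, 1.0),
            ("screen_alpha", self.screen_alpha, 0.0, 1.0),
            ("alpha_enter", self.alpha_enter, 0.0, 1.0),
            ("alpha_remove", self.alpha_remove, 0.0, 1.0),
            ("cutoff", self.cutoff, 0.0, 1.0),
        ]:
            if not lo <= value <= hi:
                raise CohortError(f"{name}={value} outside [{lo}, {hi}]")
        if self.testing_mode not in ("refit", "frozen"):
            raise CohortError(f"unknown testing_mode {self.testing_mode!r}")
        if self.seed is None:
            raise CohortError("a run seed is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("classifiers", "subset_k"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        d["subset_k"] = list(self.subset_k)
        return d


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage sub-seed (< 2^31) from the run seed and a label."""
    seq = np.random.SeedSequence(entropy=int(seed),
                                 spawn_key=(zlib.crc32(label.encode()),))
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def rank_profile(expr: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Expression-rank matrix for heatmap export.

    Within each miRNA, expression levels (−ΔCt) are converted to midranks
    across the pooled samples.  Columns are arranged in two blocks —
    controls first, then cases — and within each block samples are ordered
    by their mean rank over the profiled miRNAs, which makes the
    between-group gradient visible.  Row order follows the input.
    """
    meta = samples.frame.loc[list(expr.sample_ids)]
    ranks = np.apply_along_axis(stats.rankdata, 1, expr.minus_delta_ct)
    frame = pd.DataFrame(ranks, index=expr.mirna_ids, columns=expr.sample_ids)
    ordered = []
    for group in ("control", "case"):
        ids = [s for s, g in zip(expr.sample_ids, meta["group"]) if g == group]
        ids.sort(key=lambda s: (frame[s].mean(), s))
        ordered += ids
    return frame[ordered]


def _evaluate_set(cfg, expr_sig, samples_set, label, frozen_fit=None):
    """All evaluation outputs for one analysis set.

    ``frozen_fit`` scores the set with coefficients fitted elsewhere
    (testing_mode="frozen"); otherwise models are (re)fitted on this set.
    """
    X = expr_sig.minus_delta_ct.T
    y = samples_set.labels(list(expr_sig.sample_ids))
    out: dict = {"n_case": int(y.sum()), "n_control": int(len(y) - y.sum())}

    variants = [("raw", False)] + ([("adjusted", True)] if cfg.adjust else [])
    if frozen_fit is not None:
        scores = frozen_fit.predict_proba(X)
        out["mode"] = "frozen"
        out["accuracy"] = {"logistic": {
            "raw": float(((scores > cfg.cutoff).astype(int) == y).mean())}}
        out["auc_full_fit"] = {"raw": auc(scores, y)}
        perm = label_permutation_test(
            X, y, samples_set, n_perm=cfg.n_perm, adjusted=False,
            seed=derive_seed(cfg.seed, f"perm:{label}:raw"), refit=False)
        out["label_permutation"] = {"raw": perm.summary()}
        return out

    out["mode"] = "refit"
    out["accuracy"] = {}
    for clf in cfg.classifiers:
        out["accuracy"][clf] = {}
        for name, adj in variants:
            adjust = confounder_score(samples_set, y) if adj else None
            cv = loocv(X, y, classifier=clf, adjust=adjust, cutoff=cfg.cutoff)
            out["accuracy"][clf][name] = cv.accuracy
            if clf == "logistic":
                out.setdefault("auc_loocv", {})[name] = auc(cv.scores, y)
    out["auc_full_fit"] = {}
    out["label_permutation"] = {}
    for name, adj in variants:
        out["auc_full_fit"][name] = full_fit_auc(X, y, samples_set, adjusted=adj)
        perm = label_permutation_test(
            X, y, samples_set, n_perm=cfg.n_perm, adjusted=adj,
            seed=derive_seed(cfg.seed, f"perm:{label}:{name}"))
        out["label_permutation"][name] = perm.summary()
    return out


def run_two_stage(
    config: PipelineConfig,
    ct: CtMatrix | None = None,
    samples: SampleTable | None = None,
    clinical: pd.DataFrame | None = None,
) -> dict:
    """Execute the full two-stage analysis and return the run report.

    Data may be passed in memory or read from the paths in ``config``.
    With ``config.output_dir`` set, stage outputs (screen table, signature
    JSON, rank profiles, evaluation JSON, correlation report) are written
    as TSV/JSON, each sufficient to re-run later stages in isolation.
    """
    cfg = config
    if ct is None:
        if cfg.ct_path is None or cfg.samples_path is None:
            raise CohortError("provide ct+samples in memory or via config paths")
        ct = read_ct_table(cfg.ct_path, cfg.control_id, cfg.max_cycles)
        samples = read_sample_table(cfg.samples_path)
        if cfg.clinical_path:
            clinical = read_clinical_table(cfg.clinical_path)
    assert samples is not None

    report: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "status": "ok",
    }
    sets_present = sorted(set(samples.frame["set"]))
    has_testing = "testing" in sets_present
    if not has_testing:
        log.warning("no testing set present; learning-only run")

    learning = samples.subset("learning")
    ct_learn = ct.select_samples(learning.sample_ids)
    expr = normalize_delta_ct(ct, impute_censored=cfg.impute_censored)
    expr_learn = expr.select_samples(learning.sample_ids)

    # stage 1: screen on the learning set
    screen_table = run_screen(
        expr_learn, learning, ct=ct_learn,
        detect_threshold=cfg.detect_threshold, alpha=cfg.screen_alpha,
        method=cfg.screen_method)
    retained = list(screen_table.index[screen_table["passed_detect"]])
    candidates = significant_mirnas(screen_table)
    report["screen"] = {
        "n_assayed": len(screen_table),
        "n_retained": len(retained),
        "n_significant": len(candidates),
        "alpha": cfg.screen_alpha,
        "significant": candidates,
    }

    if not candidates:
        report["status"] = "no_candidates"
        report["signature"] = {"selected": []}
        log.warning("no miRNA passed the screen; stopping after stage 1")
        _write_outputs(cfg, report, screen_table, None, None, None)
        return report

    signature = stepwise_select(
        expr_learn.subset(candidates), learning.labels(),
        alpha_enter=cfg.alpha_enter, alpha_remove=cfg.alpha_remove)
    report["signature"] = signature.to_dict()
    if not signature.mirna_ids:
        report["status"] = "empty_signature"
        log.warning("stepwise selection retained no miRNA; stopping")
        _write_outputs(cfg, report, screen_table, signature, None, None)
        return report

    # evaluation: learning set
    sig_ids = signature.mirna_ids
    report["evaluation"] = {
        "learning": _evaluate_set(cfg, expr_learn.subset(sig_ids),
                                  learning, "learning")}

    # random-subset optimism null on the learning set's retained pool
    y_learn = learning.labels()
    pool = expr_learn.subset(retained)
    obs = report["evaluation"]["learning"]["auc_full_fit"]["raw"]
    obs_adj = report["evaluation"]["learning"]["auc_full_fit"].get("adjusted")
    report["subset_null"] = {}
    for k in cfg.subset_k:
        entry = {}
        entry["raw"] = subset_draw_null(
            pool, y_learn, learning, k=k, n_draws=cfg.n_draws, adjusted=False,
            seed=derive_seed(cfg.seed, f"subset:{k}:raw"),
            observed_auc=obs).summary()
        if cfg.adjust:
            entry["adjusted"] = subset_draw_null(
                pool, y_learn, learning, k=k, n_draws=cfg.n_draws, adjusted=True,
                seed=derive_seed(cfg.seed, f"subset:{k}:adjusted"),
                observed_auc=obs_adj).summary()
        report["subset_null"][str(k)] = entry

    # stage 2: independent testing set
    corr = None
    if has_testing:
        testing = samples.subset("testing")
        expr_test = expr.select_samples(testing.sample_ids).subset(sig_ids)
        frozen = signature.fit if cfg.testing_mode == "frozen" else None
        report["evaluation"]["testing"] = _evaluate_set(
            cfg, expr_test, testing, "testing", frozen_fit=frozen)

    if clinical is not None:
        pooled = standardize_and_pool(expr.subset(sig_ids), samples)
        corr = correlation_report(pooled, clinical, samples)
        report["phenotype_correlations"] = {
            "n_pairs_tested": int(len(corr)),
            "n_significant_0.05": int((corr["p"] < 0.05).sum()) if len(corr) else 0,
        }

    _write_outputs(cfg, report, screen_table, signature, expr.subset(sig_ids), corr,
                   samples=samples)
    return report


def _write_outputs(cfg, report, screen_table, signature, expr_sig, corr,
                   samples=None) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen_table.to_csv(out / "screen.tsv", sep="\t")
    if signature is not None:
        (out / "signature.json").write_text(
            json.dumps(signature.to_dict(), indent=2, sort_keys=True))
    if expr_sig is not None and samples is not None:
        for analysis_set in sorted(set(samples.frame["set"])):
            sub = samples.subset(analysis_set)
            prof = rank_profile(expr_sig.select_samples(sub.sample_ids), sub)
            prof.to_csv(out / f"rank_profile_{analysis_set}.tsv", sep="\t")
    if corr is not None:
        corr.to_csv(out / "phenotype_correlations.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
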