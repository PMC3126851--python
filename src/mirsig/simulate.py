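"""Seeded synthetic case–control qPCR cohorts.

The generator emulates the data structure the discovery pipeline assumes: a
TaqMan-style panel of several hundred miRNA assays profiled in a learning set
(array platform) and an independent testing set (single-assay qRT-PCR), with

* a per-sample endogenous-control Ct (RNU48-like) drawn once per sample,
* a per-miRNA baseline ΔCt drawn once, with a configurable fraction of
  assays expressed near the detection limit so that only ``detect_fraction``
  of the panel passes the ≥30% detectability rule,
* planted case–control effects specified on the ΔCt scale (cycles); fold
  change = 2^(−ΔΔCt), so ΔΔCt = −1.32 plants a 2.5-fold up-regulation in
  cases and ΔΔCt = +0.49 plants a −1.4-fold (1.4-fold down) effect,
* measurement noise on each well, censoring of reactions beyond the cycle
  limit, a small additive platform shift for the testing set,
* confounder imbalance in the direction typical of schizophrenia cohorts
  (cases: fewer years of education, more smoking), and
* clinical/neurocognitive scores optionally rank-correlated with the
  expression of chosen miRNAs.

Randomness is split into fixed named sub-streams (samples, panel, wells,
clinical) derived from one seed, so e.g. enlarging the panel does not perturb
the sample-level draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_CONTROL_ID,
    DEFAULT_MAX_CYCLES,
    CohortError,
    CtMatrix,
    ExpressionMatrix,
    SampleTable,
)

# sub-stream keys: one RNG per stage of the generator
_STREAM_SAMPLES = 0
_STREAM_PANEL = 1
_STREAM_WELLS = 2
_STREAM_CLINICAL = 3


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design the pipeline targets: a 365-assay
    panel, ~60% detectable, a 30+30 learning set and a 60+30 testing set,
    well noise of 1 cycle on the ΔCt scale.
    """

    seed: int
    n_case_learning: int = 30
    n_control_learning: int = 30
    n_case_testing: int = 60
    n_control_testing: int = 30
    n_mirna: int = 365
    detect_fraction: float = 0.60
    #: (mirna_index, delta_delta_ct in cycles); negative = up in cases
    planted: list[tuple[int, float]] = field(default_factory=list)
    ct_noise_sd: float = 1.0
    control_ct_mean: float = 24.0
    control_ct_sd: float = 0.5
    max_cycles: float = DEFAULT_MAX_CYCLES
    control_id: str = DEFAULT_CONTROL_ID
    #: baseline ΔCt of expressed assays ~ N(mean, sd)
    expressed_delta_ct_mean: float = 6.0
    expressed_delta_ct_sd: float = 2.5
    #: assays beyond the detection limit ~ N(mean, sd); with the default
    #: control Ct of 24 and a 40-cycle limit these sit ~3 cycles past it
    silent_delta_ct_mean: float = 20.0
    silent_delta_ct_sd: float = 1.5
    #: additive cycles applied to testing-set (qRT-PCR) target wells
    platform_shift: float = 0.3
    # confounder model (cases: less education, more smoking, more males)
    age_mean: float = 38.0
    age_sd: float = 9.0
    case_male_p: float = 0.6
    control_male_p: float = 0.5
    case_education_mean: float = 11.5
    control_education_mean: float = 14.0
    education_sd: float = 2.5
    case_smoking_p: float = 0.45
    control_smoking_p: float = 0.20
    #: (score_name, mirna_index, spearman_target)
    clinical_links: list[tuple[str, int, float]] = field(default_factory=list)
    clinical_confounder_weight: float = 0.3
    clinical_missing_p: float = 0.08

    def __post_init__(self) -> None:
        if self.seed is None:
            raise CohortError("seed is mandatory")
        if not 0 < self.detect_fraction <= 1:
            raise CohortError("detect_fraction must be in (0, 1]")
        if len(self.planted) >= self.n_mirna:
            raise CohortError("more planted effects than miRNAs")
        for idx, _ in self.planted:
            if not 0 <= idx < self.n_mirna:
                raise CohortError(f"planted miRNA index out of range: {idx}")

    def rng(self, stream: int) -> np.random.Generator:
        seq = np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        return np.random.default_rng(seq)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def mirna_name(i: int) -> str:
    """Synthetic assay name for panel position ``i``."""
    return f"hsa-miR-sim{i + 1:03d}"


def _sample_block(rng, cfg, group, analysis_set, n, start):
    male_p = cfg.case_male_p if group == "case" else cfg.control_male_p
    edu_mean = (cfg.case_education_mean if group == "case"
                else cfg.control_education_mean)
    smoke_p = cfg.case_smoking_p if group == "case" else cfg.control_smoking_p
    rows = []
    for k in range(n):
        rows.append({
            "sample_id": f"{analysis_set}_{group}_{start + k:03d}",
            "group": group,
            "set": analysis_set,
            "platform": "array" if analysis_set == "learning" else "qrtpcr",
            "age": float(np.round(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18, 70), 1)),
            "sex": "M" if rng.random() < male_p else "F",
            "education": int(np.clip(np.round(rng.normal(edu_mean, cfg.education_sd)), 6, 20)),
            "smoking": "yes" if rng.random() < smoke_p else "no",
        })
    return rows


def generate_cohort(config: SimulationConfig) -> tuple[CtMatrix, SampleTable]:
    """Draw one cohort: a raw Ct matrix (control row included) and metadata.

    Deterministic given ``config.seed``; the same seed yields bit-identical
    output on any platform (all draws go through numpy's PCG64 streams).
    """
    cfg = config
    rng_s = cfg.rng(_STREAM_SAMPLES)
    rng_p = cfg.rng(_STREAM_PANEL)
    rng_w = cfg.rng(_STREAM_WELLS)

    rows = []
    rows += _sample_block(rng_s, cfg, "case", "learning", cfg.n_case_learning, 1)
    rows += _sample_block(rng_s, cfg, "control", "learning", cfg.n_control_learning, 1)
    if cfg.n_case_testing and cfg.n_control_testing:
        rows += _sample_block(rng_s, cfg, "case", "testing", cfg.n_case_testing, 1)
        rows += _sample_block(rng_s, cfg, "control", "testing", cfg.n_control_testing, 1)
    meta = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(meta)
    control_ct = rng_s.normal(cfg.control_ct_mean, cfg.control_ct_sd, size=n_samples)

    # panel-level draws: expressed status and baseline ΔCt, one per assay
    expressed = rng_p.random(cfg.n_mirna) < cfg.detect_fraction
    baseline_expr = rng_p.normal(cfg.expressed_delta_ct_mean,
                                 cfg.expressed_delta_ct_sd, size=cfg.n_mirna)
    baseline_silent = rng_p.normal(cfg.silent_delta_ct_mean,
                                   cfg.silent_delta_ct_sd, size=cfg.n_mirna)
    for idx, _ in cfg.planted:
        expressed[idx] = True  # planted markers must be measurable
    baseline = np.where(expressed, np.maximum(baseline_expr, 1.0), baseline_silent)

    effect = np.zeros(cfg.n_mirna)
    for idx, ddct in cfg.planted:
        effect[idx] = ddct

    is_case = (meta["group"] == "case").to_numpy()
    is_testing = (meta["set"] == "testing").to_numpy()
    noise = rng_w.normal(0.0, cfg.ct_noise_sd, size=(cfg.n_mirna, n_samples))
    ct = (control_ct[None, :] + baseline[:, None]
          + effect[:, None] * is_case[None, :]
          + cfg.platform_shift * is_testing[None, :]
          + noise)
    detected = ct <= cfg.max_cycles

    mirna_ids = [cfg.control_id] + [mirna_name(i) for i in range(cfg.n_mirna)]
    full_ct = np.vstack([control_ct[None, :], ct])
    full_detected = np.vstack([np.ones((1, n_samples), dtype=bool), detected])
    matrix = CtMatrix(
        mirna_ids=mirna_ids,
        sample_ids=list(meta.index),
        ct=full_ct,
        detected=full_detected,
        control_id=cfg.control_id,
        max_cycles=cfg.max_cycles,
    )
    return matrix, SampleTable(meta)


# ---------------------------------------------------------------------------
# Clinical / neurocognitive scores

#: instrument registry: column -> (instrument block, cases_only, kind, loc, scale)
#: kind "rate" squashes the latent score through a logistic so values lie in
#: (0, 1); the transform is monotone, so rank correlations are unaffected.
SCORE_REGISTRY: dict[str, tuple[str, bool, str, float, float]] = {
    "panss_positive": ("panss", True, "linear", 18.0, 5.0),
    "panss_negative": ("panss", True, "linear", 20.0, 6.0),
    "panss_general": ("panss", True, "linear", 38.0, 9.0),
    "cpt_undegraded_dprime": ("cpt", False, "linear", 3.0, 0.8),
    "cpt_undegraded_false_alarm": ("cpt", False, "rate", -2.2, 0.6),
    "cpt_degraded_dprime": ("cpt", False, "linear", 2.2, 0.8),
    "cpt_degraded_lnbeta": ("cpt", False, "linear", 0.4, 0.5),
    "cpt_degraded_false_alarm": ("cpt", False, "rate", -1.8, 0.6),
    "wcst_total_errors": ("wcst", False, "linear", 40.0, 18.0),
    "wcst_perseverative_responses": ("wcst", False, "linear", 25.0, 12.0),
    "wcst_perseverative_errors": ("wcst", False, "linear", 22.0, 10.0),
    "wcst_nonperseverative_errors": ("wcst", False, "linear", 18.0, 9.0),
    "wcst_categories_achieved": ("wcst", False, "linear", 4.5, 1.6),
    "wcst_conceptual_level": ("wcst", False, "linear", 55.0, 15.0),
    "mmn_cz": ("mmn", False, "linear", -2.5, 1.0),
    "mmn_fcz": ("mmn", False, "linear", -2.3, 1.0),
    "p50_ratio": ("p50", False, "linear", 0.6, 0.25),
}


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def generate_clinical(
    samples: SampleTable,
    expr: ExpressionMatrix,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate instrument scores, optionally linked to miRNA expression.

    Every column in :data:`SCORE_REGISTRY` is produced.  For a link
    (name, mirna_index, spearman_target) the score is a linear mix of the
    target miRNA's −ΔCt, a confounder component (age/education), and noise.
    The mixing weight is calibrated through the bivariate-normal relation
    ρ_Pearson = 2·sin(π·ρ_Spearman/6), so the realized rank correlation
    concentrates around ``spearman_target``.  Unlinked scores are noise with
    the same confounder component.  Whole instrument blocks go missing per
    subject with probability ``clinical_missing_p`` (as in real batteries
    where a subject skips a test), and PANSS applies to cases only.
    """
    cfg = config
    links: dict[str, tuple[int, float]] = {}
    for name, idx, rho_s in cfg.clinical_links:
        if name not in SCORE_REGISTRY:
            raise CohortError(
                f"unknown score name {name!r}; known: {sorted(SCORE_REGISTRY)}")
        if not 0 <= idx < len(expr.mirna_ids):
            raise CohortError(f"clinical link miRNA index out of range: {idx}")
        if not -1 < rho_s < 1:
            raise CohortError("spearman_target must be in (-1, 1)")
        links[name] = (idx, rho_s)

    rng = cfg.rng(_STREAM_CLINICAL)
    meta = samples.frame.loc[list(expr.sample_ids)]
    is_case = (meta["group"] == "case").to_numpy()
    age = pd.to_numeric(meta["age"]).to_numpy(dtype=float)
    edu = pd.to_numeric(meta["education"]).to_numpy(dtype=float)
    z_conf = (_zscore(age) - _zscore(edu)) / np.sqrt(2.0)

    n = len(meta)
    w_c = cfg.clinical_confounder_weight
    out = pd.DataFrame(index=meta.index)
    blocks = sorted({block for block, *_ in SCORE_REGISTRY.values()})
    block_missing = {b: rng.random(n) < cfg.clinical_missing_p for b in blocks}

    for name, (block, cases_only, kind, loc, scale) in SCORE_REGISTRY.items():
        eps = rng.standard_normal(n)
        background = w_c * z_conf + np.sqrt(1.0 - w_c**2) * eps
        if name in links:
            idx, rho_s = links[name]
            rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
            z_mir = _zscore(expr.minus_delta_ct[idx])
            latent = rho_p * z_mir + np.sqrt(1.0 - rho_p**2) * background
        else:
            latent = background
        if kind == "rate":
            value = 1.0 / (1.0 + np.exp(-(loc + scale * latent)))
        else:
            value = loc + scale * latent
        value = np.where(block_missing[block], np.nan, value)
        if cases_only:
            value = np.where(is_case, value, np.nan)
        out[name] = value
    return out


def write_cohort(ct: CtMatrix, samples: SampleTable, directory) -> None:
    """Write the TSV files the reading side consumes (ct.tsv, samples.tsv)."""
    from pathlib import Path

    from .cohort import write_ct_table, write_sample_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ct_table(ct, directory / "ct.tsv")
    write_sample_table(samples, directory / "samples.tsv")
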