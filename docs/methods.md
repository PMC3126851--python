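# Methods

`mirsig` implements the classical two-stage design for discovering a blood
miRNA biomarker signature from qPCR panel data and validating it in an
independent sample. This note records the statistical model at each stage,
the defaults and why they were chosen, what the synthetic cohorts emulate,
and the numerical decisions a maintainer would want spelled out.

## Expression model

qPCR reports a threshold cycle Ct per (assay, sample) well; expression is
log2-linear in −Ct. Normalization against an endogenous small-RNA control
(RNU48 by default) gives

    ΔCt = Ct(miRNA) − Ct(control),   relative expression = 2^(−ΔCt).

−ΔCt is the "expression level" scale used everywhere downstream (higher =
more expressed). Wells that never cross threshold within `max_cycles`
(default 40) cycles are *censored at the detection limit*, not missing at
random. By default such wells are imputed at the limit, ΔCt =
max_cycles − Ct(control), and flagged: rank-based tests tolerate this
because imputed values tie at the extreme of the ordering, and it keeps a
constant n per comparison. `impute_censored=False` leaves them missing
instead; both behaviors are surfaced in the screen output (`imputed`
flags, `drop_censored` option) because the right choice depends on how a
real instrument was thresholded.

## Stage 1: screening

1. **Detectability filter.** An assay is retained if detected in ≥ 30% of
   cases *or* ≥ 30% of controls (threshold configurable). The one-group
   version of the rule keeps markers expressed in only one condition —
   exactly the interesting case — at the cost of admitting some
   half-censored assays.
2. **Wilcoxon rank-sum test**, two-sided, on ΔCt (rank-equivalent to
   testing 2^(−ΔCt)). Midranks for ties; the null is enumerated exactly
   when both groups have ≤ 10 observations and the pooled sample is
   tie-free, otherwise the normal approximation with tie and continuity
   correction is used (`method` forces either). No multiplicity correction
   is applied at this stage by default: the design controls false
   discovery through the independent testing set and the permutation
   nulls, not through per-test adjustment. α = 0.05.
3. **Fold change** is reported from group-mean ΔCt, r = 2^(mean ΔCt_ctrl −
   mean ΔCt_case), i.e. a ratio of geometric-mean expressions (the
   standard ΔΔCt convention), signed: r if r ≥ 1 else −1/r, so −1.4 means
   1.4-fold lower in cases. Geometric rather than arithmetic averaging is
   the natural choice on a log-scale measurement; the ranking of markers
   is unaffected.

## Stage 1: signature selection

Forward–backward stepwise logistic regression over the screen's
significant set, predictors entered as −ΔCt, main effects only:
α-to-enter 0.10, α-to-remove 0.15. Term p-values come from
likelihood-ratio tests (more reliable than Wald at n of tens); Wald-style
selection was deliberately not implemented to keep one well-tested path.
Ties in the entry p break by candidate order (the screen orders candidates
by ascending p), making selection fully deterministic; the trace records
every add/remove with its p so order sensitivity is visible rather than
hidden.

Maximum-likelihood logistic fits use Newton–Raphson with step halving
(tolerance 1e-10 on the deviance, max 60 iterations). With tens of samples
and several strong predictors the MLE frequently diverges (complete or
quasi-complete separation) — especially inside permutation resamples. A
fit is declared separated when a slope exceeds 12 in absolute value (a
log-odds slope that large per unit −ΔCt is far outside anything a finite
MLE produces on this data scale) or Newton fails to converge; it is then
refit with a small ridge penalty on the slopes, 0.5 · 0.05 · ‖β‖², and
flagged `penalized_fallback`. When a likelihood-ratio comparison involves
a separated model, *both* models are refit under the same ridge so the
deviance difference compares like with like. The weight 0.05 is small
enough to leave well-conditioned fits essentially unchanged (verified
against statsmodels in the tests) and large enough to keep separated fits
finite.

A consequence worth knowing: when several planted effects of ~1 cycle
each are present at n = 60, four to five included terms typically separate
the data perfectly, after which no additional term can improve the
likelihood and selection stops. Stepwise signatures here are *shorter*
than the set of true markers — which is the expected behavior of the
procedure, not an implementation artifact (an independent
statsmodels-based stepwise reproduces it).

## Stage 2: evaluation

* **LOOCV.** Each sample is scored by a model fitted on the remaining
  n−1. Logistic scores are probabilities (class call at the 0.5 cutoff);
  the linear-kernel SVM (margin cost C = 1.0) uses decision values (call
  at 0), with features z-scored by the training fold's statistics.
  Accuracy is the fraction of correct calls; the out-of-fold scores also
  give an honest LOOCV AUC.
* **AUC** is the Mann–Whitney estimator — the probability a random case
  outscores a random control, ties counted half — computed from midranks.
* **Confounder adjustment** follows the confounder-score approach: the
  linear predictor of a logistic regression of case status on age, sex,
  education and smoking enters the model as one extra covariate. This
  preserves degrees of freedom at n = 60–90 where entering four covariates
  into every CV fold would not; zero-variance confounders are dropped with
  a warning.
* **Apparent vs honest AUC.** The "global performance" AUC is the
  full-data fitted (apparent) AUC, because the permutation scheme refits
  on full data and exchangeability demands the observed statistic be
  computed the same way. The LOOCV AUC is reported alongside as the
  honest counterpart; both appear in every report, labeled.
* **Label-permutation null.** Disease status is permuted within the
  analysis set (learning and testing handled separately); each permutation
  refits the (adjusted) logistic and records its apparent AUC. The
  significance level is the exceedance count over n_perm, reported
  "< 1/n_perm" at zero. A `refit=False` variant freezes the fitted scores
  and permutes only the labels; its null is centred at exactly 0.5 but its
  p-values are anti-conservative (the scores were fit to the observed
  labels), so the refitting scheme is the default and the frozen scheme is
  reserved for frozen-coefficient evaluation.
* **Random-subset (optimism) null.** Keeping the true labels, k miRNAs
  are drawn uniformly from the retained pool, fitted, and the apparent
  AUC recorded. Its mean (~0.70 at k = 7, n = 60, pure noise) is the
  overfitting optimism a k-predictor model enjoys at this sample size;
  non-decreasing in k. A signature is only credible against this band,
  not against 0.5.
* **Testing set.** Default `refit`: the signature's miRNAs are kept and
  coefficients refit on testing samples, so the testing set has its own
  well-defined permutation significance. `frozen` scores the testing
  samples with learning-set coefficients (frozen-score permutation null);
  both modes exist because published two-stage designs are usually
  ambiguous on this point.

## Phenotype correlation

Learning (array) and testing (single-assay qRT-PCR) expression are pooled
by z-scoring each miRNA's −ΔCt within each set; any per-set affine
platform distortion cancels, and Spearman correlation is invariant to the
within-set monotone rescaling. Symptom and ERP instruments (PANSS, MMN,
P50) are residualized on age, sex and education by OLS before correlation;
performance instruments (CPT, WCST) are not. Correlations are computed
over patients only, pairwise-complete per instrument (so n varies by
instrument block), with three significance tiers marked (0.05 / 0.01 /
0.006); exact p-values are always emitted so no tier interpretation is
forced. CPT signal-detection indices are d′ = z(H) − z(F) and ln β =
(z(F)² − z(H)²)/2, with extreme rates clamped by the 1/(2N) rule.

## Synthetic cohorts

The generator produces the data structure the pipeline assumes, not a
biophysical simulation:

* per-sample control Ct ~ Normal(24, 0.5); per-assay baseline ΔCt drawn
  once — expressed assays ~ Normal(6, 2.5), near-limit assays ~
  Normal(20, 1.5), mixed so that ~60% of a 365-assay panel passes the 30%
  detectability rule (matching a typical mononuclear-leukocyte panel);
* planted case–control effects specified as ΔΔCt in cycles (fold change
  2^(−ΔΔCt); the conventional |FC| 1.4–2.5 range maps to |ΔΔCt|
  0.49–1.32); planted assays are forced into the expressed class;
* well noise Normal(0, 1 cycle) on the ΔCt scale; wells beyond 40 cycles
  are censored; the testing set gets a +0.3-cycle platform shift;
* cohort sizes default to 30+30 learning and 60+30 testing;
* confounders imbalanced in the direction typical of schizophrenia
  case–control samples: cases average ~2.5 fewer years of education,
  smoke more (45% vs 20%), and skew male; age matched by design;
* clinical scores are linear mixes of a target miRNA's −ΔCt, an
  age/education component, and noise, with the miRNA weight set through
  the bivariate-normal relation ρ_Pearson = 2·sin(π·ρ_Spearman/6) so the
  realized rank correlation concentrates on the requested target; rate
  scores pass through a logistic squash (monotone, so ranks are
  untouched); instrument blocks go missing per subject with probability
  0.08 and PANSS applies to cases only.

Randomness is split into named sub-streams (samples / panel / wells /
clinical) off one seed, so enlarging the panel does not perturb
sample-level draws and every run is bit-reproducible.

What the generator does *not* emulate: amplification-efficiency
differences between assays, probe-specific platform biases beyond the
additive shift, correlated miRNA co-regulation, batch effects within a
set, and outlier samples. Tests passing on these cohorts therefore
demonstrate the statistical machinery (calibration, power against planted
effects, null behavior) — they do not certify performance on any real
cohort.

## Problem sizes in the test suite

The suite exercises the study-scale configuration (365 assays, 30+30 and
60+30) for single end-to-end runs, and replicate-based calibration checks
at 40–365 assays with 50–100 replicates, 1,000–2,000 permutations and
2,000–10,000 subset draws — sizes at which the Monte-Carlo error of each
checked quantity is comfortably below the asserted tolerance.

## Known limitations

* The Wilcoxon exact path is limited to ≤ 10 per group without ties;
  beyond that the corrected normal approximation is used (accurate to a
  few percent relative at n = 30/30, verified against a 10^5-resample
  permutation oracle).
* The ridge fallback makes separated fits reproducible but its
  coefficients (and LRT p-values computed under it) depend mildly on the
  fixed weight; the flag is propagated so consumers can tell which
  results leaned on it.
* `standardize_and_pool` requires ≥ 2 samples and nonzero variance per
  set per miRNA; degenerate sets are a hard error rather than a silent
  drop.
* The confounder score is fitted on the same samples it adjusts, as in
  the classical usage; with very few samples per class this can absorb
  outcome signal, which is why raw and adjusted results are always
  reported side by side.
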