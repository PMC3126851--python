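"""Cross-platform pooling, covariate adjustment, Spearman correlation, and
signal-detection indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsig import (
    CohortError,
    ExpressionMatrix,
    SimulationConfig,
    adjust_scores,
    correlation_report,
    generate_clinical,
    generate_cohort,
    normalize_delta_ct,
    sdt_indices,
    spearman,
    standardize_and_pool,
)
from mirsig.phenotype import tier_marker

from conftest import make_sample_table


def two_set_expr(seed=1, shift=3.0, scale=2.0):
    """Same latent signal measured on two 'platforms' differing by an
    affine transform of −ΔCt in the second set."""
    rng = np.random.default_rng(seed)
    learn = make_sample_table(6, 6, "learning", seed=seed)
    test = make_sample_table(5, 5, "testing", seed=seed + 1)
    samples_frame = pd.concat([learn.frame, test.frame])
    from mirsig import SampleTable
    samples = SampleTable(samples_frame)
    latent = rng.normal(size=(3, len(samples_frame)))
    delta = latent.copy()
    is_test = (samples_frame["set"] == "testing").to_numpy()
    delta[:, is_test] = scale * delta[:, is_test] + shift
    expr = ExpressionMatrix(["m0", "m1", "m2"], list(samples_frame.index), delta)
    return expr, samples, latent


class TestStandardizeAndPool:
    def test_per_set_mean_zero_sd_one(self):
        expr, samples, _ = two_set_expr()
        pooled = standardize_and_pool(expr, samples)
        for aset in ("learning", "testing"):
            ids = samples.frame.index[samples.frame["set"] == aset]
            block = pooled.loc[ids]
            assert np.allclose(block.mean(), 0, atol=1e-12)
            assert np.allclose(block.std(ddof=0), 1, atol=1e-12)

    def test_removes_per_set_affine_shift(self):
        """Pooled z-scores recover the shared latent signal despite the
        second platform's affine distortion."""
        expr, samples, latent = two_set_expr()
        pooled = standardize_and_pool(expr, samples)
        for aset in ("learning", "testing"):
            cols = (samples.frame["set"] == aset).to_numpy()
            block_z = pooled.to_numpy().T[:, cols]
            lat = latent[:, cols]
            lat_z = (lat - lat.mean(1, keepdims=True)) / lat.std(1, keepdims=True)
            assert np.allclose(block_z, -lat_z, atol=1e-12)  # z(−ΔCt) = −z(ΔCt)

    def test_zero_variance_names_mirna(self):
        expr, samples, _ = two_set_expr()
        expr.delta_ct[1, :] = 7.0
        with pytest.raises(CohortError, match="m1"):
            standardize_and_pool(expr, samples)

    def test_single_sample_set_rejected(self):
        expr, samples, _ = two_set_expr()
        keep = list(samples.frame.index[samples.frame["set"] == "learning"]) + \
            [samples.frame.index[samples.frame["set"] == "testing"][0]]
        from mirsig import SampleTable
        with pytest.raises(CohortError):
            standardize_and_pool(expr.select_samples(keep),
                                 SampleTable(samples.frame.loc[keep]))


class TestAdjustScores:
    def covariates(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.normal(40, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(12, 3, n),
        }, index=[f"s{i}" for i in range(n)])

    def test_orthogonal_score_left_centered(self):
        cov = pd.DataFrame({"age": [1, -1, 1, -1, 1, -1.0],
                            "sex": [0, 0, 1, 1, 0, 1.0],
                            "education": [2, 2, -2, -2, 0, 0.0]},
                           index=[f"s{i}" for i in range(6)])
        score = pd.Series([1, 1, 1, 1, -2, -2.0], index=cov.index, name="q")
        # orthogonalize score against covariate columns by construction
        resid = adjust_scores(score, cov)
        design = np.column_stack([np.ones(6), cov.to_numpy()])
        beta = np.linalg.lstsq(design, score.to_numpy(), rcond=None)[0]
        assert np.allclose(resid, score.to_numpy() - design @ beta, atol=1e-10)

    def test_exact_linear_function_of_covariate_residuals_to_zero(self):
        cov = self.covariates(10)
        score = pd.Series(2.0 * cov["age"].to_numpy(), index=cov.index)
        resid = adjust_scores(score, cov)
        assert np.allclose(resid, 0, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        cov = self.covariates(5, seed=3)
        rng = np.random.default_rng(4)
        score = pd.Series(rng.normal(size=5), index=cov.index)
        resid = adjust_scores(score, cov)
        design = np.column_stack([np.ones(5), cov.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ score.to_numpy())
        assert np.allclose(resid, score.to_numpy() - design @ beta, atol=1e-10)

    def test_missing_rows_stay_missing(self):
        cov = self.covariates(12)
        vals = np.arange(12, dtype=float)
        vals[3] = np.nan
        resid = adjust_scores(pd.Series(vals, index=cov.index), cov)
        assert np.isnan(resid.iloc[3]) and np.isfinite(resid.drop(resid.index[3])).all()

    def test_too_few_observations_rejected(self):
        cov = self.covariates(4)
        with pytest.raises(CohortError):
            adjust_scores(pd.Series([1.0, 2, 3, 4], index=cov.index), cov)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.9])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        # Σd² = 4, n = 5 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_pairwise_deletion(self):
        x = [1, 2, 3, 4, 5, np.nan]
        y = [2, 1, 4, 3, 5, 7]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(0.8)

    def test_invariance_to_monotone_transform_of_either_argument(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(CohortError):
            spearman([1, 2, 3], [1, 2, 3])            # too few pairs
        with pytest.raises(CohortError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])      # zero variance


class TestSdtIndices:
    def test_symmetric_rates_give_dprime_two(self):
        d, lb = sdt_indices(0.8413447, 0.1586553, 100, 100)
        assert d == pytest.approx(2.0, abs=1e-4)
        assert lb == pytest.approx(0.0, abs=1e-6)

    def test_chance_performance(self):
        d, lb = sdt_indices(0.5, 0.5, 50, 50)
        assert d == 0.0 and lb == 0.0

    def test_extreme_rate_clamped(self):
        d, _ = sdt_indices(1.0, 0.2, 50, 50)
        d_clamped, _ = sdt_indices(0.99, 0.2, 50, 50)
        assert np.isfinite(d) and d == pytest.approx(d_clamped)

    def test_extreme_rate_without_counts_rejected(self):
        with pytest.raises(CohortError):
            sdt_indices(1.0, 0.2, 0, 50)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(CohortError):
            sdt_indices(1.2, 0.2, 50, 50)


class TestCorrelationReport:
    def build(self, rho=0.8, seed=55):
        cfg = SimulationConfig(
            seed=seed, n_mirna=30, clinical_missing_p=0.05,
            clinical_links=[("wcst_total_errors", 0, rho)])
        ct, samples = generate_cohort(cfg)
        expr = normalize_delta_ct(ct)
        clinical = generate_clinical(samples, expr, cfg)
        pooled = standardize_and_pool(expr.subset(expr.mirna_ids[:5]), samples)
        return pooled, clinical, samples

    def test_patients_only_and_varying_n(self):
        pooled, clinical, samples = self.build()
        rep = correlation_report(pooled, clinical, samples)
        n_cases = int((samples.frame["group"] == "case").sum())
        assert (rep["n"] <= n_cases).all()
        assert rep["n"].nunique() > 1        # instruments missing per subject

    def test_linked_pair_found_significant(self):
        pooled, clinical, samples = self.build()
        rep = correlation_report(pooled, clinical, samples)
        row = rep[(rep.score == "wcst_total_errors")
                  & (rep.mirna_id == "hsa-miR-sim001")].iloc[0]
        assert row.rho > 0.5 and row.p < 0.006 and row.tier == "***"

    def test_tier_markers(self):
        assert tier_marker(0.04) == "*"
        assert tier_marker(0.009) == "**"
        assert tier_marker(0.005) == "***"
        assert tier_marker(0.2) == ""

    def test_pooling_invariant_to_per_set_affine_rescaling(self):
        """Correlations computed after pooling must not change if one
        platform's −ΔCt values are affinely rescaled."""
        pooled, clinical, samples = self.build()
        cfg = SimulationConfig(
            seed=55, n_mirna=30, clinical_missing_p=0.05,
            clinical_links=[("wcst_total_errors", 0, 0.8)])
        ct, samples2 = generate_cohort(cfg)
        expr = normalize_delta_ct(ct)
        is_test = (samples2.frame.loc[expr.sample_ids, "set"] == "testing").to_numpy()
        expr.delta_ct[:, is_test] = expr.delta_ct[:, is_test] * 1.7 - 4.0
        pooled2 = standardize_and_pool(expr.subset(expr.mirna_ids[:5]), samples2)
        rep1 = correlation_report(pooled, clinical, samples)
        rep2 = correlation_report(pooled2, clinical, samples2)
        merged = rep1.merge(rep2, on=["score", "mirna_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged["rho_a"], merged["rho_b"], atol=1e-12)
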