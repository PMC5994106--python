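import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sevscan import association, famd, sev, synthetic
from sevscan.errors import ValidationError

from conftest import small_config


# ---------------------------------------------------------------------------
# Fisher's method
# ---------------------------------------------------------------------------

def test_fisher_no_evidence():
    statistic, df, p = association.fisher_combine([1.0, 1.0, 1.0])
    assert statistic == 0.0
    assert df == 6
    assert p == pytest.approx(1.0)


def test_fisher_k1_is_identity():
    _, df, p = association.fisher_combine([0.2])
    assert df == 2
    assert p == pytest.approx(0.2, rel=1e-12)


def test_fisher_three_equal_pvalues_vs_chisquare_oracle():
    statistic, df, p = association.fisher_combine([0.05, 0.05, 0.05])
    assert statistic == pytest.approx(-2 * 3 * math.log(0.05), rel=1e-12)
    assert statistic == pytest.approx(17.974, abs=1e-3)
    assert p == pytest.approx(float(stats.chi2.sf(statistic, 6)), rel=1e-12)


def test_fisher_rejects_zero_pvalues():
    with pytest.raises(ValidationError, match="floor"):
        association.fisher_combine([0.5, 0.0])


def test_fisher_monotone_in_inputs():
    s1, _, p1 = association.fisher_combine([0.5, 0.5])
    s2, _, p2 = association.fisher_combine([0.5, 0.1])
    assert s2 > s1 and p2 < p1


# ---------------------------------------------------------------------------
# genomic inflation factor
# ---------------------------------------------------------------------------

def test_lambda_is_one_at_p_half():
    assert association.genomic_lambda([0.5, 0.5, 0.5]) == 1.0


def test_lambda_near_one_under_uniform_null():
    rng = np.random.default_rng(0)
    lam = association.genomic_lambda(rng.uniform(1e-12, 1.0, 10_000))
    assert lam == pytest.approx(1.0, abs=0.05)


def test_lambda_scaling_oracle():
    # chi-squares inflated by 2 -> lambda approx 2
    rng = np.random.default_rng(1)
    chi = 2.0 * rng.chisquare(1, 20_000)
    p = stats.chi2.sf(chi, 1)
    lam = association.genomic_lambda(np.clip(p, 1e-300, 1.0))
    assert lam == pytest.approx(2.0, rel=0.05)


def test_lambda_rejects_empty_and_out_of_range():
    with pytest.raises(ValidationError):
        association.genomic_lambda([])
    with pytest.raises(ValidationError):
        association.genomic_lambda([0.0, 0.5])


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def test_sample_size_normal_quantile_oracle():
    # alpha 0.05, power 0.95, unit standardized effect:
    # ceil(2 * (1.95996 + 1.64485)^2) = 26
    assert association.sample_size_two_group(1.0, 1.0, alpha=0.05, power=0.95) == 26


def test_sample_size_floors_at_one():
    assert association.sample_size_two_group(1e9, 1.0, alpha=0.05, power=0.95) == 1


def test_sample_size_quadruples_when_delta_halves():
    n1 = association.sample_size_two_group(0.10, 0.05, alpha=1e-7, power=0.95)
    n2 = association.sample_size_two_group(0.05, 0.05, alpha=1e-7, power=0.95)
    assert abs(n2 - 4 * n1) <= 4  # exact 4x on the un-ceiled formula


def test_sample_size_invalid_ranges():
    with pytest.raises(ValidationError):
        association.sample_size_two_group(-0.1, 0.05)
    with pytest.raises(ValidationError):
        association.sample_size_two_group(0.1, 0.05, alpha=0.5, power=0.2)


# ---------------------------------------------------------------------------
# SEV ~ dimensions regression
# ---------------------------------------------------------------------------

def _toy_inputs(seed=0, n=50, n_dims=4, effect=0.0):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    scores = pd.DataFrame(
        rng.normal(size=(n, n_dims)), index=idx,
        columns=[f"Dim{j + 1}" for j in range(n_dims)],
    )
    batch = pd.Series(["b1", "b2"] * (n // 2), index=idx)
    log_sev = pd.DataFrame(index=idx)
    for mode in ["m1", "m2", "m3"]:
        noise = rng.normal(0, 0.3, n)
        log_sev[mode] = 3.0 + effect * scores["Dim1"] + noise
    return log_sev, scores, batch


def test_single_mode_combined_p_equals_mode_p():
    log_sev, scores, batch = _toy_inputs(seed=2)
    table = association.sev_dim_regression(log_sev[["m1"]], scores, batch)
    res = table.results.set_index("dimension")
    for dim in scores.columns:
        assert res.loc[dim, "p_combined"] == pytest.approx(
            res.loc[dim, "p_m1"], rel=1e-12
        )


def test_affine_rescaling_of_scores_leaves_pvalues():
    log_sev, scores, batch = _toy_inputs(seed=3)
    a = association.sev_dim_regression(log_sev, scores, batch)
    b = association.sev_dim_regression(log_sev, scores * 7.3, batch)
    np.testing.assert_allclose(
        a.results["p_combined"], b.results["p_combined"], rtol=1e-8
    )


def test_planted_dimension_effect_detected():
    log_sev, scores, batch = _toy_inputs(seed=4, effect=0.5)
    table = association.sev_dim_regression(log_sev, scores, batch)
    res = table.results.set_index("dimension")
    assert res.loc["Dim1", "significant"]
    assert res.loc["Dim1", "p_adj"] == pytest.approx(
        min(1.0, res.loc["Dim1", "p_combined"] * len(scores.columns)), rel=1e-12
    )


def test_rank_deficient_design_names_column():
    log_sev, scores, batch = _toy_inputs(seed=5)
    scores["Dim4"] = scores["Dim1"] * 2.0  # exact collinearity
    with pytest.raises(ValidationError, match="Dim4"):
        association.sev_dim_regression(log_sev, scores, batch)


def test_bonferroni_uses_number_of_dimensions():
    log_sev, scores, batch = _toy_inputs(seed=6)
    table = association.sev_dim_regression(log_sev, scores, batch)
    res = table.results
    np.testing.assert_allclose(
        res["p_adj"], np.minimum(1.0, res["p_combined"] * len(scores.columns))
    )


# ---------------------------------------------------------------------------
# EWAS-lite
# ---------------------------------------------------------------------------

def _ewas_data(seed=0, n_probes=200, n=40):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    beta = pd.DataFrame(
        np.clip(rng.normal(0.5, 0.05, (n_probes, n)), 0, 1),
        index=[f"cg{i}" for i in range(n_probes)],
        columns=samples,
    )
    group = pd.Series(["case"] * (n // 2) + ["control"] * (n - n // 2), index=samples)
    return beta, group


def test_ewas_matches_matrix_algebra_oracle():
    beta, group = _ewas_data(seed=7)
    results, _ = association.ewas_lite(beta, group)
    g = group.astype("category").cat.codes.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(g)), g])
    for probe in beta.index[:20]:
        y = beta.loc[probe].to_numpy()
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        sigma2 = (resid**2).sum() / (len(y) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
        t = coef[1] / se
        assert results.loc[probe, "t"] == pytest.approx(t, abs=1e-10)
        p = 2 * stats.t.sf(abs(t), len(y) - 2)
        assert results.loc[probe, "p"] == pytest.approx(p, rel=1e-10)


def test_ewas_planted_difference_is_genomewide():
    beta, group = _ewas_data(seed=8, n=64)
    cases = group == "case"
    beta.loc["cg0", cases[cases].index] += 0.3  # planted 0.3 beta difference
    beta = beta.clip(0, 1)
    results, _ = association.ewas_lite(beta, group)
    assert results.loc["cg0", "genomewide"]
    assert results.drop(index="cg0")["genomewide"].sum() == 0


def test_ewas_collinear_covariate_rejected():
    beta, group = _ewas_data(seed=9)
    cov = pd.DataFrame(
        {"copy": group.astype("category").cat.codes.astype(float)}, index=beta.columns
    )
    with pytest.raises(ValidationError, match="copy"):
        association.ewas_lite(beta, group, covariates=cov)


def test_ewas_null_lambda_near_one():
    beta, group = _ewas_data(seed=10, n_probes=2000, n=64)
    _, lam = association.ewas_lite(beta, group)
    assert lam == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# end-to-end planted effect through the generator
# ---------------------------------------------------------------------------

def test_generator_effect_recovered_end_to_end():
    cfg = small_config(seed=21, phenotype_effect={"f1": 0.3}, sev_rate=20.0,
                       n_reference=41, n_cases=23, n_probes=1000)
    ann = synthetic.generate_annotation(cfg)
    beta, _, truth = synthetic.generate_cohort(cfg, ann)
    pheno = synthetic.generate_phenotypes(cfg, truth).drop(columns=["case_control"])
    model = famd.famd_fit(pheno, n_dims=10)
    controls, _ = cfg.sample_ids()
    refs = {
        "internal_pooled": beta[controls],
        "external_cord": synthetic.generate_reference_cohort(
            cfg, ann, truth.probe_means, 41, mean_shift_sd=0.02, prefix="cord"
        ),
        "external_wholeblood": synthetic.generate_reference_cohort(
            cfg, ann, truth.probe_means, 41, mean_shift_sd=0.05, prefix="wb"
        ),
    }
    profile = sev.sev_profile(beta, refs)
    batch = synthetic.batch_labels(cfg)
    table = association.sev_dim_regression(
        profile.log_sev_table(), model.dimension_scores, batch
    )
    res = table.results.set_index("dimension")
    # the dimension most correlated with factor 1 carries the planted slope
    corrs = model.dimension_scores.apply(
        lambda c: abs(np.corrcoef(c, truth.latent_factors["f1"])[0, 1])
    )
    best = corrs.idxmax()
    assert corrs[best] > 0.9
    assert res.loc[best, "significant"]
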