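"""Association of SEV burden with phenotype dimensions, plus diagnostics.

Per reference mode, the natural-log SEV count is regressed on all retained
phenotype dimensions with chip-batch indicators as covariates (ordinary
least squares); per-dimension p-values from the three modes are then
combined with Fisher's method (-2 * sum(ln p) ~ chi-square with 2k df) and
Bonferroni-corrected over the tested dimensions.  The module also provides
a plain per-probe linear-model scan ("EWAS-lite") whose p-values feed the
genomic inflation factor lambda, and the normal-approximation two-group
sample-size formula used at design time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

P_FLOOR = 1e-300  # floor applied before Fisher combination


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: (statistic, df, combined p) for k p-values.

    statistic = -2 * sum(ln p); combined p is the upper tail of chi-square
    with 2k degrees of freedom.  With k = 1 this is the identity.  Zero
    p-values are rejected: callers must floor them (``P_FLOOR``) first.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("fisher_combine needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]; floor zeros first")
    statistic = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return statistic, df, float(stats.chi2.sf(statistic, df))


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns not adding rank, scanning left to right
        collinear, kept = [], np.empty((x.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.hstack([kept, x[:, [j]]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                collinear.append(name)
            else:
                kept = cand
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _batch_indicators(batch: pd.Series) -> tuple[np.ndarray, list[str]]:
    codes = pd.Series(batch).astype("category")
    dummies = pd.get_dummies(codes, drop_first=True, prefix="batch")
    return dummies.to_numpy(dtype=float), list(dummies.columns)


@dataclass
class AssociationTable:
    """Per-dimension association of log SEV count across reference modes."""

    results: pd.DataFrame  # dimension, p per mode, fisher stat/df, p_combined, p_adj
    per_mode_fits: dict[str, pd.DataFrame]


def sev_dim_regression(
    log_sev: pd.DataFrame,
    scores: pd.DataFrame,
    batch: pd.Series | None = None,
    alpha: float = 0.05,
) -> AssociationTable:
    """OLS of log SEV burden on dimension scores, combined across modes.

    Parameters
    ----------
    log_sev
        Samples x modes table of natural-log SEV counts (one column per
        reference mode; one column is allowed).
    scores
        Samples x dimensions FAMD score table, aligned on sample id.
    batch
        Optional chip-batch labels; expanded to indicator covariates.

    All dimensions enter each per-mode model jointly.  Per dimension, the
    per-mode t-test p-values are Fisher-combined and Bonferroni-adjusted
    over the number of dimensions tested.
    """
    import statsmodels.api as sm

    if not log_sev.index.equals(scores.index):
        scores = scores.loc[log_sev.index]
    dims = list(scores.columns)
    x_parts = [np.ones((len(scores), 1)), scores.to_numpy(dtype=float)]
    names = ["const"] + dims
    if batch is not None:
        b, b_names = _batch_indicators(pd.Series(batch).loc[log_sev.index])
        x_parts.append(b)
        names += b_names
    x = np.hstack(x_parts)
    _check_full_rank(x, names)

    per_mode_fits: dict[str, pd.DataFrame] = {}
    mode_p: dict[str, pd.Series] = {}
    for mode in log_sev.columns:
        fit = sm.OLS(log_sev[mode].to_numpy(dtype=float), x).fit()
        table = pd.DataFrame(
            {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
            index=names,
        )
        per_mode_fits[mode] = table
        mode_p[mode] = table.loc[dims, "p"]

    rows = []
    for dim in dims:
        ps = np.maximum([mode_p[m][dim] for m in log_sev.columns], P_FLOOR)
        statistic, df, p_comb = fisher_combine(ps)
        row = {"dimension": dim}
        for m in log_sev.columns:
            row[f"p_{m}"] = float(mode_p[m][dim])
            row[f"coef_{m}"] = float(per_mode_fits[m].loc[dim, "coef"])
        row.update(
            fisher_statistic=statistic,
            fisher_df=df,
            p_combined=p_comb,
            p_adj=min(1.0, p_comb * len(dims)),
        )
        rows.append(row)
    results = pd.DataFrame(rows)
    results["significant"] = results["p_adj"] < alpha
    return AssociationTable(results=results, per_mode_fits=per_mode_fits)


def ewas_lite(
    beta: pd.DataFrame,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
    batch: pd.Series | None = None,
    genomewide_threshold: float = 1e-7,
) -> tuple[pd.DataFrame, float]:
    """Per-probe OLS of beta on group status with covariates; lambda diagnostic.

    Returns (per-probe results, genomic inflation factor of the scan).  The
    per-probe t-test concerns the group coefficient; probes with
    p < *genomewide_threshold* carry the genome-wide flag.  This is a plain
    classical-standard-error scan intended for covariate-adjustment
    demonstrations and the lambda diagnostic, not a moderated EWAS.
    """
    samples = beta.columns
    g = pd.Series(group).loc[samples].astype("category").cat.codes.to_numpy(dtype=float)
    x_parts = [np.ones((len(samples), 1)), g[:, None]]
    names = ["const", "group"]
    if covariates is not None:
        cov = covariates.loc[samples]
        x_parts.append(cov.to_numpy(dtype=float))
        names += list(cov.columns)
    if batch is not None:
        b, b_names = _batch_indicators(pd.Series(batch).loc[samples])
        x_parts.append(b)
        names += b_names
    x = np.hstack(x_parts)
    n, p_cols = x.shape
    if n <= p_cols + 2:
        raise ValidationError("need n_samples > n_covariates + 2")
    _check_full_rank(x, names)

    y = beta.to_numpy(dtype=float).T  # samples x probes
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = xtx_inv @ x.T @ y
    resid = y - x @ coefs
    dof = n - p_cols
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coefs[1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    results = pd.DataFrame(
        {
            "effect": coefs[1],
            "se": se,
            "t": t,
            "p": pvals,
            "genomewide": pvals < genomewide_threshold,
        },
        index=beta.index,
    )
    lam = genomic_lambda(np.clip(pvals, P_FLOOR, 1.0))
    return results, lam


def genomic_lambda(pvalues) -> float:
    """Genomic inflation factor: median association chi-square / null median.

    P-values are converted to 1-df chi-square quantiles; lambda is their
    median divided by the median of the chi-square(1) distribution
    (~0.4549).  Uniform p-values give lambda = 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("genomic_lambda needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    observed = stats.chi2.isf(p, df=1)
    null_median = stats.chi2.isf(0.5, df=1)
    return float(np.median(observed) / null_median)


def sample_size_two_group(
    delta: float, sd: float, alpha: float = 1e-7, power: float = 0.95
) -> int:
    """Two-group normal-approximation sample size per group.

    n = ceil(2 * (z_{1-alpha/2} + z_power)^2 * sd^2 / delta^2), floored at 1.
    Defaults reflect an epigenome-wide design: a methylation difference
    worth detecting of at least 10% (delta = 0.10 on the beta scale) at a
    multiple-testing-aware significance level near 1e-7 with 95% power.
    """
    if delta <= 0 or sd <= 0:
        raise ValidationError("delta and sd must be positive")
    if not (0 < alpha < 1) or not (alpha < power < 1):
        raise ValidationError("require 0 < alpha < power < 1")
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    z_power = stats.norm.ppf(power)
    n = math.ceil(2 * (z_alpha + z_power) ** 2 * sd**2 / delta**2)
    return max(n, 1)
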