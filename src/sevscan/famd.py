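"""Factor analysis of mixed data (FAMD) for phenotype tables.

FAMD generalises PCA to tables mixing continuous and categorical columns:
continuous columns are standardised (zero mean, unit population variance),
each categorical is expanded to level indicators scaled by the inverse
square root of the level frequency and centred.  A singular value
decomposition of the combined matrix then yields sample scores and variable
loadings.  Under this weighting each continuous column contributes inertia
1 and a categorical with L levels contributes L - 1, so the total inertia
is #continuous + sum(levels - 1); on an all-continuous table FAMD is
exactly standardised PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def split_types(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Column names split into (continuous, categorical) by dtype."""
    continuous, categorical = [], []
    for col in table.columns:
        if isinstance(table[col].dtype, pd.CategoricalDtype) or table[col].dtype == object:
            categorical.append(col)
        else:
            continuous.append(col)
    return continuous, categorical


def _preprocess(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """FAMD weighting: standardised continuous + scaled centred indicators."""
    if table.isna().any().any():
        raise ValidationError("phenotype table contains missing values")
    continuous, categorical = split_types(table)
    n = len(table)
    blocks, names = [], []
    for col in continuous:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValidationError(f"constant column {col!r} cannot enter FAMD")
        blocks.append(((x - x.mean()) / sd)[:, None])
        names.append(col)
    for col in categorical:
        codes = table[col].astype("category")
        levels = list(codes.cat.categories)
        if len(levels) < 2:
            raise ValidationError(f"categorical column {col!r} has a single level")
        ind = pd.get_dummies(codes).to_numpy(dtype=float)
        p = ind.mean(axis=0)
        z = (ind - p) / np.sqrt(p)
        blocks.append(z)
        names.extend(f"{col}={lvl}" for lvl in levels)
    if not blocks:
        raise ValidationError("empty phenotype table")
    return np.hstack(blocks), names


@dataclass
class FactorModel:
    """Fitted FAMD model.

    ``dimension_scores`` are samples x retained dimensions with zero column
    means and per-column variance equal to the corresponding eigenvalue;
    ``eigenvalues`` covers the full rank so variance fractions refer to the
    total inertia.
    """

    dimension_scores: pd.DataFrame
    variable_loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    cumulative_variance: np.ndarray
    total_inertia: float
    n_dims: int


def famd_fit(table: pd.DataFrame, n_dims: int = 10) -> FactorModel:
    """Fit FAMD and retain the leading *n_dims* dimensions.

    Each dimension is oriented so that its largest-magnitude variable
    loading is positive, making the sign convention deterministic.
    """
    if len(table) <= n_dims:
        raise ValidationError("need n_samples > n_dims")
    z, names = _preprocess(table)
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z / np.sqrt(n), full_matrices=False)
    eigenvalues = s**2
    total_inertia = float(eigenvalues.sum())
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    n_keep = min(n_dims, rank)

    v = vt.T[:, :n_keep]
    scores = np.sqrt(n) * u[:, :n_keep] * s[:n_keep]
    # deterministic orientation: largest-|loading| entry positive
    for j in range(n_keep):
        pivot = int(np.argmax(np.abs(v[:, j])))
        if v[pivot, j] < 0:
            v[:, j] = -v[:, j]
            scores[:, j] = -scores[:, j]

    dims = [f"Dim{j + 1}" for j in range(n_keep)]
    frac = eigenvalues / total_inertia
    return FactorModel(
        dimension_scores=pd.DataFrame(scores, index=table.index, columns=dims),
        variable_loadings=pd.DataFrame(v, index=names, columns=dims),
        eigenvalues=eigenvalues,
        variance_explained=frac,
        cumulative_variance=np.cumsum(frac),
        total_inertia=total_inertia,
        n_dims=n_keep,
    )


def correlation_ratio(scores: np.ndarray, labels: pd.Series) -> float:
    """eta: square root of the between-level fraction of score variance."""
    total = scores.var(ddof=0)
    if total == 0:
        return 0.0
    grand = scores.mean()
    between = 0.0
    for _, grp in pd.Series(scores).groupby(labels.to_numpy()):
        between += len(grp) * (grp.mean() - grand) ** 2
    return float(np.sqrt(between / (len(scores) * total)))


def dim_trait_correlations(
    model: FactorModel,
    table: pd.DataFrame,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Correlation of every dimension with every trait.

    Continuous traits use Pearson correlation, binary categoricals the
    point-biserial coefficient (Pearson on 0/1 codes) and multi-level
    categoricals the correlation ratio with a one-way ANOVA p-value.  Pairs
    exceeding both thresholds are flagged.
    """
    continuous, categorical = split_types(table)
    rows = []
    for dim in model.dimension_scores.columns:
        scores = model.dimension_scores[dim].to_numpy()
        for col in continuous:
            r, p = stats.pearsonr(scores, table[col].to_numpy(dtype=float))
            rows.append((dim, col, "pearson", float(r), float(p)))
        for col in categorical:
            codes = table[col].astype("category").cat
            if len(codes.categories) == 2:
                r, p = stats.pearsonr(scores, codes.codes.to_numpy(dtype=float))
                rows.append((dim, col, "point_biserial", float(r), float(p)))
            else:
                groups = [
                    scores[codes.codes.to_numpy() == i]
                    for i in range(len(codes.categories))
                ]
                groups = [g for g in groups if len(g) > 0]
                eta = correlation_ratio(scores, table[col])
                p = float(stats.f_oneway(*groups).pvalue) if len(groups) > 1 else 1.0
                rows.append((dim, col, "correlation_ratio", eta, p))
    out = pd.DataFrame(rows, columns=["dimension", "trait", "method", "rho", "p"])
    out["flagged"] = (out["rho"].abs() > rho_threshold) & (out["p"] < p_threshold)
    return out


def dims_vs_group(
    model: FactorModel,
    group: pd.Series,
    alpha: float = 0.05,
    p_floor: float = 1e-16,
) -> pd.DataFrame:
    """Per-dimension logistic regression of a binary label on the scores.

    Fitted by iteratively reweighted least squares (statsmodels Logit); a
    perfectly separating dimension is reported with ``separated = True`` and
    the documented p floor instead of raising.  Dimensions with p < alpha
    are flagged as candidate confounder covariates.
    """
    import statsmodels.api as sm

    y = pd.Series(group).astype("category").cat.codes.to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValidationError("group must have exactly two non-empty levels")
    rows = []
    for dim in model.dimension_scores.columns:
        x = sm.add_constant(model.dimension_scores[dim].to_numpy())
        separated = False
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            coef = float(fit.params[1])
            p = float(fit.pvalues[1])
            if not np.isfinite(p) or np.abs(coef) > 1e3:
                separated, p = True, p_floor
        except Exception:
            separated, coef, p = True, np.inf, p_floor
        rows.append(
            {
                "dimension": dim,
                "coef": coef,
                "p": max(p, p_floor) if separated else p,
                "significant": p < alpha,
                "separated": separated,
            }
        )
    return pd.DataFrame(rows)
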