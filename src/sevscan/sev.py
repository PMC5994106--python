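"""Stochastic epigenetic variation (SEV) calling.

A SEV is a single CpG whose methylation in one subject is an *extreme*
outlier relative to a reference population: the value lies strictly outside
the box-and-whiskers fences Q1 - 3*IQR or Q3 + 3*IQR computed per probe
from the reference beta values.  The fence multiplier 3 targets the extreme
(not the conventional 1.5 "mild") outlier regime, so calls correspond to
epimutation-scale departures rather than ordinary biological spread.

Quartiles default to Tukey hinges (the convention behind R's boxplot
statistics); linear-interpolation quantiles are available as an option.
Fences are deliberately not clipped to [0, 1]: a fence outside the feasible
beta range simply cannot produce calls on that side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

FENCE_COLUMNS = ["q1", "q3", "iqr", "lower", "upper", "n_reference", "usable"]


def _hinges_sorted(sorted_vals: np.ndarray, n: int) -> tuple[float, float]:
    """Tukey hinges (lower, upper) of the first *n* entries of a sorted array."""
    # five-number-summary positions: hinge depth floor((n+3)/2)/2, 1-based
    d = math.floor((n + 3) / 2) / 2.0
    lo = 0.5 * (sorted_vals[math.floor(d) - 1] + sorted_vals[math.ceil(d) - 1])
    hi_pos = n + 1 - d
    hi = 0.5 * (
        sorted_vals[math.floor(hi_pos) - 1] + sorted_vals[math.ceil(hi_pos) - 1]
    )
    return float(lo), float(hi)


def compute_fences(
    reference: pd.DataFrame,
    min_n: int = 10,
    multiplier: float = 3.0,
    quantile_method: str = "hinges",
) -> pd.DataFrame:
    """Per-probe quartiles and extreme-outlier fences from a reference cohort.

    Parameters
    ----------
    reference
        Probes x samples beta matrix of the reference population; missing
        values are ignored per probe.
    min_n
        Minimum number of non-missing reference values for a probe to get
        usable fences; probes below it are marked ``usable = False`` and are
        skipped during calling.
    multiplier
        Fence multiplier on the IQR (3 = extreme outliers).
    quantile_method
        ``"hinges"`` (Tukey hinges, default) or ``"linear"``
        (linear-interpolation quantiles).

    Returns a DataFrame indexed by probe with columns q1, q3, iqr, lower,
    upper, n_reference, usable.  Fences are not clipped to [0, 1].
    """
    if quantile_method not in ("hinges", "linear"):
        raise ValidationError(f"unknown quantile method {quantile_method!r}")
    values = reference.to_numpy(dtype=float)
    if values.shape[1] < min_n:
        raise ValidationError(
            f"reference has {values.shape[1]} samples, fewer than min_n={min_n}"
        )
    n_ref = np.sum(~np.isnan(values), axis=1)
    q1 = np.full(values.shape[0], np.nan)
    q3 = np.full(values.shape[0], np.nan)
    usable = n_ref >= min_n

    if quantile_method == "linear":
        with np.errstate(invalid="ignore"):
            q1[usable] = np.nanquantile(values[usable], 0.25, axis=1)
            q3[usable] = np.nanquantile(values[usable], 0.75, axis=1)
    else:
        # NaN sorts to the end; hinges read only the first n_ref entries
        ordered = np.sort(values, axis=1)
        if usable.any() and np.all(n_ref[usable] == n_ref[usable][0]):
            # fast path: one shared hinge depth when no values are missing
            n = int(n_ref[usable][0])
            d = math.floor((n + 3) / 2) / 2.0
            sub = ordered[usable]
            q1[usable] = 0.5 * (
                sub[:, math.floor(d) - 1] + sub[:, math.ceil(d) - 1]
            )
            hi_pos = n + 1 - d
            q3[usable] = 0.5 * (
                sub[:, math.floor(hi_pos) - 1] + sub[:, math.ceil(hi_pos) - 1]
            )
        else:
            for i in np.flatnonzero(usable):
                q1[i], q3[i] = _hinges_sorted(ordered[i], int(n_ref[i]))

    iqr = q3 - q1
    fences = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lower": q1 - multiplier * iqr,
            "upper": q3 + multiplier * iqr,
            "n_reference": n_ref.astype(np.int64),
            "usable": usable,
        },
        index=reference.index,
    )
    return fences


@dataclass
class SEVCallSet:
    """Per-subject SEV calls against one reference mode.

    ``calls`` has one row per flagged probe (probe_id, direction, value,
    lower, upper); ``log_sev`` is the natural log of the call count, with
    log(n + 1) substituted (and ``log_offset_used`` set) for subjects with
    zero calls.
    """

    sample_id: str
    reference_mode: str
    calls: pd.DataFrame
    n_sev: int
    log_sev: float
    n_skipped: int = 0
    n_zero_iqr: int = 0
    log_offset_used: bool = False

    @property
    def probes(self) -> set[tuple[str, str]]:
        return set(zip(self.calls["probe_id"], self.calls["direction"]))


def safe_log_count(n: int) -> tuple[float, bool]:
    """Natural-log count; zero counts use log(n + 1) = 0 and are flagged."""
    if n >= 1:
        return math.log(n), False
    return 0.0, True


def call_sevs(
    subject: pd.Series,
    fences: pd.DataFrame,
    sample_id: str | None = None,
    reference_mode: str = "internal_pooled",
) -> SEVCallSet:
    """Flag a subject's probes lying strictly outside the reference fences.

    A probe is called ``low`` iff value < lower fence, ``high`` iff value >
    upper fence (strict inequalities: values exactly on a fence are not
    outliers).  Missing subject values are never flagged.  Probes without
    usable fences are skipped and tallied in ``n_skipped``; probes whose
    reference IQR is zero remain callable but are tallied in ``n_zero_iqr``.
    """
    extra = subject.index.difference(fences.index)
    if len(extra) > 0:
        raise ValidationError(f"subject probe {extra[0]!r} has no fences")
    f = fences.loc[subject.index]
    vals = subject.to_numpy(dtype=float)
    usable = f["usable"].to_numpy(dtype=bool) & ~np.isnan(vals)
    lower = f["lower"].to_numpy()
    upper = f["upper"].to_numpy()
    with np.errstate(invalid="ignore"):
        low = usable & (vals < lower)
        high = usable & (vals > upper)
    flagged = low | high
    calls = pd.DataFrame(
        {
            "probe_id": subject.index[flagged],
            "direction": np.where(low[flagged], "low", "high"),
            "value": vals[flagged],
            "lower": lower[flagged],
            "upper": upper[flagged],
        }
    )
    n_sev = int(flagged.sum())
    log_sev, offset = safe_log_count(n_sev)
    return SEVCallSet(
        sample_id=sample_id if sample_id is not None else str(subject.name),
        reference_mode=reference_mode,
        calls=calls,
        n_sev=n_sev,
        log_sev=log_sev,
        n_skipped=int((~f["usable"].to_numpy(dtype=bool)).sum()),
        n_zero_iqr=int((usable & (f["iqr"].to_numpy() == 0)).sum()),
        log_offset_used=offset,
    )


@dataclass
class SEVProfile:
    """SEV calls for every subject under every reference mode."""

    summary: pd.DataFrame  # sample_id, mode, n_sev, log_sev, n_skipped, n_zero_iqr
    call_sets: dict[tuple[str, str], SEVCallSet] = field(default_factory=dict)
    n_common_probes: int = 0

    def log_sev_table(self) -> pd.DataFrame:
        """Samples x modes table of log SEV counts."""
        return self.summary.pivot(index="sample_id", columns="mode", values="log_sev")


def _call_matrix(
    cohort: pd.DataFrame, fences: pd.DataFrame, mode: str
) -> list[SEVCallSet]:
    """Vectorised calling of every cohort column against one fence table."""
    vals = cohort.to_numpy(dtype=float)
    usable = fences["usable"].to_numpy(dtype=bool)
    lower = fences["lower"].to_numpy()[:, None]
    upper = fences["upper"].to_numpy()[:, None]
    with np.errstate(invalid="ignore"):
        low = usable[:, None] & ~np.isnan(vals) & (vals < lower)
        high = usable[:, None] & ~np.isnan(vals) & (vals > upper)
    out = []
    n_skipped = int((~usable).sum())
    zero_iqr = usable & (fences["iqr"].to_numpy() == 0)
    for j, sample in enumerate(cohort.columns):
        flagged = low[:, j] | high[:, j]
        calls = pd.DataFrame(
            {
                "probe_id": cohort.index[flagged],
                "direction": np.where(low[flagged, j], "low", "high"),
                "value": vals[flagged, j],
                "lower": lower[flagged, 0],
                "upper": upper[flagged, 0],
            }
        )
        n_sev = int(flagged.sum())
        log_sev, offset = safe_log_count(n_sev)
        not_nan = ~np.isnan(vals[:, j])
        out.append(
            SEVCallSet(
                sample_id=str(sample),
                reference_mode=mode,
                calls=calls,
                n_sev=n_sev,
                log_sev=log_sev,
                n_skipped=n_skipped,
                n_zero_iqr=int((zero_iqr & not_nan).sum()),
                log_offset_used=offset,
            )
        )
    return out


def sev_profile(
    cohort: pd.DataFrame,
    references: dict[str, pd.DataFrame],
    internal_mode: str = "pooled",
    min_n: int = 10,
    multiplier: float = 3.0,
    quantile_method: str = "hinges",
) -> SEVProfile:
    """Call SEVs for every cohort subject under each reference mode.

    For each mode, subjects that are themselves members of the reference
    (matched by sample id) are called either against fences from the full
    reference including themselves (``internal_mode="pooled"``, default) or
    against leave-one-out fences (``internal_mode="loo"``).  Non-members are
    always called against fences from the full reference.  Probes are
    restricted to the intersection of the cohort and all references.
    """
    if internal_mode not in ("pooled", "loo"):
        raise ValidationError(f"unknown internal_mode {internal_mode!r}")
    common = cohort.index
    for ref in references.values():
        common = common.intersection(ref.index)
    if len(common) == 0:
        raise ValidationError("empty probe intersection across cohort and references")
    cohort = cohort.loc[common]

    call_sets: dict[tuple[str, str], SEVCallSet] = {}
    rows = []
    for mode, ref in references.items():
        ref = ref.loc[common]
        fences = compute_fences(ref, min_n, multiplier, quantile_method)
        members = [s for s in cohort.columns if s in set(ref.columns)]
        non_members = [s for s in cohort.columns if s not in set(ref.columns)]
        produced: dict[str, SEVCallSet] = {}
        if internal_mode == "pooled" or not members:
            for cs in _call_matrix(cohort, fences, mode):
                produced[cs.sample_id] = cs
        else:
            if non_members:
                for cs in _call_matrix(cohort[non_members], fences, mode):
                    produced[cs.sample_id] = cs
            for member in members:
                loo_fences = compute_fences(
                    ref.drop(columns=[member]), min_n, multiplier, quantile_method
                )
                produced[member] = call_sevs(
                    cohort[member], loo_fences, sample_id=member, reference_mode=mode
                )
        for sample in cohort.columns:
            cs = produced[str(sample)]
            call_sets[(cs.sample_id, mode)] = cs
            rows.append(
                {
                    "sample_id": cs.sample_id,
                    "mode": mode,
                    "n_sev": cs.n_sev,
                    "log_sev": cs.log_sev,
                    "n_skipped": cs.n_skipped,
                    "n_zero_iqr": cs.n_zero_iqr,
                    "log_offset_used": cs.log_offset_used,
                }
            )
    summary = pd.DataFrame(rows)
    return SEVProfile(summary=summary, call_sets=call_sets, n_common_probes=len(common))
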