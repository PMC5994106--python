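"""Per-subject over-representation of SEVs in genomic regions.

Each subject's SEV set is tested region by region with the hypergeometric
upper-tail probability: drawing the subject's n genome-wide SEVs from the N
post-QC probes, how surprising is observing k or more of them among the K
probes of the region?  Bonferroni correction is applied within subject over
the regions actually tested (K > 0) in one region set.  Call direction is
ignored: a cluster of extreme values in either direction is evidence of a
localised defect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .sev import SEVCallSet, safe_log_count

REPORT_COLUMNS = [
    "sample_id",
    "region_id",
    "region_kind",
    "K",
    "k",
    "N",
    "n",
    "p",
    "p_adj",
    "enriched",
]


def _log_hypergeom_pmf(j: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        gammaln(K + 1)
        - gammaln(j + 1)
        - gammaln(K - j + 1)
        + gammaln(N - K + 1)
        - gammaln(n - j + 1)
        - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N, K, n), in log space.

    N: population size (post-QC probes); K: marked items (probes in the
    region); n: draws (subject's genome-wide SEVs); k: observed overlap.

    Log-weights over the whole support are built from the stable
    pmf(j+1)/pmf(j) ratio recursion and normalised by their own total, so
    the tail is exact to ~1e-13 relative even for long supports.
    """
    if K > N or n > N:
        raise ValidationError("hypergeometric requires K <= N and n <= N")
    if min(N, K, n, k) < 0:
        raise ValidationError("hypergeometric arguments must be non-negative")
    if k > min(K, n):
        raise ValidationError("k must not exceed min(K, n)")
    kmin = max(0, n + K - N)
    kmax = min(K, n)
    if k <= kmin:
        return 1.0
    j = np.arange(kmin, kmax, dtype=float)
    log_ratio = (
        np.log(K - j) + np.log(n - j) - np.log(j + 1) - np.log(N - K - n + j + 1)
    )
    log_w = np.concatenate([[0.0], np.cumsum(log_ratio)])  # support kmin..kmax
    tail = logsumexp(log_w[k - kmin :]) - logsumexp(log_w)
    return min(float(np.exp(tail)), 1.0)


def _enrich_rows(
    callset: SEVCallSet,
    region_probe_counts: list[tuple[str, str, int, int]],
    N: int,
    alpha: float,
) -> pd.DataFrame:
    """Shared core: one hypergeometric test per (region_id, kind, K, k)."""
    n = callset.n_sev
    rows = []
    n_tested = len(region_probe_counts)
    for region_id, kind, K, k in region_probe_counts:
        p = hypergeom_upper(N, K, n, k)
        rows.append(
            {
                "sample_id": callset.sample_id,
                "region_id": region_id,
                "region_kind": kind,
                "K": K,
                "k": k,
                "N": N,
                "n": n,
                "p": p,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS[:-2])
    report["p_adj"] = np.minimum(1.0, report["p"] * n_tested)
    report["enriched"] = report["p_adj"] < alpha
    return report


def window_enrichment(
    callset: SEVCallSet,
    annotation: pd.DataFrame,
    window: int = 5000,
    step: int = 2500,
    alpha: float = 0.05,
    N: int | None = None,
) -> pd.DataFrame:
    """Sliding-window SEV enrichment along each chromosome.

    Windows of *window* bp advance by *step* bp (50% overlap by default)
    from coordinate 0 to the last annotated probe; windows containing no
    probes are skipped and do not enter the Bonferroni factor.  ``N``
    defaults to the number of annotated (post-QC) probes.
    """
    if window <= 0 or step <= 0 or window < step:
        raise ValidationError("require 0 < step <= window")
    N = int(N) if N is not None else len(annotation)
    sev_probes = set(callset.calls["probe_id"])

    counts: list[tuple[str, str, int, int]] = []
    for chrom, grp in annotation.groupby("chromosome", sort=True):
        order = np.argsort(grp["position"].to_numpy())
        pos0 = grp["position"].to_numpy()[order] - 1  # 0-based
        ids = grp.index.to_numpy(dtype=object)[order]
        is_sev = np.isin(ids, list(sev_probes)) if sev_probes else np.zeros(len(ids), bool)
        sev_cum = np.concatenate([[0], np.cumsum(is_sev)])
        last = int(pos0[-1])
        starts = np.arange(0, last + 1, step)
        los = np.searchsorted(pos0, starts, side="left")
        his = np.searchsorted(pos0, starts + window, side="left")
        for start, lo, hi in zip(starts, los, his):
            K = int(hi - lo)
            if K > 0:
                counts.append(
                    (
                        f"win_{chrom}_{start}",
                        "window",
                        K,
                        int(sev_cum[hi] - sev_cum[lo]),
                    )
                )
    return _enrich_rows(callset, counts, N, alpha)


def region_enrichment(
    callset: SEVCallSet,
    regions: pd.DataFrame,
    probe_index: dict[str, np.ndarray],
    alpha: float = 0.05,
    N: int | None = None,
) -> pd.DataFrame:
    """SEV enrichment over an arbitrary region set (genes, promoters, DMRs).

    ``probe_index`` maps region_id -> contained probe ids (see
    :func:`sevscan.io.probe_region_index`).  Regions with zero probes are
    skipped and excluded from the Bonferroni factor.
    """
    if N is None:
        raise ValidationError("N (post-QC probe count) is required")
    sev_probes = set(callset.calls["probe_id"])
    counts: list[tuple[str, str, int, int]] = []
    for _, r in regions.iterrows():
        probes = probe_index.get(r["region_id"], np.array([], dtype=object))
        K = len(probes)
        if K == 0:
            continue
        k = sum(1 for p in probes if p in sev_probes)
        counts.append((r["region_id"], r.get("kind", "region"), K, k))
    return _enrich_rows(callset, counts, int(N), alpha)


def enriched_region_counts(reports: pd.DataFrame) -> pd.DataFrame:
    """Per subject (and mode, when present) number of enriched regions.

    Input is a concatenation of enrichment reports carrying a ``sample_id``
    column and optionally a ``mode`` column; output has one row per group
    with ``n_enriched`` and its natural-log count (log(n + 1) at zero,
    flagged), mirroring the SEV-count convention.
    """
    keys = ["sample_id"] + (["mode"] if "mode" in reports.columns else [])
    rows = []
    for key, grp in reports.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n_enriched = int(grp["enriched"].sum())
        log_n, offset = safe_log_count(n_enriched)
        rows.append(
            dict(
                zip(keys, key),
                n_enriched=n_enriched,
                log_enriched=log_n,
                log_offset_used=offset,
            )
        )
    return pd.DataFrame(rows)
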