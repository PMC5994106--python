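"""Readers, writers and quality filtering for methylation matrices and regions.

Conventions
-----------
* Beta and detection-p matrices are :class:`pandas.DataFrame` objects with
  probe identifiers as the index and sample identifiers as columns; values
  are fractions in [0, 1] (missing allowed in beta matrices).
* Probe annotation is a DataFrame indexed by probe id with columns
  ``chromosome``, ``position`` (1-based bp), ``strand``, ``gene_id``,
  ``island_id`` and the boolean exclusion flags ``snp_overlap``,
  ``sex_chromosome``, ``rare_variant_overlap``.
* Region sets are DataFrames with columns ``region_id``, ``chromosome``,
  ``start``, ``end`` (0-based, half-open), ``kind`` and optional ``strand``.
  The probe -> region containment test converts the 1-based probe position
  explicitly: probe at position ``p`` lies in ``[start, end)`` iff
  ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

ANNOTATION_COLUMNS = [
    "chromosome",
    "position",
    "strand",
    "gene_id",
    "island_id",
    "snp_overlap",
    "sex_chromosome",
    "rare_variant_overlap",
]

#: fixed attribution order for probe removal criteria
FILTER_CRITERIA = ["snp_overlap", "sex_chromosome", "rare_variant_overlap"]


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path, lo: float, hi: float, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"malformed {what} file {path}: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce")
    bad_numeric = values.isna() & df.notna()
    if bad_numeric.to_numpy().any():
        row = int(np.where(bad_numeric.any(axis=1))[0][0])
        raise ParseError(f"non-numeric {what} value", line=row + 2)
    out_of_range = (values < lo) | (values > hi)
    if out_of_range.to_numpy(na_value=False).any():
        row = int(np.where(out_of_range.any(axis=1))[0][0])
        raise ParseError(
            f"{what} value outside [{lo}, {hi}]", line=row + 2
        )
    if not df.index.is_unique:
        raise ParseError(f"duplicate probe ids in {what} file {path}")
    values.index.name = "probe_id"
    return values


def read_beta_tsv(path) -> pd.DataFrame:
    """Read a probes x samples beta matrix from TSV."""
    return _read_matrix_tsv(path, 0.0, 1.0, "beta")


def read_detp_tsv(path) -> pd.DataFrame:
    """Read a detection-p matrix (same layout as the beta matrix)."""
    return _read_matrix_tsv(path, 0.0, 1.0, "detection-p")


def write_beta_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a matrix as TSV with 12 significant digits (round-trip safe)."""
    matrix.to_csv(path, sep="\t", float_format="%.12g", index_label="probe_id")


write_detp_tsv = write_beta_tsv


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def validate_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    if (annotation["position"] < 1).any():
        raise ValidationError("annotation positions must be >= 1 (1-based)")
    if not annotation.index.is_unique:
        raise ValidationError("duplicate probe ids in annotation")


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype={"gene_id": "string", "island_id": "string"},
    )
    for flag in FILTER_CRITERIA:
        ann[flag] = ann[flag].astype(bool)
    ann["position"] = ann["position"].astype(np.int64)
    validate_annotation(ann)
    return ann


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe_id")


def read_phenotypes(path, categorical: list[str] | None = None) -> pd.DataFrame:
    """Read a sample x trait table; non-numeric columns become categoricals.

    Columns listed in *categorical* are coerced to category dtype even when
    they parse as numbers (e.g. 0/1 indicators).
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.isna().any().any():
        raise ValidationError("phenotype table contains missing values")
    categorical = set(categorical or [])
    for col in table.columns:
        if col in categorical or table[col].dtype == object:
            table[col] = table[col].astype("category")
    return table


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open, BED6)
# ---------------------------------------------------------------------------

def read_bed(path, kind: str = "region") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError("BED line needs >= 4 fields", line=lineno)
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else None
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError("non-integer BED coordinate", line=lineno) from exc
            if start_i >= end_i:
                raise ParseError("BED start must be < end", line=lineno)
            rows.append(
                {
                    "region_id": name,
                    "chromosome": chrom,
                    "start": start_i,
                    "end": end_i,
                    "kind": kind,
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows)


def write_bed(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            strand = r.get("strand") or "."
            fh.write(
                f"{r['chromosome']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r['region_id']}\t0\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Outcome of flag-based probe removal.

    ``removed_by`` attributes each removed probe to the first matching
    criterion in the fixed order SNP overlap, sex chromosome, rare variant.
    """

    removed_by: dict[str, int] = field(default_factory=dict)
    n_removed: int = 0
    kept_probes: list[str] = field(default_factory=list)


def filter_probes(
    matrix: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop probes flagged for SNP overlap, sex chromosomes or rare variants.

    The input matrix is not modified; every matrix probe must be annotated.
    """
    unannotated = matrix.index.difference(annotation.index)
    if len(unannotated) > 0:
        raise ValidationError(f"unannotated probe id: {unannotated[0]!r}")
    ann = annotation.loc[matrix.index]
    attributed: pd.Series = pd.Series("", index=matrix.index, dtype=object)
    for crit in FILTER_CRITERIA:
        mask = ann[crit].to_numpy(dtype=bool) & (attributed == "").to_numpy()
        attributed[mask] = crit
    removed = attributed != ""
    report = FilterReport(
        removed_by={c: int((attributed == c).sum()) for c in FILTER_CRITERIA},
        n_removed=int(removed.sum()),
        kept_probes=list(matrix.index[~removed]),
    )
    return matrix.loc[~removed], report


# ---------------------------------------------------------------------------
# Greedycut
# ---------------------------------------------------------------------------

def greedycut(
    detp: pd.DataFrame,
    threshold: float = 0.05,
    max_unreliable: float = 0.0,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Iteratively strip the worst probe or sample by unreliable fraction.

    An entry is unreliable iff its detection p-value is **not below** the
    threshold (``p >= threshold``).  At each step the single row (probe) or
    column (sample) with the highest fraction of unreliable entries is
    removed — ties broken probe-before-sample, then lexicographic id — until
    every remaining row and column has unreliable fraction <= *max_unreliable*.

    Returns the kept probe ids, kept sample ids, and a trace DataFrame with
    one row per removal (axis, id, unreliable fraction that triggered it).
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must be in (0, 1)")
    if not (0.0 <= max_unreliable < 1.0):
        raise ValidationError("max_unreliable must be in [0, 1)")

    unreliable = detp.to_numpy() >= threshold
    probe_ids = np.asarray(detp.index, dtype=object)
    sample_ids = np.asarray(detp.columns, dtype=object)
    row_alive = np.ones(unreliable.shape[0], dtype=bool)
    col_alive = np.ones(unreliable.shape[1], dtype=bool)
    row_bad = unreliable.sum(axis=1).astype(np.int64)
    col_bad = unreliable.sum(axis=0).astype(np.int64)

    trace_rows = []
    while True:
        n_rows = int(row_alive.sum())
        n_cols = int(col_alive.sum())
        if n_rows == 0 or n_cols == 0:
            raise ValidationError("greedycut removed all data")
        row_frac = np.where(row_alive, row_bad / n_cols, -1.0)
        col_frac = np.where(col_alive, col_bad / n_rows, -1.0)
        best_row = _argmax_lexicographic(row_frac, probe_ids)
        best_col = _argmax_lexicographic(col_frac, sample_ids)
        worst = max(row_frac[best_row], col_frac[best_col])
        if worst <= max_unreliable:
            break
        if row_frac[best_row] >= col_frac[best_col]:  # probe before sample
            row_alive[best_row] = False
            col_bad -= unreliable[best_row, :]
            trace_rows.append(("probe", probe_ids[best_row], row_frac[best_row]))
        else:
            col_alive[best_col] = False
            row_bad -= unreliable[:, best_col]
            trace_rows.append(("sample", sample_ids[best_col], col_frac[best_col]))

    trace = pd.DataFrame(trace_rows, columns=["axis", "id", "fraction"])
    return list(probe_ids[row_alive]), list(sample_ids[col_alive]), trace


def _argmax_lexicographic(frac: np.ndarray, ids: np.ndarray) -> int:
    """Index of the maximum fraction, ties resolved by smallest id."""
    best = float(frac.max())
    tied = np.flatnonzero(frac == best)
    if len(tied) == 1:
        return int(tied[0])
    order = np.argsort(ids[tied].astype(str), kind="stable")
    return int(tied[order[0]])


# ---------------------------------------------------------------------------
# derived regions
# ---------------------------------------------------------------------------

def build_promoters(genes: pd.DataFrame, upstream: int = 1500, downstream: int = 500) -> pd.DataFrame:
    """Promoter regions around each gene's TSS, oriented by strand.

    For a plus-strand gene the TSS is the region start and the promoter is
    ``[TSS - upstream, TSS + downstream)``; for a minus-strand gene the TSS
    is the region end and the promoter is ``[TSS - downstream, TSS + upstream)``.
    """
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[
            genes["strand"].isna() | ~genes["strand"].isin(["+", "-"]), "region_id"
        ]
        raise ValidationError(f"gene without strand: {bad.iloc[0]!r}")
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            tss = int(g["start"])
            start, end = tss - upstream, tss + downstream
        else:
            tss = int(g["end"])
            start, end = tss - downstream, tss + upstream
        rows.append(
            {
                "region_id": f"prom_{g['region_id']}",
                "chromosome": g["chromosome"],
                "start": max(0, start),
                "end": end,
                "kind": "promoter",
                "strand": g["strand"],
            }
        )
    return pd.DataFrame(rows)


def build_tiling(
    annotation: pd.DataFrame,
    width: int = 5000,
    chromosome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Non-overlapping fixed-width windows covering each chromosome.

    Chromosome lengths default to the maximum annotated probe position; the
    last window is truncated at the chromosome length.
    """
    if width <= 0:
        raise ValidationError("tiling width must be positive")
    lengths = chromosome_lengths or (
        annotation.groupby("chromosome", sort=True)["position"].max().to_dict()
    )
    rows = []
    for chrom in sorted(lengths):
        length = int(lengths[chrom])
        start = 0
        idx = 0
        while start < length:
            end = min(start + width, length)
            rows.append(
                {
                    "region_id": f"tile_{chrom}_{idx}",
                    "chromosome": chrom,
                    "start": start,
                    "end": end,
                    "kind": "tiling",
                    "strand": None,
                }
            )
            start += width
            idx += 1
    return pd.DataFrame(rows)


def probe_region_index(
    annotation: pd.DataFrame, regions: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Map region_id -> array of probe ids contained in the region.

    Containment converts the 1-based probe position to 0-based before the
    half-open interval test.
    """
    index: dict[str, np.ndarray] = {}
    by_chrom = {
        chrom: grp.sort_values("position")
        for chrom, grp in annotation.groupby("chromosome", sort=False)
    }
    for _, r in regions.iterrows():
        grp = by_chrom.get(r["chromosome"])
        if grp is None:
            index[r["region_id"]] = np.array([], dtype=object)
            continue
        pos0 = grp["position"].to_numpy() - 1  # to 0-based
        lo = np.searchsorted(pos0, r["start"], side="left")
        hi = np.searchsorted(pos0, r["end"], side="left")
        index[r["region_id"]] = grp.index.to_numpy(dtype=object)[lo:hi]
    return index


def build_regions(
    annotation: pd.DataFrame,
    genes: pd.DataFrame,
    tiling_width: int = 5000,
    chromosome_lengths: dict[str, int] | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, dict[str, np.ndarray]]]:
    """Assemble the derived region sets (promoters, tiling) next to the genes.

    Returns ``(region_sets, indexes)`` where both are keyed by region kind.
    """
    promoters = build_promoters(genes)
    tiling = build_tiling(annotation, tiling_width, chromosome_lengths)
    region_sets = {"gene": genes, "promoter": promoters, "tiling": tiling}
    indexes = {
        kind: probe_region_index(annotation, regions)
        for kind, regions in region_sets.items()
    }
    return region_sets, indexes
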