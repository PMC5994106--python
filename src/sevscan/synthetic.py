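"""Synthetic methylome cohorts with ground truth for the SEV pipeline.

The generator emulates the statistical structure the SEV analysis assumes
on a 450K-style array study of cord blood: per-probe bimodal beta-value
baselines (hypomethylated near 0.1, hypermethylated near 0.9, a minor
intermediate mass), beta-distributed subject noise around each probe mean,
chip-batch shifts, rare per-subject outlier epimutations injected beyond
the reference cohort's own 3xIQR fences, an optional subject carrying a
clustered imprinting defect across one imprinted DMR, detection p-values
with a small unreliable fraction, and correlated mixed phenotypes driven by
a handful of latent factors that may also modulate each subject's
epimutation rate.

Two guarantees make the ground truth exact rather than approximate:

* every injected epimutation is placed at the midpoint between the fence
  and the nearer of {0, 1}, so it is strictly outside the fences whichever
  side is feasible;
* every non-injected value is rejection-resampled until it lies strictly
  inside the reference-derived fences (fences recomputed until stable), so
  calling against the uncontaminated reference recovers the injected set
  exactly, with no background calls.

One RNG stream is split from the master seed per logical component
(annotation / betas / epimutations / phenotypes / detection p), so changing
e.g. the epimutation rate does not perturb the baseline betas.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sev import compute_fences

_STREAMS = ["annotation", "betas", "sevs", "phenotypes", "detp", "external"]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Cohort sizes default to 41 naturally conceived reference newborns and
    23 cases, the design this pipeline targets.  ``sev_rate`` is the
    expected number of injected epimutations per subject (Poisson), scaled
    per subject by ``exp(sum(phenotype_effect[f] * factor_f))`` when latent
    factors carry an effect on SEV burden.
    """

    seed: int = 0
    n_probes: int = 10000
    n_chromosomes: int = 5
    n_genes: int = 100
    n_imprinted_dmrs: int = 8
    n_reference: int = 41
    n_cases: int = 23
    sev_rate: float = 20.0
    defect_subject: str | None = None
    defect_dmr: str | None = None
    batch_count: int = 2
    batch_shift_sd: float = 0.01
    unreliable_fraction: float = 0.001
    phenotype_effect: dict[str, float] = field(default_factory=dict)
    # annotation structure
    min_gene_probes: int = 5
    max_gene_probes: int = 15
    min_dmr_probes: int = 8
    max_dmr_probes: int = 12
    snp_fraction: float = 0.02
    sex_fraction: float = 0.03
    rare_variant_fraction: float = 0.01
    # beta noise: Beta(mean*nu, (1-mean)*nu)
    precision: float = 100.0
    n_latent_factors: int = 4
    fence_multiplier: float = 3.0

    def validate(self) -> None:
        counts = {
            "n_probes": self.n_probes,
            "n_chromosomes": self.n_chromosomes,
            "n_genes": self.n_genes,
            "n_imprinted_dmrs": self.n_imprinted_dmrs,
            "n_reference": self.n_reference,
            "n_cases": self.n_cases,
            "batch_count": self.batch_count,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.sev_rate < 0:
            raise ConfigError("sev_rate must be >= 0")
        if not (0.0 <= self.unreliable_fraction <= 1.0):
            raise ConfigError("unreliable_fraction must be in [0, 1]")
        for frac in (self.snp_fraction, self.sex_fraction, self.rare_variant_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("flag fractions must be in [0, 1]")
        needed = (
            self.n_genes * self.min_gene_probes
            + self.n_imprinted_dmrs * self.min_dmr_probes
        )
        if needed > self.n_probes:
            raise ConfigError(
                f"n_probes={self.n_probes} too small: {self.n_genes} genes x "
                f">= {self.min_gene_probes} probes plus {self.n_imprinted_dmrs} "
                f"DMRs x >= {self.min_dmr_probes} probes need at least {needed} probes"
            )

    def rng_streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {
            name: np.random.default_rng(seq) for name, seq in zip(_STREAMS, children)
        }

    @property
    def n_subjects(self) -> int:
        return self.n_reference + self.n_cases

    def sample_ids(self) -> tuple[list[str], list[str]]:
        controls = [f"ctl{i + 1:03d}" for i in range(self.n_reference)]
        cases = [f"case{i + 1:03d}" for i in range(self.n_cases)]
        return controls, cases


@dataclass
class SimulatedAnnotation:
    """Probe annotation plus the gene and imprinted-DMR region sets."""

    probes: pd.DataFrame
    genes: pd.DataFrame
    dmrs: pd.DataFrame


@dataclass
class GroundTruth:
    """What the generator actually planted, for exact downstream checks."""

    injected: pd.DataFrame  # sample_id, probe_id, direction, value, original_value
    defect_subject: str | None
    defect_dmr: str | None
    defect_probes: list[str]
    latent_factors: pd.DataFrame  # subjects x f1..fK
    true_sev_slopes: dict[str, float]
    probe_means: pd.Series
    fences: pd.DataFrame  # reference fences the injections were placed against

    def injected_sets(self) -> dict[str, set[tuple[str, str]]]:
        out: dict[str, set[tuple[str, str]]] = {}
        for sample, grp in self.injected.groupby("sample_id"):
            out[str(sample)] = set(zip(grp["probe_id"], grp["direction"]))
        return out

    def to_json(self, path) -> None:
        payload = {
            "injected": self.injected.to_dict(orient="records"),
            "defect_subject": self.defect_subject,
            "defect_dmr": self.defect_dmr,
            "defect_probes": self.defect_probes,
            "latent_factors": self.latent_factors.round(10).to_dict(orient="index"),
            "true_sev_slopes": self.true_sev_slopes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Lay out probes, genes and imprinted DMRs on synthetic chromosomes.

    Probes get strictly increasing 1-based positions with a minimum spacing
    of 100 bp; genes are contiguous blocks of at least ``min_gene_probes``
    probes and DMRs contiguous blocks of at least ``min_dmr_probes`` probes
    (so a clustered defect is enrichable), placed disjointly.  The first
    couple of probes of each gene are marked as its CpG island.
    """
    config.validate()
    rng = config.rng_streams()["annotation"]

    per_chrom = np.full(config.n_chromosomes, config.n_probes // config.n_chromosomes)
    per_chrom[: config.n_probes % config.n_chromosomes] += 1
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    probe_rows = []
    offsets = {}
    idx = 0
    for chrom, count in zip(chrom_names, per_chrom):
        gaps = 100 + rng.integers(0, 900, size=count)
        positions = np.cumsum(gaps)
        offsets[chrom] = idx
        for pos in positions:
            probe_rows.append((f"cg{idx:07d}", chrom, int(pos)))
            idx += 1
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chromosome", "position"])
    probes = probes.set_index("probe_id")
    probes["strand"] = np.where(rng.random(config.n_probes) < 0.5, "+", "-")
    probes["gene_id"] = ""
    probes["island_id"] = ""
    probes["dmr_id"] = ""

    # block sizes, then greedy placement on the chromosome with most room
    gene_sizes = rng.integers(
        config.min_gene_probes, config.max_gene_probes + 1, size=config.n_genes
    )
    dmr_sizes = rng.integers(
        config.min_dmr_probes, config.max_dmr_probes + 1, size=config.n_imprinted_dmrs
    )
    blocks = [("gene", f"gene{i + 1:03d}", int(s)) for i, s in enumerate(gene_sizes)]
    blocks += [("dmr", f"dmr{i + 1:02d}", int(s)) for i, s in enumerate(dmr_sizes)]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    free: dict[str, list[tuple[int, int]]] = {
        chrom: [(offsets[chrom], offsets[chrom] + int(count))]
        for chrom, count in zip(chrom_names, per_chrom)
    }
    placements = []
    for kind, name, size in blocks:
        candidates = [
            (chrom, seg_i, seg)
            for chrom, segs in free.items()
            for seg_i, seg in enumerate(segs)
            if seg[1] - seg[0] >= size
        ]
        if not candidates:
            raise ConfigError(
                f"n_probes={config.n_probes} cannot host block {name} of "
                f"{size} probes: no contiguous room left"
            )
        chrom, seg_i, (lo, hi) = candidates[int(rng.integers(len(candidates)))]
        start = int(rng.integers(lo, hi - size + 1))
        placements.append((kind, name, chrom, start, start + size))
        free[chrom].pop(seg_i)
        if start > lo:
            free[chrom].append((lo, start))
        if start + size < hi:
            free[chrom].append((start + size, hi))

    gene_rows, dmr_rows = [], []
    probe_ids = probes.index.to_numpy(dtype=object)
    positions = probes["position"].to_numpy()
    for kind, name, chrom, lo, hi in placements:
        ids = probe_ids[lo:hi]
        start0 = int(positions[lo]) - 1  # BED 0-based half-open around the probes
        end0 = int(positions[hi - 1])
        if kind == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            probes.loc[ids, "gene_id"] = name
            probes.loc[ids[:2], "island_id"] = f"isl_{name}"
            gene_rows.append((name, chrom, start0, end0, "gene", strand))
        else:
            probes.loc[ids, "dmr_id"] = name
            dmr_rows.append((name, chrom, start0, end0, "imprinted_dmr", None))

    cols = ["region_id", "chromosome", "start", "end", "kind", "strand"]
    genes = pd.DataFrame(sorted(gene_rows), columns=cols)
    dmrs = pd.DataFrame(sorted(dmr_rows), columns=cols)

    for flag, frac in (
        ("snp_overlap", config.snp_fraction),
        ("sex_chromosome", config.sex_fraction),
        ("rare_variant_overlap", config.rare_variant_fraction),
    ):
        probes[flag] = rng.random(config.n_probes) < frac

    return SimulatedAnnotation(probes=probes, genes=genes, dmrs=dmrs)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _draw_betas(
    rng: np.random.Generator, means: np.ndarray, nu: float, size: tuple[int, int]
) -> np.ndarray:
    return rng.beta(means[:, None] * nu, (1.0 - means[:, None]) * nu, size=size)


def generate_cohort(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the beta matrix, detection p-values and ground truth.

    Column order is reference subjects (controls) first, then cases.  The
    fences recorded in the ground truth are computed from the reference
    columns *before* injection (and excluding the defect subject's aberrant
    entries), i.e. from the uncontaminated reference this generator's
    guarantees refer to.
    """
    config.validate()
    streams = config.rng_streams()
    rng_b = streams["betas"]
    rng_s = streams["sevs"]
    rng_p = streams["detp"]
    rng_f = streams["phenotypes"]

    probes = annotation.probes
    n_probes = len(probes)
    if n_probes != config.n_probes:
        raise ConfigError("annotation does not match config.n_probes")
    controls, cases = config.sample_ids()
    samples = controls + cases
    n_sub = len(samples)

    # bimodal probe baselines: ~45% hypo, ~45% hyper, minor intermediate mass
    mode = rng_b.random(n_probes)
    means = np.where(
        mode < 0.45,
        rng_b.normal(0.10, 0.03, n_probes),
        np.where(
            mode < 0.90,
            rng_b.normal(0.90, 0.03, n_probes),
            rng_b.uniform(0.30, 0.70, n_probes),
        ),
    )
    means = np.clip(means, 0.02, 0.98)

    values = _draw_betas(rng_b, means, config.precision, (n_probes, n_sub))

    # chip-batch shifts, per (batch, probe), then clip to the open unit range
    batches = pd.Series(
        [f"batch{(i % config.batch_count) + 1}" for i in range(n_sub)], index=samples
    )
    batch_shift = rng_b.normal(0.0, config.batch_shift_sd, (config.batch_count, n_probes))
    batch_codes = batches.astype("category").cat.codes.to_numpy()
    values = values + batch_shift[batch_codes, :].T
    values = np.clip(values, 1e-4, 1.0 - 1e-4)

    # clustered imprinting defect: mid-range aberrant values across one DMR
    defect_subject = config.defect_subject
    defect_dmr = config.defect_dmr
    defect_probes: list[str] = []
    defect_mask = np.zeros((n_probes, n_sub), dtype=bool)
    if defect_subject is not None:
        if defect_subject not in samples:
            raise ConfigError(f"defect_subject {defect_subject!r} not in cohort")
        if defect_dmr is None:
            defect_dmr = str(annotation.dmrs["region_id"].iloc[0])
        if defect_dmr not in set(annotation.dmrs["region_id"]):
            raise ConfigError(f"defect_dmr {defect_dmr!r} not in annotation")
        dmr_rows = probes["dmr_id"].to_numpy() == defect_dmr
        col = samples.index(defect_subject)
        # ~0.5 shifted toward the opposite mode of each probe
        aberrant = 0.5 + 0.2 * np.sign(0.5 - means[dmr_rows])
        aberrant = aberrant + rng_s.normal(0.0, 0.02, aberrant.shape)
        values[dmr_rows, col] = np.clip(aberrant, 1e-4, 1.0 - 1e-4)
        defect_mask[dmr_rows, col] = True
        defect_probes = list(probes.index[dmr_rows])

    # enforce: every non-defect value strictly inside the reference fences
    ref_cols = np.arange(config.n_reference)
    fences = _enforce_within_fences(
        values, means, batch_shift, batch_codes, ref_cols, defect_mask, config, rng_b,
        probes.index,
    )

    # latent phenotype factors, shared with generate_phenotypes via the truth
    factor_names = [f"f{i + 1}" for i in range(config.n_latent_factors)]
    latent = pd.DataFrame(
        rng_f.standard_normal((n_sub, config.n_latent_factors)),
        index=samples,
        columns=factor_names,
    )
    slopes = {str(k): float(v) for k, v in config.phenotype_effect.items()}
    unknown = set(slopes) - set(factor_names)
    if unknown:
        raise ConfigError(f"phenotype_effect names unknown factors: {sorted(unknown)}")
    log_rate_shift = np.zeros(n_sub)
    for fac, slope in slopes.items():
        log_rate_shift += slope * latent[fac].to_numpy()

    # injected epimutations: Poisson count per subject, feasible-side placement
    lower = fences["lower"].to_numpy()
    upper = fences["upper"].to_numpy()
    usable = fences["usable"].to_numpy(dtype=bool)
    flagged = (
        probes["snp_overlap"] | probes["sex_chromosome"] | probes["rare_variant_overlap"]
    ).to_numpy()
    feasible_low = usable & ~flagged & (lower > 0.0)
    feasible_high = usable & ~flagged & (upper < 1.0)
    eligible = feasible_low | feasible_high
    eligible_idx = np.flatnonzero(eligible)

    injected_rows = []
    probe_ids = probes.index.to_numpy(dtype=object)
    for j, sample in enumerate(samples):
        rate = config.sev_rate * float(np.exp(log_rate_shift[j]))
        count = int(rng_s.poisson(rate)) if rate > 0 else 0
        count = min(count, len(eligible_idx))
        if count == 0:
            continue
        chosen = rng_s.choice(eligible_idx, size=count, replace=False)
        if defect_subject is not None and sample == defect_subject:
            chosen = np.array(
                [i for i in chosen if probe_ids[i] not in set(defect_probes)],
                dtype=int,
            )
        for i in chosen:
            sides = []
            if feasible_low[i]:
                sides.append("low")
            if feasible_high[i]:
                sides.append("high")
            direction = sides[int(rng_s.integers(len(sides)))]
            new_val = lower[i] / 2.0 if direction == "low" else (upper[i] + 1.0) / 2.0
            injected_rows.append(
                {
                    "sample_id": sample,
                    "probe_id": probe_ids[i],
                    "direction": direction,
                    "value": float(new_val),
                    "original_value": float(values[i, j]),
                }
            )
            values[i, j] = new_val

    beta = pd.DataFrame(values, index=probes.index, columns=samples)

    detp_vals = rng_p.uniform(0.0, 0.01, (n_probes, n_sub))
    if config.unreliable_fraction > 0:
        bad = rng_p.random((n_probes, n_sub)) < config.unreliable_fraction
        detp_vals[bad] = rng_p.uniform(0.05, 0.5, int(bad.sum()))
    detp = pd.DataFrame(detp_vals, index=probes.index, columns=samples)

    truth = GroundTruth(
        injected=pd.DataFrame(
            injected_rows,
            columns=["sample_id", "probe_id", "direction", "value", "original_value"],
        ),
        defect_subject=defect_subject,
        defect_dmr=defect_dmr,
        defect_probes=defect_probes,
        latent_factors=latent,
        true_sev_slopes=slopes,
        probe_means=pd.Series(means, index=probes.index),
        fences=fences,
    )
    return beta, detp, truth


def _enforce_within_fences(
    values, means, batch_shift, batch_codes, ref_cols, defect_mask, config, rng,
    probe_index,
    max_iter: int = 50,
):
    """Rejection-resample natural outliers until fences are stable and clean.

    Fences come from the reference columns; any non-defect entry (any
    subject) outside them is redrawn from its probe's beta distribution
    (batch shift re-applied).  Reference resampling can move the fences, so
    the loop recomputes them until no violations remain; pathological
    leftovers are finally clamped to the probe's reference median.
    """
    fences = None
    for _ in range(max_iter):
        ref_df = pd.DataFrame(values[:, ref_cols], index=probe_index)
        fences = compute_fences(
            ref_df,
            min_n=min(10, len(ref_cols)),
            multiplier=config.fence_multiplier,
        )
        lower = fences["lower"].to_numpy()[:, None]
        upper = fences["upper"].to_numpy()[:, None]
        outside = ((values <= lower) | (values >= upper)) & ~defect_mask
        # values exactly on a fence are not outliers, but resample them too
        # so replicate noise cannot flip them across the fence ambiguously
        outside &= fences["usable"].to_numpy(dtype=bool)[:, None]
        if not outside.any():
            return fences
        rows, cols = np.nonzero(outside)
        m = means[rows]
        new = rng.beta(m * config.precision, (1.0 - m) * config.precision)
        new = new + batch_shift[batch_codes[cols], rows]
        values[rows, cols] = np.clip(new, 1e-4, 1.0 - 1e-4)
    # fallback: clamp to the reference median (inside [q1, q3] by definition)
    med = 0.5 * (fences["q1"].to_numpy() + fences["q3"].to_numpy())
    rows, cols = np.nonzero(outside)
    values[rows, cols] = med[rows]
    ref_df = pd.DataFrame(values[:, ref_cols], index=probe_index)
    return compute_fences(
        ref_df, min_n=min(10, len(ref_cols)), multiplier=config.fence_multiplier
    )


def generate_reference_cohort(
    config: SimulationConfig,
    annotation: SimulatedAnnotation,
    probe_means: pd.Series,
    n_samples: int,
    mean_shift_sd: float = 0.0,
    prefix: str = "ext",
    stream: str = "external",
) -> pd.DataFrame:
    """An external reference population sharing the cohort's probe baselines.

    ``mean_shift_sd`` perturbs the probe means before drawing, emulating a
    related cohort (small shift: external cord blood) or a different tissue
    (larger shift: general-population whole blood).
    """
    # one deterministic stream per (seed, prefix) population
    tag = zlib.crc32(f"{stream}:{prefix}".encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, tag]))
    means = probe_means.to_numpy().copy()
    if mean_shift_sd > 0:
        means = means + rng.normal(0.0, mean_shift_sd, means.shape)
    means = np.clip(means, 0.02, 0.98)
    vals = _draw_betas(rng, means, config.precision, (len(means), n_samples))
    cols = [f"{prefix}{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(vals, index=probe_means.index, columns=cols)


def make_replicates(
    beta: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Technical replicates: small beta noise, identical injected SEVs.

    Emulates re-running subjects through independent bisulfite conversions:
    every value gets N(0, noise_sd) noise, then the injected epimutation
    values are restored exactly (the epimutation is a property of the
    sample, not of the assay noise).
    """
    rng = np.random.default_rng(seed)
    rep = beta.to_numpy() + rng.normal(0.0, noise_sd, beta.shape)
    rep = np.clip(rep, 1e-4, 1.0 - 1e-4)
    rep = pd.DataFrame(rep, index=beta.index, columns=beta.columns)
    for _, row in truth.injected.iterrows():
        rep.loc[row["probe_id"], row["sample_id"]] = row["value"]
    return rep


def uncontaminated_reference(
    beta: pd.DataFrame, truth: GroundTruth, n_reference: int
) -> pd.DataFrame:
    """Reference columns with injected values restored to their originals."""
    ref = beta.iloc[:, :n_reference].copy()
    ref_samples = set(ref.columns)
    for _, row in truth.injected.iterrows():
        if row["sample_id"] in ref_samples:
            ref.loc[row["probe_id"], row["sample_id"]] = row["original_value"]
    return ref


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def batch_labels(config: SimulationConfig) -> pd.Series:
    controls, cases = config.sample_ids()
    samples = controls + cases
    return pd.Series(
        [f"batch{(i % config.batch_count) + 1}" for i in range(len(samples))],
        index=samples,
        name="batch",
    )


#: continuous traits: (name, intercept, scale, {factor: loading}, noise_sd)
_CONTINUOUS_TRAITS = [
    ("birth_weight", 3300.0, 350.0, {"f1": 0.8, "f2": 0.2}, 150.0),
    ("birth_centile", 50.0, 28.0, {"f1": 0.75}, 8.0),
    ("gestational_age", 39.5, 1.1, {"f1": 0.7}, 0.6),
    ("mother_age", 33.0, 2.2, {"f3": 0.6}, 2.0),
    ("pregestational_weight", 62.0, 7.0, {"f1": 0.7}, 4.0),
    ("mother_bmi", 23.0, 2.5, {"f1": 0.7}, 1.2),
    ("father_bmi", 25.0, 2.0, {"f1": 0.5}, 1.5),
    ("gestational_weight_gain", 12.0, 2.5, {"f2": 0.5}, 2.0),
]

#: binary traits: (name, intercept, {factor: loading}) on the logit scale
_BINARY_TRAITS = [
    ("smoking", -1.4, {"f2": 1.5}),
    ("cesarean", -0.7, {"f1": 1.4}),
    ("folate_supplementation", 0.4, {"f4": 1.5}),
    ("adverse_outcome", -2.0, {"f1": 1.0}),
]

_CELL_TYPES = ["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]
_CELL_BASE = np.array([0.08, 0.14, 0.04, 0.06, 0.08, 0.55])
_CELL_LOADINGS = {
    "CD8T": {"f1": 0.5},
    "CD4T": {"f1": 0.4},
    "NK": {"f3": 0.5},
    "Bcell": {"f1": 0.4},
    "Mono": {},
    "Gran": {"f1": -0.2},
}

_SEASONS = ["winter", "spring", "summer", "autumn"]


def generate_phenotypes(
    config: SimulationConfig,
    truth: GroundTruth,
    loading_scale: float = 1.0,
    season_noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Mixed phenotype table driven by the cohort's latent factors.

    Continuous traits (weights, BMI, gestational age, centiles, six cord
    blood cell proportions) and categoricals (sex, smoking, cesarean,
    folate supplementation, season of birth, parity, case/control) are
    noisy functions of at most four latent factors; factor 1 dominates, so
    the leading FAMD dimension tracks it.  ``loading_scale`` rescales every
    factor loading (0 gives mutually independent traits);
    ``season_noise_sd`` is the noise on the factor-3 score behind season of
    birth (0 makes season deterministic in that factor).

    Cell proportions are non-negative and sum to 0.97 per subject.
    """
    rng = config.rng_streams()["phenotypes"]
    rng = np.random.default_rng(rng.integers(2**31))  # after latent draw in cohort
    latent = truth.latent_factors
    samples = latent.index
    n = len(samples)

    def combo(loadings: dict[str, float]) -> np.ndarray:
        out = np.zeros(n)
        for fac, w in loadings.items():
            out += loading_scale * w * latent[fac].to_numpy()
        return out

    table = pd.DataFrame(index=samples)
    for name, mu, scale, loadings, noise in _CONTINUOUS_TRAITS:
        table[name] = mu + scale * combo(loadings) + rng.normal(0.0, noise, n)
    table["birth_centile"] = table["birth_centile"].clip(1.0, 99.0)

    raw = np.empty((n, len(_CELL_TYPES)))
    for c, cell in enumerate(_CELL_TYPES):
        raw[:, c] = _CELL_BASE[c] * np.exp(
            combo(_CELL_LOADINGS[cell]) + rng.normal(0.0, 0.15, n)
        )
    raw = 0.97 * raw / raw.sum(axis=1, keepdims=True)
    for c, cell in enumerate(_CELL_TYPES):
        table[cell] = raw[:, c]

    for name, intercept, loadings in _BINARY_TRAITS:
        prob = 1.0 / (1.0 + np.exp(-(intercept + combo(loadings))))
        table[name] = pd.Categorical(
            np.where(rng.random(n) < prob, "yes", "no"), categories=["no", "yes"]
        )
    table["sex"] = pd.Categorical(
        np.where(rng.random(n) < 0.5, "F", "M"), categories=["F", "M"]
    )

    parity_latent = combo({"f2": 0.6}) + rng.normal(0.0, 1.0, n)
    table["parity"] = pd.Categorical(
        np.select(
            [parity_latent < 0.0, parity_latent < 1.0], ["0", "1"], default="2plus"
        ),
        categories=["0", "1", "2plus"],
    )

    season_score = loading_scale * latent["f3"].to_numpy()
    if season_noise_sd > 0:
        season_score = season_score + rng.normal(0.0, season_noise_sd, n)
    edges = np.quantile(season_score, [0.25, 0.5, 0.75]) if loading_scale or season_noise_sd else None
    if edges is None or not np.all(np.diff(edges) > 0):
        idx = np.zeros(n, dtype=int)
    else:
        idx = np.searchsorted(edges, season_score, side="right")
    table["season_of_birth"] = pd.Categorical(
        [_SEASONS[i] for i in idx], categories=_SEASONS
    )

    controls, _ = config.sample_ids()
    table["case_control"] = pd.Categorical(
        ["control" if s in set(controls) else "case" for s in samples],
        categories=["control", "case"],
    )
    return table
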