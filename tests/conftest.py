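import numpy as np
import pandas as pd
import pytest

from sevscan.synthetic import SimulationConfig, generate_annotation, generate_cohort


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        seed=11,
        n_probes=800,
        n_chromosomes=3,
        n_genes=15,
        n_imprinted_dmrs=2,
        n_reference=20,
        n_cases=10,
        sev_rate=10.0,
        batch_shift_sd=0.005,
        unreliable_fraction=0.002,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small cohort: (config, annotation, beta, detp, truth)."""
    cfg = small_config()
    ann = generate_annotation(cfg)
    beta, detp, truth = generate_cohort(cfg, ann)
    return cfg, ann, beta, detp, truth


def toy_annotation(positions_by_chrom: dict[str, list[int]]) -> pd.DataFrame:
    """Minimal probe annotation from 1-based positions per chromosome."""
    rows = []
    i = 0
    for chrom, positions in positions_by_chrom.items():
        for pos in positions:
            rows.append(
                {
                    "probe_id": f"p{i:03d}",
                    "chromosome": chrom,
                    "position": pos,
                    "strand": "+",
                    "gene_id": "",
                    "island_id": "",
                    "snp_overlap": False,
                    "sex_chromosome": False,
                    "rare_variant_overlap": False,
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("probe_id")


def fivenum_oracle(values: np.ndarray) -> tuple[float, float]:
    """Independent Tukey-hinge oracle via explicit median-of-halves."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    half = (n + 1) // 2
    lower_half = x[:half]
    upper_half = x[n - half:]
    return float(np.median(lower_half)), float(np.median(upper_half))
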