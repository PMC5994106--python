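"""Generate the synthetic study cohort.

Emulates a cord-blood methylation study of 41 naturally conceived
(reference/control) and 23 case newborns on a 10,000-probe array: bimodal
per-probe beta baselines, per-subject epimutations at a mean rate of 20,
chip-batch shifts, one control subject carrying a clustered imprinting
defect across an imprinted DMR, and correlated mixed phenotypes.  Writes
all inputs of the downstream stages under results/study/.
"""

from pathlib import Path

from sevscan import io, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 2026

CONFIG = synthetic.SimulationConfig(
    seed=SEED,
    n_probes=10_000,
    sev_rate=20.0,
    defect_subject="ctl005",  # the imprinting defect sits in the control group
    phenotype_effect={"f1": 0.3},  # latent factor 1 modulates epimutation rate
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = synthetic.generate_annotation(CONFIG)
    beta, detp, truth = synthetic.generate_cohort(CONFIG, ann)
    pheno = synthetic.generate_phenotypes(CONFIG, truth)

    io.write_beta_tsv(beta, OUT / "beta.tsv")
    io.write_detp_tsv(detp, OUT / "detp.tsv")
    io.write_annotation_tsv(ann.probes, OUT / "annotation.tsv")
    io.write_bed(ann.genes, OUT / "genes.bed")
    io.write_bed(ann.dmrs, OUT / "imprinted_dmrs.bed")
    pheno.to_csv(OUT / "phenotypes.tsv", sep="\t", index_label="sample_id")
    truth.to_json(OUT / "ground_truth.json")
    truth.probe_means.rename("mean").to_csv(OUT / "probe_means.tsv", sep="\t")

    print(f"cohort: {beta.shape[1]} subjects x {len(beta)} probes -> {OUT}")
    print(f"genes: {len(ann.genes)}, imprinted DMRs: {len(ann.dmrs)}")
    print(
        f"injected epimutations: {len(truth.injected)} "
        f"(mean {len(truth.injected) / beta.shape[1]:.1f} per subject)"
    )
    print(
        f"defect subject {truth.defect_subject} carries {len(truth.defect_probes)} "
        f"aberrant probes in {truth.defect_dmr}"
    )


if __name__ == "__main__":
    main()
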