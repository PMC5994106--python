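"""Quality control: flag-based probe removal, then Greedycut.

Probes overlapping SNPs, on sex chromosomes, or overlapping rare variants
are dropped first; Greedycut then iteratively strips whichever probe or
sample has the highest fraction of unreliable entries (detection p >= 0.05)
until the matrix is fully reliable.  Writes results/study/beta_qc.tsv.
"""

from pathlib import Path

from sevscan import io

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    beta = io.read_beta_tsv(STUDY / "beta.tsv")
    detp = io.read_detp_tsv(STUDY / "detp.tsv")
    ann = io.read_annotation_tsv(STUDY / "annotation.tsv")

    filtered, report = io.filter_probes(beta, ann)
    kept_probes, kept_samples, trace = io.greedycut(
        detp.loc[filtered.index], threshold=0.05, max_unreliable=0.0
    )
    qc = filtered.loc[kept_probes, kept_samples]
    io.write_beta_tsv(qc, STUDY / "beta_qc.tsv")
    trace.to_csv(STUDY / "greedycut_trace.tsv", sep="\t", index=False)

    print(f"flag filtering removed {report.n_removed} probes: {report.removed_by}")
    removed_samples = trace.loc[trace["axis"] == "sample", "id"].tolist()
    print(
        f"greedycut removed {len(trace)} rows/columns "
        f"({len(removed_samples)} samples: {removed_samples or 'none'})"
    )
    print(f"post-QC matrix: {len(qc)} probes x {qc.shape[1]} samples")


if __name__ == "__main__":
    main()
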