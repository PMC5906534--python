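"""Generate the synthetic study: element library, design, counts, and reads.

Emulates the targeted experiment: ~300 elements in 10 families (with exact
duplicates and fragments to exercise the uniqueness filter), four donors each
untreated and treated at 10 µM, |log2FC| = 4 effects injected into LTR12 (up)
and LTR16C/LTR33 (down), and stranded error-free 50 bp paired-end reads.

Writes: results/sim/{config.json, library.fa, library.gtf, design.tsv,
truth.tsv, true_counts.tsv, reads/<sample>_R{1,2}.fastq}
"""

import argparse
from pathlib import Path

from hervex import refindex, synthdata


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    out = args.out
    (out / "reads").mkdir(parents=True, exist_ok=True)

    cfg = synthdata.SimulationConfig(seed=args.seed, baseline_mean_log2=(6.0, 1.5))
    cfg.to_json(out / "config.json")

    library, truth = synthdata.generate_library(cfg)
    refindex.write_library(library, out / "library.fa")
    refindex.write_annotation(library, out / "library.gtf")
    print(
        f"library: {len(library)} elements, "
        f"{len(truth.duplicate_pairs)} duplicate pairs, "
        f"{len(truth.fragment_of)} fragments"
    )

    counts, truth = synthdata.simulate_counts(library, cfg)
    counts.to_csv(out / "true_counts.tsv", sep="\t")
    truth.design.to_csv(out / "design.tsv", sep="\t")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t")

    total_pairs = 0
    for sample in counts.columns:
        pairs = synthdata.simulate_reads(library, counts, cfg, sample)
        synthdata.write_paired_fastq(
            pairs, out / "reads" / f"{sample}_R1.fastq", out / "reads" / f"{sample}_R2.fastq"
        )
        total_pairs += len(pairs)
    print(f"counts: {counts.shape[0]} elements x {counts.shape[1]} samples; "
          f"{total_pairs} read pairs written to {out/'reads'}")


if __name__ == "__main__":
    main()
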