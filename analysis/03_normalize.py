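"""cpm conversion, low-expression filter (>=1 cpm in half the samples), TMM.

Reads: results/quant/counts.tsv.  Writes: results/norm/{cpm.tsv,
retained.txt, tmm_factors.tsv}
"""

import argparse
from pathlib import Path

import pandas as pd

from hervex import normfilter


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--counts", type=Path, default=Path("results/quant/counts.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/norm"))
    ap.add_argument("--min-cpm", type=float, default=1.0)
    ap.add_argument("--min-frac", type=float, default=0.5)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.counts, sep="\t", index_col=0)
    norm = normfilter.normalize(counts, min_cpm=args.min_cpm, min_fraction=args.min_frac)
    norm.cpm.to_csv(args.out / "cpm.tsv", sep="\t")
    (args.out / "retained.txt").write_text("\n".join(norm.retained) + "\n")
    pd.DataFrame(
        {"tmm_factor": norm.tmm, "library_size": norm.library_sizes,
         "effective_library_size": norm.effective_library_sizes}
    ).to_csv(args.out / "tmm_factors.tsv", sep="\t")

    print(f"retained {len(norm.retained)}/{counts.shape[0]} elements "
          f"(>= {args.min_cpm} cpm in >= {args.min_frac:.0%} of samples)")
    print("TMM factors:", {s: round(f, 4) for s, f in norm.tmm.items()})


if __name__ == "__main__":
    main()
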