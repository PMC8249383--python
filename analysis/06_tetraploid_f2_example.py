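#!/usr/bin/env python
"""Worked example: proportion of tetraploids in the interspecific F2 screen.

A wide cross between the two diploid progenitor lineages produced F2
offspring whose ploidy was screened by flow cytometry: 105 tetraploids out
of 589 screened individuals. Computes the proportion and writes
results/f2_ploidy.tsv.
"""

import argparse
from pathlib import Path

from sdmod.pipeline import tetraploid_fraction


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tetraploid", type=int, default=105)
    ap.add_argument("--screened", type=int, default=589)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    frac = tetraploid_fraction(args.tetraploid, args.screened)
    print(
        f"{args.tetraploid} tetraploid of {args.screened} screened F2s: "
        f"{100 * frac:.2f}% (~{round(100 * frac)}%)"
    )
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "f2_ploidy.tsv", "w") as fh:
        fh.write("n_tetraploid\tn_screened\tfraction\tpercent\n")
        fh.write(f"{args.tetraploid}\t{args.screened}\t{frac:.6f}\t{100 * frac:.2f}\n")


if __name__ == "__main__":
    main()
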