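#!/usr/bin/env python
"""Quartile differential expression per drug: every gene's log2 fold-change
between the most and least sensitive cell-line quartiles, moderated t, p and
BH q, with significant-gene counts at the primary (p < 0.05) and strict
(p < 0.0025) thresholds.
"""

import argparse
from pathlib import Path

import pandas as pd

from ufgpanel import core_io, diffexpr, potency


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    manifest = core_io.read_manifest(args.data / "manifest.json")
    top_conc = dict(zip(manifest["config"]["drugs"], manifest["config"]["top_conc"]))
    expr = core_io.read_expression_matrix(args.data / "expression.tsv")
    table = core_io.read_potency_table(args.data / "ic50.tsv", top_conc)

    frames = []
    for drug in table.drugs:
        assignment = potency.assign_quartiles(table, drug)
        frames.append(diffexpr.diffexpr_table(expr, assignment, "auto"))
    de = pd.concat(frames, ignore_index=True)
    de.to_csv(args.out / "diffexpr.tsv", sep="\t", index=False)

    for drug in table.drugs:
        for alpha in (0.05, 0.0025):
            n, up, down = diffexpr.count_significant(de, drug, alpha)
            print(f"{drug}: {n} genes at p<{alpha} ({up} up, {down} down)")


if __name__ == "__main__":
    main()
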