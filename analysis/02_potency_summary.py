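#!/usr/bin/env python
"""Summarise drug potencies on the simulated panel: per-drug mean/SD/SEM/
median IC50 (nM), cross-drug potency ratios, and the Venn overlap of
sensitivity quartiles between the three drugs.

The quartile Venn is the panel-level view of drug specificity: lines
uniquely sensitive to one drug are what make drug-specific expression
signatures discoverable at all.
"""

import argparse
from pathlib import Path

import pandas as pd

from ufgpanel import core_io, potency


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    manifest = core_io.read_manifest(args.data / "manifest.json")
    top_conc = dict(zip(manifest["config"]["drugs"], manifest["config"]["top_conc"]))
    table = core_io.read_potency_table(args.data / "ic50.tsv", top_conc)

    summary = potency.summarize_potency(table)
    summary.reset_index().to_csv(args.out / "potency_summary.tsv", sep="\t", index=False)
    print(summary.round(2).to_string())

    drugs = table.drugs
    print("\npotency ratios vs", drugs[0])
    for other in drugs[1:]:
        mean_r, median_r = potency.potency_ratio(summary, other, drugs[0])
        print(f"  {other}: {mean_r:.1f}-fold (means), {median_r:.1f}-fold (medians)")

    assignments = [potency.assign_quartiles(table, d) for d in drugs]
    rows = []
    for side in ("top", "bottom"):
        counts = potency.quartile_overlap(assignments, side)
        for region, count in sorted(counts.items()):
            rows.append({"side": side, "region": "|".join(region), "count": count})
        unique = [counts[(d,)] for d in drugs]
        core = counts[tuple(sorted(drugs))]
        print(f"{side} quartiles: unique per drug {unique}, shared by all {core}")
    pd.DataFrame(rows).to_csv(args.out / "quartile_venn.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
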