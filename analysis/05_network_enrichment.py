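#!/usr/bin/env python
"""Expand the selected eribulin UFGs over the interaction graph by random
walk with restart, take the 100-gene subnetwork, and test it for pathway
enrichment against the GMT collection (hypergeometric, p < 0.05 and
q < 0.1).

The planted UFGs live inside one graph module, so the propagated
subnetwork should recover that module and its pathway set while leaving
decoy sets unenriched.
"""

import argparse
from pathlib import Path

import pandas as pd

from ufgpanel import network


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--k", type=int, default=100)
    args = parser.parse_args()

    graph = network.read_edge_list(args.data / "graph.tsv")
    pathways = network.read_gmt(args.data / "pathways.gmt")
    ufgs = pd.read_csv(args.out / "ufgs.tsv", sep="\t")
    seeds = sorted(ufgs.loc[ufgs["cognate_drug"] == "eribulin", "gene"])

    result = network.rwr_propagate(graph, seeds, restart=0.5)
    members, sub = network.top_k_subnetwork(graph, result, k=args.k)
    network.write_edge_list(sub, args.out / "subnetwork_eribulin.tsv")

    print(f"seeds used {len(result.seeds_used)}, dropped {len(result.seeds_dropped)}"
          + (f" ({', '.join(result.seeds_dropped)})" if result.seeds_dropped else ""))
    captured = sorted(set(seeds) & set(members))
    print(f"subnetwork of {len(members)} genes captures {len(captured)}/{len(seeds)} seeds")

    rows = network.hypergeometric_enrichment(set(members), pathways, set(graph.nodes))
    rows.to_csv(args.out / "enrichment_eribulin.tsv", sep="\t", index=False)
    kept = network.filter_pathways(rows, p_max=0.05, q_max=0.1)
    print(f"{len(kept)} pathways pass p<0.05 and q<0.1:")
    if len(kept):
        print(kept[["pathway", "p", "q", "pathway_size", "overlap"]].to_string(index=False))


if __name__ == "__main__":
    main()
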