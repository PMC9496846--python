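"""Seed-based network propagation and hypergeometric pathway enrichment.

Propagation is a random walk with restart on an undirected weighted gene
graph: the stationary distribution of

    p = restart * s + (1 - restart) * W @ p

where ``s`` is uniform over the seed genes present in the graph and ``W``
is the column-normalised weighted adjacency matrix.  The top-K nodes by
stationary score form the propagated subnetwork; seeds missing from the
graph are reported, never imputed, so a dropped seed cannot appear in the
subnetwork.

Enrichment of a propagated gene set against GMT pathway collections uses
the one-sided upper-tail hypergeometric test over a stated gene universe
(by default all graph nodes) with Benjamini-Hochberg adjustment across
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .diffexpr import bh_adjust

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "PropagationResult",
    "rwr_propagate",
    "top_k_subnetwork",
    "hypergeometric_enrichment",
    "filter_pathways",
    "ENRICHMENT_COLUMNS",
]

ENRICHMENT_COLUMNS = ["pathway", "p", "q", "pathway_size", "overlap", "genes"]


def read_edge_list(path) -> nx.Graph:
    """Undirected weighted TSV edge list (gene_a, gene_b[, weight])."""
    graph = nx.Graph()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(f"line {line_no}: expected 2 or 3 columns")
        a, b = parts[0].strip(), parts[1].strip()
        w = float(parts[2]) if len(parts) == 3 else 1.0
        if a == b:
            raise ValueError(f"line {line_no}: self-loop on {a!r}")
        if w <= 0:
            raise ValueError(f"line {line_no}: non-positive weight")
        if graph.has_edge(a, b):
            raise ValueError(f"line {line_no}: duplicate edge {a!r}-{b!r}")
        graph.add_edge(a, b, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT pathway file: name, description, member genes per line."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"line {line_no}: GMT lines need name, description, genes")
        name = parts[0]
        if name in sets:
            raise ValueError(f"line {line_no}: duplicate pathway {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


@dataclass(frozen=True)
class PropagationResult:
    """Stationary scores plus the bookkeeping of which seeds were usable."""

    scores: pd.Series
    seeds_used: tuple[str, ...]
    seeds_dropped: tuple[str, ...]
    restart: float


def rwr_propagate(
    graph: nx.Graph,
    seeds,
    restart: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> PropagationResult:
    """Random walk with restart from a seed set; scores sum to 1.

    Seeds absent from the graph are recorded in ``seeds_dropped``.  Nodes
    unreachable from the seeds keep score 0; with ``restart=1`` the scores
    are exactly the uniform seed vector.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    nodes = sorted(graph.nodes)
    node_pos = {n: i for i, n in enumerate(nodes)}
    seeds = list(dict.fromkeys(seeds))  # dedupe, keep order
    used = tuple(s for s in seeds if s in node_pos)
    dropped = tuple(s for s in seeds if s not in node_pos)
    if not used:
        raise ValueError("no seed gene is present in the graph")

    s = np.zeros(len(nodes))
    s[[node_pos[g] for g in used]] = 1.0 / len(used)
    if restart == 1.0:
        scores = s
    else:
        A = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csc")
        col_sums = np.asarray(A.sum(axis=0)).ravel()
        col_sums[col_sums == 0] = 1.0  # isolated nodes: column stays zero anyway
        W = A @ sparse.diags(1.0 / col_sums)
        p = s.copy()
        for _ in range(max_iter):
            p_next = restart * s + (1.0 - restart) * (W @ p)
            if np.abs(p_next - p).sum() < tol:
                p = p_next
                break
            p = p_next
        else:
            raise RuntimeError("propagation did not converge")
        scores = p
    return PropagationResult(
        scores=pd.Series(scores, index=nodes),
        seeds_used=used,
        seeds_dropped=dropped,
        restart=restart,
    )


def top_k_subnetwork(
    graph: nx.Graph, result: PropagationResult, k: int = 100
) -> tuple[list[str], nx.Graph]:
    """The k highest-scoring nodes (ties by gene symbol) and induced edges.

    Seeds are not force-included: a seed that was dropped from propagation
    cannot appear, and a low-scoring seed can be outranked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(result.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    members = [g for g, _ in ranked[: min(k, len(ranked))]]
    return members, graph.subgraph(members).copy()


def hypergeometric_enrichment(
    query, pathways: dict[str, set[str]], universe
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene set per pathway.

    Each pathway is intersected with the universe before testing; the
    p-value is P(overlap >= observed) drawing |query| genes without
    replacement from the universe.  q is BH across all tested pathways.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    M, N = len(universe), len(query)
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        overlap = sorted(query & members)
        n = len(members)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(len(overlap) - 1, M, n, N))
        rows.append(
            {
                "pathway": name,
                "p": min(p, 1.0),
                "pathway_size": n,
                "overlap": len(overlap),
                "genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q"])
    df.insert(2, "q", bh_adjust(df["p"].to_numpy()) if len(df) else [])
    return df[ENRICHMENT_COLUMNS]


def filter_pathways(
    rows: pd.DataFrame, p_max: float = 0.05, q_max: float = 0.1
) -> pd.DataFrame:
    """Keep pathways with p < p_max AND q < q_max, sorted by ascending p."""
    if rows.empty:
        return rows.copy()
    kept = rows[(rows["p"] < p_max) & (rows["q"] < q_max)]
    return kept.sort_values(["p", "pathway"]).reset_index(drop=True)
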