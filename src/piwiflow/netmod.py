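"""Seed-centered correlation-network module extraction.

A complete undirected correlation graph is built over the combined
PCG + TE + piRNA panel (Pearson r of log2(x+1)-transformed normalized
values by default).  For a chosen seed molecule, the module consists of
the seed, its top-k neighbors by absolute correlation, and those
neighbors' own top-k neighbors; the module's edges are then filtered to
those whose absolute correlation strictly exceeds the third quartile of
correlations over the complete graph on the module's members.  Modules are
exported as GraphML and SIF for external viewers such as Cytoscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SeedModule:
    seed: str
    members: list[str]
    edges: pd.DataFrame  # node1, node2, r (retained edges only)
    q3_threshold: float
    k: int = 0
    pre_filter_pairs: int = field(default=0)


def build_graph(
    panel: pd.DataFrame,
    kinds: pd.Series | None = None,
    method: str = "pearson",
    log_transform: bool = True,
) -> nx.Graph:
    """Complete correlation graph over the panel's molecules.

    Parameters
    ----------
    panel
        Molecules x samples matrix of normalized expression; molecule
        identifiers must be unique across kinds.
    kinds
        Optional per-molecule kind tag stored as a node attribute.
    method
        ``pearson`` (default, on log2(x+1) values) or ``spearman``.
    """
    if panel.index.duplicated().any():
        raise ValueError("molecule identifiers must be unique across the panel")
    if panel.shape[1] < 3:
        raise ValueError("panel needs >= 3 samples")
    x = panel.to_numpy(dtype=float)
    if log_transform and method == "pearson":
        x = np.log2(x + 1.0)
    keep = x.std(axis=1) > 0
    if not keep.all():
        dropped = panel.index[~keep].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance molecules: {dropped[:5]}...")
        x = x[keep]
    ids = panel.index[keep]
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.corrcoef(x)
    g = nx.Graph()
    for i, node in enumerate(ids):
        attrs = {}
        if kinds is not None and node in kinds.index:
            attrs["kind"] = str(kinds.loc[node])
        g.add_node(node, **attrs)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(ids[i], ids[j], r=float(r[i, j]))
    return g


def _top_k_neighbors(graph: nx.Graph, node: str, k: int) -> list[str]:
    """Top-k neighbors by |r|; ties in |r| broken by ascending identifier."""
    nbrs = [(-abs(d["r"]), str(v), v) for v, d in graph[node].items()]
    nbrs.sort(key=lambda t: (t[0], t[1]))
    return [v for _, _, v in nbrs[:k]]


def extract_module(graph: nx.Graph, seed: str, k: int = 10) -> SeedModule:
    """Pre-filter module membership: the seed, its top-k neighbors by |r|,
    and each such neighbor's own top-k neighbors (merged, deduplicated)."""
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    members = {seed}
    first = _top_k_neighbors(graph, seed, k)
    members.update(first)
    for nb in first:
        members.update(_top_k_neighbors(graph, nb, k))
    ordered = sorted(members)
    return SeedModule(seed=seed, members=ordered, edges=pd.DataFrame(columns=["node1", "node2", "r"]),
                      q3_threshold=float("nan"), k=k)


def filter_edges(module: SeedModule, graph: nx.Graph, quartile_on: str = "all_pairs_abs") -> SeedModule:
    """Retain edges with |r| strictly above the Q3 threshold.

    ``all_pairs_abs`` (default): threshold = linear-interpolation third
    quartile of |r| over ALL unordered member pairs (the complete graph on
    the module's nodes).  ``signed_all_pairs``: quartile of signed r, edges
    retained when r strictly exceeds it (sensitivity variant).
    """
    members = module.members
    if len(members) < 2:
        raise ValueError("module needs >= 2 members")
    pairs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if graph.has_edge(a, b):
                pairs.append((a, b, float(graph[a][b]["r"])))
    rvals = np.array([r for _, _, r in pairs])
    if quartile_on == "all_pairs_abs":
        q3 = float(np.quantile(np.abs(rvals), 0.75))  # type-7 linear interpolation
        retained = [(a, b, r) for a, b, r in pairs if abs(r) > q3]
    elif quartile_on == "signed_all_pairs":
        q3 = float(np.quantile(rvals, 0.75))
        retained = [(a, b, r) for a, b, r in pairs if r > q3]
    else:
        raise ValueError(f"unknown quartile_on mode {quartile_on!r}")
    edges = pd.DataFrame(retained, columns=["node1", "node2", "r"])
    return SeedModule(seed=module.seed, members=members, edges=edges, q3_threshold=q3,
                      k=module.k, pre_filter_pairs=len(pairs))


def export_graph(module: SeedModule, graph: nx.Graph, outdir: str | Path, prefix: str | None = None) -> dict[str, str]:
    """Write the final module as GraphML (kind / is_seed node attributes,
    r edge attribute), SIF (``node1 cc node2``), and a members TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or module.seed.replace("/", "_")
    g = nx.Graph()
    for node in module.members:
        kind = graph.nodes[node].get("kind", "") if node in graph else ""
        g.add_node(node, kind=kind, is_seed=bool(node == module.seed))
    for _, row in module.edges.iterrows():
        g.add_edge(row["node1"], row["node2"], r=float(row["r"]))
    gml = outdir / f"{prefix}.graphml"
    nx.write_graphml(g, gml)
    sif = outdir / f"{prefix}.sif"
    with open(sif, "w") as fh:
        for _, row in module.edges.iterrows():
            fh.write(f"{row['node1']}\tcc\t{row['node2']}\n")
    members = outdir / f"{prefix}_members.tsv"
    pd.DataFrame(
        {
            "member": module.members,
            "kind": [g.nodes[m]["kind"] for m in module.members],
            "is_seed": [m == module.seed for m in module.members],
        }
    ).to_csv(members, sep="\t", index=False)
    return {"graphml": str(gml), "sif": str(sif), "members": str(members)}
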