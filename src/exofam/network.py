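"""Induced network modules over PPI edge lists, plus gene-set
over-representation analysis.

A non-seed node is admitted as an intermediate iff it lies on a seed-to-seed
path of at most ``max_path_len`` edges whose internal nodes are all admitted
(greatest fixed point: mutually supporting intermediates such as a
two-intermediate bridge are kept).  The module graph is the induced subgraph
of the input over seeds plus admitted intermediates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
from scipy import stats

from .io_formats.models import EdgeList, FormatError, GeneSetCollection

__all__ = [
    "InducedModule",
    "EnrichmentResult",
    "induce_module",
    "hypergeometric_enrichment",
    "benjamini_hochberg",
    "export_module",
    "import_module",
]


@dataclass
class InducedModule:
    seeds: frozenset
    intermediates: frozenset
    edges: frozenset  # frozenset of frozenset node pairs
    connections: list = field(default_factory=list)  # (seed_a, seed_b, path)

    @property
    def nodes(self) -> frozenset:
        return self.seeds | self.intermediates

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InducedModule)
            and self.seeds == other.seeds
            and self.intermediates == other.intermediates
            and self.edges == other.edges
            and self.connections == other.connections
        )


def _valid_internal_nodes(
    g: nx.Graph,
    seeds: set,
    admitted: set,
    max_path_len: int,
) -> set:
    """Internal nodes of seed-seed simple paths of <= max_path_len edges
    whose internal nodes are non-seed members of ``admitted``."""
    allowed = seeds | admitted
    sub = g.subgraph(allowed)
    present_seeds = sorted(s for s in seeds if s in sub)
    used: set = set()
    for i, a in enumerate(present_seeds):
        for b in present_seeds[i + 1 :]:
            for path in nx.all_simple_paths(sub, a, b, cutoff=max_path_len):
                internal = path[1:-1]
                if all(n not in seeds for n in internal):
                    used.update(internal)
    return used


def induce_module(
    edge_list: EdgeList,
    seeds: Iterable,
    max_path_len: int = 3,
) -> InducedModule:
    """Compute the induced module of ``seeds`` over an undirected edge list.

    Seeds absent from the edge list are reported isolated.  For every seed
    pair connected inside the module within ``max_path_len`` edges, one
    deterministic shortest connecting path is recorded.
    """
    seeds = set(seeds)
    if not seeds:
        raise FormatError("seed set must be non-empty")
    if max_path_len < 1:
        raise FormatError(f"max_path_len must be >= 1, got {max_path_len}")
    g = edge_list.to_networkx()

    admitted = set(g.nodes) - seeds
    while True:
        kept = _valid_internal_nodes(g, seeds, admitted, max_path_len)
        if kept == admitted:
            break
        admitted = kept

    module_nodes = (seeds & set(g.nodes)) | admitted
    sub = g.subgraph(module_nodes)
    edges = frozenset(frozenset(e) for e in sub.edges)

    connections = []
    present_seeds = sorted(s for s in seeds if s in sub)
    for i, a in enumerate(present_seeds):
        for b in present_seeds[i + 1 :]:
            path = _best_path(sub, a, b, seeds, max_path_len)
            if path is not None:
                connections.append((a, b, path))
    return InducedModule(
        seeds=frozenset(seeds),
        intermediates=frozenset(admitted),
        edges=edges,
        connections=connections,
    )


def _best_path(
    g: nx.Graph, a, b, seeds: set, max_path_len: int
) -> Optional[list]:
    """Lexicographically smallest shortest seed-free-interior path a->b."""
    best = None
    for path in nx.all_simple_paths(g, a, b, cutoff=max_path_len):
        if any(n in seeds for n in path[1:-1]):
            continue
        key = (len(path), path)
        if best is None or key < (len(best), best):
            best = path
    return best


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    q_value: float


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p-values (monotone, clipped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_index in range(m - 1, -1, -1):
        i = order[rank_index]
        running_min = min(running_min, p_values[i] * m / (rank_index + 1))
        q[i] = min(running_min, 1.0)
    return q


def hypergeometric_enrichment(
    query_genes: Iterable,
    gene_sets: GeneSetCollection,
    background: Optional[Iterable] = None,
    min_overlap: int = 0,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per gene set.

    ``background`` defaults to the union of all supplied gene sets; the
    query must be contained in it.  q-values are Benjamini-Hochberg across
    every tested set; ``min_overlap`` filters the report only (after
    adjustment).  Results sort by p-value then set name.
    """
    query = set(query_genes)
    bg = set(background) if background is not None else set(gene_sets.universe)
    stray = query - bg
    if stray:
        raise FormatError(
            f"query genes missing from background: {sorted(stray)}"
        )
    rows = []
    for name in sorted(gene_sets):
        genes = set(gene_sets[name]) & bg
        overlap = len(genes & query)
        # P(X >= overlap) drawing |query| from background with |genes| marked
        p = float(
            stats.hypergeom.sf(overlap - 1, len(bg), len(genes), len(query))
        )
        rows.append((name, overlap, len(genes), p))
    qvals = benjamini_hochberg([r[3] for r in rows])
    results = [
        EnrichmentResult(
            set_name=name,
            overlap_count=overlap,
            set_size=size,
            query_size=len(query),
            background_size=len(bg),
            p_value=min(max(p, 0.0), 1.0),
            q_value=q,
        )
        for (name, overlap, size, p), q in zip(rows, qvals)
    ]
    results = [r for r in results if r.overlap_count >= min_overlap]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def export_module(module: InducedModule, out_dir: Union[str, Path]) -> dict:
    """Write node table (node, role), edge table, and GraphML.

    Returns the paths written.  Node roles partition seeds vs intermediates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "module_nodes.tsv"
    edges_path = out_dir / "module_edges.tsv"
    graphml_path = out_dir / "module.graphml"
    with open(nodes_path, "w") as fh:
        fh.write("node\trole\n")
        for n in sorted(module.seeds):
            fh.write(f"{n}\tseed\n")
        for n in sorted(module.intermediates):
            fh.write(f"{n}\tintermediate\n")
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for e in sorted(tuple(sorted(e)) for e in module.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    g = module.graph()
    for n in g.nodes:
        g.nodes[n]["role"] = "seed" if n in module.seeds else "intermediate"
    nx.write_graphml(g, graphml_path)
    return {
        "nodes": str(nodes_path),
        "edges": str(edges_path),
        "graphml": str(graphml_path),
    }


def import_module(
    out_dir: Union[str, Path], max_path_len: int = 3
) -> InducedModule:
    """Re-read an exported module; connections are recomputed
    deterministically from the stored edges and roles."""
    out_dir = Path(out_dir)
    seeds, intermediates = set(), set()
    with open(out_dir / "module_nodes.tsv") as fh:
        next(fh)
        for line in fh:
            node, role = line.rstrip("\n").split("\t")
            (seeds if role == "seed" else intermediates).add(node)
    edges = set()
    with open(out_dir / "module_edges.tsv") as fh:
        next(fh)
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            edges.add(frozenset((a, b)))
    g = nx.Graph()
    g.add_nodes_from(sorted(seeds | intermediates))
    g.add_edges_from(tuple(sorted(e)) for e in edges)
    connections = []
    present = sorted(s for s in seeds if s in g)
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            path = _best_path(g, a, b, seeds, max_path_len)
            if path is not None:
                connections.append((a, b, path))
    return InducedModule(
        seeds=frozenset(seeds),
        intermediates=frozenset(intermediates),
        edges=frozenset(edges),
        connections=connections,
    )
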