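"""Hypergeometric annotation enrichment with network linkage.

Cluster-characteristic protein lists are tested against annotation
collections (GMT semantics: KEGG/GO/TRRUST-style named sets) by the exact
one-sided hypergeometric tail, with a [10, 300] set-size filter (applied
after intersecting each set with the protein universe) and Benjamini-
Hochberg reporting at q < 0.01.  Enriched sets are linked by a modified
Hausdorff distance over shortest paths in a protein-interaction graph and
exported as SIF/GraphML networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "enrich",
    "shortest_path_distances",
    "modified_hausdorff",
    "hausdorff_classic",
    "build_network",
    "write_sif",
    "write_graphml",
    "read_graphml",
]

SIZE_FILTER = (10, 300)
Q_REPORT = 0.01


@dataclass(frozen=True)
class AnnotationCollection:
    """Named protein sets (GMT semantics) from one source."""

    sets: tuple  # ((name, frozenset members), ...)
    source: str = ""

    def __post_init__(self) -> None:
        sets = tuple((str(n), frozenset(m)) for n, m in self.sets)
        names = [n for n, _ in sets]
        if len(set(names)) != len(names):
            raise ValueError("set names must be unique")
        if any(not m for _, m in sets):
            raise ValueError("annotation sets must be non-empty")
        object.__setattr__(self, "sets", sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return iter(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    set_size: int  # after universe intersection
    overlap: int
    p_value: float
    q_value: float
    direction: str = ""  # UP/DOWN tag
    cluster: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= self.set_size:
            raise ValueError("overlap must lie in [0, set size]")


def read_gmt(path) -> AnnotationCollection:
    """Tab-separated GMT: name, description, member ids."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append((parts[0], frozenset(p for p in parts[2:] if p)))
    return AnnotationCollection(tuple(sets), source=str(path))


def write_gmt(collection: AnnotationCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(members)]))
            fh.write("\n")


def read_edge_list(path) -> nx.Graph:
    """Two-column (optionally weighted) TSV edge list."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            g.add_edge(parts[0], parts[1])
    return g


def enrich(
    query,
    collection: AnnotationCollection,
    universe,
    size_filter: tuple = SIZE_FILTER,
    q_threshold: float = Q_REPORT,
    direction: str = "",
    cluster: int | None = None,
    report_all: bool = False,
) -> list:
    """Exact one-sided hypergeometric enrichment of ``query`` in each
    annotation set, over ``universe``.

    Sets are intersected with the universe first and kept only when their
    intersected size lies within ``size_filter``; BH correction runs across
    the tested sets and results are reported at q < ``q_threshold`` (or all
    tested sets with ``report_all``).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    if not query <= universe:
        raise ValueError(
            f"query must be a subset of the universe; foreign ids: "
            f"{sorted(query - universe)[:5]}"
        )
    if not query:
        warnings.warn("empty query: no enrichment computed")
        return []
    M, N = len(universe), len(query)
    tested = []
    for name, members in collection.items():
        inter = members & universe
        K = len(inter)
        if not size_filter[0] <= K <= size_filter[1]:
            continue
        k = len(inter & query)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        tested.append((name, K, k, min(p, 1.0)))
    if not tested:
        return []
    qs = multipletests([t[3] for t in tested], method="fdr_bh")[1]
    out = [
        EnrichmentResult(name=name, set_size=K, overlap=k, p_value=p,
                         q_value=float(q), direction=direction, cluster=cluster)
        for (name, K, k, p), q in zip(tested, qs)
    ]
    if not report_all:
        out = [r for r in out if r.q_value < q_threshold]
    return out


def shortest_path_distances(graph: nx.Graph, nodes=None,
                            disconnected: float | None = None) -> pd.DataFrame:
    """All-pairs shortest-path length table over ``nodes`` (default: all).

    Disconnected pairs get ``disconnected`` (default: largest finite
    shortest-path length in the graph plus one).
    """
    nodes = list(nodes) if nodes is not None else list(graph.nodes)
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    finite_max = max(
        (d for src in lengths.values() for d in src.values()), default=0
    )
    fill = disconnected if disconnected is not None else finite_max + 1
    mat = np.full((len(nodes), len(nodes)), float(fill))
    for i, a in enumerate(nodes):
        row = lengths.get(a, {})
        for j, b in enumerate(nodes):
            if b in row:
                mat[i, j] = row[b]
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=nodes, columns=nodes)


def _directed_mean_min(a, b, dist: pd.DataFrame) -> float:
    sub = dist.loc[list(a), list(b)].to_numpy()
    return float(sub.min(axis=1).mean())


def modified_hausdorff(set_a, set_b, dist: pd.DataFrame) -> float:
    """Dubuisson-Jain modified Hausdorff distance between two node sets:
    max of the two directed mean-of-minima distances."""
    a, b = frozenset(set_a), frozenset(set_b)
    for s in (a, b):
        missing = [x for x in s if x not in dist.index]
        if missing:
            raise KeyError(f"members missing from the distance table: {missing}")
    if not a or not b:
        raise ValueError("sets must be non-empty")
    return max(_directed_mean_min(a, b, dist), _directed_mean_min(b, a, dist))


def hausdorff_classic(set_a, set_b, dist: pd.DataFrame) -> float:
    """Classical max-min Hausdorff distance (alternative linkage dialect)."""
    a, b = list(set_a), list(set_b)
    sub = dist.loc[a, b].to_numpy()
    return float(max(sub.min(axis=1).max(), sub.min(axis=0).max()))


def build_network(
    results: list,
    collection: AnnotationCollection,
    graph: nx.Graph,
    link_threshold: float,
    universe=None,
    linkage: str = "modified",
) -> nx.Graph:
    """Enrichment network: nodes are enriched sets (with q/direction/cluster
    attributes), weighted edges where the Hausdorff link value over the
    protein graph is <= ``link_threshold``."""
    members_by_name = dict(collection.items())
    universe = frozenset(universe) if universe is not None else frozenset(graph.nodes)
    net = nx.Graph()
    eff_members = {}
    for r in results:
        mem = members_by_name[r.name] & universe & set(graph.nodes)
        eff_members[r.name] = mem
        net.add_node(r.name, q=r.q_value, direction=r.direction,
                     cluster=-1 if r.cluster is None else int(r.cluster),
                     size=r.set_size, overlap=r.overlap)
    needed = sorted(set().union(*eff_members.values())) if eff_members else []
    if needed:
        dist = shortest_path_distances(graph, nodes=needed)
        link = modified_hausdorff if linkage == "modified" else hausdorff_classic
        names = [r.name for r in results]
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                if not eff_members[na] or not eff_members[nb]:
                    continue
                w = link(eff_members[na], eff_members[nb], dist)
                if w <= link_threshold:
                    net.add_edge(na, nb, weight=float(w))
    return net


def write_sif(net: nx.Graph, path, relation: str = "link") -> None:
    """One edge per line: "setA link setB"; isolated nodes on their own line."""
    with open(path, "w") as fh:
        connected = set()
        for a, b in net.edges:
            fh.write(f"{a}\t{relation}\t{b}\n")
            connected.update((a, b))
        for n in net.nodes:
            if n not in connected:
                fh.write(f"{n}\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def node_attribute_table(net: nx.Graph) -> pd.DataFrame:
    recs = [{"name": n, **attrs} for n, attrs in net.nodes(data=True)]
    return pd.DataFrame(recs)
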