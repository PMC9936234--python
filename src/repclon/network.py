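"""Repertoire networks and Gini-index quantification of clonality.

Each sample's repertoire (per receptor class: BCR pooling IGH/IGK/IGL, or
TCR pooling TRA/TRB) is a graph in which

* a **vertex** is a unique receptor sequence — records sharing (chain,
  V gene, J gene, CDR3 nucleotides) collapse into one vertex whose *size* is
  the number of identical chains observed (summed read count);
* an **edge** joins two vertices satisfying the clone rule (same chain, V, J,
  CDR3 length, CDR3 identity at or above the class threshold);
* a **cluster** (connected component) is a clone.

The shape of this graph is summarised with two Gini indices — the relative
mean absolute difference of a size distribution, 0 for perfect equality and
approaching 1 for maximal inequality:

* Gini over **vertex sizes** measures *clonal expansion*: how unevenly reads
  concentrate on particular sequences;
* Gini over **cluster sizes** (vertices per clone by default; summed reads
  behind a flag) measures *clonal dominance / diversification*: whether a few
  clones dominate the repertoire's sequence variety.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clonality import (
    BCR_IDENTITY_THRESHOLD,
    TCR_IDENTITY_THRESHOLD,
    _mismatch_budget,
)
from .io_clonotypes import BCR_CHAINS, TCR_CHAINS

RECEPTOR_CLASSES = {
    "BCR": (BCR_CHAINS, BCR_IDENTITY_THRESHOLD),
    "TCR": (TCR_CHAINS, TCR_IDENTITY_THRESHOLD),
}


@dataclass
class RepertoireGraph:
    """One sample × receptor-class clonality network.

    ``graph`` is an undirected networkx graph whose nodes are vertex indices
    in deterministic input order, each with attributes ``key`` (chain,
    v_gene, j_gene, cdr3_nt) and ``size`` (summed read count). ``clusters``
    lists the connected components as sorted node-index lists, ordered by
    first member.
    """

    sample_id: str | None
    receptor_class: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    clusters: list[list[int]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def vertex_sizes(self) -> np.ndarray:
        return np.array(
            [self.graph.nodes[v]["size"] for v in sorted(self.graph.nodes)], dtype=float
        )

    def cluster_sizes(self, weighted: bool = False) -> np.ndarray:
        """Vertices per cluster, or summed read counts when ``weighted``."""
        if weighted:
            return np.array(
                [sum(self.graph.nodes[v]["size"] for v in c) for c in self.clusters],
                dtype=float,
            )
        return np.array([len(c) for c in self.clusters], dtype=float)


def build_repertoire_graph(
    records: pd.DataFrame, receptor_class: str
) -> RepertoireGraph:
    """Build a sample's clonality network for one receptor class.

    ``records`` must already be restricted to the class's chains (BCR:
    IGH/IGK/IGL; TCR: TRA/TRB). Records with identical (chain, v_gene,
    j_gene, cdr3_nt) collapse into one vertex. Empty input gives an empty
    graph. The component partition is, by construction, the clone partition
    of the collapsed vertices under the class threshold.
    """
    if receptor_class not in RECEPTOR_CLASSES:
        raise ValueError(f"unknown receptor class {receptor_class!r}")
    chains, threshold = RECEPTOR_CLASSES[receptor_class]

    sample_id = None
    g = nx.Graph()
    if len(records) == 0:
        return RepertoireGraph(sample_id, receptor_class, g, [])

    samples = records["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("build_repertoire_graph expects records of a single sample")
    sample_id = samples[0]
    bad = set(records["chain"].unique()) - set(chains)
    if bad:
        raise ValueError(
            f"records contain chains {sorted(bad)} outside receptor class {receptor_class}"
        )

    # collapse to vertices in input order
    vertex_index: dict[tuple, int] = {}
    sizes: list[int] = []
    for chain, v, j, cdr3, count in records[
        ["chain", "v_gene", "j_gene", "cdr3_nt", "read_count"]
    ].itertuples(index=False):
        key = (chain, v, j, cdr3)
        if key in vertex_index:
            sizes[vertex_index[key]] += count
        else:
            vertex_index[key] = len(sizes)
            sizes.append(count)
    for key, idx in vertex_index.items():
        g.add_node(idx, key=key, size=int(sizes[idx]))

    # edges within (chain, v, j, CDR3 length) groups
    groups: dict[tuple, list[int]] = {}
    for (chain, v, j, cdr3), idx in vertex_index.items():
        groups.setdefault((chain, v, j, len(cdr3)), []).append(idx)
    keys = {idx: key for key, idx in vertex_index.items()}
    for (chain, v, j, length), idxs in groups.items():
        budget = _mismatch_budget(length, threshold)
        for a in range(len(idxs)):
            sa = keys[idxs[a]][3]
            for b in range(a + 1, len(idxs)):
                sb = keys[idxs[b]][3]
                mism = 0
                for x, y in zip(sa, sb):
                    if x != y:
                        mism += 1
                        if mism > budget:
                            break
                if mism <= budget:
                    g.add_edge(idxs[a], idxs[b])

    clusters = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return RepertoireGraph(sample_id, receptor_class, g, clusters)


def gini_coefficient(sizes) -> float:
    """Gini index of a size distribution.

    Relative mean absolute difference, G = Σ_i Σ_j |x_i − x_j| / (2 n² x̄),
    with no small-sample correction. 0 for perfect equality; bounded above
    by (n − 1)/n. A single element gives 0; an all-zero vector is an error.

    Computed via the sorted cumulative form, algebraically identical to the
    double sum but O(n log n).
    """
    x = np.sort(np.asarray(sizes, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("gini_coefficient requires a nonempty vector")
    if np.any(x < 0):
        raise ValueError("sizes must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("gini_coefficient requires a positive total size")
    if n == 1:
        return 0.0
    i = np.arange(1, n + 1)
    return float((2.0 * (i * x).sum()) / (n * total) - (n + 1.0) / n)


@dataclass
class NetworkSummary:
    """Per sample × receptor class clonality summary.

    ``gini_vertex`` quantifies clonal expansion, ``gini_cluster`` clonal
    dominance. Both are NaN for an empty graph.
    """

    sample_id: str | None
    receptor_class: str
    n_vertices: int
    n_clusters: int
    gini_vertex: float
    gini_cluster: float


def network_summary(
    graph: RepertoireGraph, weighted_clusters: bool = False
) -> NetworkSummary:
    """Gini indices over a repertoire graph's vertex and cluster sizes."""
    if graph.n_vertices == 0:
        return NetworkSummary(
            graph.sample_id, graph.receptor_class, 0, 0, float("nan"), float("nan")
        )
    return NetworkSummary(
        sample_id=graph.sample_id,
        receptor_class=graph.receptor_class,
        n_vertices=graph.n_vertices,
        n_clusters=graph.n_clusters,
        gini_vertex=gini_coefficient(graph.vertex_sizes()),
        gini_cluster=gini_coefficient(graph.cluster_sizes(weighted=weighted_clusters)),
    )


def network_table(
    cohort_records: pd.DataFrame, weighted_clusters: bool = False
) -> pd.DataFrame:
    """Per-sample BCR and TCR network summaries for a whole record table.

    Returns columns ``sample_id, receptor_class, n_vertices, n_clusters,
    gini_vertex, gini_cluster``; samples with no records for a class get NaN
    Gini values.
    """
    rows = []
    for sample_id, sample_records in cohort_records.groupby("sample_id", sort=True):
        for rc, (chains, _) in RECEPTOR_CLASSES.items():
            sub = sample_records[sample_records["chain"].isin(chains)].reset_index(
                drop=True
            )
            graph = build_repertoire_graph(sub, rc)
            if graph.sample_id is None:
                graph.sample_id = sample_id
            s = network_summary(graph, weighted_clusters=weighted_clusters)
            rows.append(
                dict(
                    sample_id=sample_id,
                    receptor_class=rc,
                    n_vertices=s.n_vertices,
                    n_clusters=s.n_clusters,
                    gini_vertex=s.gini_vertex,
                    gini_cluster=s.gini_cluster,
                )
            )
    return pd.DataFrame(rows)


def export_edge_list(graph: RepertoireGraph, path) -> None:
    """Write the network as a TSV edge list (isolated vertices as self-rows)
    for external layout/plotting tools."""
    rows = []
    for u, v in graph.graph.edges:
        rows.append((u, v))
    isolated = [v for v in graph.graph.nodes if graph.graph.degree[v] == 0]
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")
        for v in isolated:
            fh.write(f"{v}\t{v}\n")
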