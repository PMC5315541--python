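"""Co-regulation networks and hypergeometric over-representation tests.

A co-regulation network is the graph whose edges are row pairs of an
expression matrix with |Pearson r| at or above a cutoff (0.75 in the study
design). Two enrichment questions are asked with the hypergeometric upper
tail: whether a query network's edges are over-represented among a reference
network's edges, and whether a probe/gene set is over-represented among the
differentially expressed probes of an array. The hypergeometric universe is
always an explicit argument — published analyses of this kind often leave it
unstated, and the p-value depends on it strongly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_stats import hypergeom_upper_tail, pearson_corr_matrix
from .io_model import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["CoregulationNetwork", "OverlapTestResult",
           "build_coregulation_network", "edge_overlap_test",
           "probe_set_overlap_test"]


@dataclass
class CoregulationNetwork:
    """Undirected graph of co-regulated features at a correlation cutoff."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted id pairs (canonical unordered representation)."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        return sorted((min(a, b), max(a, b), self.graph[a][b]["r"])
                      for a, b in self.graph.edges)


@dataclass(frozen=True)
class OverlapTestResult:
    overlap: int            # k
    query_size: int         # n drawn
    reference_size: int     # K marked
    universe: int           # N
    percentage: float
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.query_size, self.reference_size):
            raise ValueError("overlap exceeds the smaller set")


def build_coregulation_network(matrix: ExpressionMatrix,
                               cutoff: float = 0.75) -> CoregulationNetwork:
    """All-to-all Pearson correlation thresholded into an edge list.

    Rows with zero variance cannot be correlated and are excluded with a
    warning. Edge order and node ids are deterministic and invariant to
    sample column order.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    values = matrix.values
    ids = np.array(matrix.probe_ids)
    sd = values.std(axis=1)
    if (sd == 0).any():
        dropped = ids[sd == 0].tolist()
        logger.warning("excluding %d constant rows from network: %s",
                       len(dropped), dropped[:10])
        values = values[sd > 0]
        ids = ids[sd > 0]
    r = pearson_corr_matrix(values)
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = np.abs(r[iu, ju]) >= cutoff
    g = nx.Graph()
    g.add_nodes_from(ids.tolist())
    for a, b, rv in zip(ids[iu[keep]], ids[ju[keep]], r[iu[keep], ju[keep]]):
        g.add_edge(str(a), str(b), r=float(rv))
    return CoregulationNetwork(graph=g, cutoff=cutoff)


def edge_overlap_test(reference: CoregulationNetwork,
                      query: CoregulationNetwork,
                      universe_size: int) -> OverlapTestResult:
    """Hypergeometric over-representation of query edges among reference edges.

    ``universe_size`` is the number of feature pairs eligible to be an edge
    in either network; it must be supplied explicitly. The reported
    percentage is the overlap relative to the reference edge count.
    """
    ref_edges = reference.edges
    qry_edges = query.edges
    K, n = len(ref_edges), len(qry_edges)
    if universe_size < max(K, n):
        raise ValueError("universe smaller than an edge set")
    k = len(ref_edges & qry_edges)
    lo = max(0, n + K - universe_size)
    p = hypergeom_upper_tail(universe_size, K, n, max(k, lo))
    pct = 100.0 * k / K if K else float("nan")
    return OverlapTestResult(overlap=k, query_size=n, reference_size=K,
                             universe=universe_size, percentage=pct, p_value=p)


def probe_set_overlap_test(significant_probes, geneset_probes,
                           array_size: int) -> OverlapTestResult:
    """Hypergeometric over-representation of a gene set among significant probes.

    ``array_size`` is the total number of probe sets on the array (the
    universe). Percentage is the overlap relative to the gene-set size.
    """
    sig = set(significant_probes)
    gs = set(geneset_probes)
    if array_size < len(sig | gs):
        raise ValueError("array universe smaller than the union of the sets")
    k = len(sig & gs)
    lo = max(0, len(gs) + len(sig) - array_size)
    p = hypergeom_upper_tail(array_size, len(sig), len(gs), max(k, lo))
    pct = 100.0 * k / len(gs) if gs else float("nan")
    return OverlapTestResult(overlap=k, query_size=len(gs),
                             reference_size=len(sig), universe=array_size,
                             percentage=pct, p_value=p)
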