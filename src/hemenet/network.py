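"""Cross-taxon MHC homology networks.

Query MHCs (e.g. one family's proteomes) are searched against a reference
MHC panel carrying taxonomy labels; edges join proteins whose best local
alignment passes the E-value and percent-identity cutoffs (defaults 1e-20
and 50%, with identity interpreted per hit). Components containing only
query nodes, or no query node, are pruned — what remains are the clusters
linking the query repertoire to homologs in other lineages, candidate
evidence of lateral transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx

from .errors import ConfigurationError
from .hemescan import find_heme_motifs
from .homology import DEFAULT_PARAMS, AlignmentParams, align_pair
from .records import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class MHCNetwork:
    """A protein homology network with query/reference node partitioning."""

    graph: nx.Graph
    max_evalue: float
    min_identity: float

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    queries: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    taxonomy: Mapping[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
    max_evalue: float = 1e-20,
    min_identity: float = 50.0,
    include_query_edges: bool = True,
) -> MHCNetwork:
    """Build the thresholded homology network.

    All query nodes are present (isolated ones are removed later by
    pruning); reference proteins appear only when they participate in at
    least one passing edge. Node attributes carry the partition (``kind``),
    taxonomy and heme count; edge weight is percent identity.
    """
    if not queries:
        raise ConfigurationError("query set must be non-empty")
    graph = nx.Graph()
    for q in queries:
        graph.add_node(
            q.protein_id,
            kind="query",
            taxonomy=taxonomy.get(q.protein_id, q.genome_id),
            hemes=len(find_heme_motifs(q.sequence)),
        )
    n_ref = sum(len(r) for r in reference)

    def add_edge(a: ProteinRecord, b: ProteinRecord, db_residues: int) -> None:
        hit = align_pair(
            a.sequence, b.sequence, params,
            query_id=a.protein_id, subject_id=b.protein_id,
            db_residues=db_residues,
        )
        if hit.evalue <= max_evalue and hit.pident >= min_identity:
            if b.protein_id not in graph:
                graph.add_node(
                    b.protein_id,
                    kind="reference",
                    taxonomy=taxonomy.get(b.protein_id, b.genome_id),
                    hemes=len(find_heme_motifs(b.sequence)),
                )
            graph.add_edge(
                a.protein_id, b.protein_id,
                identity=hit.pident, evalue=hit.evalue, bit_score=hit.bit_score,
            )

    for q in queries:
        for r in reference:
            add_edge(q, r, n_ref)
    if include_query_edges:
        n_q = sum(len(q) for q in queries)
        for i, a in enumerate(queries):
            for b in queries[i + 1:]:
                add_edge(a, b, n_q)
    logger.info(
        "network: %d nodes, %d edges at E<=%g, identity>=%g",
        graph.number_of_nodes(), graph.number_of_edges(), max_evalue, min_identity,
    )
    return MHCNetwork(graph=graph, max_evalue=max_evalue, min_identity=min_identity)


def prune_components(network: MHCNetwork) -> MHCNetwork:
    """Remove components that are all-query or query-free; idempotent."""
    graph = network.graph.copy()
    for comp in list(nx.connected_components(graph)):
        kinds = {graph.nodes[n]["kind"] for n in comp}
        if kinds != {"query", "reference"}:
            graph.remove_nodes_from(comp)
    return MHCNetwork(
        graph=graph, max_evalue=network.max_evalue, min_identity=network.min_identity
    )


def export_graph(network: MHCNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML (round-trip safe), edge-list TSV, or SIF."""
    path = Path(path)
    graph = network.graph
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tidentity\tevalue\n")
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['identity']:.2f}\t{data['evalue']:.3g}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\thomology\t{v}\n")
            for n in sorted(nx.isolates(graph)):
                fh.write(f"{n}\n")
    else:
        raise ConfigurationError(f"unknown export format {format!r}")


def load_graphml(path: str | Path, max_evalue: float, min_identity: float) -> MHCNetwork:
    graph = nx.read_graphml(path)
    return MHCNetwork(graph=graph, max_evalue=max_evalue, min_identity=min_identity)
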