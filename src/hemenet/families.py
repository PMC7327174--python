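"""Orthologous-family clustering of MHCs and conservation summaries.

Families are built from a reciprocal homology graph: an undirected edge joins
two proteins when hits in both directions pass the E-value and identity
thresholds. The default clustering is connected components of that graph; an
``mcl-like`` mode runs a Markov-cluster flow simulation (expansion then
inflation with a fixed parameter) for finer granularity. This is a
deterministic reimplementation of the orthogroup step, not a faithful clone
of any external orthology tool — family counts on real data are
tool-dependent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, ParameterError
from .homology import PairwiseHit, best_hits
from .records import parse_header_id


def build_homology_graph(
    hits: Sequence[PairwiseHit],
    max_evalue: float = 1e-3,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    nodes: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Reciprocal thresholded homology graph over protein ids.

    For each ordered pair the best hit is kept; an undirected edge requires
    both directed hits to pass ``evalue <= max_evalue``,
    ``pident >= min_identity`` and ``qcov >= min_coverage`` (percent of the
    shorter sequence aligned — heme-dense proteins can share short
    motif-periodic local alignments at high identity, and the coverage
    requirement keeps such fragments from linking unrelated proteins).
    Self-hits never create edges. ``nodes`` adds isolated vertices (proteins
    with no passing hits).
    """
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    best: dict[tuple[str, str], PairwiseHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        prev = best.get(key)
        if prev is None or (hit.bit_score, hit.length) > (prev.bit_score, prev.length):
            best[key] = hit
    for (q, s), hit in sorted(best.items()):
        if q >= s:
            continue
        back = best.get((s, q))
        if back is None:
            continue
        if (
            hit.evalue <= max_evalue
            and back.evalue <= max_evalue
            and hit.pident >= min_identity
            and back.pident >= min_identity
            and hit.qcov >= min_coverage
            and back.qcov >= min_coverage
        ):
            graph.add_node(q)
            graph.add_node(s)
            graph.add_edge(q, s, identity=hit.pident, evalue=max(hit.evalue, back.evalue))
    return graph


def _mcl_partition(
    graph: nx.Graph, inflation: float = 2.0, max_iter: int = 100, tol: float = 1e-8
) -> list[set[str]]:
    """Markov-cluster flow simulation on the (weighted-by-1) adjacency matrix."""
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v in graph.edges:
        m[index[u], index[v]] = 1.0
        m[index[v], index[u]] = 1.0
    np.fill_diagonal(m, 1.0)  # self-loops stabilise the flow
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        inflated[inflated < 1e-9] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    # attractors are rows with mass; nodes sharing an attractor share a cluster
    attract = nx.Graph()
    attract.add_nodes_from(nodes)
    rows, cols = np.nonzero(m > 1e-6)
    for r, c in zip(rows, cols):
        attract.add_edge(nodes[r], nodes[c])
    return [set(c) for c in nx.connected_components(attract)]


@dataclass(frozen=True)
class OrthoFamily:
    """One orthologous protein family: members across genomes."""

    family_id: str
    members: tuple[str, ...]
    genomes: tuple[str, ...]
    per_genome_counts: tuple[tuple[str, int], ...]

    @property
    def size(self) -> int:
        return len(self.members)

    def counts(self) -> dict[str, int]:
        return dict(self.per_genome_counts)


def _genome_lookup(
    genome_of: Optional[dict[str, str] | Callable[[str], str]]
) -> Callable[[str], str]:
    if genome_of is None:
        def from_header(pid: str) -> str:
            g, _ = parse_header_id(pid)
            if g is None:
                raise IntegrityError(
                    f"cannot infer genome for {pid!r}; pass genome_of explicitly"
                )
            return g

        return from_header
    if callable(genome_of):
        return genome_of
    return lambda pid: genome_of[pid]


def cluster_families(
    graph: nx.Graph,
    genome_of: Optional[dict[str, str] | Callable[[str], str]] = None,
    method: str = "components",
    inflation: float = 2.0,
) -> list[OrthoFamily]:
    """Partition the graph's proteins into orthologous families.

    ``components`` takes connected components; ``mcl-like`` runs the flow
    clustering per component. Family ids are assigned by descending size then
    lexicographically smallest member, so output is stable across runs.
    """
    if method == "components":
        parts = [set(c) for c in nx.connected_components(graph)]
    elif method == "mcl-like":
        parts = []
        for comp in nx.connected_components(graph):
            parts.extend(_mcl_partition(graph.subgraph(comp), inflation=inflation))
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")
    lookup = _genome_lookup(genome_of)
    parts.sort(key=lambda p: (-len(p), min(p)))
    families = []
    for i, part in enumerate(parts):
        members = tuple(sorted(part))
        counts: dict[str, int] = {}
        for pid in members:
            g = lookup(pid)
            counts[g] = counts.get(g, 0) + 1
        families.append(
            OrthoFamily(
                family_id=f"OF{i + 1:05d}",
                members=members,
                genomes=tuple(sorted(counts)),
                per_genome_counts=tuple(sorted(counts.items())),
            )
        )
    return families


def abundance_matrix(
    families: Sequence[OrthoFamily], genomes: Sequence[str]
) -> pd.DataFrame:
    """Genomes x families count matrix; all-zero rows kept for MHC-free genomes."""
    genomes = list(genomes)
    known = set(genomes)
    mat = pd.DataFrame(
        0, index=genomes, columns=[f.family_id for f in families], dtype=int
    )
    for fam in families:
        for g, c in fam.per_genome_counts:
            if g not in known:
                raise IntegrityError(
                    f"family {fam.family_id} has member from unknown genome {g!r}"
                )
            mat.loc[g, fam.family_id] = c
    return mat


def conservation_summary(matrix: pd.DataFrame, k: int) -> tuple[int, int]:
    """(families present in >= k genomes, families present in all genomes)."""
    n_genomes = matrix.shape[0]
    if not (1 <= k <= n_genomes):
        raise ParameterError(f"k must be in [1, {n_genomes}], got {k}")
    present = (matrix > 0).sum(axis=0)
    return int((present >= k).sum()), int((present >= n_genomes).sum())


def display_order(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Cosmetic row/column ordering by average-linkage clustering (Euclidean).

    Purely presentational — the counts themselves are the computational
    output. Returns (row order, column order).
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    def order(frame: pd.DataFrame) -> list[str]:
        if frame.shape[0] < 3:
            return list(frame.index)
        linkage = average(pdist(frame.values.astype(float)))
        return [frame.index[i] for i in leaves_list(linkage)]

    return order(matrix), order(matrix.T)


def families_frame(families: Sequence[OrthoFamily], genome_of=None) -> pd.DataFrame:
    lookup = _genome_lookup(genome_of)
    rows = [
        {"family_id": f.family_id, "protein_id": pid, "genome_id": lookup(pid)}
        for f in families
        for pid in f.members
    ]
    return pd.DataFrame(rows, columns=["family_id", "protein_id", "genome_id"])


def write_families(
    families: Sequence[OrthoFamily], path: str | Path, genome_of=None
) -> None:
    families_frame(families, genome_of).to_csv(path, sep="\t", index=False)


def write_matrix(matrix: pd.DataFrame, path: str | Path, ordered: bool = False) -> None:
    if ordered and min(matrix.shape) > 0:
        rows, cols = display_order(matrix)
        matrix = matrix.loc[rows, cols]
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def write_summary(
    families: Sequence[OrthoFamily], matrix: pd.DataFrame, path: str | Path
) -> dict:
    n_genomes = matrix.shape[0]
    summary = {
        "n_families": len(families),
        "n_mhc": int(sum(f.size for f in families)),
        "n_core_families": conservation_summary(matrix, n_genomes)[1] if n_genomes else 0,
        "families_in_ge_k": {
            str(k): conservation_summary(matrix, k)[0] for k in range(2, n_genomes + 1)
        },
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
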