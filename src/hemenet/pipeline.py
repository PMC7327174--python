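"""End-to-end orchestration: scan -> homology -> families -> neighborhood -> network.

``run_pipeline`` wires the stage modules together over a directory of
per-genome protein FASTA files (plus optional GFF3, label tables and a
reference panel) and writes every stage's tabular output along with a
summary JSON that embeds the full effective configuration and its hash, so
a rerun on identical inputs is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import families as fam_mod
from . import neighborhood as nbr_mod
from . import network as net_mod
from .errors import InputError
from .hemescan import scan_proteome, write_annotations, write_stats
from .homology import search, write_hits
from .io import ensure_dir, read_fasta, read_gff, read_labels, read_taxonomy
from .records import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full run."""

    proteome_dir: str
    gff_dir: Optional[str] = None
    labels_path: Optional[str] = None
    reference_fasta: Optional[str] = None
    taxonomy_path: Optional[str] = None
    min_motifs: int = 3
    family_max_evalue: float = 1e-3
    family_min_identity: float = 50.0
    family_min_coverage: float = 50.0
    family_method: str = "components"
    network_max_evalue: float = 1e-20
    network_min_identity: float = 50.0
    conservation_k: int = 8

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Aggregated stage results of one pipeline run."""

    config: dict
    config_hash: str
    per_genome_stats: dict[str, dict]
    n_mhc_total: int
    n_families: int
    n_core_families: int
    families_in_ge_k: int
    cluster_matches_per_pattern: dict[str, int]
    marker_matrix_digest: Optional[str]
    network_nodes: int
    network_edges: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunSummary:
    """Execute the stages in order and write all outputs under ``out_dir``."""
    out = ensure_dir(out_dir)
    proteome_dir = Path(config.proteome_dir)
    if not proteome_dir.is_dir():
        raise InputError(f"missing proteome directory: {proteome_dir}")
    fasta_files = sorted(proteome_dir.glob("*.faa")) + sorted(proteome_dir.glob("*.fasta"))
    if not fasta_files:
        raise InputError(f"no FASTA files in {proteome_dir}")
    for path_attr in ("labels_path", "reference_fasta", "taxonomy_path"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise InputError(f"missing input: {p}")

    proteins: list[ProteinRecord] = []
    genomes: list[str] = []
    for fp in fasta_files:
        recs = read_fasta(fp)
        proteins.extend(recs)
        genomes.extend(sorted({r.genome_id for r in recs}))
    genomes = sorted(set(genomes))

    # 1. scan
    annotations, stats = scan_proteome(
        proteins, min_motifs=config.min_motifs, genomes=genomes
    )
    write_annotations(annotations, out / "mhc_annotations.tsv")
    write_stats(stats, out / "genome_stats.tsv")
    mhc_ids = {a.protein_id for a in annotations if a.is_mhc}
    mhc_proteins = [p for p in proteins if p.protein_id in mhc_ids]
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    logger.info("scan: %d proteins, %d MHCs", len(proteins), len(mhc_proteins))

    # 2. homology among MHCs
    hits = search(mhc_proteins, mhc_proteins)
    write_hits(hits, out / "mhc_hits.tsv")

    # 3. families
    graph = fam_mod.build_homology_graph(
        hits,
        max_evalue=config.family_max_evalue,
        min_identity=config.family_min_identity,
        min_coverage=config.family_min_coverage,
        nodes=sorted(mhc_ids),
    )
    families = fam_mod.cluster_families(
        graph, genome_of=genome_of, method=config.family_method
    )
    matrix = fam_mod.abundance_matrix(families, genomes)
    fam_mod.write_families(families, out / "families.tsv", genome_of=genome_of)
    fam_mod.write_matrix(matrix, out / "family_matrix.tsv")
    k = min(config.conservation_k, max(1, len(genomes)))
    n_ge_k, n_core = fam_mod.conservation_summary(matrix, k) if len(genomes) else (0, 0)
    fam_mod.write_summary(families, matrix, out / "family_summary.json")

    # 4. neighborhood
    matches: list[nbr_mod.ClusterMatch] = []
    marker_digest = None
    if config.gff_dir is not None and config.labels_path is not None:
        labels = read_labels(config.labels_path)
        ann_by_id = {a.protein_id: a for a in annotations}
        labels_by_genome: dict[str, dict[str, str]] = {g: {} for g in genomes}
        for pid, lab in labels.items():
            g = genome_of.get(pid)
            if g is not None:
                labels_by_genome[g][pid] = lab
        for gff_path in sorted(Path(config.gff_dir).glob("*.gff")):
            genes = read_gff(gff_path)
            ordered = nbr_mod.order_genes(genes)
            matches.extend(
                nbr_mod.match_all(ordered, labels, ann_by_id)
            )
        nbr_mod.write_matches(matches, out / "cluster_matches.tsv")
        markers = nbr_mod.marker_matrix(labels_by_genome)
        markers.to_csv(out / "marker_matrix.tsv", sep="\t", index_label="genome_id")
        marker_digest = hashlib.sha256(
            markers.to_csv(sep="\t").encode()
        ).hexdigest()[:16]

    # 5. network
    net_nodes = net_edges = 0
    if config.reference_fasta is not None:
        reference = read_fasta(config.reference_fasta, genome_id="reference")
        taxonomy = (
            read_taxonomy(config.taxonomy_path) if config.taxonomy_path else {}
        )
        network = net_mod.build_network(
            mhc_proteins,
            reference,
            taxonomy,
            max_evalue=config.network_max_evalue,
            min_identity=config.network_min_identity,
        )
        pruned = net_mod.prune_components(network)
        net_mod.export_graph(pruned, out / "mhc_network.graphml", "graphml")
        net_mod.export_graph(pruned, out / "mhc_network_edges.tsv", "tsv")
        net_nodes, net_edges = pruned.n_nodes, pruned.n_edges

    pattern_counts: dict[str, int] = {}
    for m in matches:
        pattern_counts[m.pattern] = pattern_counts.get(m.pattern, 0) + 1

    summary = RunSummary(
        config=config.to_dict(),
        config_hash=config.digest(),
        per_genome_stats={g: dataclasses.asdict(s) for g, s in stats.items()},
        n_mhc_total=len(mhc_proteins),
        n_families=len(families),
        n_core_families=n_core,
        families_in_ge_k=n_ge_k,
        cluster_matches_per_pattern=pattern_counts,
        marker_matrix_digest=marker_digest,
        network_nodes=net_nodes,
        network_edges=net_edges,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
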