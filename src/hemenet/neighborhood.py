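"""Gene-neighborhood signature detection and marker presence/absence matrices.

A :class:`ClusterPattern` is a declarative collocation signature: an
unordered multiset of components (functional labels and/or MHC heme-count
constraints) that must occur within a window of consecutive genes, with at
most ``max_gap`` intervening non-component genes between consecutive matched
genes. Matching is strand- and order-agnostic, reflecting "adjacent" gene
clusters whose internal arrangement varies between genomes.

Five menaquinone:cytochrome-c oxidoreductase signatures ship as built-ins:
group 1 a noncanonical bc1/b6f complex with two hypothetical proteins and two
6-heme MHCs; groups 2 and 3 a b-type cytochrome with one or two 6-heme MHCs;
groups 4 and 5 an NrfD-like transmembrane protein with a 4Fe-4S ferredoxin
and MHCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
import yaml

from .errors import ConfigurationError, IntegrityError
from .hemescan import MHCAnnotation
from .io import GeneFeature
from .records import parse_header_id


def order_genes(genes: Sequence[GeneFeature]) -> dict[str, list[GeneFeature]]:
    """Per-scaffold gene lists sorted by start (ties: end, then id)."""
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise IntegrityError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    by_scaffold: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for scaffold in by_scaffold:
        by_scaffold[scaffold].sort(key=lambda g: (g.start, g.end, g.gene_id))
    return dict(sorted(by_scaffold.items()))


@dataclass(frozen=True)
class PatternComponent:
    """One required component: a label match and/or a heme-count constraint."""

    label: Optional[str] = None
    heme_count: Optional[int] = None  # exact requirement
    min_hemes: Optional[int] = None   # at-least requirement
    count: int = 1

    def __post_init__(self) -> None:
        if self.label is None and self.heme_count is None and self.min_hemes is None:
            raise ConfigurationError("component needs a label or a heme constraint")
        if self.count < 1:
            raise ConfigurationError("component count must be >= 1")

    def matches(self, label: Optional[str], hemes: int) -> bool:
        if self.label is not None and label != self.label:
            return False
        if self.heme_count is not None and hemes != self.heme_count:
            return False
        if self.min_hemes is not None and hemes < self.min_hemes:
            return False
        return True


@dataclass(frozen=True)
class ClusterPattern:
    """A named gene-collocation signature."""

    name: str
    components: tuple[PatternComponent, ...]
    max_gap: int = 2

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError(f"pattern {self.name!r} has no components")
        if self.max_gap < 0:
            raise ConfigurationError(f"pattern {self.name!r} has negative max_gap")

    @property
    def total_genes(self) -> int:
        return sum(c.count for c in self.components)


#: The five built-in oxidoreductase cluster signatures. Groups 2/3 and 4/5
#: are distinguished by MHC copy number and heme count; see docs/methods.md.
BUILTIN_PATTERNS: tuple[ClusterPattern, ...] = (
    ClusterPattern(
        "group1",
        (
            PatternComponent(label="bc_complex"),
            PatternComponent(label="hypothetical", count=2),
            PatternComponent(heme_count=6, count=2),
        ),
    ),
    ClusterPattern(
        "group2",
        (PatternComponent(label="cytb"), PatternComponent(heme_count=6)),
    ),
    ClusterPattern(
        "group3",
        (PatternComponent(label="cytb"), PatternComponent(heme_count=6, count=2)),
    ),
    ClusterPattern(
        "group4",
        (
            PatternComponent(label="nrfd_like"),
            PatternComponent(label="ferredoxin_4fe4s"),
            PatternComponent(heme_count=6),
        ),
    ),
    ClusterPattern(
        "group5",
        (
            PatternComponent(label="nrfd_like"),
            PatternComponent(label="ferredoxin_4fe4s"),
            PatternComponent(min_hemes=3, count=2),
        ),
    ),
)


@dataclass(frozen=True)
class ClusterMatch:
    """An occurrence of a pattern: matched genes with their component roles."""

    genome_id: str
    scaffold_id: str
    pattern: str
    matched: tuple[tuple[str, str], ...]  # (gene_id, role)
    span: tuple[int, int]  # first..last gene index on the scaffold

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.matched)


def _component_role(comp: PatternComponent) -> str:
    if comp.label is not None:
        return comp.label
    if comp.heme_count is not None:
        return f"mhc{comp.heme_count}"
    return f"mhc>={comp.min_hemes}"


def _assign(
    candidates: list[tuple[int, GeneFeature, list[int]]],
    pattern: ClusterPattern,
) -> Optional[list[tuple[int, GeneFeature, int]]]:
    """Match candidate genes to component slots via maximum bipartite matching."""
    slots: list[int] = []  # component index per slot
    for ci, comp in enumerate(pattern.components):
        slots.extend([ci] * comp.count)
    graph = nx.Graph()
    gene_nodes = [f"gene{i}" for i in range(len(candidates))]
    slot_nodes = [f"slot{i}" for i in range(len(slots))]
    graph.add_nodes_from(gene_nodes, bipartite=0)
    graph.add_nodes_from(slot_nodes, bipartite=1)
    for i, (_, _, comps) in enumerate(candidates):
        for si, ci in enumerate(slots):
            if ci in comps:
                graph.add_edge(f"gene{i}", f"slot{si}")
    matching = nx.bipartite.maximum_matching(graph, top_nodes=gene_nodes)
    matched_slots = [s for s in slot_nodes if s in matching]
    if len(matched_slots) < len(slots):
        return None
    out = []
    for si, ci in enumerate(slots):
        gene_node = matching[f"slot{si}"]
        gi = int(gene_node[4:])
        idx, gene, _ = candidates[gi]
        out.append((idx, gene, ci))
    out.sort(key=lambda t: t[0])
    return out


def match_pattern(
    ordered: Mapping[str, Sequence[GeneFeature]],
    labels: Mapping[str, str],
    annotations: Mapping[str, MHCAnnotation],
    pattern: ClusterPattern,
    genome_id: Optional[str] = None,
    claimed: Optional[set[str]] = None,
) -> list[ClusterMatch]:
    """Find every occurrence of ``pattern`` in per-scaffold ordered gene lists.

    Candidate genes (those satisfying at least one component) are grouped
    into maximal runs in which consecutive candidates are separated by at
    most ``max_gap`` intervening genes; each run that can cover the full
    component multiset is reported once as the maximal match. Genes listed in
    ``claimed`` are ignored (used for cross-pattern exclusivity).
    """
    claimed = claimed or set()
    matches: list[ClusterMatch] = []
    for scaffold_id, genes in ordered.items():
        candidates: list[tuple[int, GeneFeature, list[int]]] = []
        for idx, gene in enumerate(genes):
            if gene.gene_id in claimed:
                continue
            label = labels.get(gene.gene_id)
            ann = annotations.get(gene.gene_id)
            hemes = ann.heme_count if ann is not None else 0
            comps = [
                ci
                for ci, comp in enumerate(pattern.components)
                if comp.matches(label, hemes)
            ]
            if comps:
                candidates.append((idx, gene, comps))
        # split candidates into maximal runs under the gap limit
        runs: list[list[tuple[int, GeneFeature, list[int]]]] = []
        for cand in candidates:
            if runs and cand[0] - runs[-1][-1][0] - 1 <= pattern.max_gap:
                runs[-1].append(cand)
            else:
                runs.append([cand])
        for run in runs:
            assignment = _assign(run, pattern)
            if assignment is None:
                continue
            gid = genome_id
            if gid is None:
                gid, _ = parse_header_id(assignment[0][1].gene_id)
                gid = gid or "unknown"
            matches.append(
                ClusterMatch(
                    genome_id=gid,
                    scaffold_id=scaffold_id,
                    pattern=pattern.name,
                    matched=tuple(
                        (gene.gene_id, _component_role(pattern.components[ci]))
                        for _, gene, ci in assignment
                    ),
                    span=(assignment[0][0], assignment[-1][0]),
                )
            )
    return matches


def match_all(
    ordered: Mapping[str, Sequence[GeneFeature]],
    labels: Mapping[str, str],
    annotations: Mapping[str, MHCAnnotation],
    patterns: Sequence[ClusterPattern] = BUILTIN_PATTERNS,
    genome_id: Optional[str] = None,
    exclusive: bool = True,
) -> list[ClusterMatch]:
    """Match several patterns; with ``exclusive`` the most specific wins.

    Patterns are evaluated from most to fewest required genes, and genes
    matched by a more specific pattern are not reused by a less specific one
    — this prevents a signature that is a sub-multiset of another (group 2
    within group 3) from double-reporting the same cluster.
    """
    order = sorted(patterns, key=lambda p: (-p.total_genes, p.name))
    claimed: set[str] = set()
    matches: list[ClusterMatch] = []
    for pattern in order:
        found = match_pattern(
            ordered, labels, annotations, pattern,
            genome_id=genome_id, claimed=claimed if exclusive else None,
        )
        matches.extend(found)
        if exclusive:
            for m in found:
                claimed.update(m.gene_ids)
    matches.sort(key=lambda m: (m.genome_id, m.scaffold_id, m.span, m.pattern))
    return matches


# --- marker presence/absence -------------------------------------------------

#: terminal-electron-acceptor / electron-donor marker definitions: a marker is
#: present in a genome when any gene carries one of the listed labels.
DEFAULT_MARKER_DEFS: dict[str, frozenset[str]] = {
    "NarG": frozenset({"NarG"}),
    "NrfA": frozenset({"NrfA"}),
    "NxrA": frozenset({"NxrA"}),
    "SrdA": frozenset({"SrdA"}),
    "SreABC": frozenset({"SreA", "SreB", "SreC"}),
    "Arx/Arr": frozenset({"ArxA", "ArrA"}),
    "FdhAB": frozenset({"FdhA", "FdhB"}),
    "NiFe group 1": frozenset({"NiFe_group1"}),
    "NiFe group 3b": frozenset({"NiFe_group3b"}),
}


def marker_matrix(
    labels_by_genome: Mapping[str, Mapping[str, str]],
    marker_defs: Mapping[str, Iterable[str]] = DEFAULT_MARKER_DEFS,
) -> pd.DataFrame:
    """Binary genomes x markers presence matrix from per-gene label tables."""
    genomes = sorted(labels_by_genome)
    markers = list(marker_defs)
    mat = pd.DataFrame(0, index=genomes, columns=markers, dtype=int)
    for g in genomes:
        present_labels = set(labels_by_genome[g].values())
        for marker, accepted in marker_defs.items():
            if present_labels & set(accepted):
                mat.loc[g, marker] = 1
    return mat


# --- pattern files -----------------------------------------------------------

def load_patterns(path: str | Path) -> list[ClusterPattern]:
    """Load patterns from a YAML file.

    Layout: a list of ``{name, max_gap, components: [{label, heme_count,
    min_hemes, count}]}`` entries.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ConfigurationError(f"{path}: pattern file must be a list")
    patterns = []
    for entry in data:
        try:
            comps = tuple(
                PatternComponent(
                    label=c.get("label"),
                    heme_count=c.get("heme_count"),
                    min_hemes=c.get("min_hemes"),
                    count=int(c.get("count", 1)),
                )
                for c in entry["components"]
            )
            patterns.append(
                ClusterPattern(
                    name=str(entry["name"]),
                    components=comps,
                    max_gap=int(entry.get("max_gap", 2)),
                )
            )
        except (KeyError, TypeError, AttributeError) as exc:
            raise ConfigurationError(f"{path}: malformed pattern entry: {exc}") from exc
    return patterns


def matches_frame(matches: Sequence[ClusterMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "scaffold_id": m.scaffold_id,
                "pattern": m.pattern,
                "gene_ids": ";".join(m.gene_ids),
                "roles": ";".join(r for _, r in m.matched),
                "span_start": m.span[0],
                "span_end": m.span[1],
            }
            for m in matches
        ],
        columns=[
            "genome_id", "scaffold_id", "pattern", "gene_ids", "roles",
            "span_start", "span_end",
        ],
    )


def write_matches(matches: Sequence[ClusterMatch], path: str | Path) -> None:
    matches_frame(matches).to_csv(path, sep="\t", index=False)
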