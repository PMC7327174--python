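"""Heme-binding motif scanning and putative MHC calling.

Multiheme c-type cytochromes (MHCs) covalently attach heme c at CXXCH sites —
cysteine, two arbitrary residues, cysteine, histidine. A protein is called a
putative MHC when it carries at least ``min_motifs`` such sites (default 3).
This module scans proteomes for the motif, aggregates per-genome repertoire
statistics, and checks the NiFe-hydrogenase L1/L2 binding motifs used to
support hydrogenase annotations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, IntegrityError, ParameterError
from .records import ProteinRecord, clean_sequence

logger = logging.getLogger(__name__)

#: Overlap-aware scanner for the heme c attachment site.
_HEME_RE = re.compile(r"(?=(C..CH))")
_HEME_RE_DISJOINT = re.compile(r"C..CH")

#: Built-in NiFe-hydrogenase large-subunit binding motifs (L1 near the N
#: terminus, L2 near the C terminus, each contributing a Cys pair to the NiFe
#: centre). These are heuristic defaults chosen by this package and should be
#: overridden when organism-specific motif definitions are available.
DEFAULT_NIFE_L1 = "RxCGxCxxxH"
DEFAULT_NIFE_L2 = "DPCxxCxxH"


def find_heme_motifs(sequence: str, disjoint: bool = False) -> list[int]:
    """Return the 0-based start offsets of every CXXCH site.

    Overlapping sites are all reported by default (two sites may share the
    cysteine at offset i+3); ``disjoint=True`` instead counts greedily
    left-to-right without overlap.
    """
    seq = clean_sequence(sequence) if sequence else ""
    if not seq:
        return []
    pattern = _HEME_RE_DISJOINT if disjoint else _HEME_RE
    return [m.start() for m in pattern.finditer(seq)]


@dataclass(frozen=True)
class MHCAnnotation:
    """Per-protein heme-motif annotation.

    ``has_cyt_domain`` / ``has_slayer_domain`` record the optional external
    domain-verification step; they stay ``"untested"`` unless a domain table
    is supplied.
    """

    protein_id: str
    genome_id: str
    motif_positions: tuple[int, ...]
    is_mhc: bool
    has_cyt_domain: str = "untested"
    has_slayer_domain: str = "untested"

    @property
    def heme_count(self) -> int:
        return len(self.motif_positions)


@dataclass(frozen=True)
class GenomeMHCStats:
    """Per-genome MHC repertoire summary."""

    genome_id: str
    n_proteins: int
    n_mhc: int
    max_hemes: int
    mean_hemes: float
    total_hemes: int


def call_mhc(
    protein: ProteinRecord, min_motifs: int = 3, disjoint: bool = False
) -> MHCAnnotation:
    """Annotate one protein; ``is_mhc`` is true iff it has >= ``min_motifs`` sites."""
    if min_motifs < 1:
        raise ParameterError(f"min_motifs must be >= 1, got {min_motifs}")
    positions = find_heme_motifs(protein.sequence, disjoint=disjoint)
    return MHCAnnotation(
        protein_id=protein.protein_id,
        genome_id=protein.genome_id,
        motif_positions=tuple(positions),
        is_mhc=len(positions) >= min_motifs,
    )


def scan_proteome(
    proteins: Sequence[ProteinRecord],
    min_motifs: int = 3,
    disjoint: bool = False,
    genomes: Optional[Iterable[str]] = None,
) -> tuple[list[MHCAnnotation], dict[str, GenomeMHCStats]]:
    """Annotate every protein and aggregate per-genome repertoire statistics.

    ``genomes`` may list genome ids that must appear in the stats even when
    they contribute no proteins (zeroed rows). Duplicate protein ids within a
    genome raise :class:`IntegrityError`.
    """
    seen: set[tuple[str, str]] = set()
    annotations: list[MHCAnnotation] = []
    by_genome: dict[str, list[MHCAnnotation]] = {g: [] for g in (genomes or [])}
    for prot in proteins:
        key = (prot.genome_id, prot.protein_id)
        if key in seen:
            raise IntegrityError(
                f"duplicate protein id {prot.protein_id!r} in genome {prot.genome_id!r}"
            )
        seen.add(key)
        ann = call_mhc(prot, min_motifs=min_motifs, disjoint=disjoint)
        annotations.append(ann)
        by_genome.setdefault(prot.genome_id, []).append(ann)

    stats: dict[str, GenomeMHCStats] = {}
    for genome_id in sorted(by_genome):
        anns = by_genome[genome_id]
        mhc = [a for a in anns if a.is_mhc]
        heme_counts = [a.heme_count for a in mhc]
        stats[genome_id] = GenomeMHCStats(
            genome_id=genome_id,
            n_proteins=len(anns),
            n_mhc=len(mhc),
            max_hemes=max(heme_counts, default=0),
            mean_hemes=(sum(heme_counts) / len(heme_counts)) if heme_counts else 0.0,
            total_hemes=sum(heme_counts),
        )
    return annotations, stats


# --- motif expressions ------------------------------------------------------

_MOTIF_TOKEN = re.compile(
    r"[ACDEFGHIKLMNPQRSTVWY]"  # literal residue
    r"|[xX.]"                   # wildcard
    r"|\[[ACDEFGHIKLMNPQRSTVWY]+\]"  # character class
    r"|\{\d+(,\d+)?\}"          # repeat of the previous token
)


def compile_motif(expression: str) -> re.Pattern:
    """Compile a restricted motif expression into a regex.

    The language supports literal residues, ``x``/``.`` wildcards, ``[...]``
    residue classes and ``{m}``/``{m,n}`` repeats. Anything else raises
    :class:`ConfigurationError`.
    """
    if not expression:
        raise ConfigurationError("empty motif expression")
    pos = 0
    out: list[str] = []
    while pos < len(expression):
        m = _MOTIF_TOKEN.match(expression, pos)
        if m is None:
            raise ConfigurationError(
                f"malformed motif expression {expression!r} at position {pos}"
            )
        token = m.group(0)
        if token in ("x", "X"):
            token = "."
        if token.startswith("{") and not out:
            raise ConfigurationError(
                f"repeat without preceding token in {expression!r}"
            )
        out.append(token)
        pos = m.end()
    try:
        return re.compile("".join(out))
    except re.error as exc:  # pragma: no cover - token grammar should prevent this
        raise ConfigurationError(f"cannot compile motif {expression!r}: {exc}") from exc


def check_nife_motifs(
    sequence: str,
    l1_pattern: str = DEFAULT_NIFE_L1,
    l2_pattern: str = DEFAULT_NIFE_L2,
) -> tuple[bool, bool]:
    """Check a (putative NiFe catalytic subunit) sequence for the L1 and L2 motifs.

    Returns (l1_found, l2_found). The shipped default patterns are this
    package's heuristics; a log line flags them so analyses that need
    curated motif definitions override them explicitly.
    """
    if l1_pattern == DEFAULT_NIFE_L1 and l2_pattern == DEFAULT_NIFE_L2:
        logger.info(
            "check_nife_motifs: using built-in heuristic L1/L2 patterns (%s, %s); "
            "override with curated motifs where available",
            DEFAULT_NIFE_L1,
            DEFAULT_NIFE_L2,
        )
    l1 = compile_motif(l1_pattern)
    l2 = compile_motif(l2_pattern)
    seq = clean_sequence(sequence) if sequence else ""
    if not seq:
        return (False, False)
    return (l1.search(seq) is not None, l2.search(seq) is not None)


# --- domain verification hook ----------------------------------------------

def apply_domain_table(
    annotations: Sequence[MHCAnnotation],
    domain_table: pd.DataFrame,
    cyt_domains: Iterable[str] = ("Cytochrom_C", "Cytochrom_C3", "Multi_heme_cyto"),
    slayer_domains: Iterable[str] = ("SLH", "S_layer"),
    max_evalue: float = 1e-5,
) -> list[MHCAnnotation]:
    """Fill ``has_cyt_domain``/``has_slayer_domain`` from an external domain TSV.

    The table must have columns (protein_id, domain, evalue), e.g. produced by
    an hmmsearch against Pfam. Core MHC calling never depends on this step.
    """
    required = {"protein_id", "domain", "evalue"}
    if not required.issubset(domain_table.columns):
        raise ConfigurationError(
            f"domain table needs columns {sorted(required)}"
        )
    keep = domain_table[domain_table["evalue"].astype(float) <= max_evalue]
    cyt = set(cyt_domains)
    slayer = set(slayer_domains)
    has_cyt = set(keep.loc[keep["domain"].isin(cyt), "protein_id"])
    has_slayer = set(keep.loc[keep["domain"].isin(slayer), "protein_id"])
    tested = set(domain_table["protein_id"])
    out = []
    for ann in annotations:
        if ann.protein_id not in tested:
            out.append(ann)
            continue
        out.append(
            MHCAnnotation(
                protein_id=ann.protein_id,
                genome_id=ann.genome_id,
                motif_positions=ann.motif_positions,
                is_mhc=ann.is_mhc,
                has_cyt_domain="yes" if ann.protein_id in has_cyt else "no",
                has_slayer_domain="yes" if ann.protein_id in has_slayer else "no",
            )
        )
    return out


# --- writers ----------------------------------------------------------------

def annotations_frame(annotations: Sequence[MHCAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in annotations],
            "genome_id": [a.genome_id for a in annotations],
            "heme_count": [a.heme_count for a in annotations],
            "is_mhc": [a.is_mhc for a in annotations],
            "motif_positions": [
                ";".join(map(str, a.motif_positions)) for a in annotations
            ],
            "has_cyt_domain": [a.has_cyt_domain for a in annotations],
            "has_slayer_domain": [a.has_slayer_domain for a in annotations],
        }
    )


def stats_frame(stats: dict[str, GenomeMHCStats]) -> pd.DataFrame:
    rows = [vars(s) for _, s in sorted(stats.items())]
    return pd.DataFrame(rows)


def write_annotations(annotations: Sequence[MHCAnnotation], path: str | Path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)


def write_stats(stats: dict[str, GenomeMHCStats], path: str | Path) -> None:
    stats_frame(stats).to_csv(path, sep="\t", index=False)
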