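"""Protein records with genome/scaffold provenance.

A :class:`ProteinRecord` is the unit every stage of the pipeline consumes: an
amino-acid sequence plus where it came from (genome, scaffold, 1-based
nucleotide coordinates, strand) and an optional functional label supplied by
external annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError

_VALID_SEQ = re.compile(r"^[A-Z]+$")


def clean_sequence(sequence: str) -> str:
    """Normalise an amino-acid sequence: uppercase, strip one terminal stop symbol.

    Gene callers commonly emit a trailing ``*``; it is removed. Internal stops
    or any non-letter character raise :class:`InputError`.
    """
    if sequence is None:
        raise InputError("sequence is None")
    seq = sequence.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise InputError("empty sequence after stripping terminal stop")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
        raise InputError(f"sequence contains invalid characters: {bad}")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with provenance.

    Coordinates are 1-based inclusive nucleotide positions on the scaffold;
    they are optional and only needed for neighborhood analysis.
    """

    protein_id: str
    genome_id: str
    sequence: str
    scaffold_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    functional_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))
        if not self.protein_id:
            raise InputError("protein_id must be non-empty")
        if (self.start is None) != (self.end is None):
            raise InputError(f"{self.protein_id}: start and end must be given together")
        if self.start is not None and self.start > self.end:
            raise InputError(f"{self.protein_id}: start > end")
        if self.strand is not None and self.strand not in ("+", "-"):
            raise InputError(f"{self.protein_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_header_id(protein_id: str) -> tuple[Optional[str], Optional[str]]:
    """Extract (genome_id, scaffold_id) from a ``genome|scaffold|index`` header id.

    Returns (None, None) when the id does not follow the convention.
    """
    parts = protein_id.split("|")
    if len(parts) == 3:
        return parts[0], parts[1]
    return None, None
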