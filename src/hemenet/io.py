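"""Readers and writers for the standard flat formats the pipeline exchanges.

FASTA goes through Biopython, GFF3 reading through gffutils; the TSV tables
(annotation labels, taxonomy, hits, matrices) are plain pandas round-trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, IntegrityError
from .records import ProteinRecord, parse_header_id


def read_fasta(path: str | Path, genome_id: Optional[str] = None) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Header ids of the form ``genome|scaffold|index`` carry their own
    provenance; otherwise ``genome_id`` (or the file stem) is used.
    """
    path = Path(path)
    fallback = genome_id if genome_id is not None else path.stem
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid, scaffold = parse_header_id(rec.id)
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                genome_id=gid if gid is not None else fallback,
                scaffold_id=scaffold,
                sequence=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


@dataclass(frozen=True)
class GeneFeature:
    """A CDS feature read from GFF3: id plus coordinates on its scaffold."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str


def read_gff(path: str | Path) -> list[GeneFeature]:
    """Read CDS features (with ID attributes) from a GFF3 file."""
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted parse/sqlite errors
        raise InputError(f"failed to parse GFF3 {path}: {exc}") from exc
    genes: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        if "ID" not in feat.attributes:
            raise InputError(f"{path}: CDS at {feat.seqid}:{feat.start} lacks ID attribute")
        gene_id = feat.attributes["ID"][0]
        if gene_id in seen:
            raise IntegrityError(f"{path}: duplicate CDS ID {gene_id}")
        seen.add(gene_id)
        if feat.start > feat.end:
            raise InputError(f"{path}: malformed coordinates for {gene_id}")
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                scaffold_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
            )
        )
    return genes


def write_gff(genes: Iterable[GeneFeature], path: str | Path, source: str = "hemenet") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\t{source}\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}\n"
            )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (protein_id, label) TSV; a header line is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise InputError(f"{path}: label table needs two columns (protein_id, label)")
    first = str(df.iloc[0, 0]).lower()
    if first in ("protein_id", "protein", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a (protein_id, lineage) TSV mapping reference proteins to taxonomy."""
    return read_labels(path)


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
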