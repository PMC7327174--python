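"""Pairwise protein homology: local alignment, E-values, RBH and genome AAI.

The search step is a Smith-Waterman local alignment under BLOSUM62 with
affine gaps (open 11, extend 1), the common blastp parameterisation; scores
are converted to bit scores with the Karlin-Altschul statistics
``S' = (lambda*S - ln K) / ln 2`` and E-values follow the bit-score form
``E = m * n * 2^(-S')``. Exact blastp score parity is not a goal: thresholds
downstream are applied to this aligner's own outputs.

Average amino-acid identity (AAI) between two genomes is the mean percent
identity over reciprocal-best-hit ortholog pairs passing identity and
coverage filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .records import ProteinRecord

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring model for the local-alignment search."""

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ParameterError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ParameterError("Karlin-Altschul lambda and K must be positive")
        if self.matrix != "BLOSUM62":
            raise ParameterError("only BLOSUM62 is shipped")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class PairwiseHit:
    """One scored local alignment, in blastp tabular vocabulary."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    pident: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    qcov: float  # % of the shorter sequence covered by the alignment


def evalue(bit_score: float, m: int, n: int) -> float:
    """Closed-form E-value ``E = m * n * 2^(-bit_score)``."""
    if m < 1 or n < 1:
        raise ParameterError(f"search-space sizes must be >= 1, got m={m}, n={n}")
    # 2**-x underflows to 0.0 for very strong hits, which is acceptable
    try:
        return float(m) * float(n) * 2.0 ** (-bit_score)
    except OverflowError:
        return math.inf


def align_pair(
    a: str,
    b: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    query_id: str = "query",
    subject_id: str = "subject",
    db_residues: Optional[int] = None,
) -> PairwiseHit:
    """Optimal local alignment of two sequences.

    Percent identity uses all alignment columns (gap columns included) as the
    denominator, mirroring common blastp reporting. ``db_residues`` sets the
    database size for the E-value; it defaults to ``len(b)``.
    """
    if not a or not b:
        raise InputError("cannot align empty sequences")
    # align in canonical sequence order so that among co-optimal alignments
    # the same one is chosen for (a, b) and (b, a): identity is symmetric
    flipped = (b, a) < (a, b)
    first, second = (b, a) if flipped else (a, b)
    alns = balign.align_optimal(
        bseq.ProteinSequence(first),
        bseq.ProteinSequence(second),
        _BLOSUM62,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=True,
        max_number=1,
    )
    aln = alns[0]
    trace = aln.trace[:, ::-1] if flipped else aln.trace
    length = trace.shape[0]
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    ident = int(
        np.sum(arr_a[trace[both, 0]] == arr_b[trace[both, 1]])
    ) if both.any() else 0
    mismatches = int(both.sum()) - ident
    gap_opens = 0
    for col in (0, 1):
        gaps = trace[:, col] < 0
        if gaps.any():
            prev = np.concatenate(([False], gaps[:-1]))
            gap_opens += int(np.sum(gaps & ~prev))
    q_cols = trace[trace[:, 0] >= 0, 0]
    s_cols = trace[trace[:, 1] >= 0, 1]
    qstart, qend = (int(q_cols.min()) + 1, int(q_cols.max()) + 1) if len(q_cols) else (0, 0)
    sstart, send = (int(s_cols.min()) + 1, int(s_cols.max()) + 1) if len(s_cols) else (0, 0)
    shorter = min(len(a), len(b))
    aligned_shorter = len(q_cols) if len(a) <= len(b) else len(s_cols)
    bit = params.bit_score(aln.score)
    n_db = db_residues if db_residues is not None else len(b)
    return PairwiseHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(aln.score),
        bit_score=bit,
        pident=100.0 * ident / length if length else 0.0,
        length=length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=evalue(bit, len(a), n_db),
        qcov=100.0 * aligned_shorter / shorter if shorter else 0.0,
    )


def search(
    queries: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
    max_evalue: Optional[float] = None,
) -> list[PairwiseHit]:
    """All-vs-all local alignment of queries against a database.

    E-values use the total residue count of the database as ``n``.
    """
    n_db = sum(len(p) for p in database)
    hits = []
    for q in queries:
        for s in database:
            hit = align_pair(
                q.sequence,
                s.sequence,
                params,
                query_id=q.protein_id,
                subject_id=s.protein_id,
                db_residues=n_db,
            )
            if max_evalue is None or hit.evalue <= max_evalue:
                hits.append(hit)
    return hits


def _hit_rank_key(hit: PairwiseHit) -> tuple:
    # higher bit score, then longer alignment, then smallest subject id
    return (-hit.bit_score, -hit.length, hit.subject_id)


def best_hits(hits: Sequence[PairwiseHit]) -> dict[str, PairwiseHit]:
    """Best-scoring hit per query, with deterministic tie-breaking."""
    best: dict[str, PairwiseHit] = {}
    for hit in sorted(hits, key=lambda h: (h.query_id,) + _hit_rank_key(h)):
        if hit.query_id not in best:
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[PairwiseHit], hits_ba: Sequence[PairwiseHit]
) -> list[tuple[str, str]]:
    """Pairs (a, b) where each protein is the other's best hit."""
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = []
    for a_id, hit in sorted(best_ab.items()):
        b_id = hit.subject_id
        back = best_ba.get(b_id)
        if back is not None and back.subject_id == a_id:
            pairs.append((a_id, b_id))
    return pairs


@dataclass(frozen=True)
class AAIResult:
    """Genome-pair AAI over RBH orthologs; ``aai`` is None when undefined."""

    genome_a: str
    genome_b: str
    aai: Optional[float]
    n_rbh_pairs: int
    min_identity: float
    min_coverage: float

    @property
    def defined(self) -> bool:
        return self.aai is not None


def compute_aai(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
) -> AAIResult:
    """AAI between two proteomes from reciprocal-best-hit ortholog pairs.

    Symmetric by construction: genomes are ordered canonically by id and each
    unordered protein pair is aligned once, so AAI(a, b) == AAI(b, a). Zero
    qualifying RBH pairs yield an explicitly undefined result (``aai=None``).
    """
    if not proteome_a or not proteome_b:
        raise InputError("both proteomes must be non-empty")
    ga = proteome_a[0].genome_id
    gb = proteome_b[0].genome_id
    if gb < ga:
        proteome_a, proteome_b = proteome_b, proteome_a
        ga, gb = gb, ga
    n_a = sum(len(p) for p in proteome_a)
    n_b = sum(len(p) for p in proteome_b)
    hits_ab: list[PairwiseHit] = []
    hits_ba: list[PairwiseHit] = []
    for p in proteome_a:
        for q in proteome_b:
            hit = align_pair(
                p.sequence, q.sequence, params,
                query_id=p.protein_id, subject_id=q.protein_id, db_residues=n_b,
            )
            hits_ab.append(hit)
            hits_ba.append(
                replace(
                    hit,
                    query_id=q.protein_id,
                    subject_id=p.protein_id,
                    qstart=hit.sstart, qend=hit.send,
                    sstart=hit.qstart, send=hit.qend,
                    evalue=evalue(hit.bit_score, len(q), n_a),
                )
            )
    pairs = reciprocal_best_hits(hits_ab, hits_ba)
    by_key = {(h.query_id, h.subject_id): h for h in hits_ab}
    idents = [
        by_key[(a, b)].pident
        for a, b in pairs
        if by_key[(a, b)].pident >= min_identity and by_key[(a, b)].qcov >= min_coverage
    ]
    return AAIResult(
        genome_a=ga,
        genome_b=gb,
        aai=float(np.mean(idents)) if idents else None,
        n_rbh_pairs=len(idents),
        min_identity=min_identity,
        min_coverage=min_coverage,
    )


def aai_matrix(
    proteomes: dict[str, Sequence[ProteinRecord]],
    params: AlignmentParams = DEFAULT_PARAMS,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
) -> pd.DataFrame:
    """Symmetric genomes x genomes AAI matrix (diagonal 100, undefined = NaN)."""
    genomes = sorted(proteomes)
    mat = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    for g in genomes:
        mat.loc[g, g] = 100.0
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            res = compute_aai(
                list(proteomes[ga]), list(proteomes[gb]), params,
                min_identity=min_identity, min_coverage=min_coverage,
            )
            val = res.aai if res.defined else np.nan
            mat.loc[ga, gb] = val
            mat.loc[gb, ga] = val
    return mat


_TAB_COLS = [
    "query_id", "subject_id", "pident", "length", "mismatches", "gap_opens",
    "qstart", "qend", "sstart", "send", "evalue", "bit_score",
]


def hits_frame(hits: Sequence[PairwiseHit]) -> pd.DataFrame:
    """12-column tabular layout mirroring blastp -outfmt 6 ordering."""
    return pd.DataFrame([
        {c: getattr(h, c) for c in _TAB_COLS} for h in hits
    ], columns=_TAB_COLS)


def write_hits(hits: Sequence[PairwiseHit], path: str | Path) -> None:
    hits_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[PairwiseHit]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            PairwiseHit(
                query_id=str(d["query_id"]), subject_id=str(d["subject_id"]),
                raw_score=int(d.get("raw_score", 0)), bit_score=float(d["bit_score"]),
                pident=float(d["pident"]), length=int(d["length"]),
                mismatches=int(d["mismatches"]), gap_opens=int(d["gap_opens"]),
                qstart=int(d["qstart"]), qend=int(d["qend"]),
                sstart=int(d["sstart"]), send=int(d["send"]),
                evalue=float(d["evalue"]), qcov=float(d.get("qcov", 100.0)),
            )
        )
    return out
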