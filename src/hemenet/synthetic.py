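"""Seeded synthetic genome sets with planted ground truth.

The generator emulates the comparative setting the package analyses: a set of
archaeal-sized proteomes (defaults: 16 genomes of 1,700-4,700 proteins) in
which a small minority of proteins are multiheme c-type cytochromes with
controlled CXXCH counts (per-genome MHC counts drawn from 3-49, one showcase
protein with 113 hemes), orthologous MHC families shared across genomes at a
controlled amino-acid identity, collocated gene clusters matching the five
menaquinone:cytochrome-c oxidoreductase signatures, decoy proteins with <3
motifs, and per-gene functional labels for marker and neighborhood analysis.

Truth is exact, not probabilistic: background sequence is drawn from the 20
canonical amino acids with cysteine and histidine excluded outside planted
sites, so a CXXCH site exists exactly where one was planted, and every
emitted protein is re-scanned against its planted count before release.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InputError, IntegrityError, SizingError
from .hemescan import find_heme_motifs
from .io import GeneFeature, ensure_dir, write_fasta, write_gff
from .records import ProteinRecord

#: canonical amino acids minus C and H; background sequence is drawn from
#: these so heme motifs can only exist where planted.
BACKGROUND_ALPHABET = np.array(list("ADEFGIKLMNPQRSTVWY"))

#: functional labels used by the five built-in oxidoreductase signatures.
CLUSTER_COMPONENTS: dict[str, tuple[tuple[Optional[str], int], ...]] = {
    # (label, planted heme count); label None = an unlabeled MHC gene
    "group1": (("bc_complex", 0), ("hypothetical", 0), ("hypothetical", 0), (None, 6), (None, 6)),
    "group2": (("cytb", 0), (None, 6)),
    "group3": (("cytb", 0), (None, 6), (None, 6)),
    "group4": (("nrfd_like", 0), ("ferredoxin_4fe4s", 0), (None, 6)),
    "group5": (("nrfd_like", 0), ("ferredoxin_4fe4s", 0), (None, 8), (None, 8)),
}

#: terminal-electron-acceptor / electron-donor marker labels planted on decoy
#: proteins so the marker presence/absence matrix has a known answer.
MARKER_LABELS = (
    "NarG", "NrfA", "NxrA", "SrdA", "SreA", "SreB", "SreC",
    "ArxA", "ArrA", "FdhA", "FdhB", "NiFe_group1", "NiFe_group3b",
)

#: literal instances of the default NiFe L1/L2 motifs, planted into proteins
#: labeled as NiFe catalytic subunits (neither contains a CXXCH site).
_NIFE_L1_LITERAL = "RACGACAAAH"
_NIFE_L2_LITERAL = "DPCAACAAH"


def _background(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(BACKGROUND_ALPHABET, size=length)


def _scan_count(seq: str) -> int:
    return len(find_heme_motifs(seq))


# ---------------------------------------------------------------------------
# planting primitives
# ---------------------------------------------------------------------------

def plant_motifs(sequence: str, k: int, seed: int) -> str:
    """Plant exactly ``k`` CXXCH sites into ``sequence`` by substitution.

    The input must not already contain a CXXCH site. Length is never changed.
    The result is verified with the scanner; if stray C/H residues in the
    input keep combining with planted residues into extra sites after
    repeated redraws, :class:`InputError` is raised.
    """
    return _plant_motifs(sequence, k, np.random.default_rng(seed))


def _plant_motifs(sequence: str, k: int, rng: np.random.Generator) -> str:
    if k < 0:
        raise SizingError(f"k must be >= 0, got {k}")
    if _scan_count(sequence) > 0:
        raise InputError("input sequence already contains CXXCH sites")
    if k == 0:
        return sequence
    n = len(sequence)
    if n < 5 * k:
        raise SizingError(f"sequence of length {n} cannot hold {k} CXXCH sites")
    base = n // k
    arr0 = np.array(list(sequence))
    for _ in range(50):
        arr = arr0.copy()
        offsets = rng.integers(0, base - 4, size=k)
        starts = np.arange(k) * base + offsets
        for p in starts:
            arr[p] = "C"
            arr[p + 1] = rng.choice(BACKGROUND_ALPHABET)
            arr[p + 2] = rng.choice(BACKGROUND_ALPHABET)
            arr[p + 3] = "C"
            arr[p + 4] = "H"
        out = "".join(arr)
        if _scan_count(out) == k:
            return out
    raise InputError(
        "input residues keep combining with planted sites into extra motifs"
    )


def mutate_to_identity(sequence: str, target: float, seed: int) -> str:
    """Substitute residues so the output is ``target`` percent identical to the input.

    Positions inside CXXCH sites are never touched, so heme counts are
    preserved; substitutions draw from the C/H-free alphabet, so no new site
    can appear. The realized identity is exact up to rounding of the
    substitution count; if that rounding cannot reach within 2 percentage
    points of the target (pathologically short sequences), or if the motif
    density leaves too few mutable positions, :class:`SizingError` is raised.
    """
    return _mutate_to_identity(sequence, target, np.random.default_rng(seed))


def _mutate_to_identity(
    sequence: str, target: float, rng: np.random.Generator
) -> str:
    from .errors import ParameterError

    if not (0 < target <= 100):
        raise ParameterError(f"target identity must be in (0, 100], got {target}")
    n = len(sequence)
    if n == 0:
        raise InputError("empty sequence")
    m = int(round(n * (1.0 - target / 100.0)))
    if m == 0:
        return sequence
    protected = set()
    for p in find_heme_motifs(sequence):
        protected.update(range(p, p + 5))
    candidates = np.array([i for i in range(n) if i not in protected])
    if m > len(candidates):
        raise SizingError(
            f"cannot mutate {m} positions: only {len(candidates)} outside motif sites"
        )
    realized = 100.0 * (n - m) / n
    if abs(realized - target) > 2.0:
        raise SizingError(
            f"length {n} cannot realize identity within 2 points of {target}"
        )
    idx = rng.choice(candidates, size=m, replace=False)
    arr = np.array(list(sequence))
    for i in idx:
        choices = BACKGROUND_ALPHABET[BACKGROUND_ALPHABET != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic genome set.

    ``mhc_fraction`` is a feasibility cap (planted MHCs may not exceed this
    fraction of a proteome), not the realized fraction; realized per-genome
    MHC counts are drawn from ``mhc_per_genome_range``.
    """

    n_genomes: int = 16
    proteins_per_genome: tuple[int, int] = (1700, 4700)
    mhc_fraction: float = 0.05
    mhc_per_genome_range: tuple[int, int] = (3, 49)
    heme_count_range: tuple[int, int] = (3, 24)
    giant_heme_count: Optional[int] = 113
    giant_genome: Optional[str] = None
    n_families: int = 20
    family_identity: float = 75.0
    family_presence: Optional[list[list[bool]]] = None
    planted_clusters: Optional[list[tuple[str, str]]] = None
    cluster_probability: float = 0.6
    marker_probability: float = 0.5
    decoy_motif_max: int = 2
    n_scaffolds: int = 2
    protein_length_range: tuple[int, int] = (120, 400)
    seed: int = 0

    def genome_ids(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_genomes)]

    def validate(self) -> None:
        if self.n_genomes < 0:
            raise ConfigurationError("n_genomes must be >= 0")
        if self.heme_count_range[0] < 3:
            raise ConfigurationError("heme_count_range minimum must be >= 3")
        if self.heme_count_range[0] > self.heme_count_range[1]:
            raise ConfigurationError("heme_count_range must be (lo, hi) with lo <= hi")
        if not (0 <= self.decoy_motif_max <= 2):
            raise ConfigurationError("decoy_motif_max must be in {0, 1, 2}")
        if not (0 < self.family_identity <= 100):
            raise ConfigurationError("family_identity must be in (0, 100]")
        if not (0 <= self.mhc_fraction <= 1):
            raise ConfigurationError("mhc_fraction must be in [0, 1]")
        if self.family_presence is not None:
            if len(self.family_presence) != self.n_families:
                raise ConfigurationError("family_presence needs one vector per family")
            for vec in self.family_presence:
                if len(vec) != self.n_genomes:
                    raise ConfigurationError(
                        "family_presence vectors must have length n_genomes"
                    )
        if self.planted_clusters is not None:
            genomes = set(self.genome_ids())
            for pattern, genome in self.planted_clusters:
                if pattern not in CLUSTER_COMPONENTS:
                    raise ConfigurationError(f"unknown cluster pattern {pattern!r}")
                if genome not in genomes:
                    raise ConfigurationError(f"unknown genome id {genome!r}")
        if self.giant_genome is not None and self.giant_genome not in self.genome_ids():
            raise ConfigurationError(f"unknown giant_genome {self.giant_genome!r}")
        if self.n_genomes > len(BACKGROUND_ALPHABET):
            raise ConfigurationError(
                "family planting supports at most 18 genomes (distinct-letter scheme)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class PlantedCluster:
    genome_id: str
    scaffold_id: str
    pattern: str
    gene_ids: tuple[str, ...]
    roles: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Exact planted ground truth for one generated genome set."""

    heme_counts: dict[str, int]
    family_of: dict[str, str]
    per_genome_mhc: dict[str, int]
    per_genome_max_hemes: dict[str, int]
    clusters: list[PlantedCluster]
    markers: dict[str, tuple[str, ...]]
    seed: int

    def family_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, fam in self.family_of.items():
            out.setdefault(fam, []).append(pid)
        return out


@dataclass
class GenomeSet:
    """In-memory result of :func:`generate_genome_set`."""

    config: SyntheticConfig
    proteins: dict[str, list[ProteinRecord]]
    genes: dict[str, list[GeneFeature]]
    labels: dict[str, str]
    truth: SyntheticTruth

    def all_proteins(self) -> list[ProteinRecord]:
        return [p for g in sorted(self.proteins) for p in self.proteins[g]]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _Entry:
    sequence: str
    hemes: int
    family: Optional[str] = None
    label: Optional[str] = None
    role: Optional[str] = None


def _family_sequences(
    cfg: SyntheticConfig,
    presence: list[list[bool]],
    rng: np.random.Generator,
) -> tuple[list[dict[int, str]], list[int]]:
    """Build per-family member sequences with exact pairwise identity.

    Every family has a fixed set of variable positions; at each such position
    each member genome receives a distinct letter (one column of a shuffled
    alphabet), so any two members are identical everywhere except at exactly
    those positions — pairwise identity equals the target up to count
    rounding. Motif sites are excluded from the variable set, so every member
    carries the family's full heme complement.
    """
    t = cfg.family_identity
    members: list[dict[int, str]] = []
    hemes_per_family: list[int] = []
    lo, hi = cfg.protein_length_range
    for f in range(cfg.n_families):
        k = int(rng.integers(cfg.heme_count_range[0], cfg.heme_count_range[1] + 1))
        min_len = int(np.ceil(5 * k * 100.0 / t)) + 20
        length = max(int(rng.integers(lo, hi + 1)), min_len, 5 * k + 20)
        ancestor = _plant_motifs("".join(_background(rng, length)), k, rng)
        m = int(round(length * (1.0 - t / 100.0)))
        protected = set()
        for p in find_heme_motifs(ancestor):
            protected.update(range(p, p + 5))
        candidates = np.array([i for i in range(length) if i not in protected])
        var_positions = rng.choice(candidates, size=m, replace=False)
        present = [i for i in range(cfg.n_genomes) if presence[f][i]]
        seqs: dict[int, str] = {}
        letter_cols = {
            int(pos): rng.permutation(BACKGROUND_ALPHABET) for pos in var_positions
        }
        for slot, genome_idx in enumerate(present):
            arr = np.array(list(ancestor))
            for pos, col in letter_cols.items():
                arr[pos] = col[slot]
            seq = "".join(arr)
            if _scan_count(seq) != k:  # pragma: no cover - guaranteed by construction
                raise IntegrityError("family member lost/gained a motif")
            seqs[genome_idx] = seq
        members.append(seqs)
        hemes_per_family.append(k)
    return members, hemes_per_family


def _nife_decoy(seq: str) -> str:
    """Substitute literal L1/L2 NiFe motifs into a background sequence."""
    if len(seq) < 60:
        seq = seq + seq  # only reachable with extreme length configs
    arr = np.array(list(seq))
    arr[5 : 5 + len(_NIFE_L1_LITERAL)] = list(_NIFE_L1_LITERAL)
    start = len(seq) - 20 - len(_NIFE_L2_LITERAL)
    arr[start : start + len(_NIFE_L2_LITERAL)] = list(_NIFE_L2_LITERAL)
    return "".join(arr)


def generate_genome_set(config: SyntheticConfig) -> GenomeSet:
    """Generate a seeded genome set; deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_ids = config.genome_ids()
    if config.n_genomes == 0:
        truth = SyntheticTruth({}, {}, {}, {}, [], {}, config.seed)
        return GenomeSet(config, {}, {}, {}, truth)

    # -- draw the global plan -------------------------------------------------
    if config.family_presence is not None:
        presence = [[bool(v) for v in vec] for vec in config.family_presence]
    else:
        presence = []
        for _ in range(config.n_families):
            vec = list(rng.random(config.n_genomes) < 0.6)
            if sum(vec) < min(2, config.n_genomes):
                force = rng.choice(config.n_genomes, size=min(2, config.n_genomes), replace=False)
                for i in force:
                    vec[int(i)] = True
            presence.append(vec)

    if config.planted_clusters is not None:
        planted_clusters = list(config.planted_clusters)
    else:
        planted_clusters = []
        for g in genome_ids:
            for pattern in sorted(CLUSTER_COMPONENTS):
                if rng.random() < config.cluster_probability:
                    planted_clusters.append((pattern, g))

    giant_genome = config.giant_genome
    if config.giant_heme_count is not None and giant_genome is None:
        giant_genome = genome_ids[-1]

    fam_seqs, fam_hemes = _family_sequences(config, presence, rng)

    markers_plan: dict[str, list[str]] = {}
    for g in genome_ids:
        markers_plan[g] = [
            lab for lab in MARKER_LABELS if rng.random() < config.marker_probability
        ]

    # -- per-genome assembly ---------------------------------------------------
    proteins: dict[str, list[ProteinRecord]] = {}
    genes: dict[str, list[GeneFeature]] = {}
    labels: dict[str, str] = {}
    heme_truth: dict[str, int] = {}
    family_truth: dict[str, str] = {}
    per_genome_mhc: dict[str, int] = {}
    per_genome_max: dict[str, int] = {}
    cluster_truth: list[PlantedCluster] = []
    lo_len, hi_len = config.protein_length_range

    for gi, g in enumerate(genome_ids):
        n_p = int(rng.integers(config.proteins_per_genome[0], config.proteins_per_genome[1] + 1))
        fam_here = [f for f in range(config.n_families) if presence[f][gi]]
        drawn = int(rng.integers(config.mhc_per_genome_range[0], config.mhc_per_genome_range[1] + 1))
        planned = max(drawn, len(fam_here))
        n_singles = planned - len(fam_here)
        my_clusters = [p for (p, gg) in planted_clusters if gg == g]
        cluster_mhc = sum(
            1 for p in my_clusters for (lab, h) in CLUSTER_COMPONENTS[p] if h >= 3
        )
        cluster_other = sum(
            1 for p in my_clusters for (lab, h) in CLUSTER_COMPONENTS[p] if h < 3
        )
        giant_here = 1 if (giant_genome == g and config.giant_heme_count) else 0
        total_mhc = planned + cluster_mhc + giant_here
        n_markers = len(markers_plan[g])
        n_buffer = 6 * len(my_clusters)
        n_fixed = planned + cluster_mhc + cluster_other + giant_here + n_markers + n_buffer
        if total_mhc > config.mhc_fraction * n_p:
            raise SizingError(
                f"{g}: {total_mhc} planted MHCs exceed mhc_fraction cap "
                f"({config.mhc_fraction} x {n_p} proteins)"
            )
        if n_fixed + 10 > n_p:
            raise SizingError(
                f"{g}: {n_fixed} planted proteins do not fit in a {n_p}-protein proteome"
            )

        entries: list[_Entry] = []
        for f in fam_here:
            entries.append(
                _Entry(sequence=fam_seqs[f][gi], hemes=fam_hemes[f], family=f"F{f + 1:04d}")
            )
        for _ in range(n_singles):
            k = int(rng.integers(config.heme_count_range[0], config.heme_count_range[1] + 1))
            length = max(int(rng.integers(lo_len, hi_len + 1)), 5 * k + 15)
            seq = _plant_motifs("".join(_background(rng, length)), k, rng)
            entries.append(_Entry(sequence=seq, hemes=k))
        if giant_here:
            k = int(config.giant_heme_count)
            seq = _plant_motifs("".join(_background(rng, 6 * k + 50)), k, rng)
            entries.append(_Entry(sequence=seq, hemes=k))
        for lab in markers_plan[g]:
            length = int(rng.integers(max(lo_len, 80), hi_len + 1))
            seq = "".join(_background(rng, length))
            if lab.startswith("NiFe"):
                seq = _nife_decoy(seq)
            entries.append(_Entry(sequence=seq, hemes=0, label=lab))

        # plain decoys fill the proteome
        n_decoys = n_p - len(entries) - (cluster_mhc + cluster_other) - n_buffer
        weights = np.array([0.85, 0.10, 0.05][: config.decoy_motif_max + 1])
        weights = weights / weights.sum()
        decoy_ks = rng.choice(
            np.arange(config.decoy_motif_max + 1), size=n_decoys, p=weights
        )
        lengths = rng.integers(lo_len, hi_len + 1, size=n_decoys)
        for k, length in zip(decoy_ks, lengths):
            length = max(int(length), 5 * int(k) + 10)
            seq = "".join(_background(rng, length))
            if k > 0:
                seq = _plant_motifs(seq, int(k), rng)
            entries.append(_Entry(sequence=seq, hemes=int(k)))

        # shuffle non-cluster genes, then insert each cluster block (with
        # zero-motif unlabeled buffer genes on both sides) as one unit
        order = rng.permutation(len(entries))
        elements: list[list[_Entry]] = [[entries[i]] for i in order]
        block_spans: list[tuple[int, str, list[_Entry]]] = []
        for pattern in my_clusters:
            buf = [
                _Entry(sequence="".join(_background(rng, int(rng.integers(lo_len, hi_len + 1)))), hemes=0)
                for _ in range(6)
            ]
            payload: list[_Entry] = []
            for lab, h in CLUSTER_COMPONENTS[pattern]:
                length = max(int(rng.integers(lo_len, hi_len + 1)), 5 * h + 15)
                seq = "".join(_background(rng, length))
                if h >= 3:
                    seq = _plant_motifs(seq, h, rng)
                payload.append(
                    _Entry(
                        sequence=seq,
                        hemes=h,
                        label=lab,
                        role=lab if lab is not None else f"mhc{h}",
                    )
                )
            block = buf[:3] + payload + buf[3:]
            pos = int(rng.integers(0, len(elements) + 1))
            elements.insert(pos, block)
            block_spans.append((id(block), pattern, payload))

        # scaffold split on element boundaries keeps blocks intact
        n_sc = max(1, min(config.n_scaffolds, len(elements)))
        boundaries = [len(elements) * j // n_sc for j in range(n_sc + 1)]
        scaffold_of_element: list[int] = []
        for j in range(n_sc):
            scaffold_of_element.extend([j] * (boundaries[j + 1] - boundaries[j]))

        # assign ids and coordinates
        genome_proteins: list[ProteinRecord] = []
        genome_genes: list[GeneFeature] = []
        gene_index = 0
        pos_by_scaffold = {j: 1 for j in range(n_sc)}
        strand_by_scaffold = {j: "+" for j in range(n_sc)}
        element_pids: list[list[str]] = []
        for ei, block in enumerate(elements):
            sc = scaffold_of_element[ei]
            scaffold_id = f"s{sc + 1:02d}"
            pids: list[str] = []
            for entry in block:
                gene_index += 1
                pid = f"{g}|{scaffold_id}|{gene_index:05d}"
                aa_len = len(entry.sequence)
                start = pos_by_scaffold[sc]
                end = start + 3 * aa_len + 2
                strand = strand_by_scaffold[sc]
                strand_by_scaffold[sc] = "-" if strand == "+" else "+"
                pos_by_scaffold[sc] = end + 51
                genome_proteins.append(
                    ProteinRecord(
                        protein_id=pid,
                        genome_id=g,
                        scaffold_id=scaffold_id,
                        sequence=entry.sequence,
                        start=start,
                        end=end,
                        strand=strand,
                        functional_label=entry.label,
                    )
                )
                genome_genes.append(
                    GeneFeature(pid, scaffold_id, start, end, strand)
                )
                if entry.label is not None:
                    labels[pid] = entry.label
                heme_truth[pid] = entry.hemes
                if entry.family is not None:
                    family_truth[pid] = entry.family
                pids.append(pid)
            element_pids.append(pids)

        # recover planted-cluster gene ids: blocks are matched by identity
        # (three buffer genes flank each side, exceeding the default gap limit)
        span_by_id = {bid: (pattern, payload) for bid, pattern, payload in block_spans}
        for ei, block in enumerate(elements):
            if id(block) not in span_by_id:
                continue
            pattern, payload = span_by_id[id(block)]
            pids = element_pids[ei][3:-3]
            roles = tuple(e.role for e in payload)
            sc = scaffold_of_element[ei]
            cluster_truth.append(
                PlantedCluster(
                    genome_id=g,
                    scaffold_id=f"s{sc + 1:02d}",
                    pattern=pattern,
                    gene_ids=tuple(pids),
                    roles=roles,
                )
            )

        # verification pass: emitted sequences must scan to the planted counts
        for rec in genome_proteins:
            if _scan_count(rec.sequence) != heme_truth[rec.protein_id]:
                raise IntegrityError(
                    f"verification failed for {rec.protein_id}: realized motif "
                    f"count differs from planted truth"
                )
        proteins[g] = genome_proteins
        genes[g] = genome_genes
        per_genome_mhc[g] = sum(
            1 for rec in genome_proteins if heme_truth[rec.protein_id] >= 3
        )
        per_genome_max[g] = max(
            (heme_truth[rec.protein_id] for rec in genome_proteins), default=0
        )

    truth = SyntheticTruth(
        heme_counts=heme_truth,
        family_of=family_truth,
        per_genome_mhc=per_genome_mhc,
        per_genome_max_hemes=per_genome_max,
        clusters=cluster_truth,
        markers={g: tuple(markers_plan[g]) for g in genome_ids},
        seed=config.seed,
    )
    return GenomeSet(config=config, proteins=proteins, genes=genes, labels=labels, truth=truth)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_genome_set(gs: GenomeSet, out_dir: str | Path) -> Path:
    """Write FASTA + GFF3 per genome, truth/label TSVs and a manifest JSON."""
    out = ensure_dir(out_dir)
    for g in sorted(gs.proteins):
        write_fasta(gs.proteins[g], out / f"{g}.faa")
        write_gff(gs.genes[g], out / f"{g}.gff")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("protein_id\tgenome_id\theme_count\tfamily_id\n")
        for g in sorted(gs.proteins):
            for rec in gs.proteins[g]:
                pid = rec.protein_id
                fam = gs.truth.family_of.get(pid, "")
                fh.write(f"{pid}\t{g}\t{gs.truth.heme_counts[pid]}\t{fam}\n")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("protein_id\tlabel\n")
        for pid in sorted(gs.labels):
            fh.write(f"{pid}\t{gs.labels[pid]}\n")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("genome_id\tscaffold_id\tpattern\tgene_ids\troles\n")
        for c in gs.truth.clusters:
            fh.write(
                f"{c.genome_id}\t{c.scaffold_id}\t{c.pattern}\t"
                f"{';'.join(c.gene_ids)}\t{';'.join(c.roles)}\n"
            )
    manifest = {
        "config": gs.config.to_dict(),
        "seed": gs.config.seed,
        "per_genome_mhc": gs.truth.per_genome_mhc,
        "per_genome_max_hemes": gs.truth.per_genome_max_hemes,
        "markers": {g: list(v) for g, v in sorted(gs.truth.markers.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
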