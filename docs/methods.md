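# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## MHC calling

A heme *c* attachment site is the literal three-position condition
`seq[i] == 'C' and seq[i+3] == 'C' and seq[i+4] == 'H'`. The scanner
enumerates **all** occurrences, including overlapping ones (two sites may
share the cysteine at offset i+3, so consecutive motif starts can be as
close as 3 residues). Overlap counting is the default because the biology
does not forbid shared cysteines; a `disjoint` mode counts greedily
left-to-right for users who prefer non-overlapping sites. A protein is a
putative MHC when it carries at least `min_motifs` sites (default 3 — below
three hemes a protein is more likely a mono/diheme cytochrome with a
different role).

Conventions: one terminal `*` is stripped (gene-caller artifact); internal
stops are rejected; sequences are uppercased before scanning; the ambiguity
character `X` is treated as "not C, not H" — it can occupy the two wildcard
positions but never satisfies the anchor residues. This is deliberately
conservative: an ambiguous residue never creates a motif.

Domain verification (cytochrome-*c* and S-layer domains) is a pluggable
filter over an externally produced `(protein_id, domain, evalue)` table;
core calling never requires it and reports `untested` by default.

The NiFe-hydrogenase L1/L2 checks accept a restricted motif language
(literals, `x`/`.` wildcards, `[..]` classes, `{m,n}` repeats). The shipped
defaults (`RxCGxCxxxH`, `DPCxxCxxH`) are heuristics chosen by this package
— curated, organism-specific patterns should be passed in when available; a
log line flags when the defaults are in use.

## Alignment model and statistics

Pairwise search is an optimal Smith–Waterman local alignment under BLOSUM62
with affine gaps: the first residue of a gap costs 11, each further residue
1 (the common blastp parameterisation). The implementation delegates the
dynamic program to `biotite.sequence.align.align_optimal`; the test suite
checks it against an independently written Gotoh dynamic program over
Biopython's BLOSUM62 table. Exact blastp score parity is **not** a goal —
all downstream thresholds are applied to this aligner's own outputs, and an
adapter can substitute an external search tool where parity matters.

Numerical conventions:

- **Percent identity** = identical aligned columns / total alignment
  columns, gap columns included in the denominator (mirrors common blastp
  tabular reporting); configurable in principle by post-processing the hit,
  which carries all column counts.
- **Bit score** S′ = (λ·S − ln K)/ln 2 with gapped-BLOSUM62 defaults
  λ = 0.267, K = 0.041; **E-value** E = m·n·2^(−S′) with m the query length
  and n the database residue count. The closed form keeps the statistics
  testable and keeps λ/K confined to the raw→bit conversion.
- **Tie-breaking** for best hits: higher bit score, then longer alignment,
  then lexicographically smallest subject id — determinism over elegance.
- Among co-optimal alignments the aligner picks one arbitrarily, which
  could make identity asymmetric between `align(a,b)` and `align(b,a)`;
  `align_pair` therefore always aligns the lexicographically smaller
  sequence first and swaps the trace back, making score *and* identity
  symmetric by construction.

**AAI** between two genomes is the mean percent identity over
reciprocal-best-hit pairs passing identity ≥ 30% and coverage ≥ 70% of the
shorter sequence (standard AAI-style filters; both configurable and
recorded in the result). Genomes are ordered canonically and each unordered
protein pair aligned once, so AAI is exactly symmetric. Zero qualifying
pairs yield an explicitly undefined result rather than a number.

## Orthologous families

Families are clustered on the *reciprocal* homology graph: an edge requires
hits in both directions, each passing E ≤ 1e−3, identity ≥ 50% **and
alignment coverage ≥ 50% of the shorter sequence**. The coverage condition
exists because heme-dense proteins share the periodic `C..CH` spine: two
otherwise unrelated MHCs can produce a short (~25–30 column) local
alignment that touches 50% identity with a strong E-value purely from
motif-register matching. Requiring half the shorter protein to align keeps
such fragments from linking unrelated proteins, while genuine orthologs —
which align near full length — are unaffected. This mirrors what
production orthology tools do (length-normalised scores, coverage filters).

Default clustering is connected components of that graph — deterministic,
dependency-free, and adequate when families are well separated. An
`mcl-like` mode runs a Markov-cluster flow simulation (expansion by matrix
squaring, inflation 2.0, column renormalisation, pruning below 1e−9,
convergence at max-change < 1e−8 or 100 iterations, self-loops added for
stability) per component for finer granularity. Neither mode is a faithful
reimplementation of any external orthology tool; family counts on real
data are tool-dependent and should be treated as approximate benchmarks.
Family ids are assigned by descending size, then lexicographically smallest
member, so outputs are stable across runs.

The abundance matrix (genomes × families) keeps all-zero rows for genomes
without MHCs; column sums equal family sizes and row sums equal per-genome
MHC counts by construction. The optional heatmap row/column ordering
(average linkage on Euclidean distances) is cosmetic display ordering only
and never feeds back into any computation.

## Gene-neighborhood signatures

A cluster pattern is an unordered multiset of components — functional
labels and/or MHC heme-count constraints (exact or at-least) — plus a gap
limit: consecutive matched genes may be separated by at most `max_gap`
intervening genes (default 2; the adjacency distance delimiting a "gene
cluster" is a judgment call, and 2 tolerates small annotation gaps without
spanning unrelated loci). Matching is strand- and order-agnostic within the
window, since conserved clusters are described by composition and
adjacency, not orientation. Candidate genes are grouped into maximal runs
under the gap limit; a run that can cover the full multiset (decided by
maximum bipartite matching of genes to component slots) is reported once as
the maximal match, so each gene joins at most one match per pattern.

The five built-in menaquinone:cytochrome-*c* oxidoreductase signatures are:

| name   | components |
|--------|------------|
| group1 | bc1/b6f-like complex, 2× hypothetical protein, 2× 6-heme MHC |
| group2 | *b*-type cytochrome, 1× 6-heme MHC |
| group3 | *b*-type cytochrome, 2× 6-heme MHC |
| group4 | NrfD-like transmembrane protein, 4Fe-4S ferredoxin, 1× 6-heme MHC |
| group5 | NrfD-like transmembrane protein, 4Fe-4S ferredoxin, 2× MHC (≥ 3 hemes) |

The source material distinguishes groups 2 from 3 and 4 from 5 by the
phylogeny of their membrane subunits, not by composition; compositionally
this package separates them by MHC copy number and heme-count constraint,
which makes group2 a sub-multiset of group3. Cross-pattern double-reporting
is resolved by **most-specific-pattern-wins** exclusive matching: patterns
are evaluated from most to fewest required genes and genes claimed by a
match are unavailable to later, less specific patterns. Users encoding
clade-resolved labels can instead ship their own pattern file with distinct
labels per group.

Marker presence/absence is pure label lookup: a marker (NarG, NrfA, NxrA,
SrdA, SreABC, Arx/Arr, FdhAB, NiFe groups 1/3b) is present in a genome when
any gene carries one of its accepted labels. Label assignment itself is an
input contract — functional annotation is upstream of this package.

## Homology networks

Query MHCs are aligned against a user-supplied reference MHC panel with
taxonomy labels. The "≥ 50% AAI" cutoff in this context is interpreted as
**per-hit percent identity** (the search is protein-against-database, not
genome-against-genome); edges require E ≤ 1e−20 and identity ≥ 50%.
Query–query edges are included (so clusters of related query proteins form,
and purely internal clusters exist to be pruned); edge weight is the
identity of the best hit per pair. Pruning deletes components that are all
query or all reference — what survives links the query repertoire to other
lineages — and is idempotent. A `--by-family` style collapse is available
by passing one representative per family as the query set. GraphML export
round-trips nodes, edges and attributes; SIF and edge-list TSV serve
Cytoscape workflows.

## Synthetic genome sets

The generator's defaults emulate the comparative study design the package
targets: 16 genomes of 1,700–4,700 proteins; per-genome MHC counts drawn
uniformly from 3–49 (the source reports only min/mean/max, so the uniform
draw is a stand-in, not a claim about the real distribution); planted heme
counts 3–24 per family/singleton MHC plus one showcase 113-heme protein
(the largest repertoire protein on record); 20 orthologous families planted
at 75% within-family identity (inside the 61–89% AAI span typical of a
genus-to-family comparison); each of the five cluster signatures planted in
~60% of genomes; marker labels planted with probability 0.5 per genome;
decoys with at most 2 motifs.

Truth exactness is engineered, not sampled:

- Background residues are drawn from the 18 canonical amino acids minus C
  and H, so CXXCH sites exist exactly where planted; planting substitutes
  residues in place (never inserts) and fills motif interiors from the
  C/H-free alphabet.
- Identity-controlled mutation only ever substitutes C/H-free letters
  outside motif spans, so it can neither create nor destroy a site.
- Family members share one fixed set of variable positions; at each such
  position every member genome receives a distinct letter (a column of a
  shuffled alphabet), making *pairwise* identity between any two members
  equal the target up to count rounding (this is why family planting is
  limited to 18 genomes).
- Planted cluster genes are laid out consecutively and flanked by three
  motif-free unlabeled buffer genes per side — more than the default gap
  limit — so neighboring decoy MHCs cannot extend a planted window.
- Every emitted protein is re-scanned and compared with its planted count;
  any deviation aborts generation.

GFF3 layout is fixed: genes left-to-right, 1-based inclusive coordinates,
non-overlapping, alternating strand, 50-bp intergenic gaps — deterministic
layout makes neighborhood tests exact. Output is byte-identical for a fixed
seed; the truth TSV and a manifest JSON carrying the full configuration and
seed are written beside the FASTA/GFF3 files.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: realistic amino-acid composition (no C/H
background, uniform usage otherwise), insertions/deletions between
orthologs (identity is substitution-only, so real alignments with indels
may behave differently), paralogs and gene duplication within families,
annotation errors in labels, fragmented assemblies, and any nucleotide- or
read-level artifacts. Family recovery being exact on synthetic sets shows
the clustering machinery is correct under separated-identity conditions
(within ≥ 70%, between background-level), not that real orthogroup counts
will match any particular external tool.

## Problem sizes and determinism in the acceptance script

`scripts/acceptance.py` runs: the scanner-vs-brute-force comparison on
10,000 random sequences; one full-scale default genome set (16 genomes,
~52,000 proteins) for repertoire totals and truth agreement; five
desk-scale sets (4 genomes × 100–130 proteins, 5 families) for family
recovery and cluster detection — sizes chosen so the quadratic all-vs-all
alignment stays a desk-scale computation while every planted structure is
still exercised; a two-genome set for AAI properties; and a planted
query/reference panel for the network contract. Every random draw derives
from the single `--seed` argument through fixed affine sub-seeds, so the
output JSON is reproducible byte for byte.

## Known limitations

- The aligner is exact but quadratic; there is no seeding/indexing, so
  all-vs-all search beyond a few hundred proteins per side is slow by
  design. Delegating search to an external tool is the intended escape
  hatch at scale.
- Only strict CXXCH is scanned; extended heme-attachment variants
  (CX₃CH, CX₄CH, CXXCK) are out of scope.
- E-values use a fixed λ/K pair rather than per-composition estimation, so
  they are comparable within a run, not calibrated against blastp output.
- Orthologous-family counts are clustering-method-dependent; the
  `components` default errs toward merging relative to inflation-based
  methods.
- Marker and neighborhood analyses trust the supplied functional labels;
  no homology-based label inference is performed.
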