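# Methods

This note records the models, parameter choices and numerical conventions
behind `cytofam`, and what its synthetic corpus does and does not emulate.

## Quality gate and isoform reduction

A species enters the analysis iff its BUSCO five-number summary satisfies
C > 2.4, S ≥ 0.60, D ≥ 0.10, F ≥ 0.50, M ≤ 97.00 (percent of BUSCO
orthologs).  These are deliberately permissive *minimums* — they exclude
only genomes with essentially no recoverable single-copy orthologs — and
the inequality senses (strict for C, non-strict otherwise) are implemented
exactly as stated; every failed clause is reported, never just the first.

"Longest isoform" means maximal **total coding length** (sum of CDS segment
lengths), not transcript span; ties break to the lexicographically smallest
transcript id so the choice is order-invariant.  Translation uses the
standard genetic code only, applies the GFF3 phase of the first CDS segment,
drops a trailing stop, and excludes (with a tally) any protein with an
internal stop; a coding length not divisible by three translates the floor
and flags the transcript as partial.

## Pairwise alignment and E-values

Local alignment is Smith–Waterman with affine gaps under BLOSUM62, gap open
11 / extend 1 (a gap of length k costs 11 + k), delegated to biotite's
`align_optimal`; biotite charges its `open` penalty on the first gap symbol,
so the penalty tuple is (−12, −1).  Percent identity follows the BLAST
`pident` convention — identical columns over the full alignment length,
gap columns in the denominator — so internally computed and ingested
identities are directly comparable.

Bit scores use fixed gapped-BLOSUM62 Karlin–Altschul constants λ = 0.267,
K = 0.041; the E-value search space is the product of the two sequence
lengths (no database-size correction), the simplest defensible choice at
desk scale.  When precomputed BLAST tabular files are ingested instead, the
external tool's own E-values are preserved unchanged.  When no alignment
cell scores positive, the alignment is empty with raw score 0 and identity
0 — such pairs can never be accepted downstream.

## Dual-evidence acceptance

Domain evidence for a query is the presence (version-insensitive, order- and
copy-number-free) of **every** required Pfam accession among the protein's
domain hits; domain intervals come from the HMMER **envelope** coordinates.
Similarity evidence is any hit at E ≤ 1e-5.  A protein is accepted iff both
routes fire, except when its best query (maximal bitscore; ties by higher
identity, then query-table order) is one of the three subunits defined
without Pfam domains (p28, IL-23R, WSX-1), which accept on similarity alone
— the family has no seed alignment that detects them.  Searches run
query-vs-proteome (directional), with the ten human subunits as queries.

## Group I–V classification

The published group descriptions are prototypes, so they are operationalized
as an ordered decision list, most specific domain first:

* ligand: IL12p40_C → I; else IL23 → IV; else IL12 → III; else fn3 → II;
  else best query p28/CNTF-like → V; else unassigned.
* receptor: with Lep_receptor_Ig — exactly 2 fn3 → V, ≥1 fn3 → III;
  without it — IL6Ra-bind → IV; a lone fn3 → I; 1–2 fn3 with fn3 as the
  **final** domain → II ("at the C-terminus" has no coordinate rule, so
  terminal position is the criterion); else unassigned.

Before classification, same-label domain hits overlapping >50% of both
intervals merge (best score kept), so repeated model hits over one physical
domain cannot inflate fn3 copy counts.  Every accepted homolog gets exactly
one assignment; `unassigned` is counted, never dropped.  Group V ligand
detection is similarity-only: whether the original analysis used a CNTF
domain model is unknowable from its description, and no Pfam model covers
the p28-like proteins.

## Clustering

Features are the rows of the symmetric pairwise-identity matrix, reduced by
PCA to the components covering ≥90% variance.  k-means runs for each
k ∈ [min 6, max 11] with 10 restarts from a fixed seed; k is selected by
maximal mean silhouette on the PCA features — the criterion of the helper
tool the analysis is modeled on is undocumented, so a standard, testable one
substitutes.  Per-cluster mean/median identity is computed on the original
identity matrix (NaN for singletons).  All-identical inputs are degenerate:
k is forced to the range minimum and flagged.  The 2-D projection fixes
signs by making each component's largest-magnitude loading positive, so
coordinates are stable under row permutation.

## Alignment, trimming, profiles

The multiple aligner is biotite's guide-tree progressive alignment under the
same scoring as the pairwise search (pairs use an optimal global alignment
with free terminal gaps); it replaces the external MSA tools at desk scale,
and externally produced FASTA alignments can be supplied instead — the
conservation logic, not the aligner, is the analysis's substance.

Trimming keeps columns with non-gap fraction ≥ 0.85; if fewer than 30% of
the original columns survive, the ⌈30% · n⌉ highest-occupancy columns are
kept instead (ties leftmost) — a reimplementation of the conserved-percentage
floor whose original internal ordering is unspecified, hence the documented
tie-break.  A kept-column index map preserves original coordinates.

Column profiles report residue frequencies over non-gap standard residues
(`X` ignored), gap fraction, consensus, and information content
log₂20 − H in bits (no small-sample correction by default); a probability
view is just the frequency vector.

## Signature motifs and key residues

A signature is an ordered anchor list with inter-anchor intervals of 1 to
`gap_max` residues; `gap_max` defaults to 20 so a match stays within one
~90-residue fn3 domain.  "K/F" is a one-position alternative; "WS" inside
V-A-S-WS is a two-residue literal anchor.  Matching is leftmost-shortest in
the lazy-regular-expression sense — each anchor placed as early as feasible,
with backtracking — and non-overlapping (scanning resumes after a match).
WSXWS is the contiguous pentapeptide W-S-x-W-S, reported non-overlapping.
Zero-length intervals never match: "FIKPDPP" is not an F-I-KPDPP match.

Key residues are specified in 1-based ungapped reference numbering (human
numbering for the literature set).  Mapping fails loudly when the reference
does not carry the claimed residue at the stated position; the conservation
fraction is the share of alignment rows matching the reference residue at
the mapped column.

## Distribution and synteny

Class-level tables report counts and row percentages (rounded half-even to
2 decimals, blank for zero rows) over the closed Class set {Mammalia, Aves,
Actinopteri, Lepidosauria, Reptilia, Chondrichthyes, Cladistia, Leptocardii,
Other}.  Neighborhoods are windows of `window` = 5 annotated genes per side
on the focal gene's contig, measured in genes (matching the "no other genes
in between" notion of adjacency), truncated at contig ends; genes without a
symbol annotation are excluded with a warning rather than guessed.  The
pair score is |shared flanking symbols| / max(neighborhood sizes), plus a
symmetric flag for a preserved immediate neighbor.

## Synthetic corpus

The generator emulates the study inputs end to end: multi-isoform gene
models (GFF3 + genome FASTA with introns, mixed strands, non-trivial CDS
phases), BUSCO summaries, Class-labelled species metadata, and ten planted
family templates — one per query subunit — plus random decoys.  Template
masters double as the query sequences; a species' copy is its master with
seeded point substitutions (default rate 0.1, giving ≈90% identity to the
query, the high-identity end of what real homolog searches report), so
similarity evidence behaves like a real BLASTp search.  Domain calls are
emitted in domtblout format directly from the truth table.  The Group I
ligand template deliberately carries its three signatures in a C-terminal
fn3-like segment **without** a domain call, mirroring the observation that
the p40 C-terminus is fn3-like yet undetected by the fn3 model.

Deliberate simplifications, and hence what passing tests do *not* show
about real data: backgrounds are i.i.d. over residues (flat distribution;
motif-bearing templates additionally exclude the five residues F, W, V, I, K
that could start or terminate a signature, which makes every planted motif
occurrence unique and its coordinates exactly recoverable); there is no
indel process, no substitution matrix structure, no evolution along a tree,
and back-translation uses one fixed codon per residue so translation tests
are deterministic.  Real proteomes have compositional bias, repeats and
fragmented annotations that this corpus does not probe.  One global integer
seed determines every output byte; per-file substreams are derived by
hashing (seed, tags) so content is independent of emission order.

Default study conditions: 9 species over 5 Classes ({Mammalia: 3, Aves: 2,
Actinopteri: 2, Lepidosauria: 1, Reptilia: 1}), 12 genes per species (one
copy of each of the ten templates + 2 decoys, decoy fraction 1/6), up to two
isoforms per gene (the secondary isoform is a shorter coding prefix, to
exercise longest-isoform selection).  The robustness check uses 24 species
(288 proteins) at the same 10% substitution rate.  These sizes were chosen
once as a faithful desk-scale miniature of a multi-hundred-genome corpus.

## Determinism and error handling

All randomness (generator, k-means) flows from explicit integer seeds;
rerunning any stage with the same config and inputs reproduces its output
files byte for byte (the JSON run report's wall-clock fields are the one
exception, excluded from that contract).  Readers raise a typed
`FormatError` on malformed input; GFF3 features with unresolvable parents
are dropped and tallied rather than fatal, since real annotation sets
routinely require repair.  CLI exit codes separate config (2), format (3)
and contract (4) errors.

## Known limitations

Tree inference, divergence dating, structure prediction/superposition and
figure rendering are out of scope (Newick trees are consumed for annotation
only).  The internal aligner has no heuristic seeding, so it is quadratic
per pair and meant for desk-scale corpora; for hundreds of full proteomes,
ingest real hmmscan/BLAST outputs instead.  Cross-build gene-symbol
harmonization for synteny is not attempted: species lacking curated symbols
are flagged and skipped.
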