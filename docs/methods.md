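# Methods

## Scope and shape of the analysis

The package re-implements, as a reusable library, the downstream comparative
analysis of the heme *a* synthase (HAS) family: filtering raw homology hits
into an analysis set, typing each sequence by its cysteine pairs and
membrane topology, tabulating catalytic-motif conservation, measuring gene
neighborhood (synteny) co-occurrence and per-lineage taxonomic distribution,
and checking type assignments against a phylogeny. Database searching, MSA
construction, ML tree inference and structure prediction are out of scope:
hit tables, alignments and trees are consumed as inputs.

Because the family's real sequence collection is not redistributable at this
scale, every stage is exercised on synthetic corpora whose *statistical*
structure matches the published family description. The generator is
first-class, tested code, and its defaults are the study conditions: the
published per-type census (273 type 1A, 2,339 1B, 924 1C, 4,321 type 2, 42
1D, 73 type 0, 121 1A\*; total 8,093), the printed motif percentages, the
printed synteny fractions, and the printed fusion (154/273) and
sole-record (111/121) fractions.

## The type classifier

Types are defined by cysteine-pair location × helix count:

| type | TM | Cys pairs |
|---|---|---|
| 1A | 4 | ECL1 |
| 1A\* | 8 | ECL1 |
| 1B | 8 | ECL1 + ECL3 |
| 1C | 8 | ECL1 |
| 0, 1D, 2 | 8 | none |

The cascade: sequences under 100 residues are never assigned (partial);
3–5 predicted helices with an ECL1 pair → 1A; 7–9 helices with pairs in both
loops → 1B; ECL1 only → 1C vs 1A\* by nearest reference panel (mean global
identity), with H3 = Phe breaking ties toward 1A\*; no pairs → nearest panel
among {0, 1D, 2}, flagged ambiguous when the winner leads by less than 2
identity points; other helix counts → nearest panel + `tm_atypical`. The
TM-count bands absorb predictor wobble around the true 4/8. Cys pairs are
"two cysteines in one periplasmic loop at spacing 2–12", bracketing the two
textbook exemplars (spacings 6 and 5); the operational window is an
assumption (the original rule is unpublished) and is configurable.

The cys-free trio was originally resolved by phylogenetic placement; the
panel-identity rule is the sequence-only operational counterpart, and
`phylo.verify_types` (majority type among the k = 5 patristic nearest
leaves) mirrors the phylogeny-side verification.

## Motif reading

The helix-II motif `E57–X1–X2–H1–R` and helix-VI mirror `X1–X2–X3–H3–X4`
are read primarily by global alignment against an annotated per-type
reference whose anchor columns are known; the mapping is accepted only if
the three constrained slots validate (E57 = Glu, H1 ∈ {His, Asn}, R = Arg).
On failure the fallback is the pattern `E..[HN]R` within predicted helix II
± 5 residues, with the mirror block read at the helix-register position on
helix VI. Absence is reported as a distinct outcome, never fabricated.
Frequency tables round half-up to integers (co-occurrence tables to one
decimal), matching the precision conventions of published tables.

## Alignment and homology gating

Global alignment is Needleman–Wunsch with affine gaps (BLOSUM62, open 10,
extend 0.5 — the EMBOSS `needle` defaults; end gaps penalized), implemented
via Biopython's `PairwiseAligner`; a gap of length L costs open +
(L−1)·extend. Percent identity uses the full alignment length including gap
columns (the `needle` convention; the shorter-sequence denominator is a
switch). Local mode is Smith–Waterman with the same matrix. Any NCBI-format
matrix over any alphabet works, so 3Di structural strings align with the
Foldseek matrix without code changes. The homology gate follows the
canonical comparative-genomics cut-off: a group is included only when both
mean and median identity exceed 25%, the level below which alignment-based
phylogenetics is unreliable — the operational form of the argument for
excluding the proposed DUF420 outgroup (8–13% mean/median identity).

Markov clustering is implemented directly (no installed package provides
it): expansion = matrix squaring, inflation = entrywise power 2.0 with
column renormalization, pruning at 1e-5, convergence at 1e-6; clusters are
connected components of the converged matrix. The similarity transform
(mean directed bitscore, max-normalized) is a package default — the
original input transform is unpublished — with −log10 E and identity as
alternatives. Cluster merging joins clusters whose inter-cluster mean AND
median global identity both exceed 25% and closes transitively. Redundancy
reduction is greedy longest-first at 90% global identity, computed exactly
rather than k-mer screened: desk-scale corpora make exact alignment
affordable.

## Topology stand-in

A full HMM topology predictor is out of scope; the stand-in is hydropathy
based: Kyte–Doolittle means over a 19-residue window, threshold 1.6, runs of
above-threshold window centres seed helix cores (merged across gaps ≤ 3),
and each core is extended outward by an X-drop rule on the cumulative
per-residue hydropathy sum (X = 22, boundary at the argmax). The X-drop
extension is what lets a helix survive its own polar catalytic block — the
five-residue motif depresses per-residue hydropathy by up to ~21 units,
which a plain positive-run extension cannot cross — while still refusing to
cross a real loop (generator loops are built to dip by ≥ ~28). Segments
under 15 residues are discarded. Orientation follows the positive-inside
rule: the N-terminal side is chosen so that Lys/Arg-richer loops are
cytoplasmic. Loop indexing: internal periplasmic loops are ECL1, ECL2, … in
N→C order; for the canonical 8-TM, cytoplasmic-N architecture this maps
loop L1 → ECL1 and L5 → ECL3. Coordinates are 1-based inclusive everywhere.

This stand-in is correct by construction on generator output (exact helix
count, boundaries within ±3 residues — covered by tests) and on unambiguous
real cases; it is *not* a TMHMM replacement for borderline real sequences,
and a TMHMM-2.0 long-format parser is provided for importing real
predictions instead.

## Synthetic corpora

Sequences: each type owns a fixed TM template (helix lengths drawn once,
uniform 19–24; motif blocks centred on helices II and VI; H2/H4 anchors on
helices IV and VIII) from which each record mutates 12% of filler positions
within the hydrophobic set ({L,I,V} core, ≥70%, plus F/A/M). Homologous
families share cores: per-record random helices would leave same-type
sequences mutually unrecognizable, destroying panel identity, fusion
footprints and reference-anchored motif reading. Loops are resampled per
record: hydrophilic (3 of 4 positions strongly so), Lys/Arg-enriched on the
cytoplasmic side, cysteine-free except for planted pairs (spacing 4–8, ≥2
residues from loop ends). Motif residues are drawn from the per-type
frequency profiles, which transcribe the published percentages, with
residual mass uniform over the remaining amino acids; partially-conserved
mirror positions whose exact levels are unpublished default to 60–70%.

Helix length sampling starts at 19, not 18: an 18-residue helix has no
fully-interior 19-residue window, so a worst-case motif draw could make a
planted helix undetectable, violating the noise-free recovery guarantee.
Internal loops have a floor of 10 residues (cysteine loops 14): shorter
loops do not reliably break the hydropathy run between helices, and their
cumulative dip must exceed the X-drop constant while a worst-case motif dip
stays under it (28 vs 21.2 vs X = 22).

Loop-length means per type (0: 11, 1A: 12, 1C: 12, 1A\*: 14, 1B: 18,
1D: 22, 2: 30; sd 3) are package defaults chosen once: only the ordering
"type 2 longest, type 0 shortest" is established. They also give each type
a distinctive length profile, which contributes to panel separability.
Sequence length ranges per type bracket the published descriptions (type 1A
under 200 residues; type 1A\* near 280).

Genomes: one assembly per HAS record (1A\* assemblies co-host one of the 1A
records with probability 10/121), an 11-gene contig with the focal gene at
position 6, neighbor families placed uniformly into free slots of the ±5
window with the published per-type probabilities, decoy annotations
elsewhere, and HAS–HOS fusions emitted for type 1A with probability
154/273 as single two-label records. The heme *o* synthase stand-in domain
is a fixed 6-helix membrane template with 10% per-record substitutions.
Taxonomy is drawn from per-type lineage pools mirroring the published
distribution (1A/1A\* archaeal, 1B/1D/2 bacterial, 0 and 1C mixed).

Trees: the "clean" scenario gives each type one clade; "intercalated"
hangs k disjoint type-1C clades off distinct pendant edges of a type-1B
backbone, so the parsimony minimum for the 1C label is exactly k — the
testbed for "cysteine loss occurred multiple times independently".

What the corpora do **not** emulate: real substitution processes along a
tree (no per-site rate variation, no correlated evolution between motif
positions and lineage), real loop composition, signal peptides, sequencing
artifacts, or genome incompleteness. Passing tests therefore demonstrate
the correctness of the analysis machinery under the published family
statistics — not predictor accuracy on real proteomes.

## MAD rooting and transition counting

MAD rooting is implemented from the method's definition (the published tool
is a script, not a library): for a candidate root at position x on a
branch, each leaf pair (b, c) contributes the relative deviation
r = |2·d(a, b)/d(b, c) − 1|, where a is the pair's induced ancestor — the
candidate root itself for pairs spanning the branch, the median node
otherwise. The per-branch score is the RMS of r over all pairs; the
spanning-pair sum is quadratic in x and minimized in closed form; the tree
is rooted at the global minimizer (zero-length branches perturbed by
ε = 1e-8). Tests verify the analytic optimum against a dense grid scan on
random trees.

Transition counting is Fitch small parsimony (unordered costs; the count is
root-invariant), verified by exhaustive enumeration of internal labelings
on trees of ≤ 8 leaves. A directional (1B→1C) cost matrix is deliberately
not the default: only the minimum count is testable.

## Numerical and convention choices

* Percentages: half-up rounding; integers for motif tables, one decimal for
  co-occurrence, matching published precision.
* Co-occurrence denominators are per-type *record* counts (the convention
  behind 2,140/2,339 = 91.5%), presence-based per window; a fusion record
  satisfies co-occurrence with its fused partner label.
* Windows are strand-agnostic and positional; upstream/downstream =
  left/right by start coordinate.
* MSA trimming: drop columns with occupancy < 0.05, then restore the
  best-occupied dropped columns until ≥ 60% of the original columns remain
  (minimum-columns floor semantics; the alternative per-column conservation
  score reading of the published setting is not adopted).
* Fusion detection requires, per family panel, a local footprint ≥ 100
  residues at ≥ 50% identity, with < 30 residues of footprint overlap
  between the two families. The identity guard goes beyond the plain
  length/overlap rule because any two polytopic membrane proteins align
  locally on hydrophobic-helix composition alone.
* Greedy reduction visits sequences longest-first with id tie-break;
  deterministic throughout — every generator and pipeline entry point takes
  an explicit seed, and a pipeline rerun is byte-identical except the
  manifest timestamp.

## Problem sizes

Defaults used by the shipped checks: motif-recovery runs simulate 2,000
records per type; classifier recovery uses 700 records (100 per type);
pipeline tests run the census scaled down 400–900×; oracle sweeps use 500
random alignment pairs (length ≤ 8), 200 random trees (≤ 8 leaves) for
parsimony, and 50 random 6–10-leaf trees for rooting. These sizes were
chosen as the smallest at which the binomial tolerances quoted in the tests
are meaningful.

## Known limitations

* The topology stand-in and the classifier are validated on synthetic data
  and easy real cases; borderline real membrane proteins need an external
  predictor (import path provided).
* Reference panels default to generated exemplars; on real data they should
  be replaced with curated sequences per type (the interfaces accept any
  panel).
* The published "12 distinct clusters" of the original hit set depends on a
  35,307-assembly in-house database and is not reproducible at desk scale;
  the clustering stage is validated on constructed graphs instead.
* Fitch counting on hard polytomies uses pairwise folding, which upper
  bounds the polytomy optimum; trees here are binary.
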