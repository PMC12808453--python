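# hastools

Comparative genomics of **heme *a* synthase (HAS)**, the Cox15/CtaA-family
integral membrane enzyme that converts heme *o* to heme *a*, the cofactor of
heme-copper terminal oxidases. The family splits into seven types — 0, 1A,
1A\*, 1B, 1C, 1D and 2 — distinguished by:

* **transmembrane-helix count**: 4 for the short archaeal type 1A, 8 for all
  others (the long form likely arose by duplication + fusion of the short
  one);
* **conserved cysteine pairs** in the periplasmic loops: ECL1 + ECL3 in type
  1B, ECL1 only in 1A/1A\*/1C, none in 0/1D/2 (exemplar pairs Cys35/Cys42 and
  Cys191/Cys197, *B. subtilis* numbering);
* **catalytic motifs**: the helix-II block `E57–X1–X2–H1–R` and its less
  conserved helix-VI "mirror" `X1–X2–X3–H3–X4`, whose X-position residue
  frequencies are type-diagnostic (e.g. Trp at X1 in 85% of type 1A; Asn
  replacing H1 in 34% of type 1C; Phe replacing H3 in 55% of type 1A\*).

`hastools` is for people who study the evolution and distribution of this
family (or want a worked, fully testable template for an analysis of this
shape): it implements the complete downstream analysis — homology gating,
clustering, membrane-topology-based typing, motif conservation tables,
±5-gene synteny co-occurrence, per-lineage distribution matrices, and
phylogeny-side verification — together with a synthetic-corpus generator
that emulates the family's published statistical structure, so every stage
runs and is tested entirely offline.

## What is implemented

| stage | module | method |
|---|---|---|
| global/local alignment, identity stats | `pairwise_align` | Needleman–Wunsch / Smith–Waterman (BLOSUM62, gap 10/0.5, `needle` identity convention), arbitrary matrices (incl. 3Di) |
| hit filtering & clustering | `cluster` | identity > 25% ∧ E ≤ 1e-10 gate; Markov clustering (expansion/inflation); mean∧median > 25% cluster merging; greedy 90% reduction |
| TM topology | `topology` | Kyte–Doolittle window cores + X-drop extension; positive-inside orientation; sided loops, ECL1/ECL3 lengths |
| type classification | `has_typing` | cys-pair location × TM count, reference-panel identity for 1C/1A\* and the cys-free trio, partial (<100 aa) gate, HAS–HOS fusion detection |
| motifs | `has_typing` | reference-anchored motif reading with validated anchors, regex fallback, per-type frequency tables; trimAl-style MSA trimming |
| synteny & distribution | `synteny_distribution` | ±5-gene windows, presence-based co-occurrence, per-lineage percent-of-assemblies matrices |
| phylogeny | `phylo` | Newick I/O (dendropy), minimal-ancestor-deviation (MAD) rooting, monophyly, Fitch minimum transitions, patristic k-NN verification |
| simulation | `synthetic_data` | per-type sequence/genome/taxonomy/tree generators parameterized by the published census |
| orchestration | `pipeline`, `cli` | staged runs with manifests, YAML config, `hastools` console script |

## Worked example

Generate one type-1B-like sequence, recover its topology and type:

```python
from hastools.profiles import default_profiles
from hastools.synthetic_data import gen_sequence
from hastools.topology import predict_tm, extract_loops, ecl_lengths
from hastools.has_typing import detect_cys_pairs, assign_type, build_reference_panels

profiles = default_profiles()
gs = gen_sequence(profiles["1B"], rng_seed=7, record_id="demo")

topo = predict_tm(gs.record.seq)
print(topo.n_tm, topo.n_term_side)            # 8 in
loops = extract_loops(topo, len(gs.record.seq))
print(ecl_lengths(loops))                     # (19, 15)
pairs = detect_cys_pairs(loops, gs.record.seq)
print([(p.ecl_index, p.i, p.j) for p in pairs])   # [(1, 44, 53), (3, 198, 203)]

a = assign_type(gs.record, topo, pairs, build_reference_panels())
print(a.type)                                 # 1B
```

The 314-residue record is predicted to have 8 TM helices with a cytoplasmic
N-terminus; cysteine pairs are found in both ECL1 (positions 44/53) and ECL3
(198/203), which together with the 8-TM architecture assigns type 1B.

Or run the whole pipeline on a simulated corpus and read the digest:

```bash
hastools run-all --out run1 --seed 3
hastools report --dir run1
```

which prints per-type counts (their ratios mirror the published census,
e.g. 43 type 2 vs 23 type 1B at 1/100 scale), the neighbor co-occurrence
table (heme *o* synthase leads with 19/23 ≈ 82.6% of type-1B windows at this
corpus size), the per-type motif consensus, and the count of leaves whose
type conflicts with their phylogenetic neighborhood.

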