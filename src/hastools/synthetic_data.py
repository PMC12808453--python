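"""Synthetic HAS corpora: sequences, genomes, taxonomy, and labeled trees.

Every downstream stage of the pipeline (topology prediction, cysteine-pair
typing, motif tables, synteny, phylogeny-side verification) is exercised
offline on corpora produced here. The generator emulates the *statistical*
structure of the real family, not its evolution:

* Each type draws its transmembrane helices from a fixed per-type template
  (helix lengths 19–24, hydrophobic residues, the two catalytic motif blocks
  centred on helices II and VI, H2/H4 anchors on helices IV and VIII) with
  per-record substitutions confined to the hydrophobic set — so same-type
  sequences are recognizably homologous while types stay distinct.
* Loops are hydrophilic and resampled per record from per-type length
  distributions; cytoplasmic loops are Lys/Arg-enriched (positive-inside
  rule); the designated periplasmic loops carry a planted cysteine pair with
  intra-pair spacing 4–8.
* Motif residues are drawn from the per-type frequency profiles, so observed
  frequencies converge to the configured (published) percentages.
* Gene neighborhoods place neighbor families inside the ±5 window with
  per-type co-occurrence probabilities mirroring the published fractions, and
  type 1A records fuse to heme o synthase with the published probability.

No substitution model runs along a tree: labeled trees are built directly for
the "clean" (one clade per type) and "intercalated" (k independent 1B→1C
transitions) scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import as_rng, round_half_up
from .profiles import (
    CENSUS_TYPE_COUNTS,
    DECOY_FAMILIES,
    HAS_LABEL,
    HAS_TYPES,
    HOS,
    MIRROR_SLOTS,
    PRIMARY_SLOTS,
    TAXONOMY_POOLS,
    H2_RESIDUE,
    H4_RESIDUE,
    NeighborModel,
    TypeProfile,
    default_neighbor_model,
    default_profiles,
)
from .records import LABEL_SEP, ProteinRecord
from .topology import Topology

__all__ = [
    "DegenerateProfileError", "GeneratedSequence", "CorpusConfig", "CorpusTruth",
    "gen_sequence", "gen_genome", "gen_corpus", "gen_labeled_tree",
    "gen_hos_domain", "default_corpus_counts", "write_gene_table_tsv",
    "write_gene_table_gff3",
]


class DegenerateProfileError(ValueError):
    """Raised when a profile's loop distribution cannot satisfy its minima."""


# residue pools; cytoplasmic loops are K/R-enriched (positive-inside rule),
# loops never contain C (planted pairs only), W/Y/H/F stay out of loops so
# loop residues never collide with motif vocabulary. Loops interleave strongly
# hydrophilic residues (3 of every 4 positions) with mildly hydrophilic ones,
# which guarantees every loop is a deep hydropathy dip: helices never merge
# across a loop and X-drop extension never crosses one.
_OUT_STRONG = ("D", "E", "N", "Q")
_IN_STRONG = ("D", "E", "N", "Q", "K", "K", "R", "R")  # K/R weighted up
_LOOP_WEAK = ("S", "T", "G", "P")
#: minimum internal loop length; shorter loops would not reliably break the
#: hydropathy window run between two helices
LOOP_FLOOR = 10
#: minimum length of a cysteine-bearing loop (pair + margins + dip guarantee)
CYS_LOOP_FLOOR = 14
_TM_CORE = ("L", "I", "V")
_TM_CORE_P = (0.4, 0.3, 0.3)
_TM_EXTRA = ("F", "A", "M")

_TEMPLATE_SEED = 7_654_321  # fixed: templates are shared constants, not per-run draws
_MUTATION_RATE = 0.12


@dataclass(frozen=True)
class GeneratedSequence:
    """A generated record plus its planted truth."""

    record: ProteinRecord
    topology: Topology
    motif: dict[str, tuple[int, str]]       # slot -> (1-based position, residue)
    cys_pairs: tuple[tuple[str, int, int], ...]  # (loop name, pos_i, pos_j)


def _draw(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    residues = list(freqs)
    probs = np.array([freqs[r] for r in residues], dtype=float)
    return residues[int(rng.choice(len(residues), p=probs / probs.sum()))]


def _loop_length(rng, dist: tuple[float, float, int], floor: int | None = None,
                 max_tries: int = 50) -> int:
    mean, sd, lo = dist
    lo = max(lo, floor or 0)
    for _ in range(max_tries):
        n = int(round(rng.normal(mean, sd)))
        if n >= lo:
            return n
    raise DegenerateProfileError(
        f"loop length distribution {dist} cannot reach its minimum {lo}"
    )


class _TmTemplate:
    """Fixed helix residues for one type; motif/anchor offsets precomputed."""

    def __init__(self, profile: TypeProfile):
        idx = HAS_TYPES.index(profile.type_label)
        rng = np.random.default_rng(_TEMPLATE_SEED + idx)
        self.helices: list[list[str]] = []
        self.core_mask: list[list[bool]] = []  # True where residue is in the LIV core
        for i in range(profile.n_tm):
            length = int(rng.integers(19, 25))
            motif_helix = (i + 1) in (2, 6)
            res, mask = [], []
            for _ in range(length):
                if motif_helix or rng.random() < 0.8:
                    res.append(_TM_CORE[int(rng.choice(3, p=_TM_CORE_P))])
                    mask.append(True)
                else:
                    res.append(_TM_EXTRA[int(rng.integers(3))])
                    mask.append(False)
            # guarantee >= 70% L/I/V
            while sum(mask) / length < 0.7:
                j = mask.index(False)
                res[j] = _TM_CORE[int(rng.choice(3, p=_TM_CORE_P))]
                mask[j] = True
            self.helices.append(res)
            self.core_mask.append(mask)
        # planted positions (0-based offsets within each helix)
        self.slot_offsets: dict[str, tuple[int, int]] = {}  # slot -> (helix idx, offset)
        b2 = (len(self.helices[1]) - 5) // 2
        for k, slot in enumerate(PRIMARY_SLOTS):
            self.slot_offsets[slot] = (1, b2 + k)
        if profile.n_tm >= 4:
            self.slot_offsets["H2"] = (3, len(self.helices[3]) // 2)
        if profile.has_mirror:
            b6 = (len(self.helices[5]) - 5) // 2
            for k, slot in enumerate(MIRROR_SLOTS):
                self.slot_offsets[slot] = (5, b6 + k)
            self.slot_offsets["H4"] = (7, len(self.helices[7]) // 2)


_TEMPLATE_CACHE: dict[str, _TmTemplate] = {}


def _template(profile: TypeProfile) -> _TmTemplate:
    key = f"{profile.type_label}|{profile.n_tm}"
    if key not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[key] = _TmTemplate(profile)
    return _TEMPLATE_CACHE[key]


def _mutate_helix(rng, residues: list[str], mask: list[bool],
                  skip: set[int]) -> list[str]:
    out = list(residues)
    for j in range(len(out)):
        if j in skip:
            continue
        if rng.random() < _MUTATION_RATE:
            pool = _TM_CORE if mask[j] else _TM_EXTRA
            out[j] = pool[int(rng.integers(len(pool)))]
    return out


def _loop_residues(rng, n: int, side: str) -> list[str]:
    if n <= 0:
        return []
    strong = _OUT_STRONG if side == "out" else _IN_STRONG
    out = []
    for j in range(n):
        pool = _LOOP_WEAK if j % 4 == 3 else strong
        out.append(pool[int(rng.integers(len(pool)))])
    return out


def gen_sequence(
    profile: TypeProfile,
    rng_seed,
    record_id: str = "synthetic",
    n_term_side: str = "in",
    max_tries: int = 20,
) -> GeneratedSequence:
    """Generate one HAS-like record with its true topology and planted motifs.

    Deterministic for a given (profile, seed): two calls with the same seed
    yield identical records.
    """
    rng = as_rng(rng_seed)
    tpl = _template(profile)
    n_tm = profile.n_tm
    lo_len, hi_len = profile.length_range

    for _ in range(max_tries):
        # helix residues: template + bounded mutations, anchors overwritten below
        helix_seqs: list[list[str]] = []
        skip_by_helix: dict[int, set[int]] = {}
        for slot, (h, off) in tpl.slot_offsets.items():
            skip_by_helix.setdefault(h, set()).add(off)
        for i in range(n_tm):
            helix_seqs.append(
                _mutate_helix(rng, tpl.helices[i], tpl.core_mask[i],
                              skip_by_helix.get(i, set()))
            )
        planted_res: dict[str, str] = {}
        for slot, (h, off) in tpl.slot_offsets.items():
            if slot == "H2":
                res = H2_RESIDUE
            elif slot == "H4":
                res = H4_RESIDUE
            else:
                res = _draw(rng, profile.motif_freqs[slot])
            helix_seqs[h][off] = res
            planted_res[slot] = res

        # loops: sides alternate from the N terminus; internal out loops get
        # ECL ordinals; cys-bearing loops draw spacing first, then a length
        # that can host the pair with a 2-residue margin on both sides
        sides = []
        side = n_term_side
        for i in range(n_tm + 1):
            sides.append(side)
            side = "out" if side == "in" else "in"
        ecl_by_loop: dict[int, str] = {}
        ecl = 0
        for i in range(1, n_tm):
            if sides[i] == "out":
                ecl += 1
                ecl_by_loop[i] = f"ECL{ecl}"

        loop_seqs: list[list[str]] = []
        cys_local: list[tuple[str, int, int, int]] = []  # (name, loop idx, oi, oj)
        for i in range(n_tm + 1):
            name = ecl_by_loop.get(i)
            dist = profile.loop_dist(name) if name else profile.loop_dist("default")
            internal = 0 < i < n_tm
            if name and name in profile.cys_pairs:
                spacing = int(rng.integers(profile.cys_spacing[0],
                                           profile.cys_spacing[1] + 1))
                need = max(spacing + 6, CYS_LOOP_FLOOR)  # 2 + C + spacing + C + 2
                length = _loop_length(rng, dist, floor=need)
                res = _loop_residues(rng, length, sides[i])
                oi = int(rng.integers(2, length - spacing - 3))
                oj = oi + spacing + 1
                res[oi] = "C"
                res[oj] = "C"
                cys_local.append((name, i, oi, oj))
            else:
                length = _loop_length(rng, dist, floor=LOOP_FLOOR if internal else None)
                res = _loop_residues(rng, length, sides[i])
            loop_seqs.append(res)

        # assemble, tracking coordinates (1-based)
        parts: list[str] = []
        pos = 0
        segments: list[tuple[int, int]] = []
        loop_starts: list[int] = []
        helix_starts: list[int] = []
        for i in range(n_tm):
            loop_starts.append(pos + 1)
            parts.extend(loop_seqs[i])
            pos += len(loop_seqs[i])
            helix_starts.append(pos + 1)
            segments.append((pos + 1, pos + len(helix_seqs[i])))
            parts.extend(helix_seqs[i])
            pos += len(helix_seqs[i])
        loop_starts.append(pos + 1)
        parts.extend(loop_seqs[n_tm])
        pos += len(loop_seqs[n_tm])
        seq = "".join(parts)

        if not (lo_len <= len(seq) <= hi_len):
            continue

        motif = {
            slot: (helix_starts[h] + off, planted_res[slot])
            for slot, (h, off) in tpl.slot_offsets.items()
        }
        cys_pairs = tuple(
            (name, loop_starts[i] + oi, loop_starts[i] + oj)
            for name, i, oi, oj in cys_local
        )
        record = ProteinRecord(
            id=record_id, seq=seq, labels=(HAS_LABEL,),
            truth_type=profile.type_label,
        )
        topo = Topology(tuple(segments), n_term_side)
        return GeneratedSequence(record, topo, motif, cys_pairs)

    raise DegenerateProfileError(
        f"could not generate a type {profile.type_label} sequence within "
        f"length bounds {profile.length_range} in {max_tries} tries"
    )


# --------------------------------------------------------------------------
# heme o synthase stand-in domain (fusion partner)
# --------------------------------------------------------------------------

def _hos_template() -> tuple[list[str], list[bool]]:
    rng = np.random.default_rng(_TEMPLATE_SEED + 100)
    res: list[str] = []
    mask: list[bool] = []
    side = "in"
    for i in range(6):
        for r in _loop_residues(rng, int(rng.integers(10, 17)), side):
            res.append(r)
            mask.append(False)
        for _ in range(int(rng.integers(19, 25))):
            res.append(_TM_CORE[int(rng.choice(3, p=_TM_CORE_P))])
            mask.append(True)
        side = "out" if side == "in" else "in"
    for r in _loop_residues(rng, 8, side):
        res.append(r)
        mask.append(False)
    return res, mask


_HOS_CACHE: tuple[list[str], list[bool]] | None = None


def gen_hos_domain(rng_seed) -> str:
    """A heme o synthase stand-in domain: fixed 6-helix membrane template with
    per-record substitutions (helix positions stay hydrophobic)."""
    global _HOS_CACHE
    if _HOS_CACHE is None:
        _HOS_CACHE = _hos_template()
    rng = as_rng(rng_seed)
    tpl, mask = _HOS_CACHE
    out = []
    for r, in_tm in zip(tpl, mask):
        if rng.random() < 0.10:
            out.append(_TM_CORE[int(rng.integers(3))] if in_tm
                       else _OUT_STRONG[int(rng.integers(len(_OUT_STRONG)))])
        else:
            out.append(r)
    return "".join(out)


# --------------------------------------------------------------------------
# genomes
# --------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ["assembly", "contig", "gene_id", "start", "end", "strand",
                      "annotation"]


def gen_genome(
    n_genes: int,
    planted: list[tuple[str, int]],
    neighbor_model: NeighborModel | None = None,
    rng_seed=0,
    assembly: str = "asm0001",
    contig: str = "contig1",
    profiles: dict[str, TypeProfile] | None = None,
    allow_fusion: bool = True,
) -> tuple[pd.DataFrame, list[ProteinRecord], dict[str, GeneratedSequence]]:
    """One synthetic genome: a gene table plus the proteins it encodes.

    ``planted`` lists (HAS type, 1-based gene position). Neighbor families are
    placed inside the ±5 window around each planted gene with the model's
    probabilities; remaining genes carry decoy annotations. Type 1A records
    become HAS–HOS fusions with probability ``neighbor_model.fusion_prob``,
    emitted as single records tagged with both family labels.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    neighbor_model = neighbor_model or default_neighbor_model()
    profiles = profiles or default_profiles()
    rng = as_rng(rng_seed)

    positions = [p for _, p in planted]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate planted positions in {positions}")
    for t, p in planted:
        if not (1 <= p <= n_genes):
            raise ValueError(f"planted position {p} outside 1..{n_genes}")
        if t not in profiles:
            raise ValueError(f"no profile for type {t!r}")

    annotations: dict[int, str] = {}
    records: list[ProteinRecord] = []
    truth: dict[str, GeneratedSequence] = {}

    model_labels = {lbl for fam in neighbor_model.probs.values() for lbl in fam}
    decoys = [d for d in DECOY_FAMILIES if d not in model_labels]

    gene_ids = {p: f"{assembly}_g{p:04d}" for p in range(1, n_genes + 1)}
    planted_set = {p for _, p in planted}

    # focal HAS genes (and fusions)
    for t, p in planted:
        gs = gen_sequence(profiles[t], rng, record_id=gene_ids[p])
        labels = [HAS_LABEL]
        if t == "1A" and allow_fusion and rng.random() < neighbor_model.fusion_prob:
            hos_seq = gen_hos_domain(rng)
            fused_seq = gs.record.seq + hos_seq
            rec = replace(gs.record, seq=fused_seq, labels=(HAS_LABEL, HOS))
            gs = GeneratedSequence(rec, gs.topology, gs.motif, gs.cys_pairs)
            labels = [HAS_LABEL, HOS]
        records.append(gs.record)
        truth[gene_ids[p]] = gs
        annotations[p] = LABEL_SEP.join(labels)

    # neighbors inside the ±5 window
    for t, p in planted:
        fam = neighbor_model.probs.get(t, {})
        for label in sorted(fam):
            if rng.random() >= fam[label]:
                continue
            window = [q for d in range(-5, 6) if d != 0
                      and 1 <= (q := p + d) <= n_genes
                      and q not in annotations and q not in planted_set]
            if not window:
                continue
            q = int(window[int(rng.integers(len(window)))])
            annotations[q] = label

    # fillers
    for p in range(1, n_genes + 1):
        if p not in annotations:
            annotations[p] = decoys[int(rng.integers(len(decoys)))]

    rows = []
    nt_pos = 0
    for p in range(1, n_genes + 1):
        gid = gene_ids[p]
        if gid in truth:
            length_nt = 3 * len(truth[gid].record.seq) + 3
        else:
            length_nt = int(rng.integers(300, 1200))
            aa_len = max(50, length_nt // 3 - 1)
            prot = "".join(_loop_residues(rng, aa_len, "in"))
            records.append(ProteinRecord(id=gid, seq=prot, assembly=assembly,
                                         labels=tuple(annotations[p].split(LABEL_SEP))))
        start = nt_pos + int(rng.integers(50, 200))
        end = start + length_nt - 1
        nt_pos = end
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((assembly, contig, gid, start, end, strand, annotations[p]))

    table = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    for rec in records:
        rec.assembly = assembly
    return table, records, truth


# --------------------------------------------------------------------------
# whole corpora
# --------------------------------------------------------------------------

def default_corpus_counts(scale: int = 10) -> dict[str, int]:
    """The published per-type census scaled down by ``scale`` (half-up)."""
    return {t: max(1, int(round_half_up(n / scale)))
            for t, n in CENSUS_TYPE_COUNTS.items()}


@dataclass
class CorpusConfig:
    counts: dict[str, int] = field(default_factory=lambda: default_corpus_counts())
    n_genes: int = 11
    focal_position: int = 6
    neighbor_model: NeighborModel = field(default_factory=default_neighbor_model)
    profiles: dict[str, TypeProfile] = field(default_factory=default_profiles)
    #: probability that a 1A* assembly also hosts one of the 1A records
    co_resident_prob: float = 10 / 121
    allow_fusion: bool = True

    def __post_init__(self) -> None:
        # YAML reads a bare type token like 2 as an integer key
        self.counts = {str(t): int(n) for t, n in self.counts.items()}

    def validate(self) -> None:
        if sum(self.counts.values()) <= 0:
            raise ValueError("corpus must contain at least one sequence")
        for t in self.counts:
            if t not in self.profiles:
                raise ValueError(f"missing type profile for {t!r}")
        if not (1 <= self.focal_position <= self.n_genes):
            raise ValueError("focal_position outside the genome")


@dataclass
class CorpusTruth:
    records: list[ProteinRecord]
    topologies: dict[str, Topology]
    truth: pd.DataFrame          # record_id, assembly, true_type, is_fusion, motif, cys
    gene_tables: pd.DataFrame
    taxonomy: pd.DataFrame       # assembly, domain, phylum, class
    generated: dict[str, GeneratedSequence]

    @property
    def has_records(self) -> list[ProteinRecord]:
        ids = set(self.truth.record_id)
        return [r for r in self.records if r.id in ids]


def gen_corpus(config: CorpusConfig, rng_seed, out_dir=None) -> CorpusTruth:
    """Generate a full corpus: per-type counts exactly as requested, one
    assembly per HAS record (1A* assemblies may co-host a 1A record with the
    configured probability), taxonomy drawn from per-type lineage pools."""
    config.validate()
    rng = as_rng(rng_seed)

    jobs: list[tuple[str, ...]] = []          # (assembly, type) or (assembly, t1, t2)
    remaining_1a = config.counts.get("1A", 0)
    n_cohosted = 0
    order = [t for t in HAS_TYPES if config.counts.get(t, 0) > 0]
    for t in order:
        n = config.counts[t]
        if t == "1A":
            continue  # planted standalone below, minus co-hosted ones
        for _ in range(n):
            if (t == "1A*" and remaining_1a > n_cohosted
                    and rng.random() < config.co_resident_prob):
                n_cohosted += 1
                jobs.append(("1A*", "1A"))
            else:
                jobs.append((t,))
    for _ in range(remaining_1a - n_cohosted):
        jobs.append(("1A",))

    all_records: list[ProteinRecord] = []
    topologies: dict[str, Topology] = {}
    truth_rows = []
    tables = []
    tax_rows = []
    generated: dict[str, GeneratedSequence] = {}

    for i, types in enumerate(jobs, start=1):
        assembly = f"asm{i:05d}"
        planted = [(types[0], config.focal_position)]
        if len(types) > 1:
            planted.append((types[1], 1))
        table, records, truth = gen_genome(
            config.n_genes, planted, config.neighbor_model, rng,
            assembly=assembly, profiles=config.profiles,
            allow_fusion=config.allow_fusion,
        )
        tables.append(table)
        # the corpus FASTA is the HAS analysis set; genome context (incl.
        # filler genes) lives in the gene tables
        all_records.extend(r for r in records if r.id in truth)
        pool = TAXONOMY_POOLS[types[0]]
        dom, phy, cls = pool[int(rng.integers(len(pool)))]
        tax_rows.append((assembly, dom, phy, cls))
        for gid, gs in truth.items():
            topologies[gid] = gs.topology
            generated[gid] = gs
            motif_str = "|".join(f"{s}={p}:{r}" for s, (p, r) in sorted(gs.motif.items()))
            cys_str = "|".join(f"{n}:{a}-{b}" for n, a, b in gs.cys_pairs)
            truth_rows.append((gid, assembly, gs.record.truth_type,
                               int(len(gs.record.labels) > 1), motif_str, cys_str))

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["record_id", "assembly", "true_type", "is_fusion", "motif", "cys"],
    )
    corpus = CorpusTruth(
        records=all_records,
        topologies=topologies,
        truth=truth_df,
        gene_tables=pd.concat(tables, ignore_index=True),
        taxonomy=pd.DataFrame(tax_rows, columns=["assembly", "domain", "phylum", "class"]),
        generated=generated,
    )
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def write_corpus(corpus: CorpusTruth, out_dir) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "genes": out / "genes.tsv",
        "gff3": out / "genes.gff3",
        "topology": out / "topology.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.tsv",
    }
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description=r.annotation)
            for r in corpus.records]
    SeqIO.write(seqs, paths["fasta"], "fasta")
    write_gene_table_tsv(corpus.gene_tables, paths["genes"])
    write_gene_table_gff3(corpus.gene_tables, paths["gff3"])
    from .topology import write_topology_tsv
    write_topology_tsv(paths["topology"], corpus.topologies)
    corpus.taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    corpus.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_gene_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})


def write_gene_table_gff3(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in table.itertuples():
            attrs = f"ID={row.gene_id};product={row.annotation};assembly={row.assembly}"
            fh.write(f"{row.contig}\thastools_sim\tCDS\t{row.start}\t{row.end}"
                     f"\t.\t{row.strand}\t0\t{attrs}\n")


# --------------------------------------------------------------------------
# labeled trees
# --------------------------------------------------------------------------

def _random_binary_subtree(taxa: list, rng) -> "dendropy.Node":
    nodes = []
    for t in taxa:
        leaf = dendropy.Node()
        leaf.taxon = t
        leaf.edge.length = float(rng.uniform(0.05, 1.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        nodes.append(parent)
    return nodes[0]


def gen_labeled_tree(
    assignments: dict[str, str],
    scenario: str,
    rng_seed,
    k: int = 3,
) -> tuple[dendropy.Tree, dict]:
    """A labeled tree for phylogeny-side checks.

    ``"clean"``: each type occupies one clade. ``"intercalated"``: plants ``k``
    independent 1B→1C transitions by hanging k disjoint 1C clades off distinct
    pendant edges of a 1B backbone, so the parsimony minimum for the 1C label
    is exactly k. Truth (scenario, planted transition count) is returned.
    """
    if len(assignments) < 2:
        raise ValueError("need at least 2 leaves")
    if scenario not in ("clean", "intercalated"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = as_rng(rng_seed)
    tns = dendropy.TaxonNamespace()
    taxa = {leaf: tns.new_taxon(label=leaf) for leaf in assignments}
    by_type: dict[str, list[str]] = {}
    for leaf, t in assignments.items():
        by_type.setdefault(t, []).append(leaf)

    def subtree(leaves):
        return _random_binary_subtree([taxa[x] for x in leaves], rng)

    if scenario == "clean":
        clades = [subtree(leaves) for _, leaves in sorted(by_type.items())]
        root = clades[0]
        for c in clades[1:]:
            new_root = dendropy.Node()
            new_root.add_child(root)
            new_root.add_child(c)
            new_root.edge.length = float(rng.uniform(0.05, 1.0))
            root = new_root
        truth = {"scenario": "clean", "k": 0}
    else:
        b_leaves = by_type.get("1B", [])
        c_leaves = by_type.get("1C", [])
        if len(b_leaves) < max(2, k) or len(c_leaves) < k:
            raise ValueError(
                f"intercalated scenario with k={k} needs >= {max(2, k)} 1B "
                f"and >= {k} 1C leaves"
            )
        root = subtree(b_leaves)
        # partition 1C leaves into k non-empty groups
        perm = list(rng.permutation(len(c_leaves)))
        groups: list[list[str]] = [[] for _ in range(k)]
        for idx, pos in enumerate(perm):
            groups[idx % k].append(c_leaves[pos])
        # attach each group to a distinct 1B pendant edge
        tmp = dendropy.Tree(taxon_namespace=tns)
        tmp.seed_node = root
        pendant = [lf for lf in tmp.leaf_node_iter()]
        chosen = rng.choice(len(pendant), size=k, replace=False)
        for g_idx, p_idx in enumerate(chosen):
            leaf = pendant[int(p_idx)]
            parent = leaf.parent_node
            mid = dendropy.Node()
            mid.edge.length = leaf.edge.length / 2
            parent.remove_child(leaf)
            leaf.edge.length = leaf.edge.length / 2
            mid.add_child(leaf)
            mid.add_child(_random_binary_subtree([taxa[x] for x in groups[g_idx]], rng))
            parent.add_child(mid)
        for t, leaves in sorted(by_type.items()):
            if t in ("1B", "1C"):
                continue
            new_root = dendropy.Node()
            new_root.add_child(root)
            new_root.add_child(subtree(leaves))
            new_root.edge.length = float(rng.uniform(0.05, 1.0))
            root = new_root
        truth = {"scenario": "intercalated", "k": k}

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree, truth
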