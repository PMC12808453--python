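"""HAS type classification, motif extraction, conservation tables, MSA trimming.

The classifier follows the family's published definition: presence and loop
location of conserved cysteine pairs plus transmembrane-helix count, with
reference-panel identity resolving the cases the cysteine rule cannot
(1C vs 1A*, and the cys-free trio 0/1D/2, which the original analysis told
apart by phylogenetic placement — mirrored here by ``phylo.verify_types``).
Partial sequences (< 100 residues) are never assigned.

Motif residues (helix-II ``E57–X1–X2–H1–R`` and the helix-VI mirror
``X1–X2–X3–H3–X4``) are read primarily by global alignment against an
annotated reference with known anchor columns, validated at the three
constrained slots (E57 = Glu, H1 ∈ {His, Asn}, R = Arg); if validation fails
the fallback is a direct pattern search anchored on the predicted helix II
(and a positional read on helix VI). Absence is reported, never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean as _mean

import pandas as pd
import re

from ._util import round_half_up
from .profiles import (
    MIRROR_SLOTS,
    PRIMARY_SLOTS,
    TypeProfile,
    default_profiles,
)
from .pairwise_align import local_footprint, nw_align
from .records import ProteinRecord
from .topology import Loop, Topology

__all__ = [
    "CysPair", "HASTypeAssignment", "MotifResult", "MotifReference",
    "detect_cys_pairs", "assign_type", "locate_motifs", "motif_frequency_table",
    "trim_msa", "detect_fusion", "build_reference_panels", "motif_reference",
]

_PANEL_SEED = 20_240_901  # fixed: shipped panels are package constants


@dataclass(frozen=True)
class CysPair:
    ecl_index: int
    i: int  # 1-based protein coordinates of the two cysteines
    j: int

    @property
    def spacing(self) -> int:
        return self.j - self.i - 1


@dataclass(frozen=True)
class HASTypeAssignment:
    record_id: str
    type: str  # one of the seven types or "unassigned"
    tm_count: int
    cys_ecl1: bool
    cys_ecl3: bool
    nearest_ref: str | None
    mean_identity: float | None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if "partial" in self.flags and self.type != "unassigned":
            raise ValueError("partial records must stay unassigned")


@dataclass(frozen=True)
class MotifResult:
    found: bool
    method: str | None  # "reference_alignment" | "regex" | None
    e57_pos: int | None
    primary: dict[str, str | None]
    mirror: dict[str, str | None] | None
    positions: dict[str, int]


@dataclass(frozen=True)
class MotifReference:
    """A reference sequence with known anchor positions for every motif slot."""

    type_label: str
    seq: str
    anchors: dict[str, int]  # slot -> 1-based position


def detect_cys_pairs(
    loops: list[Loop],
    seq: str,
    min_gap: int = 2,
    max_gap: int = 12,
) -> list[CysPair]:
    """First (most N-terminal) cysteine pair per periplasmic loop with spacing
    ``j - i - 1`` within [min_gap, max_gap]; at most one pair per loop.

    The spacing window brackets the two textbook exemplars (Cys35/Cys42 and
    Cys191/Cys197, spacings 6 and 5, B. subtilis numbering).
    """
    pairs: list[CysPair] = []
    for lp in loops:
        if lp.ecl_index is None or lp.length == 0:
            continue
        cys = [p for p in range(lp.start, lp.end + 1) if seq[p - 1] == "C"]
        found = None
        for a in range(len(cys)):
            for b in range(a + 1, len(cys)):
                gap = cys[b] - cys[a] - 1
                if min_gap <= gap <= max_gap:
                    found = CysPair(lp.ecl_index, cys[a], cys[b])
                    break
            if found:
                break
        if found:
            pairs.append(found)
    return pairs


# --------------------------------------------------------------------------
# reference panels
# --------------------------------------------------------------------------

def build_reference_panels(
    profiles: dict[str, TypeProfile] | None = None,
    n_per_type: int = 6,
) -> dict[str, list[str]]:
    """Labeled exemplar sequences per type, generated deterministically from
    the shipped profiles. Replaceable with curated references."""
    from .synthetic_data import gen_sequence  # deferred: avoids import cycle
    profiles = profiles or default_profiles()
    panels: dict[str, list[str]] = {}
    for i, (t, prof) in enumerate(sorted(profiles.items())):
        panels[t] = [
            gen_sequence(prof, _PANEL_SEED + 100 * i + k, record_id=f"ref_{t}_{k}").record.seq
            for k in range(n_per_type)
        ]
    return panels


def motif_reference(profile: TypeProfile) -> MotifReference:
    """An annotated motif reference for one type (fixed-seed exemplar whose
    planted anchor positions are known exactly)."""
    from .synthetic_data import gen_sequence
    gs = gen_sequence(profile, _PANEL_SEED, record_id=f"motifref_{profile.type_label}")
    anchors = {slot: pos for slot, (pos, _res) in gs.motif.items()}
    return MotifReference(profile.type_label, gs.record.seq, anchors)


# --------------------------------------------------------------------------
# type assignment
# --------------------------------------------------------------------------

def _mean_panel_identity(seq: str, panel: list[str]) -> float:
    return _mean(nw_align(seq, ref).identity_pct for ref in panel)


def _nearest_panel(seq: str, panels: dict[str, list[str]],
                   candidates: list[str]) -> list[tuple[str, float]]:
    if not candidates or any(not panels.get(c) for c in candidates):
        raise ValueError(f"empty reference panel among {candidates}")
    scored = [(c, _mean_panel_identity(seq, panels[c])) for c in candidates]
    scored.sort(key=lambda x: (-x[1], x[0]))
    return scored


def assign_type(
    record: ProteinRecord,
    topology: Topology,
    pairs: list[CysPair],
    reference_panels: dict[str, list[str]],
    margin: float = 2.0,
    h3_residue: str | None = None,
    min_length: int = 100,
) -> HASTypeAssignment:
    """Rule cascade: partial gate, then cysteine-pair location x TM count,
    with reference panels resolving 1C/1A* and the cys-free trio 0/1D/2.

    ``h3_residue`` (from :func:`locate_motifs`) breaks a 1C/1A* panel tie
    toward 1A* when the H3 slot holds phenylalanine. A nearest-panel win of
    less than ``margin`` identity points flags the call ambiguous.
    """
    tm = topology.n_tm
    ecl1 = any(p.ecl_index == 1 for p in pairs)
    ecl3 = any(p.ecl_index == 3 for p in pairs)
    flags: set[str] = set()

    if len(record.seq) < min_length:
        return HASTypeAssignment(record.id, "unassigned", tm, ecl1, ecl3,
                                 None, None, frozenset({"partial"}))

    if 3 <= tm <= 5 and ecl1:
        return HASTypeAssignment(record.id, "1A", tm, ecl1, ecl3, None, None)

    if 7 <= tm <= 9:
        if ecl1 and ecl3:
            return HASTypeAssignment(record.id, "1B", tm, ecl1, ecl3, None, None)
        if ecl1:
            scored = _nearest_panel(record.seq, reference_panels, ["1A*", "1C"])
            (t1, s1), (_t2, s2) = scored
            if s1 - s2 < margin:
                t1 = "1A*" if h3_residue == "F" else "1C"
                flags.add("ambiguous")
            return HASTypeAssignment(record.id, t1, tm, ecl1, ecl3,
                                     scored[0][0], s1, frozenset(flags))
        scored = _nearest_panel(record.seq, reference_panels, ["0", "1D", "2"])
        (t1, s1), (_t2, s2) = scored[0], scored[1]
        if s1 - s2 < margin:
            flags.add("ambiguous")
        return HASTypeAssignment(record.id, t1, tm, ecl1, ecl3, t1, s1,
                                 frozenset(flags))

    flags.add("tm_atypical")
    scored = _nearest_panel(record.seq, reference_panels,
                            sorted(reference_panels))
    t1, s1 = scored[0]
    if len(scored) > 1 and s1 - scored[1][1] < margin:
        flags.add("ambiguous")
    return HASTypeAssignment(record.id, t1, tm, ecl1, ecl3, t1, s1,
                             frozenset(flags))


# --------------------------------------------------------------------------
# motif location
# --------------------------------------------------------------------------

_PRIMARY_RE = re.compile(r"E.{2}[HN]R")


def _column_map(aligned_a: str, aligned_b: str) -> dict[int, int | None]:
    """Map 1-based positions of b (reference) to 1-based positions of a
    (record); None where the record has a gap under the reference column."""
    out: dict[int, int | None] = {}
    pa = pb = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            pa += 1
        if cb != "-":
            pb += 1
            out[pb] = pa if ca != "-" else None
    return out


def _read_by_reference(seq: str, reference: MotifReference) -> dict[str, int] | None:
    aln = nw_align(seq, reference.seq)
    cmap = _column_map(aln.aligned_a, aln.aligned_b)
    positions: dict[str, int] = {}
    for slot, ref_pos in reference.anchors.items():
        p = cmap.get(ref_pos)
        if p is None:
            return None
        positions[slot] = p
    # validate the constrained slots before trusting the mapping
    if seq[positions["E57"] - 1] != "E":
        return None
    if seq[positions["H1"] - 1] not in "HN":
        return None
    if seq[positions["R"] - 1] != "R":
        return None
    return positions


def _read_by_regex(seq: str, topology: Topology) -> dict[str, int] | None:
    if topology.n_tm < 2:
        return None
    s2, e2 = topology.segments[1]
    lo = max(0, s2 - 1 - 5)
    hi = min(len(seq), e2 + 5)
    m = _PRIMARY_RE.search(seq[lo:hi])
    if not m:
        return None
    e57 = lo + m.start() + 1
    positions = {slot: e57 + k for k, slot in enumerate(PRIMARY_SLOTS)}
    if topology.n_tm >= 6:
        s6, e6 = topology.segments[5]
        length = e6 - s6 + 1
        b6 = s6 + (length - 5) // 2  # helix-register position of the block
        for k, slot in enumerate(MIRROR_SLOTS):
            positions[slot] = b6 + k
    return positions


def locate_motifs(
    record: ProteinRecord,
    topology: Topology,
    reference: MotifReference | None = None,
) -> MotifResult:
    """Read the helix-II motif (and the helix-VI mirror when >= 6 TM).

    With a reference: align globally, read residues under the annotated anchor
    columns, and accept only if the constrained slots validate; otherwise fall
    back to the pattern search. Reports absence rather than fabricating."""
    if topology.n_tm < 2:
        return MotifResult(False, None, None, {}, None, {})
    seq = record.seq
    positions = None
    method = None
    if reference is not None:
        positions = _read_by_reference(seq, reference)
        if positions is not None:
            method = "reference_alignment"
    if positions is None:
        positions = _read_by_regex(seq, topology)
        if positions is not None:
            method = "regex"
    if positions is None:
        return MotifResult(False, None, None, {}, None, {})
    primary = {slot: seq[positions[slot] - 1] for slot in PRIMARY_SLOTS
               if slot in positions}
    mirror = None
    if all(slot in positions for slot in MIRROR_SLOTS):
        mirror = {slot: seq[positions[slot] - 1] for slot in MIRROR_SLOTS}
    return MotifResult(True, method, positions.get("E57"), primary, mirror,
                       dict(positions))


def motif_frequency_table(
    results_by_type: dict[str, list[MotifResult]],
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-type, per-position residue percentages (integers, half-up).

    Rows: (type, position, residue, count, n, percent, low_support). The
    denominator per position is the number of records of the type where the
    motif (and, for mirror slots, the mirror) was found.
    """
    if not results_by_type or all(not v for v in results_by_type.values()):
        raise ValueError("no motif results to tabulate")
    rows = []
    for t, results in sorted(results_by_type.items()):
        for slot in PRIMARY_SLOTS + MIRROR_SLOTS:
            residues = []
            for r in results:
                if not r.found:
                    continue
                src = r.primary if slot in PRIMARY_SLOTS else (r.mirror or {})
                res = src.get(slot)
                if res is not None:
                    residues.append(res)
            n = len(residues)
            if n == 0:
                continue
            counts = pd.Series(residues).value_counts()
            for res, c in counts.items():
                rows.append((t, slot, res, int(c), n,
                             int(round_half_up(100.0 * c / n)), n < min_n))
    return pd.DataFrame(
        rows, columns=["type", "position", "residue", "count", "n",
                       "percent", "low_support"])


def position_percent(table: pd.DataFrame, has_type: str, position: str,
                     residue: str) -> int:
    """Convenience lookup into a motif frequency table (0 when absent)."""
    m = table[(table.type == has_type) & (table.position == position)
              & (table.residue == residue)]
    return int(m.percent.iloc[0]) if len(m) else 0


# --------------------------------------------------------------------------
# MSA trimming
# --------------------------------------------------------------------------

def trim_msa(
    msa: list[str],
    gap_fraction_keep: float = 0.05,
    conservation_keep: float = 0.60,
) -> tuple[list[str], list[int]]:
    """Gap-threshold column trim with a minimum-columns floor.

    Columns whose non-gap fraction is below ``gap_fraction_keep`` are dropped;
    if fewer than ``conservation_keep`` of the original columns survive, the
    highest-occupancy dropped columns are added back until the floor is met.
    Returns the trimmed rows and the kept original column indices (0-based).
    """
    if not msa:
        raise ValueError("empty alignment")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("ragged alignment")
    nrow = len(msa)
    occupancy = [sum(1 for row in msa if row[c] not in "-.") / nrow
                 for c in range(ncol)]
    kept = [c for c in range(ncol) if occupancy[c] >= gap_fraction_keep]
    floor = int(-(-conservation_keep * ncol // 1))  # ceil
    if len(kept) < floor:
        dropped = sorted((c for c in range(ncol) if c not in set(kept)),
                         key=lambda c: (-occupancy[c], c))
        for c in dropped:
            kept.append(c)
            if len(kept) >= floor:
                break
        kept.sort()
    trimmed = ["".join(row[c] for c in kept) for row in msa]
    return trimmed, kept


# --------------------------------------------------------------------------
# fusion detection
# --------------------------------------------------------------------------

def detect_fusion(
    record: ProteinRecord,
    panels: dict[str, list[str]],
    min_len: int = 100,
    max_overlap: int = 30,
    min_identity: float = 50.0,
) -> str:
    """``"fusion"`` when two distinct family panels each place a confident
    local footprint (>= min_len residues at >= min_identity) on the record
    with < max_overlap residues shared; ``"single"`` when exactly one does;
    ``"neither"`` otherwise.

    The identity guard is essential for membrane families: hydrophobic-helix
    composition alone lets any two polytopic proteins align locally.
    """
    if len(panels) < 2:
        raise ValueError("need at least two family panels")
    footprints: dict[str, tuple[int, int]] = {}
    for label, members in panels.items():
        if not members:
            raise ValueError(f"empty panel {label!r}")
        best = None
        for m in members:
            s, e, ident, score = local_footprint(record.seq, m)
            if (e - s + 1) >= min_len and ident >= min_identity:
                if best is None or score > best[2]:
                    best = (s, e, score)
        if best is not None:
            footprints[label] = (best[0], best[1])
    if len(footprints) >= 2:
        (s1, e1), (s2, e2) = list(footprints.values())[:2]
        overlap = max(0, min(e1, e2) - max(s1, s2) + 1)
        if overlap < max_overlap:
            return "fusion"
        return "single"
    if len(footprints) == 1:
        return "single"
    return "neither"
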