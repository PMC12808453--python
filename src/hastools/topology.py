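"""Membrane topology: TM-segment prediction, parsing, and sided loop extraction.

Coordinates are 1-based inclusive throughout (the TMHMM convention). The
prediction here is a hydropathy stand-in for a full HMM predictor: maximal
runs of Kyte–Doolittle sliding-window means above a threshold seed candidate
helices, which are then extended over the surrounding hydrophobic stretch and
length-filtered. That is sufficient for generator output and unambiguous real
cases; it makes no claim to TMHMM's accuracy on borderline sequences.

Loop sidedness alternates along the chain starting from the N-terminal side,
which is set by the positive-inside rule (the cytoplasmic side is enriched in
lysine/arginine). Extracellular loops are numbered ECL1, ECL2, ... in N→C
order over the internal periplasmic loops; for the canonical 8-TM HAS with a
cytoplasmic N-terminus this maps loop L1 to ECL1 and loop L5 to ECL3, the two
loops that may carry conserved cysteine pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as KD_SCALE

__all__ = [
    "Topology", "Loop", "parse_topology", "format_topology", "predict_tm",
    "extract_loops", "ecl_lengths", "read_topology_tsv", "write_topology_tsv",
    "parse_tmhmm_long",
]


@dataclass(frozen=True)
class Topology:
    """Ordered TM segments (1-based inclusive) plus N-terminal sidedness."""

    segments: tuple[tuple[int, int], ...]
    n_term_side: str  # "in" | "out"

    def __post_init__(self) -> None:
        if self.n_term_side not in ("in", "out"):
            raise ValueError(f"n_term_side must be 'in' or 'out', got {self.n_term_side!r}")
        prev_end = 0
        for s, e in self.segments:
            if s < 1 or e < s:
                raise ValueError(f"bad segment ({s},{e})")
            if s <= prev_end:
                raise ValueError(f"segments overlap or are unsorted at ({s},{e})")
            prev_end = e

    @property
    def n_tm(self) -> int:
        return len(self.segments)

    def validate_against_length(self, seq_length: int) -> None:
        if self.segments and self.segments[-1][1] > seq_length:
            raise ValueError(
                f"segment {self.segments[-1]} exceeds sequence length {seq_length}"
            )


@dataclass(frozen=True)
class Loop:
    ordinal: int          # loop index from the N terminus (0 = N-terminal tail)
    side: str             # "in" | "out"
    ecl_index: int | None  # extracellular ordinal (internal out loops only)
    start: int            # 1-based; start > end means an empty loop
    end: int

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


def parse_topology(text: str, seq_length: int) -> Topology:
    """Parse ``"in;10-30,45-65"`` into a validated :class:`Topology`."""
    try:
        side, seg_str = text.split(";", 1)
    except ValueError as exc:
        raise ValueError(f"malformed topology string {text!r}") from exc
    segments = []
    if seg_str.strip():
        for part in seg_str.split(","):
            s, e = part.strip().split("-")
            segments.append((int(s), int(e)))
    topo = Topology(tuple(segments), side.strip())
    topo.validate_against_length(seq_length)
    return topo


def format_topology(t: Topology) -> str:
    segs = ",".join(f"{s}-{e}" for s, e in t.segments)
    return f"{t.n_term_side};{segs}"


def _window_means(seq: str, window: int) -> list[float]:
    """Centred Kyte–Doolittle window means; index i is the mean of the window
    centred at residue i (full windows only; half-window margins get None)."""
    vals = [KD_SCALE[a] for a in seq]
    n = len(vals)
    half = window // 2
    means: list[float | None] = [None] * n
    s = sum(vals[:window])
    for c in range(half, n - half):
        means[c] = s / window
        if c + half + 1 < n:
            s += vals[c + half + 1] - vals[c - half]
    return means


def predict_tm(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    merge_gap: int = 3,
    xdrop: float = 22.0,
) -> Topology:
    """Hydropathy-based TM segment prediction.

    Runs of centred window means above ``threshold`` are candidate helix cores;
    cores closer than ``merge_gap`` are merged. A centred-window core
    systematically underestimates the helix (edge windows mix in loop
    residues), and polar catalytic residues inside a helix can interrupt
    per-residue hydrophobicity, so each core is extended outward by an X-drop
    rule on the cumulative Kyte–Doolittle sum: extension walks outward
    tracking the running sum, stops once it falls more than ``xdrop`` below
    its best value, and places the boundary at the best (argmax) position.
    This crosses short polar motifs inside a helix but not a genuinely
    hydrophilic loop. Segments shorter than ``min_len`` after extension are
    discarded. N-terminal sidedness follows the positive-inside rule: the
    orientation placing the lysine/arginine-richer loops on the cytoplasmic
    side wins.
    """
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    bad = set(seq) - set(KD_SCALE)
    if bad:
        raise ValueError(f"unknown residues for hydropathy scale: {sorted(bad)}")
    means = _window_means(seq, window)

    # candidate cores: maximal runs of centre positions above threshold
    cores: list[list[int]] = []
    for i, m in enumerate(means):
        if m is not None and m > threshold:
            if cores and i - cores[-1][1] <= merge_gap + 1:
                cores[-1][1] = i
            else:
                cores.append([i, i])

    vals = [KD_SCALE[a] for a in seq]
    extended: list[list[int]] = []  # 0-based [lo, hi]
    for lo, hi in cores:
        # X-drop extension left
        best, cum, best_pos = 0.0, 0.0, lo
        j = lo - 1
        while j >= 0:
            cum += vals[j]
            if cum > best:
                best, best_pos = cum, j
            if best - cum > xdrop:
                break
            j -= 1
        lo = best_pos
        # X-drop extension right
        best, cum, best_pos = 0.0, 0.0, hi
        j = hi + 1
        while j < n:
            cum += vals[j]
            if cum > best:
                best, best_pos = cum, j
            if best - cum > xdrop:
                break
            j += 1
        hi = best_pos
        if extended and lo <= extended[-1][1] + 1:  # touching/overlap after extension
            extended[-1][1] = max(extended[-1][1], hi)
        else:
            extended.append([lo, hi])
    segments = [(lo + 1, hi + 1) for lo, hi in extended if hi - lo + 1 >= min_len]

    n_term = _positive_inside_side(seq, segments)
    return Topology(tuple(segments), n_term)


def _positive_inside_side(seq: str, segments: list[tuple[int, int]]) -> str:
    """Choose the N-terminal side so that K/R-rich loops end up inside."""
    if not segments:
        return "in"
    # collect loop residue stretches with their parity (0 = same side as N terminus)
    stretches: list[tuple[int, str]] = []
    prev_end = 0
    for i, (s, e) in enumerate(segments):
        stretches.append((i % 2, seq[prev_end:s - 1]))
        prev_end = e
    stretches.append((len(segments) % 2, seq[prev_end:]))
    kr = [0, 0]
    for parity, chunk in stretches:
        kr[parity] += chunk.count("K") + chunk.count("R")
    # parity 0 loops share the N-terminal side; richer side is "in"
    return "in" if kr[0] >= kr[1] else "out"


def extract_loops(t: Topology, seq_length: int) -> list[Loop]:
    """Loops between consecutive TM segments plus both termini, with sides
    alternating from ``n_term_side`` and ECL ordinals on internal out loops."""
    t.validate_against_length(seq_length)
    loops: list[Loop] = []
    side = t.n_term_side
    ecl = 0
    prev_end = 0
    for i, (s, e) in enumerate(t.segments):
        start, end = prev_end + 1, s - 1
        is_internal = i > 0
        idx = None
        if is_internal and side == "out":
            ecl += 1
            idx = ecl
        loops.append(Loop(ordinal=i, side=side, ecl_index=idx, start=start, end=end))
        side = "out" if side == "in" else "in"
        prev_end = e
    loops.append(Loop(ordinal=len(t.segments), side=side, ecl_index=None,
                      start=prev_end + 1, end=seq_length))
    return loops


def ecl_lengths(loops: list[Loop]) -> tuple[int | None, int | None]:
    """(ECL1 length, ECL3 length); ECL3 is None for 4-TM topologies."""
    by_idx = {lp.ecl_index: lp for lp in loops if lp.ecl_index is not None}
    l1 = by_idx[1].length if 1 in by_idx else None
    l3 = by_idx[3].length if 3 in by_idx else None
    return l1, l3


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

TSV_HEADER = "# gene_id\tn_term_side\tsegments (1-based inclusive, 'start-end' comma-separated)"


def write_topology_tsv(path, topologies: dict[str, Topology]) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for gid, t in topologies.items():
            segs = ",".join(f"{s}-{e}" for s, e in t.segments)
            fh.write(f"{gid}\t{t.n_term_side}\t{segs}\n")


def read_topology_tsv(path, seq_lengths: dict[str, int] | None = None) -> dict[str, Topology]:
    out: dict[str, Topology] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, side, segs = line.rstrip("\n").split("\t")
            length = seq_lengths.get(gid, 10 ** 9) if seq_lengths else 10 ** 9
            out[gid] = parse_topology(f"{side};{segs}", length)
    return out


def parse_tmhmm_long(text: str) -> dict[str, Topology]:
    """Parse TMHMM-2.0 long-format output into Topology objects.

    Lines look like ``name  TMHMM2.0  inside   1  27`` / ``... TMhelix 28 50``.
    """
    rows: dict[str, list[tuple[str, int, int]]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5 or parts[1] != "TMHMM2.0":
            continue
        name, kind, s, e = parts[0], parts[2], int(parts[3]), int(parts[4])
        rows.setdefault(name, []).append((kind, s, e))
    out = {}
    for name, feats in rows.items():
        feats.sort(key=lambda f: f[1])
        segs = tuple((s, e) for kind, s, e in feats if kind == "TMhelix")
        first = feats[0][0]
        n_term = "in" if first == "inside" else "out"
        out[name] = Topology(segs, n_term)
    return out
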