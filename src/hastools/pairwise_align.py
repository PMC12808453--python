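"""Global/local pairwise alignment, percent identity, and group identity stats.

Used for the homology gating cascade: raw search hits are filtered on local
identity, survivors are globally aligned (Needleman–Wunsch, BLOSUM62, gap open
10 / extend 0.5 — the classic ``needle`` defaults) and retained above 25%
global identity, the canonical comparative-genomics homology cut-off. The same
machinery computes inter-type and decoy-vs-family identity statistics — the
argument for excluding sub-homology outgroups (e.g. the proposed DUF420
ancestor, at 8–13% mean/median identity) from phylogenetic reconstruction.

Alignment itself is delegated to :class:`Bio.Align.PairwiseAligner` (affine
gaps, end gaps penalized in global mode). A gap of length L costs
``open + (L-1) * extend``. Matrices are Biopython substitution matrices; any
NCBI-format text matrix works, so non-amino-acid alphabets (e.g. 3Di
structural strings with the Foldseek matrix) align without code changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from statistics import median as _median

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult", "GroupIdentityStats", "load_matrix", "nw_align",
    "sw_align", "global_identity", "group_identity_stats", "homology_gate",
]


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    mode: str = "global"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings differ in length")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct out of [0, 100]")


@dataclass(frozen=True)
class GroupIdentityStats:
    mean: float
    median: float
    min: float
    max: float
    n_pairs: int
    mode: str

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("min <= median <= max violated")


def load_matrix(name_or_path: str):
    """Load a named Biopython matrix (e.g. ``"BLOSUM62"``) or an NCBI-format
    matrix file from disk."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        return substitution_matrices.read(name_or_path)


def _make_aligner(matrix, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = mode
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _sanitize(seq: str, alphabet: set[str], neutral: str = "X") -> str:
    """Map residues outside the matrix alphabet to the neutral symbol."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) <= alphabet:
        return seq
    if neutral not in alphabet:
        bad = sorted(set(seq) - alphabet)
        raise ValueError(f"symbols {bad} not in matrix alphabet and no neutral symbol")
    return "".join(c if c in alphabet else neutral for c in seq)


def _identity_from_strings(a: str, b: str, denominator: str = "alignment") -> float:
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    if denominator == "alignment":
        denom = len(a)
    elif denominator == "shorter":
        denom = min(len(a.replace("-", "")), len(b.replace("-", "")))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * ident / denom if denom else 0.0


def _align(a, b, matrix, gap_open, gap_extend, mode, denominator) -> AlignmentResult:
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    alphabet = set(str(matrix.alphabet))
    a = _sanitize(a, alphabet)
    b = _sanitize(b, alphabet)
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return AlignmentResult(ga, gb, float(aln.score),
                           _identity_from_strings(ga, gb, denominator), mode)


def nw_align(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    identity_denominator: str = "alignment",
) -> AlignmentResult:
    """Optimal global affine-gap alignment (end gaps penalized)."""
    return _align(a, b, matrix, gap_open, gap_extend, "global", identity_denominator)


def sw_align(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment with the same matrix.

    Identity uses the aligned region as denominator, as local identities do.
    """
    return _align(a, b, matrix, gap_open, gap_extend, "local", "alignment")


def local_footprint(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[int, int, float, float]:
    """Best local alignment of ``b`` against ``a``; returns the footprint on
    ``a`` as (start, end) 1-based inclusive plus (identity_pct, score)."""
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    alphabet = set(str(matrix.alphabet))
    a = _sanitize(a, alphabet)
    b = _sanitize(b, alphabet)
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    aln = aligner.align(a, b)[0]
    blocks_a = aln.aligned[0]
    start, end = int(blocks_a[0][0]) + 1, int(blocks_a[-1][1])
    ga, gb = str(aln[0]), str(aln[1])
    return start, end, _identity_from_strings(ga, gb, "alignment"), float(aln.score)


def global_identity(r: AlignmentResult) -> float:
    """Percent identical columns over the full alignment length (gap columns
    count in the denominator — the ``needle`` convention)."""
    return _identity_from_strings(r.aligned_a, r.aligned_b, "alignment")


def group_identity_stats(
    group_a,
    group_b=None,
    mode: str = "global",
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> GroupIdentityStats:
    """Identity statistics over all cross pairs (or within-group pairs when
    ``group_b`` is omitted)."""
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    group_a = list(group_a)
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    fn = nw_align if mode == "global" else sw_align
    if group_b is None:
        if len(group_a) < 2:
            raise ValueError("intra-group statistics need at least 2 sequences")
        pairs = list(itertools.combinations(group_a, 2))
    else:
        group_b = list(group_b)
        if not group_a or not group_b:
            raise ValueError("groups must be non-empty")
        pairs = list(itertools.product(group_a, group_b))
    idents = [fn(a, b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend).identity_pct
              for a, b in pairs]
    return GroupIdentityStats(
        mean=sum(idents) / len(idents),
        median=float(_median(idents)),
        min=min(idents),
        max=max(idents),
        n_pairs=len(pairs),
        mode=mode,
    )


def homology_gate(stats: GroupIdentityStats, threshold: float = 25.0) -> str:
    """``"include"`` iff both mean and median identity exceed the threshold —
    below it, alignment-based phylogenetics is unreliable and the group is
    excluded."""
    return "include" if (stats.mean > threshold and stats.median > threshold) else "exclude"
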