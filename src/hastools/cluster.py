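"""Hit filtering, redundancy reduction, Markov clustering, and cluster merging.

This is the cascade that turns a raw homology-search hit table into the
analysis sequence set: hits are gated on local identity (strictly > 25%) and
E-value (≤ 1e-10), survivors are clustered with the Markov clustering (MCL)
algorithm on a similarity graph, clusters whose mean AND median inter-cluster
global identity both exceed the homology cut-off are merged (connected
components of the merge graph), and the set is made non-redundant with a
greedy 90%-identity reduction.

The MCL iteration is implemented here directly (expansion = matrix squaring,
inflation = entrywise power + column renormalization, pruning of small
entries) because no installed package provides it; clusters are read off the
converged matrix as connected components of its nonzero structure. Greedy
reduction is exact (all-pairs global identity via the alignment module), not
k-mer screened — corpora at this scale make exact computation affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean as _mean, median as _median

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .pairwise_align import nw_align
from .records import ProteinRecord

__all__ = [
    "HitRecord", "ClusterSet", "read_blast_tab", "filter_hits",
    "greedy_reduce", "mcl_cluster", "merge_clusters", "similarity_from_hits",
    "write_clusters_tsv",
]

BLAST_TAB_COLUMNS = [
    "query_id", "subject_id", "local_identity_pct", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    local_identity_pct: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.local_identity_pct <= 100.0):
            raise ValueError("identity out of [0, 100]")


@dataclass
class ClusterSet:
    clusters: list[set[str]]
    representatives: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cl, rep in zip(self.clusters, self.representatives):
            if rep not in cl:
                raise ValueError(f"representative {rep!r} not in its cluster")
            if cl & seen:
                raise ValueError("clusters overlap")
            seen |= cl

    @property
    def members(self) -> set[str]:
        return set().union(*self.clusters) if self.clusters else set()

    def cluster_of(self, member: str) -> int:
        for i, cl in enumerate(self.clusters):
            if member in cl:
                return i
        raise KeyError(member)


def read_blast_tab(path) -> list[HitRecord]:
    """Read a 12-column blast-tab hit table."""
    df = pd.read_csv(path, sep="\t", names=BLAST_TAB_COLUMNS, comment="#")
    hits = []
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            hits.append(HitRecord(
                query_id=str(row.query_id), subject_id=str(row.subject_id),
                local_identity_pct=float(row.local_identity_pct),
                alignment_length=int(row.alignment_length),
                evalue=float(row.evalue), bitscore=float(row.bitscore),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed hit table row {i}: {exc}") from exc
    return hits


def filter_hits(
    hits: list[HitRecord],
    min_identity: float = 25.0,
    max_evalue: float = 1e-10,
) -> list[HitRecord]:
    """Keep hits with identity strictly above ``min_identity`` and E-value at
    or below ``max_evalue``. Idempotent."""
    return [h for h in hits
            if h.local_identity_pct > min_identity and h.evalue <= max_evalue]


def greedy_reduce(
    seqs: list[ProteinRecord],
    threshold: float = 0.90,
    **align_kwargs,
) -> ClusterSet:
    """Greedy incremental redundancy reduction at a global-identity cut-off.

    Sequences are visited longest-first (ties by id); each joins the first
    existing representative it matches at ``threshold`` global identity or
    founds a new cluster. Representatives therefore cover all members at
    >= threshold identity.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    order = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    reps: list[ProteinRecord] = []
    clusters: list[set[str]] = []
    for rec in order:
        placed = False
        for i, rep in enumerate(reps):
            ident = nw_align(rec.seq, rep.seq, **align_kwargs).identity_pct
            if ident >= 100.0 * threshold:
                clusters[i].add(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            clusters.append({rec.id})
    return ClusterSet(clusters, [r.id for r in reps])


def mcl_cluster(
    similarity,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    node_ids: list[str] | None = None,
) -> ClusterSet:
    """Markov clustering on a non-negative symmetric similarity matrix.

    Self-loops are added, columns normalized to a stochastic matrix, then
    expansion (M @ M) alternates with inflation (entrywise power ``inflation``
    followed by column renormalization) and pruning of entries below ``prune``
    until the matrix changes by less than ``tol``. Clusters are the connected
    components of the converged matrix's nonzero structure.
    """
    M = sp.csr_matrix(similarity, dtype=float) if not sp.issparse(similarity) \
        else similarity.tocsr().astype(float)
    n, m = M.shape
    if n != m:
        raise ValueError(f"similarity matrix must be square, got {n}x{m}")
    if (M.data < 0).any():
        raise ValueError("similarity entries must be non-negative")
    M = M + sp.eye(n, format="csr")
    M = _col_normalize(M)
    for _ in range(max_iter):
        prev = M.copy()
        M = M @ M                      # expansion
        M = M.power(inflation)         # inflation
        M = _col_normalize(M)
        M.data[M.data < prune] = 0.0   # pruning
        M.eliminate_zeros()
        M = _col_normalize(M)
        if abs(M - prev).max() < tol:
            break
    graph = (M + M.T) > 0
    n_comp, labels = connected_components(graph, directed=False)
    ids = node_ids if node_ids is not None else [str(i) for i in range(n)]
    clusters = [set() for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].add(ids[i])
    reps = [min(cl) for cl in clusters]
    return ClusterSet(clusters, reps)


def _col_normalize(M: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    D = sp.diags(1.0 / sums)
    return (M @ D).tocsr()


def similarity_from_hits(
    hits: list[HitRecord],
    node_ids: list[str],
    transform: str = "bitscore",
) -> sp.csr_matrix:
    """Build the MCL input graph from a hit table.

    ``"bitscore"``: mean of the two directed bitscores, max-normalized;
    ``"neglog_evalue"``: -log10(E) capped at 200; ``"identity"``: percent/100.
    """
    index = {x: i for i, x in enumerate(node_ids)}
    n = len(node_ids)
    acc: dict[tuple[int, int], list[float]] = {}
    for h in hits:
        if h.query_id not in index or h.subject_id not in index:
            continue
        i, j = index[h.query_id], index[h.subject_id]
        if i == j:
            continue
        if transform == "bitscore":
            v = h.bitscore
        elif transform == "neglog_evalue":
            v = min(200.0, -np.log10(h.evalue)) if h.evalue > 0 else 200.0
        elif transform == "identity":
            v = h.local_identity_pct / 100.0
        else:
            raise ValueError(f"unknown transform {transform!r}")
        acc.setdefault((min(i, j), max(i, j)), []).append(v)
    rows, cols, vals = [], [], []
    for (i, j), vs in acc.items():
        v = float(np.mean(vs))
        rows += [i, j]
        cols += [j, i]
        vals += [v, v]
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    if transform == "bitscore" and M.nnz:
        M = M / M.max()
    return sp.csr_matrix(M)


def merge_clusters(
    cs: ClusterSet,
    seqs: dict[str, str],
    min_identity: float = 25.0,
    rule: str = "both",
    **align_kwargs,
) -> ClusterSet:
    """Merge clusters whose inter-cluster global identities pass the homology
    cut-off: an edge joins two clusters when mean and median identity over all
    cross pairs both exceed ``min_identity`` (``rule="any"`` relaxes to
    either); merged clusters are the connected components (transitive)."""
    if rule not in ("both", "any"):
        raise ValueError(f"unknown rule {rule!r}")
    k = len(cs.clusters)
    adj = sp.lil_matrix((k, k), dtype=bool)
    members = [sorted(cl) for cl in cs.clusters]
    for a in range(k):
        for b in range(a + 1, k):
            idents = [
                nw_align(seqs[x], seqs[y], **align_kwargs).identity_pct
                for x in members[a] for y in members[b]
            ]
            m, md = _mean(idents), _median(idents)
            hit = (m > min_identity and md > min_identity) if rule == "both" \
                else (m > min_identity or md > min_identity)
            if hit:
                adj[a, b] = True
    n_comp, labels = connected_components(adj.tocsr(), directed=False)
    merged = [set() for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        merged[lab] |= cs.clusters[i]
    reps = []
    for lab in range(n_comp):
        cands = [cs.representatives[i] for i in range(k) if labels[i] == lab]
        reps.append(min(cands))
    return ClusterSet(merged, reps)


def write_clusters_tsv(cs: ClusterSet, path) -> None:
    rows = []
    for i, (cl, rep) in enumerate(zip(cs.clusters, cs.representatives)):
        for m in sorted(cl):
            rows.append((f"cluster{i:04d}", m, int(m == rep)))
    pd.DataFrame(rows, columns=["cluster_id", "member_id", "is_representative"]) \
        .to_csv(path, sep="\t", index=False)
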