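"""Tree I/O, MAD rooting, monophyly, minimum-transition counts, verification.

Trees are consumed as Newick inputs (ML inference itself is out of scope) and
handled as :class:`dendropy.Tree` objects. Two pieces are authored here
because no installed package provides them:

* **Minimal ancestor deviation (MAD) rooting.** For a candidate root at
  position x on a branch, every leaf pair (b, c) deviates from the molecular
  clock by ``r = |2 d(a, b) / d(b, c) - 1``, where ``a`` is the pair's
  ancestor induced by that root. The branch score is the root-mean-square of
  the deviations over all pairs, minimized analytically in x per branch; the
  tree is rooted at the global minimizer. Zero-length branches are perturbed
  by a small epsilon.

* **Fitch small parsimony** for the minimum number of label transitions on a
  tree (e.g. independent cysteine-pair losses); the count is root-invariant
  under symmetric costs.

Type verification mirrors "classification verified by phylogenetic
placement": each leaf's assigned type is compared with the majority type of
its k nearest leaves by patristic distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TransitionReport", "read_newick", "write_newick", "mad_root",
    "is_monophyletic", "min_transitions", "verify_types",
    "patristic_distance_matrix",
]

_EPS = 1e-8


@dataclass(frozen=True)
class TransitionReport:
    count: int
    labeling: dict[str, str]  # node key -> state (one optimal assignment)
    label: str | None = None


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; duplicate leaf labels are rejected."""
    from dendropy.dataio.newickreader import NewickReader
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


# --------------------------------------------------------------------------
# MAD rooting
# --------------------------------------------------------------------------

def _adjacency(tree: dendropy.Tree):
    """Undirected adjacency with per-edge lengths (None/0 -> eps)."""
    adj: dict[int, list[tuple[int, float, object]]] = {}
    nodes = {}
    for nd in tree.preorder_node_iter():
        nodes[id(nd)] = nd
        if nd.parent_node is not None:
            ln = nd.edge.length
            ln = _EPS if ln is None or ln <= 0 else float(ln)
            adj.setdefault(id(nd.parent_node), []).append((id(nd), ln, nd))
            adj.setdefault(id(nd), []).append((id(nd.parent_node), ln, nd))
    return adj, nodes


def _node_leaf_distances(tree: dendropy.Tree):
    """dist[node_id][leaf_index] via one BFS per leaf."""
    adj, nodes = _adjacency(tree)
    leaves = [nd for nd in tree.leaf_node_iter()]
    dist = {nid: np.zeros(len(leaves)) for nid in nodes}
    for li, leaf in enumerate(leaves):
        seen = {id(leaf)}
        stack = [(id(leaf), 0.0)]
        while stack:
            nid, d = stack.pop()
            dist[nid][li] = d
            for mid, ln, _ in adj.get(nid, []):
                if mid not in seen:
                    seen.add(mid)
                    stack.append((mid, d + ln))
    return dist, leaves


def mad_root(tree: dendropy.Tree) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Root at the branch position minimizing the RMS relative ancestor
    deviation over all leaf pairs. Returns the rooted tree and the per-branch
    score table (branch keyed by the leaf set below it)."""
    work = tree.clone(depth=1)
    if len(work.seed_node.child_nodes()) == 2:
        work.deroot()
    leaves_all = [nd for nd in work.leaf_node_iter()]
    n = len(leaves_all)
    if n < 3:
        raise ValueError("MAD rooting needs at least 3 leaves")
    dist, leaves = _node_leaf_distances(work)
    leaf_index = {id(lf): i for i, lf in enumerate(leaves)}
    labels = [lf.taxon.label for lf in leaves]

    # pairwise leaf distances
    D = np.zeros((n, n))
    for i, lf in enumerate(leaves):
        D[i] = dist[id(lf)]
    iu, ju = np.triu_indices(n, k=1)

    best = None
    rows = []
    for child in work.preorder_node_iter():
        if child.parent_node is None:
            continue
        parent = child.parent_node
        length = child.edge.length
        length = _EPS if length is None or length <= 0 else float(length)
        side = np.zeros(n, dtype=bool)  # True = below child (child side)
        for lf in child.leaf_iter():
            side[leaf_index[id(lf)]] = True
        dv = dist[id(child)]   # distances from child node
        du = dist[id(parent)]  # distances from parent node

        pair_side_i = side[iu]
        pair_side_j = side[ju]
        spanning = pair_side_i != pair_side_j
        both_v = pair_side_i & pair_side_j
        both_u = ~pair_side_i & ~pair_side_j
        d_pair = D[iu, ju]

        # same-side deviations: |d(w,b) - d(w,c)| / d(b,c), w = near-side node
        sq = 0.0
        if both_v.any():
            r = np.abs(dv[iu[both_v]] - dv[ju[both_v]]) / d_pair[both_v]
            sq += float((r ** 2).sum())
        if both_u.any():
            r = np.abs(du[iu[both_u]] - du[ju[both_u]]) / d_pair[both_u]
            sq += float((r ** 2).sum())

        # spanning pairs: r(x) = 2 (d(v,b) + x) / d(b,c) - 1, b on child side
        d_vb = np.where(pair_side_i[spanning],
                        dv[iu[spanning]], dv[ju[spanning]])
        dp = d_pair[spanning]
        a = 2.0 / dp
        c = 2.0 * d_vb / dp - 1.0
        denom = float((a ** 2).sum())
        x = float(-(a * c).sum() / denom) if denom > 0 else 0.0
        x = min(max(x, 0.0), length)
        r = a * x + c
        sq += float((r ** 2).sum())

        score = float(np.sqrt(sq / len(d_pair)))
        below_labels = frozenset(lab for lab, s in zip(labels, side) if s)
        rows.append((sorted(below_labels), length, x, score))
        if best is None or score < best[0]:
            best = (score, child, x, length)

    scores = pd.DataFrame(rows, columns=["below", "length", "rho", "score"]) \
        .sort_values("score").reset_index(drop=True)

    _score, child, x, length = best
    rooted = _reroot_on_edge(work, child, x)
    return rooted, scores


def _reroot_on_edge(tree: dendropy.Tree, child: dendropy.Node,
                    x: float) -> dendropy.Tree:
    """Insert a root node on the edge above ``child`` at distance x from it."""
    parent = child.parent_node
    x = min(max(x, 0.0), child.edge.length or _EPS)
    new_node = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(new_node)
    new_node.edge.length = (child.edge.length or _EPS) - x
    new_node.add_child(child)
    child.edge.length = x
    tree.reseed_at(new_node, update_bipartitions=False,
                   collapse_unrooted_basal_bifurcation=False)
    tree.is_rooted = True
    return tree


# --------------------------------------------------------------------------
# monophyly / parsimony / verification
# --------------------------------------------------------------------------

def is_monophyletic(tree: dendropy.Tree, leaf_set) -> tuple[bool, int]:
    """True iff some clade's leaf set equals ``leaf_set`` exactly; also the
    size of the smallest clade containing the set (rooted semantics)."""
    leaf_set = set(leaf_set)
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = leaf_set - all_labels
    if unknown:
        raise KeyError(f"unknown leaves: {sorted(unknown)}")
    if not leaf_set:
        raise ValueError("empty leaf set")
    tree.is_rooted = True  # rooted semantics: the seed node is the root
    taxa = [t for t in tree.taxon_namespace if t.label in leaf_set]
    mrca = tree.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == leaf_set, len(clade)


def min_transitions(tree: dendropy.Tree, leaf_labels: dict[str, str],
                    label: str | None = None) -> TransitionReport:
    """Fitch minimum number of label changes, plus one optimal labeling.

    Every leaf must be labeled; the count is invariant to root placement."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    missing = [lf.taxon.label for lf in leaves
               if lf.taxon.label not in leaf_labels]
    if missing:
        raise KeyError(f"unlabeled leaves: {sorted(missing)}")

    count = 0
    sets: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[id(nd)] = frozenset({leaf_labels[nd.taxon.label]})
            continue
        child_sets = [sets[id(c)] for c in nd.child_nodes()]
        acc = child_sets[0]
        for cs in child_sets[1:]:  # left fold; plain Fitch on binary nodes
            inter = acc & cs
            if inter:
                acc = inter
            else:
                acc = acc | cs
                count += 1
        sets[id(nd)] = acc
    # top-down pass for one optimal labeling
    labeling: dict[str, str] = {}
    states: dict[int, str] = {}
    for i, nd in enumerate(tree.preorder_node_iter()):
        if nd.parent_node is None:
            states[id(nd)] = min(sets[id(nd)])
        else:
            p = states[id(nd.parent_node)]
            states[id(nd)] = p if p in sets[id(nd)] else min(sets[id(nd)])
        key = nd.taxon.label if nd.is_leaf() else f"node{i}"
        labeling[key] = states[id(nd)]
    return TransitionReport(count=count, labeling=labeling, label=label)


def patristic_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric leaf-to-leaf path-length matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    labels = sorted(taxa)
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            M[i, j] = M[j, i] = d
    return pd.DataFrame(M, index=labels, columns=labels)


def verify_types(
    tree: dendropy.Tree,
    assignments: dict[str, str],
    k: int = 5,
    ambiguous: set[str] | None = None,
) -> pd.DataFrame:
    """Compare each leaf's assigned type with the majority type of its k
    nearest leaves (patristic distance).

    Rows: (leaf, assigned, majority, votes, margin, status, resolved).
    ``status``: "ok" (agreement), "conflict" (assigned differs from a clear
    majority), "unresolved" (tied neighborhood vote). Ambiguous assignments
    are resolved to the neighborhood majority when its margin over the
    runner-up is at least k - 1 votes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ambiguous = ambiguous or set()
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = [x for x in leaves if x not in assignments]
    if missing:
        raise KeyError(f"no assignment for leaves: {missing}")
    M = patristic_distance_matrix(tree)
    rows = []
    for leaf in leaves:
        others = M.loc[leaf].drop(leaf).sort_values(kind="stable")
        nn = list(others.index[:k])
        votes = pd.Series([assignments[x] for x in nn]).value_counts()
        top = votes.iloc[0]
        tied = (votes == top).sum() > 1
        majority = None if tied else votes.index[0]
        margin = int(top - (votes.iloc[1] if len(votes) > 1 else 0))
        assigned = assignments[leaf]
        resolved = assigned
        if tied:
            status = "unresolved"
        elif majority == assigned:
            status = "ok"
        else:
            status = "conflict"
            if leaf in ambiguous and margin >= k - 1:
                resolved = majority
        rows.append((leaf, assigned, majority, int(top), margin, status,
                     resolved))
    return pd.DataFrame(rows, columns=["leaf", "assigned", "majority",
                                       "votes", "margin", "status", "resolved"])
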