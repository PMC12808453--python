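"""Gene-neighborhood (synteny) analysis and taxonomic distribution matrices.

The neighborhood of a focal HAS gene is the window of 5 genes upstream and 5
downstream on the same contig (fewer at contig edges), ordered by start
coordinate and strand-agnostic. Co-occurrence of a neighbor family (heme o
synthase, cytochrome c oxidase subunits, SCO1, ...) is presence-based: a
window counts once however many copies it contains, and the denominator is
the number of HAS records of the type — the convention behind printed
fractions like 2,140/2,339 (91.5%). A fusion protein counts as carrying its
partner family inside its own window.

Distribution matrices report, per lineage (phylum, or class within
Euryarchaeota), the percentage of the lineage's assemblies containing at
least one record of each type; lineage sets with no hits can be collapsed
into a single row for compact display.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import percent
from .records import split_labels

__all__ = [
    "SyntenyContext", "extract_window", "cooccurrence_table",
    "distribution_matrix", "sole_has_fraction",
]


@dataclass(frozen=True)
class SyntenyContext:
    focal_id: str
    focal_type: str | None
    focal_annotation: str
    #: (offset in -5..+5 excluding 0, gene_id, annotation, strand)
    neighbors: tuple[tuple[int, str, str, str], ...]

    def labels(self, include_focal: bool = True) -> set[str]:
        out: set[str] = set()
        for _off, _gid, ann, _strand in self.neighbors:
            out |= set(split_labels(ann))
        if include_focal:
            out |= set(split_labels(self.focal_annotation))
        return out


def extract_window(
    gene_table: pd.DataFrame,
    focal_id: str,
    k: int = 5,
    focal_type: str | None = None,
) -> SyntenyContext:
    """Up to ``k`` genes on each side of the focal gene, by start-coordinate
    order on its contig; truncated at contig edges."""
    if k < 0:
        raise ValueError("k must be >= 0")
    row = gene_table[gene_table.gene_id == focal_id]
    if row.empty:
        raise KeyError(f"focal gene {focal_id!r} not in table")
    row = row.iloc[0]
    contig = gene_table[
        (gene_table.assembly == row.assembly) & (gene_table.contig == row.contig)
    ].sort_values("start").reset_index(drop=True)
    pos = int(contig.index[contig.gene_id == focal_id][0])
    neighbors = []
    for off in range(-k, k + 1):
        if off == 0:
            continue
        q = pos + off
        if 0 <= q < len(contig):
            g = contig.iloc[q]
            neighbors.append((off, g.gene_id, g.annotation, g.strand))
    return SyntenyContext(focal_id, focal_type, row.annotation, tuple(neighbors))


def cooccurrence_table(
    contexts_by_type: dict[str, list[SyntenyContext]],
    target_labels: list[str],
    count_focal_fusion: bool = True,
) -> pd.DataFrame:
    """Per-type presence fractions of each target neighbor family.

    Rows: (type, label, n_with, n_total, percent) with percent to one decimal,
    half-up. ``count_focal_fusion`` lets a fusion record satisfy co-occurrence
    with its own fused partner label.
    """
    if not contexts_by_type:
        raise ValueError("no synteny contexts")
    rows = []
    for t, contexts in sorted(contexts_by_type.items()):
        n_total = len(contexts)
        for label in target_labels:
            n_with = sum(
                1 for c in contexts
                if label in c.labels(include_focal=count_focal_fusion)
            )
            rows.append((t, label, n_with, n_total,
                         percent(n_with, n_total, 1) if n_total else 0.0))
    return pd.DataFrame(rows, columns=["type", "label", "n_with", "n_total",
                                       "percent"])


def distribution_matrix(
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame,
    collapse_rules: dict[str, list[str]] | None = None,
    euryarchaeota_by_class: bool = True,
) -> pd.DataFrame:
    """Percent of each lineage's assemblies containing >= 1 record per type.

    ``assignments`` needs columns (record_id, assembly, type); ``taxonomy``
    needs (assembly, domain, phylum, class). Lineage = phylum, except within
    Euryarchaeota where classes (e.g. Halobacteria) are resolved separately.
    ``collapse_rules`` maps a display name to a set of lineages merged into
    one row when none of them has any hit.
    """
    missing = sorted(set(assignments.assembly) - set(taxonomy.assembly))
    if missing:
        raise ValueError(f"assemblies missing from taxonomy: {missing}")
    tax = taxonomy.copy()
    if euryarchaeota_by_class:
        is_eury = tax.phylum == "Euryarchaeota"
        tax["lineage"] = tax.phylum.where(~is_eury, tax.phylum + ":" + tax["class"])
    else:
        tax["lineage"] = tax.phylum
    merged = assignments.merge(tax[["assembly", "lineage"]], on="assembly")
    types = sorted(assignments["type"].unique())
    lineages = sorted(tax.lineage.unique())
    n_assemblies = tax.groupby("lineage").assembly.nunique()

    cells = {}
    for lin in lineages:
        row = {}
        sub = merged[merged.lineage == lin]
        for t in types:
            n_hit = sub[sub["type"] == t].assembly.nunique()
            row[t] = percent(n_hit, int(n_assemblies[lin]), 1)
        cells[lin] = row
    mat = pd.DataFrame.from_dict(cells, orient="index", columns=types)
    mat.index.name = "lineage"
    mat["n_assemblies"] = n_assemblies

    if collapse_rules:
        for name, group in collapse_rules.items():
            present = [g for g in group if g in mat.index]
            if not present:
                continue
            if mat.loc[present, types].to_numpy().sum() == 0:
                n = int(mat.loc[present, "n_assemblies"].sum())
                mat = mat.drop(index=present)
                mat.loc[name] = [0.0] * len(types) + [n]
    return mat


def sole_has_fraction(
    assignments: pd.DataFrame,
    has_type: str,
) -> tuple[int, int, int]:
    """Fraction of records of ``has_type`` that are the only HAS-family record
    in their assembly; returns (n_sole, n_total, integer percent)."""
    per_assembly = assignments.groupby("assembly").record_id.count()
    sub = assignments[assignments["type"] == has_type]
    n_total = len(sub)
    n_sole = int(sum(per_assembly[a] == 1 for a in sub.assembly))
    pct = int(percent(n_sole, n_total, 0)) if n_total else 0
    return n_sole, n_total, pct
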