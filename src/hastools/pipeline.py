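"""End-to-end orchestration: stage sequencing, manifests, and the text report.

Stages run in a fixed order (filter → reduce → cluster → topology → typing →
motifs → synteny → distribution → phylo-verify), each reading the previous
stage's TSVs and logging row counts into ``manifest.json``. A run is
deterministic for a given config + inputs + seed: outputs are byte-identical
except the manifest timestamp. Stages whose inputs are absent (e.g. no hit
table for the filter stage on a simulated corpus) are recorded as skipped
rather than failing, unless explicitly required.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as _cluster
from . import has_typing as _typing
from . import phylo as _phylo
from . import synteny_distribution as _synteny
from . import topology as _topology
from .profiles import HAS_LABEL, NEIGHBOR_FAMILIES, default_profiles
from .records import ProteinRecord, split_labels
from .synthetic_data import (
    CorpusConfig,
    default_corpus_counts,
    gen_corpus,
    gen_hos_domain,
    gen_labeled_tree,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report"]

STAGE_ORDER = ["filter", "reduce", "cluster", "topology", "typing", "motifs",
               "synteny", "distribution", "phylo_verify"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(v, dict):
            v = _from_dict(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class Thresholds:
    min_identity: float = 25.0        # local-hit and homology gates
    max_evalue: float = 1e-10
    reduce_threshold: float = 0.90
    inflation: float = 2.0
    cys_min_gap: int = 2
    cys_max_gap: int = 12
    margin: float = 2.0
    min_length: int = 100
    window_k: int = 5
    knn_k: int = 5


@dataclass
class Inputs:
    fasta: str | None = None
    genes: str | None = None
    topology: str | None = None
    taxonomy: str | None = None
    hits: str | None = None
    tree: str | None = None
    truth: str | None = None


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    corpus_scale: int = 50      # divide the published census counts by this
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    inputs: Inputs = field(default_factory=Inputs)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return _from_dict(cls, data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _read_fasta(path) -> list[ProteinRecord]:
    from Bio import SeqIO
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels = tuple(split_labels(rec.description.split(None, 1)[1])) \
            if " " in rec.description else ()
        out.append(ProteinRecord(id=rec.id, seq=str(rec.seq), labels=labels))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest (also written to
    ``out_dir/manifest.json``). A failing stage aborts with the stage named;
    its partial output keeps a ``.partial`` suffix."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "versions": _versions()}
    profiles = default_profiles()

    if config.simulate:
        sim_dir = out / "sim"
        cc = CorpusConfig(counts=default_corpus_counts(config.corpus_scale))
        corpus = gen_corpus(cc, config.seed, out_dir=sim_dir)
        # a clean labeled tree over the HAS records for phylogeny-side checks
        assign = dict(zip(corpus.truth.record_id, corpus.truth.true_type))
        tree, _ = gen_labeled_tree(assign, "clean", config.seed + 1)
        (sim_dir / "tree.nwk").write_text(_phylo.write_newick(tree) + "\n")
        config.inputs = Inputs(
            fasta=str(sim_dir / "proteins.fasta"),
            genes=str(sim_dir / "genes.tsv"),
            topology=str(sim_dir / "topology.tsv"),
            taxonomy=str(sim_dir / "taxonomy.tsv"),
            tree=str(sim_dir / "tree.nwk"),
            truth=str(sim_dir / "truth.tsv"),
        )
        manifest["stages"]["simulate"] = {
            "n_records": len(corpus.records),
            "n_has": len(corpus.truth),
        }

    inp = config.inputs
    th = config.thresholds
    if not inp.fasta:
        raise PipelineError("typing", "no FASTA input (enable simulate or set inputs.fasta)")
    records = _read_fasta(inp.fasta)
    by_id = {r.id: r for r in records}
    has_ids = [r.id for r in records if HAS_LABEL in r.labels]
    genes = pd.read_csv(inp.genes, sep="\t") if inp.genes else None
    truth = pd.read_csv(inp.truth, sep="\t") if inp.truth else None

    def stage_on(name: str) -> bool:
        return name in config.stages

    # ---- filter / reduce / cluster --------------------------------------
    if stage_on("filter"):
        if inp.hits:
            hits = _cluster.read_blast_tab(inp.hits)
            kept = _cluster.filter_hits(hits, th.min_identity, th.max_evalue)
            pd.DataFrame([h.__dict__ for h in kept]).to_csv(
                out / "filtered_hits.tsv", sep="\t", index=False)
            manifest["stages"]["filter"] = {"n_in": len(hits), "n_out": len(kept)}
        else:
            manifest["stages"]["filter"] = {"skipped": "no hit table"}

    if stage_on("reduce"):
        has_records = [by_id[i] for i in has_ids]
        cs = _cluster.greedy_reduce(has_records, th.reduce_threshold)
        _cluster.write_clusters_tsv(cs, out / "reduced_clusters.tsv")
        manifest["stages"]["reduce"] = {"n_in": len(has_records),
                                        "n_out": len(cs.clusters)}

    if stage_on("cluster"):
        if inp.hits:
            hits = _cluster.filter_hits(_cluster.read_blast_tab(inp.hits),
                                        th.min_identity, th.max_evalue)
            ids = sorted({h.query_id for h in hits} | {h.subject_id for h in hits})
            sim = _cluster.similarity_from_hits(hits, ids)
            cs = _cluster.mcl_cluster(sim, inflation=th.inflation, node_ids=ids)
            _cluster.write_clusters_tsv(cs, out / "mcl_clusters.tsv")
            manifest["stages"]["cluster"] = {"n_in": len(ids),
                                             "n_out": len(cs.clusters)}
        else:
            manifest["stages"]["cluster"] = {"skipped": "no hit table"}

    # ---- topology --------------------------------------------------------
    topologies: dict[str, _topology.Topology] = {}
    if stage_on("topology"):
        if inp.topology:
            topologies = _topology.read_topology_tsv(
                inp.topology, {r.id: len(r.seq) for r in records})
        else:
            for i in has_ids:
                topologies[i] = _topology.predict_tm(by_id[i].seq)
            _topology.write_topology_tsv(out / "topology_predicted.tsv",
                                         topologies)
        manifest["stages"]["topology"] = {"n_out": len(topologies)}

    # ---- typing ----------------------------------------------------------
    assignments_df = None
    refs: dict[str, _typing.MotifReference] = {}
    if stage_on("typing"):
        try:
            panels = _typing.build_reference_panels(profiles)
            refs = {t: _typing.motif_reference(p) for t, p in profiles.items()}
            hos_panel = [gen_hos_domain(s) for s in range(3)]
            has_panel = [panels[t][0] for t in sorted(panels)]
            asg_rows = []
            assembly_of = dict(zip(genes.gene_id, genes.assembly)) if genes is not None else {}
            for i in has_ids:
                rec = by_id[i]
                topo = topologies.get(i)
                if topo is None:
                    raise PipelineError("typing", f"no topology for {i}")
                loops = _topology.extract_loops(topo, min(len(rec.seq), 10 ** 9))
                pairs = _typing.detect_cys_pairs(loops, rec.seq,
                                                 th.cys_min_gap, th.cys_max_gap)
                mres = _typing.locate_motifs(rec, topo)
                h3 = (mres.mirror or {}).get("H3") if mres.found else None
                a = _typing.assign_type(rec, topo, pairs, panels,
                                        margin=th.margin, h3_residue=h3,
                                        min_length=th.min_length)
                fusion = _typing.detect_fusion(
                    rec, {"HAS": has_panel, "HOS": hos_panel}) \
                    if len(rec.labels) > 1 or len(rec.seq) > 450 else "single"
                asg_rows.append((i, assembly_of.get(i, i), a.type, a.tm_count,
                                 a.cys_ecl1, a.cys_ecl3, a.nearest_ref,
                                 a.mean_identity, ",".join(sorted(a.flags)),
                                 fusion))
            assignments_df = pd.DataFrame(asg_rows, columns=[
                "record_id", "assembly", "type", "tm_count", "cys_ecl1",
                "cys_ecl3", "nearest_ref", "mean_identity", "flags", "fusion"])
            assignments_df.to_csv(out / "assignments.tsv", sep="\t", index=False)
            manifest["stages"]["typing"] = {
                "n_out": len(assignments_df),
                "per_type": assignments_df["type"].value_counts().to_dict(),
                "n_fusion": int((assignments_df.fusion == "fusion").sum()),
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("typing", str(exc)) from exc

    # ---- motifs ----------------------------------------------------------
    if stage_on("motifs"):
        if assignments_df is None:
            raise PipelineError("motifs", "typing stage did not run")
        results: dict[str, list] = {}
        for row in assignments_df.itertuples():
            if row.type == "unassigned":
                continue
            ref = refs.get(row.type)
            mres = _typing.locate_motifs(by_id[row.record_id],
                                         topologies[row.record_id], ref)
            results.setdefault(row.type, []).append(mres)
        table = _typing.motif_frequency_table(results)
        table.to_csv(out / "motif_frequencies.tsv", sep="\t", index=False)
        manifest["stages"]["motifs"] = {"n_rows": len(table)}

    # ---- synteny ---------------------------------------------------------
    if stage_on("synteny"):
        if genes is None:
            manifest["stages"]["synteny"] = {"skipped": "no gene table"}
        else:
            contexts: dict[str, list] = {}
            for row in assignments_df.itertuples():
                if row.type == "unassigned":
                    continue
                ctx = _synteny.extract_window(genes, row.record_id,
                                              th.window_k, row.type)
                contexts.setdefault(row.type, []).append(ctx)
            cooc = _synteny.cooccurrence_table(contexts, list(NEIGHBOR_FAMILIES))
            cooc.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
            manifest["stages"]["synteny"] = {"n_rows": len(cooc)}

    # ---- distribution ----------------------------------------------------
    if stage_on("distribution"):
        if not inp.taxonomy:
            raise PipelineError("distribution", "no taxonomy table configured")
        taxonomy = pd.read_csv(inp.taxonomy, sep="\t")
        assigned = assignments_df[assignments_df["type"] != "unassigned"]
        mat = _synteny.distribution_matrix(
            assigned[["record_id", "assembly", "type"]], taxonomy)
        mat.to_csv(out / "distribution_matrix.tsv", sep="\t")
        manifest["stages"]["distribution"] = {"n_lineages": len(mat)}

    # ---- phylogeny-side verification ------------------------------------
    if stage_on("phylo_verify"):
        if not inp.tree:
            manifest["stages"]["phylo_verify"] = {"skipped": "no tree"}
        else:
            tree = _phylo.read_newick(Path(inp.tree).read_text())
            amap = dict(zip(assignments_df.record_id, assignments_df["type"]))
            leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
            amap = {k: v for k, v in amap.items() if k in leaves}
            conflicts = _phylo.verify_types(tree, amap, k=th.knn_k)
            conflicts.to_csv(out / "phylo_conflicts.tsv", sep="\t", index=False)
            manifest["stages"]["phylo_verify"] = {
                "n_leaves": len(conflicts),
                "n_conflicts": int((conflicts.status == "conflict").sum()),
            }

    if truth is not None and assignments_df is not None:
        merged = truth.merge(assignments_df, on="record_id")
        manifest["recovery"] = {
            "n": len(merged),
            "n_correct": int((merged.true_type == merged["type"]).sum()),
        }

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _versions() -> dict:
    import Bio
    import dendropy
    import numpy
    import pandas
    from . import __version__
    return {"hastools": __version__, "numpy": numpy.__version__,
            "pandas": pandas.__version__, "biopython": Bio.__version__,
            "dendropy": dendropy.__version__}


def report(output_dir) -> str:
    """Human-readable digest of a completed run."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {output_dir}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    missing = [s for s in ("typing",) if s not in manifest["stages"]]
    if missing:
        raise ValueError(f"incomplete run; missing stages: {missing}")
    lines = [f"hastools pipeline report (seed {manifest['seed']})", ""]
    per_type = manifest["stages"]["typing"].get("per_type", {})
    total = sum(per_type.values())
    lines.append("Type counts:")
    for t in sorted(per_type):
        lines.append(f"  {t:12s} {per_type[t]:6d}")
    lines.append(f"  {'total':12s} {total:6d}")
    cooc_path = out / "cooccurrence.tsv"
    if cooc_path.exists():
        cooc = pd.read_csv(cooc_path, sep="\t")
        top = cooc[cooc.n_with > 0].sort_values("percent", ascending=False)
        lines.append("")
        lines.append("Neighbor co-occurrence (top rows):")
        for row in top.head(10).itertuples():
            lines.append(f"  type {row.type:4s} {row.label:24s} "
                         f"{row.n_with}/{row.n_total} ({row.percent}%)")
    motif_path = out / "motif_frequencies.tsv"
    if motif_path.exists():
        table = pd.read_csv(motif_path, sep="\t")
        lines.append("")
        lines.append("Motif consensus (>= 50% positions):")
        for row in table[table.percent >= 50].itertuples():
            lines.append(f"  type {row.type:4s} {row.position:4s} "
                         f"{row.residue} {row.percent}%")
    if "phylo_verify" in manifest["stages"] and \
            "n_conflicts" in manifest["stages"]["phylo_verify"]:
        lines.append("")
        lines.append(f"Phylogeny-side conflicts: "
                     f"{manifest['stages']['phylo_verify']['n_conflicts']}")
    if "recovery" in manifest:
        r = manifest["recovery"]
        lines.append(f"Truth recovery: {r['n_correct']}/{r['n']}")
    return "\n".join(lines)
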