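"""End-to-end orchestration of the flowering-transcriptome analysis.

A single config drives the full cascade: detection-call filtering →
fold-change selection → normalization → pattern clustering → per-cluster
GO enrichment → BLAST homolog filtering → Mutual-Rank co-expression
network → module extraction and candidate recruitment → qPCR
concordance. Every threshold defaults to the published analysis values,
so the published-threshold analysis is the zero-config behaviour; a manifest records the
config snapshot, input digests and per-stage row counts. One global
seed fans out to per-stage seeds by fixed offsets so stages stay
decoupled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .clustering import cluster_trends, kmeans_cluster
from .coexpression import (
    annotate_module,
    build_network,
    extract_modules,
    mutual_rank,
    pcc_matrix,
    recruit_candidates,
)
from .differential import (
    FilterMode,
    filter_detected,
    fold_change_select,
    normalize,
    stage_updown_counts,
)
from .enrichment import enrich_set
from .homology import filter_homologs, identify_floral_genes, top_hit_per_query
from .io import (
    CoreGeneList,
    read_blast_tabular,
    read_core_genes,
    read_expression,
    read_go_table,
    write_expression,
    write_network,
)
from .qpcr import CtTable, concordance, rq_profile
from .synthetic import (
    SyntheticConfig,
    generate_ct_table,
    generate_expression,
    generate_go_table,
)

# fixed per-stage seed offsets from the global seed
SEED_CLUSTER = 11
SEED_QPCR = 23


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published thresholds."""

    expression_path: str | None = None
    go_path: str | None = None
    core_genes_path: str | None = None
    blast_path: str | None = None
    blast_lengths_path: str | None = None
    ct_path: str | None = None
    outdir: str = "floralnet_out"
    seed: int = 1

    filter_mode: str = "discard_all_absent"
    fold_threshold: float = 4.0
    signal_floor: float = 1.0
    baseline: str = "first"
    call_threshold: float = 1.0

    k: int = 9
    restarts: int = 10

    alpha: float = 0.01

    homolog_evalue: float = 1e-5
    homolog_identity: float = 80.0
    homolog_coverage: float = 50.0
    cross_evalue: float = 1e-10

    mr_cut: float = 50.0
    recruit_mr: float = 30.0
    recruit_pcc: float = 0.8
    module_method: str = "components_mr30"
    pcc_scale: str = "normalized"

    qpcr_reference: str = "actin"
    qpcr_calibrator: str = "S1"

    def validate(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be ≥ 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for name in ("homolog_evalue", "cross_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("homolog_identity", "homolog_coverage"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must be in [0, 100]")
        if self.mr_cut < 1 or self.recruit_mr < 1:
            raise ValueError("MR cuts must be ≥ 1")
        if not -1 <= self.recruit_pcc <= 1:
            raise ValueError("recruit_pcc must be in [−1, 1]")
        if self.module_method not in ("components_mr30", "greedy-modularity"):
            raise ValueError(f"unknown module_method {self.module_method!r}")
        if self.pcc_scale not in ("raw", "normalized"):
            raise ValueError("pcc_scale must be 'raw' or 'normalized'")
        if self.baseline not in ("first", "previous"):
            raise ValueError("baseline must be 'first' or 'previous'")
        FilterMode(self.filter_mode)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class RunManifest:
    """Provenance record emitted on every run."""

    config: dict
    version: str
    python: str
    started: str
    finished: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, matrix=None, go=None, core=None):
    """Execute the staged analysis and write per-stage artifacts.

    Inputs may be passed in memory (matrix/go/core) or read from the
    configured paths; config errors and missing files surface before any
    computation. Returns (manifest, results dict).
    """
    config.validate()
    outdir = Path(config.outdir)
    for name in ("expression_path", "go_path", "core_genes_path",
                 "blast_path", "blast_lengths_path", "ct_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p} does not exist")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        python=platform.python_version(),
        started=datetime.now(timezone.utc).isoformat(),
    )
    for name in ("expression_path", "go_path", "core_genes_path",
                 "blast_path", "blast_lengths_path", "ct_path"):
        p = getattr(config, name)
        if p is not None:
            manifest.input_digests[name] = _digest(p)

    if matrix is None:
        if config.expression_path is None:
            raise ValueError("no expression matrix: pass one or set expression_path")
        matrix = read_expression(config.expression_path)
    if go is None and config.go_path is not None:
        go = read_go_table(config.go_path, flower_terms=("GO:0009908",))
    if core is None and config.core_genes_path is not None:
        core = read_core_genes(config.core_genes_path)

    results: dict = {}
    manifest.stage_counts["input_genes"] = matrix.n_genes

    # stage 1: detection-call filtering
    detected = filter_detected(matrix, FilterMode(config.filter_mode))
    manifest.stage_counts["detected_genes"] = detected.n_genes

    # stage 2: fold-change selection + normalization + up/down counts
    selected = fold_change_select(
        detected, threshold=config.fold_threshold, floor=config.signal_floor
    )
    floored = np.clip(detected.signal, config.signal_floor, None)
    nm_all = normalize(
        type(detected)(
            gene_ids=detected.gene_ids,
            stage_labels=detected.stage_labels,
            signal=floored,
            call=detected.call,
        )
    )
    selected_order = [g for g in detected.gene_ids if g in selected]
    nm_selected = nm_all.subset(selected_order)
    counts = stage_updown_counts(
        nm_selected,
        call_threshold=config.call_threshold,
        baseline=config.baseline,
    )
    manifest.stage_counts["differential_genes"] = len(selected)
    results["selected"] = selected
    results["updown_counts"] = counts
    with open(outdir / "differential.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in selected_order:
            fh.write(g + "\n")
    with open(outdir / "stage_counts.tsv", "w") as fh:
        fh.write("stage\tup\tdown\n")
        for stage, up, down in counts:
            fh.write(f"{stage}\t{up}\t{down}\n")

    # stage 3: pattern clustering
    assignment = None
    if len(selected_order) >= config.k:
        assignment = kmeans_cluster(
            nm_selected,
            k=config.k,
            seed=config.seed + SEED_CLUSTER,
            restarts=config.restarts,
        )
        results["clusters"] = assignment
        results["trends"] = cluster_trends(assignment)
        manifest.stage_counts["clusters"] = assignment.k
        with open(outdir / "clusters.tsv", "w") as fh:
            fh.write("gene_id\tcluster\n")
            for g in assignment.gene_ids:
                fh.write(f"{g}\t{assignment.label[g]}\n")

    # stage 4: per-cluster GO enrichment against the whole-array background
    if go is not None and assignment is not None:
        background = set(matrix.gene_ids)
        enrichments = {}
        for c in range(1, assignment.k + 1):
            members = set(assignment.members(c))
            enrichments[c] = enrich_set(
                members, background, go, alpha=config.alpha, set_id=f"cluster_{c}"
            )
        results["enrichment"] = enrichments
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("set\tterm\tk\tn\tK\tN\tp\tq\tenriched\n")
            for c in sorted(enrichments):
                for r in enrichments[c]:
                    fh.write(
                        f"{r.set_id}\t{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                        f"{r.p_value:.6g}\t{r.q_value:.6g}\t{int(r.enriched)}\n"
                    )
        manifest.stage_counts["enriched_terms"] = sum(
            1 for rs in enrichments.values() for r in rs if r.enriched
        )

    # stage 5: homolog filtering
    if config.blast_path is not None and core is not None:
        hits = read_blast_tabular(config.blast_path, config.blast_lengths_path)
        calls = filter_homologs(
            top_hit_per_query(hits),
            e_cut=config.homolog_evalue,
            id_cut=config.homolog_identity,
            cov_cut=config.homolog_coverage,
        )
        floral = identify_floral_genes(calls, core)
        results["homolog_calls"] = calls
        results["floral_genes"] = floral
        manifest.stage_counts["homologs_passed"] = sum(c.passed for c in calls)
        manifest.stage_counts["putative_floral_genes"] = len(floral)
        with open(outdir / "homologs.tsv", "w") as fh:
            fh.write("query\tsubject\tevalue\tidentity\tcoverage\tpassed\n")
            for c in calls:
                fh.write(
                    f"{c.query_id}\t{c.subject_id}\t{c.evalue:.3g}\t"
                    f"{c.percent_identity:.2f}\t{c.query_coverage:.2f}\t"
                    f"{int(c.passed)}\n"
                )

    # stage 6: co-expression network, modules, recruitment
    network = None
    if core is not None:
        present = filter_detected(matrix, FilterMode.require_one_present)
        floored = np.clip(present.signal, config.signal_floor, None)
        present = type(present)(
            gene_ids=present.gene_ids,
            stage_labels=present.stage_labels,
            signal=floored,
            call=present.call,
        )
        nm_present = normalize(present)
        if config.pcc_scale == "raw":
            nm_present = dataclasses.replace(
                nm_present, value=np.asarray(present.signal, dtype=float)
            )
        core_present = [g for g in core.genes if g in set(nm_present.gene_ids)]
        if core_present:
            order, pcc = pcc_matrix(nm_present)
            mr = mutual_rank(pcc)
            network = build_network(order, mr, pcc, core, mr_cut=config.mr_cut)
            modules = extract_modules(network, method=config.module_method)
            if go is not None:
                for m in modules:
                    annotate_module(m, go)
            candidates = (
                recruit_candidates(
                    network,
                    go,
                    mr_max=config.recruit_mr,
                    pcc_min=config.recruit_pcc,
                    modules=modules,
                )
                if go is not None
                else []
            )
            results["network"] = network
            results["modules"] = modules
            results["candidates"] = candidates
            manifest.stage_counts["network_nodes"] = network.number_of_nodes()
            manifest.stage_counts["network_edges"] = network.number_of_edges()
            manifest.stage_counts["modules"] = len(modules)
            manifest.stage_counts["candidates"] = len(candidates)
            write_network(network, outdir / "network.tsv", dialect="tsv")
            write_network(network, outdir / "network.graphml", dialect="graphml")
            with open(outdir / "modules.tsv", "w") as fh:
                fh.write("module\tflowering\tmembers\ttop_terms\n")
                for m in modules:
                    top = sorted(
                        m.go_profile, key=lambda t: (-m.go_profile[t], t)
                    )[:3]
                    fh.write(
                        f"{m.module_id}\t{int(m.flowering_flag)}\t"
                        f"{','.join(sorted(m.members))}\t"
                        f"{','.join(f'{t}:{m.go_profile[t]:.2f}' for t in top)}\n"
                    )
            with open(outdir / "candidates.tsv", "w") as fh:
                fh.write("contig\tpartners\tgo_basis\tmodule\n")
                for c in candidates:
                    parts = ";".join(
                        f"{p}(pcc={v:.3f},mr={m_:.2f})" for p, v, m_ in c.partners
                    )
                    fh.write(
                        f"{c.contig_id}\t{parts}\t{','.join(sorted(c.go_basis))}\t"
                        f"{c.module_id if c.module_id is not None else ''}\n"
                    )

    # stage 7: qPCR concordance
    if config.ct_path is not None:
        from .io import read_ct_table

        df = read_ct_table(config.ct_path)
        ct = CtTable(
            data=df,
            reference_gene=config.qpcr_reference,
            calibrator_sample=config.qpcr_calibrator,
        )
        genes = sorted(set(df["gene_id"]) - {config.qpcr_reference})
        qpcr_results = {}
        nm_index = {g: i for i, g in enumerate(nm_all.gene_ids)}
        for gene in genes:
            if gene not in nm_index:
                continue
            rq = rq_profile(ct, gene, samples=list(matrix.stage_labels))
            arr = nm_all.value[nm_index[gene]]
            qpcr_results[gene] = concordance(rq, arr)
        results["qpcr_concordance"] = qpcr_results
        manifest.stage_counts["qpcr_genes"] = len(qpcr_results)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return manifest, results


def demo(
    outdir,
    seed: int = 1,
    noise_sd: float | None = None,
    config: SyntheticConfig | None = None,
) -> dict:
    """One-command synthetic run with a ground-truth recovery report.

    Generates the default synthetic dataset, runs the full pipeline at
    default thresholds, and scores recovery: clustering ARI against the planted
    archetypes, planted-partner recovery in the network (fraction
    present; fraction at MR ≤ 5), and candidate recruitment
    precision/recall against the planted flower-annotated partners.
    """
    syn = config or SyntheticConfig(seed=seed)
    if noise_sd is not None:
        syn = dataclasses.replace(syn, noise_sd=noise_sd)
    matrix, truth = generate_expression(syn)
    go = generate_go_table(truth, syn)
    core = CoreGeneList(genes=truth.core_genes)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(matrix, outdir / "expression.tsv")

    pipe_cfg = PipelineConfig(outdir=str(outdir), seed=seed)
    # qPCR: synthesize Ct tables for three planted partner genes
    qpcr_genes = sorted(truth.all_partners())[:3]
    ct_frames = []
    nm = normalize(matrix)
    nm_index = {g: i for i, g in enumerate(nm.gene_ids)}
    for i, gene in enumerate(qpcr_genes):
        ct_frames.append(
            generate_ct_table(
                nm.value[nm_index[gene]],
                gene,
                list(matrix.stage_labels),
                seed=seed + SEED_QPCR + i,
            )
        )
    if ct_frames:
        import pandas as pd

        df = pd.concat(ct_frames, ignore_index=True)
        df = df.drop_duplicates(subset=["gene_id", "sample_id", "replicate"])
        ct_path = outdir / "qpcr_ct.csv"
        df.to_csv(ct_path, index=False)
        pipe_cfg.ct_path = str(ct_path)

    manifest, results = run_pipeline(pipe_cfg, matrix=matrix, go=go, core=core)

    report: dict = {"seed": seed, "n_genes": matrix.n_genes}

    # clustering recovery over planted archetype genes
    if "clusters" in results:
        a = results["clusters"]
        arch_names = set(syn.archetypes)
        labelled = [
            g for g in a.gene_ids if truth.archetype_of.get(g) in arch_names
        ]
        if labelled:
            true_labels = [truth.archetype_of[g] for g in labelled]
            pred = [a.label[g] for g in labelled]
            report["cluster_ari"] = float(adjusted_rand_score(true_labels, pred))
            report["clustered_archetype_genes"] = len(labelled)

    # partner recovery in the network
    partners = truth.all_partners()
    network = results.get("network")
    if network is not None and partners:
        in_net = {p for p in partners if network.has_node(p)}
        mr5 = set()
        for core_gene, pset in truth.planted_partners.items():
            for p in pset:
                if network.has_edge(core_gene, p) and (
                    network.edges[core_gene, p]["mr"] <= 5
                ):
                    mr5.add(p)
        report["partner_recall_mr50"] = len(in_net) / len(partners)
        report["partner_frac_mr5"] = len(mr5) / len(partners)

    # recruitment fidelity vs planted flower partners
    candidates = results.get("candidates")
    if candidates is not None:
        recruited = {c.contig_id for c in candidates}
        planted = truth.flower_partners()
        tp = len(recruited & planted)
        report["recruit_precision"] = tp / len(recruited) if recruited else 1.0
        report["recruit_recall"] = tp / len(planted) if planted else 1.0
        report["n_candidates"] = len(recruited)

    if "qpcr_concordance" in results:
        vals = list(results["qpcr_concordance"].values())
        if vals:
            report["qpcr_min_concordance"] = float(min(vals))

    report["stage_counts"] = manifest.stage_counts
    with open(outdir / "demo_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
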