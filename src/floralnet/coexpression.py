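"""Pearson-correlation / Mutual-Rank co-expression networks seeded on
core flowering genes.

For each ordered gene pair the correlation rank R(a→b) is the position
of b in a's partner list sorted by descending PCC (self excluded, best
partner rank 1, PCC ties receiving the mean of their tied positions);
the Mutual Rank MR(a,b) = sqrt(R(a→b) · R(b→a)) is symmetric and ≥ 1,
and equals 1 exactly when two genes are each other's top partner. The
network keeps only edges touching a core gene with MR ≤ 50, drawn in
the three conventional width bands (bold MR ≤ 5, normal ≤ 30, thin
≤ 50). Function modules are the connected components of the MR ≤ 30
subgraph, annotated with the percentage of members carrying each GO
term, and candidates are recruited by the rule: a non-core gene with a
core partner at MR ≤ 30 and PCC ≥ 0.8 that itself carries a
flower-development GO term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .differential import NormalizedMatrix
from .io import CoreGeneList, GoAnnotationTable


def pcc_matrix(nm: NormalizedMatrix, genes=None) -> tuple[list[str], np.ndarray]:
    """Symmetric Pearson-correlation matrix over gene profiles.

    Returns (gene order, n × n matrix) with unit diagonal and values
    clipped to [−1, 1] against round-off. Zero-variance genes have no
    defined correlation and raise.
    """
    if genes is None:
        genes = list(nm.gene_ids)
    sub = nm.subset(list(genes))
    flat = np.where(sub.value.std(axis=1) == 0)[0]
    if flat.size:
        names = [sub.gene_ids[i] for i in flat[:10]]
        raise ValueError(f"zero-variance genes have no correlation: {names}")
    pcc = np.corrcoef(sub.value)
    np.clip(pcc, -1.0, 1.0, out=pcc)
    np.fill_diagonal(pcc, 1.0)
    return list(sub.gene_ids), pcc


def mutual_rank(pcc: np.ndarray) -> np.ndarray:
    """Mutual Rank matrix from a symmetric PCC matrix.

    MR(a,b) = sqrt(R(a→b) × R(b→a)); the diagonal is set to 0 as a
    sentinel (a gene has no rank against itself).
    """
    pcc = np.asarray(pcc, dtype=float)
    n = pcc.shape[0]
    if pcc.ndim != 2 or pcc.shape != (n, n) or n < 2:
        raise ValueError("pcc must be a square matrix with n ≥ 2")
    ranks = np.zeros((n, n))
    idx = np.arange(n)
    for a in range(n):
        others = idx != a
        # descending PCC → rank 1 is the best partner; ties get mean rank
        ranks[a, others] = rankdata(-pcc[a, others])
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return mr


@dataclass
class FunctionModule:
    """A connected group of network genes sharing dominant GO functions."""

    module_id: int
    members: set[str]
    go_profile: dict[str, float] = field(default_factory=dict)
    flowering_flag: bool = False


@dataclass
class CandidateGene:
    """A contig recruited as a potential flowering/floral gene."""

    contig_id: str
    partners: list[tuple[str, float, float]]  # (core gene, pcc, mr)
    go_basis: set[str]
    module_id: int | None = None


def edge_class_of(mr: float) -> str:
    if mr <= 5:
        return "bold"
    if mr <= 30:
        return "normal"
    return "thin"


def build_network(
    gene_ids: list[str],
    mr: np.ndarray,
    pcc: np.ndarray,
    core: CoreGeneList,
    mr_cut: float = 50.0,
) -> nx.Graph:
    """Core-seeded co-expression graph.

    Edges are the pairs (core, g), g ≠ core, with MR ≤ mr_cut —
    core–core pairs meeting the cut included — classed bold/normal/thin
    by the MR bands. Nodes are the endpoints of retained edges, flagged
    ``is_core``.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    core_present = [g for g in core.genes if g in index]
    if not core_present:
        raise ValueError("no core gene found in the expression matrix")
    core_set = set(core_present)
    g = nx.Graph()
    for c in core_present:
        i = index[c]
        for other in gene_ids:
            if other == c:
                continue
            j = index[other]
            if g.has_edge(c, other):
                continue
            m = float(mr[i, j])
            if m <= mr_cut:
                g.add_node(c, is_core=True)
                g.add_node(other, is_core=other in core_set)
                g.add_edge(
                    c,
                    other,
                    pcc=float(pcc[i, j]),
                    mr=m,
                    edge_class=edge_class_of(m),
                )
    return g


def extract_modules(
    graph: nx.Graph, method: str = "components_mr30", mr_max: float = 30.0
) -> list[FunctionModule]:
    """Partition the network into function modules.

    Default method: connected components of the subgraph restricted to
    edges with MR ≤ mr_max, singletons discarded. Alternative
    ``greedy-modularity`` runs Clauset–Newman–Moore community detection
    on the same subgraph. Module ids are assigned by descending size,
    ties by smallest member id.
    """
    sub = graph.edge_subgraph(
        [(a, b) for a, b, d in graph.edges(data=True) if d["mr"] <= mr_max]
    ).copy()
    if method == "components_mr30":
        groups = [set(c) for c in nx.connected_components(sub)]
    elif method == "greedy-modularity":
        if sub.number_of_edges() == 0:
            groups = []
        else:
            groups = [
                set(c)
                for c in nx.algorithms.community.greedy_modularity_communities(sub)
            ]
    else:
        raise ValueError(f"unknown module method {method!r}")
    groups = [g for g in groups if len(g) > 1]
    groups.sort(key=lambda g: (-len(g), min(g)))
    return [FunctionModule(module_id=i + 1, members=g) for i, g in enumerate(groups)]


def annotate_module(
    module: FunctionModule,
    ann: GoAnnotationTable,
    flower_floor: float | None = None,
) -> FunctionModule:
    """Attach the GO percentage profile to a module (in place).

    For each term, the percentage of members carrying it, to two
    decimals. ``flowering_flag`` is set when a flower-development term
    sits among the module's top-3 terms; if ``flower_floor`` is given
    the flag instead requires a flower term at ≥ that percentage.
    """
    if not module.members:
        raise ValueError(f"module {module.module_id} is empty")
    counts: dict[str, int] = {}
    for gene in module.members:
        for term in ann.terms_of(gene):
            counts[term] = counts.get(term, 0) + 1
    size = len(module.members)
    module.go_profile = {
        t: round(100.0 * c / size, 2) for t, c in sorted(counts.items())
    }
    flower_pcts = [
        module.go_profile[t] for t in ann.flower_terms if t in module.go_profile
    ]
    if flower_floor is not None:
        module.flowering_flag = any(p >= flower_floor for p in flower_pcts)
    else:
        top3 = sorted(
            module.go_profile, key=lambda t: (-module.go_profile[t], t)
        )[:3]
        module.flowering_flag = any(t in ann.flower_terms for t in top3)
    return module


def recruit_candidates(
    graph: nx.Graph,
    ann: GoAnnotationTable,
    mr_max: float = 30.0,
    pcc_min: float = 0.8,
    modules: list[FunctionModule] | None = None,
) -> list[CandidateGene]:
    """Nominate non-core genes as potential flowering/floral genes.

    A candidate has ≥ 1 core partner with MR ≤ mr_max and PCC ≥ pcc_min
    (both inclusive) and carries ≥ 1 flower-development GO term. All
    qualifying partners are listed, strongest (lowest MR) first.
    """
    module_of: dict[str, int] = {}
    for m in modules or []:
        for gene in m.members:
            module_of[gene] = m.module_id
    out = []
    for node in sorted(graph.nodes):
        if graph.nodes[node].get("is_core", False):
            continue
        flower = ann.terms_of(node) & ann.flower_terms
        if not flower:
            continue
        partners = []
        for nbr in graph.neighbors(node):
            if not graph.nodes[nbr].get("is_core", False):
                continue
            d = graph.edges[node, nbr]
            if d["mr"] <= mr_max and d["pcc"] >= pcc_min:
                partners.append((nbr, d["pcc"], d["mr"]))
        if partners:
            partners.sort(key=lambda t: (t[2], -t[1], t[0]))
            out.append(
                CandidateGene(
                    contig_id=node,
                    partners=partners,
                    go_basis=flower,
                    module_id=module_of.get(node),
                )
            )
    return out
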