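"""Readers and writers for every file the pipeline touches.

All formats are plain text: an expression TSV with paired signal/call
columns per stage, 12-column BLAST tabular (outfmt 6) with a two-column
query-length sidecar, a two-column gene→GO TSV, a one/two-column core-gene
list, network edge-list TSV or GraphML, and a qPCR Ct CSV.

Readers validate strictly and reject rather than coerce malformed input;
every writer/reader pair is an inverse on valid data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

VALID_CALLS = frozenset({"P", "M", "A"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene × stage signal intensities with paired P/M/A detection calls.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene/contig identifiers, row order meaningful.
    stage_labels : list of str
        Developmental stage labels in time order (default S1..S8).
    signal : ndarray, shape (n_genes, n_stages)
        Positive fluorescence intensities (arbitrary units).
    call : ndarray of str, same shape
        Per-cell detection call: 'P' (present), 'M' (marginal),
        'A' (absent).
    """

    gene_ids: list[str]
    stage_labels: list[str]
    signal: np.ndarray
    call: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.call = np.asarray(self.call, dtype="U1")
        n, s = len(self.gene_ids), len(self.stage_labels)
        if self.signal.shape != (n, s):
            raise ValueError(
                f"signal shape {self.signal.shape} != ({n} genes, {s} stages)"
            )
        if self.call.shape != (n, s):
            raise ValueError(
                f"call shape {self.call.shape} != ({n} genes, {s} stages)"
            )
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids contain duplicates")
        bad = set(np.unique(self.call)) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        """Row-subset preserving the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            stage_labels=list(self.stage_labels),
            signal=self.signal[rows],
            call=self.call[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Interleaved signal/call frame matching the on-disk layout."""
        data: dict[str, object] = {"gene_id": self.gene_ids}
        for j, stage in enumerate(self.stage_labels):
            data[f"{stage}_signal"] = self.signal[:, j]
            data[f"{stage}_call"] = self.call[:, j]
        return pd.DataFrame(data)


def read_expression(path) -> ExpressionMatrix:
    """Parse an expression TSV (gene_id, then S*_signal / S*_call pairs).

    Raises :class:`FormatError` naming the line for malformed headers,
    non-numeric signals, invalid calls or duplicate gene ids.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene_id":
            raise FormatError(f"{path}: header must start with 'gene_id'")
        stages: list[str] = []
        cols = header[1:]
        if len(cols) == 0 or len(cols) % 2 != 0:
            raise FormatError(
                f"{path}: expected paired <stage>_signal/<stage>_call columns"
            )
        for i in range(0, len(cols), 2):
            sig, cal = cols[i], cols[i + 1]
            if not sig.endswith("_signal") or not cal.endswith("_call"):
                raise FormatError(f"{path}: malformed header pair {sig!r}/{cal!r}")
            stage = sig[: -len("_signal")]
            if cal[: -len("_call")] != stage:
                raise FormatError(
                    f"{path}: signal/call stage mismatch {sig!r} vs {cal!r}"
                )
            stages.append(stage)

        gene_ids: list[str] = []
        seen: set[str] = set()
        signals: list[list[float]] = []
        calls: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(parts)}"
                )
            gid = parts[0]
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            row_sig, row_call = [], []
            for j, stage in enumerate(stages):
                raw_sig = parts[1 + 2 * j]
                raw_call = parts[2 + 2 * j]
                try:
                    val = float(raw_sig)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric signal {raw_sig!r} "
                        f"in column {stage}_signal"
                    ) from None
                if raw_call not in VALID_CALLS:
                    raise FormatError(
                        f"{path}:{lineno}: invalid call {raw_call!r} for gene "
                        f"{gid!r} at stage {stage} (expected P, M or A)"
                    )
                row_sig.append(val)
                row_call.append(raw_call)
            gene_ids.append(gid)
            signals.append(row_sig)
            calls.append(row_call)

    return ExpressionMatrix(
        gene_ids=gene_ids,
        stage_labels=stages,
        signal=np.array(signals, dtype=float).reshape(len(gene_ids), len(stages)),
        call=np.array(calls, dtype="U1").reshape(len(gene_ids), len(stages)),
    )


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write the interleaved signal/call TSV; inverse of read_expression."""
    with open(path, "w") as fh:
        cols = ["gene_id"]
        for stage in m.stage_labels:
            cols += [f"{stage}_signal", f"{stage}_call"]
        fh.write("\t".join(cols) + "\n")
        for i, gid in enumerate(m.gene_ids):
            parts = [gid]
            for j in range(m.n_stages):
                parts.append(repr(float(m.signal[i, j])))
                parts.append(m.call[i, j])
            fh.write("\t".join(parts) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

BLAST_COLUMNS = (
    "query_id subject_id percent_identity alignment_length mismatches "
    "gap_opens q_start q_end s_start s_end evalue bitscore"
).split()


@dataclass
class BlastHit:
    """One row of 12-column BLAST tabular output plus the query length.

    Coordinates are kept 1-based inclusive (the format's native
    convention); ``s_start > s_end`` marks a minus-strand subject
    alignment and is accepted as-is.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    query_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end

    @property
    def query_coverage(self) -> float:
        """Aligned query span as a percentage of query length, in [0, 100]."""
        span = abs(self.q_end - self.q_start) + 1
        return 100.0 * span / self.query_length


def read_query_lengths(path) -> dict[str, int]:
    """Two-column TSV: query_id, length (bases)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            qid, raw = parts
            try:
                n = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {raw!r}"
                ) from None
            if n <= 0:
                raise FormatError(f"{path}:{lineno}: length must be positive")
            lengths[qid] = n
    return lengths


def read_blast_tabular(path, lengths_path) -> list[BlastHit]:
    """Parse outfmt-6 tabular hits, joining query lengths from the sidecar.

    A query id missing from the lengths table is an error: coverage is
    uncomputable without it.
    """
    lengths = read_query_lengths(lengths_path)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            qid = parts[0]
            if qid not in lengths:
                raise FormatError(
                    f"{path}:{lineno}: query {qid!r} missing from lengths table"
                )
            try:
                hit = BlastHit(
                    query_id=qid,
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    query_length=lengths[qid],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_blast_tabular(hits: list[BlastHit], path, lengths_path) -> None:
    """Write hits as outfmt-6 plus the query-length sidecar."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.percent_identity,
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bitscore,
                    )
                )
                + "\n"
            )
    lengths = {h.query_id: h.query_length for h in hits}
    with open(lengths_path, "w") as fh:
        for qid, n in lengths.items():
            fh.write(f"{qid}\t{n}\n")


# ---------------------------------------------------------------------------
# GO annotations and core gene lists
# ---------------------------------------------------------------------------


@dataclass
class GoAnnotationTable:
    """Flat gene→GO mapping with term labels and flower-development flags.

    No GO-graph propagation: a gene carries exactly its listed terms.
    """

    mapping: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    flower_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for gene, terms in self.mapping.items():
            if not terms:
                raise ValueError(f"gene {gene!r} mapped to an empty term set")
        missing = self.flower_terms - set(self.term_names)
        if missing:
            raise ValueError(
                f"flower terms missing from term_names: {sorted(missing)}"
            )

    def terms_of(self, gene: str) -> set[str]:
        return self.mapping.get(gene, set())

    def has_flower_term(self, gene: str) -> bool:
        return bool(self.terms_of(gene) & self.flower_terms)


def read_go_table(path, term_names_path=None, flower_terms=()) -> GoAnnotationTable:
    """Two-column TSV, one (gene, term) pair per row.

    ``term_names_path`` is an optional two-column id→label TSV; labels
    default to the id itself so flower_terms always resolves.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            gene, term = parts
            mapping.setdefault(gene, set()).add(term)
    term_names: dict[str, str] = {}
    if term_names_path is not None:
        with open(term_names_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        f"{term_names_path}:{lineno}: expected 2 columns"
                    )
                term_names[parts[0]] = parts[1]
    all_terms = set().union(*mapping.values()) if mapping else set()
    for t in all_terms | set(flower_terms):
        term_names.setdefault(t, t)
    return GoAnnotationTable(
        mapping=mapping, term_names=term_names, flower_terms=set(flower_terms)
    )


def write_go_table(table: GoAnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table.mapping):
            for term in sorted(table.mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


@dataclass
class CoreGeneList:
    """Curated core flowering/floral regulator identifiers.

    Optionally carries an Arabidopsis locus cross-reference per gene.
    """

    genes: list[str]
    locus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("core gene identifiers must be unique")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_core_genes(path) -> CoreGeneList:
    """One or two tab-separated columns: gene id, optional locus."""
    genes: list[str] = []
    locus: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2):
                raise FormatError(
                    f"{path}:{lineno}: expected 1 or 2 columns, got {len(parts)}"
                )
            genes.append(parts[0])
            if len(parts) == 2 and parts[1]:
                locus[parts[0]] = parts[1]
    try:
        return CoreGeneList(genes=genes, locus=locus)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["gene_a", "gene_b", "pcc", "mr", "edge_class", "is_core_a", "is_core_b"]


def write_network(graph: nx.Graph, path, dialect: str = "tsv") -> None:
    """Write a co-expression graph as an edge-list TSV or GraphML.

    Edge attributes ``pcc``, ``mr``, ``edge_class`` and the node attribute
    ``is_core`` are preserved at full float precision; round-tripping
    through :func:`read_network` is the identity on the graph.
    """
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for a, b, data in sorted(graph.edges(data=True)):
                fh.write(
                    "\t".join(
                        [
                            a,
                            b,
                            repr(float(data["pcc"])),
                            repr(float(data["mr"])),
                            data["edge_class"],
                            str(int(graph.nodes[a].get("is_core", False))),
                            str(int(graph.nodes[b].get("is_core", False))),
                        ]
                    )
                    + "\n"
                )
    elif dialect == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network dialect {dialect!r} (tsv or graphml)")


def read_network(path, dialect: str = "tsv") -> nx.Graph:
    if dialect == "graphml":
        g = nx.read_graphml(path)
        for n in g.nodes:
            g.nodes[n]["is_core"] = bool(g.nodes[n].get("is_core", False))
        return g
    if dialect != "tsv":
        raise ValueError(f"unknown network dialect {dialect!r} (tsv or graphml)")
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_COLUMNS:
            raise FormatError(f"{path}: unexpected edge-list header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            a, b, pcc, mr, cls, core_a, core_b = parts
            g.add_node(a, is_core=bool(int(core_a)))
            g.add_node(b, is_core=bool(int(core_b)))
            g.add_edge(a, b, pcc=float(pcc), mr=float(mr), edge_class=cls)
    return g


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def read_ct_table(path) -> pd.DataFrame:
    """qPCR Ct CSV with columns gene_id, sample_id, replicate, ct."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["gene_id", "sample_id", "replicate", "ct"]:
            raise FormatError(
                f"{path}: expected header gene_id,sample_id,replicate,ct"
            )
        rows = []
        for lineno, parts in enumerate(reader, start=2):
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (parts[0], parts[1], int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate", "ct"])
    if (df["ct"] <= 0).any():
        bad = df.loc[df["ct"] <= 0].iloc[0]
        raise FormatError(
            f"{path}: non-positive Ct for gene {bad.gene_id!r} "
            f"sample {bad.sample_id!r}"
        )
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["gene_id", "sample_id", "replicate", "ct"])
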