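"""Rule-based filtering of BLAST tabular results.

Three stages: reduce each query's hit list to its single top hit
(maximal bitscore, deterministic tie-breaks), apply the homolog filter
(e-value strictly below 1e-5, identity ≥ 80%, query coverage ≥ 50%),
and classify contigs of two assemblies as common or sample-specific by
the best cross-sample hit (common at e ≤ 1e-10). Contigs whose filtered
subject is a curated core flowering gene become putative floral genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import BlastHit, CoreGeneList


@dataclass
class HomologCall:
    """Top-hit filter verdict for one query contig."""

    query_id: str
    subject_id: str
    evalue: float
    percent_identity: float
    query_coverage: float
    bitscore: float
    passed: bool


@dataclass
class ContigClassification:
    """Partition of two assemblies into specific and common contigs.

    Classification runs independently per direction, so the two common
    sets need not be the same size.
    """

    sample_a_specific: set[str]
    sample_b_specific: set[str]
    common_a: set[str]
    common_b: set[str]
    evalue_cut: float

    def __post_init__(self) -> None:
        if self.sample_a_specific & self.common_a:
            raise ValueError("sample A sets are not disjoint")
        if self.sample_b_specific & self.common_b:
            raise ValueError("sample B sets are not disjoint")


def top_hit_per_query(hits: list[BlastHit]) -> dict[str, BlastHit]:
    """Best hit per query: max bitscore, then min e-value, then
    lexicographically smallest subject id.

    The cascade is total, so permuting the input order never changes the
    result.
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bitscore, h.evalue, h.subject_id)
        key_cur = (-cur.bitscore, cur.evalue, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


def filter_homologs(
    top: dict[str, BlastHit],
    e_cut: float = 1e-5,
    id_cut: float = 80.0,
    cov_cut: float = 50.0,
) -> list[HomologCall]:
    """Apply the three-threshold homolog filter to each top hit.

    passed ⇔ evalue < e_cut (strict) ∧ identity ≥ id_cut ∧
    coverage ≥ cov_cut (both inclusive). One call per query, in sorted
    query order.
    """
    calls = []
    for qid in sorted(top):
        h = top[qid]
        cov = h.query_coverage
        calls.append(
            HomologCall(
                query_id=qid,
                subject_id=h.subject_id,
                evalue=h.evalue,
                percent_identity=h.percent_identity,
                query_coverage=cov,
                bitscore=h.bitscore,
                passed=(
                    h.evalue < e_cut
                    and h.percent_identity >= id_cut
                    and cov >= cov_cut
                ),
            )
        )
    return calls


def classify_contigs(
    a_vs_b: list[BlastHit],
    b_vs_a: list[BlastHit],
    universe_a: set[str],
    universe_b: set[str],
    e_cut: float = 1e-10,
) -> ContigClassification:
    """Split each assembly into common and sample-specific contigs.

    A contig is common when its best cross-sample hit reaches
    e ≤ e_cut (inclusive); contigs with no hit, or only weaker hits,
    are sample-specific. The two assemblies are distinct namespaces: an
    id present in both universes is an error.
    """
    overlap = set(universe_a) & set(universe_b)
    if overlap:
        raise ValueError(
            f"contig ids present in both universes: {sorted(overlap)[:5]}"
        )

    def common_of(hits: list[BlastHit], universe: set[str]) -> set[str]:
        best = top_hit_per_query([h for h in hits if h.query_id in universe])
        return {q for q, h in best.items() if h.evalue <= e_cut}

    common_a = common_of(a_vs_b, set(universe_a))
    common_b = common_of(b_vs_a, set(universe_b))
    return ContigClassification(
        sample_a_specific=set(universe_a) - common_a,
        sample_b_specific=set(universe_b) - common_b,
        common_a=common_a,
        common_b=common_b,
        evalue_cut=e_cut,
    )


def identify_floral_genes(
    calls: list[HomologCall],
    core: CoreGeneList,
    extended: set[str] | None = None,
    classification: ContigClassification | None = None,
) -> list[dict]:
    """Putative flowering/floral genes: passed calls hitting a core locus.

    ``extended`` optionally widens the reference set (e.g. a curated
    literature network's gene list). When a classification is supplied
    each row is labelled by its source sample: A-specific, B-specific or
    common.
    """
    reference = set(core.genes) | set(core.locus.values())
    if extended:
        reference |= set(extended)
    rows = []
    for c in calls:
        if not c.passed or c.subject_id not in reference:
            continue
        label = "unknown"
        if classification is not None:
            if c.query_id in classification.sample_a_specific:
                label = "A-specific"
            elif c.query_id in classification.sample_b_specific:
                label = "B-specific"
            elif (
                c.query_id in classification.common_a
                or c.query_id in classification.common_b
            ):
                label = "common"
        rows.append(
            {
                "contig_id": c.query_id,
                "subject_id": c.subject_id,
                "evalue": c.evalue,
                "percent_identity": c.percent_identity,
                "query_coverage": c.query_coverage,
                "source": label,
            }
        )
    return rows
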