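"""Synthetic eight-stage expression data with planted ground truth.

The generator emulates the substrate of a time-course flowering
transcriptome study: a gene × stage signal matrix with P/M/A detection
calls, a flat gene→GO table, BLAST-like tabular hits and qPCR Ct
tables. Everything downstream — filtering, fold-change selection,
pattern clustering, enrichment, homolog filtering, the Mutual-Rank
network, recruitment and qPCR concordance — can therefore be tested
against known planted structure.

Planted structure:

* nine temporal archetypes (early dips at stages 2/3/4/6, step rises at
  4/5, rise-then-fall, slow drift down, slow drift up), each assigned a
  block of genes whose log2 signals are the archetype mean plus
  additive Gaussian noise (multiplicative on the signal scale, matching
  ratio-based microarray fold changes);
* designated core flowering genes with individual random log-profiles,
  each surrounded by planted partner genes that are scaled/shifted
  copies of the core profile with smaller noise, so partner–core PCC is
  high by construction;
* a set of all-'A' (absent) genes that every detection filter must
  remove, and unstructured background genes;
* GO labels: partners of flower-module cores carry a
  flower-development term; everything else draws from the generic
  vocabulary.

Archetype means are fixed constants in code, not random, so fixtures
are stable across versions. Every generator is bit-deterministic under
its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (
    BlastHit,
    ExpressionMatrix,
    GoAnnotationTable,
    write_blast_tabular,
    write_expression,
    write_go_table,
)

# log2-scale deviations from the base signal level, one row per archetype,
# eight stages; shapes chosen to be mutually distinguishable under Pearson
# correlation distance
ARCHETYPE_SHAPES: dict[str, tuple[float, ...]] = {
    "dip-S2": (1.5, -1.5, -0.8, -0.8, -0.8, -0.8, -0.8, -0.8),
    "dip-S3": (1.5, 0.8, -1.5, -0.8, -0.8, -0.8, -0.8, -0.8),
    "dip-S4": (1.5, 1.0, 0.5, -1.5, -0.8, -0.8, -0.8, -0.8),
    "dip-S6": (1.2, 0.9, 0.6, 0.3, 0.0, -1.5, -0.6, -0.6),
    "rise-S4": (-1.0, -1.0, -1.0, 1.2, 1.2, 1.2, 1.2, 1.2),
    "rise-S5": (-1.0, -1.0, -1.0, -1.0, 1.2, 1.2, 1.2, 1.2),
    "rise-fall": (-1.2, 0.5, 1.5, 0.8, -0.2, -0.8, -1.2, -1.5),
    "slow-down": (1.25, 0.89, 0.54, 0.18, -0.18, -0.54, -0.89, -1.25),
    "slow-up": (-1.25, -0.89, -0.54, -0.18, 0.18, 0.54, 0.89, 1.25),
}

BASE_LOG_SIGNAL = 8.0  # signals centred near 2^8 = 256 intensity units

DEFAULT_GO_VOCAB = (
    "GO:0009908",  # flower development
    "GO:0009416",  # response to light stimulus
    "GO:0009409",  # response to cold
    "GO:0008152",  # metabolic process
    "GO:0006810",  # transport
    "GO:0006412",  # translation
    "GO:0007049",  # cell cycle
    "GO:0007165",  # signal transduction
    "GO:0006950",  # response to stress
    "GO:0015979",  # photosynthesis
    "GO:0006260",  # DNA replication
    "GO:0016192",  # vesicle-mediated transport
)

DEFAULT_FLOWER_TERMS = ("GO:0009908",)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions."""

    n_genes: int = 1000
    n_stages: int = 8
    archetypes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(ARCHETYPE_SHAPES)
    )
    genes_per_archetype: dict[str, int] | None = None  # None → 100 each
    noise_sd: float = 0.25
    n_core: int = 10
    n_flower_cores: int = 3
    partners_per_core: int = 5
    partner_noise_sd: float = 0.1
    core_profile_sd: float = 1.5
    absent_fraction: float = 0.02
    marginal_rate: float = 0.0
    go_vocab: tuple[str, ...] = DEFAULT_GO_VOCAB
    flower_terms: tuple[str, ...] = DEFAULT_FLOWER_TERMS
    background_flower_rate: float = 0.02
    seed: int = 0

    def resolved_genes_per_archetype(self) -> dict[str, int]:
        """Explicit counts, or an even split of the genes left over after
        cores, partners and a background reserve."""
        if self.genes_per_archetype is not None:
            return dict(self.genes_per_archetype)
        available = self.n_genes - self.n_core * (1 + self.partners_per_core)
        reserve = 2 * int(round(self.absent_fraction * self.n_genes))
        per = max(0, (available - reserve) // max(len(self.archetypes), 1))
        return {name: per for name in self.archetypes}

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_stages < 2:
            raise ValueError(f"n_stages must be ≥ 2, got {self.n_stages}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be ≥ 0, got {self.noise_sd}")
        if self.partner_noise_sd < 0:
            raise ValueError(
                f"partner_noise_sd must be ≥ 0, got {self.partner_noise_sd}"
            )
        if not 0 <= self.absent_fraction <= 1:
            raise ValueError(
                f"absent_fraction must be in [0, 1], got {self.absent_fraction}"
            )
        if not 0 <= self.marginal_rate <= 1:
            raise ValueError(
                f"marginal_rate must be in [0, 1], got {self.marginal_rate}"
            )
        if self.n_core < 0 or self.partners_per_core < 0:
            raise ValueError("n_core and partners_per_core must be ≥ 0")
        if self.n_flower_cores > self.n_core:
            raise ValueError("n_flower_cores cannot exceed n_core")
        for name, shape in self.archetypes.items():
            if len(shape) != self.n_stages:
                raise ValueError(
                    f"archetypes[{name!r}] has {len(shape)} stages, "
                    f"expected {self.n_stages}"
                )
        gpa = self.resolved_genes_per_archetype()
        planted = (
            sum(gpa.values())
            + self.n_core * (1 + self.partners_per_core)
        )
        if sum(gpa.values()) > self.n_genes:
            raise ValueError(
                f"genes_per_archetype sums to {sum(gpa.values())} "
                f"> n_genes = {self.n_genes}"
            )
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes}); "
                "raise n_genes or shrink archetype/core counts"
            )


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    archetype_of: dict[str, str]  # every gene → archetype name or role
    planted_partners: dict[str, set[str]]  # core gene → its partner set
    planted_absent: set[str]
    flower_cores: set[str]
    go_of: dict[str, set[str]] = field(default_factory=dict)

    @property
    def core_genes(self) -> list[str]:
        return sorted(self.planted_partners)

    def all_partners(self) -> set[str]:
        out: set[str] = set()
        for s in self.planted_partners.values():
            out |= s
        return out

    def flower_partners(self) -> set[str]:
        out: set[str] = set()
        for c in self.flower_cores:
            out |= self.planted_partners.get(c, set())
        return out


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Build the planted gene × stage matrix with detection calls."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.n_stages
    gpa = config.resolved_genes_per_archetype()

    gene_ids: list[str] = []
    log_rows: list[np.ndarray] = []
    archetype_of: dict[str, str] = {}
    planted_partners: dict[str, set[str]] = {}
    flower_cores: set[str] = set()

    # core genes: individual random log-profiles, partners as noisy
    # scaled/shifted copies
    core_profiles: dict[str, np.ndarray] = {}
    for c in range(config.n_core):
        cid = f"core_{c + 1:02d}"
        profile = BASE_LOG_SIGNAL + rng.normal(0.0, config.core_profile_sd, size=s)
        core_profiles[cid] = profile
        gene_ids.append(cid)
        log_rows.append(profile)
        archetype_of[cid] = "core"
        planted_partners[cid] = set()
        if c < config.n_flower_cores:
            flower_cores.add(cid)
    for cid in list(planted_partners):
        base = core_profiles[cid] - BASE_LOG_SIGNAL
        for p in range(config.partners_per_core):
            pid = f"partner_{cid.split('_')[1]}_{p + 1}"
            scale = rng.uniform(0.6, 1.4)
            shift = rng.uniform(-1.0, 1.0)
            profile = (
                BASE_LOG_SIGNAL
                + shift
                + scale * base
                + rng.normal(0.0, config.partner_noise_sd, size=s)
            )
            gene_ids.append(pid)
            log_rows.append(profile)
            archetype_of[pid] = "partner"
            planted_partners[cid].add(pid)

    # archetype blocks
    g_index = 0
    for name, count in gpa.items():
        shape = np.asarray(config.archetypes[name], dtype=float)
        for _ in range(count):
            g_index += 1
            gid = f"gene_{g_index:04d}"
            profile = (
                BASE_LOG_SIGNAL + shape + rng.normal(0.0, config.noise_sd, size=s)
            )
            gene_ids.append(gid)
            log_rows.append(profile)
            archetype_of[gid] = name

    # background fills up to n_genes; the absent genes are carved from it
    n_background = config.n_genes - len(gene_ids)
    n_absent = int(round(config.absent_fraction * config.n_genes))
    n_absent = min(n_absent, n_background)
    background_ids = []
    for b in range(n_background):
        bid = f"bg_{b + 1:03d}"
        profile = BASE_LOG_SIGNAL + rng.normal(0.0, 1.0, size=s)
        gene_ids.append(bid)
        log_rows.append(profile)
        archetype_of[bid] = "background"
        background_ids.append(bid)
    planted_absent = set(background_ids[:n_absent])
    for gid in planted_absent:
        archetype_of[gid] = "absent"

    signal = np.power(2.0, np.vstack(log_rows)) if log_rows else np.empty((0, s))
    call = np.full(signal.shape, "P", dtype="U1")
    if config.marginal_rate > 0:
        marginal = rng.random(signal.shape) < config.marginal_rate
        call[marginal] = "M"
    for i, gid in enumerate(gene_ids):
        if gid in planted_absent:
            call[i, :] = "A"

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        stage_labels=[f"S{i + 1}" for i in range(s)],
        signal=signal,
        call=call,
    )
    truth = GroundTruth(
        archetype_of=archetype_of,
        planted_partners=planted_partners,
        planted_absent=planted_absent,
        flower_cores=flower_cores,
    )
    return matrix, truth


def generate_go_table(
    truth: GroundTruth, config: SyntheticConfig
) -> GoAnnotationTable:
    """Flat gene→GO table with planted flower-development structure.

    Flower-module cores and their partners carry the designated
    flower-development term; all other genes draw one or two generic
    terms, plus the flower term at the small configured background rate.
    Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    flower_term = config.flower_terms[0]
    generic = [t for t in config.go_vocab if t not in set(config.flower_terms)]
    if not generic:
        raise ValueError("go_vocab needs at least one non-flower term")
    flowered = truth.flower_cores | truth.flower_partners()

    mapping: dict[str, set[str]] = {}
    for gene in sorted(truth.archetype_of):
        terms: set[str] = set()
        n_generic = int(rng.integers(1, 3))
        terms.update(rng.choice(generic, size=n_generic, replace=False))
        if gene in flowered:
            terms.add(flower_term)
        elif rng.random() < config.background_flower_rate:
            terms.add(flower_term)
        mapping[gene] = terms
    truth.go_of = {g: set(t) for g, t in mapping.items()}
    term_names = {t: t for t in config.go_vocab}
    return GoAnnotationTable(
        mapping=mapping,
        term_names=term_names,
        flower_terms=set(config.flower_terms),
    )


def generate_blast_table(
    n_queries: int,
    fraction_pass: float,
    seed: int,
    core_subjects: tuple[str, ...] = (),
    n_core_hits: int = 0,
    e_cut: float = 1e-5,
    id_cut: float = 80.0,
    cov_cut: float = 50.0,
) -> tuple[list[BlastHit], dict[str, dict]]:
    """BLAST-like top hits where exactly round(fraction_pass × n_queries)
    queries satisfy the homolog filter.

    Failing queries violate exactly one randomly chosen threshold.
    Optionally the first ``n_core_hits`` passing queries hit subjects
    drawn from ``core_subjects``. Returns (hits, truth) where truth maps
    query id → {passed, identity, subject}.
    """
    if not 0 <= fraction_pass <= 1:
        raise ValueError(f"fraction_pass must be in [0, 1], got {fraction_pass}")
    if n_queries < 0:
        raise ValueError("n_queries must be ≥ 0")
    rng = np.random.default_rng(seed)
    n_pass = int(round(fraction_pass * n_queries))
    pass_idx = set(rng.choice(n_queries, size=n_pass, replace=False)) if n_pass else set()

    hits: list[BlastHit] = []
    truth: dict[str, dict] = {}
    core_cycle = list(core_subjects)
    used_core = 0
    for q in range(n_queries):
        qid = f"contig_{q + 1:04d}"
        qlen = int(rng.integers(400, 1200))
        passed = q in pass_idx
        if passed:
            evalue = float(10.0 ** -rng.uniform(10, 60))
            identity = float(rng.uniform(id_cut, 99.5))
            cov_frac = float(rng.uniform(cov_cut / 100.0, 1.0))
        else:
            mode = rng.integers(0, 3)
            evalue = float(10.0 ** -rng.uniform(10, 60))
            identity = float(rng.uniform(id_cut, 99.5))
            cov_frac = float(rng.uniform(cov_cut / 100.0, 1.0))
            if mode == 0:
                evalue = float(10.0 ** -rng.uniform(0, 4))  # ≥ 1e-4 > e_cut
            elif mode == 1:
                identity = float(rng.uniform(40.0, id_cut - 1.0))
            else:
                cov_frac = float(rng.uniform(0.05, cov_cut / 100.0 - 0.05))
        if passed and used_core < n_core_hits and core_cycle:
            subject = core_cycle[used_core % len(core_cycle)]
            used_core += 1
        else:
            subject = f"REF_{int(rng.integers(1, 10 ** 5)):05d}"
        if passed:
            # ceil so the span can never round below the coverage cut
            span = min(qlen, int(np.ceil(cov_frac * qlen)))
        else:
            span = min(qlen, max(30, int(cov_frac * qlen)))
        q_start = 1
        q_end = span
        align_len = span
        mismatches = int(round(align_len * (100.0 - identity) / 100.0))
        hits.append(
            BlastHit(
                query_id=qid,
                subject_id=subject,
                percent_identity=round(identity, 2),
                alignment_length=align_len,
                mismatches=mismatches,
                gap_opens=0,
                q_start=q_start,
                q_end=q_end,
                s_start=1,
                s_end=align_len,
                evalue=evalue,
                bitscore=round(2.0 * align_len * identity / 100.0, 1),
                query_length=qlen,
            )
        )
        truth[qid] = {
            "passed": passed,
            "identity": round(identity, 2),
            "subject": subject,
        }
    return hits, truth


def generate_ct_table(
    array_profile: np.ndarray,
    gene: str,
    stage_labels: list[str],
    seed: int,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    reference_gene: str = "actin",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    replicate_sd: float = 0.05,
):
    """Replicate-level Ct rows for one gene tracking an array profile.

    The gene's per-stage Ct is the base cycle minus the array's
    normalized log2 value plus N(0, noise_sd) biological noise, so
    2^-ΔΔCt recovers the array profile up to that noise; the reference
    gene is flat. Returns a DataFrame in Ct-table layout.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for j, stage in enumerate(stage_labels):
        gene_ct = base_ct - (float(array_profile[j]) + rng.normal(0.0, noise_sd))
        for rep in range(1, n_replicates + 1):
            rows.append(
                (gene, stage, rep, gene_ct + rng.normal(0.0, replicate_sd))
            )
        for rep in range(1, n_replicates + 1):
            rows.append(
                (reference_gene, stage, rep,
                 reference_ct + rng.normal(0.0, replicate_sd))
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate", "ct"])


def write_synthetic_dataset(outdir, config: SyntheticConfig) -> dict[str, str]:
    """Generate and write the standard pipeline inputs plus truth JSON.

    Emits expression.tsv, go.tsv, blast.tsv + blast_lengths.tsv,
    core_genes.tsv and truth.json under ``outdir``; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    go = generate_go_table(truth, config)
    hits, blast_truth = generate_blast_table(
        n_queries=200, fraction_pass=0.4, seed=config.seed + 2
    )
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "go": str(outdir / "go.tsv"),
        "blast": str(outdir / "blast.tsv"),
        "blast_lengths": str(outdir / "blast_lengths.tsv"),
        "core_genes": str(outdir / "core_genes.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_expression(matrix, paths["expression"])
    write_go_table(go, paths["go"])
    write_blast_tabular(hits, paths["blast"], paths["blast_lengths"])
    with open(paths["core_genes"], "w") as fh:
        for cid in truth.core_genes:
            fh.write(cid + "\n")
    payload = {
        "config": {
            k: v for k, v in asdict(config).items() if k != "archetypes"
        },
        "archetype_of": truth.archetype_of,
        "planted_partners": {
            c: sorted(p) for c, p in truth.planted_partners.items()
        },
        "planted_absent": sorted(truth.planted_absent),
        "flower_cores": sorted(truth.flower_cores),
        "go_of": {g: sorted(t) for g, t in truth.go_of.items()},
        "blast_truth": blast_truth,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
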