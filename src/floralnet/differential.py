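"""Detection-call filtering, fold-change selection and normalization.

The selection cascade for a time-course array: drop undetected genes by
their P/M/A calls, keep genes whose max/min signal ratio across stages
reaches a fold-change threshold (fourfold by default), express each kept
gene as log2 of its signal over its own across-stage mean, and count
up/down genes per stage against a baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix


class FilterMode(enum.Enum):
    """Detection-call filter variants.

    ``discard_all_absent`` removes genes called 'A' at every stage (the
    differential-expression filter); ``require_one_present`` keeps only
    genes with at least one 'P' call (the stricter co-expression filter).
    A gene called 'M' everywhere survives the first mode but fails the
    second: marginal is neither absent nor present.
    """

    discard_all_absent = "discard_all_absent"
    require_one_present = "require_one_present"


@dataclass
class NormalizedMatrix:
    """Gene × stage matrix of log2 mean-ratio values (dimensionless).

    value[g, s] = log2(signal[g, s] / mean_s signal[g, ·]), so for every
    gene the across-stage mean of 2**value is exactly 1.
    """

    gene_ids: list[str]
    stage_labels: list[str]
    value: np.ndarray

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValueError("value shape does not match gene/stage labels")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, genes) -> "NormalizedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return NormalizedMatrix(
            gene_ids=list(genes),
            stage_labels=list(self.stage_labels),
            value=self.value[rows],
        )


def filter_detected(m: ExpressionMatrix, mode: FilterMode) -> ExpressionMatrix:
    """Drop undetected genes according to their detection calls.

    Row order of the survivors is preserved.
    """
    mode = FilterMode(mode)
    if mode is FilterMode.discard_all_absent:
        keep = ~np.all(m.call == "A", axis=1)
    else:
        keep = np.any(m.call == "P", axis=1)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return m.subset(genes)


def fold_change_select(
    m: ExpressionMatrix, threshold: float = 4.0, floor: float = 1.0
) -> set[str]:
    """Genes whose max/min signal ratio across stages is ≥ threshold.

    Signals are floored at ``floor`` intensity units first so that
    near-zero readings cannot inflate the ratio; the boundary is
    inclusive (ratio exactly equal to the threshold selects the gene).
    Selection is computed on raw signal, before normalization.
    """
    if threshold <= 1:
        raise ValueError(f"fold-change threshold must exceed 1, got {threshold}")
    if floor <= 0:
        raise ValueError(f"signal floor must be positive, got {floor}")
    sig = np.maximum(m.signal, floor)
    ratio = sig.max(axis=1) / sig.min(axis=1)
    return {g for g, r in zip(m.gene_ids, ratio) if r >= threshold}


def normalize(m: ExpressionMatrix) -> NormalizedMatrix:
    """log2 of each signal over the gene's across-stage mean signal."""
    if np.any(m.signal <= 0):
        i, j = np.argwhere(m.signal <= 0)[0]
        raise ValueError(
            f"non-positive signal for gene {m.gene_ids[i]!r} at stage "
            f"{m.stage_labels[j]!r}; floor signals upstream"
        )
    mean = m.signal.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        gene_ids=list(m.gene_ids),
        stage_labels=list(m.stage_labels),
        value=np.log2(m.signal / mean),
    )


def stage_updown_counts(
    nm: NormalizedMatrix,
    selected: set[str] | None = None,
    call_threshold: float = 1.0,
    baseline: str = "first",
) -> list[tuple[str, int, int]]:
    """Per-stage counts of up- and down-regulated genes.

    A gene is *up* at stage s when its normalized value exceeds the
    baseline stage's value by at least ``call_threshold`` log2 units
    (default 1, i.e. twofold), *down* for the mirror condition. The
    baseline is stage 1 (``first``) or the preceding stage
    (``previous``); the first stage always reports (0, 0).

    Returns [(stage_label, up_count, down_count), ...] in stage order.
    """
    if baseline not in ("first", "previous"):
        raise ValueError(f"baseline must be 'first' or 'previous', got {baseline!r}")
    if selected is not None:
        missing = set(selected) - set(nm.gene_ids)
        if missing:
            raise ValueError(
                f"selected genes absent from matrix: {sorted(missing)[:5]}"
            )
        nm = nm.subset([g for g in nm.gene_ids if g in selected])
    out: list[tuple[str, int, int]] = []
    for j, stage in enumerate(nm.stage_labels):
        if j == 0:
            out.append((stage, 0, 0))
            continue
        ref = nm.value[:, 0] if baseline == "first" else nm.value[:, j - 1]
        delta = nm.value[:, j] - ref
        up = int(np.sum(delta >= call_threshold))
        down = int(np.sum(delta <= -call_threshold))
        out.append((stage, up, down))
    return out
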