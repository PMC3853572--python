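"""Comparative-Ct (2^-ΔΔCt) relative quantification and array concordance.

Ct is the PCR cycle at which amplification crosses a fixed threshold;
one cycle is one doubling, so with amplification efficiency fixed at 2
the relative quantity of a target gene, normalized to a reference gene
(actin) and to a calibrator sample, is

    ΔCt   = mean Ct(gene) − mean Ct(reference)        per sample
    ΔΔCt  = ΔCt(sample) − ΔCt(calibrator)
    RQ    = 2^−ΔΔCt

Replicates are averaged on the Ct scale. Concordance with the array is
the Pearson correlation of log2 RQ against the array's normalized log2
profile over the same stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CtTable:
    """Replicate-level Ct measurements with reference and calibrator."""

    data: pd.DataFrame  # columns: gene_id, sample_id, replicate, ct
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        samples = set(self.data["sample_id"])
        if self.calibrator_sample not in samples:
            raise ValueError(
                f"calibrator sample {self.calibrator_sample!r} not measured"
            )
        ref = self.data[self.data["gene_id"] == self.reference_gene]
        missing_ref = samples - set(ref["sample_id"])
        if missing_ref:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not measured in "
                f"samples: {sorted(missing_ref)}"
            )

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample_id"]))

    def mean_ct(self, gene: str, sample: str) -> float:
        rows = self.data[
            (self.data["gene_id"] == gene) & (self.data["sample_id"] == sample)
        ]
        if rows.empty:
            raise ValueError(
                f"no Ct measurement for gene {gene!r} in sample {sample!r}"
            )
        return float(rows["ct"].mean())


def relative_quantity(ct: CtTable, gene: str, sample: str) -> float:
    """2^−ΔΔCt fold change of ``gene`` in ``sample`` vs the calibrator."""
    d_sample = ct.mean_ct(gene, sample) - ct.mean_ct(ct.reference_gene, sample)
    d_cal = ct.mean_ct(gene, ct.calibrator_sample) - ct.mean_ct(
        ct.reference_gene, ct.calibrator_sample
    )
    ddct = d_sample - d_cal
    return float(2.0 ** (-ddct))


def rq_profile(ct: CtTable, gene: str, samples: list[str] | None = None) -> np.ndarray:
    """Relative quantities of one gene across samples (stage order)."""
    if samples is None:
        samples = ct.samples
    return np.array([relative_quantity(ct, gene, s) for s in samples])


def concordance(rq_profile: np.ndarray, array_profile: np.ndarray) -> float:
    """Pearson r between log2 RQ and the array's normalized log2 profile."""
    rq = np.asarray(rq_profile, dtype=float)
    arr = np.asarray(array_profile, dtype=float)
    if rq.shape != arr.shape or rq.size < 3:
        raise ValueError("profiles must have equal length ≥ 3")
    if np.any(rq <= 0):
        raise ValueError("relative quantities must be positive")
    log_rq = np.log2(rq)
    if np.std(log_rq) == 0 or np.std(arr) == 0:
        raise ValueError("zero-variance profile has no defined correlation")
    return float(np.corrcoef(log_rq, arr)[0, 1])
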