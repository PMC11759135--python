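"""Marker and sample quality control.

Filters follow the common pre-evaluation protocol for imputed SNP data:
marker call rate >= 0.90, exclusion of monomorphic SNPs, minor allele
frequency >= 0.05, and exclusion of SNPs whose observed heterozygote
frequency deviates from the Hardy-Weinberg expectation 2p(1-p) by more than
0.15; samples are dropped when their own call rate falls below 0.90.

Markers are tested in a fixed order (call rate, monomorphic, MAF, HWE) and
each removed marker is attributed to the first filter that rejects it, so
the per-filter counts sum to the total number removed. The surviving set
itself does not depend on the order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .datatypes import GenotypeMatrix


@dataclass
class QCReport:
    n_input_markers: int = 0
    removed_call_rate: int = 0
    removed_monomorphic: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_output_markers: int = 0
    n_input_samples: int = 0
    removed_sample_call_rate: int = 0
    n_output_samples: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __str__(self) -> str:
        lines = [
            f"markers in: {self.n_input_markers}",
            f"  removed, call rate      : {self.removed_call_rate}",
            f"  removed, monomorphic    : {self.removed_monomorphic}",
            f"  removed, MAF            : {self.removed_maf}",
            f"  removed, HWE deviation  : {self.removed_hwe}",
            f"markers out: {self.n_output_markers}",
            f"samples in: {self.n_input_samples}",
            f"  removed, sample call rate: {self.removed_sample_call_rate}",
            f"samples out: {self.n_output_samples}",
        ]
        return "\n".join(lines)


def _check_threshold(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def variant_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_dev_max: float = 0.15,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers; returns the surviving matrix and the removal tally."""
    for nm, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                  ("hwe_dev_max", hwe_dev_max)):
        _check_threshold(nm, v)
    if genotypes.n_markers == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")

    x = genotypes.dosage_float()
    n = genotypes.n_samples
    n_called = (~genotypes.missing).sum(axis=0)
    call_rate = n_called / n

    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    p = np.where(n_called > 0, p, np.nan)
    maf = np.minimum(p, 1.0 - p)
    monomorphic = np.array([
        n_called[j] == 0 or np.unique(x[~genotypes.missing[:, j], j]).size == 1
        for j in range(genotypes.n_markers)
    ])
    with np.errstate(invalid="ignore"):
        het_obs = np.nansum(x == 1, axis=0) / np.where(n_called > 0, n_called, 1)
    het_exp = 2.0 * p * (1.0 - p)
    hwe_dev = np.abs(het_obs - het_exp)

    fail_call = call_rate < call_rate_min
    fail_mono = monomorphic & ~fail_call
    fail_maf = (np.nan_to_num(maf, nan=0.0) < maf_min) & ~fail_call & ~monomorphic
    fail_hwe = (
        (np.nan_to_num(hwe_dev, nan=0.0) > hwe_dev_max)
        & ~fail_call & ~monomorphic & ~fail_maf
    )
    keep = ~(fail_call | fail_mono | fail_maf | fail_hwe)

    report = QCReport(
        n_input_markers=genotypes.n_markers,
        removed_call_rate=int(fail_call.sum()),
        removed_monomorphic=int(fail_mono.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        n_output_markers=int(keep.sum()),
        n_input_samples=n,
        n_output_samples=n,
    )
    return genotypes.subset(marker_idx=np.where(keep)[0]), report


def sample_qc(
    genotypes: GenotypeMatrix, call_rate_min: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose fraction of non-missing markers is below threshold."""
    _check_threshold("call_rate_min", call_rate_min)
    if genotypes.n_markers == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    call_rate = (~genotypes.missing).mean(axis=1)
    keep = call_rate >= call_rate_min
    report = QCReport(
        n_input_markers=genotypes.n_markers,
        n_output_markers=genotypes.n_markers,
        n_input_samples=genotypes.n_samples,
        removed_sample_call_rate=int((~keep).sum()),
        n_output_samples=int(keep.sum()),
    )
    return genotypes.subset(sample_idx=np.where(keep)[0]), report
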