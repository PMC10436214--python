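"""Regional GM/WM analysis of synthetic volumes.

Region masks segment gray and white matter from real and synthetic
volumes; the four image metrics are recomputed inside each region
(histograms built from mask-interior voxels only), per-slice metric
profiles locate where in the volume a model struggles, and per-subject
regional medians of real vs synthetic scalar values are compared with
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .exceptions import ContractError, DegenerateInputError
from .metrics import MetricConfig, MetricReport, metric_report

__all__ = [
    "RegionalStats",
    "CorrelationResult",
    "masked_metrics",
    "per_slice_profile",
    "median_correlation",
    "regional_medians",
    "MIN_MASK_VOXELS",
]

# slices with fewer in-region voxels than this are skipped in profiles;
# tiny-sample image statistics are meaningless
MIN_MASK_VOXELS = 8


@dataclass
class RegionalStats:
    """Per-volume regional metrics plus the real/synthetic median scalar values."""

    region_label: str
    report: MetricReport
    median_real: float
    median_synthetic: float


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def masked_metrics(
    real: np.ndarray,
    synthetic: np.ndarray,
    mask: np.ndarray,
    config: MetricConfig | None = None,
    region_label: str | None = None,
) -> MetricReport:
    """All four metrics restricted to mask-interior voxels."""
    config = config or MetricConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateInputError("region mask is empty")
    return metric_report(real, synthetic, config, mask=mask, region_label=region_label)


def per_slice_profile(
    real: np.ndarray,
    synthetic: np.ndarray,
    masks: dict[str, np.ndarray],
    config: MetricConfig | None = None,
) -> list[MetricReport]:
    """One MetricReport per (slice, region) with a populated in-slice mask.

    Slices whose regional mask holds fewer than :data:`MIN_MASK_VOXELS`
    voxels are skipped.  The slice axis is the last axis.
    """
    config = config or MetricConfig()
    real = np.asarray(real, dtype=float)
    synthetic = np.asarray(synthetic, dtype=float)
    if real.shape != synthetic.shape:
        raise ContractError("real and synthetic volumes must share a shape")
    reports: list[MetricReport] = []
    for label, mask in masks.items():
        mask = np.asarray(mask).astype(bool)
        if mask.shape != real.shape:
            raise ContractError(f"mask {label!r} shape mismatch")
        for z in range(real.shape[2]):
            msk = mask[:, :, z]
            if msk.sum() < MIN_MASK_VOXELS:
                continue
            rep = metric_report(
                real[:, :, z], synthetic[:, :, z], config,
                mask=msk, region_label=label, slice_index=z,
            )
            reports.append(rep)
    return reports


def regional_medians(
    real: np.ndarray, synthetic: np.ndarray, mask: np.ndarray, region_label: str,
    config: MetricConfig | None = None,
) -> RegionalStats:
    """Per-volume regional metrics and median scalar values inside the mask."""
    mask_b = np.asarray(mask).astype(bool)
    if not mask_b.any():
        raise DegenerateInputError("region mask is empty")
    report = masked_metrics(real, synthetic, mask_b, config, region_label)
    return RegionalStats(
        region_label=region_label,
        report=report,
        median_real=float(np.median(np.asarray(real, dtype=float)[mask_b])),
        median_synthetic=float(np.median(np.asarray(synthetic, dtype=float)[mask_b])),
    )


def median_correlation(real_medians, synthetic_medians) -> CorrelationResult:
    """Pearson correlation between per-subject real and synthetic regional
    medians, with the two-sided p-value from the t distribution on n - 2
    degrees of freedom."""
    real_medians = np.asarray(real_medians, dtype=float)
    synthetic_medians = np.asarray(synthetic_medians, dtype=float)
    if real_medians.shape != synthetic_medians.shape:
        raise ContractError("median sequences must have equal length")
    n = real_medians.size
    if n < 3:
        raise ContractError("need at least 3 subjects for a correlation")
    if np.ptp(real_medians) == 0 or np.ptp(synthetic_medians) == 0:
        raise DegenerateInputError("zero variance in a median sequence")
    res = scipy.stats.pearsonr(real_medians, synthetic_medians)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)
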