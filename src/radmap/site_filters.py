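"""Visualization-guided depth/balance filters applied in a fixed cascade.

The cascade removes whole loci (pooled allele balance, pooled total
depth, offspring missingness) and masks individual genotypes (per-call
depth window, heterozygote allele balance), recording an audit row after
every step. Removal boundaries are strict inequalities: a locus at
exactly the printed threshold survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import AB, MISSING, AlleleDepthMatrix, GenotypeMatrix


@dataclass
class FilterConfig:
    """Thresholds for the six filter steps (A-F).

    Depth windows are inclusive; log-ratio windows are inclusive; the
    heterozygote-balance cut masks calls strictly beyond +/- the bound.
    """

    prefilter_log10_depth_min: float = 2.0
    prefilter_log10_depth_max: float = 3.2
    locus_log2_refalt_min: float = -2.32
    locus_log2_refalt_max: float = 2.6
    locus_total_depth_min: int = 320
    locus_total_depth_max: int = 1400
    genotype_depth_min: int = 8
    genotype_depth_max: int = 40
    het_abs_log2_ratio_max: float = 3.26
    min_called_offspring: int = 50
    # alternative reading of the missingness rule: retain loci with at
    # most (n_offspring - min_called_offspring) MISSING calls instead of
    # at least min_called_offspring called ones. Identical unless sample
    # counts differ from the nominal design.
    missingness_counts_missing: bool = False

    def __post_init__(self) -> None:
        pairs = [
            ("prefilter_log10_depth_min", "prefilter_log10_depth_max"),
            ("locus_log2_refalt_min", "locus_log2_refalt_max"),
            ("locus_total_depth_min", "locus_total_depth_max"),
            ("genotype_depth_min", "genotype_depth_max"),
        ]
        for lo, hi in pairs:
            if getattr(self, lo) >= getattr(self, hi):
                raise ValueError(f"{lo} must be < {hi}")


@dataclass
class FilterAudit:
    """Per-step survivor counts mirroring the audit-table layout:
    step name, loci retained, offspring genotypes retained, % missing."""

    rows: list[dict] = field(default_factory=list)

    def record(self, step: str, gt: GenotypeMatrix, offspring_idx: np.ndarray) -> None:
        calls = gt.calls[:, offspring_idx]
        n_cells = calls.size
        n_called = int((calls != MISSING).sum())
        self.rows.append(
            {
                "step": step,
                "loci": gt.n_loci,
                "genotypes": n_called,
                "pct_missing": 100.0 * (n_cells - n_called) / n_cells if n_cells else 0.0,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ---------------------------------------------------------------------------
# A. pre-genotyping per-base depth filter
# ---------------------------------------------------------------------------

def prefilter_positions(
    depth_records: Iterable[tuple[str, int, int]], cfg: FilterConfig
) -> tuple[set[tuple[str, int]], pd.DataFrame]:
    """Keep positions whose pooled depth lies inside the log10 window.

    Bounds are evaluated on integer read counts (round(10^min) <= depth
    <= round(10^max)); zero depth is always dropped. Also returns a
    log10-depth histogram table for threshold-setting plots.
    """
    lo = int(round(10 ** cfg.prefilter_log10_depth_min))
    hi = int(round(10 ** cfg.prefilter_log10_depth_max))
    keep: set[tuple[str, int]] = set()
    depths = []
    for scaffold, pos, depth in depth_records:
        depths.append(depth)
        if depth >= max(lo, 1) and depth <= hi:
            keep.add((scaffold, pos))
    depths = np.asarray(depths)
    pos_depths = depths[depths > 0]
    if pos_depths.size:
        hist, edges = np.histogram(np.log10(pos_depths), bins=50)
        hist_df = pd.DataFrame(
            {"log10_depth_low": edges[:-1], "log10_depth_high": edges[1:], "count": hist}
        )
    else:
        hist_df = pd.DataFrame(columns=["log10_depth_low", "log10_depth_high", "count"])
    return keep, hist_df


# ---------------------------------------------------------------------------
# B. pooled allele-balance locus filter
# ---------------------------------------------------------------------------

def filter_loci_allele_balance(ad: AlleleDepthMatrix, cfg: FilterConfig) -> np.ndarray:
    """Boolean keep-mask: pooled log2(ref/alt) within the window; loci
    with either pooled allele at zero reads are dropped."""
    ref_tot = ad.ref_depth.sum(axis=1).astype(float)
    alt_tot = ad.alt_depth.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(ref_tot / alt_tot)
    keep = (
        (ref_tot > 0)
        & (alt_tot > 0)
        & (ratio >= cfg.locus_log2_refalt_min)
        & (ratio <= cfg.locus_log2_refalt_max)
    )
    return keep


# ---------------------------------------------------------------------------
# C. pooled total-depth locus filter
# ---------------------------------------------------------------------------

def filter_loci_total_depth(ad: AlleleDepthMatrix, cfg: FilterConfig) -> np.ndarray:
    """Boolean keep-mask: inclusive pooled-depth window (strict removal
    below min / above max, matching the printed '<'/'>' criteria)."""
    total = ad.total_depth.sum(axis=1)
    return (total >= cfg.locus_total_depth_min) & (total <= cfg.locus_total_depth_max)


# ---------------------------------------------------------------------------
# D + E. per-genotype masks
# ---------------------------------------------------------------------------

def mask_genotype_depth(
    ad: AlleleDepthMatrix, gt: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, int]:
    """Step D: mask calls whose per-genotype depth falls outside the
    inclusive [min, max] window. Calls only ever become MISSING."""
    depth = ad.total_depth
    calls = gt.calls.copy()
    called = calls != MISSING
    bad = called & ((depth < cfg.genotype_depth_min) | (depth > cfg.genotype_depth_max))
    calls[bad] = MISSING
    return GenotypeMatrix(calls), int(bad.sum())


def mask_het_allele_balance(
    ad: AlleleDepthMatrix, gt: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, int]:
    """Step E: mask heterozygous calls with |log2(ref/alt)| strictly
    beyond the bound; a het with either allele at zero reads is by
    definition mis-called and is masked too."""
    calls = gt.calls.copy()
    het = calls == AB
    ref = ad.ref_depth.astype(float)
    alt = ad.alt_depth.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.abs(np.log2(ref / alt))
    bad = het & ((ref == 0) | (alt == 0) | (log_ratio > cfg.het_abs_log2_ratio_max))
    calls[bad] = MISSING
    return GenotypeMatrix(calls), int(bad.sum())


def filter_genotypes(
    ad: AlleleDepthMatrix, gt: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, int, int]:
    """Steps D then E combined; returns (masked matrix, n_masked_depth,
    n_masked_het_balance)."""
    gt, n_depth = mask_genotype_depth(ad, gt, cfg)
    gt, n_het = mask_het_allele_balance(ad, gt, cfg)
    return gt, n_depth, n_het


# ---------------------------------------------------------------------------
# F. offspring missingness locus filter
# ---------------------------------------------------------------------------

def filter_missingness(
    gt: GenotypeMatrix, offspring_idx: np.ndarray, cfg: FilterConfig,
    n_offspring_nominal: int | None = None,
) -> np.ndarray:
    """Boolean keep-mask: loci with enough called offspring genotypes.
    Parents are excluded from the count."""
    called = (gt.calls[:, offspring_idx] != MISSING).sum(axis=1)
    if cfg.missingness_counts_missing:
        n = n_offspring_nominal if n_offspring_nominal is not None else len(offspring_idx)
        max_missing = n - cfg.min_called_offspring
        return (len(offspring_idx) - called) <= max_missing
    return called >= cfg.min_called_offspring


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_filter_cascade(
    ad: AlleleDepthMatrix,
    gt: GenotypeMatrix,
    cfg: FilterConfig,
) -> tuple[AlleleDepthMatrix, GenotypeMatrix, FilterAudit]:
    """Apply filters B..F in order on already pre-filtered matrices,
    recording survivor counts after every step."""
    audit = FilterAudit()
    off_idx = ad.offspring_indices
    audit.record("input", gt, off_idx)

    keep = np.where(filter_loci_allele_balance(ad, cfg))[0]
    ad, gt = ad.take(keep), gt.take(keep)
    audit.record("B_locus_allele_balance", gt, off_idx)

    keep = np.where(filter_loci_total_depth(ad, cfg))[0]
    ad, gt = ad.take(keep), gt.take(keep)
    audit.record("C_locus_total_depth", gt, off_idx)

    gt, n_depth = mask_genotype_depth(ad, gt, cfg)
    audit.record("D_genotype_depth", gt, off_idx)
    gt, n_het = mask_het_allele_balance(ad, gt, cfg)
    audit.record("E_het_allele_balance", gt, off_idx)

    keep = np.where(filter_missingness(gt, off_idx, cfg))[0]
    ad, gt = ad.take(keep), gt.take(keep)
    audit.record("F_locus_missingness", gt, off_idx)

    if ad.n_loci == 0:
        raise ValueError(
            "filter cascade removed every locus; review the thresholds "
            "against the depth/balance histograms"
        )
    return ad, gt, audit
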