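"""ML inference of parental cross-type under a heterozygote-dropout model.

At a biallelic locus in an outbred F1 family the informative parental
cross-types are aa x ab, ab x bb, ab x ab and aa x bb. A truly
heterozygous offspring fails to show one of its alleles with
per-direction probability ``e`` (total dropout probability 2e), turning
an ab call into aa or bb. Offspring genotype counts (n_aa, n_ab, n_bb)
then follow a multinomial with category probabilities

    aa x ab : (0.5 + e/2,  0.5 - e,   e/2)
    ab x bb : (e/2,        0.5 - e,   0.5 + e/2)
    ab x ab : (0.25 + e/2, 0.5 - e,   0.25 + e/2)
    aa x bb : (e,          1 - 2e,    e)

A single global ``e`` is profiled over all loci jointly (each locus
contributing its best cross-type), then loci are classified at the
estimate, impossible genotypes are corrected to heterozygotes, and loci
are screened for segregation distortion and parent concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy

from .core import AA, AB, BB, MISSING, GenotypeMatrix

CROSS_TYPES = ("AAxAB", "ABxBB", "ABxAB", "AAxBB")
SINGLE_HET = ("AAxAB", "ABxBB")


def category_probs(cross_type: str, e: float) -> np.ndarray:
    """(p_aa, p_ab, p_bb) for offspring observed genotypes under the
    dropout model; sums to 1 for every e in [0, 0.5]."""
    if not 0.0 <= e <= 0.5:
        raise ValueError(f"e must be in [0, 0.5], got {e}")
    if cross_type == "AAxAB":
        return np.array([0.5 + e / 2, 0.5 - e, e / 2])
    if cross_type == "ABxBB":
        return np.array([e / 2, 0.5 - e, 0.5 + e / 2])
    if cross_type == "ABxAB":
        return np.array([0.25 + e / 2, 0.5 - e, 0.25 + e / 2])
    if cross_type == "AAxBB":
        return np.array([e, 1 - 2 * e, e])
    raise ValueError(f"unknown cross type {cross_type!r}")


def crosstype_loglik(counts, cross_type: str, e: float) -> float:
    """Multinomial log-likelihood sum n_g log p_g (constant term
    dropped); categories with n_g = 0 contribute 0, n_g > 0 with
    p_g = 0 gives -inf."""
    n = np.asarray(counts, dtype=float)
    if n.min() < 0:
        raise ValueError("counts must be non-negative")
    p = category_probs(cross_type, e)
    with np.errstate(divide="ignore"):
        terms = xlogy(n, p)
    return float(terms.sum())


def genotype_counts(gt: GenotypeMatrix, offspring_idx: np.ndarray) -> np.ndarray:
    """(n_loci, 3) offspring counts of AA/AB/BB calls."""
    calls = gt.calls[:, offspring_idx]
    return np.stack(
        [(calls == g).sum(axis=1) for g in (AA, AB, BB)], axis=1
    ).astype(float)


def _profile_loglik(counts: np.ndarray, e: float) -> float:
    """Sum over loci of the best cross-type log-likelihood at e."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.stack(
            [np.log(category_probs(ct, e)) for ct in CROSS_TYPES]
        )  # (4, 3)
        per_type = counts @ logp.T  # (n_loci, 4); 0 * -inf -> nan
        # recompute cleanly with xlogy where -inf * 0 matters
        if np.isnan(per_type).any() or np.isneginf(logp).any():
            per_type = np.stack(
                [xlogy(counts, category_probs(ct, e)).sum(axis=1) for ct in CROSS_TYPES],
                axis=1,
            )
    return float(per_type.max(axis=1).sum())


@dataclass
class GlobalEstimate:
    e_hat: float
    loglik: float
    grid_e: np.ndarray
    grid_loglik: np.ndarray


def estimate_global_e(counts: np.ndarray, grid_step: float = 0.005) -> GlobalEstimate:
    """Profile-ML estimate of the global dropout rate: coarse grid over
    [0, 0.5] followed by bounded scalar refinement around the best grid
    point."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[0] < 1:
        raise ValueError("need at least one locus")
    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    grid_ll = np.array([_profile_loglik(counts, e) for e in grid])
    best = int(np.argmax(grid_ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda e: -_profile_loglik(counts, e),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        e_hat, ll = float(res.x), float(-res.fun)
        if ll < grid_ll[best]:
            e_hat, ll = float(grid[best]), float(grid_ll[best])
    else:
        e_hat, ll = float(grid[best]), float(grid_ll[best])
    return GlobalEstimate(e_hat, ll, grid, grid_ll)


@dataclass
class CrossTypeCall:
    """Per-locus ML cross-type at the global e."""

    cross_type: str
    logliks: dict[str, float]
    tied: bool = False
    het_parent: str | None = None  # set by the concordance step
    unoriented: bool = False


def classify_loci(counts: np.ndarray, e_hat: float) -> list[CrossTypeCall]:
    """Argmax cross-type per locus at the fixed global e; ties broken by
    the fixed enumeration order (AAxAB, ABxBB, ABxAB, AAxBB) and
    flagged."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    per_type = np.stack(
        [xlogy(counts, category_probs(ct, e_hat)).sum(axis=1) for ct in CROSS_TYPES],
        axis=1,
    )
    calls = []
    for row in per_type:
        best = int(np.argmax(row))
        tied = bool((row == row[best]).sum() > 1)
        calls.append(
            CrossTypeCall(
                CROSS_TYPES[best],
                dict(zip(CROSS_TYPES, map(float, row))),
                tied=tied,
            )
        )
    return calls


def correct_dropout_genotypes(
    gt: GenotypeMatrix,
    calls: list[CrossTypeCall],
    offspring_idx: np.ndarray,
) -> tuple[GenotypeMatrix, int]:
    """Correct impossible offspring genotypes to heterozygotes:
    aa x ab loci turn bb into ab, ab x bb loci turn aa into ab and
    aa x bb loci turn both homozygotes into ab. ab x ab loci are left
    unchanged (all three genotypes are possible there, which prevents
    the correction)."""
    out = gt.calls.copy()
    n_corrected = 0
    for i, call in enumerate(calls):
        if call.cross_type == "ABxAB":
            continue
        row = out[i, offspring_idx]
        if call.cross_type == "AAxAB":
            bad = row == BB
        elif call.cross_type == "ABxBB":
            bad = row == AA
        else:  # AAxBB
            bad = (row == AA) | (row == BB)
        if bad.any():
            row[bad] = AB
            out[i, offspring_idx] = row
            n_corrected += int(bad.sum())
    return GenotypeMatrix(out), n_corrected


def test_segregation(counts, cross_type: str, alternative: str = "two-sided") -> float:
    """Segregation-distortion p-value after dropout correction.

    Single-heterozygote cross-types: exact binomial test of the two
    permitted genotype classes against 1:1. ab x ab: chi-square goodness
    of fit against 1:2:1 (df 2). aa x bb: p = 1 by convention (no
    segregation to test). Zero total count returns nan (caller should
    drop the locus)."""
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    total = n_aa + n_ab + n_bb
    if total == 0:
        return float("nan")
    if cross_type == "AAxBB":
        return 1.0
    if cross_type == "ABxAB":
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        exp = total * np.array([0.25, 0.5, 0.25])
        return float(stats.chisquare(obs, exp).pvalue)
    if cross_type == "AAxAB":
        k, n = n_aa, n_aa + n_ab
    elif cross_type == "ABxBB":
        k, n = n_bb, n_bb + n_ab
    else:
        raise ValueError(f"unknown cross type {cross_type!r}")
    if n == 0:
        return float("nan")
    return float(stats.binomtest(k, n, 0.5, alternative=alternative).pvalue)


_COMPATIBLE = {
    "AAxAB": frozenset({(AA, AB), (AB, AA)}),
    "ABxBB": frozenset({(AB, BB), (BB, AB)}),
    "ABxAB": frozenset({(AB, AB)}),
    "AAxBB": frozenset({(AA, BB), (BB, AA)}),
}


def concordance_filter(
    calls: list[CrossTypeCall],
    mother_gt: np.ndarray,
    father_gt: np.ndarray,
) -> np.ndarray:
    """Check observed parental genotypes against each locus's ML
    cross-type. Returns a keep-mask; compatible single-het loci get
    their ``het_parent`` orientation tag set, loci with a MISSING parent
    are retained but flagged unoriented."""
    keep = np.ones(len(calls), dtype=bool)
    for i, call in enumerate(calls):
        m, f = int(mother_gt[i]), int(father_gt[i])
        if m == MISSING or f == MISSING:
            call.unoriented = True
            continue
        if (m, f) not in _COMPATIBLE[call.cross_type]:
            keep[i] = False
            continue
        if call.cross_type in SINGLE_HET:
            call.het_parent = "mother" if m == AB else "father"
    return keep
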