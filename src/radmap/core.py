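"""Core in-memory containers shared across the pipeline.

Genotype calls are encoded as small integers on a per-(locus, sample)
matrix: ``AA``/``AB``/``BB`` for homozygous-reference, heterozygous and
homozygous-alternate, ``MISSING`` for no call. All genomic coordinates are
1-based inclusive throughout the package (VCF/GFF/AGP convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# genotype codes
MISSING: int = -1
AA: int = 0
AB: int = 1
BB: int = 2

GT_LABELS = {MISSING: "./.", AA: "0/0", AB: "0/1", BB: "1/1"}
GT_FROM_LABEL = {v: k for k, v in GT_LABELS.items()}
GT_FROM_LABEL["1/0"] = AB


@dataclass(frozen=True)
class LocusMeta:
    """A biallelic SNP: the unit of analysis.

    ``position`` is the 1-based coordinate on ``scaffold``; ``(scaffold,
    position)`` is unique across loci.
    """

    locus_id: str
    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical at {self.locus_id}")


class AlleleDepthMatrix:
    """Per-locus, per-sample reference/alternate read counts.

    Samples are ordered; exactly one sample is tagged mother and one
    father, the rest are offspring. The same sample ordering is shared
    with the :class:`GenotypeMatrix` derived from the same source.
    """

    def __init__(
        self,
        loci: list[LocusMeta],
        samples: list[str],
        mother: str,
        father: str,
        ref_depth: np.ndarray,
        alt_depth: np.ndarray,
    ):
        ref_depth = np.asarray(ref_depth, dtype=np.int32)
        alt_depth = np.asarray(alt_depth, dtype=np.int32)
        if ref_depth.shape != (len(loci), len(samples)):
            raise ValueError("ref_depth shape does not match loci x samples")
        if alt_depth.shape != ref_depth.shape:
            raise ValueError("alt_depth shape does not match ref_depth")
        if (ref_depth < 0).any() or (alt_depth < 0).any():
            raise ValueError("depths must be non-negative")
        if mother not in samples or father not in samples:
            raise ValueError("mother/father must be among the samples")
        if mother == father:
            raise ValueError("mother and father must be distinct samples")
        if len(samples) < 3:
            raise ValueError("need at least one offspring sample")
        seen = set()
        for loc in loci:
            key = (loc.scaffold, loc.position)
            if key in seen:
                raise ValueError(f"duplicate locus at {key}")
            seen.add(key)
        self.loci = list(loci)
        self.samples = list(samples)
        self.mother = mother
        self.father = father
        self.ref_depth = ref_depth
        self.alt_depth = alt_depth

    # -- indexing helpers -------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def mother_index(self) -> int:
        return self.samples.index(self.mother)

    @property
    def father_index(self) -> int:
        return self.samples.index(self.father)

    @property
    def offspring_indices(self) -> np.ndarray:
        par = {self.mother_index, self.father_index}
        return np.array([i for i in range(self.n_samples) if i not in par])

    @property
    def n_offspring(self) -> int:
        return self.n_samples - 2

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def take(self, locus_indices) -> "AlleleDepthMatrix":
        idx = np.asarray(locus_indices)
        return AlleleDepthMatrix(
            [self.loci[i] for i in idx],
            self.samples,
            self.mother,
            self.father,
            self.ref_depth[idx],
            self.alt_depth[idx],
        )


class GenotypeMatrix:
    """Calls per (locus, sample) in {AA, AB, BB, MISSING}.

    Shares shape and sample ordering with its source AlleleDepthMatrix.
    """

    def __init__(self, calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if not np.isin(calls, [MISSING, AA, AB, BB]).all():
            raise ValueError("invalid genotype code in calls")
        self.calls = calls

    @property
    def n_loci(self) -> int:
        return self.calls.shape[0]

    def take(self, locus_indices) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[np.asarray(locus_indices)])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy())


ScaffoldIndex = dict  # scaffold id -> length in bp


def check_scaffold_index(index: ScaffoldIndex, loci: list[LocusMeta]) -> None:
    for name, length in index.items():
        if length < 1:
            raise ValueError(f"scaffold {name} has non-positive length")
    missing = {loc.scaffold for loc in loci} - set(index)
    if missing:
        raise ValueError(f"loci reference scaffolds absent from index: {sorted(missing)[:5]}")


@dataclass
class ScaffoldPlacement:
    """One scaffold anchored on a chromosome.

    ``orientation`` is '+', '-' or '?' (anchored but not orientable);
    ``offset`` is the 0-based chromosome coordinate at which the scaffold
    starts, i.e. the scaffold occupies [offset+1, offset+length].
    """

    scaffold: str
    orientation: str
    offset: int = 0


@dataclass
class ConsensusMap:
    """Chromosome-level scaffold order/orientation plus unplaced scaffolds."""

    chromosomes: dict[str, list[ScaffoldPlacement]] = field(default_factory=dict)
    unplaced: list[str] = field(default_factory=list)

    def placement_of(self, scaffold: str) -> tuple[str, ScaffoldPlacement] | None:
        for chrom, placements in self.chromosomes.items():
            for p in placements:
                if p.scaffold == scaffold:
                    return chrom, p
        return None

    def assign_offsets(self, scaffold_index: ScaffoldIndex, gap_length: int = 100) -> None:
        """Recompute offsets from cumulative scaffold lengths + gaps."""
        for placements in self.chromosomes.values():
            offset = 0
            for i, p in enumerate(placements):
                if i > 0:
                    offset += gap_length
                p.offset = offset
                offset += scaffold_index[p.scaffold]
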