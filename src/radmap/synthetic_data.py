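"""Synthetic F1 outbred-cross RAD-seq datasets with known truth.

The generator emulates the study design every downstream stage expects:
a 24-chromosome genome fragmented into shuffled, randomly-flipped
scaffolds; a single outbred family (two parents, 90 offspring); RAD-tag
loci whose pooled depth is centred near 1000 reads; repeat-region
coverage inflation; heterozygote allelic dropout at a per-direction rate
``e`` (total 2e); and the four informative parental cross-types.
Crossovers are placed as a Poisson process along the true chromosome
(no interference), matching the Haldane map function used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AA,
    AB,
    BB,
    MISSING,
    AlleleDepthMatrix,
    ConsensusMap,
    GenotypeMatrix,
    LocusMeta,
    ScaffoldIndex,
    ScaffoldPlacement,
)
from . import formats_io

# (cross class, heterozygous parent); single-het classes appear in both
# parental orientations, double-het and fully-informative have none.
_CROSS_KINDS = [
    ("AAxAB", "mother"),
    ("AAxAB", "father"),
    ("ABxBB", "mother"),
    ("ABxBB", "father"),
    ("ABxAB", None),
    ("AAxBB", None),
]
_CROSS_PROBS = np.array([0.175, 0.175, 0.175, 0.175, 0.20, 0.10])


@dataclass
class SimConfig:
    """Study conditions for the synthetic cross.

    Chromosome length is scaled down from the ~35 Mb killifish
    chromosomes to keep desk-scale runs fast; the recombination density
    (2.34 cM/Mb) and family size (90 offspring) are kept as in the study
    being emulated.
    """

    n_chromosomes: int = 24
    chromosome_length_bp: int = 5_000_000
    n_scaffolds_per_chromosome: int = 20
    n_offspring: int = 90
    rad_sites_per_scaffold: tuple[int, int] = (5, 10)
    cm_per_mb: float = 2.34
    dropout_e: float = 0.05
    mean_pooled_depth: float = 1000.0
    nb_dispersion: float = 10.0
    parent_depth_multiplier: float = 2.5
    repeat_fraction: float = 0.02
    repeat_multiplier: float = 30.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_e <= 0.5:
            raise ValueError("dropout_e must be in [0, 0.5]")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        for name in ("n_chromosomes", "chromosome_length_bp",
                     "n_scaffolds_per_chromosome", "n_offspring"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def rate_per_bp(self) -> float:
        """Crossover rate per bp per meiosis (Morgans/bp)."""
        return self.cm_per_mb / 100.0 / 1e6


@dataclass
class TruthSet:
    """Simulator ground truth for scoring every downstream stage."""

    loci: list[LocusMeta]
    chrom_of_locus: np.ndarray  # chromosome id per locus
    chrom_pos: np.ndarray  # true chromosome coordinate per locus
    cross_class: np.ndarray  # AAxAB / ABxBB / ABxAB / AAxBB
    het_parent: np.ndarray  # mother / father / '' per locus
    mother_haps: np.ndarray  # (n_loci, 2) alleles 0=ref 1=alt, phased
    father_haps: np.ndarray
    transmitted_mother: np.ndarray  # (n_loci, n_offspring) allele 0/1
    transmitted_father: np.ndarray
    crossovers: dict  # (parent, offspring, chrom) -> array of bp positions
    truth_map: ConsensusMap  # true scaffold order/orientation
    repeat_locus: np.ndarray  # bool per locus
    dropout_events: list = field(default_factory=list)  # (locus, sample, kept allele)
    samples: list[str] = field(default_factory=list)

    def true_genotypes(self) -> np.ndarray:
        """Offspring genotype codes derived from transmissions."""
        s = self.transmitted_mother + self.transmitted_father
        out = np.full(s.shape, AB, dtype=np.int8)
        out[s == 0] = AA
        out[s == 2] = BB
        return out


# ---------------------------------------------------------------------------
# Genome fragmentation
# ---------------------------------------------------------------------------

def fragment_genome(cfg: SimConfig, rng: np.random.Generator) -> tuple[ScaffoldIndex, ConsensusMap]:
    """Partition each chromosome into contiguous scaffolds (Dirichlet
    lengths), then shuffle and randomly flip them to define the
    "assembly" frame. The returned ConsensusMap is the inverse mapping
    (the truth AGP)."""
    n_total = cfg.n_chromosomes * cfg.n_scaffolds_per_chromosome
    perm = rng.permutation(n_total)
    names = [f"scaffold_{perm[i] + 1:04d}" for i in range(n_total)]
    index: ScaffoldIndex = {}
    truth = ConsensusMap()
    k = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        w = rng.dirichlet(np.full(cfg.n_scaffolds_per_chromosome, 3.0))
        lengths = np.maximum(1, np.round(w * cfg.chromosome_length_bp).astype(int))
        lengths[-1] += cfg.chromosome_length_bp - lengths.sum()
        lengths[-1] = max(lengths[-1], 1)
        placements = []
        offset = 0
        for length in lengths:
            name = names[k]
            k += 1
            index[name] = int(length)
            orientation = "+" if rng.random() < 0.5 else "-"
            placements.append(ScaffoldPlacement(name, orientation, offset))
            offset += int(length)
        truth.chromosomes[chrom] = placements
    return index, truth


def scaffold_to_chrom(
    placement: ScaffoldPlacement, length: int, pos: int
) -> int:
    """Map a 1-based scaffold-local position to its true chromosome
    coordinate through a placement."""
    if placement.orientation == "-":
        return placement.offset + (length - pos + 1)
    return placement.offset + pos


def flip_scaffolds(consensus: ConsensusMap, scaffolds: set[str]) -> ConsensusMap:
    """Copy of a map with the orientation of the given scaffolds reversed."""
    out = ConsensusMap(unplaced=list(consensus.unplaced))
    for chrom, placements in consensus.chromosomes.items():
        out.chromosomes[chrom] = [
            ScaffoldPlacement(
                p.scaffold,
                {"+": "-", "-": "+"}.get(p.orientation, p.orientation)
                if p.scaffold in scaffolds else p.orientation,
                p.offset,
            )
            for p in placements
        ]
    return out


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis_states(
    rng: np.random.Generator,
    positions: np.ndarray,
    n_meioses: int,
    rate_per_bp: float,
    length: float | None = None,
) -> np.ndarray:
    """Haplotype index (0/1) transmitted at each position for each
    meiosis. Crossovers are a Poisson process with the given per-bp rate;
    the starting haplotype is uniform."""
    positions = np.asarray(positions, dtype=float)
    L = float(length if length is not None else positions.max())
    states = np.empty((n_meioses, positions.size), dtype=np.int8)
    for m in range(n_meioses):
        n_xo = rng.poisson(rate_per_bp * L)
        start = rng.integers(0, 2)
        if n_xo == 0:
            states[m] = start
            continue
        xo = np.sort(rng.uniform(0, L, size=n_xo))
        states[m] = (start + np.searchsorted(xo, positions)) % 2
    return states


# ---------------------------------------------------------------------------
# Pedigree genotypes
# ---------------------------------------------------------------------------

def simulate_pedigree_genotypes(
    cfg: SimConfig,
    scaffold_index: ScaffoldIndex,
    truth_map: ConsensusMap,
    rng: np.random.Generator,
) -> TruthSet:
    """Draw RAD loci, parental phased genotypes and offspring
    transmissions. Every informative cross-type occurs; gametes carry
    Poisson crossovers along the true chromosome coordinate."""
    loci: list[LocusMeta] = []
    chrom_of, chrom_pos = [], []
    lo, hi = cfg.rad_sites_per_scaffold
    for chrom, placements in truth_map.chromosomes.items():
        for p in placements:
            length = scaffold_index[p.scaffold]
            n_sites = int(rng.integers(lo, hi + 1))
            n_sites = min(n_sites, length)
            pos = np.sort(rng.choice(length, size=n_sites, replace=False) + 1)
            for q in pos:
                ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
                loci.append(
                    LocusMeta(f"{p.scaffold}:{q}", p.scaffold, int(q), ref, alt)
                )
                chrom_of.append(chrom)
                chrom_pos.append(scaffold_to_chrom(p, length, int(q)))
    n_loci = len(loci)
    chrom_of = np.array(chrom_of)
    chrom_pos = np.array(chrom_pos)

    kinds = rng.choice(len(_CROSS_KINDS), size=n_loci, p=_CROSS_PROBS)
    cross_class = np.array([_CROSS_KINDS[k][0] for k in kinds])
    het_parent = np.array([_CROSS_KINDS[k][1] or "" for k in kinds])

    def parent_haps(parent: str) -> np.ndarray:
        haps = np.zeros((n_loci, 2), dtype=np.int8)
        for i in range(n_loci):
            cls, hp = cross_class[i], het_parent[i]
            if cls == "AAxBB":
                # mother aa, father bb
                alleles = (0, 0) if parent == "mother" else (1, 1)
            elif cls == "ABxAB" or hp == parent:
                alleles = (0, 1) if rng.random() < 0.5 else (1, 0)
            else:
                # homozygous parent of a single-het cross: AA under AAxAB,
                # BB under ABxBB
                alleles = (0, 0) if cls == "AAxAB" else (1, 1)
            haps[i] = alleles
        return haps

    mother_haps = parent_haps("mother")
    father_haps = parent_haps("father")

    transmitted = {}
    crossovers: dict = {}
    for parent, haps in (("mother", mother_haps), ("father", father_haps)):
        out = np.zeros((n_loci, cfg.n_offspring), dtype=np.int8)
        for chrom in truth_map.chromosomes:
            sel = np.where(chrom_of == chrom)[0]
            order = sel[np.argsort(chrom_pos[sel])]
            pos = chrom_pos[order].astype(float)
            L = float(cfg.chromosome_length_bp)
            for m in range(cfg.n_offspring):
                n_xo = rng.poisson(cfg.rate_per_bp * L)
                start = int(rng.integers(0, 2))
                if n_xo:
                    xo = np.sort(rng.uniform(0, L, size=n_xo))
                    state = (start + np.searchsorted(xo, pos)) % 2
                else:
                    xo = np.empty(0)
                    state = np.full(pos.size, start)
                crossovers[(parent, m, chrom)] = xo
                out[order, m] = haps[order, state]
        transmitted[parent] = out

    repeat_locus = rng.random(n_loci) < cfg.repeat_fraction
    samples = ["mother", "father"] + [f"off_{i + 1:03d}" for i in range(cfg.n_offspring)]
    return TruthSet(
        loci=loci,
        chrom_of_locus=chrom_of,
        chrom_pos=chrom_pos,
        cross_class=cross_class,
        het_parent=het_parent,
        mother_haps=mother_haps,
        father_haps=father_haps,
        transmitted_mother=transmitted["mother"],
        transmitted_father=transmitted["father"],
        crossovers=crossovers,
        truth_map=truth_map,
        repeat_locus=repeat_locus,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Read depths and observed genotypes
# ---------------------------------------------------------------------------

def _truncated_binomial_split(rng: np.random.Generator, depth: np.ndarray) -> np.ndarray:
    """Reference-read counts for heterozygotes: binomial(d, 0.5)
    conditioned on both alleles being seen (1 <= k <= d-1). Depths < 2
    give all reads to one allele at random."""
    depth = np.asarray(depth)
    k = rng.binomial(depth, 0.5)
    bad = (depth >= 2) & ((k == 0) | (k == depth))
    while bad.any():
        k[bad] = rng.binomial(depth[bad], 0.5)
        bad = (depth >= 2) & ((k == 0) | (k == depth))
    low = depth < 2
    if low.any():
        k[low] = np.where(rng.random(low.sum()) < 0.5, depth[low], 0)
    return k


def simulate_read_depths(
    truth: TruthSet, cfg: SimConfig, rng: np.random.Generator
) -> tuple[AlleleDepthMatrix, GenotypeMatrix]:
    """Per-genotype negative-binomial depths, binomial allele splits for
    heterozygotes, explicit allelic dropout for offspring heterozygotes
    (probability 2e, all reads assigned to one allele), repeat-locus
    depth inflation and optional uniform call errors.

    Observed call: AB when both alleles have >= 1 read, otherwise the
    homozygote of the seen allele; zero depth is MISSING.
    """
    n_loci = len(truth.loci)
    samples = truth.samples
    n_samples = len(samples)
    mu_off = cfg.mean_pooled_depth / n_samples
    true_off = truth.true_genotypes()

    # true genotype per (locus, sample): parents first two columns
    def hap_gt(haps: np.ndarray) -> np.ndarray:
        s = haps.sum(axis=1)
        out = np.full(n_loci, AB, dtype=np.int8)
        out[s == 0] = AA
        out[s == 2] = BB
        return out

    true_gt = np.empty((n_loci, n_samples), dtype=np.int8)
    true_gt[:, 0] = hap_gt(truth.mother_haps)
    true_gt[:, 1] = hap_gt(truth.father_haps)
    true_gt[:, 2:] = true_off

    mu = np.full((n_loci, n_samples), mu_off)
    mu[:, :2] *= cfg.parent_depth_multiplier
    mu[truth.repeat_locus, :] *= cfg.repeat_multiplier
    r = cfg.nb_dispersion
    depth = rng.negative_binomial(r, r / (r + mu))

    ref_d = np.zeros_like(depth)
    alt_d = np.zeros_like(depth)
    hom_ref = true_gt == AA
    hom_alt = true_gt == BB
    het = true_gt == AB
    ref_d[hom_ref] = depth[hom_ref]
    alt_d[hom_alt] = depth[hom_alt]
    if het.any():
        k = _truncated_binomial_split(rng, depth[het])
        ref_d[het] = k
        alt_d[het] = depth[het] - k

    # explicit allelic dropout: offspring heterozygotes only (parents are
    # deeply sequenced in the emulated design)
    if cfg.dropout_e > 0:
        off_het = het.copy()
        off_het[:, :2] = False
        idx = np.where(off_het)
        hit = rng.random(idx[0].size) < 2.0 * cfg.dropout_e
        keep_ref = rng.random(idx[0].size) < 0.5
        for li, si, h, kr in zip(idx[0], idx[1], hit, keep_ref):
            if not h:
                continue
            d = depth[li, si]
            if kr:
                ref_d[li, si], alt_d[li, si] = d, 0
            else:
                ref_d[li, si], alt_d[li, si] = 0, d
            truth.dropout_events.append((int(li), int(si), "ref" if kr else "alt"))

    calls = np.full((n_loci, n_samples), MISSING, dtype=np.int8)
    both = (ref_d > 0) & (alt_d > 0)
    only_ref = (ref_d > 0) & (alt_d == 0)
    only_alt = (alt_d > 0) & (ref_d == 0)
    calls[both] = AB
    calls[only_ref] = AA
    calls[only_alt] = BB

    if cfg.genotype_error_rate > 0:
        called = calls != MISSING
        flip = called & (rng.random(calls.shape) < cfg.genotype_error_rate)
        if flip.any():
            shift = rng.integers(1, 3, size=int(flip.sum()))
            calls[flip] = (calls[flip] + shift) % 3

    ad = AlleleDepthMatrix(truth.loci, samples, "mother", "father", ref_d, alt_d)
    return ad, GenotypeMatrix(calls)


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig, seed: int | None = None):
    """One-call simulation: returns (truth, scaffold_index, ad, gt)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    scaffold_index, truth_map = fragment_genome(cfg, rng)
    truth = simulate_pedigree_genotypes(cfg, scaffold_index, truth_map, rng)
    ad, gt = simulate_read_depths(truth, cfg, rng)
    return truth, scaffold_index, ad, gt


def depth_table_records(
    truth: TruthSet,
    ad: AlleleDepthMatrix,
    rng: np.random.Generator,
    background_per_scaffold: int = 2,
):
    """Pooled per-base depth records at RAD positions plus a sprinkle of
    low-coverage background positions (the paired-end mass the
    pre-genotyping filter removes)."""
    pooled = ad.total_depth.sum(axis=1)
    records = [
        (loc.scaffold, loc.position, int(pooled[i]))
        for i, loc in enumerate(ad.loci)
    ]
    used = {(loc.scaffold, loc.position) for loc in ad.loci}
    scaffolds = sorted({loc.scaffold for loc in ad.loci})
    for s in scaffolds:
        for _ in range(background_per_scaffold):
            pos = int(rng.integers(1, 10_000))
            if (s, pos) in used:
                continue
            records.append((s, pos, int(rng.integers(1, 100))))
    records.sort()
    return records


def write_dataset(out_dir, cfg: SimConfig, truth, scaffold_index, ad, gt) -> dict:
    """Write VCF, depth table, scaffold index, truth AGP and truth
    tables; returns the path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "family.vcf"),
        "depth": os.path.join(out_dir, "depth.tsv"),
        "scaffolds": os.path.join(out_dir, "scaffolds.tsv"),
        "truth_agp": os.path.join(out_dir, "truth.agp"),
        "truth_loci": os.path.join(out_dir, "truth_loci.tsv"),
        "config": os.path.join(out_dir, "sim_config.yaml"),
    }
    formats_io.write_vcf(paths["vcf"], ad, gt, header_extra=[f"radmap_seed={cfg.seed}"])
    rng = np.random.default_rng(cfg.seed + 101)
    formats_io.write_depth_table(paths["depth"], depth_table_records(truth, ad, rng))
    formats_io.write_scaffold_index(paths["scaffolds"], scaffold_index)
    # truth chromosomes are contiguous: no gap components, true offsets
    formats_io.write_agp(paths["truth_agp"], truth.truth_map, scaffold_index, gap_length=0)
    df = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in truth.loci],
            "scaffold": [l.scaffold for l in truth.loci],
            "position": [l.position for l in truth.loci],
            "chromosome": truth.chrom_of_locus,
            "chrom_pos": truth.chrom_pos,
            "cross_class": truth.cross_class,
            "het_parent": truth.het_parent,
            "repeat_locus": truth.repeat_locus,
        }
    )
    df.to_csv(paths["truth_loci"], sep="\t", index=False)
    formats_io.dump_config(paths["config"], asdict(cfg))
    return paths


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------

def score_consensus(consensus: ConsensusMap, truth: ConsensusMap) -> dict:
    """Score scaffold-order recovery (Kendall tau per chromosome, sign
    removed: a whole-chromosome reflection is unidentifiable) and
    orientation accuracy among oriented scaffolds."""
    truth_of: dict[str, tuple[str, ScaffoldPlacement]] = {}
    for chrom, placements in truth.chromosomes.items():
        for p in placements:
            truth_of[p.scaffold] = (chrom, p)
    taus = []
    n_orient_correct = n_oriented = 0
    for placements in consensus.chromosomes.values():
        chroms = [truth_of[p.scaffold][0] for p in placements if p.scaffold in truth_of]
        if not chroms:
            continue
        major = pd.Series(chroms).mode().iloc[0]
        members = [p for p in placements if truth_of.get(p.scaffold, ("",))[0] == major]
        if len(members) < 2:
            continue
        x = np.arange(len(members))
        y = np.array([truth_of[p.scaffold][1].offset for p in members])
        tau = stats.kendalltau(x, y).statistic
        if np.isnan(tau):
            continue
        taus.append(abs(tau))
        reversed_chrom = tau < 0
        for p in members:
            if p.orientation not in ("+", "-"):
                continue
            n_oriented += 1
            expected = truth_of[p.scaffold][1].orientation
            if reversed_chrom:
                expected = "+" if expected == "-" else "-"
            if p.orientation == expected:
                n_orient_correct += 1
    return {
        "per_chromosome_tau": taus,
        "mean_abs_tau": float(np.mean(taus)) if taus else float("nan"),
        "n_oriented": n_oriented,
        "orientation_accuracy": (n_orient_correct / n_oriented) if n_oriented else float("nan"),
    }


# ---------------------------------------------------------------------------
# Ortholog / synteny fixture
# ---------------------------------------------------------------------------

def synthetic_ortholog_tables(
    scaffold_index: ScaffoldIndex,
    truth_map: ConsensusMap,
    assembly_map: ConsensusMap,
    genes_per_scaffold: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-position tables for a three-species triangulation fixture.

    Species A carries the focal (possibly mis-oriented) ``assembly_map``
    coordinates; species B and C are fully syntenic comparators laid out
    on the true chromosome coordinates. One-to-one ortholog pairs link
    identical gene ids across species.

    Returns (genes_a, genes_b, genes_c, pairs).
    """
    rows_a, rows_b, rows_c, pairs = [], [], [], []
    place_a: dict[str, tuple[str, ScaffoldPlacement]] = {}
    for chrom, placements in assembly_map.chromosomes.items():
        for p in placements:
            place_a[p.scaffold] = (chrom, p)
    for chrom, placements in truth_map.chromosomes.items():
        for p in placements:
            length = scaffold_index[p.scaffold]
            local = np.linspace(1, length, genes_per_scaffold + 2)[1:-1].astype(int)
            for j, q in enumerate(np.unique(local)):
                gid = f"g_{p.scaffold}_{j}"
                true_pos = scaffold_to_chrom(p, length, int(q))
                hit = place_a.get(p.scaffold)
                if hit is not None:
                    chrom_a, pa = hit
                    rows_a.append(
                        {
                            "gene_id": gid,
                            "chromosome": chrom_a,
                            "start": scaffold_to_chrom(pa, length, int(q)),
                            "scaffold": p.scaffold,
                            "strand": "+",
                        }
                    )
                rows_b.append(
                    {"gene_id": f"b_{gid}", "chromosome": chrom, "start": true_pos,
                     "scaffold": "", "strand": "+"}
                )
                rows_c.append(
                    {"gene_id": f"c_{gid}", "chromosome": chrom, "start": true_pos,
                     "scaffold": "", "strand": "+"}
                )
                pairs.append({"gene_a": gid, "gene_b": f"b_{gid}", "gene_c": f"c_{gid}"})
    return (
        pd.DataFrame(rows_a),
        pd.DataFrame(rows_b),
        pd.DataFrame(rows_c),
        pd.DataFrame(pairs),
    )
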