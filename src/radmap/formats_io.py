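"""Readers/writers for the standard formats the pipeline touches.

VCF is read through ``cyvcf2``; AGP, GFF3, the per-base depth table and
the scaffold index are line formats handled here directly. All
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import yaml
from cyvcf2 import VCF

from .core import (
    AA,
    AB,
    BB,
    MISSING,
    GT_LABELS,
    AlleleDepthMatrix,
    ConsensusMap,
    GenotypeMatrix,
    LocusMeta,
    ScaffoldIndex,
    ScaffoldPlacement,
)

logger = logging.getLogger(__name__)

_NUCS = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_biallelic(
    vcf_path: str, mother: str, father: str
) -> tuple[AlleleDepthMatrix, GenotypeMatrix, int]:
    """Read biallelic SNPs with per-sample allele depths from a VCF.

    Multi-allelic records and indels are skipped; the skip count is
    returned and logged. Genotype calls come from the caller's GT field
    (MISSING when absent); absent AD values are read as depth 0.

    Returns ``(depths, genotypes, n_skipped)``.
    """
    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    for parent, tag in ((mother, "mother"), (father, "father")):
        if parent not in samples:
            raise ValueError(f"{tag} sample {parent!r} not in VCF header")
    loci: list[LocusMeta] = []
    ref_rows, alt_rows, call_rows = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in _NUCS or var.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} lacks the per-sample AD field"
            )
        ad = np.asarray(ad)
        if ad.shape[1] < 2:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} AD field has no alt-depth column"
            )
        ref_d = np.where(ad[:, 0] < 0, 0, ad[:, 0])
        alt_d = np.where(ad[:, 1] < 0, 0, ad[:, 1])
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = var.gt_types.astype(np.int8)
        calls = np.full(g.shape, MISSING, dtype=np.int8)
        calls[g == 0] = AA
        calls[g == 1] = AB
        calls[g == 2] = BB
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(LocusMeta(vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        ref_rows.append(ref_d)
        alt_rows.append(alt_d)
        call_rows.append(calls)
    if n_skipped:
        logger.info("read_vcf_biallelic: skipped %d non-biallelic-SNP records", n_skipped)
    if not loci:
        raise ValueError(f"no biallelic SNP records found in {vcf_path}")
    ad_matrix = AlleleDepthMatrix(
        loci, samples, mother, father, np.array(ref_rows), np.array(alt_rows)
    )
    return ad_matrix, GenotypeMatrix(np.array(call_rows)), n_skipped


def write_vcf(
    path: str,
    ad_matrix: AlleleDepthMatrix,
    gt_matrix: GenotypeMatrix,
    header_extra: list[str] | None = None,
) -> None:
    """Write matrices as a minimal VCF 4.2 file with GT:AD per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radmap\n")
        for line in header_extra or []:
            fh.write(f"##{line}\n")
        scaffolds = sorted({loc.scaffold for loc in ad_matrix.loci})
        for s in scaffolds:
            fh.write(f"##contig=<ID={s}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ad_matrix.samples)
            + "\n"
        )
        order = np.lexsort(
            (
                [loc.position for loc in ad_matrix.loci],
                [loc.scaffold for loc in ad_matrix.loci],
            )
        )
        for i in order:
            loc = ad_matrix.loci[i]
            fields = [
                loc.scaffold,
                str(loc.position),
                loc.locus_id,
                loc.ref_allele,
                loc.alt_allele,
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            for j in range(ad_matrix.n_samples):
                gt = GT_LABELS[int(gt_matrix.calls[i, j])]
                fields.append(
                    f"{gt}:{ad_matrix.ref_depth[i, j]},{ad_matrix.alt_depth[i, j]}"
                )
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Depth table
# ---------------------------------------------------------------------------

def read_depth_table(path: str) -> Iterator[tuple[str, int, int]]:
    """Stream (scaffold, position, pooled_depth) records from a 3-column
    whitespace-delimited text file. Malformed lines are counted, warned
    about once at the end, and skipped."""
    n_bad = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            try:
                scaffold, pos, depth = parts[0], int(parts[1]), int(parts[2])
            except (ValueError, IndexError):
                n_bad += 1
                continue
            yield scaffold, pos, depth
    if n_bad:
        warnings.warn(f"read_depth_table: skipped {n_bad} malformed lines in {path}")


def write_depth_table(path: str, records: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for scaffold, pos, depth in records:
            fh.write(f"{scaffold}\t{pos}\t{depth}\n")


# ---------------------------------------------------------------------------
# Scaffold index
# ---------------------------------------------------------------------------

def read_scaffold_index(path: str) -> ScaffoldIndex:
    """Read a FASTA-index-style table: scaffold <tab> length (extra
    columns, as in .fai, ignored)."""
    index: ScaffoldIndex = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            index[parts[0]] = int(parts[1])
    return index


def write_scaffold_index(path: str, index: ScaffoldIndex) -> None:
    with open(path, "w") as fh:
        for name, length in index.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

@dataclass
class AGPRecord:
    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # W (scaffold) or U (gap)
    component_id: str | None = None  # W only
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # +, -, ?
    gap_length: int | None = None  # U only


DEFAULT_GAP_LENGTH = 100


def consensus_to_agp(
    consensus: ConsensusMap,
    scaffold_index: ScaffoldIndex,
    gap_length: int = DEFAULT_GAP_LENGTH,
) -> list[AGPRecord]:
    """Tile each chromosome with W scaffold components separated by U
    gaps; unplaced scaffolds become single-component objects."""
    records: list[AGPRecord] = []
    for chrom, placements in consensus.chromosomes.items():
        pos = 0
        part = 0
        for i, p in enumerate(placements):
            if p.scaffold not in scaffold_index:
                raise ValueError(f"scaffold {p.scaffold} missing from scaffold index")
            if i > 0 and gap_length > 0:
                part += 1
                records.append(
                    AGPRecord(chrom, pos + 1, pos + gap_length, part, "U",
                              gap_length=gap_length)
                )
                pos += gap_length
            length = scaffold_index[p.scaffold]
            part += 1
            records.append(
                AGPRecord(chrom, pos + 1, pos + length, part, "W",
                          p.scaffold, 1, length, p.orientation)
            )
            pos += length
    for scaffold in consensus.unplaced:
        length = scaffold_index[scaffold]
        records.append(AGPRecord(scaffold, 1, length, 1, "W", scaffold, 1, length, "?"))
    return records


def write_agp(
    path: str,
    consensus: ConsensusMap,
    scaffold_index: ScaffoldIndex,
    gap_length: int = DEFAULT_GAP_LENGTH,
    header_extra: list[str] | None = None,
) -> None:
    records = consensus_to_agp(consensus, scaffold_index, gap_length)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for line in header_extra or []:
            fh.write(f"# {line}\n")
        for r in records:
            if r.component_type == "W":
                cols = [r.object, r.object_beg, r.object_end, r.part_number, "W",
                        r.component_id, r.component_beg, r.component_end, r.orientation]
            else:
                cols = [r.object, r.object_beg, r.object_end, r.part_number, "U",
                        r.gap_length, "map", "no", "na"]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_agp(path: str) -> ConsensusMap:
    """Re-parse an AGP file into a ConsensusMap. Objects whose single W
    component is the object itself are treated as unplaced scaffolds."""
    consensus = ConsensusMap()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            obj, beg = cols[0], int(cols[1])
            if cols[4] == "U":
                continue
            scaffold, orientation = cols[5], cols[8]
            if obj == scaffold:
                consensus.unplaced.append(scaffold)
                continue
            consensus.chromosomes.setdefault(obj, []).append(
                ScaffoldPlacement(scaffold, orientation, beg - 1)
            )
    for placements in consensus.chromosomes.values():
        placements.sort(key=lambda p: p.offset)
    return consensus


# ---------------------------------------------------------------------------
# GFF liftover
# ---------------------------------------------------------------------------

def liftover_gff(
    gff_path: str,
    consensus: ConsensusMap,
    scaffold_index: ScaffoldIndex,
    out_path: str,
) -> tuple[int, int, int]:
    """Rewrite scaffold-local GFF3 features into chromosome coordinates.

    '+' scaffolds shift by the scaffold offset; '-' scaffolds reflect the
    interval (new_start = offset + length - end + 1) and flip strand.
    Features on unplaced or unknown-orientation scaffolds pass through
    unchanged with a ``liftover=unplaced`` attribute. Features extending
    past the scaffold end are skipped with a warning.

    Returns (n_lifted, n_passthrough, n_skipped).
    """
    placement: dict[str, tuple[str, ScaffoldPlacement]] = {}
    for chrom, placements in consensus.chromosomes.items():
        for p in placements:
            placement[p.scaffold] = (chrom, p)
    n_lift = n_pass = n_skip = 0
    flip = {"+": "-", "-": "+", ".": ".", "?": "?"}
    with open(gff_path) as fin, open(out_path, "w") as fout:
        for line in fin:
            if line.startswith("#") or not line.strip():
                fout.write(line)
                continue
            cols = line.rstrip("\n").split("\t")
            scaffold, start, end, strand = cols[0], int(cols[3]), int(cols[4]), cols[6]
            hit = placement.get(scaffold)
            if hit is None or hit[1].orientation == "?":
                attrs = cols[8] if len(cols) > 8 else ""
                cols = cols[:8] + [(attrs + ";" if attrs and attrs != "." else "") + "liftover=unplaced"]
                fout.write("\t".join(cols) + "\n")
                n_pass += 1
                continue
            chrom, p = hit
            length = scaffold_index[scaffold]
            if end > length:
                warnings.warn(
                    f"liftover_gff: feature {scaffold}:{start}-{end} exceeds "
                    f"scaffold length {length}; skipped"
                )
                n_skip += 1
                continue
            if p.orientation == "+":
                new_start, new_end = p.offset + start, p.offset + end
                new_strand = strand
            else:
                new_start = p.offset + (length - end + 1)
                new_end = p.offset + (length - start + 1)
                new_strand = flip.get(strand, strand)
            cols[0], cols[3], cols[4], cols[6] = chrom, str(new_start), str(new_end), new_strand
            fout.write("\t".join(cols) + "\n")
            n_lift += 1
    return n_lift, n_pass, n_skip


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str) -> dict:
    """Load a YAML (or flat key: value) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def dump_config(path: str, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
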