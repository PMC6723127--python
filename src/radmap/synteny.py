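"""One-to-one ortholog synteny comparison between mapped genomes.

Given gene positions in a focal species A (with known scaffold of each
gene) and a comparator B, chromosomes are paired by maximal ortholog
count, translocated genes are split into singletons and co-translocated
blocks, and runs of orthologs in reversed relative order
(micro-inversions) are detected. With a third species C, each inversion
block is triangulated: a block delimited by one species' scaffold
boundaries and co-linear in the third comparison is classified as a
scaffold mis-orientation in that species rather than a real inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_GENES = 3


def _merge_pairs(
    genes_a: pd.DataFrame, genes_b: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join ortholog pairs with both position tables.

    Gene tables need columns gene_id, chromosome, start (plus scaffold
    for the focal species); pairs needs gene_a, gene_b."""
    if pairs["gene_a"].duplicated().any() or pairs["gene_b"].duplicated().any():
        raise ValueError("ortholog pairs must be one-to-one")
    a = genes_a.rename(columns=lambda c: f"{c}_a" if c != "gene_id" else "gene_a")
    b = genes_b.rename(columns=lambda c: f"{c}_b" if c != "gene_id" else "gene_b")
    return pairs.merge(a, on="gene_a").merge(b, on="gene_b")


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------

def assign_homologs(
    genes_a: pd.DataFrame, genes_b: pd.DataFrame, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """For each A-chromosome, the B-chromosome with the most shared
    orthologs (raw counts, no length normalisation). Ties go to the
    lexicographically smaller B id and are flagged.

    Returns (homology table, full ortholog-count matrix)."""
    merged = _merge_pairs(genes_a, genes_b, pairs)
    counts = (
        merged.groupby(["chromosome_a", "chromosome_b"]).size().unstack(fill_value=0)
    )
    rows = []
    for chrom_a, row in counts.iterrows():
        best = row.max()
        winners = sorted(row.index[row == best])
        rows.append(
            {
                "chromosome_a": chrom_a,
                "homolog_b": winners[0],
                "n_orthologs": int(best),
                "tied": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows), counts


# ---------------------------------------------------------------------------
# Singleton / block translocations
# ---------------------------------------------------------------------------

def count_singletons(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    pairs: pd.DataFrame,
    homology: pd.DataFrame,
) -> pd.DataFrame:
    """Per-A-chromosome partition of shared orthologs into syntenic
    genes, singleton translocations (a lone gene on a non-homologous
    B-chromosome whose A-neighbours are both on the homolog), block
    translocations (runs of >= 2 co-translocated genes) and other
    (lone translocated genes without syntenic flanks)."""
    merged = _merge_pairs(genes_a, genes_b, pairs)
    homolog = dict(zip(homology["chromosome_a"], homology["homolog_b"]))
    out = []
    for chrom_a, sub in merged.groupby("chromosome_a"):
        sub = sub.sort_values("start_a").reset_index(drop=True)
        h = homolog[chrom_a]
        syntenic = (sub["chromosome_b"] == h).to_numpy()
        bchrom = sub["chromosome_b"].to_numpy()
        n = len(sub)
        n_singleton = n_block_genes = n_blocks = n_other = 0
        i = 0
        while i < n:
            if syntenic[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and not syntenic[j + 1] and bchrom[j + 1] == bchrom[i]:
                j += 1
            run = j - i + 1
            if run >= 2:
                n_blocks += 1
                n_block_genes += run
            else:
                flanks_syntenic = (i > 0 and syntenic[i - 1]) and (
                    i + 1 < n and syntenic[i + 1]
                )
                if flanks_syntenic:
                    n_singleton += 1
                else:
                    n_other += 1
            i = j + 1
        out.append(
            {
                "chromosome_a": chrom_a,
                "homolog_b": h,
                "n_orthologs": n,
                "n_syntenic": int(syntenic.sum()),
                "n_singletons": n_singleton,
                "n_block_translocations": n_blocks,
                "n_block_genes": n_block_genes,
                "n_other_translocated": n_other,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Micro-inversion blocks
# ---------------------------------------------------------------------------

@dataclass
class InversionBlock:
    chromosome_a: str
    chromosome_b: str
    gene_ids: list[str]
    first_gene: str
    last_gene: str
    scaffolds_a: list[str] = field(default_factory=list)
    verdict: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def detect_inversion_blocks(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    pairs: pd.DataFrame,
    chromosome_a: str,
    chromosome_b: str,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[InversionBlock]:
    """Maximal runs of >= min_genes consecutive orthologs (ordered by
    A-position on the chromosome pair) whose B-position rank strictly
    decreases."""
    merged = _merge_pairs(genes_a, genes_b, pairs)
    sub = merged[
        (merged["chromosome_a"] == chromosome_a)
        & (merged["chromosome_b"] == chromosome_b)
    ].sort_values("start_a").reset_index(drop=True)
    if len(sub) < min_genes:
        return []
    rank_b = stats.rankdata(sub["start_b"].to_numpy())
    blocks: list[InversionBlock] = []
    start = 0
    n = len(sub)
    for i in range(1, n + 1):
        if i < n and rank_b[i] < rank_b[i - 1]:
            continue
        run = i - start
        if run >= min_genes:
            rows = sub.iloc[start:i]
            blocks.append(
                InversionBlock(
                    chromosome_a,
                    chromosome_b,
                    list(rows["gene_a"]),
                    rows["gene_a"].iloc[0],
                    rows["gene_a"].iloc[-1],
                    scaffolds_a=sorted(rows["scaffold_a"].dropna().unique())
                    if "scaffold_a" in rows
                    else [],
                )
            )
        start = i
    return blocks


# ---------------------------------------------------------------------------
# Mis-orientation classification
# ---------------------------------------------------------------------------

def _delimited_by_scaffold(
    block_genes: list[str], genes: pd.DataFrame, tol_genes: int
) -> bool:
    """True when the block's boundary genes coincide (within tol_genes)
    with a single scaffold's first and last mapped genes."""
    if "scaffold" not in genes.columns:
        return False
    sub = genes.set_index("gene_id")
    scaffolds = {
        sub.at[g, "scaffold"] for g in block_genes if g in sub.index
    } - {"", None}
    if len(scaffolds) != 1:
        return False
    scaffold = scaffolds.pop()
    on_scaf = genes[genes["scaffold"] == scaffold].sort_values("start")
    ids = list(on_scaf["gene_id"])
    try:
        i0, i1 = ids.index(block_genes[0]), ids.index(block_genes[-1])
    except ValueError:
        return False
    lo, hi = min(i0, i1), max(i0, i1)
    return lo <= tol_genes and (len(ids) - 1 - hi) <= tol_genes


def classify_misorientation(
    blocks: list[InversionBlock],
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    genes_c: pd.DataFrame | None = None,
    pairs_ac: pd.DataFrame | None = None,
    tol_genes: int = 1,
) -> list[InversionBlock]:
    """Attach a verdict to each inversion block.

    With a third species: a block delimited by a single A scaffold and
    also inverted in the A-vs-C comparison is a mis-orientation in A; a
    block delimited by a single B scaffold but co-linear in A-vs-C is a
    mis-orientation in B; a block delimited in neither species, or
    inverted against both comparators without scaffold support, is a
    putative real inversion; anything else is ambiguous. Without a
    third species verdicts are limited to scaffold-delimited /
    not-delimited."""
    c_pos = None
    if genes_c is not None and pairs_ac is not None:
        merged_ac = _merge_pairs(genes_a, genes_c, pairs_ac.rename(
            columns={"gene_c": "gene_b"})[["gene_a", "gene_b"]])
        c_pos = dict(zip(merged_ac["gene_a"], merged_ac["start_b"]))
        a_pos = dict(zip(merged_ac["gene_a"], merged_ac["start_a"]))
    for block in blocks:
        delim_a = _delimited_by_scaffold(block.gene_ids, genes_a, tol_genes)
        delim_b = _delimited_by_scaffold(block.gene_ids, genes_b, tol_genes)
        if c_pos is None:
            block.verdict = "scaffold-delimited" if (delim_a or delim_b) else "not-delimited"
            continue
        xy = np.array(
            [
                (a_pos[g], c_pos[g])
                for g in block.gene_ids
                if g in c_pos and g in a_pos
            ]
        )
        inv_ac = False
        if xy.shape[0] >= 2 and np.unique(xy[:, 0]).size >= 2:
            rho = stats.spearmanr(xy[:, 0], xy[:, 1]).statistic
            inv_ac = bool(np.isfinite(rho) and rho < 0)
        if delim_a and inv_ac:
            block.verdict = "misorientation-in-A"
        elif delim_b and not inv_ac:
            block.verdict = "misorientation-in-B"
        elif not delim_a and not delim_b:
            block.verdict = "putative-real-inversion"
        else:
            block.verdict = "ambiguous"
    return blocks


def blocks_to_frame(blocks: list[InversionBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome_a": b.chromosome_a,
                "chromosome_b": b.chromosome_b,
                "n_genes": b.n_genes,
                "first_gene": b.first_gene,
                "last_gene": b.last_gene,
                "scaffolds_a": ",".join(b.scaffolds_a),
                "verdict": b.verdict,
            }
            for b in blocks
        ]
    )
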