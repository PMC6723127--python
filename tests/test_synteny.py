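import numpy as np
import pandas as pd
import pytest

from radmap import synteny as syn


def genes(species_prefix, rows):
    """rows: (gene, chromosome, start[, scaffold])"""
    out = []
    for r in rows:
        gene, chrom, start = r[:3]
        scaffold = r[3] if len(r) > 3 else ""
        out.append(
            {
                "gene_id": f"{species_prefix}{gene}",
                "chromosome": chrom,
                "start": start,
                "scaffold": scaffold,
                "strand": "+",
            }
        )
    return pd.DataFrame(out)


def pair_frame(ids):
    return pd.DataFrame({"gene_a": [f"a{g}" for g in ids], "gene_b": [f"b{g}" for g in ids]})


class TestAssignHomologs:
    def test_identity_correspondence(self):
        a = genes("a", [(i, f"chr{i % 2}", i * 10) for i in range(8)])
        b = genes("b", [(i, f"chr{i % 2}", i * 10) for i in range(8)])
        hom, counts = syn.assign_homologs(a, b, pair_frame(range(8)))
        assert dict(zip(hom["chromosome_a"], hom["homolog_b"])) == {
            "chr0": "chr0",
            "chr1": "chr1",
        }
        assert not hom["tied"].any()

    def test_majority_split(self):
        a = genes("a", [(i, "A1", i * 10) for i in range(10)])
        b = genes("b", [(i, "B1" if i < 6 else "B2", i * 10) for i in range(10)])
        hom, counts = syn.assign_homologs(a, b, pair_frame(range(10)))
        assert hom.loc[0, "homolog_b"] == "B1"
        assert counts.loc["A1", "B2"] == 4  # both counts reported

    def test_tie_flagged_to_smaller_id(self):
        a = genes("a", [(i, "A1", i * 10) for i in range(4)])
        b = genes("b", [(i, "B2" if i < 2 else "B1", i * 10) for i in range(4)])
        hom, _ = syn.assign_homologs(a, b, pair_frame(range(4)))
        assert hom.loc[0, "homolog_b"] == "B1" and bool(hom.loc[0, "tied"])

    def test_non_one_to_one_pairs_rejected(self):
        a = genes("a", [(0, "A1", 10), (1, "A1", 20)])
        b = genes("b", [(0, "B1", 10)])
        bad = pd.DataFrame({"gene_a": ["a0", "a1"], "gene_b": ["b0", "b0"]})
        with pytest.raises(ValueError, match="one-to-one"):
            syn.assign_homologs(a, b, bad)


class TestSingletons:
    def _tables(self, b_chroms):
        n = len(b_chroms)
        a = genes("a", [(i, "A1", (i + 1) * 10) for i in range(n)])
        b = genes("b", [(i, b_chroms[i], (i + 1) * 10) for i in range(n)])
        hom = pd.DataFrame({"chromosome_a": ["A1"], "homolog_b": ["B1"]})
        return syn.count_singletons(a, b, pair_frame(range(n)), hom).iloc[0]

    def test_fully_syntenic(self):
        row = self._tables(["B1"] * 6)
        assert row["n_singletons"] == 0 and row["n_block_translocations"] == 0

    def test_one_moved_gene_is_singleton(self):
        row = self._tables(["B1", "B1", "B9", "B1", "B1"])
        assert row["n_singletons"] == 1

    def test_three_gene_block_counts_once(self):
        row = self._tables(["B1", "B9", "B9", "B9", "B1", "B1"])
        assert row["n_singletons"] == 0
        assert row["n_block_translocations"] == 1 and row["n_block_genes"] == 3

    def test_partition_invariant(self):
        row = self._tables(["B1", "B9", "B1", "B8", "B8", "B1", "B7"])
        total = (
            row["n_syntenic"]
            + row["n_singletons"]
            + row["n_block_genes"]
            + row["n_other_translocated"]
        )
        assert total == row["n_orthologs"]


def inversion_tables(b_order, a_scaffolds=None):
    """A-chromosome genes in order 0..n-1; B positions permuted."""
    n = len(b_order)
    rows_a = []
    for i in range(n):
        scaffold = a_scaffolds[i] if a_scaffolds else ""
        rows_a.append((i, "A1", (i + 1) * 100, scaffold))
    a = genes("a", rows_a)
    b = genes("b", [(i, "B1", (b_order.index(i) + 1) * 100) for i in range(n)])
    return a, b, pair_frame(range(n))


class TestInversionBlocks:
    def test_colinear_no_blocks(self):
        a, b, p = inversion_tables(list(range(6)))
        assert syn.detect_inversion_blocks(a, b, p, "A1", "B1") == []

    def test_single_reversed_run(self):
        # B ranks along A order: 1,2,5,4,3,6
        a, b, p = inversion_tables([0, 1, 4, 3, 2, 5])
        blocks = syn.detect_inversion_blocks(a, b, p, "A1", "B1")
        assert len(blocks) == 1
        assert blocks[0].gene_ids == ["a2", "a3", "a4"]

    def test_whole_chromosome_reversal(self):
        a, b, p = inversion_tables(list(range(7))[::-1])
        blocks = syn.detect_inversion_blocks(a, b, p, "A1", "B1")
        assert len(blocks) == 1 and blocks[0].n_genes == 7

    def test_reflection_symmetry(self):
        order = [0, 1, 4, 3, 2, 5, 8, 7, 6]
        a, b, p = inversion_tables(order)
        fwd = syn.detect_inversion_blocks(a, b, p, "A1", "B1")
        a2, b2, p2 = inversion_tables(order[::-1])
        rev = syn.detect_inversion_blocks(a2, b2, p2, "A1", "B1")
        fwd_sets = {frozenset(bl.gene_ids) for bl in fwd}
        # genes are renumbered by the reflection: map back
        n = len(order)
        rev_sets = {
            frozenset(f"a{n - 1 - int(g[1:])}" for g in bl.gene_ids) for bl in rev
        }
        assert fwd_sets == rev_sets

    def test_min_genes_threshold(self):
        a, b, p = inversion_tables([0, 2, 1, 3])  # 2-gene flip only
        assert syn.detect_inversion_blocks(a, b, p, "A1", "B1", min_genes=3) == []


class TestClassification:
    def _fixture(self, flip_scaffold=True, third_colinear=True):
        """Five scaffolds of 3 genes; scaffold s2 inverted in A."""
        n = 15
        scaffolds = [f"s{i // 3}" for i in range(n)]
        a_order = list(range(n))
        if flip_scaffold:
            a_order[6:9] = a_order[6:9][::-1]  # s2 genes reversed in A frame
        rows_a = [
            (g, "A1", (a_order.index(g) + 1) * 100, scaffolds[g]) for g in range(n)
        ]
        a = genes("a", rows_a)
        b = genes("b", [(i, "B1", (i + 1) * 100) for i in range(n)])
        c = genes("c", [(i, "C1", (i + 1) * 100) for i in range(n)])
        if not third_colinear:
            # third species shares A's inversion
            c = genes(
                "c", [(g, "C1", (a_order.index(g) + 1) * 100) for g in range(n)]
            )
        pairs = pd.DataFrame(
            {
                "gene_a": [f"a{i}" for i in range(n)],
                "gene_b": [f"b{i}" for i in range(n)],
                "gene_c": [f"c{i}" for i in range(n)],
            }
        )
        return a, b, c, pairs

    def test_flipped_scaffold_is_misorientation_in_a(self):
        a, b, c, pairs = self._fixture()
        blocks = syn.detect_inversion_blocks(
            a, b, pairs[["gene_a", "gene_b"]], "A1", "B1"
        )
        assert len(blocks) == 1
        out = syn.classify_misorientation(
            blocks, a, b, c, pairs[["gene_a", "gene_c"]]
        )
        assert out[0].verdict == "misorientation-in-A"
        assert out[0].scaffolds_a == ["s2"]

    def test_inverted_in_both_comparators_is_putative_real(self):
        """A block not delimited by a scaffold and inverted against both
        comparators is treated as a real inversion."""
        a, b, c, pairs = self._fixture(third_colinear=True)
        # strip scaffold info: block no longer scaffold-delimited
        a_noscaf = a.assign(scaffold="")
        blocks = syn.detect_inversion_blocks(
            a_noscaf, b, pairs[["gene_a", "gene_b"]], "A1", "B1"
        )
        out = syn.classify_misorientation(
            blocks, a_noscaf, b, c, pairs[["gene_a", "gene_c"]]
        )
        assert out[0].verdict == "putative-real-inversion"

    def test_without_third_species_limited_verdicts(self):
        a, b, _, pairs = self._fixture()
        blocks = syn.detect_inversion_blocks(
            a, b, pairs[["gene_a", "gene_b"]], "A1", "B1"
        )
        out = syn.classify_misorientation(blocks, a, b)
        assert out[0].verdict == "scaffold-delimited"

    def test_block_spanning_multiple_scaffolds_not_delimited(self):
        n = 12
        scaffolds = [f"s{i // 4}" for i in range(n)]
        a_order = list(range(n))
        a_order[2:8] = a_order[2:8][::-1]  # spans s0 and s1
        a = genes(
            "a",
            [(g, "A1", (a_order.index(g) + 1) * 100, scaffolds[g]) for g in range(n)],
        )
        b = genes("b", [(i, "B1", (i + 1) * 100) for i in range(n)])
        blocks = syn.detect_inversion_blocks(a, b, pair_frame(range(n)), "A1", "B1")
        out = syn.classify_misorientation(blocks, a, b)
        assert all(bl.verdict == "not-delimited" for bl in out)


class TestEndToEndFlipFixture:
    def test_flipped_scaffolds_detected_and_attributed(self, small_sim, rng):
        """Flipping k scaffolds in the assembly map yields blocks that
        classify as mis-orientations in the focal species."""
        from radmap import synthetic_data as sd

        _, truth, index, _, _ = small_sim
        eligible = [
            p.scaffold
            for pls in truth.truth_map.chromosomes.values()
            for p in pls
            if index[p.scaffold] > 200_000
        ]
        flipped = set(rng.choice(eligible, size=5, replace=False))
        assembly = sd.flip_scaffolds(truth.truth_map, flipped)
        genes_a, genes_b, genes_c, pairs = sd.synthetic_ortholog_tables(
            index, truth.truth_map, assembly, genes_per_scaffold=4
        )
        hom, _ = syn.assign_homologs(genes_a, genes_b, pairs[["gene_a", "gene_b"]])
        hits = set()
        n_misattributed = 0
        for _, row in hom.iterrows():
            blocks = syn.detect_inversion_blocks(
                genes_a, genes_b, pairs[["gene_a", "gene_b"]],
                row["chromosome_a"], row["homolog_b"],
            )
            out = syn.classify_misorientation(
                blocks, genes_a, genes_b, genes_c, pairs[["gene_a", "gene_c"]]
            )
            for bl in out:
                if bl.verdict == "misorientation-in-A" and len(bl.scaffolds_a) == 1:
                    if bl.scaffolds_a[0] in flipped:
                        hits.add(bl.scaffolds_a[0])
                    else:
                        n_misattributed += 1
        assert len(hits) >= 0.9 * len(flipped)
        assert n_misattributed == 0
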