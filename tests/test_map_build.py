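import itertools

import numpy as np
import pandas as pd
import pytest

from radmap import map_build as mb
from radmap.core import ConsensusMap, ScaffoldPlacement


def linear_rf(positions, cm_per_unit=1.0):
    """Noise-free rf matrix from 1-D positions via Haldane."""
    positions = np.asarray(positions, dtype=float)
    d = np.abs(positions[:, None] - positions[None, :]) * cm_per_unit
    return 0.5 * (1 - np.exp(-2 * d / 100))


class TestOrderMarkers:
    def test_recovers_true_linear_order(self):
        rf = linear_rf([0, 3, 7, 12], cm_per_unit=2.0)
        ids = ["m0", "m1", "m2", "m3"]
        order = mb.order_markers(rf, ids, ids)
        assert order in ([0, 1, 2, 3], [3, 2, 1, 0])
        # brute-force SARF oracle over all 4! orders
        best = min(
            itertools.permutations(range(4)),
            key=lambda o: mb.sarf(np.array(o), rf),
        )
        assert mb.sarf(np.array(order), rf) == pytest.approx(
            mb.sarf(np.array(best), rf)
        )

    def test_two_markers_unique(self):
        rf = linear_rf([0, 5])
        assert mb.order_markers(rf, ["a", "b"], ["a", "b"]) == [0, 1]

    def test_two_opt_never_worsens_input_order(self, rng):
        m = 12
        rf = linear_rf(rng.uniform(0, 30, m))
        ids = [f"m{i:02d}" for i in range(m)]
        order = mb.order_markers(rf, ids, ids)
        input_sarf = mb.sarf(np.arange(m), rf)
        assert mb.sarf(np.array(order), rf) <= input_sarf + 1e-12

    def test_deterministic(self, rng):
        m = 10
        rf = linear_rf(rng.uniform(0, 20, m))
        ids = [f"m{i:02d}" for i in range(m)]
        assert mb.order_markers(rf, ids, ids) == mb.order_markers(rf, ids, ids)


class TestMapDistances:
    def test_zero_rf_is_zero_cm(self):
        assert mb.map_distances([0.0])[-1] == 0.0

    def test_haldane_closed_form(self):
        cm = mb.map_distances([0.2])
        assert cm[-1] == pytest.approx(-50 * np.log(0.6), rel=1e-9)
        assert cm[-1] == pytest.approx(25.54, abs=0.01)

    def test_near_linear_at_small_rf(self):
        assert mb.map_distances([0.01])[-1] == pytest.approx(1.01, abs=0.01)

    def test_kosambi(self):
        cm = mb.map_distances([0.2], map_function="kosambi")
        assert cm[-1] == pytest.approx(25 * np.log(1.4 / 0.6), rel=1e-9)

    def test_clamps_independent_rf_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            cm = mb.map_distances([0.5])
        assert np.isfinite(cm[-1])

    def test_cumulative_from_zero(self):
        cm = mb.map_distances([0.1, 0.1, 0.1])
        assert cm[0] == 0.0
        assert np.all(np.diff(cm) >= 0)


class TestPhaseAlignAndConsensus:
    def test_phase_alignment_flips_repulsion_rows(self, rng):
        x = rng.choice([0.0, 1.0], 50)
        sub = np.array([x, 1 - x, x])
        aligned = mb.phase_align_states(sub)
        np.testing.assert_array_equal(aligned[1], aligned[0])

    def test_consensus_majority_and_ties(self):
        states = np.array(
            [
                [1.0, 0.0, np.nan, 1.0],
                [1.0, 0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0, np.nan],
            ]
        )
        names, cons = mb.scaffold_consensus_states(states, ["S", "S", "S"])
        assert names == ["S"]
        np.testing.assert_array_equal(cons[0, :3], [1.0, 0.0, 0.0])
        assert np.isnan(cons[0, 3])  # 1 vs 0 tie

    def test_consensus_outvotes_isolated_error(self, rng):
        x = rng.choice([0.0, 1.0], 50)
        sub = np.array([x, x, x])
        sub[1, 4] = 1 - sub[1, 4]
        _, cons = mb.scaffold_consensus_states(sub, ["S"] * 3)
        np.testing.assert_array_equal(cons[0], x)


def _sex_map(parent, frames):
    sm = mb.SexMap(parent)
    for lg, rows in frames.items():
        sm.groups[lg] = pd.DataFrame(
            rows, columns=["locus_id", "scaffold", "position", "cm"]
        )
    return sm


def _toy_map(parent):
    return _sex_map(
        parent,
        {
            "LG01": [
                ("a1", "A", 100, 0.0),
                ("a2", "A", 900, 1.0),
                ("b1", "B", 100, 6.0),
                ("c1", "C", 500, 12.0),
            ]
        },
    )


class TestMergeMaps:
    index = {"A": 1000, "B": 800, "C": 600, "Z": 400}

    def test_self_merge_reproduces_order(self):
        consensus, conflicts = mb.merge_maps(
            _toy_map("maternal"), _toy_map("paternal"), self.index
        )
        assert not conflicts
        (placements,) = consensus.chromosomes.values()
        assert [p.scaffold for p in placements] == ["A", "B", "C"]
        assert consensus.unplaced == ["Z"]

    def test_orientation_from_bp_cm_correlation(self):
        consensus, _ = mb.merge_maps(
            _toy_map("maternal"), _toy_map("paternal"), self.index
        )
        (placements,) = consensus.chromosomes.values()
        by = {p.scaffold: p.orientation for p in placements}
        assert by["A"] == "+"  # bp and cm both increase
        assert by["B"] == "?"  # single marker
        assert by["C"] == "?"

    def test_reversed_inputs_reflect_consensus(self):
        def reversed_map(parent):
            sm = _toy_map(parent)
            out = mb.SexMap(parent)
            for lg, f in sm.groups.items():
                g = f.iloc[::-1].reset_index(drop=True).copy()
                g["cm"] = f["cm"].max() - g["cm"]
                out.groups[lg] = g
            return out

        fwd, _ = mb.merge_maps(_toy_map("maternal"), _toy_map("paternal"), self.index)
        rev, _ = mb.merge_maps(
            reversed_map("maternal"), reversed_map("paternal"), self.index
        )
        (pf,) = fwd.chromosomes.values()
        (pr,) = rev.chromosomes.values()
        assert [p.scaffold for p in pr] == [p.scaffold for p in pf][::-1]
        flip = {"+": "-", "-": "+", "?": "?"}
        assert [p.orientation for p in pr] == [flip[p.orientation] for p in pf][::-1]

    def test_scaffold_only_in_one_map_still_placed(self):
        maternal = _toy_map("maternal")
        paternal = _sex_map(
            "paternal",
            {"LG01": [("a9", "A", 50, 0.0), ("c9", "C", 100, 9.0)]},
        )
        consensus, _ = mb.merge_maps(maternal, paternal, self.index)
        (placements,) = consensus.chromosomes.values()
        assert "B" in [p.scaffold for p in placements]

    def test_length_conservation(self):
        consensus, _ = mb.merge_maps(
            _toy_map("maternal"), _toy_map("paternal"), self.index
        )
        anchored = sum(
            self.index[p.scaffold]
            for pls in consensus.chromosomes.values()
            for p in pls
        )
        unplaced = sum(self.index[s] for s in consensus.unplaced)
        assert anchored + unplaced == sum(self.index.values())

    def test_offsets_strictly_increase(self):
        consensus, _ = mb.merge_maps(
            _toy_map("maternal"), _toy_map("paternal"), self.index, gap_length=100
        )
        (placements,) = consensus.chromosomes.values()
        offsets = [p.offset for p in placements]
        assert offsets == sorted(offsets) and len(set(offsets)) == len(offsets)
        assert offsets[1] == self.index["A"] + 100


class TestSexMapFromSimulation:
    @pytest.fixture(scope="class")
    def long_chrom_run(self, tmp_path_factory):
        """Two 20 Mb chromosomes: ~47 cM each, enough crossovers that
        ordering is unambiguous."""
        from radmap import pipeline, synthetic_data as sd

        cfg = sd.SimConfig(
            n_chromosomes=2,
            chromosome_length_bp=20_000_000,
            n_scaffolds_per_chromosome=20,
            n_offspring=90,
            dropout_e=0.0,
            seed=21,
        )
        root = tmp_path_factory.mktemp("long")
        truth, index, ad, gt = sd.simulate_dataset(cfg)
        paths = sd.write_dataset(str(root / "sim"), cfg, truth, index, ad, gt)
        rc = pipeline.RunConfig(
            vcf=paths["vcf"],
            depth_table=paths["depth"],
            scaffold_index=paths["scaffolds"],
            out_dir=str(root / "out"),
            seed=21,
        )
        return cfg, truth, pipeline.run_pipeline(rc)

    def test_one_lg_per_chromosome_per_sex(self, long_chrom_run):
        _, _, res = long_chrom_run
        assert len(res.maternal_map.groups) == 2
        assert len(res.paternal_map.groups) == 2

    def test_map_length_consistent_with_recombination_rate(self, long_chrom_run):
        """Total map length ~ cM_per_Mb x genome size within 3 standard
        errors of the total crossover count."""
        cfg, _, res = long_chrom_run
        expected = cfg.cm_per_mb * cfg.n_chromosomes * cfg.chromosome_length_bp / 1e6
        n_events = expected / 100 * cfg.n_offspring  # ~ Poisson total
        se_cm = 100 * np.sqrt(n_events) / cfg.n_offspring
        for sex_map in (res.maternal_map, res.paternal_map):
            total = sum(f["cm"].max() for f in sex_map.groups.values())
            assert abs(total - expected) <= 3 * se_cm + 5.0

    def test_scaffold_order_recovered(self, long_chrom_run):
        from scipy import stats

        _, truth, res = long_chrom_run
        toff = {
            p.scaffold: p.offset
            for pls in truth.truth_map.chromosomes.values()
            for p in pls
        }
        for sex_map in (res.maternal_map, res.paternal_map):
            for f in sex_map.groups.values():
                cm = f.groupby("scaffold", sort=False)["cm"].mean()
                rho = stats.spearmanr(
                    cm.to_numpy(), [toff[s] for s in cm.index]
                ).statistic
                assert abs(rho) >= 0.9
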