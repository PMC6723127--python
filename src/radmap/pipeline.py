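"""End-to-end orchestration of the linkage-map construction run.

Stages run in a fixed order: per-base prefilter, VCF read, the filter
cascade, cross-type/dropout inference, dropout correction, segregation
and parent-concordance screens, scaffold linkage grouping, marker
thinning and double-crossover removal, sex-specific map building,
consensus merge with AGP export, optional GFF liftover and optional
synteny tables. Every stage logs its in/out counts; identical config
and seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cross_inference as ci
from . import formats_io, linkage_grouping, map_build, site_filters
from .core import AlleleDepthMatrix, ConsensusMap, GenotypeMatrix

logger = logging.getLogger("radmap.pipeline")

STAGES = (
    "prefilter",
    "cascade",
    "inference",
    "grouping",
    "maps",
    "merge",
    "liftover",
)


@dataclass
class RunConfig:
    vcf: str = ""
    depth_table: str | None = None
    scaffold_index: str = ""
    gff: str | None = None
    out_dir: str = "radmap_out"
    mother: str = "mother"
    father: str = "father"
    filters: site_filters.FilterConfig = field(default_factory=site_filters.FilterConfig)
    alpha: float = 0.05
    binomial_alternative: str = "two-sided"
    rf_threshold: float = 0.07
    min_informative: int = 20
    thin_k: int = 5
    dxo_min_individuals: int = 1
    map_function: str = "haldane"
    gap_length: int = 100
    # remove the residual-dropout noise floor (2q(1-q), q = e_hat/2)
    # from rf values used for grouping and mapping
    debias_dropout: bool = True
    seed: int = 0
    stop_after: str | None = None

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the
        same analysis in a different directory hashes identically)."""
        payload = asdict(self)
        for key in ("vcf", "depth_table", "scaffold_index", "gff", "out_dir"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    audit: site_filters.FilterAudit | None = None
    n_prefilter_kept: int | None = None
    e_hat: float | None = None
    n_corrected: int | None = None
    n_distorted: int | None = None
    n_discordant: int | None = None
    ad: AlleleDepthMatrix | None = None
    gt: GenotypeMatrix | None = None
    calls: list | None = None
    groups: list | None = None
    chimera_flags: dict = field(default_factory=dict)
    maternal_map: map_build.SexMap | None = None
    paternal_map: map_build.SexMap | None = None
    consensus: ConsensusMap | None = None
    conflicts: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: str, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# radmap seed={cfg.seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    os.makedirs(cfg.out_dir, exist_ok=True)
    res = PipelineResult(cfg)
    t0 = time.time()

    def done(stage: str) -> bool:
        logger.info("stage %-10s done at %.1fs", stage, time.time() - t0)
        return cfg.stop_after == stage

    scaffold_index = formats_io.read_scaffold_index(cfg.scaffold_index)

    # -- A. pre-genotyping position filter --------------------------------
    keep_positions = None
    if cfg.depth_table:
        records = formats_io.read_depth_table(cfg.depth_table)
        keep_positions, hist = site_filters.prefilter_positions(records, cfg.filters)
        res.n_prefilter_kept = len(keep_positions)
        _write_tsv(hist, os.path.join(cfg.out_dir, "depth_histogram.tsv"), cfg)
        logger.info("prefilter: %d positions kept", len(keep_positions))
    if done("prefilter"):
        return res

    # -- read VCF ----------------------------------------------------------
    ad, gt, n_skipped = formats_io.read_vcf_biallelic(cfg.vcf, cfg.mother, cfg.father)
    logger.info("vcf: %d biallelic loci (%d records skipped)", ad.n_loci, n_skipped)
    if keep_positions is not None:
        idx = [
            i for i, loc in enumerate(ad.loci)
            if (loc.scaffold, loc.position) in keep_positions
        ]
        ad, gt = ad.take(idx), gt.take(idx)
        logger.info("prefilter intersect: %d loci remain", ad.n_loci)

    # -- B..F cascade ------------------------------------------------------
    ad, gt, audit = site_filters.run_filter_cascade(ad, gt, cfg.filters)
    res.audit = audit
    _write_tsv(audit.to_frame(), os.path.join(cfg.out_dir, "filter_audit.tsv"), cfg)
    if done("cascade"):
        res.ad, res.gt = ad, gt
        return res

    # -- cross-type / dropout inference -----------------------------------
    off_idx = ad.offspring_indices
    counts = ci.genotype_counts(gt, off_idx)
    est = ci.estimate_global_e(counts)
    res.e_hat = est.e_hat
    calls = ci.classify_loci(counts, est.e_hat)
    gt, n_corrected = ci.correct_dropout_genotypes(gt, calls, off_idx)
    res.n_corrected = n_corrected
    counts = ci.genotype_counts(gt, off_idx)
    logger.info("inference: e_hat=%.4f, %d genotypes corrected", est.e_hat, n_corrected)

    pvals = np.array(
        [
            ci.test_segregation(counts[i], calls[i].cross_type, cfg.binomial_alternative)
            for i in range(len(calls))
        ]
    )
    keep_seg = ~np.isnan(pvals) & (pvals >= cfg.alpha)
    res.n_distorted = int((~keep_seg).sum())

    mother_gt = gt.calls[:, ad.mother_index]
    father_gt = gt.calls[:, ad.father_index]
    keep_conc = ci.concordance_filter(calls, mother_gt, father_gt)
    res.n_discordant = int((keep_seg & ~keep_conc).sum())

    per_locus = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in ad.loci],
            "scaffold": [l.scaffold for l in ad.loci],
            "position": [l.position for l in ad.loci],
            "n_aa": counts[:, 0].astype(int),
            "n_ab": counts[:, 1].astype(int),
            "n_bb": counts[:, 2].astype(int),
            "cross_type": [c.cross_type for c in calls],
            "het_parent": [c.het_parent or "" for c in calls],
            "unoriented": [c.unoriented for c in calls],
            "p_segregation": pvals,
            "kept": keep_seg & keep_conc,
        }
    )
    per_locus["e_hat"] = est.e_hat
    _write_tsv(per_locus, os.path.join(cfg.out_dir, "cross_inference.tsv"), cfg)

    keep = np.where(keep_seg & keep_conc)[0]
    ad, gt = ad.take(keep), gt.take(keep)
    calls = [calls[i] for i in keep]
    counts = counts[keep]
    logger.info(
        "screens: %d distorted, %d parent-discordant removed; %d loci remain",
        res.n_distorted, res.n_discordant, ad.n_loci,
    )
    res.ad, res.gt, res.calls = ad, gt, calls
    if done("inference"):
        return res

    # -- per-parent pseudo-testcross marker sets ---------------------------
    parent_sets: dict[str, dict] = {}
    for parent in ("mother", "father"):
        sel = np.array(
            [
                i
                for i, c in enumerate(calls)
                if c.cross_type in ci.SINGLE_HET and c.het_parent == parent
            ],
            dtype=int,
        )
        states = linkage_grouping.het_hom_states(gt, sel, off_idx) if sel.size else np.empty((0, off_idx.size))
        if sel.size:
            rf, n = linkage_grouping.rf_matrix(states, cfg.min_informative)
            if cfg.debias_dropout:
                rf = linkage_grouping.debias_rf(rf, est.e_hat)
        else:
            rf, n = np.empty((0, 0)), np.empty((0, 0))
        parent_sets[parent] = {
            "idx": sel,
            "states": states,
            "rf": rf,
            "scaffolds": np.array([ad.loci[i].scaffold for i in sel]),
            "positions": np.array([ad.loci[i].position for i in sel]),
            "n_called": (~np.isnan(states)).sum(axis=1).astype(int) if sel.size else np.empty(0, int),
        }

    # -- grouping ----------------------------------------------------------
    scaffold_rf = linkage_grouping.scaffold_rf_matrix(
        [(p["rf"], p["scaffolds"]) for p in parent_sets.values()]
    )
    groups = linkage_grouping.cluster_scaffolds(
        scaffold_rf, scaffold_index, cfg.rf_threshold
    )
    res.groups = groups
    scaffold_group = {s: g.group_id for g in groups for s in g.scaffolds}
    _write_tsv(
        pd.DataFrame(
            [
                {"group": g.group_id, "scaffold": s}
                for g in groups
                for s in g.scaffolds
            ]
        ),
        os.path.join(cfg.out_dir, "linkage_groups.tsv"),
        cfg,
    )
    scaffold_rf.to_csv(os.path.join(cfg.out_dir, "scaffold_rf.tsv"), sep="\t")

    for parent, p in parent_sets.items():
        if not p["idx"].size:
            continue
        flags = linkage_grouping.flag_chimeric_scaffolds(
            p["rf"], p["scaffolds"], p["positions"],
            within_max=cfg.rf_threshold,
        )
        for s, v in flags.items():
            if v == "chimeric":
                res.chimera_flags[s] = v
        keep_mg = linkage_grouping.exclude_multigroup_loci(
            p["rf"], p["scaffolds"], scaffold_group, cfg.rf_threshold
        )
        _subset_parent(p, np.where(keep_mg)[0])
    logger.info(
        "grouping: %d groups, %d chimera flags", len(groups), len(res.chimera_flags)
    )
    if done("grouping"):
        return res

    # -- thinning + double-crossover removal ------------------------------
    for parent, p in parent_sets.items():
        if not p["idx"].size:
            continue
        table = pd.DataFrame(
            {
                "row": np.arange(p["idx"].size),
                "locus_id": [ad.loci[i].locus_id for i in p["idx"]],
                "scaffold": p["scaffolds"],
                "position": p["positions"],
                "n_called": p["n_called"],
                "informative_class": [calls[i].cross_type for i in p["idx"]],
            }
        )
        kept = linkage_grouping.thin_markers(table, cfg.thin_k)
        _subset_parent(p, np.sort(kept["row"].to_numpy()))
        keep_dxo = linkage_grouping.remove_double_crossover_loci(
            p["states"], p["scaffolds"], p["positions"], cfg.dxo_min_individuals
        )
        _subset_parent(p, np.where(keep_dxo)[0])

    # -- sex maps ----------------------------------------------------------
    sex_maps = {}
    for parent, p in parent_sets.items():
        markers = pd.DataFrame(
            {
                "locus_id": [ad.loci[i].locus_id for i in p["idx"]],
                "scaffold": p["scaffolds"],
                "position": p["positions"],
                "lg": [scaffold_group.get(s) for s in p["scaffolds"]],
            }
        )
        tag = "maternal" if parent == "mother" else "paternal"
        sex_maps[tag] = map_build.build_sex_map(
            tag, markers, p["states"], cfg.map_function, cfg.min_informative,
            error_rate=est.e_hat if cfg.debias_dropout else 0.0,
        )
        rows = []
        for lg, frame in sex_maps[tag].groups.items():
            rows.append(frame.assign(lg=lg))
        if rows:
            _write_tsv(
                pd.concat(rows, ignore_index=True),
                os.path.join(cfg.out_dir, f"map_{tag}.tsv"),
                cfg,
            )
    res.maternal_map = sex_maps["maternal"]
    res.paternal_map = sex_maps["paternal"]
    logger.info(
        "maps: maternal %d LGs, paternal %d LGs",
        len(res.maternal_map.groups), len(res.paternal_map.groups),
    )
    if done("maps"):
        return res

    # -- consensus merge ---------------------------------------------------
    consensus, conflicts = map_build.merge_maps(
        res.maternal_map, res.paternal_map, scaffold_index, cfg.gap_length
    )
    res.consensus = consensus
    res.conflicts = conflicts
    formats_io.write_agp(
        os.path.join(cfg.out_dir, "consensus.agp"),
        consensus,
        scaffold_index,
        cfg.gap_length,
        header_extra=[f"radmap seed={cfg.seed} config={cfg.config_hash()}"],
    )
    res.report = _build_report(res, scaffold_index)
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(res.report, fh, indent=2)
    if done("merge"):
        return res

    # -- liftover ----------------------------------------------------------
    if cfg.gff:
        n_lift, n_pass, n_skip = formats_io.liftover_gff(
            cfg.gff,
            consensus,
            scaffold_index,
            os.path.join(cfg.out_dir, "lifted.gff"),
        )
        logger.info("liftover: %d lifted, %d passthrough, %d skipped", n_lift, n_pass, n_skip)
    done("liftover")
    return res


def _subset_parent(p: dict, rows: np.ndarray) -> None:
    p["idx"] = p["idx"][rows]
    p["states"] = p["states"][rows]
    p["scaffolds"] = p["scaffolds"][rows]
    p["positions"] = p["positions"][rows]
    p["n_called"] = p["n_called"][rows]
    p["rf"] = p["rf"][np.ix_(rows, rows)] if p["rf"].size else p["rf"]


def _build_report(res: PipelineResult, scaffold_index: dict) -> dict:
    """Run report: the filter audit in the familiar six-step table shape
    plus map summary statistics (markers, scaffolds anchored/oriented/
    unplaced, bases, cM totals, genome-wide cM/Mb)."""
    consensus = res.consensus
    anchored = [p for pls in consensus.chromosomes.values() for p in pls]
    oriented = [p for p in anchored if p.orientation in ("+", "-")]
    anchored_bp = sum(scaffold_index[p.scaffold] for p in anchored)
    unplaced_bp = sum(scaffold_index[s] for s in consensus.unplaced)
    summary = {}
    for tag, sex_map in (("maternal", res.maternal_map), ("paternal", res.paternal_map)):
        total_cm = sum(f["cm"].max() for f in sex_map.groups.values() if len(f))
        n_markers = sum(len(f) for f in sex_map.groups.values())
        mapped_bp = sum(
            scaffold_index[s]
            for s in {s for f in sex_map.groups.values() for s in f["scaffold"]}
        )
        summary[tag] = {
            "n_linkage_groups": len(sex_map.groups),
            "n_markers": n_markers,
            "total_cm": round(total_cm, 2),
            "mapped_bp": mapped_bp,
            "cm_per_mb": round(total_cm / (mapped_bp / 1e6), 3) if mapped_bp else None,
        }
    return {
        "seed": res.config.seed,
        "config_hash": res.config.config_hash(),
        "filter_audit": res.audit.rows if res.audit else [],
        "e_hat": res.e_hat,
        "n_dropout_corrected": res.n_corrected,
        "n_distorted_removed": res.n_distorted,
        "n_parent_discordant_removed": res.n_discordant,
        "n_linkage_groups": len(res.groups) if res.groups else 0,
        "n_chimera_flags": len(res.chimera_flags),
        "sex_maps": summary,
        "consensus": {
            "n_chromosomes": len(consensus.chromosomes),
            "n_scaffolds_anchored": len(anchored),
            "n_scaffolds_oriented": len(oriented),
            "n_scaffolds_unplaced": len(consensus.unplaced),
            "anchored_bp": anchored_bp,
            "unplaced_bp": unplaced_bp,
            "pct_assembly_anchored": round(
                100.0 * anchored_bp / (anchored_bp + unplaced_bp), 2
            )
            if anchored_bp + unplaced_bp
            else None,
        },
    }
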