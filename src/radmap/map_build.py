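"""Marker ordering, centimorgan conversion and consensus map merging.

Within each linkage group and parent, markers are ordered by a
seriation that minimises the sum of adjacent recombination fractions
(greedy nearest-neighbour construction followed by 2-opt improvement),
then converted to cumulative centimorgans with the Haldane map function
(Kosambi available). The two sex-specific maps are merged into a
chromosome-level scaffold order by equally weighted mean scaffold
positions, with per-scaffold orientation from the rank correlation
between physical (bp) and genetic (cM) marker positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConsensusMap, ScaffoldPlacement
from .linkage_grouping import rf_matrix


@dataclass
class SexMap:
    """Ordered, distanced markers of one parent, per linkage group."""

    parent: str  # maternal / paternal
    groups: dict[str, pd.DataFrame] = field(default_factory=dict)
    # each frame: locus_id, scaffold, position, cm (ordered, cm from 0)


# ---------------------------------------------------------------------------
# Seriation
# ---------------------------------------------------------------------------

_UNKNOWN_RF = 0.5


def sarf(order: np.ndarray, dist: np.ndarray) -> float:
    """Sum of adjacent recombination fractions along an order."""
    o = np.asarray(order)
    return float(dist[o[:-1], o[1:]].sum())


def _spectral_order(dist: np.ndarray) -> np.ndarray:
    """Initial seriation from the Fiedler vector of the similarity
    graph (similarity 0.5 - rf). Uses the whole distance profile of
    every marker, so sampling zeros in individual entries cannot chain
    markers from distant regions the way a nearest-neighbour
    construction can."""
    m = dist.shape[0]
    if m < 2:
        return np.arange(m)
    sim = 0.5 - np.minimum(dist, 0.5)
    np.fill_diagonal(sim, 0.0)
    lap = np.diag(sim.sum(axis=1)) - sim
    _, vec = np.linalg.eigh(lap)
    return np.argsort(vec[:, 1], kind="stable")


def order_markers(
    rf: np.ndarray,
    locus_ids: list[str],
    scaffolds: list[str] | None = None,
    max_passes: int = 60,
    min_gain: float = 0.005,
) -> list[int]:
    """SARF-minimising seriation of one linkage group's markers:
    spectral (Fiedler-vector) construction followed by 2-opt
    improvement to a local optimum.

    Unknown rf entries are penalised at 0.5. 2-opt moves must improve
    SARF by at least ``min_gain``: with ~100 meioses an rf difference
    below ~0.005 is sampling noise, and chasing it shuffles blocks of
    tied markers. The resulting order is normalised so the
    lexicographically smallest terminal scaffold (or locus id) comes
    first; single markers are returned as-is."""
    m = rf.shape[0]
    if m <= 1:
        return list(range(m))
    dist = np.where(np.isnan(rf), _UNKNOWN_RF, rf)
    np.fill_diagonal(dist, 0.0)
    path = _spectral_order(dist)
    # 2-opt to a local optimum
    for _ in range(max_passes):
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                left = dist[path[i - 1], path[i]] if i > 0 else 0.0
                right = dist[path[j], path[j + 1]] if j < m - 1 else 0.0
                new_left = dist[path[i - 1], path[j]] if i > 0 else 0.0
                new_right = dist[path[i], path[j + 1]] if j < m - 1 else 0.0
                if new_left + new_right < left + right - min_gain:
                    path[i:j + 1] = path[i:j + 1][::-1]
                    improved = True
        if not improved:
            break
    # orientation normalisation
    keys = scaffolds if scaffolds is not None else locus_ids
    first, last = keys[path[0]], keys[path[-1]]
    if (last, locus_ids[path[-1]]) < (first, locus_ids[path[0]]):
        path = path[::-1]
    return [int(i) for i in path]


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def haldane_cm(r: float) -> float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r)."""
    return -50.0 * np.log(1.0 - 2.0 * r)


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in cM: d = 25 ln((1 + 2r)/(1 - 2r))."""
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def map_distances(
    adjacent_rf: np.ndarray,
    map_function: str = "haldane",
    rf_ceiling: float = 0.49,
) -> np.ndarray:
    """Cumulative cM positions from adjacent recombination fractions.

    Unknown (nan) adjacent rf contributes 0 cM; rf >= 0.5 is clamped to
    ``rf_ceiling`` with a warning. The first locus sits at 0 cM."""
    import warnings

    fun = {"haldane": haldane_cm, "kosambi": kosambi_cm}.get(map_function)
    if fun is None:
        raise ValueError(f"unknown map function {map_function!r}")
    r = np.array(adjacent_rf, dtype=float)
    r = np.nan_to_num(r, nan=0.0)
    if (r >= 0.5).any():
        warnings.warn(
            f"map_distances: {(r >= 0.5).sum()} adjacent rf >= 0.5 clamped to {rf_ceiling}"
        )
        r[r >= 0.5] = rf_ceiling
    d = np.array([fun(x) for x in r])
    return np.concatenate([[0.0], np.cumsum(d)])


# ---------------------------------------------------------------------------
# Sex maps
# ---------------------------------------------------------------------------

def pooled_distance_matrix(rf: np.ndarray, scaffolds: list[str]) -> np.ndarray:
    """Marker distance matrix with cross-scaffold entries pooled to the
    scaffold-pair mean rf.

    A single marker pair observes too few meioses to distinguish nearby
    from moderately distant loci (an rf of exactly 0 is common by
    sampling even 1 Mb apart), which lets a SARF seriation chain
    spurious zero edges across the group. Scaffolds are anchored as
    units, so every marker pair spanning the same two scaffolds
    estimates the same quantity; their mean is the better-resolved
    distance. Within-scaffold entries keep the direct pairwise rf."""
    scaf = np.asarray(scaffolds)
    names, codes = np.unique(scaf, return_inverse=True)
    m = names.size
    total = np.zeros((m, m))
    count = np.zeros((m, m))
    known = ~np.isnan(rf)
    ii, jj = np.where(np.triu(known, k=1))
    si, sj = codes[ii], codes[jj]
    cross = si != sj
    np.add.at(total, (si[cross], sj[cross]), rf[ii[cross], jj[cross]])
    np.add.at(count, (si[cross], sj[cross]), 1.0)
    total += total.T
    count += count.T
    with np.errstate(invalid="ignore"):
        scaffold_mean = total / count
    out = rf.copy()
    diff = codes[:, None] != codes[None, :]
    out[diff] = scaffold_mean[codes[:, None], codes[None, :]][diff]
    return out


def phase_align_states(sub: np.ndarray) -> np.ndarray:
    """Chain-align het/hom state rows so coupling/repulsion phase
    differences between markers of one scaffold do not look like
    crossovers: each row is flipped when its majority relationship to
    the previous row is discordant."""
    aligned = sub.copy()
    for j in range(1, aligned.shape[0]):
        a, b = aligned[j - 1], aligned[j]
        both = ~np.isnan(a) & ~np.isnan(b)
        if not both.any():
            continue
        d = int((a[both] != b[both]).sum())
        if d > both.sum() - d:
            aligned[j] = 1.0 - aligned[j]
    return aligned


def scaffold_consensus_states(
    states: np.ndarray, scaffolds: list[str]
) -> tuple[list[str], np.ndarray]:
    """Per-scaffold, per-offspring majority het/hom state.

    Markers of one scaffold are phase-aligned, then each offspring's
    state is the majority vote over its called markers (exact ties and
    all-missing give nan). Voting raises the effective call rate of a
    scaffold far above that of any single marker and cancels isolated
    dropout miscalls, so scaffold-level recombination fractions are
    estimated on near-complete data."""
    scaf = np.asarray(scaffolds)
    names = list(dict.fromkeys(scaffolds))  # first-appearance order
    cons = np.full((len(names), states.shape[1]), np.nan)
    for si, name in enumerate(names):
        rows = np.where(scaf == name)[0]
        aligned = phase_align_states(states[rows])
        with np.errstate(invalid="ignore"):
            frac = np.nanmean(aligned, axis=0)
        cons[si] = np.where(frac > 0.5, 1.0, np.where(frac < 0.5, 0.0, np.nan))
    return names, cons


def _boundary_distance(rf: np.ndarray, i: int, j: int) -> float:
    """Direct recombination distance between two adjacent scaffolds
    (0 when unknown). Sampling zeros are kept as exact cM ties: the
    consensus merge resolves them with the other parent's map."""
    direct = rf[i, j]
    return 0.0 if np.isnan(direct) else float(direct)


def _smooth_ordered_states(ordered: np.ndarray) -> np.ndarray:
    """One pass of singleton correction along an ordered, phase-aligned
    state matrix: an offspring state disagreeing with both flanking
    scaffolds (which agree with each other) is an apparent double
    crossover over a fraction of a centimorgan — overwhelmingly a
    residual dropout miscall — and is flipped to the flanking value;
    a missing state between agreeing flanks is imputed likewise."""
    out = ordered.copy()
    m = out.shape[0]
    for i in range(1, m - 1):
        a, b, c = out[i - 1], out[i], out[i + 1]
        flank = (a == c) & ~np.isnan(a) & ~np.isnan(c)
        flip = flank & ~np.isnan(b) & (b != a)
        fill = flank & np.isnan(b)
        out[i, flip] = a[flip]
        out[i, fill] = a[fill]
    return out


def _pair_rf(a: np.ndarray, b: np.ndarray) -> float:
    """Phase-minimised discordance between two state vectors."""
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    d = int((a[both] != b[both]).sum())
    return min(d, n - d) / n


def _glue_costs(
    first: np.ndarray, last: np.ndarray, neighbour: np.ndarray
) -> tuple[float, float]:
    """Discordance counts of a scaffold's two end markers against a
    neighbouring scaffold's consensus states, evaluated on the shared
    offspring subset so the comparison is paired: the difference is
    driven only by offspring that recombine inside the scaffold, not by
    which offspring happen to be called at each marker. The phase is
    chosen jointly (minimising the summed discordance)."""
    both = ~np.isnan(first) & ~np.isnan(last) & ~np.isnan(neighbour)
    n = int(both.sum())
    if n == 0:
        return 0.0, 0.0
    df = int((first[both] != neighbour[both]).sum())
    dl = int((last[both] != neighbour[both]).sum())
    if df + dl > n:  # opposite phase fits better
        df, dl = n - df, n - dl
    return float(df), float(dl)


def _order_within_scaffold(rf_sub: np.ndarray, ids: list[str]) -> list[int]:
    """Deterministic spectral order of one scaffold's markers, with
    ties broken by a hash of the locus id so no assembly-coordinate
    information leaks into the genetic order."""
    import hashlib

    m = rf_sub.shape[0]
    if m <= 1:
        return list(range(m))
    dist = np.where(np.isnan(rf_sub), _UNKNOWN_RF, rf_sub)
    np.fill_diagonal(dist, 0.0)
    sim = 0.5 - np.minimum(dist, 0.5)
    np.fill_diagonal(sim, 0.0)
    lap = np.diag(sim.sum(axis=1)) - sim
    _, vec = np.linalg.eigh(lap)
    fied = vec[:, 1]
    return sorted(
        range(m),
        key=lambda i: (round(float(fied[i]), 12),
                       hashlib.md5(ids[i].encode()).hexdigest()),
    )


def build_sex_map(
    parent: str,
    markers: pd.DataFrame,
    states: np.ndarray,
    map_function: str = "haldane",
    min_informative: int = 20,
    error_rate: float = 0.0,
) -> SexMap:
    """Order and distance one parent's markers per linkage group.

    ``markers`` rows (locus_id, scaffold, position, lg) align with
    ``states`` rows (het/hom/nan offspring states). Scaffolds are
    ordered as whole units on their consensus (majority-vote) states;
    markers are then seriated within each scaffold and the scaffold's
    internal direction chosen to minimise the discordance against the
    neighbouring scaffolds. A non-zero ``error_rate`` (the global
    dropout e) removes the residual-dropout noise floor from the
    between-scaffold rf used for genetic distances."""
    from .linkage_grouping import debias_rf

    sex_map = SexMap(parent)
    for lg in sorted(markers["lg"].dropna().unique()):
        sel = np.where((markers["lg"] == lg).to_numpy())[0]
        sub = markers.iloc[sel].reset_index(drop=True)
        if sel.size == 1:
            sex_map.groups[str(lg)] = sub.assign(cm=[0.0])[
                ["locus_id", "scaffold", "position", "cm"]
            ]
            continue
        lg_states = states[sel]
        scaffolds = list(sub["scaffold"])
        ids = list(sub["locus_id"])
        names, cons = scaffold_consensus_states(lg_states, scaffolds)
        # scaffold backbone order from consensus states; spectral only —
        # a SARF local search will tunnel through sampling zeros
        # (distant scaffold pairs showing rf 0 by chance) and collapse
        # the group onto a spurious zero-cost path
        cons_rf, _ = rf_matrix(cons, min_informative)
        cons_dist = np.where(np.isnan(cons_rf), _UNKNOWN_RF, cons_rf)
        np.fill_diagonal(cons_dist, 0.0)
        scaffold_order = list(_spectral_order(cons_dist))
        # iterate order <-> error correction: smooth singleton state
        # flips (residual dropout) along the current order, re-estimate
        # rf, reorder
        for _ in range(2):
            order_arr = np.array(scaffold_order)
            smoothed = _smooth_ordered_states(
                phase_align_states(cons[order_arr])
            )
            cons[order_arr] = smoothed
            cons_rf, _ = rf_matrix(cons, min_informative)
            cons_dist = np.where(np.isnan(cons_rf), _UNKNOWN_RF, cons_rf)
            np.fill_diagonal(cons_dist, 0.0)
            scaffold_order = list(_spectral_order(cons_dist))
        first_s, last_s = names[scaffold_order[0]], names[scaffold_order[-1]]
        if last_s < first_s:
            scaffold_order = scaffold_order[::-1]
        # markers within each scaffold, direction glued to neighbours
        marker_rf, marker_n = rf_matrix(lg_states, min_informative)
        marker_rf_deb = debias_rf(marker_rf, error_rate)
        path: list[int] = []
        boundary_rf: list[float] = []
        cons_of = {name: cons[i] for i, name in enumerate(names)}
        ordered_names = [names[i] for i in scaffold_order]
        for k, name in enumerate(ordered_names):
            rows = [i for i, s in enumerate(scaffolds) if s == name]
            aligned = phase_align_states(lg_states[rows])
            inner = _order_within_scaffold(
                marker_rf[np.ix_(rows, rows)], [ids[i] for i in rows]
            )
            seq = [rows[i] for i in inner]
            if len(seq) > 1:
                al_first, al_last = aligned[inner[0]], aligned[inner[-1]]
                cost_fwd = cost_rev = 0.0
                if k > 0:
                    f, l = _glue_costs(al_first, al_last, cons_of[ordered_names[k - 1]])
                    cost_fwd += f  # forward: first marker faces the previous scaffold
                    cost_rev += l
                if k < len(ordered_names) - 1:
                    f, l = _glue_costs(al_first, al_last, cons_of[ordered_names[k + 1]])
                    cost_fwd += l  # forward: last marker faces the next scaffold
                    cost_rev += f
                if cost_rev < cost_fwd:
                    seq = seq[::-1]
            if path:
                i = names.index(ordered_names[k - 1])
                j = names.index(name)
                boundary_rf.append(_boundary_distance(cons_rf, i, j))
            path.extend(seq)
        # adjacent rf: within scaffolds from marker pairs, across
        # boundaries from the (debiased) consensus-state estimates
        adj = []
        bi = 0
        for a, b in zip(path[:-1], path[1:]):
            if scaffolds[a] == scaffolds[b]:
                v = marker_rf_deb[a, b]
                # require >= 2 noise-corrected recombinant observations
                # inside a scaffold: a single discordant offspring is
                # indistinguishable from one residual dropout miscall,
                # and within-scaffold cm spread drives orientation
                if np.isnan(v) or round(v * marker_n[a, b]) < 2:
                    v = 0.0
                adj.append(float(v))
            else:
                adj.append(boundary_rf[bi])
                bi += 1
        cm = map_distances(np.array(adj, dtype=float), map_function)
        frame = sub.iloc[path].assign(cm=cm).reset_index(drop=True)
        # orientation normalisation: smallest terminal scaffold first
        first, last = frame["scaffold"].iloc[0], frame["scaffold"].iloc[-1]
        if (last, frame["locus_id"].iloc[-1]) < (first, frame["locus_id"].iloc[0]):
            cm_max = frame["cm"].max()
            frame = frame.iloc[::-1].reset_index(drop=True)
            frame["cm"] = cm_max - frame["cm"]
        sex_map.groups[str(lg)] = frame[["locus_id", "scaffold", "position", "cm"]]
    return sex_map


# ---------------------------------------------------------------------------
# Consensus merge
# ---------------------------------------------------------------------------

def _rescaled(frame: pd.DataFrame) -> pd.DataFrame:
    """Marker frame with cm rescaled to [0, 1] within the LG."""
    cm = frame["cm"].to_numpy(dtype=float)
    span = cm.max() - cm.min()
    pos = (cm - cm.min()) / span if span > 0 else np.full(cm.size, 0.5)
    return frame.assign(relpos=pos)


def _scaffold_rank_positions(frame: pd.DataFrame) -> pd.Series:
    """Per-scaffold map position as the average rank of the scaffold's
    mean cM, rescaled to [0, 1]. Average ranks keep genuinely tied
    scaffolds (no recombination observed between them in this parent)
    exactly tied, so the other map decides their consensus order, while
    being robust to the absolute cM scale."""
    mean_cm = frame.groupby("scaffold")["cm"].mean()
    r = stats.rankdata(np.round(mean_cm.to_numpy(), 9), method="average")
    pos = (r - 1) / (len(r) - 1) if len(r) > 1 else np.full(1, 0.5)
    return pd.Series(pos, index=mean_cm.index)


def merge_maps(
    maternal: SexMap,
    paternal: SexMap,
    scaffold_index: dict,
    gap_length: int = 100,
) -> tuple[ConsensusMap, list[str]]:
    """Merge equally weighted sex maps into a chromosome-level scaffold
    order and orientation.

    Linkage groups are paired across maps by maximal Jaccard overlap of
    scaffold content; each scaffold's consensus position is the mean of
    its rescaled per-map positions (maps aligned in direction first);
    orientation is the sign of the Spearman correlation between marker
    bp and consensus-frame genetic position pooled over both maps, '?'
    when undefined. Scaffolds claimed by conflicting group pairs stay
    with their maternal group and the conflict is logged."""
    conflicts: list[str] = []
    m_groups = {lg: _rescaled(f) for lg, f in maternal.groups.items()}
    p_groups = {lg: _rescaled(f) for lg, f in paternal.groups.items()}
    m_scafs = {lg: set(f["scaffold"]) for lg, f in m_groups.items()}
    p_scafs = {lg: set(f["scaffold"]) for lg, f in p_groups.items()}

    # pair LGs by Jaccard
    cand = []
    for ml, ms in m_scafs.items():
        for pl, ps in p_scafs.items():
            inter = len(ms & ps)
            if inter:
                jac = inter / len(ms | ps)
                cand.append((-jac, ml, pl))
    cand.sort()
    pair_of_m: dict[str, str | None] = {lg: None for lg in m_groups}
    used_p = set()
    for _, ml, pl in cand:
        if pair_of_m[ml] is None and pl not in used_p:
            pair_of_m[ml] = pl
            used_p.add(pl)
    groups: list[tuple[str | None, str | None]] = [
        (ml, pl) for ml, pl in pair_of_m.items()
    ] + [(None, pl) for pl in p_groups if pl not in used_p]

    assigned: dict[str, int] = {}
    built: list[list[ScaffoldPlacement]] = []
    for gi, (ml, pl) in enumerate(groups):
        mf = m_groups.get(ml) if ml else None
        pf = p_groups.get(pl) if pl else None
        mpos = _scaffold_rank_positions(mf) if mf is not None else None
        ppos = _scaffold_rank_positions(pf) if pf is not None else None
        # align paternal direction to maternal
        if mf is not None and pf is not None:
            shared = mpos.index.intersection(ppos.index)
            if len(shared) >= 2:
                rho = stats.spearmanr(mpos[shared], ppos[shared]).statistic
                if np.isfinite(rho) and rho < 0:
                    pf = pf.assign(relpos=1.0 - pf["relpos"])
                    ppos = 1.0 - ppos
        # membership with conflict resolution (maternal wins)
        members: dict[str, list[tuple[float, float]]] = {}
        marker_rows: dict[str, list[tuple[float, float]]] = {}
        for frame, spos, owner in ((mf, mpos, "maternal"), (pf, ppos, "paternal")):
            if frame is None:
                continue
            for scaffold, sub in frame.groupby("scaffold"):
                prev = assigned.get(scaffold)
                if prev is not None and prev != gi:
                    if owner == "maternal":
                        conflicts.append(
                            f"{scaffold}: moved to maternal group {ml}"
                        )
                        # maternal claim overrides
                        built[prev] = [p for p in built[prev] if p.scaffold != scaffold]
                    else:
                        conflicts.append(
                            f"{scaffold}: paternal group {pl} ignored, kept earlier assignment"
                        )
                        continue
                assigned[scaffold] = gi
                members.setdefault(scaffold, []).append(float(spos[scaffold]))
                # centre genetic positions per map so inter-map offsets
                # cannot masquerade as within-scaffold orientation signal
                centred = np.round(
                    sub["relpos"].astype(float) - sub["relpos"].mean(), 9
                )
                marker_rows.setdefault(scaffold, []).extend(
                    zip(sub["position"].astype(float), centred)
                )
        order = sorted(members, key=lambda s: (float(np.mean(members[s])), s))
        placements = []
        for scaffold in order:
            xy = np.array(marker_rows[scaffold])
            orientation = "?"
            if (
                xy.shape[0] >= 2
                and np.unique(xy[:, 0]).size >= 2
                and np.unique(xy[:, 1]).size >= 2
                and xy[:, 1].max() - xy[:, 1].min() > 1e-9
            ):
                rho = stats.spearmanr(xy[:, 0], xy[:, 1]).statistic
                if np.isfinite(rho) and rho > 0:
                    orientation = "+"
                elif np.isfinite(rho) and rho < 0:
                    orientation = "-"
            placements.append(ScaffoldPlacement(scaffold, orientation))
        built.append(placements)

    consensus = ConsensusMap()
    anchored: set[str] = set()
    order_by_len = sorted(
        range(len(built)),
        key=lambda gi: -sum(scaffold_index.get(p.scaffold, 0) for p in built[gi]),
    )
    chrom_n = 0
    for gi in order_by_len:
        if not built[gi]:
            continue
        chrom_n += 1
        consensus.chromosomes[f"chr{chrom_n:02d}"] = built[gi]
        anchored.update(p.scaffold for p in built[gi])
    consensus.unplaced = sorted(set(scaffold_index) - anchored)
    consensus.assign_offsets(scaffold_index, gap_length)
    return consensus, conflicts
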