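"""Overlap-Layout-Consensus assembly of molecules into consensus maps.

Stages, in driver order:

1. all-vs-all pairwise molecule alignment -> overlap graph;
2. layout along a maximum-weight spanning tree per connected component,
   initial consensus by clustering projected molecule labels;
3. Refine-B: realign molecules to maps, keep each molecule's single best
   map, remove chimeric joins (cross-map interior junctions and coverage
   cliffs), re-estimate label positions;
4. extension and merge (five rounds by default): molecules aligning past
   map ends extend the map, overlapping maps are merged;
5. extend-and-split: molecules whose unaligned ends exceed 30 kb are
   pooled per map and re-assembled (depth 1), recovering alleles that
   differ from the seeded consensus by large events;
6. final refinement and haplotype conversion: molecules re-assigned at the
   final cutoff; a map whose molecules separate into two clusters by the
   span between well-supported flanking labels (internal alignment gap
   below 50 kb) is converted into two haplotype maps.

Consensus label positions live in an arbitrary per-map frame (first label
normalized to 1000 bp); member molecules carry the affine transform
(orientation, offset) into that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from omsv import _kernels
from omsv.map_align import (
    Alignment,
    NullModel,
    ScoringParams,
    align_maps,
)
from omsv.molecule_sim import Molecule

__all__ = [
    "AssemblyParams",
    "ConsensusMap",
    "MemberFit",
    "OverlapGraph",
    "StageLog",
    "pairwise_overlap_graph",
    "layout_and_initial_consensus",
    "refine_b",
    "extend_and_merge_round",
    "extend_and_split",
    "final_refine_haplotype",
    "run_assembly",
    "estimate_positions",
]


@dataclass
class AssemblyParams:
    """Staged assembly thresholds (P cutoffs on the configured scale)."""

    pairwise_p: float = 1e-9
    refine_b_p: float = 1e-11
    extension_p: float = 1e-11
    merge_p: float = 1e-15
    refine_final_p: float = 1e-11
    n_extend_merge_rounds: int = 5
    end_gap_split_bp: float = 30_000.0
    internal_gap_haplotype_bp: float = 50_000.0
    min_molecules: int = 3
    min_labels: int = 8
    min_overlap_bp: float = 50_000.0
    min_pairwise_pairs: int = 9
    chimera_cov_frac: float = 0.3        # coverage-cliff split threshold
    merge_min_cov_frac: float = 0.8      # matched fraction of smaller map
    offset_tolerance_bp: float = 20_000.0
    haplotype_min_sep_bp: float = 4_000.0
    haplotype_sep_sd_mult: float = 3.0
    max_internal_gap_bp: float = 40_000.0
    resolution_limit: float = 1500.0
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        for name in ("pairwise_p", "refine_b_p", "extension_p", "merge_p",
                     "refine_final_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_extend_merge_rounds < 1:
            raise ValueError("need at least one extend-merge round")
        if self.end_gap_split_bp <= 0 or self.internal_gap_haplotype_bp <= 0:
            raise ValueError("gap thresholds must be positive")

    @property
    def cluster_gap(self) -> float:
        """Point-scatter gap for the first consensus clustering stage."""
        return max(self.resolution_limit / 2.0, 50.0)


@dataclass
class MemberFit:
    """A molecule's placement in a consensus map frame.

    The base transform is affine, ``orientation * p + offset``.  When
    anchor arrays are present (matched label pairs from an alignment),
    projection is piecewise linear between anchors, which removes the
    cumulative sizing drift a single affine would accumulate along a long
    molecule; beyond the outermost anchors it extrapolates with unit
    slope.  ``q_lo``/``q_hi`` bound the matched query range (bp, molecule
    frame); labels outside it are unaligned flanks and only contribute to
    the consensus when they project beyond the current map ends
    (extension).
    """

    orientation: int
    offset: float
    q_lo: float | None = None
    q_hi: float | None = None
    anchors_q: np.ndarray | None = None  # molecule frame, ascending
    anchors_t: np.ndarray | None = None  # map frame at those anchors

    def project(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        if self.anchors_q is None or self.anchors_q.size < 2:
            return self.orientation * pos + self.offset
        # windowed local offsets: each anchor's offset is averaged over
        # its neighborhood, so a projected label is carried by the
        # molecule's own relative geometry rather than pinned to the old
        # consensus position it was matched to
        w = 5
        off = self.anchors_t - self.orientation * self.anchors_q
        n = off.size
        cum = np.concatenate([[0.0], np.cumsum(off)])
        lo = np.maximum(np.arange(n) - w, 0)
        hi = np.minimum(np.arange(n) + w + 1, n)
        loc = (cum[hi] - cum[lo]) / (hi - lo)
        return self.orientation * pos + np.interp(pos, self.anchors_q, loc)

    def shifted(self, shift: float) -> "MemberFit":
        return MemberFit(
            self.orientation, self.offset + shift, self.q_lo, self.q_hi,
            self.anchors_q,
            None if self.anchors_t is None else self.anchors_t + shift)


@dataclass
class ConsensusMap:
    """An assembled consensus map for one enzyme channel."""

    map_id: int
    channel: int
    labels: np.ndarray
    support: np.ndarray
    members: dict[int, MemberFit]
    haplotype: int = 0          # 0 = untagged, 1/2 = haplotype pair

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    @property
    def span(self) -> float:
        return float(self.labels[-1] - self.labels[0]) if self.n_labels else 0.0

    def validate(self, min_support: int = 1) -> None:
        if self.labels.size:
            if np.any(np.diff(self.labels) <= 0):
                raise ValueError("consensus labels must be strictly increasing")
            if np.any(self.support < min_support):
                raise ValueError("consensus label below minimum support")


@dataclass
class OverlapGraph:
    """Molecule overlap graph; edges carry the best pairwise alignment."""

    graph: nx.Graph
    molecules: dict[int, Molecule]
    channel: int


@dataclass
class StageLog:
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_maps: int, **info) -> None:
        self.entries.append({"stage": stage, "n_maps": n_maps, **info})

    @property
    def n_extend_merge_rounds(self) -> int:
        return sum(1 for e in self.entries if e["stage"] == "extend_merge")

    def __str__(self) -> str:
        return "\n".join(
            f"{e['stage']}: {e['n_maps']} maps "
            + " ".join(f"{k}={v}" for k, v in e.items()
                       if k not in ("stage", "n_maps"))
            for e in self.entries
        )


def _mol_labels(mol: Molecule, channel: int) -> np.ndarray:
    return mol.labels[channel - 1]


def _support_floor(params: AssemblyParams, n_members: int) -> int:
    """Per-label support threshold, adapted for small member sets.

    With only a handful of staggered members no label can reach the full
    minimum-molecule support, so small assemblies fall back to pair
    support."""
    if n_members <= params.min_molecules:
        return 1
    if n_members < 2 * params.min_molecules:
        return 2
    return params.min_molecules


# ------------------------------------------------------------ stage 1


def pairwise_overlap_graph(
    molecules: Sequence[Molecule],
    params: AssemblyParams,
    null: NullModel,
    channel: int = 1,
    position_hints: dict | None = None,
) -> OverlapGraph:
    """All-vs-all pairwise comparison of molecules (both orientations).

    An edge is kept when the alignment P-value passes the pairwise cutoff,
    the matched span reaches the minimum overlap on both molecules, and
    enough label pairs are matched.  Edges carry the screening alignment's
    orientation and an approximate offset (endpoint mean); exact
    alignments are recomputed on demand for layout.
    """
    sp = params.scoring
    eligible = [m for m in molecules
                if _mol_labels(m, channel).size >= params.min_labels]
    G = nx.Graph()
    for m in eligible:
        G.add_node(m.molecule_id)
    byid = {m.molecule_id: m for m in molecules}
    if len(eligible) < 2:
        return OverlapGraph(G, byid, channel)

    labs = [_mol_labels(m, channel) for m in eligible]
    flat = np.ascontiguousarray(np.concatenate(labs))
    mirror = np.ascontiguousarray(np.concatenate(
        [(m.backbone_length - q)[::-1] for m, q in zip(eligible, labs)]))
    offs = np.zeros(len(labs) + 1, dtype=np.int64)
    np.cumsum([q.size for q in labs], out=offs[1:])
    centers = np.full(len(eligible), -1.0)
    halfs = np.zeros(len(eligible))
    use_hints = False
    if position_hints:
        for k, m in enumerate(eligible):
            hint = position_hints.get(m.molecule_id)
            if hint is not None:
                centers[k], halfs[k] = hint
        use_hints = bool(np.any(centers >= 0.0))
    oi, oj, sc, orient, npair, qs, qe, ts, te = _kernels.all_pairs_scores(
        flat, mirror, offs, sp.match_bonus, sp.miss_penalty,
        sp.false_penalty, sp.sd0_sq, sp.sizing_sd_scale, sp.max_skip,
        sp.resolution_limit, sp.max_residual_penalty, params.min_labels,
        centers, halfs, use_hints)

    nlab = np.array([q.size for q in labs])
    pvals = null.pvalue(sc, np.minimum(nlab[oi], nlab[oj]),
                        np.maximum(nlab[oi], nlab[oj]))
    emp = sp.empirical_cutoff(params.pairwise_p)
    span_q = np.array([abs(labs[i][e] - labs[i][s])
                       for i, s, e in zip(oi, qs, qe)])
    span_t = np.array([abs(labs[j][e] - labs[j][s])
                       for j, s, e in zip(oj, ts, te)])
    keep = ((pvals < emp) & (npair >= params.min_pairwise_pairs)
            & (span_q >= params.min_overlap_bp)
            & (span_t >= params.min_overlap_bp))
    for k in np.nonzero(keep)[0]:
        i, j = int(oi[k]), int(oj[k])
        q, t = labs[i], labs[j]
        s_e = int(orient[k])
        # offset of the q -> t transform, estimated from matched endpoints
        o1 = t[ts[k]] - s_e * q[qs[k]]
        o2 = t[te[k]] - s_e * q[qe[k]]
        G.add_edge(
            eligible[i].molecule_id, eligible[j].molecule_id,
            score=float(sc[k]), orient=s_e, offset=float((o1 + o2) / 2.0),
            npairs=int(npair[k]), p=float(pvals[k]),
            query=eligible[i].molecule_id,
            q_range=(float(min(q[qs[k]], q[qe[k]])),
                     float(max(q[qs[k]], q[qe[k]]))),
            t_range=(float(min(t[ts[k]], t[te[k]])),
                     float(max(t[ts[k]], t[te[k]]))),
        )
    return OverlapGraph(G, byid, channel)


# ------------------------------------------------------------ stage 2


def estimate_positions(
    molecules: Sequence[Molecule],
    target_labels: np.ndarray,
    params: AssemblyParams,
    channel: int = 1,
) -> dict[int, tuple[float, float]]:
    """Approximate placements of molecules on a guide map.

    Used only to prune molecule pairs whose bounding boxes cannot
    overlap before the all-vs-all comparison; molecules that fail to
    place are screened against everything.
    """
    sp = params.scoring
    eligible = [m for m in molecules
                if _mol_labels(m, channel).size >= params.min_labels]
    if not eligible:
        return {}
    labs = [_mol_labels(m, channel) for m in eligible]
    flat = np.ascontiguousarray(np.concatenate(labs))
    mirror = np.ascontiguousarray(np.concatenate(
        [(m.backbone_length - q)[::-1] for m, q in zip(eligible, labs)]))
    offs = np.zeros(len(labs) + 1, dtype=np.int64)
    np.cumsum([q.size for q in labs], out=offs[1:])
    score, orient, npair, ts, te = _kernels.molecules_vs_target_ends(
        flat, mirror, offs, np.ascontiguousarray(target_labels),
        sp.match_bonus, sp.miss_penalty, sp.false_penalty, sp.sd0_sq,
        sp.sizing_sd_scale, sp.max_skip, sp.resolution_limit,
        sp.max_residual_penalty, params.min_labels)
    hints: dict[int, tuple[float, float]] = {}
    for k, m in enumerate(eligible):
        if npair[k] < params.min_pairwise_pairs or ts[k] < 0:
            continue
        lo = float(target_labels[ts[k]])
        hi = float(target_labels[te[k]])
        if hi < lo:
            lo, hi = hi, lo
        hints[m.molecule_id] = ((lo + hi) / 2.0,
                                max(hi - lo, m.backbone_length) / 2.0)
    return hints





def _edge_transform(G: nx.Graph, u: int, v: int) -> tuple[int, float]:
    """Transform mapping the frame of u into the frame of v along (u, v)."""
    d = G.edges[u, v]
    s, o = d["orient"], d["offset"]
    if d["query"] == u:
        return s, o
    return s, -s * o  # inverse affine (orientation is its own inverse)


def _build_consensus(
    members: dict[int, MemberFit],
    molecules: dict[int, Molecule],
    channel: int,
    params: AssemblyParams,
    prev_span: tuple[float, float] | None = None,
    min_support: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[int, MemberFit]] | None:
    """Cluster projected member labels into consensus label positions.

    Labels outside a member's matched range are unaligned flanks; they are
    dropped when they project into the interior of the previous map span
    (they belong to a different allele or a chimeric partner) and kept
    when they project beyond the map ends (extension).  Returns (labels,
    support, members with offsets re-normalized) or None when nothing
    survives the support threshold.
    """
    if min_support is None:
        min_support = _support_floor(params, len(members))
    slack = 2.0 * params.resolution_limit
    pts, owner = [], []
    for mid, fit in members.items():
        q = _mol_labels(molecules[mid], channel)
        if q.size == 0:
            continue
        proj = fit.project(q)
        keep = np.ones(q.size, dtype=bool)
        if fit.q_lo is not None:
            flank = (q < fit.q_lo - slack) | (q > fit.q_hi + slack)
            if prev_span is not None:
                interior = ((proj > prev_span[0] - slack)
                            & (proj < prev_span[1] + slack))
                keep = ~(flank & interior)
            else:
                keep = ~flank
        pts.append(proj[keep])
        owner.append(np.full(int(keep.sum()), mid))
    if not pts:
        return None
    pts = np.concatenate(pts)
    owner = np.concatenate(owner)
    if pts.size == 0:
        return None
    labels, support = _cluster_points(pts, owner, params.cluster_gap,
                                      min_support)
    if labels.size == 0:
        return None
    shift = 1000.0 - labels[0]
    labels = labels + shift
    out_members = {mid: fit.shifted(shift) for mid, fit in members.items()}
    return labels, support, out_members


def _cluster_points(pts: np.ndarray, owner: np.ndarray, gap: float,
                    min_support: int, resolution: float = 0.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Cluster projected points into consensus labels.

    Stage 1 gap-clusters the points at the projection-scatter scale;
    stage 2 fuses cluster means closer than the optical resolution, so
    the consensus reproduces the label fusion the molecules themselves
    undergo.  Fusing means (not raw points) keeps noisy point clouds of
    genuinely distinct labels from chaining together.
    """
    order = np.argsort(pts, kind="stable")
    pts, owner = pts[order], owner[order]
    labels, support = [], []
    start = 0
    breaks = np.nonzero(np.diff(pts) > gap)[0]
    for end in np.concatenate([breaks + 1, [pts.size]]).astype(int):
        sup = len(set(owner[start:end].tolist()))
        if sup >= min_support:
            labels.append(float(np.mean(pts[start:end])))
            support.append(sup)
        start = end
    labels = np.array(labels)
    support = np.array(support, dtype=float)
    if resolution > 0 and labels.size > 1:
        fused_l, fused_s = [], []
        cl, cs = [labels[0]], [support[0]]
        for p, su in zip(labels[1:], support[1:]):
            if p - cl[-1] < resolution:
                cl.append(p)
                cs.append(su)
            else:
                fused_l.append(float(np.average(cl, weights=cs)))
                fused_s.append(max(cs))
                cl, cs = [p], [su]
        fused_l.append(float(np.average(cl, weights=cs)))
        fused_s.append(max(cs))
        labels = np.array(fused_l)
        support = np.array(fused_s)
    return labels, support.astype(int)


def _mst_priors(sub: nx.Graph, overlap: OverlapGraph, params: AssemblyParams
                ) -> tuple[dict[int, MemberFit], list[int], int]:
    """BFS-composed placement priors along the maximum-weight spanning tree.

    Tree edges are re-aligned exactly so that composed offsets stay
    accurate to about a kilobase per hop; returns (priors, BFS order
    excluding the root, root).
    """
    channel = overlap.channel
    sp = params.scoring
    mst = nx.maximum_spanning_tree(sub, weight="score")
    root = min(sub.nodes, key=lambda n: (-sub.degree(n), n))
    priors: dict[int, MemberFit] = {root: MemberFit(1, 0.0)}
    order: list[int] = []
    for u, v in nx.bfs_edges(mst, root):
        qmol, tmol = overlap.molecules[v], overlap.molecules[u]
        ea = align_maps(_mol_labels(qmol, channel),
                        _mol_labels(tmol, channel), sp,
                        query_extent=qmol.backbone_length)
        if ea.is_empty:
            s, o = _edge_transform(sub, v, u)
        else:
            s, o = ea.orientation, ea.offset
        fu = priors[u]
        priors[v] = MemberFit(fu.orientation * s,
                              fu.orientation * o + fu.offset)
        order.append(v)
    return priors, order, root


def detect_junction_molecules(
    overlap: OverlapGraph,
    params: AssemblyParams,
) -> set[int]:
    """Molecules whose pairwise overlaps all break at one interior locus.

    A molecule spanning an allele junction (heterozygous SV breakpoint,
    inversion breakpoint) or a chimeric join overlaps one group of
    partners only up to the junction and the other group only from the
    junction on: the matched-range endpoints of its edges cluster sharply
    at the same interior position from both sides.  Overlaps of an
    ordinary molecule end wherever the partner happens to end, so their
    endpoints scatter.  Detected molecules are excluded from the initial
    layout; they re-enter through refinement and seed the
    extend-and-split pools.
    """
    G = overlap.graph
    channel = overlap.channel
    junctions: set[int] = set()
    margin = 40_000.0
    window = 15_000.0
    for v in sorted(G.nodes):
        if G.degree(v) < 6:
            continue
        length = overlap.molecules[v].backbone_length
        ends, starts = [], []
        for u in G.neighbors(v):
            d = G.edges[v, u]
            lo, hi = d["q_range"] if d["query"] == v else d["t_range"]
            if hi < length - margin:
                ends.append(hi)
            if lo > margin:
                starts.append(lo)
        if len(ends) < params.min_molecules or \
                len(starts) < params.min_molecules:
            continue

        def biggest_cluster(vals: list[float]) -> tuple[int, float]:
            vals = sorted(vals)
            best_n, best_pos = 0, 0.0
            i = 0
            for j in range(len(vals)):
                while vals[j] - vals[i] > window:
                    i += 1
                if j - i + 1 > best_n:
                    best_n = j - i + 1
                    best_pos = (vals[i] + vals[j]) / 2.0
            return best_n, best_pos

        ne, pe = biggest_cluster(ends)
        ns, ps = biggest_cluster(starts)
        if (ne >= params.min_molecules and ns >= params.min_molecules
                and abs(pe - ps) <= 2 * window):
            junctions.add(v)
    return junctions


def layout_and_initial_consensus(
    overlap: OverlapGraph,
    params: AssemblyParams,
    next_map_id: int = 0,
    log: StageLog | None = None,
    null: NullModel | None = None,
) -> list[ConsensusMap]:
    """Lay out each connected component and form the initial consensus.

    Junction-spanning molecules (overlap edges implying two placements)
    are set aside first.  The rest of the component is traversed in BFS
    order over its maximum-weight spanning tree (weight = alignment
    score) and the consensus is grown by accretion: each molecule is
    aligned against the current target and its labels are projected in
    through the matched anchors, so placement never accumulates offset
    drift.  The target consists of the confirmed core (clusters supported
    by at least two molecules) plus provisional single-support clusters
    beyond the core ends, which lets the frontier advance without
    re-estimating positions by extrapolation.  Molecules that fail both
    the alignment evidence and the spanning-tree position prior are left
    out and logged; refinement re-admits them if they genuinely belong.
    """
    G = overlap.graph
    channel = overlap.channel
    sp = params.scoring
    junctions = detect_junction_molecules(overlap, params)
    H = G.subgraph([n for n in G.nodes if n not in junctions])
    consensi: list[ConsensusMap] = []
    n_dropped = 0
    for comp in sorted(nx.connected_components(H), key=min):
        if len(comp) < params.min_molecules:
            continue
        sub = H.subgraph(comp)
        approx, bfs_order, root = _mst_priors(sub, overlap, params)

        rootq = _mol_labels(overlap.molecules[root], channel)
        members: dict[int, MemberFit] = {
            root: MemberFit(1, 0.0, float(rootq[0]), float(rootq[-1]),
                            rootq.copy(), rootq.copy())
        }
        pts = [rootq.copy()]
        owner = [np.full(rootq.size, root)]
        labels = rootq.copy()
        core_lo, core_hi = float(rootq[0]), float(rootq[-1])
        slack = 2.0 * params.resolution_limit
        queue = list(bfs_order)
        while queue:
            progressed = False
            deferred: list[int] = []
            for v in queue:
                mol = overlap.molecules[v]
                q = _mol_labels(mol, channel)
                aln = align_maps(q, labels, sp,
                                 query_extent=mol.backbone_length,
                                 null=null)
                if (aln.is_empty or aln.n_pairs < params.min_pairwise_pairs
                        or aln.query_span < params.min_overlap_bp):
                    deferred.append(v)
                    continue
                # accept on a decisive P-value alone, or on a moderate
                # P-value when the placement agrees with the
                # spanning-tree position prior (two independent placement
                # estimates agreeing)
                ax = approx.get(v)
                consistent = (
                    ax is not None
                    and ax.orientation == aln.orientation
                    and abs(ax.offset - aln.offset)
                    <= params.offset_tolerance_bp)
                strong = (null is None
                          or aln.p_value < sp.empirical_cutoff(
                              params.pairwise_p))
                if not (strong or (consistent and aln.p_value < 0.1)):
                    deferred.append(v)
                    continue
                fit = _fit_from_alignment(aln)
                # pinned interpolation keeps the growing target stable:
                # matched labels land exactly on the clusters they hit
                proj = np.interp(q, fit.anchors_q, fit.anchors_t)
                left = q < fit.anchors_q[0]
                right = q > fit.anchors_q[-1]
                proj[left] = fit.anchors_t[0] + fit.orientation * (
                    q[left] - fit.anchors_q[0])
                proj[right] = fit.anchors_t[-1] + fit.orientation * (
                    q[right] - fit.anchors_q[-1])
                flank = (q < fit.q_lo - slack) | (q > fit.q_hi + slack)
                interior = ((proj > core_lo - slack)
                            & (proj < core_hi + slack))
                keep = ~(flank & interior)
                members[v] = fit
                pts.append(proj[keep])
                owner.append(np.full(int(keep.sum()), v))
                cpos, csup = _cluster_points(
                    np.concatenate(pts), np.concatenate(owner),
                    params.cluster_gap, 1)
                core = csup >= min(2, len(members))
                if np.any(core):
                    core_lo = float(cpos[core][0])
                    core_hi = float(cpos[core][-1])
                    labels = cpos[core | (cpos < core_lo)
                                  | (cpos > core_hi)]
                else:
                    labels = cpos
                progressed = True
            if not progressed:
                break
            queue = deferred
        n_dropped += len(queue)
        if len(members) < params.min_molecules:
            n_dropped += len(members)
            continue
        # final initial consensus straight from the accretion points: each
        # point was admitted under the clipping rules in force when its
        # molecule was added, so no re-projection is needed (refinement
        # realigns everything next anyway)
        labels, support = _cluster_points(
            np.concatenate(pts), np.concatenate(owner), params.cluster_gap,
            _support_floor(params, len(members)))
        if labels.size == 0:
            continue
        shift = 1000.0 - labels[0]
        labels = labels + shift
        members = {mid: fit.shifted(shift) for mid, fit in members.items()}
        consensi.append(ConsensusMap(next_map_id, channel, labels, support,
                                     members))
        next_map_id += 1
    if log is not None:
        log.add("layout", len(consensi), dropped_molecules=n_dropped,
                junction_molecules=len(junctions))
    return consensi


# ------------------------------------------------------------ realignment


def _align_molecule(mol: Molecule, cmap: ConsensusMap, params: AssemblyParams,
                    null: NullModel) -> Alignment:
    return align_maps(
        _mol_labels(mol, cmap.channel), cmap.labels, params.scoring,
        query_id=mol.molecule_id, target_id=cmap.map_id,
        query_extent=mol.backbone_length, null=null)


def _assign_molecules(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    cutoff_vendor: float,
    cache: dict | None = None,
) -> dict[int, tuple[ConsensusMap, Alignment]]:
    """Best-map assignment of every eligible molecule below the cutoff.

    Molecules are screened against every map with a batched score-only
    pass; the winning map's alignment is then recomputed with a full
    traceback.
    """
    if not consensi:
        return {}
    sp = params.scoring
    emp = sp.empirical_cutoff(cutoff_vendor)
    channel = consensi[0].channel
    by_map_id = {c.map_id: c for c in consensi}
    out: dict[int, tuple[ConsensusMap, Alignment]] = {}
    remaining = dict(molecules)
    if cache:
        # banded fast path: realign each molecule against a window of its
        # previously assigned map; fall back to the full screen on miss
        pad = 100_000.0
        for mid in sorted(molecules):
            hit = cache.get(mid)
            if hit is None:
                continue
            map_id, lo, hi = hit
            cmap = by_map_id.get(map_id)
            if cmap is None:
                continue
            labels = cmap.labels
            i0 = int(np.searchsorted(labels, lo - pad))
            i1 = int(np.searchsorted(labels, hi + pad))
            window = labels[i0:i1]
            mol = molecules[mid]
            q = _mol_labels(mol, channel)
            if q.size < params.min_labels or window.size < 2:
                continue
            aln = align_maps(q, np.ascontiguousarray(window), sp,
                             query_id=mid, target_id=cmap.map_id,
                             query_extent=mol.backbone_length)
            if aln.is_empty:
                continue
            p = null.pvalue(aln.score, q.size, cmap.n_labels)
            if p >= emp:
                continue
            aln.p_value = float(p)
            # lift window pair indices back to the full map
            aln.pairs = aln.pairs.copy()
            aln.pairs[:, 1] += i0
            aln.tlabels = labels
            out[mid] = (cmap, aln)
            del remaining[mid]
    molecules = remaining
    mids = sorted(molecules)
    if not mids:
        if cache is not None:
            cache.clear()
            for mid, (cmap, aln) in out.items():
                t = aln.tlabels[aln.pairs[:, 1]]
                cache[mid] = (cmap.map_id, float(min(t[0], t[-1])),
                              float(max(t[0], t[-1])))
        return out
    labs = [_mol_labels(molecules[m], channel) for m in mids]
    sizes = np.array([q.size for q in labs])
    flat = np.ascontiguousarray(
        np.concatenate(labs) if labs else np.empty(0))
    mirror = np.ascontiguousarray(np.concatenate(
        [(molecules[m].backbone_length - q)[::-1]
         for m, q in zip(mids, labs)]) if labs else np.empty(0))
    offs = np.zeros(len(labs) + 1, dtype=np.int64)
    np.cumsum(sizes, out=offs[1:])
    best_p = np.full(len(mids), np.inf)
    best_map = np.full(len(mids), -1)
    active = np.ones(len(mids), dtype=bool)
    emp_strong = emp * 1e-4
    # largest maps first: molecules decisively placed on a map skip the
    # remaining screens
    order = sorted(range(len(consensi)),
                   key=lambda i: -consensi[i].n_labels)
    for ci in order:
        cmap = consensi[ci]
        if cmap.n_labels < 2 or not np.any(active):
            continue
        idx = np.nonzero(active)[0]
        sub_offs = np.zeros(idx.size + 1, dtype=np.int64)
        np.cumsum(sizes[idx], out=sub_offs[1:])
        sub_flat = np.concatenate([flat[offs[i]:offs[i + 1]]
                                   for i in idx])
        sub_mirror = np.concatenate([mirror[offs[i]:offs[i + 1]]
                                     for i in idx])
        score, orient, npair = _kernels.molecules_vs_target(
            np.ascontiguousarray(sub_flat),
            np.ascontiguousarray(sub_mirror), sub_offs,
            np.ascontiguousarray(cmap.labels),
            sp.match_bonus, sp.miss_penalty, sp.false_penalty, sp.sd0_sq,
            sp.sizing_sd_scale, sp.max_skip, sp.resolution_limit,
            sp.max_residual_penalty, params.min_labels)
        p = null.pvalue(score, sizes[idx], cmap.n_labels)
        better = (p < emp) & (p < best_p[idx])
        best_p[idx[better]] = p[better]
        best_map[idx[better]] = ci
        # only a full-length fit may skip the remaining screens: a
        # molecule matched on one flank only might fit a junction map
        # end-to-end even better
        full = npair >= 0.8 * sizes[idx]
        active[idx[(p < emp_strong) & full]] = False
    for k in np.nonzero(best_map >= 0)[0]:
        mid = mids[int(k)]
        cmap = consensi[int(best_map[k])]
        aln = _align_molecule(molecules[mid], cmap, params, null)
        if not aln.is_empty and aln.p_value < emp:
            out[mid] = (cmap, aln)
    if cache is not None:
        cache.clear()
        for mid, (cmap, aln) in out.items():
            t = aln.tlabels[aln.pairs[:, 1]]
            cache[mid] = (cmap.map_id, float(min(t[0], t[-1])),
                          float(max(t[0], t[-1])))
    return out


def _fit_from_alignment(aln: Alignment) -> MemberFit:
    q = aln.qlabels[aln.pairs[:, 0]]
    t = aln.tlabels[aln.pairs[:, 1]]
    return MemberFit(aln.orientation, aln.offset,
                     q_lo=float(q[0]), q_hi=float(q[-1]),
                     anchors_q=q.astype(float), anchors_t=t.astype(float))


def _end_gaps(mol: Molecule, aln: Alignment, channel: int) -> tuple[float, float]:
    """Unaligned molecule span (bp) before/after the matched range."""
    q = _mol_labels(mol, channel)
    mq = q[aln.pairs[:, 0]]
    return float(mq[0]), float(mol.backbone_length - mq[-1])


def _rebuild_maps(
    consensi: list[ConsensusMap],
    assignments: dict[int, tuple[ConsensusMap, Alignment]],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
) -> list[ConsensusMap]:
    out = []
    for cmap in consensi:
        members = {
            mid: _fit_from_alignment(aln)
            for mid, (c, aln) in assignments.items() if c is cmap
        }
        if len(members) < params.min_molecules:
            continue
        prev = (float(cmap.labels[0]), float(cmap.labels[-1]))
        built = _build_consensus(members, molecules, cmap.channel, params,
                                 prev_span=prev)
        if built is None:
            continue
        labels, support, members = built
        out.append(ConsensusMap(cmap.map_id, cmap.channel, labels, support,
                                members, cmap.haplotype))
    return out


def _gap_split(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    next_id: int,
) -> tuple[list[ConsensusMap], int, int]:
    """Split maps at label-free internal gaps.

    No molecule can span a gap wider than any plausible inter-label
    spacing, so the two sides of such a gap are independently anchored
    frames glued at an arbitrary distance; their relative geometry is
    unsupported and can silently absorb a real variant.  Each side
    becomes its own map.
    """
    out: list[ConsensusMap] = []
    n_splits = 0
    for cmap in consensi:
        gaps = np.diff(cmap.labels)
        cuts = np.nonzero(gaps > params.max_internal_gap_bp)[0]
        if cuts.size == 0:
            out.append(cmap)
            continue
        n_splits += 1
        bounds = [float(cmap.labels[k]) + gaps[k] / 2.0 for k in cuts]
        edges = [-np.inf] + bounds + [np.inf]
        for b0, b1 in zip(edges, edges[1:]):
            side: dict[int, MemberFit] = {}
            for mid, fit in cmap.members.items():
                q = _mol_labels(molecules[mid], cmap.channel)
                if q.size == 0:
                    continue
                center = float(np.median(fit.project(q)))
                if b0 <= center < b1:
                    side[mid] = fit
            if len(side) < params.min_molecules:
                continue
            built = _build_consensus(side, molecules, cmap.channel, params,
                                     prev_span=(float(cmap.labels[0]),
                                                float(cmap.labels[-1])))
            if built is None:
                continue
            labels, support, members = built
            out.append(ConsensusMap(next_id, cmap.channel, labels, support,
                                    members, cmap.haplotype))
            next_id += 1
    return out, next_id, n_splits


def _coverage_split(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    next_id: int,
) -> tuple[list[ConsensusMap], int, int]:
    """Split maps at coverage cliffs (chimeric mis-join signature)."""
    out: list[ConsensusMap] = []
    n_splits = 0
    for cmap in consensi:
        sup = cmap.support
        if sup.size < 6:
            out.append(cmap)
            continue
        med = float(np.median(sup))
        low = sup < params.chimera_cov_frac * med
        high = sup >= 0.7 * med
        # first interior run of >=2 consecutive low-support labels flanked
        # by well-supported labels on both sides (a true coverage cliff,
        # not an end taper)
        split_at = None
        run_start = None
        for i in range(1, sup.size - 1):
            if low[i]:
                if run_start is None:
                    run_start = i
                if (i - run_start + 1 >= 2
                        and np.any(high[:run_start])
                        and np.any(high[i + 1:])):
                    split_at = (run_start + i) // 2
                    break
            else:
                run_start = None
        if split_at is None:
            out.append(cmap)
            continue
        n_splits += 1
        cut = float(cmap.labels[split_at])
        left: dict[int, MemberFit] = {}
        right: dict[int, MemberFit] = {}
        for mid, fit in cmap.members.items():
            q = _mol_labels(molecules[mid], cmap.channel)
            center = float(np.mean(fit.project(q)))
            (left if center < cut else right)[mid] = fit
        for side in (left, right):
            if len(side) < params.min_molecules:
                continue
            built = _build_consensus(
                side, molecules, cmap.channel, params,
                prev_span=(float(cmap.labels[0]), float(cmap.labels[-1])))
            if built is None:
                continue
            labels, support, members = built
            out.append(ConsensusMap(next_id, cmap.channel, labels, support,
                                    members, cmap.haplotype))
            next_id += 1
    return out, next_id, n_splits


def refine_b(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    next_id: int = 10_000,
    log: StageLog | None = None,
    n_iterations: int = 3,
    cache: dict | None = None,
) -> tuple[list[ConsensusMap], int]:
    """Refine label positions from best-match molecules; remove chimeras.

    Each molecule is re-assigned to its single best map; a molecule whose
    unaligned end aligns to the interior of a *different* map is a
    chimeric join and is removed outright; coverage cliffs split maps.
    """
    chimeric: set[int] = set()
    n_splits_total = 0
    for it in range(n_iterations):
        if not consensi:
            break
        pool = {mid: m for mid, m in molecules.items() if mid not in chimeric}
        # the first pass realigns against the still-coarse initial
        # consensus, so it runs at a relaxed cutoff; later passes use the
        # configured one
        cutoff = max(params.refine_b_p, 1e-6) if it == 0             else params.refine_b_p
        assignments = _assign_molecules(consensi, pool, params, null, cutoff,
                                        cache=cache)
        emp = params.scoring.empirical_cutoff(params.refine_b_p)
        for mid, (cmap, aln) in list(assignments.items()):
            mol = molecules[mid]
            gl, gr = _end_gaps(mol, aln, cmap.channel)
            if max(gl, gr) <= params.end_gap_split_bp:
                continue
            q = _mol_labels(mol, cmap.channel)
            mq = q[aln.pairs[:, 0]]
            tail = q[q < mq[0] - params.resolution_limit] if gl > gr \
                else q[q > mq[-1] + params.resolution_limit]
            if tail.size < max(4, params.min_labels // 2):
                continue
            for other in consensi:
                if other is cmap:
                    continue
                a2 = align_maps(tail, other.labels, params.scoring, null=null)
                if a2.is_empty or a2.p_value >= emp:
                    continue
                lo, hi = a2.target_interval()
                edge = params.end_gap_split_bp
                at_end = (lo < other.labels[0] + edge
                          or hi > other.labels[-1] - edge)
                if not at_end:  # interior junction on another map: chimera
                    chimeric.add(mid)
                    del assignments[mid]
                    break
        consensi = _rebuild_maps(consensi, assignments, molecules, params)
        # mis-join detection waits until the last pass: earlier passes
        # re-admit molecules the layout left out, which evens out support
        # dips that are artifacts of the initial consensus rather than
        # chimeric joins
        if it == n_iterations - 1:
            consensi, next_id, n_splits = _coverage_split(
                consensi, molecules, params, next_id)
            n_splits_total += n_splits
    if log is not None:
        log.add("refine_b", len(consensi), chimeric_removed=len(chimeric),
                splits=n_splits_total)
    return consensi, next_id, chimeric


# ------------------------------------------------------------ stage 4


def _align_map_pair(a: ConsensusMap, b: ConsensusMap,
                    params: AssemblyParams, null: NullModel) -> Alignment:
    return align_maps(a.labels, b.labels, params.scoring, query_id=a.map_id,
                      target_id=b.map_id, null=null)


def _is_dovetail(q: ConsensusMap, t: ConsensusMap, aln: Alignment,
                 slack: float) -> bool:
    """True when the alignment is a proper dovetail or containment.

    Unaligned overhangs must lie on opposite sides of the matched region
    (or be absent).  A pair of maps whose overhangs sit on the *same* side
    diverges mid-overlap — the signature of two different alleles sharing
    one flank — and must not be merged.
    """
    ql = aln.qlabels[aln.pairs[:, 0]]
    q_left = float(ql[0] - q.labels[0])
    q_right = float(q.labels[-1] - ql[-1])
    tl, th = aln.target_interval()
    t_left = float(tl - t.labels[0])
    t_right = float(t.labels[-1] - th)
    if aln.orientation < 0:
        t_left, t_right = t_right, t_left
    return (min(q_left, t_left) <= slack) and (min(q_right, t_right) <= slack)


def extend_and_merge_round(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    log: StageLog | None = None,
    next_id: list[int] | None = None,
    cache: dict | None = None,
) -> list[ConsensusMap]:
    """One extension + merge round.

    Extension: molecules aligning at the extension cutoff contribute their
    labels, including overhangs projecting past the map ends, to a
    rebuild.  Merge: map pairs aligning at the merge cutoff with
    near-complete coverage of the smaller map are combined; a merge that
    would produce non-monotone labels is rejected.
    """
    if not consensi:
        if log is not None:
            log.add("extend_merge", 0, merges=0)
        return consensi
    assignments = _assign_molecules(consensi, molecules, params, null,
                                    params.extension_p, cache=cache)
    # extend-and-split belongs to the extension step: clusters of
    # molecules with large unaligned ends are re-assembled here, and the
    # merge step immediately below re-absorbs any re-assembly that turns
    # out to be the same allele (different alleles fail the dovetail test)
    n_pooled = 0
    new_maps: list[ConsensusMap] = []
    if next_id is not None:
        new_maps, n_pooled, next_id[0], pooled_ids = _split_pools(
            consensi, molecules, params, null, next_id[0],
            assignments=assignments)
        if cache is not None:
            # pooled molecules must be re-screened against the maps their
            # pool just produced; a cached placement on the seed map would
            # starve the new allele map
            for mid in pooled_ids:
                cache.pop(mid, None)
    consensi = _rebuild_maps(consensi, assignments, molecules, params)
    consensi = consensi + new_maps

    emp = params.scoring.empirical_cutoff(params.merge_p)
    cands = []
    for i in range(len(consensi)):
        for j in range(i + 1, len(consensi)):
            a, b = consensi[i], consensi[j]
            q, t = (a, b) if a.n_labels <= b.n_labels else (b, a)
            aln = _align_map_pair(q, t, params, null)
            if aln.is_empty or aln.p_value >= emp:
                continue
            if aln.target_span < params.min_overlap_bp:
                continue
            if not _is_dovetail(q, t, aln, params.end_gap_split_bp):
                continue
            cands.append((aln.p_value, q, t, aln))
    cands.sort(key=lambda c: c[0])
    n_merges = 0
    merged: set[int] = set()
    out = {c.map_id: c for c in consensi}
    for p, q, t, aln in cands:
        if q.map_id in merged or t.map_id in merged:
            continue
        s, o = aln.orientation, aln.offset
        members = dict(out[t.map_id].members)
        for mid, fit in out[q.map_id].members.items():
            members.setdefault(
                mid, MemberFit(s * fit.orientation, s * fit.offset + o,
                               fit.q_lo, fit.q_hi))
        built = _build_consensus(members, molecules, t.channel, params)
        if built is None:
            continue
        labels, support, members2 = built
        if np.any(np.diff(labels) <= 0):
            continue  # non-monotone merge rejected
        out[t.map_id] = ConsensusMap(t.map_id, t.channel, labels, support,
                                     members2, t.haplotype)
        del out[q.map_id]
        merged.add(q.map_id)
        merged.add(t.map_id)
        n_merges += 1
    result = sorted(out.values(), key=lambda c: c.map_id)
    if log is not None:
        log.add("extend_merge", len(result), merges=n_merges,
                pooled=n_pooled)
    return result


# ------------------------------------------------------------ stage 5


def _mini_assemble(
    mol_ids: Sequence[int],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    channel: int,
    next_id: int,
) -> tuple[list[ConsensusMap], int]:
    """Depth-1 re-assembly of a molecule pool (pairwise -> layout -> refine)."""
    pool = [molecules[m] for m in sorted(mol_ids)]
    if len(pool) < params.min_molecules:
        return [], next_id
    overlap = pairwise_overlap_graph(pool, params, null, channel)
    maps = layout_and_initial_consensus(overlap, params, next_map_id=next_id,
                                        null=null)
    next_id += len(maps) + 1
    sub = {m.molecule_id: m for m in pool}
    maps, next_id, _ = refine_b(maps, sub, params, null, next_id=next_id,
                                n_iterations=2)
    return maps, next_id


def extend_and_split(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    next_id: int = 20_000,
    log: StageLog | None = None,
) -> tuple[list[ConsensusMap], int]:
    """Re-assemble clusters of molecules with large unaligned ends.

    Molecules whose best alignment leaves more than the end-gap threshold
    unaligned on one side (with enough unmatched labels there) are pooled
    per map and re-assembled at depth 1; the resulting maps capture
    alleles that differ from the seeded consensus by large events.  The
    assembly driver runs this inside every extension round.
    """
    if not consensi:
        if log is not None:
            log.add("extend_split", 0, new_maps=0)
        return consensi, next_id
    new_maps, n_pooled, next_id, _ = _split_pools(
        consensi, molecules, params, null, next_id)
    result = consensi + new_maps
    if log is not None:
        log.add("extend_split", len(result), new_maps=len(new_maps),
                pooled=n_pooled)
    return result, next_id


def _split_pools(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    next_id: int,
    assignments=None,
) -> tuple[list[ConsensusMap], int, int, list[int]]:
    if assignments is None:
        assignments = _assign_molecules(consensi, molecules, params, null,
                                        params.extension_p)
    sp = params.scoring
    # candidate (map, break position, molecule) triples
    cands: dict[int, list[tuple[float, int]]] = {}
    for mid, (cmap, aln) in assignments.items():
        gl, gr = _end_gaps(molecules[mid], aln, cmap.channel)
        if max(gl, gr) <= params.end_gap_split_bp:
            continue
        q = _mol_labels(molecules[mid], cmap.channel)
        mq = q[aln.pairs[:, 0]]
        left_side = gl > gr
        tail = q[q < mq[0]] if left_side else q[q > mq[-1]]
        if tail.size < 3:
            continue
        # break position on the map; a break at a map end is extension
        # material (the molecule simply overhangs the map), not an allele
        # junction
        ta = aln.tlabels[aln.pairs[:, 1]]
        brk = float(ta[0] if left_side else ta[-1])
        edge = max(2.0 * params.resolution_limit, 20_000.0)
        tail_dir_low = (left_side and aln.orientation > 0) or \
            (not left_side and aln.orientation < 0)
        if tail_dir_low and brk < cmap.labels[0] + edge:
            continue
        if not tail_dir_low and brk > cmap.labels[-1] - edge:
            continue
        # a tail that bridges under a wide skip allowance is a broken
        # alignment chain with no net span change, not a divergent allele
        wide = replace(sp, max_skip=12)
        a2 = align_maps(q, cmap.labels, wide,
                        query_extent=molecules[mid].backbone_length)
        if not a2.is_empty:
            g2l, g2r = _end_gaps(molecules[mid], a2, cmap.channel)
            if max(g2l, g2r) <= params.end_gap_split_bp:
                continue
        cands.setdefault(cmap.map_id, []).append((brk, mid))
    # a real junction pools molecules that all break at the same locus
    pools: list[list[int]] = []
    n_pooled = 0
    for map_id, entries in sorted(cands.items()):
        entries.sort()
        cluster: list[int] = []
        cstart = None
        for brk, mid in entries + [(np.inf, -1)]:
            if cstart is None or brk - cstart > params.end_gap_split_bp:
                if len(cluster) >= params.min_molecules:
                    pools.append(cluster)
                    n_pooled += len(cluster)
                cluster = []
                cstart = brk
            cluster.append(mid)
        # trailing sentinel handled above
    new_maps: list[ConsensusMap] = []
    pooled_ids: list[int] = []
    # largest pools first; a bounded number of re-assemblies per round
    # keeps a heavily fragmented region from spawning dozens of
    # mini-assemblies each round
    pools.sort(key=len, reverse=True)
    for pool in pools[:8]:
        pooled_ids.extend(pool)
        maps, next_id = _mini_assemble(pool, molecules, params, null,
                                       consensi[0].channel, next_id)
        new_maps.extend(maps)
    return new_maps, n_pooled, next_id, pooled_ids


# ------------------------------------------------------------ stage 6


def _haplotype_scan(
    cmap: ConsensusMap,
    assignments: dict[int, tuple[ConsensusMap, Alignment]],
    params: AssemblyParams,
) -> tuple[int, dict[int, int], float] | None:
    """Find the strongest bimodal internal-span locus of a map.

    Candidate loci are intervals between consecutive well-supported
    ("strong") labels; for every molecule matching both flanks of a locus
    the signed residual between its span and the consensus span is
    collected.  A locus whose residuals separate into two clusters
    (separation above the noise floor, below the haplotype gap threshold,
    both clusters at minimum support) marks a haplotype difference.
    Returns (locus label index, molecule -> cluster, separation).
    """
    sup = cmap.support
    if sup.size < 4:
        return None
    med = float(np.median(sup))
    strong_set = {int(i) for i in np.nonzero(sup >= 0.7 * med)[0]}
    if len(strong_set) < 2:
        return None
    res: dict[int, list[tuple[int, float]]] = {}
    for mid, (c, aln) in assignments.items():
        if c is not cmap or aln.n_pairs < 2:
            continue
        q = aln.qlabels[aln.pairs[:, 0]]
        t_idx = aln.pairs[:, 1]
        keep = [k for k in range(len(t_idx)) if int(t_idx[k]) in strong_set]
        for a, b in zip(keep, keep[1:]):
            j0, j1 = int(t_idx[a]), int(t_idx[b])
            lo, hi = min(j0, j1), max(j0, j1)
            qd = abs(float(q[b] - q[a]))
            td = float(cmap.labels[hi] - cmap.labels[lo])
            res.setdefault(lo, []).append((mid, qd - td))
    best = None
    for locus, entries in sorted(res.items()):
        if len(entries) < 2 * params.min_molecules:
            continue
        vals = np.array([r for _, r in entries])
        order = np.argsort(vals, kind="stable")
        svals = vals[order]
        n = svals.size
        cum = np.cumsum(svals)
        tot = cum[-1]
        best_split = None
        k_min = max(params.min_molecules, int(np.ceil(0.25 * n)))
        for k in range(k_min, n - k_min + 1):
            mu1 = cum[k - 1] / k
            mu2 = (tot - cum[k - 1]) / (n - k)
            sd1 = float(np.std(svals[:k])) if k > 1 else 0.0
            sd2 = float(np.std(svals[k:])) if n - k > 1 else 0.0
            within = max(float(np.hypot(sd1, sd2)), 150.0)
            sep = mu2 - mu1
            if (sep > params.haplotype_sep_sd_mult * within
                    and sep >= params.haplotype_min_sep_bp
                    and sep < params.internal_gap_haplotype_bp):
                if best_split is None or sep > best_split[0]:
                    best_split = (sep, k)
        if best_split is None:
            continue
        sep, k = best_split
        clusters = {int(entries[int(order[i])][0]): (0 if i < k else 1)
                    for i in range(n)}
        if best is None or sep > best[2]:
            best = (locus, clusters, sep)
    return best


def final_refine_haplotype(
    consensi: list[ConsensusMap],
    molecules: dict[int, Molecule],
    params: AssemblyParams,
    null: NullModel,
    next_id: int = 30_000,
    log: StageLog | None = None,
    cache: dict | None = None,
) -> tuple[list[ConsensusMap], int]:
    """Final refinement; convert bimodal maps into two haplotype maps.

    Every molecule is assigned to its single best map at the final cutoff
    and positions are re-estimated.  A map with a bimodal internal-span
    locus below the haplotype gap threshold is split: molecules spanning
    the locus go to their residual cluster, non-spanning molecules to
    both; each haplotype map is rebuilt from its own molecules.
    """
    if not consensi:
        if log is not None:
            log.add("final_refine", 0, haplotype_splits=0)
        return consensi, next_id
    assignments = _assign_molecules(consensi, molecules, params, null,
                                    params.refine_final_p, cache=cache)
    consensi = _rebuild_maps(consensi, assignments, molecules, params)
    assignments = _assign_molecules(consensi, molecules, params, null,
                                    params.refine_final_p, cache=cache)

    out: list[ConsensusMap] = []
    n_hap = 0
    for cmap in consensi:
        scan = _haplotype_scan(cmap, assignments, params)
        if scan is None:
            out.append(cmap)
            continue
        locus, clusters, sep = scan
        members_by_hap: list[set[int]] = [set(), set()]
        for mid, (c, aln) in assignments.items():
            if c is not cmap:
                continue
            h = clusters.get(mid)
            if h is None:
                members_by_hap[0].add(mid)
                members_by_hap[1].add(mid)
            else:
                members_by_hap[h].add(mid)
        halves: list[ConsensusMap] = []
        for h, ids in enumerate(members_by_hap):
            maps, next_id = _mini_assemble(sorted(ids), molecules, params,
                                           null, cmap.channel, next_id)
            for m in maps:
                m.haplotype = h + 1
            halves.extend(maps)
        if len(halves) >= 2:
            n_hap += 1
            out.extend(halves)
        else:
            out.append(cmap)
    if log is not None:
        log.add("final_refine", len(out), haplotype_splits=n_hap)
    return out, next_id


# ------------------------------------------------------------ driver


def run_assembly(
    molecules: Sequence[Molecule],
    params: AssemblyParams,
    null: NullModel,
    channel: int = 1,
    seed: int = 0,
    position_hints: dict | None = None,
) -> tuple[list[ConsensusMap], StageLog]:
    """Full OLC assembly: pairwise -> layout -> Refine-B -> five
    extend-and-merge rounds -> extend-and-split -> final refinement with
    haplotype conversion.

    Deterministic: every stage is deterministic given its inputs; ``seed``
    is accepted for interface stability.
    """
    log = StageLog()
    byid = {m.molecule_id: m for m in molecules}
    overlap = pairwise_overlap_graph(molecules, params, null, channel,
                                     position_hints=position_hints)
    log.add("pairwise", 0, n_molecules=len(byid),
            n_edges=overlap.graph.number_of_edges())
    consensi = layout_and_initial_consensus(overlap, params, log=log,
                                            null=null)
    next_id = 10_000
    cache: dict = {}
    consensi, next_id, chimeric = refine_b(consensi, byid, params, null,
                                           next_id=next_id, log=log,
                                           cache=cache)
    # chimeric joins stay removed for the rest of the pipeline
    byid = {mid: m for mid, m in byid.items() if mid not in chimeric}
    idbox = [next_id]
    for _ in range(params.n_extend_merge_rounds):
        consensi = extend_and_merge_round(consensi, byid, params, null,
                                          log=log, next_id=idbox,
                                          cache=cache)
    consensi, next_id = final_refine_haplotype(consensi, byid, params, null,
                                               next_id=idbox[0], log=log,
                                               cache=cache)
    consensi, next_id, _ = _gap_split(consensi, byid, params, next_id)
    for c in consensi:
        c.validate()
    return consensi, log
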