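"""Dynamic-programming alignment of label maps with empirical P-values.

One kernel serves the whole pipeline: molecule-to-molecule overlaps for the
layout graph, molecule-to-consensus realignment during refinement, and
consensus-to-reference alignment for SV calling.  An alignment is a
monotone pairing of query labels to target labels (both orientations
searched) scored under the sizing-error model; its significance is the
right-tail probability of the score under a null of interval-shuffled
synthetic queries, fitted with a Gumbel (extreme-value) tail per
query-label-count bucket.

The vendor-style thresholds quoted in configuration (10^-11, 10^-12,
10^-15, ...) live on a steeper internal scale than this empirical null; a
single calibration exponent (``ScoringParams.pvalue_scale``) maps a
configured cutoff onto the empirical scale as ``cutoff ** (1/scale)``.
``alignment_pvalue`` itself always returns the raw empirical probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from omsv import _kernels
from omsv.reference_maps import ReferenceMap

__all__ = [
    "ScoringParams",
    "Alignment",
    "NullModel",
    "align_maps",
    "alignment_pvalue",
    "fit_null",
    "filter_best_alignments",
]


@dataclass
class ScoringParams:
    """Scoring scheme and P-value calibration for map alignment."""

    match_bonus: float = 3.0
    miss_penalty: float = 2.3     # per skipped target label (~ -ln miss rate)
    false_penalty: float = 2.3    # per skipped query label
    max_skip: int = 5
    sizing_sd0: float = 400.0
    sizing_sd_scale: float = 20.0
    resolution_limit: float = 1500.0  # free skip of resolution-fused labels
    max_residual_z: float = 5.0   # hard gate on per-interval residuals
    jump_cost: float = 0.0        # >0 allows gated residuals at fixed cost
    pvalue_scale: float = 2.0     # vendor-scale -> empirical-scale exponent

    def __post_init__(self) -> None:
        if self.miss_penalty < 0 or self.false_penalty < 0:
            raise ValueError("penalties must be non-negative")
        if self.max_skip < 1:
            raise ValueError("max_skip must be >= 1")
        if self.pvalue_scale <= 0:
            raise ValueError("pvalue_scale must be positive")

    @property
    def sd0_sq(self) -> float:
        return self.sizing_sd0 ** 2

    @property
    def max_residual_penalty(self) -> float:
        return self.max_residual_z ** 2 / 2.0

    def empirical_cutoff(self, vendor_p: float) -> float:
        """Map a configured vendor-scale cutoff onto the empirical scale."""
        return float(vendor_p) ** (1.0 / self.pvalue_scale)


@dataclass
class Alignment:
    """A monotone pairing of query labels to target labels.

    ``pairs[k] = (query_idx, target_idx)``; query indices are strictly
    increasing, target indices strictly increasing for ``orientation=+1``
    and strictly decreasing for ``-1``.  ``residuals[k]`` is the interval
    residual between consecutive matched pairs (query span minus target
    span, bp).
    """

    query_id: object
    target_id: object
    orientation: int
    pairs: np.ndarray                       # (k, 2) int
    score: float
    qlabels: np.ndarray = field(repr=False, default=None)
    tlabels: np.ndarray = field(repr=False, default=None)
    p_value: float = 1.0

    @property
    def n_pairs(self) -> int:
        return 0 if self.pairs is None else len(self.pairs)

    @property
    def is_empty(self) -> bool:
        return self.n_pairs == 0

    @property
    def residuals(self) -> np.ndarray:
        if self.n_pairs < 2:
            return np.empty(0)
        q = self.qlabels[self.pairs[:, 0]]
        t = self.tlabels[self.pairs[:, 1]]
        return np.abs(np.diff(q)) - np.abs(np.diff(t))

    @property
    def query_span(self) -> float:
        if self.n_pairs < 2:
            return 0.0
        q = self.qlabels[self.pairs[:, 0]]
        return float(q[-1] - q[0])

    @property
    def target_span(self) -> float:
        if self.n_pairs < 2:
            return 0.0
        t = self.tlabels[self.pairs[:, 1]]
        return float(abs(t[-1] - t[0]))

    @property
    def offset(self) -> float:
        """Offset of the query-to-target transform t = orientation*q + offset."""
        q = self.qlabels[self.pairs[:, 0]]
        t = self.tlabels[self.pairs[:, 1]]
        return float(np.mean(t - self.orientation * q))

    def transform(self, pos: np.ndarray | float) -> np.ndarray | float:
        """Project query-frame positions into the target frame."""
        return self.orientation * pos + self.offset

    def target_interval(self) -> tuple[float, float]:
        t = self.tlabels[self.pairs[:, 1]]
        return float(min(t[0], t[-1])), float(max(t[0], t[-1]))


def _empty_alignment(query_id, target_id) -> Alignment:
    return Alignment(query_id, target_id, 1, np.empty((0, 2), dtype=int),
                     _kernels.NEG_INF, np.empty(0), np.empty(0), 1.0)


def _traceback(BI, BJ, bi, bj) -> np.ndarray:
    path = []
    i, j = bi, bj
    while i >= 0:
        path.append((i, j))
        i, j = BI[i, j], BJ[i, j]
    path.reverse()
    return np.array(path, dtype=int)


def mirror_labels(labels: np.ndarray, extent: float | None = None) -> np.ndarray:
    """Mirror a sorted label array (reverse-strand view)."""
    if labels.size == 0:
        return labels.copy()
    if extent is None:
        extent = labels[0] + labels[-1]
    return (extent - labels)[::-1].copy()


def align_maps(
    query: np.ndarray,
    target: np.ndarray,
    params: ScoringParams,
    query_id=None,
    target_id=None,
    orientation: str = "both",
    query_extent: float | None = None,
    null: "NullModel | None" = None,
) -> Alignment:
    """Best monotone alignment of query labels to target labels.

    Searches both orientations unless ``orientation`` is "+" or "-".
    Fewer than 2 labels on either side yields an empty alignment with a
    sentinel score.  If ``null`` is given the empirical P-value is filled.
    """
    query = np.ascontiguousarray(query, dtype=float)
    target = np.ascontiguousarray(target, dtype=float)
    if query.size < 2 or target.size < 2:
        return _empty_alignment(query_id, target_id)

    args = (params.match_bonus, params.miss_penalty, params.false_penalty,
            params.sd0_sq, params.sizing_sd_scale, params.max_skip,
            params.resolution_limit, params.max_residual_penalty)
    candidates = []
    args = args + (params.jump_cost,)
    if orientation in ("both", "+"):
        S, NP, AR, BI, BJ, s, bi, bj = _kernels.dp_tables(query, target, *args)
        pairs = _traceback(BI, BJ, bi, bj)
        candidates.append((s, len(pairs), 1, pairs))
    if orientation in ("both", "-"):
        qm = mirror_labels(query, query_extent)
        S, NP, AR, BI, BJ, s, bi, bj = _kernels.dp_tables(qm, target, *args)
        pairs_m = _traceback(BI, BJ, bi, bj)
        # mirrored query index k corresponds to original nq-1-k; re-sort by
        # original query index so target indices come out decreasing
        pairs = pairs_m.copy()
        pairs[:, 0] = query.size - 1 - pairs_m[:, 0]
        pairs = pairs[::-1]
        candidates.append((s, len(pairs), -1, pairs))
    # prefer higher score; tie -> plus orientation
    candidates.sort(key=lambda c: (-c[0], -c[1], -c[2]))
    score, _, orient, pairs = candidates[0]
    aln = Alignment(query_id, target_id, orient, pairs, float(score),
                    query, target)
    if null is not None:
        aln.p_value = null.pvalue(score, query.size, target.size)
    return aln


# ------------------------------------------------------------- null model


@dataclass
class NullModel:
    """Gumbel right-tail null of alignment scores, per query-size bucket.

    ``loc``/``scale`` are the fitted Gumbel location and scale at each
    query-label-count bucket center, estimated from interval-shuffled
    synthetic queries aligned against a target of ``target_size`` labels.
    For other target sizes the location is shifted by
    ``scale * log(T / target_size)`` (extreme-value scaling of the number
    of candidate placements).
    """

    centers: np.ndarray
    loc: np.ndarray
    scale: np.ndarray
    target_size: int

    def _params_at(self, m: np.ndarray):
        m = np.clip(np.asarray(m, dtype=float), self.centers[0],
                    self.centers[-1])
        loc = np.interp(m, self.centers, self.loc)
        scale = np.interp(m, self.centers, self.scale)
        return loc, scale

    def pvalue(self, score, query_size, target_size=None):
        """Right-tail empirical probability of ``score``; monotone in score."""
        loc, scale = self._params_at(query_size)
        if target_size is not None:
            ratio = np.maximum(np.asarray(target_size, dtype=float), 2.0)
            loc = loc + scale * np.log(ratio / self.target_size)
        z = (np.asarray(score, dtype=float) - loc) / scale
        with np.errstate(over="ignore"):
            p = np.where(z > 30.0, np.exp(-z), -np.expm1(-np.exp(-np.minimum(z, 30.0))))
        return p if p.ndim else float(p)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "centers": self.centers.tolist(),
                    "loc": self.loc.tolist(),
                    "scale": self.scale.tolist(),
                    "target_size": self.target_size,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "NullModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["centers"]), np.array(d["loc"]),
                   np.array(d["scale"]), int(d["target_size"]))


def alignment_pvalue(score: float, query_label_count: int, null: NullModel,
                     target_label_count: int | None = None) -> float:
    """Empirical right-tail P of an alignment score (see ``NullModel``)."""
    if null is None:
        raise ValueError("null model not fitted")
    return null.pvalue(score, query_label_count, target_label_count)


_BUCKET_CENTERS = (6, 10, 16, 24, 34, 48, 64)


def fit_null(
    reference: ReferenceMap | np.ndarray,
    params: ScoringParams,
    n_draws: int = 2000,
    seed: int = 0,
    channel: int = 1,
) -> NullModel:
    """Fit the alignment-score null from interval-shuffled queries.

    Synthetic queries of varying label counts are built by resampling the
    reference's inter-label intervals with replacement and aligned against
    the reference; a Gumbel is fitted to the best scores per label-count
    bucket.  Deterministic under ``seed``.
    """
    from scipy import stats

    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    if isinstance(reference, ReferenceMap):
        target = np.concatenate(
            [c.labels[channel - 1] for c in reference.contigs]
        )
    else:
        target = np.asarray(reference, dtype=float)
    target = np.ascontiguousarray(np.sort(target))
    if target.size < 10:
        raise ValueError("reference too degenerate to fit a null (<10 labels)")
    intervals = np.diff(target)
    rng = np.random.default_rng(seed)
    args = (params.match_bonus, params.miss_penalty, params.false_penalty,
            params.sd0_sq, params.sizing_sd_scale, params.max_skip,
            params.resolution_limit, params.max_residual_penalty)
    per_bucket = max(50, n_draws // len(_BUCKET_CENTERS))
    locs, scales = [], []
    for m in _BUCKET_CENTERS:
        scores = np.empty(per_bucket)
        for d in range(per_bucket):
            gaps = rng.choice(intervals, size=m - 1, replace=True)
            q = np.concatenate([[0.0], np.cumsum(gaps)])
            s, *_ = _kernels.dp_score_ends(q, target, *args)
            scores[d] = s
        loc, scale = stats.gumbel_r.fit(scores)
        locs.append(loc)
        scales.append(max(scale, 0.25))
    return NullModel(np.array(_BUCKET_CENTERS, dtype=float),
                     np.array(locs), np.array(scales), int(target.size))


def filter_best_alignments(
    alignments: Sequence[Alignment],
    cutoff: float,
    params: ScoringParams,
) -> list[Alignment]:
    """Keep alignments below the (vendor-scale) cutoff, best per locus.

    The cutoff is mapped onto the empirical scale first.  Among alignments
    with overlapping target intervals only the lowest-P one is retained
    (ties: longer aligned target span, then lower target coordinate).
    """
    emp = params.empirical_cutoff(cutoff)
    passing = [a for a in alignments if not a.is_empty and a.p_value < emp]
    passing.sort(key=lambda a: (a.p_value, -a.target_span,
                                a.target_interval()[0]))
    kept: list[Alignment] = []
    for a in passing:
        lo, hi = a.target_interval()
        clash = False
        for b in kept:
            blo, bhi = b.target_interval()
            if (a.target_id == b.target_id) and lo < bhi and blo < hi:
                clash = True
                break
        if not clash:
            kept.append(a)
    return kept
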