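"""DP alignment kernel, empirical null model, and alignment filtering."""

import itertools

import numpy as np
import pytest

from omsv.map_align import (
    Alignment,
    ScoringParams,
    align_maps,
    alignment_pvalue,
    filter_best_alignments,
    fit_null,
    mirror_labels,
)


def brute_force_best_score(q, t, params):
    """Independent oracle: enumerate every monotone matching (<=6 labels).

    Scores a matching with the same terms as the DP: match bonus, sizing
    residual over the model variance, skip penalties inside the matched
    range (with resolution forgiveness on skipped target labels), free
    end gaps, and the hard residual gate.
    """
    nq, nt = len(q), len(t)
    best = -np.inf
    idx_q = range(nq)
    for k in range(1, min(nq, nt) + 1):
        for qs in itertools.combinations(idx_q, k):
            for ts in itertools.combinations(range(nt), k):
                score = params.match_bonus
                ok = True
                for a in range(1, k):
                    dq = q[qs[a]] - q[qs[a - 1]]
                    dt = t[ts[a]] - t[ts[a - 1]]
                    var = max(params.sd0_sq
                              + params.sizing_sd_scale * dt, 1.0)
                    pen = (dq - dt) ** 2 / (2 * var)
                    if pen > params.max_residual_penalty:
                        ok = False
                        break
                    if qs[a] - qs[a - 1] - 1 > params.max_skip or \
                            ts[a] - ts[a - 1] - 1 > params.max_skip:
                        ok = False
                        break
                    n_miss = sum(
                        1 for j in range(ts[a - 1] + 1, ts[a])
                        if (t[j] - t[ts[a - 1]] > params.resolution_limit
                            and t[ts[a]] - t[j] > params.resolution_limit))
                    score += (params.match_bonus - pen
                              - params.miss_penalty * n_miss
                              - params.false_penalty
                              * (qs[a] - qs[a - 1] - 1))
                if ok:
                    best = max(best, score)
    return best


class TestAlignMaps:
    def test_self_alignment_is_identity(self, scoring):
        labels = np.array([1000., 8000., 15000., 19000., 30000., 42000.])
        aln = align_maps(labels, labels, scoring)
        assert aln.orientation == 1
        assert aln.n_pairs == labels.size
        np.testing.assert_allclose(aln.residuals, 0.0)

    def test_mirror_gives_reverse_orientation_same_score(self, scoring):
        labels = np.array([1000., 8000., 15000., 19000., 30000., 42000.])
        mirrored = mirror_labels(labels)
        fwd = align_maps(labels, labels, scoring)
        rev = align_maps(mirrored, labels, scoring)
        assert rev.orientation == -1
        assert rev.score == pytest.approx(fwd.score)
        # target indices strictly decreasing for the reverse orientation
        assert np.all(np.diff(rev.pairs[:, 1]) < 0)

    def test_too_few_labels_gives_empty_sentinel(self, scoring):
        aln = align_maps(np.array([5.0]), np.array([1., 2., 3.]), scoring)
        assert aln.is_empty
        assert aln.score < -1e17

    @pytest.mark.parametrize("seed", range(60))
    def test_dp_equals_brute_force_on_small_instances(self, seed, scoring):
        rng = np.random.default_rng(seed)
        nq = int(rng.integers(3, 7))
        nt = int(rng.integers(3, 7))
        q = np.sort(rng.uniform(0, 40_000, nq))
        t = np.sort(rng.uniform(0, 40_000, nt))
        got = align_maps(q, t, scoring, orientation="+").score
        want = brute_force_best_score(q, t, scoring)
        assert got == pytest.approx(want, abs=1e-6)

    def test_noiseless_molecule_placement_recovery(
            self, small_ref, noiseless_molecules, scoring, small_null):
        mols, _ = noiseless_molecules
        target = small_ref.contigs[0].labels[0]
        checked = 0
        for mol in mols:
            if mol.labels[0].size < 8:
                continue
            aln = align_maps(mol.labels[0], target, scoring,
                             query_extent=mol.backbone_length,
                             null=small_null)
            checked += 1
            assert aln.orientation == mol.origin.strand
            if aln.orientation > 0:
                start = aln.offset
            else:
                start = small_ref.contigs[0].length - (
                    aln.offset - 0.0) + 0.0
            # offset recovers the placement start (plus) or end (minus)
            truth = (mol.origin.start if aln.orientation > 0
                     else mol.origin.end)
            assert abs(aln.offset - truth) < 1.0
        assert checked >= 30


class TestNullModel:
    def test_refit_determinism(self, small_ref, scoring):
        a = fit_null(small_ref, scoring, n_draws=1000, seed=11)
        b = fit_null(small_ref, scoring, n_draws=1000, seed=11)
        np.testing.assert_array_equal(a.loc, b.loc)
        np.testing.assert_array_equal(a.scale, b.scale)

    def test_pvalue_monotone_in_score(self, small_null):
        scores = np.linspace(5, 120, 40)
        ps = [small_null.pvalue(s, 20, 150) for s in scores]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_median_score_gives_half(self, small_null):
        # Gumbel median = loc - scale*ln(ln 2)
        loc = small_null.loc[2]
        scale = small_null.scale[2]
        med = loc - scale * np.log(np.log(2))
        m = small_null.centers[2]
        assert small_null.pvalue(med, m) == pytest.approx(0.5, abs=0.01)

    def test_held_out_exceedance_calibration(self, small_ref, scoring):
        from scipy import stats
        from omsv import _kernels
        null = fit_null(small_ref, scoring, n_draws=1400, seed=3)
        target = small_ref.contigs[0].labels[0]
        intervals = np.diff(target)
        rng = np.random.default_rng(99)
        m = 24
        n_held = 300
        exceed = 0
        loc = np.interp(m, null.centers, null.loc)
        scale = np.interp(m, null.centers, null.scale)
        q99 = loc - scale * np.log(-np.log(0.99))
        args = (scoring.match_bonus, scoring.miss_penalty,
                scoring.false_penalty, scoring.sd0_sq,
                scoring.sizing_sd_scale, scoring.max_skip,
                scoring.resolution_limit, scoring.max_residual_penalty)
        for _ in range(n_held):
            gaps = rng.choice(intervals, size=m - 1, replace=True)
            q = np.concatenate([[0.0], np.cumsum(gaps)])
            s, *_ = _kernels.dp_score_ends(q, target, *args)
            if s > q99:
                exceed += 1
        # ~1% expected; binomial 4 sigma band around 3/300
        assert exceed <= 3 + 4 * np.sqrt(300 * 0.01 * 0.99) + 1

    def test_self_alignment_far_below_strictest_cutoff(
            self, small_ref, small_null, scoring):
        target = small_ref.contigs[0].labels[0][:20]
        aln = align_maps(target, small_ref.contigs[0].labels[0], scoring,
                         null=small_null)
        assert aln.p_value < scoring.empirical_cutoff(1e-12)

    def test_unfitted_null_raises(self):
        with pytest.raises(ValueError, match="null"):
            alignment_pvalue(10.0, 20, None)

    def test_json_round_trip(self, small_null, tmp_path):
        path = tmp_path / "null.json"
        small_null.to_json(path)
        from omsv.map_align import NullModel
        back = NullModel.from_json(path)
        np.testing.assert_array_equal(back.loc, small_null.loc)
        assert back.target_size == small_null.target_size

    def test_degenerate_reference_rejected(self, scoring):
        with pytest.raises(ValueError, match="degenerate"):
            fit_null(np.arange(5, dtype=float), scoring, n_draws=1000,
                     seed=0)


class TestFilterBestAlignments:
    def _mk(self, p, t_lo, t_hi, target="c"):
        t = np.array([t_lo, t_hi])
        a = Alignment("q", target, 1, np.array([[0, 0], [1, 1]]), 10.0,
                      np.array([0.0, t_hi - t_lo]), t)
        a.p_value = p
        return a

    def test_all_above_cutoff_filtered(self, scoring):
        alns = [self._mk(0.5, 0, 100), self._mk(0.9, 200, 300)]
        assert filter_best_alignments(alns, 1e-12, scoring) == []

    def test_single_passer_kept(self, scoring):
        keep = self._mk(1e-20, 0, 100)
        out = filter_best_alignments([keep, self._mk(0.5, 0, 100)],
                                     1e-12, scoring)
        assert out == [keep]

    def test_overlapping_keeps_lower_p(self, scoring):
        a = self._mk(1e-20, 0, 100)
        b = self._mk(1e-15, 50, 150)
        out = filter_best_alignments([b, a], 1e-12, scoring)
        assert out == [a]

    def test_disjoint_both_kept(self, scoring):
        a = self._mk(1e-20, 0, 100)
        b = self._mk(1e-15, 500, 600)
        out = filter_best_alignments([a, b], 1e-12, scoring)
        assert len(out) == 2


class TestEmpiricalCutoffScale:
    def test_cutoff_transform(self):
        sp = ScoringParams(pvalue_scale=2.0)
        assert sp.empirical_cutoff(1e-12) == pytest.approx(1e-6)
        assert sp.empirical_cutoff(1e-11) == pytest.approx(10 ** -5.5)
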