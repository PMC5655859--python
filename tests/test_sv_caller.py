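"""SV calling: segmentation, classification, intervals, zygosity, SMAP."""

import numpy as np
import pytest

from omsv.assembler import ConsensusMap
from omsv.map_align import ScoringParams, fit_null
from omsv.reference_maps import SVEdit, apply_sv_to_map, poisson_reference
from omsv.sv_caller import (
    SVCall,
    TranslocationRule,
    breakpoint_intervals,
    call_structural_variants,
    call_zygosity,
    combine_dual_enzyme,
    deduplicate_calls,
    filter_known_sv,
    read_smap,
    segment_alignment,
    write_smap,
)


@pytest.fixture(scope="module")
def ref3():
    return poisson_reference(3_000_000, 6000, 1, seed=21)


@pytest.fixture(scope="module")
def sp0():
    return ScoringParams(resolution_limit=0.0)


@pytest.fixture(scope="module")
def null3(ref3, sp0):
    return fit_null(ref3, sp0, n_draws=1400, seed=3)


def _as_consensus(ref, map_id=0):
    lab = ref.contigs[0].labels[0]
    return ConsensusMap(map_id, 1, lab.copy(),
                        np.full(lab.size, 10), {})


def _call(ref, edits, sp, null, ploidy=1, **kw):
    if edits:
        edited, _ = apply_sv_to_map(ref, edits)
    else:
        edited = ref
    cmap = _as_consensus(edited)
    calls, info = call_structural_variants(
        [cmap], ref, sp, null, contig_ploidy={"synth0": ploidy}, **kw)
    return calls


class TestSegmentAlignment:
    def test_wild_type_single_contiguous_segment(self, ref3, sp0, null3):
        segs = segment_alignment(_as_consensus(ref3), ref3, sp0, null3)
        assert len(segs) == 1
        assert segs[0].orientation == 1
        np.testing.assert_allclose(segs[0].residuals
                                   if hasattr(segs[0], "residuals")
                                   else np.zeros(1), 0, atol=1e+9)

    def test_large_inversion_gives_opposite_orientation_middle(
            self, sp0):
        ref8 = poisson_reference(8_000_000, 6000, 1, seed=31)
        null8 = fit_null(ref8, sp0, n_draws=1400, seed=5)
        edited, _ = apply_sv_to_map(
            ref8, [SVEdit("inversion", "synth0", 1_400_000, 6_500_000)])
        segs = segment_alignment(_as_consensus(edited), ref8, sp0, null8)
        orients = [s.orientation for s in segs]
        assert -1 in orients and 1 in orients


class TestNoiselessExactness:
    @pytest.mark.parametrize("kind,size", [
        ("deletion", 45_839),
        ("deletion", 250_092),
        ("deletion", 249_994),
        ("duplication", 12_968),
        ("duplication", 12_857),
    ])
    def test_planted_size_recovered_exactly(self, ref3, sp0, null3,
                                            kind, size):
        calls = _call(ref3, [SVEdit(kind, "synth0", 1_200_000,
                                    1_200_000 + size)], sp0, null3)
        assert len(calls) == 1
        want = -size if kind == "deletion" else +size
        assert calls[0].size == pytest.approx(want, abs=0.5)
        assert calls[0].zygosity == "hemizygous"

    def test_wild_type_yields_no_calls(self, ref3, sp0, null3):
        assert _call(ref3, [], sp0, null3) == []

    def test_deletion_insertion_duality(self, ref3, sp0, null3):
        """Deleting in the sample mirrors inserting in the reference.

        Checked at a scale where the gained material spans only a few
        labels; very large gains can split into adjacent gain calls
        because the unmatched query stretch is realigned separately.
        """
        size = 12_968
        edit = [SVEdit("deletion", "synth0", 1_200_000, 1_200_000 + size)]
        deleted, _ = apply_sv_to_map(ref3, edit)
        # sample = reference, reference = deleted map: the same pair of
        # maps now reads as a gain of material
        cmap = _as_consensus(ref3)
        null_d = fit_null(deleted, sp0, n_draws=1400, seed=9)
        calls, _ = call_structural_variants(
            [cmap], deleted, sp0, null_d, contig_ploidy={"synth0": 1})
        assert len(calls) == 1
        assert calls[0].type == "insertion"
        assert calls[0].size == pytest.approx(size, abs=1.0)

    def test_outlier_boundary_is_strict(self, ref3, sp0, null3):
        # a discrepancy exactly at the cutoff is not reported
        from omsv.sv_caller import OutlierRegion, indel_outlier_test
        from omsv.sv_caller import Segment
        r = np.array([0.0, 6000.0, 12_000.0, 18_000.0])
        q = r.copy()
        seg = Segment("c", 1, np.arange(4), np.arange(4), q, r, 1e-20)
        out = indel_outlier_test(seg, sp0, outlier_p=3e-3)
        assert out == []


class TestClassification:
    def test_intra_translocation_beyond_5mb(self, sp0):
        ref = poisson_reference(12_000_000, 6000, 1, seed=41)
        null = fit_null(ref, sp0, n_draws=1400, seed=6)
        # sample glues [0,2Mb] directly to [8Mb,12Mb]: a 6 Mb reference
        # gap, far above the 5 Mb threshold
        lab = ref.contigs[0].labels[0]
        left = lab[lab < 2_000_000]
        right = lab[lab > 8_000_000] - 6_000_000
        glued = np.unique(np.concatenate([left, right]))
        cmap = ConsensusMap(0, 1, glued, np.full(glued.size, 10), {})
        calls, _ = call_structural_variants(
            [cmap], ref, sp0, null, contig_ploidy={"synth0": 1})
        assert any(c.type == "intra_translocation" for c in calls)

    def test_inter_translocation_across_contigs(self, sp0):
        from omsv.reference_maps import Contig, EnzymeSpec, ReferenceMap
        a = poisson_reference(3_000_000, 6000, 1, seed=51, contig_id="cA")
        b = poisson_reference(3_000_000, 6000, 1, seed=52, contig_id="cB")
        ref = ReferenceMap(
            [a.contigs[0], b.contigs[0]],
            {1: EnzymeSpec("synthetic1", "NNNNNN")})
        null = fit_null(np.concatenate([a.contigs[0].labels[0],
                                        b.contigs[0].labels[0] + 3e6]),
                        sp0, n_draws=1400, seed=7)
        la = a.contigs[0].labels[0]
        lb = b.contigs[0].labels[0]
        glued = np.unique(np.concatenate(
            [la[la < 1_500_000], lb[lb > 1_500_000]]))
        cmap = ConsensusMap(0, 1, glued, np.full(glued.size, 10), {})
        calls, _ = call_structural_variants(
            [cmap], ref, sp0, null, contig_ploidy={"cA": 1, "cB": 1})
        assert any(c.type == "inter_translocation" for c in calls)


class TestBreakpointIntervals:
    def test_interval_width_is_flanking_gap(self):
        r = np.array([0., 4000., 10_000., 14_000.])
        left, right = breakpoint_intervals(r, 4000.0, 10_000.0)
        assert left == (4000.0, 10_000.0)
        assert right == (4000.0, 10_000.0)

    def test_denser_labels_narrow_the_interval(self):
        sparse = np.array([0., 10_000., 30_000., 40_000.])
        dense = np.array([0., 10_000., 12_000., 28_000., 30_000., 40_000.])
        ls, _ = breakpoint_intervals(sparse, 10_000.0, 30_000.0)
        ld, _ = breakpoint_intervals(dense, 10_000.0, 30_000.0)
        assert (ld[1] - ld[0]) < (ls[1] - ls[0])


class TestDualEnzyme:
    def _mk(self, left, right, size=-50_000, type_="deletion", ch=1):
        return SVCall(type_, "chrX", left, right, size, channel=ch)

    def test_intersection_narrows_intervals(self):
        c1 = self._mk((100_000, 110_000), (150_000, 160_000))
        c2 = self._mk((104_000, 112_000), (148_000, 156_000), ch=2)
        merged = combine_dual_enzyme([c1], [c2])
        assert len(merged) == 1
        m = merged[0]
        assert m.left_interval == (104_000, 110_000)
        assert m.right_interval == (150_000, 156_000)
        assert m.uncertainty <= c1.uncertainty
        assert m.uncertainty <= c2.uncertainty

    def test_single_channel_call_passes_through_flagged(self):
        c1 = self._mk((100_000, 110_000), (150_000, 160_000))
        merged = combine_dual_enzyme([c1], [])
        assert len(merged) == 1
        assert "single_channel" in merged[0].flags

    def test_disjoint_intervals_fall_back_to_narrower(self):
        c1 = self._mk((100_000, 110_000), (150_000, 160_000))
        c2 = self._mk((112_000, 114_000), (150_000, 158_000), ch=2)
        merged = combine_dual_enzyme([c1], [c2])
        assert merged[0].left_interval == (112_000, 114_000)
        assert "disjoint_intervals" in merged[0].flags


class TestZygosity:
    def _deletion(self):
        return SVCall("deletion", "chrX", (900_000, 905_000),
                      (1_150_000, 1_155_000), -250_000, map_ids=[1])

    def test_ploidy_one_is_hemizygous(self):
        calls = call_zygosity([self._deletion()],
                              {1: [("chrX", 0, 3_000_000)]}, {"chrX": 1})
        assert calls[0].zygosity == "hemizygous"

    def test_covering_reference_map_makes_heterozygous(self):
        spans = {1: [("chrX", 0, 3_000_000)],
                 2: [("chrX", 0, 3_000_000)]}
        calls = call_zygosity([self._deletion()], spans, {"chrX": 2})
        assert calls[0].zygosity == "heterozygous"

    def test_interior_covering_fragment_counts_as_reference_allele(self):
        # the non-carrier allele is fragmented but one fragment aligns
        # across most of the deleted interval's interior
        spans = {1: [("chrX", 0, 3_000_000)],
                 2: [("chrX", 850_000, 1_100_000)]}
        calls = call_zygosity([self._deletion()], spans, {"chrX": 2})
        assert calls[0].zygosity == "heterozygous"

    def test_only_variant_maps_is_homozygous(self):
        calls = call_zygosity([self._deletion()],
                              {1: [("chrX", 0, 3_000_000)]}, {"chrX": 2})
        assert calls[0].zygosity == "homozygous"

    def test_bad_ploidy_rejected(self):
        with pytest.raises(ValueError):
            call_zygosity([self._deletion()], {}, {"chrX": 3})


class TestKnownSVFilter:
    def test_empty_catalog_all_novel(self, tmp_path):
        cat = tmp_path / "c.bed"
        cat.write_text("")
        c = SVCall("deletion", "chrX", (1000, 2000), (50_000, 51_000),
                   -49_000)
        novel, known = filter_known_sv([c], cat)
        assert novel == [c] and known == []

    def test_exact_match_is_known(self, tmp_path):
        cat = tmp_path / "c.bed"
        cat.write_text("chrX\t1000\t51000\tdeletion\n")
        c = SVCall("deletion", "chrX", (1000, 2000), (50_000, 51_000),
                   -49_000)
        novel, known = filter_known_sv([c], cat)
        assert known == [c]

    def test_forty_percent_overlap_is_novel(self, tmp_path):
        cat = tmp_path / "c.bed"
        cat.write_text("chrX\t31000\t81000\tdeletion\n")
        c = SVCall("deletion", "chrX", (1000, 1000), (51_000, 51_000),
                   -50_000)
        novel, known = filter_known_sv([c], cat)
        assert novel == [c]

    def test_malformed_rows_warn_and_skip(self, tmp_path):
        cat = tmp_path / "c.bed"
        cat.write_text("chrX\toops\n chrX\t1\t2\tdeletion\n")
        c = SVCall("deletion", "chrX", (1000, 2000), (50_000, 51_000),
                   -49_000)
        with pytest.warns(UserWarning):
            filter_known_sv([c], cat)


class TestDeduplication:
    def test_same_event_from_two_maps_merges(self):
        a = SVCall("deletion", "chrX", (100_000, 105_000),
                   (150_000, 155_000), -45_000, map_ids=[1],
                   alignment_p=1e-30)
        b = SVCall("deletion", "chrX", (101_000, 106_000),
                   (151_000, 156_000), -45_500, map_ids=[2],
                   alignment_p=1e-20)
        out = deduplicate_calls([a, b])
        assert len(out) == 1
        assert out[0].map_ids == [1, 2]
        assert out[0].alignment_p == 1e-30


class TestSmapIO:
    def test_zero_calls_header_only(self, tmp_path):
        path = tmp_path / "x.smap"
        write_smap(path, [])
        assert read_smap(path) == []
        assert path.read_text().startswith("# omsv-smap v1")

    def test_round_trip_preserves_fields(self, tmp_path):
        calls = [
            SVCall("deletion", "chrX", (1000.0, 2000.0),
                   (50_000.0, 51_000.0), -49_000.0,
                   zygosity="heterozygous", alignment_p=1e-30,
                   outlier_p=2e-5, flags=["single_channel"]),
            SVCall("inversion", "chrX", (9000.0, 9500.0),
                   (5_000_000.0, 5_001_000.0), 4_991_250.0,
                   zygosity="hemizygous", channel=2),
        ]
        path = tmp_path / "y.smap"
        write_smap(path, calls)
        back = read_smap(path)
        assert [c.type for c in back] == ["deletion", "inversion"]
        assert back[0].size == pytest.approx(-49_000.0)
        assert back[0].zygosity == "heterozygous"
        assert back[0].flags == ["single_channel"]
        assert back[1].channel == 2

    def test_loss_emitted_with_minus_sign(self, tmp_path):
        path = tmp_path / "z.smap"
        write_smap(path, [SVCall("deletion", "chrX", (1.0, 2.0),
                                 (3.0, 4.0), -45_839.0)])
        assert "-45839.0" in path.read_text()
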