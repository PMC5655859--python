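"""OLC assembly: overlap graph, layout, refinement, extension, haplotypes."""

import numpy as np
import pytest

from omsv.assembler import (
    AssemblyParams,
    ConsensusMap,
    MemberFit,
    extend_and_merge_round,
    layout_and_initial_consensus,
    pairwise_overlap_graph,
    refine_b,
    run_assembly,
)
from omsv.map_align import align_maps
from omsv.molecule_sim import ErrorModel, Molecule, simulate_run
from omsv.reference_maps import poisson_reference


@pytest.fixture(scope="module")
def params():
    return AssemblyParams()


@pytest.fixture(scope="module")
def params0():
    """Zero optical resolution: consensus labels must not fuse."""
    from omsv.map_align import ScoringParams
    return AssemblyParams(resolution_limit=0.0,
                          scoring=ScoringParams(resolution_limit=0.0))


def _window_molecule(ref, mid, start, length):
    """Noiseless molecule cut from a reference window (plus strand)."""
    labels = ref.contigs[0].labels[0]
    w = labels[(labels > start) & (labels < start + length)] - start
    return Molecule(mid, float(length), [w.copy()])


class TestPairwiseOverlapGraph:
    def test_disjoint_molecules_no_edge(self, small_ref, params,
                                        small_null):
        a = _window_molecule(small_ref, 0, 0, 200_000)
        b = _window_molecule(small_ref, 1, 600_000, 200_000)
        ov = pairwise_overlap_graph([a, b], params, small_null)
        assert ov.graph.number_of_edges() == 0

    def test_exact_overlap_has_edge_with_true_offset(self, small_ref,
                                                     params, small_null):
        a = _window_molecule(small_ref, 0, 100_000, 250_000)
        b = _window_molecule(small_ref, 1, 200_000, 250_000)
        ov = pairwise_overlap_graph([a, b], params, small_null)
        assert ov.graph.has_edge(0, 1)
        d = ov.graph.edges[0, 1]
        # molecule 1 starts 100 kb to the right of molecule 0
        assert d["orient"] == 1
        assert abs(abs(d["offset"]) - 100_000) < 2_000

    def test_staggered_trio_forms_path(self, small_ref, params,
                                       small_null):
        mols = [_window_molecule(small_ref, i, 100_000 + i * 150_000,
                                 300_000) for i in range(3)]
        ov = pairwise_overlap_graph(mols, params, small_null)
        assert ov.graph.has_edge(0, 1) and ov.graph.has_edge(1, 2)
        # offsets recover the 150 kb stagger
        assert abs(abs(ov.graph.edges[0, 1]["offset"]) - 150_000) < 2_000

    def test_no_self_edges_and_symmetry(self, noisy_molecules, params,
                                        small_null):
        mols, _ = noisy_molecules
        ov = pairwise_overlap_graph(mols[:60], params, small_null)
        for u, v in ov.graph.edges:
            assert u != v


class TestLayoutAndConsensus:
    def test_identical_copies_reproduce_the_map(self, small_ref, params0,
                                                small_null):
        mols = [_window_molecule(small_ref, i, 300_000, 400_000)
                for i in range(5)]
        ov = pairwise_overlap_graph(mols, params0, small_null)
        maps = layout_and_initial_consensus(ov, params0, null=small_null)
        assert len(maps) == 1
        from omsv.molecule_sim import _fuse
        truth = _fuse(mols[0].labels[0], params0.cluster_gap)
        assert maps[0].n_labels == truth.size
        got = maps[0].labels - maps[0].labels[0] + truth[0]
        np.testing.assert_allclose(got, truth, atol=2.0)
        assert np.all(maps[0].support == 5)

    def test_staggered_trio_consensus_spans_union(self, small_ref, params0,
                                                  small_null):
        mols = [_window_molecule(small_ref, i, 100_000 + i * 150_000,
                                 300_000) for i in range(3)]
        ov = pairwise_overlap_graph(mols, params0, small_null)
        maps = layout_and_initial_consensus(ov, params0, null=small_null)
        assert len(maps) == 1
        # union window is 600 kb wide; allow for sparse outermost labels
        assert maps[0].span > 0.85 * 600_000

    def test_component_below_min_molecules_discarded(self, small_ref,
                                                     params, small_null):
        mols = [_window_molecule(small_ref, 0, 100_000, 300_000),
                _window_molecule(small_ref, 1, 150_000, 300_000)]
        ov = pairwise_overlap_graph(mols, params, small_null)
        maps = layout_and_initial_consensus(ov, params, null=small_null)
        assert maps == []


class TestRefineB:
    def test_noiseless_positions_are_a_fixed_point(self, small_ref, params0,
                                                   small_null):
        mols = [_window_molecule(small_ref, i, 250_000 + 40_000 * i,
                                 350_000) for i in range(6)]
        ov = pairwise_overlap_graph(mols, params0, small_null)
        maps = layout_and_initial_consensus(ov, params0, null=small_null)
        before = maps[0].labels.copy()
        byid = {m.molecule_id: m for m in mols}
        refined, _, _ = refine_b(maps, byid, params0, small_null)
        assert len(refined) == 1
        span_before = before[-1] - before[0]
        span_after = refined[0].labels[-1] - refined[0].labels[0]
        assert span_after == pytest.approx(span_before, abs=5.0)

    def test_planted_interlocus_chimera_removed(self, small_ref, params,
                                                small_null):
        left = [_window_molecule(small_ref, i, 50_000 + 30_000 * i,
                                 300_000) for i in range(6)]
        right = [_window_molecule(small_ref, 10 + i,
                                  600_000 + 30_000 * i, 300_000)
                 for i in range(6)]
        # chimera: interior left fragment glued to an unrelated interior
        # right fragment (interior so the junction cannot be mistaken for
        # a map-bridging overlap)
        fa = _window_molecule(small_ref, 99, 170_000, 150_000)
        fb = _window_molecule(small_ref, 99, 680_000, 150_000)
        chim = Molecule(99, 300_000.0, [np.concatenate(
            [fa.labels[0], fb.labels[0] + 150_000.0])])
        mols = left + right + [chim]
        consensi, log = run_assembly(mols, params, small_null)
        removed = [e for e in log.entries if e["stage"] == "refine_b"]
        assert removed and removed[0]["chimeric_removed"] >= 1
        for c in consensi:
            assert 99 not in c.members


class TestExtendMerge:
    def test_extension_grows_past_map_ends(self, small_ref, params,
                                           small_null):
        core = [_window_molecule(small_ref, i, 300_000, 300_000)
                for i in range(4)]
        wings = [_window_molecule(small_ref, 10 + i, 150_000, 300_000)
                 for i in range(4)]
        mols = core + wings
        ov = pairwise_overlap_graph(mols, params, small_null)
        maps = layout_and_initial_consensus(ov, params, null=small_null)
        byid = {m.molecule_id: m for m in mols}
        maps, _, _ = refine_b(maps, byid, params, small_null)
        spans0 = sorted(c.span for c in maps)
        out = extend_and_merge_round(maps, byid, params, small_null)
        # wings reach 150 kb left of the core window
        assert max(c.span for c in out) >= max(spans0)

    def test_disjoint_maps_never_merge(self, small_ref, params,
                                       small_null):
        left = [_window_molecule(small_ref, i, 20_000 * i, 250_000)
                for i in range(4)]
        right = [_window_molecule(small_ref, 10 + i,
                                  650_000 + 20_000 * i, 250_000)
                 for i in range(4)]
        mols = left + right
        ov = pairwise_overlap_graph(mols, params, small_null)
        maps = layout_and_initial_consensus(ov, params, null=small_null)
        assert len(maps) == 2
        byid = {m.molecule_id: m for m in mols}
        out = extend_and_merge_round(maps, byid, params, small_null)
        assert len(out) == 2

    def test_same_locus_maps_merge(self, small_ref, params, small_null):
        group_a = [_window_molecule(small_ref, i, 200_000 + 15_000 * i,
                                    300_000) for i in range(4)]
        group_b = [_window_molecule(small_ref, 10 + i,
                                    330_000 + 15_000 * i, 300_000)
                   for i in range(4)]
        mols = group_a + group_b
        byid = {m.molecule_id: m for m in mols}
        ov_a = pairwise_overlap_graph(group_a, params, small_null)
        ov_b = pairwise_overlap_graph(group_b, params, small_null)
        maps_a = layout_and_initial_consensus(ov_a, params, null=small_null)
        maps_b = layout_and_initial_consensus(ov_b, params,
                                              next_map_id=50,
                                              null=small_null)
        out = extend_and_merge_round(maps_a + maps_b, byid, params,
                                     small_null)
        assert len(out) == 1  # dovetail overlap of the same locus


class TestRunAssembly:
    def test_stage_log_counts_five_extend_merge_rounds(
            self, noiseless_molecules, params, small_null):
        mols, _ = noiseless_molecules
        _, log = run_assembly(mols, params, small_null)
        assert log.n_extend_merge_rounds == 5

    def test_noiseless_run_yields_single_covering_map(
            self, small_ref, noiseless_molecules, params, small_null):
        mols, _ = noiseless_molecules
        consensi, _ = run_assembly(mols, params, small_null)
        assert len(consensi) == 1
        target = small_ref.contigs[0].labels[0]
        aln = align_maps(consensi[0].labels, target, params.scoring,
                         null=small_null)
        # nearby reference labels fuse in the consensus; on the fused
        # scale nearly every consensus label matches the reference
        assert aln.n_pairs >= 0.95 * consensi[0].n_labels

    def test_determinism(self, noiseless_molecules, params, small_null):
        mols, _ = noiseless_molecules
        a, _ = run_assembly(mols, params, small_null)
        b, _ = run_assembly(mols, params, small_null)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.labels, cb.labels)

    def test_label_support_conservation(self, noiseless_molecules, params,
                                        small_null):
        mols, _ = noiseless_molecules
        consensi, _ = run_assembly(mols, params, small_null)
        c = consensi[0]
        assert np.all(c.support >= 1)
        assert np.all(c.support <= len(c.members))


class TestHaplotypeSplit:
    def test_homozygous_runs_never_split(self, params, small_null,
                                         small_ref):
        # several seeds of plain single-haplotype data: no spurious splits
        for seed in (3, 4, 5):
            mols, _ = simulate_run(small_ref, ErrorModel(), 25.0, seed=seed)
            _, log = run_assembly(mols, params, small_null)
            final = [e for e in log.entries if e["stage"] == "final_refine"]
            assert final[0]["haplotype_splits"] == 0
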