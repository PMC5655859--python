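"""Molecule simulation: error-model behavior, coverage accounting, BNX I/O."""

import numpy as np
import pytest

from omsv.molecule_sim import (
    BnxParseError,
    ErrorModel,
    Placement,
    draw_molecule_lengths,
    effective_coverage,
    observe_molecule,
    read_bnx,
    simulate_run,
    write_bnx,
)
from omsv.reference_maps import poisson_reference


class TestErrorModel:
    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            ErrorModel(label_miss_rate=1.5)
        with pytest.raises(ValueError):
            ErrorModel(sizing_sd0=-1)

    def test_noiseless_is_all_zero(self):
        em = ErrorModel.noiseless()
        assert em.label_miss_rate == 0 and em.false_label_rate == 0


class TestDrawLengths:
    def test_stopping_rule(self, small_ref):
        pls = draw_molecule_lengths(10.0, [small_ref], seed=1)
        total = sum(p.length for p in pls)
        g = small_ref.total_length
        assert 10.0 * g <= total <= 10.0 * g + 3_000_000

    def test_min_length_filter(self, small_ref):
        pls = draw_molecule_lengths(10.0, [small_ref], seed=2)
        assert min(p.length for p in pls) >= 200_000

    def test_mean_length(self):
        from scipy import stats
        ref = poisson_reference(40e6, 6000, 1, seed=4)
        pls = draw_molecule_lengths(8.0, [ref], seed=3)
        assert len(pls) >= 500
        lengths = np.array([p.length for p in pls])
        # expectation of the 200-kb-truncated log-normal
        sigma = 0.40
        mu = np.log(500_000) - sigma ** 2 / 2
        a = (np.log(200_000) - mu) / sigma
        trunc_mean = (500_000 * stats.norm.sf(a - sigma)
                      / stats.norm.sf(a))
        assert abs(lengths.mean() - trunc_mean) / trunc_mean < 0.10

    def test_genome_shorter_than_molecule_rejected(self):
        tiny = poisson_reference(100_000, 6000, 1, seed=0)
        with pytest.raises(ValueError, match="minimum molecule length"):
            draw_molecule_lengths(5.0, [tiny], seed=0)


class TestObserve:
    def test_noiseless_identity(self, small_ref):
        pl = Placement(0, "synth0", 200_000.0, 250_000.0, 1)
        mol = observe_molecule([small_ref], pl, ErrorModel.noiseless(),
                               seed=0)
        labels = small_ref.contigs[0].labels[0]
        truth = labels[(labels > 200_000) & (labels < 450_000)] - 200_000.0
        np.testing.assert_allclose(mol.labels[0], truth)

    def test_reverse_strand_mirrors(self, small_ref):
        plus = Placement(0, "synth0", 200_000.0, 250_000.0, 1)
        minus = Placement(0, "synth0", 200_000.0, 250_000.0, -1)
        em = ErrorModel.noiseless()
        a = observe_molecule([small_ref], plus, em, seed=0)
        b = observe_molecule([small_ref], minus, em, seed=0)
        np.testing.assert_allclose(
            np.sort(250_000.0 - b.labels[0]), a.labels[0], atol=1e-6)

    def test_miss_rate_binomial(self, small_ref):
        em = ErrorModel(label_miss_rate=0.2, false_label_rate=0.0,
                        sizing_sd0=0.0, sizing_sd_scale=0.0,
                        chimera_rate=0.0, resolution_limit=0.0)
        pl = Placement(0, "synth0", 0.0, 1_000_000.0, 1)
        n_true = small_ref.contigs[0].labels[0].size
        kept = [observe_molecule([small_ref], pl, em, seed=s).n_labels
                for s in range(30)]
        total, n = sum(kept), 30 * n_true
        p_hat = total / n
        assert abs(p_hat - 0.8) < 4 * np.sqrt(0.8 * 0.2 / n)

    def test_label_count_expectation(self, small_ref):
        em = ErrorModel(chimera_rate=0.0)
        pl = Placement(0, "synth0", 100_000.0, 600_000.0, 1)
        labels = small_ref.contigs[0].labels[0]
        n_true = int(((labels > 100_000) & (labels < 700_000)).sum())
        counts = [observe_molecule([small_ref], pl, em, seed=s).n_labels
                  for s in range(40)]
        expected = n_true * 0.9 + 0.8 * 600_000 / 1e5
        # fusion of close labels removes a few; allow a one-sided band
        assert expected * 0.75 < np.mean(counts) <= expected * 1.05

    def test_fragile_breaks_only_at_fragile_sites(self, small_ref):
        ref = small_ref.copy()
        ref.contigs[0].fragile_sites = np.array([500_000.0])
        em = ErrorModel(fragile_break_prob=1.0, label_miss_rate=0.0,
                        false_label_rate=0.0, sizing_sd0=0.0,
                        sizing_sd_scale=0.0, chimera_rate=0.0,
                        resolution_limit=0.0)
        pl = Placement(0, "synth0", 400_000.0, 300_000.0, 1)
        mol = observe_molecule([ref], pl, em, seed=1)
        assert abs(mol.backbone_length - 100_000.0) < 1.0
        # a window with no fragile site never breaks
        pl2 = Placement(0, "synth0", 600_000.0, 300_000.0, 1)
        mol2 = observe_molecule([ref], pl2, em, seed=1)
        assert mol2.backbone_length == 300_000.0


class TestEffectiveCoverage:
    def test_table_style_arithmetic(self):
        assert effective_coverage(320e9, 3.2e9, 0.7) == pytest.approx(70.0)

    def test_zero_map_rate(self):
        assert effective_coverage(1e9, 1e9, 0.0) == 0.0

    def test_full_map_rate_is_raw_coverage(self):
        assert effective_coverage(5e9, 1e9, 1.0) == pytest.approx(5.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            effective_coverage(1e9, 0, 0.5)
        with pytest.raises(ValueError):
            effective_coverage(1e9, 1e9, 1.5)
        with pytest.raises(ValueError):
            effective_coverage(-1, 1e9, 0.5)


class TestSimulateRun:
    def test_raw_coverage_accounting(self, noisy_molecules, small_ref):
        mols, summary = noisy_molecules
        assert summary.raw_coverage == pytest.approx(40.0, rel=0.05)
        assert summary.genome_size == small_ref.total_length

    def test_determinism_byte_identical_bnx(self, small_ref, tmp_path):
        em = ErrorModel()
        a, _ = simulate_run(small_ref, em, 5.0, seed=77)
        b, _ = simulate_run(small_ref, em, 5.0, seed=77)
        pa, pb = tmp_path / "a.bnx", tmp_path / "b.bnx"
        write_bnx(pa, a)
        write_bnx(pb, b)
        assert pa.read_bytes() == pb.read_bytes()

    def test_molecule_substreams_independent_of_batch(self, small_ref):
        em = ErrorModel()
        mols_a, _ = simulate_run(small_ref, em, 4.0, seed=5)
        mols_b, _ = simulate_run(small_ref, em, 8.0, seed=5)
        # molecule k is identical regardless of how many follow it
        for ma, mb in zip(mols_a[:10], mols_b[:10]):
            assert ma.backbone_length == mb.backbone_length
            np.testing.assert_array_equal(ma.labels[0], mb.labels[0])


class TestBnxIO:
    def test_round_trip_with_truth(self, noisy_molecules, tmp_path):
        mols, _ = noisy_molecules
        path = tmp_path / "run.bnx"
        write_bnx(path, mols[:3])
        back = read_bnx(path)
        assert len(back) == 3
        for a, b in zip(mols[:3], back):
            assert a.molecule_id == b.molecule_id
            np.testing.assert_allclose(a.labels[0], b.labels[0], atol=0.05)
            assert b.origin is not None
            assert b.origin.start == pytest.approx(a.origin.start, abs=0.1)

    def test_truth_sidecar_optional(self, noisy_molecules, tmp_path):
        mols, _ = noisy_molecules
        path = tmp_path / "run.bnx"
        write_bnx(path, mols[:2], truth_sidecar=False)
        back = read_bnx(path)
        assert back[0].origin is None

    def test_zero_label_molecule(self, tmp_path):
        from omsv.molecule_sim import Molecule
        mol = Molecule(7, 180_000.0, [np.empty(0)])
        path = tmp_path / "z.bnx"
        write_bnx(path, [mol], truth_sidecar=False)
        back = read_bnx(path)
        assert back[0].molecule_id == 7
        assert back[0].labels[0].size == 0

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.bnx"
        path.write_text("# omsv-bnx v1\n0\t1\tnot_a_number\n")
        with pytest.raises(BnxParseError, match="line 2"):
            read_bnx(path)
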