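"""Simulator: expected VAF geometry, censoring and fixture round-trips."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import tinc
from tinc.synthetic import expected_vaf


class TestExpectedVaf:
    def test_worked_example_geometry(self):
        # 90% purity, 16% contamination, diploid: clonal VAFs 0.45 / 0.08
        assert expected_vaf(1.0, 0.9, 1, 1) == pytest.approx(0.45)
        assert expected_vaf(1.0, 0.16, 1, 1) == pytest.approx(0.08)

    def test_pure_diploid_clonal(self):
        assert expected_vaf(1.0, 1.0, 1, 1) == pytest.approx(0.5)

    def test_matches_forward_model(self):
        for (major, minor) in tinc.SUPPORTED_KARYOTYPES:
            for lam in (0.2, 0.7, 1.0):
                assert expected_vaf(1.0, lam, minor, major) == pytest.approx(
                    tinc.forward_vaf(lam, minor, major, 1))


class TestSimulatePair:
    def test_clonal_vaf_means(self):
        pair = tinc.simulate_pair(tinc.SimConfig(tit_true=0.9, tin_true=0.16, seed=5))
        clonal = pair.snvs[:400]   # clonal mutations are generated first
        assert np.mean([s.t_vaf for s in clonal]) == pytest.approx(0.45, abs=0.01)
        assert np.mean([s.n_vaf for s in clonal]) == pytest.approx(0.08, abs=0.01)
        assert pair.truth["tin_true_rf"] == pytest.approx(0.16)

    def test_zero_contamination_means_zero_alt_reads(self):
        pair = tinc.simulate_pair(tinc.SimConfig(tin_true=0.0, seed=1))
        assert all(s.n_alt == 0 for s in pair.snvs)

    def test_empirical_mean_converges_at_high_depth(self):
        cfg = tinc.SimConfig(tit_true=0.8, tin_true=0.1, n_clonal=500,
                             n_subclonal=0, subclone_ccfs=(), tail_n=0,
                             t_depth_mean=10_000, n_depth_mean=10_000, seed=2)
        pair = tinc.simulate_pair(cfg)
        t_vaf = np.mean([s.t_vaf for s in pair.snvs])
        n_vaf = np.mean([s.n_vaf for s in pair.snvs])
        assert t_vaf == pytest.approx(expected_vaf(1.0, 0.8, 1, 1), abs=2e-3)
        assert n_vaf == pytest.approx(expected_vaf(1.0, 0.1, 1, 1), abs=2e-3)

    def test_karyotype_mixture_segments(self):
        weights = {"1:1": 0.5, "2:0": 0.5}
        pair = tinc.simulate_pair(tinc.SimConfig(karyotype_weights=weights, seed=3))
        labels = {f"{s.major}:{s.minor}" for s in pair.segments}
        assert labels == {"1:1", "2:0"}
        # every SNV lies inside a segment of its drawn karyotype
        k, _ = tinc.most_prevalent_karyotype(pair.segments)
        ms = tinc.filter_by_karyotype(pair.snvs, pair.segments, k)
        assert 0 < len(ms) < len(pair.snvs)

    def test_infeasible_vaf_raises(self):
        cfg = tinc.SimConfig(tit_true=1.0, multiplicity=3,
                             karyotype_weights={"1:0": 1.0}, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            tinc.simulate_pair(cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            tinc.SimConfig(tit_true=1.5)
        with pytest.raises(ValueError):
            tinc.SimConfig(karyotype_weights={"1:1": 0.6})


class TestCensoring:
    def test_identity_at_threshold_one(self, contaminated_pair):
        assert tinc.censor_subtraction(contaminated_pair.snvs, 1.0) == \
            contaminated_pair.snvs

    def test_zero_threshold_removes_all_supported(self):
        pair = tinc.simulate_pair(tinc.SimConfig(tin_true=0.5, seed=4))
        kept = tinc.censor_subtraction(pair.snvs, 0.0)
        assert all(s.n_alt == 0 for s in kept)

    def test_removal_fraction_matches_binomial_tail(self):
        """The censored fraction of clonal SNVs equals the Binomial survival
        probability at the censoring threshold (oracle check)."""
        cfg = tinc.SimConfig(tit_true=0.9, tin_true=0.5, n_clonal=4000,
                             n_subclonal=0, subclone_ccfs=(), tail_n=0, seed=6)
        pair = tinc.simulate_pair(cfg)
        censor = 0.30
        kept = tinc.censor_subtraction(pair.snvs, censor)
        removed_frac = 1 - len(kept) / len(pair.snvs)
        v_n = tinc.synthetic.expected_vaf(1.0, 0.5, 1, 1)   # = 0.25
        # oracle: P(R/d > censor) averaged over the realised depths
        depths = np.array([s.n_depth for s in pair.snvs])
        oracle = np.mean(stats.binom.sf(np.floor(censor * depths), depths, v_n))
        assert removed_frac == pytest.approx(oracle, abs=0.03)


class TestWriteFixture:
    def test_roundtrip(self, tmp_path):
        pair = tinc.simulate_pair(tinc.SimConfig(n_clonal=30, n_subclonal=5,
                                                 tail_n=5, seed=8))
        paths = tinc.write_fixture(pair, tmp_path)
        snvs = tinc.read_snv_vcf(paths["snv_vcf"])
        segs = tinc.read_cna_segments(paths["cna_tsv"])
        key = lambda s: (s.chrom, s.pos)
        assert sorted([(s.t_alt, s.t_depth, s.n_alt, s.n_depth)
                       for s in sorted(pair.snvs, key=key)]) == \
               sorted([(s.t_alt, s.t_depth, s.n_alt, s.n_depth)
                       for s in sorted(snvs, key=key)])
        assert segs == sorted(pair.segments, key=lambda s: (s.chrom, s.start))

    def test_empty_table_valid_header_only_vcf(self, tmp_path):
        pair = tinc.SimulatedPair(snvs=[], segments=[], truth={})
        paths = tinc.write_fixture(pair, tmp_path)
        assert tinc.read_snv_vcf(paths["snv_vcf"]) == []
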