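"""Clonal-cluster choice (60/20 enrichment guard) and z+ threshold selection."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tinc
from tinc.clonal_select import (
    chromosome_enrichment,
    cluster_is_enriched,
    select_clonal_cluster,
    select_clonal_mutations,
)
from tinc.mobster_fit import MobsterFit


def exhaustive_chrom_fraction(cluster_chroms, dataset_chroms, frac=0.6):
    """Oracle: smallest chromosome subset covering > frac of the cluster,
    found by exhaustive subset search."""
    counts = {}
    for c in cluster_chroms:
        counts[c] = counts.get(c, 0) + 1
    total = len(cluster_chroms)
    chroms = sorted(counts)
    for size in range(1, len(chroms) + 1):
        best = max(sum(counts[c] for c in sub) for sub in combinations(chroms, size))
        if best / total > frac:
            return size / len(set(dataset_chroms))
    return len(chroms) / len(set(dataset_chroms))


def make_fit(z: np.ndarray, means) -> MobsterFit:
    """Hand-built fit with prescribed responsibilities (no tail)."""
    k = z.shape[1]
    return MobsterFit(
        tail_present=False, tail_shape=None, tail_scale=None,
        betas=[(m, 100.0) for m in means],
        pi=z.mean(axis=0), z=z, icl=0.0, loglik=0.0, n=z.shape[0],
    )


def snvs_on(chroms):
    return [tinc.SNVRecord(c, 1000 + i, "A", "G", 100, 45, 30, 1)
            for i, c in enumerate(chroms)]


class TestChromosomeEnrichment:
    def test_maximal_concentration_rejected(self):
        dataset = [f"chr{i}" for i in range(1, 25)]
        cluster = ["chr1"] * 100
        mut_frac, chrom_frac = chromosome_enrichment(cluster, dataset)
        assert chrom_frac == pytest.approx(1 / 24)
        assert cluster_is_enriched(cluster, dataset)

    def test_uniform_cluster_accepted(self):
        dataset = [f"chr{i}" for i in range(1, 25)]
        cluster = dataset * 10                      # 10 mutations per chromosome
        mut_frac, chrom_frac = chromosome_enrichment(cluster, dataset)
        # need 15 of 24 equal chromosomes to exceed 60% of the mutations
        assert chrom_frac == pytest.approx(15 / 24)
        assert mut_frac == pytest.approx(15 / 24)
        assert not cluster_is_enriched(cluster, dataset)

    def test_seventy_percent_on_two_of_twenty(self):
        dataset = [f"chr{i}" for i in range(1, 21)]
        # 70 of 100 mutations on chr1+chr2
        cluster = ["chr1"] * 35 + ["chr2"] * 35 + \
            [f"chr{i}" for i in range(3, 20)] + ["chr3"] * 13
        assert len(cluster) == 100
        _, chrom_frac = chromosome_enrichment(cluster, dataset)
        assert chrom_frac == pytest.approx(2 / 20)
        assert cluster_is_enriched(cluster, dataset)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            chromosome_enrichment([], ["chr1"])

    @settings(max_examples=100, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 12), min_size=2, max_size=8),
    )
    def test_matches_exhaustive_oracle(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        cluster = [c for i, n in enumerate(counts) for c in [f"chr{i + 1}"] * n]
        dataset = [f"chr{i + 1}" for i in range(len(counts))]
        _, greedy = chromosome_enrichment(cluster, dataset)
        assert greedy == pytest.approx(exhaustive_chrom_fraction(cluster, dataset))


class TestSelectClonalCluster:
    def test_cna_mode_returns_c1_without_rule(self):
        z = np.eye(2)[np.repeat([0, 1], 50)]
        fit = make_fit(z, [0.45, 0.2])
        idx, rejected, applied = select_clonal_cluster(fit, snvs_on(["chr1"] * 100),
                                                       cna_mode=True)
        assert idx == 0 and rejected == [] and not applied

    def test_cna_mode_never_calls_enrichment(self, monkeypatch):
        calls = []
        monkeypatch.setattr(
            "tinc.clonal_select.chromosome_enrichment",
            lambda *a, **k: calls.append(1) or (1.0, 1.0),
        )
        z = np.eye(1)[np.zeros(60, dtype=int)]
        fit = make_fit(z, [0.45])
        select_clonal_cluster(fit, snvs_on(["chr1"] * 60), cna_mode=True)
        assert calls == []

    def test_concentrated_c1_falls_back_to_c2(self):
        # C1: 100 mutations all on chr1 (artifactual); C2: uniform over 20 chroms
        chroms = ["chr1"] * 100 + [f"chr{i % 20 + 1}" for i in range(100)]
        labels = np.repeat([0, 1], 100)
        z = np.eye(2)[labels]
        fit = make_fit(z, [0.6, 0.45])
        idx, rejected, applied = select_clonal_cluster(fit, snvs_on(chroms),
                                                       cna_mode=False)
        assert idx == 1 and applied
        assert rejected[0]["cluster"] == "C1"

    def test_all_clusters_concentrated_fails(self):
        chroms = ["chr1"] * 100 + ["chr2"] * 100
        dataset_padding = [f"chr{i}" for i in range(3, 23)]
        all_chroms = chroms + dataset_padding
        labels = np.array([0] * 100 + [1] * 100 + [0] * 20)
        z = np.eye(2)[labels]
        fit = make_fit(z, [0.6, 0.45])
        # pad dataset with SNVs on 20 more chromosomes assigned to cluster 0
        snvs = snvs_on(chroms + dataset_padding)
        idx, rejected, _ = select_clonal_cluster(fit, snvs, cna_mode=False)
        assert idx is None and len(rejected) == 2

    def test_run_selection_failure_status(self):
        # both clusters concentrated on single chromosomes; the dataset spans 22
        chroms = ["chr1"] * 100 + ["chr2"] * 100 + [f"chr{i}" for i in range(3, 23)]
        labels = np.array([0] * 100 + [1] * 100 + [0] * 20)
        fit = make_fit(np.eye(2)[labels], [0.6, 0.45])
        sel = tinc.run_clonal_selection(fit, snvs_on(chroms), cna_mode=False)
        assert sel.failed
        assert "impossible" in sel.failure_reason


class TestSelectClonalMutations:
    def _fit_with_column(self, zw):
        z = np.column_stack([zw, 1 - np.asarray(zw)])
        return make_fit(z, [0.45, 0.2])

    def test_enough_at_default_threshold(self):
        fit = self._fit_with_column([0.95] * 378 + [0.1] * 100)
        idx, used = select_clonal_mutations(fit, 0)
        assert len(idx) == 378 and used == 0.9

    def test_threshold_lowered_to_reach_minimum(self):
        # 100 mutations at z >= 0.9 and 200 more at z >= 0.8
        fit = self._fit_with_column([0.95] * 100 + [0.85] * 200 + [0.1] * 50)
        idx, used = select_clonal_mutations(fit, 0)
        assert len(idx) >= 150
        assert used <= 0.85
        assert used >= 0.8

    def test_floor_reached_returns_what_is_there(self):
        fit = self._fit_with_column([0.6] * 20 + [0.1] * 80)
        idx, used = select_clonal_mutations(fit, 0)
        assert used == pytest.approx(0.5)
        assert len(idx) == 20

    def test_empty_at_floor_fails(self):
        fit = self._fit_with_column([0.2] * 100)
        sel = tinc.run_clonal_selection(fit, snvs_on(["chr1"] * 100), cna_mode=True)
        assert sel.failed

    def test_lowering_threshold_grows_set_monotonically(self):
        rng = np.random.default_rng(4)
        fit = self._fit_with_column(rng.uniform(0, 1, 500))
        sizes = [len(select_clonal_mutations(fit, 0, z_start=t, n_min=10**9)[0])
                 for t in np.linspace(0.95, 0.5, 10)]
        assert sizes == sorted(sizes)
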