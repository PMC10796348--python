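"""Clonal-cluster identification and high-confidence clonal mutation selection.

The highest-VAF Beta cluster ("C1") should hold the clonal mutations, but when
no copy-number data are available a large mis-called CNA (e.g. an LOH region)
can masquerade as a high-VAF cluster.  An empirical 60/20 rule guards against
this in SNV-only mode: a cluster is rejected when more than 60% of its
mutations map to fewer than 20% of the chromosomes carrying data.  Clusters
are then walked in decreasing-mean order until one passes (or all fail).

From the accepted cluster, mutations are selected by responsibility threshold
z+, which starts high (default 0.9) and is lowered in 0.01 steps until a
minimum number of mutations (default 150) is reached or a floor (0.5) is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_model import SNVRecord
from .mobster_fit import MobsterFit

ENRICHMENT_MUTATION_FRACTION = 0.6
ENRICHMENT_CHROM_FRACTION = 0.2
DEFAULT_Z_START = 0.9
DEFAULT_N_MIN = 150
DEFAULT_Z_FLOOR = 0.5
_Z_STEP = 0.01


@dataclass
class ClonalSelection:
    """Outcome of clonal-mutation selection."""

    cluster_index: Optional[int]              # Beta component index (0 = C1)
    cluster_label: Optional[str]
    snv_indices: np.ndarray                   # indices into the fitted SNV list
    z_threshold_used: Optional[float]
    rejected_clusters: list[dict] = field(default_factory=list)
    failed: bool = False
    failure_reason: Optional[str] = None
    enrichment_rule_applied: bool = False     # provably False in CNA mode

    def __len__(self) -> int:
        return len(self.snv_indices)


def chromosome_enrichment(
    cluster_chroms: Sequence[str],
    dataset_chroms: Sequence[str],
    mutation_fraction: float = ENRICHMENT_MUTATION_FRACTION,
) -> tuple[float, float]:
    """Concentration of a cluster's mutations on few chromosomes.

    Chromosomes are ranked by the cluster's mutation count; the smallest
    prefix covering strictly more than ``mutation_fraction`` of the cluster is
    found greedily.  Returns ``(covered mutation fraction, chromosome
    fraction)`` where the chromosome fraction is the prefix size over the
    number of distinct chromosomes carrying at least one SNV in the whole
    dataset.  Small chromosome fractions mean suspicious concentration.
    """
    if len(cluster_chroms) == 0:
        raise ValueError("empty cluster")
    n_dataset_chroms = len(set(dataset_chroms))
    counts: dict[str, int] = {}
    for c in cluster_chroms:
        counts[c] = counts.get(c, 0) + 1
    total = len(cluster_chroms)
    covered = 0
    used = 0
    for c in sorted(counts, key=lambda c: (-counts[c], c)):
        covered += counts[c]
        used += 1
        if covered / total > mutation_fraction:
            break
    return covered / total, used / n_dataset_chroms


def cluster_is_enriched(
    cluster_chroms: Sequence[str],
    dataset_chroms: Sequence[str],
    mutation_fraction: float = ENRICHMENT_MUTATION_FRACTION,
    chrom_fraction: float = ENRICHMENT_CHROM_FRACTION,
) -> bool:
    """60/20 rejection test: >60% of the cluster on <20% of the chromosomes."""
    _, frac = chromosome_enrichment(cluster_chroms, dataset_chroms, mutation_fraction)
    return frac < chrom_fraction


def select_clonal_cluster(
    fit: MobsterFit,
    snvs: Sequence[SNVRecord],
    cna_mode: bool,
) -> tuple[Optional[int], list[dict], bool]:
    """Pick the putative clonal Beta cluster.

    In CNA-aware mode the mutation set was already restricted to the most
    prevalent karyotype, so C1 is returned directly and the enrichment rule is
    never invoked.  In SNV-only mode, Beta clusters are tested in
    decreasing-mean order with the 60/20 rule; the first acceptable cluster
    wins.  Returns ``(cluster index or None, rejected clusters, rule applied)``.
    """
    if cna_mode:
        return 0, [], False

    hard = np.argmax(fit.z, axis=1)
    dataset_chroms = [s.chrom for s in snvs]
    rejected: list[dict] = []
    for j in range(fit.k):  # Betas are ordered C1, C2, ... by decreasing mean
        cluster_chroms = [snvs[i].chrom for i in np.flatnonzero(hard == j)]
        if not cluster_chroms:
            rejected.append({"cluster": f"C{j + 1}", "reason": "empty cluster"})
            continue
        mut_frac, chrom_frac = chromosome_enrichment(cluster_chroms, dataset_chroms)
        if chrom_frac < ENRICHMENT_CHROM_FRACTION:
            rejected.append({
                "cluster": f"C{j + 1}",
                "reason": "chromosome enrichment (60/20 rule)",
                "mutation_fraction": round(mut_frac, 4),
                "chromosome_fraction": round(chrom_frac, 4),
            })
            continue
        return j, rejected, True
    return None, rejected, True


def select_clonal_mutations(
    fit: MobsterFit,
    cluster_index: int,
    z_start: float = DEFAULT_Z_START,
    n_min: int = DEFAULT_N_MIN,
    z_floor: float = DEFAULT_Z_FLOOR,
) -> tuple[np.ndarray, Optional[float]]:
    """Mutations with responsibility for the clonal cluster above a threshold.

    The threshold starts at ``z_start`` and is lowered in 0.01 steps until at
    least ``n_min`` mutations are selected or ``z_floor`` is reached; whatever
    is selected at the stopping point is returned together with the threshold
    used.  Lowering the threshold can only grow the set.
    """
    zw = fit.z[:, cluster_index]
    threshold = z_start
    while True:
        selected = np.flatnonzero(zw >= threshold)
        if selected.size >= n_min or threshold <= z_floor:
            return selected, threshold
        threshold = round(threshold - _Z_STEP, 10)
        if threshold < z_floor:
            threshold = z_floor


def run_clonal_selection(
    fit: MobsterFit,
    snvs: Sequence[SNVRecord],
    cna_mode: bool,
    z_start: float = DEFAULT_Z_START,
    n_min: int = DEFAULT_N_MIN,
    z_floor: float = DEFAULT_Z_FLOOR,
) -> ClonalSelection:
    """Full selection: cluster choice, then dynamic-threshold mutation picking."""
    cluster_index, rejected, rule_applied = select_clonal_cluster(fit, snvs, cna_mode)
    if cluster_index is None:
        return ClonalSelection(
            cluster_index=None, cluster_label=None,
            snv_indices=np.empty(0, dtype=int), z_threshold_used=None,
            rejected_clusters=rejected, failed=True,
            failure_reason="impossible to assess reliable clonal mutations: "
                           "all clusters rejected by the 60/20 rule",
            enrichment_rule_applied=rule_applied,
        )
    indices, threshold = select_clonal_mutations(fit, cluster_index, z_start, n_min, z_floor)
    if indices.size == 0:
        return ClonalSelection(
            cluster_index=cluster_index, cluster_label=f"C{cluster_index + 1}",
            snv_indices=indices, z_threshold_used=threshold,
            rejected_clusters=rejected, failed=True,
            failure_reason="no mutations above the responsibility floor",
            enrichment_rule_applied=rule_applied,
        )
    return ClonalSelection(
        cluster_index=cluster_index, cluster_label=f"C{cluster_index + 1}",
        snv_indices=indices, z_threshold_used=threshold,
        rejected_clusters=rejected, enrichment_rule_applied=rule_applied,
    )
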