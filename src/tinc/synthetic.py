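"""Paired tumour/normal read-count simulator with known TIT/TIN ground truth.

Desk-scale stand-in for in-silico BAM mixing experiments: instead of
resampling reads, the generator draws read counts directly from the
statistical model the estimator consumes.  A tumour of purity lambda_T
carries a clonal cluster (cancer-cell fraction c = 1), optional subclones
(c < 1) and a neutral power-law tail (c ~ truncated Pareto); the matched
normal is contaminated by a fraction lambda_N of tumour cells.  For a
mutation with cancer-cell fraction c on a segment with karyotype (m, M) and
multiplicity mu, the expected VAF in a sample with tumour fraction lambda is

    E[VAF] = c * mu * lambda / (lambda * (m + M) + 2 * (1 - lambda))

Depths are Poisson around the target coverages (tumour ~100x, normal ~30x);
alternate reads are Binomial(depth, VAF).  An optional censoring step drops
variants whose observed normal VAF exceeds a threshold, mimicking
caller-side germline subtraction and its TIN-underestimation bias.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_model import CNASegment, Karyotype, SNVRecord, write_cna_tsv, write_snv_vcf
from .scores import cell_to_read_fraction

_BASES = np.array(list("ACGT"))
_N_CHROMS = 22
_CHROM_LENGTH = 120_000_000


@dataclass
class SimConfig:
    """Ground-truth architecture of one simulated tumour/normal pair.

    Defaults emulate a high-purity haematological case at WGS coverage:
    ~100x tumour / ~30x normal, a clonal cluster of 400 SNVs, two subclones
    and a neutral tail, on a diploid genome.
    """

    tit_true: float = 0.9
    tin_true: float = 0.0
    n_clonal: int = 400
    subclone_ccfs: tuple[float, ...] = (0.45, 0.22)
    n_subclonal: int = 150                     # per subclone
    tail_n: int = 250
    tail_shape: float = 2.0
    tail_ccf_scale: float = 0.10               # Pareto scale of tail CCFs
    t_depth_mean: float = 100.0
    n_depth_mean: float = 30.0
    karyotype_weights: dict = field(default_factory=lambda: {"1:1": 1.0})
    multiplicity: int = 1
    censor_vaf: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tit_true <= 1.0 and 0.0 <= self.tin_true <= 1.0):
            raise ValueError("tit_true and tin_true must lie in [0, 1]")
        if self.t_depth_mean < 1 or self.n_depth_mean < 1:
            raise ValueError("mean depths must be >= 1")
        if abs(sum(self.karyotype_weights.values()) - 1.0) > 1e-9:
            raise ValueError("karyotype weights must sum to 1")


@dataclass
class SimulatedPair:
    """Simulated SNVs, CNA segments and the ground-truth record."""

    snvs: list[SNVRecord]
    segments: list[CNASegment]
    truth: dict


def expected_vaf(ccf: float, lam: float, m: int, M: int, mu: int = 1) -> float:
    """Closed-form expected VAF of a mutation with cancer-cell fraction ccf."""
    denom = lam * (m + M) + 2.0 * (1.0 - lam)
    return ccf * mu * lam / denom if denom > 0 else 0.0


def _parse_karyotype(label: str) -> tuple[int, int]:
    major, minor = label.split(":")
    return int(major), int(minor)


def _build_segments(weights: dict) -> list[CNASegment]:
    """Partition every chromosome proportionally to the karyotype weights.

    Spreading each karyotype across all 22 autosomes keeps simulated clusters
    chromosomally uniform, as in real WGS, so the 60/20 enrichment guard sees
    realistic geometry.
    """
    segments = []
    items = sorted(weights.items())
    for c in range(1, _N_CHROMS + 1):
        start = 1
        for i, (label, w) in enumerate(items):
            length = int(round(w * _CHROM_LENGTH))
            if length <= 0:
                continue
            end = _CHROM_LENGTH if i == len(items) - 1 else start + length - 1
            major, minor = _parse_karyotype(label)
            segments.append(CNASegment(f"chr{c}", start, end, major, minor))
            start = end + 1
    return segments


def _truncated_pareto(rng: np.random.Generator, shape: float, scale: float,
                      upper: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of Pareto Type-I truncated to (scale, upper]."""
    u = rng.uniform(size=size)
    cdf_upper = 1.0 - (scale / upper) ** shape
    return scale / (1.0 - u * cdf_upper) ** (1.0 / shape)


def simulate_pair(cfg: SimConfig) -> SimulatedPair:
    """Draw one tumour/normal read-count dataset from the stated architecture."""
    rng = np.random.default_rng(cfg.seed)
    segments = _build_segments(cfg.karyotype_weights)
    by_karyotype: dict[str, list[CNASegment]] = {}
    for seg in segments:
        by_karyotype.setdefault(f"{seg.major}:{seg.minor}", []).append(seg)

    ccfs = np.concatenate([
        np.ones(cfg.n_clonal),
        np.repeat(np.asarray(cfg.subclone_ccfs, float), cfg.n_subclonal),
        _truncated_pareto(rng, cfg.tail_shape, cfg.tail_ccf_scale, 1.0, cfg.tail_n)
        if cfg.tail_n else np.empty(0),
    ])
    labels = list(cfg.karyotype_weights)
    probs = np.asarray([cfg.karyotype_weights[l] for l in labels])
    assigned = rng.choice(len(labels), size=ccfs.size, p=probs)

    snvs: list[SNVRecord] = []
    for ccf, ki in zip(ccfs, assigned):
        label = labels[ki]
        major, minor = _parse_karyotype(label)
        v_t = expected_vaf(ccf, cfg.tit_true, minor, major, cfg.multiplicity)
        v_n = expected_vaf(ccf, cfg.tin_true, minor, major, cfg.multiplicity)
        if v_t > 1.0 or v_n > 1.0:
            raise ValueError(f"infeasible expected VAF > 1 for karyotype {label}")
        seg = by_karyotype[label][rng.integers(len(by_karyotype[label]))]
        pos = int(rng.integers(seg.start, seg.end + 1))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        d_t = max(1, int(rng.poisson(cfg.t_depth_mean)))
        d_n = max(1, int(rng.poisson(cfg.n_depth_mean)))
        snvs.append(SNVRecord(
            chrom=seg.chrom, pos=pos, ref=str(ref), alt=str(alt),
            t_depth=d_t, t_alt=int(rng.binomial(d_t, v_t)),
            n_depth=d_n, n_alt=int(rng.binomial(d_n, v_n)),
        ))

    if cfg.censor_vaf is not None:
        snvs = censor_subtraction(snvs, cfg.censor_vaf)

    # read-fraction truth under the most prevalent simulated karyotype --
    # the same convention the estimator reports under
    prevalent = max(cfg.karyotype_weights, key=lambda l: cfg.karyotype_weights[l])
    major, minor = _parse_karyotype(prevalent)
    truth = {
        "tit_true_cell": cfg.tit_true,
        "tin_true_cell": cfg.tin_true,
        "tit_true_rf": cell_to_read_fraction(cfg.tit_true, minor, major),
        "tin_true_rf": cell_to_read_fraction(cfg.tin_true, minor, major),
        "prevalent_karyotype": prevalent,
        "n_snvs": len(snvs),
        "n_clonal_true": cfg.n_clonal,
        "censor_vaf": cfg.censor_vaf,
        "seed": cfg.seed,
    }
    return SimulatedPair(snvs=snvs, segments=segments, truth=truth)


def censor_subtraction(snvs: Sequence[SNVRecord], censor_vaf: float) -> list[SNVRecord]:
    """Drop variants whose observed normal VAF exceeds the threshold.

    Reproduces the caller-subtraction mechanism: the somatic variants with the
    strongest normal-sample support are the ones a paired caller silently
    removes, biasing downstream contamination estimates low.
    """
    return [s for s in snvs if s.n_vaf <= censor_vaf]


def write_fixture(pair: SimulatedPair, out_dir: str | Path) -> dict[str, Path]:
    """Write the pair as a generic-AD VCF, a segment TSV and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snv_vcf": out / "snvs.vcf",
        "cna_tsv": out / "segments.tsv",
        "truth": out / "truth.json",
    }
    write_snv_vcf(pair.snvs, paths["snv_vcf"])
    write_cna_tsv(pair.segments, paths["cna_tsv"])
    paths["truth"].write_text(json.dumps(pair.truth, indent=2, sort_keys=True) + "\n")
    return paths
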