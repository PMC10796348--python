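"""End-to-end contamination test and clinical classification.

Pipeline: read inputs -> (optional) karyotype filtering -> tumour VAF
deconvolution -> clonal cluster and mutation selection -> Binomial mixture on
the normal counts -> TIT/TIN scores -> joint-fit confirmation -> classify.

Classification (read-fraction units): samples whose estimated tumour purity
is below 25% are not eligible for contamination estimation
(``CANNOT_ESTIMATE``); eligible samples with contamination above 1% RF
``FAIL`` (the matched normal should not be used for subtraction); otherwise
``PASS``.  Both thresholds are strict inequalities, so a sample at exactly
1% RF passes.  Any stage failure on valid inputs maps to ``CANNOT_ESTIMATE``
with a reason code rather than an exception.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import bmix_fit, clonal_select, io_model, mobster_fit, scores, viber_fit
from .io_model import CNASegment, Karyotype, MutationSet, SNVRecord
from .scores import TincScores

logger = logging.getLogger("tinc")

PASS = "PASS"
FAIL = "FAIL"
CANNOT_ESTIMATE = "CANNOT_ESTIMATE"

# reason codes
R_TIN_ABOVE_THRESHOLD = "TIN_ABOVE_THRESHOLD"
R_TIT_BELOW_MINIMUM = "TIT_BELOW_MINIMUM"
R_SELECTION_FAILED = "CLONAL_SELECTION_FAILED"
R_INSUFFICIENT = "INSUFFICIENT_MUTATIONS"
R_DECONVOLUTION_FAILED = "DECONVOLUTION_FAILED"
R_RATIO_ONE = "CLONAL_TOTAL_RATIO_ONE"
R_KARYOTYPE_FALLBACK = "UNSUPPORTED_KARYOTYPE_SNV_ONLY_FALLBACK"
R_FEW_IN_KARYOTYPE = "TOO_FEW_SNVS_IN_KARYOTYPE_SNV_ONLY_FALLBACK"
R_IO_ERROR = "IO_ERROR"


@dataclass
class TincConfig:
    """Every tunable of the test, with clinical-pipeline defaults."""

    snv_dialect: str = "generic-AD"
    cna_dialect: str = "tsv"
    tumour_sample: Optional[str] = None
    normal_sample: Optional[str] = None
    vaf_floor: float = io_model.DEFAULT_VAF_FLOOR
    min_tumour_depth: int = io_model.DEFAULT_MIN_TUMOUR_DEPTH
    exclude_sex_chroms_snv_only: bool = True
    min_observations: int = mobster_fit.MIN_OBSERVATIONS
    k_max: int = 3
    tail: str = "auto"
    restarts: int = 5
    z_start: float = clonal_select.DEFAULT_Z_START
    n_min: int = clonal_select.DEFAULT_N_MIN
    z_floor: float = clonal_select.DEFAULT_Z_FLOOR
    bmix_k_max: int = 3
    run_viber: bool = True
    viber_k_max: int = 10
    concordance_tolerance_rf: float = viber_fit.DEFAULT_CONCORDANCE_TOLERANCE_RF
    multiplicity: int = 1
    fail_threshold_rf: float = 0.01
    tit_min: float = 0.25
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "TincConfig":
        """Load overrides from a key-value (YAML) file."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TincResult:
    """Full outcome of one contamination test."""

    status: str
    reasons: list[str]
    scores: Optional[TincScores]
    mode: str                               # "CNA" or "SNV-only"
    n_total_snvs: int
    n_used_snvs: int
    n_clonal: int
    clonal_total_ratio: Optional[float]
    karyotype: Optional[Karyotype]
    karyotype_genome_fraction: Optional[float]
    mobster: Optional[mobster_fit.MobsterFit] = None
    bmix: Optional[bmix_fit.BmixFit] = None
    selection: Optional[clonal_select.ClonalSelection] = None
    viber: Optional[viber_fit.ViberFit] = None
    confirmation: Optional[dict] = None
    config: Optional[TincConfig] = None
    used_snvs: list[SNVRecord] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "reasons": self.reasons,
            "mode": self.mode,
            "scores": self.scores.to_dict() if self.scores else None,
            "n_total_snvs": self.n_total_snvs,
            "n_used_snvs": self.n_used_snvs,
            "n_clonal": self.n_clonal,
            "clonal_total_ratio": (round(self.clonal_total_ratio, 4)
                                   if self.clonal_total_ratio is not None else None),
            "karyotype": self.karyotype.label if self.karyotype else None,
            "karyotype_genome_fraction": (round(self.karyotype_genome_fraction, 4)
                                          if self.karyotype_genome_fraction is not None else None),
            "clonal_selection": None if self.selection is None else {
                "cluster": self.selection.cluster_label,
                "z_threshold": self.selection.z_threshold_used,
                "rejected_clusters": self.selection.rejected_clusters,
                "enrichment_rule_applied": self.selection.enrichment_rule_applied,
            },
            "mobster": self.mobster.to_dict() if self.mobster else None,
            "bmix": self.bmix.to_dict() if self.bmix else None,
            "viber": self.viber.to_dict() if self.viber else None,
            "confirmation": self.confirmation,
            "config": self.config.to_dict() if self.config else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, out_dir: str | Path) -> None:
        """Write report.json and clonal_mutations.tsv into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        if self.selection is not None and self.used_snvs:
            selected = set(self.selection.snv_indices.tolist())
            zcol = (self.mobster.z[:, self.selection.cluster_index]
                    if self.mobster is not None and self.selection.cluster_index is not None
                    else np.zeros(len(self.used_snvs)))
            rows = []
            for i, snv in enumerate(self.used_snvs):
                rows.append(f"{snv.chrom}\t{snv.pos}\t{snv.ref}\t{snv.alt}\t"
                            f"{zcol[i]:.6f}\t{int(i in selected)}")
            header = "chrom\tpos\tref\talt\tclonal_responsibility\tselected"
            (out / "clonal_mutations.tsv").write_text("\n".join([header] + rows) + "\n")


def classify(
    result_scores: Optional[TincScores],
    selection_failed: bool,
    clonal_total_ratio: Optional[float],
    config: TincConfig,
) -> tuple[str, list[str]]:
    """Map scores and stage outcomes to PASS / FAIL / CANNOT_ESTIMATE."""
    reasons: list[str] = []
    if selection_failed or result_scores is None:
        return CANNOT_ESTIMATE, [R_SELECTION_FAILED]
    if clonal_total_ratio is not None and clonal_total_ratio >= 1.0:
        reasons.append(R_RATIO_ONE)  # warning only: estimates less reliable
    if result_scores.tit_rf < config.tit_min:
        return CANNOT_ESTIMATE, reasons + [R_TIT_BELOW_MINIMUM]
    if result_scores.tin_rf > config.fail_threshold_rf:
        return FAIL, reasons + [R_TIN_ABOVE_THRESHOLD]
    return PASS, reasons


def clonal_total_ratio(n_clonal: int, n_total: int) -> float:
    """|clonal set| over the total mutation burden entering deconvolution."""
    if n_total <= 0:
        raise ValueError("no mutations")
    return n_clonal / n_total


def _failure(status_reasons, mode, n_total, n_used, config, **kw) -> TincResult:
    return TincResult(
        status=CANNOT_ESTIMATE, reasons=status_reasons, scores=None, mode=mode,
        n_total_snvs=n_total, n_used_snvs=n_used, n_clonal=0,
        clonal_total_ratio=None, karyotype=kw.pop("karyotype", None),
        karyotype_genome_fraction=kw.pop("karyotype_genome_fraction", None),
        config=config, **kw,
    )


def run_tinc_on_records(
    snvs: Sequence[SNVRecord],
    segments: Optional[Sequence[CNASegment]] = None,
    config: Optional[TincConfig] = None,
) -> TincResult:
    """Run the full test on in-memory records (the file-free API)."""
    config = config or TincConfig()
    snvs = list(snvs)
    n_total = len(snvs)
    extra_reasons: list[str] = []

    karyotype: Optional[Karyotype] = None
    genome_fraction: Optional[float] = None
    working: Sequence[SNVRecord] = snvs
    cna_mode = False
    if segments:
        karyotype, genome_fraction = io_model.most_prevalent_karyotype(segments)
        if karyotype is None:
            extra_reasons.append(R_KARYOTYPE_FALLBACK)
        else:
            subset = io_model.filter_by_karyotype(snvs, segments, karyotype,
                                                  config.multiplicity)
            if len(subset) < config.min_observations:
                extra_reasons.append(R_FEW_IN_KARYOTYPE)
                karyotype = None
            else:
                working = subset.records
                cna_mode = True
    mode = "CNA" if cna_mode else "SNV-only"

    used = io_model.apply_quality_floor(
        working,
        vaf_floor=config.vaf_floor,
        min_tumour_depth=config.min_tumour_depth,
        exclude_sex_chroms=(not cna_mode) and config.exclude_sex_chroms_snv_only,
    )
    if len(used) < config.min_observations:
        return _failure(extra_reasons + [R_INSUFFICIENT], mode, n_total, len(used),
                        config, karyotype=karyotype,
                        karyotype_genome_fraction=genome_fraction)

    try:
        mfit = mobster_fit.fit_mobster(
            [s.t_vaf for s in used],
            k_max=config.k_max, tail=config.tail,
            restarts=config.restarts, seed=config.seed,
            min_observations=config.min_observations,
        )
    except mobster_fit.DeconvolutionError as exc:
        logger.warning("deconvolution failed: %s", exc)
        return _failure(extra_reasons + [R_DECONVOLUTION_FAILED], mode, n_total,
                        len(used), config, karyotype=karyotype,
                        karyotype_genome_fraction=genome_fraction, used_snvs=used)

    selection = clonal_select.run_clonal_selection(
        mfit, used, cna_mode=cna_mode,
        z_start=config.z_start, n_min=config.n_min, z_floor=config.z_floor,
    )
    if selection.failed:
        res = _failure(extra_reasons + [R_SELECTION_FAILED], mode, n_total,
                       len(used), config, karyotype=karyotype,
                       karyotype_genome_fraction=genome_fraction, used_snvs=used)
        res.mobster, res.selection = mfit, selection
        return res

    clonal = [used[i] for i in selection.snv_indices]
    bfit = bmix_fit.fit_bmix(
        [(s.n_alt, s.n_depth) for s in clonal],
        k_max=config.bmix_k_max, seed=config.seed,
    )
    v_t = scores.tumour_clonal_vaf(used, selection.snv_indices)
    v_n = bmix_fit.weighted_normal_vaf(bfit)
    tinc_scores = scores.compute_scores(
        v_t, v_n, karyotype=karyotype if cna_mode else None,
        multiplicity=config.multiplicity,
    )
    ratio = clonal_total_ratio(len(clonal), len(used))

    vfit = None
    confirmation = None
    if config.run_viber:
        try:
            vfit = viber_fit.fit_viber(
                [(s.t_alt, s.t_depth, s.n_alt, s.n_depth) for s in used],
                k_max=config.viber_k_max, seed=config.seed,
            )
            confirmation = viber_fit.confirm_scores(
                vfit, selection.snv_indices, tinc_scores,
                karyotype=karyotype if cna_mode else None,
                multiplicity=config.multiplicity,
                tolerance_rf=config.concordance_tolerance_rf,
            )
        except Exception as exc:  # advisory stage: never fails the test
            logger.warning("joint confirmation failed: %s", exc)
            confirmation = {"status": f"error: {exc}"}

    status, reasons = classify(tinc_scores, selection.failed, ratio, config)
    return TincResult(
        status=status, reasons=extra_reasons + reasons, scores=tinc_scores,
        mode=mode, n_total_snvs=n_total, n_used_snvs=len(used),
        n_clonal=len(clonal), clonal_total_ratio=ratio,
        karyotype=karyotype if cna_mode else None,
        karyotype_genome_fraction=genome_fraction if cna_mode else None,
        mobster=mfit, bmix=bfit, selection=selection, viber=vfit,
        confirmation=confirmation, config=config, used_snvs=used,
    )


def run_tinc(
    snv_vcf: str | Path,
    cna_input: Optional[str | Path] = None,
    config: Optional[TincConfig] = None,
) -> TincResult:
    """Run the full test from a somatic SNV VCF and optional CNA input."""
    config = config or TincConfig()
    try:
        snvs = io_model.read_snv_vcf(
            snv_vcf, dialect=config.snv_dialect,
            tumour_sample=config.tumour_sample, normal_sample=config.normal_sample,
        )
        segments = (io_model.read_cna_segments(cna_input, dialect=config.cna_dialect)
                    if cna_input is not None else None)
    except (OSError, ValueError) as exc:
        logger.error("input error: %s", exc)
        return _failure([R_IO_ERROR, str(exc)], "SNV-only", 0, 0, config)
    return run_tinc_on_records(snvs, segments, config)
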