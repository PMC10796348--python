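"""Domain types and I/O for somatic SNV read counts and allele-specific CNA segments.

The estimator consumes per-site read counts from a paired tumour/normal
whole-genome experiment: for every somatic SNV the total depth and
alternate-allele read count in each sample, and (optionally) allele-specific
copy-number segments giving the major/minor allele copies ``M:m`` of each
genomic interval.  All coordinates are 1-based inclusive, matching VCF.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger("tinc")

#: Copy-number states supported for CNA-aware estimation: LOH, heterozygous
#: diploid, copy-neutral LOH, triploid and tetraploid (genome-doubled).
SUPPORTED_KARYOTYPES: tuple[tuple[int, int], ...] = (
    (1, 0),
    (1, 1),
    (2, 0),
    (2, 1),
    (2, 2),
)

#: Default tumour-VAF floor and depth floor applied before deconvolution.
DEFAULT_VAF_FLOOR = 0.05
DEFAULT_MIN_TUMOUR_DEPTH = 10

_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide variant with paired read counts.

    ``t_depth``/``t_alt`` are the tumour total and alternate-read counts,
    ``n_depth``/``n_alt`` the matched-normal ones.  VAFs are derived, with
    0/0 treated as VAF 0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNV: {self.ref}>{self.alt}")
        for r, d, tag in ((self.t_alt, self.t_depth, "tumour"), (self.n_alt, self.n_depth, "normal")):
            if d < 0 or r < 0 or r > d:
                raise ValueError(f"invalid {tag} counts r={r}, d={d} at {self.chrom}:{self.pos}")

    @property
    def t_vaf(self) -> float:
        return self.t_alt / self.t_depth if self.t_depth > 0 else 0.0

    @property
    def n_vaf(self) -> float:
        return self.n_alt / self.n_depth if self.n_depth > 0 else 0.0


@dataclass(frozen=True)
class CNASegment:
    """Genomic interval (1-based inclusive) with major:minor allele copies."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end < start at {self.chrom}:{self.start}-{self.end}")
        if self.minor < 0 or self.major < self.minor or self.major < 1:
            raise ValueError(f"invalid karyotype {self.major}:{self.minor} at {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def karyotype(self) -> "Karyotype":
        return Karyotype(self.major, self.minor)


@dataclass(frozen=True)
class Karyotype:
    """Major:minor allele copy state, e.g. 1:1 (diploid) or 2:0 (CN-LOH)."""

    major: int
    minor: int

    @property
    def label(self) -> str:
        return f"{self.major}:{self.minor}"

    @property
    def ploidy(self) -> int:
        return self.major + self.minor

    @property
    def supported(self) -> bool:
        return (self.major, self.minor) in SUPPORTED_KARYOTYPES


@dataclass
class MutationSet:
    """The SNVs entering deconvolution, with the elicited karyotype.

    ``karyotype`` is None in SNV-only mode (diploid assumed); ``multiplicity``
    is the assumed number of genome copies carrying each mutation (mu >= 1).
    """

    records: list[SNVRecord]
    karyotype: Optional[Karyotype] = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("mutation multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# VCF reading: somatic SNVs
# ---------------------------------------------------------------------------

_TUMOUR_RE = re.compile(r"tumou?r", re.IGNORECASE)
_NORMAL_RE = re.compile(r"normal", re.IGNORECASE)


def _identify_samples(
    samples: Sequence[str],
    tumour_sample: Optional[str] = None,
    normal_sample: Optional[str] = None,
) -> tuple[int, int]:
    """Return (tumour index, normal index) among the VCF sample columns.

    Resolution order: explicit overrides, then name regexes (``tumou?r`` /
    ``normal``), then the Strelka convention of NORMAL first, TUMOR second.
    """
    if len(samples) != 2:
        raise ValueError(f"expected exactly 2 sample columns, got {list(samples)}")
    if tumour_sample is not None or normal_sample is not None:
        t_idx = samples.index(tumour_sample) if tumour_sample is not None else None
        n_idx = samples.index(normal_sample) if normal_sample is not None else None
        if t_idx is None:
            t_idx = 1 - n_idx  # type: ignore[operator]
        if n_idx is None:
            n_idx = 1 - t_idx
        if t_idx == n_idx:
            raise ValueError("tumour and normal overrides resolve to the same column")
        return t_idx, n_idx
    t_hits = [i for i, s in enumerate(samples) if _TUMOUR_RE.search(s)]
    n_hits = [i for i, s in enumerate(samples) if _NORMAL_RE.search(s)]
    if len(t_hits) == 1 and len(n_hits) == 1 and t_hits[0] != n_hits[0]:
        return t_hits[0], n_hits[0]
    if len(t_hits) == 1:
        return t_hits[0], 1 - t_hits[0]
    if len(n_hits) == 1:
        return 1 - n_hits[0], n_hits[0]
    logger.warning(
        "cannot identify tumour/normal from sample names %s; assuming Strelka order (NORMAL, TUMOR)",
        list(samples),
    )
    return 1, 0


_STRELKA_TIER_FIELDS = {"A": "AU", "C": "CU", "G": "GU", "T": "TU"}


def _strelka_counts(variant, sample_idx: int) -> tuple[int, int]:
    """Tier-1 (alt, depth) for one sample from Strelka per-base count fields."""
    alt = variant.ALT[0]
    depth = 0
    alt_count = 0
    for base, tag in _STRELKA_TIER_FIELDS.items():
        tier1 = int(variant.format(tag)[sample_idx][0])
        depth += tier1
        if base == alt:
            alt_count = tier1
    return alt_count, depth


def _ad_counts(variant, sample_idx: int) -> tuple[int, int]:
    """(alt, depth) from an allele-depth (AD) FORMAT field."""
    ad = variant.format("AD")[sample_idx]
    ref_count, alt_count = int(ad[0]), int(ad[1])
    return alt_count, ref_count + alt_count


def read_snv_vcf(
    path: str | Path,
    dialect: str = "generic-AD",
    tumour_sample: Optional[str] = None,
    normal_sample: Optional[str] = None,
    pass_only: bool = True,
) -> list[SNVRecord]:
    """Read somatic SNVs with paired read counts from a two-sample VCF.

    ``dialect`` is ``"strelka"`` (tier-1 AU/CU/GU/TU counts) or
    ``"generic-AD"`` (per-sample AD allele depths).  Indels, multi-allelic
    records and (by default) non-PASS records are skipped; records whose count
    fields cannot be parsed are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    if dialect not in ("strelka", "generic-AD"):
        raise ValueError(f"unknown SNV dialect {dialect!r}")
    vcf = VCF(str(path))
    t_idx, n_idx = _identify_samples(vcf.samples, tumour_sample, normal_sample)
    extract = _strelka_counts if dialect == "strelka" else _ad_counts

    records: list[SNVRecord] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            continue
        if pass_only and variant.FILTER is not None:  # cyvcf2: None means PASS
            continue
        try:
            t_alt, t_depth = extract(variant, t_idx)
            n_alt, n_depth = extract(variant, n_idx)
            records.append(
                SNVRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=variant.ALT[0],
                    t_depth=t_depth,
                    t_alt=t_alt,
                    n_depth=n_depth,
                    n_alt=n_alt,
                )
            )
        except (TypeError, ValueError, IndexError) as exc:
            n_skipped += 1
            logger.warning("skipping %s:%s (%s)", variant.CHROM, variant.POS, exc)
    if n_skipped:
        logger.warning("skipped %d records with unparsable counts", n_skipped)
    return records


# ---------------------------------------------------------------------------
# CNA segments
# ---------------------------------------------------------------------------

def _check_no_overlap(segments: list[CNASegment]) -> None:
    by_chrom: dict[str, list[CNASegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )


def read_cna_segments(path: str | Path, dialect: str = "tsv") -> list[CNASegment]:
    """Read allele-specific CNA segments from a Canvas-style VCF or a TSV.

    TSV dialect: columns (chrom, start, end, major, minor), tab-separated,
    header optional.  Canvas dialect: one record per segment with INFO END and
    per-sample CN (total copies) and MCC (major copy count).  Segments must be
    non-overlapping per chromosome; output is sorted by (chrom, start).
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "major", "minor"], dtype=str)
        if len(df) and df.iloc[0]["start"].lower() == "start":  # tolerate a header row
            df = df.iloc[1:]
        segments = [
            CNASegment(str(row.chrom), int(row.start), int(row.end), int(row.major), int(row.minor))
            for row in df.itertuples()
        ]
    elif dialect == "canvas-vcf":
        from cyvcf2 import VCF

        segments = []
        for variant in VCF(str(path)):
            end = variant.INFO.get("END")
            if end is None:
                raise ValueError(f"Canvas record at {variant.CHROM}:{variant.POS} lacks INFO/END")
            cn = int(variant.format("CN")[0][0])
            mcc = int(variant.format("MCC")[0][0])
            segments.append(
                CNASegment(variant.CHROM, variant.POS, int(end), major=mcc, minor=cn - mcc)
            )
    else:
        raise ValueError(f"unknown CNA dialect {dialect!r}")
    _check_no_overlap(segments)
    return sorted(segments, key=lambda s: (s.chrom, s.start))


def most_prevalent_karyotype(
    segments: Sequence[CNASegment],
) -> tuple[Optional[Karyotype], float]:
    """The karyotype spanning the largest summed segment length.

    Returns ``(karyotype, genome fraction covered)`` where the fraction is the
    winner's length over the total segmented length.  Ties prefer 1:1, then
    lower total copy number.  Returns ``(None, fraction)`` when the winner is
    not one of the five supported states, signalling SNV-only fallback.
    """
    if not segments:
        raise ValueError("empty segment list")
    lengths: dict[tuple[int, int], int] = {}
    for seg in segments:
        key = (seg.major, seg.minor)
        lengths[key] = lengths.get(key, 0) + seg.length
    total = sum(lengths.values())

    def rank(item: tuple[tuple[int, int], int]):
        (major, minor), length = item
        return (-length, (major, minor) != (1, 1), major + minor, major)

    (major, minor), best_len = min(lengths.items(), key=rank)
    fraction = best_len / total
    karyotype = Karyotype(major, minor)
    if not karyotype.supported:
        return None, fraction
    return karyotype, fraction


def filter_by_karyotype(
    snvs: Sequence[SNVRecord],
    segments: Sequence[CNASegment],
    karyotype: Karyotype,
    multiplicity: int = 1,
) -> MutationSet:
    """Restrict SNVs to those inside segments of the given karyotype.

    Membership uses 1-based inclusive coordinates, so an SNV at ``pos == end``
    is retained.  An empty result signals "insufficient mutations" upstream.
    """
    wanted = sorted(
        (s for s in segments if (s.major, s.minor) == (karyotype.major, karyotype.minor)),
        key=lambda s: (s.chrom, s.start),
    )
    by_chrom: dict[str, list[CNASegment]] = {}
    for seg in wanted:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    kept = [
        snv
        for snv in snvs
        if any(seg.start <= snv.pos <= seg.end for seg in by_chrom.get(snv.chrom, ()))
    ]
    return MutationSet(records=kept, karyotype=karyotype, multiplicity=multiplicity)


# ---------------------------------------------------------------------------
# Pre-deconvolution filters
# ---------------------------------------------------------------------------

def apply_quality_floor(
    snvs: Sequence[SNVRecord],
    vaf_floor: float = DEFAULT_VAF_FLOOR,
    min_tumour_depth: int = DEFAULT_MIN_TUMOUR_DEPTH,
    exclude_sex_chroms: bool = False,
) -> list[SNVRecord]:
    """Drop low-VAF / low-depth tumour calls (and optionally chrX/chrY).

    Low-VAF noise destabilises the power-law tail fit; sex chromosomes violate
    the diploid assumption elicited when no CNA data are given.
    """
    out = []
    for snv in snvs:
        if snv.t_depth < min_tumour_depth or snv.t_vaf < vaf_floor:
            continue
        if exclude_sex_chroms and snv.chrom in _SEX_CHROMS:
            continue
        out.append(snv)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_mutation_tsv(snvs: Iterable[SNVRecord], path: str | Path,
                       karyotype: Optional[Karyotype] = None) -> None:
    """Export SNVs (and the karyotype they were filtered to) as a TSV."""
    rows = [
        {
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "t_depth": s.t_depth, "t_alt": s.t_alt,
            "n_depth": s.n_depth, "n_alt": s.n_alt,
            "karyotype": karyotype.label if karyotype else "NA",
        }
        for s in snvs
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "t_depth", "t_alt",
                                "n_depth", "n_alt", "karyotype"]).to_csv(
        path, sep="\t", index=False)


def write_snv_vcf(snvs: Sequence[SNVRecord], path: str | Path,
                  tumour_sample: str = "TUMOR", normal_sample: str = "NORMAL") -> None:
    """Write SNVs as an uncompressed generic-AD two-sample VCF (normal first)."""
    chroms = sorted({s.chrom for s in snvs}, key=str)
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{normal_sample}\t{tumour_sample}")
    for s in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
        normal = f"0/0:{s.n_depth - s.n_alt},{s.n_alt}:{s.n_depth}"
        tumour = f"0/1:{s.t_depth - s.t_alt},{s.t_alt}:{s.t_depth}"
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT:AD:DP\t{normal}\t{tumour}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cna_tsv(segments: Sequence[CNASegment], path: str | Path) -> None:
    """Write segments as the 5-column TSV dialect."""
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.major, s.minor) for s in segments],
        columns=["chrom", "start", "end", "major", "minor"],
    ).to_csv(path, sep="\t", index=False, header=False)
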