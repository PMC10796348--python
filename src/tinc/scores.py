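"""TIT/TIN score computation with karyotype normalisation.

A clonal mutation present in mu copies on a segment with minor/major allele
copies (m, M) and tumour cell fraction rho is observed at allelic frequency

    v = mu * rho / (rho * (m + M) + 2 * (1 - rho))

(tumour cells contribute m + M chromosome copies, admixed normal cells 2).
Inverting gives the purity from an observed clonal VAF:

    rho = 2 v / (mu + v * (2 - m - M))

The same equation yields the tumour-in-tumour score (TIT, tumour purity) from
the mean clonal VAF in the tumour, and the tumour-in-normal score (TIN,
contamination) from the Binomial-mixture VAF summary in the normal: the
contaminating cells in the normal are tumour cells, so the tumour karyotype
applies to both conversions.  Cell fractions convert to read fractions via

    eta = lambda * (m + M) / (lambda * (m + M) + 2 - 2 * lambda)

which is the identity when m + M = 2 (diploid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_model import Karyotype, SNVRecord

DIPLOID = Karyotype(1, 1)


@dataclass
class TincScores:
    """TIT and TIN in cell-fraction and read-fraction units."""

    tit_cell: float
    tin_cell: float
    tit_rf: float
    tin_rf: float
    karyotype: Karyotype
    multiplicity: int
    clonal_vaf_tumour: float
    clonal_vaf_normal: float
    tit_clipped: bool = False
    tin_clipped: bool = False

    def to_dict(self) -> dict:
        return {
            "TIT": {"cell_fraction": round(self.tit_cell, 4), "read_fraction": round(self.tit_rf, 4)},
            "TIN": {"cell_fraction": round(self.tin_cell, 4), "read_fraction": round(self.tin_rf, 4)},
            "karyotype": self.karyotype.label,
            "multiplicity": self.multiplicity,
            "clonal_vaf_tumour": round(self.clonal_vaf_tumour, 4),
            "clonal_vaf_normal": round(self.clonal_vaf_normal, 4),
            "clipped": {"TIT": self.tit_clipped, "TIN": self.tin_clipped},
        }


def purity_from_vaf(v: float, m: int, M: int, mu: int = 1) -> tuple[float, bool]:
    """Cell fraction rho = 2v / (mu + v(2 - m - M)), clipped to [0, 1].

    Returns ``(rho, clipped)``; raises on a non-positive denominator, which
    signals an inconsistent karyotype/VAF combination.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"VAF {v} outside [0, 1]")
    denom = mu + v * (2 - m - M)
    if denom <= 0:
        raise ValueError(f"inconsistent karyotype/VAF: denominator {denom} <= 0 "
                         f"for v={v}, karyotype {M}:{m}, mu={mu}")
    rho = 2.0 * v / denom
    clipped = rho > 1.0 or rho < 0.0
    return float(min(max(rho, 0.0), 1.0)), clipped


def forward_vaf(rho: float, m: int, M: int, mu: int = 1) -> float:
    """Expected clonal VAF at cell fraction rho (inverse of purity_from_vaf)."""
    return mu * rho / (rho * (m + M) + 2.0 * (1.0 - rho))


def tumour_clonal_vaf(snvs: Sequence[SNVRecord], indices: Sequence[int]) -> float:
    """Mean tumour VAF over the selected clonal mutations."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty clonal mutation set")
    return float(np.mean([snvs[i].t_vaf for i in idx]))


def cell_to_read_fraction(lam: float, m: int, M: int) -> float:
    """Read fraction eta = lam(m+M) / (lam(m+M) + 2 - 2 lam); increasing in lam."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"cell fraction {lam} outside [0, 1]")
    total = m + M
    denom = lam * total + 2.0 - 2.0 * lam
    return float(lam * total / denom)


def read_to_cell_fraction(eta: float, m: int, M: int) -> float:
    """Inverse read->cell fraction: lambda = 2 eta / ((m+M)(1-eta) + 2 eta)."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"read fraction {eta} outside [0, 1]")
    return float(2.0 * eta / ((m + M) * (1.0 - eta) + 2.0 * eta))


def compute_scores(
    v_tumour: float,
    v_normal: float,
    karyotype: Optional[Karyotype] = None,
    multiplicity: int = 1,
) -> TincScores:
    """TIT and TIN from the two clonal VAF summaries.

    ``karyotype`` None means SNV-only mode: the purity equation is solved for
    a diploid tumour (m = M = mu = 1).
    """
    k = karyotype if karyotype is not None else DIPLOID
    mu = multiplicity if karyotype is not None else 1
    tit, tit_clip = purity_from_vaf(v_tumour, k.minor, k.major, mu)
    tin, tin_clip = purity_from_vaf(v_normal, k.minor, k.major, mu)
    return TincScores(
        tit_cell=tit,
        tin_cell=tin,
        tit_rf=cell_to_read_fraction(tit, k.minor, k.major),
        tin_rf=cell_to_read_fraction(tin, k.minor, k.major),
        karyotype=k,
        multiplicity=mu,
        clonal_vaf_tumour=v_tumour,
        clonal_vaf_normal=v_normal,
        tit_clipped=tit_clip,
        tin_clipped=tin_clip,
    )
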