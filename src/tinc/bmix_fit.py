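"""Binomial mixture on normal-sample read counts of the clonal mutations.

For each clonal SNV we have the matched-normal depth d and alternate count r.
Contaminating tumour cells leave a low-VAF signal in the normal, modelled as

    f(r, d | theta, pi) = sum_i pi_i Binomial(r | d, p_i)

fitted by EM (closed-form M-step) with k chosen by the same ICL construction
used for the tumour deconvolution.  Mutations with r = 0 are retained: at ~30x
normal coverage, Binomial sampling makes zero counts expected even under real
contamination, and dropping them would bias the contamination estimate upward
or downward depending on the truth.  The contamination VAF summary is the
mixing-proportion-weighted mean of the component success probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .mobster_fit import icl_score

_EM_TOL = 1e-10
_EM_MAX_ITER = 500
_P_EPS = 1e-9


@dataclass
class BmixFit:
    """Fitted Binomial mixture: success probabilities sorted ascending."""

    k: int
    p: np.ndarray
    pi: np.ndarray
    z: np.ndarray
    assignments: np.ndarray
    icl: float
    loglik: float
    n: int
    loglik_trace: np.ndarray = None  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "p": self.p.tolist(),
            "pi": self.pi.tolist(),
            "icl": self.icl,
            "loglik": self.loglik,
            "n": self.n,
        }


def _binom_loglik_matrix(r: np.ndarray, d: np.ndarray, p: np.ndarray) -> np.ndarray:
    return stats.binom.logpmf(r[:, None], d[:, None], p[None, :])


def _em_binomial(r, d, k, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = r.size
    # quantile-spread init on empirical per-site fractions, with jitter
    frac = r / np.maximum(d, 1)
    qs = np.linspace(0.15, 0.85, k)
    p = np.quantile(frac, qs) + rng.uniform(-0.02, 0.02, size=k)
    p = np.clip(p, _P_EPS, 1 - _P_EPS)
    pi = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace: list[float] = []
    z = np.full((n, k), 1.0 / k)
    for _ in range(_EM_MAX_ITER):
        log_num = _binom_loglik_matrix(r, d, p) + np.log(pi)
        log_mix = special.logsumexp(log_num, axis=1, keepdims=True)
        ll = float(log_mix.sum())
        trace.append(ll)
        z = np.exp(log_num - log_mix)
        w = z.sum(axis=0)
        pi = np.maximum(w, 1e-12) / np.maximum(w, 1e-12).sum()
        p = np.clip((z * r[:, None]).sum(axis=0) / np.maximum((z * d[:, None]).sum(axis=0), 1e-12),
                    _P_EPS, 1 - _P_EPS)
        if abs(ll - prev_ll) < _EM_TOL:
            break
        prev_ll = ll
    log_num = _binom_loglik_matrix(r, d, p) + np.log(pi)
    log_mix = special.logsumexp(log_num, axis=1, keepdims=True)
    z = np.exp(log_num - log_mix)
    trace.append(float(log_mix.sum()))
    return p, pi, z, float(log_mix.sum()), np.asarray(trace)


def _bmix_param_count(k: int) -> int:
    """k success probabilities + (k-1) free mixing proportions."""
    return k + (k - 1)


def fit_bmix(
    counts: Sequence[tuple[int, int]],
    k_max: int = 3,
    seed: int = 0,
    restarts: int = 3,
) -> BmixFit:
    """Fit Binomial mixtures for k = 1..k_max and select by minimal ICL.

    ``counts`` are per-mutation ``(alt reads, depth)`` pairs from the normal
    sample.  All-zero alternate counts are valid data (single component near
    p = 0, signalling contamination ~ 0).  Deterministic given ``seed``.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("counts must be a non-empty list of (r, d) pairs")
    r, d = arr[:, 0], arr[:, 1]
    if np.any(r < 0) or np.any(d <= 0) or np.any(r > d):
        raise ValueError("require 0 <= r <= d and d > 0")
    n = r.size

    best: BmixFit | None = None
    for k in range(1, min(k_max, n) + 1):
        rng = np.random.default_rng([seed, k])
        for restart in range(restarts):
            p, pi, z, ll, trace = _em_binomial(r, d, k, rng)
            order = np.argsort(p)
            p, pi, z = p[order], pi[order], z[:, order]
            icl = icl_score(ll, _bmix_param_count(k), n, z)
            fit = BmixFit(
                k=k, p=p, pi=pi, z=z,
                assignments=np.argmax(z, axis=1),
                icl=icl, loglik=ll, n=n, loglik_trace=trace,
            )
            if best is None or fit.icl < best.icl:
                best = fit
    assert best is not None
    return best


def weighted_normal_vaf(fit: BmixFit) -> float:
    """Contamination VAF summary: v = sum_i pi_i p_i (relabelling-invariant)."""
    return float(np.dot(fit.pi, fit.p))
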