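"""Joint tumour/normal read-count clustering by variational Bayes.

A complementary check on the univariate pipeline: all SNVs are clustered in
two dimensions at once with a mixture of products of Binomials,

    f(x | theta, pi) = sum_i pi_i Bin(r_t | d_t, theta_it) Bin(r_n | d_n, theta_in)

assuming the tumour and normal assays are independent sequencing runs.
Inference is mean-field variational Bayes with Beta(1, 1) priors on the
success probabilities and a sparse symmetric Dirichlet prior (alpha0 = 1e-2)
on the weights, so superfluous components are emptied automatically and the
number of effective clusters is data-driven.  The ELBO is monotone
non-decreasing across iterations.

If the selected clonal mutations concentrate in a single joint cluster, that
cluster's (theta_t, theta_n) yields an alternative TIT/TIN estimate used to
confirm — never override — the primary scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .clonal_select import ClonalSelection
from .io_model import Karyotype
from .scores import TincScores, cell_to_read_fraction, purity_from_vaf

_ALPHA0 = 1e-2
_BETA_PRIOR = (1.0, 1.0)
_ELBO_TOL = 1e-8
_MAX_ITER = 1000
_PRUNE_PI = 0.01
DEFAULT_CONCORDANCE_CLUSTER_FRACTION = 0.8
DEFAULT_CONCORDANCE_TOLERANCE_RF = 0.03


@dataclass
class ViberFit:
    """Variational posterior summary of the joint Binomial mixture."""

    theta: np.ndarray          # k_eff x 2 posterior-mean success probs (tumour, normal)
    pi: np.ndarray             # k_eff expected weights (renormalised after pruning)
    z: np.ndarray              # n x k_eff responsibilities (renormalised)
    assignments: np.ndarray
    elbo_trace: np.ndarray
    converged: bool

    @property
    def k_effective(self) -> int:
        return len(self.pi)

    def to_dict(self) -> dict:
        return {
            "k_effective": self.k_effective,
            "theta_tumour": self.theta[:, 0].round(6).tolist(),
            "theta_normal": self.theta[:, 1].round(6).tolist(),
            "pi": self.pi.round(6).tolist(),
            "converged": self.converged,
        }


def _elbo(r, d, alpha, a, b, z, log_binom_const) -> float:
    """Evidence lower bound for the mean-field posterior (up to no constants)."""
    n, k = z.shape
    alpha0 = np.full(k, _ALPHA0)
    a0, b0 = _BETA_PRIOR

    dig_alpha = special.digamma(alpha) - special.digamma(alpha.sum())
    e_log_theta = special.digamma(a) - special.digamma(a + b)       # k x 2
    e_log_1mtheta = special.digamma(b) - special.digamma(a + b)

    # E[log p(x | z, theta)] + E[log p(z | pi)] - E[log q(z)]
    ll = (z * (r @ e_log_theta.T + (d - r) @ e_log_1mtheta.T)).sum() + log_binom_const
    pz = (z * dig_alpha).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        qz = np.where(z > 0, z * np.log(z), 0.0).sum()

    # -KL(q(pi) || p(pi))
    kl_pi = (
        special.gammaln(alpha.sum()) - special.gammaln(alpha).sum()
        - special.gammaln(alpha0.sum()) + special.gammaln(alpha0).sum()
        + ((alpha - alpha0) * dig_alpha).sum()
    )
    # -KL(q(theta) || p(theta))
    kl_theta = (
        special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b)
        - special.gammaln(a0 + b0) + special.gammaln(a0) + special.gammaln(b0)
        + (a - a0) * special.digamma(a) + (b - b0) * special.digamma(b)
        - (a + b - a0 - b0) * special.digamma(a + b)
    ).sum()
    return float(ll + pz - qz - kl_pi - kl_theta)


def fit_viber(
    counts: Sequence[tuple[int, int, int, int]],
    k_max: int = 10,
    seed: int = 0,
    max_iter: int = _MAX_ITER,
) -> ViberFit:
    """Fit the joint mixture on (r_t, d_t, r_n, d_n) tuples.

    Coordinate-ascent variational inference is run from k-means
    initialisations with 1..``k_max`` starting components; the run with the
    highest final evidence lower bound is kept, so the effective number of
    clusters is determined automatically (the sparse Dirichlet prior empties
    redundant components and the ELBO penalises fragmented fits).  Components
    with expected weight below 1% are pruned from the report.  Deterministic
    given ``seed``; non-convergence returns the best iterate with a warning
    flag.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
        raise ValueError("counts must be non-empty (r_t, d_t, r_n, d_n) rows")
    r = arr[:, [0, 2]]
    d = arr[:, [1, 3]]
    if np.any(r < 0) or np.any(r > d) or np.any(d < 0):
        raise ValueError("require 0 <= r <= d in both samples")
    n = arr.shape[0]

    log_binom_const = float(
        (special.gammaln(d + 1) - special.gammaln(r + 1) - special.gammaln(d - r + 1)).sum()
    )
    vaf = r / np.maximum(d, 1)
    n_distinct = np.unique(vaf, axis=0).shape[0]
    rng = np.random.default_rng(seed)
    best: Optional[ViberFit] = None
    for k_init in range(1, min(k_max, n, n_distinct) + 1):
        fit = _cavi_single(r, d, vaf, k_init, int(rng.integers(2**31)),
                           max_iter, log_binom_const)
        if best is None or fit.elbo_trace[-1] > best.elbo_trace[-1]:
            best = fit
    return best


def _cavi_single(r, d, vaf, k, kmeans_seed, max_iter, log_binom_const) -> ViberFit:
    from sklearn.cluster import KMeans

    n = r.shape[0]
    labels = KMeans(n_clusters=k, n_init=3,
                    random_state=kmeans_seed).fit_predict(vaf)
    z = np.full((n, k), 1e-6)
    z[np.arange(n), labels] = 1.0
    z /= z.sum(axis=1, keepdims=True)

    a0, b0 = _BETA_PRIOR
    elbo_trace: list[float] = []
    converged = False
    alpha = np.full(k, _ALPHA0)
    a = np.full((k, 2), a0)
    b = np.full((k, 2), b0)
    for _ in range(max_iter):
        # variational M-step
        nk = z.sum(axis=0)
        alpha = _ALPHA0 + nk
        a = a0 + z.T @ r
        b = b0 + z.T @ (d - r)

        # variational E-step
        dig_alpha = special.digamma(alpha) - special.digamma(alpha.sum())
        e_log_theta = special.digamma(a) - special.digamma(a + b)
        e_log_1mtheta = special.digamma(b) - special.digamma(a + b)
        log_rho = dig_alpha + r @ e_log_theta.T + (d - r) @ e_log_1mtheta.T
        log_norm = special.logsumexp(log_rho, axis=1, keepdims=True)
        z = np.exp(log_rho - log_norm)

        elbo_trace.append(_elbo(r, d, alpha, a, b, z, log_binom_const))
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < _ELBO_TOL:
            converged = True
            break

    theta = a / (a + b)
    pi_full = alpha / alpha.sum()
    keep = np.flatnonzero(pi_full >= _PRUNE_PI)
    if keep.size == 0:
        keep = np.array([int(np.argmax(pi_full))])
    theta = theta[keep]
    pi = pi_full[keep] / pi_full[keep].sum()
    z_kept = z[:, keep]
    z_kept = z_kept / np.maximum(z_kept.sum(axis=1, keepdims=True), 1e-300)
    return ViberFit(
        theta=theta,
        pi=pi,
        z=z_kept,
        assignments=np.argmax(z_kept, axis=1),
        elbo_trace=np.asarray(elbo_trace),
        converged=converged,
    )


def confirm_scores(
    viber: ViberFit,
    clonal_indices: Sequence[int],
    primary: TincScores,
    karyotype: Optional[Karyotype] = None,
    multiplicity: int = 1,
    cluster_fraction: float = DEFAULT_CONCORDANCE_CLUSTER_FRACTION,
    tolerance_rf: float = DEFAULT_CONCORDANCE_TOLERANCE_RF,
) -> dict:
    """Advisory concordance check of the joint fit against the primary scores.

    If at least ``cluster_fraction`` of the selected clonal mutations fall in
    one joint cluster, that cluster's posterior-mean (theta_t, theta_n) give
    alternative TIT/TIN read-fraction estimates; discordance beyond
    ``tolerance_rf`` is flagged.  Purely advisory: never overrides the
    primary scores.
    """
    idx = np.asarray(clonal_indices, dtype=int)
    if idx.size == 0:
        return {"status": "no clonal mutations to track"}
    assigned = viber.assignments[idx]
    values, freq = np.unique(assigned, return_counts=True)
    top = int(values[np.argmax(freq)])
    top_fraction = float(freq.max() / idx.size)
    if top_fraction < cluster_fraction:
        return {
            "status": "no single confirming cluster",
            "top_cluster_fraction": round(top_fraction, 4),
        }
    k = karyotype if karyotype is not None else Karyotype(1, 1)
    mu = multiplicity if karyotype is not None else 1
    alt_tit, _ = purity_from_vaf(min(float(viber.theta[top, 0]), 1.0), k.minor, k.major, mu)
    alt_tin, _ = purity_from_vaf(min(float(viber.theta[top, 1]), 1.0), k.minor, k.major, mu)
    alt_tit_rf = cell_to_read_fraction(alt_tit, k.minor, k.major)
    alt_tin_rf = cell_to_read_fraction(alt_tin, k.minor, k.major)
    dev_tit = abs(alt_tit_rf - primary.tit_rf)
    dev_tin = abs(alt_tin_rf - primary.tin_rf)
    concordant = dev_tit <= tolerance_rf and dev_tin <= tolerance_rf
    return {
        "status": "confirmed" if concordant else "discordant",
        "top_cluster_fraction": round(top_fraction, 4),
        "alternative_TIT_rf": round(alt_tit_rf, 4),
        "alternative_TIN_rf": round(alt_tin_rf, 4),
        "deviation_TIT_rf": round(dev_tit, 4),
        "deviation_TIN_rf": round(dev_tin, 4),
        "tolerance_rf": tolerance_rf,
    }
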