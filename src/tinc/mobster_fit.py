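"""Tumour VAF deconvolution: Pareto power-law tail + Beta cluster mixture.

The variant allele frequency (VAF) distribution of a bulk tumour decomposes
into Beta-distributed clusters (the clonal cluster plus any subclones) and a
power-law tail of within-clone neutral passenger mutations.  The model is a
(k+1)-component mixture

    f(x | theta, pi) = pi_1 PL(x | shape, scale) + sum_i pi_i Beta(x | mean_i, prec_i)

with the tail optionally absent.  The fit uses EM with exact weighted-MLE
M-steps, and the number of Beta clusters k together with tail presence is
chosen by minimising an integrated classification likelihood (ICL) score:
a BIC-style complexity penalty plus the clustering entropy, so that poorly
separated clusterings are penalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

MIN_OBSERVATIONS = 50
_BETA_MEAN_BOUNDS = (1e-3, 1.0 - 1e-3)
_BETA_PRECISION_BOUNDS = (10.0, 5000.0)
_PARETO_SHAPE_BOUNDS = (0.05, 100.0)
_EM_TOL = 1e-8
_EM_MAX_ITER = 500


class DeconvolutionError(RuntimeError):
    """Raised when the VAF mixture cannot be fitted."""


@dataclass
class MobsterFit:
    """A fitted tumour VAF mixture.

    Beta components are ordered by decreasing mean so that cluster "C1" (the
    highest-VAF, putatively clonal cluster) is first; the tail, when present,
    is the last column of the responsibility matrix ``z``.
    """

    tail_present: bool
    tail_shape: Optional[float]
    tail_scale: Optional[float]
    betas: list[tuple[float, float]]          # (mean, precision), C1 first
    pi: np.ndarray                            # Beta proportions then tail
    z: np.ndarray                             # n x n_components responsibilities
    icl: float
    loglik: float
    n: int
    loglik_trace: np.ndarray = None  # type: ignore[assignment]

    @property
    def k(self) -> int:
        return len(self.betas)

    @property
    def n_components(self) -> int:
        return self.k + (1 if self.tail_present else 0)

    def cluster_labels(self) -> list[str]:
        labels = [f"C{i + 1}" for i in range(self.k)]
        if self.tail_present:
            labels.append("Tail")
        return labels

    def to_dict(self) -> dict:
        return {
            "tail_present": self.tail_present,
            "tail_shape": self.tail_shape,
            "tail_scale": self.tail_scale,
            "betas": [{"mean": m, "precision": p} for m, p in self.betas],
            "pi": self.pi.tolist(),
            "icl": self.icl,
            "loglik": self.loglik,
            "n": self.n,
            "cluster_labels": self.cluster_labels(),
        }


# ---------------------------------------------------------------------------
# Component densities
# ---------------------------------------------------------------------------

def _beta_logpdf(x: np.ndarray, mean: float, precision: float) -> np.ndarray:
    a, b = mean * precision, (1.0 - mean) * precision
    return stats.beta.logpdf(x, a, b)


def _pareto_logpdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Pareto Type-I log-density; -inf below the scale (support constraint)."""
    out = np.full_like(x, -np.inf, dtype=float)
    ok = x >= scale
    out[ok] = np.log(shape) + shape * np.log(scale) - (shape + 1.0) * np.log(x[ok])
    return out


def _component_logdens(
    x: np.ndarray,
    betas: Sequence[tuple[float, float]],
    tail: Optional[tuple[float, float]],
) -> np.ndarray:
    """n x n_components matrix of log component densities (Betas, then tail)."""
    cols = [_beta_logpdf(x, m, p) for m, p in betas]
    if tail is not None:
        cols.append(_pareto_logpdf(x, *tail))
    return np.column_stack(cols)


def _log_mixture(logdens: np.ndarray, pi: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return special.logsumexp(logdens + np.log(pi), axis=1)


def responsibilities_from_params(
    vafs: np.ndarray,
    betas: Sequence[tuple[float, float]],
    tail: Optional[tuple[float, float]],
    pi: np.ndarray,
) -> np.ndarray:
    """Posterior component probabilities z[n, k] = pi_k g_k(x_n) / sum_i pi_i g_i(x_n)."""
    logdens = _component_logdens(np.asarray(vafs, float), betas, tail)
    with np.errstate(divide="ignore"):
        log_num = logdens + np.log(pi)
    log_den = special.logsumexp(log_num, axis=1, keepdims=True)
    return np.exp(log_num - log_den)


def responsibilities(fit: MobsterFit, vafs: Sequence[float]) -> np.ndarray:
    """Responsibility matrix of a fitted model on (possibly new) VAFs."""
    tail = (fit.tail_shape, fit.tail_scale) if fit.tail_present else None
    return responsibilities_from_params(np.asarray(vafs, float), fit.betas, tail, fit.pi)


# ---------------------------------------------------------------------------
# ICL
# ---------------------------------------------------------------------------

def entropy_term(z: np.ndarray) -> float:
    """Clustering entropy -sum z log z with 0 log 0 := 0 (non-negative)."""
    z = np.asarray(z, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(z > 0, z * np.log(z), 0.0)
    return float(-t.sum())


def icl_score(loglik: float, n_free_params: int, n: int, z: np.ndarray) -> float:
    """ICL = -2 log L + |params| log n + entropy(z); smaller is better.

    The entropy term penalises overlapping, poorly separated clusters on top
    of the BIC-style complexity penalty.
    """
    return -2.0 * loglik + n_free_params * np.log(n) + entropy_term(z)


def count_free_params(k_betas: int, tail: bool) -> int:
    """2 per Beta (mean, precision), 1 for the tail shape, components-1 for pi."""
    n_components = k_betas + (1 if tail else 0)
    return 2 * k_betas + (1 if tail else 0) + (n_components - 1)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _clip_ab(a: float, b: float) -> tuple[float, float]:
    """Project (a, b) onto the feasible (mean, precision) box."""
    prec = np.clip(a + b, *_BETA_PRECISION_BOUNDS)
    mean = np.clip(a / (a + b), *_BETA_MEAN_BOUNDS)
    return float(mean * prec), float((1.0 - mean) * prec)


def _fit_beta_weighted(s_logx: float, s_log1mx: float, weight: float,
                       init: tuple[float, float]) -> tuple[float, float]:
    """Weighted Beta MLE in (mean, precision) from sufficient statistics.

    Maximises  (a-1) S_logx + (b-1) S_log1mx - W log B(a, b)  with
    a = mean*prec, b = (1-mean)*prec by damped Newton on (a, b), projected
    onto the (mean, precision) bounds.  Backtracking ensures the objective
    never decreases, so the surrounding EM is a monotone generalised EM.
    O(1) per evaluation: only sufficient statistics enter.
    """
    if weight <= 1e-12:
        return init

    def obj(a: float, b: float) -> float:
        return ((a - 1.0) * s_logx + (b - 1.0) * s_log1mx
                - weight * special.betaln(a, b))

    mean, prec = init
    a, b = mean * prec, (1.0 - mean) * prec
    f0 = obj(a, b)
    for _ in range(30):
        dig_ab = special.digamma(a + b)
        grad_a = s_logx - weight * (special.digamma(a) - dig_ab)
        grad_b = s_log1mx - weight * (special.digamma(b) - dig_ab)
        if max(abs(grad_a), abs(grad_b)) < 1e-9 * max(1.0, weight):
            break
        tri_ab = special.polygamma(1, a + b)
        h_aa = -weight * (special.polygamma(1, a) - tri_ab)
        h_bb = -weight * (special.polygamma(1, b) - tri_ab)
        h_ab = weight * tri_ab
        det = h_aa * h_bb - h_ab * h_ab
        if det <= 0 or h_aa >= 0:  # not concave here: fall back to gradient
            step_a, step_b = grad_a / weight, grad_b / weight
        else:
            step_a = -(h_bb * grad_a - h_ab * grad_b) / det
            step_b = -(h_aa * grad_b - h_ab * grad_a) / det
        t = 1.0
        improved = False
        for _ in range(20):
            na, nb = _clip_ab(a + t * step_a, b + t * step_b)
            f1 = obj(na, nb)
            if f1 >= f0:
                a, b, f0, improved = na, nb, f1, True
                break
            t *= 0.5
        if not improved:
            break
    prec = a + b
    return float(a / prec), float(prec)


def _fit_pareto_shape(x: np.ndarray, w: np.ndarray, scale: float) -> float:
    """Weighted Pareto shape MLE: shape = sum w / sum w log(x/scale)."""
    denom = float(np.sum(w * np.log(np.maximum(x, scale) / scale)))
    if denom <= 0:
        return _PARETO_SHAPE_BOUNDS[1]
    return float(np.clip(np.sum(w) / denom, *_PARETO_SHAPE_BOUNDS))


def _init_params(
    x: np.ndarray, k: int, tail: bool, rng: np.random.Generator, jitter: bool
) -> tuple[list[tuple[float, float]], Optional[tuple[float, float]], np.ndarray]:
    """Moment-matching initialisation: k-means on VAF for Beta means; tail
    shape by MLE on points below the lowest Beta-mean decile."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(x.reshape(-1, 1))
    means = np.sort(km.cluster_centers_.ravel())[::-1]
    if jitter:
        means = np.clip(means + rng.normal(0, 0.02, size=k), *_BETA_MEAN_BOUNDS)
    betas = [(float(np.clip(m, *_BETA_MEAN_BOUNDS)), 100.0) for m in means]

    scale = float(x.min())
    tail_params = None
    if tail:
        low_cut = np.quantile(x, 0.10) if k == 0 else min(means) * 0.9
        low = x[x <= max(low_cut, scale * 1.01)]
        shape = _fit_pareto_shape(low, np.ones_like(low), scale) if low.size else 2.0
        tail_params = (float(np.clip(shape, *_PARETO_SHAPE_BOUNDS)), scale)

    n_comp = k + (1 if tail else 0)
    pi = np.full(n_comp, 1.0 / n_comp)
    if tail:
        # start the tail small: it competes with low-VAF Beta mass
        pi = np.full(n_comp, 0.8 / k if k else 1.0)
        pi[-1] = 0.2
        counts = np.bincount(labels, minlength=k).astype(float)
        pi[:k] = 0.8 * counts[np.argsort(km.cluster_centers_.ravel())[::-1]] / counts.sum()
    else:
        counts = np.bincount(labels, minlength=k).astype(float)
        pi = counts[np.argsort(km.cluster_centers_.ravel())[::-1]] / counts.sum()
    return betas, tail_params, pi


def _fast_logdens(
    logx: np.ndarray,
    log1mx: np.ndarray,
    betas: Sequence[tuple[float, float]],
    tail: Optional[tuple[float, float]],
) -> np.ndarray:
    """EM-loop log densities from precomputed log x / log(1-x).

    Equivalent to :func:`_component_logdens` (scale <= min x, so the tail's
    support covers all points) but avoids scipy distribution overhead.
    """
    cols = []
    for mean, prec in betas:
        a, b = mean * prec, (1.0 - mean) * prec
        cols.append((a - 1.0) * logx + (b - 1.0) * log1mx - special.betaln(a, b))
    if tail is not None:
        shape, scale = tail
        cols.append(np.log(shape) + shape * np.log(scale) - (shape + 1.0) * logx)
    return np.column_stack(cols)


def _em_single(
    x: np.ndarray, k: int, tail: bool, rng: np.random.Generator, jitter: bool
) -> tuple[list[tuple[float, float]], Optional[tuple[float, float]], np.ndarray, np.ndarray, float]:
    n = x.size
    betas, tail_params, pi = _init_params(x, k, tail, rng, jitter)
    logx, log1mx = np.log(x), np.log1p(-x)
    prev_ll = -np.inf
    trace: list[float] = []
    z = np.full((n, k + (1 if tail else 0)), np.nan)
    for _ in range(_EM_MAX_ITER):
        logdens = _fast_logdens(logx, log1mx, betas, tail_params)
        with np.errstate(divide="ignore"):
            log_num = logdens + np.log(pi)
        log_mix = special.logsumexp(log_num, axis=1, keepdims=True)
        ll = float(log_mix.sum())
        trace.append(ll)
        z = np.exp(log_num - log_mix)

        # M-step (exact weighted MLEs -> monotone log-likelihood)
        weights = z.sum(axis=0)
        pi = np.maximum(weights, 1e-12) / np.maximum(weights, 1e-12).sum()
        new_betas = []
        for j, (mean, prec) in enumerate(betas):
            w = z[:, j]
            new_betas.append(
                _fit_beta_weighted(float(w @ logx), float(w @ log1mx),
                                   float(weights[j]), (mean, prec))
            )
        betas = new_betas
        if tail:
            shape = _fit_pareto_shape(x, z[:, -1], tail_params[1])
            tail_params = (shape, tail_params[1])

        if abs(ll - prev_ll) < _EM_TOL:
            prev_ll = ll
            break
        prev_ll = ll

    # final E-step so z, ll match the returned parameters
    logdens = _fast_logdens(logx, log1mx, betas, tail_params)
    with np.errstate(divide="ignore"):
        log_num = logdens + np.log(pi)
    log_mix = special.logsumexp(log_num, axis=1, keepdims=True)
    z = np.exp(log_num - log_mix)
    ll = float(log_mix.sum())
    trace.append(ll)
    return betas, tail_params, pi, z, ll, np.asarray(trace)


def _order_by_mean(betas, pi, z, tail: bool):
    """Canonical ordering: Betas by decreasing mean (C1 = highest), tail last."""
    k = len(betas)
    order = sorted(range(k), key=lambda j: -betas[j][0])
    if tail:
        cols = order + [k]
    else:
        cols = order
    return [betas[j] for j in order], pi[cols], z[:, cols]


def fit_mobster(
    vafs: Sequence[float],
    k_max: int = 3,
    tail: str = "auto",
    restarts: int = 5,
    seed: int = 0,
    min_observations: int = MIN_OBSERVATIONS,
) -> MobsterFit:
    """Fit the tail + Beta mixture and select (k, tail) by minimal ICL.

    Candidate models are every k in 1..k_max crossed with tail on/off (or the
    single tail setting when ``tail`` is ``"on"``/``"off"``); each is fitted
    with ``restarts`` jittered EM restarts.  Deterministic given ``seed``.
    The Pareto scale is fixed at the minimum retained VAF.
    """
    x_input = np.asarray(vafs, dtype=float)
    if np.any((x_input <= 0) | (x_input > 1)):
        raise ValueError("VAFs must lie in (0, 1]")
    if x_input.size < min_observations:
        raise DeconvolutionError(
            f"cannot deconvolve: {x_input.size} observations < minimum {min_observations}"
        )
    x_input = np.clip(x_input, 1e-9, 1.0 - 1e-9)
    # sort for exact permutation invariance; responsibilities are mapped back
    x = np.sort(x_input)

    if tail not in ("auto", "on", "off"):
        raise ValueError(f"unknown tail mode {tail!r}")
    tail_options = {"auto": (False, True), "on": (True,), "off": (False,)}[tail]
    # degenerate data (all identical): k-means cannot split, fit one cluster
    if np.ptp(x) < 1e-12:
        k_options: Sequence[int] = (1,)
        tail_options = (False,)
    else:
        k_options = range(1, k_max + 1)

    best: Optional[MobsterFit] = None
    failures: list[str] = []
    for use_tail in tail_options:
        for k in k_options:
            if k == 0 and not use_tail:
                continue
            rng = np.random.default_rng([seed, k, int(use_tail)])
            for restart in range(restarts):
                try:
                    betas, tail_params, pi, z, ll, trace = _em_single(
                        x, k, use_tail, rng, jitter=restart > 0
                    )
                except Exception as exc:  # pragma: no cover - diagnostic path
                    failures.append(f"k={k} tail={use_tail} restart={restart}: {exc}")
                    continue
                betas, pi, z = _order_by_mean(betas, pi, z, use_tail)
                icl = icl_score(ll, count_free_params(k, use_tail), x.size, z)
                fit = MobsterFit(
                    tail_present=use_tail,
                    tail_shape=tail_params[0] if use_tail else None,
                    tail_scale=tail_params[1] if use_tail else None,
                    betas=betas,
                    pi=pi,
                    z=z,
                    icl=icl,
                    loglik=ll,
                    n=x.size,
                    loglik_trace=trace,
                )
                if best is None or fit.icl < best.icl:
                    best = fit
    if best is None:
        raise DeconvolutionError("no EM restart converged: " + "; ".join(failures))
    # responsibilities in the caller's original row order
    tail_sel = (best.tail_shape, best.tail_scale) if best.tail_present else None
    best.z = responsibilities_from_params(x_input, best.betas, tail_sel, best.pi)
    return best
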