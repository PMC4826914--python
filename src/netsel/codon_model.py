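"""The GY94-family codon substitution model and beta site-class machinery.

The instantaneous rate from sense codon i to j is

    q_ij = 0                 if i and j differ at more than one position
         = pi_j              synonymous transversion
         = kappa * pi_j      synonymous transition
         = omega * pi_j      nonsynonymous transversion
         = omega * kappa * pi_j   nonsynonymous transition

with the diagonal filled so rows sum to zero.  omega = dN/dS measures
selection on the protein: omega < 1 purifying, omega = 1 neutral,
omega > 1 positive selection.  The chain is time-reversible with stationary
distribution pi, which makes the symmetrized form
pi^{1/2} Q pi^{-1/2} amenable to a single symmetric eigendecomposition per
omega; all transition matrices P(t) = expm(Qt) are then cheap.

Site-to-site rate variation follows the M7/M8 site models: omega at a site
is drawn from Beta(p, q) on [0, 1] (M7), optionally mixed with an extra
point mass at omega_s >= 1 with weight 1 - p0 (M8).  For fitting, the beta
is discretized into K equal-probability classes whose representative omega
is the conditional mean of the beta within each inter-quantile slice.

Scaling convention: a rate matrix built for a *mixture* of classes is
divided by the mixture-expected rate, so branch lengths are expected
substitutions per codon under the full site model (codeml's convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc
from scipy.stats import beta as beta_dist

from .codons import N_CODONS, NON_TS, NON_TV, SYN_TS, SYN_TV


@dataclass
class RateMatrixSpec:
    """Parameters of a single-omega GY94 rate matrix."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must be a {N_CODONS}-vector")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("pi entries must be >= 0")


def _unscaled_offdiag(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    rel = SYN_TV + kappa * SYN_TS + omega * (NON_TV + kappa * NON_TS)
    return rel * pi[None, :]


def mean_rate_coefficients(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """(a, b) such that the unscaled mean substitution rate equals a + b*omega.

    The mean rate of the unscaled matrix is sum_i pi_i sum_{j!=i} q_ij;
    splitting synonymous and nonsynonymous terms makes it linear in omega,
    which lets mixture scaling factors be computed in closed form.
    """
    syn = SYN_TV + kappa * SYN_TS
    non = NON_TV + kappa * NON_TS
    a = float(pi @ (syn * pi[None, :]).sum(axis=1))
    b = float(pi @ (non * pi[None, :]).sum(axis=1))
    return a, b


def build_rate_matrix(spec: RateMatrixSpec, scale: bool = True) -> np.ndarray:
    """Instantaneous 61x61 GY94 rate matrix for a single omega.

    With scale=True the matrix is normalized so the expected substitution
    rate at stationarity is 1 (branch lengths in substitutions per codon at
    this omega).  Mixture models scale by the class-weighted mean rate
    instead; see SiteClassSet.scale_factor.
    """
    q = _unscaled_offdiag(spec.kappa, spec.omega, spec.pi)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = -float(spec.pi @ np.diag(q))
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero mean rate)")
        q = q / rate
    return q


class EigenSystem:
    """Spectral form of one unscaled GY94 matrix, for fast P(t) evaluation."""

    __slots__ = ("eigvals", "left", "right")

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        pi = np.maximum(np.asarray(pi, dtype=float), 1e-12)
        q = _unscaled_offdiag(kappa, omega, pi)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        sq = np.sqrt(pi)
        sym = q * (sq[:, None] / sq[None, :])
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry against roundoff
        vals, vecs = np.linalg.eigh(sym)
        self.eigvals = vals
        # P(t) = right @ diag(exp(vals*t)) @ left
        self.right = vecs / sq[:, None]
        self.left = vecs.T * sq[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if t == 0:
            return np.eye(len(self.eigvals))
        p = (self.right * np.exp(self.eigvals * t)[None, :]) @ self.left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@dataclass
class SiteClassSet:
    """Discrete omega classes with weights (M7: beta slices; M8: + spike)."""

    omegas: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.omegas.shape != self.weights.shape:
            raise ValueError("omegas and weights must have equal shape")
        if np.any(self.weights < 0):
            raise ValueError("class weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("class weights must sum to 1")

    def scale_factor(self, kappa: float, pi: np.ndarray) -> float:
        """Mixture-expected substitution rate of the unscaled matrices."""
        a, b = mean_rate_coefficients(kappa, pi)
        return float(a + b * (self.weights @ self.omegas))


def discretize_beta(p: float, q: float, k: int) -> SiteClassSet:
    """K equal-probability classes of Beta(p, q); representatives are slice means.

    The mean of the beta restricted to quantile slice (x0, x1] is
    mu * (I(x1; p+1, q) - I(x0; p+1, q)) / (1/K) with mu = p/(p+q) and I the
    regularized incomplete beta — the standard identity used to avoid
    numerical quadrature.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shapes must be > 0")
    if k < 2:
        raise ValueError("need at least 2 classes")
    edges = beta_dist.ppf(np.linspace(0, 1, k + 1), p, q)
    if not np.all(np.diff(edges) >= 0):
        raise ValueError(f"beta quantile inversion failed for p={p}, q={q}")
    mu = p / (p + q)
    inc = betainc(p + 1, q, edges)
    means = mu * np.diff(inc) * k
    means = np.clip(means, 0.0, 1.0)
    return SiteClassSet(omegas=means, weights=np.full(k, 1.0 / k))


def m8_class_set(p: float, q: float, p0: float, omega_s: float, k: int) -> SiteClassSet:
    """M8 classes: K beta slices with total weight p0, plus omega_s at 1 - p0."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if omega_s < 1.0:
        raise ValueError("omega_s must be >= 1")
    base = discretize_beta(p, q, k)
    omegas = np.append(base.omegas, omega_s)
    weights = np.append(base.weights * p0, 1.0 - p0)
    return SiteClassSet(omegas=omegas, weights=weights)
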