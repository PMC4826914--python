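"""Maximum-likelihood fitting of the M7 and M8 site models and the LRT.

M7 draws site omega from Beta(p, q) on [0, 1]; M8 adds a class with
omega_s >= 1 and weight 1 - p0.  Each model is fitted by bounded
quasi-Newton (L-BFGS-B) on transformed parameters (log for p, q, kappa,
omega_s - 1 and branch lengths; logit for p0), restarted from three
omega starting values to guard against local optima, and the best
log-likelihood wins.  The models are compared with

    2*delta_l = 2 * (l_M8 - l_M7),   P = exp(-delta / 2)

the closed-form chi-square(2 df) survival function.  A gene is called
under positive selection when the P (or BH-adjusted q) threshold is met
AND the fitted omega_s exceeds 1 strictly.

Two fitting engines:

* "exact": direct likelihood evaluation at every optimizer step; supports
  joint optimization of branch lengths and kappa, and mixture rescaling of
  branch lengths (substitutions-per-codon units under the candidate model).
* "grid": interpolated per-site likelihood curves from a shared OmegaGrid;
  branch lengths, kappa and the overall rate scale are fixed.  Orders of
  magnitude faster; intended for simulation studies where many genes share
  one tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc, betaincinv, expit, logit

from . import codons
from .codon_model import SiteClassSet, discretize_beta, m8_class_set
from .likelihood import OmegaGrid, PatternAlignment, mixture_loglik
from .msa import Alignment
from .trees import ArrayTree

DEFAULT_OMEGA_STARTS = (0.04, 0.4, 4.0)

_LOG_EPS = 1e-6
_BL_FLOOR = 1e-8


@dataclass
class SiteModelFit:
    """Result of fitting one site model to one gene."""

    model: str
    loglik: float
    params: dict[str, float]
    converged: bool
    start_omega: float
    n_starts_converged: int = 0
    branch_lengths: np.ndarray | None = None
    engine: str = "exact"
    n_classes: int = 10

    def class_set(self) -> SiteClassSet:
        p, q = self.params["p"], self.params["q"]
        if self.model == "M8":
            return m8_class_set(p, q, self.params["p0"], self.params["omega_s"], self.n_classes)
        return discretize_beta(p, q, self.n_classes)


@dataclass
class SelectionCall:
    """Per-gene LRT outcome and selection flags (each requires omega_s > 1)."""

    gene: str
    two_delta_l: float
    p_value: float
    q_value: float | None = None
    omega_s: float = float("nan")
    sel_p05: bool = False
    sel_p01: bool = False
    sel_q10: bool = False


def _resolve_pi(codon_freqs, alignment: Alignment | None) -> np.ndarray:
    if isinstance(codon_freqs, str):
        if codon_freqs == "equal":
            return codons.equal_frequencies()
        if codon_freqs == "f3x4":
            if alignment is None:
                raise ValueError("f3x4 frequencies require the alignment rows")
            return codons.f3x4_frequencies(alignment.seqs)
        raise ValueError(f"unknown codon frequency model: {codon_freqs!r}")
    return np.asarray(codon_freqs, dtype=float)


def _m7_start(omega: float) -> tuple[float, float]:
    mean = min(max(float(omega), 0.02), 0.9)
    conc = 2.0
    return mean * conc, (1.0 - mean) * conc


def _m8_start(omega: float) -> dict[str, float]:
    return {"p": 1.0, "q": 3.0, "p0": 0.9, "omega_s": 1.0 + float(omega)}


class _ParamCodec:
    """Pack/unpack model parameters to the unconstrained optimizer vector."""

    def __init__(self, model: str, *, fit_kappa: bool, n_branches: int, max_omega_s: float):
        self.model = model
        self.fit_kappa = fit_kappa
        self.n_branches = n_branches
        self.max_omega_s = max_omega_s
        names = ["p", "q"]
        if model == "M8":
            names += ["p0", "omega_s"]
        if fit_kappa:
            names.append("kappa")
        self.names = names

    def pack(self, params: dict[str, float], blens: np.ndarray | None) -> np.ndarray:
        out = []
        for name in self.names:
            v = params[name]
            if name == "p0":
                out.append(logit(min(max(v, 1e-6), 1 - 1e-6)))
            elif name == "omega_s":
                out.append(np.log(max(v - 1.0, _LOG_EPS)))
            else:
                out.append(np.log(v))
        if blens is not None:
            out.extend(np.log(np.maximum(blens, _BL_FLOOR)))
        return np.asarray(out)

    def unpack(self, theta: np.ndarray) -> tuple[dict[str, float], np.ndarray | None]:
        params = {}
        for i, name in enumerate(self.names):
            if name == "p0":
                params[name] = float(expit(theta[i]))
            elif name == "omega_s":
                params[name] = 1.0 + float(np.exp(theta[i]))
            else:
                params[name] = float(np.exp(theta[i]))
        blens = np.exp(theta[len(self.names) :]) if self.n_branches else None
        return params, blens

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for name in self.names:
            if name in ("p", "q"):
                out.append((np.log(5e-3), np.log(99.0)))
            elif name == "p0":
                out.append((logit(1e-6), logit(1 - 1e-6)))
            elif name == "omega_s":
                out.append((np.log(_LOG_EPS), np.log(self.max_omega_s - 1.0)))
            elif name == "kappa":
                out.append((np.log(0.05), np.log(50.0)))
        out.extend([(np.log(_BL_FLOOR), np.log(50.0))] * self.n_branches)
        return out


def _class_set_for(model: str, params: dict[str, float], k: int) -> SiteClassSet:
    if model == "M8":
        return m8_class_set(params["p"], params["q"], params["p0"], params["omega_s"], k)
    return discretize_beta(params["p"], params["q"], k)


def _beta_class_arrays(p: float, q: float, k: int, _cache={}) -> tuple[np.ndarray, np.ndarray]:
    """Slice-mean discretization via scipy.special ufuncs (optimizer hot path).

    Same quantity as `discretize_beta` without the distribution-object and
    dataclass overhead; the quantile probabilities are cached per K.
    """
    probs = _cache.get(k)
    if probs is None:
        probs = _cache[k] = np.linspace(0.0, 1.0, k + 1)[1:-1]
    edges = np.empty(k + 1)
    edges[0], edges[-1] = 0.0, 1.0
    edges[1:-1] = betaincinv(p, q, probs)
    inc = betainc(p + 1, q, edges)
    means = (p / (p + q)) * (inc[1:] - inc[:-1]) * k
    return np.clip(means, 0.0, 1.0), np.full(k, 1.0 / k)


def _beta_class_arrays3(p: float, q: float, k: int, h: float, _cache={}) -> np.ndarray:
    """Class means at (p, q), (p e^h, q) and (p, q e^h) in one ufunc sweep.

    Returns a (3, K) array; rows 1 and 2 feed forward-difference
    sensitivities of the slice means to the log-shape parameters.
    """
    probs = _cache.get(k)
    if probs is None:
        probs = _cache[k] = np.tile(np.linspace(0.0, 1.0, k + 1)[1:-1], (3, 1))
    ps = np.array([p, p * np.exp(h), p])
    qs = np.array([q, q, q * np.exp(h)])
    edges = np.empty((3, k + 1))
    edges[:, 0], edges[:, -1] = 0.0, 1.0
    edges[:, 1:-1] = betaincinv(ps[:, None], qs[:, None], probs)
    inc = betainc(ps[:, None] + 1.0, qs[:, None], edges)
    means = (ps / (ps + qs))[:, None] * (inc[:, 1:] - inc[:, :-1]) * k
    return np.clip(means, 0.0, 1.0)


def fit_model(
    alignment,
    tree: ArrayTree | None = None,
    model: str = "M7",
    omega_starts=DEFAULT_OMEGA_STARTS,
    *,
    K: int = 10,
    codon_freqs="f3x4",
    kappa: float = 2.0,
    fit_kappa: bool = True,
    optimize_branch_lengths: bool = True,
    engine: str = "exact",
    rate_scale: float | None = None,
    grid: OmegaGrid | None = None,
) -> SiteModelFit:
    """Fit M7 or M8 to one codon alignment by multi-start bounded quasi-Newton.

    `alignment` is an `msa.Alignment` of codon rows (or a PatternAlignment
    when `grid` is given).  With engine="grid" a prebuilt OmegaGrid supplies
    the tree, kappa, codon frequencies and rate scale, and only the site-
    model parameters are optimized.  With engine="exact", kappa and branch
    lengths are optimized jointly by default, and `rate_scale=None` means
    branch lengths are in substitutions per codon under the candidate
    mixture (rescaled every evaluation).
    """
    if model not in ("M7", "M8"):
        raise ValueError(f"unknown model {model!r}")
    if engine == "grid" or grid is not None:
        if grid is None:
            pi = _resolve_pi(codon_freqs, alignment if isinstance(alignment, Alignment) else None)
            grid = OmegaGrid(tree, kappa, pi, rate_scale=1.0 if rate_scale is None else rate_scale)
        return _fit_grid(alignment, grid, model, omega_starts, K)
    if tree is None:
        raise ValueError("exact engine requires a tree")
    pi = _resolve_pi(codon_freqs, alignment if isinstance(alignment, Alignment) else None)
    patterns = (
        alignment
        if isinstance(alignment, PatternAlignment)
        else PatternAlignment.from_alignment(alignment, tree)
    )
    if patterns.n_sites < 1:
        raise ValueError("alignment has no codon columns")

    n_branches = tree.n_nodes - 1 if optimize_branch_lengths else 0
    codec = _ParamCodec(model, fit_kappa=fit_kappa, n_branches=n_branches, max_omega_s=999.0)
    base_blens = tree.branch_lengths.copy()
    nonroot = np.array([i for i in range(tree.n_nodes) if i != tree.root])

    def objective(theta: np.ndarray) -> float:
        params, blens = codec.unpack(theta)
        kap = params.get("kappa", kappa)
        cs = _class_set_for(model, params, K)
        if blens is not None:
            full = base_blens.copy()
            full[nonroot] = blens
            local = ArrayTree(tree.tip_labels, tree.children, full, tree.postorder_internal)
        else:
            local = tree
        try:
            ll = mixture_loglik(local, cs, kap, pi, patterns, rate_scale=rate_scale)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    best = None
    n_ok = 0
    for w0 in omega_starts:
        if model == "M7":
            p0_, q0_ = _m7_start(w0)
            start = {"p": p0_, "q": q0_}
        else:
            start = _m8_start(w0)
        if fit_kappa:
            start["kappa"] = kappa
        theta0 = codec.pack(start, base_blens[nonroot] if n_branches else None)
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=codec.bounds(),
            options={"maxiter": 500, "ftol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            n_ok += 1
            if best is None or res.fun < best[0].fun - 0.0:
                best = (res, w0)
    if best is None:
        return SiteModelFit(model, float("-inf"), {}, False, float("nan"), 0, engine="exact")
    res, w0 = best
    params, blens = codec.unpack(res.x)
    params.setdefault("kappa", kappa)
    full_blens = base_blens.copy()
    if blens is not None:
        full_blens[nonroot] = blens
    return SiteModelFit(
        model=model,
        loglik=-float(res.fun),
        params=params,
        converged=n_ok > 0,
        start_omega=w0,
        n_starts_converged=n_ok,
        branch_lengths=full_blens if optimize_branch_lengths else None,
        engine="exact",
        n_classes=K,
    )


def _fit_grid(alignment, grid: OmegaGrid, model: str, omega_starts, K: int) -> SiteModelFit:
    patterns = (
        alignment
        if isinstance(alignment, PatternAlignment)
        else PatternAlignment.from_alignment(alignment, grid.tree)
    )
    curves = grid.site_curves(patterns)
    return _fit_grid_curves(curves, patterns.weights, grid, model, omega_starts, K)


def fit_gene(
    alignment,
    grid: OmegaGrid,
    omega_starts=DEFAULT_OMEGA_STARTS,
    K: int = 10,
) -> tuple[SiteModelFit, SiteModelFit]:
    """Fit M7 and M8 to one gene sharing a single set of likelihood curves."""
    patterns = (
        alignment
        if isinstance(alignment, PatternAlignment)
        else PatternAlignment.from_alignment(alignment, grid.tree)
    )
    curves = grid.site_curves(patterns)
    f7 = _fit_grid_curves(curves, patterns.weights, grid, "M7", omega_starts, K)
    # Seed M8's beta component at the M7 optimum: the omega starts still
    # vary omega_s per the multi-start rule, but the shared beta part
    # starts near its likely optimum, roughly halving M8 iterations.
    hint = {k: f7.params[k] for k in ("p", "q")} if f7.converged else None
    f8 = _fit_grid_curves(curves, patterns.weights, grid, "M8", omega_starts, K, beta_hint=hint)
    if f7.converged and f8.loglik < f7.loglik:
        # optimizer noise at the nested boundary: the M7 optimum embedded
        # at (p0 -> 1, omega_s -> 1) is an admissible M8 solution
        boundary = {
            "p": f7.params["p"], "q": f7.params["q"],
            "p0": 1.0 - 1e-9, "omega_s": 1.0,
        }
        cs = m8_class_set(boundary["p"], boundary["q"], boundary["p0"], 1.0, K)
        ll = grid.mixture_loglik(curves, patterns.weights, cs)
        if ll > f8.loglik:
            boundary["kappa"] = grid.kappa
            f8 = SiteModelFit(
                model="M8", loglik=float(ll), params=boundary, converged=f8.converged,
                start_omega=f7.start_omega, n_starts_converged=f8.n_starts_converged,
                engine="grid", n_classes=K,
            )
    return f7, f8


def _fit_grid_curves(
    curves: np.ndarray,
    weights: np.ndarray,
    grid: OmegaGrid,
    model: str,
    omega_starts,
    K: int,
    beta_hint: dict[str, float] | None = None,
) -> SiteModelFit:
    codec = _ParamCodec(model, fit_kappa=False, n_branches=0, max_omega_s=grid.max_omega)
    is_m8 = model == "M8"
    g0, gmax = grid.grid[0], grid.grid[-1]
    spl, dspl = grid.curve_spline(curves)
    _h = 1e-6  # multiplicative step for the beta-discretization sensitivities

    def fun_and_grad(theta: np.ndarray):
        # The interpolated mixture log-likelihood is C1 in the class omegas
        # (PCHIP curves) and linear in the weights; the chain to the beta
        # shapes goes through forward differences of the cheap slice-mean
        # discretization only.
        p, q = np.exp(theta[0]), np.exp(theta[1])
        om3 = _beta_class_arrays3(p, q, K, _h)
        om_b = om3[0]
        if is_m8:
            p0 = float(expit(theta[2]))
            ws = 1.0 + float(np.exp(theta[3]))
            omegas = np.append(om_b, ws)
            cw = np.full(K + 1, p0 / K)
            cw[K] = 1.0 - p0
        else:
            omegas = om_b
            cw = np.full(K, 1.0 / K)
        omc = np.clip(omegas, g0, gmax)
        gvals = spl(omc)
        top = gvals.max(axis=0)
        e = np.exp(gvals - top[None, :])
        denom = cw @ e
        ll = float(weights @ (top + np.log(denom)))
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        r = e / denom[None, :]
        slopes = dspl(omc)
        dll_dom = cw * ((r * slopes) @ weights)
        dll_dom[(omegas <= g0) | (omegas >= gmax)] = 0.0
        grad = np.empty_like(theta)
        grad[0] = dll_dom[:K] @ (om3[1] - om_b) / _h
        grad[1] = dll_dom[:K] @ (om3[2] - om_b) / _h
        if is_m8:
            dll_dcw = r @ weights
            grad[2] = (dll_dcw[:K].sum() / K - dll_dcw[K]) * p0 * (1.0 - p0)
            grad[3] = dll_dom[K] * (ws - 1.0)
        return -ll, -grad

    best = None
    n_ok = 0
    for w0 in omega_starts:
        if model == "M7":
            p0_, q0_ = _m7_start(w0)
            start = {"p": p0_, "q": q0_}
        else:
            start = _m8_start(w0)
            if beta_hint is not None:
                start["p"] = min(max(beta_hint["p"], 6e-3), 98.0)
                start["q"] = min(max(beta_hint["q"], 6e-3), 98.0)
            start["omega_s"] = min(start["omega_s"], grid.max_omega - 1e-3)
        theta0 = codec.pack(start, None)
        res = minimize(
            fun_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=codec.bounds(),
            options={"maxiter": 500, "ftol": 1e-8},
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            n_ok += 1
            if best is None or res.fun < best[0].fun:
                best = (res, w0)
    if best is None:
        return SiteModelFit(model, float("-inf"), {}, False, float("nan"), 0, engine="grid")
    res, w0 = best
    params, _ = codec.unpack(res.x)
    params["kappa"] = grid.kappa
    return SiteModelFit(
        model=model,
        loglik=-float(res.fun),
        params=params,
        converged=n_ok > 0,
        start_omega=w0,
        n_starts_converged=n_ok,
        branch_lengths=None,
        engine="grid",
        n_classes=K,
    )


def lrt(fit_m7: SiteModelFit, fit_m8: SiteModelFit) -> tuple[float, float]:
    """(2*delta_l, P) for the nested M8-vs-M7 comparison.

    Negative differences (numerical noise — the models are nested) are
    clipped to 0; P is the chi-square(2) survival function exp(-delta/2).
    """
    two_delta = max(0.0, 2.0 * (fit_m8.loglik - fit_m7.loglik))
    return two_delta, float(np.exp(-two_delta / 2.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    qsorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = qsorted
    return q


def classify(calls: list[SelectionCall], criterion: str) -> np.ndarray:
    """Selection flags under one criterion; omega_s must exceed 1 strictly."""
    if criterion not in ("p05", "p01", "q10"):
        raise ValueError(f"unknown criterion {criterion!r}")
    out = np.zeros(len(calls), dtype=bool)
    for i, call in enumerate(calls):
        has_ws = call.omega_s > 1.0
        if criterion == "p05":
            out[i] = has_ws and call.p_value < 0.05
        elif criterion == "p01":
            out[i] = has_ws and call.p_value < 0.01
        else:
            out[i] = has_ws and call.q_value is not None and call.q_value < 0.1
    return out


def annotate_calls(calls: list[SelectionCall]) -> list[SelectionCall]:
    """Attach BH q-values and the three selection flags in place."""
    qs = bh_adjust([c.p_value for c in calls])
    for c, qv in zip(calls, qs):
        c.q_value = float(qv)
    for crit, attr in (("p05", "sel_p05"), ("p01", "sel_p01"), ("q10", "sel_q10")):
        flags = classify(calls, crit)
        for c, f in zip(calls, flags):
            setattr(c, attr, bool(f))
    return calls
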