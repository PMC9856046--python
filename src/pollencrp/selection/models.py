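"""Codon site-model fits (M0, M1a, M2a, M7, M8) and likelihood ratio tests.

The site models describe among-site variation in omega = dN/dS:

* M0 — one omega shared by all sites.
* M1a — "nearly neutral": a conserved class (omega0 < 1, proportion p0)
  and a neutral class (omega = 1).
* M2a — "positive selection": M1a plus a third class with omega_s >= 1.
* M7 — omega ~ Beta(p, q) on (0, 1), discretized into K equal-probability
  categories.
* M8 — beta & omega: proportion p0 of sites follow Beta(p, q), the rest
  (p1 = 1 - p0) sit in an extra class with omega_s >= 1.

Fitting maximizes the pruning likelihood with bounded quasi-Newton
(L-BFGS-B) and random restarts.  Branch lengths are optimized under M0 and
then held fixed for the mixture models; M7 vs M8 and M1a vs M2a are
compared by a chi-square LRT with df = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import betainc, logsumexp

from .alignment import CodonAlignment, PhyloTree
from .codon import equal_codon_freqs, f3x4_freqs
from .likelihood import (
    PackedData,
    category_matrices,
    mixture_loglik,
    site_logliks_by_category,
)

MODELS = ("M0", "M1a", "M2a", "M7", "M8")
_NESTED_PAIRS = {("M1a", "M2a"): 2, ("M7", "M8"): 2}

_KAPPA_BOUNDS = (0.05, 50.0)
_OMEGA_BOUNDS = (1e-4, 30.0)
_PROP_BOUNDS = (1e-6, 1.0 - 1e-6)
_BETA_BOUNDS = (0.005, 50.0)
_OMEGA_S_BOUNDS = (1.0, 50.0)
_BL_BOUNDS = (1e-6, 20.0)


def discretize_beta(p: float, q: float, K: int = 10, rule: str = "mean"):
    """K equal-probability categories of Beta(p, q) on (0, 1).

    Category i covers the quantile interval (i/K, (i+1)/K); its
    representative omega is the conditional mean within the interval
    (``rule='mean'``, the default) or the interval's median
    (``rule='median'``).  Weights are all 1/K.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta parameters must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    if rule == "mean":
        # E[omega | bin] via the incomplete-beta identity with (p+1, q)
        upper = betainc(p + 1.0, q, edges[1:])
        lower = betainc(p + 1.0, q, edges[:-1])
        means = (p / (p + q)) * (upper - lower) * K
        omegas = np.clip(means, 0.0, 1.0)
    elif rule == "median":
        omegas = stats.beta.ppf((np.arange(K) + 0.5) / K, p, q)
    else:
        raise ValueError(f"unknown discretization rule {rule!r}")
    weights = np.full(K, 1.0 / K)
    return omegas, weights


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and model settings for :func:`fit_model`."""

    freq_model: str = "F3x4"  # or "equal"
    codon_freqs: np.ndarray | None = None  # explicit empirical-61 override
    n_beta_categories: int = 10
    n_restarts: int = 3
    seed: int = 0
    maxiter: int = 500
    lnl_tol: float = 1e-6
    reoptimize_branch_lengths: bool = False  # mixture models re-fit lengths
    stop_policy: str = "reject"


@dataclass
class SiteModelFit:
    model_id: str
    lnL: float
    kappa: float
    params: dict
    omegas: np.ndarray
    class_weights: np.ndarray
    freqs: np.ndarray
    branch_lengths: np.ndarray
    n_categories: int
    converged: bool
    flags: list = field(default_factory=list)
    n_evaluations: int = 0

    def summary_row(self) -> dict:
        return {
            "model": self.model_id,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "n_categories": self.n_categories,
            "converged": self.converged,
            **{k: v for k, v in self.params.items()},
        }


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    stat: float
    df: int
    p_value: float
    stars: str

    def summary_row(self) -> dict:
        return {
            "null": self.null_model,
            "alt": self.alt_model,
            "2dlnL": self.stat,
            "df": self.df,
            "p_value": self.p_value,
            "stars": self.stars,
        }


def significance_stars(p: float) -> str:
    """Tiered annotation: * p<0.05, ** p<0.001, *** p<0.0001."""
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit, tol: float = 1e-6) -> LRTResult:
    """Likelihood ratio test of nested site models.

    The statistic 2(lnL_alt - lnL_null) is clamped at zero (the alternative
    can fall short of the null only by optimizer noise); p is the
    chi-square upper tail with df = extra parameters.
    """
    key = (null_fit.model_id, alt_fit.model_id)
    if key not in _NESTED_PAIRS:
        raise ValueError(f"{key[0]} is not a supported null for {key[1]}")
    df = _NESTED_PAIRS[key]
    stat = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if stat < 0:
        if stat < -tol:
            # genuine optimizer failure on the alternative; still clamp but flag
            alt_fit.flags.append(f"lnL below null by {-stat / 2:.3g}")
        stat = 0.0
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(null_fit.model_id, alt_fit.model_id, stat, df, p, significance_stars(p))


# ---------------------------------------------------------------------------
# model parameterizations: pack/unpack between optimizer vector and mixture

def _model_classes(model_id: str, theta: np.ndarray, K: int):
    """Map a parameter vector to (omegas, weights, named params)."""
    if model_id == "M0":
        (w,) = theta
        return np.array([w]), np.array([1.0]), {"omega": w}
    if model_id == "M1a":
        p0, w0 = theta
        return (
            np.array([w0, 1.0]),
            np.array([p0, 1.0 - p0]),
            {"p0": p0, "p1": 1.0 - p0, "omega0": w0},
        )
    if model_id == "M2a":
        a0, a1, w0, ws = theta
        p0 = a0
        p1 = (1.0 - a0) * a1
        p2 = (1.0 - a0) * (1.0 - a1)
        return (
            np.array([w0, 1.0, ws]),
            np.array([p0, p1, p2]),
            {"p0": p0, "p1": p1, "p2": p2, "omega0": w0, "omega_s": ws},
        )
    if model_id == "M7":
        p, q = theta
        om, wt = discretize_beta(p, q, K)
        return om, wt, {"p": p, "q": q}
    if model_id == "M8":
        p0, p, q, ws = theta
        om, wt = discretize_beta(p, q, K)
        return (
            np.append(om, ws),
            np.append(wt * p0, 1.0 - p0),
            {"p0": p0, "p1": 1.0 - p0, "p": p, "q": q, "omega_s": ws},
        )
    raise ValueError(f"unknown model {model_id!r}")


def _model_bounds(model_id: str):
    return {
        "M0": [_OMEGA_BOUNDS],
        "M1a": [_PROP_BOUNDS, (1e-4, 1.0)],
        "M2a": [_PROP_BOUNDS, _PROP_BOUNDS, (1e-4, 1.0), _OMEGA_S_BOUNDS],
        "M7": [_BETA_BOUNDS, _BETA_BOUNDS],
        "M8": [_PROP_BOUNDS, _BETA_BOUNDS, _BETA_BOUNDS, _OMEGA_S_BOUNDS],
    }[model_id]


def _default_init(model_id: str):
    return {
        "M0": [0.4],
        "M1a": [0.7, 0.2],
        "M2a": [0.6, 0.8, 0.2, 2.0],
        "M7": [0.5, 1.5],
        "M8": [0.9, 0.5, 1.5, 2.0],
    }[model_id]


def _random_init(model_id: str, rng: np.random.Generator):
    bounds = _model_bounds(model_id)
    out = []
    for lo, hi in bounds:
        if hi > 5:  # rate-like parameter: sample on a modest range
            out.append(rng.uniform(max(lo, 0.05), 3.0))
        else:
            out.append(rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo)))
    return out


def resolve_freqs(alignment: CodonAlignment, config: FitConfig) -> np.ndarray:
    if config.codon_freqs is not None:
        return np.asarray(config.codon_freqs, dtype=float)
    if config.freq_model == "F3x4":
        return f3x4_freqs(alignment.codon_counts())
    if config.freq_model == "equal":
        return equal_codon_freqs()
    raise ValueError(f"unknown codon frequency model {config.freq_model!r}")


def fit_model(
    model_id: str,
    alignment: CodonAlignment,
    tree: PhyloTree,
    config: FitConfig | None = None,
    base_fit: SiteModelFit | None = None,
    init_params: dict | None = None,
) -> SiteModelFit:
    """Maximum-likelihood fit of one site model.

    M0 jointly optimizes kappa, omega and all branch lengths.  The mixture
    models fix branch lengths at the M0 estimates (pass ``base_fit`` to
    reuse one; otherwise M0 is fitted internally first) and optimize kappa
    plus their class parameters, from ``config.n_restarts`` starting
    points.  ``init_params`` seeds an extra deterministic start (e.g. M8
    started from an M7 fit).
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODELS}")
    config = config or FitConfig()
    freqs = resolve_freqs(alignment, config)
    packed = PackedData.build(alignment, tree)
    flags: list[str] = []
    if alignment.is_constant():
        flags.append("unidentifiable: alignment has no variable sites")

    K = config.n_beta_categories
    rng = np.random.default_rng(config.seed)

    optimize_bl = model_id == "M0" or config.reoptimize_branch_lengths
    if model_id != "M0" and base_fit is None and not config.reoptimize_branch_lengths:
        base_fit = fit_model("M0", alignment, tree, config)
    if base_fit is not None and not optimize_bl:
        bl0 = base_fit.branch_lengths
        kappa0 = base_fit.kappa
    else:
        bl0 = np.clip(tree.branch_lengths, 0.01, None)
        kappa0 = 2.0

    edge = tree.edge_nodes()

    def unpack(x):
        kappa = x[0]
        n_theta = len(_model_bounds(model_id))
        theta = x[1 : 1 + n_theta]
        if optimize_bl:
            bl = bl0.copy()
            bl[edge] = x[1 + n_theta :]
        else:
            bl = bl0
        return kappa, theta, bl

    n_eval = 0
    logf_cache: dict = {}

    def negloglik(x):
        nonlocal n_eval
        n_eval += 1
        kappa, theta, bl = unpack(x)
        omegas, weights, _ = _model_classes(model_id, theta, K)
        try:
            if optimize_bl:
                ll = mixture_loglik(
                    packed, None, kappa, omegas, weights, freqs, branch_lengths=bl
                )
            else:
                # branch lengths fixed: cache site likelihoods so repeated
                # evaluations at the same mixture cost nothing
                key = (
                    round(float(kappa), 14),
                    tuple(np.round(omegas, 14)),
                    tuple(np.round(weights, 14)),
                )
                logf = logf_cache.get(key)
                if logf is None:
                    pm = category_matrices(
                        kappa, omegas, freqs, bl, class_weights=weights
                    )
                    logf = site_logliks_by_category(packed, pm, freqs)
                    if len(logf_cache) > 64:
                        logf_cache.clear()
                    logf_cache[key] = logf
                logw = np.log(np.clip(weights, 1e-300, None))
                ll = float(logsumexp(logf + logw[:, None], axis=0) @ packed.weights)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    bounds = [_KAPPA_BOUNDS] + _model_bounds(model_id)
    if optimize_bl:
        bounds += [_BL_BOUNDS] * len(edge)

    # starting points in priority order (warm start, default, random),
    # truncated to n_restarts total
    starts = []
    if init_params is not None:
        x0_warm = [init_params.get("kappa", kappa0)] + [
            init_params[k] for k in _init_keys(model_id)
        ]
        if optimize_bl:
            x0_warm += list(np.clip(bl0[edge], *_BL_BOUNDS))
        starts.append(np.asarray(x0_warm, dtype=float))
    x0 = [kappa0] + list(_default_init(model_id))
    if optimize_bl:
        x0 += list(np.clip(bl0[edge], *_BL_BOUNDS))
    starts.append(np.asarray(x0, dtype=float))
    while len(starts) < max(config.n_restarts, 1):
        xr = [rng.uniform(0.5, 5.0)] + _random_init(model_id, rng)
        if optimize_bl:
            xr += list(np.clip(bl0[edge] * rng.uniform(0.5, 2.0), *_BL_BOUNDS))
        starts.append(np.asarray(xr, dtype=float))
    starts = starts[: max(config.n_restarts, 1)]

    best = None
    any_success = False
    for x_start in starts:
        res = optimize.minimize(
            negloglik,
            np.clip(x_start, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": 1e-10, "eps": 1e-6},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 0.0:
            best = res

    if not any_success and np.isfinite(best.fun):
        # quasi-Newton line searches can fail on finite-difference noise at
        # a genuine optimum; verify (or finish) with a derivative-free polish
        polish = optimize.minimize(
            negloglik,
            best.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": min(150 * len(bounds), 600),
                "fatol": config.lnl_tol,
                "xatol": 1e-7,
            },
        )
        improvement = best.fun - polish.fun
        if polish.fun <= best.fun:
            best = polish
        if polish.success or improvement < 100 * config.lnl_tol:
            any_success = True
            flags.append("converged after derivative-free polish")
        else:
            retry = optimize.minimize(
                negloglik,
                best.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.maxiter, "ftol": 1e-10, "eps": 1e-6},
            )
            if retry.fun <= best.fun:
                gained = best.fun - retry.fun
                best = retry
                if retry.success or gained < 100 * config.lnl_tol:
                    any_success = True
                    flags.append("converged after polish and restart")
    if not any_success:
        flags.append("optimizer did not report convergence after restarts")

    kappa, theta, bl = unpack(best.x)
    omegas, weights, params = _model_classes(model_id, theta, K)
    return SiteModelFit(
        model_id=model_id,
        lnL=-float(best.fun),
        kappa=float(kappa),
        params={k: float(v) for k, v in params.items()},
        omegas=omegas,
        class_weights=weights,
        freqs=freqs,
        branch_lengths=np.asarray(bl, dtype=float),
        n_categories=len(omegas),
        converged=any_success,
        flags=flags,
        n_evaluations=n_eval,
    )


def _init_keys(model_id: str):
    return {
        "M0": ["omega"],
        "M1a": ["p0", "omega0"],
        "M2a": ["a0", "a1", "omega0", "omega_s"],
        "M7": ["p", "q"],
        "M8": ["p0", "p", "q", "omega_s"],
    }[model_id]


def model_loglik(
    model_id: str,
    alignment: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    theta,
    freqs,
    branch_lengths=None,
    K: int = 10,
) -> float:
    """Evaluate (not fit) a site model's log-likelihood at given parameters."""
    omegas, weights, _ = _model_classes(model_id, np.asarray(theta, dtype=float), K)
    return mixture_loglik(
        alignment, tree, kappa, omegas, weights, freqs, branch_lengths=branch_lengths
    )


def fit_site_models(
    alignment: CodonAlignment,
    tree: PhyloTree,
    models=("M0", "M7", "M8"),
    config: FitConfig | None = None,
) -> dict:
    """Fit a set of site models sharing the M0 branch lengths.

    M8 additionally starts from the M7 optimum (with a small positive-class
    proportion), which keeps the nesting lnL(M8) >= lnL(M7) robust.
    """
    config = config or FitConfig()
    fits: dict[str, SiteModelFit] = {}
    m0 = fit_model("M0", alignment, tree, config)
    fits["M0"] = m0
    for mid in models:
        if mid == "M0":
            continue
        init = None
        if mid == "M8" and "M7" in fits:
            m7 = fits["M7"]
            init = {
                "kappa": m7.kappa,
                "p0": 1.0 - 1e-4,
                "p": m7.params["p"],
                "q": m7.params["q"],
                "omega_s": 2.0,
            }
        if mid == "M2a" and "M1a" in fits:
            m1 = fits["M1a"]
            init = {
                "kappa": m1.kappa,
                "a0": m1.params["p0"] * (1.0 - 1e-4),
                "a1": 1.0 - 1e-4,
                "omega0": max(m1.params["omega0"], 1e-3),
                "omega_s": 2.0,
            }
        fit = fit_model(mid, alignment, tree, config, base_fit=m0, init_params=init)
        null_id = {"M8": "M7", "M2a": "M1a"}.get(mid)
        if null_id in fits and fit.lnL < fits[null_id].lnL:
            # the null optimum is itself an admissible point of the
            # alternative; prefer it when the optimizer fell short
            boundary = _boundary_fit(mid, fits[null_id], alignment, tree, config)
            if boundary.lnL >= fit.lnL:
                fit = boundary
        fits[mid] = fit
    return fits


def _boundary_fit(
    model_id: str,
    null_fit: SiteModelFit,
    alignment: CodonAlignment,
    tree: PhyloTree,
    config: FitConfig,
) -> SiteModelFit:
    """Alternative-model fit pinned at the null model's optimum."""
    K = config.n_beta_categories
    if model_id == "M8":
        theta = np.array([1.0, null_fit.params["p"], null_fit.params["q"], 1.0])
    elif model_id == "M2a":
        theta = np.array([null_fit.params["p0"], 1.0, null_fit.params["omega0"], 1.0])
    else:
        raise ValueError(model_id)
    freqs = null_fit.freqs
    lnl = model_loglik(
        model_id,
        alignment,
        tree,
        null_fit.kappa,
        theta,
        freqs,
        branch_lengths=null_fit.branch_lengths,
        K=K,
    )
    omegas, weights, params = _model_classes(model_id, theta, K)
    return SiteModelFit(
        model_id=model_id,
        lnL=float(lnl),
        kappa=null_fit.kappa,
        params={k: float(v) for k, v in params.items()},
        omegas=omegas,
        class_weights=weights,
        freqs=freqs,
        branch_lengths=null_fit.branch_lengths,
        n_categories=len(omegas),
        converged=null_fit.converged,
        flags=["pinned at the null-model boundary (optimizer fell short)"],
    )
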