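"""Bayes empirical Bayes (BEB) site posteriors under the M8 site model.

Given a converged M8 fit, the probability that each codon site belongs to
the positive-selection class (omega_s >= 1) is computed by integrating
over the model's mixture parameters (p0, p, q, omega_s) on a uniform grid,
rather than plugging in the point estimates (the naive empirical Bayes,
NEB, variant — also provided).  Branch lengths, kappa and codon
frequencies stay fixed at their MLEs, and so does the rate normalization,
so the per-omega site likelihoods can be cached across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, PhyloTree
from .codon import CODON_AA, SENSE_CODONS, gy94_generator, mean_rate
from .likelihood import PackedData, category_matrices, site_logliks_by_category
from .models import SiteModelFit, discretize_beta


@dataclass(frozen=True)
class BEBConfig:
    """Grid dimensions and ranges for the BEB integration."""

    n_grid: int = 10
    p0_range: tuple = (0.0, 1.0)
    beta_range: tuple = (0.0, 2.0)  # for both p and q
    omega_s_range: tuple = (1.0, 11.0)
    n_beta_categories: int = 10


@dataclass
class SitePosterior:
    """Per-site posterior of the positive-selection class."""

    p_positive: np.ndarray  # P(site in omega_s class | data)
    mean_omega: np.ndarray  # posterior mean omega per site
    tiers: np.ndarray  # ">=0.99", ">=0.95" or "<0.95"
    method: str  # "BEB" or "NEB"
    class_posteriors: np.ndarray | None = None  # (n_classes, n_sites), NEB only

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(1, self.p_positive.size + 1),
                "p_positive": self.p_positive,
                "mean_omega": self.mean_omega,
                "tier": self.tiers,
            }
        )


def _midpoints(lo: float, hi: float, n: int) -> np.ndarray:
    return lo + (hi - lo) * (np.arange(n) + 0.5) / n


def _tier(p: np.ndarray, thresholds=(0.99, 0.95)) -> np.ndarray:
    hi, lo = thresholds
    return np.where(p >= hi, f">={hi}", np.where(p >= lo, f">={lo}", f"<{lo}"))


def _mle_rate_scale(fit: SiteModelFit) -> float:
    qs = [gy94_generator(fit.kappa, w, fit.freqs, scale=False) for w in fit.omegas]
    rates = np.array([mean_rate(q, fit.freqs) for q in qs])
    return float((fit.class_weights * rates).sum() / fit.class_weights.sum())


def beb_posteriors(
    fit: SiteModelFit,
    alignment: CodonAlignment,
    tree: PhyloTree,
    config: BEBConfig | None = None,
) -> SitePosterior:
    """BEB posterior per site of membership in the omega_s class of M8.

    The prior is uniform over an ``n_grid``-point grid in each of p0,
    p, q (beta shape parameters) and omega_s; grid points are interval
    midpoints.  Posterior grid weights are proportional to the data
    likelihood at each grid point.
    """
    if fit.model_id != "M8":
        raise ValueError("BEB is defined here for M8 fits")
    if not fit.converged:
        raise ValueError("refusing BEB on an unconverged fit")
    config = config or BEBConfig()
    packed = PackedData.build(alignment, tree)
    bl = fit.branch_lengths
    freqs = fit.freqs
    scale = _mle_rate_scale(fit)
    n = config.n_grid
    K = config.n_beta_categories

    p0_grid = _midpoints(*config.p0_range, n)
    pq_grid = _midpoints(*config.beta_range, n)
    ws_grid = _midpoints(*config.omega_s_range, n)

    # cached site likelihoods for the omega_s grid values
    pm_s = category_matrices(fit.kappa, ws_grid, freqs, bl, rate_scale=scale)
    logf_s = site_logliks_by_category(packed, pm_s, freqs)  # (n, npat)

    npat = packed.n_patterns
    wpat = packed.weights
    shift = logf_s.max(axis=0)

    post_num = np.zeros(npat)  # Σ postw * P(class s | pattern)
    mean_num = np.zeros(npat)  # Σ postw * E[omega | pattern]
    log_marg_terms = []  # log L(θ) per grid point (flattened)
    per_point_post = []  # P(s | pattern, θ) per grid point
    per_point_mean = []  # E[omega | pattern, θ] per grid point

    for p in pq_grid:
        for q in pq_grid:
            om_beta, _ = discretize_beta(p, q, K)
            pm_b = category_matrices(fit.kappa, om_beta, freqs, bl, rate_scale=scale)
            logf_b = site_logliks_by_category(packed, pm_b, freqs)  # (K, npat)
            shift_all = np.maximum(shift, logf_b.max(axis=0))
            f_b = np.exp(logf_b - shift_all)  # (K, npat)
            f_s = np.exp(logf_s - shift_all)  # (n, npat)
            mean_fb = f_b.mean(axis=0)  # (npat,)
            mean_fb_om = (om_beta[:, None] * f_b).mean(axis=0)
            for i, p0 in enumerate(p0_grid):
                # (n_ws, npat) mixture likelihood on the shifted scale
                mix = p0 * mean_fb[None, :] + (1.0 - p0) * f_s
                mix = np.clip(mix, 1e-300, None)
                logL = (np.log(mix) + shift_all[None, :]) @ wpat  # (n_ws,)
                post_s = (1.0 - p0) * f_s / mix
                mean_om = (
                    p0 * mean_fb_om[None, :] + (1.0 - p0) * ws_grid[:, None] * f_s
                ) / mix
                log_marg_terms.append(logL)
                per_point_post.append(post_s)
                per_point_mean.append(mean_om)

    logL_all = np.concatenate(log_marg_terms)  # (n^4,) over (p,q,p0,ws)
    logL_all -= logL_all.max()
    gw = np.exp(logL_all)
    gw /= gw.sum()
    idx = 0
    for post_s, mean_om in zip(per_point_post, per_point_mean):
        w = gw[idx : idx + post_s.shape[0]]
        post_num += w @ post_s
        mean_num += w @ mean_om
        idx += post_s.shape[0]

    p_pos = np.clip(post_num, 0.0, 1.0)[packed.site_of_pattern]
    mean_omega = mean_num[packed.site_of_pattern]
    return SitePosterior(p_pos, mean_omega, _tier(p_pos), method="BEB")


def neb_posteriors(
    fit: SiteModelFit, alignment: CodonAlignment, tree: PhyloTree
) -> SitePosterior:
    """Naive empirical Bayes: class posteriors at the MLE parameters only."""
    if not fit.converged:
        raise ValueError("refusing NEB on an unconverged fit")
    packed = PackedData.build(alignment, tree)
    scale = _mle_rate_scale(fit)
    pm = category_matrices(fit.kappa, fit.omegas, fit.freqs, fit.branch_lengths, rate_scale=scale)
    logf = site_logliks_by_category(packed, pm, fit.freqs)
    logw = np.log(np.clip(fit.class_weights, 1e-300, None))
    joint = logf + logw[:, None]
    joint -= joint.max(axis=0, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=0, keepdims=True)
    positive = fit.omegas > 1.0
    p_pos = post[positive].sum(axis=0)[packed.site_of_pattern]
    mean_omega = (fit.omegas @ post)[packed.site_of_pattern]
    return SitePosterior(
        p_pos,
        mean_omega,
        _tier(p_pos),
        method="NEB",
        class_posteriors=post[:, packed.site_of_pattern],
    )


def flag_sites(
    posterior: SitePosterior,
    alignment: CodonAlignment,
    reference_taxon: str,
    thresholds=(0.99, 0.95),
) -> pd.DataFrame:
    """Tiered site report keyed to a reference taxon's residues.

    Sites are labelled in the conventional "23E" style (1-based residue
    index + reference amino acid).  Cysteine columns are marked so the
    conservation of the disulphide skeleton can be inspected.
    """
    if reference_taxon not in alignment.taxa:
        raise ValueError(f"reference taxon {reference_taxon!r} not in alignment")
    hi, lo = thresholds
    row = alignment.taxa.index(reference_taxon)
    codons = alignment.codon_matrix[row]
    aas = np.array([CODON_AA[SENSE_CODONS[c]] if c >= 0 else "-" for c in codons])
    p = posterior.p_positive
    tier = np.where(p >= hi, f">={hi}", np.where(p >= lo, f">={lo}", f"<{lo}"))
    return pd.DataFrame(
        {
            "site": np.arange(1, p.size + 1),
            "ref_aa": aas,
            "label": [f"{i + 1}{a}" for i, a in enumerate(aas)],
            "p_positive": p,
            "mean_omega": posterior.mean_omega,
            "tier": tier,
            "is_cysteine": aas == "C",
        }
    )
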