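"""Codon site-model positive-selection scan (M0/M1a/M2a/M7/M8, LRT, BEB)."""

from __future__ import annotations

import pandas as pd

from .alignment import CodonAlignment, PhyloTree, read_codon_alignment, read_tree
from .beb import BEBConfig, SitePosterior, beb_posteriors, flag_sites, neb_posteriors
from .codon import (
    N_CODONS,
    SENSE_CODONS,
    equal_codon_freqs,
    f3x4_freqs,
    gy94_generator,
)
from .likelihood import PackedData, brute_force_loglik, mixture_loglik, site_logliks
from .models import (
    FitConfig,
    LRTResult,
    SiteModelFit,
    discretize_beta,
    fit_model,
    fit_site_models,
    lrt,
    model_loglik,
    significance_stars,
)

__all__ = [
    "CodonAlignment",
    "PhyloTree",
    "read_codon_alignment",
    "read_tree",
    "BEBConfig",
    "SitePosterior",
    "beb_posteriors",
    "neb_posteriors",
    "flag_sites",
    "N_CODONS",
    "SENSE_CODONS",
    "equal_codon_freqs",
    "f3x4_freqs",
    "gy94_generator",
    "PackedData",
    "brute_force_loglik",
    "mixture_loglik",
    "site_logliks",
    "FitConfig",
    "LRTResult",
    "SiteModelFit",
    "discretize_beta",
    "fit_model",
    "fit_site_models",
    "lrt",
    "model_loglik",
    "significance_stars",
    "positive_selection_scan",
]


def positive_selection_scan(
    alignment: CodonAlignment,
    tree: PhyloTree,
    config: FitConfig | None = None,
    beb_config: BEBConfig | None = None,
    reference_taxon: str | None = None,
):
    """Full scan of one gene: M0 + M7 vs M8, LRT, and BEB site posteriors.

    Returns a dict with the fitted models, the LRT, the site posterior
    (BEB, computed only when M7 is rejected at p < 0.05, mirroring common
    reporting practice; ``posterior`` is None otherwise) and a per-gene
    summary row in the layout of a selection-scan results table.
    """
    fits = fit_site_models(alignment, tree, models=("M0", "M7", "M8"), config=config)
    test = lrt(fits["M7"], fits["M8"])
    posterior = None
    sites = None
    if test.p_value < 0.05:
        posterior = beb_posteriors(fits["M8"], alignment, tree, beb_config)
        ref = reference_taxon or alignment.taxa[0]
        sites = flag_sites(posterior, alignment, ref)
    m8 = fits["M8"]
    summary = {
        "n_seqs": alignment.n_taxa,
        "n_codons": alignment.n_codons,
        "omega_M0": fits["M0"].params["omega"],
        "2dlnL_M7_M8": test.stat,
        "p_value": test.p_value,
        "stars": test.stars,
        "p1_M8": m8.params["p1"],
        "omega_s_M8": m8.params["omega_s"],
        "n_sites_p99": 0 if sites is None else int((sites.p_positive >= 0.99).sum()),
        "n_sites_p95": 0 if sites is None else int((sites.p_positive >= 0.95).sum()),
    }
    return {
        "fits": fits,
        "lrt": test,
        "posterior": posterior,
        "sites": sites,
        "summary": pd.Series(summary),
    }
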