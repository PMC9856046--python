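"""One-configuration synthetic pipeline: simulate -> analyse -> report.

Runs every stage of the toolkit on generator output with known ground
truth and collects the headline numbers of each stage into one plain
dictionary (JSON-serializable, deterministic under the seed).  Serves as
the reproducibility entry point and as a worked example of the API.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enrich import fisher_enrich, report_filter
from .expression import classify_specificity, median_of_ratios
from .grammar import classify_protein, load_class_definitions, match_pattern
from .proteome import psm_fdr
from .selection import (
    FitConfig,
    beb_posteriors,
    equal_codon_freqs,
    fit_site_models,
    lrt,
)
from .simulate import (
    gen_annotation_table,
    gen_crp_proteins,
    gen_expression_matrix,
    gen_psm_table,
    random_tree,
    sim_codon_alignment,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Problem sizes for the synthetic end-to-end run."""

    n_per_class: int = 40
    n_taxa: int = 8
    n_codons: int = 120
    positive_fraction: float = 0.2
    positive_omega: float = 4.0
    background_omega: float = 0.2
    kappa: float = 2.0
    n_psm: int = 2000
    n_genes: int = 200
    n_restarts: int = 1


def run_synthetic_pipeline(seed: int, config: PipelineConfig | None = None) -> dict:
    """Simulate every input type, run the full analysis, report key numbers."""
    config = config or PipelineConfig()
    out: dict = {"seed": int(seed)}

    # --- CRP grammar: generate, classify, knockout-reject ---------------
    defs = load_class_definitions()
    recs, truth = gen_crp_proteins(defs, config.n_per_class, seed=seed)
    correct = sum(
        classify_protein(r, defs).primary_class == c
        for r, c in zip(recs, truth.class_id)
    )
    kos, ko_truth = gen_crp_proteins(
        defs, config.n_per_class, seed=seed + 1, knockouts=True
    )
    by_id = {d.class_id: d for d in defs}
    rejected = sum(
        not match_pattern(by_id[c].envelope, r.sequence)
        for r, c in zip(kos, ko_truth.class_id)
    )
    out["crp_classification_accuracy_pct"] = 100.0 * correct / len(recs)
    out["crp_knockout_rejection_pct"] = 100.0 * rejected / len(kos)

    # --- positive-selection scan on a planted-site alignment ------------
    freqs = equal_codon_freqs()
    tree = random_tree(config.n_taxa, seed=seed + 2, mean_branch=0.15)
    aln, site_class = sim_codon_alignment(
        tree,
        config.kappa,
        [config.background_omega, config.positive_omega],
        [1.0 - config.positive_fraction, config.positive_fraction],
        freqs,
        config.n_codons,
        seed=seed + 3,
    )
    fits = fit_site_models(
        aln, tree, config=FitConfig(n_restarts=config.n_restarts, seed=seed)
    )
    test = lrt(fits["M7"], fits["M8"])
    out["m0_omega"] = round(fits["M0"].params["omega"], 6)
    out["m7_vs_m8_2dlnl"] = round(test.stat, 4)
    out["m7_vs_m8_p_value"] = float(test.p_value)
    out["m8_omega_s"] = round(fits["M8"].params["omega_s"], 4)
    out["m8_positive_proportion_pct"] = round(100.0 * fits["M8"].params["p1"], 3)
    post = beb_posteriors(fits["M8"], aln, tree)
    flagged = post.p_positive >= 0.95
    truly = site_class == 1
    out["beb_sites_flagged_095"] = int(flagged.sum())
    out["beb_precision_at_095"] = (
        round(float((flagged & truly).sum() / flagged.sum()), 4)
        if flagged.any()
        else None
    )

    # --- PSM confidence tiers --------------------------------------------
    psms = gen_psm_table(config.n_psm, config.n_psm, seed=seed + 4)
    scored = psm_fdr(psms)
    targets = scored[~scored.is_decoy]
    accepted = targets[targets.q_value <= 0.05]
    out["psm_high_tier_n"] = int((targets.tier == "high").sum())
    out["psm_medium_tier_n"] = int((targets.tier == "medium").sum())
    out["psm_empirical_fdr_at_5pct"] = round(
        float(1.0 - accepted.is_true_match.mean()), 4
    )

    # --- expression specificity ------------------------------------------
    counts, roles, expr_truth = gen_expression_matrix(
        n_genes=config.n_genes, n_specific=config.n_genes // 6, seed=seed + 5
    )
    _, norm = median_of_ratios(counts, pseudo_reference=True)
    cats = classify_specificity(norm, roles)
    called = (cats.category == "mature-anther-specific").to_numpy()
    planted = expr_truth.is_specific.to_numpy()
    out["expression_specific_recall_pct"] = round(
        100.0 * float(called[planted].mean()), 2
    )
    out["expression_specific_false_calls"] = int(called[~planted].sum())

    # --- term enrichment ---------------------------------------------------
    ann, sample, ann_truth = gen_annotation_table(seed=seed + 6)
    res = fisher_enrich(sample, ann)
    kept = set(report_filter(res).term)
    planted_terms = set(ann_truth[ann_truth.is_enriched].term)
    out["enrichment_planted_recovered_n"] = len(kept & planted_terms)
    out["enrichment_planted_total_n"] = len(planted_terms)
    out["enrichment_false_positive_n"] = len(kept - planted_terms)

    return out
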