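"""Site-model fitting, nesting, LRT calibration points and BEB posteriors."""

import numpy as np
import pytest
from scipy import stats

from pollencrp.selection import (
    BEBConfig,
    CodonAlignment,
    FitConfig,
    beb_posteriors,
    discretize_beta,
    fit_model,
    fit_site_models,
    flag_sites,
    lrt,
    model_loglik,
    neb_posteriors,
    significance_stars,
)
from pollencrp.selection.models import SiteModelFit, _model_classes
from pollencrp.simulate import random_tree, sim_codon_alignment


@pytest.fixture(scope="module")
def fitted_scan(uniform_freqs):
    """One shared small positive-selection dataset with M0/M7/M8 fits."""
    tree = random_tree(6, seed=40, mean_branch=0.15)
    aln, classes = sim_codon_alignment(
        tree, kappa=2.0, omegas=[0.2, 4.0], class_weights=[0.7, 0.3],
        freqs=uniform_freqs, n_sites=120, seed=41,
    )
    fits = fit_site_models(aln, tree, config=FitConfig(n_restarts=1))
    return tree, aln, classes, fits


class TestFitModel:
    def test_m0_recovers_omega_on_simulated_data(self, uniform_freqs):
        tree = random_tree(6, seed=30, mean_branch=0.15)
        aln, _ = sim_codon_alignment(
            tree, 2.0, [0.3], [1.0], uniform_freqs, 200, seed=31
        )
        fit = fit_model("M0", aln, tree, FitConfig(n_restarts=1))
        assert fit.converged
        assert fit.params["omega"] == pytest.approx(0.3, abs=0.15)
        assert fit.kappa == pytest.approx(2.0, abs=1.0)

    def test_constant_alignment_flagged_unidentifiable(self, uniform_freqs):
        tree = random_tree(4, seed=1)
        aln = CodonAlignment(tree.taxa, ("ATGGCT",) * 4)
        fit = fit_model("M0", aln, tree, FitConfig(n_restarts=1, maxiter=20))
        assert any("unidentifiable" in f for f in fit.flags)

    def test_unknown_model_rejected(self, small_alignment, small_tree):
        with pytest.raises(ValueError):
            fit_model("M99", small_alignment, small_tree)

    def test_class_weights_sum_to_one(self, fitted_scan):
        _, _, _, fits = fitted_scan
        for f in fits.values():
            assert f.class_weights.sum() == pytest.approx(1.0)
            assert np.isfinite(f.lnL)


class TestNesting:
    def test_m8_at_p1_zero_equals_m7(self, fitted_scan, uniform_freqs):
        tree, aln, _, fits = fitted_scan
        m7 = fits["M7"]
        bl = fits["M0"].branch_lengths
        l7 = model_loglik(
            "M7", aln, tree, m7.kappa, [m7.params["p"], m7.params["q"]],
            m7.freqs, branch_lengths=bl,
        )
        l8 = model_loglik(
            "M8", aln, tree, m7.kappa, [1.0, m7.params["p"], m7.params["q"], 5.0],
            m7.freqs, branch_lengths=bl,
        )
        assert l8 == pytest.approx(l7, abs=1e-6)

    def test_alternative_never_below_null(self, fitted_scan):
        _, _, _, fits = fitted_scan
        assert fits["M8"].lnL >= fits["M7"].lnL - 1e-9

    def test_m1a_m2a_nesting_and_fit(self, uniform_freqs):
        tree = random_tree(5, seed=50, mean_branch=0.12)
        aln, _ = sim_codon_alignment(
            tree, 2.0, [0.1, 1.0], [0.6, 0.4], uniform_freqs, 80, seed=51
        )
        fits = fit_site_models(
            aln, tree, models=("M1a", "M2a"), config=FitConfig(n_restarts=1)
        )
        assert fits["M2a"].lnL >= fits["M1a"].lnL - 1e-9
        test = lrt(fits["M1a"], fits["M2a"])
        assert test.df == 2 and 0.0 <= test.p_value <= 1.0


class TestLRT:
    def test_equal_likelihood_gives_p_one(self):
        a = _dummy_fit("M7", -100.0)
        b = _dummy_fit("M8", -100.0)
        res = lrt(a, b)
        assert res.stat == 0.0 and res.p_value == 1.0 and res.stars == ""

    def test_published_statistic_tiers(self):
        """Survival values at two published 2dlnL statistics match their
        printed star tiers (one star for 7.191, three for 74.217)."""
        p1 = stats.chi2.sf(7.191, 2)
        p3 = stats.chi2.sf(74.217, 2)
        res1 = lrt(_dummy_fit("M7", 0.0), _dummy_fit("M8", 7.191 / 2))
        res3 = lrt(_dummy_fit("M7", 0.0), _dummy_fit("M8", 74.217 / 2))
        assert res1.p_value == pytest.approx(p1, rel=1e-12)
        assert 0.001 < res1.p_value <= 0.05 and res1.stars == "*"
        assert res3.p_value == pytest.approx(p3, rel=1e-9)
        assert res3.p_value < 1e-15 and res3.stars == "***"

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.0005) == "**"
        assert significance_stars(5e-5) == "***"
        assert significance_stars(0.2) == ""
        assert significance_stars(0.05) == ""

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError):
            lrt(_dummy_fit("M8", -10), _dummy_fit("M7", -9))


class TestBEB:
    def test_posteriors_in_range_and_flagging(self, fitted_scan):
        tree, aln, classes, fits = fitted_scan
        post = beb_posteriors(fits["M8"], aln, tree, BEBConfig())
        assert post.p_positive.shape == (aln.n_codons,)
        assert np.all((post.p_positive >= 0) & (post.p_positive <= 1))
        assert np.all(post.mean_omega >= 0)
        report = flag_sites(post, aln, aln.taxa[0])
        assert len(report) == aln.n_codons
        assert set(report.tier) <= {">=0.99", ">=0.95", "<0.95"}
        # flagged sites should be mostly truly positive on this easy dataset
        flagged = post.p_positive >= 0.95
        if flagged.sum() >= 5:
            precision = (flagged & (classes == 1)).sum() / flagged.sum()
            assert precision >= 0.6

    def test_neb_class_posteriors_normalized(self, fitted_scan):
        tree, aln, _, fits = fitted_scan
        post = neb_posteriors(fits["M8"], aln, tree)
        assert np.allclose(post.class_posteriors.sum(axis=0), 1.0, atol=1e-9)

    def test_unconverged_fit_refused(self, fitted_scan):
        tree, aln, _, fits = fitted_scan
        bad = _dummy_fit("M8", -1.0)
        bad.converged = False
        with pytest.raises(ValueError):
            beb_posteriors(bad, aln, tree)

    def test_absent_reference_taxon_rejected(self, fitted_scan):
        tree, aln, _, fits = fitted_scan
        post = neb_posteriors(fits["M8"], aln, tree)
        with pytest.raises(ValueError):
            flag_sites(post, aln, "not-a-taxon")

    def test_extreme_thresholds_select_only_certain_sites(self, fitted_scan):
        tree, aln, _, fits = fitted_scan
        post = neb_posteriors(fits["M8"], aln, tree)
        report = flag_sites(post, aln, aln.taxa[0], thresholds=(1.0, 1.0))
        top = report[report.tier == ">=1.0"]
        assert (top.p_positive >= 1.0).all()


def _dummy_fit(model_id: str, lnl: float) -> SiteModelFit:
    from pollencrp.selection import equal_codon_freqs

    K = 10
    theta = {
        "M7": np.array([0.5, 1.5]),
        "M8": np.array([0.9, 0.5, 1.5, 2.0]),
    }[model_id]
    omegas, weights, params = _model_classes(model_id, theta, K)
    return SiteModelFit(
        model_id=model_id,
        lnL=lnl,
        kappa=2.0,
        params={k: float(v) for k, v in params.items()},
        omegas=omegas,
        class_weights=weights,
        freqs=equal_codon_freqs(),
        branch_lengths=np.array([0.1]),
        n_categories=len(omegas),
        converged=True,
    )
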