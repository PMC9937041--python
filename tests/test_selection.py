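"""Site and branch-site positive-selection models."""

import numpy as np
import pytest
from dataclasses import replace

from ponevo.phylo_engine import PhyloTree
from ponevo.selection_tests import (
    ModelFit,
    SiteClassModel,
    branch_site_lrt,
    fit_branch_site,
    fit_site_model,
    identify_selected_sites,
    site_model_lrt,
)
from ponevo.selection_tests import _CodonMixtureEvaluator
from ponevo.synthetic_data import SimulationSpec, simulate_alignment


@pytest.fixture(scope="module")
def marked_tree():
    return PhyloTree.from_newick(
        "(((a#1:0.2,b#1:0.2)#1:0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"
    )


@pytest.fixture(scope="module")
def m1a_alignment(marked_tree):
    truth = SiteClassModel("M1a", kappa=3.0, p0=0.7, omega0=0.2)
    aln, _ = simulate_alignment(SimulationSpec(marked_tree, truth, 400, 31))
    return aln


class TestSiteClassModel:
    def test_proportions_sum_to_one_for_every_family(self):
        models = [
            SiteClassModel("M0", omega=0.5),
            SiteClassModel("M1a", p0=0.6, omega0=0.3),
            SiteClassModel("M2a", p0=0.5, p1=0.3, omega0=0.3, omega2=2.5),
            SiteClassModel("M7", beta_p=0.4, beta_q=1.2),
            SiteClassModel("M8", p0=0.9, beta_p=0.4, beta_q=1.2, omega2=3.0),
            SiteClassModel("BranchSiteA", p0=0.5, p1=0.3, omega0=0.3, omega2=2.0),
            SiteClassModel("BranchSiteA_null", p0=0.5, p1=0.3, omega0=0.3),
        ]
        for m in models:
            props = m.class_proportions()
            assert props.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(props >= 0)
            bg, fg = m.class_omegas()
            assert len(bg) == len(fg) == len(props)

    def test_branch_site_null_pins_foreground_omega_to_one(self):
        m = SiteClassModel("BranchSiteA_null", p0=0.5, p1=0.3, omega0=0.3,
                           omega2=7.0)
        _, fg = m.class_omegas()
        assert fg[2] == fg[3] == 1.0

    def test_constraint_domains_enforced(self):
        with pytest.raises(ValueError, match="omega0"):
            SiteClassModel("M1a", omega0=1.5)
        with pytest.raises(ValueError, match="omega2"):
            SiteClassModel("M2a", p0=0.5, p1=0.3, omega0=0.3, omega2=0.5)

    def test_selection_classes_and_proportion(self):
        m = SiteClassModel("BranchSiteA", p0=0.6, p1=0.2, omega0=0.2, omega2=4.0)
        assert m.selection_class_indices == [2, 3]
        assert m.proportion_under_selection == pytest.approx(0.2)


class TestNesting:
    def test_m2a_with_vanishing_selection_class_equals_m1a(self, marked_tree,
                                                           m1a_alignment):
        fit1 = fit_site_model(m1a_alignment, marked_tree, "M1a", tol=1e-3)
        ev = _CodonMixtureEvaluator(m1a_alignment, fit1.tree)
        m2 = replace(
            fit1.model, family="M2a",
            p0=fit1.model.p0 * (1 - 1e-9),
            p1=(1 - fit1.model.p0) * (1 - 1e-9),
            omega2=2.0,
        )
        ll = ev.loglik(m2, fit1.tree.lengths)
        assert ll == pytest.approx(fit1.log_likelihood, abs=1e-4)

    def test_alternative_with_omega2_forced_to_one_equals_null(self, marked_tree,
                                                               m1a_alignment):
        null = fit_branch_site(
            m1a_alignment, marked_tree, null=True, tol=1e-3,
            fixed_branch_lengths=marked_tree.lengths,
        )
        ev = _CodonMixtureEvaluator(m1a_alignment, null.tree)
        forced = replace(null.model, family="BranchSiteA", omega2=1.0)
        ll = ev.loglik(forced, null.tree.lengths)
        assert ll == pytest.approx(null.log_likelihood, abs=1e-4)

    def test_alternative_log_likelihood_dominates_null(self, marked_tree,
                                                       m1a_alignment):
        null = fit_branch_site(
            m1a_alignment, marked_tree, null=True, tol=1e-3,
            fixed_branch_lengths=marked_tree.lengths,
        )
        alt = fit_branch_site(
            m1a_alignment, marked_tree, null=False, tol=1e-3,
            init_model=null.model, fixed_branch_lengths=marked_tree.lengths,
        )
        assert alt.log_likelihood >= null.log_likelihood - 1e-4
        rec = branch_site_lrt(null, alt)
        assert rec.df == 1
        assert 0 <= rec.p_value <= 1

    def test_mismatched_lrt_pairs_rejected(self, marked_tree, m1a_alignment):
        m1a = fit_site_model(m1a_alignment, marked_tree, "M1a", tol=1e-2,
                             max_rounds=2)
        with pytest.raises(ValueError, match="nested"):
            site_model_lrt(m1a, m1a)


class TestPosteriors:
    def test_neb_matches_brute_force_bayes_rule(self, marked_tree, m1a_alignment):
        fit = fit_site_model(m1a_alignment, marked_tree, "M1a", tol=1e-3)
        post = fit.site_posteriors
        assert np.abs(post.sum(axis=0) - 1.0).max() < 1e-9
        # direct Bayes rule from the stored per-class likelihoods
        props = fit.model.class_proportions()
        lik = np.exp(fit.class_log_likelihoods - fit.class_log_likelihoods.max(0))
        expected = (props[:, None] * lik) / (props[:, None] * lik).sum(axis=0)
        assert np.abs(post - expected).max() < 1e-8

    def test_no_selection_class_yields_empty_site_list(self, marked_tree,
                                                       m1a_alignment):
        fit = fit_site_model(m1a_alignment, marked_tree, "M1a", tol=1e-2,
                             max_rounds=2)
        assert identify_selected_sites(fit, 0.5, "NEB") == []
        assert identify_selected_sites(fit, 0.5, "BEB") == []

    def test_threshold_outside_unit_interval_rejected(self, marked_tree,
                                                      m1a_alignment):
        fit = fit_site_model(m1a_alignment, marked_tree, "M1a", tol=1e-2,
                             max_rounds=2)
        with pytest.raises(ValueError, match="threshold"):
            identify_selected_sites(fit, 1.5)

    def test_beb_recovers_planted_branch_site_selection(self, marked_tree):
        truth = SiteClassModel(
            "BranchSiteA", kappa=2.0, p0=0.66, p1=0.22, omega0=0.2, omega2=5.0
        )
        aln, truth_table = simulate_alignment(
            SimulationSpec(marked_tree, truth, 500, 41)
        )
        m0 = fit_site_model(aln, marked_tree, "M0", tol=1e-2, max_rounds=3)
        alt = fit_branch_site(
            aln, marked_tree, null=False, fixed_branch_lengths=m0.tree.lengths,
            tol=1e-3,
        )
        hits = identify_selected_sites(alt, 0.5, "BEB")
        assert hits, "no sites identified despite strong planted selection"
        true_sel = set(truth_table["selected_sites"])
        called = {i for i, _ in hits}
        # precision: most confidently-called sites are truly selected
        precision = len(called & true_sel) / len(called)
        assert precision >= 0.6
        # NEB and BEB broadly agree on this clear-cut signal
        neb = {i for i, _ in identify_selected_sites(alt, 0.5, "NEB")}
        overlap = len(neb & called) / max(1, len(neb | called))
        assert overlap > 0.5


class TestBranchSiteRequirements:
    def test_unmarked_tree_rejected(self, m1a_alignment):
        bare = PhyloTree.from_newick(
            "(((a:0.2,b:0.2):0.1,c:0.3):0.1,(d:0.2,e:0.2):0.15,f:0.4);"
        )
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_site(m1a_alignment, bare)

    def test_protein_alignment_rejected(self, marked_tree):
        from ponevo.phylo_engine import Alignment

        aln = Alignment(["a", "b", "c", "d", "e", "f"], ["AR"] * 6)
        with pytest.raises(ValueError, match="codon"):
            fit_site_model(aln, marked_tree, "M0")


def test_m7_discretization_converges_with_bin_count(marked_tree, m1a_alignment):
    ev = _CodonMixtureEvaluator(m1a_alignment, marked_tree)
    freqs = m1a_alignment.empirical_codon_frequencies()
    base = SiteClassModel(
        "M7", kappa=2.5, codon_frequencies=freqs, beta_p=0.4, beta_q=1.3,
        k_beta=10,
    )
    lls = {
        k: ev.loglik(replace(base, k_beta=k), marked_tree.lengths)
        for k in (5, 10, 20, 50, 100)
    }
    gaps = [
        abs(lls[b] - lls[a])
        for a, b in ((5, 10), (10, 20), (20, 50), (50, 100))
    ]
    # refinement gaps shrink monotonically toward the continuous limit
    assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-2
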