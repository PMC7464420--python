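import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from greyscan.bayescan_engine import (
    LocusPosterior,
    MCMCConfig,
    beta_binomial_loglik,
    compute_q_values,
    fst_from_effects,
    run_mcmc,
    significant_loci,
)
from greyscan.genotype_io import AlleleCountTable, LocusInfo

from _oracles import grid_posterior, qvalues_bruteforce


def _table(a, n, ids=None):
    a = np.asarray(a)
    ids = ids or [f"s{i}" for i in range(a.shape[0])]
    loci = [LocusInfo("1", s, 100 + i) for i, s in enumerate(ids)]
    return AlleleCountTable(populations=["A", "B"], loci=loci, a=a, n=np.asarray(n))


class TestFstFromEffects:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(0.0, 0.0, 0.5), (-2.0, 0.0, 1 / (1 + math.e**2)), (1.0, -1.0, 0.5)],
    )
    def test_logistic_values(self, alpha, beta, expected):
        assert fst_from_effects(alpha, beta) == pytest.approx(expected, rel=1e-12)


class TestBetaBinomialLoglik:
    def test_empty_data_has_likelihood_one(self):
        assert beta_binomial_loglik(0, 0, 0.3, 2.0) == 0.0

    def test_exact_beta_function_ratio(self):
        # C(2,1) * B(1+1, 1+1) / B(1, 1) = 2 * (1/6) / 1 = 1/3
        assert beta_binomial_loglik(1, 2, 0.5, 2.0) == pytest.approx(
            math.log(1 / 3), abs=1e-12
        )

    def test_large_theta_approaches_binomial(self):
        for a, n, p in [(1, 2, 0.5), (3, 10, 0.2), (0, 6, 0.7)]:
            assert beta_binomial_loglik(a, n, p, 1e6) == pytest.approx(
                binom.logpmf(a, n, p), abs=1e-4
            )

    @pytest.mark.parametrize(
        "a,n,p,theta", [(-1, 2, 0.5, 1.0), (3, 2, 0.5, 1.0), (1, 2, 0.0, 1.0), (1, 2, 0.5, 0.0)]
    )
    def test_domain_errors(self, a, n, p, theta):
        with pytest.raises(ValueError):
            beta_binomial_loglik(a, n, p, theta)


class TestQValues:
    def test_cumulative_means(self):
        np.testing.assert_allclose(
            compute_q_values([0.01, 0.03, 0.20]), [0.01, 0.02, 0.08]
        )

    def test_all_equal_peps_share_q(self):
        np.testing.assert_allclose(compute_q_values([0.3] * 5), [0.3] * 5)

    def test_empty(self):
        assert compute_q_values([]).size == 0

    def test_order_restored(self):
        q = compute_q_values([0.20, 0.01, 0.03])
        np.testing.assert_allclose(q, [0.08, 0.01, 0.02])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=100
        )
    )
    def test_matches_bruteforce_and_bounds(self, peps):
        peps = np.asarray(peps, dtype=float)
        q = compute_q_values(peps)
        np.testing.assert_allclose(q, qvalues_bruteforce(peps), atol=1e-12)
        assert q.min() >= peps.min() - 1e-12 and q.max() <= peps.max() + 1e-12
        # non-decreasing along increasing pep rank
        order = np.argsort(peps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSignificantLoci:
    def _post(self, q):
        return [
            LocusPosterior(f"s{i}", 0.5, 0.5, qi, 0.0, 0.2) for i, qi in enumerate(q)
        ]

    def test_strict_inequality_at_threshold(self):
        sig = significant_loci(self._post([0.049, 0.05, 0.2]))
        assert sig == {"s0"}

    def test_empty_input(self):
        assert significant_loci([]) == set()


class TestRunMcmc:
    def test_posterior_matches_grid_quadrature(self, short_chain):
        """Sampler agrees with dense-quadrature posteriors on tiny instances."""
        a = np.array([[1, 3], [0, 4]])
        n = np.array([[4, 4], [4, 4]])
        gamma_oracle, beta_oracle = grid_posterior(a, n)
        cfg = MCMCConfig(
            n_pilot=6, pilot_length=400, burn_in=2000, n_samples=30000, thinning=1,
            seed=11,
        )
        post = run_mcmc(_table(a, n), cfg)
        gamma = np.array([p.gamma for p in post])
        np.testing.assert_allclose(gamma, gamma_oracle, atol=0.03)
        np.testing.assert_allclose(run_mcmc.last_beta_mean, beta_oracle, atol=0.05)

    def test_duplicated_locus_rows_agree(self):
        a = np.array([[10, 2], [10, 2]])
        n = np.array([[24, 24], [24, 24]])
        cfg = MCMCConfig(
            n_pilot=5, pilot_length=300, burn_in=1000, n_samples=20000, thinning=1,
            seed=3,
        )
        post = run_mcmc(_table(a, n), cfg)
        assert post[0].gamma == pytest.approx(post[1].gamma, abs=0.03)

    def test_allele_relabel_symmetry(self):
        a = np.array([[20, 3], [5, 9]])
        n = np.array([[24, 24], [24, 24]])
        cfg = MCMCConfig(
            n_pilot=5, pilot_length=300, burn_in=1000, n_samples=20000, thinning=1,
            seed=5,
        )
        g1 = [p.gamma for p in run_mcmc(_table(a, n), cfg)]
        g2 = [p.gamma for p in run_mcmc(_table(np.asarray(n) - a, n), cfg)]
        np.testing.assert_allclose(g1, g2, atol=0.03)

    def test_locus_order_permutation_is_exact(self, short_chain):
        a = np.array([[1, 3], [0, 4], [2, 2]])
        n = np.array([[4, 4], [4, 4], [4, 4]])
        ids = ["sA", "sB", "sC"]
        post1 = {p.snp_id: p.gamma for p in run_mcmc(_table(a, n, ids), short_chain)}
        perm = [2, 0, 1]
        post2 = {
            p.snp_id: p.gamma
            for p in run_mcmc(
                _table(a[perm], np.asarray(n)[perm], [ids[i] for i in perm]),
                short_chain,
            )
        }
        assert post1 == post2

    def test_monomorphic_locus_reported_neutral(self, short_chain):
        a = np.array([[0, 0], [3, 9]])
        n = np.array([[8, 8], [8, 16]])
        post = run_mcmc(_table(a, n), short_chain)
        assert post[0].gamma == 0.0 and post[0].pep == 1.0
        assert "s0" not in significant_loci(post, q_threshold=1.0 - 1e-9)

    def test_deterministic_given_seed(self, short_chain):
        a = np.array([[5, 1]])
        n = np.array([[8, 8]])
        p1 = run_mcmc(_table(a, n), short_chain)
        p2 = run_mcmc(_table(a, n), short_chain)
        assert p1[0].gamma == p2[0].gamma and p1[0].alpha_mean == p2[0].alpha_mean

    def test_requires_two_populations(self, short_chain):
        loci = [LocusInfo("1", "s0", 100)]
        tab = AlleleCountTable(
            populations=["A"], loci=loci, a=np.array([[1]]), n=np.array([[4]])
        )
        with pytest.raises(ValueError):
            run_mcmc(tab, short_chain)


class TestCalibrationAndPower:
    def test_neutral_fdr_calibration_small(self, short_chain):
        """Under the neutral model no excess of q < 0.05 calls appears."""
        from greyscan.genotype_io import allele_counts
        from greyscan.synthetic_data import SyntheticConfig, simulate_dataset

        cfg = SyntheticConfig(
            n_grey=1, n_reference=1, n_loci=300, frac_selected=0.0, seed=21
        )
        ds, _ = simulate_dataset(cfg)
        post = run_mcmc(allele_counts(ds, ["GREY01", "REF01"]), short_chain)
        frac = len(significant_loci(post)) / len(post)
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / len(post))

    def test_power_increases_with_selection_strength(self):
        """Mean posterior inclusion at selected loci grows with the locus
        effect over the non-saturated range."""
        from greyscan.genotype_io import allele_counts
        from greyscan.synthetic_data import SyntheticConfig, simulate_dataset

        mc = MCMCConfig(
            n_pilot=4, pilot_length=300, burn_in=1000, n_samples=1500, thinning=1,
            seed=7,
        )
        means = []
        for alpha in (0.5, 1.5, 2.5):
            gammas = []
            for seed in (31, 32):
                cfg = SyntheticConfig(
                    n_grey=1, n_reference=1, n_loci=300, frac_selected=0.05,
                    alpha_selected=alpha, seed=seed,
                )
                ds, truth = simulate_dataset(cfg)
                post = run_mcmc(allele_counts(ds, ["GREY01", "REF01"]), mc)
                gammas += [post[l].gamma for l in np.flatnonzero(truth.selected)]
            means.append(np.mean(gammas))
        assert means[0] < means[1] <= means[2] + 0.02
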