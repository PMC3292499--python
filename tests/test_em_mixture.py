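import numpy as np
import pytest

import tdthet.em_mixture as em_module
from tdthet.em_mixture import (
    EMSettings,
    MixtureParams,
    TrioCounts,
    _fit_h1_batch,
    e_step,
    fit_h0,
    fit_h1,
    linked_decision,
    loglik,
    m_step,
    tdt_het,
    tdt_het_statistics,
)
from tdthet.genetic_model import (
    GeneticModel,
    HET_CELLS,
    TRIO_INDEX,
    TRIO_LABELS,
    hwe_mating_freqs,
    kernel_g,
    linked_trio_distribution,
)


def naive_loglik(counts, params):
    """Independent term-by-term summation oracle."""
    total = 0.0
    g1 = kernel_g(params.t)
    g0 = kernel_g(0.5)
    mu_by_cell = params.mu[[5, 4, 4, 3, 3, 3, 2, 1, 1, 0]]
    for i in range(10):
        n = counts.counts[i]
        if n == 0:
            continue
        prob = mu_by_cell[i] * (params.pi1 * g1[i] + (1 - params.pi1) * g0[i])
        if prob <= 0:
            return -np.inf
        total += n * np.log(prob)
    return total


def grid_search_ll(counts, two_stage=True):
    """Brute-force (t, pi1) maximization of the mu-free partial likelihood,
    reported on the full-likelihood scale (observed-frequency mu)."""
    n7 = counts.counts[HET_CELLS].astype(float)
    g0 = kernel_g(0.5)[HET_CELLS]

    def surface(tg, pg):
        T, P = np.meshgrid(tg, pg, indexing="ij")
        u = 1 - T
        G = np.stack([u, T, u * u, 2 * T * u, T * T, u, T], axis=-1)
        mix = np.maximum(P[..., None] * G + (1 - P)[..., None] * g0, 1e-300)
        return (np.log(mix) * n7).sum(-1)

    tg = np.linspace(0, 1, 201)
    pg = np.linspace(0, 1, 201)
    ll = surface(tg, pg)
    i, j = np.unravel_index(ll.argmax(), ll.shape)
    best = ll[i, j]
    if two_stage:
        tg2 = np.clip(np.linspace(tg[i] - 0.005, tg[i] + 0.005, 201), 0, 1)
        pg2 = np.clip(np.linspace(pg[j] - 0.005, pg[j] + 0.005, 201), 0, 1)
        best = surface(tg2, pg2).max()
    # add the mu part shared by H0 and H1
    h0_mixfree = float(n7 @ np.log(g0))
    return best + (fit_h0(counts) - h0_mixfree)


def penalized_ll(counts, params, c):
    pen = 0.0
    if c > 0:
        pen = c * sum(
            np.log(v)
            for v in (params.t, 1 - params.t, params.pi1, 1 - params.pi1)
        )
    return loglik(counts, params) + pen


class TestTrioCounts:
    def test_from_dict_reorders_parents(self):
        c = TrioCounts.from_dict({(0, 1, 1): 3})
        assert c.counts[TRIO_INDEX[(1, 0, 1)]] == 3

    def test_rejects_negative_and_wrong_shape(self):
        with pytest.raises(ValueError):
            TrioCounts(np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            TrioCounts(np.array([-1, 0, 0, 0, 0, 0, 0, 0, 0, 0]))

    def test_mirror_is_involution(self, random_counts):
        c = random_counts(seed=5)
        assert np.array_equal(c.mirror().mirror().counts, c.counts)

    def test_mating_counts_total(self, random_counts):
        c = random_counts(seed=6)
        assert c.mating_counts().sum() == c.n


class TestLoglik:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_summation(self, seed, random_counts):
        r = np.random.default_rng(seed)
        c = random_counts(seed=seed)
        params = MixtureParams(
            t=r.uniform(), pi1=r.uniform(), mu=r.dirichlet(np.ones(6))
        )
        assert loglik(c, params) == pytest.approx(naive_loglik(c, params), abs=1e-10)

    def test_mixture_collapses_at_boundaries(self, random_counts):
        c = random_counts(seed=1)
        mu = hwe_mating_freqs(0.4)
        base = loglik(c, MixtureParams(t=0.9, pi1=0.0, mu=mu))
        assert base == pytest.approx(
            loglik(c, MixtureParams(t=0.123, pi1=0.0, mu=mu))
        )
        assert base == pytest.approx(loglik(c, MixtureParams(t=0.5, pi1=1.0, mu=mu)))

    def test_zero_probability_cell_with_count_is_minus_inf(self):
        c = TrioCounts.from_dict({"212": 1})
        mu = np.array([0, 1.0, 0, 0, 0, 0])
        assert loglik(c, MixtureParams(t=0.0, pi1=1.0, mu=mu)) == -np.inf


class TestEStep:
    def test_homozygous_parent_types_pinned_at_pi1_exactly(self, random_counts):
        c = random_counts(seed=2)
        params = MixtureParams(t=0.83, pi1=0.37, mu=hwe_mating_freqs(0.3))
        tau = e_step(c, params)
        for label in ("000", "201", "222"):
            i = TRIO_LABELS.index(label)
            assert tau[i] == params.pi1  # exact equality, not approx

    def test_identical_components_at_half(self, random_counts):
        params = MixtureParams(t=0.5, pi1=0.42, mu=hwe_mating_freqs(0.5))
        tau = e_step(random_counts(seed=3), params)
        np.testing.assert_allclose(tau, 0.42)

    def test_hand_value_212(self):
        params = MixtureParams(t=0.9, pi1=0.5, mu=hwe_mating_freqs(0.5))
        tau = e_step(TrioCounts.from_dict({"212": 1}), params)
        assert tau[TRIO_INDEX[(2, 1, 2)]] == pytest.approx(0.9 / 1.4)


class TestMStep:
    def test_binomial_mle_with_pseudocount(self):
        c = TrioCounts.from_dict({"212": 30, "211": 10})
        s = EMSettings(penalty_c=0.001)
        params = m_step(c, np.ones(10), s)
        assert params.t == pytest.approx((30 + 0.001) / (40 + 0.002))
        assert params.pi1 == pytest.approx((40 + 0.001) / (40 + 0.002))
        # C = 0 recovers the plain transmission ratio
        params0 = m_step(c, np.ones(10), EMSettings(penalty_c=0.0))
        assert params0.t == pytest.approx(0.75)

    def test_empty_linked_class(self, random_counts):
        c = random_counts(seed=4)
        params = m_step(c, np.zeros(10), EMSettings(penalty_c=0.001))
        assert params.pi1 == pytest.approx(0.0, abs=1e-5)
        assert params.t == pytest.approx(0.5)

    def test_mu_is_observed_mating_frequencies(self, random_counts):
        c = random_counts(seed=7)
        params = m_step(c, np.full(10, 0.5))
        np.testing.assert_allclose(params.mu, c.mating_counts() / c.n)


class TestFitH0:
    def test_single_trio_closed_form(self):
        c = TrioCounts.from_dict({"111": 1})
        assert fit_h0(c) == pytest.approx(np.log(0.5))

    def test_matches_profile_likelihood_at_half(self, random_counts):
        c = random_counts(seed=8)
        mu_hat = c.mating_counts() / c.n
        assert fit_h0(c) == pytest.approx(
            loglik(c, MixtureParams(t=0.5, pi1=0.5, mu=mu_hat))
        )


class TestEMProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_iterations_never_decrease_penalized_likelihood(self, seed, random_counts):
        r = np.random.default_rng(1000 + seed)
        c = random_counts(n=120, seed=seed)
        s = EMSettings(penalty_c=0.001)
        for _ in range(2):  # two random starts per dataset
            params = MixtureParams(
                t=r.uniform(), pi1=r.uniform(), mu=c.mating_counts() / c.n
            )
            prev = penalized_ll(c, params, s.penalty_c)
            for _ in range(20):
                params = m_step(c, e_step(c, params), s)
                cur = penalized_ll(c, params, s.penalty_c)
                assert cur >= prev - 1e-9
                prev = cur

    def test_numba_and_numpy_paths_agree(self, random_counts):
        counts = np.vstack([random_counts(seed=s).counts for s in range(8)])
        settings = EMSettings(n_starts=10)
        k0 = 8 * 10
        init = (
            np.random.default_rng(1).uniform(size=k0),
            np.random.default_rng(2).uniform(size=k0),
        )
        res_default = _fit_h1_batch(counts, settings, init=init)
        saved = em_module._HAVE_NUMBA
        try:
            em_module._HAVE_NUMBA = False
            res_numpy = _fit_h1_batch(counts, settings, init=init)
        finally:
            em_module._HAVE_NUMBA = saved
        for key in ("t", "pi1", "ll_mix", "pen_ll"):
            np.testing.assert_allclose(
                res_default[key], res_numpy[key], rtol=0, atol=1e-10
            )
        assert np.array_equal(
            res_default["start_index"], res_numpy["start_index"]
        )

    def test_batch_iteration_matches_public_e_and_m_steps(self, random_counts):
        # one full EM pass of the batch engine from a fixed start equals the
        # composition of the public e_step / m_step (on t and pi1)
        c = random_counts(seed=11)
        s = EMSettings(n_starts=1, max_steps=40, penalty_c=0.001)
        init = (np.array([0.3]), np.array([0.6]))
        res = _fit_h1_batch(c.counts[None, :], s, init=init)
        params = MixtureParams(t=0.3, pi1=0.6, mu=c.mating_counts() / c.n)
        prev = -np.inf
        for step in range(1, s.max_steps + 1):
            cur = penalized_ll(c, params, s.penalty_c)
            # engine convention: stop at the parameters just evaluated
            if abs(cur - prev) < s.epsilon or step == s.max_steps:
                break
            prev = cur
            params = m_step(c, e_step(c, params), s)
        assert res["t"][0] == pytest.approx(params.t, abs=1e-6)
        assert res["pi1"][0] == pytest.approx(params.pi1, abs=1e-6)


class TestFitH1:
    def test_null_data_gives_small_statistic(self, fast_settings):
        rng = np.random.default_rng(99)
        mu = hwe_mating_freqs(0.5)
        probs = np.asarray(
            mu[[5, 4, 4, 3, 3, 3, 2, 1, 1, 0]] * kernel_g(0.5), dtype=float
        )
        c = TrioCounts(rng.multinomial(2000, probs))
        fit = tdt_het(c, fast_settings)
        assert fit.statistic < 6.0  # no signal: LRT stays small
        assert fit.statistic >= 0.0

    def test_parameter_recovery_fully_linked(self, fast_settings):
        # pi1 = 1, t = 0.75: transmission counts identify t directly
        rng = np.random.default_rng(5)
        m = GeneticModel(phi=0.05, p=0.3, moi="multiplicative", r2=9.0)
        # multiplicative r2=9 -> r1=3 -> t* = 0.75
        d = linked_trio_distribution(m, hwe_mating_freqs(0.3))
        c = TrioCounts(rng.multinomial(5000, d))
        fit = fit_h1(c, fast_settings)
        # observed-information SE for a binomial proportion at n_het parents
        n_het = int(c.counts @ np.array([0, 1, 1, 2, 2, 2, 0, 1, 1, 0]))
        se = np.sqrt(0.75 * 0.25 / n_het)
        assert fit.t_hat == pytest.approx(0.75, abs=3 * se)
        assert fit.pi1_hat > 0.9

    @pytest.mark.parametrize("seed", range(12))
    def test_em_matches_grid_search_oracle(self, seed, random_counts):
        c = random_counts(n=200, seed=300 + seed)
        settings = EMSettings(
            n_starts=50, max_steps=3000, epsilon=1e-10, penalty_c=0.0
        )
        fit = fit_h1(c, settings, np.random.default_rng(seed))
        assert fit.ll_h1 == pytest.approx(grid_search_ll(c), abs=1e-3)

    def test_all_zero_counts_rejected(self, fast_settings):
        with pytest.raises(ValueError):
            fit_h1(TrioCounts(np.zeros(10, dtype=int)), fast_settings)


class TestStatistic:
    def test_no_heterozygous_parents_gives_zero(self, fast_settings):
        c = TrioCounts.from_dict({"000": 40, "201": 25, "222": 10})
        assert tdt_het(c, fast_settings).statistic == 0.0

    def test_single_mating_type_closed_form(self, fast_settings):
        c = TrioCounts.from_dict({"212": 30, "211": 10})
        fit = tdt_het(c, fast_settings)
        t_hat = 0.75  # binomial MLE
        expected = 2 * (30 * np.log(2 * t_hat) + 10 * np.log(2 * (1 - t_hat)))
        assert fit.statistic == pytest.approx(expected, abs=1e-4)

    def test_allele_relabeling_invariance(self, random_counts):
        settings = EMSettings(n_starts=100, max_steps=500, epsilon=1e-9)
        for seed in (21, 22, 23):
            c = random_counts(n=300, seed=seed)
            s1 = tdt_het(c, settings, np.random.default_rng(1)).statistic
            s2 = tdt_het(c.mirror(), settings, np.random.default_rng(2)).statistic
            # tolerance reflects EM convergence noise, not the symmetry
            assert s1 == pytest.approx(s2, abs=0.01)

    def test_mu_cancels_from_likelihood_ratio(self, random_counts):
        # the H1 - H0 log-likelihood difference at fixed (t, pi1) does not
        # depend on which mu is plugged into both terms
        c = random_counts(seed=31)
        r = np.random.default_rng(0)
        t, pi1 = 0.77, 0.41
        diffs = []
        for _ in range(3):
            mu = r.dirichlet(np.ones(6))
            h1 = loglik(c, MixtureParams(t=t, pi1=pi1, mu=mu))
            h0 = loglik(c, MixtureParams(t=0.5, pi1=pi1, mu=mu))
            diffs.append(h1 - h0)
        assert np.ptp(diffs) < 1e-9

    def test_batch_statistics_match_single_fits(self, random_counts):
        counts = [random_counts(n=150, seed=s) for s in (41, 42, 43)]
        matrix = np.vstack([c.counts for c in counts])
        settings = EMSettings(n_starts=60, max_steps=500, epsilon=1e-9)
        batch = tdt_het_statistics(matrix, settings, np.random.default_rng(7))
        for c, stat in zip(counts, batch):
            single = tdt_het(c, settings, np.random.default_rng(8)).statistic
            assert stat == pytest.approx(single, abs=1e-4)


class TestLinkedDecision:
    def _fit(self, t, pi1, counts):
        mu = counts.mating_counts() / counts.n
        tau = e_step(counts, MixtureParams(t=t, pi1=pi1, mu=mu))
        return type(
            "F", (), {"tau1": tau, "pi1_hat": pi1, "t_hat": t}
        )()

    def test_pi1_one_selects_everything(self, random_counts):
        fit = self._fit(0.8, 1.0, random_counts(seed=51))
        assert set(linked_decision(fit)) == set(TRIO_LABELS)

    def test_overtransmission_selects_m_receivers(self, random_counts):
        fit = self._fit(0.9, 0.5, random_counts(seed=52))
        chosen = set(linked_decision(fit, require_het_parent=True))
        # children that received M from every heterozygous parent
        assert chosen == {"212", "112", "101"}

    def test_t_half_selects_all_het_types_at_equality(self, random_counts):
        # identical components put every heterozygous-parent type exactly at
        # the tau = pi1 tie, which the ">=" rule includes
        fit = self._fit(0.5, 0.6, random_counts(seed=53))
        chosen = set(linked_decision(fit, require_het_parent=True))
        assert chosen == {"100", "101", "110", "111", "112", "211", "212"}
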