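import itertools
import math

import numpy as np
import pytest
from scipy.special import betaln, ndtr
from scipy.stats import truncnorm

from gtbart.gibbs import (LatentState, SamplerConfig, TreeEnsembleSampler,
                          latent_status_probability, run_chain,
                          sample_all_statuses, sample_omega, update_accuracy)
from gtbart.group_data import AssayAccuracy, GroupTestingData
from gtbart.protocol_sim import SimulationDesign, simulate_dataset
from gtbart.tree_model import TreePrior


def joint_mass(y, data, acc, eta):
    """Enumeration oracle: un-normalized joint of (Z, Y~) for fixed
    accuracies and surface — the summand of the observed-data model."""
    lp = 0.0
    for j, pool in enumerate(data.pools):
        zt = int(any(y[i] for i in pool))
        l, z = data.stratum[j], data.Z[j]
        se, sp = acc.se[l], acc.sp[l]
        lp += zt * (z * math.log(se) + (1 - z) * math.log(1 - se))
        lp += (1 - zt) * (z * math.log(1 - sp) + (1 - z) * math.log(sp))
    for i in range(data.N):
        p = ndtr(eta[i])
        lp += y[i] * math.log(p) + (1 - y[i]) * math.log(1 - p)
    return math.exp(lp)


def exact_posterior(data, acc, eta):
    probs = {y: joint_mass(y, data, acc, eta)
             for y in itertools.product([0, 1], repeat=data.N)}
    tot = sum(probs.values())
    return {y: v / tot for y, v in probs.items()}


class TestLatentStatusProbability:
    def test_perfect_individual_test_pins_status(self):
        X = np.zeros((2, 1))
        data = GroupTestingData(X=X, Z=[1, 0],
                               pools=[np.array([0]), np.array([1])],
                               stratum=[0, 0])
        acc = AssayAccuracy.fixed([1 - 1e-12], [1 - 1e-12])
        state = LatentState.initial(data, np.zeros(2))
        assert latent_status_probability(0, state, data, acc) > 1 - 1e-9
        assert latent_status_probability(1, state, data, acc) < 1e-9

    def test_untested_individual_gets_prior(self):
        X = np.zeros((2, 1))
        data = GroupTestingData(X=X, Z=[1], pools=[np.array([0])],
                               stratum=[0])
        acc = AssayAccuracy.fixed([0.9], [0.9])
        eta = np.array([0.3, -0.7])
        state = LatentState.initial(data, eta)
        assert latent_status_probability(1, state, data, acc) == \
            pytest.approx(ndtr(-0.7), abs=1e-12)

    def test_matches_enumeration_single_pool(self, rng):
        # N=3, one pool: conditional of Y_1 given the others
        X = rng.normal(size=(3, 1))
        data = GroupTestingData(X=X, Z=[1], pools=[np.arange(3)], stratum=[0])
        acc = AssayAccuracy.fixed([0.87], [0.93])
        eta = rng.normal(size=3)
        state = LatentState.initial(data, eta)
        state.Y = np.array([0, 1, 0], dtype=np.int8)
        state.pool_pos = state.recount(data)
        got = latent_status_probability(0, state, data, acc)
        y1 = (1, 1, 0)
        y0 = (0, 1, 0)
        expect = joint_mass(y1, data, acc, eta) / (
            joint_mass(y1, data, acc, eta) + joint_mass(y0, data, acc, eta))
        assert got == pytest.approx(expect, abs=1e-12)


class TestSampleAllStatuses:
    def test_occupancy_matches_enumeration(self, dorfman_small, rng):
        # primary exactness oracle: Gibbs occupancy over {0,1}^N vs the
        # enumerated joint, eta and accuracies fixed
        data = dorfman_small
        eta = rng.normal(scale=0.8, size=data.N)
        acc = AssayAccuracy.fixed([0.9, 0.95], [0.93, 0.97])
        target = exact_posterior(data, acc, eta)
        state = LatentState.initial(data, eta)
        n_sweeps = 100_000
        n_batches = 20
        hits = {y: np.zeros(n_batches) for y in target}
        for it in range(n_sweeps):
            sample_all_statuses(state, data, acc, rng)
            hits[tuple(state.Y)][it * n_batches // n_sweeps] += 1
        for y, p in target.items():
            if p < 1e-4:
                continue
            bm = hits[y] / (n_sweeps / n_batches)
            se = bm.std(ddof=1) / math.sqrt(n_batches)
            assert abs(bm.mean() - p) < 3 * se + 2e-3, (y, bm.mean(), p)

    def test_near_perfect_negative_data_stays_negative(self, rng):
        X = np.zeros((4, 1))
        data = GroupTestingData(X=X, Z=[0], pools=[np.arange(4)], stratum=[0])
        acc = AssayAccuracy.fixed([0.9999], [0.9999])
        state = LatentState.initial(data, np.full(4, -1.0))
        pos = 0
        for _ in range(2000):
            sample_all_statuses(state, data, acc, rng)
            pos += state.Y.any()
        assert pos / 2000 < 1e-2

    def test_pool_counts_stay_consistent(self, dorfman_small, rng):
        data = dorfman_small
        acc = AssayAccuracy.fixed([0.9, 0.95], [0.93, 0.97])
        state = LatentState.initial(data, rng.normal(size=data.N))
        for _ in range(50):
            sample_all_statuses(state, data, acc, rng)
            assert np.array_equal(state.pool_pos, state.recount(data))

    def test_positive_retest_monotonicity(self, rng):
        # adding a positive individual retest never lowers the sampled
        # positive frequency (checked exactly by enumeration)
        X = np.zeros((3, 1))
        eta = np.array([-0.5, 0.0, 0.5])
        acc = AssayAccuracy.fixed([0.9, 0.95], [0.93, 0.97])
        base = GroupTestingData(X=X, Z=[1], pools=[np.arange(3)],
                                stratum=[0])
        plus = GroupTestingData(X=X, Z=[1, 1],
                                pools=[np.arange(3), np.array([0])],
                                stratum=[0, 1])
        p_base = sum(p for y, p in exact_posterior(base, acc, eta).items()
                     if y[0] == 1)
        p_plus = sum(p for y, p in exact_posterior(plus, acc, eta).items()
                     if y[0] == 1)
        assert p_plus >= p_base


class TestJointChainWithAccuracy:
    def test_matches_beta_marginalized_enumeration(self, dorfman_small, rng):
        # statuses + conjugate accuracy updates jointly: compare against
        # exact enumeration with (Se, Sp) integrated out analytically
        data = dorfman_small
        eta = rng.normal(scale=0.7, size=data.N)
        a = b = 1.0

        def marg(y):
            lp = 0.0
            for l in range(2):
                tp = fn = tn = fp = 0
                for j, pool in enumerate(data.pools):
                    if data.stratum[j] != l:
                        continue
                    zt = int(any(y[i] for i in pool))
                    z = data.Z[j]
                    tp += z * zt
                    fn += (1 - z) * zt
                    tn += (1 - z) * (1 - zt)
                    fp += z * (1 - zt)
                lp += betaln(a + tp, b + fn) - betaln(a, b)
                lp += betaln(a + tn, b + fp) - betaln(a, b)
            for i in range(data.N):
                p = ndtr(eta[i])
                lp += y[i] * math.log(p) + (1 - y[i]) * math.log(1 - p)
            return math.exp(lp)

        probs = {y: marg(y) for y in
                 itertools.product([0, 1], repeat=data.N)}
        tot = sum(probs.values())
        exact_mean = np.array([
            sum(p for y, p in probs.items() if y[i]) / tot
            for i in range(data.N)])

        acc = AssayAccuracy.uniform_prior([0.9, 0.9], [0.9, 0.9])
        state = LatentState.initial(data, eta)
        update_accuracy(state, data, acc, rng)
        S = 60_000
        freq = np.zeros(data.N)
        for _ in range(S):
            sample_all_statuses(state, data, acc, rng)
            update_accuracy(state, data, acc, rng)
            freq += state.Y
        assert np.allclose(freq / S, exact_mean, atol=0.01)


class TestSampleOmega:
    def test_sign_coupling(self, rng):
        n = 500
        state = LatentState(Y=(rng.random(n) < 0.4).astype(np.int8),
                            omega=np.zeros(n),
                            pool_pos=np.zeros(1, dtype=np.int64),
                            eta=rng.normal(scale=3, size=n))
        sample_omega(state, rng)
        assert np.all(state.omega[state.Y == 1] > 0)
        assert np.all(state.omega[state.Y == 0] <= 0)

    def test_half_normal_mean(self, rng):
        n = 100_000
        state = LatentState(Y=np.ones(n, dtype=np.int8), omega=np.zeros(n),
                            pool_pos=np.zeros(1, dtype=np.int64),
                            eta=np.zeros(n))
        sample_omega(state, rng)
        expect = math.sqrt(2 / math.pi)
        sd = math.sqrt(1 - 2 / math.pi)
        assert abs(state.omega.mean() - expect) < 3 * sd / math.sqrt(n)

    def test_deep_tail_matches_truncnorm(self, rng):
        n = 100_000
        state = LatentState(Y=np.ones(n, dtype=np.int8), omega=np.zeros(n),
                            pool_pos=np.zeros(1, dtype=np.int64),
                            eta=np.full(n, -3.0))
        sample_omega(state, rng)
        expect = truncnorm.mean(3, np.inf, loc=-3.0)
        sd = truncnorm.std(3, np.inf, loc=-3.0)
        assert abs(state.omega.mean() - expect) < 3 * sd / math.sqrt(n)

    def test_extreme_eta_finite(self, rng):
        n = 1000
        for eta_val, y in ((-10.0, 1), (10.0, 0), (8.0, 1), (-8.0, 0)):
            state = LatentState(Y=np.full(n, y, dtype=np.int8),
                                omega=np.zeros(n),
                                pool_pos=np.zeros(1, dtype=np.int64),
                                eta=np.full(n, eta_val))
            sample_omega(state, rng)
            assert np.all(np.isfinite(state.omega))


class TestUpdateAccuracy:
    def _state_with(self, data, y):
        state = LatentState.initial(data, np.zeros(data.N))
        state.Y = np.asarray(y, dtype=np.int8)
        state.pool_pos = state.recount(data)
        return state

    def test_no_data_stratum_keeps_prior(self, rng):
        X = np.zeros((2, 1))
        data = GroupTestingData(X=X, Z=[1], pools=[np.array([0])],
                                stratum=[0])
        acc = AssayAccuracy(se=[0.9, 0.9], sp=[0.9, 0.9],
                            known=[False, False],
                            hyper=[[3, 1, 1, 1]] * 2)
        draws = []
        state = self._state_with(data, [0, 0])
        for _ in range(4000):
            update_accuracy(state, data, acc, rng)
            draws.append(acc.se[1])
        # stratum 2 has no tests: Se(2) ~ beta(3, 1), mean 0.75
        assert np.mean(draws) == pytest.approx(0.75, abs=0.01)

    def test_direct_count_example(self, rng):
        # tests (Z, Z~) = (1,1), (0,1), (1,1) -> Se | data ~ beta(3, 2)
        X = np.zeros((3, 1))
        data = GroupTestingData(
            X=X, Z=[1, 0, 1],
            pools=[np.array([0]), np.array([1]), np.array([2])],
            stratum=[0, 0, 0])
        acc = AssayAccuracy.uniform_prior([0.5], [0.5])
        state = self._state_with(data, [1, 1, 1])
        draws = [
            (update_accuracy(state, data, acc, rng), acc.se[0])[1]
            for _ in range(8000)]
        assert np.mean(draws) == pytest.approx(3 / 5, abs=0.02)
        assert np.var(draws) == pytest.approx(3 * 2 / (25 * 6), abs=0.01)

    def test_counting_identity(self, dorfman_small, rng):
        data = dorfman_small
        state = self._state_with(data, [1, 0, 1, 0, 0, 1])
        z_tilde = (state.pool_pos > 0).astype(int)
        for l in range(2):
            in_l = data.stratum == l
            assert z_tilde[in_l].sum() == sum(
                z_tilde[j] for j in range(data.J) if data.stratum[j] == l)

    def test_known_strata_untouched(self, dorfman_small, rng):
        data = dorfman_small
        acc = AssayAccuracy(se=[0.9, 0.8], sp=[0.9, 0.8],
                            known=[True, False])
        state = self._state_with(data, [1, 0, 0, 0, 0, 0])
        update_accuracy(state, data, acc, rng)
        assert acc.se[0] == 0.9 and acc.sp[0] == 0.9
        assert acc.se[1] != 0.8 or acc.sp[1] != 0.8


class TestBackfit:
    def test_single_stump_conjugate_chain(self, rng):
        # K=1 stump never grown (alpha tiny): leaf chain is the standard
        # conjugate normal Gibbs sampler
        n = 40
        X = rng.uniform(size=(n, 1))
        omega = rng.normal(loc=0.7, size=n)
        prior = TreePrior(K=1, alpha=1e-9, sigma_mu=0.8)
        sampler = TreeEnsembleSampler(X, prior, 0.0)
        draws = []
        for _ in range(4000):
            sampler.sweep(omega, rng)
            draws.append(sampler.eta[0])
        expect = omega.sum() / (n + prior.sigma_mu ** -2)
        sd = math.sqrt(1.0 / (n + prior.sigma_mu ** -2))
        assert np.mean(draws) == pytest.approx(expect,
                                               abs=3 * sd / math.sqrt(100))

    def test_eta_cache_consistency(self, rng):
        X = rng.uniform(0, 10, size=(60, 3))
        omega = rng.normal(size=60)
        sampler = TreeEnsembleSampler(X, TreePrior(K=10), 0.3)
        for _ in range(30):
            sampler.sweep(omega, rng)
        recomputed = sampler.evaluate(X)
        assert np.allclose(sampler.eta, recomputed, atol=1e-10)

    def test_pure_noise_depth_matches_prior(self, rng):
        # omega fixed at 0: likelihood is flat in structure up to leaf
        # marginals; tree depth should stay near the prior's
        X = rng.uniform(size=(25, 2))
        prior = TreePrior(K=5, alpha=0.3, beta=2.0, sigma_mu=0.05)
        sampler = TreeEnsembleSampler(X, prior, 0.0)
        omega = np.zeros(25)
        stumps = total = 0
        for it in range(1500):
            sampler.sweep(omega, rng)
            if it > 300:
                stumps += sum(t.is_stump for t in sampler.trees)
                total += prior.K
        # prior P(stump) = 0.7; sigma_mu small so likelihood is nearly flat
        assert abs(stumps / total - 0.7) < 0.08


class TestRunChain:
    def test_reproducible_under_seed(self, acc_two_strata):
        design = SimulationDesign(model="M2", N=60, protocol="DT",
                                  accuracy_truth=acc_two_strata, seed=3)
        _, data = simulate_dataset(design)
        cfg = SamplerConfig(K=5, n_burn=20, n_keep=20, seed=11)
        a = run_chain(data, acc_two_strata, cfg)
        b = run_chain(data, acc_two_strata, cfg)
        assert np.array_equal(a.eta, b.eta)
        assert np.array_equal(a.se, b.se)
        assert np.array_equal(a.split_counts, b.split_counts)

    def test_perfect_it_reproduces_outcomes(self):
        # acceptance criterion 8 at module scale
        acc = AssayAccuracy.fixed([0.9999], [0.9999])
        design = SimulationDesign(model="M2", N=150, protocol="IT",
                                  accuracy_truth=acc, seed=5, pool_size=1)
        truth, data = simulate_dataset(design)
        cfg = SamplerConfig(K=10, n_burn=150, n_keep=150, seed=2)
        post = run_chain(data, acc, cfg)
        z = np.array([int(data.Z[j]) for j in range(data.J)])
        # posterior P(Y_i = 1) is pinned by the (nearly) perfect test
        assert np.allclose(post.y_mean, z, atol=0.01)

    def test_recovery_rank_correlation(self, acc_two_strata):
        design = SimulationDesign(model="M2", N=800, protocol="DT",
                                  accuracy_truth=acc_two_strata, seed=17)
        truth, data = simulate_dataset(design)
        cfg = SamplerConfig(K=20, n_burn=300, n_keep=300, seed=4)
        post = run_chain(data, acc_two_strata, cfg)
        p_hat = ndtr(post.eta).mean(axis=0)
        rho = np.corrcoef(np.argsort(np.argsort(p_hat)),
                          np.argsort(np.argsort(truth.p_true)))[0, 1]
        assert rho > 0.5

    def test_invalid_data_rejected(self, dorfman_small, acc_two_strata):
        dorfman_small.Z = np.array([1, 2, 1, 0, 0])
        with pytest.raises(ValueError, match="invalid"):
            run_chain(dorfman_small, acc_two_strata,
                      SamplerConfig(K=2, n_burn=2, n_keep=2, seed=0))

    def test_query_eta_matches_training_rows(self, acc_two_strata):
        design = SimulationDesign(model="M3", N=80, protocol="DT",
                                  accuracy_truth=acc_two_strata, seed=9)
        truth, data = simulate_dataset(design)
        cfg = SamplerConfig(K=5, n_burn=10, n_keep=10, seed=1)
        post = run_chain(data, acc_two_strata, cfg, X_query=data.X[:7])
        assert np.allclose(post.eta_query, post.eta[:, :7], atol=1e-12)
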