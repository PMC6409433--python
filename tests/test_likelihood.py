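"""Poisson random field likelihoods against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from sfsvar.likelihood import (
    Locus,
    SFSDataset,
    loglik_full,
    loglik_gradient,
    loglik_profile,
    loglik_with_divergence,
    recover_theta,
)
from sfsvar.spectrum import (
    EpochModel,
    LocusModel,
    ModelSpec,
    expected_divergence,
    expected_sfs,
)
from sfsvar.weights import branch_weights


def _replace_locus(model, k, **kw):
    loci = list(model.loci)
    old = loci[k]
    fields = dict(theta=old.theta, f=old.f, g=old.g, m=old.m,
                  epsilon=old.epsilon, id=old.id)
    fields.update(kw)
    loci[k] = LocusModel(**fields)
    return ModelSpec(epochs=model.epochs, loci=tuple(loci),
                     shared_g=model.shared_g, divergence=model.divergence,
                     reference=model.reference)


class TestFullLoglik:
    def test_single_class_contribution(self):
        # one class, psi=2, d=3: -2 + 3 ln 2
        data = SFSDataset(n=3, loci=(Locus(id="l", m=1000,
                                           counts=np.array([3, 0])),))
        lm = LocusModel(theta=2.0 / 1000, f=1.0, g=(), m=1000, id="l")
        model = ModelSpec(epochs=EpochModel(1), loci=(lm,))
        # psi = (2, 1): contributions (-2 + 3 ln 2) + (-1)
        assert loglik_full(data, model) == pytest.approx(-2 + 3 * math.log(2) - 1)

    def test_all_zero_counts_gives_minus_total(self, small_model):
        n = 12
        B = branch_weights(n)
        zero = SFSDataset(n=n, loci=tuple(
            Locus(id=lm.id, m=lm.m, counts=np.zeros(n - 1, dtype=np.int64))
            for lm in small_model.loci))
        expected = -sum(expected_sfs(lm, small_model.epochs, B).sum()
                        for lm in small_model.loci)
        assert loglik_full(zero, small_model) == pytest.approx(expected)

    def test_matches_poisson_pmf_oracle(self, small_data, small_model):
        # independent summation of Poisson log-pmfs plus the data constant
        B = branch_weights(small_data.n)
        oracle = 0.0
        for k, lm in enumerate(small_model.loci):
            psi = expected_sfs(lm, small_model.epochs, B)
            d = small_data.loci[k].counts
            oracle += poisson.logpmf(d, psi).sum()
            oracle += sum(math.lgamma(int(v) + 1) for v in d)
        assert loglik_full(small_data, small_model) == pytest.approx(oracle)

    def test_impossible_data_is_minus_inf(self):
        data = SFSDataset(n=4, loci=(Locus(id="l", m=100,
                                           counts=np.array([1, 0, 0])),))
        lm = LocusModel(theta=0.0, f=1.0, g=(), m=100, id="l")
        model = ModelSpec(epochs=EpochModel(1), loci=(lm,))
        assert loglik_full(data, model) == -np.inf

    def test_rejects_folded_with_polarization_error(self):
        data = SFSDataset(n=6, folded=True,
                          loci=(Locus(id="l", m=100, counts=np.array([4, 2, 1])),))
        lm = LocusModel(theta=0.01, f=1.0, g=(), m=100, epsilon=0.1, id="l")
        model = ModelSpec(epochs=EpochModel(1), loci=(lm,))
        with pytest.raises(ValueError, match="folded"):
            loglik_full(data, model)


class TestDivergenceLoglik:
    def test_single_locus_divergence_term(self, small_data, small_model):
        base = loglik_full(small_data, small_model)
        aug = loglik_with_divergence(small_data, small_model)
        c, t = small_model.divergence
        expected_extra = 0.0
        for k, lm in enumerate(small_model.loci):
            lam = expected_divergence(lm, c, t)
            x = small_data.loci[k].x
            expected_extra += -lam + x * math.log(lam)
        assert aug - base == pytest.approx(expected_extra)

    def test_missing_substitution_counts_rejected(self, small_model):
        data = SFSDataset(n=12, loci=(
            Locus(id="a", m=2000, counts=np.zeros(11, dtype=np.int64)),
            Locus(id="b", m=5000, counts=np.zeros(11, dtype=np.int64), x=3)))
        with pytest.raises(ValueError, match="substitution"):
            loglik_with_divergence(data, small_model)


class TestProfileLoglik:
    def test_equilibrium_closed_form(self):
        # single constant-size locus: zeta_i = (1/i) / H_{n-1}
        n = 8
        counts = np.array([5, 3, 1, 0, 2, 1, 0])
        data = SFSDataset(n=n, loci=(Locus(id="l", m=1000, counts=counts),))
        lm = LocusModel(theta=0.01, f=1.0, g=(), m=1000, id="l")
        model = ModelSpec(epochs=EpochModel(1), loci=(lm,))
        H = sum(1.0 / i for i in range(1, n))
        expected = sum(d * math.log(1.0 / (i * H))
                       for i, d in enumerate(counts, start=1))
        assert loglik_profile(data, model) == pytest.approx(expected)

    def test_decomposition_into_full(self, small_data, small_model):
        # full = profile + sum_k [-psi_k + S_k ln psi_k] at theta_k = theta_hat_k
        B = branch_weights(small_data.n)
        model = small_model
        profile = loglik_profile(small_data, model)
        extra = 0.0
        for k, lm in enumerate(model.loci):
            psi_tot = expected_sfs(lm, model.epochs, B).sum()
            S = small_data.loci[k].S
            extra += -psi_tot + S * math.log(psi_tot)
        assert loglik_full(small_data, model) == pytest.approx(profile + extra)

    def test_invariant_to_locus_rescaling(self, small_data, small_model):
        # multiplying one locus's theta by any constant leaves the profile
        # value unchanged (it conditions on S_k)
        scaled = _replace_locus(small_model, 0,
                                theta=small_model.loci[0].theta * 7.3)
        assert loglik_profile(small_data, scaled) == pytest.approx(
            loglik_profile(small_data, small_model))


class TestRecoverTheta:
    def test_watterson_form(self):
        H99 = sum(1.0 / i for i in range(1, 100))
        assert recover_theta(100, 1000, H99) == pytest.approx(0.019315, rel=1e-4)

    def test_no_segregating_sites(self):
        assert recover_theta(0, 1000, 5.0) == 0.0

    def test_rejects_nonpositive_phi(self):
        with pytest.raises(ValueError):
            recover_theta(10, 1000, 0.0)


class TestGradient:
    def test_matches_finite_differences(self, small_data, small_model):
        model = small_model
        grads = loglik_gradient(small_data, model, use_divergence=True)
        h = 1e-7

        def ll(m):
            return loglik_with_divergence(small_data, m)

        # theta, f (non-reference), g, eps at each locus
        for k in range(2):
            lm = model.loci[k]
            fd = (ll(_replace_locus(model, k, theta=lm.theta + h * lm.theta))
                  - ll(_replace_locus(model, k, theta=lm.theta - h * lm.theta))) / (2 * h * lm.theta)
            assert grads["theta"][k] == pytest.approx(fd, rel=1e-5)
            fd = (ll(_replace_locus(model, k, g=(lm.g[0] + h,)))
                  - ll(_replace_locus(model, k, g=(lm.g[0] - h,)))) / (2 * h)
            assert grads["g"][k, 0] == pytest.approx(fd, rel=1e-5)
        lm = model.loci[1]
        fd = (ll(_replace_locus(model, 1, f=lm.f + h))
              - ll(_replace_locus(model, 1, f=lm.f - h))) / (2 * h)
        assert grads["f"][1] == pytest.approx(fd, rel=1e-5)

        # tau, c, t
        def with_tau(tv):
            return ModelSpec(epochs=EpochModel(2, (tv,)), loci=model.loci,
                             divergence=model.divergence)
        tau = model.epochs.tau[0]
        fd = (ll(with_tau(tau + h)) - ll(with_tau(tau - h))) / (2 * h)
        assert grads["tau"][0] == pytest.approx(fd, rel=1e-5)
        c, t = model.divergence
        def with_div(cv, tv):
            return ModelSpec(epochs=model.epochs, loci=model.loci,
                             divergence=(cv, tv))
        fd = (ll(with_div(c + h, t)) - ll(with_div(c - h, t))) / (2 * h)
        assert grads["c"] == pytest.approx(fd, rel=1e-5)
        fd = (ll(with_div(c, t + h)) - ll(with_div(c, t - h))) / (2 * h)
        assert grads["t"] == pytest.approx(fd, rel=1e-5)

    def test_epsilon_gradient(self, bw12, two_epoch):
        lm = LocusModel(theta=0.02, f=1.0, g=(5.0,), m=4000, epsilon=0.08, id="e")
        model = ModelSpec(epochs=two_epoch, loci=(lm,))
        rng = np.random.default_rng(3)
        from sfsvar.spectrum import apply_polarization_error
        psi = apply_polarization_error(expected_sfs(lm, two_epoch, bw12), 0.08)
        data = SFSDataset(n=12, loci=(Locus(id="e", m=4000,
                                            counts=rng.poisson(psi)),))
        grads = loglik_gradient(data, model)
        h = 1e-7
        fd = (loglik_full(data, _replace_locus(model, 0, epsilon=0.08 + h))
              - loglik_full(data, _replace_locus(model, 0, epsilon=0.08 - h))) / (2 * h)
        assert grads["eps"][0] == pytest.approx(fd, rel=1e-5)

    def test_score_vanishes_at_saturated_counts(self):
        # with d = psi exactly, the Poisson score in theta is zero;
        # m * theta = lcm(1..11) = 27720 makes every psi_i = 27720/i integral
        n = 12
        lm = LocusModel(theta=27720.0 / 3000, f=1.0, g=(), m=3000, id="s")
        model = ModelSpec(epochs=EpochModel(1), loci=(lm,))
        psi = expected_sfs(lm, EpochModel(1), n=n)
        np.testing.assert_allclose(psi, np.round(psi))
        data = SFSDataset(n=n, loci=(Locus(id="s", m=3000,
                                           counts=np.round(psi).astype(np.int64)),))
        grads = loglik_gradient(data, model)
        assert grads["theta"][0] == pytest.approx(0.0, abs=1e-9)
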