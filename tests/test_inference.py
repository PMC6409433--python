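"""Multi-start fitting, constraints, LRT mechanics and bootstraps."""

import numpy as np
import pytest

from sfsvar.inference import (
    ConstraintSet,
    FitOptions,
    bootstrap_ci,
    bootstrap_pvalue,
    fit,
    fit_constrained,
    fit_pooled,
    lrt,
)
from sfsvar.likelihood import Locus, SFSDataset, loglik_full, loglik_with_divergence
from sfsvar.simulate import simulate_usfs
from sfsvar.spectrum import EpochModel, LocusModel, ModelSpec

OPTS = FitOptions(n_starts=4, seed=9)


@pytest.fixture(scope="module")
def fitted_small(small_data, small_model):
    return fit(small_data, small_model, options=FitOptions(n_starts=6, seed=9))


class TestFit:
    def test_equilibrium_theta_is_watterson(self, equilibrium_locus_data):
        data, model = equilibrium_locus_data
        res = fit(data, model, options=OPTS)
        Hn = sum(1.0 / i for i in range(1, data.n))
        S, m = data.loci[0].S, data.loci[0].m
        assert res.model.loci[0].theta == pytest.approx(S / (m * Hn), rel=1e-10)

    def test_loglik_reproducible_from_model(self, small_data, small_model, fitted_small):
        res = fitted_small
        assert loglik_with_divergence(small_data, res.model) == pytest.approx(
            res.loglik, abs=1e-8)

    def test_mle_beats_truth(self, small_data, small_model, fitted_small):
        assert fitted_small.loglik >= loglik_with_divergence(
            small_data, small_model) - 1e-6

    def test_seeded_determinism(self, small_data, small_model):
        a = fit(small_data, small_model, options=OPTS)
        b = fit(small_data, small_model, options=OPTS)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.free_values, b.free_values)

    def test_h1_with_free_f_rejected(self):
        loci = (LocusModel(theta=1e-3, f=1.0, g=(), m=100, id="a"),
                LocusModel(theta=1e-3, f=1.0, g=(), m=100, id="b"))
        model = ModelSpec(epochs=EpochModel(1), loci=loci)
        counts = np.array([3, 2, 1])
        data = SFSDataset(n=4, loci=(Locus(id="a", m=100, counts=counts),
                                     Locus(id="b", m=100, counts=counts)))
        with pytest.raises(ValueError, match="identifiab"):
            fit(data, model, options=OPTS)


class TestConstraints:
    def test_empty_set_is_plain_fit(self, small_data, small_model):
        a = fit(small_data, small_model, options=OPTS)
        b = fit_constrained(small_data, small_model, ConstraintSet(), options=OPTS)
        assert a.loglik == b.loglik

    def test_nesting_never_improves(self, small_data, small_model):
        free = fit(small_data, small_model, options=OPTS)
        pinned = fit_constrained(
            small_data, small_model,
            ConstraintSet(pins=[("f[1]", 2.5), ("tau[0]", 0.3)]),
            options=OPTS)
        assert pinned.loglik <= free.loglik + 1e-6

    def test_tie_reduces_free_count(self, small_data, small_model):
        free = fit(small_data, small_model, options=OPTS)
        tied = fit_constrained(small_data, small_model,
                               ConstraintSet(ties=[("g[0,0]", "g[1,0]")]),
                               options=OPTS)
        assert len(tied.free_names) == len(free.free_names) - 1
        g = tied.model
        assert g.loci[0].g[0] == pytest.approx(g.loci[1].g[0])

    def test_mixed_kind_tie_rejected(self, small_data, small_model):
        with pytest.raises(ValueError, match="kind"):
            fit_constrained(small_data, small_model,
                            ConstraintSet(ties=[("f[1]", "g[0,0]")]),
                            options=OPTS)

    def test_unknown_name_rejected(self, small_data, small_model):
        with pytest.raises(ValueError, match="unknown parameter"):
            fit_constrained(small_data, small_model,
                            ConstraintSet(pins=[("f[9]", 1.0)]), options=OPTS)


class TestLRT:
    def test_identical_fits(self, small_data, small_model):
        res = fit(small_data, small_model, options=OPTS)
        out = lrt(res, res, df=1)
        assert out.statistic == 0.0
        assert out.p_asymptotic == 1.0

    def test_statistic_nonnegative(self, small_data, small_model):
        full = fit(small_data, small_model, options=OPTS)
        null = fit_constrained(small_data, small_model,
                               ConstraintSet(ties=[("theta[0]", "theta[1]")]),
                               options=OPTS)
        out = lrt(full, null, df=1)
        assert out.statistic >= 0.0
        assert 0.0 <= out.p_asymptotic <= 1.0

    def test_df_validation(self, fitted_small):
        with pytest.raises(ValueError):
            lrt(fitted_small, fitted_small, df=0)


class TestPooled:
    def test_single_locus_pooling_is_identity(self, two_epoch):
        lm = LocusModel(theta=0.02, f=1.0, g=(6.0,), m=4000, id="only")
        model = ModelSpec(epochs=two_epoch, loci=(lm,))
        data = simulate_usfs(model, 12, seed=4)
        direct = fit(data, model, options=OPTS)
        pooled = fit_pooled(data, two_epoch, options=OPTS)
        assert pooled.loglik == pytest.approx(direct.loglik, abs=1e-6)

    def test_rejects_folded(self, two_epoch):
        data = SFSDataset(n=6, folded=True,
                          loci=(Locus(id="l", m=100, counts=np.array([4, 2, 1])),))
        with pytest.raises(ValueError, match="unfolded"):
            fit_pooled(data, two_epoch)


class TestBootstrap:
    def test_invalid_replicate_counts(self, small_data, small_model):
        with pytest.raises(ValueError):
            bootstrap_pvalue(small_data, small_model, ConstraintSet(), df=1,
                             B=0, seed=1)
        with pytest.raises(ValueError):
            bootstrap_ci(small_data, small_model, B=0, seed=1)

    def test_degenerate_blocks_give_zero_width(self, two_epoch):
        # identical loci: every resample is the same dataset
        lm = LocusModel(theta=0.02, f=1.0, g=(6.0,), m=4000, id="l0")
        model = ModelSpec(epochs=two_epoch, loci=(lm,) * 1)
        base = simulate_usfs(model, 12, seed=8)
        clones = tuple(Locus(id=f"c{j}", m=4000, counts=base.loci[0].counts)
                       for j in range(4))
        data = SFSDataset(n=12, loci=clones)
        template = ModelSpec(
            epochs=two_epoch, shared_g=True,
            loci=tuple(LocusModel(theta=1e-3, f=1.0, g=(1.0,), m=4000, id=f"c{j}")
                       for j in range(4)),
        )
        cis = bootstrap_ci(data, template, B=8, seed=3, level=0.95,
                           constraints=ConstraintSet(
                               ties=[tuple(f"f[{j}]" for j in range(4))]),
                           options=FitOptions(n_starts=3, seed=3))
        for lo, hi in cis.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_percentile_definition(self, two_epoch):
        # interval endpoints are the 2.5/97.5 percentiles of the refit draws
        rng = np.random.default_rng(0)
        lm = LocusModel(theta=0.05, f=1.0, g=(6.0,), m=4000, id="l")
        model = ModelSpec(epochs=two_epoch, shared_g=True,
                          loci=tuple(
                              LocusModel(theta=0.05, f=1.0, g=(6.0,), m=4000,
                                         id=f"l{j}") for j in range(6)))
        data = simulate_usfs(model, 10, seed=12)
        template = ModelSpec(
            epochs=two_epoch, shared_g=True,
            loci=tuple(LocusModel(theta=1e-3, f=1.0, g=(1.0,), m=4000, id=f"l{j}")
                       for j in range(6)))
        constraints = ConstraintSet(ties=[tuple(f"f[{j}]" for j in range(6))])
        cis = bootstrap_ci(data, template, B=12, seed=5, level=0.95,
                           constraints=constraints,
                           options=FitOptions(n_starts=3, seed=5))
        assert set(cis) == {"g[0]", "tau[0]"}
        for lo, hi in cis.values():
            assert lo <= hi
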