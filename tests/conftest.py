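import numpy as np
import pytest

from sfsvar import (
    EpochModel,
    Locus,
    LocusModel,
    ModelSpec,
    SFSDataset,
    XAParams,
    branch_weights,
    expected_sfs,
    simulate_usfs,
    xa_to_general,
)


@pytest.fixture(scope="session")
def bw12():
    return branch_weights(12)


@pytest.fixture(scope="session")
def two_epoch():
    return EpochModel(2, (0.3,))


@pytest.fixture(scope="session")
def small_model(two_epoch):
    """Two-locus H=2 model small enough for brute-force cross-checks."""
    loci = (
        LocusModel(theta=0.01, f=1.0, g=(4.0,), m=2000, id="a"),
        LocusModel(theta=0.004, f=2.5, g=(1.5,), m=5000, id="b"),
    )
    return ModelSpec(epochs=two_epoch, loci=loci, divergence=(2.0, 5.0))


@pytest.fixture(scope="session")
def small_data(small_model):
    return simulate_usfs(small_model, 12, seed=71, with_divergence=True)


@pytest.fixture(scope="session")
def model1():
    """The expansion scenario: X/A two-locus model with a 10-fold size increase."""
    return xa_to_general(XAParams(thetaX=5.25e-4, thetaA=7.5e-4, r1=0.65,
                                  r2=0.75, gX1=10.0, tau1=0.1,
                                  mX=5_000_000, mA=5_000_000))


@pytest.fixture(scope="session")
def model2():
    """The contraction scenario: 5-fold size reduction with an r shift."""
    return xa_to_general(XAParams(thetaX=5.25e-4, thetaA=7.5e-4, r1=0.9,
                                  r2=0.75, gX1=0.2, tau1=0.05,
                                  mX=5_000_000, mA=5_000_000))


@pytest.fixture(scope="session")
def equilibrium_locus_data():
    """One constant-size locus: theta* is the only identifiable parameter."""
    n, m, theta = 30, 20000, 0.01
    lm = LocusModel(theta=theta, f=1.0, g=(), m=m, id="eq")
    model = ModelSpec(epochs=EpochModel(1), loci=(lm,))
    data = simulate_usfs(model, n, seed=5)
    return data, model
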