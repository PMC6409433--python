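"""X-versus-autosome comparisons: reparameterization and the three named LRTs.

The two-locus general model (X = reference locus, A = autosomes, H = 2) is
re-expressed in the parameters population geneticists ask about directly:

* thetaX, thetaA — scaled mutation rates, both defined against N_X, the
  ancient X-linked effective size;
* r2 = N_X / N_A — the X/A ratio of N_e in the ancient epoch;
* r1 = gX1 * r2 / gA1 — the same ratio in the current epoch;
* gX1 — the X epoch-1 size multiplier; tau1 — the scaled change time
  (units of 2 N_X generations);
* optional polarization-error rates epsX, epsA.

0.75 is the neutral expectation for r1 = r2 under an even sex ratio; the r
parameters are deliberately left unbounded so that sex-ratio distortion,
variance in reproductive success and selection at linked sites can all move
them outside [9/16, 9/8].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .inference import (
    ConstraintSet,
    FitOptions,
    FitResult,
    LRTResult,
    fit,
    lrt,
)
from .likelihood import SFSDataset
from .spectrum import EpochModel, LocusModel, ModelSpec

__all__ = [
    "XAParams",
    "xa_to_general",
    "general_to_xa",
    "fit_xa",
    "test_mutation_rate",
    "test_ne_ratio_075",
    "test_ratio_change",
]


@dataclass(frozen=True)
class XAParams:
    thetaX: float
    thetaA: float
    r1: float
    r2: float
    gX1: float
    tau1: float
    epsX: float = 0.0
    epsA: float = 0.0
    mX: int = 1
    mA: int = 1

    def __post_init__(self):
        if min(self.thetaX, self.thetaA) < 0:
            raise ValueError("scaled mutation rates must be >= 0")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("r1 and r2 must be > 0")
        if min(self.gX1, self.tau1) <= 0:
            raise ValueError("gX1 and tau1 must be > 0")


def xa_to_general(p: XAParams) -> ModelSpec:
    """Map XA parameters onto the two-locus general model (X is the reference).

    f_A = 1/r2 and gA1 = gX1 * r2 / r1; theta values carry over unchanged.
    """
    loci = (
        LocusModel(theta=p.thetaX, f=1.0, g=(p.gX1,), m=p.mX,
                   epsilon=p.epsX, id="X"),
        LocusModel(theta=p.thetaA, f=1.0 / p.r2, g=(p.gX1 * p.r2 / p.r1,),
                   m=p.mA, epsilon=p.epsA, id="A"),
    )
    return ModelSpec(epochs=EpochModel(2, (p.tau1,)), loci=loci)


def general_to_xa(model: ModelSpec) -> XAParams:
    """Inverse of xa_to_general; exact round-trip."""
    if model.epochs.H != 2 or model.K != 2 or model.reference != 0:
        raise ValueError("expected a two-locus H=2 model with the X locus as reference")
    X, A = model.loci
    r2 = 1.0 / A.f
    gX1 = X.g[0]
    r1 = gX1 * r2 / A.g[0]
    return XAParams(thetaX=X.theta, thetaA=A.theta, r1=r1, r2=r2, gX1=gX1,
                    tau1=model.epochs.tau[0], epsX=X.epsilon, epsA=A.epsilon,
                    mX=X.m, mA=A.m)


def _template(data: SFSDataset) -> ModelSpec:
    if data.K != 2:
        raise ValueError("XA analyses need exactly two loci: X (first) and A")
    loci = (
        LocusModel(theta=1e-3, f=1.0, g=(1.0,), m=data.loci[0].m, id=data.loci[0].id),
        LocusModel(theta=1e-3, f=1.0, g=(1.0,), m=data.loci[1].m, id=data.loci[1].id),
    )
    return ModelSpec(epochs=EpochModel(2, (1.0,)), loci=loci)


def fit_xa(data: SFSDataset, options: Optional[FitOptions] = None,
           constraints: Optional[ConstraintSet] = None) -> FitResult:
    """Fit the full two-locus general model; report via .model / general_to_xa."""
    return fit(data, _template(data), constraints=constraints,
               options=options or FitOptions())


def test_mutation_rate(data: SFSDataset,
                       options: Optional[FitOptions] = None) -> LRTResult:
    """Test 1 — does the mutation rate differ between X and A?  Null: thetaX = thetaA (df 1)."""
    options = options or FitOptions()
    full = fit_xa(data, options)
    null = fit_xa(data, options,
                  constraints=ConstraintSet(ties=[("theta[0]", "theta[1]")]))
    return lrt(full, null, df=1)


def test_ne_ratio_075(data: SFSDataset,
                      options: Optional[FitOptions] = None) -> LRTResult:
    """Test 2 — does the X/A N_e ratio differ from 3/4?  Null: r1 = r2 = 0.75 (df 2).

    In general-model coordinates the null pins f_A = 4/3 and ties gA1 = gX1.
    """
    options = options or FitOptions()
    full = fit_xa(data, options)
    null = fit_xa(data, options,
                  constraints=ConstraintSet(ties=[("g[0,0]", "g[1,0]")],
                                            pins=[("f[1]", 4.0 / 3.0)]))
    return lrt(full, null, df=2)


def test_ratio_change(data: SFSDataset,
                      options: Optional[FitOptions] = None) -> LRTResult:
    """Test 3 — has the X/A N_e ratio changed between epochs?  Null: r1 = r2 (df 1).

    r1 = r2 is equivalent to gA1 = gX1 with f_A free.
    """
    options = options or FitOptions()
    full = fit_xa(data, options)
    null = fit_xa(data, options,
                  constraints=ConstraintSet(ties=[("g[0,0]", "g[1,0]")]))
    return lrt(full, null, df=1)
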