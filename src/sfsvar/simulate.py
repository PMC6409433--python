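"""Synthetic data: Poisson-sampled SFS and divergence counts, locus designs, replicates.

Counts are simulated as independent Poisson draws per frequency class with
means given by the expected spectrum — exactly the sampling model the
Poisson-random-field likelihood assumes (free recombination between sites).
Polarization error is injected at the expected-SFS level (sampling from
psi*), which is equivalent under this model to flipping each site's
ancestral assignment independently with probability epsilon.

All randomness flows from explicit seeds; per-replicate and per-task
substreams are derived deterministically from the master seed by index, so
results are reproducible and independent of any parallel execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import Locus, SFSDataset
from .spectrum import (
    EpochModel,
    LocusModel,
    ModelSpec,
    apply_polarization_error,
    expected_divergence,
    expected_sfs,
    fold_expected,
)
from .weights import branch_weights

__all__ = [
    "simulate_usfs",
    "simulate_divergence",
    "linear_grid_design",
    "gamma_design",
    "run_replicates",
    "ReplicateSummary",
]


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_usfs(model: ModelSpec, n: int, seed: int,
                  with_divergence: bool = False, folded: bool = False,
                  strata: Optional[tuple] = None) -> SFSDataset:
    """Poisson-sample an SFS dataset under ``model`` at sample size ``n``.

    Counts d_{k,i} ~ Poisson(psi_{k,i}), with psi* when the locus has
    epsilon > 0 and folded class sums when ``folded`` (sums of independent
    Poissons are Poisson, so folding before or after sampling is the same
    model).  Substitution counts x_k ~ Poisson(lambda_k) when requested.
    """
    B = branch_weights(n)
    loci = []
    for k, lm in enumerate(model.loci):
        rng = _substream(seed, k)
        psi = expected_sfs(lm, model.epochs, B)
        if lm.epsilon > 0:
            psi = apply_polarization_error(psi, lm.epsilon)
        if folded:
            psi = fold_expected(psi, n)
        d = rng.poisson(psi)
        x = None
        if with_divergence:
            if model.divergence is None:
                raise ValueError("model carries no divergence parameters (c, t)")
            c, t = model.divergence
            x = int(rng.poisson(expected_divergence(lm, c, t)))
        loci.append(Locus(id=lm.id or f"locus{k}", m=lm.m, counts=d, x=x))
    return SFSDataset(n=n, loci=tuple(loci), folded=folded, strata=strata)


def simulate_divergence(model: ModelSpec, seed: int) -> np.ndarray:
    """x_k ~ Poisson(lambda_k) for every locus."""
    if model.divergence is None:
        raise ValueError("model carries no divergence parameters (c, t)")
    c, t = model.divergence
    rng = _substream(seed, 0xD1)
    lam = np.array([expected_divergence(lm, c, t) for lm in model.loci])
    return rng.poisson(lam)


def linear_grid_design(K: int, theta1: float = 0.01, theta_ratio: float = 5.0,
                       f1: float = 1.0, f_ratio: float = 5.0,
                       m: int = 5000, g: Sequence[float] = (10.0,),
                       epsilon: float = 0.0) -> tuple:
    """Loci whose theta falls linearly theta1 -> theta1/theta_ratio and whose
    f rises linearly f1 -> f1*f_ratio across K loci (locus 1 is the reference,
    so f1 should be 1)."""
    if K < 2:
        raise ValueError("a linear grid needs K >= 2 loci")
    thetas = np.linspace(theta1, theta1 / theta_ratio, K)
    fs = np.linspace(f1, f1 * f_ratio, K)
    return tuple(
        LocusModel(theta=float(th), f=float(fv), g=tuple(g), m=m,
                   epsilon=epsilon, id=f"locus{k}")
        for k, (th, fv) in enumerate(zip(thetas, fs))
    )


def gamma_design(K: int, seed: int, a_theta: float = 3.0, b_theta: float = 0.005,
                 a_f: float = 5.0, b_f: float = 0.2,
                 m: int = 10000, g: Sequence[float] = (10.0,)) -> tuple:
    """Loci with theta_k ~ Gamma(a_theta, scale b_theta) and f_k ~ Gamma(a_f, scale b_f).

    theta and f are independent across and within loci.  The first locus is
    the reference, so its f is set to 1 (all scaled parameters are defined
    against the reference locus's ancient N_e); its theta is still drawn.
    """
    if min(a_theta, b_theta, a_f, b_f) <= 0:
        raise ValueError("gamma shapes and scales must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = _substream(seed, 0x9A)
    thetas = rng.gamma(a_theta, b_theta, size=K)
    fs = rng.gamma(a_f, b_f, size=K)
    fs[0] = 1.0
    return tuple(
        LocusModel(theta=float(thetas[k]), f=float(fs[k]), g=tuple(g), m=m,
                   id=f"locus{k}")
        for k in range(K)
    )


@dataclass
class ReplicateSummary:
    """Mean/SD of MLEs, test rejection rates and locus-parameter regressions."""

    params: pd.DataFrame          # index: parameter name; columns: mean, sd, truth
    rejection: dict               # test name -> rejection frequency at 5%
    regressions: pd.DataFrame     # index: (quantity); columns: slope_mean, slope_sd, ...
    n_replicates: int
    n_failed: int
    records: list = field(default_factory=list)  # raw per-replicate dicts


def run_replicates(truth: ModelSpec, n: int, R: int, seed: int,
                   fit_builder: Optional[Callable] = None,
                   tests: Optional[dict] = None,
                   report: Optional[Callable] = None,
                   with_divergence: bool = False,
                   options=None,
                   regress_locus_params: bool = False,
                   max_failures: float = 0.1) -> ReplicateSummary:
    """Simulate R datasets under ``truth``, refit each, and summarize.

    fit_builder(data, options) -> FitResult; defaults to fitting the same
    structure as ``truth``.  tests maps a name to a callable
    (data, options) -> LRTResult, evaluated per replicate.  report maps a
    FitResult to a dict of named scalars (defaults to the shared parameters).
    With regress_locus_params, each replicate also records the slope and
    intercept of the regression of the per-locus MLEs of theta_k and f_k on
    their true values.
    """
    from . import inference as _inf

    if R < 1:
        raise ValueError("R must be >= 1")
    options = options or _inf.FitOptions()
    tests = tests or {}

    if fit_builder is None:
        def fit_builder(data, opts):
            return _inf.fit(data, truth, options=opts)

    if report is None:
        def report(res):
            out = {}
            H = res.model.epochs.H
            for h in range(H - 1):
                out[f"tau[{h}]"] = res.model.epochs.tau[h]
                if res.model.shared_g:
                    out[f"g[{h}]"] = res.model.loci[0].g[h]
            if res.model.divergence is not None:
                out["c"], out["t"] = res.model.divergence
            return out

    records, n_failed = [], 0
    reject_counts = {name: 0 for name in tests}
    test_totals = {name: 0 for name in tests}
    slopes = {"theta": [], "f": []}
    intercepts = {"theta": [], "f": []}
    true_theta = np.array([lm.theta for lm in truth.loci])
    true_f = np.array([lm.f for lm in truth.loci])

    for r in range(R):
        sub = int(np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0] % (2**31))
        data = simulate_usfs(truth, n, seed=sub, with_divergence=with_divergence)
        opts = replace(options, seed=sub)
        res = fit_builder(data, opts)
        if res is None or not res.success:
            n_failed += 1
            continue
        rec = dict(report(res))
        rec["_loglik"] = res.loglik
        records.append(rec)
        if regress_locus_params:
            est_theta = np.array([lm.theta for lm in res.model.loci])
            est_f = np.array([lm.f for lm in res.model.loci])
            for name, est, tru in (("theta", est_theta, true_theta),
                                   ("f", est_f, true_f)):
                b, a = np.polyfit(tru, est, 1)
                slopes[name].append(b)
                intercepts[name].append(a)
        for name, testfn in tests.items():
            result = testfn(data, opts)
            test_totals[name] += 1
            if result.significant_5pct:
                reject_counts[name] += 1

    if n_failed > max_failures * R:
        raise RuntimeError(f"{n_failed}/{R} replicate fits failed")
    if not records:
        raise RuntimeError("no successful replicates")

    names = [k for k in records[0] if not k.startswith("_")]
    rows = []
    for name in names:
        vals = np.array([rec[name] for rec in records])
        truth_val = np.nan
        try:
            truth_val = _inf._model_param(truth, name)
        except Exception:
            pass
        rows.append({"param": name, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                     "truth": truth_val})
    params = pd.DataFrame(rows).set_index("param")

    reg_rows = []
    if regress_locus_params:
        for name in ("theta", "f"):
            s = np.array(slopes[name])
            a = np.array(intercepts[name])
            reg_rows.append({
                "quantity": name,
                "slope_mean": s.mean(), "slope_sd": s.std(ddof=1) if len(s) > 1 else np.nan,
                "intercept_mean": a.mean(),
                "intercept_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
            })
    regressions = pd.DataFrame(reg_rows).set_index("quantity") if reg_rows else pd.DataFrame()

    rejection = {name: reject_counts[name] / test_totals[name]
                 for name in tests if test_totals[name] > 0}
    return ReplicateSummary(params=params, rejection=rejection,
                            regressions=regressions,
                            n_replicates=len(records), n_failed=n_failed,
                            records=records)
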