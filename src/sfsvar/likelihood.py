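"""Poisson random field composite log-likelihoods and analytic gradients.

Under free recombination and infinite sites, the count in each frequency
class of each locus is an independent Poisson variable with mean psi_{k,i}
(psi*_{k,i} once polarization error is modelled, Psi_{k,i} once folded), and
the substitution count to the outgroup is Poisson(lambda_k).  All reported
log-likelihood values omit the data-dependent constant sum_k sum_i ln(d!),
so they are comparable only across models evaluated on the same data —
exactly what likelihood-ratio tests need.

Conventions: 0*ln(0) = 0; a class with psi = 0 but d > 0 yields -inf
(impossible data under the model, a legitimate value for an optimizer to
reject).  Polarization error requires unfolded data: the folded spectrum
carries no information about it.

The scaled mutation rates enter every Poisson mean linearly, so given the
shape parameters (f, g, tau, epsilon, c, t) the per-locus theta has the
closed-form maximizer theta_hat = S/(m*phi_tot), or (S+x)/(m*(phi_tot+c*f+t))
with divergence; groups of loci constrained to share a theta pool their
counts.  The internal kernel can profile theta out this way: by the envelope
theorem the gradient of the profiled objective with respect to the shape
parameters is simply the full gradient evaluated at theta_hat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spectrum import ModelSpec, apply_polarization_error, fold_expected, _phi_core
from .weights import BranchWeights, branch_weights

__all__ = [
    "SFSDataset",
    "Locus",
    "loglik_full",
    "loglik_profile",
    "loglik_with_divergence",
    "loglik_gradient",
    "recover_theta",
]


@dataclass(frozen=True)
class Locus:
    """Observed data for one locus: id, length in bp, SFS counts, optional substitutions."""

    id: str
    m: int
    counts: np.ndarray
    x: Optional[int] = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        if not np.issubdtype(counts.dtype, np.integer) or np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.m <= 0:
            raise ValueError("locus length m must be positive")
        if self.x is not None and self.x < 0:
            raise ValueError("substitution count x must be >= 0")

    @property
    def S(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SFSDataset:
    """A collection of per-locus SFS counts sampled at n alleles."""

    n: int
    loci: tuple
    folded: bool = False
    strata: Optional[tuple] = None  # per-locus labels used by the block bootstrap

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        L = (self.n // 2) if self.folded else (self.n - 1)
        for loc in self.loci:
            if loc.counts.size != L:
                raise ValueError(
                    f"locus {loc.id!r}: expected {L} classes for n={self.n} "
                    f"({'folded' if self.folded else 'unfolded'}), got {loc.counts.size}"
                )
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        if self.strata is not None:
            object.__setattr__(self, "strata", tuple(self.strata))
            if len(self.strata) != len(self.loci):
                raise ValueError("strata must have one label per locus")

    @property
    def K(self) -> int:
        return len(self.loci)

    @property
    def has_divergence(self) -> bool:
        return all(loc.x is not None for loc in self.loci)

    def counts_matrix(self) -> np.ndarray:
        return np.stack([loc.counts for loc in self.loci])

    def pooled(self) -> "SFSDataset":
        """Sum counts classwise across loci into one combined locus."""
        total = self.counts_matrix().sum(axis=0)
        m = sum(loc.m for loc in self.loci)
        x = sum(loc.x for loc in self.loci) if self.has_divergence else None
        return SFSDataset(n=self.n, folded=self.folded,
                          loci=(Locus(id="pooled", m=m, counts=total, x=x),))

    def subset(self, indices) -> "SFSDataset":
        """Reindex loci (bootstrap resampling); ids are made unique."""
        loci = tuple(
            Locus(id=f"{self.loci[j].id}#{b}", m=self.loci[j].m,
                  counts=self.loci[j].counts, x=self.loci[j].x)
            for b, j in enumerate(indices)
        )
        strata = tuple(self.strata[j] for j in indices) if self.strata is not None else None
        return SFSDataset(n=self.n, folded=self.folded, loci=loci, strata=strata)


class _DataCache:
    """Immutable per-fit view of a dataset plus branch weights."""

    def __init__(self, data: SFSDataset, B: Optional[BranchWeights] = None):
        self.n = data.n
        self.folded = data.folded
        self.K = data.K
        self.counts = [loc.counts.astype(float) for loc in data.loci]
        self.S = np.array([loc.S for loc in data.loci], dtype=float)
        self.m = np.array([loc.m for loc in data.loci], dtype=float)
        self.x = (np.array([loc.x for loc in data.loci], dtype=float)
                  if data.has_divergence else None)
        self.B = B if B is not None else branch_weights(data.n)


def _poisson_terms(mean: np.ndarray, d: np.ndarray):
    """sum(-mean + d ln mean) with 0 ln 0 = 0, and its derivative w.r.t. mean."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(d > 0, np.log(np.where(mean > 0, mean, np.nan)), 0.0)
    if np.isnan(lg).any():  # d > 0 in a class with mean == 0
        return -np.inf, None
    val = float(np.sum(-mean + d * lg))
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = -1.0 + np.where(d > 0, d / mean, 0.0)
    return val, grad


def _kernel(dc: _DataCache, f, g, tau, eps, theta, c, t, use_div, grad,
            theta_groups=None):
    """Log-likelihood and gradients on parameter arrays.

    theta=None profiles the scaled mutation rates out in closed form
    (per-locus, or pooled within ``theta_groups`` equivalence classes); the
    returned value is then the FULL log-likelihood at theta_hat, whose shape
    gradient equals the profiled objective's gradient (envelope theorem).

    Returns (loglik, grads-or-None, theta_used).
    """
    n, K, B = dc.n, dc.K, dc.B
    H = len(tau) + 1
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float).reshape(K, H - 1)
    tau = np.asarray(tau, dtype=float)
    eps = np.zeros(K) if eps is None else np.asarray(eps, dtype=float)

    ph_list, dph_list = [], []
    for k in range(K):
        ph, dph = _phi_core(f[k], g[k], tau, B, grad=grad)
        ph_list.append(ph)
        dph_list.append(dph)
    phitot = np.array([ph.sum() for ph in ph_list])

    if theta is None:
        denom = dc.m * phitot
        numer = dc.S.copy()
        if use_div:
            denom = dc.m * (phitot + c * f + t)
            numer = numer + dc.x
        groups = np.arange(K) if theta_groups is None else np.asarray(theta_groups)
        theta = np.empty(K)
        for gid in np.unique(groups):
            sel = groups == gid
            theta[sel] = numer[sel].sum() / denom[sel].sum()
    else:
        theta = np.asarray(theta, dtype=float)

    total = 0.0
    out = None
    if grad:
        out = {"theta": np.zeros(K), "f": np.zeros(K), "g": np.zeros((K, H - 1)),
               "tau": np.zeros(H - 1), "eps": np.zeros(K)}
        if use_div:
            out["c"] = 0.0
            out["t"] = 0.0

    for k in range(K):
        ph = ph_list[k]
        psi = dc.m[k] * theta[k] * ph
        psi_star = apply_polarization_error(psi, eps[k]) if eps[k] > 0 else psi
        mean = fold_expected(psi_star, n) if dc.folded else psi_star
        val, r = _poisson_terms(mean, dc.counts[k])
        if not np.isfinite(val):
            return -np.inf, None, theta
        total += val
        if use_div:
            lam = dc.m[k] * theta[k] * (c * f[k] + t)
            dval, dr = _poisson_terms(np.array([lam]), np.array([dc.x[k]]))
            if not np.isfinite(dval):
                return -np.inf, None, theta
            total += dval
        if not grad:
            continue

        # back-propagate dL/d(mean) to the unfolded psi scale
        if dc.folded:
            u = np.zeros(n - 1)
            half = n // 2
            u[:half] = r
            for i in range(1, half + 1):
                if i < n - i:
                    u[n - i - 1] = r[i - 1]
        else:
            u = r
        out["eps"][k] = float(np.dot(u, psi[::-1] - psi))
        u_psi = (1.0 - eps[k]) * u + eps[k] * u[::-1] if eps[k] > 0 else u
        dph = dph_list[k]
        out["theta"][k] += float(np.dot(u_psi, dc.m[k] * ph))
        coef = dc.m[k] * theta[k]
        out["f"][k] += coef * float(np.dot(u_psi, dph["f"]))
        out["g"][k] += coef * (dph["g"] @ u_psi)
        out["tau"] += coef * (dph["tau"] @ u_psi)
        if use_div:
            s = float(dr[0])  # dL/dlambda
            out["theta"][k] += s * dc.m[k] * (c * f[k] + t)
            out["f"][k] += s * dc.m[k] * theta[k] * c
            out["c"] += s * dc.m[k] * theta[k] * f[k]
            out["t"] += s * dc.m[k] * theta[k]
    return total, out, theta


def _model_arrays(model: ModelSpec):
    theta = np.array([loc.theta for loc in model.loci])
    f = np.array([loc.f for loc in model.loci])
    g = np.array([loc.g for loc in model.loci]).reshape(model.K, model.epochs.H - 1)
    eps = np.array([loc.epsilon for loc in model.loci])
    return theta, f, g, eps


def _check(data: SFSDataset, model: ModelSpec):
    if model.K != data.K:
        raise ValueError("model and data must have the same number of loci")
    theta, f, g, eps = _model_arrays(model)
    if not (np.isfinite(theta).all() and np.isfinite(f).all()
            and np.isfinite(g).all() and np.isfinite(eps).all()):
        raise ValueError("non-finite model parameters")
    if data.folded and np.any(eps > 0):
        raise ValueError("polarization error cannot be combined with folded data: "
                         "the folded spectrum carries no information about it")
    return theta, f, g, eps


def _eval_model(data: SFSDataset, model: ModelSpec, use_div: bool, grad: bool,
                B: Optional[BranchWeights] = None):
    theta, f, g, eps = _check(data, model)
    if use_div:
        if model.divergence is None:
            raise ValueError("model carries no divergence parameters (c, t)")
        if not data.has_divergence:
            raise ValueError("every locus needs a substitution count x for divergence")
    c, t = model.divergence if model.divergence is not None else (None, None)
    dc = _DataCache(data, B)
    tau = np.asarray(model.epochs.tau)
    return _kernel(dc, f, g, tau, eps, theta, c, t, use_div, grad)


def loglik_full(data: SFSDataset, model: ModelSpec,
                B: Optional[BranchWeights] = None) -> float:
    """Composite Poisson log-likelihood of the SFS (divergence terms excluded)."""
    return _eval_model(data, model, use_div=False, grad=False, B=B)[0]


def loglik_with_divergence(data: SFSDataset, model: ModelSpec,
                           B: Optional[BranchWeights] = None) -> float:
    """SFS log-likelihood plus the Poisson divergence terms -lambda_k + x_k ln lambda_k."""
    return _eval_model(data, model, use_div=True, grad=False, B=B)[0]


def loglik_gradient(data: SFSDataset, model: ModelSpec,
                    B: Optional[BranchWeights] = None,
                    use_divergence: bool = False) -> dict:
    """Analytic gradient of the (optionally divergence-augmented) log-likelihood.

    Returns arrays keyed "theta" (K,), "f" (K,), "g" (K, H-1), "tau" (H-1,),
    "eps" (K,) and, with divergence, scalars "c" and "t".  Gradients are
    reported for every parameter; callers select which are free.
    """
    return _eval_model(data, model, use_div=use_divergence, grad=True, B=B)[1]


def loglik_profile(data: SFSDataset, model: ModelSpec,
                   B: Optional[BranchWeights] = None) -> float:
    """Conditional (multinomial) log-likelihood sum_k sum_i d_{k,i}[ln phi_{k,i} - ln phi_k].

    theta-free: depends only on the spectrum shape.  phi is replaced by the
    error-perturbed phi* when epsilon > 0 and by the folded Phi for folded
    data; the locus totals are unchanged by either operation.
    """
    _check(data, model)
    if B is None:
        B = branch_weights(data.n)
    total = 0.0
    for k, dloc in enumerate(data.loci):
        lm = model.loci[k]
        ph, _ = _phi_core(lm.f, np.asarray(lm.g), np.asarray(model.epochs.tau), B, grad=False)
        phtot = ph.sum()
        if lm.epsilon > 0:
            ph = apply_polarization_error(ph, lm.epsilon)
        if data.folded:
            ph = fold_expected(ph, data.n)
        with np.errstate(divide="ignore"):
            lg = np.where(dloc.counts > 0, np.log(ph), 0.0)
        total += float(np.sum(dloc.counts * lg)) - dloc.S * np.log(phtot)
    return total


def recover_theta(S_k: int, m_k: int, phi_total: float) -> float:
    """Closed-form profile MLE of the scaled mutation rate: theta = S / (m * phi)."""
    if phi_total <= 0:
        raise ValueError("phi_total must be positive")
    if S_k < 0 or m_k <= 0:
        raise ValueError("need S_k >= 0 and m_k > 0")
    return S_k / (m_k * phi_total)
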