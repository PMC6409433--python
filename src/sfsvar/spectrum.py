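"""Expected site-frequency spectra under a stepwise demography with locus-specific scalars.

Model: going backward in time the population passes through H epochs; epoch H
(the most distant) extends indefinitely into the past with reference effective
size N1 at the reference locus.  Locus k has size f_k * N1 in epoch H and
g_{k,h} * f_k * N1 in epoch h < H (g_{k,H} = 1 implicitly).  Epoch durations
tau_h are scaled in units of 2*N1 generations and shared across loci; theta_k
(= 4*N1*u_k per site) is also defined against the reference N1 so values are
comparable between loci.

The expected number of segregating sites of derived-allele frequency i at a
locus of m bp is

    psi_i = m * theta * phi_i,   phi_i = f * [ g_1 / i + A_i ],

where A_i sums, over epochs h = 1..H-1 and lineage counts j = 2..n,

    (g_{h+1} - g_h) * exp(-binom(j,2) * sum_{l<=h} tau_l / (f g_l)) * B_i(j).

Divergence to a single outgroup sequence adds an expected substitution count
lambda = m * theta * (c*f + t) with ancestral-size scalar c and scaled split
time t shared across loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .weights import BranchWeights, branch_weights

__all__ = [
    "EpochModel",
    "LocusModel",
    "ModelSpec",
    "epoch_decay_A",
    "phi",
    "phi_with_grad",
    "expected_sfs",
    "fold_expected",
    "apply_polarization_error",
    "expected_divergence",
]


@dataclass(frozen=True)
class EpochModel:
    """Stepwise demography: H epochs, scaled durations tau (most recent first)."""

    H: int
    tau: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "tau", tuple(float(t) for t in self.tau))
        if self.H < 1:
            raise ValueError("number of epochs H must be >= 1")
        if len(self.tau) != self.H - 1:
            raise ValueError(f"need H-1={self.H - 1} epoch durations, got {len(self.tau)}")
        if any(t <= 0 for t in self.tau):
            raise ValueError("epoch durations tau must be positive")


@dataclass(frozen=True)
class LocusModel:
    """Per-locus parameters: theta, f, epoch multipliers g, length m, polarization error."""

    theta: float
    f: float
    g: tuple = ()
    m: int = 1
    epsilon: float = 0.0
    id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "g", tuple(float(v) for v in self.g))
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.f <= 0:
            raise ValueError("f must be > 0")
        if any(v <= 0 for v in self.g):
            raise ValueError("all g multipliers must be > 0")
        if self.m <= 0:
            raise ValueError("locus length m must be a positive integer")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("polarization error epsilon must lie in [0, 0.5]")


@dataclass(frozen=True)
class ModelSpec:
    """Epochs plus loci, optional shared-g simplification and divergence (c, t)."""

    epochs: EpochModel
    loci: tuple
    shared_g: bool = False
    divergence: Optional[tuple] = None  # (c, t)
    reference: int = 0

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        H = self.epochs.H
        for loc in self.loci:
            if len(loc.g) != H - 1:
                raise ValueError("each locus needs H-1 epoch multipliers g")
        if not self.loci:
            raise ValueError("at least one locus required")
        if not 0 <= self.reference < len(self.loci):
            raise ValueError("reference locus index out of range")
        if abs(self.loci[self.reference].f - 1.0) > 1e-12:
            raise ValueError("reference locus must have f = 1")
        if self.shared_g:
            g0 = self.loci[0].g
            if any(loc.g != g0 for loc in self.loci):
                raise ValueError("shared_g requires identical g vectors at all loci")
        if self.divergence is not None:
            c, t = self.divergence
            if c <= 0:
                raise ValueError("ancestral-size scalar c must be > 0")
            if t < 0:
                raise ValueError("scaled split time t must be >= 0")

    @property
    def K(self) -> int:
        return len(self.loci)


def _epoch_sums(f: float, g: Sequence[float], tau: Sequence[float]) -> np.ndarray:
    """Cumulative scaled intensities E_h = sum_{l<=h} tau_l / (f g_l)."""
    g = np.asarray(g, dtype=float)
    tau = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):  # f may underflow mid-line-search
        return np.cumsum(tau / (f * g))


def epoch_decay_A(i: int, locus: LocusModel, epochs: EpochModel, B: BranchWeights) -> float:
    """A_i for a single frequency class (see phi for the vectorized form)."""
    return float(_A_vector(locus.f, np.asarray(locus.g), np.asarray(epochs.tau), B)[i - 1])


def _A_vector(f, g, tau, B: BranchWeights) -> np.ndarray:
    H = len(tau) + 1
    if H == 1:
        return np.zeros(B.n - 1)
    E = _epoch_sums(f, g, tau)
    gH = np.append(g, 1.0)
    A = np.zeros(B.n - 1)
    cj = B.cj
    for h in range(H - 1):
        s = np.exp(-np.minimum(cj * E[h], 745.0))
        s[cj * E[h] > 700.0] = 0.0
        A += (gH[h + 1] - gH[h]) * (B.B @ s)
    return A


def phi(locus: LocusModel, epochs: EpochModel, B: Optional[BranchWeights] = None,
        n: Optional[int] = None) -> np.ndarray:
    """Scaled expected spectrum phi_i = f [g_1/i + A_i], i = 1..n-1.

    Raises FloatingPointError if any entry is non-positive (invalid parameter
    region for the optimizer).
    """
    if B is None:
        B = branch_weights(n)
    out, _ = _phi_core(locus.f, np.asarray(locus.g), np.asarray(epochs.tau), B, grad=False)
    return out


def _phi_core(f, g, tau, B: BranchWeights, grad: bool):
    """phi and (optionally) its gradients w.r.t. f, g_1..g_{H-1}, tau_1..tau_{H-1}."""
    n = B.n
    H = len(tau) + 1
    i_inv = 1.0 / np.arange(1, n, dtype=float)
    cj = B.cj
    if H == 1:
        ph = f * i_inv
        if not grad:
            return ph, None
        return ph, {"f": i_inv, "g": np.zeros((0, n - 1)), "tau": np.zeros((0, n - 1))}

    E = _epoch_sums(f, g, tau)
    gH = np.append(g, 1.0)
    w = np.diff(gH)  # w_h = g_{h+1} - g_h, h = 1..H-1
    s_list, a_list, q_list = [], [], []
    for h in range(H - 1):
        ex = cj * E[h]
        s = np.where(ex > 700.0, 0.0, np.exp(-np.minimum(ex, 745.0)))
        s_list.append(s)
        a_list.append(B.B @ s)
        if grad:
            q_list.append(B.B @ (cj * s))
    A = sum(w[h] * a_list[h] for h in range(H - 1))
    base = g[0] * i_inv + A
    ph = f * base
    if ph.min() <= 0.0:
        raise FloatingPointError("non-positive expected spectrum entry (invalid parameters)")
    if not grad:
        return ph, None

    # dA/df through the exponents: (1/f) * sum_h w_h E_h q_h
    dA_df = sum(w[h] * E[h] * q_list[h] for h in range(H - 1)) / f
    dphi_df = base + f * dA_df

    dphi_dtau = np.zeros((H - 1, n - 1))
    for l in range(H - 1):
        acc = sum(w[h] * q_list[h] for h in range(l, H - 1))
        dphi_dtau[l] = f * (-acc / (f * g[l]))

    dphi_dg = np.zeros((H - 1, n - 1))
    for m_ in range(H - 1):
        direct = -a_list[m_]
        if m_ >= 1:
            direct = direct + a_list[m_ - 1]
        expo = sum(w[h] * q_list[h] for h in range(m_, H - 1)) * (tau[m_] / (f * g[m_] ** 2))
        dA = direct + expo
        dphi_dg[m_] = f * dA
        if m_ == 0:
            dphi_dg[m_] += f * i_inv
    return ph, {"f": dphi_df, "g": dphi_dg, "tau": dphi_dtau}


def phi_with_grad(locus: LocusModel, epochs: EpochModel, B: BranchWeights):
    """phi and analytic gradients w.r.t. (f, g, tau); see _phi_core."""
    return _phi_core(locus.f, np.asarray(locus.g), np.asarray(epochs.tau), B, grad=True)


def expected_sfs(locus: LocusModel, epochs: EpochModel, B: Optional[BranchWeights] = None,
                 n: Optional[int] = None) -> np.ndarray:
    """Expected unfolded SFS psi_i = m * theta * phi_i (polarization error NOT applied)."""
    return locus.m * locus.theta * phi(locus, epochs, B=B, n=n)


def fold_expected(psi: np.ndarray, n: int) -> np.ndarray:
    """Fold an expected (or observed) unfolded spectrum onto minor-allele classes.

    Psi_i = psi_i + psi_{n-i} for i < n-i; the middle class (i = n/2, n even)
    is carried over unchanged.  The total is conserved.
    """
    psi = np.asarray(psi, dtype=float)
    if psi.shape[-1] != n - 1:
        raise ValueError(f"unfolded spectrum must have length n-1={n - 1}")
    half = n // 2
    out = psi[..., :half].copy()
    for i in range(1, half + 1):
        if i < n - i:
            out[..., i - 1] += psi[..., n - i - 1]
    return out


def apply_polarization_error(psi: np.ndarray, epsilon: float) -> np.ndarray:
    """Mix the unfolded spectrum with its reversal: psi*_i = (1-e) psi_i + e psi_{n-i}."""
    if not 0.0 <= epsilon <= 0.5:
        raise ValueError("epsilon must lie in [0, 0.5]")
    psi = np.asarray(psi, dtype=float)
    return (1.0 - epsilon) * psi + epsilon * psi[..., ::-1]


def expected_divergence(locus: LocusModel, c: float, t: float) -> float:
    """Expected substitutions to the outgroup: lambda = m * theta * (c f + t)."""
    if c <= 0:
        raise ValueError("c must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    return locus.m * locus.theta * (c * locus.f + t)
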