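"""Multi-start maximum-likelihood fitting, constrained fits, LRTs and bootstraps.

Free parameters are optimized in transformed coordinates — log for the
positive parameters (theta, f, g, tau, c, t) and a scaled logit on [0, 0.5]
for polarization-error rates — so positivity constraints are implicit and the
search is unconstrained and smooth.  Equality constraints between named
parameters, and pins to constants, are applied by parameter elimination:
tied slots collapse onto one free coordinate, pinned slots leave the free
vector entirely.

By default the scaled mutation rates are profiled out in closed form (see
likelihood), which removes K coordinates from the search; the objective is
then the full log-likelihood at theta_hat, so the values stored in FitResult
are directly comparable between nested fits on the same data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .likelihood import SFSDataset, Locus, _DataCache, _kernel
from .spectrum import EpochModel, LocusModel, ModelSpec
from .weights import branch_weights

__all__ = [
    "ConstraintSet",
    "FitOptions",
    "FitResult",
    "LRTResult",
    "fit",
    "fit_constrained",
    "fit_pooled",
    "lrt",
    "bootstrap_pvalue",
    "bootstrap_ci",
]

# natural-scale boxes from which multi-start points are drawn (log-uniform)
_START_BOXES = {
    "theta": (1e-5, 1e-1),
    "f": (0.05, 20.0),
    "g": (0.05, 50.0),
    "tau": (1e-3, 10.0),
    "c": (0.1, 10.0),
    "t": (0.1, 50.0),
    "eps": (1e-3, 0.3),
}

_PENALTY = 1e15  # objective value returned inside an invalid parameter region


@dataclass(frozen=True)
class ConstraintSet:
    """Equality ties between named parameters and pins to constants.

    Parameter names: ``theta[k]``, ``f[k]``, ``g[k,h]`` (``g[h]`` under a
    shared-g model), ``tau[h]``, ``eps[k]``, ``c``, ``t``.
    """

    ties: tuple = ()
    pins: tuple = ()  # pairs (name, value)

    def __post_init__(self):
        object.__setattr__(self, "ties", tuple(tuple(t) for t in self.ties))
        object.__setattr__(self, "pins", tuple((n, float(v)) for n, v in self.pins))

    @property
    def empty(self) -> bool:
        return not self.ties and not self.pins


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 20
    seed: int = 0
    gtol: float = 1e-8
    ftol: float = 1e-12
    maxiter: int = 1000
    use_profile: bool = True
    use_divergence: Optional[bool] = None  # None: inferred from the template
    fit_epsilon: bool = False


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_asymptotic: float
    p_bootstrap: Optional[float] = None
    n_bootstrap: Optional[int] = None

    @property
    def significant_5pct(self) -> bool:
        p = self.p_bootstrap if self.p_bootstrap is not None else self.p_asymptotic
        return p < 0.05


@dataclass
class FitResult:
    model: Optional[ModelSpec]
    loglik: float
    free_names: list
    free_values: Optional[np.ndarray]
    n_starts: int
    start_logliks: np.ndarray
    converged: np.ndarray
    best_start_index: int
    runtime_s: float
    options: FitOptions

    @property
    def success(self) -> bool:
        return self.model is not None and np.isfinite(self.loglik)

    def param(self, name: str) -> float:
        """Look up any natural parameter (free, pinned or recovered theta) by name."""
        return _model_param(self.model, name)


def _model_param(model: ModelSpec, name: str) -> float:
    if name == "c":
        return model.divergence[0]
    if name == "t":
        return model.divergence[1]
    kind, idx = _parse_name(name)
    if kind == "tau":
        return model.epochs.tau[idx[0]]
    if kind == "theta":
        return model.loci[idx[0]].theta
    if kind == "f":
        return model.loci[idx[0]].f
    if kind == "eps":
        return model.loci[idx[0]].epsilon
    if kind == "g":
        k, h = (idx[0], idx[1]) if len(idx) == 2 else (0, idx[0])
        return model.loci[k].g[h]
    raise KeyError(name)


def _parse_name(name: str):
    if name in ("c", "t"):
        return name, ()
    kind, _, rest = name.partition("[")
    if not rest.endswith("]"):
        raise ValueError(f"malformed parameter name {name!r}")
    idx = tuple(int(v) for v in rest[:-1].split(","))
    return kind, idx


class ParamMap:
    """Free-vector <-> natural-parameter-array mapping with pins and ties."""

    def __init__(self, data: SFSDataset, template: ModelSpec,
                 constraints: Optional[ConstraintSet], options: FitOptions):
        K, H = data.K, template.epochs.H
        self.K, self.H = K, H
        self.shared_g = template.shared_g
        use_div = options.use_divergence
        if use_div is None:
            use_div = template.divergence is not None
        if use_div and not data.has_divergence:
            raise ValueError("divergence model requested but data lack substitution counts")
        self.use_div = use_div
        self.use_profile = options.use_profile
        self.fit_epsilon = options.fit_epsilon
        if options.fit_epsilon and data.folded:
            raise ValueError("polarization error cannot be fitted to folded data")
        self.reference = template.reference

        slots = [f"f[{k}]" for k in range(K)]
        if self.shared_g:
            slots += [f"g[{h}]" for h in range(H - 1)]
        else:
            slots += [f"g[{k},{h}]" for k in range(K) for h in range(H - 1)]
        slots += [f"tau[{h}]" for h in range(H - 1)]
        if options.fit_epsilon:
            slots += [f"eps[{k}]" for k in range(K)]
        if use_div:
            slots += ["c", "t"]
        slots += [f"theta[{k}]" for k in range(K)]
        self.slots = slots
        self._parent = {s: s for s in slots}
        self._pin = {}

        self._pin_slot(f"f[{self.reference}]", 1.0)
        constraints = constraints or ConstraintSet()
        for group in constraints.ties:
            if len(group) < 2:
                raise ValueError("a tie needs at least two parameter names")
            kinds = set()
            for name in group:
                self._require(name)
                kinds.add(_parse_name(name)[0])
            if len(kinds) > 1:
                raise ValueError(f"tie {group} mixes parameter kinds {sorted(kinds)}")
            first = group[0]
            for other in group[1:]:
                self._union(first, other)
        for name, value in constraints.pins:
            self._require(name)
            self._pin_slot(name, value)

        theta_slots = {f"theta[{k}]" for k in range(K)}
        free_roots, seen = [], set()
        for s in slots:
            r = self._find(s)
            if r in seen or r in self._pin:
                continue
            seen.add(r)
            if self.use_profile and s in theta_slots:
                continue
            free_roots.append(r)
        if self.use_profile:
            for r in list(self._pin):
                if r in theta_slots:
                    raise ValueError("cannot pin theta under profile likelihood")
            roots = [self._find(f"theta[{k}]") for k in range(K)]
            uniq = {r: i for i, r in enumerate(dict.fromkeys(roots))}
            self.theta_groups = np.array([uniq[r] for r in roots])
        else:
            self.theta_groups = None
        self.free_roots = free_roots
        self.n_free = len(free_roots)

        if H == 1:
            bad = [r for r in free_roots if r.startswith(("f[", "g["))]
            if bad:
                raise ValueError(
                    "H=1 leaves only the composite theta*_k identifiable; "
                    f"free parameters {bad} must be pinned or absent")

        # mapping from slot -> position in the free vector (or pinned value)
        self._slot_free_index = {}
        root_index = {r: i for i, r in enumerate(free_roots)}
        for s in slots:
            r = self._find(s)
            if r in self._pin:
                self._slot_free_index[s] = ("pin", self._pin[r])
            elif r in root_index:
                self._slot_free_index[s] = ("free", root_index[r])
            else:  # profiled theta
                self._slot_free_index[s] = ("profile", None)

    # -- union-find ---------------------------------------------------------
    def _require(self, name):
        if name not in self._parent:
            raise ValueError(f"unknown parameter name {name!r} for this model")

    def _find(self, s):
        while self._parent[s] != s:
            self._parent[s] = self._parent[self._parent[s]]
            s = self._parent[s]
        return s

    def _union(self, a, b):
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            self._parent[rb] = ra

    def _pin_slot(self, name, value):
        r = self._find(name)
        if r in self._pin and self._pin[r] != value:
            raise ValueError(f"conflicting pins for {name}")
        self._pin[r] = float(value)

    # -- transforms ---------------------------------------------------------
    @staticmethod
    def _kind(name):
        return _parse_name(name)[0]

    def _to_natural(self, name, y):
        if self._kind(name) == "eps":
            return 0.5 / (1.0 + np.exp(-y))
        return np.exp(np.minimum(y, 700.0))  # clip: line searches can overshoot

    def _dnatural_dy(self, name, v):
        if self._kind(name) == "eps":
            return v * (1.0 - 2.0 * v)
        return v

    def to_transformed(self, name, v):
        if self._kind(name) == "eps":
            if not 0 < v < 0.5:
                raise ValueError("eps start must lie strictly inside (0, 0.5)")
            return np.log(2 * v / (1 - 2 * v))
        return np.log(v)

    # -- vector <-> arrays --------------------------------------------------
    def _slot_value(self, name, x):
        tag, payload = self._slot_free_index[name]
        if tag == "pin":
            return payload
        if tag == "free":
            return self._to_natural(self.free_roots[payload], x[payload])
        raise RuntimeError(f"slot {name} has no explicit value (profiled)")

    def natural(self, x):
        K, H = self.K, self.H
        f = np.array([self._slot_value(f"f[{k}]", x) for k in range(K)])
        if self.shared_g:
            grow = [self._slot_value(f"g[{h}]", x) for h in range(H - 1)]
            g = np.tile(np.array(grow), (K, 1))
        else:
            g = np.array([[self._slot_value(f"g[{k},{h}]", x) for h in range(H - 1)]
                          for k in range(K)])
        tau = np.array([self._slot_value(f"tau[{h}]", x) for h in range(H - 1)])
        if self.fit_epsilon:
            eps = np.array([self._slot_value(f"eps[{k}]", x) for k in range(K)])
        else:
            eps = np.zeros(K)
        c = self._slot_value("c", x) if self.use_div else None
        t = self._slot_value("t", x) if self.use_div else None
        if self.use_profile:
            theta = None
        else:
            theta = np.array([self._slot_value(f"theta[{k}]", x) for k in range(K)])
        return f, g, tau, eps, c, t, theta

    def collapse_grad(self, x, grads):
        """Aggregate natural-parameter gradients onto the transformed free vector."""
        out = np.zeros(self.n_free)
        K, H = self.K, self.H

        def add(name, gnat):
            tag, payload = self._slot_free_index[name]
            if tag != "free":
                return
            root = self.free_roots[payload]
            v = self._to_natural(root, x[payload])
            out[payload] += gnat * self._dnatural_dy(root, v)

        for k in range(K):
            add(f"f[{k}]", grads["f"][k])
            for h in range(H - 1):
                if self.shared_g:
                    add(f"g[{h}]", grads["g"][k, h])
                else:
                    add(f"g[{k},{h}]", grads["g"][k, h])
            if self.fit_epsilon:
                add(f"eps[{k}]", grads["eps"][k])
            if not self.use_profile:
                add(f"theta[{k}]", grads["theta"][k])
        for h in range(H - 1):
            add(f"tau[{h}]", grads["tau"][h])
        if self.use_div:
            add("c", grads["c"])
            add("t", grads["t"])
        return out

    def random_start(self, rng) -> np.ndarray:
        x = np.empty(self.n_free)
        for i, root in enumerate(self.free_roots):
            lo, hi = _START_BOXES[self._kind(root)]
            v = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            x[i] = self.to_transformed(root, v)
        return x


def _objective(dc: _DataCache, pm: ParamMap):
    def fun(x):
        f, g, tau, eps, c, t, theta = pm.natural(x)
        try:
            with np.errstate(all="ignore"):
                ll, grads, _ = _kernel(dc, f, g, tau, eps, theta, c, t,
                                       pm.use_div, grad=True,
                                       theta_groups=pm.theta_groups)
        except FloatingPointError:
            return _PENALTY, np.zeros(pm.n_free)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros(pm.n_free)
        gvec = -pm.collapse_grad(x, grads)
        if not np.isfinite(gvec).all():
            return _PENALTY, np.zeros(pm.n_free)
        return -ll, gvec
    return fun


def _assemble_model(data: SFSDataset, pm: ParamMap, template: ModelSpec, x) -> ModelSpec:
    f, g, tau, eps, c, t, theta = pm.natural(x)
    dc = _DataCache(data)
    ll, _, theta_used = _kernel(dc, f, g, tau, eps, theta, c, t, pm.use_div,
                                grad=False, theta_groups=pm.theta_groups)
    loci = tuple(
        LocusModel(theta=float(theta_used[k]), f=float(f[k]), g=tuple(g[k]),
                   m=data.loci[k].m, epsilon=float(eps[k]), id=data.loci[k].id)
        for k in range(data.K)
    )
    divergence = (float(c), float(t)) if pm.use_div else None
    return ModelSpec(epochs=EpochModel(pm.H, tuple(tau)), loci=loci,
                     shared_g=pm.shared_g, divergence=divergence,
                     reference=pm.reference)


def fit(data: SFSDataset, template: ModelSpec,
        constraints: Optional[ConstraintSet] = None,
        options: Optional[FitOptions] = None) -> FitResult:
    """Best-of-multi-start MLE of the model described by ``template``.

    ``template`` fixes the structure (H, shared_g, divergence on/off,
    reference locus); its parameter values are not used as starting points.
    Deterministic given (data, options.seed).
    """
    options = options or FitOptions()
    if options.n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    pm = ParamMap(data, template, constraints, options)
    dc = _DataCache(data)
    fun = _objective(dc, pm)
    t0 = time.perf_counter()

    if pm.n_free == 0:
        val, _ = fun(np.empty(0))
        ll = -val
        model = _assemble_model(data, pm, template, np.empty(0))
        return FitResult(model=model, loglik=ll, free_names=[],
                         free_values=np.empty(0), n_starts=1,
                         start_logliks=np.array([ll]),
                         converged=np.array([True]), best_start_index=0,
                         runtime_s=time.perf_counter() - t0, options=options)

    rng = np.random.default_rng(np.random.SeedSequence(options.seed))
    best = None
    logliks, convs, xs = [], [], []
    for s in range(options.n_starts):
        x0 = pm.random_start(rng)
        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=options.maxiter,
                                    ftol=options.ftol, gtol=options.gtol))
        ok = bool(res.success) and res.fun < _PENALTY / 2
        logliks.append(-res.fun if res.fun < _PENALTY / 2 else -np.inf)
        convs.append(ok)
        xs.append(res.x)
        # ties within 1e-6 go to the first-found start
        if ok and (best is None or res.fun < best[0] - 1e-6):
            best = (res.fun, s, res.x)

    logliks = np.array(logliks)
    convs = np.array(convs)
    if best is None:
        return FitResult(model=None, loglik=-np.inf, free_names=list(pm.free_roots),
                         free_values=None, n_starts=options.n_starts,
                         start_logliks=logliks, converged=convs,
                         best_start_index=-1,
                         runtime_s=time.perf_counter() - t0, options=options)
    _, sbest, xbest = best
    model = _assemble_model(data, pm, template, xbest)
    return FitResult(model=model, loglik=float(logliks[sbest]),
                     free_names=list(pm.free_roots), free_values=xbest,
                     n_starts=options.n_starts, start_logliks=logliks,
                     converged=convs, best_start_index=sbest,
                     runtime_s=time.perf_counter() - t0, options=options)


def fit_constrained(data: SFSDataset, template: ModelSpec,
                    constraints: ConstraintSet,
                    options: Optional[FitOptions] = None) -> FitResult:
    """fit() with an explicit ConstraintSet (constraints by parameter elimination)."""
    return fit(data, template, constraints=constraints, options=options)


def fit_pooled(data: SFSDataset, epochs_template: EpochModel,
               options: Optional[FitOptions] = None) -> FitResult:
    """Naive pooled fit: sum the per-locus uSFS classwise, fit one locus.

    Disregards between-locus variation in N_e and u: used to demonstrate the
    bias this shortcut produces under heterogeneous loci.
    """
    if data.folded:
        raise ValueError("pooled fit is defined for unfolded data")
    pooled = data.pooled()
    template = ModelSpec(
        epochs=epochs_template,
        loci=(LocusModel(theta=1e-3, f=1.0,
                         g=tuple(1.0 for _ in range(epochs_template.H - 1)),
                         m=pooled.loci[0].m, id="pooled"),),
    )
    options = options or FitOptions()
    options = replace(options, use_divergence=False)
    return fit(pooled, template, options=options)


def lrt(full: FitResult, null: FitResult, df: int) -> LRTResult:
    """Likelihood-ratio test of a null fit nested in a full fit on the same data."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (full.success and null.success):
        raise ValueError("both fits must have succeeded")
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < -1e-6:
        raise ValueError(f"negative LRT statistic ({stat:.3g}): optimization failure")
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p_asymptotic=float(chi2.sf(stat, df)))


def bootstrap_pvalue(data: SFSDataset, template: ModelSpec,
                     constraints: ConstraintSet, df: int,
                     B: int, seed: int,
                     options: Optional[FitOptions] = None,
                     max_failures: float = 0.1) -> LRTResult:
    """Parametric-bootstrap p-value for the LRT defined by ``constraints``.

    Simulates B datasets under the null MLE, refits both models on each, and
    reports p = (1 + #{stat_b >= observed}) / (B + 1); with zero exceedances
    this equals 1/(B+1), i.e. "p < 1/(B+1)".
    """
    from .simulate import simulate_usfs  # local import to avoid a cycle

    if B < 1:
        raise ValueError("B must be >= 1")
    options = options or FitOptions()
    full = fit(data, template, options=options)
    null = fit(data, template, constraints=constraints, options=options)
    observed = lrt(full, null, df)

    use_div = null.model.divergence is not None
    stats, failures = [], 0
    for b in range(B):
        sub = np.random.SeedSequence(seed, spawn_key=(b,)).generate_state(1)[0] % (2**31)
        bdata = simulate_usfs(null.model, data.n, seed=int(sub),
                              with_divergence=use_div, folded=data.folded)
        bopts = replace(options, seed=int(sub))
        bfull = fit(bdata, template, options=bopts)
        bnull = fit(bdata, template, constraints=constraints, options=bopts)
        if not (bfull.success and bnull.success):
            failures += 1
            continue
        stats.append(max(2.0 * (bfull.loglik - bnull.loglik), 0.0))
    if failures > max_failures * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    stats = np.array(stats)
    p = (1.0 + np.sum(stats >= observed.statistic)) / (len(stats) + 1.0)
    return LRTResult(statistic=observed.statistic, df=df,
                     p_asymptotic=observed.p_asymptotic,
                     p_bootstrap=float(p), n_bootstrap=len(stats))


def bootstrap_ci(data: SFSDataset, template: ModelSpec,
                 B: int, seed: int, level: float = 0.95,
                 constraints: Optional[ConstraintSet] = None,
                 options: Optional[FitOptions] = None,
                 params: Optional[Sequence[str]] = None,
                 derived: Optional[dict] = None,
                 max_failures: float = 0.1):
    """Nonparametric (block) bootstrap percentile CIs.

    Loci are resampled with replacement; when ``data.strata`` is set the
    resampling is stratified, keeping the number of loci per stratum equal to
    the original.  Each resample is refitted and percentile intervals at
    ``level`` are reported for the named parameters (default: all shared,
    i.e. non-locus-indexed, free parameters — per-locus parameters only keep
    their meaning across resamples when tied within strata).  ``derived``
    maps extra report names to callables FitResult -> float.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    options = options or FitOptions()
    pm = ParamMap(data, template, constraints, options)
    if params is None:
        params = [r for r in pm.free_roots if not r.startswith(("f[", "theta[", "eps["))]
    derived = derived or {}

    strata = data.strata if data.strata is not None else tuple("all" for _ in data.loci)
    by_stratum = {}
    for j, s in enumerate(strata):
        by_stratum.setdefault(s, []).append(j)

    draws = {name: [] for name in list(params) + list(derived)}
    failures = 0
    for b in range(B):
        sub = np.random.SeedSequence(seed, spawn_key=(b,)).generate_state(1)[0] % (2**31)
        rng = np.random.default_rng(sub)
        idx = []
        for s, members in by_stratum.items():
            idx.extend(rng.choice(members, size=len(members), replace=True))
        bdata = data.subset(idx)
        # fixed optimizer seed: identical resamples give identical refits
        res = fit(bdata, template, constraints=constraints, options=options)
        if not res.success:
            failures += 1
            continue
        for name in params:
            draws[name].append(res.param(name))
        for name, fn in derived.items():
            draws[name].append(fn(res))
    if failures > max_failures * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    out = {}
    for name, vals in draws.items():
        v = np.asarray(vals, dtype=float)
        out[name] = (float(np.percentile(v, 100 * alpha)),
                     float(np.percentile(v, 100 * (1 - alpha))))
    return out
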