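# Methods

## Model

`sfsvar` fits a Poisson random field (PRF) model of multilocus polymorphism
under a stepwise demography. Time runs backward through H epochs; epoch H
extends indefinitely into the past with effective size N₁ at a designated
reference locus. All scaled parameters are defined against N₁ so they are
comparable between loci:

| parameter | meaning | units / default |
|---|---|---|
| θ_k = 4N₁u_k | scaled mutation rate of locus k per site | dimensionless; profiled out by default |
| f_k | locus-k N_e scalar in the most distant epoch | f ≡ 1 at the reference locus |
| g_{k,h} | size multiplier in epoch h < H (size g_{k,h}f_kN₁) | g_{k,H} ≡ 1, never stored |
| τ_h | duration of epoch h, shared across loci | units of 2N₁ generations |
| ε_k | polarization-error probability | [0, ½]; 0.5 makes classes i and n−i indistinguishable, hence the bound |
| c, t | ancestral-size scalar and scaled split time of the divergence model | shared across loci |

The expected unfolded SFS of locus k (length m_k bp, n sampled alleles) is
ψ_{k,i} = m_kθ_kφ_{k,i} with φ_{k,i} = f_k[g_{k,1}/i + A_{k,i}], where
A_{k,i} = Σ_h (g_{k,h+1} − g_{k,h}) Σ_j exp(−C(j,2) Σ_{l≤h} τ_l/(f_k g_{k,l})) B_i(j).
With only one epoch φ reduces to the equilibrium f/i, and only the
composite θ*_k = θ_k f_k is identifiable — the fitter enforces this
(demanding free f or g under H = 1 is an error).

Assumptions inherited from the PRF: neutrality, the infinite-sites mutation
model, and free recombination between sites, making class counts
independent Poissons. The composite log-likelihood drops the data-only
constant Σ ln d!, so reported values are comparable only across models on
fixed data — exactly the property likelihood-ratio tests require.
Divergence to a single outgroup sequence is modelled as
x_k ~ Poisson(m_kθ_k(c·f_k + t)); this deliberately ignores substitution-model
complications (no multiple-hit or nonequilibrium base-composition
correction), so it is a long-branch approximation appropriate for
moderately diverged outgroups.

## Branch-length weights

ψ needs the weights B_i(j) — the contribution of the j-lineage portion of
the genealogy to frequency class i. The closed form is an alternating sum
whose terms cancel catastrophically in double precision as n grows (the
naive route needs hundreds of decimal digits by n = 1000). Production code
therefore uses the Polanski–Kimmel recursion for W_{i,j} = j(j−1)B_i(j):

    W_{i,2} = 6/(n+1),  W_{i,3} = 30(n−2i)/((n+1)(n+2)),
    W_{i,j+2} = −(1+j)(3+2j)(n−j)/(j(2j−1)(n+j+1)) · W_{i,j}
                + (3+2j)(n−2i)/(j(n+j+1)) · W_{i,j+1},

which is stable and fast in double precision. The alternating sum is kept
as an *exact* oracle (stdlib rational arithmetic, no floating point at all)
and the two routes are compared in tests for every (i, j) up to n = 40 at
1e−8 relative with an absolute floor of 1e−15: exact entries decay below
1e−20 near j = n, where relative comparison is meaningless and the entries
contribute nothing to any spectrum. The identity Σ_j B_i(j) = 1/i is
checked through n = 1000. Weight tables are cached per n.

## Likelihood variants and gradients

* **Full** — Σ_k Σ_i [−ψ_{k,i} + d_{k,i} ln ψ_{k,i}], with 0·ln 0 ≡ 0 and
  −∞ returned when a class has ψ = 0 but d > 0 (impossible data; the
  optimizer treats it as an invalid region).
* **Folded** — Ψ_i = ψ_i + ψ_{n−i} for i < n−i (middle class unchanged);
  totals are conserved. Folding is incompatible with ε: the folded spectrum
  carries no polarization information, and the fitter rejects the combination.
* **Polarization error** — ψ*_i = (1−ε)ψ_i + εψ_{n−i}, applied before the
  likelihood; totals again conserved.
* **Divergence-augmented** — adds −λ_k + x_k ln λ_k per locus.
* **Profile** — because every Poisson mean is linear in θ_k, the shape
  parameters can be optimized with θ eliminated in closed form:
  θ̂_k = S_k/(m_kφ_k), or (S_k+x_k)/(m_k(φ_k+cf_k+t)) with divergence, and
  pooled over loci constrained to share a θ. The optimizer's objective is
  the *full* log-likelihood evaluated at θ̂; by the envelope theorem its
  gradient with respect to the shape parameters equals the full gradient's
  shape block there, so profiling costs nothing in gradient code and the
  stored optimum is directly LRT-comparable. The textbook multinomial form
  Σ d_{k,i}(ln φ_{k,i} − ln φ_k) is exposed separately and the
  decomposition full = multinomial + Σ_k[−ψ_k + S_k ln ψ_k] is
  property-tested.

Gradients are analytic throughout (θ, f, g, τ, ε, c, t), assembled by
back-propagating ∂L/∂mean through folding and error-mixing onto
∂φ/∂(f, g, τ), and verified against central finite differences at 1e−5
relative. Exponentials with exponent beyond ~700 are flushed to zero
(error below machine epsilon; avoids underflow noise).

## Optimization

Free parameters are transformed — log for θ, f, g, τ, c, t; scaled logit
onto (0, ½) for ε — so the search is smooth and unconstrained. Equality
constraints (e.g. θX = θA) and pins (e.g. f_A = 4/3) are applied by
parameter elimination through a union-find over named slots, never by
penalties, so a constrained fit has exactly the degrees of freedom its test
needs. L-BFGS-B runs from multiple random starts drawn log-uniformly from
boxes (θ ∈ [1e−5, 1e−1], f ∈ [0.05, 20], g ∈ [0.05, 50], τ ∈ [1e−3, 10],
c ∈ [0.1, 10], t ∈ [0.1, 50], ε ∈ [1e−3, 0.3]); gradient tolerance 1e−8,
ties within 1e−6 log-likelihood broken by first found. The interactive
default is 20 starts; the replicate experiments use 6 (3 for the ~100-free-
parameter gamma design), which we found always reaches the same optimum on
these well-behaved surfaces — multi-start spread is recorded in every
FitResult so a flat disagreement is visible. An invalid region (φ ≤ 0, or
non-finite values from extreme line-search steps) returns a large penalty
with zero gradient, which the line search backtracks out of. A fit where no
start converges returns an explicit failure result rather than raising.

LRT statistics are 2Δloglik with asymptotic χ² p-values by default;
statistics below −1e−6 raise (optimization failure), tiny negatives clamp
to 0. Parametric-bootstrap p-values simulate under the null MLE and report
(1 + #{stat_b ≥ obs})/(B + 1), so "no exceedance" reads 1/(B+1).
Nonparametric CIs resample loci (stratified when strata are given, keeping
per-stratum counts) and take percentile intervals of the refits; per-locus
parameters only keep meaning across resamples when tied within strata, so
by default only shared parameters are reported.

## Synthetic data

The generator samples d_{k,i} ~ Poisson(ψ_{k,i}) independently per class —
exactly the PRF sampling model, i.e. free recombination. It emulates the
study conditions the inference targets: two-locus X/A scenarios
(expansion: θX = 5.25e−4, θA = 7.5e−4, r1 = 0.65, r2 = 0.75, gX,1 = 10,
τ₁ = 0.1; contraction: r1 = 0.9, gX,1 = 0.2, τ₁ = 0.05; both 5 Mb, n = 100),
a 20-locus linear grid (θ falling 5-fold from 0.01, f rising 5-fold from 1,
5-kb loci, g₁ = 10, τ₁ = 0.5, c = 2, t = 8 — giving 0.1 substitutions/site
at locus 1), and a gamma design (θ_k ~ Gamma(3, 0.005),
f_k ~ Gamma(5, 0.2), 10-kb loci, n = 50, t = 6; the reference locus's f is
set to 1 since all scaled parameters are defined against it). Polarization
error is injected at the expected-SFS level, equivalent under the PRF to
flipping each site independently with probability ε. What this generator
does **not** emulate: linkage (genealogical correlation between sites),
selection, sequencing/genotyping error, or missing data — passing tests
demonstrate correctness of the estimator under its own sampling model and
say nothing about robustness to linked-site distortions in real data.

All randomness flows from explicit integer seeds; replicate r, locus k and
bootstrap draw b use substreams derived from the master seed by index, so
results are reproducible and independent of execution order (tested: the
first replicates of a long run equal a short run bitwise). Replicate maps
are order-independent by construction and run serially; the CLI's
`--threads` flag is accepted for interface stability and never changes
results.

## Desk-scale experiment sizes

The replicate experiments that back the tests and `scripts/acceptance.py`
use 30 replicates for the two-locus scenarios and the 20-locus grid, 50 for
the power estimates, and reduce the gamma design from 500 loci × 50
replicates to 120 loci × 10 replicates; Monte Carlo tolerances scale
accordingly (3× the standard error of the difference between two replicate
means). These sizes were chosen so the whole suite runs comfortably on one
core while keeping every comparison statistically meaningful.

## Known limitations and observed discrepancies

* Continuous growth, migration and selection are out of scope; only
  stepwise size changes are modelled.
* The divergence model is deliberately simple (single outgroup sequence,
  Poisson substitutions, no substitution-model corrections); c and t are
  informed only by between-locus variation in divergence, so they are
  unidentifiable in practice with very few loci.
* The pooled-fit bias demonstration reproduces the downward-biased size
  change (mean ĝ₁ ≈ 9.1–9.3 against a truth of 10, inside the published
  interval [8.62, 9.63]). For the event time our pooled MLE is biased
  *downward* (τ̂₁ ≈ 0.19 against a truth of 0.5): high-f loci dominate the
  pooled spectrum and appear closer to the event on their own time scale
  (τ/f_k), and the pooled likelihood surface is unimodal there. Published
  accounts of this experiment report an upward-biased pooled time instead,
  which we could not reproduce under any orientation of the design; the
  direction of that number appears to depend on a time-scale convention in
  the pooled analysis rather than on the model fitted here. The headline
  conclusion — the pooled fit is confidently wrong in both parameters — is
  unaffected.
* Estimates of r₁ (the current-epoch X/A ratio) can be upward-biased when
  the data barely resolve very recent events; with small samples treat
  extreme r₁ values with caution.
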