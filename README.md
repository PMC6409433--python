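# sfsvar

Joint maximum-likelihood inference of stepwise population-size history and
between-locus variation in effective population size (N_e) and mutation rate
(u) from site-frequency spectra, with optional divergence data.

## The problem

Multilocus demographic inference usually pools data across loci, but both
N_e (through inheritance mode and selection at linked sites) and u vary
along the genome. Loci with large local N_e contribute more polymorphic
sites *and* sit closer to any demographic event on their own coalescent time
scale, so pooling heterogeneous loci produces confidently biased estimates
of past size changes. `sfsvar` solves this by modelling the heterogeneity
explicitly: every locus gets its own scaled mutation rate and N_e scalar
while the timing of size changes is shared, and likelihood-ratio tests ask
directly whether loci — for example the X chromosome versus the autosomes —
differ in N_e or u.

## Model

Backward in time the population passes through H epochs; epoch H extends
indefinitely with reference size N₁ (at the reference locus). Locus k has
parameters

* θ_k = 4N₁u_k — scaled mutation rate per site (comparable across loci,
  always referenced to N₁),
* f_k — N_e scalar in epoch H (reference locus: f ≡ 1),
* g_{k,h} — size multiplier in epoch h < H (so the size is g_{k,h}·f_k·N₁),
* optionally ε_k ∈ [0, ½] — the probability a site's ancestral state is
  misassigned, mapping frequency class i to n−i,

and epoch durations τ_h (units of 2N₁ generations) are shared. The expected
unfolded spectrum in a sample of n alleles is

    ψ_{k,i} = m_k θ_k f_k [ g_{k,1}/i + A_{k,i} ],

where A_{k,i} sums exponentially decaying contributions of each size change
over lineage counts j with weights B_i(j). The B table is computed by the
numerically stable Polanski–Kimmel recursion (the direct alternating sum,
kept as an exact-arithmetic oracle, suffers catastrophic cancellation beyond
n ≈ 40; the recursion is routinely accurate at n = 1000). Counts are treated
as independent Poissons (a Poisson random field: free recombination,
infinite sites), giving a composite likelihood that is maximized with
analytic gradients from multiple random starts; θ_k is profiled out in
closed form (θ̂_k = S_k/(m_k φ_k)). Divergence to an outgroup adds
x_k ~ Poisson(m_k θ_k (c·f_k + t)) with shared ancestral-size scalar c and
scaled split time t. Folded spectra and polarization-error modelling are
both supported (the latter only for unfolded data).

## A worked example

```python
from sfsvar import FitOptions, XAParams, simulate_usfs, xa_to_general
from sfsvar.xa import fit_xa, general_to_xa, test_mutation_rate

truth = XAParams(thetaX=5.25e-4, thetaA=7.5e-4, r1=0.65, r2=0.75,
                 gX1=10.0, tau1=0.1, mX=5_000_000, mA=5_000_000)
data = simulate_usfs(xa_to_general(truth), n=100, seed=20)
est = general_to_xa(fit_xa(data, FitOptions(n_starts=10, seed=1)).model)
print(est.r1, est.r2, est.gX1, est.tau1)
r = test_mutation_rate(data, FitOptions(n_starts=10, seed=1))
print(r.statistic, r.p_asymptotic)
```

prints (examples/02_xa_tests.py)

```
MLEs: thetaX=0.0005205 thetaA=0.0007034 r1=0.547 r2=0.700 gX1=9.21 tau1=0.1054
mutation rate X != A   (df 1): LRT statistic   117.70, p = 2.01e-27
```

i.e. from a single simulated 5-Mb X/A dataset the 10-fold expansion
(ĝ=9.2, τ̂=0.105) and the 30% lower X-linked mutation rate
(θ̂X/θ̂A = 0.74, true 0.70) are recovered, and the mutation-rate difference
is overwhelmingly significant. `examples/` contains one short script per
capability: expected spectra, the three X/A tests, the shared-g multilocus
model with divergence and the pooled-fit bias, folded spectra and
polarization error.

A thin CLI mirrors the library — `sfsvar expected-sfs | simulate | fit |
xa | lrt | bootstrap | replicate`, all seeded via `--seed`; see
`sfsvar --help`.

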