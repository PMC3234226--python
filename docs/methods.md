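# Methods

## The CI deposition model

Each cage × gonotrophic-cycle record is modeled as a binomial draw: of the
`n` mated females alive at that cycle, each independently deposits a larva
with a cross-specific probability. The probabilities follow the standard
unidirectional-CI structure established for *Wolbachia* in *Drosophila*:
female fecundity effects act multiplicatively on a baseline `H`, and CI
removes a fraction `s_h` of fertilizations of *Wolbachia*-free eggs by
*Wolbachia*-carrying males. An infected mother produces a fraction `mu` of
uninfected eggs (transmission failure); an uninfected mother's eggs are all
uninfected. Hence

    p(female, male) = H · (1+F)^[♀ Wolbachia] · (1+W)^[♀ Wigglesworthia]
                        · (1 − s_h · u · [♂ Wolbachia]),
    u = mu if the female carries Wolbachia, else 1.

CI rescue is applied at the egg level: an infected mother's *infected* eggs
are always rescued, her uninfected fraction `mu` remains vulnerable. A
mother-level variant (all eggs of infected mothers rescued) would set the
`(1 − s_h mu)` factor to 1 in the `w×w` and `m×m` crosses; the five formulas
live in one function (`model._probability`) so that alternative is a
one-function change. With the egg-level form the five pooled cross rates
exactly identify the five parameters (`model.moment_match` gives the
closed-form solution), which is the basis of a deterministic oracle test.

Both cycles share one parameter vector; female attrition between cycles
enters only through the per-cycle `n`, on which the likelihood conditions.

Admissibility (every modeled cross probability in [0, 1]) is enforced in
the prior rather than the likelihood, so the posterior is a well-defined
truncated-flat-prior posterior. The prior box is `H, mu, s_h ∈ [0, 1]` and
`F, W ∈ [−1, 4]`: the benefit parameters must be allowed below zero (the
data cannot exclude a fecundity cost, and the published credible interval
for the *Wolbachia* benefit extends to −9 %), and 4 is a deliberately
generous upper cap far beyond any plausible relative benefit.

## Data

Per-cage replicate counts were never published — only the mean deposition
rate ± SE over three cages and the pooled number of females at risk per
cycle. The packaged dataset therefore represents each cross × cycle as a
single pooled pseudo-cage with `k = round(rate × n)`, rounded half-to-even
in decimal arithmetic so printed two-decimal rates reconstruct
deterministically (0.59 × 50 = 29.5 → 30). This pooling is exact for the
binomial likelihood under a shared within-cross probability, which is what
the model assumes anyway; it discards only between-cage overdispersion,
which the model has no term for. Eclosion rates are packaged as a plain CSV
for completeness and feed no model.

## Posterior sampling

A plain random-walk Metropolis sampler (independent Gaussian steps per
parameter) targets `log likelihood + log prior`. Design choices:

* **Non-adaptive, fully seeded.** Reproducibility is a contract: one root
  seed drives all randomness and equal seeds give bitwise-identical chains.
  Proposals falling outside the support are rejected outright, which
  preserves the truncated-flat target.
* **Tuning.** Step scales 0.02 (`H`, `mu`, `s_h`) and 0.05 (`F`, `W`;
  wider support), start (0.5, 0.2, 0.2, 0.1, 0.5), 20 000 burn-in
  iterations, 200 000 post-burn-in iterations thinned by 10. On the
  packaged dataset this accepts ≈ 35 % of proposals and runs in about a
  second; a zero acceptance rate raises a diagnostic error, and rates
  outside [0.1, 0.6] log a tuning warning.
* **Summaries.** Posterior median and central 95 % credible interval,
  quantiles by linear interpolation between order statistics. Pushforward
  summaries apply a function to every retained draw; draws where the
  quantity is undefined (e.g. a fixation time when the release is below
  threshold) rank above all finite values, and any quantile landing among
  them is reported as undefined together with the undefined fraction —
  matching the convention of an unbounded upper credible limit.
* **Convergence.** A split-half median check (batch-means Monte-Carlo
  standard errors) is a smoke test, not a formal diagnostic; no multi-chain
  machinery is included.

The sampler is exposed as a scikit-learn-style estimator
(`CIMetropolisEstimator.fit(dataset)` with `chain_`, `acceptance_rate_`,
`summary_`), so it composes with sklearn parameter tooling; `run_mcmc` is
the functional wrapper.

## Invasion dynamics

Host abundance is collapsed into a discrete-generation recursion for the
infection frequency `p` (Hoffmann/Turelli family), with relative fecundity
`f = 1 + F` of infected females — in a natural population every fly carries
*Wigglesworthia*, so `W` drops out — transmission failure `mu`, and CI
strength `s_h`:

    p′ = p f (1−mu) / D,   D = p f (1−mu) + (1 − s_h p)(p f mu + 1 − p).

`D − numerator ≥ 0`, so the recursion maps [0, 1] into itself. Interior
equilibria are roots of `A p² + B p + C` with `A = s_h (1 − f mu)`,
`B = f − 1 − s_h`, `C = 1 − f (1−mu)`; roots within 1e−9 of 1 are snapped
to 1 (the `mu = 0` boundary root suffers quadratic cancellation). Stability
is decided by iterating from ±1e−4 perturbations rather than by derivative
sign, to avoid boundary pathologies; the neutral case `f = 1, mu = 0,
s_h = 0` is flagged degenerate. The fixation prevalence is the largest
stable root in (0, 1]; the release threshold is 0 when `f (1−mu) > 1`
(invasion from any frequency), otherwise the unstable interior root, and
"no invasion possible" (`None`) when no stable positive equilibrium exists.

Time to fixation iterates from a 10 % release until `p` first reaches 95 %
of the fixation prevalence (cap 10 000 generations) and converts
generations to days with an explicit mean generation interval, default 30
days — tsetse deposit first at about three weeks and every 9–11 days
thereafter, so a generation convention in the low tens of days is the
natural choice, but absolute times inherit its uncertainty and the
interval is exposed as a parameter (`DemographyConfig`). At the published
posterior medians this gives 15 generations = 450 days, consistent with
the published 529-day median (whose credible band starts at 296 days)
given that this output is the one most sensitive to demographic timing
assumptions.

## Sensitivity analysis

Local sensitivities are central finite differences with multiplicative
steps `θ(1 ± rel_step)`, default `rel_step = 0.01`; elasticities are
`(∂Q/∂θ)·θ/Q`. Relative steps suit parameters spanning [0, 1], and the
time to fixation is differentiated through a smoothed crossing generation
(linear interpolation between the bracketing generations) because the raw
count is piecewise constant. `θ = 0` falls back to an absolute step and
flags the elasticity undefined; `Q = 0` (the zero release threshold at the
median estimates) likewise flags the elasticity undefined rather than
dividing by zero. The standard table covers {fixation prevalence, release
threshold, days to fixation} × {f, mu, s_h, generation_days}; the
days-per-generation elasticity is exactly 1 by construction, a useful
self-check.

## Synthetic data

The generator is the sampling counterpart of the fitted likelihood: per
cage and cycle, deposits are binomial in the cross's probability. Defaults
mirror the insectary design — five crosses, triplicate cages, 15 females
per cage, two cycles — with binomial female survival (default 0.85)
between cycles, loosely matching the published decline in females at risk;
survival is cosmetic because the likelihood conditions on per-cycle `n`.
What the generator does *not* emulate: between-cage heterogeneity
(overdispersion), male limitation or insemination failure, within-cycle
mortality timing, and eclosion. Passing recovery tests therefore
demonstrate calibration of the estimation pipeline under the model's own
assumptions, not robustness to real-data violations of them.

The recovery study repeats generate → sample → summarize over replicates
with seeds derived from one root seed (all below 2³¹) and reports
per-parameter 95 %-interval coverage, median bias and median interval
width. The calibration test uses 20 replicates with 40 000-iteration
chains, a size at which coverage estimates are stable while the whole
study runs in a few seconds.

## Known limitations

* The pooled pseudo-cage fixture cannot express between-cage variance; a
  beta-binomial extension would be needed for overdispersed data.
* The frequency recursion ignores age structure, density dependence and
  finite-population stochasticity; threshold and fixation prevalence are
  robust to that collapse, absolute times are not.
* With only five pooled rates the model is exactly identified, so the
  posterior mostly reflects the likelihood's local geometry; `F`, `W` and
  `mu` are weakly constrained and their estimates depend on the egg-level
  rescue convention described above.
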