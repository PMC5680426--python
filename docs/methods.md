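# Methods

This note documents the models implemented in `evotox`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the package's known limitations.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Trees and the Brownian covariance

Trees are rooted, may contain polytomies, and either carry branch lengths
on every branch or on none.  Explicitly unrooted Newick input (`[&U]`) is
rejected because node heights and the Brownian covariance require a root.
Newick reading/writing is delegated to dendropy; lengths are serialized to
10 significant digits, and round-tripping is a fixed point for topology,
labels and lengths.

**Grafen branch lengths.**  When a topology arrives without lengths (the
form produced by subsetting a synthesis tree), each node is given height
h(v) = ((t_v − 1)/(n − 1))^ρ, with t_v its number of descendant tips and n
the total tip count; branch lengths are height differences.  The result is
ultrametric with root height exactly 1.  ρ defaults to 1 and is exposed in
the configuration.

**Pruning.**  Restricting to a species subset removes tips, suppresses
resulting single-child internal nodes (summing their incident lengths), and
retains a single-child root, so root-to-tip path lengths of kept tips are
unchanged.  By default the pruned tree keeps the merged lengths of the
full-tree Grafen assignment (the standard drop-tip behaviour);
`regrafen_after_prune` instead recomputes Grafen lengths on the subtree.
The choice matters for subgroup analyses and neither option is canonical,
hence the flag.

**Covariance and distances.**  C_ij is the shared root-to-MRCA path length
(computed as B·diag(lengths)·Bᵀ with B the tip-by-branch path indicator);
patristic distances are independent path sums, and the identity
2C_ij = C_ii + C_jj − d_ij is verified to 1e−10 in tests.  Covariance
objects are validated symmetric PSD on construction (eigenvalue tolerance
1e−8 relative to the largest diagonal entry).

## Phylogenetic signal

**Trait scale.**  LC50s are analysed on the raw mg/L scale by default, with
a `log10` option.  Chloride LC50s span roughly two orders of magnitude, so
the scale genuinely changes the answer; the choice is surfaced in every
result row rather than hidden.

**Aggregation.**  One value per species: estimates are first averaged
within study, then study means are averaged, so a study contributing many
estimates does not dominate.  An ordinary one-way F test of LC50 on
exposure-duration category (24/48/72/96 h) is reported as the pooling
check; the degrees of freedom are whatever the supplied records imply.

**Pagel's λ.**  λ multiplies the off-diagonal of C.  The profile
log-likelihood (GLS mean and ML variance profiled out analytically via a
Cholesky solve) is maximized over [0, min(1, λ_max·(1−1e−6))], where
λ_max = max diag(C)/max offdiag(C) is the algebraic feasibility bound at
which C becomes singular.  The cap at 1 reflects λ's definition as scaling
between no correlation (0) and full Brownian motion (1); on trees with a
very shallow cherry λ_max is barely above 1 and an uncapped estimator
averages just above 1 under Brownian simulation.  The bounded Brent search
(tolerance 1e−8) is restarted on three subintervals and both endpoints are
checked, because the profile can be locally flat near the boundary.
Significance is the upper χ²₁ tail of 2·(logL(λ̂) − logL(0)).  Because the
null λ = 0 sits on the boundary of the parameter space, this test is
conservative: under no-signal simulation the rejection rate at α = 0.05 is
well below 0.05 (the acceptance script reports it).

**Blomberg's K.**  K = (MSE₀/MSE)/[(tr C − n/(1ᵀC⁻¹1))/(n−1)], with the
GLS mean used in both mean squares.  K = 1 exactly on a star phylogeny for
any non-constant trait — an identity used as a test.  Significance comes
from shuffling trait values across tips and counting permutations whose
phylogenetically corrected MSE is at most the observed one, with +1
smoothing: p = (1 + #{MSE_perm ≤ MSE_obs})/(1 + n_perm).  Note that on an
exact star tree this statistic is permutation-invariant and the test is
degenerate (p ≡ 1); calibration must therefore be assessed with
exchangeable traits on a structured tree, which the tests do.

**Mantel test.**  Pearson correlation of the upper triangles of the
patristic and absolute-trait-difference matrices; one random label
permutation is applied simultaneously to rows and columns of the second
matrix; the one-tailed (positive-association) p uses the same +1 smoothing.
Default n_perm = 999 everywhere.  n = 3 is allowed but logged as having
essentially no permutation resolution.

**Suite.**  Each configured taxonomic group is pruned, analysed, and
reported as one row; groups with fewer than four usable species are skipped
with a logged record, and trait-table species absent from the tree are
reported, never silently dropped.  Per-group random streams are spawned
from the master seed, so adding or removing a group does not perturb the
others — group rows are reproducible in isolation.

## Dose-response models

**GLM.**  Mortality is aggregated binomial (deaths out of exposed per
experimental unit) with a logit link, fitted by IRLS on an internally
standardized concentration scale; coefficients and their covariance
(inverse Fisher information) are back-transformed to mg/L.  Convergence:
relative deviance change below 1e−10, cap 100 iterations.  Complete
separation is detected as coefficient divergence (|β| > 50 standardized)
and fully degenerate responses (all dead or none dead everywhere) are
rejected up front.  Zero-dose control units stay in the fit; they inform
the intercept.  Concentration enters on the raw mg/L scale (the design
includes a true zero dose, which a log scale cannot represent).

**LC50.**  LC50 = −β₀/β₁ from a per-population-type intercept+slope fit,
as the two-stage analysis prescribes (the mixed model tests the
interaction; LC50s come from plain GLMs pooling ponds within a type).  The
delta-method variance is (v₀₀ + 2·LC50·v₀₁ + LC50²·v₁₁)/β₁², and 95%
intervals use the normal quantile 1.959964.  The estimate errors out when
the slope is statistically indistinguishable from zero, where the ratio is
unidentified.

**GLMM.**  Fixed effects {1, conc, type, conc × type}; independent normal
random intercepts for pond and for each experimental unit (the
observation-level term that absorbs extra-binomial variation).  The
marginal likelihood is Laplace-approximated in the unit-variance
parametrization b = σu: penalized IRLS finds the joint mode of (β, u) given
θ = (σ_pond, σ_unit), with the observation-level block eliminated exactly
by a Schur complement (its penalized Hessian is diagonal), and
logL(θ) = ℓ(y; η̂) − ½ûᵀû − ½ log det(I + ΛᵀZᵀWZΛ).  θ is optimized by
bounded Nelder-Mead on [0, 10]²; estimates within 1e−4 of zero are flagged
as boundary fits.  Fixed-effect covariance is the top-left block of the
inverse joint penalized information; the interaction is tested with a Wald
z.  This is deliberately a maximum-likelihood replacement for Bayesian
posterior sampling over the same model structure: point estimates and
tests, not posteriors, are the contract here.  The Laplace kernel for a
single random intercept is exposed separately
(`laplace_binomial_loglik`) and agrees with 50-point adaptive
Gauss–Hermite quadrature to ~5e−4 log-likelihood units on design-sized
toys; with both variance components fixed at zero the GLMM reproduces the
GLM exactly.  The implementation was also checked against lme4's Laplace
fit on one simulated dataset during development (log-likelihoods agreed to
~1e−3).

**AIC.**  AIC = 2k − 2 logL with k counting fixed effects plus free
variance components; comparisons refuse fits whose response fingerprints
differ.  Mixed-model AICs use the Laplace marginal likelihood, the usual
convention.

**Unit conversion.**  Cl mg/L = NaCl g/L × 1000 × 35.453/58.443, with
optional rounding to a stated granularity (the nominal treatment levels are
conventionally reported to the nearest 100 mg/L).

## Synthetic data

`simulate_yule_tree` grows a pure-birth tree: exponential waiting times
with total rate k·birth_rate, a uniformly chosen lineage splits, and after
the n-th lineage appears all lineages are extended through one further
waiting period so terminal branches are strictly positive.  Trees are
binary and ultrametric — the regime the Grafen-calibrated analysis runs on;
the generators deliberately do not produce extinction, sampling artefacts
or polytomies (the analysis accepts polytomies; the generator does not make
them).

`simulate_bm_traits` draws x ~ N(root·1, σ²·C_λ) through a symmetric
eigen-factorization, so singular covariances (λ-scaled stars) are exact.
Empirical covariance over 2000 draws matches σ²C_λ entrywise within 3
Monte-Carlo standard errors in tests.

`simulate_mortality` reproduces the acute-exposure layout: 2 population
types × 5 ponds × 5 concentrations (0, 3800, 5100, 6500, 7300 mg/L Cl) ×
4 replicate units × 10 larvae = 200 units.  Default dose-response truths
are the wood-frog-like LC50s 3412 (roadside) and 4395 (woodland) mg/L with
logit slopes 1.6e−3 and 1.35e−3 per mg/L, which put the standardized
concentration × type interaction near 0.64 — the magnitude scale reported
for this design.  Default random-intercept SDs are 0.3 (pond) and 0.3
(unit) on the logit scale, moderate heterogeneity for field-collected
amphibian larvae; both are tunable and several calibration checks set them
to zero because the claims being checked (e.g. delta-method coverage) are
statements about the correctly specified GLM.

Random streams: every generator call builds its own
`default_rng([tag, seed])` with a fixed per-generator tag, so one
generator's draws never shift another's.

What the generators do *not* emulate: within-species measurement error
structure beyond lognormal study noise in the trait-table factory,
non-Brownian trait processes (no Ornstein–Uhlenbeck or early-burst),
time-to-death structure within the 96-h window, and real taxonomy (the
fixture's phylum/class labels are clade-derived stand-ins sized like the
compiled dataset).  Passing tests therefore demonstrate statistical
correctness of the machinery under its own assumptions, not robustness to
model misspecification in field data.

## Problem sizes and determinism

Calibration checks use 500 Brownian replicates on 50-tip trees (K), 200 on
100-tip trees (λ), 500 no-signal replicates for test size, 1000 design
replicates for LC50 interval coverage, and 100–200 replicates for
mixed-model sign recovery — sizes at which the Monte-Carlo error of each
summary is small relative to its acceptance band while the whole suite
stays interactive.  All permutation and simulation outputs are reproducible
from (seed, n_perm); pipeline reports contain no timestamps and are
byte-identical across reruns.

## Known limitations

* The λ likelihood-ratio test is conservative at the λ = 0 boundary; no
  mixture correction is applied, matching common practice.
* Wald z tests for the interaction use no small-sample degrees-of-freedom
  correction; with only 10 ponds they can run slightly anti-conservative,
  which is why the calibration test accepts rejection rates up to 0.12 at
  α = 0.05.
* Laplace ML is known to shrink observation-level variance estimates for
  binomial units of size 10; lme4 shows the same behaviour on the same
  data.  Interaction inference is insensitive to this in the simulations,
  but the variance components themselves should be read as rough.
* LC50 intervals come from GLMs that pool ponds within a population type;
  when pond heterogeneity is present the intervals do not account for it
  and can undercover the population-level truth.
* No probit link, no time-to-death modelling, no Bayesian posterior
  sampling, no tree inference or taxonomy resolution — these are outside
  the package's contract.
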