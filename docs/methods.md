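# Methods

`odeqtl` maps quantitative trait loci (QTLs) that act on the *dynamics*
of biomass partitioning rather than on a single end-point trait. This
note records the model, the estimator, the numerical choices, and the
limits of what the synthetic test bed can demonstrate.

## The growth system

Each line's expected leaf, stem and root dry mass (grams) follows a
coupled allometric system driven by whole-plant mass
`W = M_L + M_S + M_R`:

    dM_L/dt = alpha_L W^beta_L − gamma_L M_L
    dM_S/dt = alpha_S W^beta_S
    dM_R/dt = alpha_R W^beta_R − gamma_R M_R

`alpha_k` (g^(1−beta_k)/day) is the allometric constant of organ `k`,
`beta_k` (dimensionless) its scaling exponent with whole-plant size, and
`gamma_k` (1/day) the first-order elimination rate of senescing leaf and
root tissue; the stem only accumulates. The model treats genetic
variation mechanistically: the two homozygous genotypes at a putative
locus carry distinct parameter vectors `Theta_j` (8 structural
parameters each), and detecting a QTL means detecting a difference in
growth-system design, visible simultaneously in all three organ
trajectories.

Whole-plant growth satisfies `dW/dt = sum_k dM_k/dt` identically, which
the code exploits as an algebraic invariant. Trajectories are integrated
with adaptive Runge–Kutta (`rtol 1e-8`, `atol 1e-10`) and an automatic
LSODA retry: elimination rates of 2–4/day give a fast initial transient
that is stiff relative to the seasonal time scale. Integration failures
raise an error carrying the offending parameters — never silent NaNs.

## Genetics

The design is a population of recombinant inbred lines (RILs) produced
by repeated selfing (F7 or later; fixation probability
`1 − 0.5^(g−1) ≈ 0.98` at F7), so every locus carries one of two
homozygous parental genotypes. Genetic distances convert to
recombination fractions by the Haldane map function by default (Kosambi
selectable); the per-meiosis fraction `r` is expanded to the RIL scale
`R = 2r/(1+2r)` to account for the accumulated meioses of inbreeding.
Conditional QTL-genotype probabilities inside a marker interval use the
no-interference product model over the two sub-intervals; a missing
flank genotype drops its factor (conditioning on the informative flank
only), and two missing flanks give the 1/2–1/2 prior. Genotype labels
are anchored to the parent-1 marker phase, which eliminates mixture
label switching.

## The estimator: penalized-spline parameter cascading

The likelihood at a tested position is a two-component mixture of
multivariate normals over each line's stacked 3-trait series, with
conditional genotype probabilities as mixing weights and a diagonal,
trait-specific, time-constant residual covariance (an AR(1) option
exists but is off by default; the white-noise form matches the
synthetic-data generator). Progeny-specific time grids are supported
throughout.

Genotype mean curves are represented by cubic B-splines. Knots are
saturated — every observed measurement time — and then refined: each
measurement span is subdivided (default 4×) so the basis can actually
track an ODE solution between observations. With 20-day measurement
spacing an unrefined basis cannot represent the growth flow, and the
fidelity penalty then *biases* the fit toward artificially smooth
dynamics; the refinement removes that bias at moderate cost.

The inner criterion is the ODE-penalized weighted least squares

    U(c|Theta) = sum w_ij ||y − Phi c||²/s_k² + lambda ∫ (dmu/dt − f(mu; Theta))² dt

with Gauss–Legendre quadrature (5 nodes per knot span) for the
integral. The trait weights `s_k²` are frozen at the residual variances
of the unpenalized fit (floored relative to the data scale), keeping the
criterion a pure function of `Theta`. Because both terms decompose over
genotypes, each genotype's coefficient block is solved independently by
a damped (Levenberg–Marquardt) Gauss–Newton iteration; the sample enters
only through weighted per-grid sufficient statistics, so the inner cost
is independent of population size.

The outer level maximizes the mixture log-likelihood over the structural
parameters, with the spline coefficients treated as an implicit function
`c(Theta)` of the inner optimum and the residual variances profiled out
by an EM fixed point at every evaluation. The outer gradient is computed
analytically through the implicit function theorem — one adjoint solve
against the exact inner Hessian per genotype — which is what makes
genome scans affordable and keeps quasi-Newton steps reliable on this
likelihood's narrow valleys. Default penalty weight is `lambda = 1e2`;
an ascending `lambda` continuation (1e2 → 1e6, re-optimizing from the
previous optimum) is available for high-accuracy fits and reproduces the
profiling (exact-ODE) estimator in the limit, with the reported
estimates taken where they stabilize along the path.

### Identifiability, parameterization, and the basin sweep

With elimination rates faster than the measurement spacing the leaf and
root pools are quasi-static: the data determine the *level*
`u = log(alpha/gamma)` and exponent `beta` sharply, but the rate
`gamma` only through second-order relaxation corrections. The outer
optimizer therefore works in `(u, beta, log gamma)` coordinates, which
axis-aligns the weakly identified direction, and the likelihood is
multimodal across rate regimes (slow-relaxation vs quasi-static fits of
the same curve). Fits begin with a structured initializer — log–log
regression of smoothed organ mass on smoothed whole-plant mass for
levels and exponents, a relaxation-residual regression for rates — and
an optional *basin sweep* that profiles the likelihood over a coarse
elimination-rate grid (each candidate briefly re-optimized with the rate
pinned, then released, under frozen residual variances so that pool
contributions stay separable), iterated with full polls.

A-priori bounds constrain the search: exponents in [−0.5, 1.5] (organ
allometry is sub-linear to mildly super-linear, clustering near 3/4),
elimination rates at most 5/day (faster turnover is observationally
indistinguishable from instantaneous at any realistic sampling), and
quasi-static levels within e^±6.

### A hard limit the tests make explicit

Under the default noise setting (heritability 0.05 per trait at the
middle measurement time) the residual standard deviations are 6–28 g —
95% of mid-season phenotypic variance is noise. At that level the
(alpha, gamma) pairs of leaf and root are effectively identified only
through their ratio: an independent spline-free maximum-likelihood
oracle (ODE solving plus nonlinear least squares) shows per-replicate
estimates running along the ridge essentially unbounded. No estimator
extracts what the data do not contain, so replicate means of
`alpha_L`, `gamma_L`, `alpha_R`, `gamma_R` under this design do not
recover the generating values at two-decimal precision — the bounded
estimator reports ridge positions driven by the initializer and noise.
The well-identified quantities (stem parameters, exponents, levels, and
above all the likelihood-ratio signal used for detection) behave as
expected. The noiseless self-consistency and cascading-vs-direct-ML
equivalence tests therefore use a generating regime with moderate rates
(0.2–0.5/day, relaxation comparable to an 11-point sampling grid), where
every parameter is identifiable and recovery is within a few percent.

## Scans, thresholds, power

The genome scan evaluates the mixture fit (M1) on a cM grid over each
linkage group against the position-independent one-curve fit (M0,
computed once per dataset) and reports `LR = 2(lnL1 − lnL0)`, clamped at
zero. M1 fits are warm-started from the neighbouring position and from
the M0 solution (which also enforces nesting under finite optimization
budgets); after the scan the M0 fit is retried from the best M1
component curves, because a null fit stuck in a poor optimum would
inflate the entire profile. Significance uses the empirical genome-wide
threshold: phenotype series are permuted against genotype rows, the
genome-max LR recorded per permutation, and the requested quantile (95%
of 1000 permutations by default) taken. Power studies share one
threshold per study, estimated from permutations of a dataset drawn from
that study's own generating process — an approximation to per-replicate
permutation, at a fraction of the cost.

## The synthetic-data generator

The generator emulates a soybean RIL design: 184 lines, 950 markers in
25 linkage groups (evenly spaced at 2.5 cM by default), six measurement
times on days 20–120 after emergence, one QTL placed at a marker.
Genomes are drawn as two-state Markov chains along each group with
RIL-expanded transition probabilities; groups segregate independently.
Phenotypes are the genotype's ODE curve plus i.i.d. Gaussian noise per
trait and time, with variances either given or scaled so each trait's
heritability at the middle measurement time hits a target (default
0.05): genetic variance is a quarter of the squared genotype-mean
difference at that time (equal-frequency homozygotes), residual variance
`sigma_g²(1−h²)/h²`. Default generating parameter pairs are point
estimates from a published soybean biomass-partitioning analysis of this
design; the one-curve set used for null replicates is the corresponding
pooled fit. Initial organ masses at day 20 are not published; the
generator uses (1.5, 0.5, 0.5) g — a leaf-dominant ~2.5 g seedling —
chosen once as a realistic seedling state.

What the generator does *not* emulate: polygenic background variation
between lines (all variance beyond the focal QTL is white noise),
genotyping error, segregation distortion, measurement-time correlation,
and negative-mass truncation (large white noise can produce negative
phenotypes, which the model likelihood handles but a real scale would
not). Passing tests therefore demonstrate correctness of the machinery
and calibration under the stated stochastic model, not robustness to
real-data artefacts.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` runs the power/false-positive study on a single
linkage group (3 markers, 10 cM spacing, QTL at the middle marker),
n = 184, 50 replicates per rate, with a 95% shared threshold calibrated
on 100 independent no-QTL datasets (see above), and the
parameter-recovery study at the true marker with 20 replicates — sizes
chosen so the whole script completes on one desktop core in well under
twenty minutes while leaving the Monte-Carlo error well below the
margins being tested. Scan fits use a lean optimizer budget (warm and
null-model starts, 12 quasi-Newton iterations, 2× knot refinement);
recovery fits add the elimination-rate basin sweep.

## Known limitations

- Cross-trait residual covariance is fixed at zero; only a diagonal (or
  within-trait AR(1)) residual model is implemented.
- The fidelity penalty weight is a fixed default rather than selected by
  cross-validation; the continuation path is available but not
  automatic.
- Under quasi-static dynamics the elimination rates are reported at
  bounded ridge positions (see above); their bootstrap standard errors
  are correspondingly wide and should be read as such.
- The permutation threshold assumes exchangeability of whole phenotype
  series across lines, which the generator satisfies by construction.
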