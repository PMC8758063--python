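# Methods

## Model

`geoadditive` fits Bernoulli-logit structured additive regression models for
district-level prevalence of binary health outcomes. For respondent *j* in
district *s*, with outcome *y* ~ Bernoulli(*p*), the most general model (level
M5) is

    logit(p) = z'β + f_age(age) + f_bmi(bmi) + f_wealth(wealth)
             + f_str(s) + f_unstr(s)

* **z'β** — fixed effects of the categorical covariates under reference
  (dummy) coding, so each coefficient is the log-odds contrast against the
  covariate's reference level and exp(β) is an odds ratio.
* **f_j** — smooth functions of the continuous covariates, as Bayesian
  P-splines: cubic B-spline bases on 20 equidistant interior knots with a
  second-order random-walk prior on adjacent coefficients (equivalently a
  difference penalty K = D'D with smoothing variance τ²). Each smooth is
  constrained to sum to zero over the sample, which identifies it next to
  the intercept; the constraint is imposed by reparameterising onto an
  orthonormal basis of the constraint's null space.
* **f_str** — structured (spatially correlated) district effect with an
  intrinsic CAR / Markov-random-field prior: precision τ²_str⁻¹(diag(n_i) −
  A) from the shared-boundary contiguity graph, so each district's effect is
  conditionally Gaussian around the mean of its neighbours with variance
  τ²_str/n_i. Identified by a sum-to-zero constraint per connected
  component, enforced by re-centering after each update with the removed
  level absorbed into the intercept.
* **f_unstr** — unstructured district effect, i.i.d. N(0, τ²_unstr):
  residual geographic variation local to a district rather than shared
  across boundaries.

The nested family M0–M5 toggles these blocks (M0 all-linear, no spatial;
M1 smooths only; M2 both spatial fields with linear continuous covariates;
M3/M4 smooths plus one field; M5 everything). In M0/M2 the continuous
covariates enter as centered linear columns.

Neighbourhood is rook contiguity: two districts are neighbours only when
their polygons share a boundary segment of positive length (a corner touch
does not count); queen contiguity is available as an option. Disconnected
maps are an error by default — the analysis setting drops islands rather
than modelling them — with an opt-in to fit components under per-component
constraints.

## Outcome derivation

Diabetes: random blood glucose strictly greater than 140 mg/dl.
Hypertension: of three blood-pressure readings the first is discarded;
positive when the mean of readings 2–3 is ≥ 140 mmHg systolic or ≥ 90 mmHg
diastolic, or when the respondent takes antihypertensive medication.
Records missing a biomarker are excluded from that outcome's model only.

## Inference

Inference is exact Gibbs sampling via Pólya-Gamma data augmentation: with
ω_i ~ PG(1, η_i) latent, every coefficient block has a multivariate
Gaussian full conditional (precision X'ΩX + prior precision) and every
variance an inverse-Gamma one, IG(a + rank(K)/2, b + f'Kf/2). The scan
order is ω → fixed effects → each smooth → spatial fields → variances.

Two numerical choices matter:

* **PG sampling.** PG(b, c) is drawn from its infinite-convolution-of-gammas
  representation truncated at 16 terms, with the discarded tail replaced by
  a Gamma variate matching the exact tail mean and variance (closed forms
  via the midpoint rule, which is essentially exact because the tail terms
  sit at half-integer abscissae). The first two moments are exact by
  construction; sampling checks against E[PG(b,c)] = b/(2c)·tanh(c/2) sit
  within Monte-Carlo error at 10⁵ draws.
* **Joint spatial block.** When both spatial fields are active they are
  drawn as a single 2S-dimensional Gaussian block. Only their sum is well
  identified by the likelihood, so the two fields are strongly negatively
  correlated a posteriori; separate scans mix the structured/unstructured
  attribution far too slowly to be usable, while the joint draw makes the
  attribution mix essentially as fast as the sum.

Priors: diffuse mean-zero Gaussians (variance 10⁶) on fixed effects — kept
proper so every conditional is proper — and IG(0.001, 0.001) on all
smoothing/spatial variances, the weakly informative convention of the
structured-additive literature; both configurable, and tests exercise an
IG(10⁻⁵, 10⁻⁵) sensitivity setting. Chains are initialised at zero
coefficients and τ² = 0.1. The analysis-scale default is 40,000 iterations
with 10,000 burn-in; the test scale (synthetic studies below) uses
1,200–2,000 iterations with 300–500 burn-in, which the recovery studies
show is sufficient at n ≈ 4000 because the PG Gibbs sampler mixes quickly
for these block sizes. A fixed seed makes chains bit-reproducible.

Degenerate inputs: a singular conditional precision (e.g. an unconstrained
improper block) raises rather than silently regularising; non-finite linear
predictors abort with the iteration index; negative quadratic forms from
round-off are clipped to zero with a warning. Probabilities are clipped at
10⁻¹² when evaluating the deviance.

## Model comparison

DIC = D̄ + p_D with D̄ the posterior mean deviance and p_D = D̄ − D(η̄),
the plug-in deviance evaluated at the posterior mean of the **linear
predictor** (not at block-wise means). Differences below 3 are read as
indistinguishable, 3–7 as weak, above 7 as clear; the smallest-DIC model is
the reference and ties break by level order. Negative p_D is reported but
flagged.

## Reporting

Fixed effects: posterior mean, SD, (2.5%, 50%, 97.5%) quantiles, a
significance star when the equal-tail 95% interval excludes zero, and
exp(mean) as odds ratio. Smooths: pointwise mean and 95% band of the
centered curve on a grid inside the observed range. Spatial fields:
per-district means and bands, each field's min–max range, and the empirical
SD of the per-district means — the SD comparison is the dominance
diagnostic that says whether residual geography is neighbour-shared
(structured) or district-local (unstructured). Convergence reporting
follows the autocorrelation + sampling-path practice: an ACF table and
trace exports for every monitored scalar. Maps are exported as data
(GeoJSON properties / CSV); plotting is an optional helper.

## Synthetic-data generator

The generator is the package's test bed and runs the M5 structure
generatively on a rows×cols unit-square lattice (boustrophedon-trimmed to
any district count, so an 82-district "survey-like" preset stays
connected). Defaults emulate the study setting:

* prevalence ≈ 16% (hypertension) or ≈ 6% (diabetes) via the intercept;
* age uniform on [15, 49] with a near-linear increasing effect; BMI
  truncated-normal(22.5, 4²) with a mildly convex increasing effect; wealth
  score truncated-normal(0, 1) with an inverted-U effect peaking mid-range
  (coefficients on the standardised scale: 0.25; 0.25 + 0.12x²; −0.3x²),
  each numerically centered over its sampling distribution;
* fixed effects of moderate size (|β| ≤ 0.3) on sex, residence, marital
  status, education, smoking and alcohol, with realistic level frequencies;
  the remaining survey covariates are generated with zero effect;
* τ²_str = 0.25 and τ²_unstr = 0.1 by default; the structured field is
  drawn from the constrained ICAR prior by eigen-decomposition, the
  unstructured field i.i.d.;
* the "NE-India-like" preset uses 82 districts with Dirichlet-uneven
  district allocation mimicking DHS cluster sizes.

Biomarkers are back-filled deterministically from the simulated outcome
(glucose uniform above/below the 140 mg/dl cut; BP reading pairs whose
last-two means land the classification on the right side, with a noisier
discarded first reading and a 20% medication route among hypertensives).
This is deliberately **non-physiological**: it exists to exercise the
classification code end-to-end, not to model glucose or blood pressure.
Consequently, passing tests demonstrate correctness of the pipeline and
recoverability of the model's own structure — they say nothing about
measurement error, survey design effects (the two-stage cluster sampling is
intentionally not emulated; the analysis model uses no weights), or real
epidemiological effect sizes.

## Synthetic study scales and what they show

All scales were fixed as the package's standard test conditions:

* **Model selection**: 10 replicates at S = 25, n = 4000, 2,000/500
  iterations, fitting M0, M2, M5 on M5-truth data. DIC prefers M5 over M0
  and M2 in essentially all replicates.
* **Recovery/coverage**: 20 replicates, M5 truth, 1,200/300 iterations:
  equal-tail 95% intervals cover the true fixed effects 90–98% of the
  time; the replicate-averaged absolute bias per coefficient stays below
  0.05 log-odds. (A max-over-coefficients bias criterion would mostly
  measure Monte-Carlo noise at 20 replicates: each replicate-mean has
  SE ≈ 0.024.)
* **Dominance**: 10 replicates per direction with τ² pairs (0.25, 0.01) and
  (0.01, 0.25) at the survey-like scale S = 82, n = 8000, 1,500/400
  iterations: the SD of the fitted means of the truly dominant field wins
  in at least 8/10 replicates. This is the identifiability-limited check:
  at S = 25 the ICAR/i.i.d. attribution is posterior-ambiguous in a large
  minority of realizations (an i.i.d. prior happily explains a smooth
  field), so the dominance study runs at the many-district scale where the
  decomposition is identified — and the joint spatial block update keeps
  the attribution mixing.

## Known limitations

* The intrinsic CAR prior is improper and the structured/unstructured split
  is only weakly identified at small S; dominance conclusions need many
  districts or strong fields (no BYM2-style rescaling is implemented).
* P_D can go negative for poorly mixed chains; it is flagged, not fixed.
* The screening step uses Wald p-values from one joint ML logistic fit;
  under separation the covariate is flagged and retained, not tested.
* Survey design (weights, stratification, clustering) is out of scope by
  construction.
* `compute_dic`'s plug-in uses the posterior-mean linear predictor;
  alternatives (mean parameters, WAIC/LOO) are not implemented.
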