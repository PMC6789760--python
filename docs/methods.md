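# Methods

## Models

All families model responses to I multiple-choice items as conditionally
independent given a unidimensional latent ability θ with a standard normal
population distribution (the N(0,1) prior also fixes the latent scale).

**Binary logistic (1PL/2PL/3PL/4PL).** The probability of a correct
response is `γ + (δ−γ)·logistic(β + αθ)` in slope–intercept form: α is the
discrimination (slope), β the intercept (positive for easy items), γ the
lower asymptote (the probability that a very low-ability examinee guesses
correctly) and δ the upper asymptote (1 minus the slipping/inattention
probability at high ability). The 3PL fixes δ=1, the 2PL additionally
γ=0, and the 1PL estimates a single common slope with per-item intercepts
(so the 1PL has I+1 free parameters and differs from the 2PL by I−1).

**Nominal Response Model.** Category v of item i has propensity
`exp(ζ_iv + λ_iv θ)`; category probabilities are the softmax of the
propensities. Softmax probabilities are invariant to adding a constant to
all ζ (or λ), so identification fixes a baseline category at ζ=λ=0.

**Nested logit (2PNL/3PNL/4PNL).** A two-level model: level 1 is a binary
model (2/3/4PL) for correct vs. incorrect; level 2 distributes the
incorrect probability mass over the m−1 distractors with a softmax of
distractor propensities. The correct-response probability is therefore
unaffected by the distractor parameters, unlike in the Nominal Response
Model where all categories compete. One distractor is the baseline
(ζ=λ=0); in the shipped banks the baseline is the distractor the published
tables leave implicit, stored as the last category.

## Estimation

Marginal maximum likelihood via EM. The latent density is discretised on
61 equally spaced nodes on [−6, 6] with weights proportional to the
standard normal density, normalised to sum to one (configurable; the
discretisation error of this rule is far below sampling noise for all
quantities reported here). The E-step computes each person's posterior
over nodes and the expected category counts per item and node; the M-step
maximises the expected complete-data log-likelihood item by item with
L-BFGS-B and analytic gradients. For nested items the expected
complete-data log-likelihood separates exactly into the level-1 binary
part (on the expected correct/incorrect counts) and the distractor softmax
part, which are maximised independently; for the 1PL the common slope and
all intercepts are updated jointly.

Asymptotes are optimised on the logit scale (bounded to ±12, i.e.
probabilities within ~6e-6 of the unit interval) and reported on the
probability scale. Convergence is declared when the maximum absolute
parameter change over a cycle falls below 1e-4 (cycle cap 500); the
marginal log-likelihood is recomputed at the final parameters and is
nondecreasing over cycles by construction of EM.

Start values: slopes 1 for binary parts; binary intercepts at the inverse
logistic of the observed proportion correct; asymptote logits at −1.386
(γ≈0.2) and 2.197 (δ≈0.9); distractor softmax parameters at the log ratio
of smoothed category counts with zero slopes. The full Nominal Response
Model cannot start at zero slopes — an all-zero-slope NRM is an exact
stationary point of EM (a flat likelihood makes every posterior equal the
prior, and the M-step gradient vanishes identically) — so its slope starts
are graded, 0.25·(category index). Degenerate items (all correct or all
incorrect) get their intercept capped at ±10 with a warning instead of
diverging.

Standard errors use the cross-product (outer product of per-person score
gradients) approximation to the information matrix, with the per-node
derivatives of log category probabilities obtained analytically for binary
families and by central differences for nominal/nested families. When the
cross-product matrix cannot be Cholesky-factorised — expected for the
heavily parametrised 4-parameter families, whose estimates are unstable —
the standard errors are reported as an explicit "unavailable" marker with
a diagnostic, never as fabricated numbers.

## Scoring and reliability

Abilities are scored expected-a-posteriori (EAP): the posterior mean over
the quadrature nodes, with the posterior SD as the measurement error.
EAP (rather than ML/WLE) is used because the marginal empirical
reliability estimator needs a posterior SD for every person, including
perfect and zero scorers; persons with entirely missing rows receive the
prior mean 0 and SD 1.

Marginal empirical reliability is the variance-ratio form
`Var(θ̂) / (Var(θ̂) + mean(SE²))` with the N−1 variance denominator.
Conditional reliability is `r(θ) = I(θ) / (I(θ) + 1)` with I(θ) the test
information (sum of item informations `Σ_v (dP_v/dθ)²/P_v`, analytic for
binary items, central differences with step 1e-5 otherwise) and the unit
prior variance. Reliability curves are reported per model on that model's
own latent scale; no cross-model θ alignment is attempted, so curves of
different models may cross.

The reliability gain between a nested-logit scoring and its binary
counterpart is the difference of their marginal empirical reliabilities.
Inference resamples persons with replacement (default B=2000),
recomputing both reliabilities from the paired (θ̂, SE) records per
resample: a Wald z from the bootstrap SE with a two-sided normal p, and a
95% percentile CI. The bootstrap is conditional on the fitted item
parameters — models are not refit per resample, which would cost 2B fits
for little inferential benefit on a fixed instrument — so the CI reflects
person-sampling variability only (see Limitations). Items are never
resampled: the comparison is between scoring methods on a fixed test.

## Model comparison and absolute fit

Nested families (1PL⊂2PL⊂3PL⊂4PL and 2PNL⊂3PNL⊂4PNL) are compared by
likelihood-ratio tests; the Nominal Response Model is not nested with the
nested logit families and is compared by AICc only
(`−2ℓ + 2k + 2k(k+1)/(N−k−1)`).

Absolute fit uses a limited-information quadratic-form statistic on first-
and second-order margins. For binary data the margins are all univariate
and bivariate success probabilities (s = I + I(I−1)/2). For nominal data
the univariate margins are all category proportions but one per item and
each item pair contributes one cross-moment of the integer-scored
categories — a reduced margin set chosen so the statistic remains
computable for heavily parametrised polytomous models and matches the
degrees of freedom of the published comparison tables (e.g. 290 margins
vs. 200 parameters for the 2PNL). The statistic is
`M2 = N·e'·Δc(Δc' Ξ Δc)⁺Δc'·e`, with e the observed-minus-implied margins,
Ξ the model-implied sampling covariance of the margins, Δc an orthogonal
complement of the margin Jacobian (numeric, central differences), and a
generalised inverse for rank safety; df = margins − parameters identified
by the margins. CFI/TLI are computed against an independence baseline
(free univariate category margins, zero slopes) on the same margin set;
RMSEA is `sqrt(max(0, (M2−df)/(df·N)))`; SRMR is the root mean squared
difference between observed and model-implied pairwise score
correlations. Exact values of these indices depend on the margin
reduction, so they are validated by calibration (near-perfect fit on data
simulated from the fitted model; worse fit for misspecified models), not
by matching published digits. Cronbach's α is computed from the binary
matrix directly (`k/(k−1)·(1 − Σ item variances / total variance)`).

## Synthetic data

The generator emulates the study design the analysis assumes: abilities
drawn from N(0,1) (or supplied explicitly), responses drawn per item from
the model-implied category distribution at each person's ability, by
inverse CDF with one uniform draw per response. The draw order is fixed —
abilities first, then one uniform vector per item left to right — so a
seed fully determines the output. True abilities are always returned so
recovery and consistency tests need no re-simulation. Sample size
defaults in examples and acceptance checks follow the study (N=2949, 20
items, 6 options).

The published item-parameter tables for the fitted 2PL/3PL/4PL and
2PNL/3PNL/4PNL models are shipped as CSV fixtures, checksummed against
transcription drift. Two conventions are applied on load: the
4-parameter tables' asymptote columns are read on the probability scale
(their printed values, e.g. 0.988, are probabilities despite a
logit-labelled header, and reading them as logits would imply absurd
asymptotes), and the answer key — which the study does not publish — is
placed at category 1 with the four listed distractors at categories 2–5
and the implicit baseline distractor at category 6. Reliability and fit
results are invariant to the category labelling.

What the generator does not emulate: response times, missingness
mechanisms, careless responding (beyond what the δ parameter carries),
multidimensional abilities, or person misfit. Passing the parametric-
bootstrap checks therefore shows that the estimation/scoring pipeline
recovers the published reliability structure when the model holds; it
cannot show how these models behave under real-data violations.

## Limitations and known numerical behaviour

* The 4-parameter families are weakly identified at N≈3000; their
  cross-product information matrix is typically singular and the package
  deliberately reports standard errors as unavailable then.
* Refitting a nested model to data whose distractors carry no information
  produces a small positive spurious reliability gain of order k/N
  (~+0.001 at N=2949, ~+0.003 at N=1000 in the shipped experiments):
  maximum-likelihood noise in truly-zero distractor slopes enters the
  information quadratically. The conditional-on-fit bootstrap CI does not
  cover this estimation-induced bias, so tiny gains near that order should
  not be read as evidence of informative distractors; the published gains
  (0.015–0.019) are an order of magnitude larger.
* Parametric-bootstrap reliabilities computed from refit parameters carry
  the same mild upward bias (≲0.005 at N=2949), well within the stochastic
  tolerance of the reproduction checks.
* The exact limited-information statistic depends on the margin reduction;
  only its calibration, degrees of freedom and ordering across models are
  guaranteed, not third-decimal agreement with other software.
* EM convergence is declared on parameter change; for ridge-like
  likelihoods (3PL/4PL asymptotes) the parameters may stop short of the
  exact optimiser fixed point by ~1e-6 in log-likelihood at the default
  tolerance.
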