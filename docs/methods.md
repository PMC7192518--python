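# Methods

## Value models

Temporal discounting is hyperbolic relative to the soonest available reward.
With LL amount `A_t`, inter-reward interval `IRI_t` (days), condition
indicator `I_t` (0 = SS available now, 1 = both options delayed by 30 days)
and subject parameters `k = log_k_now` and `s = shift_logk`:

    SV(LL_t) = A_t / (1 + exp(k − I_t·s) · IRI_t)

The SS option sits at the start of the interval, so its subjective value is
its face amount ($10 throughout the designs).  A positive `s` means
discounting is shallower when no option is immediate.  Probability
discounting is hyperbolic over the odds against winning,
`SV = A / (1 + exp(h)·θ)` with `θ = (1−p)/p`; the certain $10 option is
undiscounted.  Both discount rates are carried in log space everywhere;
exponentiation happens only inside the value equations.

Task grids are full factorials: TD, 14 amounts × 7 delays × 2 conditions =
196 trials (the source description of this task states a 224-trial total
without saying which cells repeat; the generator is factorial and a
`repeat_to` option cycles the grid deterministically to any stated total);
PD, 16 amounts × 7 probabilities = 112 trials.

## Choice rules

* **softmax** — Bernoulli over the binary choice with
  `P(upper) = σ(β·ΔSV)`; β ≥ 0 is the inverse temperature.
* **DDM variants** — signed response times (negative = lower boundary =
  SS/safe choice) follow the four-parameter Wiener first-passage-time
  density with boundary separation α, non-decision time τ, relative start
  point z and drift v; within-trial diffusion coefficient fixed at 1, which
  sets the scale of α and v.  Trial-wise drift: constant (DDM0), linear
  `v_t = v_coeff·ΔSV_t` (DDMlin), or sigmoidal
  `v_t = 2·v_max/(1+e^(−v_coeff·ΔSV_t)) − v_max` (DDMS), an odd function
  with asymptotes ±v_max and slope `v_max·v_coeff/2` at zero.
* **mixture** — full DDMS and DDM0 parameter sets plus a mixture coordinate
  λ_z; the per-trial component indicator is marginalized analytically:
  `L_t = Φ(λ_z)·f_DDMS + (1−Φ(λ_z))·f_DDM0`.  Marginalization replaces the
  latent-indicator construction with an identical marginal likelihood and
  better mixing.

The Wiener log-density is evaluated by the classical small-time/large-time
series with the term count chosen per evaluation for an absolute truncation
error of the series factor below 1e−12; the branch is picked by whichever
representation needs fewer terms.  The upper-boundary density uses the exact
reflection (z, v) → (1−z, −v) of the lower-boundary form.  Response times at
or below τ have density zero (−inf log-density), not an error, so the
sampler can reject such parameter values.

## Hierarchical model and priors

For each group (patients, controls) and each subject-level parameter:
group mean μ with a uniform prior over the parameter's plausible range
(α: .01–5; τ: .1–6 s; z: .1–.9; v_coeff: −100–100; v_max: 0–100;
log k: −20–3; log h: −10–10; λ_z: −7–7; β: 0–10; the log(k) shift instead
has a Gaussian(0, 2) prior), and group precision with a gamma(.001, .001)
prior.  Subject parameters are normal around their group mean, truncated at
the domain bounds — the closest operational reading of a bounded-prior
Gibbs-sampler model, and the truncation normalizer is included in all
hyper-parameter updates.

## Sampling

The sampler is an adaptive Metropolis-within-Gibbs scheme (numba-compiled),
chosen because the estimation contract here is the prior table, the exact
likelihood, split-R̂ ≤ 1.01 and seed determinism rather than any particular
sampler brand.  Each iteration combines:

1. univariate random-walk updates of every subject parameter, proposal
   scales adapted toward 44% acceptance during warm-up (Robbins–Monro,
   frozen afterwards);
2. independence proposals from the subject's group distribution (prior
   terms cancel; weakly identified parameters mix in one step);
3. joint multivariate proposals per subject along the empirical covariance
   of that subject's parameters accumulated during warm-up (handles
   α–τ–v_coeff ridges);
4. Metropolized-Gibbs updates of each group mean and precision from their
   untruncated conjugate conditionals, accepted with the truncation-correction
   ratio (acceptance ≈ 1 when bounds are non-binding);
5. translation and rescaling group-moves that shift or scale a group mean/SD
   together with its subjects' values (the hierarchical "funnel" directions).

Initialization places group means at weakly informative interior points.
Prior midpoints were rejected for the drift parameters: the v_max midpoint
(50) and v_coeff midpoint (0) sit far outside any realistic posterior and
stall random-walk warm-up, so v_max starts at 1 and v_coeff at 0.1; τ is
additionally initialized below 0.85× each subject's fastest trial so the
likelihood is finite from the first iteration; chains are jittered.

Desk default: 2 chains × 2000 warm-up + 2000 retained draws.  The original
large-scale setting (2 chains, 50k burn-in, thinning 2, 10k retained) is
available as `MCMCConfig.paper()`.  On the default 28-subject desk cohort,
2 chains × 2000 warm-up + 6000 retained reach split-R̂ ≤ 1.01 for all
group- and subject-level parameters; shorter chains (400–800 retained) are
used inside the multi-fit simulation studies, where rankings and coverage,
not tail quantiles, are measured.  Seed determinism is exact: identical
seed and config reproduce every draw.

## Model comparison

WAIC and elpd follow the log-pointwise-predictive-density definitions with
the sample-variance (ddof = 1) penalty convention of the R `loo` package;
WAIC = −2·elpd_waic.  LOO elpd uses Pareto-smoothed importance sampling
(smoothed weights from `arviz.psislw`); trials with Pareto k > 0.7 are
flagged, not fatal.  Differences in elpd between models are summed pointwise
differences with a 95% normal-approximation CI, multiplier 1.96 (the exact
multiplier is a documented choice).  Comparison tables report −elpd
alongside elpd so smaller-is-better readers are served.

## Posterior predictive checks

Per subject, trials are sorted into five equal-count bins by the subjective
value of the LL/risky option at the subject's mean-posterior discounting
parameters (tie-break by trial order; an all-equal-SV subject is flagged
degenerate).  For each of `n_sim` simulations a joint posterior draw is
selected and a full dataset simulated per subject; predicted mean RT per bin
is averaged over simulations and compared with the observed bin means on
identical bins.  Predicted RT distributions are smoothed with a Gaussian
KDE, Silverman bandwidth.  The null DDM predicts bin-constant RTs, which is
the structural signature the checks exploit.  Desk default n_sim = 1000
(configurable; the original analysis used 10k).

## Group differences and effect sizes

All contrasts are patients minus controls on the group-mean posteriors:
the mean difference, 85% and 95% highest-density intervals (narrowest
interval by direct search over sorted draws), a directional Bayes factor
BF = i/(1−i) with i the Silverman-KDE mass of the difference posterior above
zero (capped at 1000 and 1/1000; thresholds 3 "positive", 12 "strong", 1/3
"reduction" stored as constants), and Cohen's d = (difference of posterior
mean group means) / pooled SD, where each group SD derives from its
posterior-mean precision and groups are weighted equally (group-size
weighting is unspecified in the source; equal weighting is the documented
choice).

## Synthetic cohorts: what they emulate and what they do not

The generator draws subject parameters from group-level truncated normals
and simulates every trial through the Euler–Maruyama diffusion simulator
(step 0.001 s, ≤0.1% discretization error at the task's RT scale; walks not
absorbed by 30 s are flagged censored and excluded downstream).  Default
study conditions: 9 patients, 19 controls.  Control group means α = 3.37,
τ = 0.945 s, z = 0.531 are the reported control-group posterior means; the
patient group adds +0.184 s to τ and +0.529 to the log(k) shift, matching
the sign and size of the reported group effects.  The remaining defaults are
package choices held fixed across all studies: v_max = 1.5, v_coeff = 0.5
(drift saturates for |ΔSV| beyond ~10 $, the regime that separates sigmoid
from linear scaling), log k = −3.5, shift = 1.0, log h = 0.5, λ_z = 4
(>99.99% value-sensitive trials, as reported), β = 0.3; between-subject SDs
α .5, τ .15, z .05, v_coeff .15, v_max .3, log k 1.5, shift .5, log h 1.0,
λ_z 1.0.

Desk-scale studies use reduced factorial grids (56 trials/subject: TD
7 amounts × 4 delays × 2 conditions, PD 8 amounts × 7 probabilities) chosen
as spread subsets of the printed grids; the full 196/112-trial designs are
the defaults for single fits.

What the synthetic data do **not** emulate: contaminant responses (lapses,
fast guesses, censoring by attention), inter-trial parameter variability
(the likelihood is the four-parameter Wiener form, without the full
diffusion model's sv/st/sz terms — deliberately, matching the modelled
likelihood), session or order effects, and left/right response mapping.
Consequently, passing recovery and ranking tests shows internal consistency
of estimation and comparison under the assumed model, not robustness to the
contaminants real data contain.  Relatedly, the 2.5% symmetric RT trimming
exists for real, contaminated data; applied to clean model-generated data it
truncates the genuine RT tails and visibly biases α downward and τ upward,
so the synthetic recovery and ranking studies fit untrimmed generated data
(trimming stays the default for the empirical pipeline and is exercised by
its own tests).

## Numerical and procedural choices

* RT trimming: linear-interpolation sample quantiles per subject; rows with
  |RT| strictly outside the [f, 1−f] band are dropped, default f = .025;
  an absolute 0.4–10 s filter is available as a documented non-default
  option.
* Choice prediction: upper boundary iff the closed-form upper-absorption
  probability ≥ .5 (ties, a measure-zero case, go to the upper boundary);
  accuracy is the fraction matching observed choices; the arcsine-square-root
  transform is provided for variance-stabilized accuracy comparisons.
* Drift-component simulation study: v_max ∈ {.5, 1, 1.5, 2.5, 3.5} ×
  v_coeff ∈ {.05, .1, .2, .4, 1, 2} (30 conditions), 50 RTs at each of 400
  value differences spanning ±20, other parameters fixed at the control
  posterior means; summaries are mean RT and upper-choice proportion per
  value-difference bin.
* Degenerate inputs: p = 0 gambles are rejected (odds against undefined);
  empty trial tables, single chains, sub-100-draw HDIs, sub-1000-draw BFs
  and degenerate (constant) difference distributions raise errors.

## Known limitations

* Random-walk-based MCMC needs minutes, not seconds, for R̂ ≤ 1.01 at full
  cohort size; gradient-based samplers would scale better but are not
  required by the estimation contract.
* The mixture model's component labels are identified only through the
  structural difference between its components (value-modulated vs constant
  drift); near λ ≈ .5 the null component's parameters are weakly identified
  and their R̂ can exceed the threshold even when the mixture proportion
  itself is well recovered.
* Cohen's d divides by SDs derived from posterior-mean precisions; with few
  subjects the precision posterior is heavy-tailed and d can be large even
  for modest absolute differences.  This mirrors the definition used in the
  source analysis and is calibrated (BF ≈ 1, d ≈ 0) when the group-level
  posteriors coincide.
* Euler simulation carries an O(√dt) boundary-overshoot bias; at dt = 1 ms
  it is below the resolution of every check used here but would matter for
  microsecond-scale RT work.
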