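# Methods

## Model and procedure

`crowdprior` treats each image's label θ ∈ {1, 2} as a latent binary
parameter with uniform prior P₀(θ=1) = 0.5 (no cue about image content
before anyone answers). A volunteer's response is one of four outcome
codes α ∈ {0 late, 1 threat, 2 no-threat, 3 don't-know}. Volunteers are
partitioned into reliability classes by demographics, and a class is
fully described by its conditional table P(y=α | θ=β, class) — a 2×4
row-stochastic grid. Three class mappings are supported: interest only
(≤5 classes), education only (≤5), or the ordered pair (≤25). The class
grid is assumed independent of the image: per-image difficulty is
deliberately not modeled, which makes every volunteer's response
exchangeable given (class, θ).

Classification of one image consumes a pre-drawn permutation of the
test pool without replacement. Each response multiplies the posterior
odds by the class likelihood ratio P(α|θ=1,class)/P(α|θ=2,class); the
run stops at the first step where either posterior strictly exceeds σ,
or when the pool runs out. The strictness of the stopping inequality
matters only on a measure-zero boundary but is fixed here (`>`), as is
the convention for an exhausted run with posterior exactly 0.5: the
label is drawn uniformly from the trial's seeded generator and the
outcome is recorded distinctly (`EXHAUSTED_TIE`) so it can be audited.

Because the prior is 0.5, the posterior crosses σ exactly when the
absolute cumulative log-likelihood ratio crosses logit(σ). The sweep
engine (`evaluation.trial_curves`) exploits this: one cumulative-sum
matrix per trial serves every threshold on the grid simultaneously.
The per-image reference implementation (`sequential.classify_image`)
and the vectorized path are cross-checked for equality in the tests.

## Estimation

Class tables are estimated on a training pool by counting every
(volunteer, image) pair into its (class, β, α) cell — β taken from the
image's ground truth — and normalizing each (class, β) row with an
additive pseudocount ε: (n_α + ε)/(n + 4ε). The default ε = 1
(Laplace). Smoothing is required because a Bayes update is undefined
when both likelihoods are zero, and random 45/43 pool splits regularly
leave small demographic cells empty; with ε = 0 an empty stratum is a
hard error. A class absent from training altogether falls back to the
pooled grid (counts summed over all trained classes), which equals the
estimate obtained by relabeling every training volunteer into one
class; the fallback is flagged.

No per-volunteer reliability is ever estimated, and there is no
iterative truth/reliability co-estimation: the entire point of the
class-level design is that a new volunteer's behavior is characterized
by the survey alone.

## Evaluation protocol

A trial is one (training draw, test permutation) pair: estimate the
table on the 45-volunteer training pool, classify all images with the
permuted 43-volunteer test pool, and score majority voting on exactly
the same sequence and per-image budget n_i. Reported per (spec, σ):

- χ̄, ν̄, χ̄_mv — means over all m·p trials;
- π — the percentage of trials with χ_bayes > χ_mv strictly; exact
  ties count against the Bayesian method and are reported separately
  (`tie_pct`);
- a pooled operating point: TPR/FPR of the hard decisions pooled over
  all trials (micro-average; positive = "threat"), and the one-point
  trapezoidal AUC (1 + TPR − FPR)/2. Pooling across trials rather than
  averaging per-trial rates is a declared convention — with 31 images
  per trial, per-trial rates would be coarse and undefined in corner
  cases.

The σ grid defaults to {0.52, 0.54, …, 0.98}: the open interval
(0.5, 1) in steps of 0.02, starting one step above the prior. The full
profile is m = 10,000 × p = 100; the default scaled-down profile
m = 100 × p = 10 (1,000 trials) keeps a complete 24-threshold,
three-spec sweep under a few seconds while leaving Monte-Carlo error on
π near one percentage point. Randomness is split hierarchically
(master seed → spec → training draw → permutation) via
`numpy.random.SeedSequence`, so any sub-experiment is independently
reproducible and identical configs give bit-identical summaries.

Majority voting counts codes 1 vs 2 only; codes 0 and 3 are
abstentions. This asymmetry with the Bayesian method — which extracts
likelihood information from abstentions — is preserved on purpose,
since it is precisely what the comparison is about. Vote ties are
broken uniformly with the trial's seeded generator by default; a
deterministic "always label 2" policy is available for sensitivity
checks because published baselines rarely state their tie rule.

## Synthetic populations

The generator draws exactly the process the model assumes: truths
i.i.d. Bernoulli(threat_prevalence), classes i.i.d. from the class
proportions, outcomes independent draws from the class grid given
truth. It therefore validates correctness of estimation and inference,
not robustness: real crowds violate exchangeability (image difficulty,
learning, fatigue, correlated errors), and passing tests on generated
data says nothing about those violations.

The default population mirrors the public summary tables of the
88-volunteer, 31-image canal-monitoring study: five interest classes
with proportions 16/88, 2/88, 31/88, 30/88, 9/88 and grids derived
from the per-class counts of true/false positives/negatives, late and
don't-know responses. Two explicit assumptions close gaps the printed
tables leave open:

- threat_prevalence defaults to 0.5 (the true count of threat images
  is not recoverable from the tables); configurable.
- late and don't-know counts are not printed per truth value, so they
  are split across β proportionally to the prevalence. Under the 0.5
  default this makes abstentions uninformative in the generated
  population — a conservative choice that, if anything, understates
  the Bayesian method's advantage.

Education levels are drawn independently of interest from the kept
volunteers' skewed distribution (4/88, 11/88, 73/88 at levels 2–4), so
education- and pair-keyed analyses are exercisable on generated data.

A notable property of this population: most classes answer "threat"
on non-threat images (and "no threat" on threat images) more often
than the reverse, so the *resolved* answers are worse than chance on
average. Majority voting therefore deteriorates as the budget grows,
while the Bayesian classifier learns the inversion from the training
pool and exploits it — the win-rate π exceeds 50% across essentially
the whole threshold grid. This reproduces the qualitative published
finding (Bayesian dominance, monotone accuracy/effort trade-off under
the well-specified interest variable), not its numeric values, which
would require the unpublished raw response matrix.

## Association statistics

Preliminary-analysis tools build per-class outcome contingency tables
(columns: TP, FP, TN, FN, late, don't-know; late/don't-know not split
by truth, matching the published layout), test class/outcome
independence with Pearson's χ² (no continuity correction; empty
rows/columns must be dropped by the caller), and compute Kendall's
τ-b between per-volunteer accuracy and each demographic variable.
τ-b is chosen over τ-a because both variables are heavily tied
ordinals. The published statistics are printed with European decimal
commas; they are read as 100.320 and 25.813 — the thousands-separator
reading is impossible since the Pearson statistic is bounded by
n·min(r−1, c−1). Recomputing from the printed 5×6 interest table gives
100.234, a 0.09 discrepancy within the source's own rounding; the 3×6
education table reproduces 25.813 and p = 0.004 exactly.

## Numerical choices and limitations

- Posterior products run in log space in the batch form; the
  sequential form uses direct multiplication, and both agree to 1e-12
  over random sequences (tested). Posteriors of exactly 0/1 are
  absorbing; a both-likelihoods-zero update leaves the prior unchanged.
- `trial_curves` requires strictly positive likelihoods (guaranteed by
  any positive pseudocount); the reference path handles zeros.
- Image ids are opaque; no image content, acquisition or front-end
  logic is modeled. Dynamic task allocation and EM-style
  truth/reliability co-estimation are out of scope.
- The library functions and the `crowdprior` CLI (simulate / stats /
  sweep / report) are the supported interfaces; figures are flag-gated
  so headless runs stay numeric.
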