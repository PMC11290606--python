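# Methods

## Model

`genmix` models per-trial US-expectancy ratings collected during fear
acquisition and generalization as the output of three chained processes.

**Associative learning.** Each conditioned stimulus carries an associative
strength `v` updated by the error-driven Rescorla–Wagner rule
`v[j+1] = v[j] + α (r[j] − v[j]) k[j]`. The update flag `k` is 1 on CS
trials only: strength never changes on test-stimulus trials. Outcomes are
coded `r ∈ {0, 1}` on CS+ trials (US absent/delivered). On CS− trials the
outcome is coded `r = −1` on every trial, so inhibitory strength `v⁻`
relaxes toward −1; a constant-0 coding would leave `v⁻` pinned at its
starting value and make inhibitory learning impossible, contradicting the
differential paradigm's purpose. Strength starts at `v = 0` on the first
acquisition trial — the standard convention, which also makes the
Non-Learner branch (`v ≡ 0`) the fixed point of "no learning". The rating
on trial `j` uses the *pre-trial* strength: participants rate their
expectancy before the trial's outcome is revealed.

**Similarity-based generalization.** Acquired strength transfers to a
stimulus in proportion to `s = exp(−λ d)`. The distance `d` is physical
(|x_CS − x| in mm) for Physical Generalizers and Overgeneralizers, and
perceptual for Perceptual Generalizers: the absolute difference between the
running cumulative mean of the perceived CS size and the current trial's
percept. The cumulative mean *includes* the current trial's percept when
the current stimulus is a CS; this is what allows a misperceived CS to
attenuate responding on CS trials themselves, the empirical signature that
motivates the perceptual pathway. Similarity is evaluated on every trial;
on CS trials the physical distance is 0, so `s = 1` there automatically for
the physical pathway.

**Group structure.** The boundary between Overgeneralizers and steeper
generalizers is the decay rate at which similarity retains 70% of the
learned response at the design's maximum distance (68.62 mm):
`λ* = −ln(0.7)/68.62 ≈ 0.0052` per mm. Overgeneralizers have
`λ ∈ (0, 0.0052]`, Physical/Perceptual Generalizers `λ > 0.0052`, and this
constant has a single source (`genmix.model.LAMBDA_BOUNDARY`) shared by the
priors, the simulator and the classifier. Overgeneralizers are evaluated on
the physical distance; at `s ≥ 0.7` the physical/perceptual distinction is
immaterial.

**Response mapping.** Generalized strength `g = v⁺s⁺` (simple paradigm) or
`v⁺s⁺ + v⁻s⁻` (differential) is pushed through a sigmoid with floor 1 and
ceiling 10 (the expectancy VAS endpoints), baseline `w0` and scaling `w1`,
giving the response mean `θ`. Ratings are `y ~ N(θ, σ²_m)` with *no*
truncation at the scale ends; posterior predictive draws may therefore
leave [1, 10], which is deliberate and reported as such. Response noise is
group-level only: one σ for learners (Uniform(1e-9, 1.5) prior) and one for
Non-Learners (Uniform(1.5, 3)), whose responses are unrelated to the task
and correspondingly noisier.

**Priors.** Person-specific parameters receive hierarchical priors:
`α ~ Beta(a_α, b_α)` with mean/concentration hyperpriors
(`μ_α ~ Beta(1,1)`, `κ_α ~ Uniform(1,10)`); `λ` truncated-Normal on either
side of the boundary with `μ_λ ~ N(0.1, 1) T(0, ∞)` and
`σ_λ ~ Uniform(1e-9, 1)`; `w0 ~ N(μ_w0, σ²_w0)` with
`μ_w0 ~ N(0, 10²)`, `σ_w0 ~ Half-Cauchy(0, 2)`;
`w1 ~ Gamma(a_w1, b_w1)` (shape/rate) with Half-Cauchy(0, 2) hyperpriors.
Membership is `m ~ Multinomial(1, π)`, `π ~ Dirichlet(1, 1, 1, 1)`. All
Normal scale arguments are standard deviations throughout the package; a
precision-parameterized re-implementation should convert accordingly.

## Inference

Sampling is Metropolis-within-Gibbs over participants and
hyperparameters. The discrete membership `m_i` is drawn from its exact
conditional every sweep. Because the λ truncation regions of groups 2 and
3/4 are disjoint, a single λ per participant would freeze the membership
chain; each participant therefore carries one λ copy per truncation region
(standard mixture augmentation). The copy not selected by the current
membership is refreshed from its prior, which leaves the marginal posterior
of the active parameters untouched, and the copies' prior terms cancel out
of the membership conditional. Label switching cannot occur: the
components are identified by disjoint hard constraints, not by symmetry
breaking.

Continuous parameters use Gaussian random-walk proposals with
per-parameter scales adapted toward ~35% acceptance during burn-in only
(frozen afterwards, preserving detailed balance). `μ_w0` and `π` have
conjugate updates (Normal, Dirichlet). Truncated normals are sampled by
inverse-CDF on the truncated support, and truncation normalizers are
evaluated in log space (`log_ndtr`) so deep-tail intervals stay finite.
With an empty data set every conditional reduces to its prior, which the
test suite exploits as a correctness check on the whole sweep.

Presets: the default configuration is 4 chains × 100,000 iterations with
75,000 burn-in and thinning 10 (10,000 retained draws); the package's own
analyses and tests use a short-chain preset of 4 × 4,000 / 2,000 / 2
(4,000 retained draws), which is sufficient for stable allocation on the
cohort sizes used here. Convergence is summarized by the split-chain
Gelman–Rubin statistic per parameter (cross-checked against arviz);
parameters with R̂ < 1.05 are flagged converged, a configurable reporting
threshold — non-convergence is reported, never raised.

**Simplified models.** Two ablations quantify what ignoring a mechanism
does to the inferred generalization rate. *Simplified 1* removes the
perceptual pathway (three components, all learners on physical distance).
*Simplified 2* removes learning dynamics: strength is pinned at its
asymptote (`v⁺ ≡ 1`, `v⁻ ≡ −1`) from trial 1 and the learning rate drops
out of the likelihood (its draws are prior draws). An alternative
construction — estimating a static strength per participant — was
considered and left unimplemented; pinning at the asymptote is the sharper
statement of "no learning process". Both ablations bias λ downward on the
cohorts they mis-specify, which the acceptance tests verify by sign tests
on median bias.

## Synthetic cohorts

The generator reproduces the recovery-study conditions: 50 participants
per group (the scaled test runs use 10) on the differential-conditioning
structure — one shared trial schedule, as the reference analysis reused a
single participant's experimental structure for all simulated individuals.
Generating rules: `α = 0` (group 1) or Beta(1, 1); `λ = 0`,
N(0.0026, 0.001) T(0, 0.0052), or N(0.1537, 0.1) T(0.0052, 0.3022) for
groups 1, 2 and 3/4 respectively; `σ = 2.5` (group 1) or 0.5;
`w0 ~ N(0, 5)` (group 1) or N(−2, 1); `w1 ~ Gamma(10, 1)` everywhere. The
0.3022 cap on λ applies only to the generator, not to the fitted model,
whose upper support is infinite.

Perceived sizes are simulated as `N(true size, 5 mm)` clipped to the
0–200 mm VAS. This Gaussian percept model is a synthetic stand-in: the
reference analysis reused empirical size estimates, and no generative
percept model is specified anywhere, so 5 mm (below the 7.624 mm grid
step, hence realistic single-step confusability) was chosen once as the
default and is exposed as a knob. Consequently the generator does not
emulate systematic perceptual biases (over/under-estimation drifts,
sequential dependencies, learning-induced warping) present in real size
estimates — passing recovery tests show the inference machinery works
under the model's own assumptions, not that real percepts are Gaussian.
Simulated ratings are not clipped to [1, 10], matching the untruncated
likelihood.

## Numerical and design choices

- Trial schedules: the spec-level counts fix everything except orderings,
  which are uniform random permutations (acquisition interleaving,
  within-block order, reinforced-trial positions), seeded and
  deterministic. Reinforcement applies per phase segment:
  round(rate × CS+ count) US deliveries among the CS+ trials of
  acquisition and of each generalization block (reacquisition without
  reinforcement could not prevent extinction). Test stimuli appear equally
  often within each block, remainders assigned at random.
- Missing data: a missing size estimate leaves the CS cumulative mean
  unchanged and falls back to physical distance for that trial's
  perceptual pathway; missing ratings are dropped from the likelihood.
- Allocation: the 75% criterion is inclusive; exact ties between modal
  groups go to Unknown. Cohort composition is reported both as the share
  of allocated labels and as credible intervals on the mixture weights —
  related but distinct quantities, and both are emitted.
- PPC: replicates pair each replicated data set with a single joint
  posterior draw; summaries use linear-interpolation sample quantiles
  (recorded in the report); bands are central 95% intervals of each
  statistic across replicates.
- Gradient summaries average over all generalization-phase trials of a
  stimulus (not per block), first within, then across participants.
- The differential CS− percept mean runs continuously across phases (no
  reset at the generalization phase); before the first CS− percept exists
  the inhibitory strength is still 0, so the undefined distance never
  enters the likelihood.
- Problem sizes: the packaged recovery runs use 10 participants per group
  with the short-chain preset, chosen as the smallest cohort on which
  allocation and rank-correlation recovery are stable; the full-scale run
  (50 per group, default preset) is the same code path and is documented
  as an overnight job.

## Known limitations

- The perceptual pathway equates CS memory with the cumulative mean of CS
  percepts (encoding precision only, no retrieval variability).
- Only self-reported expectancy is modelled; physiological channels
  (e.g. startle responses) are out of scope.
- The sampler is random-walk based; posteriors with strong `w0`/`w1`
  correlation for weakly identified participants can mix slowly under the
  short-chain preset, visible as elevated R̂ for a few person-level
  parameters even when allocation is stable.
- Informative priors from prior studies are not provided; all hyperpriors
  are weakly informative.
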