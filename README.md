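# genmix

Bayesian multilevel mixture modelling of fear-generalization behaviour.

Fear-generalization experiments measure how a conditioned response to a cue
(CS+) transfers to perceptually similar test stimuli (TS). A flat response
gradient is traditionally read as a strong latent generalization tendency —
but the same flat gradient can arise from failed learning, from broad
similarity-based transfer, or from simply misperceiving the test stimuli as
the CS. `genmix` implements a generative model that disentangles these
mechanisms at the individual level and allocates each participant to one of
four latent groups:

1. **Non-Learners** — no CS–US association is acquired.
2. **Overgeneralizers** — learning occurs, but similarity to the CS stays at
   or above 70% even for the most distant stimulus.
3. **Physical Generalizers** — similarity decays with physical stimulus
   distance.
4. **Perceptual Generalizers** — similarity decays with *perceived* distance,
   so trial-to-trial perceptual noise shapes the gradient.

## The model

For participant *i* on trial *j*, with US-expectancy rating *y*:

- **Learning** (Rescorla–Wagner): `v[j+1] = v[j] + α (r[j] − v[j]) k[j]`,
  with learning rate α ∈ [0, 1], trial outcome *r* (1/0 on CS+ trials, −1 on
  CS− trials in differential conditioning), and update flag *k* = 1 on CS
  trials only. Non-Learners have `v ≡ 0`.
- **Similarity** (Shepard): `s = exp(−λ d)`, where *d* is the physical
  distance |x_CS − x_TS| (groups 2, 3) or the perceptual distance between
  the running mean of the perceived CS size and the current percept
  (group 4). The generalization rate λ ≤ 0.0052 /mm defines
  Overgeneralizers (`exp(−λ·68.62) ≥ 0.7` at the maximum distance of the
  design); λ > 0.0052 otherwise.
- **Generalized strength**: `g = v⁺s⁺` (simple conditioning) or
  `g = v⁺s⁺ + v⁻s⁻` (differential conditioning).
- **Response**: `θ = 1 + 9 / (1 + exp(−(w0 + w1 g)))` and
  `y ~ N(θ, σ²_m)`, with group-level noise σ below 1.5 for learners and
  above 1.5 for Non-Learners.

All person-specific parameters get hierarchical priors; group membership
m_i is a latent categorical variable with Dirichlet-distributed mixture
weights. Inference is Metropolis-within-Gibbs MCMC (membership drawn from
its exact conditional each sweep); participants are allocated to the group
holding at least 75% of their membership draws, otherwise to an *Unknown*
category.

## Worked example

```python
from genmix import CohortSpec, FitConfig, allocate, fit, simulate_cohort

# 10 synthetic participants per latent group on the
# differential-conditioning protocol (24 acquisition + 156 generalization
# trials), with 5 mm perceived-size noise
table, truth = simulate_cohort(CohortSpec(n_per_group=(10, 10, 10, 10), seed=7))

samples = fit(table, FitConfig.test(seed=1))   # 4 chains x 4,000 iterations
alloc = allocate(samples, threshold=0.75)
merged = alloc.table.merge(truth.params, on="participant")
print((merged["modal_group"] == merged["m"]).mean())
print(alloc.counts())
```

prints

```
0.95
label
NonLearner               11
Overgeneralizer          10
PerceptualGeneralizer     9
PhysicalGeneralizer       8
Unknown                   2
Name: count, dtype: int64
```

i.e. 95% of the synthetic participants' modal memberships match the group
that generated their data; two participants near a group boundary fail the
75% certainty criterion and land in *Unknown*.

The same pipeline is available from the shell:

```sh
genmix simulate --preset small-sim --seed 7 --out cohort.csv
genmix fit --data cohort.csv --preset test --seed 1 --out fit.npz
genmix classify --posterior fit.npz --threshold 0.75
genmix ppc --posterior fit.npz --data cohort.csv -R 200
```

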