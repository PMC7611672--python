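# Methods

This note documents the models, algorithms and design choices in
`lcstop`: a pipeline linking locus-coeruleus (LC) integrity, measured as
neuromelanin contrast-to-noise ratio (CNR), to noradrenergic drug effects
on response inhibition measured by the stop-signal reaction time (SSRT).

## Stop-signal task engine (`lcstop.task`)

The simulated task is a two-choice RT task interrupted by stop signals.
Each block of 140 trials contains 110 go, 10 no-go and 20 stop trials;
the first 20 trials of a block are always go trials and are used to set
the starting stop-signal delay (SSD) as mean lead-in RT minus 200 ms.
The remaining 120 trials are interleaved by rejection resampling of
random permutations until two constraints hold: no more than seven
consecutive go trials and no more than two consecutive signal trials
(no-go and stop pooled).  The resampling cap is 10,000 attempts
(`SequencingError` beyond that); sequences are a deterministic function
of the seed.

The SSD follows a one-up/one-down staircase targeting 50% stop accuracy:
+50 ms after a successful stop, −50 ms after a failed stop, hard-clamped
to [50, 1500] ms (staircases conventionally saturate at their bounds).
No-go trials carry SSD = 0 and, by default, do not drive the staircase —
only stop trials do.  The staircase restarts from the lead-in rule each
block (`carry_ssd_across_blocks=True` switches to a shared staircase;
whether the original task shared it across blocks is not determinable
from the design description, so it is a config flag).

The generative agent races three independent ex-Gaussian runners.  On
each trial, with probability `p_gf` the go process never launches
(omission).  Otherwise the faster of the go-match/go-mismatch runners
fixes the candidate response and RT.  On signal trials, with probability
`p_tf` the stop runner never launches; otherwise the stop finish time is
SSD plus an ex-Gaussian draw and the response is emitted only if the go
winner beats it.  Responses slower than the 4.5 s response window
(matching the RT ceiling used in preprocessing) become omissions.
Go-failure draws are independent across trials.

## Race-model likelihood (`lcstop.exgauss`, `lcstop.race`)

Runner finish times are ex-Gaussian: Gaussian (mu, sigma) convolved with
an exponential of mean tau; the distribution mean is mu + tau.  Log
density and log survival are evaluated in log space (erfcx and log-Phi
forms) so small tau and deep tails stay finite; implementations are
cross-checked in the tests against scipy's exponentially-modified normal
and a direct quadrature convolution.

Trial likelihoods follow the censoring architecture in which the
signal-respond RT distribution is a right-censored go RT distribution:

- go response at t: `(1-p_gf) f_winner(t) S_loser(t)`; go omission: `p_gf`.
- signal-respond at t with delay d:
  `(1-p_gf) f_winner(t) S_loser(t) [p_tf + (1-p_tf) S_stop(t-d)]`.
- successful inhibition at delay d:
  `p_gf + (1-p_gf)(1-p_tf) ∫ f_stop(u) S_match(d+u) S_mismatch(d+u) du`.

No-go trials use the stop-trial likelihood with d = 0.  Commission errors
on go trials are carried by the mismatch runner, not a separate lapse.
Zero-probability outcomes return -inf rather than raising, so samplers
can reject.

The inhibition integral has two implementations: the public scalar API
uses adaptive quadrature (absolute tolerance 1e-9, failure raises
`QuadratureError` with diagnostics), while the sampler's vectorised path
uses a fixed two-panel Gauss-Legendre rule (24 nodes on the Gaussian core
[mu-8σ, mu+8σ] clipped to u ≥ 0, 24 on the exponential tail out to
mu+8σ+30τ).  The two agree to ~1e-9 for realistic parameters and are
compared against 10^6-race Monte-Carlo frequencies in the acceptance
tests.  Because staircased SSDs live on a 50 ms lattice, inhibited trials
are collapsed to unique (SSD, multiplicity) pairs before quadrature.

RT preprocessing removes responded trials with RT < 0.25 s or > 4.5 s,
then trims go RTs beyond ±2.5 SD of the participant's go-RT mean.  The
order of operations (absolute bounds first, SD rule on the survivors) is
a package choice; the SD rule applies to go RTs only, not signal-respond
RTs, and is skipped with a warning when fewer than two go RTs remain.

## Hierarchical inference (`lcstop.model`)

Each participant contributes 11 parameters: three runners × (mu, sigma,
tau) plus trigger- and go-failure probabilities modelled on the probit
scale (z with p = Phi(z)).  Group-level structure is independent
truncated normals per parameter: participant values are drawn from
TruncNormal(loc_k, scale_k) with fixed support bounds, and weakly
informative truncated-normal hyperpriors sit on each loc_k and scale_k.
The hyperprior means for mu_go-match (1.5 s), mu_go-mismatch (1.5 s) and
mu_stop (1 s) encode slower responses in older participants; all other
hyperprior constants are implementation defaults recorded in
`src/lcstop/priors/default_priors.yaml` (versioned; overridable per fit).

Sampling is differential-evolution MCMC with 33 chains by default (three
times the per-participant parameter count; 30 when `p_tf` is fixed).
DE crossover proposals have the form
`x' = x + γ (x_a − x_b) + ε` with γ = 2.38/√(2d) for a d-dim block,
scaled by a U(0.6, 1.2) factor, ε ~ U(−1e-4, 1e-4), and (a, b) distinct
chains drawn from the population.  One iteration comprises:

1. a participant-level block update, cycling over three phases: the full
   11-dim crossover; a small crossover on the weakly identified stop
   block (mu_stop, sigma_stop, tau_stop, z_tf); and an independence
   refresh of the prior-dominated block (the go-mismatch runner and both
   lapse probits) drawn from the conditional group prior, whose
   Metropolis ratio reduces to a pure likelihood ratio;
2. every iteration, an extra 2-dim crossover on (mu_stop, tau_stop) per
   participant — the data pin down their sum (the SSRT) much more tightly
   than the split, and the dedicated pair update keeps that valley
   direction moving;
3. every iteration, two reparametrising group moves: a *translation*
   (shift loc_k and every theta_ik together, leaving the
   participant-prior z-scores unchanged) and a *scale expansion*
   (scale_k → scale_k e^d with the participant spread inflated by the
   same factor; Jacobian (N+1)d per parameter).  These glide along the
   hierarchical location and funnel valleys that elementary conditional
   updates traverse only by a slow random walk;
4. two sweeps of group-level (loc_k, scale_k) pair updates: given the
   participant values the group posterior factorises over base
   parameters, so the pairs are updated as independent 2-dim DE blocks,
   vectorised across parameters and chains, never touching the
   likelihood;
5. during burn-in only, with probability 0.05, a migration step: a random
   subset of chains cyclically offers its full state to the next chain in
   the cycle, accepted by Metropolis ratio.  Migration is disabled in the
   final sampling phase so the retained posterior comes from a fixed
   crossover kernel.

Chains are thinned by 10 (one retained draw per 10 iterations).  Burn-in
is adaptive: after every 100 retained iterations, the split-chain
Gelman-Rubin statistic (R-hat) of every group-level parameter is computed
over the most recent half of the burn-in draws (window capped at 200);
when all fall below 1.1 the sampler discards burn-in and retains a
further 500 iterations per chain as the final posterior.  A cap of 1500
retained burn-in iterations flags the fit as non-converged rather than
looping forever.  Reported R-hat values are recomputed on the final
retained draws.

Start values are crude data-driven estimates jittered across chains:
moment-based ex-Gaussian starts for the go runners (tau ≈ 0.8 × SD of
correct go RTs), the nonparametric mean-method SSRT (mean go RT − mean
SSD) split 75/25 into mu_stop/tau_stop, and the observed omission rate
for the go-failure probit.  Chains therefore start dispersed within the
plausible region rather than random-walking in from the hyperpriors;
R-hat then measures mixing across chains in the typical set.  (With
prior-dispersed starts the same sampler converges but needs several-fold
longer burn-in than a desk-scale budget allows.)

Derived posteriors: SSRT = mu_stop + tau_stop and go RT = mu_go-match +
tau_go-match per draw; summaries report posterior medians and 95%
quantile intervals.  Group/drug contrasts subtract matched MCMC samples
(the longer sample set is evenly subsampled first); a difference is
"reliable" when its 95% quantile interval excludes zero.  The three
study groups (controls, patients-placebo, patients-drug) are fitted
independently with identical priors (`fit_by_group`).

Posterior predictive checks replay the observed trial/SSD structure
under parameter draws and compare go-RT deciles, signal-respond deciles
and the inhibition function (stop accuracy by SSD bin) against 95%
predictive bands.

## LC imaging (`lcstop.imaging`)

The CNR map is voxelwise `(V − Mean_REF)/SD_REF` with reference
statistics from a central-pontine mask (sample SD, ddof 1).  CNR is
invariant to affine intensity rescaling.  Segmentation keeps voxels with
CNR strictly greater than 5 (the "above 5 SD" rule; the boundary is
measure-zero on real data) inside a search region, slice by slice;
probabilistic atlases average N binarised segmentations (values on the
k/N lattice) with 5% and 25% probability masks available.  Rostral /
middle / caudal subdivisions split the occupied rostrocaudal slice extent
of the mask into equal thirds (anatomical cut planes are not defined in
index space); left/right are split at the x midline.  The whole-LC mean
equals the voxel-count-weighted mean of the subdivision means by
construction.

All geometry is index-space on a common grid: the registration/template
chain that real studies need is orthogonal to the quantification
arithmetic, and phantoms are generated pre-aligned.  The semi-automated
visual-checking step of real pipelines is replaced by the QC counts in
the extraction summary.  No bias-field correction or smoothing is
applied.

The phantom plants two parasagittal 2×2-voxel tubes spanning 18 axial
slices over a noisy reference block (nominal 0.4×0.4×0.5 mm voxels).
Reference noise is standardised so the sample mean/SD equal the nominal
values exactly; planted per-subdivision CNR values are therefore exact by
construction, with optional voxelwise jitter (`lc_jitter`) and
between-subject variability (`simulate_phantom_cohort`).  The phantom
emulates contrast geometry only — no partial-volume effects, motion,
B1 inhomogeneity or registration error — so passing tests demonstrate
correctness of the quantification arithmetic, not robustness to real
acquisition artefacts.

## Association stage (`lcstop.association`)

Behavioural descriptives: stop accuracy = inhibited/stop trials; go
error rate = (commission + omission)/go trials, logit-transformed via the
empirical logit log((k+0.5)/(n−k+0.5)) so zero rates stay finite (the
adjustment is recorded in output metadata).

The moderation model is `outcome ~ drug * CNR + session + (1|subject)`,
REML-fitted with statsmodels MixedLM on the patient crossover rows; drug
is coded placebo = 0 / atomoxetine = 1, session first = 0 / second = 1,
and continuous variables are z-scored so fixed effects read as
standardized betas.  Patients missing one session stay in the model (the
random intercept handles the missingness); fewer than three complete
crossover subjects is refused.  F statistics are squared Wald t ratios
with a containment (between-within) denominator df,
`n_obs − n_subjects − (k_fixed − 1)`, recorded as
`df_method="between-within"`; no installed backend provides
Kenward-Roger or Satterthwaite df, and the containment rule is the
conservative textbook fallback for a random-intercept design.  Bayes
factors are out of scope; results are frequentist.

The drug-change correlation computes per-patient
Δ = outcome(drug) − outcome(placebo) adjusted for the session fixed
effect (estimated from a drug+session random-intercept model), then
Pearson-correlates Δ with whole-LC CNR; constant Δ or CNR is flagged
undefined rather than returning a spurious r.

The subdivision analysis is a group (between) × subdivision (within)
mixed ANOVA on CNR via pingouin with Greenhouse-Geisser correction when
sphericity fails, plus Welch two-sample follow-ups per subdivision.

## Study simulator (`lcstop.study`)

Controls (default 26) are tested once; patients (default 19) twice in a
double-blind placebo/drug crossover randomized in permuted blocks of six
(three placebo-first, three drug-first per block, the final partial block
truncated from a full permuted block).  Group-level parameter defaults
put control SSRT near 0.39 s, patient-placebo SSRT near 0.46 s and go RT
near 1 s — the regime the pipeline targets — with realistic lapse rates
(trigger failure 5-8%, go failure 2-3%).  Each participant×session has a
named random substream (SeedSequence spawn keys), so any single
participant is reproducible in isolation.

Each patient carries a latent whole-LC CNR ~ N(6, 1.5) (arbitrary but
realistic CNR units; only its standardised value matters downstream).
The drug session shifts the stop-runner mean by
`drug_mean + drug_slope · z(CNR)` with defaults 0.010 s and 0.022 s per
CNR-SD: a near-zero average drug effect whose direction depends on LC
integrity, chosen analytically so the planted standardized interaction is
≈ 0.27 given the default between/within-subject SSRT spread.  A −15 ms
session-two practice effect on mu_stop is planted so the session
covariate has something to absorb.  With `drug_slope = 0` the drug effect
is independent of CNR (the negative control).

For replicated end-to-end checks of the association stage, subject-level
SSRT is estimated by the classic nonparametric mean method (mean go RT −
mean SSD), which is unbiased enough under 50% tracking and costs
microseconds; the hierarchical posterior-median path is exercised once at
reduced scale in the recovery test rather than inside every replicate.
`subject_condition_table` accepts externally supplied SSRT values (e.g.
posterior medians) for the full-pipeline variant.

## Problem sizes in the test-suite and acceptance script

The shipped checks run at desk scale, chosen as the smallest sizes at
which each property is sharply testable: staircase tracking over 2,000
stop trials; likelihood-vs-simulation agreement at 10^6 races per
setting; hierarchical recovery with 8 participants × 2 blocks (R-hat
criterion plus 95%-interval coverage of the generating group SSRT, with
a point estimate necessarily noisier than a full-size fit); the
trigger-failure bias check reuses that fit against a `p_tf = 0` refit;
moderation sign recovery over 50 replicates of 50 patients.  Full-scale
parameter-recovery studies (many replicates at four blocks) use the same
code paths and only need larger counts.

## Known limitations

- The sampler is a single-machine, single-process implementation; chains
  vectorise across numpy, not across cores.
- Group-level distributions are independent truncated normals; no
  correlations between parameters are modelled at the group level.
- The probit-scale failure probabilities assume exchangeable lapses;
  sequential effects (fatigue, post-error slowing) are not modelled.
- The phantom is geometric, not biophysical (see above).
- The mean-method SSRT estimator used in replicated checks inherits its
  well-known small biases under skewed go distributions and trigger
  failures; those biases are shared across conditions and cancel in the
  interaction contrast, which is why sign recovery — not absolute SSRT —
  is the replicated criterion.
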