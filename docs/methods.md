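# Methods notes

## The inference problem

An open-diffusion experiment offers two groups of habituated wild primates a
two-option puzzle box and records every manipulation event: actor, technique
(`lift`, `pull`, the rarer `return_*` variants, or none for attempts),
outcome, and the set of attending observers. The scientific questions are
whether a novel technique spreads by social transmission, whether
transmission is specific to the option observed, and whose demonstrations
carry more weight per observation. All inference runs on the *order* in
which naive (individual, option) pairs first succeed — an order-of-
acquisition diffusion analysis (OADA), the network-based diffusion analysis
variant that conditions away absolute event times.

## Rate model and likelihood

For a naive pair (i, l) at time t the relative acquisition rate is

    R_il(t) = [ Σ_k s_k x_k(i,l,t) ] · exp(z_i'β_social)
              + exp(z_i'β_asocial + γ·solved_i(t) + δ·1[l=pull])

* `x_k(i,l,t)` — cumulative observation counts through network component k.
  For the option-specific (OS) component this is the count of observations
  of option l itself; for the cross-option (CO) component the count for the
  other option; bias analyses (rank, sex, age, kin) replace OS/CO by a
  mutually exclusive partition of the same network, always option-specific.
* `s_k ≥ 0` — social transmission rate per observation through component k,
  relative to the asocial baseline rate, which is fixed at 1: OADA only
  identifies rate ratios (the exact scale invariance s → s/c with network
  counts → c·x is covered by a test).
* `z_i` — individual-level variables (ILVs). Binary ILVs are coded
  female/adult = +1, male/juvenile = −1; rank enters as the integer rank
  (1 = highest). Each ILV is mean-centred and divided by its range within
  the group, giving range-1 covariates centred on zero; a more negative
  standardized rank therefore means a more dominant animal. Centring on the
  mean rather than the midrange is a deliberate choice between two readings
  of "centred on zero with a range of 1"; both give range 1, and the choice
  only shifts the asocial intercept, which is not identified anyway.
* `γ` — log rate ratio for asocial learning of the second option once the
  first is mastered ("other option solved", a time-varying indicator that
  switches strictly after the individual's first acquisition).
* `δ` — asocial log rate effect of pull relative to lift.
* One shared social ILV multiplier scales the summed social term rather than
  per-component multipliers, matching a model family with three ILV effects
  on social learning.

The log-likelihood is a partial likelihood: at each acquisition event, the
learner's rate divided by the summed rate over the risk set. The risk set
pools both options within a group — every (individual, option) pair still
naive competes at every within-group event — which is what makes the
time-varying other-option indicator meaningful; the two groups are separate
diffusions contributing additive terms. Ties in acquisition time are broken
by event-log order and their incidence is reported.

## Model space and multi-model inference

For the OS/CO analysis the s-constraint hypotheses are (a) both rates free,
(b) equal rates, (c) OS only, (d) CO only, (e) asocial. Each of a–d is
crossed with every subset of five asocial ILVs {sex, age, rank, option,
other-option-solved} and three social ILVs {sex, age, rank}: 32 × 8 = 256
models per hypothesis; hypothesis (e) admits only the 32 asocial subsets.
Total 1056. Bias analyses drop the CO pathway and use the partition
components with hypotheses free / equal / each-pathway-only / asocial
(4×256+32 for two components, 6×256+32 for the four-component age and kin
partitions).

Models are compared by AICc with n = number of acquisition events. Support
for a hypothesis is its summed Akaike weight over the joint fitted set; the
asocial set's weight is computed but should not be quoted as support
(it contains far fewer models — judge asocial learning by the confidence
intervals on s instead), and a `weights_exclude_asocial` switch renormalizes
over the social hypotheses for the alternative reading. Model-averaged
estimates use full-model averaging (a variable absent from a model
contributes 0) on the estimation scale — the linear-predictor scale for ILV
effects, back-transformed with exp(); the natural scale for s — with the CI
taken as the profile interval from the best-AICc model containing the
variable. Conditional averaging was the open alternative; full averaging is
the default because it is the conservative choice under model-selection
uncertainty, and the averaging mode is recorded in output metadata.
Non-converged fits carry zero weight and are listed with reasons.

## Numerical choices

* Fitting: multi-start (default 5, seeded) bounded L-BFGS-B with analytic
  gradients; s parameters are optimized as log s in [−25, 12], coefficients
  in [−30, 30]. Any s landing below 1e−4 is compared against the exact
  s = 0 constrained optimum and the better fit is reported, so boundary
  estimates are exactly zero while K still counts the parameter. A free s
  multiplying an all-zero network is reported as 0 and flagged
  unidentifiable.
* Profile CIs: the profiled log-likelihood is re-optimized at each grid
  value; endpoints are located by doubling brackets plus bisection to 1e−4,
  with the drop χ²₁(0.95)/2 = 1.9207; s intervals are truncated at 0 and a
  profile that never drops yields an open endpoint (0 or +∞).
* AICc requires n > K + 1; models violating it (only conceivable on very
  small toy datasets) receive infinite AICc.
* Experiment clock: event times are recorded within sessions; sessions are
  concatenated per group with inter-session gaps excised, since exposure and
  solving-time denominators are defined on observable time. Session ids must
  sort chronologically (zero-padded), which makes the pipeline independent
  of event-file row order.
* The sociogram edge weight divides naive-period observation counts by the
  "cumulative solving time": per option, the span from the group's first
  success with that option to the observer's own acquisition of it (or the
  end of observation), summed over options. The per-group (rather than
  per-dyad) clock start is a choice the source protocol leaves open.

## Dominance

Ranks come from the I&SI criterion: the ordering minimising the number of
inconsistent dyads I, then their total strength SI, found exhaustively for
N ≤ 8 and by an adjacent-swap hill-climb from the David's-score order with
50 seeded random restarts for larger groups (the brute-force oracle verifies
the heuristic in the tests). A dyad's direction is decided by the larger win
count; equal non-zero counts and unobserved dyads are unknown. Linearity is
Landau's h with de Vries' unknown-dyad correction — h′ is the Monte-Carlo
expectation (default 10,000 draws) of h over random completions of the
unknown dyads — and the p-value is the share of fully random dominance
matrices reaching the observed h′.

## The simulator

`synth.simulate` inverts the fitted model as a continuous-time stochastic
process (competing exponential clocks): naive pairs acquire at absolute rate
λ₀·R_il(t); informed individuals emit demonstration successes at rate μ;
fully naive individuals emit fruitless attempts at a lower rate. Every
success samples an observer set and increments the exposure ledger; each
acquisition records a ground-truth pathway label drawn proportionally to the
rate components at that instant. The timeline is sliced into fixed-length
sessions so the event reader's clock handling is exercised. Everything is
deterministic given the seed (per-group seeds spawned from one root).

Default conditions mirror the study design that motivates the package: an
NH-like group (28 animals: 2 adult males, 6 adult females, 12 + 8 juveniles;
17 sessions of ~81 min) and a KB-like group (12: 1 adult male, 6 adult
females, 5 juvenile males; 12 sessions of ~62 min), with s_OS = 0.25,
s_CO = 0, γ = log 30, δ = 0 and no ILV effects. The behavioural nuisance
rates are the package's own calibration to that scale and were frozen after
one pass: λ₀ = 3×10⁻⁶ /s per pair, μ = 1.5×10⁻³ /s per informed individual,
attempt rate 2×10⁻⁴ /s, attendance probability 0.06 (NH) / 0.35 (KB — the
smaller group watches far more per event, consistent with reported
group-size effects on observation rates). Typical realisations then show
~20–27 NH learners and ~4–10 KB learners with roughly a third to a half of
acquisitions socially caused, comparable to the study's descriptive scale.

Two structural features reproduce properties of real attention data that
matter for identifiability. First, option choice is per-individual and
sticky: a two-option knower re-uses its first-learned option with
probability 0.9, mirroring the strong individual technique preferences seen
in such experiments. Second, attendance has a seeded lognormal per-dyad
affinity (sd 1 on the log scale, mean 1): who watches whom is strongly
structured in the field. Without these, every observer sees the same option
blend, the CO exposure becomes proportional to the OS exposure, and the
equal-rates and OS-only hypotheses are nearly indistinguishable — a
degeneracy of the homogeneous simulator, not of the method.

What the simulator does not emulate: box locations and monopolization
(attendance is independent across observers given the affinities), seasonal
or diurnal variation, observation of attempts as socially relevant events,
memory decay, and payoff-based choice. Passing recovery tests therefore
show that the estimator inverts its own generative model at field-realistic
information levels; they do not certify robustness to these unmodelled
features.

## Validation and known limitations

The test suite checks the likelihood against an independent per-event oracle
on random small problems (1e−10), the network builder against the
simulator's ledger cell for cell, partition exhaustiveness, the analytic
closed forms (uniform-toy likelihood, AICc, Akaike weights, profile interval
of a quadratic, h′ of transitive and cyclic tournaments), parameter recovery
at the default conditions, and the type-I error of the boundary
likelihood-ratio test for s = 0 (conservative, as expected for a parameter
on the boundary).

One recovery property deserves honesty: at the moderate default signal
(s_OS = 0.25) the OS-only hypothesis attains the top Akaike-weight share in
roughly three quarters of replicates, not more — with ~45–75 acquisition
events the equal-rates model is often within a weight point or two. Under
strong transmission (s_OS = 1) the top-support rate is comfortably above
80%. Point estimation is unaffected (median ŝ_OS within a few percent of
truth; median γ̂ within ~0.05 log units).

The bundled study-composition table is transcribed from the printed source
and carries its quirks (e.g. one group lists 11 of its 12 members); it is
used for desk-scale counts and as a roster template, not for refitting the
original analysis, whose raw event-level data are deposited as article
supplements only. The quasi-Poisson GLM / Poisson GLMM performance analyses
are deliberately delegated to statsmodels on the count/offset tables this
package assembles; reproducing the published regression coefficients would
require those deposited data.
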