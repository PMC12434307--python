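# Methods

`isobolo` implements the quantitative chain used in preclinical fixed-ratio
combination analgesia studies: von Frey withdrawal thresholds estimated by
the Dixon up–down staircase, reduction of threshold time courses to AUC and
%MPE, Hill dose–response fitting with ED50 standard errors, and Tallarida
isobolographic additivity analysis. A synthetic-study generator emulates a
spinal-nerve-ligation (SNL) two-drug experiment — a pregabalin-like drug A,
a thioctic-acid-like drug B and their 1:1 ED50-ratio mixture — so the whole
pipeline can be exercised and validated without animal data.

## Threshold estimation (Dixon up–down)

Filaments form a log-spaced ladder (default 0.4–15 g, 8 filaments, log10
step δ ≈ 0.225). Testing starts at the filament nearest 2 g; a withdrawal
steps the stimulus down, a non-withdrawal up, and the staircase ends four
presentations after the first direction change (or on leaving the ladder).
The 50% threshold is

    T = 10^(log10(F_final) + k·δ)

with `k` looked up by the terminal response pattern (from the trial before
the first reversal onward) in `data/dixon_k.tsv`. The table is computed,
per pattern, as the maximum-likelihood location of a normal-ogive
psychometric function whose spread equals the step size — the construction
behind Dixon's published staircase coefficients; the classic two-trial
anchors k(OX) = −0.5 and k(XO) = +0.5 and the mirror antisymmetry
k(pattern) = −k(mirrored pattern) fall out exactly. Uniform (all-withdraw /
all-non-withdraw) sequences are censored at the ladder floor (0.4 g) or
ceiling (15 g); an estimate clamped to the ladder range is likewise flagged
censored. The floor convention is symmetric to the conventional 15 g
cutoff, which is the only boundary most protocols state.

## Synthetic study generator

Ground truth is an Emax/Hill model on the Loewe "additivity unit" scale
u = d_A/ED50_A + d_B/ED50_B. An arm's peak-time effect fraction is

    E = Emax_w · u^h / (u^h + γ_true^h)

with γ_true applied only to genuine mixtures, so single-drug arms reduce
exactly to their own Hill curves and γ_true is, by construction, the same
quantity the downstream analysis estimates (γ_true = 1 ⇒ exact Loewe
additivity; < 1 ⇒ synergy). Emax and slope for mixtures are
potency-weighted blends of the component values. The latent threshold is

    latent(t) = base + (t_sham − t_vehicle) · E · g(t),  g(t) = (t/t_peak)·e^(1 − t/t_peak)

with base = t_vehicle (allodynic) or t_sham (sham). Every latent value —
including the t = 0 baseline — is then *observed* by simulating a full
staircase against a logistic psychometric function in log10 force and
applying the Dixon estimator, reproducing the discreteness and censoring of
real von Frey data. Between-animal variability enters as one lognormal
factor per animal multiplying both of its ED50s, which keeps thresholds in
range and curve shapes intact.

### Defaults and their calibration

| parameter | default | rationale |
|---|---|---|
| ED50_A, ED50_B | 2.45, 57.49 mg/kg | monotherapy potencies of the emulated study |
| Emax_A, Emax_B | 1.082, 0.913 | reported %MPE maxima as fractions of the sham–vehicle gap |
| hill_A, hill_B | 1.5 | slope implied by the reported mixture curve (≈11→72 %MPE over its 0.9-decade dose range) |
| t_sham, t_vehicle | 8.94, 3.0 g | one filament step below the 15 g ceiling; below the 4 g allodynia reference line |
| t_peak | 3 h | middle of the reported 2–4 h peak-effect window |
| σ (between-animal) | 0.05 | see calibration note |
| psychometric slope | ln(99)/δ | see calibration note |
| n per arm | 6 | design of the emulated study |
| arms | sham, vehicle, A: 0.3/1/3/10/30, B: 10/30/100/300, mix totals 3.75/7.5/15/30 mg/kg | stated dose ranges; half-log monotherapy series; mixture totals are the published component sums at the 1:1 ED50-ratio mass split |

**Noise calibration.** The staircase slope and σ jointly set the study's
precision. They are calibrated so the simulated pipeline reproduces the
*reported* dispersion of the emulated experiment — per-group %MPE SEMs of a
few percent and fitted ED50 SEMs of roughly 7–10% of the estimate — rather
than chosen freely: with much flatter psychometric functions the simulated
assay is several-fold noisier than the study it stands in for, and every
downstream comparison loses the power the real design demonstrably had.
The default slope corresponds to ~1% response misclassification one full
filament step from threshold (~9% at half a step).

### What the generator does not emulate

Pharmacokinetics (absorption/elimination asymmetries, accumulation), sex
differences, partial sham allodynia, habituation or sensitization across
the nine repeated tests, and day-to-day drift. Passing recovery tests shows
the analysis chain is consistent and well-calibrated *for this generating
model*; it does not validate the pharmacological assumptions themselves
against animals.

One structural consequence of the transient effect profile: the AUC of a
drug arm is diluted relative to the flat sham reference by the factor
∫g dt / 8 ≈ 0.76, so fitted %MPE plateaus sit near 0.76·Emax·100 (≈82% for
drug A) rather than at the reported maxima (108.2%). Reported maxima above
100% imply time courses more sustained than this one-parameter profile;
ED50s and γ, the quantities of interest, are unaffected by the common
scale factor.

## Metrics

AUC uses the trapezoidal rule over 0–8 h including the pre-dose baseline at
t = 0. %MPE = (AUC_post − AUC_vehicle)/(AUC_sham − AUC_vehicle) × 100,
computed per animal against the *group-mean* vehicle and sham AUCs (the
references are group roles, not animal pairings), and deliberately not
truncated at 100. Group time-course comparisons use one-way ANOVA and
Dunnett's many-to-one test against vehicle; adjusted p-values come from the
equicorrelated multivariate-t distribution via seeded quasi-Monte-Carlo
integration (reproducible to ~1e-4) and are floored at the pooled-variance
unadjusted p, which they can never legitimately undercut.

## Dose–response fitting

E(D) = Emax·D^h/(D^h + ED50^h) with the floor fixed at 0 (vehicle defines
0% by construction of %MPE), least squares on per-animal %MPE values
(honest residual dfs; an alternative is fitting group means, which gives
nearly identical point estimates but optimistic dfs). ED50 is parametrized
internally as log ED50; its dose-scale SEM comes from the delta method, and
confidence intervals are t-based on the log scale (positive, asymmetric).
Numerical choices: multi-start over five log-spaced ED50 starts spanning
the tested doses, Emax started at the observed maximum, slope started at 1;
trust-region least squares with ftol 1e-10; non-convergence from every
start raises rather than returning silently. The pipeline default fixes the
Hill slope at the canonical 1.5 — on four-dose designs that do not reach
the plateau a free slope is practically unidentifiable — and bounds the
fitted plateau at 120 %MPE, just above the largest plausible maximum, so
Emax and ED50 stay jointly identified on partial curves. Both constraints
are options (`fix_hill=None`, `emax_max=None`).

## Isobolographic analysis

For ED50-fraction proportions ρ_A + ρ_B = 1:

    Z_add  = ρ_A·ED50_A + ρ_B·ED50_B
    SEM(Z) = sqrt(ρ_A²·SEM_A² + ρ_B²·SEM_B²)
    γ      = ED50_exp / Z_add

The γ confidence interval uses the delta method on log γ
(SE² = (SEM_exp/ED50_exp)² + (SEM_Z/Z_add)²) back-transformed with a t
quantile — it stays positive and asymmetric, matching how such intervals
are reported. The additivity test is a Student t on the ED50 difference
with pooled SEs; a log-dose variant is provided since some practitioners
test log ED50s instead. Degrees of freedom: in simulation/fitting mode the
default is the sum of the two monotherapy fit residual dfs; in
analysis-only mode (published ED50 ± SEM inputs, no dfs available) the
conservative per-group convention 2(n−1) = 10 is used. The verdict is
"synergistic" only when γ < 1 *and* the additivity test rejects at α
(mirroring the joint γ-plus-p reporting convention), "antagonistic"
symmetrically, otherwise "additive". Isobologram geometry is emitted in
component-mass coordinates: intercepts at the monotherapy ED50s, the
additive point at the mass split of Z_add (exactly on the line), the
experimental point at the mass split of ED50_exp, plus the
point-below-line sign test.

## Known limitations and numerical notes

- γ̂ is a ratio of estimates and therefore right-skewed; its arithmetic
  mean exceeds 1 by ≈ exp(τ²/2) − 1 under exact additivity (τ = SD of
  log γ̂). Under the emulated design the additive mixture's top total dose
  (30 mg/kg) coincides with its true combination ED50 (≈30 mg/kg), the
  least favourable placement, so null γ̂ carries a few percent of positive
  mean bias while its median and geometric mean stay at 1.
- Dixon estimates are discrete (a few dozen attainable values per ladder);
  metrics inherit that granularity.
- Replicate Monte-Carlo checks in the test suite use 200 studies per
  scenario (≈15 s each scenario on one core), the size at which rate
  criteria of ±5–10 percentage points are resolvable.
- All randomness flows from explicit seeds through per-animal
  `SeedSequence([seed, arm, animal])` substreams, so cohorts are
  reproducible and stable under adding arms; pipeline output bundles are
  byte-identical for a fixed (config, seed).
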