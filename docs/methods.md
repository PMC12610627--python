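# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the tests demonstrate.

## EEG trust scoring

**Pipeline.** Raw single-channel EEG (µV, 500 Hz by default) is processed
as: (1) zero-phase 4th-order Butterworth band-pass, 1–45 Hz, applied
forward–backward; (2) wavelet artifact suppression: db4 decomposition at 5
levels, soft thresholding of all detail levels with the universal threshold
σ·√(2 ln n), σ estimated as MAD(finest detail)/0.6745, approximation
untouched; (3) 5-sample median filter. A level-dependent σ per detail band
was evaluated and rejected: with oscillatory signal content concentrated in
the deeper detail levels, per-level thresholds shrink the very alpha/beta
activity being measured and degrade within-session rank recovery
substantially, while the finest-level estimate leaves the passband intact.

**Band powers.** Powers are integrated (trapezoid) from the preprocessed
broadband signal's Welch PSD over the band limits (delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–45 Hz). Welch uses 2 s Hann windows at 50%
overlap (nperseg = 1000 at 500 Hz); a 3 s epoch therefore averages two
segments, and segments shorter than one window fall back to a single
periodogram, which the tests pin against a direct DFT computation at 1e−10
relative tolerance. The zero-phase FIR band decomposition (Hamming windows,
transition width 25% of the lower cut-off, odd order) is retained for
quality control only — it is the diagnostic view, not the scoring path,
because only the Welch path is quantitatively specified end to end.

**Scoring.** Each event's epoch spans −1 s to +2 s around the decision
point, non-overlapping with its neighbors under the default 8 s spacing.
Epoch alpha/beta ratios are standardized *within a session* (mean and SD of
that recording's task epochs, SD with n−1), then mapped through
5 + 2.5·tanh(Z). Consequences worth stating explicitly:

- scores live in the open interval (2.5, 7.5) and Z = 0 maps to 5;
- per-session standardization deliberately removes between-session level
  information — EEG scores are comparable *within* a session, not across
  sessions. Recoverability of the planted latent trajectory is therefore
  assessed as the mean within-session Spearman correlation for EEG, and
  pooled across the cohort for the globally-scaled modalities
  (questionnaire, behavior, fused). The 10 s resting baseline ratio is
  computed and stored with every curve as the individual reference state but
  does not enter the score arithmetic.
- epochs whose beta power is below 1e−12 µV² are flagged invalid and
  skipped (with a warning) rather than producing unbounded ratios; a
  session with fewer than two valid epochs, or identical ratios (σ = 0),
  raises a degenerate-input error rather than silently emitting zeros.

## Questionnaire and behavior

Items 1–3 are treated as reverse-keyed: their wording is distrust-phrased
while items 4–12 are trust-phrased. The keying set is a single constant
(`REVERSE_KEYED_ITEMS`) and the keying transform is an involution, both
tested. Aggregation is the unweighted mean (not the sum), keeping the score
on the 1–10 scale shared with the EEG output so the fusion model sees
commensurate inputs. Cronbach's α uses the standard item-variance form with
sample variances.

The behavioral score is 10 × the mean of five normalized sub-scores:
adherence/100, exp(−latency/τ), and 1/(1 + count/c) for reliance,
interventions and verifications. Defaults τ = 5 s and c = 3 events are
configurable (`BehaviorNorms`); equal weighting was chosen in the absence
of any principled ranking of the indicators. The score is 10 at perfect
behavior and approaches 0 in the limit of complete failure; it is monotone
nonincreasing in every count.

## ANFIS fusion

The classic two-input first-order Sugeno architecture: Gaussian memberships
exp(−(x−c)²/2σ²), product t-norm, normalized firing strengths (computed in
log space so extreme inputs cannot underflow to 0/0), and output
Σ w̄ᵣ(aᵣx₁ + bᵣx₂ + dᵣ) over the fixed 2×2 Low/High rule grid. Inputs are
fed on their native 1–10 scale — the common scoring scale *is* the
normalization; no further rescaling is applied.

Initialization places Low/High centers at each input's 25th/75th
percentiles with width = half the separation (floored at 1e−3); a constant
input column is rejected as degenerate. Hybrid training alternates, per
epoch: an exact linear least-squares solve of the 12 consequent
coefficients on the w̄-weighted design matrix (ridge fallback λ = 1e−8 with
a warning if the system is singular), then one full-batch gradient step
(lr = 0.01, 100 epochs by default) on centers and widths using the analytic
softmax-form gradient; widths are floored at 1e−3. The parameters with the
lowest training RMSE across epochs are returned, making the reported
training error nonincreasing by construction. Cross-validation leaves out
one *participant* at a time (all of their rows), since per-row folds would
leak within-participant structure; RMSE and R² = 1 − SSE/SST are pooled
over held-out predictions.

The fused scores used in the validation battery come from the model trained
on the full cohort — the same model that produces the input–output fusion
surface — with LOOCV reported alongside as the out-of-sample error
estimate.

## Validation battery

- Kruskal–Wallis with tie correction; effect size ε² = H/(n−1), n = total
  observations. Dunn's post hoc z-tests are computed from pooled mean ranks
  with the standard tie term, Bonferroni-corrected over the 6 modality
  pairs (an implementation was written because no installed package
  provides Dunn's test; it is oracle-tested against brute-force rank
  arithmetic). One-way ANOVA runs in parallel as the parametric complement.
- Correlation triad: Pearson r, Spearman ρ, Kendall τ-b (tie-corrected),
  each modality against behavior.
- Classification thresholds Low < 4.5 ≤ Middle < 7.0 ≤ High were chosen so
  that integer scores 4, 5/6/6.5 and 8/9 fall in Low, Middle and High
  respectively, matching how the labels are conventionally applied on a
  1–10 scale; both the thresholds and a data-driven tertile mode are
  configurable.
- Cohen's κ (unweighted) with the large-sample null standard error for its
  p value. No closed-form test exists for comparing two dependent κs, so
  pairwise comparisons use a paired percentile bootstrap: resample
  observations, recompute both κs, two-sided percentile p with +1
  continuity, B = 2000, seeded; Bonferroni ×3. Bonferroni adjustment can
  only raise p values, which is asserted as a property.
- The unit of analysis is the pooled participant×event grid; per-participant
  mean variances are emitted alongside for the coarser view.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Latent trust** is a mean-reverting random walk reflected into [0, 1]:
x₀ = 0.8, xₖ₊₁ = xₖ + 0.5·(target − xₖ) + 0.087·ε, with
target = 0.8 − 0.4·difficulty and scenario difficulties cane/walker 0.35,
handrail 0.50, stairs 0.65. This makes harder scenarios yield lower mean
trust while most variation is within-session dynamics — the regime in which
session-standardized EEG scores are informative. Eight events per scenario,
8 s apart, starting 12 s into the session (so every −1/+2 s epoch fits
inside the task segment); the event count is an arbitrary, configurable
default.

**EEG** is a two-oscillator mixture: a 10 Hz alpha component with amplitude
3 + 6·L µV and a 20 Hz beta component with amplitude 3 + 6·(1 − L) µV
(L = instantaneous latent trust, interpolated between events), plus
1/f-amplitude background noise (SD 2 µV), white sensor noise (SD 1 µV),
Poisson-scheduled EMG bursts (6/min, 200 ms Tukey envelopes of 20–45 Hz
band-limited noise, SD 15 µV) and motion transients (3/min, 1 s half-sine
pulses, ±40 µV, spectral content below 2 Hz). The alpha/beta amplitude link
is strictly monotone in L, so the true within-session ordering is
recoverable by construction; motion transients are separable by the 1–45 Hz
band-pass while EMG overlaps the beta band and genuinely perturbs the
ratio — which is the point: it reproduces the qualitative finding that the
EEG modality disperses most. A 10 s resting prefix is generated at L = 0.5.

**Questionnaire** items are round-half-up(clip(1 + 9·(L + bias) + ε, 1, 10))
with per-item noise SD 1.0 and a per-participant social-desirability bias
drawn once from N(+0.08, 0.07²); items 1–3 are stored inverted so raw
responses carry the instrument's mixed keying. Rounding is half-up then
clip, stated once and tested.

**Behavior** indicators are derived by inverting the behavioral scoring
rule at a noisy copy of L (SD 0.05 per indicator), so the behavioral score
recovers ≈ 10·L; counts are integers, so recovery is exact only in the
continuous limit.

**What the generator does not emulate:** volume conduction or any head
geometry, multichannel structure, non-stationary oscillator frequencies,
ERP components, questionnaire item heterogeneity (all 12 items share one
driver, which is why synthetic Cronbach's α ≈ 0.93 exceeds typical field
values), and coder disagreement (a single simulated coder). Passing tests
therefore demonstrate the *pipeline's* correctness and the qualitative
structure of the multimodal comparison, not quantitative agreement with any
human cohort.

## Problem sizes and determinism

Default runs use 21 participants × 3 scenarios × 8 events (504 scored
events); the cohort-level structural findings are evaluated across 50
generator seeds, and the planted-model ANFIS checks use 63 triples (21
groups of 3). All randomness flows from a single integer seed through named
`SeedSequence` substreams, so cohorts, reports and manifests are
bit-reproducible; ANFIS training itself is deterministic (full-batch), and
the κ bootstrap is seeded.

## Known limitations

- Reference cohort statistics from human data (e.g. a questionnaire α of
  0.82, LOOCV RMSE 1.17) are scale anchors only; the synthetic cohort is
  not calibrated to reproduce them and the package makes no such claim.
- The EEG score's session-relative nature means cross-session comparisons
  ride entirely on the fused/behavior channels; an absolute EEG trust scale
  would require the baseline ratio to enter the normalization, which is
  exposed but intentionally not applied.
- The κ-difference bootstrap is approximate for small n and can be
  conservative when label classes are sparse in resamples.
- Narrative EEG trust scores of 8–9/10 sometimes quoted in field reports
  are outside the (2.5, 7.5) range the tanh mapping can produce; the
  mapping is implemented exactly as defined above and that tension is left
  standing rather than resolved by rescaling.
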