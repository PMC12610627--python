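# trustfuse

Multimodal trust assessment for assistive-device rehabilitation training.

Patients undergoing lower-limb rehabilitation must trust the devices that
support them (canes, walkers, handrails, stairs); too little trust slows
recovery, too much invites over-reliance. No single measure captures this
state well: EEG tracks moment-to-moment neural dynamics but is contaminated
by muscle and motion artifacts, self-report questionnaires are stable but
biased and temporally coarse, and video-coded behavior — the ground truth —
is labor-intensive. `trustfuse` implements a complete pipeline for comparing
and fusing these measures, together with a synthetic cohort generator that
plants a known latent trust trajectory so every stage can be validated end
to end without human data.

## What it computes

**EEG trust score.** A single forehead channel sampled at 500 Hz is
band-passed 1–45 Hz (zero-phase), denoised with a db4 5-level soft-threshold
wavelet plus a 5-sample median filter, and segmented into 3 s epochs (−1 s
to +2 s around each decision point). The alpha (8–13 Hz) / beta (13–30 Hz)
power ratio *X* of each epoch comes from Welch's method (2 s Hann windows,
50% overlap). Ratios are standardized across each session's epochs,

    Z = (X − μ) / σ,        score = 5 + 2.5 · tanh(Z),

which maps onto the common 1–10 trust scale with Z = 0 at the midpoint 5 and
an attainable range of (2.5, 7.5), avoiding floor/ceiling effects. A 10 s
resting-state prefix provides a per-session baseline ratio, stored with the
curve.

**Questionnaire score.** Twelve 10-point Likert items (items 1–3
distrust-phrased and reverse-keyed as 11 − value) are averaged onto the same
1–10 scale; internal consistency is reported as Cronbach's α.

**Behavior score.** Video-coded indicators (instruction adherence %,
decision latency, device reliance, interventions, verifications) are
collapsed to 0–10 via five normalized sub-scores; inter-rater agreement uses
Cohen's κ.

**Fusion.** A first-order Takagi–Sugeno ANFIS with two Gaussian fuzzy sets
('Low'/'High') per input and the fixed 2×2 rule grid fuses the EEG and
questionnaire scores, supervised by behavior. Hybrid learning alternates an
exact least-squares solve of the 12 consequent coefficients with a gradient
step on the membership centers/widths; performance is reported by grouped
leave-one-participant-out cross-validation (RMSE, R²).

**Validation.** Shapiro–Wilk, per-modality variances, Kruskal–Wallis H with
ε² = H/(n−1) and Dunn–Bonferroni post hoc tests (ANOVA in parallel), the
Pearson/Spearman/Kendall-τb correlation triad against behavior, three-level
classification (Low < 4.5 ≤ Middle < 7.0 ≤ High), κ agreement with
large-sample p values, paired-bootstrap pairwise κ comparisons, and the
EEG-vs-questionnaire confusion matrix.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (21 participants × 3 scenarios, 8 decision points each,
EMG/motion artifacts and questionnaire bias enabled):

```sh
python analysis/01_simulate_cohort.py --seed 1 --out results/cohort
python analysis/02_score_modalities.py --seed 1 --out results/score_table.csv
python analysis/03_fuse_anfis.py --table results/score_table.csv --out results
python analysis/04_validate_stats.py --table results/score_table_fused.csv --seed 1
```

which prints (seed 1):

```
504 scored events -> results/score_table.csv
Cronbach's alpha (keyed items) = 0.934
per-modality score variance: {'eeg': 2.35, 'questionnaire': 1.29, 'behavior': 1.33}
training RMSE = 0.555 (best epoch 99)
grouped LOOCV: RMSE = 0.586, R^2 = 0.741 over 21 participant folds
Kruskal-Wallis: H = 566.2, p = 2.1e-122, epsilon^2 = 0.28
Spearman vs behavior: {'eeg': 0.7, 'questionnaire': 0.85, 'fused': 0.88}
kappa vs behavior: {'eeg': 0.16, 'questionnaire': 0.45, 'fused': 0.69}
```

Reading these numbers: EEG scores disperse the most (variance 2.35 vs 1.29
for the questionnaire), the fused score correlates with behavior more
strongly than either input alone (ρ = 0.88 vs 0.70/0.85) and classifies
trust levels most consistently with behavior (κ = 0.69) — the structural
pattern the fusion approach is designed to produce. The same pipeline is
available as a library (`trustfuse.run_pipeline`) and as a CLI
(`trustfuse simulate|score-eeg|score-questionnaire|score-behavior|fuse|validate|run-all`).

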