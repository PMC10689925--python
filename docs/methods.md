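# Methods

`epinhs` implements a computational natural-history framework for rare
genetic epilepsies whose primary longitudinal signal is an ordinal monthly
seizure-frequency (SF) score. This note documents the models, the
parameters that matter, the synthetic-data generator, and the numerical
choices made where the design was genuinely open.

## The SF scale and the cohort data model

Each patient contributes one SF score per month of life (1-based; month 1
is the neonatal month), overall and optionally per seizure type (HPO term
identifiers). The scale is ordinal:

| SF | meaning |
|----|---------------------|
| 5  | >5 seizures/day     |
| 4  | 2–5 seizures/day    |
| 3  | daily seizures      |
| 2  | weekly seizures     |
| 1  | monthly seizures    |
| 0  | no seizures         |

Months documented as "seizures present, frequency unknown" carry an
explicit marker until imputation replaces them with the cohort median SF
for that month. Two choices here were open:

- **Donor pool.** The default pool is patients with *nonzero* SF in the
  month being imputed, because the imputation target is known to be
  seizing, making seizure-free patients uninformative donors. A mode using
  all patients with a known score is available (`donors="all"`).
- **Even-count medians** are rounded half-up so imputed values stay on the
  ordinal grid. Months with no donors fall back to the global median of
  nonzero scores (logged), and imputed cells are flagged so analyses can
  exclude them.

Observation windows and drug-exposure intervals are closed month
intervals `[start, end]`.

## Onset, remission and survival analysis

Onset is the earliest month with overall SF > 0. Remission is the first
run of ≥ 12 consecutive seizure-free months beginning after onset; a
trailing run truncated by the end of observation is censored, not counted.
The reported offset age is the first seizure-free month of the qualifying
run (an alternative last-seizure-month anchor is selectable — the
convention is not standardized in the literature). Recurrence after
remission is recorded but no recurrence survival analysis is produced:
mostly-paediatric follow-up does not support robust conclusions there.

Kaplan–Meier estimation and the log-rank test delegate to `lifelines`.
Survival quantile q is the smallest t with S(t) ≤ 1 − q; quantiles never
reached are reported as such, not as numbers. Month-wise subgroup
comparisons of SF distributions use the Wilcoxon rank-sum test (exact when
the combined sample is ≤ 20 without ties, otherwise the tie-corrected
normal approximation, as provided by `scipy.stats.mannwhitneyu`). Raw
p-values are reported by default; a Benjamini–Hochberg column is optional
because no correction convention exists for these month-wise screens.

## Trajectory forecasting and predictability

For patients with a complete first-year history, pairwise resemblance is
the mean absolute monthly SF difference over months 1–12 (a true metric on
the ordinal scale; Euclidean and rank-correlation alternatives are config
options). Each patient's months-13+ trajectory is predicted as the
per-month median (round-half-up) over their k = 10 nearest neighbours
still under observation at that month; ties at the reference-set boundary
are broken by patient order after a seeded shuffle. The forecast horizon
is capped at month 60 by default — beyond age five, observation windows
thin out and forecasts would increasingly rest on a handful of neighbours.

Forecast quality is the divergence: mean absolute difference between
predicted and observed SF over the forecast months. The
"better-than-chance" test compares the observed trajectory's divergence
against the divergence of trajectories drawn i.i.d. uniform on {0..5} per
month; p = (1 + #{null ≤ observed}) / (n_perm + 1), so p is never 0. The
production default is 100,000 permutations; tests use 2,000 with
Monte-Carlo error bounds. A cohort-month resampling null is available as
an option: "random seizure frequencies" admits both readings and the
uniform one is declared as the default, not inferred.

One calibration subtlety: because the null resamples trajectories against
the *observed* series, the p-value is uniform under the null exactly when
the forecast itself carries no information (i.e. is exchangeable with the
null draws). Calibration checks therefore pair a random observed
trajectory with a random forecast.

The fidelity partition labels a patient low-fidelity when the forecast is
not better than chance (p ≥ 0.05) **or** the divergence exceeds the
cohort's 66.7th percentile of divergence among patients with any seizure
history. The percentile is a declared free parameter: the two-subgroup
structure is reported in the field with only the resulting split, not the
cut rule. Never-seizing patients correctly forecast as all-zero are
high-fidelity by construction.

## Treatment effectiveness

The unit of analysis is the patient-month. Each month after the first
seizure is classified against its predecessor: `reduced` (SF fell from a
nonzero level), `freedom_maintained` (two consecutive seizure-free months
after prior seizures), `unchanged_or_worse` (otherwise); pre-onset months
are not evaluable. Per drug, a 2×2 table of exposed/unexposed ×
favorable/unfavorable patient-months is built — favorable is {reduced}
for the short-term outcome, {reduced, freedom_maintained} long-term,
{freedom_maintained} freedom-only — and summarized as an odds ratio.

Estimation: two-sided Fisher's exact p on the raw counts; cross-product
OR with a Haldane–Anscombe 0.5 correction applied to all cells when any
cell is zero; Woolf (log-normal) 95% CI on the corrected counts. Woolf
CIs ignore within-patient correlation of months, so a patient-level
bootstrap CI is available (`ci="bootstrap"`). A month under several drugs
counts as exposed for each (a sole-exposure sensitivity mode exists), and
drugs used by fewer than 10 patients are skipped. Note that patient-month
ORs are associative and age-confounded by construction: a drug prescribed
at ages when seizures wane will look favorable. This mirrors the method's
real-world framing; no causal adjustment is attempted.

Time-locked response aligns patients at first initiation (of one drug or
of any ASM) and reports reduction(m) = 1 − mean SF(t₀+m) / mean SF(t₀−1)
over patients still observed, excluding patients with a zero baseline
month; for spasm-type series it also reports the cumulative fraction with
spasm offset by m months post-initiation.

## Virtual clinical trials and OFTS

A trial at start month t samples up to 20 patients with SF > 0 at t and
follow-up covering the window (6 or 12 months), scales their observed
window SF by (1 − reduction) on a continuous scale (an ordinal-rounding
mode exists for sensitivity analysis), and evaluates treated vs observed —
a synthetic-control design where the cohort's own histories are the
comparator. The default test is a one-sided Wilcoxon signed-rank on
per-patient cumulative window SF. The signed-rank tail probability is
computed exactly for n ≤ 25 by dynamic programming over tied mid-ranks
(identical differences still give the minimal one-sided p of 2⁻ⁿ); larger
samples use the tie-corrected normal approximation.

OFTS at a start month is the fraction of 1,000 (200 in tests and the
acceptance script) independently sampled trials reaching p < 0.05. Months
with fewer than 5 eligible patients are undefined, never zero-filled, and
the eligible-pool size is always reported so sparse-window artefacts stay
visible.

A structural consequence of the paired default: scaling each patient's own
series produces all-negative differences, so any nonzero reduction is
detected whenever ≥ 5 sampled patients have nonzero window SF. The default
OFTS curve therefore primarily traces eligibility across the age span
(0 where reduction is 0, ~1 wherever an adequate seizing pool exists). The
unpaired rank-sum option (`test="rank_sum"`) compares treated vs observed
cumulative SF as independent samples and yields graded success
probabilities that depend on effect size relative to between-patient
variability.

## Developmental outcomes

Milestone acquisition quantiles default to achievers-only conditioning
(empirical quantiles of age among patients who achieved the milestone),
matching how such tables are conventionally reported; because that
conditioning is optimistic under short follow-up, a Kaplan–Meier mode over
all assessed patients (non-achievers censored at last assessment) is
provided, and the achievers-only quantile is never later than the KM one.
Binary milestone vs onset-timing associations use the Fisher OR machinery
above; five-level classification scales (GMFCS-ER, MACS, CFCS; Level I
best) use rank-sum tests; continuous scores (GMFM-66-IS, PDMS-2 raw) use
Spearman correlation against onset age for ordinal robustness. CDC
reference ages for typical development ship as a static annotation table,
never computed from cohort data.

## The synthetic-cohort generator

The generator's defaults encode the study conditions the analyses assume;
it is the test bed for every downstream stage.

- **Prevalence and onset.** Epilepsy prevalence 0.71; 31/72 of epileptic
  patients have neonatal onset (month 1); non-neonatal onset is
  1 + round(exp(N(1.82, 1.20))), calibrated so overall onset quantiles
  approximate 25th neonatal / median 2 months / 75th 7 months /
  90th ≈ 1.6 years.
- **Dynamics.** While active, SF follows an ordinal random walk on {1..5}
  with subgroup persistence ~0.8; an active/remitted state machine adds
  remission entry (hazard 0.02/month for PTV/del rising to 0.30 after the
  month-5–6 spasm window; 0.03 for missense, damped ×0.3 during their
  month-10–24 focal window) and relapse (0.04/month).
- **Variant signatures.** Variant mix 0.53/0.44/0.03
  (PTV-del/missense/in-frame). Epileptic PTV/del patients draw an
  infantile-spasm episode (probability 0.6, SF 4–5 in months 5–6, spasm
  HPO series); missense patients keep focal seizures (SF ≥ 2, persistence
  0.85) through months 10–24. Both classes start at the same low-moderate
  severity so the month-5–6 contrast is spasm-driven and the late contrast
  persistence-driven.
- **Drug effects.** A drug with multiplier m < 1 tilts the monthly
  transition distribution downward in proportion to 1 − m and triggers a
  step-down at initiation; freedom-maintenance drugs multiply the relapse
  hazard by their freedom factor. Default injections: phenobarbital 0.5
  (months 1–4, neonatal patients), ACTH 0.6 / vigabatrin 0.7 around the
  spasm window, levetiracetam 0.9, topiramate 0.85, clobazam freedom 0.4,
  ketogenic diet freedom 0.55. Exposure windows follow age-typical
  prescribing, so recovered ORs include realistic age confounding; a
  `randomized_exposures` mode places windows uniformly at random for clean
  effect-recovery and null-calibration designs.
- **Milestones and scores.** Lognormal acquisition ages (medians: head
  control 6.3, roll 7.6, grasp 10, sit 12, walk 29 months, words 24) with
  an additive delay and reduced achievement probability for neonatal-onset
  patients (e.g. walking unassisted 0.68 vs 0.25), which injects the
  onset–outcome coupling. GMFM-66-IS scores follow a saturating age curve
  (≈26 at 6 months to ≈58 past age five) with noise.
- **Predictability injection.** `inject_predictability_structure`
  overwrites a fixed rounded count of epileptic patients with early-offset
  patterns (seizures resolving by month 7, zero after) and the rest with
  uniform-random refractory patterns, recording ground-truth labels.

Every latent draw is returned in a `GroundTruth` record serialized beside
the cohort; analysis modules never read it.

**What the generator does not emulate:** medical-record abstraction noise,
within-month seizure-type co-occurrence structure beyond the two modelled
types, dose titration, EEG, genomic background, or real prescribing
cascades. Passing tests therefore demonstrate that the pipeline recovers
known structure under the stated conditions — not that the clinical
estimates from any real cohort are unbiased.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; identical
(config, seed) pairs produce byte-identical serialized cohorts and
identical analysis outputs. The test suite and the acceptance script run
at reduced replicate counts chosen to keep Monte-Carlo error well inside
the asserted tolerances: permutation tests at 2,000–20,000 draws (100,000
in production defaults), OFTS at 200 trials/month, null-coverage at 50
simulated cohorts, oracle sweeps at 10,000 random seizure strings and the
exhaustive set of 2×2 tables with n ≤ 40.

## Known limitations

- Patient-month ORs inherit within-patient correlation and age
  confounding; the bootstrap CI mitigates only the former.
- The paired virtual-trial evaluation is deliberately literal about the
  described synthetic-control comparison; its OFTS is close to an
  eligibility indicator, and the rank-sum mode should be preferred when a
  graded power surface is wanted.
- The 66.7th-percentile fidelity threshold and the uniform permutation
  null are declared conventions; results labelled high/low fidelity shift
  with both.
- Achievers-only milestone quantiles are biased early under censoring; the
  KM mode exists precisely because of this.
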