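# Methods

This note documents the models, decision rules, numerical conventions and
known limitations of `tinnipy`.

## Startle-trial signal model

A trial is two force-transducer windows on a common sample rate (default
1 kHz): a 200 ms pre-stimulus baseline and a 200 ms startle-response window.
The baseline is zero-mean Gaussian noise with standard deviation
`baseline_noise_sd` (force units; default 1). The startle window adds a
half-sine transient (default 100 ms) whose peak amplitude is lognormal:

    A = startle_amp_median · habituation_decay^(trial−1) · exp(σ·Z),  Z ~ N(0,1)

with defaults median 50 force units and σ = 0.5. The half-sine shape is a
convenience: the scoring statistic is an RMS ratio, so only the amplitude
scale of the transient matters, not its waveform. Habituation is a geometric
per-trial decay of the amplitude median (default 0.99 per trial), which is
why the scorer excludes the first trials of each test. An inhibitory
pre-stimulus (gap or prepulse) multiplies the amplitude by
`1 − suppression`; healthy gap and prepulse suppression both default to 0.5,
which gives the per-test t-test essentially full power at 46 scored trials
while leaving realistic trial-level spread.

Inter-stimulus intervals are drawn uniformly from 15–30 s and recorded, but
carry no effect on amplitudes.

**Tinnitus ("fill-in") model.** Tinnitus at a background frequency
multiplies *gap* suppression by `tinnitus_effect` from the animal's onset
week onward (0 = gap detection abolished; default 0.1, a strong deficit).
Prepulse detection is untouched: a tinnitus percept masks a silent gap in
matched background noise but not a sound above it. Treatment with efficacy
*e* restores effective gap suppression to
`gap_suppression · (tinnitus_effect + e·(1 − tinnitus_effect))`.

**Hearing-loss confound.** The optional hearing-loss flag multiplies *both*
gap and prepulse suppression by `hearing_loss_factor` (default 0 =
abolished), and only at the 14 kHz background — the frequency region of the
simulated threshold loss — and only post-trauma. A pure "PPI failure" would
never be observed by the decision tree, which tests PPI only after a GPIAS
failure; abolishing both is what produces the GPIAS-fail + PPI-fail pattern
the classifier maps to `undetermined`. The default probability of the flag
is 0, matching a cohort in which no animal was excluded for failed hearing
controls.

## Scoring conventions

* RMS ratio per trial; trials with a zero-RMS baseline are flagged and
  dropped with a logged warning, never imputed.
* Exclusion: the first 4 trials of the 50, by overall trial order regardless
  of condition (the literal reading of "first 4/50"); configurable.
* The t-test is an unpaired two-sample Student's t (equal variance) by
  default, Welch optionally. The implementation computes the definitional
  formulas directly with the p-value from the t distribution; the test
  suite cross-checks it against `scipy.stats.ttest_ind` to 1e-12.
* `passed` requires two-tailed p < α **and** mean(inhibited) <
  mean(uninhibited): paradoxical startle facilitation is never a pass.
  Consequently the *pass* rate under the null is α/2; the type-I-error
  calibration in the acceptance checks is therefore stated on the
  significance rate (p < α), which is the quantity the binomial band around
  α describes.
* Percent suppression defaults to the ratio-of-means form
  `100·(1 − mean(inh)/mean(uninh))`; a mean-of-ratios alternative (pairing
  trials by within-condition order) is available via configuration. The two
  differ only in weighting; the ratio-of-means form is the default because
  it is well-defined for unequal per-condition counts after exclusions.

## Cohort protocol

Each animal is run through the study flow: baseline GPIAS sessions (both
frequencies per session) until two sessions pass in full, one passing
baseline PPI session, then weekly post-trauma sessions. A failed weekly
GPIAS at frequency f triggers a same-week PPI at f and, if the PPI passes, a
confirmation GPIAS at f; a confirmed failure establishes the deficit. The
confirmation retest ("two days later" in the protocol) is represented as a
second session within the same week — calendar-day resolution is not
modelled. Confirmed animals are assigned alternately to LI-rTMS and sham in
order of confirmation and receive a day-15 session; unconfirmed animals
leave the study after 12 weeks, mirroring the design in which only animals
with behavioural evidence of tinnitus proceeded to treatment and
electrophysiology.

Cohort defaults encode the study conditions: 18 animals, two-thirds
prevalence, deficit frequency split 5:5:2 over 8 kHz/14 kHz/both, onset
weeks drawn from a normal(5.2, 1.7) rounded and clipped to 2–9, a 12-week
window, and treatment efficacy 1 for LI-rTMS (full restoration) versus 0 for
sham.

## Classifier

Classification is a pure function of the scored test sequence. Within a
week, tests are ordered by session id; the first GPIAS per frequency is the
initial test, later ones the confirmation. Status is `tinnitus` at the first
qualifying week (with the frequency, or "both" if both qualify that week),
`undetermined` if a confound week occurred and no later week qualified,
otherwise `no_tinnitus`. Phase outcomes report percent suppression at the
tinnitus frequency for BT (mean over fully passed baseline sessions), AT
(the onset week's initial and confirmation tests) and D15; animals with a
deficit at both frequencies contribute the mean over both frequencies and
have no non-tinnitus-frequency value.

## Neural analysis

Nominal CF is assigned from electrode depth with an exponential tonotopic
map `f(d) = f_min · 2^(octaves/mm · d/1000)`; defaults f_min = 1 kHz at map
origin and 1 octave/mm, a placeholder calibration — individual nominal CFs
are map-dependent, and only the stratified analysis (< 10 kHz vs ≥ 10 kHz,
boundary in the high stratum) is treated as meaningful. Simulated
populations draw 77–95 units per animal with lognormal spontaneous rates
(median 5 spikes/s, σ = 0.8), the ≥ 10 kHz stratum elevated by a
hyperactivity factor (default 2) and LI-rTMS animals' rates scaled by 0.9 —
a deliberately sub-significant treatment trend.

Mann-Whitney U uses mid-ranks, exact enumeration of the permutation
distribution when both groups have ≤ 7 observations (enumeration handles
ties naturally), and otherwise the normal approximation with tie and
continuity corrections. Kruskal-Wallis H carries the tie correction, with
the convention H = 0, p = 1 when every pooled value is identical. Dunn's
pairwise z uses mean ranks with the pooled tie-corrected variance; the
default multiplicity correction is Bonferroni-style over all pairs (the
common convention in Dunn implementations), with Šidák and uncorrected
variants available.

## Split-plot ANOVA

The mixed ANOVA uses the classical weighted sums of squares and supports
unequal numbers of subjects per between-group, provided every subject is
measured at every within level (incomplete designs raise an error rather
than silently dropping data; this also accommodates simulated cohorts that
confirm an odd number of animals). F for the between effect uses the
subjects-within-groups mean square; within and interaction effects use the
residual. Degenerate all-constant responses are reported as F = 0, p = 1. No
sphericity correction is applied by default; a Greenhouse–Geisser
adjustment of the within-factor degrees of freedom is available for designs
with ≥ 3 within levels. The test suite verifies the decomposition against
sequential least-squares projections to 1e-10 and against
`pingouin.mixed_anova`.

Post-hoc contrasts between design cells use the error term appropriate to
the contrast: within-subject contrasts use the residual mean square on its
df; contrasts across between-groups use the Winer pooled term
`(MS_subj + (b−1)·MS_res)/b` with Satterthwaite df. The Šidák family size is
the number of contrasts actually requested (the four planned phase
contrasts in the treatment analysis), not all possible cell pairs.

A note on degrees of freedom: a 2-arm × 3-phase design with 6 subjects per
arm puts within-subject effects on (2, 20) df, and a 2-arm × 2-side BDNF
design on (1, 10). A repeated-measures CAP analysis across 8 frequencies
with 12 animals has (7, 70) within-subject df under this model; reports of
such data with ~110 denominator df imply a different (e.g. fully pooled)
error accounting that this package deliberately does not reproduce.

## BDNF arithmetic

BDNF percent of total protein is computed with both quantities per mL of
undiluted lysate: the ELISA concentration (pg/mL) is measured on the
undiluted supernatant, while total protein (µg/mL) is measured on a 1:10
diluted aliquot and is scaled back by the dilution factor; pg convert to µg
before the percentage. All unit handling is centralised in
`bdnf_percent_total` so the number remains auditable. Standard-curve
fitting and protein quantification chemistry are out of scope: the pipeline
starts from interpolated concentrations.

## What the generator does and does not emulate

The generator reproduces the *statistical* structure the analysis assumes:
lognormal trial amplitudes with habituation, condition-dependent
suppression, a frequency-specific deficit with a defined onset, the
adaptive weekly protocol, skewed spontaneous-rate populations with a
tonotopically confined elevation, a > 10 kHz unilateral threshold loss, and
a right-vs-left inferior-colliculus BDNF offset. It does not emulate
acoustic waveforms, motion artefacts or electrical noise in force traces,
drift in startle reactivity across weeks, correlations between an animal's
behavioural deficit and its neural hyperactivity, or session-level
covariates (time of day, handling). Passing recovery tests therefore show
that the analysis correctly extracts the effects it targets under its own
assumptions — not that those assumptions exhaust real recordings. No
trial-level variability or startle magnitudes are available from the study
to calibrate against, so amplitude-scale defaults are chosen for
statistical plausibility only.

## Problem sizes and numerical conventions

The validation experiments use: 2000 tests for the t-test null calibration;
a 200-animal cohort for classifier recovery; 100 seeded 18-animal runs for
the end-to-end treatment pattern; 20 seeds × 4 groups × 250 units for
neural detection and 1000 seeds for its null calibration. Exact Mann-Whitney
enumeration is capped at 7 per group (C(14,7) = 3432 subsets). Tolerances:
oracle agreement at 1e-10 to 1e-12; Monte-Carlo rates judged against exact
binomial 95% acceptance bands. Determinism: a single master seed fans out
to per-animal and per-stage substreams via `numpy` seed sequences, and a
rerun with the same configuration reproduces byte-identical output tables.
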