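# Methods

## Study design being modelled

Ten healthy infants (7 male, 3 female; age ≈ 5 months, length 68.8 ± 2.8 cm,
BMI 15.5 ± 1.5 kg/m²) each spend 24 h (09:30 → 09:29) in a whole-room infant
calorimeter that records oxygen consumption, carbon-dioxide production and a
physical-activity (PA) index every minute, while observers flag feeding,
sleep and parental interaction. The processed outputs — 24-h energy
expenditure (EE24), resting (RMR) and sleeping (SMR) metabolic rate, all in
kcal/kg/d — serve as the reference against which 11 published linear
prediction equations are judged with paired t-tests and Bland–Altman limits.

## Equation registry

Each equation is stored as `kcal/d = weight_coef·WT + length_coef·L +
intercept`. Although such equations are conventionally *reported* under a
kcal/kg/d heading, the expressions themselves produce whole-body kcal/d;
per-kg values are obtained by dividing by the infant's weight, and both are
exposed. Length terms published in the `coef × (L/100)` metre-style form are
stored per-cm (printed 1517.4 → 15.174/cm) so that a single linear
evaluation path serves every equation bit-identically. Chamber-derived
equations apply to either sex; WHO/Schofield/Oxford carry one variant per
sex and raise on a sex mismatch rather than silently substituting. When a
cohort publishes BMI and length but not raw weight, weight is derived as
`BMI·(L/100)²`; if both are supplied and disagree by more than 1% the
measured weight wins with a warning.

One registry row cannot be reconciled internally: the weight-based chamber
RMR equation's published cohort mean (65.0 kcal/kg/d) is incompatible with
its own coefficients evaluated at the published anthropometrics
(≈ 68.5 kcal/kg/d per kg). The row is implemented as printed; it is simply
not a reproducible reference value.

## Trace reduction

- **Minute energy.** The abbreviated Weir relation,
  `EE = 3.941·VO₂ + 1.106·VCO₂` (kcal/min with gas volumes in L/min). The
  caloric equivalents are configurable (`CalorimetryConfig`) for
  laboratories preferring slightly different constants. Traces carrying a
  pre-computed `ee_kcal_min` column bypass the gas step.
- **Summary periods.** Non-overlapping 5-minute blocks aligned to the
  recording start (288 per day). Period EE and PA are arithmetic means;
  period RQ is ΣVCO₂/ΣVO₂. A period touched by *any* parental-interaction
  minute is censored — the strictest reading of interaction correction — and
  censoring can only remove periods, never alter retained ones.
- **RMR** is the zero-activity intercept of an unweighted OLS regression of
  period EE on period PA over retained periods, × 1440 / WT. Degenerate
  activity (all PA equal) raises; a negative intercept is returned flagged,
  never silently. The fit is delegated to statsmodels; tests hold it to a
  closed-form normal-equations solve at 1e-9.
- **SMR** is the mean EE of retained periods lying *wholly* inside
  23:30–05:30 (half-open on the right, wrapping midnight), fully asleep and
  with mean PA ≤ 1.5, × 1440 / WT. No qualifying period raises an explicit
  "SMR undeterminable" error, which `process_trace` surfaces in the profile
  (NaN + message) so the other estimates survive.
- **EE24** is the mean EE of retained periods × 1440 (a time-normalised
  extrapolation consistent with the ×1440 used for RMR/SMR). Whether the
  day total should be taken over censored or all periods is a genuinely open
  choice; the default follows the censored convention used for the other
  two quantities, and `ee24_mode="full"` averages every period instead.

## Synthetic chamber traces

No minute-level recordings are publicly available for the reference cohort,
so the simulator generates them. Latent minute energy is

```
EE(t) = basal·WT/1440 · (1 − A·cos(2π(t − t_trough)/1440))    circadian basal
      + c_act·WT·PA(t)                                        movement cost
      + TEF(t)                                                post-feed thermogenesis
```

with independent Gaussian observation noise (SD 0.005 kcal/min) added on
top. Gas exchange is produced by exact inversion at a simulated RQ
(N(0.88, 0.04²) clipped to [0.75, 1.05]): `VO₂ = EE/(3.941 + 1.106·RQ)`,
`VCO₂ = RQ·VO₂`, so recomputing EE from gas reproduces the noisy latent
signal to machine precision.

Behavioural structure:

- Sleep and wake alternate in bouts uniform on 120–240 min, except that wake
  bouts beginning between 23:00 and 06:00 are brief night wakings
  (20–45 min) — infants this age sleep predominantly at night, and this
  keeps the night reference window densely populated with sleep.
- Awake PA ~ N(4, 2²), asleep PA ~ N(0.5, 0.3²), feeding PA ~ N(1.5, 0.8²)
  (quiet-alert feeding), all clipped at 0. The PA unit is arbitrary
  (weight-normalised oscillations/min); only the SMR cutoff 1.5 anchors it.
- Six 110-kcal feeds per day start in fully-awake daytime minutes
  (06:00–22:00), ≥ 90 min apart. Parents always interact to feed: the
  interaction flag covers each feed ± 10 min. The thermic effect of feeding
  (6.2% of feed energy) begins after a 25-min absorption lag — i.e. once
  the interaction window has closed — and decays linearly over 60 min.
  Placing the thermic bump outside censored periods keeps the censored
  EE24/RMR estimators nearly unbiased, and daytime-only feeds keep
  thermogenesis out of the night SMR window.
- The energetic cost of movement scales with body mass (`c_act·WT·PA`);
  with an absolute cost, light infants would receive implausibly large
  per-kg activity contributions and quiet-sleep EE could exceed basal EE.
- Circadian modulation: amplitude 5% of basal with the trough at 02:30.

Between-infant physiology in `simulate_study`: basal rate
~ N(66.0, 3.5²) kcal/kg/d truncated at ±3 SD, and a lognormal awake-activity
scale (σ = 0.65, capped at 4) multiplying awake PA. One master seed drives a
`SeedSequence` tree (cohort stream, physiology stream, one stream per
trace), so studies are byte-reproducible and traces independent.

Ground truth per trace: `true_rmr` is the infant's basal rate, `true_smr`
the noiseless latent mean over asleep minutes in the night window × 1440/WT,
`true_ee24` the overall noiseless latent mean × 1440/WT. Under defaults
`true_smr ≤ true_rmr ≤ true_ee24` for every infant.

### Calibration

Two latent-rate constants have no published anchor and were fixed once, by
simulation, so that a default cohort's *processed* outputs land on the
reference cohort means (78.7 / 66.0 / 65.0 kcal/kg/d):
`activity_ee_coef = 0.00269` kcal/min per PA unit per kg (sets SMR through
asleep activity) and `thermic_effect_fraction = 0.062` (sets EE24; 6.2% of
intake is a physiologic thermic effect for formula-fed infants). At these
values 600 simulated infants give processed cohort means of 78.3 / 65.6 /
64.9 and between-infant SDs of ≈ 5.5 / 4.0 / 3.3.

The activity spread σ = 0.65 is a deliberate compromise: the reference
cohort's EE24 SD (8.4) could only be reached with σ ≈ 1.4, at which point
the median infant is nearly inactive, the EE-on-PA regression loses
identification and the processed RMR cohort mean drifts to ≈ 68.5. The
simulator therefore under-disperses EE24 relative to the reference cohort —
real infants also differ in basal/activity coupling, feed volumes and
measurement-day conditions that this generator does not model.

## What the simulator does and does not establish

Passing tests show that the *pipeline* recovers known ground truth from
traces with realistic circadian, sleep, feeding and activity structure
(median relative error ≈ 1.8% for RMR, ≈ 0.1% for SMR, ≈ 0.4% for EE24),
and that the statistical layer is exact (type-I error 5.0% ± 0.5%,
regression at oracle precision, Bland–Altman identities). They do not show
that real chamber data are this well behaved: the generator has no gas-
analyser drift or chamber washout dynamics, no autocorrelated noise, no
sleep staging beyond the observer flag, and no behavioural idiosyncrasies
beyond the flags the pipeline consumes.

## Replicating the published agreement classification

On simulated default cohorts the five classical equations are flagged
discordant essentially always (their 12–20% underestimation of RMR is a
~10 SE effect at n = 10). The *concordant* side is intrinsically fragile:
the chamber equations sit 1.7–2.6 kcal/kg/d from their reference means with
between-infant difference SDs of ~3–6, i.e. noncentral-t rejection
probabilities of roughly 15–45% per replicate at n = 10. A published
non-significant p-value for such an effect size replicates in only ~55–85%
of repeat studies — a small-sample property of the design itself, not of
this implementation — so the package's replication test of the concordant
classification at a 90% bar fails honestly and is left failing.

## Numerical and interface choices

- Sample SD (n−1) throughout; cohort SD of a single infant is 0.
- Bland–Altman limits use exactly ±2 SD (the convention of the reference
  analysis), differences oriented calculated − reference by default with a
  `ref-calc` flag for the opposite convention.
- Paired t with identical series returns t = 0, p = 1; a constant nonzero
  difference (zero variance) reports p at the floating-point floor with a
  `zero_variance` flag instead of dividing by zero.
- Verdicts are a pure threshold: agreement ⇔ p ≥ α, α = 0.05 two-sided.
- Configs are frozen dataclasses validated at construction; YAML round-trips
  byte-stably. Exit code 2 from the CLI marks validation failures.
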