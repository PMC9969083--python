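# Methods

This note documents the models, numerical choices and open design decisions
behind `cpetkit`, in the order data flows through the package.

## 1. The synthetic ramp test

The generator exists so that every detector can be validated against known
ground truth. It emulates an incremental cycle-ergometer protocol — 5 min
rest, 5 min warm-up at 25 W, ramp from 50 W at +25 W·min⁻¹ at 70 rpm — and
builds each channel from noiseless construction rules before applying
measurement noise.

**Oxygen uptake.** Mean V̇O2 follows first-order kinetics toward the
steady-state demand `vo2_baseline + vo2_gain · power(t)` with time constant
`vo2_tau` (default 25 s, typical of trained subjects; gain default
10.1 mL·min⁻¹·W⁻¹). The test terminates when the rolling 30-s mean of V̇O2
reaches the profile's VO2max — the same statistic the VO2max detector uses —
so a detected VO2max is an unbiased estimate of the encoded one.

**Ventilatory equivalent.** V̇E/V̇O2 as a function of V̇O2 is a convex
quadratic below VT1, with its minimum (`cop_value`) placed at
`cop_location_frac` of the VT1 V̇O2 and its left arm anchored at the
ramp-onset equivalent `eq_start`; above VT1 it rises linearly
(`eq_slope_post_vt1`, units per L·min⁻¹ V̇O2) and above VT2 with a steeper
slope (`eq_slope_post_vt2`). V̇E = (V̇E/V̇O2)·V̇O2. The minimum of this
curve **is** the cardiorespiratory optimal point, and it precedes VT1 by
construction.

**Carbon dioxide output.** V̇CO2 is a static function of V̇O2: RER·V̇O2 at
rest, then piecewise linear with a single upward slope break at VT1 (the
V-slope signature; the RER waypoint at VT1 sits 28% of the way from the
resting to the maximal RER). Beyond VT2, V̇CO2 is defined as the inverse of
a *straight* V̇E-vs-V̇CO2 segment running from the VT2 point to
(RERmax·VO2max, V̇E at VO2max). This makes the respiratory-compensation
point a crisp slope change of the V̇E–V̇CO2 relation — the defining
criterion the VT2 detector fits — rather than a gradual bend buried in
curvature, which is also how real tests present it.

**Breath timing and secondary channels.** Respiratory frequency, heart rate
and the end-tidal pressures interpolate between resting and maximal values
along the V̇O2 trajectory; breath intervals are 60/Rf(t) with a fixed
inspiratory fraction Ti/Ttot = 0.45 (deterministic timing; no breath-hold or
swallow artifacts). Tidal volume is V̇E/Rf.

**Noise.** Every measurement channel is multiplied by independent,
mean-one lognormal noise with coefficient of variation `noise_cv` (default
5%; breath-by-breath variability of this magnitude is typical of
breath-by-breath carts). Mean-one noise keeps window averages unbiased.
Breath timing itself stays noiseless.

**Cohort sampling.** `sample_cohort` draws athlete parameters from
sex-specific truncated normal distributions (±3 SD plus physiological
bounds) whose means and SDs reproduce a highly trained endurance cohort of
9 women and 24 men: VO2max 46.17 ± 5.87 vs 56.05 ± 7.57 mL·kg⁻¹·min⁻¹,
COP 27.24 ± 3.36 vs 22.64 ± 2.95 VE/VO2, VT1 at 65.3 vs 68.0 %VO2max, VT2
at 81.4 vs 84.3 %VO2max, maximal RER 1.16 vs 1.19, maximal HR ~187 vs
~190 bpm, maximal Rf ~52 breaths·min⁻¹. Resting V̇O2 means (263 / 336
mL·min⁻¹) are back-computed from the cohort's resting metabolic rates
(1834 / 2348 kcal·day⁻¹) through the Weir equation at RQ 0.82, so a
simulated rest recording reproduces the intended RMR. Constants the cohort
tables do not determine (resting HR 60 ± 8, resting Rf 12 ± 2, V̇O2 gain
and kinetics, equivalent-curve slopes estimated from the between-event
equivalent differences) use standard exercise-physiology values.

Validity constraints applied during sampling (draws violating them are
rejected and redrawn):

- VT1 and VT2 fractions are drawn jointly (bivariate normal, ρ = 0.8 —
  thresholds are strongly correlated within an athlete) and must differ by
  at least 8% of VO2max: closer "thresholds" are not distinct physiological
  events and no windowed detector could separate them.
- `cop_location_frac` ≤ 0.90: the COP is defined on a one-minute grid, so
  a VE/VO2 minimum closer than about one ramp-minute to VT1 is not a
  distinct event.
- The equivalent curve may not decelerate at VT1 (quadratic slope at VT1 ≤
  post-VT1 linear slope), and the V̇E–V̇CO2 slope must increase by ≥ 25% at
  VT2 — both are consistency requirements between the profile parameters
  and the events they claim to encode.

These constraints slightly truncate the tails of the printed distributions;
they are validity conditions of the generative model, not tuning knobs.

## 2. Windowing

Breaths are averaged into half-open tumbling windows [t, t+10 s) anchored at
ramp onset, six windows to a minute; a minute is *complete* only when all
six windows contain breaths, and only complete minutes enter the COP search.
Derived ratios use ratio-of-means (window-mean V̇E over window-mean V̇O2),
because the ventilatory equivalent is a ratio of minute quantities;
mean-of-ratios is available as a config switch and the two are deliberately
not interchangeable in tests. Isolated empty windows are linearly
interpolated; runs of empty windows invalidate their minute. Tumbling
(not rolling) windows make "the lowest minute mean" well defined.

The quality filter removes physically impossible breaths (non-positive gas
volumes) and breaths whose instantaneous V̇E/V̇O2 falls outside [10, 80]
during exercise; removing more than 20% of breaths escalates a warning.

## 3. Event detection

**Two-segment regression** (`fit_two_segment`) is the workhorse: an
exhaustive search over all admissible splits (each segment keeping at least
`min_seg = 5` points), two independent least-squares lines per split,
pooled SSE minimised, earliest split on ties (relative tolerance 1e-12),
threshold = intersection of the two lines. A fit is only a *breakpoint*
when it improves on a single line by at least 5% of SSE (`improvement ≥
0.05`); parallel fitted lines or sub-threshold improvement raise a
detection failure instead of fabricating a threshold. Series here are
≤ ~150 windows, so the exhaustive search is exact and cheap. An optional
weight vector turns the objective into weighted SSE.

**Detector inputs** are 10-s window means passed through a centred
5-window rolling mean. Smoothing the fit inputs (not the COP minutes)
roughly halves window noise while displacing an ideal kink by well under
one window.

**VT1** fits V̇CO2 against V̇O2 over the full exercise phase. An option to
cap the fit below a known VT2 exists (`vo2_ceiling`), but the pipeline does
not use it: on simulated tests the V̇CO2–V̇O2 relation has its single strong
break at VT1, and truncating the fit at a noisy VT2 estimate strips the
right segment of leverage — in a 150-test experiment at 5% noise the
truncated refit doubled VT1 RMSE (3.2% → 7.7%). Confirmation checks the
equivalents criterion in the 30 s after the estimate: V̇E/V̇O2 slope > 0
while the V̇E/V̇CO2 slope stays ≤ 0.01 units per window.

**VT2** fits V̇E against V̇CO2 restricted to windows above the VT1 estimate
(the sub-threshold part of that relation is curved, not a second line), and
weights the fit by 1/V̇E². The weighting matters: breath noise is
multiplicative, so the few largest end-of-test windows otherwise dominate
the pooled SSE and can drag the split onto a short noise-chasing end
segment with a wild intersection. An intersection falling outside the
observed V̇CO2 range falls back to the data value at the split. The V̇CO2
breakpoint is mapped to V̇O2 by interpolation along the series. VT2 must
exceed VT1; otherwise the run fails with an ordering violation rather than
reporting an inconsistent pair.

**Threshold timing** interpolates the running maximum of the fitted channel
against time — under noise this is much more stable than taking the nearest
raw window.

**COP** is the minimum minute-mean V̇E/V̇O2 over complete exercise minutes,
earliest minute on exact ties; the result carries the category
(< 22 / 22–30 / > 30), the V̇O2 at the optimum, and whether it precedes the
detected VT1.

**VO2max** is the highest rolling 30-s window-mean of V̇O2 (three
consecutive 10-s windows); the relative value divides by body mass, and a
caller-supplied predicted VO2max yields percent-of-predicted. No plateau
verification is attempted.

**Event panel.** At each event the panel reports the containing window's
channel means plus derived quantities: METs (V̇O2/mass/3.5), oxygen pulse
V̇O2/HR, FAT%/CHO% from Frayn shares, ventilatory drive VT/Ti,
Ttot = Ti + Te, heart-rate reserve against a predicted maximum (default
220 − age, replaceable), and t% as elapsed exercise time over total
exercise duration ×100. Oxygen pulse is computed per subject; any cohort
aggregation of ratios happens downstream, which is why a cohort mean of
per-subject ratios will not equal the ratio of cohort means.

## 4. Metabolic panel

Substrate oxidation uses protein-free Frayn stoichiometry (no urinary
nitrogen measurement is assumed, so protein oxidation is taken as zero) with
9.0 kcal/g fat and 4.0 kcal/g carbohydrate. Negative rates (RQ below 0.707
or above 1.0) are clamped to zero with a flag before percentages are formed,
keeping FAT% and CHO% inside [0, 100] and complementary. RQ outside
[0.6, 1.3] is flagged non-physiological. RMR discards the first 5 min of a
40-min supine recording as acclimatization and applies Weir to the mean gas
exchange of the remainder; the substrate kcal/day values are the Weir total
split by the Frayn energy shares, so fat + cho reproduces the RMR exactly.
OUE = 1000/(V̇E/V̇O2) and MET = 3.5 mL O2·kg⁻¹·min⁻¹ are definitional.

## 5. Cohort statistics

Standardization uses population σ (divisor n), matching the plain z-score
formula; sample σ is a config option. PCA is the eigendecomposition of the
correlation matrix (equivalently, covariance of the z-scores): eigenvalues
sorted descending, values below 1e-10 clamped to zero with the effective
rank reported (with n subjects < m variables the matrix is necessarily rank
deficient, at most n − 1 nonzero eigenvalues), loadings = eigenvector ×
√eigenvalue so each loading equals the Pearson correlation between component
scores and the standardized variable (asserted to 1e-8 in tests), scores =
Z·eigenvectors, and a deterministic sign convention (the largest-magnitude
loading of each component is positive) so results are identical across runs
and eigen-solver backends. Kaiser retention counts eigenvalues strictly
greater than 1. Variance attribution reports, per retained component, its
variance fraction, the dominant variable by |loading|, and the target
variable's loading and sign. The package reports all numerically nonzero
components rather than imposing any fixed component cap.

Group comparison runs per variable: Shapiro-Wilk normality within each
group and Levene homoscedasticity across groups at α = 0.05; both groups
normal → unpaired t-test (Welch's form when Levene rejects), otherwise
Mann-Whitney. No multiple-testing correction is applied by default, matching
common practice for exploratory CPET panels; the gate outcome is recorded
per variable.

The cohort assembly flattens per-athlete results into one row per athlete:
demographics, event summaries, and every panel variable at each of the four
events (~90 columns for the simulated panel; optional channels such as
stroke volume or dead-space fraction appear only when supplied for all
athletes — a variable present for some athletes but not others aborts with
the offenders listed). Columns constant across athletes (e.g. a fixed
inspiratory fraction under deterministic breath timing) are dropped with a
warning before standardization, using a relative tolerance so
constant-up-to-rounding counts as constant.

## 6. Pipeline and reproducibility

A single pydantic config (unknown keys rejected) travels through every
stage and is echoed in every result. One run seed fans out to per-athlete
sub-seeds through a counter-based `SeedSequence` derivation, so cohorts are
reproducible as a whole and each athlete is independently re-runnable.
Every stage decision (breaths removed, incomplete minutes, failed
confirmations, dropped columns) is appended to a warnings list that the
final report carries exactly once. Exit codes: 0 success, 2 validation
error, 3 detection failure.

## 7. What the synthetic validation does and does not show

Problem sizes used in the shipped validation: single tests of ~600–900
breaths; recovery experiments of 30 athletes per sex at 5% noise (mean COP
error within 0.5 VE/VO2 units, VT1/VT2 V̇O2 RMSE within 5%, detected COP
before detected VT1 in ≥ 95% of tests); 200 replicate cohorts for the
sex-difference replication; a 33-athlete cohort for the end-to-end PCA run.

The generator reproduces the marginal distributions and event structure of
a real athlete cohort, but not: correlated multi-channel noise (cart noise
is partly shared across channels), breath-detection artifacts, pedalling
cadence drift, VO2 plateau behaviour at exhaustion, day-to-day biological
variability, or sex-specific breathing-pattern differences at the optimum
(Rf at COP differs by sex in real data; the generator ties Rf to the V̇O2
trajectory only). Passing the recovery criteria therefore demonstrates that
the detectors are unbiased and precise under the stated noise model — not
that they attain the same precision on vendor-exported field data. The PCA
stage's variance fractions and top contributors on simulated cohorts
reflect the generator's correlation structure, which is simpler than a real
cohort's; the structural assertions (trace conservation, loading identity,
planted-factor recovery) are generator-independent.

Known limitations: the V̇E-vs-V̇CO2 fit can still misplace VT2 by ~10–15%
for athletes whose VT2 sits within ~5% of VO2max (few windows remain above
the break); threshold confirmation flags are conservative under noise and
are reported, not enforced; and the RMR stage assumes a stationary
recording — it does not detect drift or arousal within the retained
35 minutes.
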