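# cpetkit

Breath-by-breath analysis of cardiopulmonary exercise tests (CPET) for
exercise physiologists working with endurance athletes: detection of the
**cardiorespiratory optimal point (COP)**, both **ventilatory thresholds**,
and **VO2max**; the derived metabolic panel (substrate oxidation, resting
metabolic rate, METs, oxygen uptake efficiency); and cohort-level
**eigen-PCA** that attributes COP variance across the full CPET variable
panel. A synthetic ramp-test generator with known ground truth makes every
stage testable end to end.

## The quantities at the core

Given per-breath gas exchange (V̇O2, V̇CO2, V̇E, HR, breath timing) from an
incremental cycle-ergometer ramp (5 min rest, 5 min warm-up at 25 W, start
50 W, +25 W·min⁻¹, 70 rpm):

- **COP** — the lowest per-minute ventilatory equivalent for oxygen,
  min<sub>minute</sub> V̇E/V̇O2, where each minute is the mean of six 10-s
  window averages. It is a *submaximal* efficiency index, normally located
  below the first ventilatory threshold, and categorised as low (< 22),
  moderate (22–30) or high (> 30).
- **VT1** — the V-slope breakpoint: an exhaustive two-segment least-squares
  fit of V̇CO2 against V̇O2, the threshold being the intersection of the two
  fitted lines; confirmed when V̇E/V̇O2 starts rising while V̇E/V̇CO2 stays
  flat or falls.
- **VT2** (respiratory compensation point) — the same two-segment fit of
  V̇E against V̇CO2, confirmed by a rise of both equivalents.
- **VO2max** — the highest rolling 30-s mean of V̇O2.
- **RMR** — Weir equation on the mean resting gas exchange,
  kcal·day⁻¹ = (3.941·V̇O2 + 1.106·V̇CO2)·1.44 (gases in mL·min⁻¹), with
  protein-free Frayn substrate partitioning
  (fat = 1.67·(V̇O2 − V̇CO2), cho = 4.55·V̇CO2 − 3.21·V̇O2, L·min⁻¹).
- **Cohort PCA** — z-score standardization (population σ), Pearson
  correlation matrix, eigendecomposition, Kaiser retention (eigenvalue > 1),
  loadings defined as score–variable Pearson correlations, and a ranked
  attribution of which variables dominate each retained component.

## Worked example

```python
from cpetkit import sample_cohort, simulate_test, simulate_rest, run_athlete

profile = sample_cohort(n_female=0, n_male=1, seed=1)[0]
test, truth = simulate_test(profile, seed=11)     # 5% breath noise
rest = simulate_rest(profile, seed=12)
result = run_athlete(test, rest)
```

which prints (via the formatting in the example above):

```text
athlete M01  (male, 80.5 kg)
COP        21.11 VE/VO2 (low) at minute 7, before VT1: True
VT1        2873 mL/min (77.5% of VO2max)   [truth 2837]
VT2        3404 mL/min (91.9% of VO2max)   [truth 3362]
VO2max     3704 mL/min = 46.0 mL/kg/min   [truth 3718]
RMR        2348 kcal/day (RQ 0.81, fat 61%)
OUE at COP 47.4 mL O2 per L VE
```

The `[truth ...]` values are the generator's noiseless ground truth: for
this athlete the detected COP is within 0.05 VE/VO2 units and both
thresholds within ~1.5% of their true values despite 5% multiplicative
breath noise. `result` is a plain JSON-serializable dict with the full
variable panel (Rf, VT, V̇E, oxygen pulse, PetO2/PetCO2, FAT%/CHO%, breath
timing, heart-rate reserve, power, …) extracted at each of the four events.

From the shell the same pipeline is:

```bash
cpetkit simulate --n-female 9 --n-male 24 --seed 1 --outdir sim/
cpetkit analyze --breath-file sim/breath_M01.csv --out events.json
cpetkit report --n-female 9 --n-male 24 --seed 1 --outdir run/   # end-to-end
```

`cpetkit report` writes per-athlete event JSONs, the assembled cohort table,
and the PCA report (eigenvalues, variance fractions, retained components,
top contributors per component, biplot tables, and the Shapiro-Wilk/Levene
gated sex comparison).

## Layout

| module | contents |
| --- | --- |
| `cpetkit.io` | breath/cohort table readers and writers, dialect registry |
| `cpetkit.prep` | 10-s windowing, minute binning, quality filtering |
| `cpetkit.events` | two-segment regression, COP/VT1/VT2/VO2max detectors, event panel |
| `cpetkit.metabolic` | Frayn substrate oxidation, Weir RMR, METs, OUE |
| `cpetkit.mstats` | z-scores, Pearson matrix, eigen-PCA, Kaiser rule, attribution, group comparison |
| `cpetkit.simulate` | ramp-test and rest-recording generator with ground truth |
| `cpetkit.pipeline` / `cpetkit.cli` | orchestration, configuration, `cpetkit` command |

See `docs/methods.md` for the model underlying the generator, the detector
design choices, and known limitations.
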