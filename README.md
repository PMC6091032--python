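# vco2ree

Validation pipeline for estimating resting energy expenditure (REE) from
ventilator CO₂ production alone, benchmarked against indirect calorimetry.

## The problem

Indirect calorimetry (IC) is the reference method for measuring REE in
mechanically ventilated ICU patients: it measures oxygen consumption (VO₂)
and CO₂ production (VCO₂) and applies the Weir equation

```
REE (kcal/day) = (3.941·VO₂ + 1.106·VCO₂) × 1440,    VO₂, VCO₂ in L/min.
```

Calorimeters are scarce; modern ventilators report VCO₂ continuously. If a
fixed respiratory quotient RQ = VCO₂/VO₂ is assumed, VO₂ can be replaced by
VCO₂/RQ, giving a VCO₂-only estimator

```
REE-VCO₂ = (3.941/RQ + 1.106) · VCO₂ × 1440
```

whose per-litre multiplier is 5.534 at RQ 0.89 (clinical shorthand:
`5.5 × VCO₂ × 1.44` with VCO₂ in mL/min). This package implements, and
stress-tests end to end, the statistical machinery needed to judge whether
that shortcut is good enough:

- **`weir`** — the Weir algebra, fixed-RQ estimators, RQ grid
  (0.75/0.80/0.85/0.89), simplified linear formulas;
- **`cohort`** — a seeded synthetic ICU cohort generator (80 patients,
  median 3 IC measurements each, REE 2059.5 ± 491.7 kcal/d, RQ 0.75 ± 0.07,
  noisy autocorrelated ventilator traces) so every stage is testable
  without clinical data;
- **`pairing`** — 6-hour ventilator VCO₂ block means, strictly preceding
  each IC measurement, with coverage-based exclusion;
- **`agreement`** — the method-comparison battery: bias ± SD, percentage
  error/difference, Pearson r (Fisher-z CI), Lin's concordance correlation
  (bootstrap CI), 85–115% and 95–105% ratio-band agreement, Bland–Altman
  limits of agreement;
- **`calibration`** — cross-validated ridge regression of REE on VCO₂ (a
  scikit-learn estimator, `RidgeREECalibrator`) and its rounding to an
  integer bedside formula such as `REE = 135 + 8·VCO₂`;
- **`cli`** — `vco2ree simulate | analyze | full-run`.

It is aimed at clinical researchers evaluating VCO₂-based metabolic
monitoring and at statisticians who need a worked, reproducible
method-comparison pipeline.

## Worked example

```bash
vco2ree full-run --seed 1 --out results/demo
```

generates an 80-patient synthetic cohort (381 IC measurements), pairs each
measurement with its preceding 6-h ventilator block, and writes
`paired.csv`, `performance_table.csv`, `bland_altman.csv`,
`calibration.json` and `report.md`. The report's performance table for this
seed:

| Estimator | Mean difference | SD | % Error | % Difference | Correlation | Concordance | Agreement | Tight agreement |
|---|---|---|---|---|---|---|---|---|
| VCO2 with 0.89 RQ | -114.59 | 701.39 | 0.28 | 0.30 | 0.55 (0.48–0.62) | 0.47 (0.40–0.54) | 0.31 | 0.12 |
| VCO2 with 0.85 RQ | -43.93 | 727.55 | 0.28 | 0.29 | 0.55 (0.48–0.62) | 0.47 (0.40–0.53) | 0.33 | 0.10 |
| VCO2 with 0.80 RQ | 54.34 | 764.63 | 0.29 | 0.29 | 0.55 (0.48–0.62) | 0.45 (0.38–0.53) | 0.34 | 0.10 |
| VCO2 with 0.75 RQ | 165.71 | 807.49 | 0.31 | 0.29 | 0.55 (0.48–0.62) | 0.43 (0.36–0.51) | 0.33 | 0.12 |

Read: assuming RQ 0.85 gives the smallest bias (−44 kcal/d) but the SD of
the paired differences (~730 kcal/d) and the Bland–Altman limits of
agreement (≈ ±1430 kcal/d around the bias) are far too wide for individual
patients, and only ~33% of estimates fall within 85–115% of the measured
REE — the same qualitative verdict that motivates keeping IC as the
reference method. Lowering the assumed RQ raises every estimate (the
multiplier 3.941/RQ + 1.106 grows), so the bias rises monotonically as RQ
falls while the correlation column is unchanged (a fixed RQ only rescales
the estimator). The calibration block for this seed fits
`REE = 127.29 + 8.57·VCO₂` (R² = 0.92 on calorimeter VCO₂), rounds it to
`REE = 127 + 9·VCO₂`, and shows that even the calibrated formula reaches
only 33% agreement on ventilator blocks.

Library use mirrors the CLI:

```python
from vco2ree import (CohortConfig, generate_cohort, build_paired_dataset,
                     performance_table)

cohort = generate_cohort(CohortConfig(), seed=1)
ds = build_paired_dataset(cohort.ic, cohort.traces)
for row in performance_table(ds):
    print(f"RQ {row.rq:.2f}: bias {row.mean_difference:+.1f} kcal/d, "
          f"agreement {row.agreement:.2f}")
```

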