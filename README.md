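# ghrelkit

Test–retest reliability analysis for repeated gastrointestinal-hormone
panels. Fasting plasma levels of ghrelin, leptin, GLP-1 and pancreatic
polypeptide (PP) are candidate biomarkers in studies of appetite and body
weight control, but a hormone is only useful longitudinally if repeated
measurements of the same person agree. `ghrelkit` packages the statistics of
a typical two-assessment (baseline / six-month follow-up) reliability study
of such a panel, for biostatisticians and study teams who want to run,
stress-test or plan one:

* **ICC(A,1)** — the two-way mixed-effects, single-measurement,
  *absolute-agreement* intraclass correlation (McGraw & Wong), with its
  F-based 95% confidence interval (Satterthwaite degrees of freedom), an
  F test of H₀: ICC = 0, and the Koo & Li interpretation bands
  (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.90 excellent).
* **Covariate-adjusted ICC** — a linear mixed model with fixed effects
  (fasting glucose, HbA1c, physical activity, dietary habits index) and a
  participant random intercept is fitted by REML; the adjusted ICC is
  σ²_b / (σ²_b + σ²_e) from its variance components, with a seeded
  parametric-bootstrap interval.
* **Paired permutation tests** — baseline vs follow-up mean comparisons
  whose null distribution comes from swapping each participant's two
  assessment labels (equivalently sign-flipping paired differences); Monte
  Carlo sampler (default 100,000 iterations, add-one p-value) plus an exact
  2ⁿ enumeration oracle.
* **Assay censoring** — the deterministic ELISA post-processing rules:
  dilution back-correction (ghrelin 1:10, leptin 1:50, GLP-1 1:6, PP 1:2),
  below-detection values set to 0, values above the highest standard set to
  the standard (2276.02 pg/mL for PP).
* **Lifestyle indices** — a 37-item food-frequency score with a 127-point
  healthy-diet maximum, and MET-based physical-activity energy indices.
* **Synthetic cohorts** — a seeded generator producing participant ×
  assessment tables with log-normal hormone marginals matched to published
  medians/IQRs, a controllable true ICC per hormone, covariate structure and
  optional between-assessment weight drift, so the whole pipeline is
  testable without access to participant-level data.

## Worked example

```python
import ghrelkit as gk

cohort = gk.simulate_cohort(gk.SimulationConfig(seed=42))   # 17 × 2 panel
model = gk.ReliabilityModel(cohort)                          # statsmodels-style
results = model.fit(permutation_iterations=100_000, bootstrap_reps=500, seed=1)
print(results.summary())
```

```text
Test-retest reliability of repeated hormone measurements
participants: 17   assessments: BL vs FU   scale: raw pg/mL
covariates (adjusted ICC): glucose_mmol_l, hba1c_pct, activity_h_week, diet_index
------------------------------------------------------------------------------
hormone    ICC(A,1)          95% CI        p   category  adj ICC          95% CI
------------------------------------------------------------------------------
ghrelin        0.97    [0.93, 0.99]   0.0000  excellent     0.97    [0.91, 0.99]
leptin         0.28   [-0.25, 0.67]   0.1421       poor     0.30    [0.00, 0.70]
glp1           0.70    [0.35, 0.88]   0.0005   moderate     0.77    [0.37, 0.91]
pp             0.14   [-0.36, 0.57]   0.2961       poor     0.14    [0.00, 0.58]
------------------------------------------------------------------------------
hormone      BL vs FU permutation p   (100000 iterations, two-sided)
ghrelin                      0.5192
leptin                       0.8857
glp1                         0.1983
pp                           0.5773
glucose_mmol_l               0.1236
hba1c_pct                    0.6597
activity_h_week              0.9748
diet_index                   0.4489
```

Reading it: with only 17 participants the ICC for a strongly skewed hormone
is noisy on the raw pg/mL scale — ghrelin's latent reliability (0.99 in this
simulation) still shows as excellent, while PP's heavy right tail drags its
raw-scale estimate down. No hormone or covariate differs significantly
between assessments (all permutation p > 0.05). `results.frame()` gives the
same numbers as a DataFrame and `results.forest_frame()` exports
`label,estimate,ci_low,ci_high,panel` rows for a forest plot.

The same analysis is scriptable from a shell:

```bash
ghrelkit simulate --config sim.json --out cohort.csv
ghrelkit analyze  --config analysis.json --in cohort.csv --out report.json
ghrelkit report   --in report.json --format forest-csv
ghrelkit icc      --in cohort.csv --hormone ghrelin --adjust
ghrelkit permtest --in cohort.csv --variable leptin --seed 1
```

Cohort CSVs are long format
(`participant_id,assessment,hormone,value_pgml,glucose_mmol_l,hba1c_pct,activity_h_week,diet_index,weight_kg`),
with `BDL` accepted as a below-detection sentinel. Subgroup re-analyses
(excluding participants; splitting by between-assessment weight change) are
config options of `ghrelkit analyze`.

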