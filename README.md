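# parenclitic

Parenclitic network mapping for critically ill cohorts: population
correlation network maps from routine laboratory panels, per-patient
deviations from orthogonal-regression reference lines, and a survival
evaluation battery, with a synthetic cohort generator that plants known
ground truth.

## The problem

In sepsis, organ systems fail together, not independently. Severity scores
such as SOFA sum per-organ dysfunction and ignore the *coupling* between
systems, yet there is growing evidence that the loss or rearrangement of
physiological coupling carries prognostic information of its own. This
package implements a network-physiology workflow over 15 routine laboratory
variables (phosphate, arterial pH, urea, hemoglobin, lactate, WBC, sodium,
INR, platelets, bilirubin, glucose, creatinine, ALT, bicarbonate,
potassium), each a proxy for one or more organ systems:

1. **Population correlation maps.** Within an outcome group, every variable
   pair gets a Pearson correlation on pairwise-complete cases; the pair is
   an edge when its two-sided p-value clears the Bonferroni gate
   `alpha / C(15,2) = 0.05 / 105 ≈ 0.000476`.
2. **Parenclitic deviations (PD).** For each significant pair, a total
   least squares (orthogonal regression) line is fit on the *reference
   population* — survivors for the 30-day outcome, non-deteriorated
   patients for the 48-h outcome. The TLS line through the centroid
   `(x̄, ȳ)` along the principal axis of the 2×2 covariance minimizes
   summed squared perpendicular distances and is symmetric in the two
   variables. A patient's PD on that pair is the orthogonal distance from
   their point to the line — how far they sit from the reference coupling,
   in raw variable units.
3. **Evaluation.** Per edge: Mann–Whitney U comparison between outcome
   groups with effect size `r = |Z| / √N`; a multivariate Cox
   proportional-hazards model on the z-normalized PD adjusted for the two
   raw variables, SOFA and ventilation (optionally age, sex, ethnicity,
   Elixhauser); ROC analysis whose empirical AUC satisfies
   `AUC = U / (n0·n1)` exactly, with DeLong confidence intervals and the
   Youden cut-off `argmax(sensitivity + specificity − 1)`; and Kaplan–Meier
   curves with a log-rank test between patients beyond vs below the
   cut-off.

Because the clinical data such studies use sit behind credentialed access,
the package ships a first-class synthetic cohort generator: two latent
outcome groups with group-specific correlation matrices and mean shifts
over the 15 labs, MCAR missingness, and exponential 30-day survival whose
hazard is `λ0·exp(β·z)` in the standardized deviation `z` from a planted
pH–bicarbonate axis. Every stage of the pipeline is tested against this
planted truth.

## Worked example

```python
import parenclitic as pc

cfg = pc.default_config(seed=11)        # 162 patients, ~20% 30-day mortality
cohort, truth = pc.generate_cohort(cfg)

edge = ("arterial_ph", "bicarbonate")
pdm = pc.compute_pd_matrix(cohort, "survived30", [edge])
col = pdm.column(*edge)
event = cohort.df.set_index("patient_id")["event30"]
gc = pc.mann_whitney(col[event == 0], col[event == 1])
print(gc.U, round(gc.effect_r, 3), gc.p)
```

This fits the survivor acid–base reference line (71 survivors with both
values observed) and prints

```
1315.0 0.324 0.0014066...
```

meaning non-survivors sit farther from the survivor pH–bicarbonate coupling
(mean PD 0.161 vs 0.041 pH-scale units), a moderate effect (r = 0.324)
that is highly unlikely under the null. Scaling the same cohort to 1000
patients and running the full chain (`examples/04_survival_analysis.py`)
gives a Cox hazard ratio of 1.73 per SD of deviation (95% CI 1.51–1.98)
against a planted truth of exp(0.733) = 2.08, AUC 0.674, and a 30-day
survival split of 55.3% vs 87.4% across the Youden cut-off.

The `examples/` directory has one short narrative script per capability:
cohort simulation, network mapping, deviation computation, and the survival
battery. The same stages are exposed as a thin CLI:

```bash
parenclitic simulate --out cohort.csv --truth truth.json --seed 17
parenclitic netmap --cohort cohort.csv --group survived30 --out-prefix net_s
parenclitic netmap --cohort cohort.csv --group died30 --out-prefix net_d
parenclitic pd --cohort cohort.csv --reference survived30 \
    --edges net_s_edges.csv --edges net_d_edges.csv --out pd.csv
parenclitic analyze --cohort cohort.csv --pd-matrix pd.csv --out-dir analysis
parenclitic report --analysis-dir analysis --out summary.md
```

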