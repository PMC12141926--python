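# Methods

## Model and procedure

The pipeline treats 15 routine laboratory variables as proxies for organ
systems and asks two questions: (i) which pairs of variables are coupled
within an outcome group, and (ii) how far an individual patient departs
from the coupling observed in the reference group.

**Correlation stage.** For each of the C(15,2) = 105 unordered pairs,
Pearson's r is computed on pairwise-complete cases ("pair matching"): a
patient is dropped from a pair exactly when either variable is missing.
The two-sided p-value comes from `t = r·√((n−2)/(1−r²))` on n−2 degrees of
freedom (parametric; a Spearman option exists but is off by default). An
edge is significant when `p ≤ alpha / 105` — inclusive comparison, so the
gate at alpha = 0.05 is 0.000476190…. Pairs with fewer than 3 complete
cases or zero variance are recorded as non-significant with a logged
reason; edges evaluated on fewer than 10 pairs carry a `low_n` flag in the
export. |r| = 1 returns p = 0 (the boundary of the t convention).

**Deviation stage.** For each edge, the reference line is the first
principal axis of the 2×2 covariance of the reference population's complete
pairs, through their centroid. This is the total-least-squares line: it
minimizes summed squared *orthogonal* distances, treats both variables as
noisy, is symmetric under swapping the axes, and remains well defined for
vertical lines where slope/intercept form degenerates (slope/intercept are
derived outputs, reported only when the direction has a nonzero
x-component). The parenclitic deviation is the unsigned point-to-line
distance; the signed normal offset is kept as a diagnostic. Variables enter
in raw units with no standardization — deviations on a pH-scale pair are
naturally ~0.05 while deviations on a cell-count pair are ~3–5, and the
downstream z-transformation absorbs the scale before modelling. Reference
members are scored against a line whose fit includes themselves; a
leave-one-out mode exists for sensitivity analysis but is off by default,
since the reference regression is defined once per population. Degenerate
fits (isotropic clouds, eigengap below 1e-12 relative) raise rather than
return an arbitrary axis.

**Evaluation stage.** Group comparisons use the Mann–Whitney U oriented so
`U/(n0·n1)` is the probability a comparison-group (poor-outcome) value
exceeds a reference-group value. Z uses the tie-corrected normal
approximation with *no* continuity correction; the effect size is
`r = |Z|/√N`. This convention reproduces published effect-size cells
recomputed from printed (U, n0, n1) triples and makes the ROC identity
`AUC = U/(n0·n1)` hold exactly (the AUC is computed from the same rank-sum
expression, not by averaging placements). Cox models maximize the partial
likelihood with Efron tie handling (lifelines); Breslow is deliberately not
offered — deviations are continuous so ties are measure-zero, and Efron is
the less-biased default. The standard covariate set per edge is {PD(z),
raw var_x, raw var_y, SOFA, ventilation}; the extended set adds age, male
sex, Elixhauser index and ethnicity indicator contrasts against White.
Complete-case analysis throughout, with dropped-row counts logged and
reported. The z-transformation of a PD column uses mean/SD over *all*
patients with that PD available, not only the reference, so hazard ratios
read "per SD of deviation in the analyzed cohort". ROC confidence
intervals use the DeLong placement-value variance; the DeLong two-sample
test runs paired on the complete-case intersection (≥ 10 patients) and
falls back to an unpaired variance sum otherwise, with the mode logged.
The Youden cut-off maximizes sensitivity + specificity − 1 over observed
scores with the rule "score ≥ cut-off → predicted poor outcome"; ties at
the maximum take the lowest cut-off (the more sensitive choice).
Kaplan–Meier curves and the 1-df log-rank test compare predicted classes;
survival at day 30 is reported per arm. No multiplicity correction is
applied across edges beyond the network-stage Bonferroni gate, mirroring
the workflow's design; readers wanting Holm-adjusted Cox p-values can
apply it to the reported per-edge p-values downstream.

## Cohort conventions

Administrative censoring at the 30-day horizon: `time_days = 30` with
`event30 = 0`; deaths carry `event30 = 1` and `time_days ≤ 30`. Quartiles
in group summaries use linear interpolation between order statistics
(numpy's default, "type 7") — worth stating because published tables
rarely name a rule. Missing covariates are never imputed; each model drops
its incomplete rows and logs the count, consistent with the pairwise
deletion used upstream. Group-summary categorical tests are chi-squared
without continuity correction.

## The synthetic generator

The generator emulates the *statistical structure* the analysis assumes,
not any real database. Defaults: 162 patients; latent non-survivor
fraction 33/162; deterioration fraction 30/162. Labs are multivariate
normal per latent group on raw scales (survivor pH ~ N(7.39, 0.052²)),
with medians and IQR-derived SDs oriented so the poor-outcome group runs
higher in lactate, urea, creatinine, phosphate, WBC, glucose, INR and
lower in pH and bicarbonate. Values are truncated at the registry's
plausibility bounds rather than log-transformed, preserving the linear
correlation structure the Pearson stage assumes. Group correlation
matrices plant edges at |r| 0.5–0.8: survivors couple pH~bicarbonate
(0.75), urea~creatinine (0.75), WBC~platelets (0.55), INR~ALT (0.55);
non-survivors couple lactate~pH (−0.65), lactate~bicarbonate (−0.60),
WBC~phosphate (0.65), urea~creatinine (0.80), with the shared
urea~creatinine edge by construction. The non-survivor lactate block is
kept weaker than its survivor analogue so the matrix stays positive
definite; any template that is not PD is repaired by eigenvalue clipping
and renormalization.

Missingness is MCAR per variable (pH 0.42, lactate 0.30, ALT 0.12, INR and
bilirubin 0.10, phosphate 0.07, the rest ≤ 0.02), calibrated so the
pH–bicarbonate pair is jointly observed in ~57% of patients. Independent
MCAR cannot reproduce every published pairwise N simultaneously (blood-gas
analytes are missing *together* in real data), so these rates are
documented estimates; a group-dependent multiplier exists as a MAR hook,
off by default.

Survival: the planted axis is the principal axis of the survivor-group
(pH, bicarbonate) covariance, known in closed form from the config. Each
patient's true deviation is their orthogonal distance from that axis (true,
pre-missingness values); the signed offset per group is Gaussian, so the
deviation is folded-normal and the population mean/SD of the mixture are
exact. Event times are exponential with rate `λ0·exp(β·z)` where z is the
population-standardized deviation, censored at 30 days; β defaults to
0.733 (HR ≈ 2.08 per SD). λ0 and the deterioration-model intercept are
calibrated deterministically by quadrature over the folded-normal mixture
so expected event fractions match the configured ones — no sampling is
involved in calibration, so `default_config()` is pure. A Weibull shape
parameter generalizes the baseline hazard (1.0 = exponential default,
closed-form truth). The latent group drives the lab distribution while the
realized 30-day event comes from the hazard, so observed-outcome groups
are a noisy readout of the latent ones — deliberately, as in real cohorts.

What passing tests on this generator do *not* show: robustness to
non-Gaussian marginals (real labs are skewed), to informative missingness,
to nonlinear coupling, or to time-varying physiology. The generator makes
the pipeline's assumptions true; it validates correctness of the
machinery, not the clinical model.

## Numerical choices

- Pairwise-deletion correlations for all 105 pairs are computed by a
  single vectorized masked-sums routine; the scalar path is kept and
  tested equal to 1e-12.
- TLS uses `eigh` of the 2×2 covariance; direction sign is normalized
  (positive x-component) for deterministic output.
- Cohort CSVs render floats with shortest round-trip `repr` and parse with
  Python's `float`, because pandas' fast CSV float path is not correctly
  rounded and would break bit-exact write→read→write fixed points.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; reports contain no timestamps, so identical
  (config, seed) yields byte-identical outputs.
- Problem sizes in the heavier checks — 50 replicates at n = 1000 for
  hazard recovery, 2000 replicates for the null-calibration rates — were
  chosen to pin Monte-Carlo error well below the tolerances being
  asserted while keeping a full run in the low minutes on one CPU.

## Known limitations

- Efron is the only tie-handling rule for Cox models; software that uses
  Breslow will differ slightly on heavily tied data.
- The exact Mann–Whitney p-value is available only for small samples via
  an option; the default asymptotic p is what the effect-size convention
  assumes.
- The generator's deterioration flag is a logistic label in the planted
  deviation, not a mechanistic severity trajectory.
- Network maps stop at edge sets; graph-theoretic summaries (centrality,
  clustering) are out of scope.
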