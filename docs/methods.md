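# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Atlas and edge bookkeeping

The full atlas has 379 regions: 180 cortical parcels per hemisphere, nine
subcortical structures per hemisphere and the brainstem. FC between R
regions is a symmetric correlation matrix; the R² ordered entries
(143,641 at R = 379) are redundant — the diagonal is identically 1 and
corr(i,j) = corr(j,i) — so all computation uses the R(R−1)/2 = 71,631
unique off-diagonal edges, indexed row-major as produced by
`numpy.triu_indices(R, 1)`. Counting over unique edges halves what an
ordered-pair representation would report for cross-network tallies; any
comparison with ordered-pair bookkeeping should double cross-network
counts.

Each region carries exactly one of nine named large-scale network labels
(Accessory Language, DMN, CEN, DAN, Language, Limbic/Paralimbic, SN, SMN,
VN) or OTHER (by default the subcortex and brainstem). Network names are
treated as opaque strings throughout. An edge belongs to the set of its
endpoint networks: a cross-network edge contributes once to *each* of the
two networks (default), or only within-network edges can be counted
(`mode="within_only"`). The both-endpoints rule is the simplest reading of
"anomalies within each network" and is symmetric; it does mean network
counts are not additive across networks.

The bundled 379-region parcellation assigns the nine networks to cortical
parcels in deterministic blocks of 20 per hemisphere. It is a synthetic
stand-in for an anatomical lookup: sufficient for every aggregation the
package performs, carrying no anatomical meaning.

## Normative MAD band

Per edge, the control cohort gives median m_e and the **raw** MAD (median
of absolute deviations from m_e, no 1.4826 consistency constant). An edge
is anomalous when |x − m_e| ≥ t·MAD_e with t = 3 ("3 or more": the
boundary is inclusive). Two deliberate conventions:

* **Raw MAD.** With Gaussian edge noise the population band is
  3·Φ⁻¹(0.75) ≈ 2.02 σ, whose two-sided tail is 4.3 %; finite-sample MAD
  estimation (n = 42 controls) inflates the realised per-edge flag rate to
  ≈ 5–8 %. This is an intentionally permissive detector — a *descriptive*
  anomaly census, not a 1 %-level test. Callers who want σ-equivalent
  units can pass `consistency_scale=1.4826` to `fit_normative` (3·MAD then
  ≈ 3 σ, tail 0.27 %). The held-out-control calibration test pins the raw
  band's realised rate; the acceptance suite also records that the raw
  band does not meet a 1 % false-positive criterion — by construction, not
  by defect.
* **Zero-MAD edges.** Where the control MAD is ≤ τ (default 10⁻⁶) the band
  degenerates; the edge is flagged only when the deviation itself exceeds
  τ. Exact agreement with a degenerate control distribution is not an
  anomaly; any real departure from it is.

The model is fit on **all** controls (no held-out split), and follow-up
scans are scored against the same baseline model, since controls are
scanned once.

Group summaries report, per network: mean counts by response group and
timepoint; mean **absolute** change |fu − base| by response group (change
magnitude regardless of direction); and mean **signed** change by
treatment arm. Both readings are emitted because "change" is ambiguous
between them.

## Response labelling

* **ISI** (0–28): interpretive categories 0–7 none, 8–14 subthreshold,
  15–21 moderate, 22–28 severe (standard instrument bands, configurable).
  Response = follow-up category strictly less severe than baseline;
  within-category shifts and worsening are non-response.
* **PSQI** (0–21): Jacobson–Truax reliable change,
  RCI = (base − fu)/S_diff, S_diff = s₁·√(2(1−r)). Response = RCI ≥ 1.96
  in the improvement direction (PSQI decreases as sleep improves).
  Defaults: r = 0.85, a commonly reported PSQI test–retest reliability;
  s₁ = the treated cohort's baseline SD (ddof = 1). Both are configurable
  (`RciParameters`), and the realised S_diff is echoed in every output,
  because published RCI analyses rarely state their constants and results
  can be sensitive to them.

Aggregates (improved on either/both instruments, improvement per arm per
instrument) feed the Fisher contingency analyses directly.

## Classification and network importance

Features: the unique-edge FC vector plus age, sex (0 = female),
AUDIT, FTND. Constant covariates are retained — tree models ignore them
harmlessly, and their attribution is exactly zero. Rows are ordered by
subject id so the table is invariant to phenotype file order.

Model: `xgboost.XGBClassifier` (hist, depth 3, η = 0.1, 100 rounds,
single thread), stratified 5-fold CV with shuffling, seeded; score = mean
held-out AUC-ROC. An optional inner 3-fold random search over a small
declared grid (depth ∈ {2,3,4}, η ∈ {0.05,0.1,0.3}, rounds ∈ {50,100,200})
is off by default: with ~93 subjects an outer evaluation of a tuned model
is noisy and slower, and the fixed values are adequate for the planted
signals the generator produces.

Attributions are TreeSHAP contributions computed natively by XGBoost
(`pred_contribs=True`) **on the held-out subjects of each fold**, pooled
across folds — held-out attribution avoids the optimism of explaining
training fit. Additivity (contributions + bias = margin) is asserted in
tests. Feature importance = mean |attribution|; the top-k report adds the
correlation between feature value and attribution (the red/blue direction
of a beeswarm plot). Network importance = mean importance over the edge
features touching each network (both-endpoints attribution, covariates
excluded); `mode="sum"` gives a size-weighted variant.

## Cohort statistics

* **Fisher's exact** (two-sided): sum of hypergeometric probabilities of
  all same-margin tables with probability ≤ that of the observed table
  ("point-probability" convention, as in R and scipy), accumulated in
  exact rational arithmetic (`fractions.Fraction` over integer binomials),
  so probability ties are compared exactly and no floating-point tolerance
  is needed. On the study's printed improvement tables this gives
  p = 0.640 (10/12 vs 8/12) and p = 1 (9/12 vs 8/12).
* **Mann–Whitney U**: U_A by the rank formula (ties count ½); reported
  statistic min(U_A, U_B); p-value exact for tie-free samples with
  n_A·n_B ≤ 400, otherwise tie-corrected normal approximation (scipy).
* **χ² of independence**: Pearson, no continuity correction by default
  (Yates available), 1 d.f.

No multiple-testing correction is applied anywhere.

## Synthetic cohort generator

Defaults encode the emulated study: 42 controls, 51 patients, 24 treated
(12 drug, 12 drug+rTMS, alternating assignment).

* **Edges.** Per-edge control mean μ_e ~ U(−0.2, 0.6) drawn once; subject
  values are μ_e + N(0, σ) with σ = 0.1, clipped to [−1, 1]; matrices are
  exactly symmetric with unit diagonal. Values are sampled directly rather
  than derived from simulated time series: the analysis consumes only
  correlations, and direct sampling gives exact control of anomaly
  placement (clipping, rather than Fisher-z simulation, keeps the range
  valid at the cost of slight edge-of-range distortion).
* **Anomalies.** Each patient receives Poisson-many displaced edges (mean
  40 for latent responders, 10 for non-responders), sampled without
  replacement, 80 % of draws from edges touching the target networks
  (default {DMN, CEN, SMN}); each displaced edge moves ±5 σ (sign random).
  Untreated patients draw the same latent high/low severity mixture
  (P(high) = 0.7) so the patient/control contrast spans the whole cohort.
  `signal_edge_pool=k` restricts all patients' anomalies to one fixed pool
  of k edges — the configuration that makes patients machine-separable,
  since independent per-patient edges share no features for a tree to
  split on.
* **Follow-up.** Treated responders keep (1 − 0.8) of their displacement
  (80 % normalization); non-responders keep all of it; fresh noise either
  way.
* **Scores.** Baselines centre on the emulated cohort medians (patients
  ISI 15 / PSQI 16; controls 0 / 3). Follow-ups are *constructed against
  the scoring rules*: true responders drop past the ISI category boundary
  and past the integer PSQI drop that clears RCI ≥ 1.96 under the same
  S_diff the scoring module will compute; non-responders stay within
  category and below the reliable-change drop. A discordance parameter
  (default 0.2) makes that fraction of responders respond on one
  instrument only. Demographics are non-informative by design (AUDIT/FTND
  ~ 0, similar age/sex across groups) so classifier signal comes from FC.
* **Reproducibility.** One seed; per-stage `SeedSequence` substreams so
  adding draws in one stage cannot perturb another.

What the generator does **not** emulate: BOLD time series, motion and
physiological artefacts, spatial autocorrelation between edges, site or
scanner effects, realistic inter-edge covariance, the rTMS mechanism, or
any true effect sizes (none are published for this design — displacement
and rate defaults were chosen for testability). Passing recovery tests
therefore demonstrates the *pipeline's* correctness and calibration under
its stated assumptions, not expected performance on real MRI data; in
particular the near-perfect separable-configuration AUC is a property of
the planted signal, not a claim about clinical classification.

## Problem sizes and runtime

Unit and property tests run at 3–50 regions; cohort-level tests at 40
regions (780 edges), where one full pipeline run takes ~2 s. The
acceptance script additionally performs one full-scale 379-region run
(71,631 edge features; a few minutes single-threaded) plus the test-scale
recovery and permutation analyses. At full scale the raw-MAD band's
~6 % false-positive floor (~4,700 of 71,631 edges) dominates per-network
counts, so the injected 30-edge responder/non-responder difference is
visible in group means only at test scale where it is large relative to
the floor.

## Known limitations

* The raw-MAD band's false-positive floor makes absolute anomaly counts
  scale with edge count; compare counts only within a fixed atlas.
* Independent Gaussian edges understate the variance of network-level
  count statistics relative to real FC (positively dependent edges).
* The RCI constants (r, s₁ source) materially affect PSQI response labels
  and are not identifiable from the analysis outputs alone; they are
  always echoed in results.
* With ~24 treated subjects, arm-level contingency analyses are
  descriptive; the package deliberately reports exact p-values without
  any power claim.
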