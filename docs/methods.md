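# Methods

`metmodnet` re-implements, as a tested library, a serum-metabolome
analysis workflow for small, deeply phenotyped exercise cohorts: quality
control of untargeted metabolomics ion counts, weighted correlation
network module detection at two timepoints with consensus refinement,
module–trait and module–group association, a two-tier exercise-response
differential analysis, and the design's ANOVA power bound. This note
describes the models, the defaults and why they hold those values, the
synthetic cohort the tests run on, and the numerical choices that were
genuinely open.

## Study design assumed by the pipeline

Four groups of male subjects — endurance athletes (n = 11), natural
bodybuilders (n = 9), sprinters (n = 8) and untrained controls (n = 7) —
each sampled at rest (baseline) and immediately after a maximal cycling
test (post), giving 70 experimental serum samples measured in two
96-well batches. Each batch carries four aliquots of a commercial
reference serum (technical replicates) and one reference plasma well.
Untargeted profiling yields relative ion counts for 1020 metabolites;
22 health- and exercise-related traits are recorded per subject.

## Quality control

Stages run in fixed order; every exclusion is logged in a `QCReport`.

1. **Sample missingness outlier check.** A sample is flagged when its
   missing fraction exceeds the mean across samples plus 5 SD (n−1
   denominator). Five SDs is deliberately permissive: it removes only
   failed wells, not biological extremes.
2. **Batch-median normalization.** Each value is divided by the
   per-(metabolite, batch) median of the reference-serum aliquots, so
   normalized reference aliquots have median exactly 1 per batch and the
   operation is idempotent. A metabolite/batch with no usable reference
   value stays unscaled and is flagged.
3. **CV filter (25%).** Percent CV (100·sd/mean, n−1) over the
   normalized reference-serum aliquots pooled across both batches
   (n = 8). Pooling is the default because per-batch medians are all 1
   after normalization, which makes pooled CV a conservative, well-defined
   precision measure; a per-batch-maximum switch exists. Metabolites with
   CV > 25% — or with an undefined CV — are removed.
4. **Missingness filter (30%, strict).** Missing fraction is computed
   over the 70 experimental samples only; a metabolite at exactly 30% is
   retained.
5. **log2 transform.** Zero or negative values are a hard error naming
   the cell; no silent pseudocount.
6. **kNN imputation (k = 10).** Metabolites are the neighbours. Distance
   between metabolites is the Euclidean distance over jointly observed
   samples, rescaled by √(n_samples / n_overlap) (the nan-Euclidean
   convention). Donors for a missing cell must themselves be observed in
   that sample; fewer than k donors means use all of them, none means
   fall back to the metabolite's observed mean. Ties break by row order,
   so the imputer is fully deterministic.
7. **IQR outlier-point removal (±3·IQR).** Per metabolite, median and
   IQR (linear-interpolation quantiles) over all 70 experimental values;
   points strictly outside median ± 3·IQR are flagged, and both
   timepoint values of the affected subject are blanked — this protects
   the paired analysis from half-removed pairs, and makes the number of
   blanked cells even per (metabolite, subject). When IQR = 0 the bounds
   collapse onto the common value and only values different from it are
   flagged.
8. **Re-imputation** with the same kNN settings.

Whether the IQR statistics should be computed before or after the first
imputation is not decidable from the procedure itself; the default is
after (`iqr_on_unimputed=False`), matching the narrative order, with a
switch.

## Network construction and module detection

The unsigned weighted correlation network on the QC'd baseline (and,
separately, post) matrix uses adjacency a_ij = |cor(x_i, x_j)|^β with
Pearson correlation and soft power β = 6 — the conventional default at
which the unsigned network approximates scale-free topology; a
diagnostic scan (`soft_power_scan`) is provided but β stays fixed for
replication runs. The topological overlap similarity

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with connectivity k_i = Σ_{u≠i} a_iu smooths the adjacency by shared
neighbourhoods; 1 − TOM is the clustering dissimilarity.

Modules come from average-linkage hierarchical clustering of 1 − TOM
followed by a dynamic branch cut with these rules:

- a static cut at 99% of the dendrogram height range isolates candidate
  branches (noise features join near the top and fall out here);
- each candidate subtree is split recursively wherever both child
  branches hold at least `min_module_size` (30) leaves and the merge sits
  a minimum normalized height gap above both children. The gap ladder
  maps `deep_split` 0–4 to {0.27, 0.2025, 0.135, 0.0675, 0.0375}
  (deep_split = 2 default), i.e. (1 − maxCoreScatter)·3/4 for the
  conventional core-scatter ladder;
- branches below the minimum size dissolve; unassigned metabolites get
  the "grey" label; no PAM-like reassignment stage by default.

The reference dynamic hybrid procedure carries many additional
micro-heuristics; module quality here is validated by planted-partition
recovery (adjusted Rand index against ground truth), not by label-level
identity with any particular implementation. Labels are the conventional
size-ordered colour sequence (turquoise, blue, brown, yellow, green, …),
so module names are reproducible across runs.

Modules whose eigenmetabolites correlate at ≥ 1 − merge_height
(default 0.25) merge iteratively until stable.

**Eigenmetabolite.** Each metabolite is z-scored across subjects; the
module's PC1 score per subject (via SVD) is the eigenmetabolite. Scores
have exactly mean 0 (z-scored rows sum to zero, so the unit vector is in
the null space) and are sign-oriented to correlate positively with the
module's mean z-score, which keeps effect directions interpretable.

## Consensus modules

Baseline and post assignments are matched one-to-one by maximal set
overlap (greedy descent on intersection size; ties broken by larger
Jaccard, then label order; an exhaustive-assignment switch exists for
≤ 8×8 problems and agrees with greedy on all cases tested). A consensus
module is the intersection of a matched pair's memberships; consensus
grey is grey∩grey. Metabolites assigned differently at the two
timepoints are dropped from module-level analyses (they remain in all
per-metabolite tests); a switch can push them to grey instead.

## Association testing

Two module representatives per subject are computed at baseline: the
eigenmetabolite and the mean metabolite z-score. Eigenmetabolites drive
p-values; z-score betas drive effect-direction reporting, since the mean
z-score has an unambiguous sign in the original abundance space.

- **Module–trait:** linear model trait ~ representative with both
  variables z-scored, so the simple-model slope equals the Pearson
  correlation and lies in [−1, 1]. Group adjustment adds three athlete
  group indicators (control reference). Subjects missing a trait drop
  pairwise. BH-FDR is applied across the modules × traits family.
- **Module–group:** one-way fixed-effects ANOVA of the representative on
  group, Bonferroni threshold 0.05/n_modules, followed by Tukey-Kramer
  post-hoc contrasts. Because the groups are unequal (11/9/8/7) the
  Kramer standard error √(MSE/2·(1/n_i + 1/n_j)) is used with the
  studentized range distribution on (k, N − k) degrees of freedom. The
  studentized-range tail is scipy's double quadrature (≈1e−6 absolute
  accuracy), amortized through a per-(k, df) cubic spline of the log
  tail whose interpolation error is ≈3e−7 (verified against the direct
  quadrature in the tests).
- **Per-metabolite group ANOVA** with both Bonferroni (α/m) and BH-FDR
  columns across the metabolite family, plus Tukey-Kramer pairs.

## Exercise response

Per-subject log2 fold change is post − baseline on the log2 scale.
Cells blanked by the IQR rule exclude that (metabolite, subject) pair
listwise; the pair count per test is reported.

- **Two-tier rule.** Tier 1: two-sided paired t over all subjects with
  p below α/m, where m is the retained metabolite count — the exact
  quotient (0.05/857 = 5.834e−05 under the study design), not a rounded
  value. Tier 2: tier 1 and p < 0.05 within every group with a testable
  stratum (≥ 2 complete pairs). All-zero differences give t = 0, p = 1
  by convention. With alpha_group = 1 tier 2 collapses onto tier 1.
- **Group-specific response.** One-way ANOVA of fold change on group per
  metabolite ("differential" at p < 0.05, BH-FDR column across
  metabolites), with Tukey-Kramer pairwise contrasts by default and an
  unadjusted-Welch switch, since nominal pairwise testing is also a
  defensible reading; both are emitted.
  "Differential-and-changed" additionally requires a nominal paired
  change in ≥ 1 group.

## Power

Balanced one-way ANOVA: noncentrality λ = f²·k·n, power =
P(F′(k−1, k(n−1), λ) > F_crit(1−α)); minimum detectable f by bracketed
Brent root-finding at 1e−6 tolerance. The unequal-n variant uses
λ = f²·N with error df N − k. The replication preset is the study
design itself — sizes 11/9/8/7, α = 0.05/6 (Bonferroni across six
modules), power 0.80 — giving a minimum detectable Cohen's f of 0.743.
The equal-n variant with n = 7 (smallest group) is the conservative
alternative and yields 0.856. Both routes round-trip against the power
function to 1e−5 and agree with Monte-Carlo ANOVA simulation (10⁵
replicates) within 0.01.

## The synthetic cohort

`simulate_cohort` generates the full design on the log2 scale from a
single-factor-per-module latent model: metabolite i in module m has

    x_ist = baseline_i + loading_i · f_ms(t) + response + batch + tech + ε

with subject-level factors f ~ N(shift(group, m), 1), loadings uniform
in [0.5, 1] with ≤ 20% sign flips (to exercise the unsigned network),
and residual SD solved from the target mean within-module correlation
(0.6 by default). The single-factor form is deliberate: it is exactly
the structure eigenmetabolite extraction assumes, so recovery tests
measure the pipeline, not model mismatch. The post-exercise factor is
correlated 0.9 with baseline so modules reproduce across timepoints.
Defaults plant:

- five modules of sizes 180/120/90/60/45 (all ≥ the min module size);
- group–module factor shifts of ±1.5 SD (endurance on module 1,
  bodybuilding and sprint on modules 2–3);
- 60 metabolites with a shared exercise response of |Δlog2| in [1, 2.5]
  and 20 with an extra 1.5-log2 response in one group;
- traits: the first two traits per module track that module's baseline
  factor with unit coefficient and unit noise; the rest are pure noise;
- per-(batch, metabolite) multiplicative effects (log2 SD 0.1),
  technical well noise (log2 SD 0.05), and 69 metabolites with inflated
  technical noise (log2 SD 1.5) planted to fail the 25% CV filter;
- abundance-dependent (MNAR) missingness: each experimental cell is
  blanked with probability logistic in 1 − its abundance quantile, with
  the intercept solved so the mean rate is 4% (an MCAR switch exists for
  null designs); 94 metabolites additionally get exactly 32 of 70 wells
  blanked, planting guaranteed failures of the 30% missingness filter;
- ~1% outlier cells multiplied by 2⁸.

Reference aliquots share the metabolite-wise population mean plus batch
effect and technical noise, which makes batch-median normalization
identifiable by construction. With these defaults the QC chain retains
1020 − 69 − 94 = 857 metabolites and flags ≈ 600 outlier points (~1% of
cells), i.e. the data regime the analysis settings are tuned for.

What the generator does **not** emulate: correlated missingness across
metabolites of one pathway, retention-time drift within runs,
non-Gaussian heavy-tailed abundance noise, trait–trait correlation
beyond shared module drivers, and any annotation realism beyond class
labels. Passing tests therefore demonstrate that the implementation
recovers the structure it assumes, not that the assumptions hold for
any particular real dataset.

## Problem sizes used in tests and the acceptance script

Planted-module recovery runs 50 seeds of a 650-metabolite cohort (the
five planted modules plus ~155 background metabolites, 70 samples);
the background count is a scale choice — recovery is insensitive to it,
and this size keeps the 50-seed median a few seconds of work. Type-I
calibration runs 200 null cohorts of 40 metabolites with all planted
effects at zero, checking module-group ANOVA, module-trait regression,
the overall paired test and the response ANOVA against the binomial 95%
band around α = 0.05.

## Known limitations

- A group–module factor shift of 1.5 SD corresponds to Cohen's
  f ≈ 0.6–0.65 at these group sizes, below the design's 80%-power bound
  f = 0.743; such shifts reach the module-family Bonferroni level in
  only ~60–77% of seeds (group-size dependent). The detection property
  is therefore asserted at 2.0 SD, where the rate is ≥ 90%.
- The tree cut implements the core dynamic-hybrid rules only; on data
  with nested or strongly overlapping correlation structure its labels
  can differ from implementations carrying the full micro-heuristic set,
  even when recovery metrics agree.
- `read_maf` covers the tab-separated metabolite-assignment-file layout
  with identification columns followed by per-sample abundances; exotic
  MAF dialects (multi-assay, factor-encoded columns) are out of scope.
- No mixed-effects machinery: the analysis treats subjects as the unit
  and timepoints through explicit pairing, so designs with more than two
  timepoints need a different model.
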