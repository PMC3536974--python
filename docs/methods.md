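# Methods

## Problem setting

The pipeline asks whether a flow-mediated gene-expression signature
distinguishes the ascending aorta of bicuspid-valve (BAV) from
tricuspid-valve (TAV) patients. Because the tissue mixes endothelial and
smooth-muscle messages and the clinical groups differ in comorbidities,
the design works in four filters, each with its own statistical model:
compendium-wide co-expression with known shear-responsive genes, target-
vessel co-expression, covariate-adjusted group association, and a paired
cross-species flow-region comparison.

## Stage 1 — expression screening

**Model.** For each dataset, a gene's co-expression with the query set is
summarized by its Pearson correlation `c` with the composite query
signature (per-sample mean of z-scored query profiles), transformed to
Fisher z = atanh(c). Two Gaussians are fitted on the z scale:

- *null*: mean/sd of all genes' z in that dataset (the ambient
  correlation level, including any signature-wide bias);
- *positive*: mean/sd of the leave-one-out query z values — each query
  correlated against the signature of the remaining queries. With fewer
  than three usable queries the positive mean falls back to
  `null mean + 2·null sd`.

The gene's evidence is the log-density ratio of these two Gaussians at its
z. Evidence is integrated across datasets by weighted naive Bayes
`logit p = logit(prior) + Σ_d w_d·llr_gd` with prior 0.1 and
informativeness weights `w_d` (clipped mean pairwise query correlation;
datasets with `w_d < 0.05` are skipped, as are datasets where fewer than
two queries are measured). Selection is strict: `p > 0.5`.

**Assumptions.** Fisher z of correlations is roughly Gaussian within a
dataset; datasets are treated as independent lines of evidence (naive
Bayes); co-expression with a *composite* signature is an adequate summary
(per-query correlation is available via `corr_filter` but stage 1 uses the
composite).

**Numerical choices.**
- The positive-model sd is floored at the null sd. Five leave-one-out
  points can fit an arbitrarily tight Gaussian, under which a gene *more*
  correlated than the queries themselves would be scored as evidence
  *against* co-expression; the floor makes the LLR non-decreasing in z
  beyond the crossover, which is the intended shape.
- Query genes are scored like any other gene (their own posterior is
  reported, and the planted-module recovery check counts them), but they
  never enter the `selected` list — they are anchors, not discoveries.
  Their correlation with a signature containing themselves is inflated;
  with the sd floor this only ranks them at the top, where they belong.
- Fisher z is capped at atanh(1−1e−12) to keep perfect correlations
  finite. Missing values are handled pairwise-complete; correlations over
  fewer than 3 shared samples, or involving a constant profile, are
  undefined and carry no evidence.
- `robustness_overlap` removes the union of both runs' query genes from
  both selected lists before computing containment/Jaccard: each run
  excludes its own anchors from `selected`, so the raw lists are
  asymmetric by construction.

## Stages 2–3 — target-vessel filter and adjusted association

The correlation filter takes the best per-query Pearson correlation and
compares its magnitude to the cutoff (strict `|R| > 0.40` by default).
Magnitude, not sign, is used because the flow program includes
anti-correlated partners (e.g. PKD2 vs KLF2); a config flag restores
signed filtering.

The association model is per-gene OLS of log2 expression on
`[1, BAV, dilation, stenosis, regurgitation]`, all indicators. The p-value
is the two-sided t test of the BAV coefficient β; the fold change is
`2^β` (β ≥ 0) or `−2^(−β)` (β < 0), so `|fc| ≥ 1` and negative means
lower in BAV. Covariate columns that are constant in the (casewise
complete) sample set carry no information and are dropped from the design;
with all covariates absent the fit reduces exactly to a pooled-variance
two-sample t test, which the tests verify in closed form. A design in
which cuspidity is collinear with a covariate yields per-gene error
records rather than an exception. BH-FDR uses the standard step-up
(statsmodels' `fdr_bh` behind the package's `bh_select` surface); the
"realized threshold" reported is the largest rejected p-value.

The Pearson p-value helper uses the exact t transform
`t = r·sqrt((n−2)/(1−r²))` with n−2 df. The correspondences a reader
might try to reproduce from the original study's prose
(P < 0.0137 ↔ R = 0.143, Bonferroni P < 6.01e−05 ↔ R = 0.404) are **not**
consistent with this transform at n = 127 (they give p ≈ 0.109 and
≈ 2.5e−06 respectively); the sample size behind those printed pairs is
unknown, and this package documents rather than reconciles the
discrepancy.

## Stage 4 — paired flow-region validation

The paired test operates on within-animal differences
`d_i = disturbed_i − uniform_i`: `t = mean(d)/(sd(d)/√n)` with n−1 df,
two-sided. ("Paired … assuming unequal variance" in the source literature
is self-contradictory — a paired test sees only differences — so the
standard paired form is the only well-defined reading.) Degenerate cases
are fixed by contract: `sd(d)=0, mean(d)=0` → p=1, fc=+1;
`sd(d)=0, mean(d)≠0` → p=0, flagged degenerate. Only complete
disturbed/uniform pairs enter; incomplete animals are reported.

Concordance is a sign match between the rat disturbed-vs-uniform and the
human BAV-vs-TAV fold changes, assessed only among rat-significant genes.
Percentages in all summaries are round-half-up to integers.

**Packaged results table.** The shipped 44-gene table stores the printed
values verbatim (p-values, signed fold changes, same-direction flags,
flow-literature annotations). Rat significance defaults to the realized
threshold p < 0.031 (strict); a BH mode re-runs step-up at q = 0.05 over
the 38 on-platform p-values and — because the step-up boundary falls
between the 21st (0.02228) and 22nd (0.03103) order statistics — selects
the same 21 genes. Rat fold changes were printed only for those 21
significant genes; for concordance accounting the stored same-direction
flag substitutes where a fold change is missing (both routes give 15).

## Synthetic data

The generators state a world and keep it fixed:

- **Compendium**: 30 datasets, 1,000 genes, 20-gene module containing both
  query sets (all nine anchors are flow-responsive genes by construction),
  20–60 samples per dataset, loading 0.85, informative fraction 0.5.
  Informative datasets follow a one-factor model `x_g = λf + ε`,
  `f ~ N(0,1)`, `Var(x)=1`, so two module genes correlate at
  `λ²/(λ²+σ²)` — a closed form the tests use as an oracle. Uninformative
  datasets are pure noise.
- **Aorta-like cohort**: 81 BAV / 46 TAV (the cohort sizes of the
  motivating study), gene-wise noise sd 0.5 around a log2 baseline of 8,
  covariates sampled independently of cuspidity at prevalences
  0.5/0.4/0.3 (a config switch makes prevalence differ by group, to test
  that adjustment rather than marginal testing drives selection). Module
  genes additionally share a latent factor (loading 0.6) so the stage-2
  correlation filter sees the co-expression that real target vessels
  show. The pipeline default cuspidity effect is −0.7 log2 (|fc| 1.62),
  inside the observed human range (±1.10–1.86); the motivating study
  reports no variance components, so these are conventions, not
  calibrations.
- **Paired rat-like cohort**: 14 animals × 2 regions, animal intercept sd
  0.5 ≫ residual sd 0.3 (pairing is what rescues power, and a test
  verifies the unpaired test fails in this regime), region effect −0.46
  log2 (|fc| 1.37, the printed ZFP36-scale effect), concordance rate
  controllable (pipeline default 0.8, near the observed 71%).

What the generators do **not** emulate: probe-level/platform noise, batch
effects, correlated comorbidities, heavy-tailed expression, many-to-many
orthology. A green test therefore establishes internal correctness and
statistical calibration of the pipeline, not performance on real arrays.

## Design choices where the method description was open

- The screening algorithm is specified in the literature only at summary
  level; the concrete forms here (composite signature, clipped-mean
  informativeness, Gaussian LLR on Fisher z, naive-Bayes integration,
  prior 0.1, weight floor 0.05) are the simplest defensible versions of
  the stated ingredients, and each is a function argument.
- The prior cannot be constrained by the published gene counts without
  the original compendium; 0.1 is a convention.
- Cross-species gene matching goes through an explicit one-to-one
  ortholog map (default: identity on uppercased symbols), since symbol
  equality is how the source analysis matched genes.
- Expression input is assumed log2; `input_scale="linear"` applies
  log2(x+1) on read.

## Limitations

- The real compendium and patient arrays are not public; cohort-level
  gene lists (122 screened, 72 correlated, the specific 44) are not
  reproducible here, only the procedures and the printed 44-gene
  accounting.
- One-factor co-expression is a deliberately simple null world; screening
  performance numbers from it are upper bounds.
- Binary covariates only; severity grades are out of scope.
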