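# Methods

`oescreen` implements a multi-stage candidate-gene discovery procedure for
bulk transcriptomics of biopsied olfactory epithelium (OE), the nasal neural
tissue used as a brain surrogate in studies of schizophrenia (SZ). The core
idea: differential expression alone produces thousands of hits at small n;
filtering those hits by their within-patient correlation with cognitive
performance yields a short list of candidates tied to the clinical feature
of interest. This note records the models, parameter choices and numerical
conventions, and what the synthetic benchmark does and does not establish.

## Pipeline model

**Stage 1 — differential expression.** Per probe, a one-way two-group ANOVA
on log2 intensities. With two groups F = t² of the pooled-variance t-test,
and the implementation computes the pooled t vectorized and reports
F(1, n₁+n₂−2) p-values (verified to 1e−12 against the F-test). P-values are
Benjamini–Hochberg adjusted over all probes; q < 0.05 defines the
significant set. Fold change is reported in signed display convention
r = 2^(Δ mean log2), returned as r if r ≥ 1 and −1/r otherwise, so negative
values mean lower expression in SZ. No probe prefiltering precedes testing.

**Score normalization.** Each of the six neuropsychological domain scores
(processing speed, attention/working memory, verbal and visual
learning/memory, ideational fluency, executive functioning) and their
composite (arithmetic mean of the six) is regressed on sex (0/1) and years
of education; the residual (actual − expected score) is standardized to a
Z-score with the sample sd (n−1). The composite is residualized and
Z-scored as its own score set, not rebuilt from domain Zs. Residuals are
invariant to the sex coding and to affine rescaling of education units
(both tested). Normalization is restricted to SZ patients because the
screen asks about cognition in the disease state.

**Stage 2 — correlation screen.** For every stage-1 probe and each of the 7
score sets, the Spearman correlation (Pearson correlation of average ranks;
exact under ties) across SZ patients, with a permutation p-value: y is
permuted, rho recomputed, and two-sided p = (1 + #{|rho*| ≥ |rho|}) /
(N + 1). At n ≤ 7 patients all n! permutations are enumerated and p is
exact (and seed-independent). Pairs with p < 0.01 are retained. Two
deliberate conventions: two-sided p (candidates of both signs are
biologically meaningful) and **no multiplicity correction across the seven
score sets** — the raw 0.01 filter is applied after an FDR-controlled first
stage, trading specificity for sensitivity in an exploratory screen. Inside
the batched screen one permutation-index matrix per score set is shared
across probes; each probe's null distribution is unaffected, only the
Monte-Carlo noise is coupled between probes. The single-pair
`permutation_corr_test` draws its own permutations.

**Enrichment.** Co-regulation networks are graphs whose edges are probe (or
gene) pairs with |Pearson r| ≥ 0.75 across samples. Over-representation of
one edge set in another, and of a gene set among significant probes, uses
the hypergeometric upper tail P(X ≥ k). The universe N is a required
explicit argument everywhere: published figures of this kind are
irreproducible when the universe is unstated, and the p-value is extremely
sensitive to it. Exact rational summation is used for N ≤ 200, scipy's
log-gamma survival function beyond. Note that at n = 15 control samples a
|r| ≥ 0.75 cutoff admits many null pairs (the null sd of r is ≈ 0.27), so
control-only networks are dense; planted pairs are still recovered because
their population |r| is 0.9.

**Cross-tissue concordance.** Stage-1 differential expression is rerun on
lymphoblast (LB) matrices — "paired" (same subjects, minus one SZ patient
whose blood was unavailable) and "non-paired" (an independent cohort). A
candidate "replicates" if its q-value (BH over that LB array's full probe
set, not over the candidates only) falls below 0.05 in either LB set.

**qPCR validation.** Standard-curve method: per gene, OLS of Ct on
log10(quantity) over a dilution series spanning ≥ 2 decades (≥ 3 points);
efficiency = 10^(−1/slope) − 1. Triplicate Cts are averaged on the Ct scale
(the conventional choice; quantities are log-normal in Ct, so averaging
first is not neutral and is therefore fixed and documented), inverted
through the curve, and ratioed to the same-sample reference gene (GAPDH).
Group comparison applies the Tukey rule (outside Q1 − 1.5·IQR or
Q3 + 1.5·IQR; quartiles by linear interpolation between order statistics,
selectable) to the final relative-expression values per gene, then Welch's
unequal-variance t-test. Medication (chlorpromazine-equivalent dose) and
smoking (packs/day) effects are probed by per-gene OLS of the ratio on the
covariate within SZ, dropping missing covariates row-wise.

**Exact categorical tests.** Cohort tables use Fisher's exact test with the
"sum of tables no more probable than the observed" two-sided rule, computed
in exact rational arithmetic (`fractions.Fraction`); the doubled-one-tail
rule is available as an option. 2×3 tables use the Freeman–Halton
generalization by full enumeration (totals ≤ 200). This rule reproduces
four of the six verifiable printed cohort p-values at printed precision;
the two modal tables (paired sex and race) print 0.77 and 0.92 in the
source table where any standard two-sided rule gives 1.0 — we do not force
agreement and report the exact values.

## Synthetic study conditions

The generator reproduces the study design so every stage can be scored
against planted truth:

* **Cohort**: 16 SZ / 15 control (OE and paired LB, the latter minus one SZ
  patient), 16/18 non-paired LB. Demographics drawn from identical
  distributions in both groups (matched in expectation): age N(40, 11²),
  75% male, race 40/55/5%, education N(12.7, 2.5²), 40% smokers,
  chlorpromazine equivalents N(400, 150²) mg/day for SZ only.
* **Scores**: domain score = group mean + 0.5·(sex − E[sex]) +
  0.2·(education − E[education]) + λ_d·L + ε. Group means and sds follow
  the published cohort pattern (e.g. composite 8.6 ± 1.5 vs 9.9 ± 1.6,
  ideational fluency 5.7 ± 1.8 vs 7.8 ± 1.7). One latent cognition factor
  L ~ N(0,1) is shared across domains with loading λ_d = 0.6·sd_d and noise
  sd_d·√(1−0.6²), giving realistic inter-domain correlation (~0.36) and a
  composite deficit of d ≈ 0.84. Covariate effects sit on top of the
  nominal sds (a small, accepted inflation). The composite is computed, not
  drawn.
* **Expression**: probe baselines U(5, 12) log2 units, within-group sd 0.3.
  50 of 5000 probes (defaults) carry group shifts of |fold change|
  U(1.2, 3.3) with random sign, applied on the log2 scale so the signed-FC
  convention is exactly recoverable. 10 cognition-linked probes carry both
  a fold change and a within-SZ correlation with one score set: the target
  Spearman rho (|rho| U(0.6, 0.8), random sign) is realized by mixing the
  covariate-adjusted score direction with in-sample-orthogonalized noise
  and bisecting the mixing weight until the realized sample Spearman equals
  the target (to rank-lattice resolution). Planting against the *adjusted*
  score makes the planted quantity the same quantity the screen measures.
  20 co-regulated pairs share a latent factor (population |r| = 0.9,
  random sign). LB matrices contain independent noise and nothing planted.
* **qPCR**: curves with slope −3.3219 (efficiency 1.0) and per-gene
  intercepts; standards at 10⁰…10⁴ generated exactly from the curve
  (+ optional noise); per-subject reference quantity log-normal around 100;
  true target/reference ratio 1.0 in controls, 0.7 in SZ, between-subject
  sd 0.1; triplicates share the true quantity and differ by technical Ct
  noise (sd 0.1 cycles).

**What the benchmark does not show.** Normal noise throughout (no
heavy-tailed arrays, no batch or spatial artifacts); probes are independent
except where planted; demographics are matched exactly in expectation
rather than by recruitment; the cognition linkage is exactly monotone where
real biology need not be. Passing tests therefore demonstrates that the
*procedure* recovers what it claims under its own assumptions — not that
those assumptions hold in tissue.

## Numerical conventions and degenerate inputs

* Permutation p-values: add-one smoothing in Monte-Carlo mode (p ≥
  1/(N+1)); exact proportion in exhaustive mode; ties in the permutation
  statistic count as extreme (comparison with a 1e−12 guard).
* Constant vectors raise degenerate-input errors in correlation/Z-scoring;
  constant probes get p = 1 with a warning in stage 1; constant rows are
  excluded (warned) from networks.
* Rank-deficient regression designs raise collinearity errors; covariate
  columns that are constant are dropped in favour of the intercept (so
  all-male cohorts degrade gracefully to plain Z-scores).
* `corr_p_cutoff = 1.0` disables the stage-2 filter entirely (used for
  "keep every pair" runs); below 1 retention is strict (p < cutoff).
* Result tables are written with deterministic sort keys and fixed printed
  precision (p to 3 significant digits, rho to 2 decimals, fold change to
  1 decimal), making same-seed reruns byte-identical.
* Default problem sizes in the shipped analyses and acceptance script
  (5000 probes; 10⁴–10⁵ permutations; 20–100 replicates per power
  estimate) are chosen so the full battery runs in minutes on one core
  while keeping Monte-Carlo error well inside the tested tolerances; the
  permutation count is configurable up to the design's 10⁶.

## Known limitations

* The Freeman–Halton implementation covers 2×2 and 2×3 tables (the shapes
  that occur in cohort tables) with full enumeration up to n = 200.
* Probe-to-gene annotation is many-to-many by join; no expression-level
  collapsing of probes to genes is performed (matching the design, which
  reports candidates at probe resolution).
* The co-regulation stage validates data quality; it is not part of
  candidate selection and is off by default in the pipeline driver.
* Covariate-adjusted differential expression (limma-style moderation) is
  out of scope; stage 1 is the plain two-group ANOVA the design specifies.
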