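# oescreen

Candidate-gene discovery for olfactory-epithelium (OE) transcriptomics in
schizophrenia (SZ). Biopsied nasal neuroepithelium gives molecular access to
neuronal tissue in living patients; the problem is that a two-group
differential-expression analysis at n ≈ 16 vs 15 yields thousands of hits
with no link to the clinical feature of interest. `oescreen` implements the
two-stage screening strategy that addresses this, together with its
validation stages, as a tested, reusable pipeline:

1. **Differential expression** — per-probe one-way ANOVA on log2
   intensities (two groups ⇒ F = t²), Benjamini–Hochberg FDR across the
   array, signed fold change r = 2^(Δlog2) reported as r or −1/r.
2. **Cognition correlation screen** — six neuropsychological domain scores
   and their composite are residualized on sex and years of education and
   Z-scored (Z = (residual − mean)/sd) within SZ patients; every
   FDR-significant probe is tested against every score set with Spearman's
   rank correlation and a permutation p-value,
   p = (1 + #{|ρ*| ≥ |ρ|})/(N+1); pairs with p < 0.01 become candidates.
3. **Enrichment** — co-regulation networks (gene pairs with |Pearson r| ≥
   0.75) and hypergeometric upper-tail over-representation tests
   P(X ≥ k | N, K, n), with the universe always explicit.
4. **Cross-tissue concordance** — the same differential-expression stage on
   paired and non-paired lymphoblast matrices; a candidate replicates if
   its transcriptome-wide q < 0.05 in blood.
5. **qPCR validation** — standard-curve quantification (OLS of Ct on
   log10 quantity, efficiency 10^(−1/slope) − 1), GAPDH-normalized ratios,
   1.5-IQR outlier removal, Welch's t-test, and covariate regressions for
   medication dose and smoking.

Exact categorical tests (Fisher 2×2 and Freeman–Halton 2×3, rational
arithmetic) reproduce published cohort-table statistics from printed counts.
A first-class synthetic-data module generates the whole study — matched
cohort, correlated domain scores, expression with planted fold changes
(|FC| 1.2–3.3), planted within-patient gene–cognition correlations (target
Spearman ρ 0.6–0.8, hit exactly by calibration), null lymphoblast matrices,
co-regulated pairs, and qPCR plates from known curves — with every planted
effect recorded for recovery scoring. See `docs/methods.md` for the model
details and the benchmark's limits.

## Worked example

```bash
python analysis/01_simulate.py --seed 1          # write results/synthetic/
python analysis/03_discovery_pipeline.py --seed 1
```

prints (seed 1, default study conditions: 5000 probes, 16 SZ / 15 control):

```
stage 1: 56 probes at q < 0.05
stage 2: 16 retained (probe, score-set) pairs, 11 unique genes
network: 16139 co-regulation edges at |r| >= 0.75
lymphoblasts: 0 paired / 0 non-paired probes at q < 0.05; 0 candidates replicated
planted links recovered for their own score set: 8/10
```

Reading: of the 60 planted effects (50 pure group shifts + 10
cognition-linked probes), stage 1 recovers 56 probes at q < 0.05; the
correlation filter then cuts the list to 16 (probe, score-set) pairs, and 8
of the 10 planted gene–cognition links survive for exactly the score set
they were planted against (the misses are links planted near the ρ = 0.6
detection boundary at n = 16). Nothing was planted in the lymphoblast
matrices and no candidate replicates there — the expected cross-tissue
outcome. The remaining drivers cover the cohort tables
(`02_cohort_statistics.py`), network and gene-set enrichment
(`04_network_enrichment.py`), qPCR validation (`05_qpcr_validation.py`) and
the published candidate-list summary (`06_published_candidates.py`, 17
unique genes, SMAD5 and PABPC4L retained under multiple score sets).

The library is importable directly; each analysis driver is a thin wrapper
over `oescreen.de`, `oescreen.cognition`, `oescreen.correlation`,
`oescreen.network`, `oescreen.qpcr`, `oescreen.pipeline` and
`oescreen.synthetic`.

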