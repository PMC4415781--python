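# Methods

## Study design and scope

`pairde` implements the analysis chain used for paired tumor–normal
expression profiling on one-color microarrays that measure both mRNA and
lncRNA probes: quantile normalization and sample QC, paired differential
expression with empirical-Bayes variance moderation, gene-set
over-representation with a dual Fisher/chi-square test, interaction and
co-expression network topology, and qPCR concordance by relative
quantification. All statistics run at probe level; gene-level results
(enrichment, networks) collapse multi-probe genes by keeping the probe with
the smallest differential-expression P per symbol, a rule recorded in
output metadata.

## Quantile normalization

Sample columns are mapped onto the common reference distribution of
row-rank means: sort each column, average across columns at each rank, and
hand every sample that reference vector back in its own rank order. Tied
values within a column receive the mean of the reference values at the tied
ranks. On tie-free input the transform is exactly idempotent; we pin the
reference to the observed value whenever a rank already agrees across all
samples so that re-normalizing normalized data is bit-identical (a plain
floating-point mean of identical values can drift by one ulp).

## Sample quality control

The cohort triage emulates outlier screening by 3D PCA plus clustering. PCA
runs on sample profiles (probes as variables); a sample is flagged when its
squared Mahalanobis distance over the first three components exceeds the
chi-square(3) upper-`alpha` quantile (`alpha = 0.001` by default; `alpha =
0` disables flagging). Average-linkage hierarchical clustering on
1 − Pearson distance is recorded for the report (partner co-membership at
the two-cluster cut). A patient pair is dropped iff at least one member is
flagged. Note the interaction with normalization: a purely monotone
artifact (e.g. a constant log2 shift) is fully repaired by quantile
normalization and is therefore invisible to QC run afterwards; structural
outliers (scrambled or weakly correlated profiles) remain detectable. QC is
bypassable via the stage toggle.

## Paired differential expression

The paired design reduces to one-sample inference on within-patient
differences d_gp = tumor − normal (log2). Per probe: `log2fc` = mean(d),
`s2` = sample variance (df = n_pairs − 1). Variances are modeled as draws
from a scaled inverse-chi-square prior with hyperparameters (d0, s0²)
estimated by method of moments on log s²: Var[log s²] =
trigamma(df/2) + trigamma(d0/2) gives d0 by trigamma inversion (Newton),
and the mean relation gives s0². When the empirical variance of log s² does
not exceed trigamma(df/2) the prior is degenerate and d0 = ∞. The moderated
statistic uses the posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df) and
is referred to Student t with d0 + df degrees of freedom (standard normal
at d0 = ∞; at d0 = 0 the chain is exactly the classical paired t, which is
also how the qPCR module's paired tests are served). P-values are two-sided
and Benjamini–Hochberg adjusted. A probe is called differentially expressed
under the triple threshold |log2FC| > 1 (fold change > 2), P < 0.01 and
FDR < 0.01; the fold-change gate is applied on the log2 mean-difference
scale. Probes with missing values are rejected, not imputed.

## Gene-set over-representation

For each set and direction (up/down separately) the 2×2 overlap counts are
(k, n_set, K, N): differential genes in the set, universe genes in the set,
differential genes in the universe, universe size. Two tests run per set:

* Fisher: one-sided hypergeometric upper tail P(X ≥ k) — over-representation
  only by default (a two-sided option exists);
* Pearson chi-square on the implied table, 1 df, no continuity correction;
  when any expected cell is below 1 the Fisher P is substituted and flagged.

The enrichment ratio is observed over expected, (k/n_set)/(K/N). In GO mode
the universe is every symbol on the array after probe collapse; in pathway
mode universe and differential lists are first restricted to genes with at
least one annotation in the collection, which makes the ratio the pathway
enrichment score (ng/na)/(Ng/Na).

The dual-test FDR walks sets in ascending Fisher-P order and reports
1 − Nk/T at rank T, where Nk counts top-T sets whose Fisher P is below
their chi-square P; ties in Fisher P share the tied group's largest-rank
value, and a running maximum enforces monotonicity in Fisher P. Two
properties of this estimator matter in practice. First, it is a relative
consistency measure between the two tests, not a frequency-calibrated FDR.
Second, it degenerates under strong signal: for heavily enriched sets the
asymptotic chi-square P is usually *smaller* than the exact one-sided
Fisher P, the top rank is then discordant (Nk = 0 at T = 1), and the
running maximum pins every set at FDR = 1. For this reason the orchestrated
pipeline defaults to plain Benjamini–Hochberg on the Fisher P
(`enrich_fdr_method: bh`), while the dual-test estimator remains available
(`paper`) and is the default of the library-level `fisher_chisq_fdr`. A
continuity-corrected chi-square would invert the concordance direction;
we deliberately use the uncorrected statistic and document the consequence
instead of mixing conventions.

The GO tree induces the ontology DAG over significant terms plus minimal
connecting ancestors: a non-significant ancestor is kept (marked
`connector`) iff at least two of its child lineages contain significant
terms. Cyclic edge input is rejected with a witness cycle.

## Networks

All topology is computed on simple undirected graphs; relation types and
directions are retained as edge attributes only.

* **Gene-Act**: the interaction table induced on differentially expressed
  genes; hubs are nodes with degree > 25 (configurable).
* **Pathway-Act**: significant pathways joined when they share ≥ 3
  differential genes (edge weight = shared count).
* **Co-expression**: Pearson r across one tissue group's samples between
  differential genes; an edge requires |r| ≥ 0.8 and correlation-test
  P < 0.01 (t transform, n − 2 df). Constant genes are skipped with a
  logged count; groups with fewer than 4 samples are rejected. The r and P
  cutoffs are not dictated by the underlying methodology and are exposed in
  configuration and recorded in output metadata.
* **Key genes**: rows (gene, degree, core number) sorted by degree
  descending, then core descending, then gene name (the tiebreak is a
  documented convention), truncated to the top 20.

Core numbers come from the standard k-core decomposition (largest k such
that the node survives iterative deletion of all nodes with degree < k);
tests verify them against a brute-force deletion oracle.

## qPCR concordance

dCt = Ct(target) − Ct(reference gene) per sample; ddCt = dCt(tumor) −
dCt(paired normal); fold change = 2^−ddCt, so log2(fc) = −ddCt. Ct values
must lie in (0, 45]. Concordance against the array reports per-gene
direction agreement ((fc > 1) vs (log2FC > 0)), the overall agreement
fraction, and the Spearman correlation between log2(fc) and the array
log2FC. Fold changes are reported both per pair and as the per-gene
geometric mean across pairs.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions every
recovery statistic is measured under. Per probe g and sample s of patient p:

    x[g,s] = mu_g + b[g,s] + a_p + de[g,s] + mod[g,s] + e[g,s]

* baseline mu_g ~ U(6, 14), biological deviation b ~ N(0, sd_g) with
  sd_g ~ U(0.2, 1.0) — spanning a realistic log2 microarray dynamic range
  and exercising variance shrinkage;
* patient effect a_p ~ N(0, 0.3) shared by both members of a pair, which
  makes the paired design measurably better than an unpaired one;
* planted effects ±2 (log2) added to tumor samples of 200 of 5000 probes
  (sign random, recorded); 10% of probes are labeled lncRNA; 2% of probes
  share a symbol with another probe to exercise the collapse rule;
* two 20-gene co-expression modules (one per tissue group by default),
  driven by a latent factor with loading λ = noise_sd·sqrt(r/(1−r)) so that
  λ²/(λ² + noise_sd²) = module_r = 0.85; module probes carry no extra
  per-probe biological deviation so this calibration stays closed-form
  (the patient effect lifts the achieved population correlation to ~0.86);
* measurement noise e ~ N(0, 0.5) everywhere;
* 200 gene sets (sizes 10–40); the 3 planted-enriched sets draw two thirds
  of their members from one differential direction; set categories
  alternate GO/pathway;
* an interaction table whose 3 planted hubs are wired to exactly 30
  differential genes each (background edges avoid hub nodes so planted hub
  degree is exact by construction);
* a 10-gene qPCR panel (6 up, 4 down) with N(0, 0.3) Ct noise per well.

Modules are drawn from the planted differential probes because the
co-expression stage's default node set is the differential genes. 26
tumor–normal pairs is the default cohort size. All randomness derives from
one seed through fixed named child streams, so a fixture bundle is a pure
function of (config, seed).

What the generator does **not** emulate: probe-level dye bias, batch or
array effects, intensity-dependent variance trends, annotation ambiguity,
or missing values. Recovery results on these fixtures therefore demonstrate
correctness of the statistics under their own assumptions, not performance
on raw scanner data.

### A calibration limit worth knowing

At module_r = 0.85 the achieved within-module population correlation is
≈ 0.86. With 26 samples per group the sampling distribution of r̂ (Fisher
z, sd = 1/sqrt(23)) puts only ≈ 82% of within-module pairs above the
default edge cutoff r ≥ 0.8, and because the module shares one latent
factor the per-seed recovery co-fluctuates widely (observed range
0.36–1.00, mean ≈ 0.85–0.87). Near-complete within-module edge recovery at
this cutoff requires module_r ≈ 0.93 or a lower r threshold; at the stated
defaults the group *contrast* (module-bearing group strictly denser than
the other) is robust even though per-pair recovery is partial. The
defaults are left as stated; the acceptance suite reports the measured
recovery honestly.

## Problem sizes used by tests and the acceptance script

Unit tests run on compact cohorts (≈ 300–1200 probes); the acceptance
suite and `scripts/acceptance.py` use the full default conditions (5000
probes × 26 pairs, 200 sets) with 20 seeds for recovery statistics and 50
seeds for null calibration, sizes at which every quantity is stable to
well within its stated tolerance.

## Numerical choices

* Trigamma inversion by Newton iteration to relative 1e-10.
* Zero-variance probes are retained; shrinkage gives them s̃² > 0.
* BH adjustment delegates to `statsmodels` (`fdr_bh`); Fisher tails to
  `scipy.stats.hypergeom`; core numbers to `networkx.core_number`. Each is
  cross-checked in the tests against an independent hand-rolled oracle
  (step-up by hand, brute-force enumeration, iterative deletion).
* Result tables print 6 significant digits; intermediate caches write
  `%.17g` and are read back with round-trip float parsing, so write→read
  is bit-exact.
* All writers are deterministic (fixed column order and float format); run
  manifests record sha256 checksums per stage and reruns with the same
  config and seed reproduce them byte-for-byte.
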