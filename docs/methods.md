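# Methods

This note records the models, conventions and numerical choices behind
`ecmnet`, what the synthetic generators do and do not emulate, and the
problem sizes the test suite and `scripts/acceptance.py` use.

## Annotation model

Catalogs hold one record per gene with a division (`core_matrisome`,
`matrisome_associated`, `adhesome`) and a functional category; core
matrisome categories are restricted to collagens, glycoproteins and
proteoglycans. Divisions partition the catalog: a gene carried by both a
matrisome catalog and the adhesome keeps the matrisome division
(precedence core matrisome > matrisome-associated > adhesome) with an
`adhesome_overlap` flag, so division counts are disjoint while adhesome
composition breakdowns remain possible. Symbol matching is exact and
case-sensitive by default (`case_insensitive=True` opts into case
folding); there is no alias expansion, because alias maps are
catalog-version-dependent and silently rewriting symbols is worse than
missing a handful. The packaged catalog
(`data/synthetic_matrisome_adhesome.csv`) is a small hand-built snapshot
of real gene symbols for demos and tests, not a faithful copy of any
catalog release.

## Differential abundance

Per-protein tests are Welch *t* on the observed log2 values; normality on
the log scale is the standard working assumption for intensity
proteomics, and the unequal-variance form avoids pooling across
heterogeneous subtypes. Multiplicity control is Benjamini–Hochberg
throughout. "Upregulated" means q < 0.01 **and** mean difference ≥ 1 log2
unit (fold change ≥ 2, inclusive at the boundary); "uniquely upregulated"
means flagged in exactly one group's one-vs-rest test among the eligible
groups (those with ≥ 20 samples, the `min_n` default). Missing values:
tests use observed values only; a protein is dropped from a contrast when
either arm has fewer than 2 observed values or less than 50% observed —
below that the variance estimate is unstable. Both thresholds are
arguments, not constants, because the right missing-value policy is
dataset-dependent.

Stratum-robustness checks run Kruskal–Wallis per protein and on the
per-sample global median across ordinal strata (e.g. tumor-content bins);
strata below 2 samples merge into the nearest stratum by sorted label
order.

SAM (two-class, unpaired) uses d_i = (mean_A − mean_B)/(s_i + s0) with
the pooled scale s_i. The fudge factor s0 defaults to the median of the
s_i ("median" strategy); "zero", a fixed float, or a Tusher-style
percentile scan (minimizing the coefficient of variation of MAD(1/(s+s0))
across ten s-quantile windows) are selectable. The permutation null
enumerates all label assignments when their count is at most
`n_permutations`, otherwise draws a seeded random subset; per-threshold
FDR is the median null exceedance count over the observed count, clipped
to [0, 1].

## Coregulated networks

Similarity is pairwise-complete Pearson correlation with a `min_pairs`
floor (default 10): with fewer joint observations r is too unstable to
cluster on, so such pairs are masked, as are zero-variance proteins.
Consensus clustering follows Monti: draw `n_resamples` item subsamples
(default fraction 0.8; 1000 resamples for production runs, smaller values
configurable for quick runs), cluster each by average-linkage
hierarchical clustering — distance 1 − r for similarity input, Euclidean
for feature input (missing entries mean-imputed for distance purposes
only) — and set consensus(i, j) = co-clusterings / co-samplings. PAC is
the fraction of sampled off-diagonal consensus values in (0.1, 0.9).

Model selection is minimum PAC with one deliberate refinement: among k
values *exactly* tied at the minimum, the largest k wins. With a
deterministic hierarchical inner clusterer, coarser cuts of a clean
k*-block structure are also perfectly stable (PAC = 0 for every k ≤ k*),
so ties at the minimum indicate nested stable partitions and the finest
one is the informative choice; for noisy data exact ties do not occur and
plain minimum PAC applies. When the minimum PAC exceeds 0.5 the result is
flagged "no stable structure" (`stable=False`) rather than suppressed.
Final assignments cut an average-linkage tree of 1 − consensus at the
chosen k. Both input modes (correlation matrix or raw expression) are
supported since either is a defensible reading of standard practice.

SigClust tests a 2-cluster split against a single-Gaussian null. The
statistic is the 2-means cluster index CI = WSS₂/TSS (best of 4 seeded
Lloyd restarts). The null simulates datasets of the same shape from a
zero-mean Gaussian with diagonal covariance given by the eigenvalues of a
**Ledoit–Wolf-shrunk** covariance estimate, floored from below at a
background-noise variance (squared normal-consistent MAD of all data
values). The shrinkage is essential, not cosmetic: raw sample eigenvalues
are Marchenko–Pastur over-dispersed at small n, which makes the
parametric null spuriously anisotropic and the test severely conservative
(measured ~1/200 rejections at α = 0.05 on 20 × 4 spherical data, versus
~6/200 with shrinkage; the residual rate ≈ 0.03 is the mild conservatism
inherent to plugging an estimated covariance into a parametric
bootstrap). CI is scale-invariant, so only relative eigenvalues matter.
p-values are reported at resolution 1/n_sim (warning below 100
simulations).

Association tests: cluster scores (per-sample medians of observed member
abundances) vs grade use two-sided Mann–Whitney on graded cases with
ungradeable subtypes (desmoid) excluded; vs subtype use Kruskal–Wallis
plus Dunn pairwise z tests (pooled ranks, tie-corrected) with BH
adjustment — BH because no specific multiplicity correction is canonical
here and it matches the rest of the package. Subgroup-vs-clinical tables
use χ² of independence without Yates correction (so 2×2 tables reproduce
the textbook statistic) for categoricals, Kruskal–Wallis for continuous
variables, and median-dichotomized χ² for TIL counts.

## Enrichment

ssGSEA ranks a sample's genes by value descending with ties broken by
lexicographic symbol order (determinism over elegance), weights in-set
genes by |value|^α with α = 0.75, and sums the difference between the
weighted in-set ECDF and the unweighted out-of-set ECDF over all ranks.
Multi-set scoring optionally normalizes each sample by its score range
across sets. Errors are raised when a set misses the profile entirely or
covers it completely (the out-of-set ECDF is undefined). The hallmark
screen computes ssGSEA on whatever matrix is passed — use the full,
unfiltered proteome so non-ECM pathway sets can score — then one-way
ANOVA across subgroups per set with BH FDR at 0.05; exact score ties
across all samples short-circuit to p = 1 with a note. ORA is upper-tail
hypergeometric with the universe defaulting to the quantified proteins
(detection bias makes a genome universe anti-conservative).

## Survival

Kaplan–Meier, log-rank (O − E with hypergeometric variance, χ² on
groups − 1 df) and Cox proportional hazards are delegated to lifelines;
Breslow tie handling is available through statsmodels' PHReg, Efron being
the default as the better approximation for moderately tied data. Wald
CIs are exp(β ± 1.96·se). Coefficients with |β| > 15 are reported as
non-estimable (monotone likelihood / perfect separation); models with
more covariates than events are refused. Stratification: the median rule
sends scores ≤ the cohort median to "low" (the ≤ convention is a
configurable choice — the boundary side is not canonical); the tertile
rule bins at empirical tertiles with an optional low-vs-rest combination
for single-marker analyses. Optional administrative censoring at 60
months supports 5-year framings; it is off by default.

## Prognostic screen

Stage 1 scores every candidate set per patient (member-median by default,
ssGSEA selectable), median-splits, and runs the log-rank test per
endpoint at α = 0.05 with **no** cross-set multiplicity correction — raw
per-set p-values are the reference behavior for a 10-set screen, with a
BH option (`stage1_bh`) for stricter use. Stage 2 fits a multivariable
Cox model per passing (set, endpoint) with the stratum indicator plus
clinical covariates; by default covariates are preselected by univariable
significance (p < 0.05), with a full-model mode available. A set is
retained when its stratum indicator stays significant and estimable in at
least one passing endpoint's model. The stage-1 table, every MVA table
and all cutoffs are returned, so the filtering is fully auditable.

## Migration and IHC

Speed is total path length over elapsed time — equivalent to mean frame
displacement over frame gap on regular sampling, and robust to dropped
frames (gaps are bridged by straight segments, matching tracker exports).
DI = net displacement / total path length, defined as 0 for a zero-length
path. Condition comparisons are Mann–Whitney (2 conditions) or
Kruskal–Wallis + Dunn/BH (more), on pooled tracks.

H-score bins are closed on the left (a cell at exactly 0.18 OD is
moderate) — the cutpoints 0.14/0.18/0.23 are conventions of the staining
protocol and are parameters. TIL densities scale each replicate count to
100% section area, drop replicates below 50% preservation, average, and
multiply by the 1.274 cells/mm² area factor, treated as an opaque
protocol constant configurable per marker panel. The three-group case
split fits a 1-D three-component Gaussian mixture by EM with restarts
from quantile-based initializations plus seeded jitter, a variance floor
of 1e-6, convergence at relative log-likelihood change < 1e-10 within 500
iterations, and components labelled low/intermediate/high by ascending
mean. The EM is written in-package because the contract asserts the
log-likelihood is non-decreasing at every iteration and fixes the restart
scheme — details a library fit would hide. Component variances are free
(not shared); sharing them is a plausible alternative reading and would
only tighten the groups.

## Synthetic generators

The cohort generator is a single-factor model per latent program: sample
activity a ~ N(μ_subtype,grade, 1), member protein value
√ρ·a + √(1−ρ)·ε + protein offset with ε ~ N(0, noise_sd), background
proteins i.i.d.; with noise_sd = 1 the expected within-program Pearson r
equals ρ exactly, which is what makes closed-form recovery checks
possible. Defaults emulate a ~320-patient 11-subtype sarcoma series: 300
samples with subtype/grade/site/margins/sex/performance/pre-treatment
frequencies of that scale, 3 programs × 60 proteins (ρ = 0.8; an
ECM-regulator-like program shifted +1 SD in grade-3 tumors, a
basement-membrane-like program shifted +1.2 SD in leiomyosarcomas, a
proteoglycan-like program shifted +0.6 SD in desmoids) plus 120
background proteins, 5% missing-at-random. Survival is exponential with
hazard λ·exp(β·z), λ = 0.01/month, β = −0.7 per SD of the
proteoglycan-like activity (protective, OS only), under independent
exponential censoring (0.008/month); exponential rather than Weibull so
hazard-ratio recovery has a closed form. The truth record carries all
latents, so no recovery metric needs hidden state.

What the generator does **not** emulate: peptide-level quantification
noise, missingness that depends on abundance (MNAR), batch structure,
correlated censoring, or inter-program correlation. Passing tests
therefore demonstrate correctness of the estimators under their stated
assumptions, not robustness to those real-data pathologies.

Tracks are persistent random walks (wrapped-normal heading increments,
Rayleigh step lengths, default 37 frames at 30-minute intervals — an
18-hour film); angular noise 0 gives DI = 1 exactly, and doubling the
step scale doubles speed while leaving DI untouched, which the tests
exploit. IHC tables draw per-cell optical densities from lognormal
mixtures.

## Pipeline

Stages (cohort → filter → networks → scores → survival) are cached by
content: each stage's manifest records sha256 hashes of its inputs,
parameters and outputs. Unchanged stages are skipped; outputs that exist
but do not match their recorded hash raise a provenance error rather than
being silently consumed or rebuilt — a corrupted intermediate is a
condition to surface, not repair. Full synthetic runs are bit-reproducible
given a seed.

## Problem sizes used by the tests and acceptance script

Type-I checks use 200 replicates of 120-sample single-program cohorts
(log-rank, screen stage 1), 200 spherical-Gaussian datasets of 20 × 4
with 100 SigClust simulations each, and one 200-protein null
stratum-robustness matrix. Recovery checks use ten 180 × 120 three-block
matrices at 100 consensus resamples, one hundred n = 300 Cox simulations
(~20% censoring), a 300-case trimodal GMM fixture, and one hundred
300-sample screen simulations with three decoy sets. The end-to-end run
uses the default 300-sample cohort with 150 consensus resamples and 150
SigClust simulations, executed twice to verify bit-reproducibility. These
sizes keep the full suite around a minute on one CPU while leaving the
binomial acceptance bands meaningful.

## Known limitations

- Pairwise-complete correlation can produce non-positive-semidefinite
  similarity matrices; downstream clustering only uses 1 − r as a
  dissimilarity, so this is harmless here but the matrix should not be
  fed to methods requiring PSD inputs.
- SigClust with an estimated covariance remains mildly conservative
  (rejection ≈ 0.03 at nominal 0.05 on small spherical data) even with
  shrinkage; this is a property of the parametric bootstrap, not a bug.
- The screen's stage-1/stage-2 architecture inherits the usual caveat of
  selection-then-inference: stage-2 p-values are conditional on passing
  stage 1 and should be read as filters, not unbiased effect estimates.
- Cox separation handling reports diverging coefficients as non-estimable
  rather than applying Firth-type penalization.
- SAM's percentile-scan s0 is a simplified coefficient-of-variation scan,
  adequate for the moderate protein counts used here.
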