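# ecmnet

Extracellular-matrix (ECM) network analysis for soft-tissue-sarcoma
proteome cohorts.

Soft tissue sarcomas are rare mesenchymal tumors whose microenvironment —
in particular the ECM and the integrin adhesion machinery that reads it —
is poorly characterized compared to carcinomas. Given a cohort of log2-
normalized protein abundances with clinical annotation, `ecmnet`
implements the analysis chain that turns such a cohort into matrix
biology: restrict the proteome to matrisome/adhesome catalogs, find
coregulated ECM programs and molecular subgroups, score pathway activity
per patient, screen candidate ECM gene sets for independent prognostic
value, and quantify the companion bench readouts (cell-migration tracks,
immunohistochemistry scores). A ground-truth synthetic cohort generator
makes every stage testable without any data download.

The package is a library first: `import ecmnet` and use the module
functions, or start from the narrative scripts in `examples/`. A thin
`ecmnet` command-line wrapper exists for shell-driven runs
(`ecmnet run --config run.yaml` for the full pipeline).

## What is implemented

| module | contents |
| --- | --- |
| `ecmnet.annotations` | matrisome/adhesome catalogs, proteome filtering, coverage stats |
| `ecmnet.cohort_io` | all file dialects: abundance TSV, clinical CSV, GMT, track CSV |
| `ecmnet.diffexp` | one-vs-rest / two-group Welch tests, unique upregulation, Kruskal–Wallis stratum-robustness, two-class SAM |
| `ecmnet.networks` | pairwise-complete Pearson similarity, Monti consensus clustering with PAC, SigClust, cluster median scores, clinical association tests |
| `ecmnet.enrichment` | ssGSEA running-sum scores, one-way-ANOVA hallmark screen, hypergeometric ORA |
| `ecmnet.survival` | Kaplan–Meier, log-rank, Cox PH (Efron/Breslow ties), median/tertile stratification |
| `ecmnet.matrix_scores` | per-patient gene-set scores and the two-stage prognostic screen |
| `ecmnet.migration` | per-track speed and directionality index, condition comparisons |
| `ecmnet.ihc` | H-score, positive-pixel fraction, TIL density, 1-D Gaussian-mixture grouping |
| `ecmnet.synthetic` | cohort / track / IHC generators with full truth records |
| `ecmnet.pipeline` | hash-cached end-to-end orchestration |

## The statistics at the core

**Coregulated networks.** Protein–protein similarity is pairwise-complete
Pearson *r*; consensus clustering repeatedly subsamples items (80%,
average-linkage hierarchical clustering of 1 − *r*), records co-clustering
frequencies M<sub>ij</sub> ∈ [0, 1], and picks the number of clusters *k*
by minimum PAC = #{(i, j) : 0.1 < M<sub>ij</sub> < 0.9} / #pairs. Cluster
significance follows SigClust: the 2-means cluster index
CI = WSS₂/TSS is compared with CI under a single-Gaussian null whose
covariance eigenvalues are estimated from the data (Ledoit–Wolf-shrunk,
floored at a MAD-based background-noise variance).

**Per-patient scores.** For a gene set *G* and sample profile ranked
descending, the ssGSEA score is
ES = Σ<sub>i</sub> [P<sup>w</sup><sub>in</sub>(i) − P<sub>out</sub>(i)]
with in-set weights |x|<sup>α</sup> (α = 0.75). The simpler median score
is the median of observed member abundances.

**Prognostic screen.** Each candidate set's score is split at the cohort
median; stage 1 keeps sets with log-rank *p* < 0.05 for ≥ 1 endpoint
(OS / LRFS / MFS); stage 2 keeps sets whose stratum indicator stays
significant in a multivariable Cox model (Efron ties, Wald inference,
HR = e<sup>β</sup>) with clinical covariates — "retained" means
independently prognostic.

**SAM.** Two-class moderated statistic d<sub>i</sub> = (x̄<sub>A</sub> −
x̄<sub>B</sub>)/(s<sub>i</sub> + s₀), null from label permutations
(exhaustive when feasible), FDR(Δ) = median null #{|d*| ≥ Δ} / #{|d| ≥ Δ}.

**Migration.** Directionality index DI = net Euclidean displacement /
total path length ∈ [0, 1]; speed = path length / elapsed time (µm/h).

**IHC.** H = 100·(f<sub>weak</sub> + 2 f<sub>moderate</sub> + 3
f<sub>strong</sub>) ∈ [0, 300] with OD cutpoints 0.14 / 0.18 / 0.23;
TIL density = mean(count / preservation) × 1.274 cells/mm².

## Worked example

`python examples/04_prognostic_screen.py` builds a 300-patient synthetic
cohort whose overall survival depends only on a proteoglycan-like latent
program (log HR −0.7 per SD), then screens the three program gene sets
plus three background decoy sets:

```
stage 1 (log-rank on median-split scores):
endpoint    LRFS     MFS      OS
gene_set
BM        0.9965  0.9900  0.7968
DECOY_01  0.3234  0.5867  0.6510
DECOY_02  0.7370  0.3359  0.2473
DECOY_03  0.6508  0.1199  0.0658
ECMREG    0.3093  0.4445  0.4893
PG        0.9843  0.2557  0.0000

retained after multivariable Cox: ['PG']
  PG / OS: HR = 0.31 (95% CI 0.22-0.43), p = 0.0000
```

Only the causal proteoglycan-like set passes the log-rank filter for OS
and survives multivariable adjustment; its hazard ratio is below 1
because a high proteoglycan score is protective — patients above the
cohort median have roughly one third the death hazard of those below it.
The other examples cover annotation filtering, subtype-unique
upregulation, network discovery, migration metrics, IHC scoring, and the
full pipeline.

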