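# krassig

Cross-tumour discovery and validation of KRAS-mutation gene signatures, as a
tested Python library with a CLI and a set of narrative analysis drivers.

## The problem

Oncogenic *KRAS* drives lung, pancreatic and biliary cancers, but its
transcriptional footprint is noisy in any single model system. A robust
signature has to survive three filters:

1. **Cross-system discovery.** In each experimental model (e.g. engineered
   bronchial cells, mouse lung tumours, mouse fibroblasts), genes are tested
   for differential expression between `KRAS_mut` and `KRAS_wt` samples with
   an empirical-Bayes moderated t-statistic. Each gene's residual variance
   s² (d residual df) is shrunk toward a prior (d₀, s₀²) estimated by moment
   matching on log s²: s̃² = (d₀s₀² + d·s²)/(d₀ + d). The B statistic is the
   log posterior odds that the gene is differentially expressed. Candidates
   must satisfy **B > 0 and log₂FC > 1 in at least two of the three
   systems**, after dropping genes with expression below 5 (log₂) in more
   than half the samples.
2. **Cross-cohort validation.** Each patient cohort is ranked by the
   mutant-vs-wild-type log₂ fold change and the candidate set is scored with
   the preranked GSEA running-sum statistic (weighted Kolmogorov–Smirnov ES,
   gene-resampling permutation p and NES). The **core signature** keeps
   genes recurrent in **more than 50% of the cohort leading edges**.
3. **Clinical read-out.** Samples are scored with the signature (geometric
   mean of linear expression, or the z-sum: the sum of per-gene standardized
   expression), classified for mutation status by logistic regression
   (ROC/AUC), and patients are stratified high/low within each genotype for
   Kaplan–Meier, log-rank and multivariate Cox (age, sex, stage) analysis.

Around this core the package also implements the companion computations:
Hedges' g standardized-mean-difference meta-analysis with
DerSimonian–Laird random effects, hypergeometric category enrichment with
BH adjustment, Chou–Talalay median-effect drug-synergy analysis
(fa/fu = (D/Dm)^m; CI = d₁/Dx₁ + d₂/Dx₂ with CI < 1 synergism, = 1
additive, > 1 antagonism), two-sample t-test power via the noncentral t,
population doubling time and ellipsoid tumour volume (π/6·L·W²).

Real cohorts are deliberately out of scope: a synthetic-data module
generates multi-cohort expression with planted effect genes, score-linked
survival and median-effect dose-response, so every stage is tested against
known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (run them in order; outputs land in `results/`):

```bash
python analysis/01_simulate_cohorts.py      # 3 systems + 4 cohorts, 20 planted genes
python analysis/02_differential_expression.py
python analysis/03_gsea_recurrence.py
python analysis/04_signature_scoring.py
python analysis/05_survival_stratification.py
python analysis/06_meta_enrichment.py
python analysis/07_drug_synergy.py
```

Selected output (what the scripts actually print):

```
cross-system candidates (B>0 & logFC>1 in >=2/3 systems): 20 genes
  20/20 planted genes recovered, 0 false positives

cohort 0: ES=+0.999 (+) NES=2.85 p=0.001748 leading edge 20/20
core signature (recurrent in >50% of 4 leading edges): 20 genes
  subset of candidates: True; 20/20 planted genes

held-out cohort 3: AUC = 1.000

      stratum  n  events      rmst
KRAS_mut/high 50      48  1.898157   <- worst outcome
  KRAS_wt/low 50      47  6.436079
 KRAS_wt/high 50      43  7.984412
 KRAS_mut/low 50      28 11.521178
multivariate Cox in KRAS_mut: HR per score unit = 2.998 (2.415-3.721), p=2.43e-23
multivariate Cox in KRAS_wt:  HR per score unit = 0.957 (0.863-1.062), p=0.412

line_mut1: fa=0.93 at 1.0+0.5 uM -> CI = 0.20 (synergism)
animal design power (n=12/group, 30% difference, sd 0.25): 0.802
```

Reading it: stage 1 recovers every planted gene with no false positives;
each validation cohort shows strong positive enrichment of the candidates
(p ≈ the permutation minimum), and the recurrence filter returns a core
signature contained in the candidate set. The signature separates mutant
from wild-type samples perfectly on a held-out cohort (AUC 1.0). When the
hazard is linked to the signature score in mutants only, the mutant/high
stratum has the shortest restricted mean survival and the score is an
independent prognostic factor in mutants (HR ≈ 3) but not in wild type —
the genotype-specific survival pattern the workflow is designed to expose.
The synergy driver calls the high-effect combination synergistic (CI 0.2)
and the printed power matches the 80% animal-design target.

The same stages are available as CLI subcommands
(`krassig simulate|de|gsea|signature|survival|meta|enrich|synergy|discover`,
plus `power`, `pd-time`, `volume` utilities); see `krassig --help`.

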