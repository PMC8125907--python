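# nersig

A toolkit for deriving and applying a transcriptional signature of
**deficient nucleotide excision repair (dNER)**. NER removes helix-distorting
DNA lesions (UV photoproducts, cisplatin intra-strand crosslinks); tumors
that have lost it are hypersensitive to crosslinking chemotherapy, so
recognizing them from expression data is clinically useful. `nersig` is
aimed at computational biologists who want to derive such a signature from
an isogenic knockdown panel, score patient or cell-line cohorts with it, and
follow the downstream consequences (classification, survival, drug
vulnerability, drug synergy) — with every stage testable on synthetic data
carrying planted ground truth.

## What it computes

**Signature derivation.** For each knockdown line vs control, per-gene
differential expression on log2 values (moderated t-test with
empirical-Bayes variance shrinkage by default; Welch's t available) with
Storey q-values. The consensus signature is the set of genes with
|fold change| > 1.5 and q < 0.05 in *every* line, in a consistent direction;
each gene's coefficient c_i is its average log2 fold change across lines.

**Sample scoring.** A sample s in a cohort is scored

    S(s) = Σ_i c_i · z_i(s) / Σ_i |c_i|

where z_i is gene i's z-normalized log2 expression across the scored cohort.
Higher S means more NER-deficient.

**Cohort evaluation.** ROC/AUROC (Mann–Whitney rank form with tie
correction), operating threshold by Youden's J = sensitivity + specificity − 1
with a class-stratified percentile-bootstrap CI, two-group log-rank test,
binary-covariate Cox hazard ratio (Breslow ties, Newton iteration), and a
three-group mutational-signature concordance check (Cohen's d profiles of
gold-standard vs predicted-deficient tumors against proficient ones,
summarized by Pearson r).

**Synthetic lethality screen.** Cell lines split at the upper quartile of
the score; per-drug Welch t on AUC with BH FDR; hits are drugs with lower
AUC in deficient-high lines at q < 0.05.

**Drug synergy.** Median-effect fits fa/(1−fa) = (D/Dm)^m per drug and the
Chou–Talalay combination index CI = d1/Dx1 + d2/Dx2 (CI < 1 synergism,
CI = 1 additive, CI > 1 antagonism).

**Synthetic data.** Generators for the knockdown panel, tumor cohorts
(score shift, mutational-signature shift, exponential survival with a
planted hazard ratio), drug screens with planted lethal drugs, and
median-effect dose–response curves — all seeded and deterministic.

## Worked example

```sh
cd examples && python 01_derive_signature.py && python 02_score_and_classify_cohort.py
```

prints (abridged):

```
panel: 1000 genes x 18 samples (5 knockdown lines + shCTRL)
  shXPA: 141 genes pass |FC|>1.5 & q<0.05
  ...
consensus signature: 99 genes (99/105 planted core genes recovered, 0 false inclusions)
coefficient vs planted log2FC correlation: r = 0.987

scored 300 tumors with 56 genes
AUROC = 1.000
Youden threshold = 0.491 (95% bootstrap CI 0.463 to 0.509)
sensitivity = 100.0%, false-positive rate = 0.0%
log-rank chi2 = 27.18, p = 1.85e-07
Cox HR (predicted deficient vs proficient) = 0.41 (95% CI 0.29-0.58)
mutational-signature concordance r = 0.950
```

The first block shows the consensus filter recovering nearly all planted
core genes with no false inclusions and coefficients tracking the planted
effect sizes. The second shows a simulated cohort where the planted
deficient quarter separates cleanly (AUROC 1.0), predicted-deficient
patients live longer (HR 0.41, planted 0.46), and predicted-deficient tumors
without NER mutations share mutational-process shifts with mutated ones
(r = 0.95). `examples/03_drug_screen.py` and `examples/04_combination_index.py`
cover the screen and synergy stages.

The same pipeline runs end to end from a shell:

```sh
nersig --config cfg.yaml all   # see nersig.io.PipelineConfig for the schema
```

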