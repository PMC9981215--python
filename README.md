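# panmyeloid

Phenogenetic analysis of haematologic-neoplasm cohorts: from annotated
variant calls to a one-dimensional "Pan-Myeloid Axis" and mutation-load
risk stratification.

Myeloid neoplasms — AML, MDS, MDS/MPN overlap syndromes, MPN — are
diagnosed as distinct diseases, but their genetics suggest a continuum.
This package implements a pipeline for quantifying that continuum in a
multi-disease cohort profiled with a targeted gene panel, karyotyping,
complete blood counts and marrow/blood smears. It is aimed at
computational haematology groups who have per-patient variant calls and
clinical tables and want reproducible, tested implementations of the
analysis stages, together with a synthetic cohort generator that
provides ground truth for every stage.

## What it computes

**Somatic filtering.** Tumour-only panel calls pass an eight-step
heuristic filter (base quality Q ≥ 20, depth ≥ 30, VAF in [0.02, 0.45],
panel of normals, a COSMIC-haematopoietic rescue of VAF/PoN rejections,
laboratory recurrence ≤ 10%, non-silent consequence, population
frequency ≤ 1% in every database), plus CEBPA single/double-mutant and
FLT3 ITD-high/ITD-low/TKD/Other classification (ITD allele ratio ≥ 0.5
is "high").

**Dirichlet-process clustering of prevalence spectra.** For aberration
*i* and disease *j*, the carrier count m_ij out of n_j patients is
modelled as Binomial(n_j, θ_jC_i) with cluster-wise prevalences
θ_jk ~ Beta(a₀, b₀) and a Chinese-restaurant-process prior with
concentration α (default 10⁻⁴) on the partition C. A two-step Gibbs
sampler (label updates with the collapsed Beta-Binomial new-cluster
weight, then conjugate Beta draws; 5,000 burn-in + 500 retained sweeps)
yields a co-assignment matrix and a Binder-loss consensus partition.

**The Pan-Myeloid Axis.** A feed-forward diagnosis classifier
(339 input features → 100 ReLU → 65 ReLU → 8 softmax) is trained on the
full feature vector (174 gene variables, 72 karyotype flags, age, 36 CBC
and 56 smear variables, mean-imputed). PCA of the last hidden layer
embeds patients in 2-D; the first principal direction of the myeloid
subset, oriented so that mean(AML) > mean(MDS), is the axis. Aberrations
sit at the centroid of their carriers; order stability is assessed by
stratified bootstrap with pairwise Kendall τ.

**Risk schemes.** Axis-ordered clusters are simplified into gene groups
L / ML / MR / R (with a >1% myeloid mutation-rate floor for the middle
and right groups). The "2017 ELN enhanced" scheme crosses the 2017
European LeukemiaNet genetic risk class with the R+MR mutation load:
Group 1 = Favorable & load ≤ 2; Group 2 = Favorable & load > 2 or
Intermediate & load ≤ 2; Group 3 = Intermediate & load > 2 or Adverse.
MDS-EB patients are stratified High/Low by the L+ML load at the same
threshold. Evaluation covers AUROC, logistic regression with Wald tests,
Fisher exact tests, Kaplan–Meier curves with Greenwood standard errors,
concordance and pairwise Cox comparisons.

**Synthetic cohorts.** `panmyeloid.synthetic` generates an
eight-diagnosis cohort (default sizes AML 388, CML 27, MDS 209, MDS/MPN
36, MPN 70, ALL 321, CLL 52, MM 89) with planted aberration clusters
arranged along an axis gradient, phenotypes linear in cluster loads,
a logistic CR model and exponential survival per risk group — every
planted parameter is returned as ground truth.

## Worked example

Run the whole pipeline on a quarter-scale synthetic cohort:

```sh
cat > demo.yaml <<EOF
seed: 1
cohort_scale: 0.25
dp:
  burn_in: 1000
  n_samples: 300
EOF
panmyeloid --config demo.yaml run-all --out demo_out
```

prints

```json
{
  "n_patients": 298,
  "filter_kept": 68,
  "filter_label_agreement": 1.0,
  "n_gene_clusters": 4,
  "weighted_auroc": 0.999964778387116,
  "cr_auroc_enhanced": 0.7104347826086956,
  "cr_auroc_eln": 0.7304347826086957,
  "os_concordance_enhanced": 0.6751543209876543
}
```

Reading the numbers: all 298 simulated patients were generated and
reloaded; every raw variant call was filtered to exactly its planted
expectation (`filter_label_agreement` 1.0, 68 calls kept); the DP
sampler grouped the carried gene variables into 4 clusters; the
diagnosis classifier reached weighted one-vs-rest AUROC ≈ 1.0 in
five-fold cross-validation (the synthetic diagnoses are strongly
separable by design); and on the adult de-novo AML subset the enhanced
three-group scheme predicted complete remission with AUROC 0.71 and
ranked overall survival with concordance 0.68. At this demonstration
scale only ~70 AML patients are CR-evaluable, so the enhanced-vs-ELN
AUROC ordering fluctuates; the full-scale comparison is part of the
reproduction script below. `demo_out/` contains the reloadable
artifacts (cohort and mutation tables, filter decisions, cluster
labels, co-assignment matrix, embedding coordinates, risk assignments,
Kaplan–Meier curves, evaluation JSON and the resolved configuration).

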