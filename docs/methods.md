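# Methods

This note documents the models, the numerical choices behind them, what
the synthetic data generator does and does not emulate, and the known
limitations.

## Feature schema

A patient is a 339-vector: 174 gene-variable indicators, 72 karyotype
flags, age (years), 36 CBC and 56 smear measurements. Gene variables
are panel genes with CEBPA expanded to {sm, dm} and FLT3 to {ITD, TKD,
Other}; a 171-gene panel therefore yields 174 variables. Gene and
karyotype entries are binary presence indicators — one or more
surviving somatic events maps to 1 — rather than VAF-weighted values,
because every downstream quantity (spectra, loads, heatmap-style
summaries) counts mutations, not allele fractions. Missing continuous
values are imputed with the cohort mean of the feature; an empty cell
in the delimited tables is missing, while zero is a value (a zero
basophil count is information, not absence of measurement). The CBC and
smear name lists are configurable: laboratories report different
variable sets, and the default lists here are a representative layout,
not a standard. The bundled 171-gene panel
(`data/panel171_synthetic.txt`) is likewise a synthetic curation of
real haematologic-neoplasm gene symbols standing in for a commercial
panel.

## Somatic filter

Tumour-only calls are filtered in eight numbered steps; the reason code
of a rejected call is the first failing step. Thresholds (defaults):
Q < 20; depth < 30; VAF < 0.02 or > 0.45; exact locus+allele membership
in the panel of normals; rescue of step-3/4 rejections with COSMIC
haematopoietic/lymphoid count ≥ 2; laboratory recurrence > 10%;
synonymous/intronic consequence; population frequency > 1% in any
database. All comparisons at the boundary are strict in the direction
stated (VAF exactly 0.45 survives; depth exactly 30 survives). Rescue
never applies to quality or depth rejections, and a rescued call is
still subject to steps 6–8. The laboratory-recurrence list is
site-specific; when it is unavailable step 6 is skipped with a logged
warning rather than silently treating recurrence as zero. The filter is
monotone: tightening any rejection threshold can only shrink the kept
set (with the rescue rule held fixed), a property the test suite checks
with randomized threshold perturbations.

## Dirichlet-process clustering of prevalence spectra

The data for aberration *i* are its carrier counts m_ij across the q
diseases, with totals n_j. The model:

    m_ij | C_i = k   ~  Binomial(n_j, θ_jk)
    θ_jk             ~  Beta(a₀, b₀), independent over j and k
    C_1, …, C_p      ~  CRP(α)

Defaults: α = 10⁻⁴, a₀ = b₀ = 1. The uniform Beta prior is the
uninformative conjugate choice and is exposed as configuration. The
tiny concentration strongly favours merging aberrations whose spectra
are statistically indistinguishable, so the number of clusters is
effectively determined by the likelihood.

Sampling alternates (1) a sweep of label updates — for each aberration,
existing cluster k gets weight π_k^(−i) · Π_j Binomial(m_ij; n_j, θ_jk)
and a new cluster gets α · Π_j BetaBinomial(m_ij; n_j, a₀, b₀), the
collapsed marginal; a new cluster's θ is drawn from its single-member
conjugate posterior — and (2) conjugate Beta draws of every cluster's
θ_jk. Binomial coefficients are identical across candidate clusters for
a fixed aberration and are dropped from both weight types. All
likelihoods are accumulated in log space and normalized with
log-sum-exp, so underflow cannot produce zero divisions. The chain is
initialized with every aberration as its own singleton cluster and run
for 5,000 burn-in plus 500 retained sweeps (no thinning) by default.

Label switching is resolved at summary time: the retained partition
minimizing the Binder loss against the pairwise co-assignment matrix is
reported as the consensus, and each aberration's posterior support is
its mean co-assignment with its consensus block. Gene mutations and
karyotype abnormalities are clustered by separate invocations of the
same sampler; no joint model is attempted.

Correctness anchors: for p = 2 the posterior over the two possible
partitions is available in closed form (CRP prior odds 1 : α times the
ratio of Beta-Binomial marginals), and the chain's together-frequency
is required to match it within three batch-means Monte Carlo standard
errors; a planted three-cluster design (prevalence rows 0.05 / 0.30 /
0.70, four diseases, n_j = 200) must be recovered with adjusted Rand
index 1.0; and the expected cluster count is checked to be
non-decreasing in α.

## Diagnosis classifier and the Pan-Myeloid Axis

The classifier is a fully connected network, 339 → 100 (ReLU) → 65
(ReLU) → 8 (softmax). The layer widths are the model; the optimizer is
not — training uses cross-entropy with adaptive-moment gradient
descent, early stopping on a 10% validation split, an L2 penalty of
10⁻⁴ and a fixed seed, all configurable. Continuous features (age,
CBC, smear) are z-scored before training; indicators stay 0/1.
Performance is reported as one-vs-rest AUROC per class from
out-of-fold predictions under stratified five-fold cross-validation,
weighted by class size; the final model is refit on the full cohort.

The 65-dimensional last-hidden-layer activations are the learned
patient representation. PCA (fit on all patients) gives 2-D
coordinates; each component's sign is fixed so its largest-magnitude
loading is positive, making results reproducible across linear-algebra
backends. The Pan-Myeloid Axis is the first principal direction of the
myeloid patients' 2-D coordinates (AML, MDS, MDS/MPN, MPN only),
oriented so mean(AML) > mean(MDS); if either anchor diagnosis is
absent the orientation falls back to a configured sign with a warning.
The axis projection rule is this package's own construction — a 1-D
summary of the 2-D embedding had to be made concrete — and both
fit-on-all and fit-on-myeloid variants of the 2-D step are supported,
with fit-on-all 2-D / myeloid-subset 1-D as the default.

Gene variables are placed on the axis at the unweighted mean position
of their carriers. Phenotype features are placed at the
carrier-value-weighted mean of patient positions, with each feature
min-max scaled to [0, 1] to serve as weights; this is an
interpretation (a feature sits where its high values concentrate), and
constant features are excluded. Orders along the axis are ascending
with alphabetical tie-break, so reversing the axis exactly reverses
every order.

Stability: B stratified-by-diagnosis bootstrap resamples with
replacement, full pipeline rerun per replicate (including network
retraining with an independent seed, so replicates are fully
independent repetitions), Kendall τ for every replicate pair on the
items shared by the pair, summarized by the mean and a 2.5/97.5
percentile interval. With resampling disabled the replicates are
identical reruns and all τ equal 1, which doubles as a determinism
check. At the default design and cohort size the bootstrap mean τ is
≈ 0.92 for feature order and ≈ 0.78–0.85 for gene order; the gene
value is limited by the fine within-cluster spacing of the planted
design relative to centroid sampling noise, not by pipeline
instability (retraining-only τ ≈ 0.96).

## Risk stratification

The 2017 ELN genetic-risk table is encoded declaratively in
`data/eln2017_rules.yaml` (favorable/adverse cytogenetic lesions,
always-adverse genes, genes adverse-unless-favorable-subtype) with the
NPM1 × FLT3-ITD allele-ratio interplay and CEBPA-biallelic logic in
code. Precedence is adverse > favorable > intermediate, except that
RUNX1/ASXL1 do not count as adverse alongside a favorable subtype;
contradictory inputs (e.g. a favorable fusion plus a complex karyotype)
resolve by that precedence and are logged.

Axis gene groups: the leftmost cluster block is L unconditionally; ML,
MR and R require a myeloid mutation rate above 1% (configurable),
otherwise the gene falls to "other". Mutation loads count variant
events in the union of the named groups — two variants in one gene
count twice (a gene-level toggle exists), and genes already consulted
by the ELN class are deliberately counted again, keeping the two
dimensions of the enhanced scheme independent. The enhanced grouping
and the MDS-EB High/Low split both use the load threshold 2 (strictly
greater is "high"). Complete remission is disease-specific: AML, MRD
< 0.1% by flow cytometry; MDS-EB, post-treatment marrow blasts ≤ 5%
and a relative decrease ≥ 50%.

Outcome evaluation: AUROC uses the ordinal group index as the score
(negated so that lower-risk groups predict remission). Logistic models
are fit by maximum likelihood with two-sided Wald p-values; on perfect
separation the fit falls back to an L2-penalized solution and is
flagged, with p-values reported as missing rather than fabricated.
Kaplan–Meier standard errors use the Greenwood formula. Concordance is
computed over risk-discriminating pairs only (pairs with tied group
scores are excluded rather than counted half-concordant), so a score
that perfectly separates two groups with non-overlapping survival
reaches exactly 1; with only three distinct scores this convention
differs from the ties-as-½ variant by a roughly constant compression
toward 0.5. Pairwise group comparisons use the two-sided Wald test of
a univariate Cox model on the group indicator. The adult de-novo AML
analysis subset (age > 16, non-M3, de novo, standard induction, with
optional exclusion of AML-MRC and secondary-type cases defined by the
eight splicing/chromatin genes) is a composable set of predicates.

## Synthetic cohort generator

The generator emulates the analysis' assumed structure, with defaults
chosen as the study conditions: per-disease sizes AML 388, CML 27,
MDS 209, MDS/MPN 36, MPN 70, ALL 321, CLL 52, MM 89 (total 1,192);
five planted gene clusters — four spanning an axis gradient from
AML-enriched (R: anchor prevalence 0.45 in AML falling to 0.04 in MPN)
to MPN/MDS-enriched (L: 0.55 in MPN, 0.03 in AML) plus a lymphoid
cluster — and four karyotype clusters (favorable-AML, adverse,
t(9;22)-CML, t(12;21)-ALL). Genes within a gradient cluster do not
share an identical prevalence vector: each interpolates up to 30% of
the way toward the adjacent cluster's anchor, so the gene order along
the axis is identifiable rather than exchangeable (with identical
vectors the within-cluster order would be meaningless and order
stability untestable). Cluster anchors remain the planted cluster
truth; per-gene vectors are recorded in the ground-truth object.

Phenotypes are diagnosis-specific baselines (fixed design constants on
a z-score-like scale, separation multiplier 3 — large enough that the
diagnosis classes are separable, which is what the classifier
acceptance check requires) plus linear cluster-load effects (e.g.
marrow blasts +3 per R-cluster event, platelets −2 per R and +2 per L
event) and unit Gaussian noise. Age is a pediatric/adult mixture with
per-disease pediatric fractions (AML 17%, MDS 5%, ALL 60%, …);
pediatric ages are uniform on [1, 16], adult ages normal(55, 15)
truncated at 17. CR follows a logistic model (intercept 1.0, −0.3 per
decade over 50, −0.8 per ELN class step, log 0.25 for R+MR load > 2 —
an odds ratio of 0.25 for high mutation load); MDS-EB CR uses
log 4 for L+ML load > 2. Survival is exponential per enhanced group
with hazards 0.5/1.0/2.0 per 1,000 days and administrative censoring
at 3 years. Continuous features go missing independently at rate 5%.

What the generator does **not** emulate: linkage between karyotype
lesions (complex karyotypes arise lesion-wise independently),
co-mutation structure beyond cluster membership, measurement units and
physiologic ranges of CBC/smear variables (they live on an abstract
standardized scale), VAF clonal architecture, disease-phase effects,
and non-administrative censoring. Passing tests therefore demonstrate
that each stage recovers the structure it assumes when that structure
is present — not that real cohorts satisfy those assumptions.

The raw variant table generator plants calls on both sides of every
filter threshold (Q 19/20, depth 29/30, VAF 0.019/0.02/0.45/0.46,
COSMIC 1/2, laboratory recurrence 0.10/0.11, population frequency
0.009/0.011, panel-of-normals hits with and without rescue) and labels
each call by construction, so the filter can be checked decision by
decision without re-deriving the labels from the filter itself.

## Problem sizes and numerical choices

The test suite and the reproduction script run the sampler exactly at
its default sweep counts (5,000 + 500) on planted designs of 15
aberrations, the closed-form comparison with 20,000 retained sweeps,
and the embedding checks on the full 1,192-patient default cohort with
a B = 20 bootstrap; the CR-model comparison uses an AML-only cohort of
2,600 so the evaluable analysis subset reaches ≈ 2,000. These sizes
are the package's chosen balance between statistical resolution and a
suite that runs in about a minute. Sub-seeds for independent stages
are derived affinely from the user seed modulo 2³¹. Degenerate inputs
are handled explicitly: empty DP clusters draw from the prior,
zero-carrier aberrations are excluded from centroids with a warning,
zero-variance features yield missing correlations, contingency tables
with an empty margin yield missing p-values, and survival groups
without events are skipped in pairwise comparisons.

## Known limitations

The ELN encoding covers the genetic-risk table's main lesions but not
every footnote of the 2017 recommendation (e.g. the low-allelic-ratio
FLT3-ITD nuance within NPM1-mutated favorable is implemented, but
in-frame bZIP specificity for CEBPA is not modelled beyond the
single/double split). The axis construction fixes one of several
defensible 1-D projection rules. Bootstrap τ compares orders on the
items shared by each replicate pair, which slightly favours common
aberrations. The concordance tie convention is chosen for
interpretability of ordinal groups and differs from Harrell's
ties-as-½ variant. IPSS-R is consumed as an input score, never
recomputed from cytopenias.
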