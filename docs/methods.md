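# Methods

`plasmaclust` implements an unsupervised subtyping pipeline for cohorts with
plasma (blood) marker panels, regional brain phenotypes and clinical staging
labels. Subtypes are discovered **only** from the blood markers; brain
phenotypes and diagnosis enter afterwards, to characterise how each blood
profile interacts with disease stage. This note records the model, the
defaults, and the design decisions that were genuinely open.

## Data preparation

Subjects with missing required baseline fields are removed first, then any
marker column with a remaining missing value is dropped entirely, so the
analysis matrix is complete without imputation. Both filters are logged per
id. Regional volumes are divided by each subject's estimated intracranial
volume (ICV) to remove head-size effects. Markers are min-max scaled per
column to [0, 1]; a constant column is mapped to zeros with a warning (the
formula is 0/0 there). Scaling parameters come from the analysis cohort
itself — a single-cohort cross-sectional design, not a train/test split.
Whether ICV normalisation precedes or follows min-max scaling is immaterial
for the implemented statistics: the interaction tests are rank-based, and
ranks are invariant to both orderings. Volumes used in interaction tests are
ICV-normalised but not min-max scaled, for the same reason.

## Multi-kernel similarity learning

Each marker `m` contributes P = 15 Gaussian kernels (neighbour counts
k ∈ {30, 45, 50} × bandwidth multipliers σ ∈ {30, 35, 40, 45, 50}),

    K_mp(i, j) = exp(−(x_im − x_jm)² / (2 ε_ijm²)) / (ε_ijm √(2π)),
    ε_ijm = σ (μ_im + μ_jm) / 2,

with μ_im the mean distance from subject i to its k nearest neighbours in
marker m (self excluded, ties broken by subject index). For 172 markers this
is 2580 kernels. Grids are configuration; k is clamped to N−1 for small
cohorts. If a pair has ε = 0 (duplicate values) the smallest positive ε of
that marker is substituted; a fully constant marker yields flat kernels that
carry no information and receive vanishing weight.

The model solves

    min_{S,A,w}  −Σ w_mp K_mp(i,j) S_ij + γ tr(Aᵀ(I_N − S)A)
                 + μ Σ w_mp log w_mp + β‖S‖_F²
    s.t. AᵀA = I_C,  Σw = 1, w ≥ 0,  rows of S on the probability simplex,

by exact alternating minimisation:

* **A-step** — the C bottom eigenvectors of I − (S + Sᵀ)/2 (identical to the
  minimiser for the unsymmetrised trace, since tr(AᵀMA) depends only on the
  symmetric part of M).
* **S-step** — each row is the Euclidean projection onto the simplex of
  ((Σ w·K) + γ·AAᵀ)_i / (2β). This is the exact minimiser of the
  row-separable quadratic; schemes based on the eigenvector distance matrix
  D_A differ only by a column offset and a doubled γ and reach the same
  family of stationary points, but the exact form guarantees a monotone
  objective.
* **w-step** — the entropy-regularised closed form w_q ∝ exp(⟨K_q, S⟩/μ).

Because every step is an exact coordinate minimisation, the objective is
non-increasing once all hyperparameters are fixed; the recorded
`objective_trace` starts at that point.

### Kernel standardisation and auto-scaled hyperparameters

The density prefactor 1/(ε√2π) makes the overall scale of a kernel depend on
the marker's local density, not on whether it separates subtypes; left
uncorrected, the softmax over alignments ⟨K_q, S⟩ selects kernels by scale.
Inside the fit each kernel is therefore divided by its mean off-diagonal
value, so kernels compete on shape. (The reference MATLAB implementation of
this family of methods likewise normalises kernels before combining them.)
The stored bank keeps the unnormalised values; `normalize_kernels=False`
restores the literal objective.

Defaults, all exposed in `Hyperparams` (units: mean off-diagonal kernel value
≈ 1 after standardisation):

* `beta = 10 × mean-offdiag` — controls the sparsity of the projected rows;
  this value keeps each subject connected to a few dozen neighbours. Much
  smaller values collapse rows to near-point masses, fragmenting the
  similarity graph and degrading the embedding.
* `gamma = mean-offdiag × N / C` — the block-reinforcement term γ·AAᵀ then
  has entries of the same order as the kernel sum inside the S update
  (AAᵀ ≈ C/N within a block).
* `mu_entropy = 1.5 × std(⟨K_q, S⟩)` — the alignment spread grows by an
  order of magnitude while S sparsifies, so μ adapts during a 10-cycle
  burn-in and is then frozen. The factor 1.5 leaves weight spread over
  dozens of kernels concentrated on the informative markers; much smaller
  collapses w onto one kernel, much larger keeps it uniform and dilutes the
  signal. These factors were fixed once by simulation on planted cohorts and
  are not data-dependent beyond the stated statistics.

Initialisation is deterministic: uniform w, S = row-normalised average
kernel, A from its Laplacian. The fit contains no randomness, so it is
permutation-equivariant up to eigendecomposition degeneracies.

## Choosing the number of clusters

Two heuristics, applied sequentially as in the study design ("estimate, then
validate"):

1. **Eigengap** — eigenvalues of the normalised Laplacian of the average
   kernel; C well-separated blocks give C near-zero eigenvalues followed by
   a gap, scored as λ_{C+1} − λ_C.
2. **Elbow** — the model is fitted at the eigengap's proposal, its t-SNE
   embedding computed, and k-means dispersion W(C) scored as the drop ratio
   W(C−1)/W(C) over the candidate range (second differences of W are
   geometry-dependent for tight well-separated islands; the drop ratio peaks
   reliably at the last substantial split).

Each heuristic reports its two best candidates; `select_num_clusters` picks
the eigengap-preferred candidate confirmed by the elbow, then moves to an
integer-multiple refinement when both heuristics also support it — a
C-block structure produces near-zero Laplacian eigenvalues at every
balanced coarse grouping of its blocks, so a divisor of the true C
routinely outranks it. On pure-noise data both score vectors are flat and
no C is strongly preferred.

## Embedding and labels

t-SNE is run on the distance matrix d = max(S̄) − S̄ (S̄ the symmetrised
learned similarity) through scikit-learn's precomputed-distance interface,
perplexity min(30, (N−1)/3), fixed seed; k-means with multiple restarts on
the embedding gives the final labels. Supplying the similarity through a
monotone distance transform (rather than as a precomputed affinity) is a
deliberate trade: it keeps a single standard, well-tested t-SNE backend.
The number of embedding dimensions is a parameter (default 2).

## Bootstrap stability

N subjects are resampled with replacement; the chosen method (the full
kernel-learning pipeline, Euclidean k-means, or uniform random labels) is
refitted on the resample; clusters are matched one-to-one to the reference
clusters by maximal total Jaccard (optimal bipartite assignment, ties broken
toward the lowest reference index) and the per-reference-cluster Jaccard is
averaged over replicates (default n_boot = 100). Jaccard is computed on sets
of unique subject ids, and reference clusters are restricted to subjects
present in the resample, so out-of-sample subjects do not mechanically
depress the score. J(∅, ∅) is defined as 0 with a warning. A resample with
fewer than C distinct subjects is redrawn and logged.

## Marker profiling

Marker importance is the sum of the P kernel weights of that marker
(inheriting the simplex constraint: nonnegative, summing to 1 over markers);
markers are ranked with deterministic tie-breaks and the top 10 define the
cluster profiles. Profiles are described on min-max-scaled values: per
cluster mean, SD, and direction (higher/lower than the population mean).
One-way fixed-effects ANOVA across clusters validates each top marker at
p < 0.001; no further multiple-testing correction is applied on this screen,
matching the single-threshold design.

## Interaction analysis

Three comparison schemes per cluster and phenotype:

* **whole_cluster** — cluster members vs everyone else (diagnosis ignored);
* **diagnostic_group** — two diagnostic groups within the cluster;
* **diagnostic_interaction** — subjects of one diagnosis inside the cluster
  vs subjects of the same diagnosis outside it.

Differences are tested with a two-sided Mann-Whitney U (exact distribution
when the combined sample is ≤ 25 and tie-free, otherwise the normal
approximation with tie and continuity correction; no mid-p). Because group
sizes are unequal, the observed p is corrected against a permutation null:
cluster labels are shuffled **within each diagnostic stratum** — the unique
scheme that preserves every cluster size and every cluster × diagnosis cell
count exactly — and the observed p is significant only if it lies at or
below the α-quantile (default 5%) of the n_perm = 1000 permuted p-values
(the quantile uses linear interpolation). Diagnosis is treated as an
observed covariate: permuted groups are re-derived from the permuted cluster
labels while diagnosis stays fixed. Stratified shuffling is used for all
three schemes (an unstratified option exists for the whole-cluster scheme,
whose description does not force stratification). Comparisons with an
observed group below 2 subjects are reported as skipped rows, not silently
dropped.

## Synthetic cohorts

The generator emulates the target study population so every stage is
testable without restricted data. Defaults: 298 subjects; 172 markers on
arbitrary raw scales (random per-marker location/scale, so min-max scaling
is exercised nontrivially) of which 10 are informative; four subtypes with
proportions 82/77/61/78 per 298; diagnosis CN/MCI/AD drawn independently of
subtype with proportions 52/161/85 per 298; 39 regional volumes of which
half atrophy monotonically CN → MCI → AD and 6 additionally carry a
cluster × stage interaction; lognormal ICV; demographics (age, sex,
education, APOE4, MMSE) with stage-dependent means typical of a memory
clinic cohort.

Design choices:

* **Cluster signatures** are rows of a balanced Hadamard sign code over the
  informative markers (each cluster shifts each informative marker up or
  down by `marker_shift` noise-SDs; default 3). The code guarantees that
  every pair of subtypes differs on about half the informative markers.
  Arbitrary random sign patterns can place two subtypes at Hamming
  distance 1, i.e. differing on a single marker — a partition that no
  marker-wise similarity method can resolve reliably, which would make the
  planted truth unidentifiable rather than the method wrong. Effect sizes
  are free parameters of the generator, not calibrated to any real cohort.
* **Interaction regions** scale the stage effect by a cluster-specific
  factor 1 + e·(±1), alternating by cluster index (default e = 1: even
  clusters double the atrophy effect, odd clusters cancel it). With an even
  number of clusters every cluster then differs from the rest-of-population
  average by the same margin.
* **Seeding** — one master seed; the seven ingredient streams (signatures,
  cluster assignment, markers, diagnosis, volumes, ICV, demographics) are
  spawned from `SeedSequence(seed)` in a fixed order, so cohorts are
  byte-identical across runs and platforms.

What the generator does **not** emulate: longitudinal visits, missingness
mechanisms, marker correlation beyond the planted blocks, cortical surface
geometry, and realistic assay noise distributions. Passing tests therefore
demonstrate that the pipeline recovers structure of the planted kind at the
planted strength; they do not certify performance on real assay panels.

## Numerical choices and degenerate inputs

Simplex projection uses the vectorised sort-and-threshold algorithm (shift
invariant, exact). Convergence is declared when the relative objective
change drops below `tol = 1e-5` (default `max_iter = 40` cycles after a
10-cycle burn-in). Structure-free data converges without error and is
reported as unstable by the bootstrap (low Jaccard), which is the intended
signal. k-means uses `n_init` restarts with a fixed seed; t-SNE inherits its
seed from the caller, so labels are reproducible end to end.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full-size configuration
(N = 298, M = 172, 2580 kernels) for kernel cardinality, constraint
verification, cluster recovery, model selection and profiling; bootstrap
stability uses a reduced cohort (N = 120, M = 40, C = 3, n_boot = 50) and
the permutation-null calibration uses 200 synthetic phenotypes at
n_perm = 200, sizes chosen to keep the whole battery in the minutes range
on a single CPU while leaving every Monte-Carlo tolerance at its stated
3-SD width.

## Known limitations

* Per-marker 1-D kernels cannot separate subtypes that differ on very few
  markers (see the signature design above); multivariate kernels are out of
  scope.
* The σ grid {30…50} is far above the scale of min-max-scaled data and
  yields nearly flat Gaussian factors; the separation signal survives in
  the adaptive-bandwidth prefactor and the KNN structure, and the default
  grid is kept for fidelity, but `REFERENCE_SIGMA_GRID` (σ ∈ [1, 2]) is
  provided for users who want sharper kernels.
* Covariate-adjusted interaction testing (age, sex) is not implemented; the
  permutation correction addresses group-size imbalance only.
* No FDR control across phenotypes; each comparison is corrected against
  its own permutation null.
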