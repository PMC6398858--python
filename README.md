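# plasmaclust

Unsupervised subtyping of disease cohorts from blood-marker panels, with
bootstrap stability assessment, marker-profile discovery, and
permutation-corrected interaction analysis against brain phenotypes.

## What problem this solves

Neurodegenerative cohorts (the motivating case is Alzheimer's disease) are
heterogeneous in ways that clinical stage labels do not capture. Given a
subjects × markers plasma panel, `plasmaclust` finds natural subgroups
**without using diagnosis or imaging**, then asks two questions: which
markers define each subgroup's blood profile, and does belonging to a
subgroup change how brain phenotypes (e.g. ICV-normalised subcortical
volumes) evolve across disease stages (CN → MCI → AD)?

The clustering core is multi-kernel similarity learning (CIMLR-style): each
marker `m` contributes P = 15 Gaussian kernels K_mp with KNN-adaptive
bandwidths ε_ijm = σ(μ_im + μ_jm)/2, and the method solves

    min_{S,A,w}  −Σ_{ijmp} w_mp K_mp(x_im, x_jm) S_ij
                 + γ tr(Aᵀ(I_N − S)A) + μ Σ w_mp log w_mp + β‖S‖_F²
    s.t. AᵀA = I_C,  Σ w_mp = 1, w_mp ≥ 0,  Σ_j S_ij = 1, S_ij ≥ 0,

learning a row-stochastic similarity S with a C-block structure, kernel
weights w (whose per-marker sums rank marker importance), and an auxiliary
orthonormal A. Labels come from k-means on a t-SNE embedding of S. Cluster
stability is scored by bootstrap resampling with optimal Jaccard matching
(J(A,B) = |A∩B|/|A∪B|) against random and Euclidean k-means baselines.
Interaction analysis runs Mann-Whitney U tests under three schemes
(whole-cluster, diagnostic-group, diagnostic-interaction) and corrects each
observed p against the 5th percentile of its strata-preserving permutation
null (cluster labels shuffled within diagnostic strata, preserving all
cluster × diagnosis cell counts).

Because the motivating cohort (ADNI) is access-restricted, the package
ships a first-class synthetic-cohort generator with planted subtype
signatures, diagnosis-independent cluster assignment, and planted
cluster × stage interaction effects on selected regions — every stage of
the pipeline is testable end to end. See `docs/methods.md` for the model
details and design decisions.

## Worked example

```python
from plasmaclust import (CohortConfig, generate_cohort, minmax_scale,
                         build_kernel_bank, fit_cimlr, Hyperparams,
                         embed_and_cluster, marker_importance)
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(CohortConfig(seed=7))   # 298 subjects, 172 markers
X = minmax_scale(cohort.marker_matrix)
bank = build_kernel_bank(X)                      # 2580 kernels
model = fit_cimlr(bank, Hyperparams(n_clusters=4))
embed_and_cluster(model, seed=0)

print("kernels:", bank.n_kernels)
print("ARI vs planted truth:",
      round(adjusted_rand_score(cohort.true_cluster, model.labels), 3))
print(marker_importance(model, bank).head(3).to_string(index=False))
```

Output:

```
kernels: 2580
ARI vs planted truth: 1.0
 marker_id  importance  rank
marker_007    0.226662     1
marker_001    0.079902     2
marker_003    0.077667     3
```

The adjusted Rand index of 1.0 means the learned labels reproduce the
planted 4-subtype partition exactly, and the top-ranked markers are among
the 10 informative ones the generator shifted (markers 000–009).

The same pipeline runs from the shell:

```bash
plasmaclust simulate --seed 7 --out cohort/
plasmaclust run-all --out run/ --seed 7 --plots
```

`run/` then contains `labels.csv`, `importance.csv`, `profiles.csv`,
`stability.csv`, `interactions.csv`, a `manifest.json` with the seeds and
config hash, and (with `--plots`) the similarity heatmap, embedding scatter
and importance bar chart.

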