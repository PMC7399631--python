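# triplenet

Multilevel correlation analysis of couplings among the three large-scale
brain networks most often implicated in mild traumatic brain injury (mTBI):
the default mode network (DMN), the salience network (SN), and the central
executive network (CEN).

## The scientific problem

Resting-state fMRI studies of acute mTBI compare a patient group against
matched controls on several levels of description at once:

1. **Edgewise functional connectivity.** Each subject contributes a set of
   independent-component time courses (here, K = 7 components spanning
   DMN, SN, and CEN). For every component pair (i, j) the Pearson
   correlation r_ij is Fisher-transformed, Z_ij = arctanh(r_ij), and the
   K(K−1)/2 = 21 edges are compared between groups with two-sided Wilcoxon
   rank-sum tests, Benjamini–Hochberg corrected across the 21 edges. The
   surviving edges form the cohort's *feature set*, whose stability is
   quantified by leave-one-out jackknife: λ = (number of replicates whose
   feature set equals the full-sample feature set) / n.
2. **Graph descriptors.** Each subject's |Z| matrix is thresholded to a
   fixed edge density (strongest edges kept), and weighted global
   clustering (Onnela) and characteristic path length (edge length = 1 /
   weight) are computed at each density in a grid, then aggregated as the
   range-normalized area under the descriptor-vs-density curve (AUC).
   Group AUCs are compared by t-test with BH correction across
   descriptors.
3. **Regional homogeneity (ReHo).** Per-voxel Kendall's coefficient of
   concordance W over the 26-connected neighborhood, grand-mean scaled,
   with a voxelwise two-sample t-test corrected by a max-cluster-size
   permutation null.
4. **Brain–behavior association.** Pearson correlation of feature-set edge
   strength with executive function (NIH Toolbox DCCS, normed mean 100 /
   SD 15), plus OLS group regressions and a Yates-corrected chi-square for
   categorical demographics.
5. **Anatomical control.** Per-ROI fractional anisotropy (FA) compared by
   Mann–Whitney U with BH correction over ROIs.

Subject-level imaging data are rarely shareable, so the package includes a
**synthetic cohort generator** that emulates the statistical structure the
analysis assumes — group-specific Fisher-Z edge distributions with a
designated DMN–SN edge effect, behavior coupled to that edge through a
Gaussian copula, ReHo phantoms with controllable local coherence, and null
FA tables — making every stage testable end to end.

## Worked example

```python
import numpy as np
import triplenet as tn
from triplenet.association import feature_behavior_correlation

# 32 patients + 37 controls, 7 components x 200 timepoints each
subjects, behavior = tn.generate_cohort(tn.CohortConfig(seed=3))
matrices = [tn.connectivity_matrix(s) for s in subjects]
labels = [s.group for s in subjects]

table, fs = tn.edgewise_test(matrices, labels)
print(table.sort_values("p_raw").head(3))
print("feature set:", sorted(fs.edges))
stab = tn.jackknife_stability(matrices, labels)
print("lambda:", stab.lam, "replicates:", stab.n_replicates)
```

prints

```
  edge    p_raw    p_adj  direction  mean_control  mean_patient
(0, 4) 0.000273 0.005727          1      0.015943      0.225496
(1, 4) 0.100492 0.776015          1     -0.216046     -0.189196
(3, 6) 0.110859 0.776015          1     -0.203388     -0.176431
feature set: [(0, 4)]
lambda: 1.0 replicates: 69
```

Edge (0, 4) is the DMN–SN pair carrying the injected group difference
(patients hyperconnected, direction +1), it survives FDR (p_adj = 0.0057),
and all 69 leave-one-out replicates reproduce the same feature set
(λ = 1.0). Correlating that edge with executive function in patients:

```python
z_pat = np.array([m.z[0, 4] for m, g in zip(matrices, labels) if g == "patient"])
dccs  = np.array([b.dccs for b in behavior if b.group == "patient"])
assoc = feature_behavior_correlation(z_pat, dccs)
print(f"r={assoc.r:.3f} p={assoc.p:.4f} n={assoc.n}")
```

```
r=0.574 p=0.0006 n=32
```

Not every simulated cohort detects the edge: at the default effect size
(patient mean Z = 0.201 vs control 0.037, SDs 0.18 / 0.22) the measured
per-cohort detection rate after FDR is roughly 0.44, so single-cohort
results vary by seed exactly as they would across real studies.

The same pipeline runs from the command line:

```bash
triplenet run --out run1 --seed 3
triplenet report --run-dir run1
```

```
feature set: [[0, 4]] (lambda = 1.000)

graph_comparison.tsv:
 descriptor  mean_control  mean_patient         t    p_raw    p_adj
 clustering      0.410014      0.397267 -0.917101 0.362379 0.724758
path_length      3.900324      3.959429  0.334550 0.739009 0.739009

demographics.tsv:
         variable     patient      control        p
              age  28.8 (7.5)   31.5 (8.5) 0.158709
        education  14.7 (2.4)   16.0 (1.9) 0.012691
             dccs 99.8 (15.8) 101.9 (11.8) 0.533633
sex (female/male)        5/27        17/20 0.014845
```

Individual stages are exposed as subcommands (`simulate`, `qc`, `clean`,
`dualreg`, `match`, `connect`, `detect`, `graph`, `reho`, `associate`,
`fa-roi`); see `triplenet --help`.

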