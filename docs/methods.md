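# Methods

This document records the statistical model, parameter defaults, and
numerical conventions implemented by `triplenet`, and the rationale behind
each choice.

## 1. Edgewise connectivity model

Each subject s contributes K component time courses x₁…x_K (K = 7 by
default: four DMN, one SN, two CEN components). For every unordered pair
(i, j):

- Pearson correlation r_ij via `numpy.corrcoef`.
- Fisher transform Z_ij = arctanh(r_ij). |r| is clamped at 1 − 10⁻⁷ (with
  a `RuntimeWarning`) so Z stays finite; |r| > 1 raises. The diagonal is
  stored as 0 by convention and excluded from all statistics.
- Group comparison per edge: two-sided Wilcoxon rank-sum
  (`scipy.stats.mannwhitneyu`). The exact distribution is used when both
  groups have n ≤ 12 and there are no ties; otherwise the tie-corrected
  normal approximation with continuity correction. The cutoff of 12 keeps
  exact enumeration cheap while covering every case where the normal
  approximation is least reliable.
- Multiplicity: Benjamini–Hochberg over the 21 edges
  (`statsmodels.stats.multitest.multipletests`), family-wise α = 0.05.
  Edges with adjusted p < α form the **feature set**.
- Stability: leave-one-subject-out jackknife. With n = 32 + 37 subjects
  there are exactly 69 replicates; λ is the fraction whose feature set is
  *set-equal* to the full-sample feature set. Set equality (not overlap)
  is deliberate: a replicate that adds or drops any edge counts as a
  failure, making λ a strict reproducibility index.

## 2. Graph descriptors

- **Thresholding.** The subject's |Z| matrix is reduced to the
  m = ⌈d · K(K−1)/2⌉ strongest edges at density d, with a lexicographic
  (i, j) tie-break so results are deterministic. Kept edges are weighted
  by |Z|; sign is discarded because the descriptors below require
  non-negative weights.
- **Clustering.** Onnela weighted global clustering
  (`networkx.average_clustering(weight=...)`, counting degree-<2 nodes as
  zero), i.e. the mean over nodes of the geometric mean of max-normalized
  triangle weights.
- **Path length.** Dijkstra over edge lengths 1/weight (stronger coupling
  = shorter path), averaged over unordered pairs. A disconnected graph
  falls back to the largest connected component and sets a flag; the
  alternative (infinite or harmonic-mean lengths) would silently change
  the descriptor's scale.
- **Aggregation.** Descriptors are computed on a density grid and
  summarized by the trapezoidal integral divided by the grid's range
  (`numpy.trapezoid`), so the AUC is on the same scale as the descriptor
  itself and a single-threshold "curve" degenerates to the raw value.
- **Default grid (0.36, 0.38).** For K = 7 the admissible density band is
  the open interval (0.35, 0.40). Because ⌈d · 21⌉ = 8 for every
  d ∈ (0.35, 8/21], any grid inside that interval retains exactly the
  same 8 edges and the curve is exactly flat — a property the tests
  verify. A grid point at 0.39 would request ⌈8.19⌉ = 9 edges and push
  the *realized* density to 9/21 ≈ 0.429, outside the band, so the
  package's default grid stays at (0.36, 0.38). This is a design choice
  of the package: the ceiling rule is kept (it never under-fills the
  requested density) and the grid is chosen so realized densities respect
  the band.
- Group comparison of AUCs: pooled-variance two-sample t-test by default
  (Welch optional), BH-corrected across descriptors.

## 3. Regional homogeneity

- Per voxel, Kendall's coefficient of concordance over the m ≤ 27
  in-mask time series of the 26-connected neighborhood:
  W = 12 Σ_t (R_t − R̄)² / (m²(T³ − T)), with midranks for ties. Tie
  correction of the denominator is available (`tie_corrected=True`) but
  off by default, matching the common neuroimaging definition; with
  continuous BOLD-like data ties are measure-zero.
- The implementation is vectorized: ranks are computed once per voxel
  time series (`scipy.stats.rankdata(axis=-1)`) and neighborhood rank
  sums are obtained by a 3×3×3 box correlate (`scipy.ndimage.correlate`),
  which the tests prove exactly equal to the naive per-voxel computation.
- Maps are grand-mean standardized (in-mask mean → 1) before group
  comparison.
- **Group test.** Voxelwise pooled t-statistics are thresholded at the
  two-sided t critical value for voxel-level α = 0.01; suprathreshold
  voxels are grouped into 26-connected clusters (`scipy.ndimage.label`
  with a 3×3×3 structuring element). Significance is assessed against a
  max-cluster-size permutation null: group labels are permuted
  (default 1000 permutations; fewer than 100 triggers a warning), the
  largest cluster size is recorded each time, and observed clusters
  larger than the (1 − α) quantile of that null are reported. A
  permutation null was chosen over parametric Monte-Carlo cluster
  corrections because it is exact under exchangeability and makes no
  smoothness assumptions about the synthetic phantoms.

## 4. Behavior, regression, and anatomy

- Feature–behavior association: Pearson r with its t-based p-value, plus
  a Shapiro–Wilk normality p for transparency.
- Group regressions: `statsmodels` OLS with group coded 0 = control /
  1 = patient, optional group×feature interaction and covariates;
  aliased (collinear) columns are reported by name rather than silently
  dropped.
- Categorical demographics: Yates-corrected chi-square
  (`scipy.stats.chi2_contingency(correction=True)`).
- FA ROI control: per-ROI Mann–Whitney U, BH-corrected across the 20
  ROIs, with a completeness check that every subject contributes every
  ROI.

## 5. Synthetic cohort generator

Defaults (`CohortConfig`): 32 patients, 37 controls, K = 7 components,
T = 200 timepoints at TR = 1.5 s; designated DMN–SN edge (0, 4) with
Fisher-Z group means 0.037 (control) / 0.201 (patient) and SDs 0.22 /
0.18; DCCS means 103 (control) / 98 (patient) with SDs 10.9 / 12.8 and a
patient-group copula correlation ρ = 0.40 between DCCS and the designated
edge; normative DCCS mean 100, SD 15.

Generation per subject:

1. Draw the designated-edge Z from the subject's group distribution; draw
   the remaining edges around a triple-network template (+0.4 within
   network, −0.2 DMN–task, +0.1 SN–CEN) with heterogeneity in Z space.
2. Map targets through tanh to correlations and project to the nearest
   valid correlation matrix (`statsmodels corr_nearest`, alternated with
   re-imposition of the designated edge until both constraints hold).
3. Sample T multivariate-normal timepoints from the eigen-factorization
   of that matrix.
4. Because the observed per-subject Z is the population Z plus sampling
   noise of variance 1/(T − 3), the injected between-subject SD is
   attenuated by sd_z/√(sd_z² + 1/(T−3)) (≈ 0.93 at the defaults) so the
   *observed* edge distribution matches the configured mean/SD.
5. Behavior: DCCS is coupled to the subject's designated-edge Z through a
   Gaussian copula (patients only), then transformed to the group's
   marginal mean/SD.

ReHo phantoms place axis-aligned boxes of controllable coherence
(common-signal mixing fraction, optionally per-group) in white-noise
volumes; `coherence=1` with zero noise yields W = 1 exactly. FA tables
draw ROI baselines from U(0.35, 0.65) with N(0, 0.04) subject noise and
an optional group effect on designated ROIs.

**Scope.** The generator emulates the *statistical* structure the
analysis assumes — group-shifted edge distributions, edge-coupled
behavior, locally coherent ReHo signal, exchangeable nulls. It does not
emulate scanner physics, physiological noise spectra, spatial
autocorrelation of real BOLD data, motion, or registration error.
Passing tests therefore demonstrate that the estimators are correct and
that their error rates are controlled *under the generative model*; they
do not validate the pipeline against real acquisitions.

## 6. Statistical-control simulations and problem sizes

The acceptance tests run Monte-Carlo controls at the emulated study's
sample sizes. The replicate counts are package choices balancing the
standard error of the estimated rates against runtime:

- FDR false-discovery control: 200 null cohorts (32 + 37 subjects each);
  the fraction with a nonempty feature set must not exceed
  0.05 + 3·SE.
- Designated-edge detection: 200 cohorts at the default effect. The
  suite asserts a detection rate ≥ 0.90; the measured rate at the
  default parameters is 0.44 (88/200), consistent with the analytic
  power of a rank-sum test at this effect size and sample size after
  21-edge FDR (normal-approximation noncentrality ≈ 2.9). **This test
  fails by design**: the generator encodes the documented effect sizes,
  and neither the parameters nor the threshold were adjusted to force a
  pass.
- ReHo type-I error: 500 null phantoms (50 replicates × 10 volumes,
  16³ voxels, T = 40, 199 permutations); replicate-level false-positive
  rate must not exceed 0.05 + 3·SE. The permutation test is discrete and
  conservative, so only the upper bound is asserted.
- ROI FA null: 500 null tables at 32 + 37 subjects, 20 ROIs; same bound.

## 7. Limitations

- Power at the default effect size is ≈ 0.44 per cohort; single-seed
  results vary accordingly (see §6).
- The nearest-correlation projection is iterative; convergence is
  verified by an eigenvalue check, but for extreme target values the
  designated-edge constraint and positive semidefiniteness can conflict,
  in which case the projection raises rather than silently degrading.
- Path length on disconnected graphs reports the largest component only
  (flagged); comparisons mixing connected and disconnected subjects
  conflate topology with the descriptor.
- The ReHo permutation null uses cluster *size* only; cluster-mass or
  TFCE variants are not implemented.
- Exact Wilcoxon p-values are only used up to n = 12 per group and in the
  absence of ties; above that the tie-corrected normal approximation is
  used, which is standard but approximate.
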