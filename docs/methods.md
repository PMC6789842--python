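# Methods

`wpcna` implements a weighted protein co-expression network analysis
(WPCNA) workflow for small label-free proteomic cohorts spanning a
disease continuum (control → asymptomatic pathology → symptomatic
disease), from peptide-level quantification through network modules
and their clinical correlates. This note documents the models, the
defaults and why they were chosen, the synthetic benchmark, and the
numerical decisions that were genuinely open.

## Quantification

Protein groups are retained when supported by at least one unique
peptide and at least two peptide-spectrum matches. The spectral-count
threshold is applied cohort-wide (summed over samples and fractions);
a per-sample reading is also defensible but would make retention
depend on cohort size, so the cohort-wide rule is the default and is
exposed in configuration.

Protein abundance per sample is the arithmetic mean of the three most
intense peptides (top-3 / "top-n" label-free quantification). Proteins
observed with one or two peptides are averaged over what is available
and flagged with their peptide count rather than dropped, because the
group filter deliberately admits single-unique-peptide groups.
Zero or absent intensities are treated as missing, not as zero.

Membrane enrichment is profiled as log2((membrane + c)/(soluble + c))
spectral-count ratios with pseudocount c = 0.5, which keeps
single-fraction proteins finite without changing the sign of the
ratio. Proteins with fewer than 3 total counts are excluded. The
ranked list is cut into ten near-equal bins (sizes differ by at most
one; ties broken by protein identifier under a stable sort for
reproducibility).

## Covariate regression

Each protein's log2 abundance is modelled as
`abundance ~ group + age + sex + PMI`. Ordinary least squares is fit
on bootstrap resamples drawn with replacement *within* each clinical
group, so every draw preserves the group design exactly; the
covariate coefficients are aggregated by their median across draws (a
bootstrap-aggregated, outlier-resistant estimate) and the centered
covariate contribution is subtracted. The group term is never
subtracted, so diagnosis-related variance is preserved. Defaults:
1000 bootstrap draws, seed mandatory. Proteins with fewer complete
observations than model terms + 1 are passed through unadjusted with
a warning. Missing cells stay missing.

Rank-based "non-parametric" regression was considered and rejected as
the default: the median-over-bootstraps OLS keeps the adjustment an
exact linear function of the covariates (a property the tests
verify), which makes the procedure auditable and idempotent up to
bootstrap noise.

## Differential abundance

Per protein: one-way fixed-effects ANOVA over the three groups,
followed by Tukey's HSD for the three pairwise comparisons, with
Tukey–Kramer standard errors for unbalanced complete-case designs.
The studentized-range distribution comes from
`scipy.stats.studentized_range` (numeric integration); the test suite
checks its 5% critical points against published k = 3 tables and a
10⁶-draw permutation oracle. Reported effect sizes are directed mean
differences on the log2 scale, with the comparison order fixed
(AsymAD−control, AD−control, AD−AsymAD). Proteins with a Tukey p
below 0.05 in a comparison are counted as altered; no cross-protein
multiple-testing correction is applied at this stage by design.
Zero within-group variance with a between-group difference is
reported with the limit convention F → ∞, p → 0 and a flag.

## Network construction

The network stage consumes the regressed matrix, restricted to
complete cases (the topological overlap has no principled
missing-data extension; excluded proteins are logged).

* **Correlation** — biweight midcorrelation (bicor):
  u = (x − med)/(9·mad), weights (1 − u²)²·1[|u| < 1], correlation of
  the weighted, median-centered vectors. Rows with mad = 0 fall back
  to Pearson with a warning. Verified to 1e-12 against an
  independently coded single-pair oracle, with and without planted
  outliers.
* **Adjacency** — signed: a = ((1 + s)/2)^β with β = 11.5, so
  anti-correlated proteins are unconnected. `pick_soft_threshold`
  reports the scale-free fit R² and mean connectivity over candidate
  powers for users choosing β on their own data.
* **TOM** — topological overlap with the *mean* connectivity
  denominator: TOM_ij = (l_ij + a_ij)/((k_i + k_j)/2 + 1 − a_ij); the
  `min` denominator is available. Verified against a brute-force
  triple loop and the uniform-adjacency identity TOM_ij = a.
* **Tree cut** — average-linkage clustering of 1 − TOM, cut by a
  Dynamic-Hybrid-style procedure written for this package:
  1. the dendrogram is decomposed at a static height (99% of the
     height range above the lowest merge);
  2. each branch is recursively split wherever *both* children are
     candidates — at least `min_module_size` (20) leaves and a core
     scatter (mean of the lowest merge heights) below a deep-split
     dependent threshold. The deepSplit presets 0–4 map to maximum
     relative core scatter {0.25, 0.35, 0.45, 0.55, 0.65} on the
     scale between the 5th-percentile merge height and the static
     cut. Because core scatter is computed from a subtree's lowest
     merges, a subtree failing the criterion provably contains no
     tight cluster and dissolves into unlabeled leaves; this is what
     keeps unstructured proteins out of modules.
  3. the deepest candidate node of each branch (the module core) is
     accepted; stragglers attached above it are left unlabeled;
  4. a medoid (PAM-like) stage grows modules outward: an unlabeled
     protein joins its nearest module (by average dissimilarity) when
     that dissimilarity is at most 0.94 of its average dissimilarity
     to the whole dataset — unstructured proteins sit at ratio ≈ 1
     and are never admitted. With `pam_respects_dendro` (default)
     eligibility is restricted to modules on the protein's static
     branch.
  The scatter presets and the 0.94 admission ratio are algorithmic
  constants calibrated on the synthetic benchmark; they are not
  exposed as tuning knobs.
* **Eigenproteins** — first right-singular vector of the
  row-standardized module submatrix, sign-oriented to correlate
  positively with the module mean profile (so "up in disease" is
  readable directly), with variance explained σ₁²/Σσ².
* **kME** — Pearson correlation of every protein with every
  eigenprotein; p-values from the t transform with n − 2 df, checked
  against a permutation oracle.
* **Merging** — modules whose eigenprotein dissimilarity
  1 − cor(ME_a, ME_b) falls below 0.07 are merged (average-linkage
  grouping of eigenproteins cut at the threshold), eigenproteins
  recomputed, iterated to a fixed point. 0.07 is stricter than common
  practice (0.15–0.25); it is the configured default, not an
  endorsement.
* **Reassignment** — one pass: a protein moves to its best-kME module
  when its own-module membership is not significant (p > 0.05) and
  the alternative is (p < 0.05). Unassigned proteins with a best-kME
  p below 0.05/k (Bonferroni over the k modules, since the best of k
  correlations is selected) are adopted into that module. Final
  labels are re-ranked by size (M1 largest).

## Enrichment and trait association

Module gene symbols (uppercased, deduplicated) are tested against
gene sets by the hypergeometric upper tail (one-tailed Fisher), with
Benjamini–Hochberg FDR across all module × set pairs of a collection.
The background is the quantified proteome, not the genome — the
standard over-representation choice when the measured universe is a
small biased subset of the genome. Cross-network overlap applies the
same test to module pairs of two partitions on the intersection of
their gene universes and reports signed −log10(FDR p), positive only
where the overlap exceeds its expectation.

Module–trait association uses bicor of eigenproteins with diagnosis
(coded ordinally control = 0, AsymAD = 1, AD = 2), CASI, CERAD and
Braak, with t-based p-values; dichotomous columns (sex, binary
diagnosis codings) degrade the median/MAD machinery and automatically
fall back to Pearson. CASI is correlated as measured (higher =
better cognition), so a negative r reads as "higher module expression
with worse cognition". Kruskal–Wallis (tie-corrected) tests each
eigenprotein across the three groups. Stars mark raw p < 0.05 / 0.01;
an FDR column is additionally emitted for the module × trait grid.

## Synthetic benchmark

The generator emulates the statistical structure the analysis
assumes, not raw spectra: 3 groups × 6 samples; 8 planted modules of
sizes 120, 100, 80, 60, 50, 40, 30, 25 spanning six disease-stage
archetypes (stable; progressive increase/decrease; early decrease
then stable; transient up/down), with per-module latent factors =
archetype group means (amplitudes up to ±1 log2 unit) plus N(0, 0.4)
sample scatter; 300 unstructured noise proteins; age/sex/PMI effects
(0.05 log2/year, 0.3, 0.1 log2/h) on a random 30% of proteins; and
trait columns re-coupled to chosen module latents at a target
correlation (defaults: CERAD ↔ the progressive-increase module and
CASI ↔ the progressive-decrease module, both r = 0.7). Member
proteins load on their latent with loadings U(0.8, 1.2) and
independent noise calibrated so the within-module pairwise
correlation hits the design target, 0.7 by default — tight,
organelle-driven co-expression; at n = 18 this leaves planted
membership statistically identifiable (a member's expected
correlation with its latent is √0.7 ≈ 0.84), which is what makes
recovery a meaningful test of the algorithm rather than of sampling
noise. Cohort ages are matched in triplets across groups; PMI is
uniform on 2.5–8.5 h; CASI/CERAD/Braak are drawn group-consistent
(AsymAD carries pathology with control-like cognition). The peptide
generator emits 1–8 peptides per protein with lognormal ionization
efficiencies, intensity-monotone Poisson spectral counts and
class-dependent membrane:soluble count ratios (4:1, 2:1, 1:4).

What the generator does **not** emulate: missing-value structure
(intensities are complete apart from sampling zeros), isoform/shared
peptide ambiguity beyond a uniqueness flag, batch effects, heavy-tailed
noise, and any spectrum-level artifacts. Passing tests therefore
demonstrate correctness of the statistics and recoverability of
planted structure under idealized noise — not robustness to every
pathology of real LC-MS/MS data.

All randomness descends from a single seed through named
`numpy.random.Generator` streams, so every fixture is bit-reproducible.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1]; adjacency and TOM to [0, 1];
  TOM with zero connectivity denominators returns 0.
* Decile and label ties break by identifier under stable sorts.
* A degenerate TOM (all entries equal) yields one module or none,
  never a crash; fewer proteins than `min_module_size` yields all
  unassigned.
* Rank-deficient bootstrap designs are redrawn (up to 100 times)
  before erroring.
* Hierarchical clustering uses `scipy.cluster.hierarchy` throughout;
  problem sizes here (≲2000 proteins) need no specialized linkage
  backend, and the network stage is built single-block for the same
  reason.

## Problem sizes in the verification suite

The test suite and `scripts/acceptance.py` run the default design
(805 proteins × 18 samples) for module recovery (10 seeds), 50 seeds
for trait-coupling recovery, 1000 replicates for p-value calibration,
10⁶ permutations for the Tukey oracle, an exhaustive hypergeometric
sweep over all tables with N ≤ 60, and 100 random-relabeling
replicates for the overlap null. Bootstrap counts are reduced to
50–200 in tests (the regression estimate is already stable there);
the pipeline default remains 1000.

## Known limitations

* The tree cut is a faithful re-derivation of the Dynamic Hybrid
  *idea*, not a line-for-line port; on borderline branches it can
  split or lump differently from the R implementation.
* Reassignment/adoption is a single pass; pathological partitions
  that need iterative relabeling will not fully converge.
* Modules whose latent profiles correlate above ≈0.8 (e.g. two
  "decreasing" archetypes in an 18-sample cohort) are not reliably
  separable by any tree-based method at this sample size; the
  benchmark's archetype assignment keeps such pairs distinguishable
  on average but individual seeds can still fuse them.
* The enrichment stage assumes gene symbols are comparable across
  networks after uppercasing; no synonym resolution is attempted.
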