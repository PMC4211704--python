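# Methods

## The question and the estimand

For an n-node parcellation, each subject × condition cell yields a
symmetric Fisher-z connectivity matrix; the n(n−1)/2 unique edges are
vectorized in one canonical order (upper triangle, i < j, row-major) used
by every module. The quantity of interest is the association between an
edge's Euclidean length d_ij (mm between ROI centroids) and a per-edge
*change* statistic: an LV salience from task PLS, a bootstrap ratio, a
difference of condition-mean z matrices, or the absolute value of either.
A negative association would mean long-range connections change more
(short-range ones are more stable); a flat profile means stability is
independent of connection length.

## Task PLS

Mean-centered task PLS is used as the concrete realization of the
cross-block covariance decomposition: the cells × edges matrix of cell-mean
edge vectors, column-centered by the grand mean over cells, is decomposed
by SVD. This is equivalent (up to the constant cell-size factor) to the
SVD of Yᵀ·X with Y the stacked subject × cell observations and X a
dummy-coded, column-centered design matrix; the equivalence is asserted on
random instances in the test suite. Latent variables are ordered by
singular value; the covariance fraction is λ²/Σλ².

Sign convention: each LV's design-salience entry of largest magnitude is
made non-negative. Magnitude ties are resolved to the *first* index within
a relative tolerance of 1e−9 — balanced two-cell contrasts produce exact
ties, where bitwise argmax noise would otherwise randomize the sign of
every salience.

**Permutation test** (default 500 resamples): whole subjects are relabeled
across groups (group sizes preserved) and each subject's condition labels
are shuffled without replacement; cell means are rebuilt and the SVD
re-run. p(LV k) is the proportion of permuted *position-k* singular values
≥ the observed one (position-wise comparison; raw proportion without +1
smoothing). A `mode="conditions"` flag restricts the permutation to
condition labels only. Group relabeling requires equal condition counts
across groups.

**Bootstrap** (default 500 resamples): subjects are redrawn with
replacement within group, keeping condition labels; each resample's
saliences are aligned to the original by orthogonal Procrustes rotation of
the design saliences (otherwise sign/axis flips between resamples inflate
the SE). SE is the standard deviation over resamples (ddof 1); BSR =
salience / SE with the SE floored at 1e−12 and floored edges flagged
rather than reported.

## Independent-pairs inference

Edge statistics sharing a node are algebraically constrained (knowing
r(a,b) and r(a,c) bounds r(b,c)), so the all-edges distance–change
correlation is reported as descriptive only. Inference uses node-disjoint
edges: each resample Fisher–Yates-shuffles the node order and pairs
consecutive nodes — a uniform draw over perfect matchings — yielding
⌊n/2⌋ independent (distance, change) pairs (one node dropped when n is
odd). The correlation over those pairs, collected over 1000 matchings,
forms the sampling distribution. Reported: mean ρ; SE as the sd of the
distribution (the spread, with sd/√n_samples additionally emitted as
`se_of_mean`); P(ρ>0) as the proportion of ρ samples > 0 with exact zeros
counted half (so the two tails sum to 1); P(ρ<0) = 1 − P(ρ>0). The default
correlation is Spearman's ρ (rank-based, robust to the nonlinear decay of
z with distance); Pearson is selectable everywhere. Samples with zero
variance among the matched pairs are redrawn, at most 100 times.

Two further diagnostics run on every change map: a 2-D density histogram
(counts over a rectangular grid spanning the observed ranges), and a PCA
outlier analysis — both columns standardized, principal axis from the 2×2
covariance, signed orthogonal displacement per point, the ⌈5%⌉ most
positive and most negative displacements flagged (index order breaks
ties) and the distance–change correlation within the flagged set reported.

## Stratification

Louvain community detection runs on the grand-mean z matrix across all
cells (configurable), negative weights zeroed, resolution γ = 1; the best
of 100 seeded runs by modularity Q is kept (ties to the first run), and
the stored Q always equals a from-scratch Newman recomputation. Edges are
labeled within/between module, intra/inter hemisphere, and — among inter-
hemispheric edges — homotopic (node joined to its mirror partner) or not.
Per stratum, the descriptive correlation and the independent-pairs test
are re-run with a restricted matching: the uniform matching is drawn as
usual and only pairs whose edge lies in the stratum are retained; samples
keeping < 10 eligible pairs are redrawn. Strata with < 10 edges, or too
sparse for the restricted matching (e.g. the homotopic stratum, whose
edges form a single fixed matching), are reported as skipped rather than
failing the run.

**Homotopic stability**: all inter-hemispheric change values are pooled;
the empirical 2.5th/97.5th percentiles (linear-interpolation quantiles,
not a normal approximation) bound the interval; per class the proportion
of values strictly outside is reported, along with shared-bin histogram
data. A stable class hugs zero and rarely exceeds the pooled interval.

## Synthetic generator

The generator emulates the statistical structure of multi-subject task
connectomes, not their physiology:

- **Geometry**: n_pairs left/right mirror pairs (x negated across the
  midline, y, z shared) plus optional medial nodes at x = 0, uniform in a
  cubic box of side `extent` (default 140 mm, brain-scale).
- **Baseline**: r_ij = r0·exp(−d_ij/L) with r0 = 0.5 and decay length L
  defaulting to one third of the coordinate span (≈ 45 mm) — strong
  short-range, weak long-range correlation. Homotopic edges get +0.2
  (elevated homotopic connectivity); all correlations are capped at 0.95
  so Fisher z stays finite.
- **Condition effects**: a per-edge effect map in z units, added with a
  centered ±½ contrast over conditions in z space and mapped back through
  tanh. Profiles: `flat` (sign × half-normal magnitude, scale 0.1 z — a
  moderate effect i.i.d. of distance; the null for distance dependence),
  `increasing`/`decreasing` (effect ∝ ±(d−d̄)/sd(d) × 0.1 — perfectly
  monotone positive/negative controls). `homotopic_stability` multiplies
  the effect on homotopic edges; the default 0 makes them perfectly
  stable, the regime the stratified analyses are meant to detect.
- **Repair and sampling**: matrices are symmetrized, unit-diagonal'd and
  projected to PSD by eigenvalue clipping at 0 followed by diagonal
  renormalization (matrices with smallest eigenvalue ≥ −1e−8 pass
  untouched); subjects are T independent draws from the zero-mean MVN with
  the cell's matrix (T ≥ 30 enforced).

Not emulated: hemodynamics, temporal autocorrelation, motion artifacts,
realistic atlas geometry. Passing tests therefore certify the statistical
machinery (calibration, power, recovery under the stated covariance
model), not robustness to those real-data features.

All stochastic operations take explicit seeds; a pipeline run spawns
per-stage seeds from one master seed via `SeedSequence`, so reports are
byte-identical across repeated runs of the same config.

## Validation studies and problem sizes

The replicate studies (used by the acceptance tests and
`scripts/acceptance.py`) run at 60 nodes (30 pairs), 20 subjects, 2
conditions, T = 200, effect scale 0.1 z — sizes at which one replicate
takes well under a second so 50-replicate calibration studies stay
desk-scale:

- **Null calibration** (flat profile, 50 replicates, 1000 matchings):
  two-sided rejection (min tail p < 0.025) within the exact-binomial 95%
  region around 0.05; mean |ρ| < 0.1 in ≥ 95% of replicates.
- **Positive control** (increasing profile): two-sided and directional
  (P(ρ<0)-tail) rejection in ≥ 90% of replicates.
- **PLS recovery**: correlation between LV1 saliences and the planted
  effect map ≥ 0.9; LV1 detected (p < 0.05) in ≥ 90% of replicates; LV1
  false-positive rate under no effect within binomial bounds of 0.05
  (200 replicates at 200 permutations).
- **Homotopic recovery** (stability 0): homotopic exceedance proportion
  below the non-homotopic one in ≥ 90% of 50 replicates.

## Known limitations

- Euclidean distance is a proxy; geodesic or fiber-length distances are
  out of scope.
- The permutation scheme assumes exchangeable subjects within the stated
  relabeling scheme; unequal condition counts across groups fall back to
  condition-only permutation semantics (an error is raised for the full
  mode).
- The restricted-matching sampler cannot serve strata that form (nearly)
  a single matching — homotopic-stratum inference goes through the
  exceedance test instead.
- Signed modularity is not implemented; negative weights are zeroed
  before Louvain.
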