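# Methods

## Problem and model

`mvbc` classifies subjects from several co-registered 3-D parametric brain
maps ("views", e.g. an ICA-derived default-mode-network component map and a
fractional-anisotropy map), where each view is measured per voxel on its own
brain mask. Voxel-level features are too unstable across subjects for
single-subject classification, so the pipeline first aggregates voxels into
parcels that covary coherently across subjects and then classifies the
parcel features with random forests, combining the views either before
training (intermediate integration) or at the vote level (late
integration).

Per cross-validation training set, the stages are:

1. **Confound removal.** Per voxel, OLS of `value ~ 1 + age + sex` fitted
   on the training subjects; fitted effects are subtracted from all
   subjects. Fitting precedes parcellation so the parcels cannot encode
   covariate similarity, and is redone inside every fold so that held-out
   subjects never influence the fit (fold-wise refitting is the strict,
   leakage-safe reading; fitting once globally would leak test data into
   the training-fold model).
2. **Feature agglomeration.** Each in-mask voxel is an observation whose
   feature vector is its residualized value across training subjects.
   Agglomerative clustering with Ward's minimum-variance criterion merges
   only spatially adjacent clusters (6-connectivity by default; 18/26
   available) until `k` parcels remain. Each parcel's feature is the
   median of its member voxels' values, computable for any subject,
   including held-out ones.
3. **Forest classification.** Fully grown trees (`min_leaf = 1`, no
   pruning) on bootstraps of the training subjects drawn with replacement
   at the original size; `mtry = floor(sqrt(p))` candidate features per
   split; Gini or cross-entropy (natural log) impurity. Intermediate
   integration concatenates the views' feature blocks before training one
   forest; late integration trains one forest per view and pools every
   tree's vote (each *tree* weighs equally, so equal forest sizes per view
   — enforced by default — make this a view-majority vote). Vote ties
   break to the earlier class in the configured label order.
4. **Evaluation.** 5 outer x 3 inner stratified nested cross-validation:
   the inner loop scores every grid configuration (per-view cluster count,
   tree count, impurity criterion, `mtry`) by mean held-out accuracy, ties
   going to the first point in grid order; the winner is retrained on the
   outer-training set and scored once on the outer test fold. For the late
   model each view's configuration is selected independently by its
   single-view inner accuracy. Significance comes from a label-permutation
   null with the add-one p-value `(1 + #{null >= obs}) / (1 + n_perm)`
   (smallest attainable value `1/(n_perm+1)`); a Gaussian tail fit of the
   null is reported separately as an approximation only.

Out-of-bag accuracy is computed as a diagnostic but never used for model
selection: the parcellation is fitted before bootstrapping, so held-out
trees' subjects have already influenced the feature space and OOB is not
an honest generalization estimate in this pipeline.

## Permutation replicates and caching

A permutation replicate conceptually re-runs the whole pipeline with
permuted training labels. Every unsupervised stage (confound fit, Ward
linkage, median features) is a deterministic function of the data and the
fixed fold structure and never sees labels, so re-running it returns
bit-identical results; the implementation therefore caches those stages
per fold and re-runs only the label-dependent stages (inner scoring,
selection, forest training). This is an exact equivalence, not an
approximation, and is what makes hundreds of replicates affordable.
Outer-test predictions of every replicate are scored against the *true*
labels; fold membership is held fixed across replicates.

## Stability analysis

For each target subject, models are retrained `n_rep` times (default 100)
on random 70% subsets drawn uniformly (unstratified, matching a plain
random subset; draws missing a class are redrawn) and never containing the
target; the 30% holdout is scored each time as an over-training check. A
model's call for a subject is *stable* when the majority label's fraction
exceeds a threshold (default 0.5, the weakest reading of "majority"; ties
are never stable). Comparing stable labels across models yields five
groups: correct-stable, stable on the same wrong class (one group per
class), rescued by the multi-view models (all MV correct-stable while at
most one SV is correct), and unstable/disagreeing. The patients-only
variant removes one class from every training subset. Hyperparameters are
frozen to values passed in (e.g. nested-CV winners) rather than re-tuned
per repetition — re-tuning inside `100 x models x subjects` repetitions
would be computationally disproportionate and adds no information about
stability itself. By default the parcellation is refitted on every 70%
subset (strict no-leakage); a shared-parcellation fast mode exists and is
documented as approximate.

## Smoothness estimation and template GOF

Map smoothness uses a simple Gaussian model: per grid axis, the lag-1
Pearson correlation `r` of in-mask neighbour pairs is inverted as the
equivalent Gaussian *kernel* that would produce it from white noise.
Smoothing white noise with a kernel of width `sigma` gives a field with
lag-d autocorrelation `exp(-d^2 / (4 sigma^2))`, so `sigma^2 = -1/(4 ln r)`
and `FWHM = 2 sqrt(2 ln 2) sigma`, averaged over axes (axes with `r <= 0`
contribute 0; `r >= 1` is an error, as is a constant map). The estimator
is used to calibrate the synthetic generator, not as a scientific end in
itself. Template goodness of fit is `mean(inside) - mean(outside)` over a
strict-subset template mask; it is sign-equivariant, which is what makes
it usable to resolve ICA sign ambiguity.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes: per
subject and view, class-dependent spherical blob effects with Gaussian
falloff (`sigma = radius/2`), a linear age slope and additive sex offset
over a designated confound region, and white voxel noise, all smoothed
with a Gaussian kernel. Default study conditions: 16x16x16 grid with an
inscribed ellipsoid mask (~1,770 voxels, a scaled-down stand-in for a 3 mm
whole-brain grid), 20 subjects per class in 3 classes, ages uniform on
[38, 82], sex Bernoulli(0.5), voxel noise sd 1.0, smoothing set-points of
2.16 and 2.00 voxels FWHM for the two views (the intrinsic-smoothness
regime of unsmoothed component/FA maps). The strong preset uses blob
amplitude 3.0 (amplitude clearly dominating noise); the null preset uses
amplitude 0; the complementary preset (amplitude 2.0) marks class A in
view 1 only and class C in view 2 only, so each view leaves one class pair
unresolved and only the combination separates all three. "Mimic" subjects
are drawn from one class's effect distribution but labelled as another,
planting a systematic misassignment for the stability analysis.

What the generator does **not** emulate: anatomically structured signal
(gray/white matter geometry), spatially correlated noise beyond the
smoothing kernel, inter-subject anatomical misalignment, scanner/site
effects, or class-dependent covariate distributions. Passing tests
therefore demonstrate correctness and calibration of the *procedure*
under its own assumptions, not expected accuracy on real cohorts.

## Numerical choices

- Voxel linearization is fixed C order (last axis fastest) over mask
  coordinates; affines must agree within 1e-4 absolute.
- Ward merges break ties on the lexicographically lowest cluster-id pair;
  merged clusters take fresh increasing ids. The merge sequence matches
  `scipy.cluster.hierarchy.linkage(..., 'ward')` in the unconstrained case
  and `sklearn.AgglomerativeClustering(connectivity=...)` in the
  constrained case (used as independent cross-checks in the tests).
  Stepwise Ward is locally optimal per merge but carries **no global
  optimality guarantee**: on tiny exhaustively enumerable instances the
  greedy partition misses the minimum-variance connected k-partition in
  roughly a fifth to a third of random cases (sklearn's implementation
  returns the identical partition). Masks with several connected
  components are supported; components are never merged, so `k` must be at
  least the component count.
- Entropy uses the natural log (split ranking is base-invariant).
- Cluster counts per view default to 500 on whole-brain-scale grids; the
  desk-scale tests use k of 8-20 on 10-12 voxel cubes with 45-60 subjects
  and 20-200 trees, sizes chosen so the full suite and the acceptance
  script run in minutes while keeping every fold's class coverage intact.
- Forest seeds are derived deterministically from the schedule seed, fold
  and grid point, so identical seeds reproduce reports bit-for-bit.

## Known limitations

- Greedy constrained Ward is a heuristic for the minimum-variance
  connected partition (above); this is a property of the method itself.
- The permutation p-value cannot fall below `1/(n_perm+1)`; claims like
  p < 1e-6 at 500 permutations require the (clearly labelled) parametric
  tail approximation.
- The late model assumes per-view forests share the class label order;
  unequal tree counts per view are rejected unless explicitly allowed.
- No resampling/registration: all volumes of a view must share the mask's
  grid and affine exactly (within tolerance).
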