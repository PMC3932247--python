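# Methods

## Model and assumptions

The ranking treats each feature marginally. For feature *i* and class *j*
the *effective range* R_ij = [μ_ij − (1−p_j)γσ_ij, μ_ij + (1−p_j)γσ_ij]
summarizes where class *j*'s values concentrate. The construction assumes
only that a class's values have a finite mean and variance: by the Chebyshev
inequality the unscaled interval μ ± γσ captures at least 1 − 1/γ² of the
mass of *any* distribution, and γ = √(1/(1 − f)) is the smallest multiplier
guaranteeing fraction f. The default γ = 1.732 targets f = 2/3. The
(1−p_j) shrinkage deliberately trades that guarantee for balance across
classes of unequal prevalence; the coverage bound is therefore asserted (and
tested) only for the unscaled interval.

A feature is scored by three ingredients:

1. **Overlapping area** OA_i: summed φ over ordered class pairs, where
   φ(j,k) = r_j⁺ − r_k⁻ when positive. For pairs sorted by lower bound in a
   non-inclusion configuration this equals the length of the interval
   intersection (verified against a Monte-Carlo interval-measure oracle).
2. **Including area** IA_i: summed widths of ranges nested inside another
   class's range (ψ(j,k) = width of R_k when r_j⁺ ≥ r_k⁺). Inclusion is a
   distinct failure mode: the inner class's samples all sit inside the outer
   class's range, so no threshold on this feature can isolate them, even
   when OA looks moderate.
3. **Sample proportions** H, G: the fraction of each class's samples that
   actually fall inside the overlap / inclusion regions. Two features with
   identical areas can differ sharply here, and the sparsely populated one
   classifies more samples correctly.

These combine as W = NAC × (NH + GH) with NAC = 1 − AC/max(AC),
AC = (OA+IA)/hull width, and NH, GH the analogously max-normalized
proportion totals. Features are selected top-k by W with deterministic
tie-breaking (ascending feature index).

## Conventions where the construction is under-determined

* **Pair orientation.** φ and ψ are asymmetric in (j,k) but no class order
  is canonical. Default (`sorted`): per feature, classes are ordered by
  ascending lower bound (ties by upper bound, then class index) before the
  j<k double sums. This makes φ measure left-to-right overlap and makes ψ's
  upper-bound test coincide with true inclusion (the sort supplies the
  lower-bound condition). A `literal` mode applies the formulas in original
  label order for comparability; in that mode φ can fire across a gap for
  disorderly labeled classes, which is the formula verbatim, not a bug.
* **Double counting.** In an inclusion configuration φ fires too, so
  SA = OA + IA counts the included region more than once. The default keeps
  the formulas as printed; the `exclusive` flag subtracts ψ from φ when both
  fire.
* **Counting regions.** The scalar OA_i names no region for l > 2 classes.
  H_ij counts class-j samples in the union of nonempty pairwise
  intersections of R_ij with every other class's range; G_ij counts class-j
  samples in R_ij whenever an oriented pair includes it. This reduces to
  the obvious region for two classes and keeps H_ij ≤ K_j. Intervals are
  closed: endpoint values count as inside. An `inclusion_convention="both"`
  flag also counts the including class's samples inside the included range.
* **Proportion direction.** The proportions are H_ij/K_j (in [0,1]); the
  inverted ratio is unbounded and undefined at H_ij = 0.
* **Degenerate cases.** All-identical point ranges give hull width 0;
  AC is defined as 0 there (zero overlap width is no evidence of confusion).
  When max(AC) = 0 across features, NAC = 1 everywhere; likewise NH (GH)
  when max(H) (max(G)) = 0. Constant features are allowed: their zero-width
  ranges yield OA = IA = 0, but every sample sits exactly on the degenerate
  point, so their proportion scores are worst-case and W = 0. Because
  regions are closed while φ is strict, a feature whose ranges touch at
  exactly one point has OA = 0 yet may count boundary samples; this affects
  only measure-zero coincidences in continuous data.
* **Statistics.** Standard deviations use the unbiased (n−1) convention by
  default (`ddof` configurable) — the safer default at the small class sizes
  this method targets. Priors default to empirical frequencies K_j/N and
  accept a user-supplied override. Optional per-feature standardization is
  available at ingest, default off; ranking is shift-invariant per feature
  and scale changes cancel in AC, so standardization mainly matters for
  downstream classifiers.

## Synthetic data

The generator emulates small-n / large-d class-labeled expression data:
class-conditional continuous features, a minority of informative features
among i.i.d. noise. Defaults: two classes of 50 samples, 200 features, 20
informative, mean-shift separation 3σ, unit noise. Mean-shift features
stagger class means by `separation`·σ; inclusion-type features keep equal
means and double the standard deviation per class (variance ratio 4), which
provably nests the population effective ranges for equal priors (half-widths
0.866σ vs 1.732σ). A scaled-t family (unit variance, df > 2) exercises the
distribution-free guarantee under heavy tails.

What the generator does **not** emulate: count-like marginal distributions,
gene–gene correlation, batch effects, class imbalance beyond the
`n_per_class` vector. Passing recovery tests on this generator shows the
pipeline identifies marginally separated features under idealized
independence, not that it matches published accuracies on any real
expression dataset — those depend on dataset versions and preprocessing
beyond this package's scope.

A note on inclusion-type features: with equal means and a 4× variance ratio,
the OA-only scheme already scores them *better* than noise (their AC ≈ 0.75
versus ≈ 1 for coincident noise ranges), while the full score — by design —
penalizes inclusion (IA > 0, G > 0) and places them *below* typical noise
features. The inclusion machinery is a penalty for an untrustworthy
configuration, not a detector of variance-coded information; the acceptance
check therefore exercises the configuration the penalty was motivated by:
two features with identical OA-only area coefficient, one partial-overlap
and one inclusion, which the OA-only scheme ties and the full score
separates in the inclusion-penalizing direction.

## Evaluation harness

Leave-one-out cross-validation over subset sizes k, with feature weights
recomputed on each training fold by default (the held-out sample can never
influence selection — verified by a canary feature informative only in the
held-out sample). A `global` mode ranks once on all samples for
comparability with studies that did so. Classifiers are standard
scikit-learn estimators behind a name registry (1-nearest-neighbor,
decision tree, linear-kernel SVM); they are evaluation machinery, not part
of the method.

## Problem sizes and numerics

The test suite and acceptance script run on synthetic instances of 2–6
classes, up to a few hundred features and ≤ 400 samples — comfortably
covering the method's intended regime (the computation is linear in
features and quadratic in classes, so thousands of features pose no issue).
Monte-Carlo oracle comparisons use 4000 uniform points over the feature hull
with a 4-standard-error tolerance; count oracles are exact integer
comparisons; the OA-only reduction is exact to the bit because the reduced
pipeline executes the identical floating-point operations.
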