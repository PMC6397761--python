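# Methods

## Problem setting and model

A crown polygon digitized over airborne hyperspectral imagery yields a
*bag* of pixel reflectance spectra with a single crown-level genus and
species label. Pixel labels are unreliable: polygons include understory,
soil, and neighbouring canopy. The working assumption is the standard
multiple-instance one — every labeled crown contains at least one pixel
that genuinely belongs to the labeled species.

Pixels are modelled as Gaussian around a background: a target-bearing
pixel of class c is `x ~ N(α s_c + μ_b, σ² Σ_b)` with abundance `α ≠ 0`,
and a pure background pixel drops the `α s_c` term. Under this model the
natural detector is the adaptive cosine estimator (ACE): whiten by the
background eigensystem, unit-normalize, and take the cosine against the
whitened target signature. ACE is invariant to positive scaling of the
offset from the background mean, which is what makes it robust to
illumination/abundance variation.

## Signature estimation (MI-ACE)

For each ordered class pair (target, background) the discriminative
signature maximizes the mean ACE response of one *selected* instance per
positive bag minus the mean ACE response over all negative instances.
The optimization alternates:

1. **Selection** — per positive bag, the instance with the maximum ACE
   statistic under the current signature (ties broken by lowest instance
   index, for determinism).
2. **Update** — with selections fixed the objective is linear in the unit
   signature vector, so its exact maximizer is the normalized difference
   between the mean selected positive direction and the mean per-bag-mean
   negative direction (all in whitened, unit-normalized coordinates).

Both half-steps cannot decrease the objective, so the recorded objective
history is monotone non-decreasing; the tests assert this per iteration.

**Initialization** evaluates the objective with every positive-bag
instance as the candidate signature and starts from the best. This is
deterministic (no seed enters training) and matches the discriminative
intent of the objective.

**Convergence** is declared when the selected-instance set repeats, the
only discrete state of the procedure; an iteration cap of 1000 guards
cycling (in practice convergence takes a handful of iterations). Hitting
the cap returns the best iterate flagged `converged=False`.

## Background statistics

Each binary classifier whitens with statistics fit from the *negative*
class's pixels only — the background of a pairwise detector is the other
class, not the whole scene. A `global_background` option (all training
pixels) exists but is off by default. The covariance estimate is the
sample covariance plus a ridge of `λ · (trace/d)` on the diagonal, with
λ = 1e−6 by default and applied always: rare classes may contribute only
a few dozen pixels for hundreds of bands, so the sample covariance is
routinely rank-deficient. When the sample covariance is exactly zero
(degenerate all-identical input) the trace scale falls back to 1 so the
model remains well-defined as `λ·I`.

Cross-validation experiments at desk scale showed that when the negative
class supplies barely more pixels than bands, whitening noise — not class
separation — is the accuracy bottleneck; realistic crown sizes (dozens of
pixels each) or a larger ridge resolve it.

## Thresholding, voting, hierarchy

A bag's confidence under a classifier is the arithmetic mean ACE
statistic over its pixels. The decision threshold is scanned over the
midpoints of consecutive distinct sorted training-bag confidences, plus
one candidate below the minimum (everything target) and the maximum
itself (nothing target, under the strict `>` rule); the candidate with
the highest training accuracy wins, ties resolved by the widest margin to
the nearest confidence and then by the smallest threshold. If all
confidences coincide the threshold is degenerate and flagged.

One-vs-one prediction awards one vote per classifier; `pairs_mode="one"`
trains C(C−1)/2 classifiers with the lexicographically first class of
each pair as target, `"two"` trains both orientations and each casts an
independent vote. Vote ties are resolved by a seeded uniform draw among
the tied classes; the generator is keyed on `(seed, crc32(bag_id))` so
results are invariant to bag order. A deterministic alternative
(largest mean signed margin Σ(z−τ) over the tied class's classifiers)
is available via `tie_break="margin"`.

Hierarchical classification predicts genus first; genera with a single
species map to it directly, multi-species genera route the bag through a
species-level one-vs-one model trained only within that genus.

## Preprocessing

Water-absorption intervals (defaults 1345–1430, 1800–1956, 2482–2512 nm)
are removed by closed-interval membership of band centres — the data
provider stores a sentinel reflectance there, and the bands are sliced
out, never imputed. The operation is defined by intervals rather than a
fixed band count, since the count depends on the instrument's band grid.
Crowns labeled with a catch-all class (e.g. OTHERS) are dropped before
training: the method has no outlier-rejection mechanism, so such crowns
cannot be modelled and would corrupt pairwise training.

## Evaluation

Confusion matrices are tallied truth-by-prediction; rank-1 accuracy is
the fraction of crowns whose true class gets the highest probability
(equal to trace/total for crisp predictions, and to micro-averaged
recall); per-class scores use the one-vs-rest reduction, reporting an
undefined precision/recall/F1 as 0 with an explicit flag rather than NaN
so aggregate tables stay finite.

Crisp 0/1 probabilities give infinite cross entropy on any error, so
crisp outputs can be ε-softened: the predicted class receives
`1−(C−1)ε`, every other class ε. At rank-1 accuracy `a` the softened
cross entropy `c(ε) = −[a·ln(1−(C−1)ε) + (1−a)·ln ε]` is convex on
`0 < ε < 1/(C−1)` with minimizer `ε* = (1−a)/(C−1)`; both the closed form
and a grid-search confirmation are implemented. At the species-level
operating point a = 0.864 with C = 9 scored classes this gives
ε* = 0.017 and a softened cross entropy of 0.68.

Cross validation splits at the *bag* level (pixel-level splits would leak
crown identity across folds) with class-stratified halves so rare classes
appear in both folds; classes with a single crown are excluded with a
warning. The reported matrix is averaged over all folds, so row sums
equal per-fold truth counts.

## Synthetic data

The generator draws bags exactly from the Gaussian additive-target model
above. Choices and defaults:

- **Bands**: 50 by default (fast tests); `paper_band_axis()` provides the
  426-band 383–2512 nm airborne geometry.
- **Background**: a smooth positive reflectance curve around 0.3 with an
  AR(1) covariance (per-band sd 0.02, neighbour correlation 0.9) — the
  simplest stand-in for the strong correlation between adjacent
  wavelengths in real spectra.
- **Signatures**: random unit directions scaled to 0.5; near-orthogonal
  in moderate dimension, i.e. the well-separated regime. Two-level
  generation blends a genus base direction with a species-specific
  direction; the blend weight controls within-genus spectral similarity,
  and at weight 1 species within a genus become indistinguishable.
- **Abundance** α is uniform on a configurable interval that must exclude
  zero (a zero-abundance target pixel is just background). The noise
  scale σ² is a free generator parameter: the detector-side definition of
  the scaling is circular in the data and cannot be used to generate.
- **Bag composition**: 20 crowns per class of 10–30 pixels, a 0.7 target
  fraction (most crown pixels really are the labeled tree, with at least
  one guaranteed), and an optional contamination fraction replacing
  background pixels with other classes' target pixels to emulate
  mislabeled crowns.

What the generator does *not* emulate: spatial pixel structure within
crowns, sensor noise characteristics, atmospheric residuals, per-crown
illumination differences, and non-Gaussian background mixtures. Passing
tests therefore demonstrate correctness of the algorithms under the
generative model the method assumes, not field performance on airborne
data.

A note on baselines: with a background distribution shared across
classes, matching raw bag-mean spectra against class-mean templates is
already near-optimal, because the background term cancels. The advantage
of the discriminative whitened signature shows where the method is
actually needed — spectrally similar species (within-genus blend weight
0.9) with a single target pixel per crown — and the robustness test makes
the paired comparison in exactly that regime.

## Numerical choices and problem sizes

- Eigendecomposition via `numpy.linalg.eigh` on the symmetrized,
  ridge-regularized covariance; eigenvalues sorted descending and
  required positive.
- A pixel exactly at the background mean whitens to zero norm; its ACE
  statistic is defined as 0 with a warning.
- Signature serialization stores the whitened unit signature plus the
  background mean/eigensystem as JSON; models are directories of
  classifier files with a manifest, so persisted and in-memory models
  predict identically.
- Test problem sizes (tens of bags, 10–100 bands, ≤ 50k Monte-Carlo
  draws) are chosen so the full suite runs in seconds while keeping
  sampling error far from the asserted tolerances; the one
  high-dimensional case (d = 371, 100 bags per side) is the null
  experiment, where the selection-bias ceiling of the objective needs
  both high dimension and many bags to fall below 0.2.

## Known limitations

- No mechanism rejects crowns outside the training vocabulary; an
  unknown-class crown is always assigned to some known class.
- Class probabilities are crisp votes; ε-softening calibrates the
  aggregate cross entropy but not per-crown uncertainty.
- Classifiers are equally weighted in voting regardless of their
  training quality.
- With `pairs_mode="two"` the two per-pair classifiers vote
  independently; other combination rules were not explored.
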