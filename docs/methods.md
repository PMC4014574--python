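# Methods

## The model

`dtiparc` parcellates a diffusion-tensor image of the brain into labeled
anatomical structures by fusing information from a library of N atlases
(each an expert-labeled multi-contrast image).  Per voxel x the subject is
summarised by a 5-vector of DTI contrasts

    I(x) = (FA, MD, |e1_x|, |e1_y|, |e1_z|)

— fractional anisotropy, mean diffusivity (mm²/s), and the componentwise
absolute value of the unit primary eigenvector e1 of the tensor.  The
absolute value resolves the eigenvector's sign degeneracy at the cost of
folding orientations into one octant.  Each contrast carries complementary
anatomical information: MD separates CSF from tissue, FA separates gray
from white matter, and the eigenvector separates white-matter tracts by
fiber orientation; no single contrast separates everything, which is the
rationale for fusing all five.

The parcellation W is estimated by MAP,

    Ŵ = argmax_W  p(W | I),

with the atlas used to interpret each voxel treated as a latent variable
and the problem solved by EM.  The generative pieces are:

- **Intensity model.**  For each atlas a, structure l and channel c, the
  channel intensity inside l is modeled as a 1-D Gaussian mixture fitted
  to the atlas voxels of l by maximum-likelihood EM.  Channels are
  conditionally independent given (l, a), so the voxel likelihood is the
  product of the five channel densities.  The mixture order is 2 for
  structures smaller than 1000 mm³ and 3 otherwise (the published
  size-dependent rule fixes the 1000 mm³ cutoff; the orders themselves
  are this package's reconstruction and are configurable).  A structure
  that is homogeneous in some channel collapses to effectively one
  component; a structure that is broad and unstructured in a channel gets
  a nearly flat density there, which automatically down-weights that
  channel in likelihood ratios — gray-matter fiber orientation being the
  canonical example.
- **Geometric model.**  Each atlas is registered to the subject by a
  global diffeomorphism driven by the FA and MD channels; each
  (atlas, structure) additionally carries a local 12-parameter affine
  refinement composed with the global field.  The deformed atlas label
  images, interpolated trilinearly as per-label indicator probabilities,
  act as the spatial label prior.  Outside an atlas grid all probability
  mass belongs to the background label 0.
- **Priors.**  The prior over atlases is uniform.  Each atlas's global
  deformation contributes exp(−g), where g is a geodesic-length proxy
  (below); each local affine contributes a zero-mean diagonal Gaussian on
  its 12 parameters with variance 0.01 on the 9 linear deviations from
  identity and 100 on the 3 translations (voxels).

## The EM loop

After initialisation (identity local affines; initial parcellation =
majority vote of the nearest-neighbour-propagated atlas labels, or a
designated atlas), the loop iterates:

1. **Selector (E-step).**  The posterior weight of atlas a at voxel x
   with current label l = W(x) is proportional to
   [per-voxel intensity likelihood] × [Dice(current structure l,
   deformed atlas-a structure l)] × [deformation prior of a] ×
   [affine prior density of a's structure-l transform], normalized over
   atlases at each voxel.  The Dice term is the computable surrogate for
   the label-image likelihood: since local transforms are shared by all
   voxels of a structure, the three geometric factors are constant within
   a structure while the intensity factor varies voxelwise.
2. **Parcellation (M-step).**  Per voxel the new label maximises
   Σ_a selector(a, x) · p(I(x) | l, a) · P(deformed atlas-a label = l at x),
   over all labels (background included) with nonzero interpolated
   probability under any atlas.  Ties break to the smallest label index
   for determinism.
3. **Transforms.**  Each (atlas, structure) local affine is re-optimised
   against the new parcellation: derivative-free maximisation of soft
   Dice plus the affine log-prior.

The loop stops when the changed-voxel fraction falls below 1e-4 (the
label-stability complement of the published 30-iteration cap, which is
also enforced) and flags divergence if the changed fraction increases for
5 consecutive iterations.  The per-iteration "surrogate objective" logged
in the history is the sum over voxels of the log of the winning fused
score.

Two exact reductions anchor the implementation and are tested as such:
with the subject as its own single atlas under identity registration, its
labels are a fixpoint (every factor is maximised by the current state);
with all intensity models identical, the update reduces exactly to
trilinear-probability-weighted majority voting.

## Registration

Full time-dependent velocity-field LDDMM is replaced by a greedy
multi-resolution composed-diffeomorphic scheme: at each pyramid level
(downsampling factors 4, 2, 1) a demons-like two-channel matching force
is smoothed by a Gaussian kernel (sigma 2 voxels, standing in for an
operator-induced smoothness norm, with the pyramid providing the
coarse-to-fine cascade), capped at half a voxel, and composed into the
running transform.  Steps are accepted only if the two-channel
sum-of-squares energy decreases and the Jacobian determinant stays above
0.05; rejected steps increase the smoothing.  Channels are z-scored by
the subject statistics so FA (≈0.1–0.9) and MD (≈1e-3 mm²/s) contribute
comparably, with equal channel weights by default.  The accumulated mean
norm of the accepted velocity steps serves as the geodesic-length proxy g
feeding the deformation prior: it is 0 for the identity and grows
monotonically with deformation size, which is the only property the
fusion stage needs.  The registration backend is pluggable — anything
producing a positive-Jacobian displacement field plus a
deformation-magnitude scalar can be substituted.

The local affine is centred at the centroid of the globally-deformed
atlas structure so the Gaussian prior variances act on comparable scales
(an affine about the grid origin would turn small linear deviations into
large displacements far from the origin).  The search is Nelder-Mead,
translation block first, then all 12 parameters, over the structure
bounding box dilated by 5 voxels.  The search objective smooths the atlas
indicator (sigma 1 voxel) to widen the capture basin, but the candidate
is accepted only if it beats identity on the *unsmoothed* trilinear
objective by at least 1e-6 — this keeps perfect alignment a fixpoint,
since the smoothed surrogate's optimum is slightly biased away from
identity.

## Quantification

Peripheral (surface-adjacent) structures are split voxelwise into CSF
(MD ≥ 0.0015 mm²/s; excluded from analysis), peripheral white matter
(FA > 0.2) and cortex (the rest); boundaries are inclusive on the CSF and
cortex sides, a documented choice where the thresholds alone do not fix
membership.  Sublabels are numbered parent×100 + {1, 2, 3}.  ROI volume
is voxel count × voxel volume; ROI FA/MD are voxel means.  Scan-rescan
reproducibility uses the symmetric percent difference
100·|v1−v2|/((v1+v2)/2) — the published formula's denominator is not
recoverable from the source text, and the symmetric form is standard for
scan-rescan studies (a single-scan denominator is available as an
option).  Cross-subject variability is the per-structure sample
(n−1) standard deviation over the mean.  Dice of two empty masks is
defined as 1 with a warning.

## The phantom

The synthetic study generator builds a ground-truth label map from
geometric primitives, draws channel intensities from per-structure
Gaussian mixtures (eigenvector triples: a Gaussian perturbation of a mean
axis, renormalized to unit length and taken componentwise absolute), and
produces an atlas library by warping the truth through random smooth
stationary-velocity diffeomorphisms (Gaussian-filtered noise,
exponentiated by scaling-and-squaring, Jacobian-checked) and redrawing
intensities on the deformed labels — so atlases differ in both shape and
noise, like distinct subjects.

Default study: 48³ grid at 2.5 mm spacing (the clinical slice scale),
6 structures + background — ventricle (MD ≈ 0.0030 mm²/s), two deep-gray
nuclei (FA 0.15 / 0.32), two orthogonal white-matter tracts (FA 0.60,
tight x- and z-orientations), and a peripheral shell mixing CSF-like and
cortex-like voxels so the MD 0.0015 / FA 0.2 decomposition thresholds are
genuinely exercised — with 4 atlases, deformation magnitude 2.5 voxels
(maximum norm) and smoothness 10 mm.  Tissue MD ≈ 0.0007 mm²/s
throughout.  The ambiguity phantom is a 36³ five-slab design in which
each adjacent pair of structures is separable in exactly one channel
group (MD, FA, or eigenvector orientation), built for the
single-contrast ablation comparison.

What passing on these phantoms shows: the fusion machinery, the channel
arithmetic and the registration contracts are correct, and multi-contrast
fusion dominates single-contrast fusion when the generative assumptions
hold.  What it does not show: performance under Rician noise,
partial-volume boundary mixing, pathology-induced intensity changes, or
anatomy (cortical folding, 100+ structures) far richer than six
primitives.

## Numerical choices

- Per-channel densities are floored at 1e-300 and accumulated in log
  space: a 5-channel product of narrow Gaussians underflows double
  precision otherwise.
- GMM variance floor: max(1e-12, 1e-6 × sample variance), i.e. relative
  to the channel's scale.  An absolute floor in channel units² would have
  to be smaller than the MD channel's natural variance (~1e-8 mm⁴/s²) to
  avoid flattening the channel that separates CSF from tissue.
- EM convergence: per-sample mean log-likelihood gain < 1e-7 or 500
  iterations; monotonicity is asserted every iteration.  Components with
  weight < 1e-4 are pruned and the weights renormalized (the weight-1
  collapse on homogeneous data).  Initialisation is seeded k-means++-style
  centre selection; all stochastic steps take explicit seeds.
- Structures larger than 10000 voxels are subsampled (seeded) before the
  mixture fit; the fitted parameters are unchanged within sampling noise.
- Structure Dice factors in the selector are floored at 1e-6 so a
  transiently empty structure cannot zero out an atlas entirely; voxels
  where every atlas underflows fall back to uniform weights (counted and
  logged).
- Negative tensor eigenvalues (noise) are clamped to 0 before FA/MD, with
  the clamp count logged.  All-zero tensors yield FA = MD = 0 and a zero
  eigenvector, exempt from the unit-norm invariant (FA > 0 gates it).
- Interpolation is voxel-centred, 0-based; out-of-bounds scalar samples
  fill with 0 and out-of-bounds label probability belongs to background.
  NaN voxels are rejected at construction by default (clamping is opt-in).

## Known limitations

- The greedy registration is a stand-in at desk scale: it preserves the
  contracts the fusion needs (invertibility, energy decrease, a
  deformation-magnitude prior) but is not a geodesic method, and its
  proxy is not a metric distance.
- Tensors are not reoriented under warping; the eigenvector channels are
  resampled componentwise.
- The per-voxel selector normalisation over atlases is one of two
  readings of the fusion weighting (the alternative normalises per
  structure); the per-voxel form is implemented and the reduction tests
  pin its semantics.
- Background competes as an ordinary label with intensity models fitted
  from unlabeled voxels; with atlases whose background is heterogeneous
  this model is crude.
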