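# dtiparc

Multi-contrast multi-atlas likelihood-fusion parcellation of diffusion
tensor images (DTI).

## The problem

Quantitative DTI studies need every voxel of a subject's brain assigned
to an anatomical structure (a *parcellation*) before ROI statistics —
volumes, mean FA, mean MD — can be reported.  Transferring labels from a
single registered atlas fails wherever registration fails, and no single
DTI contrast separates all structures: mean diffusivity (MD) separates
CSF from tissue, fractional anisotropy (FA) separates gray from white
matter, and the primary eigenvector separates white-matter tracts by
fiber orientation.  `dtiparc` is for researchers who want an automated,
reproducible DTI parcellation that exploits all of these contrasts and a
whole *library* of atlases at once.

## The model

Each voxel x carries the 5-vector I(x) = (FA, MD, |e₁ₓ|, |e₁ᵧ|, |e₁𝓏|).
The parcellation W is the MAP estimate

    Ŵ = argmax_W p(W | I),

solved by EM with the interpreting atlas A as a latent variable.  Per
atlas a and structure l, each channel's intensity is a 1-D Gaussian
mixture fitted from the atlas (2 components for structures < 1000 mm³,
3 above); channels are conditionally independent, so

    p(I(x) | l, a) = ∏_c Σ_k w_k N(I_c(x); μ_k, σ²_k).

Atlases are registered to the subject by a two-channel (FA + MD)
diffeomorphic registration; each (atlas, structure) gets a local
12-parameter affine refinement with a diagonal Gaussian prior (variance
0.01 on linear deviations, 100 on translations).  The EM loop alternates
(1) a per-voxel atlas selector ∝ intensity likelihood × structure Dice ×
deformation prior × affine prior, normalized over atlases, (2) a label
update per voxel maximising Σ_a selector × likelihood × trilinear
deformed-label prior, and (3) re-optimisation of the local affines,
until labels stabilise (changed-voxel fraction < 1e-4) or 30 iterations.
Details and design rationale: `docs/methods.md`.

## Worked example

Everything is testable without clinical data through the built-in
phantom generator, which builds a deformed atlas library around a
ground-truth labeled multi-contrast volume:

```python
import dtiparc as dp

lib = dp.make_library(dp.default_spec(1), n_atlases=4, seed=1)
model = dp.MultiAtlasFusion(lib.subject.image, lib.atlases)
res = model.fit()          # registers, fits signatures, runs the EM loop
print(res.history[["iteration", "changed_fraction", "objective"]])
print(res.dice_vs(lib.subject.labels))
```

Output from this exact run:

```
   iteration  changed_fraction     objective
0          1          0.009766  1.117874e+06
1          2          0.000000  1.117928e+06
               dice
structure
1          1.000000
2          0.997118
3          1.000000
4          1.000000
5          1.000000
6          0.996796
```

The loop converged in 2 iterations (about 1% of voxels changed in the
first label update, none in the second; the fused-score objective is
non-decreasing).  The Dice table compares the fused parcellation with
the held-out subject's ground truth per structure — mean 0.999 here,
against 0.967 for the best single-atlas nearest-neighbour propagation.
`res.summary()` prints the convergence report plus the per-structure ROI
table (volume in mm³, mean FA, mean MD); `res.roi_stats()` returns it as
a DataFrame.

The same pipeline is scriptable from the shell:

```sh
dtiparc simulate --out study --seed 7 --n-atlases 4
dtiparc parcellate --subject study/subject --atlas-dir study/atlases \
        --out study/parc.nii.gz --seed 7
dtiparc quantify --labels study/parc.nii.gz --subject study/subject \
        --out study/roi.csv
```

Peripheral structures can be split into CSF / cortex / peripheral white
matter with the standard thresholds (MD ≥ 0.0015 mm²/s → CSF, excluded
from analysis; FA > 0.2 → white matter) via
`dp.decompose_peripheral(labels, image, peripheral_ids)`, and
scan-rescan / cross-subject variability summaries via
`dp.scan_rescan_report` and `dp.cross_subject_variability`.

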