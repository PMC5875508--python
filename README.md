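# atlasseg

Automatic segmentation of organs at risk in thoracic and abdominal CT by
hierarchical multi-atlas registration with level-set refinement.

Delineating normal organs for radiotherapy planning is slow manual work,
and in the abdomen the classic single-atlas approach struggles: liver,
spleen, kidneys and stomach share Hounsfield-unit (HU) ranges, patients
vary widely in habitus and posture, and scans differ in calibration and
artifacts.  `atlasseg` implements the hierarchical strategy that makes
atlas segmentation work in this regime:

1. **Multi-atlas registration** — each of N presegmented reference scans
   (atlases) is warped onto the patient by a two-phase affine alignment
   (30 iterations translations-only, then 30 iterations full affine)
   followed by a four-stage cubic B-spline free-form deformation
   (control-node spacing 100 → 20 mm, LBFGS), both driven by Mattes mutual
   information so monotone intensity differences between scanners don't
   matter.  The deformable metric is restricted to the atlas's organ masks
   dilated by 10 mm, so implants or bowel gas absent from the atlas cannot
   distort the match.
2. **STAPLE fusion** — the N warped masks for each organ are fused by
   expectation-maximization: each atlas is a rater with latent sensitivity
   p and specificity q, and 20 EM iterations estimate the voxelwise
   probability w_i that the organ is present,

       w_i = a_i / (a_i + b_i),
       a_i = pi * prod_j p_j^{D_ij} (1-p_j)^{1-D_ij},
       b_i = (1-pi) * prod_j (1-q_j)^{D_ij} q_j^{1-D_ij},

   thresholded at w >= 0.7 to form the organ seed.
3. **Per-structure refinement** — the seed's HU interval is extracted by a
   four-class, 125-bin multi-level Otsu analysis of its neighbourhood; a
   threshold level set (weights: propagation 1, curvature 0.5, up to 500
   iterations) adapts the shape to that interval; a short geodesic
   active-contour pass (curvature weight 3, 30 iterations) smooths the
   result and grows it across motion-blurred borders up to the next image
   edge.

Accuracy is reported as the Dice coefficient 2|A∩B|/(|A|+|B|) and the
symmetric mean surface distance in mm (plus Hausdorff as a spike
detector).  Since no clinical dataset ships with the package, a phantom
module generates CT-like volumes with known ground truth — similar-HU
adjacent organs, fat capsules, lungs, bone, bowel gas, smooth random
inter-subject deformations, posture changes, intensity remaps and noise —
on which every stage is validated end to end (see `docs/methods.md`).

## Worked example

```python
from atlasseg import (PhantomSpec, generate_phantom, AtlasLibrary,
                      SegmentationConfig, segment, dice)

case = generate_phantom(PhantomSpec(seed=7))        # patient + 3 atlases
library = AtlasLibrary.from_phantom(case)
masks, report = segment(case.patient, library, config=SegmentationConfig(seed=7))

for mask in masks:
    truth = case.truth_for(mask.organ_label)
    print(f"{mask.organ_label:13s} {report.per_organ[mask.organ_label]['status']:3s}"
          f"  dice={dice(mask, truth):.3f}")
```

On the seed-7 phantom this prints (about 11 minutes on one CPU — three
deformable registrations dominate):

```
kidney_left   ok   dice=0.999
kidney_right  ok   dice=1.000
liver         ok   dice=1.000
lung_left     ok   dice=1.000
spleen        ok   dice=0.999
```

The run report also records, per organ, each atlas's agreement with the
fused seed, the STAPLE sensitivity/specificity per atlas, the extracted HU
interval and per-step volumes.  Organs that fail fusion or refinement QA
are reported as `failed` (to be contoured manually) without aborting the
run.

The same pipeline is scriptable from the shell:

```bash
atlasseg phantom generate --out demo/ --seed 7
atlasseg segment --patient demo/patient.nii.gz --library demo/manifest.json \
                 --out demo/result --seed 7
atlasseg evaluate --auto demo/result/liver.nii.gz \
                  --manual demo/truth_liver.nii.gz --report liver.json
```

`atlasseg watch --inbox DIR --library manifest.json` runs the clinical-style
service loop: every new volume dropped into the directory is segmented
once (content-hash deduplicated) and results are written beside it.

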