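# erupt3d

Registration-based 3D measurement of tooth eruption from paired CBCT
scans, built for the clinical question of how an unerupted maxillary
canine moves after alveolar bone grafting in cleft lip and palate
patients — but applicable to any "how did this tooth move between two
scans of the same patient" problem.

Given a pre-operative and a follow-up cone-beam CT volume, `erupt3d`:

1. rigidly registers the follow-up onto the baseline by **mutual-information
   maximization restricted to a stable bony region of interest** (the
   maxilla away from the erupting dentition), so that patient repositioning
   between scans is cancelled without being contaminated by the moving
   tooth;
2. segments the tooth in both volumes (livewire contouring with
   shape-based contour interpolation, or intensity-band thresholding);
3. registers the two tooth surfaces by trimmed point-to-surface **ICP**
   and decomposes the recovered rigid transform — rotation via **SVD**,
   translation as the centroid displacement — into the six clinically
   named degrees of freedom:

   | symbol | meaning | units | + sign |
   |---|---|---|---|
   | dMD | mesial/distal translation | mm | mesial |
   | dPF | palatal/facial translation | mm | facial |
   | dIA | incisal/apical translation | mm | incisal |
   | pitch | rotation about the M/D axis | deg | counter-clockwise |
   | roll | rotation about the P/F axis | deg | counter-clockwise |
   | yaw | rotation about the I/A axis | deg | counter-clockwise |

   (extrinsic Euler order pitch → roll → yaw; the order and conventions
   are embedded in every output), plus pre/post tooth volumes in mm³;
4. quantifies registration error by **part comparison**: surface distance
   maps between the thresholded ROI surfaces summarized as MAD ± SD;
5. validates the whole chain with **ICC(2,1)** reliability statistics,
   exact Wilcoxon signed-rank tests, and a ground-truthed **synthetic
   phantom generator** whose paired volumes contain a bone-like block and
   a canine-like tooth moved by known rigid motions.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Generate a phantom case with a known tooth motion and measure it:

```python
import numpy as np
from erupt3d.phantom import batch_generate
from erupt3d.pipeline import run_phantom_case, truth_measures

pairs, truth_table = batch_generate(1, seed_list=[1])
pair = pairs[0]

result = run_phantom_case(pair, run_seed=7)
print("truth   ", np.round(truth_measures(pair).components(), 3))
print("measured", np.round(result.measures.components(), 3))
print("registration MAD [mm]:", round(result.registration_mad_mm, 4))
print("tooth volume pre/post [mm^3]:",
      round(result.measures.volume_pre, 1),
      round(result.measures.volume_post, 1))
```

Output from this exact script:

```
truth    [ 0.071  2.703 -2.135  7.178 -3.011 -1.227]
measured [ 0.086  2.727 -2.171  7.181 -3.109 -1.206]
registration MAD [mm]: 0.0161
tooth volume pre/post [mm^3]: 386.5 386.7
```

Reading the numbers: the phantom's tooth was moved 0.07 mm mesially,
2.70 mm facially and 2.14 mm apically (negative dIA), with 7.2° pitch,
−3.0° roll and −1.2° yaw, on top of a simulated head repositioning. The
pipeline recovers each component to within a few hundredths of a mm /
tenths of a degree; the 0.016 mm part-comparison MAD says the stable-bone
registration step itself is sub-voxel-accurate (voxels are 0.2 mm); and
the segmented tooth volumes agree with the analytic solid volume
(387.0 mm³) to well under 1%.

The same workflow runs from the shell:

```sh
erupt3d simulate --seed 1 --out case1/
erupt3d register --fixed case1/pre.mha --moving case1/post.mha \
                 --roi case1/roi.json --out case1/t.txt --resampled case1/post_reg.mha
erupt3d validate-reg --pre case1/pre.mha --post case1/post_reg.mha \
                     --band 300,1200 --out case1/mad.json
erupt3d segment --volume case1/pre.mha --auto --band 1200,1e9 --out case1/tooth_pre.stl
erupt3d analyze --pre case1/tooth_pre.stl --post case1/tooth_post_reg.stl \
                --frame case1/frame.json --out case1/measures.json
```

(`erupt3d run --config case.yaml --out out/` chains all stages;
`erupt3d config --defaults` prints every default setting.)

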