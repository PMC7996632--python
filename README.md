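# interiorct

Background-compensated interior tomography for 2D fan-beam CT.

High-resolution imaging of a small region — a temporal bone, a lung nodule, a
coronary plaque — does not require irradiating and detecting the whole head
or chest: a *local* scan whose narrow detector only covers rays through the
region of interest (ROI) is enough, at a fraction of the dose and detector
cost. The catch is that such laterally truncated projections cannot be
reconstructed accurately on their own: every measured ray still carries the
attenuation of everything outside the ROI, and naive filtered backprojection
(FBP) produces the classic cupping artifact and a large attenuation offset.

This package implements and studies the *background compensation* cure.
Projection is linear, so for any partition of the object into ROI and
background,

```
P_ROI = P_global − P_background ,
```

and when the local scan window covers the ROI, the truncated parts of
`P_ROI` vanish:

```
P_ROI = P_local − trunc(P_background) .
```

The background sinogram is *estimated*: a prior low-resolution global scan is
reconstructed, the attenuation inside the ROI is set to zero, the resulting
background volume is digitally reprojected along the local-scan geometry at
the coarse sampling, and the coarse estimate is interpolated up to the local
detector/view sampling. Residual high-frequency errors in the estimate
largely cancel during backprojection, so the pure ROI sinogram — and with it
a quantitatively accurate interior FBP reconstruction — is obtained from two
cheap ingredients: a routine global scan and a narrow-detector local scan.

Because the method subtracts a *registered* reprojection, its practical
limit is geometric misalignment between the two scans. The package
quantifies this: isocenter-offset, initial-view-angle and magnification-error
sweeps with the SSIM / PSNR / MSE / RMSRE metric suite, plus an additive
bias correction that forces a known region (air pockets inside the ROI) to
its known attenuation and rescues, in particular, the magnification-error
case.

## What is inside

| module | contents |
| --- | --- |
| `interiorct.geometry` | fan-beam scan geometry, magnification/resolution/FOV relations, misalignment parameters |
| `interiorct.phantom` | synthetic head phantom (skull ring, air cavities, temporal-bone ROI, resolution bar patterns), HU→µ conversion, TIFF/PNG I/O |
| `interiorct.projector` | ray-driven fan-beam forward model (numba), truncation, Poisson noise, focal-spot blur |
| `interiorct.recon` | flat-detector fan-beam FBP (Hann/ram-lak), naive edge-padded interior FBP |
| `interiorct.compensation` | background building, misaligned reprojection, sinogram up-sampling, compensation, bias correction, full pipeline |
| `interiorct.metrics` | masked SSIM/PSNR/MSE/RMSRE, error profiles, effective-ROI radius |
| `interiorct.study` | the desk-scale virtual study: accuracy experiment, three misalignment sweeps, CSV tables |
| `interiorct.cli` | `interiorct phantom / scan / reconstruct / accuracy / sweep-*` |

All lengths are millimetres, angles degrees, attenuation cm⁻¹; line
integrals are dimensionless.

## Worked example

```python
from interiorct.study import StudyConfig, run_accuracy_experiment

result = run_accuracy_experiment(StudyConfig(seed=1))
print(f"compensated RMSRE {result.compensated_rmsre:.4f}")
print(f"direct      RMSRE {result.direct_rmsre:.4f}  ({result.error_ratio:.1f}x worse)")
print({w: round(m, 2) for w, m in result.modulation.items()})
```

prints (seed 1, default desk-scale configuration)

```
compensated RMSRE 0.0070
direct      RMSRE 0.1448  (20.6x worse)
{50.0: 0.23, 75.0: 0.57}
```

That is: with perfect registration the compensated interior reconstruction
agrees with the untruncated high-resolution reference to 0.70 % RMS relative
error inside the 21 mm evaluation mask, while the naive truncated-data FBP is
off by 14.5 % — a 20.6× larger error, the cupping/offset failure mode the
compensation removes. The embedded 600 HU bar patterns are clearly resolved
at 75 µm bar width (modulation 0.57) but not at 50 µm (0.23), placing the
local-protocol resolution between the two, as the 110 µm detector pitch at
magnification 2 predicts.

The same study object runs the misalignment sweeps:

```python
from interiorct.study import sweep_magnification
df = sweep_magnification(StudyConfig(seed=1))
print(df.loc[["RMSRE", "RMSRE (Crt.)"]].round(4))
```

showing RMSRE growing from 0.7 % (aligned) to 15.3 % at −20 % magnification
error and the bias correction pulling it back to 1.3 %, evaluated on the
16.8 mm mask that the shrunken effective ROI dictates.

From a shell, the same experiments write run directories with TIFF images,
PNG previews, CSV tables and the resolved config:

```bash
interiorct accuracy --out runs/accuracy --seed 1
interiorct sweep-isocenter --out runs/iso --seed 1
```

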