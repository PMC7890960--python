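# roikit

Quantitative extraction and measurement of 3D structures in fluorescence
microscopy z-stacks, built for cell-nucleus analysis: chromosome
territories, chromocenters, nuclear bodies and FISH signals imaged by
confocal microscopy at anisotropic voxel spacing (typically ~70 nm in xy
and ~210 nm in z).

The library covers the full desk workflow of a microscopist:

1. **ROI extraction** — manual, Otsu, multi-level Otsu, Rényi-entropy and
   Shanbhag histogram thresholds; range thresholding; connected components
   with minimum-size filtering; two-stage (core + envelope) extraction via
   seeded watershed or **Multiscale Opening**.
2. **Incremental segmentation** — any extraction result can become the
   mask for the next level (segment the nucleus, cut it out, then segment
   structures inside it).
3. **Measurements in physical units** — volume, surface, Feret diameter,
   brightness statistics, the mass-distribution moment Σ m_v r_v²,
   weighted-PCA principal axis lengths, and mask-relative measures:
   border-rim content, concentric distance bands (equal radius or equal
   volume), and ROI-to-mask distances.
4. **Deterministic batch processing** — extraction profiles, pipelines and
   measurement sets serialize to JSON; a batch run over many TIFFs
   produces a CSV plus full provenance, byte-identical for any worker
   count.
5. **Ground-truth phantoms** — digital balls, ellipsoids, bridged blobs
   and multi-nucleus scenes with exact truth labels, so every algorithm is
   testable without microscope data.

## Multiscale Opening in one paragraph

Two bright structures separated by less than the microscope's resolution
appear as one thresholded blob. Classical seeded watershed must hand every
envelope voxel to some seed, and splits an elongated object at each
internal brightness maximum. Multiscale Opening instead works on a fuzzy
membership field μ that ramps from 0 at the envelope threshold to 1 at the
core threshold. Path costs on the 26-adjacency voxel graph are the
anisotropic physical step length weighted by (2 − μ_u − μ_v)/2 toward
objects (bright paths are cheap) and (μ_u + μ_v)/2 toward the background
(dim paths are cheap). A voxel is labeled only if its fuzzy distance to an
object is strictly smaller than its fuzzy distance to the background, and
newly labeled voxels re-seed the next iteration. Ties between objects
leave a one-voxel separating line.

## Worked example

Separate two conjoined blobs (radius 10 voxels, joined by a bridge at 30 %
of their brightness, 5 % Gaussian noise) and measure them:

```python
from roikit import multiscale_opening, MeasurementSet, MeasurementSpec, \
    evaluate_measurement_set
from roikit.phantom import bridged_blobs_phantom

ph = bridged_blobs_phantom(noise_sd=5.0, seed=7)
labels = multiscale_opening(ph.image.channel(0), core_threshold=60.0,
                            envelope_threshold=15.0, spacing=ph.image.spacing)
print("components:", labels.component_count)

mset = MeasurementSet(measurements=[
    MeasurementSpec(id="volume"), MeasurementSpec(id="diameter"),
    MeasurementSpec(id="brightness_mean"),
])
table = evaluate_measurement_set(ph.image, labels, mset, mask=ph.truth_mask)
print(table.table.to_string(index=False))
```

prints

```
components: 2
source component  volume [um3]  diameter [um]  brightness_mean [intensity]
 image         1      1.434426       1.680000                    99.771385
 image         2      1.433397       1.471666                    99.855171
 image     total           NaN            NaN                          NaN
```

Both blobs are recovered as separate components (a 700 nm ball has volume
(4/3)π·0.7³ ≈ 1.44 µm³; each measured volume also includes the blob's half
of the bridge minus the voxels the fuzzy-distance rule leaves as
background), with mean brightness ≈ 100, the generating intensity.

The same analysis from a shell:

```
roikit phantom make --kind bridged --seed 7 --out data/
roikit extract --image data/bridged.tiff --profile mso_profile.json \
       --out-labels data/labels.tiff
roikit measure --image data/bridged.tiff --labels data/labels.tiff \
       --measurements volumes.json --out data/table.csv
roikit batch --inputs 'data/*.tiff' --pipeline pipeline.json \
       --measurements volumes.json --workers 4 --out results/
```

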