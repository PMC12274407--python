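# neurophen

Quantitative neurophenotyping for mouse models of cerebellar
neurodegeneration (e.g. lysosomal-trafficking knockouts on a B6
background): Purkinje-cell **linear density** from H-DAB histology,
**inkblot gait geometry** from runway paw prints, and the **group
statistics** used to compare genotypes — plus a ground-truthed
synthetic-data module so the entire chain is verifiable without raw
slides or animals.

## What it computes

**Purkinje linear density.**  Calbindin/hematoxylin sections are
separated by color deconvolution in optical-density space
(`OD_c = -log10(I_c / I_max)`, unmixed against the Ruifrok-Johansson
H-DAB basis).  The nuclei-dense granular layer is isolated from the
hematoxylin channel by a white top-hat (disk radius 5 px), Gaussian
blur (sigma 90 px), Otsu threshold, and a slight erosion (10 px); its
outer, Purkinje-facing boundary is traced sub-pixel and the layer
length is

```
measured length = polyline length − |endpoint chord|        [mm]
linear density  = manual Purkinje count / measured length   [cells/mm]
```

**Gait metrics.**  From labeled prints (paw, step index, x/y in mm,
print-axis angle), averaged over up to four steps: stride length,
front/hind stance width (perpendicular to the animal's midline), signed
paw angle (positive = out-toeing), and stride angle (midline vs. the
hind-to-opposite-front segment).

**Statistics.**  Two-tailed Student's t (pooled or Welch, explicit
flag), one-way ANOVA, Bonferroni correction, nerve-fiber mean ± SD
summaries, and a deletion-interval utility for the knockout design
(1-based inclusive coordinates).

## Worked example

```python
from neurophen import (SceneParams, gen_cerebellum_image,
                       rgb_to_od, deconvolve, segment_granular_layer,
                       measure_layer, linear_density)

scene = gen_cerebellum_image(SceneParams(rng_seed=1))      # synthetic section
nuclear, dab, _ = deconvolve(rgb_to_od(scene.rgb))
mask = segment_granular_layer(nuclear)
res = measure_layer(mask, scene.truth.reference_point_px)
print(f"measured length: {res.measured_length_mm:.3f} mm")
print(f"density: {linear_density(scene.truth.cell_count, res.measured_length_mm):.2f} cells/mm")
print(f"truth:   {scene.truth.cell_count / scene.truth.measured_length_mm:.2f} cells/mm")
```

prints

```
measured length: 0.620 mm
density: 67.73 cells/mm
truth:   67.38 cells/mm
```

i.e. the full image pipeline recovers the ground-truth linear density
of this scene to about half a percent.  The same stages run from the
command line over a directory of TIFF/PNG sections with a manual-count
CSV:

```bash
neurophen pipeline sections/ counts.csv --out results/
neurophen gait footprints.csv
neurophen interval "chr13:13,630,083_13,778,965del"
```

The last command reports the knockout deletion as 148,883 bp = 149 kb.

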