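# speckleflow

Quantitative analysis for laser speckle contrast imaging (LSCI) of
photothrombotic stroke — temporal-contrast flow mapping, baseline-normalized
cerebral blood flow (CBF) time courses, vascular density, infarct volumetry
and beam-spot metrics — together with a dynamic-speckle phantom generator
that provides every input with known ground truth.

It is written for researchers who monitor cortical blood flow through the
intact (optically cleared) skull: a photosensitizer-plus-light occlusion is
placed at a bregma-referenced spot, flow is mapped repeatedly by LSCI, and
the injury is quantified *ex vivo* on coronal sections. Because raw animal
data are rarely shareable, the package ships a physics-based simulator so
that every stage of the pipeline can be validated against closed-form
speckle statistics and recovered ground truth.

## The statistics at the core

**Temporal speckle contrast.** Over a stack of N raw speckle frames, the
per-pixel temporal contrast is

    Kt(x, y) = σ(x, y) / ⟨I(x, y)⟩,

the standard deviation over frames divided by the mean. Moving red blood
cells decorrelate the speckle field within the camera exposure T, blurring
the speckle and lowering Kt; static scatterers (the skull) contribute to
every frame equally and are suppressed. The flow index **1/Kt²** rises
monotonically with scatterer speed, and is proportional to it when
T ≫ τc (the speckle decorrelation time). Normalizing a region's flow index
against its pre-stroke baseline gives relative CBF (rCBF).

**The validation oracle.** For a speckle field with exponential field
autocorrelation |g1(τ)| = exp(−τ/τc) integrated over an exposure T, the
contrast obeys the closed form

    K²(x) = (e^(−2x) − 1 + 2x) / (2x²),   x = T / τc.

The simulator must reproduce this, which pins down the entire chain from
field synthesis to frame statistics.

**Endpoint measures.** Vascular density is the fraction of vessel-positive
pixels inside a 1 mm × 1 mm ROI of a binarized vessel-stain image. Infarct
volume is the rectangular sum over coronal sections,
V = Σᵢ Sᵢ · h, with Sᵢ the unstained (neuron-loss) area of slice i and
h = 100 μm the slice thickness. Beam spots are summarized by the radial
intensity profile, the half-intensity distance from the spot center, and
background-subtracted total-power ratios. Group comparisons use one-way
ANOVA with ns / * / ** / *** coding.

## Worked example

Simulate a 5-minute-dose stroke scenario (occlusion at day 1, partial
recovery by day 14) and extract ROI time courses end to end:

```python
from speckleflow.io import run_pipeline
from speckleflow.phantom import dose_recovery_scenario

table = run_pipeline("demo", dose_recovery_scenario(5.0),
                     times=[1.0, 7.0, 14.0],
                     shape=(48, 48), pixel_size=0.04, seed=1)
print(table.to_string(index=False))
```

```
 time         roi     mean
  0.0        spot 1.000000
  0.0 eval_circle 1.000000
  1.0        spot 0.056862
  1.0 eval_circle 0.740209
  7.0        spot 0.419820
  7.0 eval_circle 0.850097
 14.0        spot 0.655141
 14.0 eval_circle 0.899904
```

Reading the numbers: the 1-mm irradiated spot collapses to ~0.06 of
baseline on day 1 (flow multiplier 0 leaves only slow residual tissue
dynamics, so the flow index does not reach exactly zero), then recovers to
~0.66 by day 14 — close to the configured truth of 0.64. The surrounding
2-mm evaluation circle is diluted by unaffected parenchyma, so its mean
stays higher throughout. Every output (stack TIFFs, rCBF maps, ROI CSV, a
manifest with the seed) lands in `demo/`.

The same stages are available from the shell:

```bash
speckleflow simulate --out stack.tif --dose 5 --time 14 --seed 1
speckleflow contrast stack.tif --out-prefix maps
speckleflow pipeline --out-dir run --dose 0 --times 1,4,7,14 --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `speckleflow.phantom` | flow maps, stroke scenarios, dynamic-speckle / section / beam phantoms |
| `speckleflow.contrast` | temporal contrast, 1/Kt² flow index, relative CBF |
| `speckleflow.roi` | bregma-referenced ROI geometry, time courses, ANOVA |
| `speckleflow.density` | vessel binarization, vascular-density fraction |
| `speckleflow.infarct` | infarct segmentation, area × thickness volumetry |
| `speckleflow.beam` | radial profiles, half-intensity distance, power ratios |
| `speckleflow.io` / `speckleflow.cli` | TIFF/CSV/JSON I/O, manifests, the `speckleflow` command |

See `docs/methods.md` for the models, parameter choices and limitations.
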