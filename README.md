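# renasl — semiautomatic renal ASL perfusion analysis

`renasl` quantifies renal perfusion from FAIR (flow-sensitive alternating
inversion recovery) arterial spin labeling series and reproduces the full
semiautomatic analysis chain used in scan–rescan reproducibility studies
of kidney perfusion:

1. **Live-wire (intelligent scissors) delineation** of the kidney on the
   M0 image from a handful of user seed points, via a minimum-cost path
   search over Laplacian zero-crossing, gradient-direction and
   gradient-magnitude link costs.
2. **Very stiff affine contour registration** of that outline onto every
   global-inversion image of the series (translation, rotation, scaling,
   shearing), with per-pair **quality control**: pairs whose residual
   contour-to-edge cost exceeds twice the series median are rejected.
3. **Compartment separation** of the registered kidney into calyces,
   medulla and cortex by k-means clustering on (α · gray value,
   distance-to-center) features computed on the average of the registered
   global-inversion images, followed by a **morphological cortex
   purification** that guarantees a cortex-only cortical ROI.
4. **Single-TI FAIR quantification** per pair,

       f = 60 · λ · (selective − global) · exp(TI/T1_blood) / (2 · M0 · TI)

   in mL/min/100 g (λ = 80 mL/100 g, T1_blood = 1.2 s at 1.5 T,
   TI = 1200 ms by default), then averaging of the **4 highest-perfusion
   pairs** that passed QC into the final map and per-compartment summary.
5. **Reproducibility statistics** for repeated-measures tables:
   within-subject CV, two-way random-effects absolute-agreement ICC
   (single- and average-measures), Bland–Altman limits of agreement,
   paired t-test and Pearson correlation.

Real scanner data are rarely shareable, so the package ships a
**synthetic kidney phantom generator** (bean-shaped cortex/medulla/calyx
geometry, signal differences synthesized by inverting the quantification
formula, per-pair breathing jitter, optional corrupted pairs, Gaussian
noise) with exact ground truth, plus a two-level normal **cohort
simulator** for the statistics. Every stage is tested against these
truths.

## Worked example

```python
from renasl import PhantomSpec, make_phantom, run_acquisition
from renasl.phantom import default_seed_points

spec = PhantomSpec(seed=42)          # 8 pairs + M0, 2% noise, breathing jitter
series, truth = make_phantom(spec)
summary, artifacts = run_acquisition(series, default_seed_points(spec))
print(f"whole {summary.whole_parenchyma:.1f}  cortex {summary.cortex:.1f} "
      f"medulla {summary.medulla:.1f}  pairs {summary.pair_indices_used}")
```

prints

```
whole 314.1  cortex 341.2  medulla 292.4  pairs (0, 5, 6, 7)
```

i.e. the pipeline recovers the phantom's true compartment perfusions
(cortex 337.10, medulla 279.61, area-weighted whole 307.16 mL/min/100 g)
to within a few percent from noisy, jittered data; all 8 pairs passed QC
and the 4 with the highest kidney-mean perfusion were averaged.
`artifacts` carries the contour, the compartment masks (raw and
purified), the per-pair transforms and residuals, and the averaged map.

The same run from a shell:

```bash
renasl phantom --seed 42 --out demo/
renasl run --series demo/ --seeds demo/seeds.json --out demo/out/
renasl cohort --seed 1 --out cohort.csv
renasl report --cohort cohort.csv --out report.json
```

`report.json` contains session-wise and total ICC and CV, Bland–Altman
limits, the paired t-test and Pearson R² for the simulated two-session,
three-repetition design.

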