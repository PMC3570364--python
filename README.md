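# airwayct

Quantification of airway wall thickness and emphysema on low-dose chest
CT, for researchers studying smoking-related airflow limitation.

Airflow limitation in smokers has two structural substrates: thickened
airway walls and parenchymal destruction (emphysema). Both are measurable
on a single low-dose CT. This package implements a measurement chain that

* measures **airway wall thickness at a fixed internal lumen diameter of
  3.5 mm (AWT₃.₅)** — instead of standardizing to a 10 mm perimeter (pi10)
  from a handful of selected airways, every assessable location in every
  lobe whose lumen is 3.5 ± 0.25 mm contributes, weighted by its
  **assessed perimeter fraction** (APF, the fraction of the perimeter on
  which the outer wall border is detectable; locations below 25% are
  excluded). Wall thickness is obtained by **integrating HU across the
  wall**, `AWT = Δr·Σ clip((hu−b)/(W−b))`, which is invariant under the
  scanner blur and therefore avoids the systematic overestimation that
  full-width-at-half-maximum calipers suffer on sub-millimetre walls;
* scores **emphysema** as Perc15 (the HU below which 15% of lung voxels
  fall) and %LAA−950 (fraction of voxels below −950 HU), after
  recalibrating the whole scan so trachea air is exactly −1000 HU and
  excluding the airway lumen;
* selects the optimal fixed diameter by sweeping candidates 2.5–5.0 mm and
  maximizing cumulative APF;
* relates both markers to airflow limitation (FEV₁ %predicted) with
  univariate and multivariable OLS, including a sequential / semi-partial
  variance decomposition, plus rank tests and Bland–Altman agreement.

Because screening-cohort CTs are not redistributable, the package includes
two first-class synthetic-data generators: a **digital CT phantom**
(airway trees of known lumen diameter and wall thickness embedded in
parenchyma with a controllable low-attenuation fraction, rendered at the
screening protocol's geometry: 0.59–0.68 mm pixels, 1 mm slices at 0.7 mm
increments, soft-kernel blur, low-dose noise) and a **cohort simulator**
calibrated to a heavy-smoker screening population. See
[docs/methods.md](docs/methods.md) for the models and their assumptions.

## Worked example

Generate a five-lobe phantom, measure it, and score emphysema:

```bash
airwayct phantom --template five-lobe --fov 150 --matrix 220 \
    --noise 25 --seed 1 --out phantom/
airwayct measure-awt --ct phantom/ct.nii.gz --labels phantom/labels.nii.gz \
    --diameter 3.5 --tol 0.25 --out awt/
airwayct emphysema --ct phantom/ct.nii.gz --labels phantom/labels.nii.gz \
    --out metrics.json
```

which prints

```
phantom written to phantom/
AWT_3.5 = 0.641 mm over 94 locations (APF 93.8)
Perc15 -910.7 HU, %LAA-950 0.84%
```

The phantom's generation-5 branches carry a true lumen diameter of 3.5 mm
and wall thickness 0.63 mm (18% of the diameter): the measured AWT₃.₅ of
0.641 mm recovers the truth to 0.011 mm, with 94 assessable locations of
APF ≈ 1 each. No emphysema was simulated; the 0.84% low-attenuation
fraction is what low-dose noise (SD 25 HU) alone pushes below −950 HU, and
Perc15 sits at the 15th percentile of the noisy textured parenchyma
(≈ −911 HU).

Simulate a cohort and run the statistical layer:

```bash
airwayct cohort-sim --n 492 --seed 7 --out cohort.csv
airwayct stats --cohort cohort.csv --out stats/
# -> R^2 = 0.428; outputs in stats/
```

`stats/variance_shares.json` then reports the variance decomposition of
FEV₁ %predicted — with the default calibration, log-AWT explains 34.3%
and Perc15 7.7% of the variance (sequential, AWT entered first), i.e.
airway wall thickening contributes substantially more to airflow
limitation than emphysema in this (simulated) population.

In Python the same chain is three calls:

```python
from airwayct import (build_airway_tree, PhantomTruth, AcquisitionSpec,
                      rasterize_phantom, densitometry)
from airwayct.airway_quant import measure_airways, subject_metrics

branches = build_airway_tree("five-lobe", seed=1)
truth = PhantomTruth(branches=branches, emphysema_fraction=0.05)
ct, labels = rasterize_phantom(
    branches, truth, AcquisitionSpec(fov_mm=150, matrix=220, seed=1))
sections, locations = measure_airways(ct, labels=labels)
metrics = subject_metrics(locations, densitometry(ct, labels))
print(metrics.awt35_mm, metrics.perc15_hu, metrics.laa950_pct)
```

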