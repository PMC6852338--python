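# biovocem

A tested Python implementation of a biogenic volatile organic compound
(BVOC) emission inventory for forest plantations, of the kind built for
Andean eucalypt / pine / alder stands: from two-band (red, near-infrared)
reflectance scenes and meteorological-station records to per-species
monoterpene and other-BVOC emission totals, together with the supervised
land-cover classification, temperature interpolation and statistics that
surround such an inventory.

## Who this is for

Researchers and practitioners in ecological remote sensing and air-quality
inventory work who need a transparent, scriptable version of the classic
workflow: NDVI and maximum-likelihood classification of satellite imagery,
per-class area and deforestation-rate accounting, hourly temperature
surfaces by universal kriging, and the Guenther temperature-exponential
emission model. A synthetic-data module generates every input with known
ground truth, so the whole pipeline can be exercised and validated without
any satellite or field data.

## The model

Hourly emission of compound class *c* (monoterpenes or other BVOC) from a
grid cell of land-use class *J* at leaf temperature *T* (K):

```
E_c(K, hour) = EF_J,c · M(T) · FBD_J · A          [µg h⁻¹]
M(T) = exp(β (T − T_s)),   β = 0.09 K⁻¹,  T_s = 303 K
```

where `EF_J,c` is the standard emission factor (µg g⁻¹ h⁻¹), `FBD_J` the
foliar biomass density (g m⁻²) and `A` the cell area (900 m² for a 30 m
pixel). Aggregation is fixed: a day sums its 24 hours, a month is 30 ×
one representative day, a year sums its 12 months; totals are reported in
metric tons (10¹² µg).

Around the emission core:

- **spectra** — detector-junction jump correction, robust rejection of
  out-of-trend spectra, representative (mean) signatures, field NDVI from
  the 640–670 nm and 850–880 nm window means.
- **landcover** — raster NDVI, Gaussian maximum-likelihood classification
  from training polygons, confusion matrix / overall accuracy / Cohen's
  kappa, per-class areas (ha) and two-date change with annual rates.
- **tempfield** — per-station per-hour linear models `T(h) = a·x + b`
  against the daily mean, and universal kriging (variogram + spatial
  drift) of each hour's station values onto the raster grid.
- **stats** — finite-population sample size `n = Z²pqN / (NE² + Z²pq)`,
  Pearson correlation, order-3 moving average, balanced two-way ANOVA with
  Tukey HSD.
- **synth** — seeded generators for scenes, station series, signature
  libraries and VOC/meteorology tables, all with ground truth attached.

## Worked example

```python
import numpy as np
from biovocem import synth
from biovocem.landcover import accuracy_assessment, classify_ml, train_classifier
from biovocem.emissions import inventory, synthetic_default_params

spec = synth.SceneSpec(width=100, height=100, seed=7)
red, nir, truth, training = synth.generate_scene(spec)
clf = train_classifier([red, nir], training)
predicted = classify_ml([red, nir], clf, legend=truth.legend)
report = accuracy_assessment(predicted, truth)
print(f"accuracy = {report.overall_accuracy:.4f}, kappa = {report.kappa:.4f}")
print(predicted.area_by_class())

surfaces = {m: [predicted.labels.with_values(np.full(predicted.labels.shape, 11.0))] * 24
            for m in range(1, 13)}          # constant 11 °C diurnal cycles
inv = inventory(predicted, surfaces, synthetic_default_params())
print(inv[inv["period"] == "annual"]
      .pivot(index="species", columns="compound", values="emission_tons")
      .round(3))
```

prints

```
accuracy = 0.9928, kappa = 0.9892
Eucalyptus globulus    297.00
Pinus radiata          306.81
Alnus acuminata        296.19
Name: area_ha, dtype: float64
compound              bvoc  monoterpene
species                                
Alnus acuminata      2.252        0.150
Eucalyptus globulus  2.470        4.939
Pinus radiata        2.916        5.832
```

The classifier recovers the synthetic truth map almost perfectly
(kappa ≈ 0.99, well above the 0.85 "almost perfect" bar used in
classification quality assessment); each ~300 ha species stripe then emits
a few tons per year under the bundled synthetic parameter table at a cool
constant 11 °C — monoterpene-dominated for eucalypt and pine, other-BVOC
dominated for alder, whose monoterpene factor is near zero.

The same stages are scriptable from a shell (`biovocem synth scene`,
`biovocem classify`, `biovocem change`, `biovocem stats corr`, …) and an
end-to-end configured run is `biovocem run config.yaml`, which writes all
products plus a manifest with hashes and the seed.

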