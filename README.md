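# vasculometry

Quantitative vascular anatomy for plant-organ cross-sections, built around
the morphometry of grape-berry receptacle xylem: per-vessel lumen geometry,
idealized and hydraulically weighted diameters, vessel density, relative
lumen area, and potential area-specific hydraulic conductivity with its
decomposition over diameter size classes — plus constrained logistic
sugar-ripening kinetics with AIC curve-sharing comparison, xylem/phloem
tissue-area allocation analysis, and the ANOVA/Fisher's-LSD machinery used
to compare cultivars and section positions.

It is written for plant hydraulics and fruit-development researchers who
measure vessels in light-microscopy cross-sections and want the whole chain
— segmentation, morphometry, hydraulics, statistics — reproducible and
testable. A synthetic-data module generates cross-section images, vessel
tables, TSS time series and tissue-area pairs with known ground truth, so
every stage can be validated without any external data.

## The quantities

For an elliptical lumen with semi-axes *a* ≥ *b* (μm), the idealized
(hydraulic-equivalent circle) diameter is

    d = (32 (a·b)³ / (a² + b²))^(1/4)

The population's mean hydraulically weighted diameter weights each conduit
by its Hagen–Poiseuille contribution:

    d_h = Σ d⁵ / Σ d⁴

Vessel density is VD = n / A_c-xylem (vessels mm⁻²), and the relative lumen
area is total lumen area over the xylem region area. The potential
area-specific hydraulic conductivity of the region is

    K = (π ρ / (128 η A_c-xylem)) Σ d⁴      [kg m⁻¹ MPa⁻¹ s⁻¹]

with η = 1.002×10⁻⁹ MPa·s and ρ = 998.2 kg m⁻³ (water at 20 °C). K is
decomposed over contiguous 4-μm diameter classes (default five classes,
0–20 μm), each class's K computed against the same region area so class
values sum exactly to the total.

Sugar ripening is modelled as a constrained logistic in days after anthesis:

    Y(x) = Y_M·Y_0 / ((Y_M − Y_0) e^(−k·x) + Y_0)

with Y_0 ∈ [0, 5] °Brix, Y_M fixed at 32 °Brix and rate constant k (day⁻¹);
curve sharing across cultivars is selected by small-sample corrected AICc.

## Worked example

```python
import numpy as np
import vasculometry as vm

# synthesize a 250-vessel xylem region (76,400 um^2) and render it
spec = vm.VesselSpec(n_vessels=250)
truth = vm.generate_vessel_population(spec, 76_400.0, seed=42)
side = int(round(np.sqrt(76_400.0) / 0.2))
img, sidecar = vm.render_cross_section(
    truth, vm.ImageSpec(width_px=side, height_px=side, pixel_size_um=0.2,
                        noise_sd=0.05, seed=43))

# segment and measure
vessels, labels = vm.segment_vessels(img, pixel_size_um=0.2)
pop = vm.VesselPopulation(vessels, A_c_xylem=76_400.0)
summary = vm.summarize_population(pop)
K = vm.conductivity(pop.diameters(), 76_400.0)
```

Output:

```
vessels: 250 (truth: 250)
d_h   = 11.85 um   (truth 11.79)
VD    = 3272 mm^-2 (truth 3272)
A_lum = 14.50 %    (truth 14.50)
K     = 0.436 kg m-1 MPa-1 s-1 (truth 0.422)
```

All 250 lumina are recovered; the hydraulically weighted diameter is within
0.5% of the generating truth and K — which amplifies any diameter error by
the fourth power — within ~3%. The size-class decomposition
(`vm.size_class_decomposition(pop.diameters(), 76_400.0)`) prints:

```
class_label   n  abundance_pct  K_share_pct
        0-4  16            6.4          0.2
        4-8 154           61.6         16.6
       8-12  70           28.0         43.9
      12-16   8            3.2         21.9
      16-20   2            0.8         17.3
```

i.e. most vessels are narrower than 8 μm, but the 8–16 μm classes carry the
majority of the potential conductivity — the characteristic pattern for
this tissue.

A command-line interface mirrors the library
(`vasculometry simulate|segment|morphometry|hydraulics|ripening|allocation|stats|run`);
`vasculometry run --config run.yaml` executes the full
simulate→segment→measure→report pipeline with provenance and caching.

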