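# crystalsizer

Automated facet sizing of a single faceted crystal from time-lapse
microscopy, with downstream facet growth-rate extraction and growth
interface-kinetics analysis.

## The problem

Designing a crystallization process needs face-specific growth kinetics:
how fast each habit face (hkl) of a crystal advances as a function of the
relative supersaturation σ = (C − C_e)/C_e.  For needle-like crystals such
as the β polymorph of L-glutamic acid (β-LGA), the slow {021} prismatic
side faces are notoriously hard to measure by hand from microscope images,
and manual edge tracking across hundreds of frames is slow and
error-prone.

`crystalsizer` automates the measurement.  The projected outline of the
crystal is modelled as a six-sided template — the intersection of three
pairs of parallel half-planes, parametrised by a centre, one orientation
angle θ₁ (two further directions sit at fixed crystallographic offsets,
±54° for β-LGA), and three distance *pairs* (d⁺ᵢ, d⁻ᵢ) so asymmetric
growth and faces that "grow out" of the outline are representable.  For
each frame:

1. **segment** — a point-prompted backend produces a binary mask of the
   crystal (default: global Otsu threshold, hole filling, connected
   component at the prompt; a promptable foundation-model segmenter can be
   plugged in behind the same interface);
2. **fit** — the template is soft-rasterised as a product of logistic
   half-plane factors and its free parameters are optimised by Adam with a
   decay-on-plateau learning rate, minimising the mean squared pixel
   difference to the mask plus small regularizers (sum of distances,
   within-pair symmetry, temporal smoothness along the sequence);
   gradients are analytic.  Sequences are tracked forward and backward
   from the user-selected frame, each frame seeding the next.

Paired distances Dᵢ = (d⁺ᵢ + d⁻ᵢ) · pixel size are then regressed against
time over the early linear stage (R² ≥ 0.99 prefix) and each facet growth
rate is G = slope/2 (a face's rate is its normal displacement from the
crystal centre).  Finally, (σ, G) data are fitted to serial
mass-transfer + surface-integration kinetics

    G(σ) = σ / (R_MT(σ) + R_SI(σ)),      R_MT = ρ_s / (k_mt · MW_s · C_e(σ)),

with the surface-integration term R_SI = σ/G_SI given by one of three
mechanisms:

| model | G_SI(σ) |
|---|---|
| power law | k_G σ^r (r = 1: rough interface) |
| Birth & Spread | A₁ σ^{5/6} exp(−A₂/σ) |
| BCF (screw dislocation) | A₁ σ² tanh(A₂/σ) |

Models are fitted by multi-start Levenberg–Marquardt, ranked by R² with a
parameter-plausibility gate, the MT/GSI resistances are decomposed per σ,
and the dead zone σ_c is estimated as the smallest σ where the fitted
curve reaches a detectability threshold (default 1% of the largest
observed rate).

Because raw experimental image sets of this kind are rarely deposited, the
package ships a first-class synthetic generator (`crystalsizer.synth`)
that renders growing hexagonal crystals with known ground truth and
produces kinetics datasets from known generating mechanisms; all accuracy
claims are validated against it.

## Worked example

```python
import numpy as np
from crystalsizer import (FitConfig, fit_sequence, generate_growth_sequence,
                          generate_kinetics_dataset, select_model,
                          resistance_decomposition, SoluteProperties)
from crystalsizer.synth import default_sequence_params, KINETICS_FACE_DEFAULTS
from crystalsizer.growth import distance_series, sequence_growth_rates

# --- size a synthetic 20-frame growth sequence ---------------------------
p = default_sequence_params(seed=42)
images, truths, times = generate_growth_sequence(p)
res = fit_sequence(images, times, select=(0, (126.0, 130.0)), cfg=FitConfig())
series = distance_series(res.fits, times, p.pixel_size_um)
for est in sequence_growth_rates(series):
    print(f"{est.face_pair}: G = {est.rate:.3e} m/s "
          f"(R^2 = {est.r2:.4f}, frames {est.window[0]}-{est.window[1]})")

# --- fit growth mechanisms to a (sigma, G) dataset -----------------------
props = SoluteProperties()          # L-glutamic acid defaults
spec = KINETICS_FACE_DEFAULTS["capping"]
sigma, G = generate_kinetics_dataset(spec["model"], spec["params"],
                                     spec["k_mt"], props,
                                     noise_sd=0.01, seed=0)
for f in select_model(sigma, G, props):
    print(f"{f.model:13s} R^2 = {f.r2:.4f}  plausible = {f.plausible}  "
          f"sigma_c = {f.sigma_c:.3f}")
pair = resistance_decomposition(select_model(sigma, G, props)[0],
                                props, [0.75])[0]
print(f"at sigma = {pair.sigma}: R_MT = {pair.R_mt:.3g}, "
      f"R_SI = {pair.R_si:.3g} -> {pair.limiting}-limited")
```

prints

```
(021)/(0-2-1): G = 9.144e-10 m/s (R^2 = 0.9992, frames 0-19)
(101)/(-10-1): G = 8.965e-09 m/s (R^2 = 1.0000, frames 0-19)
(10-1)/(-101): G = 8.933e-09 m/s (R^2 = 1.0000, frames 0-19)
birth_spread  R^2 = 1.0000  plausible = True  sigma_c = 0.229
bcf           R^2 = 0.9807  plausible = True  sigma_c = 0.082
power_law     R^2 = 0.9994  plausible = False  sigma_c = 0.188
at sigma = 0.75: R_MT = 9.76e+06, R_SI = 5.27e+06 -> MT-limited
```

The measured facet rates match the generator's prescribed rates (the
prismatic pair grows at 0.22 px/frame paired, i.e. 9.2e-10 m/s per face at
0.5 µm/px and 60 s frames); the capping-face dataset is correctly
identified as Birth & Spread with a dead zone at σ_c ≈ 0.23 and
mass-transfer-limited growth, while the power-law fit is rejected for an
implausible exponent despite its high R².

A command-line interface mirrors the library
(`crystalsizer synth | measure | growth | kinetics | vertices`); see
`crystalsizer --help`.

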